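"""Seeded generator of stoichiometric multitrophic webs, and river-import fluxes.

The generator emulates the structure of a subtropical nearshore shelf web:
a couple of phytoplankton producers, a microbial loop, zooplankton, zoobenthos
and fish/nekton guilds, plus particulate/dissolved detritus pools; a dissolved
inorganic pool is appended downstream by
:func:`stoichnet.multinutrient.add_inorganic_pool`.  Trophic ordering is
enforced by guild (producers < microbial < zooplankton < zoobenthos < fish)
with limited omnivory and optional detritivory, so trophic-level and
Lindeman-spine code is exercised on realistic topologies.

Webs are built feasible by construction: biomasses are raised, predators
first, until every group's predation mortality stays below a capped fraction
of its production, so :func:`stoichnet.ecopath.solve_mass_balance` always
succeeds with all ecotrophic efficiencies below one.

A *planted limitation* forces a known nutrient deficiency causally, not by
labelling: the target node's biomass is made rich in the planted element while
its prey are made poor in it (other elements are left stoichiometrically
neutral between diet and body), so the supply turnover of the planted element
is depressed by a wide margin and the limitation classifier must recover it
from the flows.

:func:`river_imports` turns river flow rates, sediment/organic/nutrient
concentrations and a plume area into per-element POM/DOM/DIM boundary import
fluxes (g m^-2 y^-1); it is a pure, scale-linear function.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .core import Element, MultiNetwork, NodeKind, NodeSpec, molar_to_mass_ratio
from .ecopath import EcopathInputs, solve_mass_balance
from .multinutrient import InorganicPoolSpec, add_inorganic_pool, derive_multinetwork

__all__ = [
    "SyntheticWebConfig",
    "RiverScenario",
    "WebTruths",
    "generate_web",
    "synthesize_multinetwork",
    "river_imports",
    "SECONDS_PER_YEAR",
]

SECONDS_PER_YEAR = 3.1536e7

#: molar ratios of the dissolved inorganic pool (DIC:DIN and DIC:DIP);
#: also the neutral anchor used when planting limitations.
POOL_CN = 8.2
POOL_CP = 131.2

CONSUMER_GUILDS = ("microbial", "zooplankton", "zoobenthos", "fish")

#: P/B bounds (y^-1) per guild: turnover falls with trophic position.
DEFAULT_PB_GRADIENT = {
    "producer": (80.0, 400.0),
    "microbial": (30.0, 150.0),
    "zooplankton": (8.0, 40.0),
    "zoobenthos": (2.0, 12.0),
    "fish": (0.3, 3.0),
}


@dataclass(frozen=True)
class SyntheticWebConfig:
    """Seeded recipe for a balanced stoichiometric web.

    Stoichiometric ranges bracket Redfield composition (molar C:N 5-12,
    C:P 40-250), wider for detritus.  ``planted_limitation`` maps a node id to
    the element forced limiting there.
    """

    seed: int = 0
    n_producers: int = 2
    n_consumers: int = 20
    n_detritus: int = 3
    connectance: float = 0.35
    biomass_range: tuple[float, float] = (0.05, 10.0)     # gC m^-2, log-uniform
    pb_gradient: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PB_GRADIENT)
    )
    cn_range: tuple[float, float] = (5.0, 12.0)           # molar
    cp_range: tuple[float, float] = (40.0, 250.0)         # molar
    detritus_cn_range: tuple[float, float] = (8.0, 20.0)
    detritus_cp_range: tuple[float, float] = (80.0, 500.0)
    ge_range: tuple[float, float] = (0.15, 0.30)          # gross efficiency P/Q
    unassimilated: float = 0.2
    ee_cap: float = 0.9
    detritivory: bool = True
    din_stock_range: tuple[float, float] = (0.1, 2.0)     # gN m^-2, sets the DIC pool
    planted_limitation: dict[int, Element] | None = None
    river_scenario: "RiverScenario | None" = None

    def __post_init__(self):
        if self.n_producers < 1 or self.n_detritus < 1:
            raise ValueError("need at least one producer and one detritus pool")
        if not 0 < self.connectance <= 1:
            raise ValueError("connectance must lie in (0, 1]")
        for rng in (self.biomass_range, self.cn_range, self.cp_range,
                    self.detritus_cn_range, self.detritus_cp_range, self.ge_range):
            if rng[0] <= 0 or rng[1] < rng[0]:
                raise ValueError(f"invalid positive range {rng}")


@dataclass(frozen=True)
class WebTruths:
    """Ground truths the generator plants, for recovery tests."""

    planted_limitation: dict[int, Element]
    acyclic: bool
    guilds: dict[int, str]            # node id -> guild
    dic_pool: InorganicPoolSpec


def _loguniform(rng: np.random.Generator, lo: float, hi: float, size=None):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size))


def _split_guilds(n_consumers: int) -> list[str]:
    """Distribute consumers across the four guilds, lowest tiers first."""
    base, extra = divmod(n_consumers, len(CONSUMER_GUILDS))
    out: list[str] = []
    for k, g in enumerate(CONSUMER_GUILDS):
        count = base + (1 if k < extra else 0)
        out.extend([g] * count)
    return out[:n_consumers]


def generate_web(config: SyntheticWebConfig) -> tuple[EcopathInputs, WebTruths]:
    """Generate solvable Ecopath-style inputs plus planted ground truths.

    Deterministic: the same config (seed included) yields bit-identical
    output.  Raises before emission if the configuration is infeasible
    (e.g. a consumer guild with no possible prey).
    """
    rng = np.random.default_rng(config.seed)
    n_p, n_c, n_d = config.n_producers, config.n_consumers, config.n_detritus
    n = n_p + n_c + n_d

    guilds = (["producer"] * n_p + _split_guilds(n_c) + ["detritus"] * n_d)
    tier = {"producer": 0, "microbial": 1, "zooplankton": 2, "zoobenthos": 3,
            "fish": 4, "detritus": -1}
    tiers = np.array([tier[g] for g in guilds])
    living = tiers >= 0
    det_idx = np.nonzero(~living)[0]

    # -- stoichiometric ratios (molar), planted nodes adjusted below ----------
    cn = np.empty(n)
    cp = np.empty(n)
    for i in range(n):
        if living[i]:
            cn[i] = _loguniform(rng, *config.cn_range)
            cp[i] = _loguniform(rng, *config.cp_range)
        else:
            cn[i] = _loguniform(rng, *config.detritus_cn_range)
            cp[i] = _loguniform(rng, *config.detritus_cp_range)

    # -- diet topology ---------------------------------------------------------
    def permitted_prey(j: int) -> list[int]:
        t = tiers[j]
        prey = [i for i in range(n) if living[i] and
                (tiers[i] < t or (t == 4 and tiers[i] == 4 and i < j))]
        if config.detritivory and guilds[j] in ("microbial", "zoobenthos",
                                                "zooplankton"):
            prey.extend(det_idx.tolist())
        return prey

    DC = np.zeros((n + 1, n))
    for j in range(n):
        if tiers[j] < 1:
            continue
        prey = permitted_prey(j)
        if not prey:
            raise ValueError(
                f"consumer {j + 1} ({guilds[j]}) has no possible prey; "
                "infeasible configuration"
            )
        chosen = [i for i in prey if rng.random() < config.connectance]
        if not chosen:
            chosen = [prey[int(rng.integers(len(prey)))]]
        props = rng.dirichlet(np.ones(len(chosen)))
        DC[chosen, j] = props

    # -- rates and biomasses ---------------------------------------------------
    B = _loguniform(rng, *config.biomass_range, size=n)
    B[det_idx] *= 5.0  # detritus stocks exceed living stocks
    PB = np.full(n, np.nan)
    QB = np.full(n, np.nan)
    U = np.zeros(n)
    for i in range(n):
        g = guilds[i]
        if g == "detritus":
            continue
        PB[i] = _loguniform(rng, *config.pb_gradient[g])
        if tiers[i] >= 1:
            QB[i] = PB[i] / _loguniform(rng, *config.ge_range)
            U[i] = config.unassimilated

    # -- feasibility: raise prey biomass until predation < capped production ---
    ee_target = rng.uniform(0.4, config.ee_cap - 0.05, size=n)
    for i in sorted(range(n), key=lambda k: (-tiers[k], -k)):
        if not living[i]:
            continue
        predation = float(np.nansum(B * QB * DC[i, :n]))
        cap = ee_target[i] * B[i] * PB[i]
        if predation > cap:
            B[i] = predation / (ee_target[i] * PB[i])

    # -- detritus fate and flow graph -----------------------------------------
    fate = rng.dirichlet(np.ones(n_d), size=n)
    fate[det_idx] = 0.0
    fate[det_idx, 0] = 1.0  # unused; detritus pools close at the boundary

    graph = nx.DiGraph()
    graph.add_nodes_from(range(n))
    prey_i, pred_j = np.nonzero(DC[:n] > 0)
    graph.add_edges_from(zip(prey_i.tolist(), pred_j.tolist()))
    for i in range(n):
        if living[i]:
            for kd, d in enumerate(det_idx):
                if fate[i, kd] > 0:
                    graph.add_edge(i, int(d))

    # -- planted limitations ---------------------------------------------------
    # A deficiency is planted causally: the target's upstream closure is set
    # stoichiometrically neutral (anchored on the inorganic pool's ratios, so
    # layered balancing leaves upstream flow stoichiometry untouched), then the
    # direct diet is skewed poor - and the target's body rich - in the planted
    # element only.  The resulting supply-turnover margin is at least ~3x,
    # far beyond the co-limitation band.
    planted = dict(config.planted_limitation or {})
    skew = 3.0
    if planted:
        for node_id, el in planted.items():
            p = node_id - 1
            if not (0 <= p < n) or not living[p] or tiers[p] < 1:
                raise ValueError(
                    f"planted limitation target {node_id} must be a consumer node"
                )
        neutral = set()
        for node_id in planted:
            neutral |= nx.ancestors(graph, node_id - 1) | {node_id - 1}
        for i in neutral:
            cn[i], cp[i] = POOL_CN, POOL_CP
        for node_id, el in planted.items():
            p = node_id - 1
            prey = np.nonzero(DC[:n, p] > 0)[0]
            if el is Element.NITROGEN:
                cn[p] = POOL_CN / skew
                cn[prey] = POOL_CN * skew
            elif el is Element.PHOSPHORUS:
                cp[p] = POOL_CP / skew
                cp[prey] = POOL_CP * skew
            else:  # carbon limiting: diet rich in N and P relative to the body
                cn[p], cp[p] = POOL_CN * skew, POOL_CP * skew
                cn[prey], cp[prey] = POOL_CN / skew, POOL_CP / skew

    # -- assemble --------------------------------------------------------------
    det_names = ["susPOM", "sedPOM", "DOM"] + [
        f"detritus_{k}" for k in range(4, n_d + 1)
    ]
    nodes = []
    counters: dict[str, int] = {}
    for i in range(n):
        g = guilds[i]
        counters[g] = counters.get(g, 0) + 1
        if g == "detritus":
            name = det_names[counters[g] - 1]
            kind = NodeKind.DETRITUS
        else:
            name = f"{g}_{counters[g]}"
            kind = NodeKind.PRODUCER if g == "producer" else NodeKind.CONSUMER
        nodes.append(NodeSpec(id=i + 1, name=name, kind=kind,
                              living=bool(living[i]),
                              cn_ratio=float(cn[i]), cp_ratio=float(cp[i])))

    # riverine imports feed the particulate and dissolved detritus pools,
    # whose stoichiometry then mirrors the river material
    imports = np.zeros(n)
    if config.river_scenario is not None:
        table = river_imports(config.river_scenario)
        pom = int(det_idx[0])
        imports[pom] = table.loc["POM", "C"]
        cn[pom] = config.river_scenario.pom_cn
        cp[pom] = config.river_scenario.pom_cp
        if n_d >= 3:
            dom = int(det_idx[2])
            imports[dom] = table.loc["DOM", "C"]
            cn[dom] = config.river_scenario.dom_cn
            cp[dom] = config.river_scenario.dom_cp
        nodes = [replace(nd, cn_ratio=float(cn[i]), cp_ratio=float(cp[i]))
                 for i, nd in enumerate(nodes)]

    inputs = EcopathInputs(
        nodes=nodes,
        B=B, PB=PB, QB=QB, EE=np.full(n, np.nan),
        U=U, imports=imports, DC=DC, detritus_fate=fate,
        meta={"seed": config.seed},
    )

    # cycles can only arise through detritus (fate out, consumption back in)
    acyclic = nx.is_directed_acyclic_graph(graph)

    din = float(_loguniform(rng, *config.din_stock_range))
    pool = InorganicPoolSpec.from_din(din)

    truths = WebTruths(planted_limitation=planted, acyclic=acyclic,
                       guilds={i + 1: guilds[i] for i in range(n)},
                       dic_pool=pool)
    return inputs, truths


def synthesize_multinetwork(
    config: SyntheticWebConfig,
    balancer_config=None,
) -> tuple[MultiNetwork, WebTruths]:
    """Full pipeline: generate -> mass-balance C -> DIC pool -> derive N/P -> balance.

    Returns the balanced three-element MultiNetwork together with the
    generator's ground truths.
    """
    from .balancer import BalancerConfig, balance_multinetwork

    inputs, truths = generate_web(config)
    solved = solve_mass_balance(inputs)
    carbon = add_inorganic_pool(solved.network, truths.dic_pool)
    multi = derive_multinetwork(carbon)
    balanced, _ = balance_multinetwork(multi, balancer_config or BalancerConfig())
    return balanced, truths


# ---------------------------------------------------------------------------
# riverine imports


@dataclass(frozen=True)
class RiverScenario:
    """River forcing: flow, sediment, organics and nutrients feeding a plume.

    Give the flow as either ``flow_rate_m3_s`` or ``annual_flow_l`` and the
    sediment as exactly one of ``sediment_conc_g_l`` / ``sediment_yield_t_y``.
    All ratios are molar.
    """

    plume_area_m2: float
    flow_rate_m3_s: float | None = None
    annual_flow_l: float | None = None
    sediment_conc_g_l: float | None = None
    sediment_yield_t_y: float | None = None
    poc_fraction_of_tss: float = 0.084
    doc_conc_mg_l: float = 6.0
    din_conc_mg_l: float = 0.0
    dip_conc_mg_l: float = 0.0
    dic_din_ratio: float = 8.2
    pom_cn: float = 9.6          # molar C:N of the particulate pool
    pom_cp: float = 51.6
    dom_cn: float = 23.3
    dom_cp: float = 2594.0

    def __post_init__(self):
        if not self.plume_area_m2 > 0:
            raise ValueError("a positive plume area is required")
        if (self.flow_rate_m3_s is None) == (self.annual_flow_l is None):
            raise ValueError("give exactly one of flow_rate_m3_s / annual_flow_l")
        if (self.sediment_conc_g_l is None) == (self.sediment_yield_t_y is None):
            raise ValueError(
                "give exactly one of sediment_conc_g_l / sediment_yield_t_y"
            )

    @property
    def annual_flow_litres(self) -> float:
        if self.annual_flow_l is not None:
            return self.annual_flow_l
        return self.flow_rate_m3_s * SECONDS_PER_YEAR * 1000.0

    @property
    def sediment_concentration_g_l(self) -> float:
        """Sediment concentration, from the yield and annual flow if needed."""
        if self.sediment_conc_g_l is not None:
            return self.sediment_conc_g_l
        return self.sediment_yield_t_y * 1e6 / self.annual_flow_litres


def river_imports(scenario: RiverScenario) -> pd.DataFrame:
    """Per-element boundary import fluxes for the POM, DOM and DIM pools.

    Fluxes are g element m^-2 y^-1 over the plume area:

    * POM-C = POC fraction x sediment load / area; N and P follow the
      particulate pool's stoichiometry.
    * DOM-C = DOC concentration x annual flow / area; N, P via DOM ratios.
    * DIM-N and DIM-P from the dissolved nutrient concentrations; DIM-C from
      the DIN load at the molar DIC:DIN ratio.

    The function is pure and linear in the flow rate and concentrations.
    """
    V = scenario.annual_flow_litres
    area = scenario.plume_area_m2

    sed_load = scenario.sediment_concentration_g_l * V           # g/y
    poc = scenario.poc_fraction_of_tss * sed_load
    pom_c = poc / area
    pom_n = pom_c / molar_to_mass_ratio(scenario.pom_cn, Element.NITROGEN)
    pom_p = pom_c / molar_to_mass_ratio(scenario.pom_cp, Element.PHOSPHORUS)

    doc = scenario.doc_conc_mg_l * 1e-3 * V
    dom_c = doc / area
    dom_n = dom_c / molar_to_mass_ratio(scenario.dom_cn, Element.NITROGEN)
    dom_p = dom_c / molar_to_mass_ratio(scenario.dom_cp, Element.PHOSPHORUS)

    din_load = scenario.din_conc_mg_l * 1e-3 * V
    dip_load = scenario.dip_conc_mg_l * 1e-3 * V
    dim_n = din_load / area
    dim_p = dip_load / area
    dim_c = dim_n * molar_to_mass_ratio(scenario.dic_din_ratio, Element.NITROGEN)

    return pd.DataFrame(
        {"C": [pom_c, dom_c, dim_c],
         "N": [pom_n, dom_n, dim_n],
         "P": [pom_p, dom_p, dim_p]},
        index=pd.Index(["POM", "DOM", "DIM"], name="pool"),
    )
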