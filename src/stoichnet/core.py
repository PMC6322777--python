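"""Domain types and elementary flow accounting for stoichiometric ecosystem networks.

An ecosystem is represented as one :class:`ElementNetwork` per chemical element
(carbon, nitrogen, phosphorus) over a shared, ordered node set.  Flows are
annualised steady-state mass fluxes in g element m⁻² y⁻¹; biomasses are stocks
in g element m⁻².  The internodal flow matrix ``T`` is oriented donor-row →
recipient-column: ``T[i, j]`` is the flow from node ``i`` to node ``j``.

All stoichiometric ratios supplied by users are molar C:N / C:P; they are
converted to mass ratios (via the atomic masses held on :class:`Element`) at the
module boundary so every internal computation runs on a single mass basis.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Element",
    "NodeKind",
    "NodeSpec",
    "ElementNetwork",
    "MultiNetwork",
    "ValidationReport",
    "molar_to_mass_ratio",
    "validate",
    "throughflow",
    "total_system_throughflow",
    "BalanceError",
]

#: default maximum relative per-node imbalance accepted as "balanced";
#: layered balancing converges approximately, not exactly.
DEFAULT_TOLERANCE = 1e-3


class BalanceError(ValueError):
    """Raised when an operation requires a mass-balanced network and gets none."""


class Element(enum.Enum):
    """The three macronutrients tracked by the networks."""

    CARBON = ("C", 12.011)
    NITROGEN = ("N", 14.007)
    PHOSPHORUS = ("P", 30.974)

    def __init__(self, symbol: str, atomic_mass: float):
        self.symbol = symbol
        self.atomic_mass = atomic_mass  # g mol^-1

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Element.{self.name}"


class NodeKind(enum.Enum):
    PRODUCER = "producer"
    CONSUMER = "consumer"
    DETRITUS = "detritus"
    NUTRIENT_POOL = "nutrient_pool"


def molar_to_mass_ratio(molar_ratio: float, element: Element) -> float:
    """Convert a molar C:X ratio to a mass C:X ratio.

    mass C:X = molar C:X × (12.011 / atomic mass of X).
    """
    return molar_ratio * Element.CARBON.atomic_mass / element.atomic_mass


@dataclass(frozen=True)
class NodeSpec:
    """One compartment of the web.

    ``cn_ratio`` and ``cp_ratio`` are *molar*; use :meth:`mass_ratio` to obtain
    the mass-basis ratio used on flows and biomasses.  Nutrient pools are
    non-living by definition and are excluded from limitation analysis (they
    have no nutrient demand of their own).
    """

    id: int
    name: str
    kind: NodeKind
    living: bool = True
    cn_ratio: float | None = None  # molar C:N
    cp_ratio: float | None = None  # molar C:P

    def __post_init__(self):
        if self.id < 1:
            raise ValueError(f"node ids are 1-based; got {self.id} for {self.name!r}")
        if self.cn_ratio is not None and self.cn_ratio <= 0:
            raise ValueError(f"cn_ratio must be > 0 for node {self.name!r}")
        if self.cp_ratio is not None and self.cp_ratio <= 0:
            raise ValueError(f"cp_ratio must be > 0 for node {self.name!r}")
        if self.kind is NodeKind.NUTRIENT_POOL and self.living:
            raise ValueError(f"nutrient pool {self.name!r} cannot be living")

    def mass_ratio(self, element: Element) -> float:
        """Mass-basis C:element ratio of this node's biomass (C gives 1)."""
        if element is Element.CARBON:
            return 1.0
        molar = self.cn_ratio if element is Element.NITROGEN else self.cp_ratio
        if molar is None:
            raise ValueError(
                f"node {self.name!r} has no C:{element.symbol} ratio"
            )
        return molar_to_mass_ratio(molar, element)


@dataclass
class ElementNetwork:
    """A single-element flow network.

    Attributes
    ----------
    element : Element
    nodes : list[NodeSpec]
        Ordered; index ``i`` in the arrays corresponds to ``nodes[i]``
        (node ids are 1-based labels, array indices 0-based).
    B : ndarray, (n,)
        Biomass stocks, g element m^-2.
    T : ndarray, (n, n)
        Internodal flows, donor row -> recipient column, g element m^-2 y^-1.
        A non-zero diagonal (cannibalism) is permitted.
    z, e, r : ndarray, (n,)
        Boundary imports, exports and respirations per node.  Respiration is a
        carbon-specific loss; non-carbon networks carry r = 0 by convention and
        represent analogous losses as exports.
    """

    element: Element
    nodes: list[NodeSpec]
    B: np.ndarray
    T: np.ndarray
    z: np.ndarray
    e: np.ndarray
    r: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.nodes)
        self.B = np.asarray(self.B, dtype=float).reshape(n)
        self.T = np.asarray(self.T, dtype=float).reshape(n, n)
        for name in ("z", "e", "r"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float).reshape(n))

    # -- elementary accounting -------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.nodes)

    def inflows(self) -> np.ndarray:
        """Total inflow per node: internodal column sums plus boundary imports."""
        return self.T.sum(axis=0) + self.z

    def outflows(self) -> np.ndarray:
        """Total outflow per node: internodal row sums plus exports and respiration."""
        return self.T.sum(axis=1) + self.e + self.r

    def node_imbalance(self) -> np.ndarray:
        """Relative per-node imbalance (inflow - outflow) / max(inflow, outflow)."""
        fin, fout = self.inflows(), self.outflows()
        scale = np.maximum(fin, fout)
        with np.errstate(invalid="ignore", divide="ignore"):
            imb = np.where(scale > 0, (fin - fout) / np.where(scale > 0, scale, 1.0), 0.0)
        return imb

    def copy(self) -> "ElementNetwork":
        return replace(
            self,
            nodes=list(self.nodes),
            B=self.B.copy(),
            T=self.T.copy(),
            z=self.z.copy(),
            e=self.e.copy(),
            r=self.r.copy(),
            meta=dict(self.meta),
        )

    def index_of(self, node_id: int) -> int:
        for i, nd in enumerate(self.nodes):
            if nd.id == node_id:
                return i
        raise KeyError(f"no node with id {node_id}")


def throughflow(network: ElementNetwork) -> np.ndarray:
    """Per-node total throughflow T_i: max of inflow and outflow sums.

    The two coincide on a balanced network; taking the max gives a
    well-defined non-negative vector on slightly unbalanced ones.
    """
    return np.maximum(network.inflows(), network.outflows())


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of :func:`validate`: structural violations and per-node imbalance."""

    imbalance: np.ndarray          # relative (in - out) / max(in, out) per node
    worst_node: int | None         # 1-based id of the worst-imbalanced node
    max_abs_imbalance: float
    violations: tuple[str, ...]    # negative entries, orphan nodes, ...
    balanced: bool
    tolerance: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        state = "balanced" if self.balanced else "UNBALANCED"
        lines = [
            f"{state}: max |relative imbalance| = {self.max_abs_imbalance:.3g} "
            f"(tolerance {self.tolerance:g}, worst node {self.worst_node})"
        ]
        lines += list(self.violations)
        return "\n".join(lines)


def validate(network: ElementNetwork, tolerance: float = DEFAULT_TOLERANCE) -> ValidationReport:
    """Check structural invariants and per-node mass balance.

    Purely reporting: never raises, never mutates.  A node is an orphan when it
    carries no flow at all (no internodal, boundary or biomass activity).
    """
    violations: list[str] = []
    for name, arr in (("B", network.B), ("T", network.T), ("z", network.z),
                      ("e", network.e), ("r", network.r)):
        if np.any(arr < 0):
            where = np.argwhere(arr < 0)
            violations.append(
                f"negative entries in {name} at indices {where[:5].tolist()}"
            )
    fin, fout = network.inflows(), network.outflows()
    for i, nd in enumerate(network.nodes):
        if fin[i] == 0 and fout[i] == 0 and network.B[i] == 0:
            violations.append(f"orphan node {nd.id} ({nd.name!r}): no flows, no biomass")
    imb = network.node_imbalance()
    if network.n:
        worst = int(np.argmax(np.abs(imb)))
        worst_id: int | None = network.nodes[worst].id
        max_imb = float(np.abs(imb[worst]))
    else:
        worst_id, max_imb = None, 0.0
    balanced = max_imb <= tolerance and not violations
    return ValidationReport(
        imbalance=imb,
        worst_node=worst_id,
        max_abs_imbalance=max_imb,
        violations=tuple(violations),
        balanced=balanced,
        tolerance=tolerance,
    )


def total_system_throughflow(
    network: ElementNetwork,
    tolerance: float = DEFAULT_TOLERANCE,
    check: bool = True,
) -> float:
    """Total system throughflow TSTf: all nodal inflows including boundary flows.

    Computed both as sum-of-inflows (internodal total + imports) and as
    sum-of-outflows (internodal total + exports + respirations); conservation
    makes the two identical on a balanced network, and both are compared when
    ``check`` is set.

    Raises
    ------
    BalanceError
        If the network's worst node imbalance exceeds ``tolerance``.
    """
    if network.n == 0:
        return 0.0
    internodal = float(network.T.sum())
    tst_in = internodal + float(network.z.sum())
    tst_out = internodal + float(network.e.sum()) + float(network.r.sum())
    if check:
        report = validate(network, tolerance)
        if report.max_abs_imbalance > tolerance:
            raise BalanceError(
                f"network not balanced within {tolerance:g}: worst node "
                f"{report.worst_node} at relative imbalance "
                f"{report.max_abs_imbalance:.3g}"
            )
        denom = max(tst_in, tst_out)
        if denom > 0 and abs(tst_in - tst_out) / denom > tolerance:
            raise BalanceError(
                f"TSTf forms disagree: inflow form {tst_in:g} vs outflow form {tst_out:g}"
            )
    return tst_in


@dataclass
class MultiNetwork:
    """Aligned per-element networks over one node set; the central object.

    Node order must be identical across elements.  Derived (non-carbon)
    networks follow donor stoichiometry at derivation time:
    ``T_ij(X) = T_ij(C) / mass-basis C:X ratio of donor i`` within the
    balancing tolerance once balanced.
    """

    networks: dict[Element, ElementNetwork]
    balanced: dict[Element, bool] = field(default_factory=dict)

    def __post_init__(self):
        items = list(self.networks.values())
        if not items:
            raise ValueError("MultiNetwork needs at least one element network")
        ref = [nd.id for nd in items[0].nodes]
        for net in items[1:]:
            if [nd.id for nd in net.nodes] != ref:
                raise ValueError("element networks must share an identical node ordering")
        for el, net in self.networks.items():
            if net.element is not el:
                raise ValueError(f"network stored under {el} is labelled {net.element}")
        for el in self.networks:
            self.balanced.setdefault(el, False)

    @property
    def nodes(self) -> list[NodeSpec]:
        return next(iter(self.networks.values())).nodes

    @property
    def elements(self) -> list[Element]:
        return list(self.networks.keys())

    def __getitem__(self, element: Element) -> ElementNetwork:
        return self.networks[element]

    def __contains__(self, element: Element) -> bool:
        return element in self.networks

    def total_flow(self) -> float:
        """Total internodal flow of all elements through all compartments."""
        return float(sum(net.T.sum() for net in self.networks.values()))

    def total_biomass(self) -> float:
        """All-element biomass total B.. ."""
        return float(sum(net.B.sum() for net in self.networks.values()))
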