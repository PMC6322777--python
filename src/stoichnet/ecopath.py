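"""Ecopath-style mass balance: parameterise a carbon network from basic inputs.

For every living group the master equation must hold::

    B_i * PB_i * EE_i = sum_j B_j * QB_j * DC[i, j] + Y_i + BA_i

i.e. production utilised in the system equals predation on the group plus
removals.  At most one of {B, PB, QB, EE} may be missing per group; missing
values are estimated.  QB can only be estimated when a gross food-conversion
efficiency GE = P/Q is supplied (QB = PB / GE).

The completed parameter set is turned into a carbon :class:`ElementNetwork`:

* consumption flows ``T[i, j] = B_j * QB_j * DC[i, j]`` (prey i -> predator j),
* diet-import fractions become boundary imports,
* respiration ``r_j = Q_j - P_j - U_j * Q_j`` (must be non-negative),
* egesta ``U_j * Q_j`` and non-utilised production ``(1 - EE_j) * P_j`` flow to
  detritus pools apportioned by the detritus-fate fractions,
* primary production enters producers as a boundary import (replaced by
  demand-driven inorganic-pool uptake downstream, see
  :func:`stoichnet.multinutrient.add_inorganic_pool`),
* detritus pools are closed by a boundary export (surplus) or import (deficit).

Every living node therefore validates exactly balanced after a successful
solve, and re-running the solve on completed inputs is a fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import Element, ElementNetwork, NodeKind, NodeSpec

__all__ = ["EcopathInputs", "MassBalanceResult", "EcopathError", "solve_mass_balance"]

#: EwE convention for the unassimilated fraction of consumption.
DEFAULT_UNASSIMILATED = 0.2


class EcopathError(ValueError):
    pass


@dataclass
class EcopathInputs:
    """Basic-input tables for an Ecopath-style carbon model.

    Arrays are aligned with ``nodes`` (living groups and detritus pools; no
    nutrient pools at this stage).  ``np.nan`` marks an unknown parameter.

    DC is the diet-composition matrix with one row per node plus a final
    *import* row; column j holds predator j's diet proportions and must sum to
    one for consumers (including the import fraction).  ``detritus_fate`` has
    one column per detritus node; each living group's row must sum to one.
    """

    nodes: list[NodeSpec]
    B: np.ndarray        # gC m^-2, nan = estimate
    PB: np.ndarray       # y^-1, nan = estimate (detritus: nan, unused)
    QB: np.ndarray       # y^-1, nan for producers/detritus or to estimate
    EE: np.ndarray       # proportion, nan = estimate
    U: np.ndarray | None = None    # unassimilated fraction of consumption
    Y: np.ndarray | None = None    # fishery/export removals, gC m^-2 y^-1
    BA: np.ndarray | None = None   # biomass accumulation, gC m^-2 y^-1
    imports: np.ndarray | None = None  # boundary imports (riverine POM/DOM into
    #                                    detritus pools), gC m^-2 y^-1
    GE: np.ndarray | None = None   # gross efficiency P/Q, only needed to estimate QB
    DC: np.ndarray = None          # (n+1, n); last row = imports
    detritus_fate: np.ndarray = None  # (n, n_detritus)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.nodes)
        for name in ("B", "PB", "QB", "EE"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float).reshape(n))
        self.U = (np.full(n, np.nan) if self.U is None
                  else np.asarray(self.U, dtype=float).reshape(n))
        consumers = np.array([nd.kind is NodeKind.CONSUMER for nd in self.nodes])
        self.U = np.where(np.isnan(self.U), np.where(consumers, DEFAULT_UNASSIMILATED, 0.0), self.U)
        self.Y = np.zeros(n) if self.Y is None else np.asarray(self.Y, dtype=float).reshape(n)
        self.BA = np.zeros(n) if self.BA is None else np.asarray(self.BA, dtype=float).reshape(n)
        self.GE = (np.full(n, np.nan) if self.GE is None
                   else np.asarray(self.GE, dtype=float).reshape(n))
        self.imports = (np.zeros(n) if self.imports is None
                        else np.asarray(self.imports, dtype=float).reshape(n))
        if self.DC is None:
            self.DC = np.zeros((n + 1, n))
        self.DC = np.asarray(self.DC, dtype=float)
        if self.DC.shape != (n + 1, n):
            raise EcopathError(f"DC must be (n+1, n) = {(n + 1, n)}; got {self.DC.shape}")
        n_det = sum(nd.kind is NodeKind.DETRITUS for nd in self.nodes)
        if self.detritus_fate is None:
            self.detritus_fate = np.zeros((n, n_det))
            if n_det:
                self.detritus_fate[:, 0] = 1.0
        self.detritus_fate = np.asarray(self.detritus_fate, dtype=float).reshape(n, n_det)
        self._check()

    # indices --------------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.nodes)

    def _kind_mask(self, kind: NodeKind) -> np.ndarray:
        return np.array([nd.kind is kind for nd in self.nodes])

    @property
    def living(self) -> np.ndarray:
        return np.array([nd.living for nd in self.nodes])

    @property
    def consumers(self) -> np.ndarray:
        return self._kind_mask(NodeKind.CONSUMER)

    @property
    def producers(self) -> np.ndarray:
        return self._kind_mask(NodeKind.PRODUCER)

    @property
    def detritus(self) -> np.ndarray:
        return self._kind_mask(NodeKind.DETRITUS)

    def _check(self):
        if any(nd.kind is NodeKind.NUTRIENT_POOL for nd in self.nodes):
            raise EcopathError("nutrient pools are added after the Ecopath stage, "
                               "not part of EcopathInputs")
        colsum = self.DC.sum(axis=0)
        for j, nd in enumerate(self.nodes):
            if nd.kind is NodeKind.CONSUMER:
                if not np.isclose(colsum[j], 1.0, atol=1e-6):
                    raise EcopathError(
                        f"diet column of {nd.name!r} sums to {colsum[j]:.6f}, expected 1"
                    )
            elif colsum[j] > 0:
                raise EcopathError(f"non-consumer {nd.name!r} has a diet column")
        given_ee = self.EE[~np.isnan(self.EE)]
        if np.any((given_ee < 0) | (given_ee > 1)):
            raise EcopathError("given EE values must lie in [0, 1]")
        if np.any((self.U < 0) | (self.U >= 1)):
            raise EcopathError("unassimilated fraction U must satisfy 0 <= U < 1")
        for i, nd in enumerate(self.nodes):
            if not nd.living:
                if np.isnan(self.B[i]):
                    raise EcopathError(f"detritus pool {nd.name!r} needs a biomass")
                continue
            missing = [p for p in ("B", "PB", "QB", "EE")
                       if np.isnan(getattr(self, p)[i])
                       and not (p == "QB" and nd.kind is NodeKind.PRODUCER)]
            if len(missing) > 1:
                raise EcopathError(
                    f"group {nd.name!r} has {len(missing)} unknowns {missing}; at most 1 allowed"
                )
            fate = self.detritus_fate[i]
            if fate.size and not np.isclose(fate.sum(), 1.0, atol=1e-6):
                raise EcopathError(
                    f"detritus fate of {nd.name!r} sums to {fate.sum():.6f}, expected 1"
                )

    def copy(self) -> "EcopathInputs":
        return replace(
            self,
            nodes=list(self.nodes),
            B=self.B.copy(), PB=self.PB.copy(), QB=self.QB.copy(), EE=self.EE.copy(),
            U=self.U.copy(), Y=self.Y.copy(), BA=self.BA.copy(), GE=self.GE.copy(),
            imports=self.imports.copy(),
            DC=self.DC.copy(), detritus_fate=self.detritus_fate.copy(),
            meta=dict(self.meta),
        )


@dataclass
class MassBalanceResult:
    """Completed parameters plus the constructed carbon network."""

    inputs: EcopathInputs          # completed copy (no NaNs among living groups)
    network: ElementNetwork        # carbon
    ee_violations: list[int]       # 1-based ids of groups with EE > 1 after solve
    messages: list[str]

    @property
    def balanced(self) -> bool:
        return not self.ee_violations


def solve_mass_balance(inputs: EcopathInputs) -> MassBalanceResult:
    """Estimate missing parameters and build the carbon flow network.

    Groups whose single unknown is locally determinable (EE or PB, given all
    predator biomasses) are solved directly; unknown biomasses - which couple
    groups through predation - are solved as one linear system, since the
    master equation is linear in B once PB, QB and EE are fixed.
    """
    inp = inputs.copy()
    nodes = inp.nodes
    n = inp.n
    messages: list[str] = []

    living_idx = [i for i in range(n) if nodes[i].living]
    det_idx = [i for i in range(n) if nodes[i].kind is NodeKind.DETRITUS]

    # -- resolve QB via gross efficiency where requested ----------------------
    for i in living_idx:
        if nodes[i].kind is NodeKind.CONSUMER and np.isnan(inp.QB[i]):
            if np.isnan(inp.GE[i]):
                raise EcopathError(
                    f"group {nodes[i].name!r}: QB unknown and no gross efficiency "
                    "GE = P/Q supplied to estimate it"
                )
            if np.isnan(inp.PB[i]):
                raise EcopathError(
                    f"group {nodes[i].name!r}: cannot estimate QB without PB"
                )
            inp.QB[i] = inp.PB[i] / inp.GE[i]

    # -- solve coupled unknown biomasses as a linear system -------------------
    unknown_B = [i for i in living_idx if np.isnan(inp.B[i])]
    if unknown_B:
        for i in unknown_B:
            if np.isnan(inp.EE[i]) or np.isnan(inp.PB[i]):
                raise EcopathError(
                    f"group {nodes[i].name!r}: B unknown but EE/PB also unknown; "
                    "pattern unsolvable"
                )
        m = len(unknown_B)
        A = np.zeros((m, m))
        b = np.zeros(m)
        pos = {i: k for k, i in enumerate(unknown_B)}
        qb = np.where(np.isnan(inp.QB), 0.0, inp.QB)
        for k, i in enumerate(unknown_B):
            A[k, k] += inp.PB[i] * inp.EE[i]
            b[k] = inp.Y[i] + inp.BA[i]
            for j in living_idx:
                coeff = qb[j] * inp.DC[i, j]
                if coeff == 0:
                    continue
                if j in pos:
                    A[k, pos[j]] -= coeff
                else:
                    b[k] += coeff * inp.B[j]
        try:
            sol = np.linalg.solve(A, b)
        except np.linalg.LinAlgError as exc:
            raise EcopathError(
                "coupled unknown-biomass system is singular; pattern unsolvable "
                f"(groups {[nodes[i].name for i in unknown_B]})"
            ) from exc
        if np.any(sol <= 0):
            bad = [nodes[unknown_B[k]].name for k in range(m) if sol[k] <= 0]
            raise EcopathError(f"estimated non-positive biomass for groups {bad}")
        for k, i in enumerate(unknown_B):
            inp.B[i] = sol[k]
            messages.append(f"estimated B[{nodes[i].name}] = {sol[k]:.6g}")

    # -- local unknowns: EE then PB -------------------------------------------
    qb = np.where(np.isnan(inp.QB), 0.0, inp.QB)
    Q = inp.B * qb                      # consumption per group
    predation = inp.DC[:n, :] @ Q       # predation mortality per prey row
    for i in living_idx:
        if np.isnan(inp.EE[i]):
            prod = inp.B[i] * inp.PB[i]
            if prod <= 0:
                raise EcopathError(f"group {nodes[i].name!r} has zero production")
            inp.EE[i] = (predation[i] + inp.Y[i] + inp.BA[i]) / prod
            messages.append(f"estimated EE[{nodes[i].name}] = {inp.EE[i]:.6g}")
        elif np.isnan(inp.PB[i]):
            demand = predation[i] + inp.Y[i] + inp.BA[i]
            if inp.B[i] * inp.EE[i] <= 0:
                raise EcopathError(
                    f"group {nodes[i].name!r}: cannot estimate PB with zero B*EE"
                )
            inp.PB[i] = demand / (inp.B[i] * inp.EE[i])
            messages.append(f"estimated PB[{nodes[i].name}] = {inp.PB[i]:.6g}")

    # realized ecotrophic efficiency: utilisation actually exerted by the web.
    # It equals the (given or estimated) EE when the inputs are consistent;
    # flows are constructed from it so every living node closes exactly.
    production = np.where(np.isnan(inp.PB), 0.0, inp.B * inp.PB)
    utilised = predation[:n] + inp.Y + inp.BA
    with np.errstate(divide="ignore", invalid="ignore"):
        realized_ee = np.where(production > 0, utilised / production, 0.0)
    ee_violations = [nodes[i].id for i in living_idx if realized_ee[i] > 1 + 1e-9]
    if ee_violations:
        messages.append(
            "EE > 1 (predation exceeds production) for groups "
            f"{[nodes[i].name for i in living_idx if realized_ee[i] > 1 + 1e-9]}"
        )

    # -- construct the carbon network -----------------------------------------
    T = np.zeros((n, n))
    z = np.zeros(n)
    e = inp.Y + inp.BA  # removals and accumulation leave the annual budget
    r = np.zeros(n)

    P = np.where(np.isnan(inp.PB), 0.0, inp.B * inp.PB)
    for j in living_idx:
        if nodes[j].kind is not NodeKind.CONSUMER:
            continue
        T[:, j] += Q[j] * inp.DC[:n, j]
        z[j] += Q[j] * inp.DC[n, j]          # diet imports cross the boundary
        resp = Q[j] - P[j] - inp.U[j] * Q[j]
        if resp < -1e-9 * max(Q[j], 1.0):
            raise EcopathError(
                f"negative respiration for {nodes[j].name!r}: "
                f"P + U*Q = {P[j] + inp.U[j] * Q[j]:.6g} exceeds Q = {Q[j]:.6g}"
            )
        r[j] = max(resp, 0.0)

    # flows to detritus: egesta + non-utilised production (the residual form
    # equals (1 - EE) * P whenever the given EE is consistent with predation)
    for i in living_idx:
        to_det = inp.U[i] * Q[i] + max(0.0, P[i] - utilised[i])
        if to_det > 0 and det_idx:
            for kd, d in enumerate(det_idx):
                T[i, d] += to_det * inp.detritus_fate[i, kd]
        elif to_det > 0:
            e[i] += to_det  # no detritus pool: unused material is exported

    # primary production enters as a boundary import placeholder
    for i in living_idx:
        if nodes[i].kind is NodeKind.PRODUCER:
            z[i] = P[i]

    # measured boundary imports (riverine POM/DOM into detrital pools)
    z = z + inp.imports

    # close detritus pools at the boundary
    for d in det_idx:
        din = T[:, d].sum() + z[d]
        dout = T[d, :].sum() + e[d] + r[d]
        if din >= dout:
            e[d] += din - dout
        else:
            z[d] += dout - din

    net = ElementNetwork(
        element=Element.CARBON,
        nodes=list(nodes),
        B=inp.B.copy(),
        T=T, z=z, e=e, r=r,
        meta={"source": "ecopath", "units": "g C m-2 y-1"},
    )
    return MassBalanceResult(inputs=inp, network=net,
                             ee_violations=ee_violations, messages=messages)
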