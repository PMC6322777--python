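"""Whole-system indices: throughflow, Finn cycling, trophic structure.

The Finn Cycling Index is the fraction of total system throughflow that passes
through cycles.  With the fractional inflow matrix ``g_ij = T_ij / T_j`` and
the integral (Leontief) matrix ``N = (I - G)^-1``, the cycled share of node
i's throughflow is ``(N_ii - 1)/N_ii``, so::

    FCI = sum_i T_i (N_ii - 1)/N_ii / TSTf

(The index is a *fraction* of throughput, hence the TSTf divisor.)

Effective trophic levels follow the standard convention: producers, detritus
and nutrient pools sit at TL 1; a consumer sits one level above the
consumption-weighted mean of its prey, with diet imports entering at TL 1
(an outside producer-equivalent source).  The Lindeman spine apportions every
node's activity onto integer levels by its fractional trophic composition
(canonical trophic aggregation); the transfer efficiency of level m is the
predatory flow passed from level m to m+1 divided by the total input to
level m.  Detrital returns are routed back to level 1 and are not counted as
"passed on".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_TOLERANCE,
    ElementNetwork,
    NodeKind,
    throughflow,
    total_system_throughflow,
)

__all__ = [
    "CyclingReport",
    "TrophicDecomposition",
    "finn_cycling_index",
    "trophic_levels",
    "transfer_efficiencies",
]


@dataclass(frozen=True)
class CyclingReport:
    tstf: float
    T_i: np.ndarray            # per-node total throughflow
    N_diag: np.ndarray         # integral-matrix diagonal, >= 1
    fci: float                 # fraction of throughflow recycled, in [0, 1)


def finn_cycling_index(
    network: ElementNetwork, tolerance: float = DEFAULT_TOLERANCE
) -> CyclingReport:
    """Finn Cycling Index of a balanced network.

    Raises a ``LinAlgError`` if (I - G) is singular, which indicates a
    pathological flow structure (a node fed entirely by cycles with no
    boundary input anywhere upstream).
    """
    tstf = total_system_throughflow(network, tolerance)
    T_i = throughflow(network)
    n = network.n
    G = np.zeros((n, n))
    pos = T_i > 0
    G[:, pos] = network.T[:, pos] / T_i[pos]
    N = np.linalg.inv(np.eye(n) - G)
    diag = N.diagonal().copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        cycled = np.where(diag > 0, T_i * (diag - 1.0) / diag, 0.0)
    fci = float(cycled.sum() / tstf) if tstf > 0 else 0.0
    return CyclingReport(tstf=tstf, T_i=T_i, N_diag=diag, fci=fci)


def trophic_levels(network: ElementNetwork) -> np.ndarray:
    """Effective trophic level per node, solved as a linear system.

    ``TL_j = 1 + sum_i g_ij TL_i`` for consumers, where ``g_ij`` is the
    fraction of j's total consumption (internodal inflow plus diet imports)
    taken from prey i; imports contribute at TL 1.  Producers, detritus and
    nutrient pools have TL 1 exactly.

    Raises
    ------
    ValueError
        For a consumer with zero consumption (its level is undefined).
    """
    n = network.n
    consumer = np.array([nd.kind is NodeKind.CONSUMER for nd in network.nodes])
    intake = network.T.sum(axis=0) + network.z
    A = np.eye(n)
    b = np.ones(n)
    for j in range(n):
        if not consumer[j]:
            continue
        if intake[j] <= 0:
            raise ValueError(
                f"consumer {network.nodes[j].id} ({network.nodes[j].name!r}) "
                "has zero consumption; trophic level undefined"
            )
        g = network.T[:, j] / intake[j]
        A[j, :] -= g
        # import fraction z_j/intake_j feeds at TL 1:
        b[j] = 1.0 + network.z[j] / intake[j]
    return np.linalg.solve(A, b)


@dataclass(frozen=True)
class TrophicDecomposition:
    TL: np.ndarray                 # effective trophic level per node
    composition: np.ndarray        # (n, m_max) share of node activity per integer level
    level_input: np.ndarray        # total input to each integer level
    level_passed: np.ndarray       # predatory flow passed from level m to m+1
    TE: np.ndarray                 # transfer efficiency per level (NaN where undefined)
    degenerate: bool               # True when some TE exceeds 1

    def te_table(self) -> pd.DataFrame:
        m = np.arange(1, len(self.TE) + 1)
        return pd.DataFrame({"level": m, "input": self.level_input[: len(self.TE)],
                             "passed_on": self.level_passed, "TE": self.TE})


def _level_composition(network: ElementNetwork, max_levels: int = 500) -> np.ndarray:
    """Fraction of each node's activity attributed to integer trophic levels.

    Path-length expansion of the diet matrix: producers/detritus/pools are
    wholly level 1; a consumer's share at level m is the diet-weighted sum of
    its prey's shares at m-1 (imports feed level 2).  Cannibalistic loops decay
    geometrically; expansion stops once the unassigned residual is < 1e-12.
    """
    n = network.n
    consumer = np.array([nd.kind is NodeKind.CONSUMER for nd in network.nodes])
    intake = network.T.sum(axis=0) + network.z
    diet = np.zeros((n, n))
    imp = np.zeros(n)
    for j in range(n):
        if consumer[j]:
            if intake[j] <= 0:
                raise ValueError(
                    f"consumer {network.nodes[j].id} has zero consumption"
                )
            diet[:, j] = network.T[:, j] / intake[j]
            imp[j] = network.z[j] / intake[j]

    cols = [np.where(consumer, 0.0, 1.0)]  # level 1
    for m in range(2, max_levels + 1):
        prev = cols[-1]
        cur = diet.T @ prev
        if m == 2:
            cur = cur + imp
        cur[~consumer] = 0.0
        cols.append(cur)
        assigned = np.sum(cols, axis=0)
        if np.all(1.0 - assigned < 1e-12):
            break
    comp = np.column_stack(cols)
    resid = 1.0 - comp.sum(axis=1)
    if np.any(resid > 1e-9):
        worst = int(np.argmax(resid))
        raise RuntimeError(
            f"trophic apportionment failed to converge for node "
            f"{network.nodes[worst].id} (residual {resid[worst]:.2e})"
        )
    comp /= comp.sum(axis=1, keepdims=True)  # absorb the < 1e-9 truncation residual
    return comp


def transfer_efficiencies(
    network: ElementNetwork, TL: np.ndarray | None = None
) -> TrophicDecomposition:
    """Lindeman-spine transfer efficiencies between discrete trophic levels.

    ``TE_m = (predatory flow from level m to level m+1) / (total input to
    level m)``, where a predation flow prey -> living consumer transfers the
    prey's level-m share to the consumer's level m+1.  Flows to detritus or
    nutrient pools are returns, not transfers.  Efficiencies above one are
    possible only for degenerate webs and are flagged.
    """
    if TL is None:
        TL = trophic_levels(network)
    comp = _level_composition(network)
    # trim trailing all-zero levels
    occupied = np.nonzero(comp.sum(axis=0) > 0)[0]
    m_max = int(occupied[-1]) + 1 if occupied.size else 1
    comp = comp[:, :m_max]

    node_input = network.T.sum(axis=0) + network.z
    level_input = comp.T @ node_input

    living_consumer = np.array(
        [nd.kind is NodeKind.CONSUMER and nd.living for nd in network.nodes]
    )
    # outflow of each node that is passed on via predation
    predated = network.T[:, living_consumer].sum(axis=1)
    level_passed_full = comp.T @ predated          # leaves level m for level m+1

    n_steps = max(m_max - 1, 0)
    TE = np.full(n_steps, np.nan)
    for m in range(n_steps):
        if level_input[m] > 0:
            TE[m] = level_passed_full[m] / level_input[m]
        # an empty level below an occupied one leaves TE undefined (NaN)
    degenerate = bool(np.any(TE[np.isfinite(TE)] > 1.0))
    return TrophicDecomposition(
        TL=TL,
        composition=comp,
        level_input=level_input,
        level_passed=level_passed_full[:n_steps],
        TE=TE,
        degenerate=degenerate,
    )
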