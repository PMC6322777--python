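"""Iterative mass balancing of derived element networks.

Donor-stoichiometry N/P networks are unbalanced wherever a consumer's food
stoichiometry differs from its own.  Flows in such networks span many orders of
magnitude, so adjustments are organised in *layers*: one layer comprises all
flows whose magnitude shares the same power of ten, and layers are treated one
by one, largest first, keeping the others fixed within a sweep, iterating to
convergence.

The repair operator itself (the literature leaves it open) is configurable:

``boundary_policy="export-only"`` (default)
    Element surpluses at a node become boundary exports (the excretion
    analogue of carbon respiration); deficits shrink the node's outflows
    proportionally - a node limited in an element passes less of it on.  This
    keeps boundary imports as measured and preserves the limitation signal the
    downstream sensitivity analysis reads.

``boundary_policy="import-export"``
    Both signs are absorbed at the boundary (deficit -> import, surplus ->
    export).  Internodal flows are never touched, so flow stoichiometry is
    preserved exactly.

``adjustable_boundary=False``
    Boundary flows are frozen (preserving measured imports/exports) and the
    imbalance is repaired by damped proportional scaling of internodal flows
    within the current layer only, sweeping layers from largest magnitude to
    smallest, nodes in fixed index order.

All modes are damped, deterministic (fixed sweep order) and preserve
non-negativity.  Convergence is judged on the worst *relative* node imbalance,
because the three element networks differ by orders of magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DEFAULT_TOLERANCE, ElementNetwork, MultiNetwork, validate

__all__ = [
    "BalancerConfig",
    "BalanceTrace",
    "ConvergenceError",
    "assign_layers",
    "balance",
    "balance_multinetwork",
]


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, trace: "BalanceTrace"):
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class BalancerConfig:
    tolerance: float = DEFAULT_TOLERANCE   # max relative node imbalance
    max_outer_iterations: int = 500
    layer_base: float = 10.0
    adjustable_boundary: bool = True
    damping: float = 0.5                   # step fraction per sweep, in (0, 1]
    boundary_policy: str = "export-only"   # or "import-export"

    def __post_init__(self):
        if not self.tolerance > 0:
            raise ValueError("tolerance must be > 0")
        if not 0 < self.damping <= 1:
            raise ValueError("damping must lie in (0, 1]")
        if self.boundary_policy not in ("export-only", "import-export"):
            raise ValueError(f"unknown boundary policy {self.boundary_policy!r}")


@dataclass
class BalanceTrace:
    """Per-outer-iteration convergence record."""

    rows: list[tuple[int, int | None, float]] = field(default_factory=list)

    @property
    def iterations(self) -> int:
        return len(self.rows)

    def worst_imbalances(self) -> list[float]:
        return [row[2] for row in self.rows]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["iteration", "worst_node", "imbalance"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _layer_of(values: np.ndarray, base: float) -> np.ndarray:
    """floor(log_base) of positive entries; NaN marks zero flows (never adjusted)."""
    out = np.full(np.shape(values), np.nan)
    pos = np.asarray(values) > 0
    out[pos] = np.floor(np.log(np.asarray(values)[pos]) / np.log(base))
    return out


def assign_layers(network: ElementNetwork, base: float = 10.0) -> dict[str, np.ndarray]:
    """Order-of-magnitude layer index for every flow in the network.

    ``layer(f) = floor(log10 f)`` for f > 0 (an exact power of ten starts its
    own layer: 10.0 -> 1); zero flows are unassigned (NaN).
    """
    return {
        "T": _layer_of(network.T, base),
        "z": _layer_of(network.z, base),
        "e": _layer_of(network.e, base),
        "r": _layer_of(network.r, base),
    }


def _node_state(net: ElementNetwork, i: int) -> tuple[float, float, float]:
    fin = net.T[:, i].sum() + net.z[i]
    fout = net.T[i, :].sum() + net.e[i] + net.r[i]
    scale = max(fin, fout)
    rel = 0.0 if scale == 0 else (fin - fout) / scale
    return fin, fout, rel


def _boundary_sweep(net: ElementNetwork, cfg: BalancerConfig, damping: float) -> None:
    for i in range(net.n):
        fin, fout, rel = _node_state(net, i)
        if abs(rel) <= cfg.tolerance:
            continue
        resid = fin - fout
        step = damping * resid
        if resid > 0:
            if cfg.boundary_policy == "import-export":
                cut = min(net.z[i], step)
                net.z[i] -= cut
                net.e[i] += step - cut
            else:
                net.e[i] += step
        else:
            deficit = -step
            if cfg.boundary_policy == "import-export":
                cut = min(net.e[i], deficit)
                net.e[i] -= cut
                deficit -= cut
                cut = min(net.r[i], deficit)
                net.r[i] -= cut
                net.z[i] += deficit - cut
            else:
                # shrink all outflows of the node proportionally
                if fout <= 0:
                    raise ConvergenceError(
                        f"node {net.nodes[i].id} ({net.nodes[i].name!r}) has an "
                        "inflow deficit but no outflow to adjust",
                        BalanceTrace(),
                    )
                factor = max(0.0, (fout - deficit) / fout)
                net.T[i, :] *= factor
                net.e[i] *= factor
                net.r[i] *= factor


def _layered_sweep(net: ElementNetwork, cfg: BalancerConfig, damping: float) -> None:
    layers = _layer_of(net.T, cfg.layer_base)
    levels = np.unique(layers[~np.isnan(layers)])[::-1]  # largest magnitude first
    if levels.size == 0:
        levels = np.array([0.0])
    for lev in levels:
        in_layer = layers == lev
        for i in range(net.n):
            fin, fout, rel = _node_state(net, i)
            if abs(rel) <= cfg.tolerance:
                continue
            gap = damping * abs(fin - fout)
            if fout > fin:
                big_mask, small_mask = in_layer[i, :], in_layer[:, i]
                big_view, small_view = net.T[i, :], net.T[:, i]
            else:
                big_mask, small_mask = in_layer[:, i], in_layer[i, :]
                big_view, small_view = net.T[:, i], net.T[i, :]
            big_mass = big_view[big_mask].sum()
            if big_mass > 0:
                factor = max(0.0, (big_mass - gap) / big_mass)
                big_view[big_mask] *= factor
            else:
                small_mass = small_view[small_mask].sum()
                if small_mass > 0:
                    small_view[small_mask] *= (small_mass + gap) / small_mass
                # else: this layer cannot help the node; other layers may


def balance(
    network: ElementNetwork,
    config: BalancerConfig | None = None,
) -> tuple[ElementNetwork, BalanceTrace]:
    """Mass-balance a network by damped layered sweeps.

    Returns the balanced network (``meta['balanced'] = True``) and the
    convergence trace (worst relative imbalance per outer iteration, monotone
    non-increasing up to plateaus; the step size is halved and the iteration
    replayed whenever a sweep would overshoot).

    Raises
    ------
    ConvergenceError
        If the tolerance is not met within ``max_outer_iterations``, or an
        imbalanced node has no adjustable flow.
    """
    cfg = config or BalancerConfig()
    net = network.copy()
    trace = BalanceTrace()

    report = validate(net, cfg.tolerance)
    if report.max_abs_imbalance <= cfg.tolerance:
        net.meta["balanced"] = True
        return net, trace  # fixed point: returned unchanged, 0 iterations

    if not cfg.adjustable_boundary:
        for i in range(net.n):
            fin, fout, rel = _node_state(net, i)
            if abs(rel) > cfg.tolerance and net.T[:, i].sum() + net.T[i, :].sum() == 0:
                raise ConvergenceError(
                    f"node {net.nodes[i].id} ({net.nodes[i].name!r}) is imbalanced "
                    "but has no adjustable internodal flow",
                    trace,
                )

    damping = cfg.damping
    best = report.max_abs_imbalance
    for it in range(1, cfg.max_outer_iterations + 1):
        snapshot = (net.T.copy(), net.z.copy(), net.e.copy(), net.r.copy())
        if cfg.adjustable_boundary:
            _boundary_sweep(net, cfg, damping)
        else:
            _layered_sweep(net, cfg, damping)
        report = validate(net, cfg.tolerance)
        worst = report.max_abs_imbalance
        if worst > best * (1 + 1e-12):
            # overshoot: revert and take a smaller step
            net.T, net.z, net.e, net.r = snapshot
            damping *= 0.5
            if damping < 1e-9:
                raise ConvergenceError(
                    "step size collapsed without reaching tolerance "
                    f"(stuck at {best:.3g})",
                    trace,
                )
            trace.rows.append((it, report.worst_node, best))
            continue
        best = worst
        trace.rows.append((it, report.worst_node, worst))
        if worst <= cfg.tolerance:
            net.meta["balanced"] = True
            return net, trace

    raise ConvergenceError(
        f"no convergence after {cfg.max_outer_iterations} outer iterations "
        f"(worst imbalance {best:.3g} at node {report.worst_node})",
        trace,
    )


def balance_multinetwork(
    multi: MultiNetwork,
    config: BalancerConfig | None = None,
) -> tuple[MultiNetwork, dict]:
    """Balance every element network that needs it; carbon is checked, not altered."""
    cfg = config or BalancerConfig()
    nets, flags, traces = {}, {}, {}
    for el, net in multi.networks.items():
        rep = validate(net, cfg.tolerance)
        if rep.max_abs_imbalance <= cfg.tolerance:
            out, trace = net.copy(), BalanceTrace()
            out.meta["balanced"] = True
        else:
            out, trace = balance(net, cfg)
        nets[el] = out
        flags[el] = True
        traces[el] = trace
    return MultiNetwork(networks=nets, balanced=flags), traces
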