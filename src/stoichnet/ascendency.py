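"""Biomass-inclusive ascendency and its nutrient-limitation sensitivities.

The biomass-inclusive ascendency conditions the information content of the
flow structure on compartment biomasses.  With ``T_ijk`` the internodal flow of
element k from node i to node j, ``T...`` the total internodal flow of all
elements, ``B_ik`` element-k biomass of node i and ``B..`` the all-element
biomass total::

    A_B = sum_{i,j,k} T_ijk * log( T_ijk * B..^2 / (T... * B_ik * B_jk) )

(logarithms base 2, so A_B is on a flow x bits scale).  A_B vanishes exactly
when every flow equals its mass-action expectation
``T... * B_ik * B_jk / B..^2``.

Two sensitivity fields derive from it:

* node sensitivities  dA_B/dB_pk = 2 [ T.../B.. - (T_.pk + T_p.k) / (2 B_pk) ]
  (per unit ln 2 in bits).  Restricted to internodal flow sums this is the
  exact gradient of A_B; including boundary flows it reads as the system-minus
  -node turnover-rate contrast, and at mass balance (inflow = outflow per node)
  its argmax over elements coincides exactly with the classical Liebig test
  supply/biomass (least relative supply = limiting nutrient).  Negative values
  flag nodes whose element turnover is faster than the system's.

* flow sensitivities  dA_B/dT_rpk = log( T_rpk * B..^2 / (T... * B_rk * B_pk) ),
  the exact gradient in the flows; the top-ranked flow depletes its source
  fastest relative to mass-action availability (the limiting flow).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Element, MultiNetwork, NodeKind

__all__ = [
    "AscendencyResult",
    "SensitivityReport",
    "biomass_ascendency",
    "node_sensitivities",
    "classify_limitation",
    "liebig_classical",
    "flow_sensitivities",
    "numeric_node_sensitivity",
    "numeric_flow_sensitivity",
]

LN2 = np.log(2.0)

#: elements whose top-two turnover rates lie within this relative band are
#: reported as co-limiting (the sensitivities are then "similar").
CO_LIMITATION_THRESHOLD = 0.05

_ORDER = [Element.CARBON, Element.NITROGEN, Element.PHOSPHORUS]


@dataclass(frozen=True)
class AscendencyResult:
    a_b: float                         # flow x bits
    i_b: float                         # Kullback divergence, bits per unit flow
    per_element: dict[Element, float]  # contributions summing to a_b
    total_flow: float                  # T... (internodal, all elements)
    total_biomass: float               # B..


def _check_flow_biomass(multi: MultiNetwork) -> None:
    for el, net in multi.networks.items():
        donors, recips = np.nonzero(net.T > 0)
        bad = (net.B[donors] <= 0) | (net.B[recips] <= 0)
        if np.any(bad):
            k = int(np.argmax(bad))
            i, j = int(donors[k]), int(recips[k])
            raise ValueError(
                f"{el.name.lower()} flow {net.nodes[i].id} -> {net.nodes[j].id} "
                f"({net.nodes[i].name!r} -> {net.nodes[j].name!r}) connects a node "
                "with zero biomass"
            )


def biomass_ascendency(multi: MultiNetwork) -> AscendencyResult:
    """Biomass-inclusive ascendency A_B of a multi-element network.

    Zero flows contribute nothing; a positive flow touching a zero-biomass
    node is an error naming the pair.  The per-element decomposition sums to
    the total, and a single-element MultiNetwork reduces to the classical
    single-nutrient form.
    """
    _check_flow_biomass(multi)
    t_dots = multi.total_flow()
    b_dots = multi.total_biomass()
    if t_dots <= 0 or b_dots <= 0:
        return AscendencyResult(0.0, 0.0, {el: 0.0 for el in multi.networks},
                                t_dots, b_dots)
    per_element: dict[Element, float] = {}
    for el, net in multi.networks.items():
        mask = net.T > 0
        if not mask.any():
            per_element[el] = 0.0
            continue
        tij = net.T[mask]
        bi = np.broadcast_to(net.B[:, None], net.T.shape)[mask]
        bj = np.broadcast_to(net.B[None, :], net.T.shape)[mask]
        per_element[el] = float(
            np.sum(tij * np.log2(tij * b_dots**2 / (t_dots * bi * bj)))
        )
    a_b = float(sum(per_element.values()))
    return AscendencyResult(a_b=a_b, i_b=a_b / t_dots, per_element=per_element,
                            total_flow=t_dots, total_biomass=b_dots)


def node_sensitivities(
    multi: MultiNetwork,
    include_boundary: bool = True,
    base: float = 2.0,
) -> pd.DataFrame:
    """Sensitivity of A_B to the element-k biomass of every node.

    With ``include_boundary=False`` the flow sums ``T_.pk`` / ``T_p.k`` are
    internodal only and the result is the exact analytic gradient of
    :func:`biomass_ascendency` (verifiable by finite differences).  With the
    default ``include_boundary=True`` boundary imports, exports and
    respirations enter the sums as the real supply and drain terms they are;
    this is the turnover-rate reading used for limitation classification.
    Nodes with zero biomass in an element are excluded (NaN) with a warning.

    Returns a DataFrame indexed by node id with one column per element.
    """
    t_dots = multi.total_flow()
    b_dots = multi.total_biomass()
    scale = 2.0 / np.log(base)
    cols: dict[str, np.ndarray] = {}
    nodes = multi.nodes
    for el in multi.elements:
        net = multi.networks[el]
        t_in = net.T.sum(axis=0)
        t_out = net.T.sum(axis=1)
        if include_boundary:
            t_in = t_in + net.z
            t_out = t_out + net.e + net.r
        sens = np.full(net.n, np.nan)
        pos = net.B > 0
        if not pos.all():
            warnings.warn(
                f"{(~pos).sum()} node(s) with zero {el.name.lower()} biomass "
                "excluded from sensitivities",
                stacklevel=2,
            )
        sens[pos] = scale * (
            t_dots / b_dots - 0.5 * (t_in[pos] + t_out[pos]) / net.B[pos]
        )
        cols[el.symbol] = sens
    return pd.DataFrame(cols, index=pd.Index([nd.id for nd in nodes], name="node"))


def _element_turnover(multi: MultiNetwork, supply_only: bool) -> pd.DataFrame:
    """Per-node, per-element turnover rate.

    ``supply_only=True``: boundary-inclusive inflow / biomass (the classical
    Liebig supply-vs-requirement rate); ``False``: mean of in- and outflow over
    biomass (the quantity the Eq-for-A_B sensitivities rank, reversed).
    """
    cols: dict[str, np.ndarray] = {}
    for el in multi.elements:
        net = multi.networks[el]
        t_in = net.T.sum(axis=0) + net.z
        if supply_only:
            flow = t_in
        else:
            flow = 0.5 * (t_in + net.T.sum(axis=1) + net.e + net.r)
        rate = np.full(net.n, np.nan)
        pos = net.B > 0
        rate[pos] = flow[pos] / net.B[pos]
        cols[el.symbol] = rate
    return pd.DataFrame(cols, index=pd.Index([nd.id for nd in multi.nodes], name="node"))


def _classify_from_turnover(
    multi: MultiNetwork, turnover: pd.DataFrame, threshold: float
) -> pd.DataFrame:
    rows = []
    symbols = [el.symbol for el in _ORDER if el in multi.networks]
    for nd in multi.nodes:
        if nd.kind is NodeKind.NUTRIENT_POOL:
            continue  # no nutrient demand, no limitation in the Liebig sense
        rates = turnover.loc[nd.id, symbols]
        if rates.isna().any():
            continue  # limiting element defined only with positive biomass everywhere
        tmin = rates.min()
        co = [s for s in symbols if rates[s] <= tmin * (1.0 + threshold)]
        rows.append({
            "node": nd.id,
            "name": nd.name,
            "limiting_element": co[0],  # deterministic C < N < P representative
            "co_limited": len(co) > 1,
            "co_limiting_set": "".join(co),
            **{f"turnover_{s}": rates[s] for s in symbols},
        })
    return pd.DataFrame(rows).set_index("node") if rows else pd.DataFrame()


def _summary(table: pd.DataFrame, multi: MultiNetwork) -> dict[str, float]:
    symbols = [el.symbol for el in _ORDER if el in multi.networks]
    n = len(table)
    return {
        s: (100.0 * float((table["limiting_element"] == s).sum()) / n
            if n else float("nan"))
        for s in symbols
    }


@dataclass(frozen=True)
class SensitivityReport:
    node_sens: pd.DataFrame        # per node id x element, dA_B/dB_pk
    limitation: pd.DataFrame       # limiting element, co-limitation, turnover rates
    summary: dict[str, float]      # % of classified nodes limited by each element
    threshold: float


def classify_limitation(
    multi: MultiNetwork, threshold: float = CO_LIMITATION_THRESHOLD
) -> SensitivityReport:
    """Limiting element per node from the ascendency sensitivities.

    The limiting element maximises the node sensitivity, equivalently
    minimises the element turnover rate; elements whose turnover lies within
    ``threshold`` (relative) of the minimum are reported as co-limiting, with
    the representative label chosen in the fixed order C < N < P.  Nutrient
    pools are excluded; so are nodes lacking positive biomass in any element.
    The summary gives the percentage of classified nodes limited by each
    element.
    """
    sens = node_sensitivities(multi, include_boundary=True)
    turnover = _element_turnover(multi, supply_only=False)
    table = _classify_from_turnover(multi, turnover, threshold)
    return SensitivityReport(
        node_sens=sens,
        limitation=table,
        summary=_summary(table, multi),
        threshold=threshold,
    )


def liebig_classical(
    multi: MultiNetwork, threshold: float = CO_LIMITATION_THRESHOLD
) -> pd.DataFrame:
    """Classical Liebig test: the element supplied at the least rate relative
    to the biomass that requires it (argmin over k of supply_k / B_pk).

    On a mass-balanced network this coincides with the ascendency-sensitivity
    classification for every node; on unbalanced networks the two can diverge
    (supply-only versus mean of supply and drain).
    """
    turnover = _element_turnover(multi, supply_only=True)
    return _classify_from_turnover(multi, turnover, threshold)


def flow_sensitivities(multi: MultiNetwork) -> pd.DataFrame:
    """Sensitivity of A_B to every positive internodal flow, ranked.

    ``dA_B/dT_rpk = log2( T_rpk B..^2 / (T... B_rk B_pk) )`` - the exact
    gradient of :func:`biomass_ascendency`; a flow at its mass-action
    expectation scores zero.  Zero flows are skipped (log undefined); boundary
    flows are not ranked (the source/recipient tallies concern internodal
    flows).  Returns a DataFrame sorted by descending sensitivity with source
    and recipient identities; the network's limiting element of flows is the
    element of the top row.
    """
    _check_flow_biomass(multi)
    t_dots = multi.total_flow()
    b_dots = multi.total_biomass()
    rows = []
    for el in multi.elements:
        net = multi.networks[el]
        donors, recips = np.nonzero(net.T > 0)
        if donors.size == 0:
            continue
        t = net.T[donors, recips]
        sens = np.log2(t * b_dots**2 / (t_dots * net.B[donors] * net.B[recips]))
        for k in range(donors.size):
            i, j = int(donors[k]), int(recips[k])
            rows.append({
                "element": el.symbol,
                "source": net.nodes[i].id,
                "source_name": net.nodes[i].name,
                "recipient": net.nodes[j].id,
                "recipient_name": net.nodes[j].name,
                "flow": float(t[k]),
                "sensitivity": float(sens[k]),
            })
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values("sensitivity", ascending=False, ignore_index=True)
        df["rank"] = np.arange(1, len(df) + 1)
    return df


# ---------------------------------------------------------------------------
# numeric differentiation validators
#
# A_B spans orders of magnitude, so a naive central difference of the summed
# index loses ~10 digits to cancellation.  These validators difference the
# perturbed and unperturbed summands *pairwise* in extended precision before
# summing, which removes the cancellation and leaves only the O(h^2)
# truncation error of the central difference.


def _state(multi: MultiNetwork, dtype):
    ts = [multi.networks[el].T.astype(dtype) for el in multi.elements]
    bs = [multi.networks[el].B.astype(dtype) for el in multi.elements]
    masks = [t > 0 for t in ts]
    return ts, bs, masks


def _log2_diff(x, h):
    """log2(x + h) - log2(x - h), evaluated without cancellation."""
    return np.log1p(2 * h / (x - h)) / np.log(np.longdouble(2))


def numeric_node_sensitivity(
    multi: MultiNetwork, node_index: int, element: Element, h_rel: float = 1e-6
) -> float:
    """Central finite difference of A_B with respect to B of one node/element.

    [A_B(B_pk + h) - A_B(B_pk - h)] / 2h, with the summand differences
    regrouped exactly: the perturbation enters every summand through
    log2(B..^2) and the summands touching node p through -log2(B_pk); both log
    differences are evaluated with log1p so no precision is lost to
    cancellation and only the O(h^2) truncation error of the central
    difference remains.  Matches :func:`node_sensitivities` with
    ``include_boundary=False`` (the exact-gradient form).
    """
    ts, bs, masks = _state(multi, np.longdouble)
    k = multi.elements.index(element)
    b0 = bs[k][node_index]
    h = np.longdouble(h_rel) * b0
    if h == 0:
        raise ValueError("cannot difference a zero biomass")
    t_dots = sum(t[m].sum() for t, m in zip(ts, masks))
    b_dots = sum(b.sum() for b in bs)
    touching = ts[k][node_index, :].sum() + ts[k][:, node_index].sum()
    diff = 2 * t_dots * _log2_diff(b_dots, h) - touching * _log2_diff(b0, h)
    return float(diff / (2 * h))


def numeric_flow_sensitivity(
    multi: MultiNetwork, element: Element, donor_index: int, recipient_index: int,
    h_rel: float = 1e-6,
) -> float:
    """Central finite difference of A_B with respect to one internodal flow.

    Matches :func:`flow_sensitivities` to the truncation error of the
    difference.
    """
    ts, bs, masks = _state(multi, np.longdouble)
    k = multi.elements.index(element)
    t0 = ts[k][donor_index, recipient_index]
    h = np.longdouble(h_rel) * t0
    if h == 0:
        raise ValueError("cannot difference a zero flow")
    t_dots = sum(t[m].sum() for t, m in zip(ts, masks))
    b_dots = sum(b.sum() for b in bs)

    # Perturbing one flow shifts T... by the same amount, which touches every
    # summand through its log(1/T...) factor.  That part of the central
    # difference is -S_other * [log2(T...+h) - log2(T...-h)], evaluated with
    # log1p so the small difference is exact; the perturbed summand itself is
    # differenced directly.
    s_other = t_dots - t0
    global_part = -s_other * np.log1p(2 * h / (t_dots - h)) / np.log(np.longdouble(2))

    bi = bs[k][donor_index]
    bj = bs[k][recipient_index]

    def summand(t, td):
        return t * np.log2(t * b_dots**2 / (td * bi * bj))

    local_part = summand(t0 + h, t_dots + h) - summand(t0 - h, t_dots - h)
    return float((global_part + local_part) / (2 * h))
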