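"""Dissolved-inorganic pool insertion and donor-stoichiometry N/P derivation.

Ecopath-style carbon models do not represent the uptake of dissolved inorganic
matter by primary producers.  :func:`add_inorganic_pool` appends a DIC-like
nutrient pool and wires demand-driven uptake flows so that every producer's
inflow balances its outflow; the pool itself is closed by a boundary import or
export, mirroring how field networks treat DIC.

:func:`derive_element_network` then builds the nitrogen or phosphorus network
from the carbon one under *donor stoichiometry*: every internodal flow carries
the elemental ratio of its donor's biomass, so
``T_ij(X) = T_ij(C) / (mass-basis C:X of donor i)``.  Boundary exports and
respiration (a carbon-only loss whose N/P analogues are excreted, i.e. exported)
are scaled by the source node's ratio; boundary imports by the recipient's.
The derived network is generally *unbalanced* - consumers ingest food whose
stoichiometry differs from their own - and is flagged so; the layered balancer
repairs it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import (
    Element,
    ElementNetwork,
    MultiNetwork,
    NodeKind,
    NodeSpec,
    molar_to_mass_ratio,
    validate,
)

__all__ = ["InorganicPoolSpec", "add_inorganic_pool", "derive_element_network",
           "derive_multinetwork", "dic_stock_from_din"]


def dic_stock_from_din(din_stock: float, dic_din_molar: float = 8.2) -> float:
    """DIC stock (gC m^-2) inferred from a DIN stock (gN m^-2) at a molar DIC:DIN ratio."""
    return din_stock * molar_to_mass_ratio(dic_din_molar, Element.NITROGEN)


@dataclass(frozen=True)
class InorganicPoolSpec:
    """A dissolved-inorganic pool (DIC and its N/P counterparts).

    ``biomass_c`` is the carbon stock; it is typically inferred from a measured
    DIN stock via :func:`dic_stock_from_din` using the conversion ratio kept in
    ``dic_din_molar``.  ``cn_ratio`` / ``cp_ratio`` are the pool's molar
    ratios, used when the pool acts as a donor in derived networks.
    """

    name: str = "DIC"
    biomass_c: float = 0.0
    cn_ratio: float = 8.2       # molar DIC:DIN
    cp_ratio: float = 131.2     # molar DIC:DIP (DIC:DIN x Redfield N:P 16)
    dic_din_molar: float = 8.2  # conversion used to infer the stock, for provenance

    def __post_init__(self):
        if self.biomass_c < 0:
            raise ValueError("pool biomass must be >= 0")

    @classmethod
    def from_din(cls, din_stock: float, dic_din_molar: float = 8.2, **kw) -> "InorganicPoolSpec":
        return cls(biomass_c=dic_stock_from_din(din_stock, dic_din_molar),
                   cn_ratio=dic_din_molar, dic_din_molar=dic_din_molar, **kw)


def add_inorganic_pool(
    network: ElementNetwork,
    pool: InorganicPoolSpec,
    producer_ids: list[int] | None = None,
    replace_producer_imports: bool = True,
    respiration_to_pool: float = 0.0,
) -> ElementNetwork:
    """Append a nutrient pool and demand-driven uptake flows to producers.

    Each producer's uptake is its outflow deficit (outflows minus non-pool
    inflows), clipped at zero with a warning if inflows already exceed
    outflows.  With ``replace_producer_imports`` (default) the producers'
    boundary-import placeholders for primary production are first removed, so
    uptake takes over the role of gross production.  ``respiration_to_pool``
    optionally reroutes that fraction of every node's respiration into the
    pool as recycling (remineralised carbon) instead of across the boundary.
    The pool node is closed by a boundary import (deficit) or export
    (surplus).  No pre-existing non-producer balance is touched.
    """
    if network.element is not Element.CARBON:
        raise ValueError("the inorganic pool is inserted on the carbon network")
    net = network.copy()
    n = net.n
    if producer_ids is None:
        producer_ids = [nd.id for nd in net.nodes if nd.kind is NodeKind.PRODUCER]
    prod_idx = [net.index_of(i) for i in producer_ids]
    if not prod_idx:
        raise ValueError("no producers identified for pool uptake")

    pool_node = NodeSpec(
        id=max(nd.id for nd in net.nodes) + 1,
        name=pool.name,
        kind=NodeKind.NUTRIENT_POOL,
        living=False,
        cn_ratio=pool.cn_ratio,
        cp_ratio=pool.cp_ratio,
    )
    nodes = net.nodes + [pool_node]
    T = np.zeros((n + 1, n + 1))
    T[:n, :n] = net.T
    B = np.append(net.B, pool.biomass_c)
    z = np.append(net.z, 0.0)
    e = np.append(net.e, 0.0)
    r = np.append(net.r, 0.0)

    if respiration_to_pool > 0:
        if not 0 < respiration_to_pool <= 1:
            raise ValueError("respiration_to_pool must lie in (0, 1]")
        recycled = r[:n] * respiration_to_pool
        T[:n, n] += recycled
        r[:n] -= recycled

    for p in prod_idx:
        if replace_producer_imports:
            z[p] = 0.0
        inflow = T[:, p].sum() + z[p]
        outflow = T[p, :].sum() + e[p] + r[p]
        uptake = outflow - inflow
        if uptake < 0:
            warnings.warn(
                f"producer {nodes[p].name!r} inflow already exceeds outflow; "
                "zero pool uptake assigned",
                stacklevel=2,
            )
            uptake = 0.0
        T[n, p] = uptake

    # close the pool at the boundary
    pool_in = T[:, n].sum() + z[n]
    pool_out = T[n, :].sum() + e[n] + r[n]
    if pool_out >= pool_in:
        z[n] += pool_out - pool_in
    else:
        e[n] += pool_in - pool_out

    meta = dict(net.meta)
    meta["inorganic_pool"] = pool.name
    return ElementNetwork(element=net.element, nodes=nodes, B=B, T=T, z=z, e=e, r=r,
                          meta=meta)


def derive_element_network(
    carbon: ElementNetwork,
    target: Element,
    ratios: dict[int, float] | None = None,
) -> ElementNetwork:
    """Derive the N or P network from a balanced carbon network.

    Parameters
    ----------
    carbon : ElementNetwork
        Balanced carbon network.
    target : Element
        NITROGEN or PHOSPHORUS.
    ratios : dict, optional
        Molar C:target ratio per node id; defaults to the ratios on the node
        specs.  Missing ratios are an error naming the node.

    Returns
    -------
    ElementNetwork
        Biomasses and flows divided by the mass-basis C:target ratio of the
        donor (imports use the recipient's ratio; carbon respiration maps to a
        boundary export scaled by the node's own ratio, since non-carbon
        networks carry no respiration).  Flagged unbalanced in ``meta``.
    """
    if carbon.element is not Element.CARBON:
        raise ValueError("derivation starts from the carbon network")
    if target is Element.CARBON:
        raise ValueError("target must be nitrogen or phosphorus")

    n = carbon.n
    rho = np.empty(n)
    for i, nd in enumerate(carbon.nodes):
        if ratios is not None and nd.id in ratios:
            rho[i] = molar_to_mass_ratio(ratios[nd.id], target)
        else:
            try:
                rho[i] = nd.mass_ratio(target)
            except ValueError as exc:
                raise ValueError(
                    f"missing C:{target.symbol} ratio for node {nd.id} ({nd.name!r})"
                ) from exc
        if not rho[i] > 0:
            raise ValueError(f"non-positive ratio for node {nd.id} ({nd.name!r})")

    B = carbon.B / rho
    T = carbon.T / rho[:, None]            # donor stoichiometry
    z = carbon.z / rho                     # imports: recipient is the donor of record
    e = (carbon.e + carbon.r) / rho        # respiration's N/P analogue is excretion
    r = np.zeros(n)

    net = ElementNetwork(
        element=target, nodes=list(carbon.nodes), B=B, T=T, z=z, e=e, r=r,
        meta={"derived_from": "carbon", "units": f"g {target.symbol} m-2 y-1"},
    )
    net.meta["balanced"] = bool(validate(net).balanced)
    return net


def derive_multinetwork(
    carbon: ElementNetwork,
    n_ratios: dict[int, float] | None = None,
    p_ratios: dict[int, float] | None = None,
) -> MultiNetwork:
    """Bundle the carbon network with freshly derived (unbalanced) N and P networks."""
    nitrogen = derive_element_network(carbon, Element.NITROGEN, n_ratios)
    phosphorus = derive_element_network(carbon, Element.PHOSPHORUS, p_ratios)
    return MultiNetwork(
        networks={
            Element.CARBON: carbon,
            Element.NITROGEN: nitrogen,
            Element.PHOSPHORUS: phosphorus,
        },
        balanced={
            Element.CARBON: bool(validate(carbon).balanced),
            Element.NITROGEN: bool(nitrogen.meta.get("balanced", False)),
            Element.PHOSPHORUS: bool(phosphorus.meta.get("balanced", False)),
        },
    )
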