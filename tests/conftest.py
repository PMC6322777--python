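"""Shared fixtures: small hand-built networks and one synthesized web."""

import numpy as np
import pytest

from stoichnet import (
    Element,
    ElementNetwork,
    MultiNetwork,
    NodeKind,
    NodeSpec,
    SyntheticWebConfig,
    synthesize_multinetwork,
)


def make_network(
    element=Element.CARBON,
    nodes=None,
    kinds=None,
    T=None,
    z=None,
    e=None,
    r=None,
    B=None,
    cn=7.0,
    cp=100.0,
):
    """Compact constructor for hand-built test networks."""
    if nodes is None:
        n = len(T) if T is not None else len(z)
        nodes = [f"node_{i+1}" for i in range(n)]
    n = len(nodes)
    if kinds is None:
        kinds = [NodeKind.CONSUMER] * n
    specs = [
        NodeSpec(
            id=i + 1,
            name=nodes[i],
            kind=kinds[i],
            living=kinds[i] in (NodeKind.PRODUCER, NodeKind.CONSUMER),
            cn_ratio=cn,
            cp_ratio=cp,
        )
        for i in range(n)
    ]
    zeros = np.zeros(n)
    return ElementNetwork(
        element=element,
        nodes=specs,
        B=np.ones(n) if B is None else np.asarray(B, float),
        T=np.zeros((n, n)) if T is None else np.asarray(T, float),
        z=zeros.copy() if z is None else np.asarray(z, float),
        e=zeros.copy() if e is None else np.asarray(e, float),
        r=zeros.copy() if r is None else np.asarray(r, float),
    )


@pytest.fixture(scope="session")
def web_multi():
    """A default 25-node synthesized, balanced three-element web."""
    multi, truths = synthesize_multinetwork(SyntheticWebConfig(seed=1))
    return multi, truths


@pytest.fixture(scope="session")
def small_multi():
    """A small balanced web for derivative-heavy tests."""
    multi, truths = synthesize_multinetwork(
        SyntheticWebConfig(seed=3, n_consumers=8)
    )
    return multi, truths
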