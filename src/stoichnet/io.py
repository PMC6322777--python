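"""File formats: native CSV bundle, Ecopath-style input tables, SCOR exchange.

The native format is a directory bundle::

    nodes.csv      id, name, kind, living, cn_ratio, cp_ratio, biomass_<El>...
    flows.csv      donor, recipient, element, value        (internodal, non-zero)
    boundary.csv   node, element, flow_type, value         (import/export/respiration)
    meta.yaml      units, balanced flags, provenance, preserved extra columns

Values are written with 17 significant digits so a write/read round trip is an
identity to full float precision.  Units are recorded explicitly and checked on
read rather than inferred.

The SCOR layout is the classic single-element ENA exchange format: a title
line, compartment counts (total and living), one name per line, then
``index value`` records for biomasses, imports, exports and respirations and
``donor recipient value`` records for internal flows, each section terminated
by ``-1``.  Compartment indexing is 1-based throughout.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import Element, ElementNetwork, MultiNetwork, NodeKind, NodeSpec
from .ecopath import EcopathInputs

__all__ = [
    "read_native", "write_native",
    "read_scor", "write_scor",
    "read_ecopath_csvs", "write_ecopath_csvs",
]

NATIVE_UNITS = "g element m-2 y-1"
_FLOAT_FMT = "%.17g"

_EL_BY_SYMBOL = {el.symbol: el for el in Element}
_KIND_BY_VALUE = {k.value: k for k in NodeKind}


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# native bundle


def write_native(multi: MultiNetwork, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    nodes = multi.nodes
    elements = multi.elements

    node_rows = {
        "id": [nd.id for nd in nodes],
        "name": [nd.name for nd in nodes],
        "kind": [nd.kind.value for nd in nodes],
        "living": [nd.living for nd in nodes],
        "cn_ratio": [nd.cn_ratio for nd in nodes],
        "cp_ratio": [nd.cp_ratio for nd in nodes],
    }
    for el in elements:
        node_rows[f"biomass_{el.symbol}"] = multi[el].B
    pd.DataFrame(node_rows).to_csv(path / "nodes.csv", index=False,
                                   float_format=_FLOAT_FMT)

    flow_rows, boundary_rows = [], []
    for el in elements:
        net = multi[el]
        donors, recips = np.nonzero(net.T != 0)
        for i, j in zip(donors.tolist(), recips.tolist()):
            flow_rows.append((nodes[i].id, nodes[j].id, el.symbol, net.T[i, j]))
        for arr, label in ((net.z, "import"), (net.e, "export"),
                           (net.r, "respiration")):
            for i in np.nonzero(arr != 0)[0].tolist():
                boundary_rows.append((nodes[i].id, el.symbol, label, arr[i]))
    pd.DataFrame(flow_rows, columns=["donor", "recipient", "element", "value"]) \
        .to_csv(path / "flows.csv", index=False, float_format=_FLOAT_FMT)
    pd.DataFrame(boundary_rows, columns=["node", "element", "flow_type", "value"]) \
        .to_csv(path / "boundary.csv", index=False, float_format=_FLOAT_FMT)

    meta = {
        "units": NATIVE_UNITS,
        "elements": [el.symbol for el in elements],
        "balanced": {el.symbol: bool(multi.balanced.get(el, False)) for el in elements},
        "network_meta": {el.symbol: _plain(multi[el].meta) for el in elements},
    }
    (path / "meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))


def _plain(obj):
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    return obj


def read_native(path: str | Path) -> MultiNetwork:
    path = Path(path)
    meta = yaml.safe_load((path / "meta.yaml").read_text())
    if meta.get("units") != NATIVE_UNITS:
        raise FormatError(
            f"unit mismatch: bundle declares {meta.get('units')!r}, "
            f"expected {NATIVE_UNITS!r}"
        )
    ndf = pd.read_csv(path / "nodes.csv", float_precision="round_trip")
    known = {"id", "name", "kind", "living", "cn_ratio", "cp_ratio"}
    extra_cols = [c for c in ndf.columns
                  if c not in known and not c.startswith("biomass_")]

    nodes = []
    for _, row in ndf.iterrows():
        if row["kind"] not in _KIND_BY_VALUE:
            raise FormatError(f"unknown node kind {row['kind']!r} for node {row['id']}")
        nodes.append(NodeSpec(
            id=int(row["id"]), name=str(row["name"]),
            kind=_KIND_BY_VALUE[row["kind"]], living=bool(row["living"]),
            cn_ratio=None if pd.isna(row["cn_ratio"]) else float(row["cn_ratio"]),
            cp_ratio=None if pd.isna(row["cp_ratio"]) else float(row["cp_ratio"]),
        ))
    index = {nd.id: k for k, nd in enumerate(nodes)}
    n = len(nodes)

    elements = [_EL_BY_SYMBOL[s] for s in meta["elements"]]
    nets = {}
    for el in elements:
        B = ndf[f"biomass_{el.symbol}"].to_numpy(dtype=float)
        nets[el] = ElementNetwork(
            element=el, nodes=list(nodes), B=B,
            T=np.zeros((n, n)), z=np.zeros(n), e=np.zeros(n), r=np.zeros(n),
            meta=dict(meta.get("network_meta", {}).get(el.symbol, {})),
        )
        if extra_cols:
            nets[el].meta["extra_node_columns"] = {
                c: ndf[c].tolist() for c in extra_cols
            }

    fdf = pd.read_csv(path / "flows.csv", float_precision="round_trip")
    for line, row in enumerate(fdf.itertuples(index=False), start=2):
        if row.element not in _EL_BY_SYMBOL:
            raise FormatError(f"flows.csv line {line}: unknown element {row.element!r}")
        for nid in (row.donor, row.recipient):
            if nid not in index:
                raise FormatError(
                    f"flows.csv line {line}: flow {row.donor} -> {row.recipient} "
                    f"references missing node {nid}"
                )
        nets[_EL_BY_SYMBOL[row.element]].T[index[row.donor], index[row.recipient]] = row.value

    bdf = pd.read_csv(path / "boundary.csv", float_precision="round_trip")
    slot = {"import": "z", "export": "e", "respiration": "r"}
    for line, row in enumerate(bdf.itertuples(index=False), start=2):
        if row.node not in index:
            raise FormatError(
                f"boundary.csv line {line}: references missing node {row.node}"
            )
        if row.flow_type not in slot:
            raise FormatError(
                f"boundary.csv line {line}: unknown flow type {row.flow_type!r}"
            )
        arr = getattr(nets[_EL_BY_SYMBOL[row.element]], slot[row.flow_type])
        arr[index[row.node]] = row.value

    balanced = {
        el: bool(meta.get("balanced", {}).get(el.symbol, False)) for el in elements
    }
    return MultiNetwork(networks=nets, balanced=balanced)


# ---------------------------------------------------------------------------
# SCOR exchange format


def write_scor(network: ElementNetwork, path: str | Path, title: str | None = None) -> None:
    nodes = network.nodes
    n = network.n
    n_living = sum(nd.living for nd in nodes)
    # SCOR expects living compartments first
    if [nd.living for nd in nodes] != sorted([nd.living for nd in nodes], reverse=True):
        raise FormatError("SCOR requires living compartments before non-living ones")
    buf = _io.StringIO()
    buf.write(f"{title or network.element.name.lower() + ' network'}\n")
    buf.write(f"{n} {n_living}\n")
    for nd in nodes:
        buf.write(f"{nd.name}\n")

    def section(records):
        for rec in records:
            buf.write(" ".join(str(x) for x in rec) + "\n")
        buf.write("-1\n")

    section([(i + 1, repr(float(network.B[i]))) for i in range(n)])
    section([(i + 1, repr(float(network.z[i]))) for i in range(n) if network.z[i] != 0])
    section([(i + 1, repr(float(network.e[i]))) for i in range(n) if network.e[i] != 0])
    section([(i + 1, repr(float(network.r[i]))) for i in range(n) if network.r[i] != 0])
    donors, recips = np.nonzero(network.T != 0)
    section([(int(i) + 1, int(j) + 1, repr(float(network.T[i, j])))
             for i, j in zip(donors, recips)])
    Path(path).write_text(buf.getvalue())


def read_scor(path: str | Path, element: Element) -> ElementNetwork:
    lines = Path(path).read_text().splitlines()
    it = iter(enumerate(lines, start=1))

    def next_line():
        try:
            return next(it)
        except StopIteration:
            raise FormatError("unexpected end of SCOR file") from None

    _, _title = next_line()
    lineno, counts = next_line()
    try:
        n, n_living = (int(x) for x in counts.split())
    except ValueError:
        raise FormatError(f"line {lineno}: expected '<n> <n_living>'") from None
    if n < 1 or n_living < 0 or n_living > n:
        raise FormatError(f"line {lineno}: inconsistent compartment counts {counts!r}")
    names = []
    for _ in range(n):
        _, name = next_line()
        names.append(name.strip())
    nodes = [
        NodeSpec(id=k + 1, name=names[k],
                 kind=NodeKind.CONSUMER if k < n_living else NodeKind.DETRITUS,
                 living=k < n_living)
        for k in range(n)
    ]

    B = np.zeros(n)
    z = np.zeros(n)
    e = np.zeros(n)
    r = np.zeros(n)
    T = np.zeros((n, n))

    def read_section(n_fields: int):
        out = []
        while True:
            lineno, line = next_line()
            parts = line.split()
            if parts and parts[0] == "-1":
                return out
            if len(parts) != n_fields:
                raise FormatError(f"line {lineno}: expected {n_fields} fields, got {line!r}")
            idxs = [int(p) for p in parts[:-1]]
            val = float(parts[-1])
            if val < 0:
                raise FormatError(f"line {lineno}: negative value {val}")
            for i in idxs:
                if not 1 <= i <= n:
                    raise FormatError(
                        f"line {lineno}: compartment {i} out of range 1..{n}"
                    )
            out.append((lineno, idxs, val))
        return out

    for _, (i,), v in read_section(2):
        B[i - 1] = v
    for _, (i,), v in read_section(2):
        z[i - 1] = v
    for _, (i,), v in read_section(2):
        e[i - 1] = v
    for _, (i,), v in read_section(2):
        r[i - 1] = v
    for _, (i, j), v in read_section(3):
        T[i - 1, j - 1] = v
    return ElementNetwork(element=element, nodes=nodes, B=B, T=T, z=z, e=e, r=r,
                          meta={"source": str(path)})


# ---------------------------------------------------------------------------
# Ecopath-style input tables


def write_ecopath_csvs(inputs: EcopathInputs, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    nodes = inputs.nodes
    basic = pd.DataFrame({
        "id": [nd.id for nd in nodes],
        "name": [nd.name for nd in nodes],
        "kind": [nd.kind.value for nd in nodes],
        "living": [nd.living for nd in nodes],
        "cn_ratio": [nd.cn_ratio for nd in nodes],
        "cp_ratio": [nd.cp_ratio for nd in nodes],
        "B": inputs.B, "PB": inputs.PB, "QB": inputs.QB, "EE": inputs.EE,
        "U": inputs.U, "Y": inputs.Y, "BA": inputs.BA, "GE": inputs.GE,
        "imports": inputs.imports,
    })
    basic.to_csv(path / "basic_input.csv", index=False, float_format=_FLOAT_FMT)

    ids = [nd.id for nd in nodes]
    diet = pd.DataFrame(inputs.DC, index=pd.Index(ids + ["import"], name="prey"),
                        columns=[str(i) for i in ids])
    diet.to_csv(path / "diet.csv", float_format=_FLOAT_FMT)

    det_ids = [nd.id for nd in nodes if nd.kind is NodeKind.DETRITUS]
    fate = pd.DataFrame(inputs.detritus_fate, index=pd.Index(ids, name="group"),
                        columns=[str(i) for i in det_ids])
    fate.to_csv(path / "detritus_fate.csv", float_format=_FLOAT_FMT)


def read_ecopath_csvs(path: str | Path) -> EcopathInputs:
    path = Path(path)
    basic = pd.read_csv(path / "basic_input.csv", float_precision="round_trip")
    nodes = []
    for _, row in basic.iterrows():
        if row["kind"] not in _KIND_BY_VALUE:
            raise FormatError(f"unknown node kind {row['kind']!r} for node {row['id']}")
        nodes.append(NodeSpec(
            id=int(row["id"]), name=str(row["name"]),
            kind=_KIND_BY_VALUE[row["kind"]], living=bool(row["living"]),
            cn_ratio=None if pd.isna(row["cn_ratio"]) else float(row["cn_ratio"]),
            cp_ratio=None if pd.isna(row["cp_ratio"]) else float(row["cp_ratio"]),
        ))
    diet = pd.read_csv(path / "diet.csv", index_col=0, float_precision="round_trip")
    fate = pd.read_csv(path / "detritus_fate.csv", index_col=0, float_precision="round_trip")
    return EcopathInputs(
        nodes=nodes,
        B=basic["B"].to_numpy(float), PB=basic["PB"].to_numpy(float),
        QB=basic["QB"].to_numpy(float), EE=basic["EE"].to_numpy(float),
        U=basic["U"].to_numpy(float), Y=basic["Y"].to_numpy(float),
        BA=basic["BA"].to_numpy(float), GE=basic["GE"].to_numpy(float),
        imports=(basic["imports"].to_numpy(float)
                 if "imports" in basic.columns else None),
        DC=diet.to_numpy(float), detritus_fate=fate.to_numpy(float),
        meta={"source": str(path)},
    )
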