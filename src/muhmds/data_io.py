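"""Readers, writers, preprocessing and graph-distance computation.

Supported inputs: dense sample-by-feature tables (CSV/TSV), Matrix Market
sparse matrices with an optional row-id sidecar, precomputed symmetric
dissimilarity matrices, and undirected graph edge lists (unweighted edges
of length 1 unless a third numeric column gives weights).  Sample order in
the input file is authoritative and preserved in every output.
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "InputBundle",
    "read_features",
    "read_dissimilarities",
    "read_edge_list",
    "graph_to_distances",
    "pca_reduce",
    "write_embedding",
    "read_embedding",
]

_DENSIFY_LIMIT = 50_000_000  # entries; beyond this sparse inputs stay sparse


@dataclass
class InputBundle:
    """One parsed input: a feature matrix, dissimilarities, or a graph."""

    kind: str  # "features" | "dissimilarity" | "graph"
    payload: np.ndarray
    ids: list = field(default_factory=list)

    def __post_init__(self):
        if self.kind not in ("features", "dissimilarity", "graph"):
            raise ValueError(f"unknown input kind {self.kind!r}")
        if len(self.ids) != len(set(self.ids)):
            raise ValueError("sample ids must be unique")
        if self.kind == "dissimilarity":
            p = self.payload
            if p.shape[0] != p.shape[1]:
                raise ValueError("dissimilarity matrix must be square")
            if not np.allclose(p, p.T, atol=1e-8):
                raise ValueError("dissimilarity matrix must be symmetric")
            if np.any(np.abs(np.diag(p)) > 1e-8):
                raise ValueError("dissimilarity diagonal must be zero")


def _read_table(path: Path, sep: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=sep, header=0, index_col=0)
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"failed to parse {path}: {exc}") from exc
    bad = df.columns[~df.dtypes.map(lambda t: np.issubdtype(t, np.number))]
    if len(bad):
        # locate the first offending cell for the error message
        for col in bad:
            coerced = pd.to_numeric(df[col], errors="coerce")
            row = int(np.argmax(coerced.isna().to_numpy()))
            raise ValueError(
                f"non-numeric cell in {path} at data row {row + 1}, column {col!r}"
            )
    if df.isna().to_numpy().any():
        row, col = np.argwhere(df.isna().to_numpy())[0]
        raise ValueError(
            f"missing value in {path} at data row {row + 1}, "
            f"column {df.columns[col]!r} (ragged or truncated row?)"
        )
    return df


def read_features(path, fmt: str | None = None) -> InputBundle:
    """Read a sample-by-feature matrix from CSV, TSV or Matrix Market.

    The format is inferred from the extension unless ``fmt`` is given.  For
    ``.mtx`` files a sidecar ``<stem>.rows.txt`` (one id per line) supplies
    sample ids when present.  Ragged or non-numeric tables raise a parse
    error naming the offending location.
    """
    path = Path(path)
    fmt = fmt or {".csv": "csv", ".tsv": "tsv", ".mtx": "mtx"}.get(path.suffix, "tsv")
    if fmt == "mtx":
        mat = spio.mmread(path)
        if sparse.issparse(mat):
            mat = mat.toarray() if mat.shape[0] * mat.shape[1] <= _DENSIFY_LIMIT else mat
        mat = np.asarray(mat, dtype=float)
        sidecar = path.with_suffix("").with_suffix(".rows.txt")
        if sidecar.exists():
            ids = sidecar.read_text().split()
            if len(ids) != mat.shape[0]:
                raise ValueError(
                    f"row-id sidecar {sidecar} has {len(ids)} ids "
                    f"for {mat.shape[0]} matrix rows"
                )
        else:
            ids = [str(i) for i in range(mat.shape[0])]
        return InputBundle("features", mat, ids)
    sep = "," if fmt == "csv" else "\t"
    df = _read_table(path, sep)
    return InputBundle("features", df.to_numpy(dtype=float), [str(i) for i in df.index])


def read_dissimilarities(path, fmt: str | None = None) -> InputBundle:
    """Read a precomputed symmetric dissimilarity matrix (CSV/TSV)."""
    path = Path(path)
    sep = "," if (fmt == "csv" or (fmt is None and path.suffix == ".csv")) else "\t"
    df = _read_table(path, sep)
    if df.shape[0] != df.shape[1]:
        raise ValueError(
            f"dissimilarity matrix in {path} is {df.shape[0]}x{df.shape[1]}, not square"
        )
    return InputBundle("dissimilarity", df.to_numpy(dtype=float), [str(i) for i in df.index])


def read_edge_list(path) -> np.ndarray:
    """Read a whitespace/tab-delimited edge list; optional third weight column."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) not in (2, 3):
                raise ValueError(f"{path}: line {ln} has {len(parts)} fields, expected 2 or 3")
            rows.append(parts)
    return np.asarray(rows, dtype=object)


def graph_to_distances(edges) -> InputBundle:
    """All-pairs shortest-path distance matrix of an undirected graph.

    Edges are unit length unless a third numeric column provides weights.
    Node order follows first appearance in the edge list.  A disconnected
    graph is an error naming the components.
    """
    edges = np.asarray(edges, dtype=object)
    G = nx.Graph()
    order: list = []
    seen = set()
    for row in edges:
        u, v = str(row[0]), str(row[1])
        w = float(row[2]) if len(row) > 2 else 1.0
        G.add_edge(u, v, weight=w)
        for node in (u, v):
            if node not in seen:
                seen.add(node)
                order.append(node)
    if not nx.is_connected(G):
        comps = [sorted(c) for c in nx.connected_components(G)]
        raise ValueError(f"graph is disconnected; components: {comps}")
    n = len(order)
    idx = {node: i for i, node in enumerate(order)}
    dist = np.zeros((n, n))
    for src, lengths in nx.all_pairs_dijkstra_path_length(G, weight="weight"):
        for dst, d in lengths.items():
            dist[idx[src], idx[dst]] = d
    return InputBundle("dissimilarity", dist, order)


def pca_reduce(features: np.ndarray, n_components: int = 100) -> np.ndarray:
    """Project features onto the top principal components via centered SVD.

    A pass-through identity when the feature count does not exceed
    ``n_components``.  Component signs follow a deterministic convention:
    the largest-magnitude loading of each component is made positive.
    """
    X = np.asarray(features, dtype=float)
    if X.shape[1] <= n_components:
        return X.copy()
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = n_components
    signs = np.sign(Vt[np.arange(k), np.argmax(np.abs(Vt[:k]), axis=1)])
    signs[signs == 0] = 1.0
    return (U[:, :k] * s[:k]) * signs


def _config_hash(provenance: dict) -> str:
    blob = json.dumps(provenance, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_embedding(result, path, ids=None) -> None:
    """Write an embedding to TSV.

    Columns: sample id, the D spacelike coordinates, the derived timelike
    coordinate x0, the hyperbolic radius, cluster id and outlier flag.
    Header comment lines record lambda, the normalization scale, the seed
    and a hash of the configuration, so a result can be reproduced and its
    units recovered.
    """
    coords = result.coords
    n, D = coords.shape
    ids = list(ids) if ids is not None else [str(i) for i in range(n)]
    if len(ids) != n:
        raise ValueError(f"{len(ids)} ids for {n} embedded points")
    pts = result.points
    x0 = pts.ambient[:, 0]
    radius = pts.radii()
    prov = dict(result.provenance)
    clusters = prov.pop("cluster_ids", None)
    outliers = prov.pop("outlier_flags", None)
    if clusters is None:
        clusters = np.full(n, -1)
    if outliers is None:
        outliers = np.zeros(n, dtype=bool)

    buf = io.StringIO()
    buf.write(f"# lambda={float(result.lam)!r}\tscale={float(result.scale)!r}\n")
    buf.write(f"# seed={prov.get('seed', '')}\tconfig_hash={_config_hash(prov)}\n")
    cols = ["id"] + [f"x{i + 1}" for i in range(D)] + ["x0", "radius", "cluster", "outlier"]
    buf.write("\t".join(cols) + "\n")
    for i in range(n):
        row = [ids[i]]
        row += [repr(float(c)) for c in coords[i]]
        row += [repr(float(x0[i])), repr(float(radius[i]))]
        row += [str(int(clusters[i])), str(int(outliers[i]))]
        buf.write("\t".join(row) + "\n")
    Path(path).write_text(buf.getvalue())


def read_embedding(path):
    """Read an embedding TSV written by :func:`write_embedding`.

    Returns ``(coords, ids, meta)`` where coords are the spacelike
    coordinates and meta holds lambda and the normalization scale.
    """
    path = Path(path)
    meta: dict = {}
    rows = []
    ids = []
    header: list | None = None
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            for item in line[1:].strip().split("\t"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    meta[k.strip()] = v.strip()
            continue
        parts = line.split("\t")
        if header is None:
            header = parts
            continue
        if len(parts) != len(header):
            raise ValueError(f"{path}: row has {len(parts)} fields, expected {len(header)}")
        ids.append(parts[0])
        rows.append(parts[1:])
    if header is None:
        raise ValueError(f"{path}: empty embedding file")
    D = len(header) - 5  # id, x0, radius, cluster, outlier
    coords = np.asarray([[float(x) for x in r[:D]] for r in rows])
    for key in ("lambda", "scale"):
        if key in meta:
            meta[key] = float(meta[key])
    return coords, ids, meta
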