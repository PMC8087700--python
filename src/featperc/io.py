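"""Plain-text readers and writers.

Dialects: UTF-8; TSV for edge lists, node-feature tables and bipartite
tables; CSV for curves (see :mod:`featperc.curves`); ``#``-prefixed header
lines are allowed everywhere and carry JSON metadata when written by the
package.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DomainError
from .simulation import FeatureNetwork, _simplify


def write_edge_list(path, net: FeatureNetwork, meta: dict | None = None):
    """Two-column TSV of 0-based integer ids, one undirected edge per line."""
    path = Path(path)
    header = {"type": "edge_list", "n": net.n, **(meta or {})}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# " + json.dumps(header, default=str) + "\n")
        for u, v in net.edges:
            fh.write(f"{u}\t{v}\n")


def read_edge_list(path, n: int | None = None) -> FeatureNetwork:
    path = Path(path)
    meta = {}
    rows = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                try:
                    meta = json.loads(line.lstrip("# "))
                except json.JSONDecodeError:
                    pass
                continue
            parts = line.replace(",", "\t").split()
            if len(parts) < 2:
                raise DomainError(f"malformed edge line: {line!r}")
            rows.append((int(parts[0]), int(parts[1])))
    edges = np.array(rows, dtype=np.int64).reshape(-1, 2)
    if n is None:
        n = meta.get("n", int(edges.max()) + 1 if edges.size else 0)
    return FeatureNetwork(n=int(n), edges=_simplify(int(n), edges), meta=meta)


def write_feature_table(path, features, meta: dict | None = None):
    """TSV: node_id <tab> feature."""
    path = Path(path)
    header = {"type": "feature_table", **(meta or {})}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# " + json.dumps(header, default=str) + "\n")
        for i, f in enumerate(np.asarray(features, dtype=float)):
            fh.write(f"{i}\t{float(f)!r}\n")


def read_feature_table(path, n: int | None = None) -> np.ndarray:
    df = pd.read_csv(path, sep=r"\s+|,", engine="python", comment="#",
                     header=None, names=["node", "feature"])
    nodes = df["node"].to_numpy(int)
    if n is None:
        n = nodes.max() + 1 if nodes.size else 0
    out = np.full(int(n), np.nan)
    out[nodes] = df["feature"].to_numpy(float)
    return out


def write_pairs_table(path, degrees, features, meta: dict | None = None):
    """TSV: node_id <tab> degree <tab> feature."""
    path = Path(path)
    header = {"type": "pairs_table", **(meta or {})}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# " + json.dumps(header, default=str) + "\n")
        for i, (k, f) in enumerate(zip(degrees, features)):
            fh.write(f"{i}\t{int(k)}\t{float(f)!r}\n")


def read_pairs_table(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep=r"\s+|,", engine="python", comment="#",
                     header=None, names=["node", "degree", "feature"])
    return df["degree"].to_numpy(int), df["feature"].to_numpy(float)


def read_bipartite(path) -> list[tuple]:
    """TSV of (left_id, right_id) rows; ids may be arbitrary tokens."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", "\t").split()
            if len(parts) < 2:
                raise DomainError(f"malformed bipartite line: {line!r}")
            out.append((parts[0], parts[1]))
    return out


def write_bipartite(path, pairs, meta: dict | None = None):
    path = Path(path)
    header = {"type": "bipartite", **(meta or {})}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# " + json.dumps(header, default=str) + "\n")
        for left, right in pairs:
            fh.write(f"{left}\t{right}\n")


def write_positions_table(path, net: FeatureNetwork, meta: dict | None = None):
    """TSV: node_id, x, y, feature (spatial graphs)."""
    if net.positions is None:
        raise DomainError("network has no positions")
    path = Path(path)
    header = {"type": "positions", **(meta or {})}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# " + json.dumps(header, default=str) + "\n")
        for i in range(net.n):
            x, y = net.positions[i]
            f = net.features[i] if net.features is not None else float("nan")
            fh.write(f"{i}\t{float(x)!r}\t{float(y)!r}\t{float(f)!r}\n")
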