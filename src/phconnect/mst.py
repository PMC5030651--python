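"""Minimum spanning trees of connectivity distance matrices.

The MST collects the edges along which components merge during graph
filtration: its edge-weight multiset equals the single-linkage merge heights,
and the MST of the SLD matrix has the same total weight as the MST of the
raw distance matrix (single-linkage/minimax duality). Trees are laid out
with a deterministic stress-majorization embedding (the same
energy-minimizing idea as the Kamada-Kawai layout) and exported in the Pajek
``.net`` dialect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .connectivity import DistanceMatrix
from .filtration import DisjointSet, SingleLinkageResult, _sorted_edges


@dataclass(frozen=True)
class SpanningTree:
    """A spanning tree over region labels with weighted edges."""

    region_labels: tuple[str, ...]
    edges: tuple[tuple[str, str, float], ...]
    #: which matrix the tree was built from: "distance" or "slm"
    source: str = "distance"

    def __post_init__(self) -> None:
        n = len(self.region_labels)
        if len(self.edges) != n - 1:
            raise ValueError(f"spanning tree over {n} regions needs {n - 1} edges")
        ds = DisjointSet(n)
        index = {lab: k for k, lab in enumerate(self.region_labels)}
        for a, b, _ in self.edges:
            if not ds.union(index[a], index[b]):
                raise ValueError(f"edge ({a}, {b}) closes a cycle")

    @property
    def total_weight(self) -> float:
        return float(sum(w for _, _, w in self.edges))

    def adjacency(self) -> dict[str, list[tuple[str, float]]]:
        adj: dict[str, list[tuple[str, float]]] = {lab: [] for lab in self.region_labels}
        for a, b, w in self.edges:
            adj[a].append((b, w))
            adj[b].append((a, w))
        return adj


def minimum_spanning_tree(d: DistanceMatrix | SingleLinkageResult) -> SpanningTree:
    """Kruskal MST with lexicographic tie-breaking; fully deterministic.

    Accepts either a raw distance matrix or a single-linkage result (whose
    ultrametric SLM is then used); the chosen input is recorded in the
    tree's ``source`` tag because tied weights can yield different — equally
    minimal — edge sets for the two inputs.
    """
    if isinstance(d, SingleLinkageResult):
        matrix, labels, source = d.slm, tuple(d.region_labels), "slm"
    else:
        matrix, labels, source = np.asarray(d.d, float), tuple(d.region_labels), "distance"
    if not np.all(np.isfinite(matrix)):
        raise ValueError("distance matrix contains non-finite entries")
    n = len(labels)
    ds = DisjointSet(n)
    edges: list[tuple[str, str, float]] = []
    for weight, i, j in _sorted_edges(matrix, labels):
        if ds.union(i, j):
            edges.append((labels[i], labels[j], float(weight)))
            if len(edges) == n - 1:
                break
    return SpanningTree(region_labels=labels, edges=tuple(edges), source=source)


def tree_path_distances(tree: SpanningTree) -> np.ndarray:
    """All-pairs path lengths along the tree (sum of edge weights)."""
    n = len(tree.region_labels)
    index = {lab: k for k, lab in enumerate(tree.region_labels)}
    adj = tree.adjacency()
    dist = np.zeros((n, n), dtype=float)
    for root in tree.region_labels:
        ri = index[root]
        stack = [(root, 0.0)]
        seen = {root}
        while stack:
            node, acc = stack.pop()
            for nxt, w in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    dist[ri, index[nxt]] = acc + w
                    stack.append((nxt, acc + w))
    return dist


def layout_positions(
    tree: SpanningTree,
    seed: int = 0,
    rtol: float = 1e-6,
    max_iter: int = 1000,
) -> dict[str, tuple[float, float]]:
    """Deterministic 2-D embedding of a tree by stress majorization.

    Minimizes the stress ``sum_{i<j} (delta_ij - |x_i - x_j|)^2`` where
    ``delta`` are tree path distances, via the SMACOF/Guttman update, which
    never increases the stress. Purely cosmetic: positions are for rendering
    and carry no statistical meaning. Iteration stops when the relative
    stress decrease falls below ``rtol`` or after ``max_iter`` updates.
    """
    labels = tree.region_labels
    n = len(labels)
    delta = tree_path_distances(tree)
    rng = np.random.default_rng(seed)
    scale = delta.max() if delta.max() > 0 else 1.0
    x = rng.standard_normal((n, 2)) * scale / max(n, 2)
    if n == 1:
        return {labels[0]: (0.0, 0.0)}

    def pairwise(coords: np.ndarray) -> np.ndarray:
        diff = coords[:, None, :] - coords[None, :, :]
        return np.sqrt((diff**2).sum(axis=-1))

    def stress(coords: np.ndarray) -> float:
        dcur = pairwise(coords)
        iu = np.triu_indices(n, k=1)
        return float(((delta[iu] - dcur[iu]) ** 2).sum())

    prev = stress(x)
    for _ in range(max_iter):
        dcur = pairwise(x)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dcur > 0, delta / dcur, 0.0)
        b = -ratio
        np.fill_diagonal(b, 0.0)
        np.fill_diagonal(b, -b.sum(axis=1))
        x = b @ x / n
        cur = stress(x)
        if prev > 0 and (prev - cur) / prev < rtol:
            prev = cur
            break
        prev = cur
    x = x - x.mean(axis=0)
    return {lab: (float(px), float(py)) for lab, (px, py) in zip(labels, x)}


def export_pajek(tree: SpanningTree, path: str | Path | None = None) -> str:
    """Serialize a tree in the Pajek ``.net`` dialect.

    ``*Vertices n`` with 1-based indices and double-quoted labels, then
    ``*Edges`` with ``i j weight`` lines. Labels containing double quotes are
    rejected; a ``%`` comment records the source matrix tag.
    """
    for lab in tree.region_labels:
        if '"' in lab:
            raise ValueError(f"label {lab!r} contains a double quote; not representable")
    index = {lab: k + 1 for k, lab in enumerate(tree.region_labels)}
    lines = [f"% source: {tree.source}", f"*Vertices {len(tree.region_labels)}"]
    lines += [f'{k + 1} "{lab}"' for k, lab in enumerate(tree.region_labels)]
    lines.append("*Edges")
    lines += [f"{index[a]} {index[b]} {float(w)!r}" for a, b, w in tree.edges]
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def read_pajek(source: str | Path) -> SpanningTree:
    """Parse a Pajek ``.net`` file written by :func:`export_pajek`.

    Tolerates CRLF line endings, blank lines and ``%`` comments; vertex and
    edge fields are whitespace-separated and section keywords are matched
    case-insensitively.
    """
    text = Path(source).read_text(encoding="utf-8") if isinstance(source, Path) else source
    if isinstance(source, str) and "\n" not in source and Path(source).exists():
        text = Path(source).read_text(encoding="utf-8")
    labels: dict[int, str] = {}
    edges: list[tuple[str, str, float]] = []
    tree_source = "distance"
    section = None
    for raw in text.splitlines():
        line = raw.strip().rstrip("\r")
        if not line:
            continue
        if line.startswith("%"):
            if "source:" in line:
                tree_source = line.split("source:", 1)[1].strip()
            continue
        lower = line.lower()
        if lower.startswith("*vertices"):
            section = "vertices"
            continue
        if lower.startswith("*edges") or lower.startswith("*arcs"):
            section = "edges"
            continue
        if section == "vertices":
            idx_str, rest = line.split(None, 1)
            label = rest.strip()
            if label.startswith('"') and label.endswith('"'):
                label = label[1:-1]
            labels[int(idx_str)] = label
        elif section == "edges":
            i_str, j_str, w_str = line.split()[:3]
            edges.append((labels[int(i_str)], labels[int(j_str)], float(w_str)))
    ordered = tuple(labels[k] for k in sorted(labels))
    return SpanningTree(region_labels=ordered, edges=tuple(edges), source=tree_source)
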