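"""Graph filtration: Betti-0 curves, barcodes and single-linkage structure.

Thresholding a distance matrix at an increasing threshold ``eps`` yields a
nested sequence of binary graphs (the filtration). The number of connected
components at each threshold is the zeroth Betti number ``beta0``; it starts
at the number of regions and decreases to one. The threshold at which two
regions first share a component is their single-linkage distance (SLD),
which equals the minimax path distance; the matrix of all SLDs (the SLM) is
an ultrametric. Components merge exactly at the minimum-spanning-tree edge
weights, which is why barcode deaths, dendrogram merge heights and MST edge
weights are three views of the same multiset.

Edges with ``d_ij`` exactly equal to ``eps`` are included (closed threshold),
so ``beta0`` is right-continuous and merge heights are attained. Ties are
broken by processing candidate edges in lexicographic label order, making
dendrograms bit-reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .connectivity import DistanceMatrix


class DisjointSet:
    """Union-find with path compression and union by size."""

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        self.size = [1] * n
        self.n_components = n

    def find(self, i: int) -> int:
        root = i
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[i] != root:
            self.parent[i], i = root, self.parent[i]
        return root

    def union(self, i: int, j: int) -> bool:
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return False
        if self.size[ri] < self.size[rj]:
            ri, rj = rj, ri
        self.parent[rj] = ri
        self.size[ri] += self.size[rj]
        self.n_components -= 1
        return True


@dataclass(frozen=True)
class FiltrationProfile:
    """Betti-0 step function and component barcode of a filtration.

    ``thresholds`` are the distinct merge heights; ``beta0[k]`` is the
    component count on the interval before ``thresholds[k]`` (so ``beta0``
    has one more entry than ``thresholds`` and ends at 1). ``bars`` are the
    (birth, death) intervals of components: births are all 0, one bar per
    region, and the component that survives the whole filtration carries an
    infinite death.
    """

    region_labels: tuple[str, ...]
    thresholds: tuple[float, ...]
    beta0: tuple[int, ...]
    bars: tuple[tuple[float, float], ...]

    def beta0_at(self, epsilon: float) -> int:
        """Component count at ``epsilon`` from the stored step function."""
        if epsilon < 0:
            raise ValueError("epsilon must be non-negative")
        idx = int(np.searchsorted(np.asarray(self.thresholds), epsilon, side="right"))
        return self.beta0[idx]

    def to_json(self) -> str:
        payload = {
            "region_labels": list(self.region_labels),
            "thresholds": list(self.thresholds),
            "beta0": list(self.beta0),
            "bars": [[b, ("inf" if math.isinf(d) else d)] for b, d in self.bars],
        }
        return json.dumps(payload, indent=1)


@dataclass(frozen=True)
class SingleLinkageResult:
    """Single-linkage merge tree and the ultrametric SLD matrix."""

    region_labels: tuple[str, ...]
    #: ordered (height, members_a, members_b) with members as sorted label tuples
    merges: tuple[tuple[float, tuple[str, ...], tuple[str, ...]], ...]
    slm: np.ndarray

    @property
    def merge_heights(self) -> tuple[float, ...]:
        return tuple(h for h, _, _ in self.merges)


def _validated(d: DistanceMatrix) -> np.ndarray:
    matrix = np.asarray(d.d, dtype=float)
    if not np.all(np.isfinite(matrix)):
        raise ValueError("distance matrix contains non-finite entries")
    return matrix


def _sorted_edges(matrix: np.ndarray, labels: tuple[str, ...]):
    """Condensed edges sorted by (weight, sorted label pair)."""
    n = matrix.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    order = sorted(
        range(len(iu)),
        key=lambda k: (matrix[iu[k], ju[k]], *sorted((labels[iu[k]], labels[ju[k]]))),
    )
    return [(matrix[iu[k], ju[k]], int(iu[k]), int(ju[k])) for k in order]


def beta0_at(d: DistanceMatrix, epsilon: float) -> int:
    """Number of connected components of the graph with edges ``d_ij <= eps``."""
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    matrix = _validated(d)
    n = matrix.shape[0]
    ds = DisjointSet(n)
    iu, ju = np.nonzero(np.triu(matrix <= epsilon, k=1))
    for i, j in zip(iu, ju):
        ds.union(int(i), int(j))
    return ds.n_components


def single_linkage(d: DistanceMatrix) -> SingleLinkageResult:
    """Single-linkage clustering of a distance matrix via Kruskal merges.

    Each accepted edge merges two clusters at its weight; the SLD between
    any region of one cluster and any region of the other is that weight,
    which equals the minimax (minimum over paths of the maximum edge) path
    distance. Merge events record full member sets so dendrogram export is
    lossless.
    """
    matrix = _validated(d)
    labels = tuple(d.region_labels)
    n = matrix.shape[0]
    slm = np.zeros((n, n), dtype=float)
    ds = DisjointSet(n)
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    merges: list[tuple[float, tuple[str, ...], tuple[str, ...]]] = []
    for weight, i, j in _sorted_edges(matrix, labels):
        ri, rj = ds.find(i), ds.find(j)
        if ri == rj:
            continue
        group_a, group_b = members.pop(ri), members.pop(rj)
        slm[np.ix_(group_a, group_b)] = weight
        slm[np.ix_(group_b, group_a)] = weight
        names_a = tuple(sorted(labels[k] for k in group_a))
        names_b = tuple(sorted(labels[k] for k in group_b))
        merges.append((float(weight), *sorted((names_a, names_b))))
        ds.union(ri, rj)
        members[ds.find(ri)] = group_a + group_b
        if ds.n_components == 1:
            break
    return SingleLinkageResult(region_labels=labels, merges=tuple(merges), slm=slm)


def minimax_distance(d: DistanceMatrix) -> np.ndarray:
    """The SLD/minimax matrix alone (convenience wrapper over single_linkage)."""
    return single_linkage(d).slm


def filtration_profile(d: DistanceMatrix) -> FiltrationProfile:
    """Betti-0 curve and barcode of the full filtration.

    The thresholds at which ``beta0`` changes are exactly the deduplicated
    single-linkage merge heights (equivalently MST edge weights); ``beta0``
    steps down by each height's multiplicity.
    """
    result = single_linkage(d)
    heights = result.merge_heights
    thresholds: list[float] = []
    counts: list[int] = []
    for h in heights:
        if thresholds and h == thresholds[-1]:
            counts[-1] += 1
        else:
            thresholds.append(h)
            counts.append(1)
    n = len(d.region_labels)
    beta0 = [n]
    for c in counts:
        beta0.append(beta0[-1] - c)
    bars = tuple((0.0, h) for h in heights) + ((0.0, math.inf),)
    return FiltrationProfile(
        region_labels=tuple(d.region_labels),
        thresholds=tuple(thresholds),
        beta0=tuple(beta0),
        bars=bars,
    )


def _newick_escape(label: str) -> str:
    unsafe = set(" ()[]:;,'\"")
    if any(ch in unsafe for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def export_dendrogram(result: SingleLinkageResult, path: str | Path | None = None) -> str:
    """Serialize the single-linkage merge tree as a Newick string.

    Internal nodes sit at their merge height; branch lengths are height
    differences, so every root-to-leaf path length equals the final merge
    height. Re-parsing the tree reproduces the merge list exactly.
    """
    # cluster state: frozen member set -> (newick fragment, height)
    state: dict[tuple[str, ...], tuple[str, float]] = {
        (lab,): (_newick_escape(lab), 0.0) for lab in result.region_labels
    }
    for height, group_a, group_b in result.merges:
        frag_a, h_a = state.pop(group_a)
        frag_b, h_b = state.pop(group_b)
        fragment = f"({frag_a}:{float(height - h_a)!r},{frag_b}:{float(height - h_b)!r})"
        state[tuple(sorted(group_a + group_b))] = (fragment, height)
    if len(state) != 1:
        fragments = ",".join(f"{frag}:0" for frag, _ in state.values())
        newick = f"({fragments});"
    else:
        (fragment, _), = state.values()
        newick = fragment + ";"
    if path is not None:
        Path(path).write_text(newick + "\n", encoding="utf-8")
    return newick
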