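"""Group correlation networks and correlation-to-distance maps.

Metabolic connectivity is a group-level construct: the Pearson correlation
``r_ij`` of regional uptake between VOIs i and j is computed across the
subjects of one group, giving one weighted network per group (not per
subject). Correlations are Fisher-z transformed for group comparison and
mapped to distances for graph filtration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic_cohort import UptakeTable

#: r is clipped to +/-(1 - FISHER_CLIP) before atanh so degenerate, perfectly
#: correlated inputs stay finite.
FISHER_CLIP = 1e-7

METRICS = ("one_minus_r", "sqrt_one_minus_r")


@dataclass(frozen=True)
class GroupCorrelation:
    """Per-group Pearson correlation matrix and its Fisher z transform."""

    region_labels: tuple[str, ...]
    r: np.ndarray
    z: np.ndarray
    n_subjects: int
    group: str = ""

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        n = len(self.region_labels)
        if r.shape != (n, n):
            raise ValueError(f"r must be {n}x{n}, got {r.shape}")
        if not np.allclose(r, r.T):
            raise ValueError("r must be symmetric")
        if np.any(np.abs(r) > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "z", np.asarray(self.z, dtype=float))


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of connection-threshold distances between regions."""

    region_labels: tuple[str, ...]
    d: np.ndarray
    metric_tag: str

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        n = len(self.region_labels)
        if d.shape != (n, n):
            raise ValueError(f"d must be {n}x{n}, got {d.shape}")
        if not np.allclose(d, d.T):
            raise ValueError("d must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("d must have a zero diagonal")
        if np.any(d < 0):
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "d", d)

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)


def fisher_z(r_value):
    """Fisher's variance-stabilizing transform ``z = atanh(r)``.

    Accepts scalars or arrays; values are clipped to ``+/-(1 - 1e-7)`` first
    so r = +/-1 maps to a large finite z rather than infinity. Odd and
    strictly increasing on its domain.
    """
    r = np.asarray(r_value, dtype=float)
    if np.any(np.abs(r) > 1):
        raise ValueError("correlation values must lie in [-1, 1]")
    z = np.arctanh(np.clip(r, -1 + FISHER_CLIP, 1 - FISHER_CLIP))
    return z.item() if np.isscalar(r_value) or r.ndim == 0 else z


def group_correlation(table: UptakeTable, group: str) -> GroupCorrelation:
    """Pearson correlation matrix of regional uptake within one group.

    Raises if the group has fewer than 3 subjects or if any region has zero
    variance within the group (the offending region is named).
    """
    values = table.group_values(group)
    if values.shape[0] < 3:
        raise ValueError(
            f"group {group!r} has {values.shape[0]} subjects; at least 3 required"
        )
    sd = values.std(axis=0)
    if np.any(sd == 0):
        bad = [lab for lab, s in zip(table.region_labels, sd) if s == 0]
        raise ValueError(f"zero-variance region(s) in group {group!r}: {', '.join(bad)}")
    r = np.corrcoef(values, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    z = fisher_z(r)
    np.fill_diagonal(z, 0.0)
    return GroupCorrelation(
        region_labels=table.region_labels,
        r=r,
        z=z,
        n_subjects=values.shape[0],
        group=group,
    )


def to_distance(corr: GroupCorrelation, metric_tag: str = "one_minus_r") -> DistanceMatrix:
    """Map a correlation matrix to a filtration distance matrix.

    ``one_minus_r`` uses ``d = 1 - r`` (so the display thresholds 0.1..0.6
    correspond to correlation cutoffs 0.9..0.4); ``sqrt_one_minus_r`` uses
    ``d = sqrt(1 - r)``. Both are strictly decreasing in r; negative
    correlations yield d > 1 and are retained, not truncated.
    """
    if metric_tag not in METRICS:
        raise ValueError(f"unknown metric_tag {metric_tag!r}; expected one of {METRICS}")
    base = 1.0 - corr.r
    d = np.sqrt(np.maximum(base, 0.0)) if metric_tag == "sqrt_one_minus_r" else base
    d = np.maximum((d + d.T) / 2.0, 0.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(region_labels=corr.region_labels, d=d, metric_tag=metric_tag)
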