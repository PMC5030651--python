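"""Group-label permutation tests for connectivity differences.

Because each group contributes a single correlation network, there is no
per-subject statistic to feed a parametric test: inference goes through
label permutation. Subjects are randomly reassigned to pseudo-groups of the
original sizes, the whole pipeline (correlation -> Fisher z, or correlation
-> distance -> single-linkage distance) is recomputed per pseudo-group, and
the observed lesion-minus-control difference of each region pair is ranked
within its permutation null. p-values use the add-one estimator
``(k + 1) / (B + 1)`` and are FDR-adjusted with Benjamini-Hochberg;
with 20 regions there are 190 pairs to correct over.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .connectivity import (
    METRICS,
    DistanceMatrix,
    fisher_z,
    group_correlation,
    to_distance,
)
from .filtration import single_linkage
from .synthetic_cohort import UptakeTable

logger = logging.getLogger(__name__)

STATISTICS = ("fisher_z", "sld")
SIDEDNESS = ("two_sided", "greater", "less")

#: exceedance comparisons use this slack so that permutations which exactly
#: recreate the observed grouping count as ties regardless of floating-point
#: summation order
TIE_TOL = 1e-12


@dataclass(frozen=True)
class PermutationComparison:
    """Observed group deltas with their permutation null summaries."""

    region_pairs: tuple[tuple[str, str], ...]
    observed_delta: np.ndarray
    null_exceed_count: np.ndarray
    B: int
    sidedness: str
    p: np.ndarray
    q: np.ndarray
    seed: int
    statistic: str
    metric_tag: str
    n_redrawn: int = 0

    def pair_index(self, a: str, b: str) -> int:
        pair = tuple(sorted((a, b)))
        try:
            return self.region_pairs.index(pair)  # type: ignore[arg-type]
        except ValueError:
            raise KeyError(f"unknown region pair {pair}") from None

    def p_of(self, a: str, b: str) -> float:
        return float(self.p[self.pair_index(a, b)])


def _condensed(matrix: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(matrix.shape[0], k=1)
    return matrix[iu]


def _group_stat(values: np.ndarray, labels: tuple[str, ...], statistic: str, metric_tag: str) -> np.ndarray:
    """Condensed per-pair statistic for one (pseudo-)group's subject rows."""
    r = np.corrcoef(values, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    if statistic == "fisher_z":
        return _condensed(fisher_z(r))
    base = 1.0 - r
    d = np.sqrt(np.maximum(base, 0.0)) if metric_tag == "sqrt_one_minus_r" else base
    d = np.maximum((d + d.T) / 2.0, 0.0)
    np.fill_diagonal(d, 0.0)
    dm = DistanceMatrix(region_labels=labels, d=d, metric_tag=metric_tag)
    return _condensed(single_linkage(dm).slm)


def _observed_stat(table: UptakeTable, group: str, statistic: str, metric_tag: str) -> np.ndarray:
    """Observed statistic via the public module pipeline (no drift vs null path)."""
    corr = group_correlation(table, group)
    if statistic == "fisher_z":
        return _condensed(corr.z)
    return _condensed(single_linkage(to_distance(corr, metric_tag)).slm)


def permute_deltas(
    table: UptakeTable,
    statistic: str = "fisher_z",
    metric_tag: str = "one_minus_r",
    B: int = 10_000,
    sidedness: str = "two_sided",
    seed: int = 0,
    control_group: str = "control",
    lesion_group: str = "lesion",
) -> PermutationComparison:
    """Permutation test of per-pair group differences.

    The observed delta is ``statistic(lesion) - statistic(control)``. Each of
    the ``B`` permutations draws ``rng.permutation(n_subjects)`` from
    ``numpy.random.default_rng(seed)`` and assigns the first ``n_control``
    shuffled rows to the pseudo-control group — the stream is therefore a
    deterministic function of (seed, B, subject order). Replicates in which
    a pseudo-group has a zero-variance region are redrawn (counted and
    logged), never silently skipped. Sidedness: ``greater`` asks whether the
    lesion statistic exceeds control (looser/longer in the lesion group),
    ``less`` the reverse, ``two_sided`` ranks ``|delta|``.
    """
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; expected one of {STATISTICS}")
    if sidedness not in SIDEDNESS:
        raise ValueError(f"unknown sidedness {sidedness!r}; expected one of {SIDEDNESS}")
    if metric_tag not in METRICS:
        raise ValueError(f"unknown metric_tag {metric_tag!r}")
    if B < 1:
        raise ValueError("B must be at least 1")

    labels = table.region_labels
    mask_control = np.array([g == control_group for g in table.group_label])
    mask_lesion = np.array([g == lesion_group for g in table.group_label])
    if not mask_control.any():
        raise KeyError(f"unknown group label: {control_group!r}")
    if not mask_lesion.any():
        raise KeyError(f"unknown group label: {lesion_group!r}")
    values = table.values[mask_control | mask_lesion]
    n_control = int(mask_control.sum())
    n_total = values.shape[0]

    observed = _observed_stat(table, lesion_group, statistic, metric_tag) - _observed_stat(
        table, control_group, statistic, metric_tag
    )

    rng = np.random.default_rng(seed)
    exceed = np.zeros(observed.shape[0], dtype=np.int64)
    n_redrawn = 0
    abs_observed = np.abs(observed)
    for b in range(B):
        while True:
            perm = rng.permutation(n_total)
            pseudo_control = values[perm[:n_control]]
            pseudo_lesion = values[perm[n_control:]]
            if pseudo_control.std(axis=0).min() > 0 and pseudo_lesion.std(axis=0).min() > 0:
                break
            n_redrawn += 1
            logger.warning("redrew permutation replicate with a zero-variance region")
        null = _group_stat(pseudo_lesion, labels, statistic, metric_tag) - _group_stat(
            pseudo_control, labels, statistic, metric_tag
        )
        if sidedness == "two_sided":
            exceed += np.abs(null) >= abs_observed - TIE_TOL
        elif sidedness == "greater":
            exceed += null >= observed - TIE_TOL
        else:
            exceed += null <= observed + TIE_TOL
        if (b + 1) % 1000 == 0:
            logger.info("permutation %d/%d", b + 1, B)

    p = (exceed + 1) / (B + 1)
    q = fdr_adjust(p)
    iu = np.triu_indices(len(labels), k=1)
    pairs = tuple(tuple(sorted((labels[i], labels[j]))) for i, j in zip(*iu))
    return PermutationComparison(
        region_pairs=pairs,  # type: ignore[arg-type]
        observed_delta=observed,
        null_exceed_count=exceed,
        B=B,
        sidedness=sidedness,
        p=p,
        q=q,
        seed=seed,
        statistic=statistic,
        metric_tag=metric_tag,
        n_redrawn=n_redrawn,
    )


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (monotone, order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def report_pairs(
    comparison: PermutationComparison,
    alpha_report: float = 0.05,
    alpha_highlight: float = 0.005,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Pairs below the reporting and highlighting thresholds.

    Mirrors the two-tier convention of reporting connections at p < 0.05 and
    singling out the most disrupted ones at p < 0.005. Both lists are sorted
    by ascending p, then lexicographically.
    """
    if alpha_highlight > alpha_report:
        raise ValueError("alpha_highlight must not exceed alpha_report")
    order = sorted(
        range(len(comparison.region_pairs)),
        key=lambda k: (comparison.p[k], comparison.region_pairs[k]),
    )
    reported = [comparison.region_pairs[k] for k in order if comparison.p[k] < alpha_report]
    highlighted = [comparison.region_pairs[k] for k in order if comparison.p[k] < alpha_highlight]
    return reported, highlighted
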