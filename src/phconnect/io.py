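"""Readers and writers for the pipeline's plain-text formats.

Uptake tables and matrices travel as UTF-8 CSV ('.' decimal separator);
labeled matrices carry ``# key: value`` comment headers so every file
declares the metric and seed it was produced under. Dendrograms are Newick,
trees are Pajek ``.net`` (see :mod:`.filtration` / :mod:`.mst`).
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .group_compare import PermutationComparison
from .synthetic_cohort import UptakeTable

SUBJECT_COL = "subject_id"
GROUP_COL = "group"


def write_uptake_csv(table: UptakeTable, path: str | Path) -> None:
    """Write an uptake table: subject_id, group, then one column per region."""
    df = pd.DataFrame(table.values, columns=list(table.region_labels))
    df.insert(0, GROUP_COL, list(table.group_label))
    df.insert(0, SUBJECT_COL, list(table.subject_ids))
    df.to_csv(path, index=False, float_format="%.17g")


def read_uptake_csv(path: str | Path) -> UptakeTable:
    """Read and validate an uptake CSV written by :func:`write_uptake_csv`.

    Rejects duplicate subject ids, a missing group column, fewer than two
    groups, and non-numeric or non-positive uptake cells — each error names
    the offending row/column.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file, header row required") from None
    if SUBJECT_COL not in df.columns:
        raise ValueError(f"{path}: missing required column {SUBJECT_COL!r}")
    if GROUP_COL not in df.columns:
        raise ValueError(f"{path}: missing required column {GROUP_COL!r}")
    region_cols = [c for c in df.columns if c not in (SUBJECT_COL, GROUP_COL)]
    if not region_cols:
        raise ValueError(f"{path}: no region columns found")
    subjects = df[SUBJECT_COL].tolist()
    dupes = {s for s in subjects if subjects.count(s) > 1}
    if dupes:
        raise ValueError(f"{path}: duplicate subject id(s): {', '.join(sorted(dupes))}")
    groups = df[GROUP_COL].tolist()
    if len(set(groups)) < 2:
        raise ValueError(f"{path}: at least two groups required, found {sorted(set(groups))}")
    values = np.empty((len(df), len(region_cols)), dtype=float)
    for j, col in enumerate(region_cols):
        for i, cell in enumerate(df[col]):
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric value {cell!r} at row {i + 2}, column {col!r}"
                ) from None
    bad = np.argwhere(~(np.isfinite(values) & (values > 0)))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"{path}: non-positive or non-finite uptake at row {i + 2}, "
            f"column {region_cols[j]!r}"
        )
    return UptakeTable(
        subject_ids=tuple(subjects),
        group_label=tuple(groups),
        region_labels=tuple(region_cols),
        values=values,
    )


def write_matrix_csv(
    labels: tuple[str, ...],
    matrix: np.ndarray,
    path: str | Path,
    metadata: dict[str, object] | None = None,
) -> None:
    """Write a labeled square matrix with ``# key: value`` metadata comments."""
    buf = _io.StringIO()
    for key, value in (metadata or {}).items():
        buf.write(f"# {key}: {value}\n")
    df = pd.DataFrame(np.asarray(matrix, float), index=list(labels), columns=list(labels))
    df.to_csv(buf, float_format="%.17g")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_matrix_csv(path: str | Path) -> tuple[tuple[str, ...], np.ndarray, dict[str, str]]:
    """Read a labeled square matrix plus its metadata comments."""
    metadata: dict[str, str] = {}
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    body_start = 0
    for body_start, line in enumerate(lines):
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition(":")
            metadata[key.strip()] = value.strip()
        else:
            break
    df = pd.read_csv(_io.StringIO("\n".join(lines[body_start:])), index_col=0)
    return tuple(df.columns), df.to_numpy(dtype=float), metadata


def write_comparison_csv(
    comparison: PermutationComparison,
    path: str | Path,
    alpha_report: float = 0.05,
    alpha_highlight: float = 0.005,
) -> None:
    """Long-format permutation results: one row per region pair."""
    rows = {
        "pair_i": [a for a, _ in comparison.region_pairs],
        "pair_j": [b for _, b in comparison.region_pairs],
        "statistic": comparison.statistic,
        "observed_delta": comparison.observed_delta,
        "p": comparison.p,
        "q": comparison.q,
        "significant_report": comparison.p < alpha_report,
        "significant_highlight": comparison.p < alpha_highlight,
    }
    buf = _io.StringIO()
    for key, value in (
        ("statistic", comparison.statistic),
        ("metric_tag", comparison.metric_tag),
        ("sidedness", comparison.sidedness),
        ("B", comparison.B),
        ("seed", comparison.seed),
        ("n_redrawn", comparison.n_redrawn),
    ):
        buf.write(f"# {key}: {value}\n")
    pd.DataFrame(rows).to_csv(buf, index=False, float_format="%.17g")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")
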