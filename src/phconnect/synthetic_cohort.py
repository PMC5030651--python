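"""Synthetic two-group uptake cohorts with known correlation structure.

The study design being emulated is a group-level metabolic-connectivity
experiment: each subject contributes one cerebellum-normalized mean uptake
value per volume of interest (VOI), and the network of interest is the
interregional correlation matrix computed *across* subjects within a group.
Because no real uptake tables ship with this package, every downstream stage
is exercised on cohorts drawn from a multivariate normal whose correlation
matrix is block-structured: regions inside an anatomical module (e.g. the
basal-ganglia structures of the cortico-striatal-thalamic loop) correlate at
``base_corr``, regions in different modules at ``cross_corr``, and selected
pairs may be weakened in the lesion group only (``disrupted_pairs``) to mimic
a focal loss of connectivity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

CONTROL = "control"
LESION = "lesion"

#: Bilateral structures of the cortico-striatal-thalamic loop used as the
#: default 20-region scheme: five subcortical loop structures (caudoputamen,
#: globus pallidus, substantia nigra, subthalamic nucleus, thalamus) and five
#: cortical areas (frontal, motor, somatosensory, auditory, visual cortex),
#: each split into right (R) and left (L) VOIs.
_DEFAULT_STRUCTURES = (
    ("CP", "basal_ganglia"),
    ("GP", "basal_ganglia"),
    ("SN", "basal_ganglia"),
    ("STN", "basal_ganglia"),
    ("THAL", "basal_ganglia"),
    ("FRO", "cortex"),
    ("MOT", "cortex"),
    ("SOM", "cortex"),
    ("AUD", "cortex"),
    ("VIS", "cortex"),
)


@dataclass(frozen=True)
class RegionScheme:
    """Ordered region labels with hemisphere tags and module assignments."""

    labels: tuple[str, ...]
    hemisphere: tuple[str, ...]
    module_id: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) == 0:
            raise ValueError("RegionScheme requires at least one region label")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("region labels must be unique")
        if any(not lab for lab in self.labels):
            raise ValueError("region labels must be non-empty")
        if len(self.hemisphere) != len(self.labels) or len(self.module_id) != len(self.labels):
            raise ValueError("hemisphere and module_id must have one entry per label")

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown region label: {label!r}") from None

    def module_members(self, module: str) -> tuple[str, ...]:
        return tuple(l for l, m in zip(self.labels, self.module_id) if m == module)

    @classmethod
    def default(cls) -> "RegionScheme":
        """The 20-VOI bilateral cortico-striatal-thalamic loop scheme."""
        labels, hemis, modules = [], [], []
        for name, module in _DEFAULT_STRUCTURES:
            for hemi in ("R", "L"):
                labels.append(f"{hemi}_{name}")
                hemis.append(hemi)
                modules.append(module)
        return cls(tuple(labels), tuple(hemis), tuple(modules))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the two-group cohort simulator.

    Parameters
    ----------
    scheme
        Region scheme; defaults to the 20-VOI bilateral loop.
    n_control, n_lesion
        Group sizes; defaults 10 and 14 mirror the study geometry of ten
        control and fourteen lesioned animals.
    base_corr, cross_corr
        Target Pearson correlation within and between anatomical modules.
    disrupted_pairs
        ``(region_a, region_b, target_corr)`` overrides applied to the
        *lesion* group's target matrix only.
    noise_sd
        Per-region uptake standard deviation in normalized SUV units.
    mean_uptake
        Per-region mean uptake (cerebellum-normalized SUV; ~1 by design).
    seed
        RNG seed; identical configs yield bit-identical tables.
    """

    scheme: RegionScheme = field(default_factory=RegionScheme.default)
    n_control: int = 10
    n_lesion: int = 14
    base_corr: float = 0.7
    cross_corr: float = 0.35
    disrupted_pairs: tuple[tuple[str, str, float], ...] = ()
    noise_sd: float = 0.1
    mean_uptake: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, value in (("base_corr", self.base_corr), ("cross_corr", self.cross_corr)):
            if not -1.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [-1, 1], got {value}")
        for a, b, target in self.disrupted_pairs:
            if not -1.0 <= target <= 1.0:
                raise ValueError(f"disrupted target for ({a}, {b}) must lie in [-1, 1]")
            self.scheme.index_of(a)
            self.scheme.index_of(b)
            if a == b:
                raise ValueError(f"disrupted pair ({a}, {b}) is not a pair")
        if self.n_control < 3 or self.n_lesion < 3:
            raise ValueError("each group needs at least 3 subjects for correlation")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.mean_uptake <= 0:
            raise ValueError("mean_uptake must be positive")


@dataclass(frozen=True)
class UptakeTable:
    """Subject-by-region matrix of normalized uptake values."""

    subject_ids: tuple[str, ...]
    group_label: tuple[str, ...]
    region_labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (len(self.subject_ids), len(self.region_labels)):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.region_labels)} regions"
            )
        if len(self.group_label) != len(self.subject_ids):
            raise ValueError("one group label per subject required")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("subject ids must be unique")
        if not np.all(np.isfinite(values)):
            raise ValueError("uptake values must be finite")
        if np.any(values <= 0):
            raise ValueError("uptake values must be strictly positive")

    @property
    def groups(self) -> tuple[str, ...]:
        seen: list[str] = []
        for g in self.group_label:
            if g not in seen:
                seen.append(g)
        return tuple(seen)

    def group_values(self, group: str) -> np.ndarray:
        """Rows of ``values`` belonging to ``group`` (order preserved)."""
        mask = np.array([g == group for g in self.group_label])
        if not mask.any():
            raise KeyError(f"unknown group label: {group!r}")
        return self.values[mask]


def _nearest_psd_correlation(matrix: np.ndarray, eig_floor: float = 1e-8) -> np.ndarray:
    """Repair an indefinite target matrix into a valid correlation matrix.

    Eigenvalues below ``eig_floor`` are clipped up to it, the matrix is
    reassembled and re-normalized to unit diagonal. Congruence with a
    diagonal matrix preserves positive semi-definiteness, so one pass
    suffices.
    """
    eigval, eigvec = np.linalg.eigh(matrix)
    clipped = np.maximum(eigval, eig_floor)
    repaired = (eigvec * clipped) @ eigvec.T
    diag = np.diag(repaired).copy()
    if np.any(diag <= eig_floor):
        raise ValueError("correlation target is not PSD-repairable (degenerate diagonal)")
    scale = 1.0 / np.sqrt(diag)
    repaired = repaired * np.outer(scale, scale)
    repaired = (repaired + repaired.T) / 2.0
    np.fill_diagonal(repaired, 1.0)
    return repaired


def build_target_correlation(config: SimulationConfig, group: str) -> np.ndarray:
    """Target correlation matrix for one group, PSD-repaired.

    The matrix is assembled from the block structure of the scheme
    (``base_corr`` within a module, ``cross_corr`` across), then — for the
    lesion group only — the ``disrupted_pairs`` overrides are applied, and
    finally the result is repaired to the nearest valid correlation matrix
    by eigenvalue clipping.
    """
    if group not in (CONTROL, LESION):
        raise KeyError(f"unknown group label: {group!r}")
    scheme = config.scheme
    modules = np.asarray(scheme.module_id, dtype=object)
    same_module = modules[:, None] == modules[None, :]
    target = np.where(same_module, config.base_corr, config.cross_corr).astype(float)
    np.fill_diagonal(target, 1.0)
    if group == LESION:
        for a, b, value in config.disrupted_pairs:
            i, j = scheme.index_of(a), scheme.index_of(b)
            target[i, j] = target[j, i] = value
    return _nearest_psd_correlation(target)


def lesion_disruption(
    scheme: RegionScheme | None = None, target_corr: float = 0.0
) -> tuple[tuple[str, str, float], ...]:
    """A disruption set shaped like the reported lesion-group findings.

    Weakens the right auditory cortex's correlations with bilateral frontal,
    right motor and bilateral visual cortices and with the left caudoputamen,
    mimicking the focal loosening of cortico-striatal connectivity observed
    in the lesioned animals.
    """
    scheme = scheme or RegionScheme.default()
    partners = ("R_FRO", "L_FRO", "R_MOT", "R_VIS", "L_VIS", "L_CP")
    pairs = tuple(("R_AUD", p, target_corr) for p in partners if p in scheme.labels)
    if not pairs:
        raise ValueError("scheme has none of the default disruption partners")
    return pairs


def simulate_cohort(config: SimulationConfig) -> UptakeTable:
    """Draw a two-group cohort from the configured correlation structure.

    Each group's subjects are independent draws from a multivariate normal
    with mean ``mean_uptake`` and covariance
    ``diag(noise_sd) @ R_group @ diag(noise_sd)``. The control group is drawn
    first, then the lesion group, from a single seeded generator, so the
    whole table is a deterministic function of the config. Draws are clipped
    at 1e-6 to keep normalized uptake strictly positive (vanishingly rare at
    the default mean/sd).
    """
    rng = np.random.default_rng(config.seed)
    n_regions = config.scheme.n_regions
    mean = np.full(n_regions, config.mean_uptake)
    sd = np.full(n_regions, config.noise_sd)

    blocks: list[np.ndarray] = []
    subject_ids: list[str] = []
    group_label: list[str] = []
    for group, n, prefix in ((CONTROL, config.n_control, "C"), (LESION, config.n_lesion, "P")):
        corr = build_target_correlation(config, group)
        cov = corr * np.outer(sd, sd)
        min_eig = np.linalg.eigvalsh(cov).min()
        if min_eig < -1e-10:
            raise ValueError(f"degenerate covariance for group {group!r}")
        draws = rng.multivariate_normal(mean, cov, size=n, method="eigh")
        n_clipped = int(np.sum(draws < 1e-6))
        if n_clipped:
            logger.warning("clipped %d non-positive draws in group %s", n_clipped, group)
        blocks.append(np.maximum(draws, 1e-6))
        subject_ids.extend(f"{prefix}{k + 1:02d}" for k in range(n))
        group_label.extend([group] * n)

    return UptakeTable(
        subject_ids=tuple(subject_ids),
        group_label=tuple(group_label),
        region_labels=config.scheme.labels,
        values=np.vstack(blocks),
    )


def null_config(config: SimulationConfig | None = None, seed: int | None = None) -> SimulationConfig:
    """The same cohort with no lesion effect (both groups share one structure)."""
    config = config or SimulationConfig()
    config = replace(config, disrupted_pairs=())
    if seed is not None:
        config = replace(config, seed=seed)
    return config
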