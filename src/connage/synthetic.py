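"""Synthetic cohort generation.

Generates cohorts of older adults with the statistical structure the
downstream analysis assumes: regional resting-state time series whose
covariance drifts with a latent "brain age", streamline-count structural
connectivity, tissue densities, and behavioural scales with realistic
marginals and per-scale missingness.  The generator plants a known
per-subject brain-age gap and a target resilience-gap correlation so that
every downstream stage (brain-age modelling, partial correlation, CCA,
k-means stratification) can be validated against ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BEHAVIOR_SCALES",
    "CohortConfig",
    "SubjectRecord",
    "generate_cohort",
    "exclusion_filter",
    "planted_features",
    "write_cohort",
    "read_cohort",
]


class ConfigurationError(ValueError):
    """Raised for invalid cohort configurations."""


#: Behavioural scale marginals: (mean, sd, low, high, integer-valued).
#: Means/SDs/ranges follow the study population this generator emulates
#: (community-dwelling older adults, Connor-Davidson resilience scale,
#: MOCA cognitive screening, and companion questionnaires).
BEHAVIOR_SCALES: dict[str, tuple[float, float, float, float, bool]] = {
    "Resilience": (65.4, 17.29, 0.0, 100.0, False),
    "Tenacity": (34.0, 9.5, 0.0, 52.0, False),
    "Strength": (21.0, 6.0, 0.0, 32.0, False),
    "Optimism": (10.4, 3.2, 0.0, 16.0, False),
    "MOCA": (21.78, 3.24, 0.0, 30.0, True),
    "PSQI": (6.20, 3.50, 1.0, 18.0, True),
    "IADL": (22.70, 0.59, 21.0, 23.0, True),
    "AD8": (1.51, 1.56, 0.0, 6.0, True),
    "GDS": (2.27, 1.46, 0.0, 5.0, True),
    "UCLA_LS": (31.28, 8.56, 20.0, 58.0, True),
    "PSS": (24.10, 7.40, 11.0, 47.0, True),
    "LSNS": (17.59, 4.86, 7.0, 29.0, True),
}

#: Default per-scale missingness, matching the per-scale n of the emulated
#: cohort (e.g. resilience observed for 70 of 93 participants).
DEFAULT_MISSINGNESS: dict[str, float] = {
    "Resilience": 23 / 93,
    "Tenacity": 23 / 93,
    "Strength": 23 / 93,
    "Optimism": 23 / 93,
    "PSQI": 1 / 93,
    "PSS": 5 / 93,
    "LSNS": 20 / 93,
}

EXCLUSION_RULES = ("missing_imaging", "head_motion", "gds")


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    ``signal_strength`` is the fraction of the age-sensitive connectivity
    loading carried by brain age (0 = no decodable age signal, 1 = fully
    age-driven); ``gap_sd`` is the SD in years of the planted brain-age gap;
    ``resilience_gap_corr`` is the planted (in-sample) correlation between
    the resilience score and the gap.
    """

    n_subjects: int = 93
    n_regions: int = 30
    n_timepoints: int = 265
    age_range: tuple[float, float] = (53.0, 76.0)
    gap_sd: float = 4.0
    signal_strength: float = 0.6
    noise_sd: float = 1.0
    resilience_gap_corr: float = -0.35
    missingness: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSINGNESS)
    )
    gds_threshold: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0 or self.n_regions <= 0 or self.n_timepoints <= 0:
            raise ConfigurationError("counts must be positive")
        lo, hi = self.age_range
        if not lo < hi:
            raise ConfigurationError(f"degenerate age range {self.age_range}")
        if not abs(self.resilience_gap_corr) < 1:
            raise ConfigurationError("|resilience_gap_corr| must be < 1")
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ConfigurationError("signal_strength must lie in [0, 1]")
        if self.gap_sd < 0 or self.noise_sd < 0:
            raise ConfigurationError("standard deviations must be nonnegative")
        for scale, p in self.missingness.items():
            if scale not in BEHAVIOR_SCALES:
                raise ConfigurationError(f"unknown behavioural scale {scale!r}")
            if not 0.0 <= p < 1.0:
                raise ConfigurationError(f"missingness for {scale!r} out of [0, 1)")


@dataclass
class SubjectRecord:
    """One participant's derived imaging matrices, covariates and scores."""

    subject_id: str
    age: float
    gender: str  # "M" / "F"
    education: float  # years
    time_series: np.ndarray  # T x R
    sc_counts: np.ndarray  # R x R symmetric, zero diagonal
    node_volumes: np.ndarray  # R positive
    tissue_density: np.ndarray  # 3 x R (GM, WM, CSF)
    behaviors: dict[str, float]  # NaN marks a missing score
    true_gap: float | None = None  # synthetic ground truth only

    @property
    def n_regions(self) -> int:
        return self.time_series.shape[1]


def _age_sensitive_regions(n_regions: int) -> np.ndarray:
    """Indices of the regions whose connectivity loading drifts with brain age.

    The first third of the regions (at least 2) carry the age signal; the
    rest load only on age-stable latent factors.
    """
    k = max(2, n_regions // 3)
    return np.arange(k)


def planted_features(n_regions: int) -> set[str]:
    """Feature names carrying planted brain-age signal, in the naming scheme
    of the feature-assembly stage (``sc:i-j``, ``fc:i-j``, ``gm:k``).

    A connectivity feature is planted when both endpoints are age-sensitive;
    a grey-matter density feature is planted when its region is.
    """
    sens = set(_age_sensitive_regions(n_regions).tolist())
    out: set[str] = set()
    for i in range(n_regions):
        for j in range(i + 1, n_regions):
            if i in sens and j in sens:
                out.add(f"sc:{i}-{j}")
                out.add(f"fc:{i}-{j}")
    out.update(f"gm:{k}" for k in sens)
    return out


def _truncated_scores(
    rng: np.random.Generator, latent: np.ndarray, scale: str
) -> np.ndarray:
    """Map a standardized latent vector onto a scale's marginal:
    mean + sd * latent, clipped to the scale's range, rounded if integer."""
    mean, sd, lo, hi, integer = BEHAVIOR_SCALES[scale]
    vals = np.clip(mean + sd * latent, lo, hi)
    if integer:
        vals = np.round(vals)
    return vals


def _plant_correlation(
    rng: np.random.Generator,
    anchor: np.ndarray,
    rho: float,
    observed: np.ndarray | None = None,
) -> np.ndarray:
    """Return a standardized vector whose sample correlation with ``anchor``
    equals ``rho`` exactly (Gram-Schmidt construction).

    When ``observed`` is given, the correlation is planted exactly over that
    boolean subset (the rows a downstream listwise-deleting analysis will
    actually see); the remaining entries follow the same construction on
    their own subset.
    """

    def planted(idx: np.ndarray) -> np.ndarray:
        a = anchor[idx].astype(float)
        if a.std() == 0:
            return rng.standard_normal(idx.size)
        a = (a - a.mean()) / a.std()
        eps = rng.standard_normal(idx.size)
        eps -= eps.mean()
        eps -= a * (eps @ a) / (a @ a)  # orthogonalize in-sample
        eps /= eps.std()
        return rho * a + np.sqrt(1.0 - rho**2) * eps

    n = anchor.size
    if observed is None:
        return planted(np.arange(n))
    out = np.empty(n)
    obs_idx = np.flatnonzero(observed)
    mis_idx = np.flatnonzero(~observed)
    if obs_idx.size >= 3:
        out[obs_idx] = planted(obs_idx)
    else:
        out[obs_idx] = rng.standard_normal(obs_idx.size)
    if mis_idx.size >= 3:
        out[mis_idx] = planted(mis_idx)
    elif mis_idx.size:
        out[mis_idx] = rng.standard_normal(mis_idx.size)
    return out


def generate_cohort(config: CohortConfig) -> list[SubjectRecord]:
    """Generate a deterministic synthetic cohort.

    Each subject's brain age is chronological age plus a planted Gaussian
    gap.  Regional time series follow a 3-factor latent model: two factors
    have age-stable loadings, one factor's loadings over the age-sensitive
    regions scale linearly with standardized brain age, mixed by
    ``signal_strength``.  Streamline counts and grey-matter density inherit
    the same age dependence, so connectivity, SC and GM features are all
    age-decodable when ``signal_strength > 0``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, R, T = cfg.n_subjects, cfg.n_regions, cfg.n_timepoints
    lo, hi = cfg.age_range

    ages = rng.uniform(lo, hi, size=n)
    gaps = rng.normal(0.0, cfg.gap_sd, size=n) if cfg.gap_sd > 0 else np.zeros(n)
    brain_age = ages + gaps
    ba_z = (brain_age - brain_age.mean()) / (brain_age.std() + 1e-12)

    genders = np.where(rng.random(n) < 33 / 93, "M", "F")
    education = np.clip(rng.normal(9.0, 4.0, size=n), 0.0, 22.0)

    sens = _age_sensitive_regions(R)
    # Age-stable factor loadings, fixed across the cohort.
    base_loadings = rng.normal(0.0, 1.0, size=(R, 3))
    # Age-sensitive direction for factor 0 over the sensitive regions.
    age_dir = rng.normal(0.0, 1.0, size=sens.size)
    age_dir /= np.linalg.norm(age_dir) / np.sqrt(sens.size)

    s = cfg.signal_strength
    gap_z = (
        (gaps - gaps.mean()) / gaps.std() if gaps.std() > 0 else np.zeros(n)
    )

    # Behavioural latents -------------------------------------------------
    miss_mask: dict[str, np.ndarray] = {
        scale: rng.random(n) < p for scale, p in cfg.missingness.items()
    }
    res_observed = ~miss_mask.get("Resilience", np.zeros(n, dtype=bool))
    res_latent = _plant_correlation(
        rng, gaps, cfg.resilience_gap_corr, observed=res_observed
    )
    # Subscales: noisy copies of the overall resilience latent.
    sub_latents = {
        name: 0.85 * res_latent
        + np.sqrt(1 - 0.85**2) * rng.standard_normal(n)
        for name in ("Tenacity", "Strength", "Optimism")
    }
    # MOCA: low scores co-occur with high planted gap and low resilience.
    moca_signal = -0.45 * gap_z + 0.35 * res_latent
    moca_latent = moca_signal / (moca_signal.std() + 1e-12) * 0.8 + np.sqrt(
        1 - 0.8**2
    ) * rng.standard_normal(n)

    behaviors_matrix: dict[str, np.ndarray] = {
        "Resilience": _truncated_scores(rng, res_latent, "Resilience"),
        "MOCA": _truncated_scores(rng, moca_latent, "MOCA"),
    }
    for name, lat in sub_latents.items():
        behaviors_matrix[name] = _truncated_scores(rng, lat, name)
    for scale in ("PSQI", "IADL", "AD8", "GDS", "UCLA_LS", "PSS", "LSNS"):
        # Mildly load the remaining scales on the same latents so CCA and
        # k-means stages see realistic cross-scale structure.
        sign = -1.0 if scale in ("IADL", "LSNS") else 1.0
        lat = sign * (0.3 * gap_z - 0.3 * res_latent) + 0.9 * rng.standard_normal(n)
        behaviors_matrix[scale] = _truncated_scores(
            rng, lat / (lat.std() + 1e-12), scale
        )

    subjects: list[SubjectRecord] = []
    width = len(str(n))
    for idx in range(n):
        # Per-subject loadings: factor 0 gains an age-scaled component on
        # the sensitive regions; mixing controlled by signal_strength.
        loadings = base_loadings.copy()
        load0 = loadings[:, 0].copy()
        load0[sens] = (
            np.sqrt(1 - s) * load0[sens] + np.sqrt(s) * age_dir * (1.0 + ba_z[idx])
        )
        loadings[:, 0] = load0

        factors = rng.standard_normal((T, 3))
        ts = factors @ loadings.T + cfg.noise_sd * rng.standard_normal((T, R))

        # Streamline counts: low-rank positive structure with the same
        # age-dependent loadings plus Poisson sampling noise.
        gram = np.abs(loadings @ loadings.T)
        np.fill_diagonal(gram, 0.0)
        lam = 20.0 * gram / (gram.max() + 1e-12)
        counts = rng.poisson(lam)
        counts = np.triu(counts, 1)
        counts = (counts + counts.T).astype(float)

        volumes = np.exp(rng.normal(np.log(5.0), 0.25, size=R))

        gm = np.clip(0.6 + 0.05 * rng.standard_normal(R), 0.05, 1.0)
        # GM density declines with brain age over the sensitive regions.
        gm[sens] = np.clip(
            0.6 - 0.08 * s * ba_z[idx] + 0.03 * rng.standard_normal(sens.size),
            0.05,
            1.0,
        )
        wm = np.clip(0.3 + 0.05 * rng.standard_normal(R), 0.02, 1.0)
        csf = np.clip(0.1 + 0.03 * rng.standard_normal(R), 0.01, 1.0)
        density = np.vstack([gm, wm, csf])

        behaviors = {}
        for scale in BEHAVIOR_SCALES:
            val = float(behaviors_matrix[scale][idx])
            if scale in miss_mask and miss_mask[scale][idx]:
                val = float("nan")
            behaviors[scale] = val

        subjects.append(
            SubjectRecord(
                subject_id=f"sub-{idx + 1:0{width}d}",
                age=float(ages[idx]),
                gender=str(genders[idx]),
                education=float(education[idx]),
                time_series=ts,
                sc_counts=counts,
                node_volumes=volumes,
                tissue_density=density,
                behaviors=behaviors,
                true_gap=float(gaps[idx]),
            )
        )
    return subjects


def exclusion_filter(
    cohort: Sequence[SubjectRecord],
    rules: Mapping[str, Sequence[bool]],
) -> tuple[list[SubjectRecord], dict[str, int]]:
    """Remove subjects flagged by any exclusion rule.

    ``rules`` maps a rule name (one of ``missing_imaging``, ``head_motion``,
    ``gds``) to a per-subject boolean flag.  Returns the retained subjects
    and, per rule in application order, the count of subjects newly removed
    by that rule (a subject flagged by several rules is counted once, under
    the first rule that flags it).
    """
    for name in rules:
        if name not in EXCLUSION_RULES:
            raise ValueError(
                f"unknown exclusion rule {name!r}; known rules: {EXCLUSION_RULES}"
            )
    n = len(cohort)
    removed = np.zeros(n, dtype=bool)
    counts: dict[str, int] = {}
    for name in EXCLUSION_RULES:
        if name not in rules:
            continue
        flags = np.asarray(rules[name], dtype=bool)
        if flags.shape != (n,):
            raise ValueError(f"rule {name!r} must provide one flag per subject")
        newly = flags & ~removed
        counts[name] = int(newly.sum())
        removed |= flags
    retained = [s for s, r in zip(cohort, removed) if not r]
    return retained, counts


# ---------------------------------------------------------------------------
# Cohort directory I/O


def write_cohort(cohort: Sequence[SubjectRecord], directory: str | Path) -> Path:
    """Write a cohort directory: manifest.csv plus per-subject tab-delimited
    matrices (ts_<id>.tsv, sc_<id>.tsv, volumes_<id>.tsv, density_<id>.tsv)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort:
        row: dict[str, object] = {
            "subject_id": s.subject_id,
            "age": s.age,
            "gender": s.gender,
            "education": s.education,
        }
        for scale in BEHAVIOR_SCALES:
            v = s.behaviors.get(scale, float("nan"))
            row[scale] = "" if (v is None or np.isnan(v)) else v
        if s.true_gap is not None:
            row["true_gap"] = s.true_gap
        rows.append(row)
        np.savetxt(directory / f"ts_{s.subject_id}.tsv", s.time_series, delimiter="\t")
        np.savetxt(directory / f"sc_{s.subject_id}.tsv", s.sc_counts, delimiter="\t")
        np.savetxt(
            directory / f"volumes_{s.subject_id}.tsv", s.node_volumes, delimiter="\t"
        )
        np.savetxt(
            directory / f"density_{s.subject_id}.tsv", s.tissue_density, delimiter="\t"
        )
    pd.DataFrame(rows).to_csv(directory / "manifest.csv", index=False)
    return directory


def read_cohort(directory: str | Path) -> list[SubjectRecord]:
    """Read a cohort directory written by :func:`write_cohort`."""
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    subjects = []
    for _, row in manifest.iterrows():
        sid = str(row["subject_id"])
        behaviors = {
            scale: float(row[scale]) if scale in row and pd.notna(row[scale]) else float("nan")
            for scale in BEHAVIOR_SCALES
        }
        true_gap = float(row["true_gap"]) if "true_gap" in row and pd.notna(row["true_gap"]) else None
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                age=float(row["age"]),
                gender=str(row["gender"]),
                education=float(row["education"]),
                time_series=np.loadtxt(directory / f"ts_{sid}.tsv", ndmin=2),
                sc_counts=np.loadtxt(directory / f"sc_{sid}.tsv", ndmin=2),
                node_volumes=np.atleast_1d(
                    np.loadtxt(directory / f"volumes_{sid}.tsv")
                ),
                tissue_density=np.loadtxt(directory / f"density_{sid}.tsv", ndmin=2),
                behaviors=behaviors,
                true_gap=true_gap,
            )
        )
    return subjects
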