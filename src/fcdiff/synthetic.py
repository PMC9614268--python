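"""Synthetic two-group cohorts of ROI time series with planted connectivity differences.

The generator emulates a resting-state functional-connectivity study: each
subject contributes a T x R matrix of ROI time series drawn from a stationary
zero-mean multivariate Gaussian whose correlation structure is shared within a
group.  The two groups share a sparse inverse-covariance backbone; a
configurable set of "planted" edges differ in correlation strength between the
groups, providing ground truth for every downstream recovery test.

A direct Bernoulli edge-indicator generator (:func:`generate_binary_cohort`)
is also provided so the prevalence Score statistic can be tested without going
through time series at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticConfig",
    "Subject",
    "CohortTimeSeries",
    "make_group_covariances",
    "generate_cohort",
    "generate_binary_cohort",
    "write_cohort",
    "read_cohort",
    "write_truth",
    "read_truth",
]

#: Minimum eigenvalue enforced when repairing a planted covariance matrix.
EIG_FLOOR = 1e-3


@dataclass
class SyntheticConfig:
    """Parameters of a simulated two-group cohort.

    Defaults mirror a 142 patient / 102 control resting-state cohort scanned
    at 150 time points, summarised on a 32-region functional network template
    (246-region atlas scale is supported via ``n_rois=246``).
    """

    n_group1: int = 142
    n_group2: int = 102
    n_rois: int = 32
    n_timepoints: int = 150
    planted_edges: list[tuple[int, int, float]] = field(default_factory=list)
    base_sparsity: float = 0.1
    noise_sd: float = 1.0
    ar_coeff: float = 0.0
    seed: int = 0
    group_labels: tuple[str, str] = ("patient", "control")

    def validate(self) -> None:
        if self.n_group1 < 2 or self.n_group2 < 2:
            raise ValueError("each group needs at least 2 subjects")
        if self.n_timepoints < 10:
            raise ValueError("n_timepoints must be >= 10")
        if self.n_rois < 2:
            raise ValueError("n_rois must be >= 2")
        if not 0.0 <= self.base_sparsity <= 1.0:
            raise ValueError("base_sparsity must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not -1.0 < self.ar_coeff < 1.0:
            raise ValueError("ar_coeff must be in (-1, 1)")
        seen = set()
        for i, j, delta in self.planted_edges:
            if not (0 <= i < j < self.n_rois):
                raise ValueError(f"planted edge ({i},{j}) must satisfy 0 <= i < j < n_rois")
            if (i, j) in seen:
                raise ValueError(f"planted edge ({i},{j}) listed twice")
            if not -0.6 <= delta <= 0.6:
                raise ValueError(f"planted delta {delta} outside [-0.6, 0.6]")
            seen.add((i, j))


@dataclass
class Subject:
    subject_id: str
    label: str
    series: np.ndarray  # T x R


@dataclass
class CohortTimeSeries:
    """Per-subject ROI time series plus group labels; the pipeline entry point."""

    subjects: list[Subject]
    roi_names: list[str]

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.subjects])

    def series_list(self) -> list[np.ndarray]:
        return [s.series for s in self.subjects]


def _rng_for(config: SyntheticConfig, stream: int) -> np.random.Generator:
    # independent reproducible streams for covariance construction vs sampling
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(stream,)))


def _random_sparse_precision(n: int, sparsity: float, rng: np.random.Generator) -> np.ndarray:
    """Sparse symmetric positive-definite precision matrix on the correlation scale."""
    theta = np.eye(n)
    iu, ju = np.triu_indices(n, k=1)
    on = rng.random(iu.size) < sparsity
    vals = rng.uniform(0.2, 0.4, size=iu.size) * rng.choice([-1.0, 1.0], size=iu.size)
    theta[iu[on], ju[on]] = vals[on]
    theta[ju[on], iu[on]] = vals[on]
    lam_min = np.linalg.eigvalsh(theta)[0]
    if lam_min < 0.1:
        theta += (0.1 - lam_min) * np.eye(n)
    return theta


def _cov_to_corr(sigma: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(sigma))
    corr = sigma / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    return (corr + corr.T) / 2.0


def _spd_repair(sigma: np.ndarray, floor: float = EIG_FLOOR) -> np.ndarray:
    """Smallest-lambda ridge (Sigma + lam*I)/(1 + lam) pushing min eigenvalue to floor."""
    lam_min = np.linalg.eigvalsh(sigma)[0]
    if lam_min >= floor:
        return sigma
    lam = (floor - lam_min) / (1.0 - floor)
    out = (sigma + lam * np.eye(sigma.shape[0])) / (1.0 + lam)
    np.fill_diagonal(out, 1.0)
    return out


def make_group_covariances(
    config: SyntheticConfig,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Build the two group correlation matrices and the planted-edge truth table.

    Both matrices are symmetric positive definite with unit diagonal.  The
    group-2 matrix differs from group 1 only at the planted edges, up to the
    minimal ridge repair needed to restore positive definiteness; the achieved
    correlation deltas after repair are recorded in the returned truth table
    (columns ``i, j, delta_requested, delta_achieved``).

    Raises ``ValueError`` if a planted delta would push a correlation outside
    (-1, 1) or if repair cannot restore positive definiteness.
    """
    config.validate()
    rng = _rng_for(config, 0)
    theta = _random_sparse_precision(config.n_rois, config.base_sparsity, rng)
    sigma1 = _cov_to_corr(np.linalg.inv(theta))
    sigma1 = _spd_repair(sigma1)

    delta_mat = np.zeros_like(sigma1)
    for i, j, delta in config.planted_edges:
        target = sigma1[i, j] + delta
        if abs(target) >= 0.99:
            raise ValueError(
                f"planted delta {delta:+.3f} on edge ({i},{j}) drives correlation to "
                f"{target:.3f}, outside the representable range"
            )
        delta_mat[i, j] = delta_mat[j, i] = delta

    # repair by shrinking the planted deltas (largest gamma in (0,1] keeping
    # the minimum eigenvalue at the floor), so that non-planted edges remain
    # exactly equal between groups and ground-truth null edges stay null
    def _eigmin(gamma: float) -> float:
        return float(np.linalg.eigvalsh(sigma1 + gamma * delta_mat)[0])

    gamma = 1.0
    if config.planted_edges and _eigmin(1.0) < EIG_FLOOR:
        lo, hi = 0.0, 1.0
        for _ in range(60):
            mid = (lo + hi) / 2
            if _eigmin(mid) >= EIG_FLOOR:
                lo = mid
            else:
                hi = mid
        gamma = lo
        if gamma < 0.05:
            raise ValueError("planted deltas cannot yield an SPD matrix after shrinkage repair")
    sigma2 = sigma1 + gamma * delta_mat

    rows = [
        {
            "i": i,
            "j": j,
            "delta_requested": delta,
            "delta_achieved": sigma2[i, j] - sigma1[i, j],
        }
        for i, j, delta in config.planted_edges
    ]
    truth = pd.DataFrame(rows, columns=["i", "j", "delta_requested", "delta_achieved"])
    return sigma1, sigma2, truth


def _sample_series(
    n_t: int, chol: np.ndarray, ar: float, rng: np.random.Generator
) -> np.ndarray:
    eps = rng.standard_normal((n_t, chol.shape[0])) @ chol.T
    if ar == 0.0:
        return eps
    # stationary AR(1) over time with the same marginal covariance
    x = np.empty_like(eps)
    x[0] = eps[0]
    scale = np.sqrt(1.0 - ar * ar)
    for t in range(1, n_t):
        x[t] = ar * x[t - 1] + scale * eps[t]
    return x


def generate_cohort(config: SyntheticConfig) -> CohortTimeSeries:
    """Draw a reproducible two-group cohort of multivariate-normal time series."""
    config.validate()
    sigma1, sigma2, _ = make_group_covariances(config)
    rng = _rng_for(config, 1)
    chol1 = np.linalg.cholesky(config.noise_sd**2 * sigma1)
    chol2 = np.linalg.cholesky(config.noise_sd**2 * sigma2)
    roi_names = [f"roi{r:03d}" for r in range(config.n_rois)]
    subjects: list[Subject] = []
    counter = 0
    for chol, n_sub, label in (
        (chol1, config.n_group1, config.group_labels[0]),
        (chol2, config.n_group2, config.group_labels[1]),
    ):
        for _ in range(n_sub):
            series = _sample_series(config.n_timepoints, chol, config.ar_coeff, rng)
            subjects.append(Subject(f"sub-{counter:04d}", label, series))
            counter += 1
    return CohortTimeSeries(subjects, roi_names)


def generate_binary_cohort(
    n1: int,
    n2: int,
    n_edges: int,
    prevalence1: float | Sequence[float],
    prevalence2: float | Sequence[float],
    seed: int = 0,
    group_labels: tuple[str, str] = ("patient", "control"),
) -> tuple[np.ndarray, np.ndarray]:
    """Bernoulli edge-indicator cohort: (n1+n2) x n_edges binary matrix + labels.

    Each subject's edge indicators are drawn independently with the prevalence
    vector of its group.  Scalar prevalences broadcast over edges.
    """
    p1 = np.broadcast_to(np.asarray(prevalence1, dtype=float), (n_edges,)).copy()
    p2 = np.broadcast_to(np.asarray(prevalence2, dtype=float), (n_edges,)).copy()
    if p1.shape != p2.shape:
        raise ValueError("prevalence vectors must have the same length")
    for p in (p1, p2):
        if np.any((p < 0) | (p > 1)):
            raise ValueError("prevalences must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    x1 = (rng.random((n1, n_edges)) < p1).astype(np.uint8)
    x2 = (rng.random((n2, n_edges)) < p2).astype(np.uint8)
    labels = np.array([group_labels[0]] * n1 + [group_labels[1]] * n2)
    return np.vstack([x1, x2]), labels


# ---------------------------------------------------------------------------
# Cohort I/O: one TSV per subject plus a manifest TSV (subject_id, label, path)
# ---------------------------------------------------------------------------

def write_cohort(cohort: CohortTimeSeries, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sub in cohort.subjects:
        fname = f"{sub.subject_id}.tsv"
        pd.DataFrame(sub.series, columns=cohort.roi_names).to_csv(
            outdir / fname, sep="\t", index=False, float_format="%.8g"
        )
        rows.append({"subject_id": sub.subject_id, "label": sub.label, "path": fname})
    manifest = outdir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def read_cohort(manifest_path: str | Path) -> CohortTimeSeries:
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    manifest = pd.read_csv(manifest_path, sep="\t", dtype={"subject_id": str, "label": str})
    subjects = []
    roi_names: list[str] | None = None
    for row in manifest.itertuples(index=False):
        df = pd.read_csv(base / row.path, sep="\t")
        if roi_names is None:
            roi_names = list(df.columns)
        elif list(df.columns) != roi_names:
            raise ValueError(f"subject {row.subject_id} has mismatched ROI columns")
        subjects.append(Subject(row.subject_id, row.label, df.to_numpy(dtype=float)))
    if roi_names is None:
        raise ValueError("empty manifest")
    labels = {s.label for s in subjects}
    if len(labels) != 2:
        raise ValueError(f"cohort must contain exactly two groups, found {sorted(labels)}")
    return CohortTimeSeries(subjects, roi_names)


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
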