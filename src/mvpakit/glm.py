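"""Trial-wise first-level GLM (least-squares-all beta series).

Each run is fit independently by ordinary least squares: one HRF-convolved
boxcar regressor per trial (code-display phase only; fixation and response
phases are not modeled), six motion regressors, a discrete-cosine high-pass
drift basis (default cutoff 128 s), and a constant.  Trial coefficients are
concatenated across runs in schedule order, yielding one beta volume per
trial (216 for the default 6 x 36 design).

The first volumes of each run cover a dummy trial and are discarded before
design construction; trial onsets are shifted accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gamma as gamma_dist

from .design import StimulusSchedule, TRIAL_S, FIXATION_S, CODE_S

__all__ = [
    "GlmConfig",
    "DesignMatrix",
    "canonical_hrf",
    "dct_drift_basis",
    "build_design_matrix",
    "fit_glm",
]


@dataclass(frozen=True)
class GlmConfig:
    """First-level model options.

    HRF parameters follow the double-gamma convention: response peak delay
    6 s, undershoot delay 16 s, undershoot ratio 1/6 (shape parameters with
    unit dispersion).
    """

    highpass_cutoff_s: float = 128.0
    hrf_peak_delay: float = 6.0
    hrf_undershoot_delay: float = 16.0
    hrf_undershoot_ratio: float = 1.0 / 6.0
    include_motion: bool = True


def canonical_hrf(tr: float, duration: float = 32.0, peak_delay: float = 6.0,
                  undershoot_delay: float = 16.0,
                  undershoot_ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Double-gamma hemodynamic response sampled at the TR, unit peak.

    h(t) = gamma_pdf(t; peak_delay) - ratio * gamma_pdf(t; undershoot_delay),
    scaled so max h = 1.  Peaks near 5 s for the default (6, 16, 1/6).
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    if duration < 10.0:
        raise ValueError("HRF window below 10 s truncates the response")
    t = np.arange(0, duration + tr / 2, tr)
    h = (gamma_dist.pdf(t, peak_delay)
         - undershoot_ratio * gamma_dist.pdf(t, undershoot_delay))
    return h / h.max()


def dct_drift_basis(n_volumes: int, tr: float, cutoff_s: float) -> np.ndarray:
    """Discrete-cosine high-pass regressors with period above the cutoff.

    Returns an (n_volumes, K) array with K = floor(2 * n_volumes * tr /
    cutoff); columns are mutually orthogonal.  K may be zero.
    """
    if cutoff_s <= 2 * tr:
        raise ValueError("cutoff must exceed twice the TR")
    k_max = int(np.floor(2.0 * n_volumes * tr / cutoff_s))
    n = np.arange(n_volumes)
    cols = [np.sqrt(2.0 / n_volumes)
            * np.cos(np.pi * k * (2 * n + 1) / (2 * n_volumes))
            for k in range(1, k_max + 1)]
    if not cols:
        return np.empty((n_volumes, 0))
    return np.column_stack(cols)


@dataclass(frozen=True)
class DesignMatrix:
    matrix: np.ndarray  # (n_volumes, n_regressors)
    labels: tuple[str, ...]  # per column: trial_<k> | motion_<k> | drift_<k> | constant

    @property
    def trial_columns(self) -> np.ndarray:
        return np.array([i for i, l in enumerate(self.labels)
                         if l.startswith("trial_")])


def build_design_matrix(run_schedule, n_volumes: int, tr: float,
                        motion: np.ndarray | None = None,
                        config: GlmConfig | None = None,
                        dummy_duration_s: float = TRIAL_S) -> DesignMatrix:
    """Design for one run: per-trial HRF regressors + motion + drift + constant.

    ``run_schedule`` is the run's slice of the schedule entries (one row per
    trial, with ``onset`` in original run time).  Onsets are shifted by the
    discarded dummy duration before sampling.
    """
    config = config or GlmConfig()
    if motion is not None and motion.shape != (n_volumes, 6):
        raise ValueError(
            f"motion table must be ({n_volumes}, 6), got {motion.shape}")
    hrf = canonical_hrf(tr, peak_delay=config.hrf_peak_delay,
                        undershoot_delay=config.hrf_undershoot_delay,
                        undershoot_ratio=config.hrf_undershoot_ratio)
    cols, labels = [], []
    onsets = run_schedule["onset"].to_numpy(dtype=float) - dummy_duration_s
    for k, onset in enumerate(onsets):
        code_onset = onset + FIXATION_S
        if code_onset + CODE_S > n_volumes * tr:
            raise ValueError(f"trial {k} onset beyond run end")
        box = np.zeros(n_volumes)
        on = int(round(code_onset / tr))
        off = int(round((code_onset + CODE_S) / tr))
        box[on:off] = 1.0
        cols.append(np.convolve(box, hrf)[:n_volumes])
        labels.append(f"trial_{k}")
    if config.include_motion and motion is not None:
        for k in range(6):
            cols.append(motion[:, k])
            labels.append(f"motion_{k}")
    drift = dct_drift_basis(n_volumes, tr, config.highpass_cutoff_s)
    for k in range(drift.shape[1]):
        cols.append(drift[:, k])
        labels.append(f"drift_{k}")
    cols.append(np.ones(n_volumes))
    labels.append("constant")
    return DesignMatrix(matrix=np.column_stack(cols), labels=tuple(labels))


def fit_glm(bold, designs: list[DesignMatrix], schedule: StimulusSchedule,
            mask: np.ndarray | None = None):
    """Per-run OLS over in-mask voxels; returns the trial beta series.

    ``bold`` is a BoldRuns object; the leading dummy volumes of each run are
    discarded before fitting.  Raises on rank-deficient designs, naming the
    collinear columns.
    """
    from .cohort import BetaSeries  # circular-import guard

    geometry = bold.geometry
    mask = geometry.mask if mask is None else mask
    mask_idx = np.flatnonzero(mask.ravel())
    betas = []
    for run_i, (vol, dm) in enumerate(zip(bold.runs, designs), start=1):
        y = vol[bold.n_dummy_volumes:]
        if dm.matrix.shape[0] != y.shape[0]:
            raise ValueError(
                f"run {run_i}: design rows {dm.matrix.shape[0]} != retained "
                f"volumes {y.shape[0]}")
        X = dm.matrix
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            bad = _collinear_columns(X, dm.labels)
            raise np.linalg.LinAlgError(
                f"run {run_i}: rank-deficient design (rank {rank} < "
                f"{X.shape[1]}); collinear columns: {bad}")
        yf = y.reshape(y.shape[0], -1)[:, mask_idx]
        coef, *_ = np.linalg.lstsq(X, yf, rcond=None)
        trial_coef = coef[dm.trial_columns]  # (n_trials_run, n_mask)
        full = np.zeros((trial_coef.shape[0],) + tuple(geometry.shape))
        full.reshape(trial_coef.shape[0], -1)[:, mask_idx] = trial_coef
        betas.append(full)
    data = np.concatenate(betas, axis=0)
    ent = schedule.entries
    return BetaSeries(data=data, mask=mask,
                      run_labels=ent["run"].to_numpy(),
                      categories=ent["category"].to_numpy(),
                      subcategories=ent["subcategory"].to_numpy(),
                      geometry=geometry)


def _collinear_columns(X: np.ndarray, labels: tuple[str, ...]) -> list[str]:
    """Name columns involved in a rank deficiency via the QR diagonal."""
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    return [labels[i] for i in np.flatnonzero(diag < tol)]
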