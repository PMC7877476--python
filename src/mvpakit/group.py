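"""Group-level (second-level) inference on searchlight accuracy maps.

Subject accuracy maps are smoothed with a 6-mm-FWHM Gaussian kernel and
submitted to random-effects tests: a one-sample t test of accuracy against
the chance level at every voxel, and a voxel-wise Pearson correlation between
decoding accuracy and a behavioral covariate.  Familywise error is controlled
by max-statistic permutation — sign flips of (map - chance) for the t test,
permutations of the behavioral scores for the correlation — rather than
random-field theory: exact under exchangeability and testable at small grid
sizes.  Cluster-extent inference thresholds the statistic map at an
uncorrected one-sided p (default 0.001), labels 18-connected components, and
compares extents against the permutation null of the maximum cluster size.

Both tests are one-sided (accuracy > chance, r > 0), matching the directional
hypotheses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "GroupConfig",
    "GroupResult",
    "smooth_map",
    "one_sample_t_map",
    "correlation_map",
    "r_to_t",
    "voxel_fwe",
    "cluster_fwe",
    "conjunction",
    "run_group_analysis",
]

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548


@dataclass(frozen=True)
class GroupConfig:
    fwhm_mm: float = 6.0
    voxel_mm: float = 2.0
    voxel_alpha: float = 0.05
    cluster_forming_p: float = 0.001  # one-sided
    cluster_alpha: float = 0.05
    connectivity: int = 18
    n_perm: int = 1000
    seed: int = 0

    def __post_init__(self):
        for a in (self.voxel_alpha, self.cluster_alpha):
            if not 0 < a <= 1:
                raise ValueError("alpha must be in (0, 1]")
        if self.fwhm_mm < 0:
            raise ValueError("FWHM must be non-negative")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")


def _connectivity_structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[connectivity])


def smooth_map(vol: np.ndarray, fwhm_mm: float, voxel_mm: float = 2.0,
               mask: np.ndarray | None = None) -> np.ndarray:
    """Separable Gaussian smoothing, sigma = FWHM / (2 sqrt(2 ln 2)) per axis.

    NaNs (outside-mask voxels) are treated as 0 before filtering; the result
    is restricted to the mask when one is given.  FWHM 0 returns the input.
    """
    if fwhm_mm < 0:
        raise ValueError("FWHM must be non-negative")
    if fwhm_mm == 0:
        return vol
    sigma_vox = fwhm_mm / FWHM_TO_SIGMA / voxel_mm
    filled = np.nan_to_num(vol, nan=0.0)
    out = ndimage.gaussian_filter(filled, sigma=sigma_vox)
    if mask is not None:
        out = np.where(mask, out, np.nan)
    return out


def _stack(subject_maps, mask: np.ndarray) -> np.ndarray:
    maps = list(subject_maps)
    shapes = {m.shape for m in maps}
    if len(shapes) != 1 or maps[0].shape != mask.shape:
        raise ValueError("subject maps must share the mask geometry")
    return np.stack([m[mask] for m in maps])  # (n_subjects, n_voxels)


def _t_stat(data: np.ndarray) -> np.ndarray:
    """One-sample t across axis 0, zero-variance voxels -> NaN."""
    n = data.shape[0]
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[sd == 0] = np.nan
    return t


def one_sample_t_map(subject_maps, null_value: float, mask: np.ndarray
                     ) -> tuple[np.ndarray, int]:
    """Voxel-wise t = (mean - null) / (SD / sqrt(n)), df = n - 1.

    Zero-variance voxels are undefined (NaN).  Returns (t-map, df).
    """
    data = _stack(subject_maps, mask)
    n = data.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    t = _t_stat(data - null_value)
    out = np.full(mask.shape, np.nan)
    out[mask] = t
    return out, n - 1


def _r_stat(data: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Pearson r of each column of data with scores (vectorized)."""
    xc = scores - scores.mean()
    yc = data - data.mean(axis=0)
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ yc) / denom
    r[denom == 0] = np.nan
    return r


def correlation_map(subject_maps, scores, mask: np.ndarray) -> np.ndarray:
    """Voxel-wise Pearson correlation between subject maps and a covariate."""
    scores = np.asarray(scores, dtype=float)
    data = _stack(subject_maps, mask)
    if data.shape[0] != len(scores):
        raise ValueError("one score per subject map required")
    if data.shape[0] < 4:
        raise ValueError("need at least 4 subjects for a correlation map")
    if np.ptp(scores) == 0:
        raise ValueError("behavioral scores are constant")
    out = np.full(mask.shape, np.nan)
    out[mask] = _r_stat(data, scores)
    return out


def r_to_t(r: float, n: int) -> float:
    """t = r sqrt(n-2) / sqrt(1-r^2), the test statistic of a Pearson r."""
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1:
        import warnings
        warnings.warn("|r| = 1: t statistic is infinite")
        return float(np.sign(r) * np.inf)
    return float(r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r))


def _check_nperm(n_perm: int) -> None:
    if n_perm < 20:
        raise ValueError("n_perm below 20 cannot estimate a tail")
    if n_perm < 100:
        import warnings
        warnings.warn("n_perm below 100 gives coarse FWE thresholds")


def _sign_flip_tmax(data: np.ndarray, n_perm: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Null distribution of max-voxel t under per-subject sign flips."""
    n = data.shape[0]
    tmax = np.empty(n_perm)
    for p in range(n_perm):
        signs = rng.choice((-1.0, 1.0), size=n)
        t = _t_stat(data * signs[:, None])
        tmax[p] = np.nanmax(t)
    return tmax


def _score_perm_rmax(data: np.ndarray, scores: np.ndarray, n_perm: int,
                     rng: np.random.Generator) -> np.ndarray:
    rmax = np.empty(n_perm)
    for p in range(n_perm):
        perm = rng.permutation(scores)
        rmax[p] = np.nanmax(_r_stat(data, perm))
    return rmax


def voxel_fwe(subject_maps, mask: np.ndarray, alpha: float = 0.05,
              n_perm: int = 1000, seed: int = 0,
              null_value: float | None = None,
              scores=None) -> tuple[float, np.ndarray]:
    """Voxel-level FWE via max-statistic permutation.

    Pass ``null_value`` for the one-sample t test (per-subject sign flips of
    map - null) or ``scores`` for the correlation test (score permutations).
    Returns (threshold on the statistic, boolean significance mask); the
    threshold is the (1 - alpha) quantile of the max-statistic null.
    """
    _check_nperm(n_perm)
    if (null_value is None) == (scores is None):
        raise ValueError("pass exactly one of null_value or scores")
    data = _stack(subject_maps, mask)
    rng = np.random.default_rng(seed)
    if null_value is not None:
        centered = data - null_value
        observed = _t_stat(centered)
        null_max = _sign_flip_tmax(centered, n_perm, rng)
    else:
        scores = np.asarray(scores, dtype=float)
        observed = _r_stat(data, scores)
        null_max = _score_perm_rmax(data, scores, n_perm, rng)
    threshold = float(np.quantile(null_max, 1.0 - alpha))
    sig = np.zeros(mask.shape, dtype=bool)
    sig[mask] = observed >= threshold
    return threshold, sig


def _label_clusters(stat: np.ndarray, mask: np.ndarray, cutoff: float,
                    connectivity: int) -> tuple[np.ndarray, int]:
    supra = np.zeros(mask.shape, dtype=bool)
    supra[mask] = np.nan_to_num(stat, nan=-np.inf) >= cutoff
    return ndimage.label(supra, structure=_connectivity_structure(connectivity))


def cluster_fwe(subject_maps, mask: np.ndarray,
                forming_p: float = 0.001, alpha: float = 0.05,
                connectivity: int = 18, n_perm: int = 1000, seed: int = 0,
                null_value: float | None = None, scores=None
                ) -> tuple[pd.DataFrame, np.ndarray]:
    """Cluster-extent FWE inference on the one-sided t (or correlation) map.

    Supra-threshold voxels (statistic above the one-sided forming cutoff) are
    labeled into connected components; the permutation null of the maximum
    cluster extent gives the corrected extent threshold.  Returns the cluster
    table (peak statistic, peak r where applicable, extent, corrected p) and
    the significance mask.  An empty table is a valid outcome.
    """
    _check_nperm(n_perm)
    if (null_value is None) == (scores is None):
        raise ValueError("pass exactly one of null_value or scores")
    data = _stack(subject_maps, mask)
    n = data.shape[0]
    rng = np.random.default_rng(seed)

    if null_value is not None:
        df = n - 1
        cutoff = float(stats.t.ppf(1.0 - forming_p, df))
        observed = _t_stat(data - null_value)
        peak_r = None

        def perm_stat():
            signs = rng.choice((-1.0, 1.0), size=n)
            return _t_stat((data - null_value) * signs[:, None])
    else:
        scores = np.asarray(scores, dtype=float)
        df = n - 2
        # forming threshold on the correlation's t statistic, mapped back to r
        tcut = float(stats.t.ppf(1.0 - forming_p, df))
        cutoff = tcut / np.sqrt(df + tcut ** 2)
        robs = _r_stat(data, scores)
        observed = robs
        peak_r = robs

        def perm_stat():
            return _r_stat(data, rng.permutation(scores))

    # permutation null of the maximum cluster extent
    max_extents = np.empty(n_perm, dtype=int)
    struct = _connectivity_structure(connectivity)
    for p in range(n_perm):
        stat_p = perm_stat()
        supra = np.zeros(mask.shape, dtype=bool)
        supra[mask] = np.nan_to_num(stat_p, nan=-np.inf) >= cutoff
        lab, nlab = ndimage.label(supra, structure=struct)
        max_extents[p] = 0 if nlab == 0 else int(
            np.bincount(lab.ravel())[1:].max())

    labels, n_clusters = _label_clusters(observed, mask, cutoff, connectivity)
    stat_vol = np.full(mask.shape, np.nan)
    stat_vol[mask] = observed
    rows = []
    sig = np.zeros(mask.shape, dtype=bool)
    for cid in range(1, n_clusters + 1):
        members = labels == cid
        extent = int(members.sum())
        vals = stat_vol[members]
        peak_flat = np.nanargmax(np.where(members, stat_vol, -np.inf))
        peak_idx = np.unravel_index(peak_flat, mask.shape)
        p_fwe = float((max_extents >= extent).mean())
        peak_stat = float(np.nanmax(vals))
        if peak_r is not None:
            pr = peak_stat
            pt = r_to_t(pr, n)
        else:
            pr = np.nan
            pt = peak_stat
        significant = p_fwe < alpha
        if significant:
            sig |= members
        rows.append({
            "cluster_id": cid, "peak_i": peak_idx[0], "peak_j": peak_idx[1],
            "peak_k": peak_idx[2], "peak_r": pr, "peak_t": pt,
            "extent": extent, "p_fwe": p_fwe, "significant": significant,
        })
    table = pd.DataFrame(rows, columns=[
        "cluster_id", "peak_i", "peak_j", "peak_k", "peak_r", "peak_t",
        "extent", "p_fwe", "significant"])
    if len(table):
        table = table.sort_values("extent", ascending=False,
                                  ignore_index=True)
    return table, sig


def conjunction(mask_a: np.ndarray, mask_b: np.ndarray,
                total_centers: int) -> tuple[np.ndarray, float]:
    """Voxel-wise AND of two significance masks and its fraction of centers."""
    if mask_a.shape != mask_b.shape:
        raise ValueError("significance masks must share geometry")
    both = mask_a & mask_b
    return both, float(both.sum()) / total_centers


@dataclass
class GroupResult:
    t_map: np.ndarray
    r_map: np.ndarray
    df_t: int
    voxel_threshold: float
    accuracy_sig: np.ndarray
    cluster_table: pd.DataFrame
    correlation_sig: np.ndarray
    conjunction_mask: np.ndarray
    conjunction_fraction: float
    chance: float
    config: GroupConfig = field(default_factory=GroupConfig)


def run_group_analysis(accuracy_maps, scores, chance: float,
                       mask: np.ndarray,
                       config: GroupConfig | None = None) -> GroupResult:
    """Full second-level analysis on a set of subject accuracy maps.

    Smooths each map, runs the voxel-FWE accuracy test against chance, the
    cluster-FWE correlation test against the behavioral scores, and their
    conjunction over all searchlight centers.
    """
    config = config or GroupConfig()
    smoothed = [smooth_map(m, config.fwhm_mm, config.voxel_mm, mask)
                for m in accuracy_maps]
    t_map, df_t = one_sample_t_map(smoothed, chance, mask)
    r_map = correlation_map(smoothed, scores, mask)
    vthr, acc_sig = voxel_fwe(smoothed, mask, alpha=config.voxel_alpha,
                              n_perm=config.n_perm, seed=config.seed,
                              null_value=chance)
    table, corr_sig = cluster_fwe(
        smoothed, mask, forming_p=config.cluster_forming_p,
        alpha=config.cluster_alpha, connectivity=config.connectivity,
        n_perm=config.n_perm, seed=config.seed + 1, scores=scores)
    conj, frac = conjunction(acc_sig, corr_sig, int(mask.sum()))
    return GroupResult(
        t_map=t_map, r_map=r_map, df_t=df_t, voxel_threshold=vthr,
        accuracy_sig=acc_sig, cluster_table=table, correlation_sig=corr_sig,
        conjunction_mask=conj, conjunction_fraction=frac, chance=chance,
        config=config)
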