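"""Time-averaged mean-squared-displacement analysis and free-diffusion fits.

For a trajectory with positions r_i at frames f_i the time-averaged MSD at
lag n is the mean of |r_j - r_i|² over all pairs with f_j - f_i = n
(overlapping windows).  The first five lags are fitted to the 2-D free
diffusion model

    MSD(n·t_lag) = 4·D₅·(n·t_lag) + c

by weighted least squares, each lag weighted by the inverse variance of its
MSD estimate.  D₅ is the short-time ("microscopic") diffusion coefficient;
the offset c absorbs the static localization error (c ≈ 4σ_loc² for
isotropic Gaussian noise of σ_loc per axis).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import MICROMETERS, AcquisitionMeta, Trajectory

DEFAULT_FIT_LAGS = range(1, 6)


@dataclass
class MSDCurve:
    """Per-trajectory MSD with per-lag dispersion and pair counts.

    ``variance`` holds the sample variance (ddof=1) of the individual
    squared displacements at each lag, in µm⁴; the variance of the MSD
    *estimate* is ``variance / n_pairs``.  For a contiguous trajectory of
    N frames, n_pairs(n) = N − n.
    """

    lags: np.ndarray          # integer lag multiples of t_lag
    msd: np.ndarray           # µm²
    variance: np.ndarray      # µm⁴, sample variance of squared displacements
    n_pairs: np.ndarray       # pairs contributing per lag
    t_lag: float              # seconds
    trajectory_id: str = ""

    def lag_times(self) -> np.ndarray:
        """Lag times in seconds."""
        return self.lags * self.t_lag

    def select(self, lags) -> "MSDCurve":
        lags = np.asarray(list(lags))
        idx = {int(l): i for i, l in enumerate(self.lags)}
        missing = [int(l) for l in lags if int(l) not in idx]
        if missing:
            raise ValueError(f"lags {missing} absent from MSD curve")
        sel = np.array([idx[int(l)] for l in lags])
        return MSDCurve(self.lags[sel], self.msd[sel], self.variance[sel],
                        self.n_pairs[sel], self.t_lag, self.trajectory_id)


@dataclass
class DiffusionFit:
    """Result of fitting MSD(n·t_lag) = 4·D₅·(n·t_lag) + c."""

    D5: float                 # µm²/s; may be negative for noise-dominated tracks
    c: float                  # µm²
    fit_lags: tuple           # lags used
    D5_stderr: float = float("nan")   # approximate standard error of D₅
    residual_ss: float = float("nan")  # weighted residual sum of squares
    weighted: bool = True     # False if the fit fell back to equal weights
    trajectory_id: str = ""
    flags: list[str] = field(default_factory=list)


def compute_msd(
    traj: Trajectory,
    meta: AcquisitionMeta,
    max_lag: int | None = None,
) -> MSDCurve:
    """Time-averaged MSD of one trajectory over all overlapping pairs.

    Coordinates must already be in micrometers.  Pairing is by absolute
    frame difference, so gapped (blink-bridged) trajectories simply
    contribute no pairs at the missing lags; lags with zero pairs are
    omitted from the curve.
    """
    if len(traj) < 2:
        raise ValueError(f"trajectory {traj.id!r} has fewer than 2 points")
    if traj.unit != MICROMETERS:
        raise ValueError(
            f"trajectory {traj.id!r} is in {traj.unit!r}; convert to µm first"
        )
    frames = traj.frames
    xy = traj.xy
    span = int(frames[-1] - frames[0])
    if max_lag is None:
        max_lag = span
    max_lag = min(max_lag, span)

    contiguous = len(traj) == span + 1
    lags, msds, variances, counts = [], [], [], []
    if contiguous:
        for n in range(1, max_lag + 1):
            d = xy[n:] - xy[:-n]
            sq = d[:, 0] ** 2 + d[:, 1] ** 2
            lags.append(n)
            msds.append(sq.mean())
            variances.append(sq.var(ddof=1) if sq.size > 1 else 0.0)
            counts.append(sq.size)
    else:
        # gapped track: pair by absolute frame difference
        order = {int(f): i for i, f in enumerate(frames)}
        for n in range(1, max_lag + 1):
            ii, jj = [], []
            for f, i in order.items():
                j = order.get(f + n)
                if j is not None:
                    ii.append(i)
                    jj.append(j)
            if not ii:
                continue
            d = xy[jj] - xy[ii]
            sq = d[:, 0] ** 2 + d[:, 1] ** 2
            lags.append(n)
            msds.append(sq.mean())
            variances.append(sq.var(ddof=1) if sq.size > 1 else 0.0)
            counts.append(sq.size)

    return MSDCurve(
        lags=np.array(lags, dtype=np.int64),
        msd=np.array(msds),
        variance=np.array(variances),
        n_pairs=np.array(counts, dtype=np.int64),
        t_lag=meta.frame_interval,
        trajectory_id=traj.id,
    )


def _wls_line(t: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Closed-form weighted straight-line fit y = a·t + b.

    Returns (a, b, var_a, wrss) with var_a the slope variance under the
    assumption that 1/w are the true observation variances.
    """
    sw = w.sum()
    st = (w * t).sum()
    stt = (w * t * t).sum()
    sy = (w * y).sum()
    sty = (w * t * y).sum()
    det = sw * stt - st * st
    if det <= 0:
        raise np.linalg.LinAlgError("degenerate design in weighted line fit")
    a = (sw * sty - st * sy) / det
    b = (sy - a * st) / sw
    resid = y - (a * t + b)
    wrss = float((w * resid**2).sum())
    var_a = sw / det
    return float(a), float(b), float(var_a), wrss


def fit_diffusion(
    curve: MSDCurve,
    fit_lags=DEFAULT_FIT_LAGS,
    weight_mode: str = "variance_of_mean",
) -> DiffusionFit:
    """Weighted least-squares fit of the free-diffusion model to an MSD curve.

    Each lag is weighted by 1/σ²(n).  With the default
    ``weight_mode="variance_of_mean"``, σ²(n) = variance(n)/n_pairs(n),
    the variance of the per-lag MSD estimate; ``"sample_variance"`` uses the
    raw per-pair variance instead.  If any fit lag has zero estimated
    variance the fit falls back to equal weights and is flagged.

    The fitted D₅ is reported as-is: noise-dominated tracks may come out
    negative, and clipping them would bias ensemble summaries.
    """
    fit_lags = tuple(int(l) for l in fit_lags)
    sub = curve.select(fit_lags)
    if np.any(sub.n_pairs < 2):
        raise ValueError(
            f"trajectory {curve.trajectory_id!r}: fewer than 2 pairs at some "
            f"fit lag; cannot estimate per-lag variance"
        )
    t = sub.lag_times()
    y = sub.msd
    if weight_mode == "variance_of_mean":
        sigma2 = sub.variance / sub.n_pairs
    elif weight_mode == "sample_variance":
        sigma2 = sub.variance.astype(float)
    else:
        raise ValueError(f"unknown weight_mode {weight_mode!r}")

    flags: list[str] = []
    weighted = True
    if np.any(sigma2 <= 0):
        weighted = False
        flags.append("zero_variance_fallback_unweighted")
        w = np.ones_like(y)
    else:
        w = 1.0 / sigma2
    try:
        a, b, var_a, wrss = _wls_line(t, y, w)
    except np.linalg.LinAlgError:
        weighted = False
        flags.append("degenerate_design_fallback_unweighted")
        a, b, var_a, wrss = _wls_line(t, y, np.ones_like(y))
    return DiffusionFit(
        D5=a / 4.0,
        c=b,
        fit_lags=fit_lags,
        D5_stderr=np.sqrt(var_a) / 4.0 if weighted else float("nan"),
        residual_ss=wrss,
        weighted=weighted,
        trajectory_id=curve.trajectory_id,
        flags=flags,
    )


def fit_trajectory(
    traj: Trajectory,
    meta: AcquisitionMeta,
    fit_lags=DEFAULT_FIT_LAGS,
    weight_mode: str = "variance_of_mean",
) -> DiffusionFit:
    """Convenience: compute the MSD curve and fit it in one call."""
    curve = compute_msd(traj, meta, max_lag=max(fit_lags))
    return fit_diffusion(curve, fit_lags, weight_mode)


def fit_contiguous_batch(
    steps_xy: np.ndarray,
    t_lag: float,
    fit_lags=DEFAULT_FIT_LAGS,
) -> np.ndarray:
    """Vectorised per-trajectory D₅ for a batch of equal-length gapless tracks.

    ``steps_xy`` has shape (n_traj, n_steps, 2) and holds displacement
    vectors.  Returns the fitted D₅ per trajectory using the same
    inverse-variance weighting as :func:`fit_diffusion`.  This is the fast
    path used by the Monte Carlo validation grids; it is cross-checked
    against the per-trajectory route in the test suite.
    """
    fit_lags = np.asarray(list(fit_lags), dtype=np.int64)
    n_traj, n_steps, _ = steps_xy.shape
    if n_steps < fit_lags.max() + 1:
        raise ValueError("trajectories too short for requested fit lags")
    xy = np.concatenate(
        [np.zeros((n_traj, 1, 2)), np.cumsum(steps_xy, axis=1)], axis=1
    )
    msd = np.empty((n_traj, fit_lags.size))
    var_mean = np.empty((n_traj, fit_lags.size))
    for k, n in enumerate(fit_lags):
        d = xy[:, n:, :] - xy[:, :-n, :]
        sq = d[..., 0] ** 2 + d[..., 1] ** 2
        msd[:, k] = sq.mean(axis=1)
        var_mean[:, k] = sq.var(axis=1, ddof=1) / sq.shape[1]
    t = fit_lags * t_lag
    w = 1.0 / var_mean
    sw = w.sum(axis=1)
    st = (w * t).sum(axis=1)
    stt = (w * t * t).sum(axis=1)
    sy = (w * msd).sum(axis=1)
    sty = (w * t * msd).sum(axis=1)
    det = sw * stt - st * st
    slope = (sw * sty - st * sy) / det
    return slope / 4.0
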