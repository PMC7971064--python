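"""T1 (inversion recovery) and T2* (multi-echo gradient echo) fitting.

T1 is estimated by a three-parameter least-squares fit of the magnitude
inversion-recovery model ``|A − B·exp(−TI/T1)|``.  Because magnitude data
lose the sign of the recovering magnetization, the fit tries every
polarity assignment that flips the first k early-TI points negative and
keeps the hypothesis with the lowest magnitude residual.

T2* is estimated by nonlinear least squares on the mono-exponential decay
``S0·exp(−TE/T2*)``, initialized from the log-linear closed form.  When the
noise scale is known, the fit runs in the squared-magnitude domain against
``S(TE)² + 2σ²`` — the exact second moment of a Rician magnitude — so the
noise floor at late echoes is modeled rather than truncated and short-T2*
estimates stay unbiased down to low echo SNR.

Fits never raise on non-convergence: voxelwise maps must always complete,
so failures are returned flagged with ``converged=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .containers import ImageSeries, ROIMask

__all__ = ["T1FitResult", "T2StarFitResult", "ParameterMap",
           "fit_t1_ir", "fit_t2star", "map_parameter"]

_LN2 = float(np.log(2.0))


@dataclass
class T1FitResult:
    t1_ms: float
    a: float
    b: float
    residual_rms: float
    n_points_used: int
    polarity_restored: bool
    converged: bool = True


@dataclass
class T2StarFitResult:
    t2star_ms: float
    s0: float
    residual_rms: float
    n_points_used: int
    converged: bool = True


@dataclass
class ParameterMap:
    """Voxelwise fitted quantity over an ROI with fit diagnostics."""

    values: np.ndarray          # fitted quantity, NaN outside mask
    param: str                  # "T1" | "T2*"
    residual_rms: np.ndarray
    converged: np.ndarray       # bool raster
    roi_mean: float = float("nan")
    roi_median: float = float("nan")


def _solve_linear_amplitudes(y: np.ndarray, ti: np.ndarray,
                             t1: float) -> tuple[float, float]:
    """Least-squares (A, B) for fixed T1 against signed data ``y``."""
    x = np.exp(-ti / t1)
    design = np.column_stack([np.ones_like(x), -x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return float(coef[0]), float(coef[1])


def fit_t1_ir(signals: np.ndarray, ti_ms: np.ndarray) -> T1FitResult:
    """Three-parameter magnitude IR fit returning T1 in ms.

    Parameters
    ----------
    signals
        Magnitude signal at each inversion time.
    ti_ms
        Inversion times in ms; sorted internally, must be non-negative.
    """
    signals = np.asarray(signals, dtype=float)
    ti_ms = np.asarray(ti_ms, dtype=float)
    if signals.shape != ti_ms.shape or signals.ndim != 1:
        raise ValueError("signals and ti_ms must be matching 1-D vectors")
    if len(signals) < 4:
        raise ValueError("need at least 4 inversion times for a 3-parameter fit")
    if not np.all(np.isfinite(signals)):
        raise ValueError("signals contain non-finite values")
    if np.any(ti_ms < 0):
        raise ValueError("inversion times must be non-negative")

    order = np.argsort(ti_ms)
    ti = ti_ms[order]
    mag = signals[order]
    n = len(mag)

    scale = float(np.max(np.abs(mag)))
    if scale == 0:
        return T1FitResult(np.nan, 0.0, 0.0, 0.0, n, False, converged=False)

    i_min = int(np.argmin(mag))
    t1_start = ti[i_min] / _LN2 if ti[i_min] > 0 else float(np.median(ti[ti > 0])) / _LN2
    t1_start = max(t1_start, 1.0)

    def resid(x: np.ndarray) -> np.ndarray:
        a, b, t1 = x
        return np.abs(a - b * np.exp(-ti / t1)) - mag

    # Polarity hypotheses: the zero crossing of the recovering magnetization
    # sits at (or next to) the magnitude minimum, so only splits around it
    # need to seed the fit.  k = 0 covers data with no crossing at all.
    candidates = sorted({0, i_min, i_min + 1, min(i_min + 2, n)})
    best: tuple[float, np.ndarray, bool] | None = None  # (rss, x, restored)
    for k in candidates:
        y = mag.copy()
        y[:k] *= -1.0
        a0, b0 = _solve_linear_amplitudes(y, ti, t1_start)
        x0 = np.array([a0, b0, t1_start])
        try:
            sol = least_squares(
                resid, x0,
                bounds=([-np.inf, -np.inf, 1e-3], [np.inf, np.inf, 1e6]),
                xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0] - 1e-12 * scale**2:
            best = (rss, sol.x, k > 0)

    if best is None:
        return T1FitResult(np.nan, np.nan, np.nan, np.nan, n, False,
                           converged=False)
    rss, (a, b, t1), restored = best
    # The magnitude model is invariant under (A, B) → (−A, −B); report the
    # convention with positive equilibrium amplitude.
    if a < 0:
        a, b = -a, -b
    return T1FitResult(float(t1), float(a), float(b),
                       float(np.sqrt(rss / n)), n, restored, converged=True)


def loglinear_t2star(signals: np.ndarray, te_ms: np.ndarray) -> tuple[float, float]:
    """Closed-form log-linear (S0, T2*) estimate from positive signals."""
    pos = signals > 0
    if pos.sum() < 2:
        raise ValueError("need at least 2 positive signals for log-linear fit")
    slope, intercept = np.polyfit(te_ms[pos], np.log(signals[pos]), 1)
    if slope >= 0:
        raise ValueError("non-decaying signal; log-linear estimate undefined")
    return float(np.exp(intercept)), float(-1.0 / slope)


def fit_t2star(signals: np.ndarray, te_ms: np.ndarray,
               noise_sigma: float = 0.0) -> T2StarFitResult:
    """Mono-exponential T2* fit with Rician noise-floor handling.

    With ``noise_sigma > 0`` the fit minimizes residuals of the squared
    magnitudes against ``S0²·exp(−2·TE/T2*) + 2σ²`` (the second moment of a
    Rician variate), so late echoes buried in the noise floor inform the
    fit without biasing it; with ``noise_sigma == 0`` a plain magnitude-
    domain fit is used and reproduces the log-linear closed form exactly on
    noiseless data.  ``n_points_used`` counts echoes above ``3·noise_sigma``;
    if fewer than 3 echoes carry signal above that floor the decay is
    unidentifiable and a non-converged result is returned rather than
    raising.
    """
    signals = np.asarray(signals, dtype=float)
    te_ms = np.asarray(te_ms, dtype=float)
    if signals.shape != te_ms.shape or signals.ndim != 1:
        raise ValueError("signals and te_ms must be matching 1-D vectors")
    if not np.all(np.isfinite(signals)):
        raise ValueError("signals contain non-finite values")
    if np.any(te_ms < 0):
        raise ValueError("echo times must be non-negative")
    if len(signals) < 3:
        return T2StarFitResult(np.nan, np.nan, np.nan, len(signals),
                               converged=False)

    if noise_sigma > 0:
        above = signals >= 3.0 * noise_sigma
        n_used = int(above.sum())
        if n_used < 3 and not (n_used >= 1 and signals.max() >= 6 * noise_sigma):
            return T2StarFitResult(np.nan, np.nan, np.nan, n_used,
                                   converged=False)
        corrected = np.sqrt(np.clip(signals**2 - 2 * noise_sigma**2,
                                    1e-12, None))
        try:
            s0_0, t2_0 = loglinear_t2star(corrected, te_ms)
        except ValueError:
            s0_0, t2_0 = float(signals.max()), float(np.median(te_ms[te_ms > 0]))

        def resid(x: np.ndarray) -> np.ndarray:
            model_sq = (x[0] * np.exp(-te_ms / x[1]))**2 + 2 * noise_sigma**2
            return model_sq - signals**2

        sol = least_squares(resid, np.array([s0_0, t2_0]),
                            bounds=([0.0, 1e-6], [np.inf, np.inf]),
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        fitted = sol.x[0] * np.exp(-te_ms / sol.x[1])
        rms = float(np.sqrt(np.mean(
            (np.sqrt(fitted**2 + 2 * noise_sigma**2) - signals)**2)))
        return T2StarFitResult(float(sol.x[1]), float(sol.x[0]), rms, n_used,
                               converged=bool(sol.success))

    n_used = len(signals)
    try:
        s0_0, t2_0 = loglinear_t2star(signals, te_ms)
    except ValueError:
        return T2StarFitResult(np.nan, np.nan, np.nan, n_used, converged=False)

    def resid_mag(x: np.ndarray) -> np.ndarray:
        return x[0] * np.exp(-te_ms / x[1]) - signals

    sol = least_squares(resid_mag, np.array([s0_0, t2_0]),
                        bounds=([0.0, 1e-6], [np.inf, np.inf]),
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    return T2StarFitResult(float(sol.x[1]), float(sol.x[0]), rms, n_used,
                           converged=True)


def map_parameter(series: ImageSeries, mask: ROIMask, which: str,
                  noise_sigma: float = 0.0) -> ParameterMap:
    """Apply the scalar fit voxel by voxel over ``mask``.

    ``which`` is ``"T1"`` (IR series) or ``"T2*"`` (multi-echo series).
    Unmasked voxels are NaN; ROI mean/median are taken over converged
    voxels only.
    """
    if which not in ("T1", "T2*"):
        raise ValueError("which must be 'T1' or 'T2*'")
    if mask.voxels.shape != series.frame_shape:
        raise ValueError("mask shape must match series frames")
    if not mask:
        raise ValueError("mask is empty")

    shape = series.frame_shape
    values = np.full(shape, np.nan)
    resid = np.full(shape, np.nan)
    conv = np.zeros(shape, dtype=bool)
    abscissa = series.frame_axis_values
    for r, c in np.argwhere(mask.voxels):
        sig = series.frames[:, r, c]
        if which == "T1":
            fit = fit_t1_ir(sig, abscissa)
            values[r, c] = fit.t1_ms
        else:
            fit = fit_t2star(sig, abscissa, noise_sigma=noise_sigma)
            values[r, c] = fit.t2star_ms
        resid[r, c] = fit.residual_rms
        conv[r, c] = fit.converged

    good = values[conv]
    return ParameterMap(values, which, resid, conv,
                        roi_mean=float(np.mean(good)) if good.size else float("nan"),
                        roi_median=float(np.median(good)) if good.size else float("nan"))
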