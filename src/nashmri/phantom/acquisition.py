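"""Synthetic MRI acquisitions over a block-geometry liver phantom.

The phantom frame contains three compartments — a liver ellipse, a skeletal
muscle slab, and air background — laid out on the acquisition matrix.  Each
simulator produces the closed-form magnitude signal of its sequence and
corrupts it with Rician noise: ``|S + n1 + i·n2|`` with independent Gaussian
``n1, n2`` of scale ``noise_sigma``, so background magnitude follows a
Rayleigh distribution as in real magnitude MRI.

Sequence defaults mirror the study protocol at 9.4 T:

* inversion recovery (IR) with 9 inversion times 0–7000 ms,
* multi-echo gradient echo (MEGRE) with 12 echo times 2.62–30.68 ms,
* two-point Dixon (in-phase TE 1.06 ms, opposed-phase TE 1.41 ms),
* T1-weighted spoiled gradient echo DCE at TR 41 ms / flip 60°, frames
  pre-injection and 5, 15, 25 min post-injection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.draw import ellipse

from ..containers import ImageSeries, ROIMask
from .trajectory import TissueState

__all__ = [
    "AcquisitionParams",
    "ProbeModel",
    "IR_TI_MS",
    "MEGRE_TE_MS",
    "DCE_FRAME_TIMES_MIN",
    "phantom_masks",
    "sigma_for_snr",
    "add_rician_noise",
    "ir_signal",
    "megre_signal",
    "spgr_signal",
    "simulate_ir_series",
    "simulate_megre_series",
    "simulate_dixon_pair",
    "simulate_ir_signal",
    "simulate_megre_signal",
    "bound_fraction",
    "probe_concentration_curves",
    "simulate_dce_series",
    "dce_true_signals",
]

IR_TI_MS = (0.0, 300.0, 550.0, 700.0, 850.0, 1500.0, 3000.0, 5000.0, 7000.0)
MEGRE_TE_MS = (2.62, 5.17, 7.72, 10.27, 12.82, 15.38, 17.93, 20.48, 23.03,
               25.58, 28.13, 30.68)
DCE_FRAME_TIMES_MIN = (0.0, 5.0, 15.0, 25.0)

# Compartment signal properties (arbitrary receiver units / ms).  Muscle
# relaxation values are fixed reference-tissue constants at 9.4 T.
LIVER_PD = 1.0
MUSCLE_PD = 0.8
MUSCLE_T1_MS = 1900.0
MUSCLE_T2STAR_MS = 15.0
MUSCLE_FAT_FRAC = 0.02


@dataclass(frozen=True)
class AcquisitionParams:
    """Sequence parameters for one synthetic acquisition."""

    kind: str  # IR | MEGRE | DIXON | DCE
    tr_ms: float
    te_ms: float | None = None
    te_list_ms: tuple[float, ...] | None = None
    ti_list_ms: tuple[float, ...] | None = None
    flip_deg: float | None = None
    matrix: tuple[int, int] = (64, 64)
    fov_cm: tuple[float, float] = (2.5, 2.5)
    noise_sigma: float = 0.0
    frame_times_min: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")

    @classmethod
    def ir_default(cls, matrix=(195, 195), noise_sigma=0.0) -> "AcquisitionParams":
        return cls(kind="IR", tr_ms=5000.0, te_ms=7.27, ti_list_ms=IR_TI_MS,
                   matrix=matrix, fov_cm=(2.5, 2.5), noise_sigma=noise_sigma)

    @classmethod
    def megre_default(cls, matrix=(128, 128), noise_sigma=0.0) -> "AcquisitionParams":
        return cls(kind="MEGRE", tr_ms=1500.0, te_list_ms=MEGRE_TE_MS,
                   flip_deg=90.0, matrix=matrix, fov_cm=(2.56, 2.56),
                   noise_sigma=noise_sigma)

    @classmethod
    def dixon_default(cls, matrix=(96, 96), noise_sigma=0.0) -> "AcquisitionParams":
        # te_ms is the in-phase echo; opposed-phase echo at 1.41 ms.
        return cls(kind="DIXON", tr_ms=500.0, te_ms=1.06, flip_deg=30.0,
                   matrix=matrix, fov_cm=(2.4, 2.4), noise_sigma=noise_sigma)

    @classmethod
    def dce_default(cls, matrix=(64, 64), noise_sigma=0.0) -> "AcquisitionParams":
        return cls(kind="DCE", tr_ms=41.0, te_ms=2.5, flip_deg=60.0,
                   matrix=matrix, fov_cm=(4.385, 2.644),
                   frame_times_min=DCE_FRAME_TIMES_MIN,
                   noise_sigma=noise_sigma)

    def with_noise(self, noise_sigma: float) -> "AcquisitionParams":
        return replace(self, noise_sigma=noise_sigma)


@dataclass(frozen=True)
class ProbeModel:
    """Pharmacokinetic/binding model of the allysine-targeted Gd probe.

    Dose, blood half-life, dissociation constant and the bound/free
    relaxivities are the probe's characterized values; blood volume,
    distribution volume, binding-site scaling and the bound-pool off-rate
    are free model parameters (see the methods note).
    """

    dose_umol_per_kg: float = 200.0
    blood_half_life_min: float = 5.0
    kd_uM: float = 650.0
    r1_bound_mM_s: float = 16.2
    r1_free_mM_s: float = 4.1
    blood_volume_mL_per_kg: float = 58.5
    distribution_volume_frac: float = 0.08
    bmax_per_allysine: float = 1.0
    koff_per_min: float = 0.02

    def __post_init__(self) -> None:
        for f in ("blood_half_life_min", "kd_uM", "r1_bound_mM_s",
                  "r1_free_mM_s", "blood_volume_mL_per_kg",
                  "distribution_volume_frac", "bmax_per_allysine"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")
        if self.dose_umol_per_kg < 0:
            raise ValueError("dose must be non-negative")
        if self.r1_bound_mM_s <= self.r1_free_mM_s:
            raise ValueError("bound relaxivity must exceed free relaxivity")

    @property
    def c0_blood_mM(self) -> float:
        """Peak blood concentration from dose over blood volume (μmol/mL ≡ mM)."""
        return self.dose_umol_per_kg / self.blood_volume_mL_per_kg


def phantom_masks(matrix: tuple[int, int]) -> dict[str, ROIMask]:
    """Compartment masks for the block phantom at a given matrix size."""
    rows, cols = matrix
    grid = np.zeros(matrix, dtype=bool)
    rr, cc = ellipse(rows * 0.40, cols * 0.5, rows * 0.28, cols * 0.38,
                     shape=matrix)
    liver = grid.copy()
    liver[rr, cc] = True
    muscle = np.zeros(matrix, dtype=bool)
    muscle[int(rows * 0.78):int(rows * 0.92), int(cols * 0.2):int(cols * 0.8)] = True
    muscle &= ~liver
    background = ~(liver | muscle)
    return {
        "liver": ROIMask(liver, "liver"),
        "muscle": ROIMask(muscle, "muscle"),
        "background": ROIMask(background, "background"),
    }


def sigma_for_snr(snr: float, reference_signal: float = LIVER_PD) -> float:
    """Noise scale giving the requested SNR at the reference amplitude."""
    if snr <= 0:
        raise ValueError("snr must be positive")
    return reference_signal / snr


def add_rician_noise(signal: np.ndarray, sigma: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Magnitude of the complex signal after additive Gaussian channel noise."""
    if sigma == 0:
        return np.asarray(signal, dtype=float)
    signal = np.asarray(signal, dtype=float)
    re = signal + rng.normal(0.0, sigma, size=signal.shape)
    im = rng.normal(0.0, sigma, size=signal.shape)
    return np.hypot(re, im)


# --- closed-form sequence signals ------------------------------------------

def ir_signal(ti_ms: np.ndarray, a: float, b: float, t1_ms: float) -> np.ndarray:
    """Magnitude inversion-recovery signal |A − B·exp(−TI/T1)|."""
    ti_ms = np.asarray(ti_ms, dtype=float)
    if np.any(ti_ms < 0):
        raise ValueError("inversion times must be non-negative")
    return np.abs(a - b * np.exp(-ti_ms / t1_ms))


def megre_signal(te_ms: np.ndarray, s0: float, t2star_ms: float) -> np.ndarray:
    """Mono-exponential gradient-echo decay S0·exp(−TE/T2*)."""
    te_ms = np.asarray(te_ms, dtype=float)
    if np.any(te_ms < 0):
        raise ValueError("echo times must be non-negative")
    return s0 * np.exp(-te_ms / t2star_ms)


def spgr_signal(t1_ms: np.ndarray, tr_ms: float, flip_deg: float,
                pd: np.ndarray | float = 1.0) -> np.ndarray:
    """Steady-state spoiled gradient-echo signal (TE decay absorbed in PD)."""
    t1_ms = np.asarray(t1_ms, dtype=float)
    e1 = np.exp(-tr_ms / t1_ms)
    a = np.deg2rad(flip_deg)
    return pd * np.sin(a) * (1.0 - e1) / (1.0 - np.cos(a) * e1)


# --- voxel-level convenience simulators (single liver voxel) ----------------

def simulate_ir_signal(t1_ms: float, seed: int, noise_sigma: float,
                       ti_list_ms=IR_TI_MS, a: float = LIVER_PD,
                       b: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """One liver voxel's noisy IR signal vector; returns (signals, ti_ms)."""
    ti = np.asarray(ti_list_ms, dtype=float)
    if b is None:
        b = 2.0 * a
    clean = ir_signal(ti, a, b, t1_ms)
    rng = np.random.default_rng(seed)
    return add_rician_noise(clean, noise_sigma, rng), ti


def simulate_megre_signal(t2star_ms: float, seed: int, noise_sigma: float,
                          te_list_ms=MEGRE_TE_MS,
                          s0: float = LIVER_PD) -> tuple[np.ndarray, np.ndarray]:
    """One liver voxel's noisy multi-echo decay; returns (signals, te_ms)."""
    te = np.asarray(te_list_ms, dtype=float)
    clean = megre_signal(te, s0, t2star_ms)
    rng = np.random.default_rng(seed)
    return add_rician_noise(clean, noise_sigma, rng), te


# --- full-frame simulators ---------------------------------------------------

def _base_meta(state: TissueState, masks: dict[str, ROIMask]) -> dict:
    return {"state": state, **{f"{k}_mask": v for k, v in masks.items()}}


def simulate_ir_series(state: TissueState, params: AcquisitionParams | None = None,
                       seed: int = 0) -> ImageSeries:
    """Inversion-recovery series over the phantom; liver T1 from ``state``."""
    if params is None:
        params = AcquisitionParams.ir_default()
    if params.kind != "IR":
        raise ValueError("params.kind must be 'IR'")
    ti = np.asarray(params.ti_list_ms, dtype=float)
    if np.any(ti < 0):
        raise ValueError("inversion times must be non-negative")
    masks = phantom_masks(params.matrix)
    t1 = np.full(params.matrix, np.nan)
    pd = np.zeros(params.matrix)
    t1[masks["liver"].voxels] = state.t1_ms
    pd[masks["liver"].voxels] = LIVER_PD
    t1[masks["muscle"].voxels] = MUSCLE_T1_MS
    pd[masks["muscle"].voxels] = MUSCLE_PD

    frames = np.zeros((len(ti),) + tuple(params.matrix))
    tissue = ~masks["background"].voxels
    for i, t in enumerate(ti):
        frames[i][tissue] = np.abs(
            pd[tissue] - 2.0 * pd[tissue] * np.exp(-t / t1[tissue]))
    rng = np.random.default_rng(seed)
    frames = add_rician_noise(frames, params.noise_sigma, rng)
    return ImageSeries(frames, "IR", ti, params, _base_meta(state, masks))


def simulate_megre_series(state: TissueState, params: AcquisitionParams | None = None,
                          seed: int = 0) -> ImageSeries:
    """Multi-echo gradient-echo series; liver T2* from ``state``."""
    if params is None:
        params = AcquisitionParams.megre_default()
    if params.kind != "MEGRE":
        raise ValueError("params.kind must be 'MEGRE'")
    te = np.asarray(params.te_list_ms, dtype=float)
    if np.any(te < 0):
        raise ValueError("echo times must be non-negative")
    masks = phantom_masks(params.matrix)
    t2s = np.full(params.matrix, np.nan)
    s0 = np.zeros(params.matrix)
    t2s[masks["liver"].voxels] = state.t2star_ms
    s0[masks["liver"].voxels] = LIVER_PD
    t2s[masks["muscle"].voxels] = MUSCLE_T2STAR_MS
    s0[masks["muscle"].voxels] = MUSCLE_PD

    frames = np.zeros((len(te),) + tuple(params.matrix))
    tissue = ~masks["background"].voxels
    for i, t in enumerate(te):
        frames[i][tissue] = s0[tissue] * np.exp(-t / t2s[tissue])
    rng = np.random.default_rng(seed)
    frames = add_rician_noise(frames, params.noise_sigma, rng)
    return ImageSeries(frames, "MEGRE", te, params, _base_meta(state, masks))


def simulate_dixon_pair(state: TissueState, params: AcquisitionParams | None = None,
                        seed: int = 0) -> tuple[ImageSeries, ImageSeries]:
    """In-phase / opposed-phase image pair with liver fat from ``state``.

    Per tissue voxel water ``W`` and fat ``F`` magnitudes satisfy
    ``F/(W+F) = fat_signal_frac``; in-phase = W+F, opposed-phase = |W−F|.
    """
    if params is None:
        params = AcquisitionParams.dixon_default()
    if params.kind != "DIXON":
        raise ValueError("params.kind must be 'DIXON'")
    if state.fat_signal_frac > 0.5:
        raise ValueError("fat_signal_frac must be ≤ 0.5 (water-dominant convention)")
    masks = phantom_masks(params.matrix)
    ff = np.zeros(params.matrix)
    total = np.zeros(params.matrix)
    ff[masks["liver"].voxels] = state.fat_signal_frac
    total[masks["liver"].voxels] = LIVER_PD
    ff[masks["muscle"].voxels] = MUSCLE_FAT_FRAC
    total[masks["muscle"].voxels] = MUSCLE_PD

    water = total * (1.0 - ff)
    fat = total * ff
    ip_clean = water + fat
    op_clean = np.abs(water - fat)
    rng = np.random.default_rng(seed)
    ip = add_rician_noise(ip_clean[None], params.noise_sigma, rng)
    op = add_rician_noise(op_clean[None], params.noise_sigma, rng)
    meta = _base_meta(state, masks)
    in_phase = ImageSeries(ip, "DIXON", [1.06], params, dict(meta, echo="in_phase"))
    opposed = ImageSeries(op, "DIXON", [1.41], params, dict(meta, echo="opposed_phase"))
    return in_phase, opposed


# --- probe binding and DCE ---------------------------------------------------

def bound_fraction(free_probe_uM: float, allysine_uM: float,
                   probe: ProbeModel) -> float:
    """Tissue bound fraction of probe under quasi-equilibrium binding.

    Site occupancy θ = free/(free + Kd); bound concentration is θ·Bmax with
    Bmax proportional to tissue allysine.  Returns bound/(bound + free).
    """
    if free_probe_uM < 0 or allysine_uM < 0:
        raise ValueError("concentrations must be non-negative")
    if free_probe_uM == 0:
        return 0.0
    theta = free_probe_uM / (free_probe_uM + probe.kd_uM)
    bound = theta * probe.bmax_per_allysine * allysine_uM
    return bound / (bound + free_probe_uM)


def probe_concentration_curves(state: TissueState, probe: ProbeModel,
                               t_end_min: float = 25.0,
                               dt_min: float = 0.05) -> dict[str, np.ndarray]:
    """Free and bound tissue probe concentrations on a fine time grid.

    Blood clears mono-exponentially with the probe half-life; the tissue
    free pool is a fixed fraction of blood; the bound pool follows the
    quasi-equilibrium occupancy on the way up and is released no faster
    than the first-order off-rate on the way down.
    """
    t = np.arange(0.0, t_end_min + dt_min / 2, dt_min)
    c_blood_mM = probe.c0_blood_mM * np.exp(
        -np.log(2.0) * t / probe.blood_half_life_min)
    free_uM = probe.distribution_volume_frac * c_blood_mM * 1000.0
    bmax = probe.bmax_per_allysine * state.allysine_uM
    eq = bmax * free_uM / (free_uM + probe.kd_uM)
    bound = np.zeros_like(t)
    decay = np.exp(-probe.koff_per_min * dt_min)
    for i in range(1, len(t)):
        bound[i] = max(eq[i], bound[i - 1] * decay)
    return {"t_min": t, "blood_mM": c_blood_mM, "free_uM": free_uM,
            "bound_uM": bound}


def _tissue_r1_per_s(t1_ms: float, free_uM: float, bound_uM: float,
                     probe: ProbeModel) -> float:
    return (1000.0 / t1_ms
            + probe.r1_free_mM_s * free_uM / 1000.0
            + probe.r1_bound_mM_s * bound_uM / 1000.0)


def dce_true_signals(state: TissueState, probe: ProbeModel,
                     times_min=DCE_FRAME_TIMES_MIN,
                     params: AcquisitionParams | None = None) -> dict[str, np.ndarray]:
    """Noiseless liver and muscle SPGR signals at the DCE frame times.

    Probe administration happens immediately after the first (pre) frame,
    so frame 0 sees no agent.  Muscle carries the free pool only; binding
    is liver-specific through tissue allysine.
    """
    if params is None:
        params = AcquisitionParams.dce_default()
    times = np.asarray(times_min, dtype=float)
    if probe.dose_umol_per_kg == 0:
        free = np.zeros_like(times)
        bound = np.zeros_like(times)
    else:
        curves = probe_concentration_curves(state, probe,
                                            t_end_min=max(times.max(), 1.0))
        free = np.interp(times, curves["t_min"], curves["free_uM"])
        bound = np.interp(times, curves["t_min"], curves["bound_uM"])
    free[times == 0.0] = 0.0
    bound[times == 0.0] = 0.0

    liver = np.empty_like(times)
    muscle = np.empty_like(times)
    for i in range(len(times)):
        r1_l = _tissue_r1_per_s(state.t1_ms, free[i], bound[i], probe)
        r1_m = _tissue_r1_per_s(MUSCLE_T1_MS, free[i], 0.0, probe)
        liver[i] = spgr_signal(1000.0 / r1_l, params.tr_ms, params.flip_deg,
                               LIVER_PD)
        muscle[i] = spgr_signal(1000.0 / r1_m, params.tr_ms, params.flip_deg,
                                MUSCLE_PD)
    return {"times_min": times, "liver": liver, "muscle": muscle,
            "free_uM": free, "bound_uM": bound}


def simulate_dce_series(state: TissueState, params: AcquisitionParams | None = None,
                        probe: ProbeModel | None = None, seed: int = 0,
                        vessel_frac: float = 0.05) -> ImageSeries:
    """Dynamic contrast-enhanced series over the phantom.

    A random subset of liver voxels (``vessel_frac``) is rendered as bright
    blood vessels at 3× the parenchymal pre-contrast signal, following the
    blood concentration over time; these are the voxels the liver-ROI
    vessel exclusion should remove.  A zero dose yields a flat series.
    """
    if params is None:
        params = AcquisitionParams.dce_default()
    if params.kind != "DCE":
        raise ValueError("params.kind must be 'DCE'")
    if probe is None:
        probe = ProbeModel()
    times = np.asarray(params.frame_times_min, dtype=float)
    if times[0] != 0.0:
        raise ValueError("frame 0 must be the pre-injection frame (t=0)")

    masks = phantom_masks(params.matrix)
    rng = np.random.default_rng(seed)
    liver_idx = np.flatnonzero(masks["liver"].voxels.ravel())
    n_vessel = int(round(vessel_frac * liver_idx.size))
    vessel_flat = rng.choice(liver_idx, size=n_vessel, replace=False)
    vessel = np.zeros(params.matrix, dtype=bool).ravel()
    vessel[vessel_flat] = True
    vessel = vessel.reshape(params.matrix)

    true = dce_true_signals(state, probe, times, params)

    # Vessel: blood-pool voxel, scaled so its pre-contrast signal is 3×
    # liver parenchyma (inflow-enhanced blood on T1-weighted SPGR).
    if probe.dose_umol_per_kg > 0:
        c_blood = probe.c0_blood_mM * np.exp(
            -np.log(2.0) * times / probe.blood_half_life_min) * 1000.0
        c_blood[times == 0.0] = 0.0
    else:
        c_blood = np.zeros_like(times)
    BLOOD_T1_MS = 2200.0
    vessel_raw = np.array([
        spgr_signal(1000.0 / _tissue_r1_per_s(BLOOD_T1_MS, c, 0.0, probe),
                    params.tr_ms, params.flip_deg, 1.0)
        for c in c_blood])
    vessel_sig = 3.0 * true["liver"][0] * vessel_raw / vessel_raw[0]

    frames = np.zeros((len(times),) + tuple(params.matrix))
    for i in range(len(times)):
        frames[i][masks["liver"].voxels] = true["liver"][i]
        frames[i][masks["muscle"].voxels] = true["muscle"][i]
        frames[i][vessel] = vessel_sig[i]
    frames = add_rician_noise(frames, params.noise_sigma, rng)

    meta = _base_meta(state, masks)
    meta["vessel_mask"] = ROIMask(vessel, "vessel")
    meta["probe"] = probe
    meta["true_signals"] = true
    return ImageSeries(frames, "DCE", times, params, meta)
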