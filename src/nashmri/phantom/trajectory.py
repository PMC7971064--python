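"""Group-level disease trajectory for the CDAHFD mouse NASH study design.

The trajectory is a lookup table of group means and dispersions for the
quantities the imaging pipeline measures: liver T1 and T2*, Dixon fat
percentage, morphometric lipid vacuolization (LV) and collagen proportional
area (CPA).  The nine groups are the study design: normal chow at 2/6/10/14
weeks, CDAHFD at 2/6/10/14 weeks, and diet withdrawal (CDAHFD for 10 weeks
then normal chow, examined at week 14).

Where a group mean was reported, the entry stores it verbatim together with
a short provenance note; weeks for which only the qualitative trend was
reported (the mid-diet fat percentage and T1/T2* values) are linearly
interpolated between the reported endpoints and flagged ``interpolated``.
Tissue allysine concentration — the binding target of the fibrogenesis
probe — is not directly measurable by any modality simulated here, so its
trajectory is a model parameter chosen to track reported lysyl-oxidase
activity (peaking at week 10 on diet, dropping on withdrawal).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Diet",
    "Quantity",
    "GroupEntry",
    "DiseaseTrajectory",
    "TissueState",
    "build_trajectory",
    "sample_tissue_state",
    "STUDY_WEEKS",
]

STUDY_WEEKS = (2, 6, 10, 14)


class Diet(str, enum.Enum):
    """Feeding arm of the study."""

    NORMAL_CHOW = "normal_chow"
    CDAHFD = "cdahfd"
    WITHDRAWAL = "withdrawal"


@dataclass(frozen=True)
class Quantity:
    """A group mean with its dispersion (SEM) and provenance."""

    mean: float
    sem: float
    source: str
    interpolated: bool = False

    def __post_init__(self) -> None:
        if self.sem < 0:
            raise ValueError("dispersion must be non-negative")

    def sd(self, n: int) -> float:
        """Between-animal SD implied by the SEM at group size ``n``."""
        return self.sem * np.sqrt(n)


@dataclass(frozen=True)
class GroupEntry:
    """All tracked quantities for one (diet, week) group."""

    diet: Diet
    week: int
    n: int
    t1_ms: Quantity
    t2star_ms: Quantity
    fat_pct: Quantity
    lv_pct: Quantity
    cpa_pct: Quantity
    allysine_uM: Quantity
    # Metadata only: wet-lab quantities carried for context, never simulated
    # from (hydroxyproline μg/g) or used as simulation input (reported DCE
    # AUCs, which the DCE simulator should approximately reproduce).
    hyp_ug_per_g: Quantity | None = None
    auc_pct_dsnr: Quantity | None = None


def _q(mean: float, sem: float, source: str, interp: bool = False) -> Quantity:
    return Quantity(mean, sem, source, interp)


def _interp(w: int, w0: int, w1: int, q0: Quantity, q1: Quantity, what: str) -> Quantity:
    f = (w - w0) / (w1 - w0)
    return Quantity(
        round(q0.mean + f * (q1.mean - q0.mean), 2),
        round(q0.sem + f * (q1.sem - q0.sem), 2),
        f"linear interpolation of {what} between week {w0} and week {w1}",
        interpolated=True,
    )


@dataclass(frozen=True)
class DiseaseTrajectory:
    """Lookup table of group means/dispersions for all nine study groups."""

    entries: dict[tuple[Diet, int], GroupEntry] = field(default_factory=dict)

    def lookup(self, diet: Diet | str, week: int) -> GroupEntry:
        key = (Diet(diet), int(week))
        if key not in self.entries:
            raise KeyError(f"no study group for diet={key[0].value}, week={key[1]}")
        return self.entries[key]

    def groups(self) -> list[tuple[Diet, int]]:
        return sorted(self.entries, key=lambda k: (k[0].value, k[1]))


def build_trajectory() -> DiseaseTrajectory:
    """Construct the study's group-mean table.

    Reported means are entered as printed (mean ± SEM); mid-diet weeks
    without a printed value are interpolated and flagged as such.
    """
    nc, cd, wd = Diet.NORMAL_CHOW, Diet.CDAHFD, Diet.WITHDRAWAL

    # --- reported endpoints -------------------------------------------------
    t1_nc_2 = _q(968.0, 32.0, "control week-2 liver T1, 968 ± 32 ms")
    t1_nc_14 = _q(1020.0, 11.0, "control week-14 liver T1, 1020 ± 11 ms")
    t1_cd_2 = _q(754.0, 19.0, "CDAHFD week-2 liver T1, 754 ± 19 ms")
    t1_cd_14 = _q(925.0, 24.0, "CDAHFD week-14 liver T1, 925 ± 24 ms")
    t1_wd = _q(944.0, 18.0, "withdrawal week-14 liver T1, 944 ± 18 ms")

    t2_nc_2 = _q(7.20, 0.23, "control week-2 liver T2*, 7.20 ± 0.23 ms")
    t2_nc_14 = _q(7.24, 0.50, "control week-14 liver T2*, 7.24 ± 0.50 ms")
    t2_cd_2 = _q(5.90, 0.11, "CDAHFD week-2 liver T2*, 5.90 ± 0.11 ms")
    t2_cd_14 = _q(5.37, 0.18, "CDAHFD week-14 liver T2*, 5.37 ± 0.18 ms")
    t2_wd = _q(6.56, 0.18, "withdrawal week-14 liver T2*, 6.56 ± 0.18 ms")

    fat_nc_2 = _q(2.41, 0.17, "control week-2 MRI fat, 2.41 ± 0.17 %")
    fat_nc_14 = _q(4.04, 0.64, "control week-14 MRI fat, 4.04 ± 0.64 %")
    fat_cd_2 = _q(19.00, 0.64, "CDAHFD week-2 MRI fat, 19.00 ± 0.64 %")
    fat_cd_14 = _q(9.24, 0.35, "CDAHFD week-14 MRI fat, 9.24 ± 0.35 %")
    fat_wd = _q(2.41, 0.17, "withdrawal week-14 MRI fat, 2.41 ± 0.17 %")

    lv = {
        (nc, 2): _q(3.28, 0.48, "control week-2 LV, 3.28 ± 0.48 %"),
        (nc, 6): _q(3.40, 0.45, "control mid-diet LV, reported <4 % throughout", True),
        (nc, 10): _q(3.40, 0.45, "control mid-diet LV, reported <4 % throughout", True),
        (nc, 14): _q(3.47, 0.42, "control week-14 LV, 3.47 ± 0.42 %"),
        (cd, 2): _q(22.90, 1.45, "CDAHFD week-2 LV, 22.90 ± 1.45 %"),
        (cd, 6): _q(30.91, 1.11, "CDAHFD week-6 LV, 30.91 ± 1.11 %"),
        (cd, 10): _q(17.28, 0.82, "CDAHFD week-10 LV, 17.28 ± 0.82 %"),
        (cd, 14): _q(14.10, 1.35, "CDAHFD week-14 LV, 14.10 ± 1.35 %"),
        (wd, 14): _q(5.17, 0.66, "withdrawal week-14 LV, 5.17 ± 0.66 %"),
    }
    cpa = {
        (nc, 2): _q(1.47, 0.21, "control week-2 CPA, 1.47 ± 0.21 %"),
        (nc, 6): _q(1.08, 0.07, "control week-6 CPA, 1.08 ± 0.07 %"),
        (nc, 10): _q(2.02, 0.46, "control week-10 CPA, 2.02 ± 0.46 %"),
        (nc, 14): _q(1.43, 0.16, "control week-14 CPA, 1.43 ± 0.16 %"),
        (cd, 2): _q(3.48, 0.40, "CDAHFD week-2 CPA, 3.48 ± 0.40 %"),
        (cd, 6): _q(6.57, 0.27, "CDAHFD week-6 CPA, 6.57 ± 0.27 %"),
        (cd, 10): _q(12.04, 0.91, "CDAHFD week-10 CPA, 12.04 ± 0.91 %"),
        (cd, 14): _q(16.57, 1.19, "CDAHFD week-14 CPA, 16.57 ± 1.19 %"),
        (wd, 14): _q(12.34, 0.85, "withdrawal week-14 CPA, 12.34 ± 0.85 %"),
    }
    hyp = {
        (nc, 2): _q(206.0, 23.0, "control week-2 hydroxyproline, 206 ± 23 μg/g"),
        (nc, 14): _q(276.4, 11.2, "control week-14 hydroxyproline, 276.4 ± 11.2 μg/g"),
        (cd, 2): _q(260.0, 29.0, "CDAHFD week-2 hydroxyproline, 260 ± 29 μg/g"),
        (cd, 14): _q(1300.0, 95.0, "CDAHFD week-14 hydroxyproline, 1300 ± 95 μg/g"),
        (wd, 14): _q(634.0, 32.0, "withdrawal week-14 hydroxyproline, 634 ± 32 μg/g"),
    }
    auc = {
        (cd, 2): _q(2030.0, 530.0, "CDAHFD week-2 %ΔSNR AUC, 2030 ± 530"),
        (cd, 6): _q(2400.0, 710.0, "CDAHFD week-6 %ΔSNR AUC, 2400 ± 710"),
        (cd, 10): _q(3750.0, 360.0, "CDAHFD week-10 %ΔSNR AUC, 3750 ± 360"),
        (cd, 14): _q(2350.0, 210.0, "CDAHFD week-14 %ΔSNR AUC, 2350 ± 210"),
        (wd, 14): _q(1530.0, 140.0, "withdrawal week-14 %ΔSNR AUC, 1530 ± 140"),
    }

    # Tissue allysine (μM): model parameter tracking lysyl-oxidase activity
    # (peak at week 10 on diet, large drop after withdrawal); calibrated once
    # so the DCE simulator lands in the reported %ΔSNR AUC range.
    ALLY_SRC = "model parameter, tracks lysyl-oxidase activity trend"
    ally = {
        (nc, 2): _q(70.0, 9.0, ALLY_SRC, True),
        (nc, 6): _q(70.0, 9.0, ALLY_SRC, True),
        (nc, 10): _q(70.0, 9.0, ALLY_SRC, True),
        (nc, 14): _q(70.0, 9.0, ALLY_SRC, True),
        (cd, 2): _q(315.0, 35.0, ALLY_SRC, True),
        (cd, 6): _q(355.0, 40.0, ALLY_SRC, True),
        (cd, 10): _q(570.0, 60.0, ALLY_SRC, True),
        (cd, 14): _q(285.0, 32.0, ALLY_SRC, True),
        (wd, 14): _q(150.0, 18.0, ALLY_SRC, True),
    }

    group_n = {
        (nc, 2): 6, (nc, 6): 6, (nc, 10): 9, (nc, 14): 5,
        (cd, 2): 6, (cd, 6): 6, (cd, 10): 12, (cd, 14): 12,
        (wd, 14): 8,
    }

    def endpoint(diet: Diet, week: int, q2: Quantity, q14: Quantity, what: str) -> Quantity:
        if week == 2:
            return q2
        if week == 14:
            return q14
        return _interp(week, 2, 14, q2, q14, what)

    entries: dict[tuple[Diet, int], GroupEntry] = {}
    for key, n in group_n.items():
        diet, week = key
        if diet is wd:
            t1, t2s, fat = t1_wd, t2_wd, fat_wd
        elif diet is nc:
            t1 = endpoint(diet, week, t1_nc_2, t1_nc_14, "control T1")
            t2s = endpoint(diet, week, t2_nc_2, t2_nc_14, "control T2*")
            fat = endpoint(diet, week, fat_nc_2, fat_nc_14, "control %fat")
        else:
            t1 = endpoint(diet, week, t1_cd_2, t1_cd_14, "CDAHFD T1")
            t2s = endpoint(diet, week, t2_cd_2, t2_cd_14, "CDAHFD T2*")
            fat = endpoint(diet, week, fat_cd_2, fat_cd_14, "CDAHFD %fat")
        entries[key] = GroupEntry(
            diet=diet, week=week, n=n,
            t1_ms=t1, t2star_ms=t2s, fat_pct=fat,
            lv_pct=lv[key], cpa_pct=cpa[key], allysine_uM=ally[key],
            hyp_ug_per_g=hyp.get(key), auc_pct_dsnr=auc.get(key),
        )
    return DiseaseTrajectory(entries)


@dataclass(frozen=True)
class TissueState:
    """Latent per-animal ground truth driving every simulator."""

    diet: Diet
    week: int
    lv_frac: float
    collagen_frac: float
    allysine_uM: float
    t1_ms: float
    t2star_ms: float
    fat_signal_frac: float
    seed: int = 0

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("lv_frac", 0.0, 1.0),
            ("collagen_frac", 0.0, 1.0),
            ("fat_signal_frac", 0.0, 0.5),
        ):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.t1_ms <= 0 or self.t2star_ms <= 0:
            raise ValueError("relaxation times must be positive")
        if self.allysine_uM < 0:
            raise ValueError("allysine_uM must be non-negative")


# Correlation between the fat-driven quantities and T1: shorter T1 with more
# fat, as observed across the cohort (T1 tracks steatosis, not fibrosis).
_RHO_FAT_T1 = 0.6

_BOUNDS = {
    "fat": (0.0, 50.0),      # percent of signal, water-dominant regime
    "lv": (0.0, 100.0),
    "cpa": (0.0, 100.0),
    "t1": (1.0, np.inf),
    "t2": (0.1, np.inf),
    "ally": (0.0, np.inf),
}


def sample_tissue_state(
    trajectory: DiseaseTrajectory,
    diet: Diet | str,
    week: int,
    seed: int,
    dispersion_scale: float = 1.0,
) -> TissueState:
    """Draw one animal's latent tissue state from its group distribution.

    Per-animal values are truncated-normal draws at the group mean with SD
    equal to the printed SEM scaled by √n (between-animal spread), times
    ``dispersion_scale``.  Fat fraction and LV share one latent deviate, as
    do collagen and allysine, so that quantities derived from the same
    biology co-vary within a cohort; T1 is negatively coupled to the fat
    deviate.  ``dispersion_scale=0`` returns the group means exactly.
    Identical arguments always return an identical state.
    """
    g = trajectory.lookup(diet, week)
    rng = np.random.default_rng(seed)

    def draw(q: Quantity, z: float, bounds: tuple[float, float]) -> float:
        lo, hi = bounds
        sd = q.sd(g.n) * dispersion_scale
        v = q.mean + sd * z
        # Truncated draw: redraw the deviate until inside physical bounds
        # (means sit far from the bounds, so this almost never loops).
        tries = 0
        while not (lo <= v <= hi):
            v = q.mean + sd * rng.standard_normal()
            tries += 1
            if tries > 200:
                v = float(np.clip(v, lo, hi))
                break
        return float(v)

    z_fat = float(rng.standard_normal())
    z_fib = float(rng.standard_normal())
    z_t1 = float(rng.standard_normal())
    z_t2 = float(rng.standard_normal())
    z_t1_mixed = -_RHO_FAT_T1 * z_fat + np.sqrt(1 - _RHO_FAT_T1**2) * z_t1

    fat_pct = draw(g.fat_pct, z_fat, _BOUNDS["fat"])
    lv_pct = draw(g.lv_pct, z_fat, _BOUNDS["lv"])
    cpa_pct = draw(g.cpa_pct, z_fib, _BOUNDS["cpa"])
    ally = draw(g.allysine_uM, z_fib, _BOUNDS["ally"])
    t1 = draw(g.t1_ms, z_t1_mixed, _BOUNDS["t1"])
    t2s = draw(g.t2star_ms, z_t2, _BOUNDS["t2"])

    return TissueState(
        diet=Diet(diet), week=int(week),
        lv_frac=lv_pct / 100.0, collagen_frac=cpa_pct / 100.0,
        allysine_uM=ally, t1_ms=t1, t2star_ms=t2s,
        fat_signal_frac=fat_pct / 100.0, seed=int(seed),
    )


def state_from_means(trajectory: DiseaseTrajectory, diet: Diet | str, week: int) -> TissueState:
    """The noiseless 'group-mean animal' — convenience for tests and demos."""
    return sample_tissue_state(trajectory, diet, week, seed=0, dispersion_scale=0.0)
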