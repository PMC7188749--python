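"""Synthetic study generator.

Emulates the three-armed volunteer study at desk scale: a 32-person cohort
(10 radiotracer / 12 static-field / 10 combined, with the published sex
splits and anthropometry), per-volunteer blood time-activity curves and
dose reports, and per-slide gammaH2AX foci-count tables for every
condition of the sampling/incubation protocol.

The per-cell foci-count model is a zero-inflated (responsive-subpopulation)
Poisson: a cell carries at least one focus with probability equal to the
condition's damage rate, in which case its count is zero-truncated
Poisson(``focus_mean``); a rare uniform 3..8 "artifact" component emulates
spurious detections of the automatic scorer and feeds the >5-foci exclusion
filter.  Defaults are calibrated so that at the study-average damage rate
the class probabilities for 0, 1 and 2 foci per cell reproduce the
published spectrum (98.58 / 1.292 / 0.093 %).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import poisson

from .blood import BloodKineticsParams, TimeActivityCurve, Volunteer, sample_tac
from .dosimetry import (
    INCUBATION_TIMES_MIN,
    DoseReport,
    PhysicsConstants,
    TubeSAFTable,
    dose_report,
)

__all__ = [
    "REFERENCE_FOCUS_SPECTRUM_PCT",
    "ArmSpec",
    "CohortParams",
    "FociGeneratorParams",
    "StudyData",
    "generate_cohort",
    "focus_class_probabilities",
    "sample_cell_focus_count",
    "condition_plan",
    "generate_foci_table",
    "generate_study",
]

#: Published study-wide per-cell foci spectrum, percent of cells with
#: 0, 1, 2, 3, 4, 5 and >5 foci.
REFERENCE_FOCUS_SPECTRUM_PCT = (98.58, 1.292, 0.093, 0.020, 0.007, 0.004, 0.004)

#: Damage rate (percent of cells with >=1 focus, before artifact override)
#: at which the calibrated generator reproduces the published 0/1/2-foci
#: class probabilities exactly.
SPECTRUM_MATCHING_RATE_PCT = 1.3901

FOCI_CLASS_COLUMNS = ["n_foci_0", "n_foci_1", "n_foci_2", "n_foci_3", "n_foci_4", "n_foci_5"]


@dataclass(frozen=True)
class ArmSpec:
    """Group characteristics of one study arm (mean, SD, range as published)."""

    name: str
    n_male: int
    n_female: int
    age: tuple[float, float, float, float]  # mean, sd, lo, hi
    weight_kg: tuple[float, float, float, float]
    bmi: tuple[float, float, float, float]
    fdg_exposed: bool = True

    @property
    def n(self) -> int:
        return self.n_male + self.n_female


@dataclass(frozen=True)
class CohortParams:
    """The three-arm allocation with published group statistics."""

    arms: tuple[ArmSpec, ...] = (
        ArmSpec("SA1", 5, 5, (26.0, 3.1, 22, 32), (77.0, 11.3, 63, 100), (25.2, 3.8, 20.3, 33.4)),
        ArmSpec("SA2", 4, 8, (25.1, 2.2, 23, 30), (64.7, 9.5, 46, 80), (21.5, 2.0, 18.0, 24.7), fdg_exposed=False),
        ArmSpec("SA3", 5, 5, (24.8, 2.7, 21, 30), (72.9, 9.7, 59, 87), (23.7, 2.5, 19.5, 28.1)),
    )
    activity_MBq_per_kg: float = 4.3
    activity_jitter_cv: float = 0.05


from functools import lru_cache


@lru_cache(maxsize=None)
def _truncnorm_location(mean: float, sd: float, lo: float, hi: float) -> float:
    """Latent location of a normal truncated to [lo, hi] whose truncated
    mean equals ``mean`` (published group means are sample means of the
    bounded data, so the location must be shifted to compensate)."""
    from scipy.stats import truncnorm as _tn

    def trunc_mean(mu: float) -> float:
        a, b = (lo - mu) / sd, (hi - mu) / sd
        return float(_tn.mean(a, b, loc=mu, scale=sd))

    span = hi - lo
    return brentq(lambda m: trunc_mean(m) - mean, lo - 2 * span, hi + 2 * span, xtol=1e-10)


def _truncnorm_matching_mean(
    mean: float, sd: float, lo: float, hi: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample a [lo, hi]-truncated normal whose truncated mean is ``mean``,
    by rejection from the location-adjusted parent normal."""
    mu = _truncnorm_location(mean, sd, lo, hi)
    out = np.empty(0)
    while out.size < size:
        draw = rng.normal(mu, sd, size=max(4 * size, 16))
        out = np.concatenate([out, draw[(draw >= lo) & (draw <= hi)]])
    return out[:size]


def generate_cohort(
    seed: int | np.random.Generator = 0, params: CohortParams | None = None
) -> list[Volunteer]:
    """Draw the 32-volunteer cohort.

    Weight, BMI and age are truncated normals matched to the published
    per-arm mean/SD/range; height follows from weight and BMI; the
    administered activity is 4.3 MBq/kg of body weight with a small
    multiplicative jitter (radiotracer arms only).
    """
    p = params or CohortParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    volunteers: list[Volunteer] = []
    for arm in p.arms:
        n = arm.n
        ages = _truncnorm_matching_mean(*arm.age, n, rng)
        weights = _truncnorm_matching_mean(*arm.weight_kg, n, rng)
        bmis = _truncnorm_matching_mean(*arm.bmi, n, rng)
        heights = np.sqrt(weights / bmis)
        sexes = ["M"] * arm.n_male + ["F"] * arm.n_female
        if arm.fdg_exposed:
            sigma = math.sqrt(math.log1p(p.activity_jitter_cv**2))
            activities = p.activity_MBq_per_kg * weights * np.exp(rng.normal(0, sigma, n))
        else:
            activities = [None] * n
        for i in range(n):
            volunteers.append(
                Volunteer(
                    id=f"{arm.name}-{i + 1:02d}",
                    arm=arm.name,
                    sex=sexes[i],
                    age=float(ages[i]),
                    height_m=float(heights[i]),
                    weight_kg=float(weights[i]),
                    administered_activity_MBq=(None if activities[i] is None else float(activities[i])),
                )
            )
    return volunteers


@dataclass(frozen=True)
class FociGeneratorParams:
    """Calibrated parameters of the foci-count generator.

    ``focus_mean`` and ``artifact_prob`` solve the published 0/1/2-foci
    class probabilities exactly at the study-average damage rate (see
    module docstring); the remaining fields set the background level and
    dispersion, the linear dose response of the binary damage rate, the
    venipuncture artifact at immediate fixation, and the slide layout.
    """

    focus_mean: float = 0.143963
    artifact_prob: float = 3.033e-4
    artifact_range: tuple[int, int] = (3, 8)
    background_rate_median_pct: float = 1.04
    background_rate_sd_pct: float = 0.35
    dose_slope_pct_per_mGy: float = 0.095
    venipuncture_excess_pct: float = 0.16
    venipuncture_variance_ratio: float = 7.56
    slide_count_probs: tuple[float, ...] = (0.01, 0.01, 0.02, 0.03, 0.04, 0.06, 0.10, 0.18, 0.35, 0.20)
    cells_per_slide_median: int = 2009
    cells_per_slide_sigma: float = 0.25
    cells_per_slide_min: int = 1002
    rate_floor_pct: float = 0.02

    def __post_init__(self) -> None:
        if not 0 < self.focus_mean:
            raise ValueError("focus_mean must be positive")
        if not 0 <= self.artifact_prob < 1:
            raise ValueError("artifact_prob must be in [0, 1)")
        if self.dose_slope_pct_per_mGy < 0:
            raise ValueError("dose slope must be non-negative")
        if abs(sum(self.slide_count_probs) - 1.0) > 1e-9 or len(self.slide_count_probs) != 10:
            raise ValueError("slide_count_probs must be 10 probabilities summing to 1")

    @property
    def venipuncture_excess_sd_pct(self) -> float:
        """SD of the venipuncture excess chosen so that the across-volunteer
        variance of immediate-fixation rates is ``venipuncture_variance_ratio``
        times the background variance."""
        extra = max(self.venipuncture_variance_ratio - 1.0, 0.0)
        return self.background_rate_sd_pct * math.sqrt(extra)


def _ztp_pmf(mu: float, kmax: int = 16) -> np.ndarray:
    """Zero-truncated Poisson pmf over counts 1..kmax (tail folded into kmax)."""
    k = np.arange(1, kmax + 1)
    pmf = poisson.pmf(k, mu) / -math.expm1(-mu)
    pmf[-1] += max(1.0 - pmf.sum(), 0.0)  # fold the far tail into kmax
    return pmf


def focus_class_probabilities(
    params: FociGeneratorParams, condition_rate_pct: float
) -> np.ndarray:
    """Analytic per-cell probabilities of the classes 0..5 and >5 foci.

    A cell is responsive with probability ``condition_rate_pct``/100 and
    then draws a zero-truncated Poisson count; independently, with
    ``artifact_prob`` the count is replaced by a uniform draw on
    ``artifact_range``.
    """
    if not 0 <= condition_rate_pct <= 100:
        raise ValueError("condition rate must be a percentage in [0, 100]")
    q = condition_rate_pct / 100.0
    a = params.artifact_prob
    ztp = _ztp_pmf(params.focus_mean)
    base = np.zeros(17)
    base[0] = 1.0 - q
    base[1:] = q * ztp
    p = (1.0 - a) * base
    lo, hi = params.artifact_range
    p[lo : hi + 1] += a / (hi - lo + 1)
    out = np.empty(7)
    out[:6] = p[:6]
    out[6] = p[6:].sum()
    return out


def sample_cell_focus_count(
    params: FociGeneratorParams,
    condition_rate_pct: float,
    rng: np.random.Generator,
    size: int = 1,
) -> np.ndarray:
    """Draw per-cell foci counts (integers >= 0) for one condition."""
    if not 0 <= condition_rate_pct <= 100:
        raise ValueError("condition rate must be a percentage in [0, 100]")
    q = condition_rate_pct / 100.0
    counts = np.zeros(size, dtype=np.int64)
    responsive = rng.random(size) < q
    n_resp = int(responsive.sum())
    if n_resp:
        ztp = _ztp_pmf(params.focus_mean)
        cdf = np.cumsum(ztp)
        draws = 1 + np.searchsorted(cdf, rng.random(n_resp) * cdf[-1])
        counts[responsive] = draws
    artifact = rng.random(size) < params.artifact_prob
    n_art = int(artifact.sum())
    if n_art:
        lo, hi = params.artifact_range
        counts[artifact] = rng.integers(lo, hi + 1, size=n_art)
    return counts


def _slide_class_counts(
    params: FociGeneratorParams, rate_pct: float, n_cells: int, rng: np.random.Generator
) -> np.ndarray:
    """Multinomial class counts (0..5, >5) for one slide -- equivalent in
    distribution to per-cell sampling, but O(1) in the cell count."""
    probs = focus_class_probabilities(params, rate_pct)
    return rng.multinomial(n_cells, probs / probs.sum())


def condition_plan(arm: str) -> list[tuple[str, int]]:
    """The (sampling point, incubation time) conditions realised for an arm:
    pre-exposure samples at immediate fixation and 60-min incubation, the
    post-imaging-component sample (radiotracer arms), and the post-exposure
    series over all incubation times."""
    plan: list[tuple[str, int]] = [("SP1", 0), ("SP1", 60)]
    if arm in ("SA1", "SA3"):
        plan.append(("SP2", 60))
    plan.extend(("SP3", it) for it in INCUBATION_TIMES_MIN)
    return plan


def _condition_rate(
    arm: str,
    sp: str,
    it: int,
    background_pct: float,
    venipuncture_pct: float,
    dose_rep: DoseReport,
    params: FociGeneratorParams,
) -> float:
    rate = background_pct
    if sp == "SP1" and it == 0:
        rate += venipuncture_pct
    if sp == "SP3" and arm in ("SA1", "SA3"):
        rate += params.dose_slope_pct_per_mGy * dose_rep.D_total_mGy[it]
    return float(min(max(rate, params.rate_floor_pct), 100.0))


def generate_foci_table(
    volunteer: Volunteer,
    dose_rep: DoseReport | None,
    params: FociGeneratorParams | None = None,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Per-slide foci-class counts for all conditions of one volunteer.

    The volunteer's true background rate is drawn once; the immediate-
    fixation sample adds a venipuncture excess with inflated variance; the
    post-exposure samples of radiotracer arms add a linear dose response on
    the total dose accrued by the respective incubation time.
    """
    p = params or FociGeneratorParams()
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if volunteer.is_fdg_exposed:
        if dose_rep is None:
            raise ValueError("FDG-exposed volunteers require a dose report")
    else:
        dose_rep = dose_rep or DoseReport.zeros(volunteer.id)

    background = -1.0
    while background <= p.rate_floor_pct:
        background = gen.normal(p.background_rate_median_pct, p.background_rate_sd_pct)
    venipuncture = gen.normal(p.venipuncture_excess_pct, p.venipuncture_excess_sd_pct)

    rows = []
    for sp, it in condition_plan(volunteer.arm):
        rate = _condition_rate(volunteer.arm, sp, it, background, venipuncture, dose_rep, p)
        n_slides = 1 + int(gen.choice(10, p=p.slide_count_probs))
        for slide in range(1, n_slides + 1):
            n_cells = max(
                int(round(p.cells_per_slide_median * math.exp(gen.normal(0, p.cells_per_slide_sigma)))),
                p.cells_per_slide_min,
            )
            classes = _slide_class_counts(p, rate, n_cells, gen)
            rows.append(
                {
                    "volunteer_id": volunteer.id,
                    "arm": volunteer.arm,
                    "sampling_point": sp,
                    "incubation_min": it,
                    "slide_id": slide,
                    "n_cells_scanned": n_cells,
                    **{col: int(c) for col, c in zip(FOCI_CLASS_COLUMNS, classes[:6])},
                    "n_excluded_gt5": int(classes[6]),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class StudyData:
    """Everything the analysis pipeline consumes."""

    volunteers: list[Volunteer]
    tacs: dict[str, TimeActivityCurve]
    dose_reports: dict[str, DoseReport]
    foci: pd.DataFrame
    saf_table: TubeSAFTable
    seed: int | None = None


def generate_study(
    seed: int = 0,
    cohort_params: CohortParams | None = None,
    kinetics_params: BloodKineticsParams | None = None,
    foci_params: FociGeneratorParams | None = None,
    constants: PhysicsConstants | None = None,
    saf_table: TubeSAFTable | None = None,
    saf_histories: int = 100_000,
    tac_noise_cv: float = 0.05,
    phi_gamma_body: float = 0.33,
    tube_volume_range_ml: tuple[float, float] = (3.0, 7.5),
) -> StudyData:
    """End-to-end synthetic study: cohort, TACs, dose reports, foci tables.

    Deterministic for a fixed seed: every volunteer gets an independent
    child random stream, so the data of volunteer k do not depend on how
    many draws earlier volunteers consumed.
    """
    ss = np.random.SeedSequence(seed)
    s_cohort, s_saf, s_vols = ss.spawn(3)
    kin = kinetics_params or BloodKineticsParams()
    fp = foci_params or FociGeneratorParams()
    consts = constants or PhysicsConstants()
    volunteers = generate_cohort(np.random.default_rng(s_cohort), cohort_params)
    table = saf_table or TubeSAFTable.compute(
        n_histories=saf_histories, seed=int(s_saf.generate_state(1)[0] % (2**31))
    )
    tacs: dict[str, TimeActivityCurve] = {}
    reports: dict[str, DoseReport] = {}
    tables: list[pd.DataFrame] = []
    for child, vol in zip(s_vols.spawn(len(volunteers)), volunteers):
        rng = np.random.default_rng(child)
        if vol.is_fdg_exposed:
            v_params = kin.individualized(rng)
            tac = sample_tac(v_params, vol, noise_cv=tac_noise_cv, rng=rng)
            volumes = {it: float(rng.uniform(*tube_volume_range_ml)) for it in INCUBATION_TIMES_MIN}
            rep = dose_report(tac, vol, table, consts, tube_volumes_ml=volumes, phi_gamma_body=phi_gamma_body)
            tacs[vol.id] = tac
        else:
            rep = DoseReport.zeros(vol.id)
        reports[vol.id] = rep
        tables.append(generate_foci_table(vol, rep, fp, rng))
    return StudyData(
        volunteers=volunteers,
        tacs=tacs,
        dose_reports=reports,
        foci=pd.concat(tables, ignore_index=True),
        saf_table=table,
        seed=seed,
    )
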