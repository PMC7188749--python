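"""Blood kinetics of [18F]FDG.

Anthropometric blood volume (Nadler), a three-exponential surrogate for the
blood concentration-time course after bolus injection, and framed
time-activity curves (TACs) as measured over the aorta by dynamic PET.

Concentrations are carried in kBq/ml, times internally in minutes post
injection (p.i.); frame boundaries in files and in :class:`TimeActivityCurve`
are in seconds, matching the PET reconstruction convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "F18_HALF_LIFE_MIN",
    "Volunteer",
    "BloodKineticsParams",
    "TimeActivityCurve",
    "blood_volume",
    "concentration",
    "default_frame_schedule",
    "sample_tac",
    "integrate_tac",
]

#: Physical half-life of fluorine-18 in minutes.
F18_HALF_LIFE_MIN = 109.77

_ARMS = ("SA1", "SA2", "SA3")
_FDG_ARMS = ("SA1", "SA3")


@dataclass(frozen=True)
class Volunteer:
    """A study participant.

    Parameters
    ----------
    id : str
        Volunteer identifier.
    arm : {"SA1", "SA2", "SA3"}
        Study arm: radiotracer alone, static field alone, or both combined.
    sex : {"M", "F"}
    age : float
        Age in years.
    height_m : float
        Body height in metres.
    weight_kg : float
        Body weight in kilograms.
    administered_activity_MBq : float or None
        Injected [18F]FDG activity.  ``None`` for arm SA2, which receives
        no radiotracer.
    """

    id: str
    arm: str
    sex: str
    age: float
    height_m: float
    weight_kg: float
    administered_activity_MBq: float | None = None

    def __post_init__(self) -> None:
        if self.arm not in _ARMS:
            raise ValueError(f"unknown study arm {self.arm!r}")
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if not self.height_m > 0 or not self.weight_kg > 0:
            raise ValueError("height and weight must be positive")
        if self.arm in _FDG_ARMS:
            if self.administered_activity_MBq is None or self.administered_activity_MBq <= 0:
                raise ValueError(f"arm {self.arm} requires a positive administered activity")
        elif self.administered_activity_MBq is not None:
            raise ValueError("arm SA2 volunteers receive no radiotracer")

    @property
    def is_fdg_exposed(self) -> bool:
        return self.arm in _FDG_ARMS

    @property
    def blood_volume_l(self) -> float:
        return blood_volume(self.sex, self.height_m, self.weight_kg)


def blood_volume(sex: str, height_m: float, weight_kg: float) -> float:
    """Total blood volume in litres from Nadler's sex-specific formula.

    V = 0.3669 h^3 + 0.03219 w + 0.6041 (men) or
    V = 0.3561 h^3 + 0.03308 w + 0.1833 (women), h in m, w in kg.
    """
    if height_m <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be positive")
    if sex == "M":
        return 0.3669 * height_m**3 + 0.03219 * weight_kg + 0.6041
    if sex == "F":
        return 0.3561 * height_m**3 + 0.03308 * weight_kg + 0.1833
    raise ValueError(f"sex must be 'M' or 'F', got {sex!r}")


@dataclass(frozen=True)
class BloodKineticsParams:
    """Three-exponential surrogate for the FDG blood clearance curve.

    The activity concentration is modelled as

        c(t) = (A0/V) * sum_i f_i 2^(-t/T_i) * 2^(-t/T_phys)

    with fast vascular mixing (T1), intermediate tissue uptake (T2) and a
    near-constant residual component (T3), all damped by physical decay.
    ``f3_cv`` and ``t2_cv`` are lognormal (median-preserving) dispersion
    coefficients applied per volunteer by :meth:`individualized`.
    """

    fractions: tuple[float, float, float] = (0.73, 0.20, 0.07)
    half_times_min: tuple[float, float, float] = (2.0, 20.0, 5000.0)
    physical_half_life_min: float = F18_HALF_LIFE_MIN
    f3_cv: float = 0.25
    t2_cv: float = 0.25

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if any(f < 0 for f in self.fractions):
            raise ValueError("fractions must be non-negative")
        if any(t <= 0 for t in self.half_times_min) or self.physical_half_life_min <= 0:
            raise ValueError("half-times must be positive")
        if self.f3_cv < 0 or self.t2_cv < 0:
            raise ValueError("dispersion CVs must be non-negative")

    def individualized(self, rng: np.random.Generator) -> "BloodKineticsParams":
        """Draw per-volunteer kinetics: lognormal jitter on f3 and T2.

        The multipliers have median 1 so the population medians equal the
        defaults.  Fractions are renormalised to keep their sum at 1.
        """
        sigma_f = np.sqrt(np.log1p(self.f3_cv**2))
        sigma_t = np.sqrt(np.log1p(self.t2_cv**2))
        f1, f2, f3 = self.fractions
        f3_new = min(f3 * float(np.exp(rng.normal(0.0, sigma_f))), 0.9)
        scale = (1.0 - f3_new) / (f1 + f2)
        t1, t2, t3 = self.half_times_min
        t2_new = t2 * float(np.exp(rng.normal(0.0, sigma_t)))
        return replace(
            self,
            fractions=(f1 * scale, f2 * scale, f3_new),
            half_times_min=(t1, t2_new, t3),
        )


def concentration(
    params: BloodKineticsParams,
    volunteer: Volunteer,
    t_min: float | np.ndarray,
) -> float | np.ndarray:
    """Model blood activity concentration in kBq/ml at ``t_min`` min p.i.

    At t=0 this equals A0/V_blood (MBq/l == kBq/ml).  Negative times raise.
    """
    t = np.asarray(t_min, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    if not volunteer.is_fdg_exposed:
        out = np.zeros_like(t)
        return float(out) if np.isscalar(t_min) else out
    c0 = volunteer.administered_activity_MBq / volunteer.blood_volume_l
    mix = sum(
        f * np.exp2(-t / half)
        for f, half in zip(params.fractions, params.half_times_min)
    )
    c = c0 * mix * np.exp2(-t / params.physical_half_life_min)
    return float(c) if np.isscalar(t_min) else c


@dataclass(frozen=True)
class TimeActivityCurve:
    """Framed blood concentration measurements for one volunteer.

    Frames are half-open intervals ``[t_start, t_end)`` in seconds p.i.,
    contiguous and non-overlapping; concentrations in kBq/ml refer to the
    frame average and are attached to the frame midpoint for integration.
    """

    volunteer_id: str
    frame_start_s: np.ndarray
    frame_end_s: np.ndarray
    conc_kBq_per_ml: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.frame_start_s, dtype=float)
        end = np.asarray(self.frame_end_s, dtype=float)
        conc = np.asarray(self.conc_kBq_per_ml, dtype=float)
        object.__setattr__(self, "frame_start_s", start)
        object.__setattr__(self, "frame_end_s", end)
        object.__setattr__(self, "conc_kBq_per_ml", conc)
        if not (start.shape == end.shape == conc.shape) or start.ndim != 1 or start.size == 0:
            raise ValueError("frame arrays must be equal-length 1-D and non-empty")
        if np.any(end <= start):
            raise ValueError("frames must have t_start < t_end")
        if np.any(np.abs(start[1:] - end[:-1]) > 1e-9):
            raise ValueError("frames must be contiguous and non-overlapping")
        if np.any(conc < 0):
            raise ValueError("concentrations must be non-negative")

    @property
    def midpoints_s(self) -> np.ndarray:
        return 0.5 * (self.frame_start_s + self.frame_end_s)

    @property
    def t_span_s(self) -> tuple[float, float]:
        return float(self.frame_start_s[0]), float(self.frame_end_s[-1])

    def conc_at_end(self) -> float:
        """Concentration of the last frame (the 60-min residual by default)."""
        return float(self.conc_kBq_per_ml[-1])


def default_frame_schedule() -> np.ndarray:
    """The default 55-frame schedule spanning [0, 3600] s.

    Blocks of 12x5, 6x10, 8x30, 9x60 and 20x135 s -- 55 non-equidistant
    frames with fine sampling of the injection bolus.
    Returns an array of shape (55, 2) with (start, end) seconds.
    """
    durations = np.concatenate(
        [
            np.full(12, 5.0),
            np.full(6, 10.0),
            np.full(8, 30.0),
            np.full(9, 60.0),
            np.full(20, 135.0),
        ]
    )
    edges = np.concatenate([[0.0], np.cumsum(durations)])
    return np.column_stack([edges[:-1], edges[1:]])


def sample_tac(
    params: BloodKineticsParams,
    volunteer: Volunteer,
    frame_schedule: np.ndarray | None = None,
    noise_cv: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> TimeActivityCurve:
    """Simulate a measured TAC: model value at frame midpoints with
    multiplicative lognormal ROI noise of coefficient of variation
    ``noise_cv`` (median-unbiased; ``noise_cv=0`` reproduces the model
    exactly)."""
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    schedule = default_frame_schedule() if frame_schedule is None else np.asarray(frame_schedule, float)
    if schedule.ndim != 2 or schedule.shape[1] != 2:
        raise ValueError("frame_schedule must have shape (n, 2)")
    start, end = schedule[:, 0], schedule[:, 1]
    mid_min = 0.5 * (start + end) / 60.0
    c = np.asarray(concentration(params, volunteer, mid_min), dtype=float)
    if noise_cv > 0:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        sigma = np.sqrt(np.log1p(noise_cv**2))
        c = c * np.exp(gen.normal(0.0, sigma, size=c.shape))
    return TimeActivityCurve(volunteer.id, start, end, c)


def _interp_points(tac: TimeActivityCurve) -> tuple[np.ndarray, np.ndarray]:
    # piecewise-linear support: frame midpoints, extended flat to the span edges
    t = tac.midpoints_s
    c = tac.conc_kBq_per_ml
    t0, t1 = tac.t_span_s
    return (
        np.concatenate([[t0], t, [t1]]),
        np.concatenate([[c[0]], c, [c[-1]]]),
    )


def integrate_tac(tac: TimeActivityCurve, t0_s: float, t1_s: float) -> float:
    """Trapezoidal time-integral of concentration over [t0, t1] s.

    Returns kBq*s/ml.  The integrand is the piecewise-linear interpolant
    through the frame-midpoint concentrations.  The interval must lie within
    the TAC support.
    """
    lo, hi = tac.t_span_s
    if t0_s < lo - 1e-9 or t1_s > hi + 1e-9 or t0_s > t1_s:
        raise ValueError(f"integration interval [{t0_s}, {t1_s}] outside TAC support [{lo}, {hi}]")
    if t1_s == t0_s:
        return 0.0
    tp, cp = _interp_points(tac)
    inner = tp[(tp > t0_s) & (tp < t1_s)]
    grid = np.concatenate([[t0_s], inner, [t1_s]])
    vals = np.interp(grid, tp, cp)
    return float(np.trapezoid(vals, grid))
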