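"""Absorbed dose to blood from [18F]FDG, in vivo and in vitro.

In vivo, blood receives a beta self-dose proportional to the time-integrated
activity concentration (MIRD formalism with an absorbed fraction of 1 for
positrons stopping within blood) plus an annihilation-photon cross-fire
component estimated from whole-body retention.  In vitro, a blood sample in
a conical centrifuge tube continues to irradiate itself during incubation;
the tube-geometry specific absorbed fractions (SAFs) are computed by a
self-contained Monte Carlo and interpolated logarithmically in volume.

Units: activities kBq, concentrations kBq/ml, energies MeV, doses mGy,
times minutes unless suffixed ``_s``.  Blood is treated as water-equivalent
with density 1 g/ml.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .blood import F18_HALF_LIFE_MIN, TimeActivityCurve, Volunteer, integrate_tac

__all__ = [
    "PhysicsConstants",
    "TubeGeometry",
    "TubeSAFTable",
    "DoseReport",
    "decay_integral",
    "tube_saf",
    "in_vivo_blood_dose",
    "in_vitro_dose",
    "dose_report",
    "INCUBATION_TIMES_MIN",
]

#: mGy per (kBq*s/g of cumulated activity concentration x MeV per decay):
#: 1 kBq*s = 1000 decays; 1 MeV = 1.602176634e-13 J; 1 J/g = 1e6 mGy.
K_MGY_PER_KBQ_S_MEV_G = 1e3 * 1.602176634e-13 * 1e6

#: Incubation times of the study protocol, minutes.
INCUBATION_TIMES_MIN = (0, 15, 30, 45, 60)

#: Default predefined blood volumes (ml) for which tube SAFs are simulated.
DEFAULT_TUBE_VOLUMES_ML = (3.0, 4.0, 5.0, 6.0, 7.5)


@dataclass(frozen=True)
class PhysicsConstants:
    """Decay data for fluorine-18.

    The positron spectrum is collapsed to its mean energy (0.2498 MeV) times
    the positron yield (0.9686); the photon term carries both 511-keV
    annihilation quanta per positron.
    """

    mean_beta_energy_MeV: float = 0.2498
    beta_yield: float = 0.9686
    photon_energy_MeV: float = 2 * 0.511 * 0.9686
    physical_half_life_min: float = F18_HALF_LIFE_MIN

    def __post_init__(self) -> None:
        for name in ("mean_beta_energy_MeV", "beta_yield", "photon_energy_MeV", "physical_half_life_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def decay_constant_per_min(self) -> float:
        return math.log(2.0) / self.physical_half_life_min

    @property
    def delta_beta_MeV(self) -> float:
        """Mean beta energy emitted per decay."""
        return self.mean_beta_energy_MeV * self.beta_yield


def decay_integral(lam_per_min: float, duration_min: float) -> float:
    """Time-integral of unit initial activity over ``duration_min``:
    (1 - exp(-lam*T)) / lam, in minutes."""
    if lam_per_min <= 0:
        raise ValueError("decay constant must be positive")
    if duration_min < 0:
        raise ValueError("duration must be non-negative")
    return float(-math.expm1(-lam_per_min * duration_min) / lam_per_min)


# ---------------------------------------------------------------------------
# Tube geometry and SAF Monte Carlo
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TubeGeometry:
    """Water-filled 15-ml conical centrifuge tube, idealised as a conical
    frustum bottom (tip radius ``tip_radius_mm`` widening to the inner tube
    radius over ``cone_height_mm``) topped by a cylinder.  z=0 at the tip."""

    inner_radius_mm: float = 7.5
    cone_height_mm: float = 20.0
    tip_radius_mm: float = 1.5

    @property
    def cone_volume_mm3(self) -> float:
        r0, r1, h = self.tip_radius_mm, self.inner_radius_mm, self.cone_height_mm
        return math.pi * h / 3.0 * (r0**2 + r0 * r1 + r1**2)

    def radius_at(self, z_mm: np.ndarray) -> np.ndarray:
        r0, r1, h = self.tip_radius_mm, self.inner_radius_mm, self.cone_height_mm
        return np.where(z_mm < h, r0 + (r1 - r0) * np.clip(z_mm, 0.0, h) / h, r1)

    def fill_height_mm(self, volume_ml: float) -> float:
        if volume_ml <= 0:
            raise ValueError("volume must be positive")
        v_mm3 = volume_ml * 1000.0
        r0, r1, h = self.tip_radius_mm, self.inner_radius_mm, self.cone_height_mm
        if v_mm3 <= self.cone_volume_mm3:
            # volume of frustum up to z: pi*z/3*(r0^2 + r0*r(z) + r(z)^2); monotone -> bisect
            lo, hi = 0.0, h
            for _ in range(80):
                mid = 0.5 * (lo + hi)
                rz = r0 + (r1 - r0) * mid / h
                v = math.pi * mid / 3.0 * (r0**2 + r0 * rz + rz**2)
                lo, hi = (mid, hi) if v < v_mm3 else (lo, mid)
            return 0.5 * (lo + hi)
        return h + (v_mm3 - self.cone_volume_mm3) / (math.pi * r1**2)

    def contains(self, pts: np.ndarray, fill_mm: float) -> np.ndarray:
        """Boolean mask: points (n, 3) inside the blood column."""
        x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
        r = np.hypot(x, y)
        return (z >= 0.0) & (z <= fill_mm) & (r <= self.radius_at(z))

    def sample_points(self, n: int, fill_mm: float, rng: np.random.Generator) -> np.ndarray:
        """Uniform points in the blood column by rejection from the bounding
        cylinder."""
        out = np.empty((0, 3))
        r1 = self.inner_radius_mm
        while out.shape[0] < n:
            m = max(2 * (n - out.shape[0]), 1000)
            xy = rng.uniform(-r1, r1, size=(m, 2))
            z = rng.uniform(0.0, fill_mm, size=m)
            pts = np.column_stack([xy, z])
            out = np.vstack([out, pts[self.contains(pts, fill_mm)]])
        return out[:n]


@dataclass(frozen=True)
class SAFResult:
    phi_beta: float
    phi_photon: float
    se_beta: float
    se_photon: float


def _isotropic_directions(n: int, rng: np.random.Generator) -> np.ndarray:
    u = rng.uniform(-1.0, 1.0, size=n)
    phi = rng.uniform(0.0, 2.0 * math.pi, size=n)
    s = np.sqrt(1.0 - u**2)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), u])


def _exit_distance(
    geom: TubeGeometry, fill_mm: float, pts: np.ndarray, dirs: np.ndarray, d_max: float
) -> np.ndarray:
    """Distance from each interior point to the surface along its direction,
    by bracketing + bisection (the blood column is convex)."""
    n = pts.shape[0]
    lo = np.zeros(n)
    hi = np.full(n, d_max)
    # bracket: grow until outside (points beyond d_max treated as d_max)
    step = np.full(n, 0.5)
    pos = lo.copy()
    for _ in range(32):
        trial = np.minimum(pos + step, d_max)
        inside = geom.contains(pts + trial[:, None] * dirs, fill_mm)
        pos = np.where(inside, trial, pos)
        step = np.where(inside, step * 2.0, step)
        hi = np.where(inside, hi, np.minimum(hi, trial))
        if np.all(~inside | (pos >= d_max)):
            break
    lo = pos
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        inside = geom.contains(pts + mid[:, None] * dirs, fill_mm)
        lo = np.where(inside, mid, lo)
        hi = np.where(inside, hi, mid)
    return 0.5 * (lo + hi)


def tube_saf(
    volume_ml: float,
    geometry: TubeGeometry | None = None,
    n_histories: int = 100_000,
    seed: int | np.random.Generator = 0,
    beta_range_mm: float = 0.6,
    mu_photon_per_mm: float = 0.0096,
) -> SAFResult:
    """Monte Carlo absorbed fractions for a blood volume in a conical tube.

    Electrons travel straight over a fixed CSDA range ``beta_range_mm``
    (mean [18F] positron range in water); phi_beta is the mean fraction of
    the path length inside the blood.  Photons deposit 1 - exp(-mu*d) of
    their energy, with d the chord length to the surface and mu the 511-keV
    linear attenuation coefficient of water.
    """
    if volume_ml <= 0:
        raise ValueError("volume must be positive")
    geom = geometry or TubeGeometry()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fill = geom.fill_height_mm(volume_ml)
    pts = geom.sample_points(n_histories, fill, rng)
    dirs = _isotropic_directions(n_histories, rng)
    d_max = fill + 2 * geom.inner_radius_mm + 5.0
    d_exit = _exit_distance(geom, fill, pts, dirs, d_max)
    frac_beta = np.minimum(d_exit, beta_range_mm) / beta_range_mm
    frac_photon = -np.expm1(-mu_photon_per_mm * d_exit)
    return SAFResult(
        phi_beta=float(frac_beta.mean()),
        phi_photon=float(frac_photon.mean()),
        se_beta=float(frac_beta.std(ddof=1) / math.sqrt(n_histories)),
        se_photon=float(frac_photon.std(ddof=1) / math.sqrt(n_histories)),
    )


@dataclass(frozen=True)
class TubeSAFTable:
    """SAFs at the predefined tube volumes, with log-volume interpolation."""

    volumes_ml: tuple[float, ...]
    phi_beta: tuple[float, ...]
    phi_photon: tuple[float, ...]
    se_beta: tuple[float, ...] = ()
    se_photon: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.volumes_ml)
        if v.size < 2 or np.any(np.diff(v) <= 0):
            raise ValueError("volumes must be increasing and at least two")
        for phi in (self.phi_beta, self.phi_photon):
            if len(phi) != v.size:
                raise ValueError("phi arrays must match volumes")
        if not all(0 < p < 1 for p in self.phi_beta):
            raise ValueError("phi_beta must lie in (0, 1)")
        if not all(0 < p < 0.2 for p in self.phi_photon):
            raise ValueError("phi_photon must lie in (0, 0.2)")

    @classmethod
    def compute(
        cls,
        volumes_ml: tuple[float, ...] = DEFAULT_TUBE_VOLUMES_ML,
        geometry: TubeGeometry | None = None,
        n_histories: int = 100_000,
        seed: int = 0,
    ) -> "TubeSAFTable":
        rng = np.random.default_rng(seed)
        results = [
            tube_saf(v, geometry=geometry, n_histories=n_histories, seed=rng)
            for v in volumes_ml
        ]
        return cls(
            volumes_ml=tuple(volumes_ml),
            phi_beta=tuple(r.phi_beta for r in results),
            phi_photon=tuple(r.phi_photon for r in results),
            se_beta=tuple(r.se_beta for r in results),
            se_photon=tuple(r.se_photon for r in results),
        )

    def interp(self, volume_ml: float) -> tuple[float, float]:
        """SAFs at ``volume_ml`` by linear interpolation against ln(V);
        exact at the tabulated volumes.  Out-of-range volumes raise."""
        v = np.asarray(self.volumes_ml)
        if not (v[0] <= volume_ml <= v[-1]):
            raise ValueError(
                f"volume {volume_ml} ml outside tabulated range [{v[0]}, {v[-1]}] ml"
            )
        lv = math.log(volume_ml)
        lvs = np.log(v)
        return (
            float(np.interp(lv, lvs, np.asarray(self.phi_beta))),
            float(np.interp(lv, lvs, np.asarray(self.phi_photon))),
        )


# ---------------------------------------------------------------------------
# Dose computations
# ---------------------------------------------------------------------------


def in_vivo_blood_dose(
    tac: TimeActivityCurve,
    volunteer: Volunteer,
    constants: PhysicsConstants | None = None,
    phi_gamma_body: float = 0.33,
    window_min: float = 60.0,
) -> dict[str, float]:
    """Absorbed dose to blood over the in vivo window, mGy.

    beta_self integrates the measured concentration curve (absorbed fraction
    1 for positrons within blood); photon_cross assumes complete whole-body
    retention of the administered activity, a uniform source, and a
    whole-body photon absorbed fraction ``phi_gamma_body``.
    """
    consts = constants or PhysicsConstants()
    lo, hi = tac.t_span_s
    if hi < window_min * 60.0 - 1e-6:
        raise ValueError("TAC does not cover the in vivo window")
    conc_integral = integrate_tac(tac, 0.0, window_min * 60.0)  # kBq*s/ml
    beta_self = K_MGY_PER_KBQ_S_MEV_G * consts.delta_beta_MeV * conc_integral

    a0_kBq = (volunteer.administered_activity_MBq or 0.0) * 1e3
    a_tilde_s = a0_kBq * decay_integral(consts.decay_constant_per_min, window_min) * 60.0
    body_mass_g = volunteer.weight_kg * 1e3
    photon_cross = (
        K_MGY_PER_KBQ_S_MEV_G
        * consts.photon_energy_MeV
        * phi_gamma_body
        * a_tilde_s
        / body_mass_g
    )
    return {
        "beta_self": beta_self,
        "photon_cross": photon_cross,
        "total": beta_self + photon_cross,
    }


def in_vitro_dose(
    c60_kBq_per_ml: float,
    volume_ml: float,
    incubation_min: float,
    table: TubeSAFTable,
    constants: PhysicsConstants | None = None,
) -> float:
    """Self-dose (mGy) to a blood sample incubated ``incubation_min`` min,
    starting from the residual concentration ``c60_kBq_per_ml`` at
    withdrawal.  Increasing and concave in the incubation time because only
    physical decay removes activity."""
    if c60_kBq_per_ml < 0:
        raise ValueError("residual concentration must be non-negative")
    if incubation_min < 0:
        raise ValueError("incubation time must be non-negative")
    consts = constants or PhysicsConstants()
    phi_beta, phi_photon = table.interp(volume_ml)
    cumulated = c60_kBq_per_ml * decay_integral(consts.decay_constant_per_min, incubation_min) * 60.0
    energy_per_decay = consts.delta_beta_MeV * phi_beta + consts.photon_energy_MeV * phi_photon
    return K_MGY_PER_KBQ_S_MEV_G * energy_per_decay * cumulated


@dataclass(frozen=True)
class DoseReport:
    """Per-volunteer absorbed doses to blood (mGy)."""

    volunteer_id: str
    D_invivo_mGy: float
    components: dict[str, float]
    D_invitro_mGy: dict[int, float]
    D_total_mGy: dict[int, float]

    def to_dict(self) -> dict:
        return {
            "volunteer_id": self.volunteer_id,
            "D_invivo_mGy": self.D_invivo_mGy,
            "components": dict(self.components),
            "D_invitro_mGy": {str(k): v for k, v in self.D_invitro_mGy.items()},
            "D_total_mGy": {str(k): v for k, v in self.D_total_mGy.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DoseReport":
        return cls(
            volunteer_id=d["volunteer_id"],
            D_invivo_mGy=float(d["D_invivo_mGy"]),
            components={k: float(v) for k, v in d["components"].items()},
            D_invitro_mGy={int(k): float(v) for k, v in d["D_invitro_mGy"].items()},
            D_total_mGy={int(k): float(v) for k, v in d["D_total_mGy"].items()},
        )

    @classmethod
    def zeros(cls, volunteer_id: str) -> "DoseReport":
        zero = {it: 0.0 for it in INCUBATION_TIMES_MIN}
        return cls(volunteer_id, 0.0, {"beta_self": 0.0, "photon_cross": 0.0}, dict(zero), dict(zero))


def dose_report(
    tac: TimeActivityCurve | None,
    volunteer: Volunteer,
    table: TubeSAFTable,
    constants: PhysicsConstants | None = None,
    tube_volumes_ml: dict[int, float] | float = 5.0,
    phi_gamma_body: float = 0.33,
) -> DoseReport:
    """Assemble the full dose report: in vivo dose over [0, 60] min p.i.
    plus in vitro doses at the protocol incubation times.

    SA2 volunteers (no radiotracer) receive an all-zero report.
    """
    if not volunteer.is_fdg_exposed:
        return DoseReport.zeros(volunteer.id)
    if tac is None:
        raise ValueError("FDG-exposed volunteers require a TAC")
    consts = constants or PhysicsConstants()
    invivo = in_vivo_blood_dose(tac, volunteer, consts, phi_gamma_body=phi_gamma_body)
    c60 = tac.conc_at_end()
    if isinstance(tube_volumes_ml, dict):
        volumes = {it: tube_volumes_ml[it] for it in INCUBATION_TIMES_MIN}
    else:
        volumes = {it: float(tube_volumes_ml) for it in INCUBATION_TIMES_MIN}
    invitro = {
        it: in_vitro_dose(c60, volumes[it], it, table, consts)
        for it in INCUBATION_TIMES_MIN
    }
    total = {it: invivo["total"] + invitro[it] for it in INCUBATION_TIMES_MIN}
    return DoseReport(
        volunteer_id=volunteer.id,
        D_invivo_mGy=invivo["total"],
        components={"beta_self": invivo["beta_self"], "photon_cross": invivo["photon_cross"]},
        D_invitro_mGy=invitro,
        D_total_mGy=total,
    )
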