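"""Shared test helpers and independent oracles."""

import numpy as np

from petdsb.blood import Volunteer

LN2 = np.log(2.0)


def make_volunteer(activity=338.0, weight=75.0, height=1.80, sex="M", arm="SA1"):
    return Volunteer(
        "v", arm, sex, 26.0, height, weight, None if arm == "SA2" else activity
    )


def analytic_integral_kBq_s(params, volunteer, t0_min, t1_min):
    """Closed-form integral of the three-exponential concentration model
    over [t0, t1] min, in kBq*s/ml (independent of the trapezoid path)."""
    c0 = volunteer.administered_activity_MBq / volunteer.blood_volume_l
    total = 0.0
    for f, t_bio in zip(params.fractions, params.half_times_min):
        lam = LN2 * (1.0 / t_bio + 1.0 / params.physical_half_life_min)
        total += c0 * f * (np.exp(-lam * t0_min) - np.exp(-lam * t1_min)) / lam
    return total * 60.0


def tube_phi_beta_quadrature(volume_ml, beta_range_mm=0.6,
                             n_z=90, n_r=64, n_cos=32, n_phi=32, n_steps=96):
    """Deterministic dense-grid evaluation of the tube beta absorbed
    fraction: midpoint quadrature over source position (area-weighted z
    levels x radial shells) and emission direction, with the in-volume
    fraction of each straight 0.6-mm track found by fine sub-sampling.

    Re-derives the tube geometry independently of the package: a conical
    frustum (tip radius 1.5 mm to inner radius 7.5 mm over 20 mm) under a
    cylinder, filled to the height matching ``volume_ml``.
    """
    r0, r1, h_cone = 1.5, 7.5, 20.0

    def radius_at(z):
        return np.where(z < h_cone, r0 + (r1 - r0) * np.clip(z, 0, h_cone) / h_cone, r1)

    def frustum_volume(z):
        rz = r0 + (r1 - r0) * z / h_cone
        return np.pi * z / 3.0 * (r0**2 + r0 * rz + rz**2)

    v_mm3 = volume_ml * 1000.0
    v_cone = frustum_volume(h_cone)
    if v_mm3 <= v_cone:
        lo, hi = 0.0, h_cone
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            lo, hi = (mid, hi) if frustum_volume(mid) < v_mm3 else (lo, mid)
        fill = 0.5 * (lo + hi)
    else:
        fill = h_cone + (v_mm3 - v_cone) / (np.pi * r1**2)

    def inside(x, y, z):
        r = np.hypot(x, y)
        return (z >= 0) & (z <= fill) & (r <= radius_at(z))

    # midpoint nodes
    z_nodes = (np.arange(n_z) + 0.5) * fill / n_z
    z_weights = radius_at(z_nodes) ** 2
    z_weights = z_weights / z_weights.sum()
    u_r = (np.arange(n_r) + 0.5) / n_r          # uniform in r^2 -> area weights equal
    cos_nodes = -1.0 + 2.0 * (np.arange(n_cos) + 0.5) / n_cos
    phi_nodes = 2.0 * np.pi * (np.arange(n_phi) + 0.5) / n_phi
    sin_nodes = np.sqrt(1.0 - cos_nodes**2)
    dx = (sin_nodes[:, None] * np.cos(phi_nodes)[None, :]).ravel()
    dy = (sin_nodes[:, None] * np.sin(phi_nodes)[None, :]).ravel()
    dz = np.repeat(cos_nodes, n_phi)
    steps = (np.arange(n_steps) + 0.5) * beta_range_mm / n_steps

    total = 0.0
    for zi, wz in zip(z_nodes, z_weights):
        radii = np.sqrt(u_r) * radius_at(zi)    # source points at azimuth 0 (symmetry)
        # positions (n_r, n_dir, n_steps)
        x = radii[:, None, None] + dx[None, :, None] * steps[None, None, :]
        y = dy[None, :, None] * steps[None, None, :]
        z = zi + dz[None, :, None] * steps[None, None, :]
        frac = inside(x, y, np.broadcast_to(z, x.shape)).mean(axis=2)
        total += wz * frac.mean()
    return float(total)
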