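"""Synthetic velocity planes and cohorts with known ground truth.

The jet generator builds a single peak-systolic cross-section: a circular
lumen containing an eccentric plug (or parabolic) jet with controllable
displacement, tilt, swirl, retrograde fraction and additive Gaussian
noise.  The cohort generator emulates the 3 valve sizes x 2 activity
states simulation design: per patient a peak systolic flow rate, an
effective orifice area per candidate size, gradients from the
reduced-order transvalvular model, and flow-profile metrics drawn from
configurable distributions that stay constant across sizes and states.

Closed forms used by the tests: a plug jet offset by d in a lumen of
radius R has NFD = d / (2R); a uniform field tilted by t degrees has flow
angle t; a pure stress scaling by factor f multiplies gradients by f².
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParameterError
from .model import apply_stress, dp_from_vmax, vmax_from_dp, vmax_from_flow
from .plane import VelocityPlane

__all__ = [
    "JetParams",
    "CohortGenParams",
    "make_jet_plane",
    "make_cohort",
    "DEFAULT_EOA_BY_SIZE",
]

#: Ground-truth effective orifice areas (cm²) per label size (mm) used by
#: the synthetic cohort generator.  Arbitrary but monotone in size; not
#: manufacturer chart values.
DEFAULT_EOA_BY_SIZE = {21: 1.4, 23: 1.7, 25: 2.0, 27: 2.3}

SIZE_CLASSES = ("smaller", "reference", "larger")
STATES = ("rest", "stress")


@dataclass(frozen=True)
class JetParams:
    """Parameters of one synthetic eccentric jet plane.

    Lengths in mm, velocities in m/s, tilt in degrees.
    """

    lumen_radius: float = 12.5
    grid_spacing: float = 0.5
    jet_center_offset: tuple[float, float] = (0.0, 0.0)
    jet_radius: float = 6.0
    peak_velocity: float = 1.5
    tilt_deg: float = 0.0
    swirl_strength: float = 0.0
    retrograde_fraction: float = 0.0
    noise_sd: float = 0.0
    profile: str = "plug"  # 'plug' or 'parabolic'
    seed: int = 0

    def validate(self) -> None:
        off = math.hypot(*self.jet_center_offset)
        if self.jet_radius <= 0:
            raise ParameterError("jet_radius must be positive")
        if self.jet_radius > self.lumen_radius:
            raise ParameterError("jet_radius exceeds lumen_radius")
        if off + self.jet_radius > self.lumen_radius + 1e-12:
            raise ParameterError(
                "jet not fully inside lumen: |jet_center_offset| + jet_radius "
                f"= {off + self.jet_radius:g} > lumen_radius = {self.lumen_radius:g}")
        if self.peak_velocity < 0:
            raise ParameterError("peak_velocity must be non-negative")
        if not (0 <= self.tilt_deg < 90):
            raise ParameterError("tilt_deg must lie in [0, 90)")
        if not (0 <= self.retrograde_fraction < 1):
            raise ParameterError("retrograde_fraction must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")
        if self.grid_spacing <= 0 or self.grid_spacing >= self.lumen_radius / 4:
            raise ParameterError("grid_spacing must satisfy "
                                 "0 < grid_spacing < lumen_radius / 4")
        if self.profile not in ("plug", "parabolic"):
            raise ParameterError(f"unknown jet profile '{self.profile}'")


def make_jet_plane(params: JetParams) -> VelocityPlane:
    """Generate a velocity plane containing one eccentric jet.

    The lumen mask is the disk of ``lumen_radius`` about the grid origin.
    Through-plane velocity is a plug (or parabolic) jet of ``jet_radius``
    centered at ``jet_center_offset`` with peak ``peak_velocity``.  Tilt
    adds an in-plane component ``vz * tan(tilt_deg)`` along +x (uniform
    deflection of the jet axis); swirl adds solid-body rotation about the
    jet center reaching ``swirl_strength`` at the lumen-radius distance.
    Outside the jet an optional uniform retrograde flow of
    ``retrograde_fraction * peak_velocity`` is applied.  Gaussian noise of
    ``noise_sd`` is added per component inside the lumen.  Deterministic
    under ``seed``.
    """
    params.validate()
    r = params.lumen_radius
    s = params.grid_spacing
    half = int(math.floor(r / s))
    axis = np.arange(-half, half + 1) * s
    xg, yg = np.meshgrid(axis, axis)
    x = xg.ravel()
    y = yg.ravel()
    mask = x ** 2 + y ** 2 <= r ** 2

    cx, cy = params.jet_center_offset
    dist_jet = np.hypot(x - cx, y - cy)
    in_jet = mask & (dist_jet <= params.jet_radius)

    vz = np.zeros_like(x)
    if params.profile == "plug":
        vz[in_jet] = params.peak_velocity
    else:
        rel = dist_jet[in_jet] / params.jet_radius
        vz[in_jet] = params.peak_velocity * (1.0 - rel ** 2)
    if params.retrograde_fraction > 0:
        vz[mask & ~in_jet] = -params.retrograde_fraction * params.peak_velocity

    vx = np.zeros_like(x)
    vy = np.zeros_like(x)
    if params.tilt_deg > 0:
        vx += vz * math.tan(math.radians(params.tilt_deg))
    if params.swirl_strength != 0:
        # tangential speed grows linearly with distance from the jet center
        vt = params.swirl_strength * dist_jet / r
        with np.errstate(invalid="ignore", divide="ignore"):
            ux = np.where(dist_jet > 0, -(y - cy) / dist_jet, 0.0)
            uy = np.where(dist_jet > 0, (x - cx) / dist_jet, 0.0)
        vx[mask] += (vt * ux)[mask]
        vy[mask] += (vt * uy)[mask]

    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        noise = rng.normal(0.0, params.noise_sd, size=(3, x.size))
        vx[mask] += noise[0][mask]
        vy[mask] += noise[1][mask]
        vz[mask] += noise[2][mask]

    vx[~mask] = 0.0
    vy[~mask] = 0.0
    vz[~mask] = 0.0
    return VelocityPlane(x=x, y=y, vx=vx, vy=vy, vz=vz, mask=mask,
                         spacing=s, lumen_radius=r)


@dataclass(frozen=True)
class CohortGenParams:
    """Configuration of a synthetic virtual-replacement cohort."""

    n_patients: int = 10
    eoa_by_size: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_EOA_BY_SIZE))
    flow_range: tuple[float, float] = (230.0, 540.0)  # ml/s, peak systolic
    stress_factor: float = 1.25
    stress_nonlinearity: float = 0.0  # multiplicative perturbation on stress DP
    nfd_distribution: tuple[float, float] = (0.12, 0.03)
    wpd_distribution: tuple[float, float] = (0.44, 0.05)
    angle_distribution: tuple[float, float] = (28.0, 5.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ParameterError("n_patients must be >= 1")
        if self.stress_factor <= 1:
            raise ParameterError("stress_factor must exceed 1")
        if any(eoa <= 0 for eoa in self.eoa_by_size.values()):
            raise ParameterError("all EOA values must be positive")
        lo, hi = self.flow_range
        if not (0 < lo <= hi):
            raise ParameterError("flow_range must be positive and ordered")
        if len(self.eoa_by_size) < 3:
            raise ConfigurationError(
                "eoa_by_size needs at least 3 sizes for the smaller/"
                "reference/larger design")


def make_cohort(params: CohortGenParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a cohort table plus the full 3-size x 2-state results grid.

    Per patient: a reference label size (an interior size of
    ``eoa_by_size`` so both neighbours exist), a peak systolic flow rate
    from ``flow_range``, body measures, and per (size class, state) cell a
    peak velocity and gradient from the reduced-order model.  Stress cells
    scale the flow by ``stress_factor`` and the gradient additionally by
    ``1 + stress_nonlinearity``.  NFD/WPD/angle are drawn once per patient
    and held constant across cells.  Deterministic under ``seed``.

    Returns
    -------
    (records, results) : tuple of DataFrame
        ``records`` carries one row per patient; ``results`` carries the
        6-cell grid per patient with columns ``patient_id, valve_size_mm,
        size_class, state, q_mls, vmax_mps, dp_mmhg, nfd, wpd, angle_deg``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    sizes = sorted(params.eoa_by_size)
    interior = sizes[1:-1]

    records = []
    rows = []
    for pid in range(1, params.n_patients + 1):
        ref_size = int(rng.choice(interior))
        idx = sizes.index(ref_size)
        size_of = {"smaller": sizes[idx - 1], "reference": ref_size,
                   "larger": sizes[idx + 1]}
        for cls in SIZE_CLASSES:
            if size_of[cls] not in params.eoa_by_size:
                raise ConfigurationError(
                    f"eoa_by_size missing size {size_of[cls]} "
                    f"({cls} valve of patient {pid})")
        q_rest = float(rng.uniform(*params.flow_range))
        nfd_val = float(np.clip(rng.normal(*params.nfd_distribution), 0.0, 0.5))
        wpd_val = float(np.clip(rng.normal(*params.wpd_distribution), 0.0, 1.0))
        angle_val = float(np.clip(rng.normal(*params.angle_distribution),
                                  0.0, 90.0))
        sex = str(rng.choice(["F", "M"]))
        height = float(rng.uniform(160, 200))
        weight = float(rng.uniform(60, 110))
        bsa = float(np.sqrt(height * weight / 3600.0))  # Mosteller
        records.append({"patient_id": pid, "sex": sex,
                        "height_cm": round(height, 1),
                        "weight_kg": round(weight, 1),
                        "bsa_m2": round(bsa, 2),
                        "age_years": int(rng.integers(50, 80)),
                        "reference_valve_size_mm": ref_size,
                        "peak_systolic_flow_mls": round(q_rest, 1)})
        for cls in SIZE_CLASSES:
            eoa = params.eoa_by_size[size_of[cls]]
            for state in STATES:
                if state == "rest":
                    q = q_rest
                    dp = dp_from_vmax(vmax_from_flow(q, eoa))
                else:
                    q = apply_stress(q_rest, params.stress_factor)
                    dp = dp_from_vmax(vmax_from_flow(q, eoa))
                    dp *= 1.0 + params.stress_nonlinearity
                rows.append({"patient_id": pid,
                             "valve_size_mm": size_of[cls],
                             "size_class": cls, "state": state,
                             "q_mls": q,
                             "vmax_mps": vmax_from_dp(dp),
                             "dp_mmhg": dp,
                             "nfd": nfd_val, "wpd": wpd_val,
                             "angle_deg": angle_val})
    return pd.DataFrame(records), pd.DataFrame(rows)
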