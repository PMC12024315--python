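"""Aortic flow-profile metrics on a cross-sectional velocity plane.

Implements the three ascending-aorta profile statistics used for
post-valve-replacement assessment — normalized flow displacement (NFD),
degree of wall parallelism (WPD) and mean flow angle — plus the peak
velocity magnitude and the lumen geometry they depend on.

Conventions
-----------
* NFD: distance between the unweighted lumen centroid and the centroid of
  forward flow (through-plane velocity > 0), normalized by the
  equivalent-circle lumen diameter.  The forward-flow centroid is weighted
  by the through-plane velocity by default; set ``weighted=False`` for the
  unweighted variant.
* WPD: mean over lumen samples of |v_through| / (|v_through| + |v_inplane|).
  Samples with zero total velocity are excluded.
* Flow angle: mean of arccos(v_through / |v|) in degrees over nonzero
  lumen samples.  Retrograde vectors contribute angles > 90 degrees (not
  folded); set ``forward_only=True`` to restrict WPD/angle to forward flow.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .errors import InputError, UndefinedMetricError
from .plane import VelocityPlane

__all__ = [
    "FlowMetrics",
    "lumen_geometry",
    "nfd",
    "wpd",
    "flow_angle",
    "vmax",
    "compute_metrics",
]


@dataclass(frozen=True)
class FlowMetrics:
    """Bundle of profile metrics for one plane."""

    nfd: float
    wpd: float
    angle_deg: float
    vmax_mps: float

    def to_dict(self) -> dict:
        return asdict(self)


def lumen_geometry(plane: VelocityPlane) -> tuple[np.ndarray, float]:
    """Lumen centroid and equivalent-circle diameter.

    Parameters
    ----------
    plane : VelocityPlane

    Returns
    -------
    centroid : ndarray, shape (2,)
        Unweighted area centroid of the lumen samples, in mm.
    diameter : float
        Equivalent-circle diameter ``2 * sqrt(A / pi)`` in mm, where the
        lumen area ``A`` is the sample count times the squared spacing.
    """
    if plane.mask.sum() == 0:
        raise InputError("empty lumen mask")
    m = plane.mask
    centroid = np.array([plane.x[m].mean(), plane.y[m].mean()])
    area = float(m.sum()) * plane.spacing ** 2
    diameter = 2.0 * np.sqrt(area / np.pi)
    return centroid, diameter


def nfd(plane: VelocityPlane, weighted: bool = True) -> float:
    """Normalized flow displacement.

    Distance between the forward-flow centroid and the lumen centroid,
    divided by the equivalent-circle lumen diameter.  A perfectly centered
    jet gives 0; the value grows as the jet shifts toward the wall.

    Parameters
    ----------
    plane : VelocityPlane
    weighted : bool
        Weight the forward-flow centroid by through-plane velocity
        (default).  ``False`` uses the unweighted centroid of the
        forward-flow region.

    Raises
    ------
    UndefinedMetricError
        If no lumen sample has positive through-plane velocity (fully
        retrograde plane).
    """
    centroid, diameter = lumen_geometry(plane)
    m = plane.mask
    fwd = m & (plane.vz > 0)
    if not fwd.any():
        raise UndefinedMetricError("no forward flow on plane; NFD undefined")
    if weighted:
        w = plane.vz[fwd]
    else:
        w = np.ones(int(fwd.sum()))
    cx = float(np.sum(plane.x[fwd] * w) / np.sum(w))
    cy = float(np.sum(plane.y[fwd] * w) / np.sum(w))
    return float(np.hypot(cx - centroid[0], cy - centroid[1]) / diameter)


def _nonzero_lumen(plane: VelocityPlane, forward_only: bool) -> np.ndarray:
    sel = plane.mask.copy()
    if forward_only:
        sel &= plane.vz > 0
    speed = np.sqrt(plane.vx ** 2 + plane.vy ** 2 + plane.vz ** 2)
    sel &= speed > 0
    return sel


def wpd(plane: VelocityPlane, forward_only: bool = False) -> float:
    """Degree of wall parallelism.

    Mean over (nonzero-velocity) lumen samples of
    ``|v_through| / (|v_through| + |v_inplane|)``.  1 for flow perfectly
    parallel to the centerline, 0 for purely in-plane flow.
    """
    sel = _nonzero_lumen(plane, forward_only)
    if not sel.any():
        raise UndefinedMetricError("all lumen velocities are zero; WPD undefined")
    through = np.abs(plane.vz[sel])
    inplane = np.hypot(plane.vx[sel], plane.vy[sel])
    return float(np.mean(through / (through + inplane)))


def flow_angle(plane: VelocityPlane, forward_only: bool = False) -> float:
    """Mean angular deviation from the plane normal, in degrees.

    Averages ``arccos(v_through / |v|)`` over nonzero-velocity lumen
    samples; retrograde vectors give angles above 90 degrees.
    """
    sel = _nonzero_lumen(plane, forward_only)
    if not sel.any():
        raise UndefinedMetricError("all lumen velocities are zero; angle undefined")
    speed = np.sqrt(plane.vx[sel] ** 2 + plane.vy[sel] ** 2 + plane.vz[sel] ** 2)
    cosang = np.clip(plane.vz[sel] / speed, -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)).mean())


def vmax(plane: VelocityPlane) -> float:
    """Maximum velocity magnitude over lumen samples, in m/s."""
    if plane.mask.sum() == 0:
        raise InputError("empty lumen mask")
    vx, vy, vz = plane.lumen_velocities()
    return float(np.sqrt(vx ** 2 + vy ** 2 + vz ** 2).max())


def compute_metrics(plane: VelocityPlane, weighted_nfd: bool = True,
                    forward_only: bool = False) -> FlowMetrics:
    """Evaluate all four profile metrics on one plane."""
    plane.validate()
    return FlowMetrics(
        nfd=nfd(plane, weighted=weighted_nfd),
        wpd=wpd(plane, forward_only=forward_only),
        angle_deg=flow_angle(plane, forward_only=forward_only),
        vmax_mps=vmax(plane),
    )
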