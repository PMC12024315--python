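"""Reduced-order transvalvular hemodynamics.

Peak-gradient prediction via the clinical simplified Bernoulli relation
(DP = 4 V²), continuity-based peak velocity through an effective orifice,
exercise scaling of the peak systolic flow rate, cube-law outflow
splitting for the aortic arch branches, and the shear-thinning
Carreau-Yasuda blood viscosity model.

Units follow clinical convention: flow rates in ml/s, effective orifice
area (EOA) in cm², velocities in m/s, gradients in mmHg.  The Bernoulli
constant 4 absorbs rho/2 and the Pa-to-mmHg conversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import InputError

__all__ = [
    "ValveSpec",
    "FluidProperties",
    "OutflowSplit",
    "dp_from_vmax",
    "vmax_from_dp",
    "vmax_from_flow",
    "calibrate_eoa",
    "apply_stress",
    "murray_split",
    "carreau_yasuda_viscosity",
    "DEFAULT_STRESS_FACTOR",
]

#: Relative increase in peak systolic flow rate used to emulate
#: high-intensity dynamic exercise (+25%).
DEFAULT_STRESS_FACTOR = 1.25


@dataclass(frozen=True)
class ValveSpec:
    """A prosthesis label size and its effective orifice area."""

    label_size: int  # mm
    eoa: float  # cm²

    def __post_init__(self) -> None:
        if self.eoa <= 0:
            raise InputError(f"eoa must be positive, got {self.eoa}")


@dataclass(frozen=True)
class FluidProperties:
    """Blood rheology parameters (Carreau-Yasuda) and density.

    Defaults are the standard literature values for blood:
    rho = 1050 kg/m³, mu0 = 0.16 Pa·s, mu_inf = 0.0035 Pa·s,
    n = 0.2128, a = 0.64, lambda = 8.2 s.
    """

    density: float = 1050.0  # kg/m³
    mu0: float = 0.16  # Pa·s, zero-shear viscosity
    mu_inf: float = 0.0035  # Pa·s, infinite-shear viscosity
    n: float = 0.2128  # power constant
    a: float = 0.64  # transition parameter
    lam: float = 8.2  # s, relaxation parameter

    def __post_init__(self) -> None:
        if not (self.mu0 > self.mu_inf > 0):
            raise InputError("require mu0 > mu_inf > 0")
        if self.lam <= 0:
            raise InputError("lambda must be positive")


@dataclass(frozen=True)
class OutflowSplit:
    """Flow distribution over the aortic arch branches.

    ``flows`` maps branch names (BCT, LCC, LSA) to ml/s; they sum to the
    arch flow ``q_inlet - q_descending`` and the brachiocephalic trunk
    (BCT) carries the combined left-common-carotid (LCC) plus
    left-subclavian (LSA) flow.
    """

    q_inlet: float
    q_descending: float
    branch_diameters: dict[str, float]
    flows: dict[str, float]

    @property
    def q_arch(self) -> float:
        return self.q_inlet - self.q_descending


def dp_from_vmax(v: float) -> float:
    """Peak transvalvular gradient from peak velocity (simplified Bernoulli).

    Parameters
    ----------
    v : float
        Peak velocity in m/s, must be >= 0.

    Returns
    -------
    float
        Gradient ``4 * v**2`` in mmHg.
    """
    if v < 0:
        raise InputError(f"velocity must be non-negative, got {v}")
    return 4.0 * v * v


def vmax_from_dp(dp: float) -> float:
    """Peak velocity implied by a gradient: ``sqrt(dp / 4)`` in m/s."""
    if dp < 0:
        raise InputError(f"gradient must be non-negative, got {dp}")
    return math.sqrt(dp / 4.0)


def vmax_from_flow(q_peak: float, eoa: float) -> float:
    """Peak velocity through an effective orifice by continuity.

    Parameters
    ----------
    q_peak : float
        Peak systolic flow rate in ml/s.
    eoa : float
        Effective orifice area in cm².

    Returns
    -------
    float
        ``(q_peak / eoa) / 100`` in m/s (the 100 converts cm/s to m/s).
    """
    if eoa <= 0:
        raise InputError(f"eoa must be positive, got {eoa}")
    if q_peak < 0:
        raise InputError(f"flow must be non-negative, got {q_peak}")
    return (q_peak / eoa) / 100.0


def calibrate_eoa(q_peak: float, dp: float) -> float:
    """Effective orifice area consistent with a (flow, gradient) pair.

    Inverts the continuity + Bernoulli chain:
    ``eoa = q_peak / (100 * sqrt(dp / 4))`` in cm².

    Raises
    ------
    InputError
        If ``dp`` or ``q_peak`` is not strictly positive (zero gradient
        would imply an infinite orifice).
    """
    if dp <= 0:
        raise InputError(f"gradient must be positive to calibrate, got {dp}")
    if q_peak <= 0:
        raise InputError(f"flow must be positive to calibrate, got {q_peak}")
    return q_peak / (100.0 * vmax_from_dp(dp))


def apply_stress(q_rest: float, factor: float = DEFAULT_STRESS_FACTOR) -> float:
    """Scale a resting peak flow rate to the exercise state.

    With a fixed orifice this implies a gradient ratio of ``factor**2``
    (1.5625 for the default +25%).
    """
    if q_rest < 0:
        raise InputError(f"flow must be non-negative, got {q_rest}")
    if factor <= 0:
        raise InputError(f"stress factor must be positive, got {factor}")
    return q_rest * factor


def murray_split(q_inlet: float, q_descending: float, d_lcc: float,
                 d_lsa: float, exponent: float = 3.0) -> OutflowSplit:
    """Distribute arch flow over the three head-and-neck branches.

    The brachiocephalic trunk is assumed to carry the combined flow of the
    left common carotid and left subclavian arteries, i.e. half the arch
    flow; the remaining half is split LCC:LSA by the cube law
    ``d_lcc**exponent : d_lsa**exponent``.

    Parameters
    ----------
    q_inlet, q_descending : float
        Inlet and descending-aorta flow rates in ml/s.
    d_lcc, d_lsa : float
        Branch diameters in mm.
    exponent : float
        Diameter exponent of the branching law (default 3).
    """
    if q_descending < 0 or q_descending > q_inlet:
        raise InputError(
            f"need 0 <= q_descending <= q_inlet, got {q_descending} of {q_inlet}")
    if d_lcc <= 0 or d_lsa <= 0:
        raise InputError("branch diameters must be positive")
    q_arch = q_inlet - q_descending
    q_bct = q_arch / 2.0
    w_lcc = d_lcc ** exponent
    w_lsa = d_lsa ** exponent
    q_lcc = q_bct * w_lcc / (w_lcc + w_lsa)
    q_lsa = q_bct * w_lsa / (w_lcc + w_lsa)
    return OutflowSplit(
        q_inlet=q_inlet,
        q_descending=q_descending,
        branch_diameters={"LCC": d_lcc, "LSA": d_lsa},
        flows={"BCT": q_bct, "LCC": q_lcc, "LSA": q_lsa},
    )


def carreau_yasuda_viscosity(shear_rate: float,
                             props: FluidProperties | None = None) -> float:
    """Apparent blood viscosity at a given shear rate.

    ``mu = mu_inf + (mu0 - mu_inf) * (1 + (lam * g)**a) ** ((n - 1) / a)``

    Monotone non-increasing in the shear rate ``g``; tends to ``mu0`` at
    zero shear and ``mu_inf`` at infinite shear.

    Parameters
    ----------
    shear_rate : float
        Shear rate in 1/s, must be >= 0.
    props : FluidProperties, optional
        Rheology parameters; defaults to the standard blood set.

    Returns
    -------
    float
        Viscosity in Pa·s.
    """
    if shear_rate < 0:
        raise InputError(f"shear rate must be non-negative, got {shear_rate}")
    p = props or FluidProperties()
    if math.isinf(shear_rate):
        return p.mu_inf
    return p.mu_inf + (p.mu0 - p.mu_inf) * (
        1.0 + (p.lam * shear_rate) ** p.a) ** ((p.n - 1.0) / p.a)
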