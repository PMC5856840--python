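"""Growth laws for the clathrin coat and the morphology timeline.

Two explicit time-course models are provided.

Constant-area law (flat growth)
    The coat grows as a flat disc.  Triskelia can only be incorporated at
    the lattice edge (rate ``alpha * sqrt(A)``) and growth is balanced by a
    loss or negative-feedback process proportional to the disc area
    (``beta * A``)::

        dA/dt = alpha * sqrt(A) - beta * A

    whose solution is the saturating curve

        A(t) = A_max * (1 - exp(-(t - t0)/tau))^2,
        A_max = (alpha/beta)^2,   tau = 2/beta.

    Under the constant-area hypothesis the coat grows flat all the way to
    ``A_max`` and only then bends at constant surface area.

Flat-to-curved law (early bending)
    The coat grows flat by the same law but starts to bend once it reaches
    a fraction ``f_star`` (default 0.70) of its final content.  Bending
    proceeds on a sphere of fixed tip radius ``R`` with the contact angle
    increasing linearly in time (``d theta / dt = omega``), so the surface
    keeps growing as ``S(t) = 2 pi R^2 (1 - cos theta(t))`` until the cap
    closes at ``theta_max``, which stops growth intrinsically: there is no
    need for an area-coupled balancing process once curvature regulates
    assembly.

The curved phase of either model is split into dome and pit sub-phases in
the duration ratio observed in EM snapshots (default 40:60).

Units: areas in nm² (or arbitrary intensity units under a linear
calibration), times in s, angles in radians.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import CapShape, FlatDisc

__all__ = [
    "DEFAULT_THETA_MAX",
    "FlatGrowthParams",
    "CurvedGrowthParams",
    "TransitionRule",
    "MorphologyTimeline",
    "TwoPhaseModel",
    "constant_area_curve",
    "two_phase_curve",
    "assign_morphology_timeline",
    "plateau_time",
]

#: Default maximal contact angle for a pit.  Pits are "almost complete
#: spheres": theta = pi degenerates the neck, so we stop slightly short.
DEFAULT_THETA_MAX = np.deg2rad(160.0)


@dataclass(frozen=True)
class FlatGrowthParams:
    """Parameters of the flat (constant-area) growth law.

    ``alpha`` is the edge assembly rate (area^{1/2} s^-1), ``beta`` the
    area-coupled loss rate (s^-1) and ``t0`` the nucleation time (s).
    """

    alpha: float
    beta: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")

    @property
    def a_max(self) -> float:
        """Asymptotic area (alpha/beta)^2."""
        return (self.alpha / self.beta) ** 2

    @property
    def tau(self) -> float:
        """Relaxation time 2/beta of the saturating curve."""
        return 2.0 / self.beta

    @classmethod
    def from_plateau(cls, a_max: float, tau: float, t0: float = 0.0) -> "FlatGrowthParams":
        """Build from the observable parametrisation (A_max, tau, t0)."""
        if a_max <= 0 or tau <= 0:
            raise ValueError("a_max and tau must be positive")
        beta = 2.0 / tau
        alpha = beta * np.sqrt(a_max)
        return cls(alpha=alpha, beta=beta, t0=t0)


@dataclass(frozen=True)
class CurvedGrowthParams:
    """Bending-phase parameters: angular rate omega (rad/s), tip radius R
    (nm) and the maximal contact angle of a pit."""

    omega: float
    tip_radius: float
    theta_max: float = DEFAULT_THETA_MAX

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise ValueError("omega must be positive")
        if self.tip_radius <= 0:
            raise ValueError("tip_radius must be positive")
        if not (0 < self.theta_max <= np.pi):
            raise ValueError("theta_max must be in (0, pi]")


@dataclass(frozen=True)
class TransitionRule:
    """When bending starts and how the curved phase divides into dome/pit.

    ``f_star`` is the fraction of final content at which a flat coat starts
    to curve (default 0.70); ``dome_fraction`` the fraction of the curved
    phase duration spent as a dome (default 0.40, the dome:pit = 40:60
    split seen in EM).
    """

    f_star: float = 0.70
    dome_fraction: float = 0.40

    def __post_init__(self) -> None:
        if not (0.0 < self.f_star < 1.0):
            raise ValueError("f_star must be in (0, 1)")
        if not (0.0 <= self.dome_fraction <= 1.0):
            raise ValueError("dome_fraction must be in [0, 1]")

    @property
    def pit_fraction(self) -> float:
        return 1.0 - self.dome_fraction


@dataclass(frozen=True)
class MorphologyTimeline:
    """Event timeline: nucleation, flat-to-curved transition, dome-to-pit
    conversion and scission times (s)."""

    t_nucleation: float
    t_transition: float
    t_dome_end: float
    t_scission: float

    def __post_init__(self) -> None:
        if not (
            self.t_nucleation
            <= self.t_transition
            <= self.t_dome_end
            <= self.t_scission
        ):
            raise ValueError("timeline must be ordered")

    @property
    def lifetime(self) -> float:
        return self.t_scission - self.t_nucleation

    def morphology_at(self, t: float) -> str:
        """Morphology class at time ``t`` within the event's lifetime."""
        if not (self.t_nucleation <= t <= self.t_scission):
            raise ValueError(f"t={t} outside event lifetime")
        if t < self.t_transition:
            return "flat"
        if t < self.t_dome_end:
            return "dome"
        return "pit"


def constant_area_curve(params: FlatGrowthParams, t) -> np.ndarray | float:
    """Area of a flat coat at time(s) ``t`` under the constant-area law.

    Closed form ``A_max (1 - exp(-(t - t0)/tau))^2`` for ``t >= t0`` and 0
    before nucleation.  Accepts scalars or arrays.
    """
    t = np.asarray(t, dtype=float)
    x = np.clip((t - params.t0) / params.tau, 0.0, None)
    out = params.a_max * (1.0 - np.exp(-x)) ** 2
    return out if out.ndim else float(out)


def plateau_time(params: FlatGrowthParams, epsilon: float = 0.05) -> float:
    """Smallest t with ``A(t) >= (1 - epsilon) * A_max``.

    Closed form ``t0 + tau * (-ln(1 - sqrt(1 - epsilon)))``; the saturating
    curve never reaches its asymptote exactly, so the plateau is defined by
    the tolerance ``epsilon``.
    """
    if not (0.0 < epsilon < 1.0):
        raise ValueError("epsilon must be in (0, 1)")
    return params.t0 + params.tau * (-np.log(1.0 - np.sqrt(1.0 - epsilon)))


class TwoPhaseModel:
    """Flat-to-curved growth: flat disc growth interrupted by bending.

    The flat phase follows ``constant_area_curve(flat, t)`` until the area
    reaches ``rule.f_star * s_final``; from then on the coat is a spherical
    cap on a sphere whose tip radius is fixed by
    ``s_final = 2 pi R^2 (1 - cos theta_max)`` with contact angle growing
    linearly at rate ``omega``.  The initial angle ``theta0`` is set by
    surface continuity at the transition.  Growth stops when the cap
    reaches ``theta_max`` (formation of a near-complete sphere).

    ``curved.tip_radius`` is ignored; the radius is derived from
    ``s_final`` and ``theta_max`` so that the final surface matches the
    track's final content.
    """

    def __init__(
        self,
        flat: FlatGrowthParams,
        curved: CurvedGrowthParams,
        rule: TransitionRule,
        s_final: float,
    ) -> None:
        if s_final <= 0:
            raise ValueError("s_final must be positive")
        s_star = rule.f_star * s_final
        if s_star >= flat.a_max:
            raise ValueError(
                "flat phase saturates below the transition surface "
                f"(f_star * s_final = {s_star:.4g} >= A_max = {flat.a_max:.4g})"
            )
        self.flat = flat
        self.curved = curved
        self.rule = rule
        self.s_final = float(s_final)
        # tip radius from the final surface and closure angle
        self.tip_radius = float(
            np.sqrt(s_final / (2.0 * np.pi * (1.0 - np.cos(curved.theta_max))))
        )
        # contact angle at the transition, from surface continuity
        cos_theta0 = 1.0 - rule.f_star * (1.0 - np.cos(curved.theta_max))
        self.theta0 = float(np.arccos(np.clip(cos_theta0, -1.0, 1.0)))
        # transition time: invert the flat curve at s_star
        x = -np.log(1.0 - np.sqrt(s_star / flat.a_max))
        self.t_transition = flat.t0 + flat.tau * x
        # time at which the cap closes and growth stops
        self.t_closure = self.t_transition + (curved.theta_max - self.theta0) / curved.omega

    def theta(self, t) -> np.ndarray | float:
        """Contact angle at time(s) t (0 during the flat phase)."""
        t = np.asarray(t, dtype=float)
        th = self.theta0 + self.curved.omega * (t - self.t_transition)
        th = np.where(t < self.t_transition, 0.0, np.minimum(th, self.curved.theta_max))
        return th if th.ndim else float(th)

    def surface(self, t) -> np.ndarray | float:
        """Coat surface area at time(s) t; continuous and nondecreasing."""
        t = np.asarray(t, dtype=float)
        flat_part = constant_area_curve(self.flat, t)
        th = self.theta0 + self.curved.omega * (t - self.t_transition)
        th = np.minimum(th, self.curved.theta_max)
        r = self.tip_radius
        curved_part = 2.0 * np.pi * r * r * (1.0 - np.cos(th))
        out = np.where(t < self.t_transition, flat_part, curved_part)
        return out if out.ndim else float(out)

    def shape(self, t: float) -> CapShape | FlatDisc:
        """Geometric state at time t: a FlatDisc before the transition, a
        CapShape after."""
        if t < self.t_transition:
            return FlatDisc(area=float(constant_area_curve(self.flat, t)))
        return CapShape(tip_radius=self.tip_radius, contact_angle=float(self.theta(t)))


def two_phase_curve(
    flat: FlatGrowthParams,
    curved: CurvedGrowthParams,
    rule: TransitionRule,
    s_final: float,
    t: float,
) -> tuple[float, CapShape | FlatDisc]:
    """Surface area and geometric state of a flat-to-curved coat at time t.

    Convenience wrapper over :class:`TwoPhaseModel` for single time points;
    build the model object directly for vectorised evaluation.
    """
    model = TwoPhaseModel(flat, curved, rule, s_final)
    return float(model.surface(t)), model.shape(t)


def assign_morphology_timeline(
    t_nucleation: float,
    t_transition: float,
    t_scission: float,
    rule: TransitionRule,
) -> MorphologyTimeline:
    """Split the curved phase [t_transition, t_scission] into dome and pit
    sub-intervals in the rule's duration ratio.

    The dome sub-interval occupies ``rule.dome_fraction`` of the curved
    phase, matching the dome:pit abundance ratio of a steady-state EM
    snapshot (equal nucleation flux makes abundance proportional to
    duration).
    """
    if not (t_nucleation <= t_transition <= t_scission):
        raise ValueError("times must satisfy t_nucleation <= t_transition <= t_scission")
    t_dome_end = t_transition + rule.dome_fraction * (t_scission - t_transition)
    return MorphologyTimeline(
        t_nucleation=t_nucleation,
        t_transition=t_transition,
        t_dome_end=t_dome_end,
        t_scission=t_scission,
    )
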