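"""Reduced-order in-branch velocity field and Poiseuille wall-load surrogates.

The resolved (large-eddy) airway flow is replaced by piecewise analytic
elliptic-Poiseuille flow: within each straight branch the axial velocity is

    u(x, y) = 2 u_mean (1 - (x/b)^2 - (y/a)^2),

where (a, b) are the local ellipse semi-axes and u_mean = Q / (pi a b). The
cross-sectional integral equals the branch flow rate exactly. For tapered
branches (a, b linear in arc length) a self-similar lateral component is
added so that fluid streamlines contract with the wall and the field remains
flux-conserving; for uniform branches the field is exactly divergence-free.

Frame convention: the lumen's *minor* axis is placed in the local branching
plane (the plane containing the parent's axis), which is the direction a
particle's unrelaxed momentum points after a bifurcation hand-off. This is
what couples reduced circularity to increased impaction: at equal Dave, a
flatter lumen puts the wall closer along exactly that direction.

Turbulence above the glottis is emulated by an Ornstein–Uhlenbeck velocity
fluctuation whose rms is ``intensity * |u|`` and whose correlation time is
``eddy_length / |u|``, applied only in a configurable proximal extent of the
trachea. Poiseuille surrogates give the wall shear stress
``tau_w = 32 mu Q / (pi Dave^3)`` and pressure drop
``dP = 128 mu L Q / (pi Dave^4)`` used in the constriction-coupling report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

from .airway_model import AirwayTree, ellipse_axes_from_section
from .boundary_conditions import FlowSolution

__all__ = [
    "BranchFrame",
    "TurbulenceSurrogate",
    "OutsideLumenError",
    "build_frames",
    "velocity_field",
    "velocity_at",
    "perturb_velocity",
    "ou_update",
    "wall_shear_stress",
    "pressure_drop",
]


class OutsideLumenError(ValueError):
    """The queried point lies outside the branch lumen."""


@dataclass(frozen=True)
class BranchFrame:
    """Local orthonormal frame and ellipse geometry of one branch.

    ``axis`` points distally; ``normal_u`` spans the branching plane (minor
    axis b along u), ``normal_v = axis x normal_u`` carries the major axis a.
    Semi-axes vary linearly from (a0, b0) at the proximal end to (a1, b1)
    at the distal end.
    """

    branch_id: str
    origin: np.ndarray
    axis: np.ndarray
    normal_u: np.ndarray
    normal_v: np.ndarray
    a0: float
    a1: float
    b0: float
    b1: float
    length: float
    Q: float

    def axes_at(self, s) -> Tuple[np.ndarray, np.ndarray]:
        """Semi-axes (a, b) at arc length s (clamped to [0, L])."""
        t = np.clip(np.asarray(s, dtype=float) / self.length, 0.0, 1.0)
        return self.a0 + (self.a1 - self.a0) * t, self.b0 + (self.b1 - self.b0) * t

    def local_coords(self, points: np.ndarray):
        """(s, x_u, y_v) of lab-frame points; points may be (3,) or (n,3)."""
        r = np.asarray(points, dtype=float) - self.origin
        s = r @ self.axis
        x = r @ self.normal_u
        y = r @ self.normal_v
        return s, x, y

    def lumen_excess(self, points: np.ndarray):
        """(x/b)^2 + (y/a)^2; >= 1 means at/outside the wall."""
        s, x, y = self.local_coords(points)
        a, b = self.axes_at(s)
        return (x / b) ** 2 + (y / a) ** 2

    @property
    def is_tapered(self) -> bool:
        return self.a0 != self.a1 or self.b0 != self.b1


def _frame_orientation(
    axis: np.ndarray, parent_axis: Optional[np.ndarray]
) -> Tuple[np.ndarray, np.ndarray]:
    """normal_u along the in-plane component of the parent axis."""
    u = None
    if parent_axis is not None:
        w = parent_axis - np.dot(parent_axis, axis) * axis
        n = np.linalg.norm(w)
        if n > 1e-9:
            u = w / n
    if u is None:
        for ref in (np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0])):
            w = ref - np.dot(ref, axis) * axis
            n = np.linalg.norm(w)
            if n > 1e-9:
                u = w / n
                break
    v = np.cross(axis, u)
    return u, v


def build_frames(tree: AirwayTree, flow: FlowSolution) -> Dict[str, BranchFrame]:
    """Construct the local frame of every branch from tree + flow solution."""
    frames: Dict[str, BranchFrame] = {}
    for bid in tree.topological_order():
        b = tree.branches[bid]
        parent_axis = (
            tree.branches[b.parent_id].direction if b.parent_id is not None else None
        )
        u, v = _frame_orientation(b.direction, parent_axis)
        a0, b0 = ellipse_axes_from_section(b.proximal)
        a1, b1 = ellipse_axes_from_section(b.distal)
        frames[bid] = BranchFrame(
            branch_id=bid,
            origin=b.origin,
            axis=b.direction,
            normal_u=u,
            normal_v=v,
            a0=a0, a1=a1, b0=b0, b1=b1,
            length=b.length,
            Q=flow.Q_branch[bid],
        )
    return frames


def velocity_field(frame: BranchFrame, points: np.ndarray):
    """Vectorized fluid velocity at (n,3) lab points.

    Returns (vel (n,3), inside (n,) bool). Points outside the lumen get zero
    velocity and ``inside=False``; callers decide whether that is a wall hit.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    s, x, y = frame.local_coords(pts)
    a, b = frame.axes_at(s)
    xi = x / b
    eta = y / a
    r2 = xi**2 + eta**2
    inside = r2 <= 1.0
    u_mean = frame.Q / (math.pi * a * b)
    u_ax = 2.0 * u_mean * (1.0 - r2)
    vel = u_ax[:, None] * frame.axis[None, :]
    if frame.is_tapered:
        da = (frame.a1 - frame.a0) / frame.length
        db = (frame.b1 - frame.b0) / frame.length
        # self-similar contraction: streamlines keep constant (x/b, y/a)
        vel += (u_ax * x * db / b)[:, None] * frame.normal_u[None, :]
        vel += (u_ax * y * da / a)[:, None] * frame.normal_v[None, :]
    vel[~inside] = 0.0
    return vel, inside


def velocity_at(frame: BranchFrame, Q: float, point: np.ndarray) -> np.ndarray:
    """Fluid velocity (m/s) at one lab-frame point inside the lumen.

    Raises :class:`OutsideLumenError` for points at or beyond the wall —
    the signal the deposition detector consumes.
    """
    from dataclasses import replace as _replace

    f = frame if Q == frame.Q else _replace(frame, Q=Q)
    vel, inside = velocity_field(f, point)
    if not bool(inside[0]):
        raise OutsideLumenError(
            f"point outside lumen of branch {frame.branch_id}"
        )
    return vel[0]


@dataclass(frozen=True)
class TurbulenceSurrogate:
    """Ornstein–Uhlenbeck surrogate for glottal synthetic turbulence.

    ``intensity`` is rms fluctuation over local mean speed; ``eddy_length``
    sets the correlation time ``eddy_length / |u|``. Defaults follow the
    tracheal jet values used for scans lacking the oropharynx: 0.29 and 8 mm.
    """

    intensity: float = 0.29
    eddy_length: float = 0.008
    seed: int = 0

    def __post_init__(self) -> None:
        if self.intensity < 0.0:
            raise ValueError("intensity must be >= 0")
        if not self.eddy_length > 0.0:
            raise ValueError("eddy_length must be > 0")


def ou_update(
    ts: TurbulenceSurrogate,
    eta: np.ndarray,
    u_base_mag: np.ndarray,
    dt: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One OU step of the *standardized* fluctuation vectors ``eta`` (n,3).

    ``eta`` is dimensionless with stationary vector rms 1 (per-component
    variance 1/3) and correlation time ``eddy_length / |u_base|``. The
    physical perturbation is ``intensity * |u_base| * eta``, so its rms is
    ``intensity * |u_base|`` and — because it is scaled by the *local* base
    speed — it vanishes at the wall the way real near-wall fluctuations do.
    """
    if ts.intensity == 0.0:
        return np.zeros_like(eta)
    umag = np.maximum(np.asarray(u_base_mag, dtype=float), 1e-12)
    theta = umag / ts.eddy_length
    decay = np.exp(-theta * dt)
    noise = rng.standard_normal(eta.shape)
    return (
        eta * decay[:, None]
        + (np.sqrt((1.0 - decay**2) / 3.0))[:, None] * noise
    )


def perturb_velocity(
    ts: TurbulenceSurrogate,
    u_base: np.ndarray,
    dt: float,
    eta: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Perturbed velocity and updated standardized OU state for one point.

    Returns ``(u_base + intensity |u_base| eta', eta')``. With
    ``intensity = 0`` the base velocity is returned unchanged.
    """
    u_base = np.asarray(u_base, dtype=float)
    if eta is None:
        eta = np.zeros(3)
    if ts.intensity == 0.0:
        return u_base, np.zeros(3)
    if rng is None:
        rng = np.random.default_rng(ts.seed)
    umag = float(np.linalg.norm(u_base))
    eta_new = ou_update(ts, eta[None, :], np.array([umag]), dt, rng)[0]
    return u_base + ts.intensity * umag * eta_new, eta_new


def wall_shear_stress(Q: float, dave: float, mu_f: float) -> float:
    """Poiseuille wall shear stress tau_w = 32 mu Q / (pi Dave^3), Pa."""
    if dave <= 0.0 or mu_f <= 0.0:
        raise ValueError("dave and mu_f must be positive")
    return 32.0 * mu_f * Q / (math.pi * dave**3)


def pressure_drop(Q: float, dave: float, length: float, mu_f: float) -> float:
    """Poiseuille pressure drop dP = 128 mu L Q / (pi Dave^4), Pa.

    Identity: dP = 4 L tau_w / Dave.
    """
    if length < 0.0:
        raise ValueError("length must be >= 0")
    if dave <= 0.0 or mu_f <= 0.0:
        raise ValueError("dave and mu_f must be positive")
    return 128.0 * mu_f * length * Q / (math.pi * dave**4)
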