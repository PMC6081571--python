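"""Phenotype-controlled synthetic airway trees, lobar ventilation and waveforms.

This module emulates the inputs that a CT-based workflow would supply:

* an airway tree segmented down to (sub)segmental branches with the standard
  anatomical names (Trachea, RMB, LMB, TriRUL, BronInt, RB1–RB10, LB1+2–LB10b),
* a per-lobe air-volume-change table (the lobar aggregate of the
  TLC-to-FRC registration-derived ventilation map), and
* a sinusoidal breathing waveform.

A phenotype is controlled by three scalars:

``cr_target``
    mean circularity of airway lumens (elliptic lumens; lower in severe
    asthma),
``constriction_factor``
    multiplicative reduction of average diameter applied to lower-lobe
    (RLL/LLL) branches (airway narrowing),
``upper_shift``
    fraction of the total air-volume change allocated to the upper lobes
    (RUL+LUL); severe asthma shifts ventilation apically.

The topology is a fixed 34-branch anatomical template (31 named branches
after the first generation); diameters follow a Murray-type parent-to-child
ratio with lognormal jitter, and lengths follow a fixed length-to-diameter
ratio. Everything is reproducible from ``seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
from scipy.optimize import brentq

from .airway_model import (
    LOBES,
    UPPER_LOBES,
    LOWER_AND_MIDDLE_LOBES,
    AirwayTree,
    Branch,
    CrossSection,
    InvalidSectionError,
    MAX_ASPECT_RATIO,
    ellipse_perimeter,
)

__all__ = [
    "PhenotypeSpec",
    "LobarVolumeChange",
    "BreathingWaveform",
    "PHENOTYPES",
    "DEFAULT_TOTAL_DV_L",
    "elliptic_section_from",
    "generate_tree",
    "generate_volume_change",
    "default_waveform",
]


@dataclass(frozen=True)
class PhenotypeSpec:
    """Generator controls for one subject phenotype."""

    name: str
    cr_target: float = 0.96
    constriction_factor: float = 1.0
    upper_shift: float = 0.33
    seed: int = 0
    #: angle between the two daughters of the RMB (TriRUL vs BronInt), degrees
    rmb_angle_deg: float = 90.0
    #: tracheal average diameter (m)
    trachea_dave: float = 0.018
    #: optional focal constrictions: branch name -> target Dave (m); the
    #: scale is propagated to the branch's descendants.
    focal_constrictions: Mapping[str, float] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.cr_target <= 1.0):
            raise ValueError("require 0 < cr_target <= 1")
        if not (0.0 < self.constriction_factor <= 1.0):
            raise ValueError("require 0 < constriction_factor <= 1")
        if not (0.0 < self.upper_shift < 1.0):
            raise ValueError("require 0 < upper_shift < 1")
        if not self.trachea_dave > 0.0:
            raise ValueError("require trachea_dave > 0")
        if not (0.0 < self.rmb_angle_deg < 180.0):
            raise ValueError("require 0 < rmb_angle_deg < 180")


#: Study phenotypes: two healthy subjects (circular lumens, basal-dominant
#: ventilation), one severe phenotype with reduced circularity only, and one
#: with reduced circularity plus lower-lobe constriction. RMB bifurcation
#: angles follow the four subjects' printed values (90/91 healthy, 83/88
#: severe).
PHENOTYPES: Dict[str, PhenotypeSpec] = {
    "healthy_1": PhenotypeSpec(name="healthy_1", cr_target=0.96, constriction_factor=1.0,
                               upper_shift=0.33, rmb_angle_deg=90.0, seed=11),
    "healthy_2": PhenotypeSpec(name="healthy_2", cr_target=0.96, constriction_factor=1.0,
                               upper_shift=0.33, rmb_angle_deg=91.0, seed=12),
    "severe_cr": PhenotypeSpec(name="severe_cr", cr_target=0.88, constriction_factor=1.0,
                               upper_shift=0.45, rmb_angle_deg=83.0, seed=13),
    "severe_cr_dh": PhenotypeSpec(name="severe_cr_dh", cr_target=0.85, constriction_factor=0.6,
                                  upper_shift=0.45, rmb_angle_deg=88.0, seed=14),
}

#: Default total air-volume change (L): TLC − FRC of the first healthy
#: subject, 5.37 − 2.04.
DEFAULT_TOTAL_DV_L = 5.37 - 2.04


@dataclass(frozen=True)
class LobarVolumeChange:
    """Air-volume change (litres) per lobe between TLC and FRC."""

    delta_v_L: Mapping[str, float]

    def __post_init__(self) -> None:
        dv = dict(self.delta_v_L)
        if set(dv) != set(LOBES):
            raise ValueError(f"delta_v_L must be keyed by {LOBES}")
        if any(v < 0.0 for v in dv.values()):
            raise ValueError("all lobar volume changes must be >= 0")
        if not sum(dv.values()) > 0.0:
            raise ValueError("total volume change must be > 0")
        object.__setattr__(self, "delta_v_L", dv)

    @property
    def total_L(self) -> float:
        return sum(self.delta_v_L.values())

    @property
    def uml_ratio(self) -> float:
        """U/(M+L)|v: upper-lobe over middle+lower-lobe air-volume change."""
        upper = sum(self.delta_v_L[lb] for lb in UPPER_LOBES)
        rest = sum(self.delta_v_L[lb] for lb in LOWER_AND_MIDDLE_LOBES)
        if rest <= 0.0:
            raise ZeroDivisionError("middle+lower volume change is zero")
        return upper / rest


@dataclass(frozen=True)
class BreathingWaveform:
    """Sinusoidal breath: tidal volume (L) delivered over one period (s)."""

    tidal_volume_L: float = 0.5
    period_s: float = 4.8

    def __post_init__(self) -> None:
        if not (self.tidal_volume_L > 0.0 and self.period_s > 0.0):
            raise ValueError("tidal volume and period must be > 0")


def default_waveform() -> BreathingWaveform:
    return BreathingWaveform(tidal_volume_L=0.5, period_s=4.8)


# -- elliptic lumen construction ------------------------------------------


def elliptic_section_from(
    cr_target: float, dave_target: float, station: float = 0.0
) -> CrossSection:
    """Ellipse with prescribed circularity and average diameter.

    Finds semi-axes ``a >= b`` with ``pi a b = pi Dave^2/4`` whose
    Ramanujan-II perimeter yields ``Cr = pi Dave / Pe = cr_target``, by
    monotone root-finding on the aspect ratio (capped at 5:1).
    """
    if not (0.0 < cr_target <= 1.0):
        raise InvalidSectionError("require 0 < cr_target <= 1")
    if not dave_target > 0.0:
        raise InvalidSectionError("require dave_target > 0")
    area = math.pi * dave_target**2 / 4.0
    if cr_target == 1.0:
        r = 1.0
    else:
        def f(r: float) -> float:
            a = 0.5 * dave_target * math.sqrt(r)
            b = 0.5 * dave_target / math.sqrt(r)
            return math.pi * dave_target / ellipse_perimeter(a, b) - cr_target

        if f(MAX_ASPECT_RATIO) > 0.0:
            raise InvalidSectionError(
                f"cr_target {cr_target} not attainable with aspect ratio <= {MAX_ASPECT_RATIO}"
            )
        r = brentq(f, 1.0, MAX_ASPECT_RATIO, xtol=1e-14, rtol=1e-15)
    a = 0.5 * dave_target * math.sqrt(r)
    b = 0.5 * dave_target / math.sqrt(r)
    return CrossSection(
        area=area,
        perimeter=ellipse_perimeter(a, b),
        station=station,
        semi_major=a,
        semi_minor=b,
    )


# -- anatomical template ---------------------------------------------------

# (name, parent, lobe, diameter ratio, polar angle deg, azimuth deg)
# Polar angle is measured from the parent axis. The azimuth rotates about
# the parent axis within a basis whose phi = 0 direction is the projection
# of the *grandparent* axis onto the parent's cross-plane — i.e. the side
# toward which the incoming flow's momentum keeps pointing after the
# parent's own turn (the outer wall of the bend). Continuing trunks
# (BronInt, RLLB, RLL7, LLB, ..., LB10) sit at phi = 0 and side/upper
# branches at phi = 180, which is what makes large particles overshoot
# upper-lobe takeoffs, as real inertial aerosols do. "A" marks the
# phenotype-controlled RMB daughter angles (split 0.61/0.39 of
# rmb_angle_deg, opposite azimuths, hence coplanar and summing exactly to
# rmb_angle_deg).
_TOPOLOGY: Tuple[Tuple[str, Optional[str], str, float, object, float], ...] = (
    ("Trachea", None, "none", 1.00, 0.0, 0.0),
    ("RMB", "Trachea", "none", 0.72, 33.0, 180.0),
    ("LMB", "Trachea", "none", 0.65, 42.0, 0.0),
    ("TriRUL", "RMB", "RUL", 0.64, "A1", 180.0),
    ("BronInt", "RMB", "none", 0.86, "A2", 0.0),
    ("RB1", "TriRUL", "RUL", 0.70, 40.0, 0.0),
    ("RB2", "TriRUL", "RUL", 0.70, 40.0, 120.0),
    ("RB3", "TriRUL", "RUL", 0.70, 40.0, 240.0),
    ("RMLB", "BronInt", "RML", 0.60, 48.0, 180.0),
    ("RLLB", "BronInt", "RLL", 0.88, 22.0, 0.0),
    ("RB4", "RMLB", "RML", 0.75, 35.0, 90.0),
    ("RB5", "RMLB", "RML", 0.75, 35.0, 270.0),
    ("RB6", "RLLB", "RLL", 0.62, 50.0, 180.0),
    ("RLL7", "RLLB", "RLL", 0.90, 18.0, 0.0),
    ("RB7", "RLL7", "RLL", 0.66, 45.0, 180.0),
    ("RB8", "RLL7", "RLL", 0.68, 45.0, 90.0),
    ("RB9+10", "RLL7", "RLL", 0.82, 22.0, 0.0),
    ("RB9", "RB9+10", "RLL", 0.72, 40.0, 180.0),
    ("RB10", "RB9+10", "RLL", 0.72, 40.0, 0.0),
    ("LULB", "LMB", "LUL", 0.80, 40.0, 180.0),
    ("LLB", "LMB", "LLL", 0.85, 25.0, 0.0),
    ("LB1+2", "LULB", "LUL", 0.72, 38.0, 180.0),
    ("LB3", "LULB", "LUL", 0.70, 38.0, 60.0),
    ("LB4+5", "LULB", "LUL", 0.68, 45.0, 300.0),
    ("LB4", "LB4+5", "LUL", 0.75, 35.0, 90.0),
    ("LB5", "LB4+5", "LUL", 0.75, 35.0, 270.0),
    ("LB6", "LLB", "LLL", 0.62, 48.0, 180.0),
    ("LLBbasal", "LLB", "LLL", 0.88, 18.0, 0.0),
    ("LB8", "LLBbasal", "LLL", 0.70, 42.0, 180.0),
    ("LB9+10", "LLBbasal", "LLL", 0.80, 22.0, 0.0),
    ("LB9", "LB9+10", "LLL", 0.72, 42.0, 180.0),
    ("LB10", "LB9+10", "LLL", 0.78, 35.0, 0.0),
    ("LB10a", "LB10", "LLL", 0.74, 38.0, 90.0),
    ("LB10b", "LB10", "LLL", 0.74, 38.0, 270.0),
)

#: Parent-to-child diameter jitter (lognormal sigma) and length jitter.
_DIAMETER_JITTER_SIGMA = 0.05
_LENGTH_JITTER_SIGMA = 0.10
#: Length-to-diameter ratio (conventional airway morphometry).
_LENGTH_TO_DIAMETER = 3.0
#: Circularity scatter about cr_target (clipped at +/- 0.04).
_CR_SIGMA = 0.015
_CR_CLIP = 0.04
#: Lower lobes subject to constriction_factor.
_CONSTRICTED_LOBES = ("RLL", "LLL")


def _local_basis(
    axis: np.ndarray, grandparent_dir: Optional[np.ndarray]
) -> Tuple[np.ndarray, np.ndarray]:
    """In-plane basis of a parent branch; phi=0 along the incoming-momentum
    continuation (projection of the grandparent axis), matching the frame
    convention of the flow model."""
    u = None
    if grandparent_dir is not None:
        w = grandparent_dir - np.dot(grandparent_dir, axis) * axis
        n = np.linalg.norm(w)
        if n > 1e-9:
            u = w / n
    if u is None:
        ref = np.array([1.0, 0.0, 0.0])
        if abs(float(np.dot(ref, axis))) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        u = ref - np.dot(ref, axis) * axis
        u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    return u, v


def _child_direction(
    parent_dir: np.ndarray,
    grandparent_dir: Optional[np.ndarray],
    polar_deg: float,
    azim_deg: float,
) -> np.ndarray:
    u, v = _local_basis(parent_dir, grandparent_dir)
    th = math.radians(polar_deg)
    ph = math.radians(azim_deg)
    d = (
        math.cos(th) * parent_dir
        + math.sin(th) * (math.cos(ph) * u + math.sin(ph) * v)
    )
    return d / np.linalg.norm(d)


def generate_tree(spec: PhenotypeSpec) -> AirwayTree:
    """Generate the phenotype-controlled airway tree.

    Deterministic given ``spec.seed``. Branch ``Dave`` follows the template
    diameter ratios with lognormal jitter; lower-lobe branches are scaled by
    ``constriction_factor``; focal constrictions rescale a named branch (and
    its descendants) to a target ``Dave``. Each lumen is an ellipse whose
    measured circularity is drawn around ``cr_target``; the ellipse
    orientation is resolved by the flow model (minor axis in the local
    branching plane).
    """
    rng = np.random.default_rng(spec.seed)
    by_name: Dict[str, dict] = {}
    branches = []
    for name, parent, lobe, ratio, polar, azim in _TOPOLOGY:
        if name == "Trachea":
            base_dave = spec.trachea_dave
            direction = np.array([0.0, 0.0, 1.0])
            origin = np.zeros(3)
            generation = 0
            parent_id = None
        else:
            p = by_name[parent]
            jitter = math.exp(rng.normal(0.0, _DIAMETER_JITTER_SIGMA))
            base_dave = p["base_dave"] * ratio * jitter
            if polar == "A1":
                polar_deg = 0.61 * spec.rmb_angle_deg
            elif polar == "A2":
                polar_deg = 0.39 * spec.rmb_angle_deg
            else:
                polar_deg = float(polar)
            gp = by_name[p["parent_id"]]["direction"] if p["parent_id"] else None
            direction = _child_direction(p["direction"], gp, polar_deg, azim)
            origin = p["origin"] + p["length"] * p["direction"]
            generation = p["generation"] + 1
            parent_id = parent

        length = _LENGTH_TO_DIAMETER * base_dave * math.exp(
            rng.normal(0.0, _LENGTH_JITTER_SIGMA)
        )
        dave = base_dave
        if lobe in _CONSTRICTED_LOBES:
            dave *= spec.constriction_factor

        cr = float(
            np.clip(
                rng.normal(spec.cr_target, _CR_SIGMA),
                spec.cr_target - _CR_CLIP,
                min(1.0, spec.cr_target + _CR_CLIP),
            )
        )
        by_name[name] = {
            "base_dave": base_dave,
            "dave": dave,
            "cr": cr,
            "direction": direction,
            "origin": origin,
            "length": length,
            "generation": generation,
            "parent_id": parent_id,
            "lobe": lobe,
        }

    # focal constrictions: rescale named branch and all its descendants
    if spec.focal_constrictions:
        children: Dict[str, list] = {n: [] for n in by_name}
        for n, d in by_name.items():
            if d["parent_id"] is not None:
                children[d["parent_id"]].append(n)
        for fname, target in spec.focal_constrictions.items():
            if fname not in by_name:
                raise ValueError(f"focal constriction names unknown branch {fname!r}")
            if not target > 0.0:
                raise ValueError("focal constriction target Dave must be > 0")
            scale = target / by_name[fname]["dave"]
            stack = [fname]
            while stack:
                n = stack.pop()
                by_name[n]["dave"] *= scale
                stack.extend(children[n])

    for name, d in by_name.items():
        sections = (
            elliptic_section_from(d["cr"], d["dave"], station=0.0),
            elliptic_section_from(d["cr"], d["dave"], station=1.0),
        )
        branches.append(
            Branch(
                id=name,
                name=name,
                parent_id=d["parent_id"],
                lobe=d["lobe"],
                generation=d["generation"],
                length=d["length"],
                origin=d["origin"],
                direction=d["direction"],
                cross_sections=sections,
            )
        )
    return AirwayTree(branches)


#: Fixed intra-group lobar proportions (typical lobar ventilation shares).
_UPPER_SPLIT = {"RUL": 0.47, "LUL": 0.53}
_LOWER_SPLIT = {"RML": 0.15, "RLL": 0.45, "LLL": 0.40}


def generate_volume_change(
    spec: PhenotypeSpec, total_dv_L: float = DEFAULT_TOTAL_DV_L
) -> LobarVolumeChange:
    """Lobar air-volume-change table with the phenotype's apical shift.

    The upper lobes (RUL+LUL) receive ``upper_shift`` of the total; the
    remainder is split over RML/RLL/LLL in fixed proportions, so
    ``U/(M+L)|v = upper_shift / (1 - upper_shift)`` exactly.
    """
    if not total_dv_L > 0.0:
        raise ValueError("total_dv_L must be > 0")
    dv = {}
    for lobe, w in _UPPER_SPLIT.items():
        dv[lobe] = spec.upper_shift * total_dv_L * w
    for lobe, w in _LOWER_SPLIT.items():
        dv[lobe] = (1.0 - spec.upper_shift) * total_dv_L * w
    return LobarVolumeChange(delta_v_L=dv)
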