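"""Airway-tree data model, cross-section morphometry and tree I/O.

The conducting airways are represented as a rooted tree of straight branches.
Each branch carries at least two cross-sections (proximal and distal), and a
cross-section is reduced to the two scalars that the morphometric metrics
need: lumen area ``Ac`` and lumen perimeter ``Pe``. From these,

* ``Dave = sqrt(4 Ac / pi)`` — the area-equivalent (average) diameter,
* ``Cr   = pi Dave / Pe``    — circularity, the perimeter of the
  area-equivalent circle over the actual perimeter (1 for a circle, < 1 for
  elliptic or irregular lumens),
* ``Dh   = 4 Ac / Pe``       — hydraulic diameter,

with the algebraic identity ``Dh = Cr * Dave``. ``Cr`` indexes lumen shape
(ellipticity), ``Dh`` combines shape with narrowing; both are reduced in
severe asthma, and together with the Stokes number they organise where
inhaled particles deposit.

All quantities are SI internally (m, m²). File I/O uses mm / mm² for
readability; see ``docs/file_formats.md``.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "LOBES",
    "CrossSection",
    "Branch",
    "AirwayTree",
    "BifurcationGeometry",
    "InvalidSectionError",
    "TreeValidationError",
    "TopologyError",
    "TreeParseError",
    "compute_dave",
    "compute_cr",
    "compute_dh",
    "dave_from_area",
    "ellipse_perimeter",
    "ellipse_axes_from_section",
    "bifurcation_angle",
    "section_at",
    "read_tree",
    "write_tree",
]

#: Recognised lobe labels. ``none`` marks central (pre-lobar) branches.
LOBES = ("RUL", "RML", "RLL", "LUL", "LLL")
UPPER_LOBES = ("RUL", "LUL")
LOWER_AND_MIDDLE_LOBES = ("RML", "RLL", "LLL")


class InvalidSectionError(ValueError):
    """A cross-section violates its geometric invariants."""


class TreeValidationError(ValueError):
    """An airway tree violates its structural invariants."""


class TopologyError(ValueError):
    """An operation was applied to an unsupported local topology."""


class TreeParseError(ValueError):
    """A tree file does not conform to the documented schema."""


# Relative slack on the isoperimetric inequality Pe >= 2 sqrt(pi Ac); admits
# float round-off from perimeter formulas without admitting Cr > 1 materially.
_ISOPERIMETRIC_RTOL = 1e-9


@dataclass(frozen=True)
class CrossSection:
    """Lumen area and perimeter at one station along a branch.

    Parameters
    ----------
    area : float
        Lumen cross-sectional area ``Ac`` (m²).
    perimeter : float
        Lumen perimeter ``Pe`` (m).
    station : float
        Arc-length fraction along the branch in [0, 1].
    semi_major, semi_minor : float, optional
        Ellipse semi-axes (m) when the section is an analytic ellipse.
        Purely informative for morphometry; the flow model uses them to
        orient the lumen, and recovers them from (area, perimeter) if absent.
    """

    area: float
    perimeter: float
    station: float = 0.0
    semi_major: Optional[float] = None
    semi_minor: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.area > 0.0) or not math.isfinite(self.area):
            raise InvalidSectionError(f"area must be positive, got {self.area!r}")
        min_perimeter = 2.0 * math.sqrt(math.pi * self.area)
        if self.perimeter < min_perimeter * (1.0 - _ISOPERIMETRIC_RTOL):
            raise InvalidSectionError(
                f"perimeter {self.perimeter!r} below isoperimetric minimum "
                f"{min_perimeter!r} for area {self.area!r}"
            )
        if not (0.0 <= self.station <= 1.0):
            raise InvalidSectionError(f"station must lie in [0,1], got {self.station!r}")
        if (self.semi_major is None) != (self.semi_minor is None):
            raise InvalidSectionError("ellipse axes must be given together or not at all")
        if self.semi_major is not None and self.semi_minor is not None:
            if not (self.semi_major >= self.semi_minor > 0.0):
                raise InvalidSectionError("require semi_major >= semi_minor > 0")


def compute_dave(cs: CrossSection) -> float:
    """Area-equivalent diameter ``sqrt(4 Ac / pi)`` in metres."""
    return dave_from_area(cs.area)


def dave_from_area(area: float) -> float:
    if not area > 0.0:
        raise InvalidSectionError(f"area must be positive, got {area!r}")
    return math.sqrt(4.0 * area / math.pi)


def compute_cr(cs: CrossSection) -> float:
    """Circularity ``pi Dave / Pe`` in (0, 1]; 1 iff the section is a circle."""
    cr = math.pi * compute_dave(cs) / cs.perimeter
    # isoperimetric slack can push a circle's Cr a hair above 1
    return min(cr, 1.0)


def compute_dh(cs: CrossSection) -> float:
    """Hydraulic diameter ``4 Ac / Pe`` in metres; satisfies Dh = Cr * Dave."""
    return 4.0 * cs.area / cs.perimeter


def ellipse_perimeter(a: float, b: float) -> float:
    """Perimeter of an ellipse with semi-axes a, b (Ramanujan II approximation).

    Relative error < 1e-9 for aspect ratios up to ~5, far below airway
    measurement precision.
    """
    if not (a > 0.0 and b > 0.0):
        raise InvalidSectionError("ellipse semi-axes must be positive")
    h = ((a - b) / (a + b)) ** 2
    return math.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + math.sqrt(4.0 - 3.0 * h)))


#: Aspect-ratio cap for ellipse inversion (and generation).
MAX_ASPECT_RATIO = 5.0


def ellipse_axes_from_section(cs: CrossSection) -> Tuple[float, float]:
    """Recover ellipse semi-axes (a, b), a >= b, from (area, perimeter).

    If the section stores analytic axes they are returned directly; otherwise
    the aspect ratio is found by monotone root-finding on the Ramanujan-II
    perimeter at fixed area.
    """
    if cs.semi_major is not None and cs.semi_minor is not None:
        return cs.semi_major, cs.semi_minor
    ab = cs.area / math.pi  # a*b
    target = cs.perimeter

    def f(r: float) -> float:
        a = math.sqrt(ab * r)
        b = math.sqrt(ab / r)
        return ellipse_perimeter(a, b) - target

    if f(1.0) >= 0.0:  # at or below circle perimeter -> circle
        r0 = math.sqrt(ab)
        return r0, r0
    if f(MAX_ASPECT_RATIO) < 0.0:
        raise InvalidSectionError(
            "perimeter exceeds that of the maximum-aspect ellipse; "
            "section is not representable as an ellipse with aspect <= "
            f"{MAX_ASPECT_RATIO}"
        )
    r = brentq(f, 1.0, MAX_ASPECT_RATIO, xtol=1e-14, rtol=1e-15)
    return math.sqrt(ab * r), math.sqrt(ab / r)


@dataclass(frozen=True)
class Branch:
    """One straight airway branch.

    ``origin`` is the proximal end point; the branch occupies
    ``origin + s * direction`` for s in [0, length]. Terminal branches (no
    children) must carry a lobe label; central branches use ``"none"``.
    """

    id: str
    parent_id: Optional[str]
    length: float
    origin: np.ndarray
    direction: np.ndarray
    cross_sections: Tuple[CrossSection, ...]
    name: str = ""
    lobe: str = "none"
    generation: int = 0

    def __post_init__(self) -> None:
        if not self.id:
            raise TreeValidationError("branch id must be a non-empty token")
        if not (self.length > 0.0):
            raise TreeValidationError(f"branch {self.id}: length must be > 0")
        d = np.asarray(self.direction, dtype=float)
        o = np.asarray(self.origin, dtype=float)
        if d.shape != (3,) or o.shape != (3,):
            raise TreeValidationError(f"branch {self.id}: origin/direction must be 3-vectors")
        if abs(float(np.linalg.norm(d)) - 1.0) > 1e-8:
            raise TreeValidationError(f"branch {self.id}: direction must be a unit vector")
        object.__setattr__(self, "direction", d)
        object.__setattr__(self, "origin", o)
        if len(self.cross_sections) < 2:
            raise TreeValidationError(
                f"branch {self.id}: need >= 2 cross-sections (proximal, distal)"
            )
        stations = [cs.station for cs in self.cross_sections]
        if stations != sorted(stations):
            raise TreeValidationError(f"branch {self.id}: cross-sections must be station-ordered")
        if self.lobe not in LOBES + ("none",):
            raise TreeValidationError(f"branch {self.id}: unknown lobe label {self.lobe!r}")
        if self.generation < 0:
            raise TreeValidationError(f"branch {self.id}: generation must be >= 0")

    @property
    def proximal(self) -> CrossSection:
        return self.cross_sections[0]

    @property
    def distal(self) -> CrossSection:
        return self.cross_sections[-1]

    @property
    def distal_point(self) -> np.ndarray:
        return self.origin + self.length * self.direction


def section_at(branch: Branch, station: float) -> CrossSection:
    """Cross-section at an arbitrary arc-length fraction.

    Area and perimeter are linearly interpolated between the stored stations
    (the simplest monotone within-branch profile).
    """
    if not (0.0 <= station <= 1.0):
        raise InvalidSectionError(f"station must lie in [0,1], got {station!r}")
    stations = np.array([cs.station for cs in branch.cross_sections])
    areas = np.array([cs.area for cs in branch.cross_sections])
    perims = np.array([cs.perimeter for cs in branch.cross_sections])
    area = float(np.interp(station, stations, areas))
    perim = float(np.interp(station, stations, perims))
    return CrossSection(area=area, perimeter=perim, station=station)


@dataclass(frozen=True)
class BifurcationGeometry:
    """Angle between the two daughter axes of a bifurcation, in degrees."""

    parent_id: str
    angle_deg: float

    def __post_init__(self) -> None:
        if not (0.0 < self.angle_deg < 180.0):
            raise TopologyError(
                f"bifurcation angle must lie in (0, 180) deg, got {self.angle_deg!r}"
            )


class AirwayTree:
    """Rooted, connected, acyclic collection of branches.

    Internal branches may have 1–3 children (trifurcations allowed); every
    terminal branch must carry a lobe label.
    """

    def __init__(self, branches: Iterable[Branch], validate: bool = True):
        self.branches: Dict[str, Branch] = {}
        for b in branches:
            if b.id in self.branches:
                raise TreeValidationError(f"duplicate branch id {b.id!r}")
            self.branches[b.id] = b
        roots = [b.id for b in self.branches.values() if b.parent_id is None]
        if len(roots) != 1:
            raise TreeValidationError(f"tree must have exactly one root, found {len(roots)}")
        self.root_id: str = roots[0]
        self._children: Dict[str, List[str]] = {bid: [] for bid in self.branches}
        for b in self.branches.values():
            if b.parent_id is None:
                continue
            if b.parent_id not in self.branches:
                raise TreeValidationError(
                    f"branch {b.id}: parent_id {b.parent_id!r} does not resolve"
                )
            self._children[b.parent_id].append(b.id)
        if validate:
            self.validate()

    # -- structure ---------------------------------------------------------

    def children(self, branch_id: str) -> List[str]:
        return list(self._children[branch_id])

    def is_terminal(self, branch_id: str) -> bool:
        return not self._children[branch_id]

    def terminals(self) -> List[str]:
        return [bid for bid in self.branches if self.is_terminal(bid)]

    def lobe_terminals(self) -> Dict[str, List[str]]:
        out: Dict[str, List[str]] = {lobe: [] for lobe in LOBES}
        for bid in self.terminals():
            lobe = self.branches[bid].lobe
            if lobe in out:
                out[lobe].append(bid)
        return out

    def topological_order(self) -> List[str]:
        """Root-first order; every parent precedes its children."""
        order: List[str] = []
        stack = [self.root_id]
        while stack:
            bid = stack.pop()
            order.append(bid)
            stack.extend(reversed(self._children[bid]))
        return order

    def descendants(self, branch_id: str) -> List[str]:
        out: List[str] = []
        stack = list(self._children[branch_id])
        while stack:
            bid = stack.pop()
            out.append(bid)
            stack.extend(self._children[bid])
        return out

    def find_by_name(self, name: str) -> str:
        for bid, b in self.branches.items():
            if b.name == name:
                return bid
        raise KeyError(f"no branch named {name!r}")

    def validate(self) -> None:
        order = self.topological_order()
        if len(order) != len(self.branches):
            raise TreeValidationError("tree is disconnected or contains a cycle")
        for bid in self.branches:
            nchild = len(self._children[bid])
            if nchild > 3:
                raise TreeValidationError(f"branch {bid}: {nchild} children (max 3)")
            if nchild == 0 and self.branches[bid].lobe == "none":
                raise TreeValidationError(f"terminal branch {bid} lacks a lobe label")

    def __len__(self) -> int:
        return len(self.branches)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AirwayTree):
            return NotImplemented
        if set(self.branches) != set(other.branches):
            return False
        for bid, b in self.branches.items():
            o = other.branches[bid]
            if (
                b.parent_id != o.parent_id
                or b.name != o.name
                or b.lobe != o.lobe
                or b.generation != o.generation
                or b.length != o.length
                or not np.array_equal(b.origin, o.origin)
                or not np.array_equal(b.direction, o.direction)
                or b.cross_sections != o.cross_sections
            ):
                return False
        return True


def bifurcation_angle(tree: AirwayTree, parent_id: str) -> BifurcationGeometry:
    """Angle between the two daughter axes of ``parent_id``, in degrees."""
    kids = tree.children(parent_id)
    if len(kids) != 2:
        raise TopologyError(
            f"bifurcation angle requires exactly 2 children, branch {parent_id} has {len(kids)}"
        )
    d1 = tree.branches[kids[0]].direction
    d2 = tree.branches[kids[1]].direction
    cosang = float(np.clip(np.dot(d1, d2), -1.0, 1.0))
    angle = math.degrees(math.acos(cosang))
    return BifurcationGeometry(parent_id=parent_id, angle_deg=angle)


# -- file I/O --------------------------------------------------------------

CSV_HEADER = [
    "id", "name", "parent_id", "lobe", "generation", "length_mm",
    "x", "y", "z", "dx", "dy", "dz",
    "Ac_prox_mm2", "Pe_prox_mm", "Ac_dist_mm2", "Pe_dist_mm",
]


def write_tree(tree: AirwayTree, path) -> None:
    """Write a tree to CSV (mm units, two stations) or JSON (SI, lossless).

    The format is chosen by suffix. The JSON form round-trips field-for-field
    (full float precision, all stations, ellipse axes); the CSV form is the
    human-readable mm table documented in ``docs/file_formats.md``.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        _write_csv(tree, path)
    elif path.suffix.lower() == ".json":
        _write_json(tree, path)
    else:
        raise ValueError(f"unsupported tree file suffix {path.suffix!r}")


def read_tree(path) -> AirwayTree:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return _read_csv(path)
    if path.suffix.lower() == ".json":
        return _read_json(path)
    raise ValueError(f"unsupported tree file suffix {path.suffix!r}")


def _write_csv(tree: AirwayTree, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(CSV_HEADER)
        for bid in tree.topological_order():
            b = tree.branches[bid]
            prox, dist = b.proximal, b.distal
            row = [
                b.id, b.name, b.parent_id or "", b.lobe, b.generation,
                repr(float(b.length * 1e3)),
                *[repr(float(v) * 1e3) for v in b.origin],
                *[repr(float(v)) for v in b.direction],
                repr(float(prox.area * 1e6)), repr(float(prox.perimeter * 1e3)),
                repr(float(dist.area * 1e6)), repr(float(dist.perimeter * 1e3)),
            ]
            w.writerow(row)


def _read_csv(path: Path) -> AirwayTree:
    branches: List[Branch] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != CSV_HEADER:
            raise TreeParseError(
                f"{path}: header mismatch; expected {CSV_HEADER}, got {reader.fieldnames}"
            )
        for i, row in enumerate(reader, start=2):
            try:
                sections = (
                    CrossSection(
                        area=float(row["Ac_prox_mm2"]) * 1e-6,
                        perimeter=float(row["Pe_prox_mm"]) * 1e-3,
                        station=0.0,
                    ),
                    CrossSection(
                        area=float(row["Ac_dist_mm2"]) * 1e-6,
                        perimeter=float(row["Pe_dist_mm"]) * 1e-3,
                        station=1.0,
                    ),
                )
                branches.append(
                    Branch(
                        id=row["id"],
                        name=row["name"],
                        parent_id=row["parent_id"] or None,
                        lobe=row["lobe"],
                        generation=int(row["generation"]),
                        length=float(row["length_mm"]) * 1e-3,
                        origin=np.array([float(row[k]) for k in ("x", "y", "z")]) * 1e-3,
                        direction=np.array([float(row[k]) for k in ("dx", "dy", "dz")]),
                        cross_sections=sections,
                    )
                )
            except (KeyError, ValueError, TypeError) as exc:
                if isinstance(exc, TreeValidationError):
                    raise
                raise TreeParseError(f"{path}: row {i}: {exc}") from exc
    try:
        return AirwayTree(branches)
    except TreeValidationError as exc:
        raise TreeParseError(f"{path}: {exc}") from exc


def _section_to_json(cs: CrossSection) -> dict:
    d = {"area_m2": cs.area, "perimeter_m": cs.perimeter, "station": cs.station}
    if cs.semi_major is not None:
        d["semi_major_m"] = cs.semi_major
        d["semi_minor_m"] = cs.semi_minor
    return d


def _section_from_json(d: Mapping) -> CrossSection:
    return CrossSection(
        area=d["area_m2"],
        perimeter=d["perimeter_m"],
        station=d.get("station", 0.0),
        semi_major=d.get("semi_major_m"),
        semi_minor=d.get("semi_minor_m"),
    )


def _write_json(tree: AirwayTree, path: Path) -> None:
    payload = {
        "format": "aerotree-tree",
        "version": 1,
        "root_id": tree.root_id,
        "branches": [
            {
                "id": b.id,
                "name": b.name,
                "parent_id": b.parent_id,
                "lobe": b.lobe,
                "generation": b.generation,
                "length_m": b.length,
                "origin_m": list(b.origin),
                "direction": list(b.direction),
                "cross_sections": [_section_to_json(cs) for cs in b.cross_sections],
            }
            for bid in tree.topological_order()
            for b in (tree.branches[bid],)
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def _read_json(path: Path) -> AirwayTree:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "aerotree-tree":
        raise TreeParseError(f"{path}: not an aerotree tree file")
    branches = []
    for i, d in enumerate(payload["branches"]):
        try:
            branches.append(
                Branch(
                    id=d["id"],
                    name=d.get("name", ""),
                    parent_id=d.get("parent_id"),
                    lobe=d.get("lobe", "none"),
                    generation=d.get("generation", 0),
                    length=d["length_m"],
                    origin=np.array(d["origin_m"], dtype=float),
                    direction=np.array(d["direction"], dtype=float),
                    cross_sections=tuple(_section_from_json(s) for s in d["cross_sections"]),
                )
            )
        except (KeyError, ValueError, TypeError) as exc:
            if isinstance(exc, TreeValidationError):
                raise
            raise TreeParseError(f"{path}: branch entry {i}: {exc}") from exc
    try:
        return AirwayTree(branches)
    except TreeValidationError as exc:
        raise TreeParseError(f"{path}: {exc}") from exc
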