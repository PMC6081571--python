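"""Cross-section morphometry, tree validation and tree I/O."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import ellipe

from aerotree.airway_model import (
    AirwayTree,
    Branch,
    CrossSection,
    InvalidSectionError,
    TopologyError,
    TreeParseError,
    TreeValidationError,
    bifurcation_angle,
    compute_cr,
    compute_dave,
    compute_dh,
    ellipse_axes_from_section,
    ellipse_perimeter,
    read_tree,
    section_at,
    write_tree,
)
from aerotree.synthetic_data import PHENOTYPES, elliptic_section_from, generate_tree


def circle_section(radius: float) -> CrossSection:
    return CrossSection(
        area=math.pi * radius**2, perimeter=2.0 * math.pi * radius
    )


def exact_ellipse_perimeter(a: float, b: float) -> float:
    # complete elliptic integral of the second kind: independent oracle
    e2 = 1.0 - (b / a) ** 2
    return 4.0 * a * float(ellipe(e2))


class TestAreaEquivalentDiameter:
    @pytest.mark.parametrize(
        "area, expected_m, tol_m",
        [
            (math.pi / 4.0, 1.0, 1e-12),          # unit circle identity
            (1.2272e-4, 12.5e-3, 0.05e-3),        # main-bronchus calibre
            (2.9225e-5, 6.1e-3, 0.05e-3),         # upper-lobe trifurcation calibre
        ],
    )
    def test_dave_examples(self, area, expected_m, tol_m):
        cs = CrossSection(area=area, perimeter=2.0 * math.sqrt(math.pi * area))
        assert compute_dave(cs) == pytest.approx(expected_m, abs=tol_m)

    def test_rejects_nonpositive_area(self):
        with pytest.raises(InvalidSectionError):
            CrossSection(area=0.0, perimeter=1.0)
        with pytest.raises(InvalidSectionError):
            CrossSection(area=-1e-4, perimeter=1.0)


class TestCircularity:
    def test_circle_is_one(self):
        for r in (1e-3, 5e-3, 9e-3):
            assert compute_cr(circle_section(r)) == pytest.approx(1.0, abs=1e-12)

    def test_two_to_one_ellipse_matches_elliptic_integral(self):
        # independent oracle: exact perimeter via scipy's elliptic integral
        a, b = 2e-3, 1e-3
        cs = CrossSection(area=math.pi * a * b, perimeter=exact_ellipse_perimeter(a, b))
        dave = 2.0 * math.sqrt(a * b)
        expected = math.pi * dave / exact_ellipse_perimeter(a, b)
        assert compute_cr(cs) == pytest.approx(expected, rel=1e-12)
        assert compute_cr(cs) == pytest.approx(0.917, abs=2e-3)

    def test_printed_table_row_consistency(self):
        # Dave 12.5 mm with perimeter chosen so Dh = 11.6 mm gives Cr ~ 0.927
        dave = 12.5e-3
        area = math.pi * dave**2 / 4.0
        pe = 4.0 * area / 11.6e-3
        cs = CrossSection(area=area, perimeter=pe)
        assert compute_cr(cs) == pytest.approx(0.927, abs=0.005)

    def test_perimeter_below_isoperimetric_rejected(self):
        with pytest.raises(InvalidSectionError):
            CrossSection(area=math.pi, perimeter=2.0 * math.pi * 0.99)


class TestHydraulicDiameter:
    def test_circle_dh_equals_dave(self):
        cs = circle_section(4e-3)
        assert compute_dh(cs) == pytest.approx(compute_dave(cs), rel=1e-12)

    @pytest.mark.parametrize(
        "cr, dave_mm, expected_dh_mm",
        [(0.820, 6.1, 5.0), (0.926, 15.9, 14.7)],
    )
    def test_printed_dh_values(self, cr, dave_mm, expected_dh_mm):
        cs = elliptic_section_from(cr, dave_mm * 1e-3)
        assert compute_dh(cs) * 1e3 == pytest.approx(expected_dh_mm, abs=0.05)


@settings(max_examples=200, deadline=None)
@given(
    dave=st.floats(min_value=1e-4, max_value=0.05),
    cr=st.floats(min_value=0.68, max_value=1.0),
    scale=st.floats(min_value=0.1, max_value=10.0),
)
def test_morphometry_identities(dave, cr, scale):
    """Dh = Cr * Dave to machine precision; Dh <= Dave <= Pe/pi; Cr scale-free."""
    cs = elliptic_section_from(cr, dave)
    d, c, h = compute_dave(cs), compute_cr(cs), compute_dh(cs)
    assert h == pytest.approx(c * d, rel=1e-12)
    assert h <= d * (1.0 + 1e-12)
    assert d <= cs.perimeter / math.pi * (1.0 + 1e-12)
    scaled = CrossSection(
        area=cs.area * scale**2, perimeter=cs.perimeter * scale
    )
    assert compute_cr(scaled) == pytest.approx(c, rel=1e-9)
    assert compute_dave(scaled) == pytest.approx(d * scale, rel=1e-12)
    assert compute_dh(scaled) == pytest.approx(h * scale, rel=1e-12)


def test_ellipse_axes_roundtrip():
    cs = elliptic_section_from(0.85, 8e-3)
    bare = CrossSection(area=cs.area, perimeter=cs.perimeter)
    a, b = ellipse_axes_from_section(bare)
    assert a == pytest.approx(cs.semi_major, rel=1e-6)
    assert b == pytest.approx(cs.semi_minor, rel=1e-6)
    assert ellipse_perimeter(a, b) == pytest.approx(cs.perimeter, rel=1e-9)


def _stub_branch(bid, parent, direction, lobe="none", generation=0):
    return Branch(
        id=bid,
        parent_id=parent,
        length=0.02,
        origin=np.zeros(3),
        direction=np.asarray(direction, dtype=float),
        cross_sections=(circle_section(3e-3), circle_section(3e-3)),
        lobe=lobe,
        generation=generation,
    )


class TestBifurcationAngle:
    def test_orthogonal_daughters(self):
        tree = AirwayTree(
            [
                _stub_branch("p", None, [0, 0, 1]),
                _stub_branch("a", "p", [1, 0, 0], lobe="RUL"),
                _stub_branch("b", "p", [0, 1, 0], lobe="RLL"),
            ]
        )
        assert bifurcation_angle(tree, "p").angle_deg == pytest.approx(90.0)

    def test_antiparallel_daughters_rejected(self):
        tree = AirwayTree(
            [
                _stub_branch("p", None, [0, 0, 1]),
                _stub_branch("a", "p", [1, 0, 0], lobe="RUL"),
                _stub_branch("b", "p", [-1, 0, 0], lobe="RLL"),
            ]
        )
        with pytest.raises(TopologyError):
            bifurcation_angle(tree, "p")

    def test_wrong_child_count_rejected(self):
        tree = AirwayTree(
            [
                _stub_branch("p", None, [0, 0, 1]),
                _stub_branch("a", "p", [1, 0, 0], lobe="RUL"),
            ]
        )
        with pytest.raises(TopologyError):
            bifurcation_angle(tree, "p")

    def test_generated_rmb_angle_recovered(self, healthy_tree):
        # the healthy generator default is a 90 deg main-bronchus bifurcation
        angle = bifurcation_angle(healthy_tree, "RMB").angle_deg
        assert angle == pytest.approx(90.0, abs=1e-9)


class TestTreeValidation:
    def test_two_roots_rejected(self):
        with pytest.raises(TreeValidationError):
            AirwayTree(
                [
                    _stub_branch("a", None, [0, 0, 1], lobe="RUL"),
                    _stub_branch("b", None, [0, 0, 1], lobe="RLL"),
                ]
            )

    def test_cycle_rejected(self):
        with pytest.raises(TreeValidationError):
            AirwayTree(
                [
                    _stub_branch("r", None, [0, 0, 1], lobe="RUL"),
                    _stub_branch("a", "b", [0, 0, 1], lobe="RUL"),
                    _stub_branch("b", "a", [0, 0, 1], lobe="RLL"),
                ]
            )

    def test_unlabeled_terminal_rejected(self):
        with pytest.raises(TreeValidationError):
            AirwayTree(
                [
                    _stub_branch("r", None, [0, 0, 1]),
                    _stub_branch("a", "r", [1, 0, 0], lobe="none"),
                ]
            )

    def test_orphan_parent_rejected(self):
        with pytest.raises(TreeValidationError):
            AirwayTree(
                [
                    _stub_branch("r", None, [0, 0, 1]),
                    _stub_branch("a", "ghost", [1, 0, 0], lobe="RUL"),
                ]
            )

    def test_too_many_children_rejected(self):
        kids = [
            _stub_branch(f"k{i}", "r", [1, 0, 0], lobe="RUL") for i in range(4)
        ]
        with pytest.raises(TreeValidationError):
            AirwayTree([_stub_branch("r", None, [0, 0, 1])] + kids)

    def test_non_unit_direction_rejected(self):
        with pytest.raises(TreeValidationError):
            _stub_branch("r", None, [0, 0, 2])


class TestTreeIO:
    def test_json_roundtrip_exact(self, healthy_tree, tmp_path):
        path = tmp_path / "tree.json"
        write_tree(healthy_tree, path)
        assert read_tree(path) == healthy_tree

    def test_csv_roundtrip_to_machine_precision(self, healthy_tree, tmp_path):
        # the mm-format CSV preserves values to double precision; exact
        # field-for-field round-trips are the JSON format's contract
        p1 = tmp_path / "tree.csv"
        write_tree(healthy_tree, p1)
        back = read_tree(p1)
        for bid, b in healthy_tree.branches.items():
            o = back.branches[bid]
            assert o.length == pytest.approx(b.length, rel=1e-15)
            assert o.proximal.area == pytest.approx(b.proximal.area, rel=1e-15)
            np.testing.assert_allclose(o.origin, b.origin, rtol=1e-15, atol=1e-18)
            assert (o.name, o.parent_id, o.lobe, o.generation) == (
                b.name, b.parent_id, b.lobe, b.generation
            )

    def test_orphan_parent_is_parse_error(self, healthy_tree, tmp_path):
        path = tmp_path / "tree.csv"
        write_tree(healthy_tree, path)
        text = path.read_text().replace(",RMB,RUL,", ",Ghost,RUL,")
        assert ",Ghost,RUL," in text
        bad = tmp_path / "bad.csv"
        bad.write_text(text)
        with pytest.raises(TreeParseError):
            read_tree(bad)

    def test_phenotype_set_loads_with_31_named_segments(self, tmp_path):
        for name, spec in PHENOTYPES.items():
            path = tmp_path / f"{name}.json"
            write_tree(generate_tree(spec), path)
            tree = read_tree(path)
            named = [
                b for b in tree.branches.values()
                if b.generation >= 2 and b.name
            ]
            assert len(named) >= 31
            for key in ("Trachea", "RMB", "LMB", "TriRUL", "BronInt",
                        "RB6", "RB9+10", "LB10"):
                assert tree.find_by_name(key)


def test_section_interpolation_midpoint(healthy_tree):
    b = healthy_tree.branches["Trachea"]
    mid = section_at(b, 0.5)
    assert mid.area == pytest.approx(
        0.5 * (b.proximal.area + b.distal.area), rel=1e-12
    )
    with pytest.raises(InvalidSectionError):
        section_at(b, 1.5)
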