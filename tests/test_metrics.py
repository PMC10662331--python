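import numpy as np
import pytest

from territoria.errors import (
    DataError,
    SchemeMismatchError,
    UndefinedAngleError,
    UserError,
)
from territoria.io import ChannelImage
from territoria.metrics import (
    AxialMeasurement,
    area_occupancy,
    axial_angle,
    classify_cell,
    density_ratio,
    inter_territory_angle,
    inter_territory_distance,
)
from territoria.morphometry import NuclearShape, nucleus_morphometry
from territoria.segment import NuclearMask, TerritoryMask
from territoria.synth import NucleusSpec, generate_nucleus


def _nucleus(shape=(100, 100), rows=slice(20, 70), cols=slice(20, 60)):
    pix = np.zeros(shape, dtype=bool)
    pix[rows, cols] = True
    return NuclearMask(label=1, pixels=pix, area_px=int(pix.sum()), touches_border=False)


def _territory(shape=(100, 100), rows=slice(30, 40), cols=slice(30, 40), label=1):
    pix = np.zeros(shape, dtype=bool)
    pix[rows, cols] = True
    return TerritoryMask(label=label, pixels=pix, area_px=int(pix.sum()))


SHAPE_EAST = NuclearShape(
    centroid_xy=(50.0, 50.0),
    major_axis_um=10.0,
    minor_axis_um=5.0,
    area_um2=40.0,
    eccentricity=0.866,
    orientation_deg=0.0,
)


class TestAreaOccupancy:
    def test_simple_ratio(self):
        nuc = _nucleus(rows=slice(0, 40), cols=slice(0, 25))  # 1000 px
        terr = _territory(rows=slice(5, 10), cols=slice(5, 16))  # 55 px
        assert area_occupancy([terr], nuc) == pytest.approx(55 / 1000)

    def test_overlapping_territories_count_once(self):
        nuc = _nucleus()
        t1 = _territory(rows=slice(30, 40), cols=slice(30, 40))
        t2 = _territory(rows=slice(35, 45), cols=slice(30, 40), label=2)
        union = 10 * 10 + 5 * 10
        assert area_occupancy([t1, t2], nuc) == pytest.approx(union / nuc.area_px)

    def test_empty_and_full(self):
        nuc = _nucleus()
        assert area_occupancy([], nuc) == 0.0
        full = TerritoryMask(label=1, pixels=nuc.pixels, area_px=nuc.area_px)
        assert area_occupancy([full], nuc) == 1.0


class TestDensityRatio:
    def test_uniform_dapi_is_one(self):
        img = ChannelImage(np.full((100, 100), 70.0), 0.13)
        assert density_ratio(img, _territory(), _nucleus()).r_fragment == 1.0

    def test_bright_territory_doubles_ratio(self):
        pixels = np.full((100, 100), 100.0)
        terr = _territory()
        pixels[terr.pixels] = 200.0
        img = ChannelImage(pixels, 0.13)
        assert density_ratio(img, terr, _nucleus()).r_fragment == pytest.approx(2.0)

    def test_scale_invariance(self, rng):
        pixels = rng.random((100, 100)) * 50 + 1
        img_a = ChannelImage(pixels, 0.13)
        img_b = ChannelImage(pixels * 3.7, 0.13)
        nuc, terr = _nucleus(), _territory()
        assert density_ratio(img_a, terr, nuc).r_fragment == pytest.approx(
            density_ratio(img_b, terr, nuc).r_fragment, abs=1e-12
        )

    def test_zero_nuclear_median_errors(self):
        img = ChannelImage(np.zeros((100, 100)), 0.13)
        with pytest.raises(DataError):
            density_ratio(img, _territory(), _nucleus())


class TestAxialAngle:
    @pytest.mark.parametrize(
        "centroid,theta,cls",
        [
            ((70.0, 50.0), 0.0, "major_parallel"),  # displaced along major axis
            ((50.0, 30.0), 90.0, "minor_parallel"),  # displaced along minor axis
            ((30.0, 50.0), 180.0 % 180, "major_parallel"),  # opposite end folds to 0
        ],
    )
    def test_cardinal_directions(self, centroid, theta, cls):
        m = axial_angle(centroid, SHAPE_EAST)
        assert m.theta_deg == pytest.approx(theta, abs=1e-9)
        assert m.axial_class == cls

    def test_boundary_angles_classify_major(self):
        for theta in (45.0, 135.0):
            rad = np.radians(theta)
            centroid = (50 + 10 * np.cos(rad), 50 - 10 * np.sin(rad))
            m = axial_angle(centroid, SHAPE_EAST)
            assert m.theta_deg == pytest.approx(theta, abs=1e-9)
            assert m.axial_class == "major_parallel"

    def test_coincident_centroids_flagged(self):
        with pytest.raises(UndefinedAngleError):
            axial_angle((50.0, 50.0), SHAPE_EAST)

    def test_invariant_under_scene_rotation(self):
        mask, _ = generate_nucleus(NucleusSpec(orientation_deg=30.0), (160, 160))
        shape = nucleus_morphometry(mask, 0.13)
        offset = (
            shape.centroid_xy[0] + 20 * np.cos(np.radians(95.0)),
            shape.centroid_xy[1] - 20 * np.sin(np.radians(95.0)),
        )
        theta = axial_angle(offset, shape).theta_deg
        rot_mask = np.rot90(mask)
        rot_shape = nucleus_morphometry(rot_mask, 0.13)
        rot_offset = (
            rot_shape.centroid_xy[0] + 20 * np.cos(np.radians(185.0)),
            rot_shape.centroid_xy[1] - 20 * np.sin(np.radians(185.0)),
        )
        rot_theta = axial_angle(rot_offset, rot_shape).theta_deg
        assert min(abs(rot_theta - theta), 180 - abs(rot_theta - theta)) < 0.5


def _m(cls):
    return AxialMeasurement(theta_deg=10.0 if cls == "major_parallel" else 90.0, axial_class=cls)


class TestClassifyCell:
    def test_normal_scheme(self):
        both = classify_cell([_m("minor_parallel"), _m("minor_parallel")], "normal")
        assert both.label == "both_minor"
        mixed = classify_cell([_m("major_parallel"), _m("minor_parallel")], "normal")
        assert mixed.label == "one_plus_major"

    def test_tumor_scheme_threshold(self):
        two_of_four = [_m("major_parallel")] * 2 + [_m("minor_parallel")] * 2
        assert classify_cell(two_of_four, "tumor").label == "ge50_major"
        one_of_three = [_m("major_parallel")] + [_m("minor_parallel")] * 2
        assert classify_cell(one_of_three, "tumor").label == "lt50_major"

    def test_normal_scheme_requires_two(self):
        with pytest.raises(SchemeMismatchError):
            classify_cell([_m("major_parallel")], "normal")

    def test_schemes_agree_on_two_territory_inputs(self):
        """both_minor <-> lt50_major except the exactly-one-major case."""
        for a in ("major_parallel", "minor_parallel"):
            for b in ("major_parallel", "minor_parallel"):
                normal = classify_cell([_m(a), _m(b)], "normal").label
                tumor = classify_cell([_m(a), _m(b)], "tumor").label
                n_major = (a == "major_parallel") + (b == "major_parallel")
                if n_major == 0:
                    assert (normal, tumor) == ("both_minor", "lt50_major")
                else:
                    assert normal == "one_plus_major"
                    assert tumor == "ge50_major"


class TestPairGeometry:
    def test_three_four_five_triangle(self):
        assert inter_territory_distance((0, 0), (3, 4), 1.0) == pytest.approx(5.0)
        assert inter_territory_distance((0, 0), (3, 4), 0.5) == pytest.approx(2.5)
        assert inter_territory_distance((2, 2), (2, 2), 1.0) == 0.0

    @pytest.mark.parametrize(
        "c1,c2,expected",
        [((10, 0), (-10, 0), 180.0), ((10, 0), (5, 0), 0.0), ((10, 0), (0, 7), 90.0)],
    )
    def test_angle_at_nuclear_centroid(self, c1, c2, expected):
        assert inter_territory_angle(c1, c2, (0, 0)) == pytest.approx(expected)

    def test_degenerate_vertex_flagged(self):
        with pytest.raises(UndefinedAngleError):
            inter_territory_angle((0, 0), (1, 1), (0, 0))

    def test_bad_pixel_size(self):
        with pytest.raises(UserError):
            inter_territory_distance((0, 0), (1, 1), 0.0)
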