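import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kneeload.knee_model import (
    AssemblyError,
    ConstraintSystem,
    DEFAULT_PCSA_CM2,
    Formulation,
    GeometryError,
    LineOfAction,
    MuscleProperties,
    ResultantLoad,
    StructureSet,
    assemble_equipollence,
    moment_contribution,
    validate_frame_geometry,
)
from oracles import cross_product_reference, summed_force_and_moment


@pytest.fixture()
def props():
    return MuscleProperties(dict(DEFAULT_PCSA_CM2))


class TestLineOfAction:
    def test_rejects_non_unit_direction(self):
        with pytest.raises(GeometryError):
            LineOfAction(direction=[0, 2, 0], lever_arm=[0, 0, 0])

    def test_rejects_oversized_lever_arm(self):
        with pytest.raises(GeometryError):
            LineOfAction(direction=[0, 1, 0], lever_arm=[1.0, 0, 0])

    def test_rejects_non_finite(self):
        with pytest.raises(GeometryError):
            LineOfAction(direction=[0, 1, 0], lever_arm=[np.nan, 0, 0])


class TestMomentContribution:
    @pytest.mark.parametrize("d, l, expected", [
        ([0.05, 0, 0], [0, 1, 0], [0, 0, 0.05]),
        ([0, 0, 0], [0, 1, 0], [0, 0, 0]),
        ([0, 0, 0], [1, 0, 0], [0, 0, 0]),
    ])
    def test_known_cross_products(self, d, l, expected):
        geom = LineOfAction(direction=l, lever_arm=d)
        np.testing.assert_allclose(moment_contribution(geom), expected,
                                   atol=1e-15)

    def test_matches_independent_cross_product(self):
        d = np.array([0.03, -0.02, 0.01])
        l = np.array([0.1, 0.9899495, 0.1])
        l = l / np.linalg.norm(l)
        geom = LineOfAction(direction=l, lever_arm=d)
        np.testing.assert_allclose(moment_contribution(geom),
                                   cross_product_reference(d, l), atol=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-0.2, 0.2), min_size=3, max_size=3),
           st.lists(st.floats(-1, 1), min_size=3, max_size=3))
    def test_agrees_with_reference_for_arbitrary_geometry(self, d, l):
        l = np.asarray(l)
        if np.linalg.norm(l) < 1e-3:
            return
        l = l / np.linalg.norm(l)
        geom = LineOfAction(direction=l, lever_arm=d)
        np.testing.assert_allclose(moment_contribution(geom),
                                   cross_product_reference(np.asarray(d), l),
                                   atol=1e-12)


def _full_geometry():
    """A hand-built valid frame covering every structure."""
    rng = np.random.default_rng(3)
    geom = {}
    for name in StructureSet().all_names:
        l = rng.normal(size=3)
        l /= np.linalg.norm(l)
        d = rng.uniform(-0.04, 0.04, size=3)
        geom[name] = LineOfAction(direction=l, lever_arm=d)
    return geom


class TestAssembleEquipollence:
    load = ResultantLoad(force_R=[10.0, -400.0, 5.0], moment_M=[1.0, 0.2, 20.0])

    @pytest.mark.parametrize("tag, shape", [
        ("RM", (3, 14)), ("RML", (3, 18)), ("RFML", (6, 18)),
    ])
    def test_matrix_shapes(self, props, tag, shape):
        sys_ = assemble_equipollence(_full_geometry(), self.load,
                                     Formulation(tag), props)
        assert sys_.matrix_A.shape == shape
        assert sys_.rhs_b.shape == (shape[0],)

    def test_rfml_rhs_stacks_force_over_moment(self, props):
        sys_ = assemble_equipollence(_full_geometry(), self.load,
                                     Formulation("RFML"), props)
        np.testing.assert_allclose(sys_.rhs_b[:3], self.load.force_R)
        np.testing.assert_allclose(sys_.rhs_b[3:], self.load.moment_M)

    def test_rfml_contains_rml_as_bottom_rows(self, props):
        geom = _full_geometry()
        rfml = assemble_equipollence(geom, self.load, Formulation("RFML"), props)
        rml = assemble_equipollence(geom, self.load, Formulation("RML"), props)
        np.testing.assert_allclose(rfml.matrix_A[3:], rml.matrix_A, atol=0)
        assert rfml.column_labels == rml.column_labels

    def test_column_order_is_muscles_ligaments_contacts(self, props):
        s = StructureSet()
        sys_ = assemble_equipollence(_full_geometry(), self.load,
                                     Formulation("RFML"), props)
        assert sys_.column_labels == s.muscles + s.ligaments + s.contacts
        rm = assemble_equipollence(_full_geometry(), self.load,
                                   Formulation("RM"), props)
        assert rm.column_labels == s.muscles + s.contacts

    def test_bounds(self, props):
        sys_ = assemble_equipollence(_full_geometry(), self.load,
                                     Formulation("RFML"), props,
                                     contact_upper_bound=12000.0)
        assert np.all(sys_.lower_bounds == 0.0)
        np.testing.assert_allclose(sys_.upper_bounds[:16], 5000.0)
        np.testing.assert_allclose(sys_.upper_bounds[16:], 12000.0)

    def test_single_structure_column_stacks_l_and_d_cross_l(self):
        geom = LineOfAction(direction=[0, 1, 0], lever_arm=[0.05, 0, 0])
        col = np.concatenate([geom.direction, moment_contribution(geom)])
        np.testing.assert_allclose(col, [0, 1, 0, 0, 0, 0.05])

    def test_missing_structure_raises(self, props):
        geom = _full_geometry()
        del geom["LCL"]
        with pytest.raises(AssemblyError, match="LCL"):
            assemble_equipollence(geom, self.load, Formulation("RFML"), props)

    def test_rows_match_loop_oracle(self, props, rng=np.random.default_rng(11)):
        """A·x reproduces the looped force and moment sums to 1e-12."""
        geom = _full_geometry()
        sys_ = assemble_equipollence(geom, self.load, Formulation("RFML"), props)
        for _ in range(5):
            x = rng.uniform(0, 500, size=sys_.n_variables)
            items = [(geom[n].direction, geom[n].lever_arm)
                     for n in sys_.column_labels]
            F, M = summed_force_and_moment(items, x)
            np.testing.assert_allclose(sys_.force_rows @ x, F, atol=1e-12 * 500)
            np.testing.assert_allclose(sys_.moment_rows @ x, M, atol=1e-12 * 500)


class TestFormulation:
    def test_variable_and_constraint_counts(self):
        assert Formulation("RM").n_variables == 14
        assert Formulation("RM").n_constraints == 3
        assert Formulation("RML").n_variables == 18
        assert Formulation("RML").n_constraints == 3
        assert Formulation("RFML").n_variables == 18
        assert Formulation("RFML").n_constraints == 6

    def test_unknown_tag_rejected(self):
        with pytest.raises(ValueError):
            Formulation("RF")


class TestStructureSet:
    def test_counts_and_uniqueness(self):
        s = StructureSet()
        assert len(s.muscles) == 12
        assert len(s.ligaments) == 4
        assert len(s.contacts) == 2
        assert len(set(s.all_names)) == 18

    def test_wrong_counts_rejected(self):
        with pytest.raises(ValueError):
            StructureSet(muscles=("a", "b"))


class TestValidateFrameGeometry:
    def test_valid_frame_gives_empty_report(self):
        report = validate_frame_geometry(
            {"m": ([0, 1, 0], [0.05, 0, 0])})
        assert report == []

    def test_reports_unit_norm_violation(self):
        report = validate_frame_geometry({"m": ([0, 2, 0], [0, 0, 0])})
        assert len(report) == 1 and "m" in report[0]

    def test_reports_lever_arm_violation(self):
        report = validate_frame_geometry({"m": ([0, 1, 0], [1.0, 0, 0])})
        assert len(report) == 1 and "sanity" in report[0]


class TestMuscleProperties:
    def test_rejects_nonpositive_pcsa(self):
        with pytest.raises(ValueError):
            MuscleProperties({"rectus_femoris": -1.0})

    def test_pcsa_array_order_and_missing(self):
        props = MuscleProperties(dict(DEFAULT_PCSA_CM2))
        arr = props.pcsa_array()
        assert arr.shape == (12,)
        with pytest.raises(KeyError):
            MuscleProperties({"rectus_femoris": 1.0}).pcsa_array()
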