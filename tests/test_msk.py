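"""Passive musculoskeletal model: scaling, paths, Hill curve, statics."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from scipy.stats import spearmanr

from hiptension.msk import (
    G_ACCEL,
    JointState,
    MuscleParam,
    generic_model,
    hip_reaction,
    load_muscle_csv,
    muscle_path_length,
    passive_fiber_force,
    patient4_model,
    save_muscle_csv,
    scale_model,
    sweep_flexion,
)

# the antagonistic pairs whose stretch produces the U-shaped profile:
# hamstrings + gluteus maximus lengthen with flexion, the iliopsoas and
# rectus femoris lengthen with extension (adductors and abductors sit close
# to the flexion axis and are not monotone)
EXTENSORS = ["glut_max1", "glut_max2", "glut_max3", "semimem", "semiten",
             "bifem_lh"]
FLEXORS = ["iliacus", "psoas", "rect_fem"]


def two_point_muscle(origin, insertion, seg="femur", **kw):
    params = dict(f_iso_max=500.0, l_opt=0.10, l_ts=0.05)
    params.update(kw)
    return MuscleParam("probe", [("pelvis", np.array(origin)),
                                 (seg, np.array(insertion))], **params)


class TestScaling:
    def test_identity_scaling_changes_nothing(self):
        gen = generic_model()
        same = scale_model(gen, gen.height_cm, gen.mass_kg)
        for a, b in zip(gen.muscles, same.muscles):
            assert b.l_opt == pytest.approx(a.l_opt)
            assert b.l_ts == pytest.approx(a.l_ts)
        assert same.segments["femur"].mass_kg == \
            pytest.approx(gen.segments["femur"].mass_kg)

    def test_uniform_factor_scales_every_path_length(self):
        gen = generic_model()
        scaled = scale_model(gen, gen.height_cm * 1.1, gen.mass_kg)
        state = JointState(hip_flexion_deg=0.0)
        for a, b in zip(gen.muscles, scaled.muscles):
            la = muscle_path_length(a, state, gen)
            lb = muscle_path_length(b, state, scaled)
            assert lb == pytest.approx(1.1 * la, rel=1e-9)

    def test_patient4_masses_scale_with_mass_ratio(self):
        gen = generic_model()
        pat = scale_model(gen, 151.0, 58.0)
        ratio = 58.0 / gen.mass_kg
        for name in ("femur", "shank"):
            assert pat.segments[name].mass_kg == \
                pytest.approx(ratio * gen.segments[name].mass_kg)
        total_gen = sum(s.mass_kg for s in gen.segments.values())
        total_pat = sum(s.mass_kg for s in pat.segments.values())
        assert total_pat == pytest.approx(ratio * total_gen)

    def test_nonpositive_anthropometry_rejected(self):
        with pytest.raises(ValueError):
            scale_model(generic_model(), -150.0, 58.0)
        with pytest.raises(ValueError):
            scale_model(generic_model(), 150.0, 0.0)


class TestPathLength:
    def test_two_point_neutral_distance(self):
        m = two_point_muscle([0.0, 0.0, -0.05], [0.0, 0.0, 0.07])
        model = generic_model()
        assert muscle_path_length(m, JointState(0.0), model) == \
            pytest.approx(0.12)

    def test_flexion_rotates_femoral_insertion(self):
        """Length matches an explicit rigid-transform oracle."""
        model = generic_model()
        origin = np.array([0.02, -0.03, -0.06])
        insertion = np.array([-0.01, 0.02, 0.15])
        m = two_point_muscle(origin, insertion)
        for gamma in (15.0, 47.5, 90.0):
            rot = Rotation.from_euler("y", gamma, degrees=True).as_matrix()
            expected = np.linalg.norm(rot @ insertion - origin)
            got = muscle_path_length(m, JointState(gamma), model)
            assert got == pytest.approx(expected, abs=1e-12)

    def test_collinear_via_point_leaves_length_unchanged(self):
        model = generic_model()
        a, b = np.array([0.0, 0.0, -0.05]), np.array([0.0, 0.0, 0.07])
        straight = two_point_muscle(a, b)
        mid = ("pelvis", 0.25 * a + 0.75 * b)  # on the segment, pelvis-fixed
        bent = MuscleParam("probe_via",
                           [("pelvis", a), mid, ("femur", b)],
                           f_iso_max=500.0, l_opt=0.10, l_ts=0.05)
        s = JointState(0.0)
        assert muscle_path_length(bent, s, model) == \
            pytest.approx(muscle_path_length(straight, s, model), abs=1e-12)


class TestPassiveForce:
    def test_zero_at_optimal_length(self):
        m = two_point_muscle([0, 0, 0], [0, 0, 0.1], l_opt=0.10, l_ts=0.05)
        f, slack = passive_fiber_force(m, 0.15)  # l~ = 1 exactly
        assert f == 0.0 and slack

    def test_reaches_isometric_force_at_full_strain(self):
        m = two_point_muscle([0, 0, 0], [0, 0, 0.1], l_opt=0.10, l_ts=0.05)
        path = m.l_ts + (1 + m.eps0) * m.l_opt
        f, slack = passive_fiber_force(m, path)
        assert not slack
        assert f == pytest.approx(m.f_iso_max, rel=1e-12)

    def test_strictly_increasing_beyond_optimal(self):
        m = two_point_muscle([0, 0, 0], [0, 0, 0.1], l_opt=0.10, l_ts=0.05)
        paths = m.l_ts + m.l_opt * np.linspace(1.001, 1.6, 50)
        forces = [passive_fiber_force(m, p)[0] for p in paths]
        assert (np.diff(forces) > 0).all()

    def test_buckled_fiber_flagged_slack(self):
        m = two_point_muscle([0, 0, 0], [0, 0, 0.1], l_opt=0.10, l_ts=0.05)
        f, slack = passive_fiber_force(m, 0.03)  # shorter than the tendon
        assert f == 0.0 and slack

    def test_stiffness_scale_is_multiplicative(self):
        m = two_point_muscle([0, 0, 0], [0, 0, 0.1], l_opt=0.10, l_ts=0.05)
        path = m.l_ts + 1.3 * m.l_opt
        f1, _ = passive_fiber_force(m, path)
        f2, _ = passive_fiber_force(m, path, stiffness_scale=2.0)
        assert f2 == pytest.approx(2.0 * f1)


class TestStatics:
    def test_all_slack_no_gravity_gives_zero_reaction(self):
        model = generic_model()
        for m in model.muscles:
            m.l_ts = 10.0  # slack everywhere
        r, _ = hip_reaction(model, JointState(30.0, knee_flexion_deg=30.0),
                            gravity=False)
        np.testing.assert_allclose(r, 0.0, atol=1e-12)

    def test_single_muscle_closed_form(self):
        model = generic_model()
        origin = np.array([0.0, 0.0, -0.06])
        insertion = np.array([0.0, 0.0, 0.10])
        m = two_point_muscle(origin, insertion, l_opt=0.10, l_ts=0.02)
        model.muscles = [m]
        state = JointState(0.0)
        length = 0.16
        force, _ = passive_fiber_force(m, length)
        assert force > 0
        unit = (origin - insertion) / np.linalg.norm(origin - insertion)
        r, _ = hip_reaction(model, state, gravity=False)
        np.testing.assert_allclose(r, -force * unit, atol=1e-9)

    def test_gravity_only_reaction_equals_limb_weight(self):
        model = patient4_model()
        model.muscles = []
        limb_mass = sum(s.mass_kg for s in model.segments.values())
        for gamma in (0.0, 45.0, 90.0):
            r, _ = hip_reaction(model, JointState(gamma, knee_flexion_deg=gamma))
            assert np.linalg.norm(r) == pytest.approx(limb_mass * G_ACCEL)
            np.testing.assert_allclose(r / np.linalg.norm(r), [1, 0, 0],
                                       atol=1e-12)  # anterior support

    def test_equilibrium_residual_below_nano_newton(self):
        sweep = sweep_flexion(patient4_model())
        assert sweep.residual.max() < 1e-9

    def test_doubling_isometric_forces_doubles_muscle_reaction(self):
        base = patient4_model()
        sw1 = sweep_flexion(base, gravity=False)
        doubled = patient4_model()
        for m in doubled.muscles:
            m.f_iso_max *= 2.0
        sw2 = sweep_flexion(doubled, gravity=False)
        np.testing.assert_allclose(sw2.reaction, 2.0 * sw1.reaction, atol=1e-9)


class TestSweepPattern:
    @pytest.fixture(scope="class")
    @staticmethod
    def sweep():
        return sweep_flexion(patient4_model())

    def test_resultant_is_u_shaped_with_interior_minimum(self, sweep):
        res = sweep.resultant_N
        imin = int(np.argmin(res))
        assert 0 < imin < len(res) - 1
        assert res[0] > res[imin] < res[-1]
        assert 10.0 < sweep.gamma_deg[imin] < 50.0

    def test_extensors_stretch_with_flexion_flexors_with_extension(self):
        model = patient4_model()
        gammas = np.arange(0.0, 91.0, 5.0)
        lengths = {
            m.name: np.array([muscle_path_length(
                m, JointState(g, knee_flexion_deg=g), model) for g in gammas])
            for m in model.muscles
        }
        for name in EXTENSORS:
            assert (np.diff(lengths[name]) > 0).all(), name
        for name in FLEXORS:
            assert (np.diff(lengths[name]) < 0).all(), name

    def test_posterior_component_increases_with_flexion(self, sweep):
        p = np.array([r.posterior for r in sweep.reported])
        assert p[-1] > p[0]
        rho = spearmanr(sweep.gamma_deg, p).statistic
        assert rho > 0.95

    def test_superior_component_decreases_with_flexion(self, sweep):
        superior = -np.array([r.inferior for r in sweep.reported])
        assert superior[0] > 0  # extension loads the cup superiorly
        assert superior[-1] < 0.25 * superior[0]

    def test_knee_coupling_configurable(self):
        fixed_knee = sweep_flexion(patient4_model(), knee_coupling=0.0)
        coupled = sweep_flexion(patient4_model(), knee_coupling=1.0)
        assert not np.allclose(fixed_knee.resultant_N, coupled.resultant_N)


class TestFixtureFile:
    def test_shipped_csv_matches_programmatic_model(self):
        built = generic_model()
        loaded = load_muscle_csv()
        assert [m.name for m in loaded.muscles] == [m.name for m in built.muscles]
        for a, b in zip(built.muscles, loaded.muscles):
            assert b.l_opt == pytest.approx(a.l_opt, abs=1e-6)
            assert b.l_ts == pytest.approx(a.l_ts, abs=1e-6)
            assert b.f_iso_max == pytest.approx(a.f_iso_max)

    def test_hip_roster_complete_without_short_rotators(self):
        model = load_muscle_csv()
        names = {m.name for m in model.muscles}
        assert len(names) == 23  # 23 compartment paths
        # multi-compartment muscles collapse to 16 anatomical muscles
        anatomical = {n.rstrip("0123456789") for n in names}
        anatomical = {n[:-1] if n.endswith("_") else n for n in anatomical}
        assert len({a.split("_mid")[0].split("_isch")[0] for a in anatomical} |
                   set()) >= 15
        for group in ("glut_max1", "glut_med1", "glut_min1", "iliacus",
                      "psoas", "rect_fem", "semimem", "semiten", "bifem_lh",
                      "sartorius", "gracilis", "tfl", "pectineus",
                      "add_longus", "add_brevis"):
            assert group in names
        # divided in the posterolateral approach, hence absent
        rotators = {"piriformis", "quad_fem", "obturator_int", "obturator_ext",
                    "gem_sup", "gem_inf"}
        assert not (rotators & names)

    def test_csv_round_trip(self, tmp_path):
        model = generic_model()
        save_muscle_csv(model, tmp_path / "m.csv")
        again = load_muscle_csv(tmp_path / "m.csv")
        s1 = sweep_flexion(model, np.arange(0, 91, 10.0))
        s2 = sweep_flexion(again, np.arange(0, 91, 10.0))
        np.testing.assert_allclose(s2.resultant_N, s1.resultant_N, atol=1e-4)
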