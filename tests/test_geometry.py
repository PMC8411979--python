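import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from bpval import geometry
from bpval.geometry import (HBOND_ATOMS, BaseFrame, IncompleteBaseError,
                            base_frame, hbond_lengths, simple_parameters,
                            superpose)
from bpval.model import Atom, Residue
from bpval.synthetic import PairSpec, build_pair


def random_rotation(seed):
    return Rotation.from_rotvec(np.random.default_rng(seed).normal(size=3)).as_matrix()


class TestSuperpose:
    def test_identical_point_sets(self):
        pts = np.random.default_rng(0).normal(size=(8, 3))
        rot, t, rmsd = superpose(pts, pts)
        assert np.allclose(rot, np.eye(3), atol=1e-12)
        assert np.allclose(t, 0, atol=1e-12)
        assert rmsd == pytest.approx(0, abs=1e-12)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_recovers_known_rigid_motion(self, seed):
        rng = np.random.default_rng(seed)
        ref = rng.normal(size=(6, 3))
        true_r = random_rotation(seed)
        true_t = rng.normal(size=3) * 10
        obs = ref @ true_r.T + true_t
        rot, t, rmsd = superpose(ref, obs)
        assert np.allclose(rot, true_r, atol=1e-9)
        assert np.allclose(t, true_t, atol=1e-9)
        assert rmsd < 1e-9
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_noisy_points_rmsd_is_least_squares_minimum(self):
        """The returned rmsd must beat any rotation from a random grid
        (independent brute-force check of the quadratic cost)."""
        rng = np.random.default_rng(42)
        ref = rng.normal(size=(9, 3))
        obs = ref @ random_rotation(7).T + rng.normal(size=3) + \
            rng.normal(scale=0.01, size=(9, 3))
        rot, t, rmsd = superpose(ref, obs)
        assert 0 <= rmsd <= 0.05
        for seed in range(50):
            r_try = random_rotation(seed + 100)
            # best translation for a fixed rotation aligns the centroids
            t_try = obs.mean(0) - r_try @ ref.mean(0)
            cost = np.sqrt(((obs - (ref @ r_try.T + t_try)) ** 2).sum() / len(ref))
            assert rmsd <= cost + 1e-12

    def test_agrees_with_scipy_align_vectors(self):
        rng = np.random.default_rng(5)
        ref = rng.normal(size=(7, 3))
        obs = ref @ random_rotation(11).T + 3.0 + rng.normal(scale=0.02, size=(7, 3))
        rot, _, _ = superpose(ref, obs)
        est, _ = Rotation.align_vectors(obs - obs.mean(0), ref - ref.mean(0))
        assert np.allclose(rot, est.as_matrix(), atol=1e-6)

    def test_degenerate_input_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError):
            superpose(line, line)
        with pytest.raises(ValueError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestBaseFrame:
    def test_standard_coordinates_give_identity_frame(self, standards):
        std = standards["G"]
        res = Residue(chain_id="A", seq_num=1, comp_id="DG", parent_base="G",
                      atoms=[Atom(name=n, element=n[0], position=xyz)
                             for n, xyz in std.coords.items()])
        frame = base_frame(res)
        assert np.allclose(frame.origin, 0, atol=1e-12)
        assert np.allclose(frame.axes, np.eye(3), atol=1e-12)
        assert frame.fit_rmsd == pytest.approx(0, abs=1e-12)

    def test_rigid_moved_base_carries_the_frame(self, standards):
        rot = random_rotation(3)
        t = np.array([4.0, -2.0, 7.0])
        std = standards["C"]
        res = Residue(chain_id="A", seq_num=1, comp_id="DC", parent_base="C",
                      atoms=[Atom(name=n, element=n[0], position=rot @ xyz + t)
                             for n, xyz in std.coords.items()])
        frame = base_frame(res)
        assert np.allclose(frame.origin, t, atol=1e-9)
        assert np.allclose(frame.axes, rot, atol=1e-9)

    def test_missing_ring_atom_raises(self, standards):
        std = standards["G"]
        atoms = [Atom(name=n, element=n[0], position=xyz)
                 for n, xyz in std.coords.items() if n != "N7"]
        res = Residue(chain_id="A", seq_num=1, comp_id="DG", parent_base="G",
                      atoms=atoms)
        with pytest.raises(IncompleteBaseError, match="N7"):
            base_frame(res)

    def test_frame_axes_validated(self):
        with pytest.raises(ValueError):
            BaseFrame(origin=np.zeros(3), axes=np.eye(3) * 2, fit_rmsd=0)
        left = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ValueError):
            BaseFrame(origin=np.zeros(3), axes=left, fit_rmsd=0)


PARAM_SPECS = [
    dict(shear=0.30, stretch=-0.10, buckle=10.0, propeller=-12.0),
    dict(shear=-0.5, stretch=0.2, stagger=0.4, buckle=-20.0, propeller=15.0,
         opening=-4.0),
    dict(stagger=1.0, opening=8.0),
]


class TestSimpleParameters:
    def test_ideal_pair_has_all_zero_parameters(self, ideal_gc_pair, measure):
        p = measure(ideal_gc_pair)
        assert all(abs(v) < 1e-9 for v in p.as_dict().values())

    @pytest.mark.parametrize("kwargs", PARAM_SPECS)
    def test_round_trip_against_builder(self, kwargs, measure):
        spec = PairSpec(pair_type="A-U", category="RNA-RNA", **kwargs)
        p = measure(build_pair(spec))
        for key, want in spec.params().as_dict().items():
            assert p.as_dict()[key] == pytest.approx(want, abs=1e-6)

    def test_rigid_body_invariance(self, measure):
        spec = PairSpec(pair_type="G-C", shear=0.3, buckle=12.0, propeller=-8.0)
        base = measure(build_pair(spec))
        moved = measure(build_pair(PairSpec(
            **{**spec.__dict__, "rotation": random_rotation(9),
               "translation": np.array([11.0, -6.0, 3.0])})))
        for key in base.as_dict():
            assert moved.as_dict()[key] == pytest.approx(base.as_dict()[key],
                                                         abs=1e-9)

    def test_order_swap_flips_shear_and_buckle_only(self):
        spec = PairSpec(pair_type="G-C", shear=0.3, stretch=-0.12, stagger=0.15,
                        buckle=8.0, propeller=-11.0, opening=2.0)
        res_i, res_j = build_pair(spec).residues
        fi, fj = base_frame(res_i), base_frame(res_j)
        ci, cj = res_i.atom("C1'").position, res_j.atom("C1'").position
        fwd = simple_parameters(fi, fj, ci, cj).as_dict()
        rev = simple_parameters(fj, fi, cj, ci).as_dict()
        for key in ("shear", "buckle"):
            assert rev[key] == pytest.approx(-fwd[key], abs=1e-9)
        for key in ("stretch", "stagger", "propeller", "opening"):
            assert rev[key] == pytest.approx(fwd[key], abs=1e-9)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(buckle=st.floats(-28, 28), propeller=st.floats(-28, 28))
    def test_buckle_propeller_decompose_interbase_angle(self, buckle, propeller):
        spec = PairSpec(pair_type="A-T", buckle=buckle, propeller=propeller)
        res_i, res_j = build_pair(spec).residues
        fi, fj = base_frame(res_i), base_frame(res_j)
        p = simple_parameters(fi, fj, res_i.atom("C1'").position,
                              res_j.atom("C1'").position)
        gamma = np.degrees(np.arccos(np.clip(fi.z @ (-fj.z), -1, 1)))
        assert p.buckle ** 2 + p.propeller ** 2 == pytest.approx(gamma ** 2,
                                                                 abs=1e-6)

    def test_antialigned_normals_not_pairable(self):
        # a partner with the *same* orientation has its normal pointing the
        # wrong way after the anti-parallel flip (γ = 180°)
        frame = BaseFrame(origin=np.zeros(3), axes=np.eye(3), fit_rmsd=0.0)
        partner = BaseFrame(origin=np.array([0, 9.0, 0]),
                            axes=np.eye(3), fit_rmsd=0.0)
        with pytest.raises(geometry.NotPairableError):
            simple_parameters(frame, partner, np.array([-2.5, 5.4, 0.0]),
                              np.array([-2.5, 3.6, 0.0]))


class TestHBondLengths:
    def test_bond_counts_per_pair_type(self):
        at = build_pair(PairSpec(category="DNA-DNA", pair_type="A-T")).residues
        gc = build_pair(PairSpec(category="DNA-DNA", pair_type="G-C")).residues
        assert [(h.atom_i, h.atom_j) for h in hbond_lengths(*at, "A-T")] == \
            [("N1", "N3"), ("N6", "O4")]
        assert [(h.atom_i, h.atom_j) for h in hbond_lengths(*gc, "G-C")] == \
            [("O6", "N4"), ("N1", "N3"), ("N2", "O2")]

    def test_distance_is_euclidean(self):
        res_i = Residue(chain_id="A", seq_num=1, comp_id="DA", parent_base="A",
                        atoms=[Atom(name="N1", element="N", position=np.zeros(3)),
                               Atom(name="N6", element="N", position=np.ones(3))])
        res_j = Residue(chain_id="B", seq_num=1, comp_id="DT", parent_base="T",
                        atoms=[Atom(name="N3", element="N",
                                    position=np.array([2.825, 0, 0])),
                               Atom(name="O4", element="O",
                                    position=np.array([1.0, 1.0, 4.0]))])
        measures = hbond_lengths(res_i, res_j, "A-T")
        assert measures[0].distance == pytest.approx(2.825, abs=1e-12)
        assert measures[1].distance == pytest.approx(3.0, abs=1e-12)

    def test_missing_atom_is_flagged_not_omitted(self):
        res_i, res_j = build_pair(PairSpec(pair_type="G-C")).residues
        res_j = Residue(chain_id=res_j.chain_id, seq_num=res_j.seq_num,
                        comp_id=res_j.comp_id, parent_base="C",
                        atoms=[a for a in res_j.atoms if a.name != "N4"])
        measures = hbond_lengths(res_i, res_j, "G-C")
        assert len(measures) == 3
        assert measures[0].missing and measures[0].distance is None
        assert not measures[1].missing

    def test_unknown_pair_type_rejected(self, ideal_gc_pair):
        with pytest.raises(KeyError):
            hbond_lengths(*ideal_gc_pair.residues, "G-U")
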