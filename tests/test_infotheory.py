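import math

import numpy as np
import pytest

from mdinfonet import synthetic as syn
from mdinfonet.infotheory import (
    BinSpec,
    aggregate_mi,
    assign_rotamer_states,
    dihedral_angle,
    entropy,
    extract_dihedrals,
    fluctuation_series,
    mi_calpha,
    mi_categorical,
    mi_dihedral,
    mi_matrix_calpha,
    MIMatrix,
    optimize_bins,
)
from mdinfonet.trajio import Selection

from .conftest import make_traj
from .oracles import (
    binned_gaussian_mi,
    gaussian_mi_numeric,
    loop_categorical_mi,
    loop_entropy,
    loop_mi,
    scan_bins,
)


class TestOptimizeBins:
    def test_constant_series_flagged(self):
        spec = optimize_bins(np.ones(100))
        assert spec.constant
        assert spec.n_bins == 1
        assert spec.entropy_trace == [0.0]

    def test_uniform_entropy_tracks_log2(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(size=100_000)
        low, high = x.min(), x.max()
        for n in (2, 4, 8, 16):
            h, _ = loop_entropy(x[:5000], n, low, high)
        # library trace on the full sample: H(N) ~ log2 N along the scan
        spec = optimize_bins(x)
        for idx, h in enumerate(spec.entropy_trace[:15]):
            assert h == pytest.approx(math.log2(idx + 2), abs=0.01)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_literal_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=1500) ** 2 + 0.3 * rng.uniform(size=1500)
        assert optimize_bins(x).n_bins == scan_bins(list(x))

    def test_bin_cap_respected(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(size=400)   # uniform keeps gaining entropy
        spec = optimize_bins(x)
        assert spec.n_bins <= max(2, int(math.sqrt(400)))

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            optimize_bins(np.array([1.0]))


class TestEntropy:
    def test_two_equiprobable_bins_one_bit(self):
        x = np.array([0.0] * 500 + [1.0] * 500)
        spec = BinSpec(n_bins=2, low=0.0, high=1.0)
        est = entropy(x, spec)
        assert est.h_observed == pytest.approx(1.0)
        assert est.n_occupied == 2

    def test_correction_arithmetic(self):
        """N_b = 9, N_c = 1000 adds exactly 0.008 bits."""
        rng = np.random.default_rng(4)
        x = rng.uniform(size=1000)
        spec = BinSpec(n_bins=9, low=float(x.min()), high=float(x.max()))
        est = entropy(x, spec)
        assert est.n_occupied == 9
        assert est.h_corrected - est.h_observed == pytest.approx(
            (9 - 1) / 1000, abs=1e-15)

    def test_corrected_never_below_observed(self, rng):
        x = rng.normal(size=700)
        spec = optimize_bins(x)
        est = entropy(x, spec)
        assert est.h_corrected >= est.h_observed
        assert 0.0 <= est.h_observed <= math.log2(spec.n_bins)

    def test_known_distribution_entropy_recovered(self):
        """Discretized 4-level distribution at N_c = 1e5."""
        p = np.array([0.4, 0.3, 0.2, 0.1])
        h_true = float(-(p * np.log2(p)).sum())
        rng = np.random.default_rng(5)
        x = rng.choice(4, size=100_000, p=p).astype(float)
        spec = BinSpec(n_bins=4, low=-0.5, high=3.5)
        assert entropy(x, spec).h_observed == pytest.approx(h_true, abs=0.02)

    def test_matches_loop_oracle(self, rng):
        x = rng.normal(size=180)
        spec = optimize_bins(x)
        est = entropy(x, spec)
        h, occ = loop_entropy(list(x), spec.n_bins, spec.low, spec.high)
        assert est.h_observed == pytest.approx(h, abs=1e-10)
        assert est.n_occupied == occ


class TestMICalpha:
    def test_self_mi_equals_entropy(self, rng):
        x = rng.normal(size=400)
        spec = optimize_bins(x)
        r = mi_calpha(x, x, spec, spec)
        assert r.mi_observed == pytest.approx(
            entropy(x, spec).h_observed, abs=1e-10)

    def test_correction_formula_exact(self, rng):
        x = rng.normal(size=300)
        y = rng.normal(size=300)
        sx, sy = optimize_bins(x), optimize_bins(y)
        r = mi_calpha(x, y, sx, sy)
        expected = r.mi_observed - (
            r.nb_joint - r.nb_i - r.nb_j + 1) / (2 * 300)
        assert max(expected, 0.0) == pytest.approx(r.mi, abs=1e-15)

    def test_independence_null_small(self):
        """Mean corrected MI over seeded independent pairs stays low
        (the full 50-seed check runs in the acceptance suite)."""
        vals = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            x, y = r.normal(size=7500), r.normal(size=7500)
            vals.append(mi_calpha(x, y, optimize_bins(x),
                                  optimize_bins(y)).mi)
        assert float(np.mean(vals)) <= 0.02

    def test_correlated_gaussian_approaches_numeric_integral(self):
        """Corrected MI of a rho=0.8 Gaussian pair approaches the exact
        MI of the generator's distribution discretized onto the same
        adaptive bins, computed by numerical integration."""
        rho = 0.8
        rng = np.random.default_rng(6)
        z0 = rng.standard_normal(100_000)
        z1 = rng.standard_normal(100_000)
        x = z0
        y = rho * z0 + math.sqrt(1 - rho ** 2) * z1
        sx, sy = optimize_bins(x), optimize_bins(y)
        r = mi_calpha(x, y, sx, sy)
        oracle = binned_gaussian_mi(rho, sx.edges(), sy.edges())
        assert r.mi == pytest.approx(oracle, abs=0.05)
        # and the discretized MI is bounded by the continuous MI
        assert oracle < gaussian_mi_numeric(rho)

    def test_matches_nested_loop_oracle(self, rng):
        x = rng.normal(size=200)
        y = x * 0.5 + rng.normal(size=200)
        sx, sy = optimize_bins(x), optimize_bins(y)
        r = mi_calpha(x, y, sx, sy)
        mi, nb, nbi, nbj = loop_mi(list(x), list(y), sx.n_bins, sx.low,
                                   sx.high, sy.n_bins, sy.low, sy.high)
        assert r.mi_observed == pytest.approx(mi, abs=1e-10)
        assert (r.nb_joint, r.nb_i, r.nb_j) == (nb, nbi, nbj)

    def test_correction_shrinks_as_one_over_n(self):
        rng = np.random.default_rng(7)
        gaps = []
        for n_c in (500, 5000, 50000):
            x = rng.normal(size=n_c)
            y = rng.normal(size=n_c)
            r = mi_calpha(x, y, optimize_bins(x), optimize_bins(y))
            gaps.append(abs(r.mi_observed - (r.mi_observed - (
                r.nb_joint - r.nb_i - r.nb_j + 1) / (2 * n_c)))
            )
        # magnitude of the correction falls with sample size
        assert gaps[0] > gaps[1] > gaps[2]

    def test_length_mismatch_raises(self, rng):
        x = rng.normal(size=50)
        y = rng.normal(size=60)
        with pytest.raises(ValueError):
            mi_calpha(x, y, optimize_bins(x), optimize_bins(y))

    def test_merging_bins_never_increases_observed_mi(self, rng):
        x = rng.normal(size=2000)
        y = 0.7 * x + rng.normal(size=2000)
        lo_x, hi_x = float(x.min()), float(x.max())
        lo_y, hi_y = float(y.min()), float(y.max())
        prev = None
        for n in (16, 8, 4, 2):   # each halving merges adjacent bins
            r = mi_calpha(x, y, BinSpec(n, lo_x, hi_x), BinSpec(n, lo_y, hi_y))
            if prev is not None:
                assert r.mi_observed <= prev + 1e-12
            prev = r.mi_observed


class TestMIMatrixCalpha:
    def test_planted_block_outranks_background(self, blocked_gaussian_traj):
        traj, gt = blocked_gaussian_traj
        sel = Selection.calpha(traj)
        mat = mi_matrix_calpha([traj], sel)
        block = [r for b in gt.blocks for r in b.residues]
        within = [mat.matrix[i, j] for i in block for j in block if i < j]
        cross = [mat.matrix[i, j] for i in block
                 for j in range(mat.n_residues) if j not in block]
        assert min(within) > max(cross)

    def test_independent_ensemble_null(self):
        """At the pooled frame count of a production condition (7500),
        an uncorrelated ensemble's off-diagonal MI stays at the null
        level (residual coupling from the shared rigid-body fit and
        finite sampling included)."""
        traj, _ = syn.gen_gaussian_traj(
            syn.GaussianTrajSpec(n_res=30, n_frames=7500, sigma=0.5,
                                 seed=17))
        sel = Selection.calpha(traj)
        mat = mi_matrix_calpha([traj], sel)
        off = mat.matrix[~np.eye(30, dtype=bool)]
        assert float(off.mean()) <= 0.02

    def test_symmetry_and_diagonal_entropy(self, small_gaussian_traj):
        sel = Selection.calpha(small_gaussian_traj)
        mat = mi_matrix_calpha([small_gaussian_traj], sel)
        assert np.array_equal(mat.matrix, mat.matrix.T)
        series = fluctuation_series(small_gaussian_traj.coords, sel)
        for i in range(3):
            spec = optimize_bins(series[i])
            assert mat.matrix[i, i] == pytest.approx(
                entropy(series[i], spec).h_corrected, abs=1e-12)

    def test_identical_series_give_common_entropy_offdiagonal(self):
        """Three residues with the same fluctuation series: every
        off-diagonal pair carries the common corrected self-MI."""
        rng = np.random.default_rng(19)
        s = np.abs(rng.normal(size=500))
        series = [s, s.copy(), s.copy()]
        specs = [optimize_bins(x) for x in series]
        vals = {}
        for i in range(3):
            for j in range(3):
                if i != j:
                    vals[(i, j)] = mi_calpha(series[i], series[j],
                                             specs[i], specs[j])
        common = vals[(0, 1)].mi
        assert all(v.mi == pytest.approx(common, abs=1e-12)
                   for v in vals.values())
        # observed self-MI is exactly the observed entropy
        assert vals[(0, 1)].mi_observed == pytest.approx(
            entropy(s, specs[0]).h_observed, abs=1e-10)


class TestDihedrals:
    def test_cis_quad_is_zero(self):
        p = np.array([[1.0, 1.0, 0.0], [1.0, 0.0, 0.0],
                      [2.0, 0.0, 0.0], [2.0, 1.0, 0.0]])
        assert dihedral_angle(*p) == pytest.approx(0.0, abs=1e-10)

    def test_trans_quad_is_180(self):
        p = np.array([[1.0, 1.0, 0.0], [1.0, 0.0, 0.0],
                      [2.0, 0.0, 0.0], [2.0, -1.0, 0.0]])
        assert abs(dihedral_angle(*p)) == pytest.approx(180.0, abs=1e-10)

    def test_mirror_negates_angle(self, rng):
        p = rng.normal(size=(4, 3))
        a = dihedral_angle(*p)
        mirrored = p * np.array([1.0, 1.0, -1.0])
        b = dihedral_angle(*mirrored)
        if abs(abs(a) - 180.0) > 1e-9:
            assert b == pytest.approx(-a, abs=1e-9)

    def test_extraction_marks_missing_absent(self):
        # lone residue: no previous/next neighbors -> phi/psi absent;
        # ALA has no chi
        coords = np.zeros((1, 3, 3))
        coords[0] = [[0, 0, 0], [1.5, 0, 0], [2.1, 1.3, 0]]
        traj = make_traj(coords, names=["N", "CA", "C"],
                         elements=["N", "C", "C"], res_ids=[1, 1, 1])
        dh = extract_dihedrals(traj, "A", 1)
        assert dh.angles["phi"] is None
        assert dh.angles["psi"] is None
        assert dh.angles["chi1"] is None

    def test_serine_chi1_extracted_at_planted_torsions(self):
        """OG rotated about the CA-CB axis plants known chi1 values."""
        n_frames = 4
        planted = [-60.0, -20.0, 20.0, 60.0]
        coords = np.zeros((n_frames, 4, 3))
        for t, deg in enumerate(planted):
            ang = math.radians(deg)
            coords[t, 0] = [1.0, 1.0, 0.0]          # N
            coords[t, 1] = [1.0, 0.0, 0.0]          # CA
            coords[t, 2] = [2.0, 0.0, 0.0]          # CB (axis along x)
            coords[t, 3] = [3.0, math.cos(ang), math.sin(ang)]  # OG
        traj = make_traj(coords, names=["N", "CA", "CB", "OG"],
                         elements=["N", "C", "C", "O"],
                         res_ids=[1, 1, 1, 1], res_names=["SER"] * 4)
        got = extract_dihedrals(traj, "A", 1).angles["chi1"]
        assert got is not None
        # the rotation parameter maps to the torsion up to a fixed
        # offset/sign of this construction; check pairwise differences
        diffs = np.diff(got)
        assert np.allclose(np.abs(diffs), 40.0, atol=1e-6)


class TestRotamerStates:
    def _series(self, res_name, **angles):
        from mdinfonet.infotheory import DihedralSeries
        full = {k: (np.asarray(v, dtype=float) if v is not None else None)
                for k, v in angles.items()}
        return DihedralSeries(res_name=res_name, angles=full)

    def test_sp3_chi_65_is_gauche_plus(self):
        rs = assign_rotamer_states(
            self._series("SER", phi=None, psi=None, chi1=[65.0]))
        assert rs.states["chi1"][0] == 1
        assert rs.n_states["chi1"] == 3

    def test_backbone_sector_boundary_convention(self):
        rs = assign_rotamer_states(
            self._series("ALA", phi=[-180.0, -60.0001, -60.0, 59.9, 60.0,
                                     180.0],
                         psi=None))
        assert list(rs.states["phi"]) == [1, 1, 2, 2, 3, 3]
        assert rs.n_states["phi"] == 3

    def test_sp3_sector_membership(self):
        rs = assign_rotamer_states(
            self._series("SER", phi=None, psi=None,
                         chi1=[65.0, 175.0, -150.0, -65.0, -5.0]))
        assert list(rs.states["chi1"]) == [1, 2, 2, 3, 3]

    def test_terminal_sp2_two_states(self):
        rs = assign_rotamer_states(
            self._series("ASP", phi=None, psi=None, chi1=[60.0],
                         chi2=[30.0, -80.0, 110.0, -170.0]))
        assert list(rs.states["chi2"]) == [1, 1, 2, 2]
        assert rs.n_states["chi2"] == 2

    def test_state_roundtrip_through_sector_centers(self):
        """States drawn in state space, rendered at sector centers,
        re-assigned -> identical states."""
        rng = np.random.default_rng(11)
        states = rng.integers(1, 4, size=500)
        centers = {1: 60.0, 2: 180.0, 3: -60.0}   # sp3 g+/t/g-
        angles = np.array([centers[s] for s in states])
        rs = assign_rotamer_states(
            self._series("LEU", phi=None, psi=None, chi1=angles, chi2=None))
        assert np.array_equal(rs.states["chi1"], states)
        # backbone sectors anchored at -180: centers -120, 0, 120
        bb_centers = {1: -120.0, 2: 0.0, 3: 120.0}
        bb_angles = np.array([bb_centers[s] for s in states])
        rs2 = assign_rotamer_states(
            self._series("ALA", phi=bb_angles, psi=None))
        assert np.array_equal(rs2.states["phi"], states)

    def test_unknown_residue_type_raises(self):
        with pytest.raises(KeyError):
            assign_rotamer_states(self._series("XYZ", phi=[0.0], psi=None))


class TestMIDihedral:
    def _rot(self, res_name, **state_arrays):
        from mdinfonet.infotheory import RotamerStateSeries
        return RotamerStateSeries(
            res_name=res_name,
            states={k: np.asarray(v) for k, v in state_arrays.items()},
            n_states={k: 3 for k in state_arrays})

    def test_identical_sequences_mi_equals_entropy(self):
        rng = np.random.default_rng(13)
        seq = rng.integers(1, 4, size=5000)
        r = mi_categorical(seq, seq)
        p = np.bincount(seq)[1:] / seq.size
        h = float(-(p[p > 0] * np.log2(p[p > 0])).sum())
        assert r.mi_observed == pytest.approx(h, abs=1e-10)

    def test_independence_null_small(self):
        vals = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            a = rng.integers(1, 4, size=7500)
            b = rng.integers(1, 4, size=7500)
            vals.append(mi_categorical(a, b).mi)
        assert float(np.mean(vals)) <= 0.01

    def test_planted_table_recovery(self):
        joint = np.array([[0.3, 0.05, 0.05],
                          [0.05, 0.25, 0.05],
                          [0.02, 0.03, 0.2]])
        sa, sb, mi_true = syn.gen_rotamer_series(
            syn.RotamerJointSpec(joint=joint, n_frames=100_000, seed=21))
        assert mi_categorical(sa, sb).mi == pytest.approx(mi_true, abs=0.02)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(23)
        a = rng.integers(1, 4, size=200)
        b = np.where(rng.random(200) < 0.7, a, rng.integers(1, 4, size=200))
        r = mi_categorical(a, b)
        assert r.mi_observed == pytest.approx(
            loop_categorical_mi(list(a), list(b)), abs=1e-10)

    def test_residue_pair_aggregation_modes(self):
        rng = np.random.default_rng(29)
        a1 = rng.integers(1, 4, size=2000)
        a2 = rng.integers(1, 4, size=2000)
        b1 = a1.copy()          # perfectly coupled with a1
        ri = self._rot("LYS", chi1=a1, chi2=a2)
        rj = self._rot("GLN", chi1=b1)
        v_sum, pairs = mi_dihedral(ri, rj, aggregate="sum")
        v_max, _ = mi_dihedral(ri, rj, aggregate="max")
        v_mean, _ = mi_dihedral(ri, rj, aggregate="mean")
        assert set(pairs) == {("chi1", "chi1"), ("chi2", "chi1")}
        assert v_sum == pytest.approx(sum(pairs.values()))
        assert v_max == pytest.approx(max(pairs.values()))
        assert v_mean == pytest.approx(np.mean(list(pairs.values())))
        assert v_max > 1.0   # coupled pair carries ~log2(3) bits

    def test_no_usable_dihedrals_flagged_absent(self):
        from mdinfonet.infotheory import RotamerStateSeries
        empty = RotamerStateSeries(res_name="ALA", states={}, n_states={})
        other = self._rot("LYS", chi1=np.array([1, 2, 3]))
        v, pairs = mi_dihedral(empty, other)
        assert v is None
        assert pairs == {}


class TestMIMatrixDihedral:
    def _serine_chain_traj(self, chi1_by_residue):
        """Serine-like residues (N, CA, CB, OG) with planted chi1 series.

        chi1_by_residue: dict residue index (0-based) -> angle array in
        degrees; OG is rotated about the CA-CB axis per frame.
        """
        n_res = max(chi1_by_residue) + 1
        n_frames = len(next(iter(chi1_by_residue.values())))
        coords = np.zeros((n_frames, 4 * n_res, 3))
        names, elements, res_ids, res_names = [], [], [], []
        for r in range(n_res):
            off = np.array([0.0, 20.0 * r, 0.0])
            names += ["N", "CA", "CB", "OG"]
            elements += ["N", "C", "C", "O"]
            res_ids += [r + 1] * 4
            res_names += ["SER"] * 4
            ang = np.radians(np.asarray(chi1_by_residue[r], float))
            base = 4 * r
            coords[:, base + 0] = off + [1.0, 1.0, 0.0]
            coords[:, base + 1] = off + [1.0, 0.0, 0.0]
            coords[:, base + 2] = off + [2.0, 0.0, 0.0]
            coords[:, base + 3, 0] = off[0] + 3.0
            coords[:, base + 3, 1] = off[1] + np.cos(ang)
            coords[:, base + 3, 2] = off[2] + np.sin(ang)
        return make_traj(coords, names=names, elements=elements,
                         res_ids=res_ids, res_names=res_names)

    def test_planted_coupled_pair_dominates_matrix(self):
        """Residues 1 and 8 share one chi1 rotamer schedule; distant
        independent pairs stay near zero; close pairs are excluded."""
        from mdinfonet.infotheory import mi_matrix_dihedral

        rng = np.random.default_rng(31)
        centers = np.array([60.0, 180.0, -60.0])
        shared = centers[rng.integers(0, 3, size=1500)]
        chi1 = {r: centers[rng.integers(0, 3, size=1500)]
                for r in range(8)}
        chi1[0] = shared
        chi1[7] = shared.copy()
        traj = self._serine_chain_traj(chi1)
        sel = Selection.calpha(traj)
        mat = mi_matrix_dihedral(traj, sel, min_separation=5)
        assert mat.mode == "dihedral"
        assert np.isnan(mat.matrix[0, 1])          # |i-j| <= 5 excluded
        assert mat.matrix[0, 7] > 1.0              # ~log2(3) coupled
        others = [mat.matrix[i, j] for i in range(8) for j in range(8)
                  if i < j and abs(i - j) > 5 and (i, j) != (0, 7)]
        assert max(others) < 0.05
        # aggregation runs on the dihedral matrix
        table = aggregate_mi(mat, "type_mean")
        assert list(table.group) == ["SER"]


class TestAggregation:
    def _matrix(self, values, res_names, res_ids=None):
        n = len(res_names)
        res_ids = res_ids or list(range(1, n + 1))
        return MIMatrix(
            residue_keys=[("A", r) for r in res_ids],
            res_names=list(res_names),
            matrix=np.asarray(values, dtype=float),
            n_samples=1000, mode="dihedral")

    def test_all_ones_matrix_every_aggregate_is_one(self):
        n = 16
        vals = np.ones((n, n))
        names = ["LYS", "GLN", "ASP", "LEU"] * 4
        mat = self._matrix(vals, names)
        for scheme in ("type_mean", "class_mean", "chi_count_mean"):
            table = aggregate_mi(mat, scheme)
            assert np.allclose(table.mean_mi_bits.values, 1.0)
        pair = aggregate_mi(mat, "class_pair")
        assert np.allclose(pair.mean_mi_bits.values, 1.0)

    def test_delta_of_matrix_with_itself_is_zero(self):
        mat = self._matrix(np.random.default_rng(1).random((8, 8)),
                           ["LYS"] * 8)
        delta = aggregate_mi(mat, "delta", reference=mat)
        assert np.all(delta == 0.0)

    def test_planted_lys_gln_pair_tops_type_ranking(self):
        n = 20
        vals = np.full((n, n), 0.01)
        names = (["LYS"] + ["LEU"] * 9 + ["GLN"] + ["VAL"] * 9)
        vals[0, 10] = vals[10, 0] = 0.9    # Lys1 - Gln11, separation 10
        mat = self._matrix(vals, names)
        table = aggregate_mi(mat, "type_mean").set_index("group")
        ranked = table.mean_mi_bits.sort_values(ascending=False)
        assert set(ranked.index[:2]) == {"LYS", "GLN"}

    def test_residue_mean_respects_separation(self):
        n = 8
        vals = np.ones((n, n))
        mat = self._matrix(vals, ["ALA"] * n)
        table = aggregate_mi(mat, "residue_mean", min_separation=5)
        # residue 1 has distant partners 7 and 8 only
        assert table.mean_mi_bits.iloc[0] == pytest.approx(1.0)
        table_all = aggregate_mi(mat, "residue_mean", min_separation=0)
        assert np.allclose(table_all.mean_mi_bits.values, 1.0)

    def test_missing_class_entry_raises(self):
        mat = self._matrix(np.ones((8, 8)), ["UNK"] * 8)
        with pytest.raises(KeyError):
            aggregate_mi(mat, "class_mean")
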