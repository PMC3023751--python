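"""CIM scan, cofactor selection, permutation thresholds, heritability."""

import numpy as np
import pandas as pd
import pytest

import radmap
from radmap import linkage as lk
from radmap import qtl, simdata


def trait_table(values):
    rows = []
    for ind, (trait, reps) in values.items():
        for r, v in enumerate(reps, start=1):
            rows.append((ind, trait, r, v))
    return pd.DataFrame(rows, columns=["individual", "trait", "replicate",
                                       "value"])


@pytest.fixture(scope="module")
def planted(study_truth, study_matrix, study_map):
    truth, _ = study_truth
    gmap, _ = study_map
    locus = truth.mapped_loci["locus_id"].iloc[10]  # chr1, 50 cM
    tbl = radmap.simulate_phenotypes(truth, [(locus, 1.0)], n_reps=1,
                                     residual_sd=0.5, seed=301)
    y = (qtl.trait_means(tbl).reindex(study_matrix.columns)["TRAIT"]
         .to_numpy())
    return truth, gmap, study_matrix, locus, y


class TestDeriveGy:
    def test_literal_product(self):
        tbl = pd.DataFrame({
            "individual": ["I1"] * 3, "trait": ["SN", "GN", "HGW"],
            "replicate": [1, 1, 1], "value": [2.0, 30.0, 5.0]})
        out = qtl.derive_gy(tbl)
        gy = out[out["trait"] == "GY"]["value"].iloc[0]
        assert gy == 300.0

    def test_zero_component_zero_yield(self):
        tbl = pd.DataFrame({
            "individual": ["I1"] * 3, "trait": ["SN", "GN", "HGW"],
            "replicate": [1, 1, 1], "value": [0.0, 30.0, 5.0]})
        out = qtl.derive_gy(tbl)
        assert out[out["trait"] == "GY"]["value"].iloc[0] == 0.0

    def test_missing_component_missing_yield(self):
        tbl = pd.DataFrame({
            "individual": ["I1"] * 3 + ["I2"] * 3,
            "trait": ["SN", "GN", "HGW"] * 2,
            "replicate": [1] * 6,
            "value": [2.0, 30.0, 5.0, 1.0, np.nan, 4.0]})
        out = qtl.derive_gy(tbl)
        gy = out[out["trait"] == "GY"].set_index("individual")["value"]
        assert gy["I1"] == 300.0
        assert np.isnan(gy["I2"])


class TestGenotypeExpectation:
    def test_hard_call_at_marker(self, study_map, study_matrix):
        gmap, _ = study_map
        grid, exps = qtl.genotype_expectation(gmap, study_matrix)
        scores = qtl._score_matrix(study_matrix)
        pos = gmap.set_index("marker")
        for marker in study_matrix.index[:20]:
            group, cm = pos.loc[marker, ["group", "position_cM"]]
            gi = np.flatnonzero((grid["group"] == group)
                                & np.isclose(grid["cM"], cm))
            if gi.size == 0:
                continue
            mi = study_matrix.index.get_loc(marker)
            called = scores[mi] != 0
            np.testing.assert_allclose(exps[gi[0], called],
                                       scores[mi, called])

    def test_midpoint_matches_enumeration_oracle(self):
        """20-cM interval, equal flanks: compare with direct enumeration."""
        d = 10.0
        r = lk.haldane_inverse(d)
        r_lr = lk.haldane_inverse(20.0)
        # enumeration over the interior genotype given flanks A,A
        p_aa = (1 - r) * (1 - r) / (1 - r_lr)
        p_ab = r * r / (1 - r_lr)
        expected = p_aa - p_ab
        gmap = pd.DataFrame({"marker": ["L", "R"], "group": "LG1",
                             "bin": [0, 1], "position_cM": [0.0, 20.0]})
        mat = pd.DataFrame({"I1": ["A", "A"], "I2": ["A", "B"]},
                           index=["L", "R"])
        grid, exps = qtl.genotype_expectation(gmap, mat, step_cM=10.0)
        mid = np.flatnonzero(np.isclose(grid["cM"], 10.0))[0]
        assert exps[mid, 0] == pytest.approx(expected, rel=1e-12)
        assert exps[mid, 1] == pytest.approx(0.0, abs=1e-12)  # symmetry

    def test_single_flank_decay(self):
        gmap = pd.DataFrame({"marker": ["L", "R"], "group": "LG1",
                             "bin": [0, 1], "position_cM": [0.0, 20.0]})
        mat = pd.DataFrame({"I1": ["A", "-"]}, index=["L", "R"])
        grid, exps = qtl.genotype_expectation(gmap, mat, step_cM=20.0)
        end = np.flatnonzero(np.isclose(grid["cM"], 20.0))[0]
        assert exps[end, 0] == pytest.approx(np.exp(-0.4))

    def test_scores_bounded(self, study_map, study_matrix):
        gmap, _ = study_map
        _, exps = qtl.genotype_expectation(gmap, study_matrix, step_cM=5.0)
        assert np.all(exps <= 1.0 + 1e-12)
        assert np.all(exps >= -1.0 - 1e-12)


class TestSelectCofactors:
    def test_single_candidate_null_selection_rate(self):
        """With one candidate marker, P(selected | null) ~ alpha."""
        rng = np.random.default_rng(310)
        gmap = pd.DataFrame({"marker": ["M1"], "group": "LG1", "bin": [0],
                             "position_cM": [0.0]})
        calls = rng.choice(["A", "B"], size=(1, 40))
        mat = pd.DataFrame(calls, index=["M1"],
                           columns=[f"I{i}" for i in range(40)])
        eng = qtl.ScanEngine(gmap, mat)
        n_sel = sum(bool(eng.select_cofactors(rng.normal(size=40)))
                    for _ in range(400))
        rate = n_sel / 400
        sd = np.sqrt(0.1 * 0.9 / 400)
        assert abs(rate - 0.1) < 3 * sd

    def test_planted_qtl_selects_nearest_marker(self, planted):
        truth, gmap, mat, locus, _ = planted
        tbl = radmap.simulate_phenotypes(truth, [(locus, 2.0)], n_reps=1,
                                         residual_sd=0.1, seed=311)
        y = (qtl.trait_means(tbl).reindex(mat.columns)["TRAIT"].to_numpy())
        cof = qtl.select_cofactors(mat, gmap, y)
        pos = gmap.set_index("marker")
        qtl_group, qtl_cm = pos.loc[locus, ["group", "position_cM"]]
        best = min(cof, key=lambda m: (pos.loc[m, "group"] != qtl_group,
                                       abs(pos.loc[m, "position_cM"]
                                           - qtl_cm)))
        assert pos.loc[best, "group"] == qtl_group
        assert abs(pos.loc[best, "position_cM"] - qtl_cm) <= 5.0

    def test_zero_max_cofactors_is_sim(self, planted):
        _, gmap, mat, _, y = planted
        assert qtl.select_cofactors(mat, gmap, y, max_cofactors=0) == []

    def test_respects_cap(self, planted):
        _, gmap, mat, _, y = planted
        cof = qtl.select_cofactors(mat, gmap, y)
        assert len(cof) <= 7


class TestCimScan:
    def test_lod_is_0217_times_lr(self, planted):
        """Reported LOD equals 0.217*LR identically on the grid."""
        _, gmap, mat, _, y = planted
        eng = qtl.ScanEngine(gmap, mat, step_cM=2.0)
        cof = eng.select_cofactors(y)
        scan = qtl.cim_scan(gmap, mat, y, cofactors=cof, engine=eng)
        # recompute LR by explicit nested OLS at every position
        n = len(y)
        grid, exps = eng.grid, eng.exps
        pos = gmap.set_index("marker")
        scores = qtl._score_matrix(mat)
        midx = {m: i for i, m in enumerate(mat.index)}
        for i in range(0, len(grid), 7):
            group, cm = grid.iloc[i][["group", "cM"]]
            active = [c for c in cof
                      if pos.loc[c, "group"] != group
                      or abs(pos.loc[c, "position_cM"] - cm) >= 50.0]
            C = np.column_stack([np.ones(n)]
                                + [scores[midx[c]] for c in active])
            X1 = np.column_stack([C[:, :1], exps[i], C[:, 1:]])
            rss0 = _rss(C, y)
            rss1 = _rss(X1, y)
            lr = n * np.log(rss0 / rss1)
            assert scan.profile["lod"].iloc[i] == pytest.approx(
                0.217 * lr, abs=1e-8)

    def test_no_cofactors_reduces_to_sim(self, planted):
        _, gmap, mat, _, y = planted
        scan_none = qtl.cim_scan(gmap, mat, y, cofactors=None)
        scan_empty = qtl.cim_scan(gmap, mat, y, cofactors=[])
        pd.testing.assert_frame_equal(scan_none.profile, scan_empty.profile)

    def test_lod_affine_invariant(self, planted):
        _, gmap, mat, _, y = planted
        eng = qtl.ScanEngine(gmap, mat, step_cM=5.0)
        cof = eng.select_cofactors(y)
        a = qtl.cim_scan(gmap, mat, y, cofactors=cof, engine=eng)
        b = qtl.cim_scan(gmap, mat, 3.0 * y - 7.0, cofactors=cof, engine=eng)
        np.testing.assert_allclose(a.profile["lod"], b.profile["lod"],
                                   atol=1e-8)

    def test_planted_qtl_recovered(self, planted):
        _, gmap, mat, locus, y = planted
        eng = qtl.ScanEngine(gmap, mat)
        cof = eng.select_cofactors(y)
        scan = qtl.cim_scan(gmap, mat, y, cofactors=cof, engine=eng)
        peak = scan.profile.loc[scan.profile["lod"].idxmax()]
        pos = gmap.set_index("marker")
        assert peak["group"] == pos.loc[locus, "group"]
        assert abs(peak["cM"] - pos.loc[locus, "position_cM"]) <= 5.0
        assert peak["additive"] == pytest.approx(1.0, abs=0.2)


class TestPermutationThreshold:
    def test_constant_trait_zero_threshold(self, planted):
        _, gmap, mat, _, _ = planted
        eng = qtl.ScanEngine(gmap, mat, step_cM=10.0)
        thr = qtl.permutation_threshold(gmap, mat, np.ones(mat.shape[1]),
                                        n_perm=120, seed=1, engine=eng)
        assert thr == 0.0

    def test_reproducible_and_exchangeable(self, planted):
        _, gmap, mat, _, y = planted
        eng = qtl.ScanEngine(gmap, mat, step_cM=10.0)
        t1 = qtl.permutation_threshold(gmap, mat, y, n_perm=150, seed=42,
                                       engine=eng)
        t2 = qtl.permutation_threshold(gmap, mat, y, n_perm=150, seed=42,
                                       engine=eng)
        assert t1 == t2
        # permuting individual order leaves the null distribution unchanged
        rng = np.random.default_rng(0)
        t3 = qtl.permutation_threshold(gmap, mat, rng.permutation(y),
                                       n_perm=150, seed=42, engine=eng)
        assert t3 == pytest.approx(t1, rel=0.2)

    def test_small_n_perm_warns(self, planted):
        _, gmap, mat, _, y = planted
        eng = qtl.ScanEngine(gmap, mat, step_cM=20.0)
        with pytest.warns(UserWarning, match="unstable"):
            qtl.permutation_threshold(gmap, mat, y, n_perm=50, seed=1,
                                      engine=eng)


class TestSupportInterval:
    def test_unimodal_interval_contains_peak(self, planted):
        _, gmap, mat, _, y = planted
        scan = qtl.cim_scan(gmap, mat, y)
        peak = scan.profile.loc[scan.profile["lod"].idxmax()]
        lo, hi = qtl.support_interval(scan, peak["group"], peak["cM"])
        assert lo <= peak["cM"] <= hi

    def test_flat_profile_spans_group(self):
        prof = pd.DataFrame({"group": "LG1", "cM": [0.0, 5.0, 10.0],
                             "lod": [4.0, 4.0, 4.0],
                             "additive": 0.0, "r2": 0.0})
        scan = qtl.QtlScan("t", prof, [])
        assert qtl.support_interval(scan, "LG1", 5.0) == (0.0, 10.0)


class TestHeritability:
    def test_formula_arithmetic(self):
        est = qtl.HeritabilityEstimate("t", 3.0, 1.0, 2)
        assert est.h2 == pytest.approx(6 / 7)

    def test_pure_noise_clamps_to_zero_ish(self):
        rng = np.random.default_rng(320)
        tbl = trait_table({f"I{i}": ("T", rng.normal(size=2))
                           for i in range(200)})
        est = qtl.estimate_heritability(tbl)["T"]
        assert est.sigma_g2 >= 0.0
        assert est.h2 < 0.2

    def test_single_replicate_rejected(self):
        tbl = trait_table({"I1": ("T", [1.0]), "I2": ("T", [2.0])})
        with pytest.raises(ValueError):
            qtl.estimate_heritability(tbl)


def _rss(X, y):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    e = y - X @ beta
    return float(e @ e)
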