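"""Normalization (CPM/TPM/TMM), induction profiling and PUL target calling,
checked against brute-force oracles and simulated experiments with known truth."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import pulkit as pk
from pulkit import expression as ex


def make_cm(counts, substrates=None, lengths=None):
    counts = pd.DataFrame(counts)
    counts.index = [f"g{i}" for i in range(counts.shape[0])]
    counts.columns = [f"s{j}" for j in range(counts.shape[1])]
    substrates = substrates or ["glucose"] * counts.shape[1]
    meta = pd.DataFrame(
        {"substrate": substrates, "replicate": list(range(1, counts.shape[1] + 1))},
        index=counts.columns,
    )
    if lengths is not None:
        lengths = pd.Series(np.asarray(lengths, float), index=counts.index)
    return ex.CountMatrix(counts, meta, lengths)


# ---------------------------------------------------------------------------
# within-sample normalization
# ---------------------------------------------------------------------------

class TestCPM:
    def test_single_gene_full_library(self):
        cm = make_cm([[10]])
        assert pk.cpm(cm).iloc[0, 0] == pytest.approx(1e6)

    def test_columns_sum_to_one_million(self, random_count_matrix):
        sums = pk.cpm(random_count_matrix).sum(axis=0)
        np.testing.assert_allclose(sums, 1e6, rtol=1e-9)

    def test_matches_per_cell_division(self, random_count_matrix):
        cm = random_count_matrix
        expected = np.empty(cm.counts.shape)
        arr = cm.counts.to_numpy(float)
        for j in range(arr.shape[1]):
            expected[:, j] = arr[:, j] / arr[:, j].sum() * 1e6
        np.testing.assert_allclose(pk.cpm(cm).to_numpy(), expected)

    def test_zero_library_rejected(self):
        cm = make_cm([[0, 5], [0, 5]])
        with pytest.raises(ValueError, match="library"):
            pk.cpm(cm)


class TestTPM:
    def test_equal_counts_equal_lengths_symmetric(self):
        cm = make_cm([[5], [5], [5], [5]], lengths=[100] * 4)
        np.testing.assert_allclose(pk.tpm(cm).iloc[:, 0], 2.5e5)

    def test_columns_sum_to_one_million(self, random_count_matrix):
        sums = pk.tpm(random_count_matrix).sum(axis=0)
        np.testing.assert_allclose(sums, 1e6, rtol=1e-9)

    def test_matches_brute_force_and_length_scaling(self, random_count_matrix):
        cm = random_count_matrix
        arr = cm.counts.to_numpy(float)
        lens = cm.gene_lengths.to_numpy()
        rates = arr / lens[:, None]
        expected = rates / rates.sum(axis=0) * 1e6
        np.testing.assert_allclose(pk.tpm(cm).to_numpy(), expected)
        # doubling one gene's length halves its rate contribution
        lens2 = lens.copy()
        lens2[0] *= 2
        cm2 = ex.CountMatrix(
            cm.counts, cm.sample_meta, pd.Series(lens2, index=cm.counts.index)
        )
        rates2 = arr / lens2[:, None]
        np.testing.assert_allclose(
            pk.tpm(cm2).to_numpy(), rates2 / rates2.sum(axis=0) * 1e6
        )

    def test_missing_length_named(self, random_count_matrix):
        cm = random_count_matrix
        lengths = cm.gene_lengths.drop("g3")
        cm2 = ex.CountMatrix(cm.counts, cm.sample_meta, lengths)
        with pytest.raises(ValueError, match="g3"):
            pk.tpm(cm2)


# ---------------------------------------------------------------------------
# TMM between-sample factors
# ---------------------------------------------------------------------------

def tmm_oracle(counts, logratio_trim=0.30, abs_trim=0.05):
    """Independent brute-force TMM: doubly trimmed, precision-weighted mean
    of per-gene log2 ratios against the upper-quartile-nearest reference."""
    mat = np.asarray(counts, float)
    lib = mat.sum(axis=0)
    props = mat / lib
    uq = np.quantile(props, 0.75, axis=0)
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = []
    for s in range(mat.shape[1]):
        o, r = mat[:, s], mat[:, ref]
        keep = (o > 0) & (r > 0)
        o, r = o[keep], r[keep]
        m = np.log2((o / lib[s]) / (r / lib[ref]))
        a = 0.5 * np.log2((o / lib[s]) * (r / lib[ref]))
        w = 1.0 / ((lib[s] - o) / (lib[s] * o) + (lib[ref] - r) / (lib[ref] * r))
        if np.max(np.abs(m)) < 1e-6:
            factors.append(1.0)
            continue
        n = m.size
        lo_m, hi_m = np.floor(n * logratio_trim) + 1, n - np.floor(n * logratio_trim)
        lo_a, hi_a = np.floor(n * abs_trim) + 1, n - np.floor(n * abs_trim)
        rm = pd.Series(m).rank().to_numpy()
        ra = pd.Series(a).rank().to_numpy()
        sel = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        factors.append(2 ** (np.sum(m[sel] * w[sel]) / np.sum(w[sel])))
    factors = np.array(factors)
    return factors / np.exp(np.mean(np.log(factors)))


# 8-gene, 3-sample hand example: sample 2 is compositionally biased (one
# dominant gene), sample 1 is a pure depth change of sample 0.
HAND_COUNTS = np.array(
    [
        [100, 200, 80],
        [50, 100, 40],
        [300, 600, 250],
        [80, 160, 900],
        [20, 40, 15],
        [500, 1000, 420],
        [10, 20, 8],
        [60, 120, 50],
    ]
)


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        cm = make_cm(np.tile([[10], [60], [200], [30]], (1, 4)))
        np.testing.assert_allclose(pk.tmm_factors(cm), 1.0)

    def test_pure_depth_difference_absorbed_by_library_size(self):
        col = np.array([10, 60, 200, 30, 90])
        cm = make_cm(np.column_stack([col, 2 * col]))
        f = pk.tmm_factors(cm)
        assert f.iloc[0] == pytest.approx(f.iloc[1], rel=1e-9)
        np.testing.assert_allclose(np.exp(np.mean(np.log(f))), 1.0)

    def test_hand_example_matches_oracle(self):
        cm = make_cm(HAND_COUNTS)
        np.testing.assert_allclose(
            pk.tmm_factors(cm).to_numpy(), tmm_oracle(HAND_COUNTS), atol=1e-8
        )

    def test_random_matrices_match_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            mat = rng.negative_binomial(4, 0.005, size=(60, 5))
            mat[0, 2] *= 20  # composition outlier
            np.testing.assert_allclose(
                pk.tmm_factors(make_cm(mat)).to_numpy(), tmm_oracle(mat), atol=1e-8
            )

    def test_scaling_one_sample_leaves_its_factor_unchanged(self):
        cm1 = make_cm(HAND_COUNTS)
        scaled = HAND_COUNTS.copy()
        scaled[:, 1] *= 13
        cm2 = make_cm(scaled)
        np.testing.assert_allclose(
            pk.tmm_factors(cm1).to_numpy(), pk.tmm_factors(cm2).to_numpy(), rtol=1e-9
        )

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="two samples"):
            pk.tmm_factors(make_cm([[5], [10]]))

    def test_no_common_genes_warns_factor_one(self):
        counts = np.array([[100, 0], [0, 100], [50, 0], [0, 50]])
        with pytest.warns(UserWarning, match="common"):
            f = pk.tmm_factors(make_cm(counts))
        np.testing.assert_allclose(f, 1.0)


class TestFilterExpressed:
    def test_all_zero_gene_removed(self, random_count_matrix):
        cm = random_count_matrix
        counts = cm.counts.copy()
        counts.loc["g0"] = 0
        cm2 = ex.CountMatrix(counts, cm.sample_meta)
        kept = pk.filter_expressed(cm2, min_cpm=1, min_samples=1)
        assert "g0" not in kept.counts.index

    def test_min_samples_zero_is_identity(self, random_count_matrix):
        kept = pk.filter_expressed(random_count_matrix, min_cpm=1, min_samples=0)
        assert kept.counts.shape == random_count_matrix.counts.shape

    def test_matches_row_scan_oracle(self, random_count_matrix):
        cm = random_count_matrix
        kept = pk.filter_expressed(cm, min_cpm=50, min_samples=3)
        arr = cm.counts.to_numpy(float)
        cpms = arr / arr.sum(axis=0) * 1e6
        expected = [
            g
            for i, g in enumerate(cm.counts.index)
            if (cpms[i] >= 50).sum() >= 3
        ]
        assert list(kept.counts.index) == expected

    def test_everything_removed_suggests_thresholds(self, random_count_matrix):
        with pytest.raises(ValueError, match="min_cpm"):
            pk.filter_expressed(random_count_matrix, min_cpm=1e9, min_samples=6)


# ---------------------------------------------------------------------------
# log2FC and gene selection
# ---------------------------------------------------------------------------

class TestLog2FC:
    def test_identical_replicates_give_zero(self):
        col = [40, 80, 10, 200]
        cm = make_cm(
            np.tile(np.array(col)[:, None], (1, 4)),
            substrates=["glucose", "glucose", "starch", "starch"],
        )
        prof = pk.log2fc_vs_reference(cm, "glucose")
        np.testing.assert_allclose(prof.log2fc["starch"], 0.0, atol=1e-12)

    def test_eightfold_mean_ratio_gives_three(self):
        # gene 0: mean CPM 80 on substrate vs 10 on reference, pseudocount 0
        glc = np.array([[10], [999990 // 3], [333330], [333330]])
        sta = np.array([[80], [333240], [333340], [333340]])
        counts = np.column_stack([glc, glc, sta, sta])
        cm = make_cm(counts, substrates=["glucose", "glucose", "starch", "starch"])
        prof = pk.log2fc_vs_reference(
            cm, "glucose", pseudocount=0.0, norm_factors=pd.Series(1.0, index=cm.counts.columns)
        )
        assert prof.log2fc.loc["g0", "starch"] == pytest.approx(3.0, abs=1e-6)

    def test_antisymmetry_when_reference_swapped(self, minimal_experiment):
        _, cm, _ = minimal_experiment
        f = pk.tmm_factors(cm)
        a = pk.log2fc_vs_reference(cm, "glucose", norm_factors=f)
        b = pk.log2fc_vs_reference(cm, "starch", norm_factors=f)
        np.testing.assert_allclose(
            a.log2fc["starch"], -b.log2fc["glucose"], atol=1e-9
        )

    def test_null_scenario_centred_near_zero(self):
        sc = pk.build_fixture_scenario("minimal", seed=2)
        null = pk.Scenario(
            strain_label="null",
            puls=tuple(
                pk.PULSpec(p.pul_id, p.genes, p.targets, 0.0, 0.0) for p in sc.puls
            ),
            substrates=sc.substrates,
            baseline_cpm=sc.baseline_cpm,
            seed=2,
        )
        means = []
        for seed in range(10):
            cm, _ = pk.simulate_count_experiment(null, seed=seed)
            prof = pk.log2fc_vs_reference(cm)
            means.append(prof.log2fc.to_numpy().mean())
        assert abs(np.mean(means)) < 0.2

    def test_unknown_reference_rejected(self, random_count_matrix):
        with pytest.raises(ValueError, match="reference"):
            pk.log2fc_vs_reference(random_count_matrix, "mannose")


class TestSelectRegulated:
    def make_profile(self, data, substrates):
        df = pd.DataFrame(data, columns=substrates)
        df.index = [f"g{i}" for i in range(df.shape[0])]
        return ex.InductionProfile(df, pd.Series(1.0, index=df.index), "glucose")

    def test_zero_profile_empty(self):
        prof = self.make_profile(np.zeros((4, 2)), ["a", "b"])
        assert pk.select_regulated(prof) == set()

    def test_threshold_is_strict(self):
        prof = self.make_profile([[3.0, 0.0], [3.0001, 0.0], [0.0, -3.0]], ["a", "b"])
        assert pk.select_regulated(prof, 3.0) == {"g1"}

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(0)
        prof = self.make_profile(rng.normal(0, 2.5, size=(50, 4)), list("abcd"))
        got = pk.select_regulated(prof, 3.0)
        expected = {
            g
            for g in prof.log2fc.index
            if any(v > 3.0 or v < -3.0 for v in prof.log2fc.loc[g])
        }
        assert got == expected

    @given(st.floats(max_value=0, allow_nan=False))
    def test_nonpositive_threshold_rejected(self, thr):
        prof = self.make_profile(np.zeros((2, 1)), ["a"])
        with pytest.raises(ValueError):
            pk.select_regulated(prof, thr)


# ---------------------------------------------------------------------------
# PUL aggregation and target calls
# ---------------------------------------------------------------------------

def annotation_from(rows):
    df = pd.DataFrame(rows, columns=["locus_tag", "pul_id", "role"])
    df["predicted_substrate"] = ""
    df["cazy_families"] = [[] for _ in range(len(df))]
    return ex.PULAnnotation(df)


class TestPULHeatmap:
    def make_profile(self, values, genes, substrates):
        df = pd.DataFrame(values, index=genes, columns=substrates)
        return ex.InductionProfile(df, pd.Series(1.0, index=df.index), "glucose")

    def test_single_susc_equals_gene_row(self):
        prof = self.make_profile([[4.0, 1.0]], ["x1"], ["a", "b"])
        ann = annotation_from([("x1", "P1", "susC")])
        _, summary = pk.pul_heatmap_matrix(prof, ann)
        np.testing.assert_allclose(summary.loc["P1"], [4.0, 1.0])

    def test_summary_is_marker_mean(self):
        prof = self.make_profile(
            [[4.0, 0.0], [6.0, 0.0], [9.0, 9.0]], ["x1", "x2", "x3"], ["a", "b"]
        )
        ann = annotation_from(
            [("x1", "P1", "susC"), ("x2", "P1", "susD"), ("x3", "P1", "CAZyme")]
        )
        _, summary = pk.pul_heatmap_matrix(prof, ann)
        # CAZyme excluded from the marker mean
        np.testing.assert_allclose(summary.loc["P1"], [5.0, 0.0])

    def test_filtered_genes_reported_missing_not_zero(self):
        prof = self.make_profile([[4.0]], ["x1"], ["a"])
        ann = annotation_from([("x1", "P1", "susC"), ("x9", "P1", "susD")])
        gene_matrix, _ = pk.pul_heatmap_matrix(prof, ann)
        assert np.isnan(gene_matrix.loc[("P1", "x9"), "a"])

    def test_disjoint_annotation_rejected(self):
        prof = self.make_profile([[4.0]], ["x1"], ["a"])
        ann = annotation_from([("y1", "P1", "susC")])
        with pytest.raises(ValueError, match="no genes"):
            pk.pul_heatmap_matrix(prof, ann)


class TestCallPULTargets:
    def summary(self, rows, substrates):
        return pd.DataFrame(rows, index=[f"P{i}" for i in range(len(rows))],
                            columns=substrates)

    def status_map(self, calls, pul):
        return {c.substrate: c.status for c in calls if c.pul_id == pul}

    def test_exclusive_target_confirmed_others_not(self):
        s = self.summary([[8.0, 0.5, 0.3]], ["starch", "xylan", "arabinan"])
        m = self.status_map(pk.call_pul_targets(s), "P0")
        assert m == {"starch": "confirmed", "xylan": "not_induced",
                     "arabinan": "not_induced"}

    def test_cross_activation_called(self):
        s = self.summary([[9.0, 7.0, 0.0]], ["arabinan", "pectic_galactan", "starch"])
        m = self.status_map(pk.call_pul_targets(s), "P0")
        assert m["arabinan"] == "confirmed"
        assert m["pectic_galactan"] == "cross_activated"

    def test_moderate_band(self):
        s = self.summary([[2.0, 0.5]], ["hg", "starch"])
        m = self.status_map(pk.call_pul_targets(s), "P0")
        assert m == {"hg": "moderate", "starch": "not_induced"}

    def test_all_zero_not_induced(self):
        s = self.summary([[0.0, 0.0]], ["a", "b"])
        assert {c.status for c in pk.call_pul_targets(s)} == {"not_induced"}


class TestEndToEndRecovery:
    def test_minimal_scenario_perfect_confirmed_calls(self):
        """Sensitivity and specificity of confirmed calls are 1.0 at
        marker effect 6 log2 units over a seeded grid."""
        sc0 = pk.build_fixture_scenario("minimal")
        ann = ex.PULAnnotation(sc0.annotation_frame())
        hits = 0
        n_runs = 100
        for seed in range(n_runs):
            sc = pk.build_fixture_scenario("minimal", seed=seed)
            cm, truth = pk.simulate_count_experiment(sc)
            prof = pk.log2fc_vs_reference(pk.filter_expressed(cm))
            _, summary = pk.pul_heatmap_matrix(prof, ann)
            calls = pk.call_pul_targets(summary)
            confirmed = {(c.pul_id, c.substrate)
                         for c in calls if c.status == "confirmed"}
            expected = {
                (r.pul_id, r.substrate)
                for r in truth.itertuples()
                if r.induced
            }
            if confirmed == expected:
                hits += 1
        assert hits == n_runs
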