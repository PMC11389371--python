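"""Bray-Curtis scoring, leave-one-out protocol, subsampling experiments,
and the correlation analyses."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import braycurtis
from scipy.stats import pearsonr

import mbinterp as mi
from mbinterp.evaluation import EvaluationRecord

from conftest import make_profile


def make_record(ind="p", ds="d", idx=1, t=1.0, method="knn", bc=0.5,
                gap_prev=1.0, gap_next=1.0, n_avail=10, failed=False,
                rel=None):
    return EvaluationRecord(
        individual_id=ind, dataset=ds, target_index=idx, target_time=t,
        method_name=method, predicted=None, bc_similarity=bc,
        relative_errors=rel, gap_prev=gap_prev, gap_next=gap_next,
        n_samples_available=n_avail, failed=failed,
    )


class TestBrayCurtis:
    def test_examples(self):
        assert mi.bray_curtis_similarity([0.5, 0.5], [0.5, 0.5]) == 1.0
        assert mi.bray_curtis_similarity([1, 0], [0, 1]) == 0.0
        assert mi.bray_curtis_similarity([0.5, 0.5, 0.0],
                                         [1.0, 0.0, 0.0]) == pytest.approx(0.5)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 10_000))
    def test_min_identity_symmetry_and_scipy_agreement(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(2, 20))
        x = rng.dirichlet(np.full(m, 0.6))
        y = rng.dirichlet(np.full(m, 0.6))
        s = mi.bray_curtis_similarity(x, y)
        assert s == pytest.approx(np.minimum(x, y).sum(), abs=1e-12)
        assert s == pytest.approx(mi.bray_curtis_similarity(y, x), abs=1e-15)
        assert s == pytest.approx(1.0 - braycurtis(x, y), abs=1e-10)


class TestRelativeError:
    def test_exact_prediction_is_zero(self):
        np.testing.assert_allclose(
            mi.relative_error([0.3, 0.7], [0.3, 0.7]), 0.0
        )

    def test_halved_abundance_and_zero_truth(self):
        out = mi.relative_error([0.2, 0.0, 0.8], [0.1, 0.3, 0.6])
        assert out[0] == pytest.approx(0.5)
        assert np.isnan(out[1])
        assert np.nanmean(out) == pytest.approx((0.5 + 0.25) / 2)


class TestLOO:
    def test_interior_targets_only(self, small_profile):
        records = mi.loo_evaluate(small_profile, "weighted_average")
        assert len(records) == small_profile.n_samples - 2
        assert [r.target_index for r in records] == \
            list(range(1, small_profile.n_samples - 1))
        assert all(r.gap_prev > 0 and r.gap_next > 0 for r in records)

    def test_constant_profile_perfect_last_method(self):
        x = [0.4, 0.6]
        prof = mi.LongitudinalProfile("c", np.arange(10.0), ("a", "b"),
                                      np.tile(x, (10, 1)))
        records = mi.loo_evaluate(prof, "last")
        assert len(records) == 8
        assert all(r.bc_similarity == pytest.approx(1.0) for r in records)

    def test_equal_method_matches_min_sum_oracle(self, small_profile):
        records = mi.loo_evaluate(small_profile, "equal")
        for r in records:
            truth = small_profile.sample(r.target_index).values
            oracle = np.minimum(truth, 1.0 / small_profile.n_taxa).sum()
            assert r.bc_similarity == pytest.approx(oracle, abs=1e-12)

    def test_method_failure_is_flagged_not_dropped(self, monkeypatch):
        prof = make_profile(seed=1, n_samples=6, n_taxa=4)
        import mbinterp.evaluation as ev

        original = ev.interpolate
        calls = {"n": 0}

        def flaky(profile, t, spec, **kw):
            calls["n"] += 1
            if calls["n"] == 2:
                raise RuntimeError("boom")
            return original(profile, t, spec, **kw)

        monkeypatch.setattr(ev, "interpolate", flaky)
        records = mi.loo_evaluate(prof, "knn")
        assert len(records) == 4
        assert sum(r.failed for r in records) == 1
        failed = next(r for r in records if r.failed)
        assert "boom" in failed.message and np.isnan(failed.bc_similarity)


class TestSummaries:
    def test_single_record_mean(self):
        df = mi.summarize_accuracy([make_record(bc=0.8)])
        assert df.loc["knn", "mean_bc"] == pytest.approx(0.8)
        assert df.loc["knn", "n"] == 1

    def test_ranking_matches_hand_sorted_means(self):
        records = [make_record(method="knn", bc=b) for b in (0.9, 0.8)]
        records += [make_record(method="equal", bc=b) for b in (0.4, 0.5)]
        df = mi.summarize_accuracy(records)
        assert df.loc["knn", "rank"] == 1
        assert df.loc["equal", "rank"] == 2

    def test_failed_records_counted_separately(self):
        records = [make_record(bc=0.8), make_record(bc=np.nan, failed=True)]
        df = mi.summarize_accuracy(records)
        assert df.loc["knn", "n"] == 1
        assert df.loc["knn", "n_failed"] == 1
        assert df.loc["knn", "mean_bc"] == pytest.approx(0.8)


class TestSubsample:
    def test_row_count_contract(self, small_profile):
        results = mi.subsample_experiment(
            small_profile, "knn", sizes=[5, 10], replicates=3, seed=0
        )
        assert len(results) == 6
        assert {r.sample_size for r in results} == {5, 10}

    def test_seeded_determinism(self, small_profile):
        a = mi.subsample_experiment(small_profile, "knn", sizes=[6],
                                    replicates=5, seed=3)
        b = mi.subsample_experiment(small_profile, "knn", sizes=[6],
                                    replicates=5, seed=3)
        assert [(r.target_time, r.bc_similarity) for r in a] == \
            [(r.target_time, r.bc_similarity) for r in b]

    def test_full_size_reproduces_loo_scores(self, small_profile):
        n = small_profile.n_samples
        loo = {r.target_time: r.bc_similarity
               for r in mi.loo_evaluate(small_profile, "knn", K=5)}
        results = mi.subsample_experiment(
            small_profile, mi.InterpolatorSpec("knn", {"K": 5}),
            sizes=[n], replicates=8, seed=1,
        )
        for r in results:
            assert r.bc_similarity == pytest.approx(loo[r.target_time],
                                                    abs=1e-12)

    def test_oversized_request_skipped_with_warning(self, small_profile):
        with pytest.warns(UserWarning, match="skipped"):
            out = mi.subsample_experiment(
                small_profile, "knn",
                sizes=[small_profile.n_samples + 5], replicates=2, seed=0,
            )
        assert out == []


class TestStratifiedEffects:
    def _fake_results(self, gaps, sizes):
        return [
            mi.SubsampleResult(
                individual_id="p", method_name="knn", sample_size=s,
                replicate=i, seed=0, target_time=float(i), gap_prev=g,
                bc_similarity=1.0 - 0.01 * g,
            )
            for i, (g, s) in enumerate(zip(gaps, sizes))
        ]

    def test_single_stratum_equals_overall_mean(self):
        res = self._fake_results([1.0, 2.0, 3.0], [10, 10, 10])
        df = mi.stratified_effects(res, fix="sample_size", bins=[0, 10])
        assert len(df) == 1
        assert df["mean_bc"].iloc[0] == pytest.approx(
            np.mean([0.99, 0.98, 0.97])
        )

    def test_constructed_monotone_gap_effect_recovered(self):
        rng = np.random.default_rng(0)
        gaps = rng.uniform(0, 30, 300)
        res = self._fake_results(gaps, [12] * 300)
        df = mi.stratified_effects(res, fix="sample_size",
                                   bins=[0, 10, 20, 30])
        means = df["mean_bc"].to_numpy()
        assert np.all(np.diff(means) < 0)

    def test_partition_conserves_counts(self):
        res = self._fake_results([1.0, 5.0, 15.0, 25.0], [10, 10, 20, 20])
        df = mi.stratified_effects(res, fix="sample_size", bins=[0, 10, 30])
        assert df["n"].sum() == 4


class TestAutocorrelation:
    def test_constant_accuracy_is_nan(self):
        records = [make_record(idx=i, t=float(i), bc=0.7) for i in range(12)]
        df = mi.accuracy_autocorrelation(records, lag_bins=[0, 6, 12])
        assert df["pearson_r"].isna().all()
        assert df["n_pairs"].sum() == 12 * 11 // 2

    def test_ar1_accuracy_decays_across_lags(self):
        rng = np.random.default_rng(1)
        acc, a = [], 0.0
        for _ in range(120):
            a = 0.95 * a + 0.1 * rng.standard_normal()
            acc.append(0.8 + a)
        records = [make_record(idx=i, t=float(i), bc=b)
                   for i, b in enumerate(acc)]
        df = mi.accuracy_autocorrelation(records, lag_bins=[0, 5, 40, 120])
        r = df["pearson_r"].to_numpy()
        assert r[0] > r[1] > r[2]


class TestNeighborContext:
    def _cohort_records(self, seed=0, autocorr=0.95):
        rng = np.random.default_rng(seed)
        records = []
        for ds in ("ds1", "ds2"):
            for ind in range(4):
                level = rng.normal(0.7, 0.15)
                a = 0.0
                for i in range(25):
                    a = autocorr * a + 0.05 * rng.standard_normal()
                    records.append(
                        make_record(ind=f"{ds}_p{ind}", ds=ds, idx=i,
                                    t=float(i), bc=level + a)
                    )
        return records

    def test_identical_accuracy_everywhere_gives_nan(self):
        records = [make_record(ind=f"p{k}", ds=f"d{k % 2}", idx=i, t=float(i))
                   for k in range(4) for i in range(10)]
        out = mi.neighbor_context_correlation(records, seed=0)
        assert all(np.isnan(v) for v in out.values())

    def test_adjacent_beats_other_dataset(self):
        out = mi.neighbor_context_correlation(self._cohort_records(),
                                              seed=0, n_draws=5)
        assert out["adjacent"] > out["random_other_dataset"]
        assert out["adjacent"] > 0.5

    def test_seeded_pairings_reproducible(self):
        records = self._cohort_records(seed=3)
        a = mi.neighbor_context_correlation(records, seed=11)
        b = mi.neighbor_context_correlation(records, seed=11)
        assert a == b


class TestDiversityCorrelation:
    def test_hand_table_matches_closed_form(self):
        bc = np.array([0.5, 0.62, 0.58, 0.75, 0.8])
        # two-taxon compositions of increasing evenness (hence diversity)
        ps = [0.05, 0.15, 0.25, 0.35, 0.48]
        rows = [[p, 1 - p] for p in ps]
        prof = mi.LongitudinalProfile(
            "p", np.arange(7.0), ("a", "b"),
            np.array([rows[0]] + rows + [rows[-1]]),
        )
        records = [make_record(idx=i + 1, t=float(i + 1), bc=float(b))
                   for i, b in enumerate(bc)]
        df = mi.diversity_accuracy_correlation(records, [prof])
        truth_div = [mi.shannon_diversity(prof.sample(i + 1)) for i in range(5)]
        expected = pearsonr(truth_div, bc)[0]
        assert df["pearson_r"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_constant_diversity_gives_nan(self):
        prof = mi.LongitudinalProfile(
            "p", np.arange(7.0), ("a", "b"), np.tile([0.5, 0.5], (7, 1))
        )
        records = [make_record(idx=i + 1, t=float(i + 1), bc=0.5 + 0.01 * i)
                   for i in range(5)]
        df = mi.diversity_accuracy_correlation(records, [prof])
        assert np.isnan(df["pearson_r"].iloc[0])


class TestMethodAgreement:
    def _records(self, scores_by_method):
        records = []
        for method, scores in scores_by_method.items():
            for k, bc in enumerate(scores):
                records.append(
                    make_record(ind=f"p{k}", method=method, bc=bc)
                )
        return records

    def test_identical_methods_fully_correlated(self):
        recs = self._records({"knn": [0.9, 0.7, 0.5],
                              "spline": [0.9, 0.7, 0.5]})
        mat = mi.method_agreement(recs)
        assert mat.loc["knn", "spline"] == pytest.approx(1.0)
        np.testing.assert_allclose(np.diag(mat), 1.0)

    def test_reversed_method_anticorrelated(self):
        recs = self._records({"knn": [0.9, 0.7, 0.5],
                              "equal": [0.1, 0.3, 0.5]})
        mat = mi.method_agreement(recs)
        assert mat.loc["knn", "equal"] == pytest.approx(-1.0)

    def test_hand_table(self):
        a, b = [0.9, 0.6, 0.7], [0.8, 0.5, 0.75]
        recs = self._records({"knn": a, "mlrr": b})
        mat = mi.method_agreement(recs)
        assert mat.loc["knn", "mlrr"] == pytest.approx(pearsonr(a, b)[0])
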