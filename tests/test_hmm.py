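from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import methylseg as ms
from methylseg.hmm import _viterbi_path, binom_logpmf


def make_model(betas, d0=1250.0, pi=None, **kw):
    betas = np.asarray(betas, float)
    pi = np.full(len(betas), 1 / len(betas)) if pi is None else np.asarray(pi)
    return ms.HMMModel(betas=betas, pi=pi, d0=d0, **kw)


def brute_force_best_path(model, series):
    """Exhaustive max-probability path over all K^T state sequences.

    Independent of the Viterbi recursion: multiplies per-step transition
    matrices and emission probabilities directly.
    """
    K, T = model.K, len(series)
    mats = [ms.transition_probs(model, d) for d in series.gaps]
    best_lp, best_path = -np.inf, None
    for path in product(range(K), repeat=T):
        lp = np.log(model.pi[path[0]])
        lp += float(binom_logpmf(series.meth[0], series.depth[0], model.betas[path[0]]))
        for t in range(1, T):
            lp += np.log(mats[t - 1][path[t - 1], path[t]])
            lp += float(
                binom_logpmf(series.meth[t], series.depth[t], model.betas[path[t]])
            )
        if lp > best_lp:
            best_lp, best_path = lp, path
    return best_lp, np.array(best_path)


class TestTransitionProbs:
    @pytest.mark.parametrize("K", [2, 3, 4, 5, 6])
    @pytest.mark.parametrize("d", [0.0, 1.0, 1250.0, 12500.0, 1e9])
    def test_rows_sum_to_one(self, K, d):
        model = make_model(np.linspace(0.1, 0.9, K))
        A = ms.transition_probs(model, d)
        np.testing.assert_allclose(A.sum(axis=1), 1.0, atol=1e-12)

    def test_k4_printed_coefficients_exact(self):
        """At K = 4 the general form equals 1/4 + 3/4 e^(-d/d0), 1/4 - 1/4 e^(-d/d0)."""
        model = make_model([0.1, 0.3, 0.6, 0.9], d0=1250.0)
        for d in (0.0, 100.0, 1250.0, 5000.0):
            e = np.exp(-d / 1250.0)
            A = ms.transition_probs(model, d)
            assert A[0, 0] == 0.25 + 0.75 * e
            assert A[0, 1] == 0.25 - 0.25 * e

    def test_zero_distance_is_identity(self):
        A = ms.transition_probs(make_model([0.1, 0.5, 0.9]), 0.0)
        np.testing.assert_allclose(A, np.eye(3), atol=1e-15)

    def test_large_distance_limit_uniform(self):
        for K in (3, 4):
            A = ms.transition_probs(make_model(np.linspace(0.1, 0.9, K)), 1e12)
            np.testing.assert_allclose(A, np.full((K, K), 1 / K), atol=1e-12)

    def test_stay_at_one_decay_length(self):
        A = ms.transition_probs(make_model([0.1, 0.3, 0.6, 0.9], d0=1250.0), 1250.0)
        assert A[2, 2] == pytest.approx(0.25 + 0.75 * np.exp(-1.0), abs=1e-12)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            ms.transition_probs(make_model([0.1, 0.9]), -1.0)

    def test_literal_form_renormalized(self):
        model = make_model([0.1, 0.5, 0.9], transition_form="literal")
        A = ms.transition_probs(model, 500.0)
        np.testing.assert_allclose(A.sum(axis=1), 1.0, atol=1e-12)
        # matches generalized form exactly at K = 4
        g4 = make_model([0.1, 0.3, 0.6, 0.9])
        l4 = make_model([0.1, 0.3, 0.6, 0.9], transition_form="literal")
        np.testing.assert_allclose(
            ms.transition_probs(g4, 777.0), ms.transition_probs(l4, 777.0), atol=1e-15
        )

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(d=st.floats(0, 1e8), K=st.integers(2, 6))
    def test_rows_stochastic_property(self, d, K):
        A = ms.transition_probs(make_model(np.linspace(0.05, 0.95, K)), d)
        assert np.all(A >= 0)
        np.testing.assert_allclose(A.sum(axis=1), 1.0, atol=1e-12)


class TestEmission:
    def test_zero_depth_uninformative(self):
        model = make_model([0.05, 0.5, 0.85])
        for k in range(3):
            assert ms.emission_prob(model, k, 0, 0) == 1.0

    def test_binomial_closed_form(self):
        model = make_model([0.3, 0.5])
        assert ms.emission_prob(model, 1, 2, 4) == pytest.approx(6 / 16, rel=1e-12)

    def test_beta_one_all_methylated(self):
        model = make_model([0.1, 1.0])
        assert ms.emission_prob(model, 1, 2, 2) == pytest.approx(1.0, abs=1e-5)

    def test_never_nan_at_clamped_extremes(self):
        model = make_model([0.0, 1.0])
        lp = binom_logpmf(3, 3, 0.0)
        assert np.isfinite(lp)  # clamped floor, never NaN
        assert ms.emission_prob(model, 0, 3, 3) >= 0.0


def test_training_weight_is_depth_plus_two():
    assert ms.training_weight(1) == 3
    assert ms.training_weight(0) == 2
    assert ms.training_weight(8) == 10
    np.testing.assert_array_equal(ms.training_weight(np.array([0, 3])), [2, 5])


class TestBidirectional:
    def test_gap_mirror(self):
        s = ms.ObservationSeries([100, 150, 300], [0, 1, 1], [1, 2, 2], chrom="chr1")
        fwd, rev = ms.prepare_bidirectional(s)
        assert rev.gaps.tolist() == [150, 50]
        assert fwd.gaps.tolist() == [50, 150]

    def test_single_site_reverse_equals_forward(self):
        s = ms.ObservationSeries([42], [1], [2])
        _, rev = ms.prepare_bidirectional(s)
        assert rev.meth.tolist() == [1] and rev.depth.tolist() == [2]

    def test_gap_multiset_preserved(self, small_series):
        _, rev = ms.prepare_bidirectional(small_series)
        assert sorted(rev.gaps) == sorted(small_series.gaps)
        assert rev.meth.tolist() == small_series.meth.tolist()[::-1]


class TestFit:
    def test_k1_closed_form(self):
        """Single-state EM reduces to the (n+2)-weighted pooled fraction."""
        rng = np.random.default_rng(0)
        depth = rng.integers(0, 6, size=200)
        meth = rng.binomial(depth, 0.37)
        s = ms.ObservationSeries(np.arange(1, 201) * 50, meth, depth)
        res = ms.fit([s], K=1, d0=1250.0, seed=0)
        w = depth + 2
        expected = (w * meth).sum() / (w * depth).sum()
        assert res.model.betas[0] == pytest.approx(expected, abs=1e-9)

    def test_weighted_loglik_monotone(self):
        cfg = ms.SimulationConfig(chrom_lengths={"chr1": 300_000}, seed=5)
        sim = ms.simulate(cfg)
        res = ms.fit(sim.series, K=3, d0=1250.0, seed=5)
        diffs = np.diff(res.log_likelihoods)
        assert np.all(diffs >= -1e-6 * np.abs(res.log_likelihoods[0]))

    def test_betas_canonically_sorted(self, fitted_k3):
        assert np.all(np.diff(fitted_k3.model.betas) > 0)

    def test_empty_series_list_rejected(self):
        with pytest.raises(ValueError):
            ms.fit([], K=2, d0=1250.0)

    def test_too_few_covered_sites_rejected(self):
        s = ms.ObservationSeries([10, 20, 30], [1, 0, 1], [2, 1, 2])
        with pytest.raises(ValueError, match="covered sites"):
            ms.fit([s], K=3, d0=1250.0)

    def test_model_json_round_trip(self, fitted_k3, tmp_path):
        path = tmp_path / "model.json"
        fitted_k3.model.to_json(path, seed=1)
        back = ms.HMMModel.from_json(path)
        np.testing.assert_allclose(back.betas, fitted_k3.model.betas, atol=0)
        np.testing.assert_allclose(back.pi, fitted_k3.model.pi, atol=0)
        assert back.d0 == fitted_k3.model.d0


class TestViterbiOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_bruteforce_enumeration(self, seed):
        """Viterbi path score equals the exhaustive maximum over all 3^10 paths."""
        rng = np.random.default_rng(seed)
        T = 10
        pos = np.cumsum(rng.integers(20, 2000, size=T))
        depth = rng.integers(0, 7, size=T)
        meth = rng.binomial(depth, rng.choice([0.05, 0.5, 0.85], size=T))
        series = ms.ObservationSeries(pos, meth, depth, chrom="chr1")
        model = make_model([0.07, 0.48, 0.83], d0=900.0, pi=[0.2, 0.5, 0.3])
        path, score = _viterbi_path(model, series)
        bf_score, bf_path = brute_force_best_path(model, series)
        assert score == pytest.approx(bf_score, abs=1e-9)
        np.testing.assert_array_equal(path, bf_path)

    def test_two_state_short_series(self):
        series = ms.ObservationSeries([100, 180, 900], [0, 2, 3], [3, 2, 3])
        model = make_model([0.1, 0.8], d0=500.0)
        path, score = _viterbi_path(model, series)
        bf_score, bf_path = brute_force_best_path(model, series)
        assert score == pytest.approx(bf_score, abs=1e-9)
        np.testing.assert_array_equal(path, bf_path)


class TestDecode:
    def test_homogeneous_series_single_state_no_un(self):
        model = make_model([0.05, 0.5, 0.85])
        T = 50
        series = ms.ObservationSeries(
            np.arange(1, T + 1) * 100, np.zeros(T, int), np.full(T, 5)
        )
        path = ms.decode(model, series)
        assert path.n_un == 0
        assert set(path.states.tolist()) == {0}

    def test_un_marks_direction_disagreement(self):
        """Sites where forward and reverse Viterbi differ get the 'un' label."""
        rng = np.random.default_rng(11)
        T = 8
        # non-uniform pi and depth >= 1 keep path scores tie-free, so the
        # lexicographic brute-force winner is unique
        model = make_model([0.1, 0.5, 0.9], d0=600.0, pi=[0.5, 0.3, 0.2])
        for trial in range(6):
            pos = np.cumsum(rng.integers(20, 1500, size=T))
            depth = rng.integers(1, 5, size=T)
            meth = rng.binomial(depth, rng.random(T))
            series = ms.ObservationSeries(pos, meth, depth)
            decoded = ms.decode(model, series)
            fwd, rev = ms.prepare_bidirectional(series)
            f_path = brute_force_best_path(model, fwd)[1]
            r_path = brute_force_best_path(model, rev)[1][::-1]
            expected = np.where(f_path == r_path, f_path, ms.UN)
            np.testing.assert_array_equal(decoded.states, expected)

    def test_direction_symmetric_un_set(self, fitted_k3, default_sim_runs):
        series = default_sim_runs[1].series[0]
        sub = ms.ObservationSeries(
            series.positions[:2000], series.meth[:2000], series.depth[:2000],
            chrom=series.chrom,
        )
        model = fitted_k3.model
        fwd_decode = ms.decode(model, sub)
        _, rev = ms.prepare_bidirectional(sub)
        rev_decode = ms.decode(model, rev)
        un_fwd = set(np.flatnonzero(fwd_decode.states == ms.UN))
        un_rev = {len(sub) - 1 - i for i in np.flatnonzero(rev_decode.states == ms.UN)}
        assert un_fwd == un_rev

    def test_posterior_mode_available(self, fitted_k3, small_series):
        path = ms.decode(fitted_k3.model, small_series, method="posterior")
        assert len(path) == len(small_series)


class TestSelectModel:
    def test_returns_argmin_bic_of_table(self):
        cfg = ms.SimulationConfig(
            chrom_lengths={"chr1": 400_000}, betas=(0.45, 0.5, 0.55), pi=(1.0, 0.0, 0.0),
            d0=1e12, seed=3,
        )
        sim = ms.simulate(cfg)
        best, table = ms.select_model(sim.series, K_grid=[2, 3], d0_grid=[1250.0], seed=3)
        row = table.loc[table["BIC"].idxmin()]
        assert best.K == int(row["K"]) and best.d0 == row["d0"]

    def test_criterion_formulas(self, default_sim_runs):
        res = default_sim_runs[1]
        sub = [ms.ObservationSeries(s.positions[:5000], s.meth[:5000], s.depth[:5000],
                                    chrom=s.chrom) for s in res.series]
        _, table = ms.select_model(sub, K_grid=[2, 3], d0_grid=[1250.0], seed=1)
        for _, row in table.iterrows():
            assert row["AIC"] == pytest.approx(2 * row["p"] - 2 * row["lnL"])
            assert row["BIC"] == pytest.approx(
                row["p"] * np.log(row["N"]) - 2 * row["lnL"]
            )
            assert row["p"] == 2 * row["K"]

    def test_empty_grid_rejected(self, small_series):
        with pytest.raises(ValueError):
            ms.select_model([small_series], K_grid=[], d0_grid=[1250.0])


class TestTrainTestLoci:
    CHROM_SIZES = {
        **{f"chr{i}": 40_000_000 for i in range(1, 6)},
        **{f"chr{i}": 15_000_000 for i in range(6, 11)},
        **{f"chr{i}": 6_000_000 for i in range(11, 29)},
    }

    def test_default_call_counts_and_lengths(self):
        train, test = ms.make_train_test_loci(self.CHROM_SIZES, seed=4)
        loci = train + test
        assert len(loci) == 54
        assert all(end - start + 1 == 300_000 for _, start, end in loci)
        assert len(train) == len(test) == 27

    def test_equal_class_representation(self):
        from methylseg.hmm import default_chrom_classes

        classes = default_chrom_classes(self.CHROM_SIZES)
        train, test = ms.make_train_test_loci(self.CHROM_SIZES, seed=4)
        for split in (train, test):
            counts = {}
            for chrom, _, _ in split:
                counts[classes[chrom]] = counts.get(classes[chrom], 0) + 1
            assert counts == {"macro": 9, "intermediate": 9, "micro": 9}

    def test_no_overlaps(self):
        train, test = ms.make_train_test_loci(self.CHROM_SIZES, seed=4)
        by_chrom = {}
        for chrom, start, end in train + test:
            by_chrom.setdefault(chrom, []).append((start, end))
        for ivs in by_chrom.values():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                assert e1 < s2

    def test_deterministic_under_seed(self):
        a = ms.make_train_test_loci(self.CHROM_SIZES, seed=9)
        b = ms.make_train_test_loci(self.CHROM_SIZES, seed=9)
        assert a == b

    def test_infeasible_quota_names_class(self):
        sizes = {"chr1": 40_000_000, "chr6": 15_000_000, "chr12": 100_000}
        with pytest.raises(ValueError, match="micro"):
            ms.make_train_test_loci(sizes, seed=0)
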