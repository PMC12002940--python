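import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genestrat.io import CountMatrix
from genestrat.normalize import (
    NormalizationParams,
    compute_rpk,
    cpm,
    getmm_log2cpm,
    low_count_filter,
    select_reference_sample,
    tmm_factor,
)
from oracles import tmm_bruteforce


def _random_cm(rng, n_genes, n_samp):
    mu = rng.lognormal(3, 1.5, n_genes)
    depth = rng.uniform(0.5, 2, n_samp)
    counts = rng.negative_binomial(5, 5 / (5 + mu[:, None] * depth[None, :]))
    if np.any(counts.sum(axis=0) == 0):
        counts[0] += 1
    gene_ids = [f"g{i}" for i in range(n_genes)]
    return CountMatrix(gene_ids, [f"s{j}" for j in range(n_samp)], counts), rng.integers(300, 8000, n_genes).astype(float)


class TestComputeRpk:
    def test_definition(self):
        cm = CountMatrix(["g1"], ["s1", "s2"], np.array([[10, 7]]))
        rpk = compute_rpk(cm, np.array([2000.0]))
        assert rpk[0, 0] == 5.0

    def test_count7_length350(self):
        cm = CountMatrix(["g1"], ["s1"], np.array([[7]]))
        assert compute_rpk(cm, np.array([350.0]))[0, 0] == 20.0

    def test_zero_count_zero_rpk(self):
        cm = CountMatrix(["g1"], ["s1"], np.array([[0]]))
        assert compute_rpk(cm, np.array([12345.0]))[0, 0] == 0.0

    def test_missing_length_raises(self):
        cm = CountMatrix(["g1", "g2"], ["s1"], np.array([[1], [2]]))
        with pytest.raises(ValueError, match="missing length"):
            compute_rpk(cm, pd.Series({"g1": 100.0}))

    def test_length_below_one_raises(self):
        cm = CountMatrix(["g1"], ["s1"], np.array([[1]]))
        with pytest.raises(ValueError):
            compute_rpk(cm, np.array([0.0]))


class TestSelectReference:
    def test_identical_samples_tie_to_first(self):
        rpk = np.tile(np.arange(1.0, 11.0)[:, None], (1, 3))
        assert select_reference_sample(rpk) == 0

    def test_closest_to_mean_quartile(self):
        # three samples with equal library sizes (10) and 75th percentiles
        # {0.9, 1.0, 2.0}: mean upper quartile 1.3 -> the 1.0 sample wins
        rpk = np.column_stack([
            [0.05, 0.05, 0.1, 0.9, 8.9],
            [0.10, 0.20, 0.2, 1.0, 8.5],
            [0.20, 0.30, 0.5, 2.0, 7.0],
        ])
        assert np.allclose(rpk.sum(axis=0), 10.0)
        assert np.allclose(np.percentile(rpk, 75, axis=0), [0.9, 1.0, 2.0])
        assert select_reference_sample(rpk) == 1

    def test_single_sample_raises(self):
        with pytest.raises(ValueError):
            select_reference_sample(np.ones((5, 1)))

    def test_all_zero_sample_raises(self):
        rpk = np.ones((5, 2))
        rpk[:, 1] = 0
        with pytest.raises(ValueError, match="all-zero"):
            select_reference_sample(rpk)


class TestTmmFactor:
    def test_self_factor_is_one(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(2, 1, 100)
        assert tmm_factor(x, x) == pytest.approx(1.0)

    def test_pure_depth_change_absorbed(self):
        rng = np.random.default_rng(1)
        x = rng.lognormal(2, 1, 100)
        assert tmm_factor(2 * x, x) == pytest.approx(1.0)

    def test_against_bruteforce_oracle_suite(self):
        # acceptance-grade agreement: 20 seeded NB matrices
        rng = np.random.default_rng(123)
        n_checked = 0
        while n_checked < 20:
            cm, lengths = _random_cm(rng, int(rng.integers(10, 51)),
                                     int(rng.integers(2, 7)))
            rpk = compute_rpk(cm, lengths)
            ref = select_reference_sample(rpk)
            for s in range(rpk.shape[1]):
                assert tmm_factor(rpk[:, s], rpk[:, ref]) == pytest.approx(
                    tmm_bruteforce(rpk[:, s], rpk[:, ref]), abs=1e-9)
            n_checked += 1

    def test_upregulated_genes_shift_factor(self):
        # 2 of 20 genes 50-fold up in obs: the trimmed mean must not be 1
        rng = np.random.default_rng(5)
        ref = rng.lognormal(3, 0.5, 20)
        obs = ref.copy()
        obs[:2] *= 50
        expected = tmm_bruteforce(obs, ref)
        assert tmm_factor(obs, ref) == pytest.approx(expected, abs=1e-12)
        assert expected != pytest.approx(1.0, abs=1e-3)

    def test_factor_symmetry(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            a = rng.lognormal(3, 1, 80)
            b = rng.lognormal(3, 1, 80)
            assert tmm_factor(a, b) * tmm_factor(b, a) == pytest.approx(1.0, abs=1e-6)

    def test_degenerate_pair_warns_factor_one(self):
        obs = np.array([1.0, 0.0, 0.0, 0.0])
        ref = np.array([0.0, 1.0, 1.0, 1.0])
        with pytest.warns(UserWarning):
            assert tmm_factor(obs, ref) == 1.0


class TestGetmmLog2cpm:
    def test_closed_form_single_gene(self):
        # rpk 5 against an effective library of 1e6 with no prior:
        # log2cpm = log2(5 / 1e6 * 1e6) = log2(5)
        assert np.log2(5 / 1e6 * 1e6) == pytest.approx(2.321928, abs=1e-6)

    def test_identical_samples_identical_profiles(self):
        counts = np.tile(np.array([[10], [100], [1000]]), (1, 4))
        cm = CountMatrix(["g1", "g2", "g3"], [f"s{i}" for i in range(4)], counts)
        norm = getmm_log2cpm(cm, np.array([500.0, 1000.0, 2000.0]))
        assert np.allclose(norm.log2cpm, norm.log2cpm[:, :1])

    def test_cpm_threshold_identity(self):
        # 10 counts in a 20 M library is CPM 0.5, below the log2 cutoff
        assert cpm(np.array([[10]]), np.array([20e6]))[0, 0] == 0.5
        cm = CountMatrix(["g1", "g2"], ["s1", "s2"],
                         np.array([[10, 10], [20_000_000 - 10, 20_000_000 - 10]]))
        norm = getmm_log2cpm(cm, np.array([1000.0, 1000.0]))
        assert norm.log2cpm[0, 0] < 0

    def test_factors_geometric_mean_one(self, default_sim):
        norm = getmm_log2cpm(default_sim.counts, default_sim.lengths)
        assert np.exp(np.mean(np.log(norm.tmm_factors))) == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.isfinite(norm.log2cpm))

    def test_scale_invariance_with_vanishing_prior(self):
        rng = np.random.default_rng(11)
        counts = rng.negative_binomial(5, 0.1, (40, 3))
        counts[0] += 1
        cm = CountMatrix([f"g{i}" for i in range(40)], ["a", "b", "c"], counts)
        lengths = rng.integers(300, 3000, 40).astype(float)
        params = NormalizationParams(prior_count=1e-9)
        n1 = getmm_log2cpm(cm, lengths, params)
        # power-of-two depth factor: exact in floating point, so M/A values
        # and the TMM trim set are bit-identical
        scaled = counts.copy()
        scaled[:, 1] *= 8
        cm2 = CountMatrix(cm.gene_ids, cm.sample_ids, scaled)
        n2 = getmm_log2cpm(cm2, lengths, params)
        nz = counts[:, 1] > 0
        # the within-sample profile is exactly preserved; the absolute
        # level moves only through the (slightly depth-dependent) TMM
        # weights, a small uniform offset
        p1 = n1.log2cpm[nz, 1] - n1.log2cpm[nz, 1].mean()
        p2 = n2.log2cpm[nz, 1] - n2.log2cpm[nz, 1].mean()
        assert np.allclose(p1, p2, atol=1e-9)
        assert np.allclose(n1.log2cpm[nz, 1], n2.log2cpm[nz, 1], atol=0.05)

    def test_monotone_in_counts(self):
        rng = np.random.default_rng(13)
        counts = rng.negative_binomial(5, 0.05, (30, 4))
        counts[0] += 1
        lengths = rng.integers(300, 3000, 30).astype(float)
        cm = CountMatrix([f"g{i}" for i in range(30)], list("abcd"), counts)
        base = getmm_log2cpm(cm, lengths)
        bumped = counts.copy()
        bumped[3, 2] += 50
        cm2 = CountMatrix(cm.gene_ids, cm.sample_ids, bumped)
        after = getmm_log2cpm(cm2, lengths)
        assert after.log2cpm[3, 2] >= base.log2cpm[3, 2]

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_log2cpm_always_finite(self, seed):
        rng = np.random.default_rng(seed)
        cm, lengths = _random_cm(rng, 25, 3)
        norm = getmm_log2cpm(cm, lengths)
        assert np.all(np.isfinite(norm.log2cpm))


class TestLowCountFilter:
    def _cm(self, cpm_rows, libsize=1e6):
        # build counts whose CPM equal cpm_rows exactly via one filler gene
        counts = np.asarray(cpm_rows, dtype=np.int64)
        filler = (np.full(counts.shape[1], libsize, dtype=np.int64)
                  - counts.sum(axis=0))
        mat = np.vstack([counts, filler])
        ids = [f"g{i}" for i in range(counts.shape[0])] + ["filler"]
        return CountMatrix(ids, [f"s{j}" for j in range(counts.shape[1])], mat)

    def test_kept_above_threshold(self):
        row = [1 if i < 25 else 0 for i in range(30)]  # CPM 1.0 in 25 samples
        cm = self._cm([row])
        assert low_count_filter(cm, 0.5, 20)[0]

    def test_dropped_at_19_samples(self):
        row = [1 if i < 19 else 0 for i in range(30)]
        cm = self._cm([row])
        assert not low_count_filter(cm, 0.5, 20)[0]

    def test_all_zero_gene_dropped(self):
        cm = self._cm([[0] * 25])
        assert not low_count_filter(cm, 0.5, 20)[0]

    def test_min_samples_exceeds_samples_raises(self):
        cm = self._cm([[1, 1]])
        with pytest.raises(ValueError):
            low_count_filter(cm, 0.5, 3)


class TestParams:
    @pytest.mark.parametrize("kwargs", [
        {"trim_m": 0.5}, {"trim_a": -0.1}, {"prior_count": 0.0},
    ])
    def test_invalid_params(self, kwargs):
        with pytest.raises(ValueError):
            NormalizationParams(**kwargs)
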