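"""NGS screen: TPM, abundance filter, TMM, dispersion, NB exact test, BH."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import gammaln

from mirfingerprint.containers import CountMatrix
from mirfingerprint.screen import (
    bh_fdr,
    estimate_common_dispersion,
    filter_by_abundance,
    nb_exact_test,
    select_candidates,
    tmm_factors,
    tpm_normalize,
)
from mirfingerprint.synthetic import CountSimSpec, simulate_counts


def cm(data, columns=None):
    df = pd.DataFrame(data, columns=columns)
    df.index = [f"g{i}" for i in range(len(df))]
    return CountMatrix(df)


class TestTpm:
    def test_equal_split(self):
        tpm = tpm_normalize(cm({"a": [50, 50]}))
        assert np.allclose(tpm["a"], 5e5)

    def test_column_sums_are_1e6(self, count_matrix):
        tpm = tpm_normalize(count_matrix)
        assert np.allclose(tpm.sum(axis=0), 1e6)

    def test_million_library_fixed_point(self):
        tpm = tpm_normalize(cm({"a": [1, 999_999]}))
        assert tpm["a"].tolist() == [1.0, 999_999.0]

    def test_all_zero_sample_named(self):
        with pytest.raises(ValueError, match="b"):
            tpm_normalize(cm({"a": [1, 2], "b": [0, 0]}))


class TestAbundanceFilter:
    def test_threshold_zero_keeps_all(self, count_matrix):
        tpm = tpm_normalize(count_matrix)
        assert filter_by_abundance(tpm, 0.0) == count_matrix.genes

    def test_rules_differ_on_borderline_gene(self):
        tpm = pd.DataFrame({"s1": [0.5, 0.0], "s2": [1.6, 0.0]}, index=["g1", "g2"])
        assert filter_by_abundance(tpm, 1.0, "mean") == ["g1"]  # mean 1.05
        assert filter_by_abundance(tpm, 1.0, "all-samples") == []


def brute_force_tmm(df, ref, trim_m=0.30, trim_a=0.05):
    """Independent TMM oracle: explicit sort-based double trim + weighting."""
    libs = df.sum(axis=0).astype(float)
    logf = {}
    for s in df.columns:
        if s == ref:
            logf[s] = 0.0
            continue
        rows = []
        for g in df.index:
            yj, yr = df.loc[g, s], df.loc[g, ref]
            if yj > 0 and yr > 0:
                pj, pr = yj / libs[s], yr / libs[ref]
                m = np.log2(pj / pr)
                a = 0.5 * np.log2(pj * pr)
                v = (libs[s] - yj) / (libs[s] * yj) + (libs[ref] - yr) / (libs[ref] * yr)
                rows.append((g, m, a, v))
        n = len(rows)
        km, ka = int(np.floor(n * trim_m)), int(np.floor(n * trim_a))
        by_m = sorted(rows, key=lambda r: r[1])
        keep_m = {r[0] for r in by_m[km : n - km]}
        by_a = sorted(rows, key=lambda r: r[2])
        keep_a = {r[0] for r in by_a[ka : n - ka]}
        kept = [r for r in rows if r[0] in keep_m and r[0] in keep_a]
        num = sum(r[1] / r[3] for r in kept)
        den = sum(1.0 / r[3] for r in kept)
        logf[s] = num / den
    vals = pd.Series(logf)
    vals -= vals.mean()
    return np.exp2(vals)


class TestTmm:
    def test_identical_columns_give_unit_factors(self):
        col = np.arange(1, 21)
        factors = tmm_factors(cm({"a": col, "b": col, "c": col}))
        assert np.allclose(factors, 1.0)

    def test_scaled_column_absorbed_by_library_size(self):
        col = np.arange(1, 21)
        factors = tmm_factors(cm({"a": col, "b": 2 * col}))
        assert np.allclose(factors, 1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        base = rng.poisson(200, size=20)
        other = base.copy()
        other[:5] *= 4  # 5 of 20 genes 4-fold up in one sample
        df = pd.DataFrame({"a": base + 1, "b": other + 1, "c": rng.poisson(180, 20) + 1})
        df.index = [f"g{i}" for i in range(20)]
        factors = tmm_factors(CountMatrix(df), ref_sample="a")
        oracle = brute_force_tmm(df, ref="a")
        assert np.allclose(factors, oracle[factors.index], atol=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(scale=st.integers(min_value=2, max_value=12), seed=st.integers(0, 100))
    def test_invariant_to_column_scaling(self, scale, seed):
        """Multiplying a column by a constant leaves factors (nearly)
        unchanged: count fractions, hence M, A and the trim, are scale-free;
        only the precision-weight mixture (sample + reference terms) shifts,
        a second-order effect."""
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            rng.poisson(100, size=(30, 3)) + 1, columns=list("abc"),
            index=[f"g{i}" for i in range(30)],
        )
        f1 = tmm_factors(CountMatrix(df), ref_sample="a")
        scaled = df.copy()
        scaled["b"] = scaled["b"] * scale  # integer scale keeps counts exact
        f2 = tmm_factors(CountMatrix(scaled), ref_sample="a")
        assert np.allclose(f2, f1, atol=0.01)

    def test_needs_two_samples(self):
        with pytest.raises(ValueError):
            tmm_factors(cm({"a": [1, 2]}))


class TestDispersion:
    def test_poisson_data_gives_near_zero(self):
        cmx, _ = simulate_counts(
            CountSimSpec(n_genes=500, n_de=0, dispersion=0.0,
                         library_sizes=[5e4] * 20, seed=4),
            ["control"] * 10 + ["case"] * 10,
        )
        assert estimate_common_dispersion(cmx, ["control"] * 10 + ["case"] * 10) <= 0.05

    def test_recovers_true_dispersion(self):
        groups = ["control"] * 10 + ["case"] * 10
        cmx, _ = simulate_counts(
            CountSimSpec(n_genes=500, n_de=0, dispersion=0.4,
                         library_sizes=[5e4] * 20, seed=3),
            groups,
        )
        assert estimate_common_dispersion(cmx, groups) == pytest.approx(0.4, abs=0.1)

    def test_row_replication_leaves_estimate_unchanged(self):
        row = [13, 5, 20, 11, 9, 16]
        groups = ["control"] * 3 + ["case"] * 3
        one = cm([row])
        many = cm([row] * 8)
        assert estimate_common_dispersion(one, groups) == pytest.approx(
            estimate_common_dispersion(many, groups), abs=1e-6
        )

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            estimate_common_dispersion(cm({"a": [0, 0], "b": [0, 0]}), ["control", "case"])


def enumerate_exact_p(s1, s2, n1, n2, phi):
    """Enumeration oracle: conditional split probabilities from raw NB pmfs."""
    total = s1 + s2

    def log_nb(x, n, mu):
        if phi == 0:
            return x * np.log(n * mu) - n * mu - gammaln(x + 1)
        r = n / phi
        m = n * mu
        return (
            gammaln(x + r) - gammaln(r) - gammaln(x + 1)
            + x * np.log(m / (m + r)) + r * np.log(r / (m + r))
        )

    mu = total / (n1 + n2)
    logs = np.array([log_nb(s, n1, mu) + log_nb(total - s, n2, mu) for s in range(total + 1)])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    obs = probs[s1]
    return float(probs[probs <= obs * (1 + 1e-9)].sum())


class TestNbExactTest:
    def test_equal_split_is_p_one(self):
        counts = cm({"a": [10], "b": [10]})
        p = nb_exact_test(counts, ["control", "case"], 0.1)
        assert p["g0"] == pytest.approx(1.0)

    def test_binomial_limit_extreme_split(self):
        # equalized libraries, phi=0, total 10 split 0|10 -> 2 * (1/2)^10
        counts = cm({"a": [0, 990], "b": [10, 980]})
        p = nb_exact_test(counts, ["control", "case"], 0.0)
        assert p["g0"] == pytest.approx(2 * 0.5**10, rel=1e-9)

    @pytest.mark.parametrize("phi", [0.0, 0.1, 0.5])
    def test_matches_enumeration_oracle(self, phi):
        rng = np.random.default_rng(0)
        genes = rng.integers(0, 26, size=(12, 2))  # totals <= 50
        pad = 2000 - genes.sum(axis=0)  # equalize the two libraries
        data = np.vstack([genes, pad])
        counts = cm({"a": data[:, 0], "b": data[:, 1]})
        p = nb_exact_test(counts, ["control", "case"], phi)
        for i, (s1, s2) in enumerate(genes):
            oracle = enumerate_exact_p(int(s1), int(s2), 1, 1, phi)
            assert p[f"g{i}"] == pytest.approx(oracle, abs=1e-12)

    def test_rejects_more_than_two_groups(self):
        with pytest.raises(ValueError, match="2 groups"):
            nb_exact_test(cm({"a": [1], "b": [2], "c": [3]}), ["x", "y", "z"], 0.1)

    def test_type_one_error_calibrated_on_null(self):
        groups = ["control"] * 10 + ["case"] * 10
        cmx, _ = simulate_counts(
            CountSimSpec(n_genes=2000, n_de=0, dispersion=0.15,
                         library_sizes=[4e4] * 20, seed=8),
            groups,
        )
        phi = estimate_common_dispersion(cmx, groups)
        p = nb_exact_test(cmx, groups, phi)
        assert (p < 0.05).mean() == pytest.approx(0.05, abs=0.01)


class TestBh:
    def test_hand_computed_example(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_all_ones(self):
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_q_dominates_p_and_is_monotone_in_sorted_p(self, pvals):
        q = bh_fdr(pvals)
        assert np.all(q >= np.asarray(pvals) - 1e-12)
        assert np.all(q <= 1.0 + 1e-12)
        order = np.argsort(pvals)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestSelectCandidates:
    def make(self, pmap):
        return pd.DataFrame(
            {"gene": list(pmap), "p": list(pmap.values())}
        )

    def test_empty_when_nothing_significant(self):
        assert select_candidates(self.make({"g1": 0.2}), 0.05) == []

    def test_whitelist_requires_detection(self):
        out = select_candidates(self.make({"g1": 0.2}), 0.05, whitelist=["zz"])
        assert out == []

    def test_significant_then_whitelist_order(self):
        out = select_candidates(
            self.make({"g1": 0.01, "g2": 0.2}), 0.05, whitelist=["g2"]
        )
        assert out == ["g1", "g2"]
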