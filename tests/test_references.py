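"""NormFinder-style stability ranking and geNorm pairwise variation."""

import numpy as np
import pandas as pd
import pytest

from mirfingerprint.references import (
    genorm_pairwise_variation,
    normfinder_stability,
    select_reference_genes,
)
from mirfingerprint.synthetic import SimulationSpec, simulate_qpcr_cohort


def direct_stability(data: pd.DataFrame, groups):
    """Independent step-by-step evaluation of the stability definition."""
    centered = data - data.mean(axis=0)
    labels = list(dict.fromkeys(groups))
    garr = np.asarray(groups)
    rho = {}
    for gene in data.index:
        terms = []
        mus = {g: centered.loc[gene, garr == g].mean() for g in labels}
        grand = np.mean(list(mus.values()))
        for g in labels:
            vals = centered.loc[gene, garr == g]
            terms.append(abs(mus[g] - grand) + vals.std(ddof=1) / np.sqrt(len(vals)))
        rho[gene] = np.mean(terms)
    return pd.Series(rho)


@pytest.fixture
def three_gene_table():
    # 3 genes, 2 groups of 2 samples, hand-enterable values
    data = pd.DataFrame(
        {
            "c1": [20.0, 24.0, 28.0],
            "c2": [20.4, 24.2, 27.8],
            "k1": [20.1, 24.9, 28.1],
            "k2": [20.3, 24.7, 27.7],
        },
        index=["gA", "gB", "gC"],
    )
    groups = ["control", "control", "case", "case"]
    return data, groups


class TestNormfinder:
    def test_matches_direct_formula(self, three_gene_table):
        data, groups = three_gene_table
        table = normfinder_stability(data, groups).table
        oracle = direct_stability(data, groups)
        assert np.allclose(table["rho"], oracle[table.index], atol=1e-12)

    def test_constant_gene_ranks_first_with_zero_rho(self):
        rng = np.random.default_rng(1)
        data = pd.DataFrame(
            rng.normal(24, 0.5, size=(3, 8)), index=["noisy1", "noisy2", "flat"],
            columns=[f"s{i}" for i in range(8)],
        )
        data.loc["flat"] = 22.0
        groups = ["control"] * 4 + ["case"] * 4
        table = normfinder_stability(data, groups).table
        # the flat gene picks up 1/3 of the others' noise through sample
        # centering, but still ranks best
        assert table.loc["flat", "rank"] == 1

    def test_group_offset_raises_rho_by_predicted_amount(self, three_gene_table):
        data, groups = three_gene_table
        base = normfinder_stability(data, groups).table["rho"]
        delta = 2.0
        bumped = data.copy()
        case_cols = ["k1", "k2"]
        bumped.loc["gB", case_cols] += delta
        after = normfinder_stability(bumped, groups).table["rho"]
        oracle = direct_stability(bumped, groups)
        assert np.allclose(after, oracle[after.index], atol=1e-12)
        # sample centering spreads the offset over the K genes and the grand
        # mean splits it over the 2 groups: rho grows by delta * (1 - 1/K) / 2
        k = data.shape[0]
        assert after["gB"] - base["gB"] == pytest.approx(delta * (1 - 1 / k) / 2, abs=1e-9)

    def test_invariant_to_per_sample_shift(self, three_gene_table):
        data, groups = three_gene_table
        shifted = data + pd.Series({"c1": 1.0, "c2": -2.0, "k1": 0.5, "k2": 3.0})
        a = normfinder_stability(data, groups).table["rho"]
        b = normfinder_stability(shifted, groups).table["rho"]
        assert np.allclose(a, b, atol=1e-12)

    def test_single_group_reduces_to_standard_error(self):
        rng = np.random.default_rng(0)
        data = pd.DataFrame(rng.normal(24, 1, size=(3, 6)), index=list("abc"),
                            columns=[f"s{i}" for i in range(6)])
        table = normfinder_stability(data, ["g1"] * 6).table
        centered = data - data.mean(axis=0)
        se = centered.std(axis=1, ddof=1) / np.sqrt(6)
        assert np.allclose(table["rho"], se[table.index], atol=1e-12)

    def test_requires_three_candidates(self):
        data = pd.DataFrame(np.ones((2, 4)), index=["a", "b"],
                            columns=list("wxyz"))
        with pytest.raises(ValueError, match="3"):
            normfinder_stability(data, ["control", "control", "case", "case"])

    def test_destabilized_gene_ranked_last_across_seeds(self):
        """A reference gene with 5x noise lands last in >= 95/100 seeds."""
        last = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            data = pd.DataFrame(
                rng.normal(0, 0.1, size=(4, 20)),
                index=["r1", "r2", "r3", "bad"],
                columns=[f"s{i}" for i in range(20)],
            ) + 24.0
            data.loc["bad"] += rng.normal(0, 0.4, size=20)  # extra noise on top
            groups = ["control"] * 10 + ["case"] * 10
            table = normfinder_stability(data, groups).table
            last += table.loc["bad", "rank"] == 4
        assert last >= 95


class TestGenorm:
    def test_redundant_gene_gives_zero_v(self):
        samples = [f"s{i}" for i in range(5)]
        rng = np.random.default_rng(2)
        g = rng.normal(24, 1, size=5)
        data = pd.DataFrame(
            [g, g + 1.0, g - 0.5, g + 0.25], index=["a", "b", "c", "d"], columns=samples
        )
        pv = genorm_pairwise_variation(data, ["a", "b", "c", "d"])
        # every gene equals the profile up to a constant -> all V are 0
        assert np.allclose(pv.v, 0.0, atol=1e-12)

    def test_two_point_sample_sd(self):
        # NF3 - NF4 differences {0.1, 0.3} -> V = sd(n-1) = 0.1414...
        data = pd.DataFrame(np.zeros((4, 2)), index=list("abcd"), columns=["s1", "s2"])
        data.loc["d"] = [-0.4, -1.2]
        pv = genorm_pairwise_variation(data, list("abcd"))
        assert pv[3] == pytest.approx(np.std([0.1, 0.3], ddof=1))

    def test_sample_shift_cancels(self):
        rng = np.random.default_rng(3)
        data = pd.DataFrame(rng.normal(24, 1, size=(4, 6)), index=list("abcd"),
                            columns=[f"s{i}" for i in range(6)])
        shifted = data + rng.normal(0, 2, size=6)
        a = genorm_pairwise_variation(data, list("abcd")).v
        b = genorm_pairwise_variation(shifted, list("abcd")).v
        assert np.allclose(a, b, atol=1e-12)

    def test_missing_ct_drops_sample_and_reports(self):
        data = pd.DataFrame(np.ones((3, 4)), index=list("abc"),
                            columns=["s1", "s2", "s3", "s4"])
        data.loc["a", "s3"] = np.nan
        pv = genorm_pairwise_variation(data, list("abc"))
        assert pv.dropped_samples == ["s3"]


class TestSelection:
    def make_stability(self, order):
        table = pd.DataFrame(
            {"rho": np.arange(len(order), dtype=float)}, index=order
        )
        table["rank"] = np.arange(1, len(order) + 1)
        from mirfingerprint.references import StabilityTable
        return StabilityTable(table)

    def test_low_v_stops_at_three(self):
        samples = [f"s{i}" for i in range(6)]
        rng = np.random.default_rng(4)
        g = rng.normal(24, 1, size=6)
        # four near-redundant genes: V(3,4) ~ 0 < 0.05
        data = pd.DataFrame([g, g + 1, g - 1, g + 0.5], index=list("abcd"), columns=samples)
        st = self.make_stability(list("abcd"))
        assert select_reference_genes(st, data, v_threshold=0.05) == ["a", "b", "c"]

    def test_high_v_adds_fourth_gene(self):
        samples = [f"s{i}" for i in range(6)]
        rng = np.random.default_rng(5)
        g = rng.normal(24, 1, size=6)
        data = pd.DataFrame(
            [g, g + 1, g - 1, g + rng.normal(0, 1.5, 6), g + 0.1],
            index=list("abcde"), columns=samples,
        )
        # gene d disagrees -> V(3,4) large; gene e redundant -> V(4,5) ~ sd/20
        st = self.make_stability(list("abcde"))
        selected = select_reference_genes(st, data, v_threshold=0.05)
        assert selected[:3] == ["a", "b", "c"] and len(selected) >= 4

    def test_exactly_three_candidates_returned_regardless(self):
        samples = [f"s{i}" for i in range(4)]
        rng = np.random.default_rng(6)
        data = pd.DataFrame(rng.normal(24, 2, size=(3, 4)), index=list("abc"),
                            columns=samples)
        st = self.make_stability(list("abc"))
        assert select_reference_genes(st, data) == ["a", "b", "c"]


def test_default_simulation_selects_three_references():
    """Four equally stable candidates: V(3,4) < 0.05, so three are kept."""
    spec = SimulationSpec(seed=17)
    ct, sheet, _ = simulate_qpcr_cohort(spec, "1")
    groups = list(sheet.groups_for(ct.samples))
    cand = ct.ct.loc[ct.reference_candidates]
    st = normfinder_stability(cand, groups)
    selected = select_reference_genes(st, cand)
    assert len(selected) == 3
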