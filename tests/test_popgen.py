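"""D / f4 statistics, jackknife, pseudo-haploid and diploid calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from refbias import (
    GenotypeTable,
    SNPPanel,
    SNPRecord,
    d_statistic,
    f4_ratio,
    f4_statistic,
    naive_diploid_call,
    pseudo_haploid_sample,
    stratified_d,
    weighted_block_jackknife,
)
from refbias.bias_metrics import PileupObservation, PileupSite
from refbias.popgen import genotype_table_from_columns
from refbias.simulate import simulate_admixture_table

NUM = ("Target", "Mbuti", "Nea1", "Outgroup")
DEN = ("Nea2", "Mbuti", "Nea1", "Outgroup")


def random_table(n, pops="WXYZ", seed=0, haploid=False, spacing=500_000):
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame(
        {"chrom": "chr1", "pos": spacing * (np.arange(n, dtype=np.int64) + 1)}
    )
    for p in pops:
        vals = (
            rng.integers(0, 2, n).astype(float) if haploid else rng.random(n)
        )
        frame[p] = vals
    return GenotypeTable(frame)


def brute_force_d(frame, w, x, y, z):
    num = den = 0.0
    for _, r in frame.iterrows():
        num += (r[w] - r[x]) * (r[y] - r[z])
        den += (r[w] + r[x] - 2 * r[w] * r[x]) * (r[y] + r[z] - 2 * r[y] * r[z])
    return num / den


class TestDStatistic:
    def test_identical_y_z_columns_give_exact_zero(self):
        table = random_table(1000, haploid=True, seed=3)
        frame = table.frame.copy()
        frame["Y2"] = frame["Y"]
        res = d_statistic(GenotypeTable(frame), "W", "X", "Y", "Y2")
        assert res.d == 0.0
        assert res.se == 0.0
        assert res.z is None

    def test_single_fixed_difference_site(self):
        frame = pd.DataFrame(
            {"chrom": ["chr1"], "pos": [100], "W": [0.0], "X": [1.0], "Y": [1.0], "Z": [0.0]}
        )
        res = d_statistic(GenotypeTable(frame), "W", "X", "Y", "Z")
        assert res.d == -1.0

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_brute_force_summation(self, seed):
        table = random_table(1000, seed=seed)
        res = d_statistic(table, "W", "X", "Y", "Z")
        assert res.d == pytest.approx(
            brute_force_d(table.frame, "W", "X", "Y", "Z"), abs=1e-12
        )

    @given(st.integers(0, 10_000))
    @settings(deadline=None, max_examples=25)
    def test_antisymmetry(self, seed):
        table = random_table(60, seed=seed)
        d1 = d_statistic(table, "W", "X", "Y", "Z").d
        assert d_statistic(table, "W", "X", "Z", "Y").d == pytest.approx(-d1, abs=1e-12)
        assert d_statistic(table, "X", "W", "Y", "Z").d == pytest.approx(-d1, abs=1e-12)
        assert abs(d1) <= 1.0

    def test_missing_sites_are_complete_case(self):
        table = random_table(50, seed=9)
        frame = table.frame.copy()
        frame.loc[10:20, "X"] = np.nan
        res = d_statistic(GenotypeTable(frame), "W", "X", "Y", "Z")
        kept = frame.dropna()
        assert res.d == pytest.approx(
            brute_force_d(kept, "W", "X", "Y", "Z"), abs=1e-12
        )

    def test_all_missing_errors(self):
        frame = pd.DataFrame(
            {"chrom": ["chr1"], "pos": [1], "W": [np.nan], "X": [0.5], "Y": [0.5], "Z": [0.5]}
        )
        with pytest.raises(ValueError, match="non-missing"):
            d_statistic(GenotypeTable(frame), "W", "X", "Y", "Z")


class TestF4:
    def test_identical_a_b_is_zero(self):
        table = random_table(100, seed=2)
        frame = table.frame.copy()
        frame["W2"] = frame["W"]
        assert f4_statistic(GenotypeTable(frame), "W", "W2", "Y", "Z").f4 == 0.0

    def test_antisymmetry(self):
        table = random_table(100, seed=4)
        f1 = f4_statistic(table, "W", "X", "Y", "Z").f4
        f2 = f4_statistic(table, "X", "W", "Y", "Z").f4
        assert f2 == pytest.approx(-f1, abs=1e-15)

    def test_matches_brute_force_mean(self):
        table = random_table(50, seed=5)
        res = f4_statistic(table, "W", "X", "Y", "Z")
        expected = np.mean(
            [
                (r.W - r.X) * (r.Y - r.Z)
                for _, r in table.frame.iterrows()
            ]
        )
        assert res.f4 == pytest.approx(expected, abs=1e-12)


class TestWeightedJackknife:
    def test_constant_blocks_zero_se(self):
        assert weighted_block_jackknife(0.4, [0.4, 0.4, 0.4], [5, 3, 2]) == 0.0

    def test_equal_weights_reduce_to_delete_one(self):
        theta, tm = 0.3, np.array([0.28, 0.31, 0.33, 0.29])
        g = len(tm)
        pseudo = g * theta - (g - 1) * tm
        expected = np.sqrt(np.sum((pseudo - pseudo.mean()) ** 2) / (g * (g - 1)))
        assert weighted_block_jackknife(theta, tm, np.ones(g)) == pytest.approx(
            expected, abs=1e-14
        )

    def test_four_block_toy_matches_direct_formula(self):
        theta = 0.5
        tm = np.array([0.45, 0.52, 0.55, 0.48])
        m = np.array([10.0, 20.0, 30.0, 40.0])
        n = m.sum()
        g = 4
        h = n / m
        theta_j = g * theta - np.sum((1 - m / n) * tm)
        var = np.sum((h * theta - (h - 1) * tm - theta_j) ** 2 / (h - 1)) / g
        assert weighted_block_jackknife(theta, tm, m) == pytest.approx(
            np.sqrt(var), abs=1e-14
        )

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            weighted_block_jackknife(0.1, [0.1], [5])
        with pytest.raises(ValueError):
            weighted_block_jackknife(0.1, [0.1, 0.2], [5, 0])

    def test_jackknife_se_calibrated_on_iid_sites(self):
        """Across replicates of an i.i.d.-site table, the spread of D
        should match the mean jackknife SE to within 20%."""
        ds, ses = [], []
        for rep in range(200):
            table = random_table(1000, seed=10_000 + rep, haploid=True, spacing=100_000)
            res = d_statistic(table, "W", "X", "Y", "Z")
            ds.append(res.d)
            ses.append(res.se)
        emp_sd = np.std(ds, ddof=1)
        mean_se = np.mean(ses)
        assert abs(emp_sd - mean_se) / mean_se < 0.2


class TestF4Ratio:
    def test_target_equals_numerator_source(self):
        table = random_table(200, pops=list("ABCD"), seed=6)
        frame = table.frame.copy()
        frame["T"] = frame["A"]
        t = GenotypeTable(frame)
        res = f4_ratio(t, ("T", "B", "C", "D"), ("A", "B", "C", "D"))
        assert res.alpha == pytest.approx(1.0, abs=1e-12)

    def test_target_equals_reference_population(self):
        table = random_table(200, pops=list("ABCD"), seed=7)
        frame = table.frame.copy()
        frame["T"] = frame["B"]
        t = GenotypeTable(frame)
        res = f4_ratio(t, ("T", "B", "C", "D"), ("A", "B", "C", "D"))
        assert res.alpha == pytest.approx(0.0, abs=1e-12)

    def test_zero_denominator_errors(self):
        frame = pd.DataFrame(
            {"chrom": ["chr1"], "pos": [1], "A": [0.5], "B": [0.5], "C": [0.2], "D": [0.1], "T": [0.4]}
        )
        with pytest.raises(ValueError, match="denominator"):
            f4_ratio(GenotypeTable(frame), ("T", "B", "C", "D"), ("A", "B", "C", "D"))

    @pytest.mark.parametrize("alpha", [0.0, 1.0])
    def test_recovery_at_extremes(self, alpha):
        table = simulate_admixture_table(30_000, alpha, seed=13)
        res = f4_ratio(table, NUM, DEN)
        assert res.alpha == pytest.approx(alpha, abs=3 * res.se + 0.02)


def pile_site(pos, n_ref, n_alt, ancestry=None):
    rec = SNPRecord("chr1", pos, "A", "T", ancestry=ancestry)
    obs = [
        PileupObservation(f"r{i}", "ref", 40, 37, 50) for i in range(n_ref)
    ] + [
        PileupObservation(f"a{i}", "alt", 40, 37, 50) for i in range(n_alt)
    ]
    return PileupSite(rec, obs)


class TestCalls:
    def test_single_read_pseudo_haploid(self):
        calls = pseudo_haploid_sample([pile_site(10, 1, 0)], seed=0)
        assert calls.iloc[0] == 0.0

    def test_majority_mode(self):
        calls = pseudo_haploid_sample(
            [pile_site(10, 3, 7)], mode="majority", seed=0
        )
        assert calls.iloc[0] == 1.0

    def test_no_observations_missing(self):
        calls = pseudo_haploid_sample([pile_site(10, 0, 0)], seed=0)
        assert np.isnan(calls.iloc[0])

    def test_random_sampling_matches_binomial_oracle(self):
        sites = [pile_site(10 * (i + 1), 5, 5) for i in range(1000)]
        calls = pseudo_haploid_sample(sites, mode="random", seed=12)
        mean = calls.mean()
        se = np.sqrt(0.25 / 1000)
        assert abs(mean - 0.5) < 3 * se

    @pytest.mark.parametrize(
        "n_ref,n_alt,expected",
        [(5, 5, 0.5), (10, 0, 0.0), (0, 10, 1.0), (2, 8, 1.0)],
    )
    def test_naive_diploid_calls(self, n_ref, n_alt, expected):
        assert naive_diploid_call(pile_site(10, n_ref, n_alt)) == expected

    def test_naive_diploid_low_depth_missing(self):
        assert np.isnan(naive_diploid_call(pile_site(10, 5, 4)))


class TestStratifiedD:
    def test_single_stratum_equals_unstratified(self):
        table = random_table(100, seed=20)
        panel = SNPPanel(
            [
                SNPRecord("chr1", int(p), "A", "T", ancestry="African")
                for p in table.frame["pos"]
            ]
        )
        res = stratified_d(table, "W", "X", "Y", "Z", panel)
        full = d_statistic(table, "W", "X", "Y", "Z")
        assert res["African"].d == pytest.approx(full.d, abs=1e-15)

    def test_bias_confined_to_one_stratum(self):
        """Inject allele sharing between X and Y only at European-labeled
        sites; |D| there should exceed the African stratum's."""
        rng = np.random.default_rng(33)
        n = 4000
        pos = 2000 * (np.arange(n) + 1)
        labels = np.where(np.arange(n) % 2 == 0, "European", "African")
        w = rng.integers(0, 2, n).astype(float)
        x = rng.integers(0, 2, n).astype(float)
        y = rng.integers(0, 2, n).astype(float)
        z = rng.integers(0, 2, n).astype(float)
        euro = labels == "European"
        copy_mask = euro & (rng.random(n) < 0.4)
        y[copy_mask] = x[copy_mask]  # excess X-Y sharing in one stratum
        frame = pd.DataFrame(
            {"chrom": "chr1", "pos": pos, "W": w, "X": x, "Y": y, "Z": z}
        )
        panel = SNPPanel(
            [
                SNPRecord("chr1", int(p), "A", "T", ancestry=lab)
                for p, lab in zip(pos, labels)
            ]
        )
        res = stratified_d(GenotypeTable(frame), "W", "X", "Y", "Z", panel)
        assert abs(res["European"].d) > abs(res["African"].d)
        assert res["European"].d < 0  # X shares with Y => negative

    def test_empty_stratum_reported_missing(self):
        table = random_table(10, seed=21)
        panel = SNPPanel(
            [SNPRecord("chr1", 999_999_999, "A", "T", ancestry="EastAsian")]
            + [
                SNPRecord("chr1", int(p), "A", "T", ancestry="African")
                for p in table.frame["pos"]
            ]
        )
        res = stratified_d(table, "W", "X", "Y", "Z", panel)
        assert res["EastAsian"] is None


def test_genotype_table_validation():
    with pytest.raises(ValueError, match="sorted"):
        GenotypeTable(
            pd.DataFrame({"chrom": ["1", "1"], "pos": [20, 10], "A": [0.0, 1.0]})
        )
    with pytest.raises(ValueError, match="duplicate"):
        GenotypeTable(
            pd.DataFrame({"chrom": ["1", "1"], "pos": [10, 10], "A": [0.0, 1.0]})
        )
    with pytest.raises(ValueError):
        GenotypeTable(
            pd.DataFrame({"chrom": ["1"], "pos": [10], "A": [1.5]})
        )


def test_eigenstrat_round_trip(tmp_path):
    (tmp_path / "t.snp").write_text(
        "rs1 1 0.0 100 A T\nrs2 1 0.0 200 G C\nrs3 1 0.0 300 C A\n"
    )
    (tmp_path / "t.ind").write_text(
        "ind1 M PopA\nind2 F PopA\nind3 M PopB\n"
    )
    # rows are sites, columns individuals; digits count ref-allele copies
    (tmp_path / "t.geno").write_text("022\n910\n201\n")
    table = GenotypeTable.from_eigenstrat(
        tmp_path / "t.geno", tmp_path / "t.snp", tmp_path / "t.ind"
    )
    assert table.populations == ["PopA", "PopB"]
    popa = table.freqs("PopA")
    popb = table.freqs("PopB")
    # site 1: ind1 g=0 -> alt freq 1.0, ind2 g=2 -> 0.0 => mean 0.5
    assert popa[0] == pytest.approx(0.5)
    assert popb[0] == pytest.approx(0.0)
    # site 2: ind1 missing, ind2 g=1 -> 0.5
    assert popa[1] == pytest.approx(0.5)
    assert popb[1] == pytest.approx(1.0)


def test_genotype_table_from_columns():
    s1 = pd.Series(
        [0.0, 1.0],
        index=pd.MultiIndex.from_tuples([("chr1", 10), ("chr1", 20)]),
    )
    s2 = pd.Series(
        [1.0, 0.5],
        index=pd.MultiIndex.from_tuples([("chr1", 10), ("chr1", 20)]),
    )
    table = genotype_table_from_columns({"A": s1, "B": s2})
    assert table.populations == ["A", "B"]
    assert list(table.freqs("B")) == [1.0, 0.5]
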