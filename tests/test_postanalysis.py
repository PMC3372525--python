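import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import longsel as ls
from longsel.postanalysis import CompositionTable, rolling_median_p_frame
from naive import naive_pearson_chisq


def fake_result(pvals, klasses=None, bvals=None, ref_len=None, alignment="a"):
    """Assemble a minimal ScanResult with given per-column p/b values."""
    n = len(pvals)
    klasses = klasses or ["fit"] * n
    bvals = bvals if bvals is not None else [1.0] * n
    records, fits = [], {}
    for i, (p, k, b) in enumerate(zip(pvals, klasses, bvals)):
        chars = {"ref": "Y", "x": "H", "y": "C", "z": "F"}
        records.append(ls.ColumnRecord(alignment, i, chars, "Y", k, i + 1))
        if k != "excluded":
            fits[(alignment, i)] = ls.ColumnFit(
                b if k == "fit" else 0.0,
                p if k == "fit" else 1.0,
                0.0, 1.0, 10,
            )
    return ls.ScanResult(records, fits, {alignment: ref_len or n},
                         ls.ScanConfig())


class TestPvalueHistogram:
    def test_point_mass_in_first_bin(self):
        res = fake_result([0.005] * 50)
        dens, edges = ls.pvalue_histogram(res, bins=10)
        assert dens[0] == pytest.approx(10.0)
        assert np.all(dens[1:] == 0.0)

    def test_normalization(self):
        rng = np.random.default_rng(0)
        res = fake_result(list(rng.random(500)))
        dens, edges = ls.pvalue_histogram(res, bins=17)
        assert np.sum(dens * np.diff(edges)) == pytest.approx(1.0)

    def test_uniform_pvalues_near_flat(self):
        rng = np.random.default_rng(1)
        res = fake_result(list(rng.random(10000)))
        dens, _ = ls.pvalue_histogram(res, bins=10)
        assert dens.max() / dens.min() < 1.5

    def test_only_positive_slopes_included(self):
        res = fake_result([0.001, 0.5], bvals=[1.0, -1.0])
        dens, edges = ls.pvalue_histogram(res, bins=2)
        # the b<0 column at p=0.5 must not appear
        assert dens[1] == 0.0

    def test_empty_subset_rejected(self):
        res = fake_result([0.5], bvals=[-1.0])
        with pytest.raises(ls.LongselError):
            ls.pvalue_histogram(res)


class TestCompositionChisq:
    def test_matching_proportions_give_zero(self):
        obs = CompositionTable(30, 30, 40)
        ref = CompositionTable(300, 300, 400)
        stat, df, p = ls.composition_chisq_gof(obs, ref)
        assert stat == pytest.approx(0.0)
        assert df == 2 and p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # equal reference thirds at n=100: (30,30,40) gives chi2 = 2 exactly
        obs = CompositionTable(30, 30, 40)
        ref = CompositionTable(1000, 1000, 1000)
        stat, df, _ = ls.composition_chisq_gof(obs, ref)
        assert stat == pytest.approx(2.0)

    @given(
        counts=st.tuples(*[st.integers(0, 500)] * 3).filter(lambda t: sum(t) > 0),
        ref=st.tuples(*[st.integers(1, 500)] * 3),
    )
    def test_matches_brute_force_pearson(self, counts, ref):
        obs = CompositionTable(*counts)
        reft = CompositionTable(*ref)
        stat, _, _ = ls.composition_chisq_gof(obs, reft)
        expected = [obs.total * r / reft.total for r in ref]
        assert stat == pytest.approx(naive_pearson_chisq(counts, expected))

    def test_contingency_variant(self):
        obs = CompositionTable(30, 30, 40)
        ref = CompositionTable(40, 30, 30)
        stat, df, p = ls.composition_chisq_gof(obs, ref, method="contingency")
        from scipy.stats import chi2_contingency

        expect = chi2_contingency([[30, 30, 40], [40, 30, 30]],
                                  correction=False)
        assert stat == pytest.approx(expect.statistic) and df == 2

    def test_zero_reference_cell_rejected(self):
        with pytest.raises(ls.LongselError):
            ls.composition_chisq_gof(CompositionTable(1, 1, 1),
                                     CompositionTable(5, 5, 0))


class TestDomainSummary:
    def domains(self):
        return [
            ls.DomainAnnotation("a", 2, 5, "kinase"),
            ls.DomainAnnotation("a", 7, 9, "tail"),
        ]

    def test_no_hits_empty(self):
        res = fake_result([0.9] * 10)
        assert ls.domain_summary(res, self.domains()) == []

    def test_counts_and_threshold(self):
        # significant columns at ref positions 2, 3, 8 -> kinase has 2, tail 1
        pv = [0.9] * 10
        pv[1] = pv[2] = pv[7] = 0.001
        res = fake_result(pv)
        out = ls.domain_summary(res, self.domains(), min_positions=2)
        assert len(out) == 1
        assert out[0].name == "kinase" and out[0].n_positions == 2
        assert out[0].positions == [2, 3]

    def test_order_invariance(self):
        pv = [0.001] * 10
        res = fake_result(pv)
        a = ls.domain_summary(res, self.domains())
        b = ls.domain_summary(res, list(reversed(self.domains())))
        assert [(d.name, d.n_positions) for d in a] == [
            (d.name, d.n_positions) for d in b
        ]

    def test_out_of_range_domain_rejected(self):
        res = fake_result([0.9] * 10)
        with pytest.raises(ls.LongselError, match="beyond"):
            ls.domain_summary(res, [ls.DomainAnnotation("a", 5, 40, "big")])

    def test_frame_variant_agrees(self):
        pv = [0.9] * 10
        pv[1] = pv[2] = pv[7] = 0.001
        res = fake_result(pv)
        from longsel.postanalysis import domain_summary_frame

        a = ls.domain_summary(res, self.domains(), min_positions=1)
        b = domain_summary_frame(res.to_frame(), self.domains(), min_positions=1)
        assert [(d.name, d.positions) for d in a] == [
            (d.name, d.positions) for d in b
        ]


class TestRollingMedian:
    def test_nine_selected_positions_no_window(self):
        res = fake_result([0.5] * 9)
        assert ls.rolling_median_p(res, "a") == []

    def test_single_window_all_ones(self):
        res = fake_result([1.0] * 10, klasses=["conserved"] * 10)
        assert ls.rolling_median_p(res, "a") == [(0, 1.0)]

    def test_three_windows_hand_medians(self):
        pv = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 0.05, 0.15]
        res = fake_result(pv)
        out = ls.rolling_median_p(res, "a")
        assert [c for c, _ in out] == [0, 1, 2]
        assert out[0][1] == pytest.approx(np.median(pv[0:10]))
        assert out[1][1] == pytest.approx(np.median(pv[1:11]))
        assert out[2][1] == pytest.approx(np.median(pv[2:12]))

    def test_excluded_breaks_runs(self):
        klasses = ["fit"] * 10 + ["excluded"] + ["fit"] * 10
        pv = [0.5] * 21
        res = fake_result(pv, klasses=klasses)
        out = ls.rolling_median_p(res, "a")
        starts = [c for c, _ in out]
        assert starts == [0, 11]  # one window per 10-run, none spanning col 10

    def test_frame_variant_agrees(self):
        pv = list(np.linspace(0.05, 0.95, 12))
        res = fake_result(pv)
        assert rolling_median_p_frame(res.to_frame(), "a") == \
            ls.rolling_median_p(res, "a")


class TestRegionResidueCount:
    def star(self, n=6):
        nwk = "(" + ",".join(f"t{i}:1" for i in range(n)) + ");"
        return ls.PhylogeneticTree.from_newick(nwk, "time")

    def test_count_is_plain_substring_count(self):
        msa = {f"t{i}": "ACCA" for i in range(6)}
        assert msa["t0"][0:4].count("C") == 2  # the response definition

    def test_identical_counts_degenerate(self):
        tree = self.star()
        species = sorted(tree.tip_labels())
        msa = {sp: "ACCA" for sp in species}
        traits = ls.TraitTable.from_dict(
            {sp: (3.0 + i, 100.0 + 17 * i) for i, sp in enumerate(species)}
        )
        fit = ls.region_residue_count_pgls(
            ls.AlignmentPanel({"a": msa}), "a", (0, 4), "C", traits, tree
        )
        assert fit.degenerate and fit.coef[1] == 0.0 and fit.pvalues[1] == 1.0

    def test_linear_counts_recover_slope(self):
        tree = self.star(8)
        species = sorted(tree.tip_labels())
        # counts = 2 * log10(MLS) exactly, with MLS = 10^(1..8)
        traits = ls.TraitTable.from_dict(
            {sp: (10.0 ** (i + 1), 100.0 + 13 * i)
             for i, sp in enumerate(species)}
        )
        msa = {
            sp: "C" * (2 * (i + 1)) + "A" * (16 - 2 * (i + 1))
            for i, sp in enumerate(species)
        }
        fit = ls.region_residue_count_pgls(
            ls.AlignmentPanel({"a": msa}), "a", (0, 16), "C", traits, tree
        )
        assert fit.coef[1] == pytest.approx(2.0, abs=1e-8)
        assert fit.pvalues[1] < 0.01

    def test_reference_included_in_fit(self):
        tree = self.star()
        species = sorted(tree.tip_labels())
        msa = {sp: "ACCA" for sp in species}
        traits = ls.TraitTable.from_dict(
            {sp: (3.0 + i, 100.0 + i) for i, sp in enumerate(species)},
            reference=species[0],
        )
        fit = ls.region_residue_count_pgls(
            ls.AlignmentPanel({"a": msa}), "a", (0, 4), "C", traits, tree
        )
        assert fit.n == len(species)

    def test_bad_range_rejected(self):
        tree = self.star()
        msa = {sp: "ACCA" for sp in sorted(tree.tip_labels())}
        traits = ls.TraitTable.from_dict(
            {sp: (3.0, 100.0) for sp in msa}
        )
        with pytest.raises(ls.LongselError):
            ls.region_residue_count_pgls(
                ls.AlignmentPanel({"a": msa}), "a", (2, 9), "C", traits, tree
            )
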