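"""TE statistics: definitions, normalization, ranges, enrichment, codons."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ribote.stats import (
    DEK_CODONS,
    codon_frequency,
    codon_set_comparison,
    compute_te,
    fold_range_table,
    group_comparison,
    normalize_fold_changes,
    overlap_enrichment,
    select_switchers,
    significance_tier,
    te_range,
)


def _table(fp_rpkm, mrna_rpkm):
    idx = pd.Index([f"g{i}" for i in range(len(fp_rpkm))], name="gene_id")
    return pd.DataFrame({"fp_rpkm": fp_rpkm, "mrna_rpkm": mrna_rpkm}, index=idx)


class TestTe:
    def test_definition(self):
        te = compute_te(_table([20.0, 5.0], [10.0, 5.0]))
        assert te.tolist() == [2.0, 1.0]

    def test_zero_mrna_errors(self):
        with pytest.raises(ValueError):
            compute_te(_table([1.0], [0.0]))


class TestNormalize:
    def test_median_one_unchanged(self):
        out = normalize_fold_changes([0.5, 1, 2])
        assert out.tolist() == [0.5, 1, 2]

    def test_rescaling(self):
        assert normalize_fold_changes([2, 4, 8]).tolist() == [0.5, 1, 2]

    def test_even_length_median_is_mean_of_middle_two(self):
        out = normalize_fold_changes([1, 2, 3, 4])
        np.testing.assert_allclose(out, [0.4, 0.8, 1.2, 1.6])

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            normalize_fold_changes([])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.01, 100.0), min_size=1, max_size=40))
    def test_median_exactly_one_and_idempotent(self, values):
        out = normalize_fold_changes(values)
        assert float(np.median(out)) == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(normalize_fold_changes(out), out, rtol=1e-12)


class TestTeRange:
    def test_examples(self):
        assert te_range([2, 4, 8]) == (0.25, 4.0)
        assert te_range([3, 3, 3]) == (1.0, 1.0)

    def test_single_timepoint_errors(self):
        with pytest.raises(ValueError):
            te_range([2.0])

    def test_rescaling_invariance(self):
        series = [1.0, 2.5, 0.7, 4.0]
        assert te_range(series)[1] == pytest.approx(te_range([7 * x for x in series])[1])

    def test_matrix_drops_sparse_genes(self):
        m = pd.DataFrame(
            {"t0": [1.0, 2.0, np.nan], "t1": [4.0, np.nan, np.nan]},
            index=["a", "b", "c"],
        )
        fr = fold_range_table(m)
        assert list(fr.index) == ["a"]
        assert fr.loc["a", "fold_range"] == 4.0


class TestSwitchers:
    def test_threshold_is_inclusive(self):
        fr = pd.Series({"a": 8.0, "b": 7.99, "c": 12.0})
        assert set(select_switchers(fr)) == {"a", "c"}

    def test_threshold_one_selects_everything(self):
        fr = pd.Series({"a": 1.0, "b": 3.0})
        assert set(select_switchers(fr, threshold=1)) == {"a", "b"}


class TestEnrichment:
    def test_exact_enumeration_small_universe(self):
        """All 5 flagged genes in a 5-gene intersection: p = 1/C(20,5)."""
        universe = [f"g{i}" for i in range(20)]
        flagged = universe[:5]
        res = overlap_enrichment(flagged, flagged, universe, flagged)
        assert res.p_value == pytest.approx(1 / comb(20, 5), rel=1e-9)

    def test_exhaustive_enumeration_oracle(self):
        """Upper-tail p equals direct enumeration over all draws (universe <= 25)."""
        universe = [f"g{i}" for i in range(18)]
        flagged = set(universe[:6])
        inter = universe[3:10]  # 3 flagged of 7 drawn
        res = overlap_enrichment(inter, inter, universe, flagged)
        k_obs = len(set(inter) & flagged)
        n, K, N = len(inter), len(flagged), len(universe)
        p_enum = sum(
            comb(K, k) * comb(N - K, n - k) for k in range(k_obs, min(K, n) + 1)
        ) / comb(N, n)
        assert res.p_value == pytest.approx(p_enum, rel=1e-12)

    def test_empty_intersection_p_one(self):
        universe = list("abcdefgh")
        res = overlap_enrichment(["a"], ["b"], universe, ["a", "b"])
        assert res.n_intersection == 0
        assert res.p_value == pytest.approx(1.0)

    def test_null_flag_frequency_not_enriched(self):
        universe = [f"g{i}" for i in range(20)]
        flagged = universe[::4]  # 25% flagged
        inter = [universe[0], universe[1], universe[2], universe[3]]  # 1 of 4 flagged
        res = overlap_enrichment(inter, inter, universe, flagged)
        assert 0.3 <= res.p_value <= 1.0

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError):
            overlap_enrichment([], [], [], [])


class TestGroupComparison:
    def _tables(self, ratios_ribi, n_other=60, seed=0):
        rng = np.random.default_rng(seed)
        ribi = [f"r{i}" for i in range(len(ratios_ribi))]
        other = [f"o{i}" for i in range(n_other)]
        idx = pd.Index(ribi + other, name="gene_id")
        base = pd.Series(rng.lognormal(2, 0.5, size=len(idx)), index=idx)
        ratio = pd.Series(
            np.concatenate([ratios_ribi, np.exp(rng.normal(0, 0.02, n_other))]), index=idx
        )
        minus = pd.DataFrame({"fp_rpkm": base, "mrna_rpkm": base})
        plus = pd.DataFrame({"fp_rpkm": base * ratio, "mrna_rpkm": base * ratio})
        return plus, minus, ribi

    def test_identical_distributions_are_ns(self):
        plus, minus, ribi = self._tables(np.ones(20))
        res, _ = group_comparison(plus, plus, {"ribi": ribi}, "mrna", "starved")
        two = [r for r in res if r.test == "two-sample"][0]
        assert two.tier == "NS"

    def test_threefold_ribi_shift_detected(self):
        jitter = np.exp(np.random.default_rng(1).normal(0, 0.02, 50))
        plus, minus, ribi = self._tables(3.0 * jitter)
        res, ratios = group_comparison(plus, minus, {"ribi": ribi}, "mrna", "starved")
        one = [r for r in res if r.label == "ribi" and r.test == "one-sample"][0]
        assert one.mean_log2_ratio == pytest.approx(np.log2(3), abs=0.1)
        assert one.p < 1e-2 and one.tier != "NS"

    def test_tier_mapping(self):
        assert significance_tier(1e-3) == "*"
        assert significance_tier(0.5) == "NS"
        assert significance_tier(1e-7) == "**"
        assert significance_tier(1e-12) == "***"
        assert significance_tier(1e-30) == "****"

    def test_small_set_errors(self):
        plus, minus, ribi = self._tables(np.ones(2))
        with pytest.raises(ValueError, match="fewer than 3"):
            group_comparison(plus, minus, {"ribi": ribi}, "mrna", "starved")


class TestCodons:
    def test_all_dek_codons(self):
        freqs = codon_frequency({"g": "GATGAAAAA"}, {"GAT", "GAA", "AAA"})
        assert freqs["g"] == 1.0

    def test_full_sense_set_gives_one(self):
        all_sense = {c for c in (a + b + d for a in "ACGT" for b in "ACGT" for d in "ACGT")
                     if c not in {"TAA", "TAG", "TGA"}}
        freqs = codon_frequency({"g": "ATGGCTTGTAAA"}, all_sense)
        assert freqs["g"] == 1.0

    def test_default_set_counts_dek_only(self):
        freqs = codon_frequency({"g": "ATGGAAGCT"})  # 1 of 3 codons in DEK set
        assert freqs["g"] == pytest.approx(1 / 3)

    def test_bad_sequences_rejected(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            codon_frequency({"g": "ATGNNA"})
        with pytest.raises(ValueError, match="multiple of 3"):
            codon_frequency({"g": "ATGA"})

    def test_simulated_bias_recovered(self):
        """Generator DEK bias minus background is recovered within 0.02."""
        from ribote.sim import SimulationConfig, build_toy_genome
        from ribote.sim.genome import cds_sequence

        cfg = SimulationConfig(n_genes=40, seed=5, frac_ribi=0.2, cds_length_range=(2700, 3300))
        genome, ann = build_toy_genome(cfg)
        freqs = codon_frequency({g.gene_id: cds_sequence(genome, g) for g in ann})
        comp = codon_set_comparison(freqs, ann.in_set("ribi"))
        expected = cfg.dek_codon_bias - cfg.background_dek_frequency
        assert comp["median_difference"] == pytest.approx(expected, abs=0.02)
        assert comp["p_value"] < 0.05
        assert DEK_CODONS == {"GAT", "GAC", "GAA", "GAG", "AAA", "AAG"}
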