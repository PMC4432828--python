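"""Genome-scale methylation metrics and differential-site calling."""

import numpy as np
import pandas as pd
import pytest

from bsmeth.genome import (
    annotate_sites,
    base_composition,
    c_count_summary,
    call_sites,
    composition_delta,
    differential_sites,
    extract_flanks,
    methylation_bin_profile,
)
from bsmeth.io import GenomicInterval, ReadRecord, SequenceRecord, ValidationError
from bsmeth.simulate import (
    ConversionSpec,
    MethylomeSpec,
    generate_reference,
    simulate_bisulfite_reads,
)

from .oracles import brute_force_gene_labels


def _truth(rows):
    return pd.DataFrame(rows, columns=["read_id", "chrom", "start", "end", "strand"])


class TestBaseComposition:
    def test_uniform(self):
        t = base_composition([SequenceRecord("s", "ACGT")])
        assert t.percentages == pytest.approx(
            {"A": 25, "C": 25, "G": 25, "T": 25, "N": 0}
        )

    def test_single_base(self):
        t = base_composition([SequenceRecord("s", "AAAA")])
        assert t.percentages["A"] == 100.0

    def test_percentages_sum_to_100(self, rng):
        seqs = ["".join(rng.choice(list("ACGTN"), 100)) for _ in range(5)]
        t = base_composition([SequenceRecord(f"s{i}", s) for i, s in enumerate(seqs)])
        assert sum(t.percentages.values()) == pytest.approx(100.0, abs=1e-6)

    def test_matches_position_tally_oracle(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 1000)) for _ in range(10)]
        t = base_composition(seqs)
        for base in "ACGT":
            expected = sum(s.count(base) for s in seqs)
            assert t.counts[base] == expected

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            base_composition([])


class TestCompositionDelta:
    def test_identical_tables(self):
        t = base_composition([SequenceRecord("s", "ACGT" * 100)])
        delta = composition_delta(t, t)
        acgt = delta[delta.base.isin(list("ACGT"))]
        assert acgt["ratio"].tolist() == pytest.approx([1.0] * 4)
        assert (acgt["chi2_p"] > 0.99).all()
        assert (acgt["fisher_p"] > 0.99).all()

    def test_c_excess_with_compensating_t(self):
        control = base_composition([SequenceRecord("c", "C" * 5000 + "T" * 5000)])
        treated = base_composition([SequenceRecord("t", "C" * 5500 + "T" * 4500)])
        delta = composition_delta(treated, control).set_index("base")
        assert delta.loc["C", "ratio"] == pytest.approx(1.1)
        assert delta.loc["T", "ratio"] < 1.0

    def test_zero_control_count_flagged(self):
        control = base_composition([SequenceRecord("c", "AATT")])
        treated = base_composition([SequenceRecord("t", "AACT")])
        delta = composition_delta(treated, control).set_index("base")
        assert delta.loc["C", "flagged_undefined"]
        assert np.isnan(delta.loc["C", "ratio"])


class TestCallSites:
    def test_two_c_one_t(self):
        ref = SequenceRecord("r", "AACAA")
        reads = [
            ReadRecord("a", "AACAA"),
            ReadRecord("b", "AACAA"),
            ReadRecord("c", "AATAA"),
        ]
        truth = _truth([(r.id, "r", 0, 5, "+") for r in reads])
        calls = call_sites(reads, truth, ref)
        assert len(calls) == 1
        row = calls.iloc[0]
        assert (row.pos, row.strand, row.n_meth, row.n_unmeth) == (2, "+", 2, 1)
        assert row.methylation_percent == pytest.approx(200 / 3)

    def test_uncovered_sites_absent(self):
        ref = SequenceRecord("r", "CCCCCCCC")
        reads = [ReadRecord("a", "TT")]
        calls = call_sites(reads, _truth([("a", "r", 0, 2, "+")]), ref)
        assert set(calls["pos"]) == {0, 1}

    def test_minus_strand_symmetry(self):
        # reference G at pos 1 is a minus-strand CpG cytosine (CG at 0-1)
        ref = SequenceRecord("r", "CGAAA")
        # minus-strand read over [0,5): reverse complement of ref is TTTCG;
        # retained minus C reads C at its position
        reads = [ReadRecord("a", "TTTCG")]
        calls = call_sites(reads, _truth([("a", "r", 0, 5, "-")]), ref)
        row = calls[(calls.pos == 1) & (calls.strand == "-")].iloc[0]
        assert row.n_meth == 1 and row.context == "CpG"

    def test_interval_outside_reference_raises(self):
        ref = SequenceRecord("r", "ACGT")
        with pytest.raises(ValidationError):
            call_sites(
                [ReadRecord("a", "ACGTA")], _truth([("a", "r", 0, 5, "+")]), ref
            )

    def test_mean_methylation_matches_closed_form(self):
        # p_cpg=0.7 with u=0.02: expected mean CpG methylation is
        # 100*(0.7 + 0.3*0.02) = 70.6%
        ref = generate_reference(20_000, seed=5)
        reads, truth = simulate_bisulfite_reads(
            ref, MethylomeSpec(0.7, 0, 0), ConversionSpec(0.02), 20_000, 100,
            seed=6,
        )
        calls = call_sites(reads, truth, ref)
        cpg = calls[calls.context == "CpG"]
        assert cpg["methylation_percent"].mean() == pytest.approx(70.6, abs=1.5)


class TestCCountSummary:
    def _calls(self, n_meth, n_unmeth):
        return pd.DataFrame(
            {
                "chrom": ["r"], "pos": [0], "strand": ["+"], "context": ["CpG"],
                "n_meth": [n_meth], "n_unmeth": [n_unmeth],
                "methylation_percent": [100 * n_meth / (n_meth + n_unmeth)],
            }
        )

    def test_ratio_arithmetic(self):
        s = c_count_summary(self._calls(96, 4), total_bases=1000)
        assert s["meth_unmeth_ratio"] == pytest.approx(24.0)
        assert s["methylated_c_percent"] == pytest.approx(9.6)

    def test_zero_methylated(self):
        assert c_count_summary(self._calls(0, 10), 100)["meth_unmeth_ratio"] == 0.0

    def test_zero_unmethylated_flagged_infinite(self):
        s = c_count_summary(self._calls(10, 0), 100)
        assert s["meth_unmeth_ratio"] == float("inf")
        assert s["ratio_flagged_infinite"]

    def test_ratio_recovers_bernoulli_odds(self):
        # p_cpg=0.9615 with u~0 at deep coverage: ratio -> p/(1-p) = 24.97
        p = 0.9615
        ref = generate_reference(4000, seed=7)
        reads, truth = simulate_bisulfite_reads(
            ref, MethylomeSpec(p, 0, 0), ConversionSpec(0.0), 8000, 100, seed=8
        )
        calls = call_sites(reads, truth, ref)
        s = c_count_summary(calls, total_bases=8000 * 100)
        expected = p / (1 - p)
        assert abs(s["meth_unmeth_ratio"] - expected) / expected < 0.10

    def test_invariant_to_read_order(self):
        ref = generate_reference(3000, seed=9)
        reads, truth = simulate_bisulfite_reads(
            ref, MethylomeSpec(0.5), ConversionSpec(0.05), 500, 80, seed=10
        )
        total = 500 * 80
        a = c_count_summary(call_sites(reads, truth, ref), total)
        b = c_count_summary(call_sites(reads[::-1], truth, ref), total)
        assert a == b


class TestBinProfile:
    def _calls(self, pcts):
        return pd.DataFrame(
            {
                "chrom": "r", "pos": range(len(pcts)), "strand": "+",
                "context": "CpG", "n_meth": 1, "n_unmeth": 0,
                "methylation_percent": pcts,
            }
        )

    def test_sites_land_in_their_bins(self):
        prof = methylation_bin_profile(self._calls([5.0, 15.0, 95.0]))
        assert prof.loc[0, "n_sites"] == 1
        assert prof.loc[1, "n_sites"] == 1
        assert prof.loc[9, "n_sites"] == 1

    def test_last_bin_closed_at_100(self):
        prof = methylation_bin_profile(self._calls([100.0, 100.0]))
        assert prof.loc[9, "n_sites"] == 2

    def test_bin_width_must_divide_100(self):
        with pytest.raises(ValueError):
            methylation_bin_profile(self._calls([50.0]), bin_width=7)

    def test_shift_concentrated_in_high_bins(self):
        # raising p_cpg 0.75 -> 0.85 moves methylated-C share into the
        # 70-90% bins, mirroring a shift at highly methylated regions
        ref = generate_reference(12_000, seed=11)
        conv = ConversionSpec(0.02)
        out = {}
        for name, p in (("control", 0.75), ("treated", 0.85)):
            reads, truth = simulate_bisulfite_reads(
                ref, MethylomeSpec(p, 0, 0), conv, 12_000, 100, seed=12
            )
            calls = call_sites(reads, truth, ref)
            out[name] = methylation_bin_profile(calls[calls.context == "CpG"])
        delta = out["treated"]["meth_c_share"] - out["control"]["meth_c_share"]
        assert delta.idxmax() in (7, 8)  # the 70-80 or 80-90 bin


class TestDifferentialSites:
    def _calls(self, rows):
        df = pd.DataFrame(
            rows, columns=["chrom", "pos", "strand", "n_meth", "n_unmeth"]
        )
        df["context"] = "CpG"
        cov = df["n_meth"] + df["n_unmeth"]
        df["methylation_percent"] = 100 * df["n_meth"] / cov
        return df

    def test_opposite_extremes_flagged(self):
        a = self._calls([("r", 10, "+", 10, 0)])
        b = self._calls([("r", 10, "+", 0, 10)])
        out = differential_sites(a, b, alpha=0.01)
        assert len(out) == 1
        assert out.iloc[0]["fisher_p"] == pytest.approx(2 / 184756, rel=1e-9)
        assert out.iloc[0]["flagged"]

    def test_identical_counts_not_flagged(self):
        a = self._calls([("r", 10, "+", 10, 0)])
        out = differential_sites(a, a.copy(), alpha=0.01)
        assert out.iloc[0]["fisher_p"] == pytest.approx(1.0)
        assert not out.iloc[0]["flagged"]

    def test_reality_screen_removes_conversion_noise(self):
        # 1 meth of 20 is indistinguishable from 5% under-conversion
        # (binomial tail P(X>=1 | n=20, q=0.05) ~ 0.64): never tested
        a = self._calls([("r", 10, "+", 1, 19)])
        b = self._calls([("r", 10, "+", 0, 20)])
        out = differential_sites(a, b, alpha=0.01, conversion_error=0.05)
        assert len(out) == 0
        from scipy.stats import binom

        assert binom.sf(0, 20, 0.05) == pytest.approx(0.6415, abs=1e-4)

    def test_strict_mode_lists_orphans(self):
        a = self._calls([("r", 10, "+", 10, 0), ("r", 20, "+", 10, 0)])
        b = self._calls([("r", 10, "+", 10, 0)])
        with pytest.raises(ValidationError, match="1 site"):
            differential_sites(a, b, strict=True)

    def test_null_type_one_error_controlled(self):
        # both arms drawn from identical generator parameters: the per-site
        # Fisher flags at most alpha of tested sites (thousands of sites
        # serve as replicates)
        ref = generate_reference(20_000, seed=13)
        conv = ConversionSpec(0.05)
        spec = MethylomeSpec(0.75, 0.01, 0.01)
        ra, ta = simulate_bisulfite_reads(ref, spec, conv, 8000, 100, seed=14)
        rb, tb = simulate_bisulfite_reads(ref, spec, conv, 8000, 100, seed=15)
        out = differential_sites(
            call_sites(ra, ta, ref), call_sites(rb, tb, ref), alpha=0.01
        )
        assert len(out) >= 2000
        assert out["flagged"].mean() <= 0.01


class TestAnnotateSites:
    def _sites(self, positions, chrom="r"):
        return pd.DataFrame({"chrom": chrom, "pos": positions})

    def test_inside_gene(self):
        genes = [GenomicInterval("r", 10_000, 20_000)]
        out = annotate_sites(self._sites([15_000]), genes)
        assert out.iloc[0]["gene_label"] == "genic"

    def test_boundary_distance_inclusive(self):
        genes = [GenomicInterval("r", 10_000, 20_000)]
        out = annotate_sites(self._sites([24_999]), genes, distance=5000)
        assert out.iloc[0]["gene_distance"] == 5000
        assert out.iloc[0]["gene_label"] == "proximal"
        out2 = annotate_sites(self._sites([25_000]), genes, distance=5000)
        assert out2.iloc[0]["gene_label"] == "intergenic"

    def test_unknown_chromosome_warns_not_errors(self):
        genes = [GenomicInterval("other", 0, 100)]
        with pytest.warns(UserWarning):
            out = annotate_sites(self._sites([50]), genes)
        assert out.iloc[0]["gene_label"] == "intergenic"

    def test_matches_brute_force_oracle(self, rng):
        genes = [
            GenomicInterval("r", int(s), int(s) + int(l))
            for s, l in zip(
                rng.integers(0, 90_000, 15), rng.integers(100, 3000, 15)
            )
        ]
        sites = self._sites(sorted(rng.integers(0, 100_000, 200)))
        out = annotate_sites(sites, genes, distance=5000)
        expected = brute_force_gene_labels(sites, genes, 5000)
        assert out["gene_label"].tolist() == expected


class TestExtractFlanks:
    def test_window_arithmetic(self):
        genome = generate_reference(10_000, seed=16)
        sites = pd.DataFrame({"chrom": genome.id, "pos": [500]})
        [(iv, seq)] = extract_flanks(sites, genome, radius=100)
        assert (iv.start, iv.end) == (400, 601)
        assert len(seq) == 201
        assert seq == genome.sequence[400:601]

    def test_overlapping_window_skipped(self):
        genome = generate_reference(10_000, seed=16)
        sites = pd.DataFrame({"chrom": genome.id, "pos": [500, 550, 900]})
        flanks = extract_flanks(sites, genome, radius=100)
        assert [iv.start for iv, _ in flanks] == [400, 800]

    def test_clipped_at_chromosome_start(self):
        genome = generate_reference(10_000, seed=16)
        sites = pd.DataFrame({"chrom": genome.id, "pos": [50]})
        [(iv, _)] = extract_flanks(sites, genome, radius=100)
        assert (iv.start, iv.end) == (0, 151)
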