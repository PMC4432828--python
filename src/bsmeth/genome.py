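"""Genome-scale methylation metrics and differential-site calling.

After bisulfite treatment, unmethylated cytosines read as T, so the
cytosine content of sequenced bases (the "C count") is a proxy for
methylated-cytosine content, and per-site C/T read counts at reference
cytosines give per-site methylation percentages. This module computes base
composition and its between-sample shifts, per-cytosine site calls from
reads placed by truth intervals, genome-level summaries (methylated and
unmethylated C count percentages and their ratio in CpG context), the
distribution of methylated C over methylation-frequency bins, per-site
differential methylation by Fisher's exact test guarded by a
conversion-error reality screen, gene-distance annotation, and extraction of
fixed-width flanks around differential sites.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats
from .io import GenomicInterval, ReadRecord, SequenceRecord, ValidationError
from .simulate import cytosine_contexts

_BASES = ("A", "C", "G", "T", "N")


@dataclass
class CompositionTable:
    """Per-base counts and percentages over a sequence set."""

    counts: dict[str, int]
    dinucleotide_counts: Optional[dict[str, int]] = None

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def percentages(self) -> dict[str, float]:
        t = self.total
        return {b: 100.0 * self.counts.get(b, 0) / t for b in _BASES}

    def to_frame(self) -> pd.DataFrame:
        pct = self.percentages
        return pd.DataFrame(
            {
                "base": list(_BASES),
                "count": [self.counts.get(b, 0) for b in _BASES],
                "percent": [pct[b] for b in _BASES],
            }
        )


def base_composition(
    sequences: Sequence, dinucleotides: bool = False
) -> CompositionTable:
    """Tally base (and optionally dinucleotide) content of a sequence set."""
    seqs = [getattr(s, "sequence", s) for s in sequences]
    if not seqs or all(len(s) == 0 for s in seqs):
        raise ValidationError("empty sequence set")
    counts: Counter = Counter()
    for s in seqs:
        counts.update(s)
    dinuc: Optional[dict[str, int]] = None
    if dinucleotides:
        dc: Counter = Counter()
        for s in seqs:
            dc.update(s[i : i + 2] for i in range(len(s) - 1))
        dinuc = {k: v for k, v in dc.items() if "N" not in k}
    return CompositionTable({b: counts.get(b, 0) for b in _BASES}, dinuc)


def composition_delta(
    table_treated: CompositionTable,
    table_control: CompositionTable,
    fisher: bool = True,
) -> pd.DataFrame:
    """Per-base relative change with the control normalised to 1.

    The ratio is treated%/control% per base. Significance of each base's
    shift is a 2x2 test (this base vs all others, treated vs control) by
    chi-square with Yates' correction on the raw counts, plus Fisher's exact
    test when enabled.
    """
    rows = []
    t_total, c_total = table_treated.total, table_control.total
    t_pct, c_pct = table_treated.percentages, table_control.percentages
    for b in _BASES:
        tc = table_treated.counts.get(b, 0)
        cc = table_control.counts.get(b, 0)
        if cc == 0:
            rows.append(
                dict(base=b, treated_count=tc, control_count=cc,
                     ratio=float("nan"), flagged_undefined=True,
                     chi2_stat=float("nan"), chi2_p=float("nan"),
                     fisher_p=float("nan"))
            )
            continue
        table = [[tc, t_total - tc], [cc, c_total - cc]]
        chi2_stat, chi2_p = stats.chi_square_yates(table)
        fisher_p = stats.fisher_exact_2x2(table) if fisher else float("nan")
        rows.append(
            dict(base=b, treated_count=tc, control_count=cc,
                 ratio=t_pct[b] / c_pct[b], flagged_undefined=False,
                 chi2_stat=chi2_stat, chi2_p=chi2_p, fisher_p=fisher_p)
        )
    return pd.DataFrame(rows)


def call_sites(
    reads: Sequence[ReadRecord],
    truth: pd.DataFrame,
    reference: SequenceRecord,
    context_filter: Optional[str] = None,
) -> pd.DataFrame:
    """Per-cytosine methylation calls from truth-placed bisulfite reads.

    At each reference cytosine covered by a read on the cytosine's strand, a
    read base C increments ``n_meth`` (retained, methylated) and T increments
    ``n_unmeth`` (converted); other bases are ignored. Both strands are
    handled symmetrically (minus-strand cytosines are reference Gs read on
    the reverse complement). Sites with zero coverage are absent. Columns:
    chrom, pos, strand, context, n_meth, n_unmeth, methylation_percent.
    """
    ref = reference.sequence
    L = len(ref)
    ref_arr = np.frombuffer(ref.encode(), dtype="S1")
    meth = {"+": np.zeros(L, dtype=np.int64), "-": np.zeros(L, dtype=np.int64)}
    unmeth = {"+": np.zeros(L, dtype=np.int64), "-": np.zeros(L, dtype=np.int64)}
    truth_by_id = truth.set_index("read_id")
    for read in reads:
        try:
            row = truth_by_id.loc[read.id]
        except KeyError as exc:
            raise ValidationError(f"read {read.id!r} missing from truth") from exc
        s, e, strand = int(row["start"]), int(row["end"]), row["strand"]
        if not 0 <= s < e <= L:
            raise ValidationError(
                f"read {read.id!r}: truth interval [{s},{e}) outside reference"
            )
        read_arr = np.frombuffer(read.sequence.encode(), dtype="S1")
        if len(read_arr) != e - s:
            raise ValidationError(f"read {read.id!r}: length != interval length")
        if strand == "+":
            plus_read = read_arr
            c_mask = ref_arr[s:e] == b"C"
            is_meth = plus_read == b"C"
            is_unmeth = plus_read == b"T"
        else:
            # reverse (not complement): plus_read[i] is then the minus-strand
            # base over plus position s+i, so a retained minus-strand C is
            # still read as C and a converted one as T
            plus_read = read_arr[::-1]
            c_mask = ref_arr[s:e] == b"G"
            is_meth = plus_read == b"C"
            is_unmeth = plus_read == b"T"
        idx = np.nonzero(c_mask)[0] + s
        np.add.at(meth[strand], idx, is_meth[c_mask])
        np.add.at(unmeth[strand], idx, is_unmeth[c_mask])

    ctx = cytosine_contexts(ref)
    ctx_lookup = {
        (int(r.pos), r.strand): r.context for r in ctx.itertuples()
    }
    rows = []
    for strand in ("+", "-"):
        covered = np.nonzero(meth[strand] + unmeth[strand] > 0)[0]
        for pos in covered:
            context = ctx_lookup.get((int(pos), strand))
            if context is None:
                continue  # N-context cytosine, excluded
            if context_filter and context != context_filter:
                continue
            nm, nu = int(meth[strand][pos]), int(unmeth[strand][pos])
            rows.append(
                dict(chrom=reference.id, pos=int(pos), strand=strand,
                     context=context, n_meth=nm, n_unmeth=nu,
                     methylation_percent=100.0 * nm / (nm + nu))
            )
    df = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "strand", "context",
                 "n_meth", "n_unmeth", "methylation_percent"],
    )
    return df.sort_values(["pos", "strand"], kind="stable").reset_index(drop=True)


def c_count_summary(site_calls: pd.DataFrame, total_bases: int) -> dict:
    """CpG-context methylated/unmethylated C counts as % of sequenced bases.

    The "C count (%)" is C count x 100 / total sequenced bases; the headline
    metric is the methylated:unmethylated ratio in CpG context.
    """
    if total_bases <= 0:
        raise ValidationError("total_bases must be positive")
    cpg = site_calls[site_calls["context"] == "CpG"]
    n_meth = int(cpg["n_meth"].sum())
    n_unmeth = int(cpg["n_unmeth"].sum())
    if n_unmeth == 0:
        ratio, flagged = float("inf"), True
    else:
        ratio, flagged = n_meth / n_unmeth, False
    return {
        "methylated_c_count": n_meth,
        "unmethylated_c_count": n_unmeth,
        "methylated_c_percent": 100.0 * n_meth / total_bases,
        "unmethylated_c_percent": 100.0 * n_unmeth / total_bases,
        "meth_unmeth_ratio": ratio,
        "ratio_flagged_infinite": flagged,
    }


def methylation_bin_profile(
    site_calls: pd.DataFrame, bin_width: int = 10
) -> pd.DataFrame:
    """Distribution of sites and methylated C count over methylation% bins.

    Bins are [0,w), [w,2w), ..., with the last bin closed at 100. Reports
    per-bin site counts and each bin's share of the total methylated C
    count. Only sites with coverage enter (site calls always have coverage).
    """
    if bin_width <= 0 or 100 % bin_width != 0:
        raise ValueError(f"bin_width {bin_width} must divide 100")
    nbins = 100 // bin_width
    pct = site_calls["methylation_percent"].to_numpy()
    idx = np.minimum((pct // bin_width).astype(int), nbins - 1)  # close last bin
    n_meth = site_calls["n_meth"].to_numpy()
    total_meth = n_meth.sum()
    rows = []
    for b in range(nbins):
        in_bin = idx == b
        meth_in_bin = int(n_meth[in_bin].sum())
        rows.append(
            dict(
                bin_low=b * bin_width,
                bin_high=(b + 1) * bin_width,
                n_sites=int(in_bin.sum()),
                meth_c_count=meth_in_bin,
                meth_c_share=meth_in_bin / total_meth if total_meth else 0.0,
            )
        )
    return pd.DataFrame(rows)


def differential_sites(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    alpha: float = 0.01,
    conversion_error: float = 0.05,
    strict: bool = False,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Per-site differential methylation between two samples.

    Sites shared by both samples (with coverage in both) are tested. A
    site's methylation is deemed real in a sample only if its n_meth exceeds
    the binomial expectation under retention probability ``conversion_error``
    at one-sided p < alpha; sites real in neither sample are screened out
    (apparent methylation indistinguishable from under-conversion). Screened
    sites get a two-sided Fisher exact test on the 2x2 (n_meth, n_unmeth)
    table and are flagged at p < alpha (optionally Benjamini-Hochberg
    adjusted, off by default). With ``strict=True``, sites present in one
    sample only raise an error listing the orphans.
    """
    keys = ["chrom", "pos", "strand"]
    merged = calls_a.merge(calls_b, on=keys, suffixes=("_a", "_b"), how="outer",
                           indicator=True)
    orphans = merged[merged["_merge"] != "both"]
    if strict and len(orphans):
        listing = orphans[keys].head(10).to_dict("records")
        raise ValidationError(
            f"{len(orphans)} site(s) present in only one sample: {listing}"
        )
    shared = merged[merged["_merge"] == "both"].drop(columns="_merge").copy()
    if not len(shared):
        return pd.DataFrame(
            columns=keys + ["context", "n_meth_a", "n_unmeth_a", "n_meth_b",
                            "n_unmeth_b", "screen_p_a", "screen_p_b",
                            "fisher_p", "flagged"]
        )
    for arm in ("a", "b"):
        n = shared[f"n_meth_{arm}"] + shared[f"n_unmeth_{arm}"]
        shared[f"screen_p_{arm}"] = sps.binom.sf(
            shared[f"n_meth_{arm}"] - 1, n.astype(int), conversion_error
        )
    real = (shared["screen_p_a"] < alpha) | (shared["screen_p_b"] < alpha)
    tested = shared[real].copy()
    pvals = [
        stats.fisher_exact_2x2(
            [[r.n_meth_a, r.n_unmeth_a], [r.n_meth_b, r.n_unmeth_b]]
        )
        for r in tested.itertuples()
    ]
    tested["fisher_p"] = pvals
    if bh_correct and len(tested):
        p = tested["fisher_p"].to_numpy()
        order = np.argsort(p)
        adj = np.empty_like(p)
        m = len(p)
        running = 1.0
        for rank in range(m - 1, -1, -1):
            running = min(running, p[order[rank]] * m / (rank + 1))
            adj[order[rank]] = running
        tested["fisher_p_adj"] = adj
        tested["flagged"] = tested["fisher_p_adj"] < alpha
    else:
        tested["flagged"] = tested["fisher_p"] < alpha
    out_cols = keys + ["context_a", "n_meth_a", "n_unmeth_a", "n_meth_b",
                       "n_unmeth_b", "screen_p_a", "screen_p_b", "fisher_p"]
    if bh_correct:
        out_cols.append("fisher_p_adj")
    out_cols.append("flagged")
    out = tested[out_cols].rename(columns={"context_a": "context"})
    return out.reset_index(drop=True)


def annotate_sites(
    sites: pd.DataFrame,
    genes: Sequence[GenomicInterval],
    distance: int = 5000,
) -> pd.DataFrame:
    """Label sites genic / proximal / intergenic by distance to genes.

    Genic: inside a gene interval. Proximal: within ``distance`` bases of
    the nearest gene edge (boundary inclusive); the distance to a gene is
    the gap to its nearest included base under half-open arithmetic.
    Intergenic otherwise, including sites on chromosomes absent from the
    gene set (with a warning). Also emits the dichotomous split used for
    reporting (intergenic_5kb: farther than ``distance`` from any gene).
    """
    import warnings

    by_chrom: dict[str, list[GenomicInterval]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    starts_ends: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, gs in by_chrom.items():
        gs.sort(key=lambda g: g.start)
        starts_ends[chrom] = (
            np.array([g.start for g in gs]),
            np.array([g.end for g in gs]),
        )
    labels, dists = [], []
    warned: set[str] = set()
    for r in sites.itertuples():
        chrom, pos = r.chrom, int(r.pos)
        if chrom not in starts_ends:
            if chrom not in warned:
                warnings.warn(
                    f"chromosome {chrom!r} absent from gene annotation; "
                    "sites labelled intergenic", stacklevel=2
                )
                warned.add(chrom)
            labels.append("intergenic")
            dists.append(np.inf)
            continue
        starts, ends = starts_ends[chrom]
        inside = (starts <= pos) & (pos < ends)
        if inside.any():
            labels.append("genic")
            dists.append(0)
            continue
        # distance to nearest gene base: gap to end-1 of genes left of pos,
        # gap to start of genes right of pos
        d = np.inf
        left = ends <= pos
        if left.any():
            d = min(d, pos - (ends[left].max() - 1))
        right = starts > pos
        if right.any():
            d = min(d, starts[right].min() - pos)
        dists.append(int(d) if np.isfinite(d) else np.inf)
        labels.append("proximal" if d <= distance else "intergenic")
    out = sites.copy()
    out["gene_label"] = labels
    out["gene_distance"] = dists
    out["intergenic_5kb"] = [l == "intergenic" for l in labels]
    return out


def extract_flanks(
    sites: pd.DataFrame,
    genome: SequenceRecord,
    radius: int = 100,
) -> list[tuple[GenomicInterval, str]]:
    """Non-overlapping +/- radius windows around sites, left to right.

    Windows are [pos-radius, pos+radius+1) clipped to the chromosome; a
    window overlapping the previously emitted one is skipped (greedy rule,
    preserving fixed-width windows where possible). Sites must be sorted by
    coordinate.
    """
    L = len(genome.sequence)
    out: list[tuple[GenomicInterval, str]] = []
    prev_end = -1
    for pos in sites["pos"].astype(int):
        s = max(pos - radius, 0)
        e = min(pos + radius + 1, L)
        if s < prev_end:
            continue
        out.append((GenomicInterval(genome.id, s, e), genome.sequence[s:e]))
        prev_end = e
    return out
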