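"""Synthetic bisulfite-sequencing data generator.

Emulates the data the analysis assumes: a reference genome with a tunable
CpG dinucleotide rate, a per-cytosine methylome drawn by context, in-silico
bisulfite conversion with an under-conversion rate (unmethylated C retained
as C with probability ``u``) and an over-conversion rate (methylated C read
as T with probability ``v``), uniformly placed genomic reads on both strands,
and repeat-amplicon molecules whose per-molecule CpG methylation level is
drawn from a 1-4 component beta mixture — the structure that produces
unimodal or bimodal per-read CpG-frequency distributions.

Every operation is deterministic for a fixed seed. Truth sidecars record the
simulation ground truth (source interval and strand for genomic reads;
mixture component and methylation level for amplicon molecules) and stand in
for read alignment downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import (
    GenomicInterval,
    ReadRecord,
    SequenceRecord,
    ValidationError,
    reverse_complement,
)

_BASES = np.array(["A", "C", "G", "T"])


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Specs


@dataclass
class MethylomeSpec:
    """Per-context methylation probabilities for drawing a methylome."""

    p_cpg: float = 0.8
    p_chg: float = 0.01
    p_chh: float = 0.01
    site_overrides: Optional[dict[int, float]] = None

    def __post_init__(self) -> None:
        for name in ("p_cpg", "p_chg", "p_chh"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name}={p} outside [0, 1]")
        if self.site_overrides:
            for pos, p in self.site_overrides.items():
                if not 0.0 <= p <= 1.0:
                    raise ValidationError(f"override at {pos}: {p} outside [0, 1]")


@dataclass
class ConversionSpec:
    """Bisulfite conversion error model.

    ``under_conversion`` (u): probability an unmethylated C fails to convert
    and is read as C. ``over_conversion`` (v): probability a methylated C is
    erroneously converted and read as T.
    """

    under_conversion: float = 0.05
    over_conversion: float = 0.0

    def __post_init__(self) -> None:
        for name in ("under_conversion", "over_conversion"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name}={p} outside [0, 1]")


@dataclass
class MixtureSpec:
    """Mixture of per-molecule methylation-level populations.

    Each molecule draws a component by ``weights``, then a methylation level
    from a beta distribution with mean ``levels[k]`` and concentration
    ``dispersion[k]`` (larger = tighter; a non-positive value collapses to a
    point mass at the level).
    """

    weights: Sequence[float]
    levels: Sequence[float]
    dispersion: Sequence[float] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.weights = [float(w) for w in self.weights]
        self.levels = [float(x) for x in self.levels]
        k = len(self.weights)
        if not 1 <= k <= 4:
            raise ValidationError(f"{k} components outside 1..4")
        if len(self.levels) != k:
            raise ValidationError("weights and levels must have equal length")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValidationError(f"weights sum to {sum(self.weights)}, not 1")
        if any(not 0.0 <= x <= 1.0 for x in self.levels):
            raise ValidationError("levels must lie in [0, 1]")
        if self.dispersion is None:
            self.dispersion = [50.0] * k
        else:
            self.dispersion = [float(d) for d in self.dispersion]
            if len(self.dispersion) != k:
                raise ValidationError("dispersion must have one value per component")


@dataclass
class AmpliconSpec:
    """A consensus amplicon with the primer pair that defines it."""

    consensus: SequenceRecord
    primer_pair: "object"  # amplicon.PrimerPair; kept loose to avoid a cycle
    min_observed_len: int = 50

    def __post_init__(self) -> None:
        if self.min_observed_len < 1:
            raise ValidationError("min_observed_len must be >= 1")


# ---------------------------------------------------------------------------
# Cytosine contexts


def cytosine_contexts(sequence: str) -> pd.DataFrame:
    """Context (CpG/CHG/CHH) of every cytosine on both strands.

    Positions are plus-strand 0-based; minus-strand cytosines appear as G on
    the plus strand. The standard 3-base rule applies on each strand's own
    5'->3' reading; a context window that runs off the sequence end falls
    through to CHH, and any cytosine whose window contains N is excluded.
    """
    arr = np.frombuffer(sequence.encode(), dtype="S1")
    n = len(arr)
    pad = np.concatenate([arr, np.array([b"$", b"$"], dtype="S1")])
    rows = []
    # plus strand: C at i, look at i+1, i+2
    cpos = np.nonzero(arr == b"C")[0]
    n1, n2 = pad[cpos + 1], pad[cpos + 2]
    ctx = np.where(n1 == b"G", "CpG", np.where(n2 == b"G", "CHG", "CHH"))
    keep = (n1 != b"N") & (n2 != b"N")
    rows.append(pd.DataFrame({"pos": cpos[keep], "strand": "+", "context": ctx[keep]}))
    # minus strand: G at i is a C on the reverse complement; look at i-1, i-2
    gpos = np.nonzero(arr == b"G")[0]
    pad2 = np.concatenate([np.array([b"$", b"$"], dtype="S1"), arr])
    m1, m2 = pad2[gpos + 1], pad2[gpos]  # plus bases at i-1 and i-2
    ctx_m = np.where(m1 == b"C", "CpG", np.where(m2 == b"C", "CHG", "CHH"))
    keep_m = (m1 != b"N") & (m2 != b"N")
    rows.append(
        pd.DataFrame({"pos": gpos[keep_m], "strand": "-", "context": ctx_m[keep_m]})
    )
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["pos", "strand"], kind="stable").reset_index(drop=True)


@dataclass
class MethylationMap:
    """Drawn per-cytosine methylation states for one reference."""

    reference_id: str
    reference_length: int
    sites: pd.DataFrame  # pos, strand, context, p, methylated

    def strand_states(self, strand: str) -> pd.DataFrame:
        return self.sites[self.sites["strand"] == strand]

    def fraction_methylated(self, context: str = "CpG") -> float:
        sub = self.sites[self.sites["context"] == context]
        return float(sub["methylated"].mean()) if len(sub) else float("nan")


# ---------------------------------------------------------------------------
# Generators


def generate_reference(
    length: int, gc_fraction: float = 0.5, cpg_factor: float = 1.0, seed=None
) -> SequenceRecord:
    """Random reference with i.i.d. base composition and a CpG tilt.

    Bases are drawn from a first-order chain that is i.i.d. except that the
    probability of G following a C is multiplied by ``cpg_factor`` and the
    row renormalised, so ``cpg_factor=1`` gives a plain i.i.d. sequence with
    expected CpG dinucleotide rate (gc/2)^2.
    """
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction outside [0, 1]")
    if cpg_factor < 0:
        raise ValueError("cpg_factor must be >= 0")
    rng = _rng(seed)
    base_p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    if gc_fraction in (0.0, 1.0) or cpg_factor == 1.0:
        idx = rng.choice(4, size=length, p=base_p)
    else:
        after_c = base_p.copy()
        after_c[2] *= cpg_factor  # G after C
        after_c /= after_c.sum()
        idx = np.empty(length, dtype=np.int64)
        idx[0] = rng.choice(4, p=base_p)
        u = rng.random(length)
        cum_base = np.cumsum(base_p)
        cum_c = np.cumsum(after_c)
        for i in range(1, length):
            cum = cum_c if idx[i - 1] == 1 else cum_base
            idx[i] = np.searchsorted(cum, u[i], side="right")
    seq = "".join(_BASES[idx])
    return SequenceRecord("synthetic_ref", seq, f"length={length} gc={gc_fraction}")


def assign_methylome(
    reference: SequenceRecord, spec: MethylomeSpec, seed=None
) -> MethylationMap:
    """Draw Bernoulli methylation states for every cytosine on both strands."""
    rng = _rng(seed)
    ctx = cytosine_contexts(reference.sequence)
    p = np.select(
        [ctx["context"] == "CpG", ctx["context"] == "CHG"],
        [spec.p_cpg, spec.p_chg],
        default=spec.p_chh,
    ).astype(float)
    if spec.site_overrides:
        seq = reference.sequence
        pos_index = {
            (int(r.pos), r.strand): i for i, r in enumerate(ctx.itertuples())
        }
        for pos, prob in spec.site_overrides.items():
            strand = (
                "+" if 0 <= pos < len(seq) and seq[pos] == "C"
                else "-" if 0 <= pos < len(seq) and seq[pos] == "G"
                else None
            )
            if strand is None or (pos, strand) not in pos_index:
                raise ValidationError(f"override at {pos}: not a cytosine position")
            p[pos_index[(pos, strand)]] = prob
    sites = ctx.copy()
    sites["p"] = p
    sites["methylated"] = rng.random(len(p)) < p
    return MethylationMap(reference.id, len(reference.sequence), sites)


def bisulfite_convert(
    sequence: str,
    positions: np.ndarray,
    methylated: np.ndarray,
    conv: ConversionSpec,
    seed=None,
) -> tuple[str, pd.DataFrame]:
    """In-silico bisulfite conversion of one strand.

    ``positions``/``methylated`` give the state of every C in ``sequence``
    (its own 5'->3' coordinates). Unmethylated C converts to T with
    probability 1-u; methylated C converts with probability v. Only C
    positions may change, and only to T. Returns the converted sequence and
    an event log (pos, methylated, converted).
    """
    positions = np.asarray(positions, dtype=np.int64)
    methylated = np.asarray(methylated, dtype=bool)
    arr = np.frombuffer(sequence.encode(), dtype="S1").copy()
    c_pos = set(np.nonzero(arr == b"C")[0].tolist())
    missing = c_pos - set(positions.tolist())
    if missing:
        raise ValidationError(
            f"no methylation state for C position(s) {sorted(missing)[:5]}"
        )
    rng = _rng(seed)
    u, v = conv.under_conversion, conv.over_conversion
    p_convert = np.where(methylated, v, 1.0 - u)
    converted = rng.random(len(positions)) < p_convert
    arr[positions[converted]] = b"T"
    events = pd.DataFrame(
        {"pos": positions, "methylated": methylated, "converted": converted}
    )
    return arr.tobytes().decode(), events


@dataclass
class ConvertedGenome:
    """Both bisulfite-converted strands of one reference.

    ``top`` is plus-oriented; ``bottom`` is the converted reverse complement
    in minus orientation (``bottom[j]`` covers plus position L-1-j).
    """

    reference_id: str
    length: int
    top: str
    bottom: str
    events_top: pd.DataFrame
    events_bottom: pd.DataFrame


def convert_genome(
    reference: SequenceRecord,
    meth: MethylationMap,
    conv: ConversionSpec,
    seed=None,
) -> ConvertedGenome:
    """Convert both strands of a reference under a drawn methylome.

    The minus strand is converted as the reverse complement, so only C
    positions change on each strand's own reading (plus-strand A and G
    counts are untouched by the top-strand conversion and vice versa).
    """
    rng = _rng(seed)
    L = len(reference.sequence)
    plus = meth.strand_states("+")
    top, ev_top = bisulfite_convert(
        reference.sequence,
        plus["pos"].to_numpy(),
        plus["methylated"].to_numpy(),
        conv,
        rng,
    )
    minus = meth.strand_states("-")
    rc = reverse_complement(reference.sequence)
    bottom, ev_bot = bisulfite_convert(
        rc,
        L - 1 - minus["pos"].to_numpy(),
        minus["methylated"].to_numpy(),
        conv,
        rng,
    )
    ev_bot = ev_bot.assign(pos=L - 1 - ev_bot["pos"])  # report in plus coords
    return ConvertedGenome(reference.id, L, top, bottom, ev_top, ev_bot)


def simulate_genomic_reads(
    converted: ConvertedGenome,
    n_reads: int,
    read_len: int,
    paired: bool = False,
    seed=None,
    fragment_len: Optional[int] = None,
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Uniformly placed single- or paired-end reads from a converted genome.

    Minus-strand reads are taken from the converted bottom strand (so they
    arrive reverse-complemented relative to plus coordinates). The truth
    table records each read's source interval and strand.
    """
    L = converted.length
    if read_len > L:
        raise ValueError(f"read_len {read_len} > genome length {L}")
    if paired:
        fragment_len = fragment_len or min(2 * read_len, L)
        if not read_len <= fragment_len <= L:
            raise ValueError("need read_len <= fragment_len <= genome length")
    rng = _rng(seed)
    reads: list[ReadRecord] = []
    truth_rows = []
    span = fragment_len if paired else read_len
    starts = rng.integers(0, L - span + 1, size=n_reads)
    strands = np.where(rng.random(n_reads) < 0.5, "+", "-")

    def slice_strand(s: int, e: int, strand: str) -> str:
        if strand == "+":
            return converted.top[s:e]
        return converted.bottom[L - e : L - s]

    for i in range(n_reads):
        s, strand = int(starts[i]), strands[i]
        if not paired:
            seq = slice_strand(s, s + read_len, strand)
            rid = f"read{i}"
            reads.append(ReadRecord(rid, seq))
            truth_rows.append(
                dict(read_id=rid, chrom=converted.reference_id, start=s,
                     end=s + read_len, strand=strand)
            )
        else:
            e = s + fragment_len
            # R1 from the fragment 5' end on the fragment strand, R2 from the
            # 3' end on the opposite strand.
            if strand == "+":
                r1 = slice_strand(s, s + read_len, "+")
                r2 = slice_strand(e - read_len, e, "-")
                iv1 = (s, s + read_len, "+")
                iv2 = (e - read_len, e, "-")
            else:
                r1 = slice_strand(e - read_len, e, "-")
                r2 = slice_strand(s, s + read_len, "+")
                iv1 = (e - read_len, e, "-")
                iv2 = (s, s + read_len, "+")
            for mate, seq, iv in ((1, r1, iv1), (2, r2, iv2)):
                rid = f"read{i}/{mate}"
                reads.append(ReadRecord(rid, seq))
                truth_rows.append(
                    dict(read_id=rid, chrom=converted.reference_id,
                         start=iv[0], end=iv[1], strand=iv[2])
                )
    truth = pd.DataFrame(
        truth_rows, columns=["read_id", "chrom", "start", "end", "strand"]
    )
    return reads, truth


def simulate_bisulfite_reads(
    reference: SequenceRecord,
    methylome: MethylomeSpec,
    conv: ConversionSpec,
    n_reads: int,
    read_len: int,
    seed=None,
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Per-molecule bisulfite reads: states and conversion drawn per read.

    Each read is an independent molecule — its cytosines draw fresh
    Bernoulli methylation states from the methylome spec and fresh
    conversion outcomes — so per-site C/T counts across reads are binomial,
    as across cells in a sequencing library. (Contrast with
    :func:`simulate_genomic_reads`, which slices one fixed converted genome
    and therefore shares conversion outcomes between overlapping reads.)
    """
    seq = reference.sequence
    L = len(seq)
    if read_len > L:
        raise ValueError(f"read_len {read_len} > genome length {L}")
    rng = _rng(seed)
    ctx = cytosine_contexts(seq)
    # per-position methylation probability, one array per strand
    prob = {s: np.zeros(L) for s in "+-"}
    is_c = {s: np.zeros(L, dtype=bool) for s in "+-"}
    p_by_ctx = {"CpG": methylome.p_cpg, "CHG": methylome.p_chg,
                "CHH": methylome.p_chh}
    for r in ctx.itertuples():
        prob[r.strand][r.pos] = p_by_ctx[r.context]
        is_c[r.strand][r.pos] = True
    u, v = conv.under_conversion, conv.over_conversion
    starts = rng.integers(0, L - read_len + 1, size=n_reads)
    strands = np.where(rng.random(n_reads) < 0.5, "+", "-")
    reads: list[ReadRecord] = []
    truth_rows = []
    for i in range(n_reads):
        s, strand = int(starts[i]), strands[i]
        e = s + read_len
        if strand == "+":
            arr = np.frombuffer(seq[s:e].encode(), dtype="S1").copy()
            cmask = is_c["+"][s:e]
            p = prob["+"][s:e][cmask]
        else:
            arr = np.frombuffer(
                reverse_complement(seq[s:e]).encode(), dtype="S1"
            ).copy()
            cmask = is_c["-"][s:e][::-1]
            p = prob["-"][s:e][::-1][cmask]
        meth = rng.random(len(p)) < p
        converted = rng.random(len(p)) < np.where(meth, v, 1.0 - u)
        idx = np.nonzero(cmask)[0][converted]
        arr[idx] = b"T"
        rid = f"read{i}"
        reads.append(ReadRecord(rid, arr.tobytes().decode()))
        truth_rows.append(
            dict(read_id=rid, chrom=reference.id, start=s, end=e, strand=strand)
        )
    truth = pd.DataFrame(
        truth_rows, columns=["read_id", "chrom", "start", "end", "strand"]
    )
    return reads, truth


def simulate_amplicon_reads(
    amplicon: AmpliconSpec,
    mixture: MixtureSpec,
    conv: ConversionSpec,
    n_molecules: int,
    seed=None,
    p_truncate: float = 0.2,
    priming_bias: float = 0.0,
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Per-molecule bisulfite amplicon reads from a consensus.

    Each molecule draws a mixture component, a per-molecule CpG methylation
    level from that component's beta, then conditionally independent
    Bernoulli states at the amplicon's CpG cytosines (non-CpG cytosines are
    unmethylated), and is converted under ``conv``. A fraction ``p_truncate``
    of molecules is truncated to a uniform length >= ``min_observed_len``,
    emulating incomplete inserts. ``priming_bias`` > 0 enables a per-molecule
    acceptance probability penalising molecules with unmethylated CpGs in the
    priming regions (off by default).
    """
    from . import amplicon as _amp  # deferred: amplicon does not import simulate

    if n_molecules < 0:
        raise ValueError("n_molecules must be >= 0")
    rng = _rng(seed)
    definition = _amp.locate_amplicon(
        amplicon.primer_pair, amplicon.consensus, bisulfite_space=True
    )
    amp_seq = amplicon.consensus.sequence[definition.start : definition.end]
    L = len(amp_seq)
    ctx = cytosine_contexts(amp_seq)
    plus = ctx[ctx["strand"] == "+"]
    c_positions = plus["pos"].to_numpy()
    cpg_mask = (plus["context"] == "CpG").to_numpy()
    primer_span = max(len(definition.forward_match), len(definition.reverse_match))

    reads: list[ReadRecord] = []
    truth_rows = []
    for i in range(n_molecules):
        while True:
            comp = int(rng.choice(len(mixture.weights), p=mixture.weights))
            mean, c = mixture.levels[comp], mixture.dispersion[comp]
            if c <= 0 or mean in (0.0, 1.0):
                level = mean
            else:
                level = float(rng.beta(mean * c, (1 - mean) * c))
            states = np.zeros(len(c_positions), dtype=bool)
            states[cpg_mask] = rng.random(int(cpg_mask.sum())) < level
            if priming_bias > 0:
                in_primer = (c_positions < primer_span) | (
                    c_positions >= L - primer_span
                )
                n_unmeth_primer = int((in_primer & cpg_mask & ~states).sum())
                if rng.random() < 1 - (1 - priming_bias) ** n_unmeth_primer:
                    continue  # molecule fails to amplify; redraw
            break
        seq, _ = bisulfite_convert(amp_seq, c_positions, states, conv, rng)
        if p_truncate > 0 and rng.random() < p_truncate:
            # incomplete insert: a random contiguous window of the product
            obs_len = int(rng.integers(min(amplicon.min_observed_len, L), L + 1))
            off = int(rng.integers(0, L - obs_len + 1))
            seq = seq[off : off + obs_len]
        rid = f"mol{i}"
        reads.append(ReadRecord(rid, seq))
        truth_rows.append(
            dict(read_id=rid, component=comp, level=level, length=len(seq))
        )
    truth = pd.DataFrame(
        truth_rows, columns=["read_id", "component", "level", "length"]
    )
    return reads, truth


def generate_genes(
    genome_length: int,
    n_genes: int,
    seed=None,
    chrom: str = "synthetic_ref",
    mean_len: int = 2000,
) -> list[GenomicInterval]:
    """Random non-overlapping gene intervals for annotation tests."""
    rng = _rng(seed)
    genes: list[GenomicInterval] = []
    attempts = 0
    while len(genes) < n_genes and attempts < 50 * max(n_genes, 1):
        attempts += 1
        length = max(50, int(rng.exponential(mean_len)))
        if length >= genome_length:
            continue
        start = int(rng.integers(0, genome_length - length))
        end = start + length
        if any(g.start < end and start < g.end for g in genes):
            continue
        genes.append(GenomicInterval(chrom, start, end, "+"))
    genes.sort(key=lambda g: g.start)
    return genes
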