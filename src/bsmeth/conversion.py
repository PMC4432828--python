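"""Bisulfite conversion-efficiency QC from an unmethylated spike-in.

A fully unmethylated spike-in (phage lambda DNA in the original protocol)
is treated alongside the samples; any cytosine still read as C in spike-in
reads is an under-conversion event. The under-conversion rate is the number
of C-C matches divided by the total read coverage of reference-C positions,
and conversion efficiency is 100 x (1 - rate). Reads are placed on the
spike-in by their truth intervals (the generator's stand-in for alignment).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ReadRecord, SequenceRecord, ValidationError, reverse_complement


@dataclass
class ConversionEstimate:
    """Spike-in under-conversion estimate.

    ``c_c_matches``: reference-C positions read as C.
    ``c_coverage``: total read coverage of reference-C positions.
    """

    c_c_matches: int
    c_coverage: int

    def __post_init__(self) -> None:
        if not 0 <= self.c_c_matches <= self.c_coverage:
            raise ValidationError(
                f"invalid counts: {self.c_c_matches} matches of "
                f"{self.c_coverage} covered"
            )

    @property
    def under_conversion_rate(self) -> float:
        return self.c_c_matches / self.c_coverage

    @property
    def efficiency_percent(self) -> float:
        return 100.0 * (1.0 - self.under_conversion_rate)


def estimate_under_conversion(
    reads: list[ReadRecord],
    truth: pd.DataFrame,
    spike_in_reference: SequenceRecord,
) -> ConversionEstimate:
    """Count C-C matches over reference-C coverage in spike-in reads.

    Only the strand a read derives from contributes C positions: plus-strand
    reads are assessed at plus-strand reference Cs, minus-strand reads at
    minus-strand Cs (reference Gs, via the reverse complement). Each read
    contributes once per covered position. Reads whose truth places them off
    the reference raise; zero covered C positions is an error, not a silent
    zero estimate.
    """
    ref = spike_in_reference.sequence
    L = len(ref)
    ref_arr = np.frombuffer(ref.encode(), dtype="S1")
    truth_by_id = truth.set_index("read_id")
    matches = 0
    coverage = 0
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
        if strand == "+":
            ref_slice = ref_arr[s:e]
            read_arr = np.frombuffer(read.sequence.encode(), dtype="S1")
            target = b"C"
        else:
            # assess against the reverse complement: reference Gs are the
            # minus-strand Cs, and the read is already minus-oriented
            ref_slice = np.frombuffer(
                reverse_complement(ref[s:e]).encode(), dtype="S1"
            )
            read_arr = np.frombuffer(read.sequence.encode(), dtype="S1")
            target = b"C"
        if len(read_arr) != len(ref_slice):
            raise ValidationError(
                f"read {read.id!r}: length {len(read_arr)} != interval "
                f"length {len(ref_slice)}"
            )
        c_mask = ref_slice == target
        coverage += int(c_mask.sum())
        matches += int((read_arr[c_mask] == b"C").sum())
    if coverage == 0:
        raise ValidationError("no cytosine positions covered")
    return ConversionEstimate(matches, coverage)


def qc_verdict(
    estimate: ConversionEstimate, min_efficiency_percent: float = 95.0
) -> dict:
    """Pass/fail verdict and a report row for the run summary.

    Passes iff efficiency_percent >= threshold (boundary inclusive).
    """
    eff = estimate.efficiency_percent
    return {
        "c_c_matches": estimate.c_c_matches,
        "c_coverage": estimate.c_coverage,
        "under_conversion_rate": estimate.under_conversion_rate,
        "efficiency_percent": eff,
        "min_efficiency_percent": min_efficiency_percent,
        "verdict": "pass" if eff >= min_efficiency_percent else "fail",
    }
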