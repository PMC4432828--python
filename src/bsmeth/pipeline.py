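"""End-to-end seeded pipeline runs: simulate -> QC -> analyses -> reports.

``run_global`` covers the genome-wide arm (spike-in conversion QC, per-site
calls, C-count summaries, methylation-bin profiles, differential sites,
gene annotation, flank extraction); ``run_amplicon`` covers the repeat
amplicon arm (per-read CG/TG tables, normalised histograms, tail-shift
tests, 1- vs 2-Gaussian mixture fits, CG/TG correlation, mean comparison).
Both are deterministic for a fixed config seed, log each stage with ISO
timestamps, and write a JSON summary carrying every threshold applied.
"""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import amplicon as amp
from . import conversion, genome, simulate
from .config import ConfigError, RunConfig
from .io import (
    SequenceRecord,
    read_sequences,
    write_intervals,
    write_sequences,
    write_table,
    write_truth,
)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, float) and obj == float("inf"):
        return "inf"
    return obj


class _RunLog:
    def __init__(self, path: Path):
        self.path = path
        self.path.write_text("")

    def info(self, msg: str) -> None:
        stamp = datetime.now(timezone.utc).isoformat(timespec="seconds")
        with open(self.path, "a") as fh:
            fh.write(f"{stamp}\t{msg}\n")


def _stage_seeds(seed: int, n: int) -> list[np.random.Generator]:
    """Deterministic independent generators, one per pipeline stage."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _spike_in_qc(config: RunConfig, rng_ref, rng_reads, outdir: Path, log) -> dict:
    spike = simulate.generate_reference(
        config.spike_in_length, 0.5, 1.0, seed=rng_ref
    )
    spike = SequenceRecord("spike_in", spike.sequence, "unmethylated spike-in")
    conv = simulate.ConversionSpec(config.under_conversion, config.over_conversion)
    reads, truth = simulate.simulate_bisulfite_reads(
        spike, simulate.MethylomeSpec(0.0, 0.0, 0.0), conv,
        config.spike_in_reads, config.read_len, seed=rng_reads,
    )
    est = conversion.estimate_under_conversion(reads, truth, spike)
    verdict = conversion.qc_verdict(est, config.qc_min_efficiency)
    write_table(pd.DataFrame([verdict]), outdir / "conversion_qc.tsv")
    log.info(
        f"conversion QC: efficiency {est.efficiency_percent:.3f}% "
        f"({verdict['verdict']}; threshold {config.qc_min_efficiency}%)"
    )
    return verdict


def run_global(config: RunConfig, outdir=None) -> dict:
    """Genome-wide pipeline; returns the JSON-ready run summary."""
    config.validate()
    outdir = Path(outdir or config.outdir) / "global"
    outdir.mkdir(parents=True, exist_ok=True)
    log = _RunLog(outdir / "run.log")
    log.info(f"run_global start (seed {config.seed})")
    config.to_yaml(outdir / "config.yaml")
    rngs = _stage_seeds(config.seed, 8)

    reference = simulate.generate_reference(
        config.reference_length, config.gc_fraction, config.cpg_factor, seed=rngs[0]
    )
    write_sequences([reference], outdir / "reference.fasta")
    log.info(f"reference: {len(reference)} b")

    qc = _spike_in_qc(config, rngs[1], rngs[2], outdir, log)

    conv = simulate.ConversionSpec(config.under_conversion, config.over_conversion)
    calls = {}
    summaries = {}
    profiles = {}
    arm_rngs = {"control": rngs[3], "treated": rngs[4]}
    for arm_name in ("control", "treated"):
        arm = config.arms[arm_name]
        rng = arm_rngs[arm_name]
        # per-molecule simulation: each read is an independently methylated
        # and converted molecule, so per-site counts are binomial across reads
        reads, truth = simulate.simulate_bisulfite_reads(
            reference,
            simulate.MethylomeSpec(arm["p_cpg"], arm["p_chg"], arm["p_chh"]),
            conv, config.n_reads, config.read_len, seed=rng,
        )
        write_sequences(reads, outdir / f"{arm_name}_reads.fastq", "fastq")
        write_truth(truth, outdir / f"{arm_name}_truth.tsv")
        arm_calls = genome.call_sites(reads, truth, reference)
        write_table(arm_calls, outdir / f"{arm_name}_site_calls.tsv")
        total_bases = int(sum(len(r) for r in reads))
        summaries[arm_name] = genome.c_count_summary(arm_calls, total_bases)
        profiles[arm_name] = genome.methylation_bin_profile(arm_calls)
        write_table(profiles[arm_name], outdir / f"{arm_name}_bin_profile.tsv")
        calls[arm_name] = arm_calls
        log.info(
            f"{arm_name}: {len(arm_calls)} sites called; CpG meth:unmeth ratio "
            f"{summaries[arm_name]['meth_unmeth_ratio']:.3f}"
        )

    diff = genome.differential_sites(
        calls["control"], calls["treated"],
        alpha=config.alpha, conversion_error=config.conversion_error,
    )
    genes = simulate.generate_genes(
        config.reference_length, config.n_genes, seed=rngs[5],
        chrom=reference.id,
    )
    write_intervals(genes, outdir / "genes.bed")
    flagged = diff[diff["flagged"]].copy()
    annotated = genome.annotate_sites(flagged, genes, config.gene_distance) \
        if len(flagged) else flagged.assign(gene_label=[], gene_distance=[],
                                            intergenic_5kb=[])
    write_table(diff, outdir / "differential_sites.tsv")
    write_table(annotated, outdir / "differential_sites_annotated.tsv")
    flanks = genome.extract_flanks(
        flagged.sort_values("pos"), reference, config.flank_radius
    ) if len(flagged) else []
    write_sequences(
        [SequenceRecord(f"flank_{iv.start}_{iv.end}", seq)
         for iv, seq in flanks],
        outdir / "flanks.fasta",
    )
    log.info(
        f"differential: {len(diff)} tested, {len(flagged)} flagged at "
        f"alpha {config.alpha} (conversion_error screen {config.conversion_error})"
    )

    summary = {
        "pipeline": "global",
        "seed": config.seed,
        "thresholds": {
            "qc_min_efficiency": config.qc_min_efficiency,
            "alpha": config.alpha,
            "conversion_error": config.conversion_error,
            "gene_distance": config.gene_distance,
            "flank_radius": config.flank_radius,
        },
        "conversion_qc": qc,
        "c_count_summary": summaries,
        "n_sites_tested": len(diff),
        "n_sites_flagged": int(len(flagged)),
        "n_flagged_intergenic_5kb": int(annotated["intergenic_5kb"].sum())
        if len(annotated) else 0,
        "n_flanks": len(flanks),
    }
    (outdir / "summary.json").write_text(
        json.dumps(_jsonable(summary), indent=2)
    )
    log.info("run_global done")
    return summary


def run_amplicon(config: RunConfig, outdir=None) -> dict:
    """Repeat-amplicon pipeline; returns the JSON-ready run summary."""
    config.validate()
    if config.n_molecules <= 0:
        raise ConfigError("n_molecules must be > 0 for an amplicon run")
    outdir = Path(outdir or config.outdir) / "amplicon"
    outdir.mkdir(parents=True, exist_ok=True)
    log = _RunLog(outdir / "run.log")
    log.info(f"run_amplicon start (seed {config.seed})")
    config.to_yaml(outdir / "config.yaml")
    rngs = _stage_seeds(config.seed, 4)

    if config.amplicon_fasta:
        consensus = read_sequences(config.amplicon_fasta, "fasta")[0]
    else:
        consensus = amp.load_consensus(config.amplicon_family)
    primers = (
        amp.LINE1_PRIMERS if config.amplicon_family == "line1" else amp.ALU_PRIMERS
    )
    spec = amp.locate_amplicon(primers, consensus, bisulfite_space=True)
    log.info(
        f"amplicon on {consensus.id}: [{spec.start},{spec.end}) "
        f"length {spec.length}"
    )
    conv = simulate.ConversionSpec(config.under_conversion, config.over_conversion)

    tables = {}
    fits = {}
    correlations = {}
    filter_stats = {}
    arm_rngs = {"control": rngs[0], "treated": rngs[1]}
    values = {}
    for arm_name in ("control", "treated"):
        mix_cfg = config.amplicon_mixtures[arm_name]
        mixture = simulate.MixtureSpec(
            mix_cfg["weights"], mix_cfg["levels"], mix_cfg.get("dispersion")
        )
        aspec = simulate.AmpliconSpec(consensus, primers, config.min_observed_len)
        reads, truth = simulate.simulate_amplicon_reads(
            aspec, mixture, conv, config.n_molecules,
            seed=arm_rngs[arm_name], p_truncate=config.p_truncate,
        )
        write_sequences(reads, outdir / f"{arm_name}_reads.fastq", "fastq")
        write_truth(truth, outdir / f"{arm_name}_truth.tsv")
        kept, n_short, n_dup = amp.filter_and_dedup(reads, config.min_len)
        filter_stats[arm_name] = {
            "n_input": len(reads), "n_too_short": n_short,
            "n_exact_duplicates": n_dup, "n_kept": len(kept),
        }
        table = amp.per_read_table(kept)
        write_table(table, outdir / f"{arm_name}_per_read.tsv")
        metric = table[config.tail_metric].to_numpy(dtype=float)
        hist = amp.distribution_summary(metric, config.histogram_bin_width)
        write_table(hist, outdir / f"{arm_name}_cg_histogram.tsv")
        fits[arm_name] = amp.fit_methylation_mixture(
            metric, seed=arm_rngs[arm_name]
        )
        correlations[arm_name] = amp.cg_tg_correlation(table)
        tables[arm_name] = table
        values[arm_name] = metric
        log.info(
            f"{arm_name}: kept {len(kept)}/{len(reads)} reads "
            f"(min_len {config.min_len}); mixture k={fits[arm_name].k_selected}; "
            f"CG/TG slope {correlations[arm_name].slope:.3f}"
        )

    def _shift(thresholds: dict) -> dict:
        try:
            return amp.tail_shift_test(
                values["control"], values["treated"], thresholds
            )
        except Exception as exc:  # empty control tail category
            return {"undefined": True, "reason": str(exc)}

    tails = _shift({"low": config.tail_low, "high": config.tail_high})
    split = _shift({"split": config.split})
    means = amp.compare_mean_methylation(tables["control"], tables["treated"])
    log.info(
        f"tail shift (<{config.tail_low}/>{config.tail_high}) on "
        f"{config.tail_metric}: p {tails.get('p_value', 'undefined')}; "
        f"split {config.split}: p {split.get('p_value', 'undefined')}"
    )

    summary = {
        "pipeline": "amplicon",
        "seed": config.seed,
        "amplicon": {
            "consensus_id": consensus.id,
            "start": spec.start, "end": spec.end, "length": spec.length,
        },
        "thresholds": {
            "min_len": config.min_len,
            "tail_low": config.tail_low, "tail_high": config.tail_high,
            "split": config.split, "tail_metric": config.tail_metric,
            "histogram_bin_width": config.histogram_bin_width,
        },
        "filters": filter_stats,
        "arms": {
            name: {
                "k_selected": fits[name].k_selected,
                "mixture": fits[name].to_dict(),
                "cg_tg_slope": correlations[name].slope,
                "cg_tg_r_squared": correlations[name].r_squared,
                "cg_tg_p": correlations[name].p_value,
                "correlation_sign": "negative"
                if correlations[name].slope < 0 else "non-negative",
            }
            for name in ("control", "treated")
        },
        "tail_shift_test": tails,
        "split_shift_test": split,
        "mean_comparison": means,
    }
    (outdir / "summary.json").write_text(json.dumps(_jsonable(summary), indent=2))
    log.info("run_amplicon done")
    return summary


def run_all(config: RunConfig, outdir=None) -> dict:
    """Both pipelines under one seed; returns the combined summary."""
    out = {
        "global": run_global(config, outdir),
        "amplicon": run_amplicon(config, outdir),
    }
    base = Path(outdir or config.outdir)
    (base / "summary.json").write_text(json.dumps(_jsonable(out), indent=2))
    return out
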