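"""End-to-end orchestration: alignments -> calls -> sites -> filters ->
group / peak / motif analyses, with a run log of record counts at every
stage so no row is dropped silently."""

from __future__ import annotations

import dataclasses
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import groups, io_formats, methylcall, motifs, peaks as peaks_mod
from .core import sites_to_frame

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    genome_fasta: str
    reads_sam: str
    peaks_file: str
    outdir: str
    compare_cov: Optional[str] = None  # second assay (Bismark .cov) for quadrants
    motif_pfm: Optional[str] = None
    motif_offsets: tuple[int, ...] = (2, 12)
    mapq_min: int = 30
    min_base_quality: int = 20
    min_coverage: int = 5
    merge_strands: bool = True
    quadrant_threshold: float = 0.5
    motif_pvalue: float = 1e-4
    seed: int = 0

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["motif_offsets"] = list(self.motif_offsets)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "motif_offsets" in d:
            d["motif_offsets"] = tuple(d["motif_offsets"])
        return cls(**d)


@dataclass
class RunResult:
    stage_counts: dict = field(default_factory=dict)
    tables: dict = field(default_factory=dict)


def run_pipeline(config: RunConfig) -> RunResult:
    """Run every configured downstream stage and write the TSV outputs.

    Deterministic: no stage draws random numbers, so reruns with the same
    config produce byte-identical outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = RunResult()
    log_lines: list[str] = []

    def log(stage: str, **counts) -> None:
        result.stage_counts[stage] = dict(counts)
        msg = f"{stage}: " + ", ".join(f"{k}={v}" for k, v in counts.items())
        logger.info(msg)
        log_lines.append(msg)

    stage = "load_inputs"
    try:
        genome = io_formats.read_fasta(config.genome_fasta)
        peak_list = io_formats.read_narrowpeak(config.peaks_file)
        aln_stats: Counter = Counter()
        fragments = io_formats.read_alignments(
            config.reads_sam, mapq_min=config.mapq_min, stats=aln_stats
        )
        log(
            stage,
            contigs=len(genome.sequences),
            n_cpg_index=sum(len(v) for v in genome.cpg_index.values()),
            peaks=len(peak_list),
            **dict(aln_stats),
        )

        stage = "methylation_calling"
        calls = methylcall.call_fragments(
            fragments, genome, min_base_quality=config.min_base_quality
        )
        contig = next(iter(genome.sequences))
        sites = methylcall.aggregate_sites(
            calls, merge_strands=config.merge_strands, contig=contig
        )
        io_formats.write_bismark_cov(outdir / "sites.cov", sites)
        log(stage, fragments_called=len(calls), cpg_sites=len(sites))

        stage = "site_filtering"
        filtered = methylcall.filter_sites(
            sites, peak_list, min_coverage=config.min_coverage
        )
        sites_to_frame(filtered).to_csv(
            outdir / "filtered_sites.tsv", sep="\t", index=False
        )
        log(stage, sites_in=len(sites), sites_retained=len(filtered))

        stage = "grouping"
        summary = groups.group_summary(filtered)
        summary.to_csv(outdir / "groups.tsv", sep="\t", index=False)
        counts_df = groups.group_counts(summary)
        counts_df.to_csv(outdir / "group_counts.tsv", sep="\t", index=False)
        result.tables["groups"] = summary
        result.tables["group_counts"] = counts_df
        log(stage, **dict(zip(counts_df["label"], counts_df["n"])))

        stage = "peak_methylation"
        pm = peaks_mod.peak_mean_methylation(peak_list, filtered)
        pm_df = pd.DataFrame(
            [(x.peak_id, x.n_cpgs_used, x.mean_beta) for x in pm],
            columns=["peak", "n_cpgs", "mean_beta"],
        )
        pm_df.to_csv(outdir / "peak_methylation.tsv", sep="\t", index=False)
        result.tables["peak_methylation"] = pm_df
        log(stage, peaks_with_cpgs=len(pm_df))

        if config.compare_cov is not None:
            stage = "quadrants"
            other_sites = io_formats.read_bismark_cov(
                config.compare_cov, merge_strands=config.merge_strands,
                genome=genome,
            )
            other_filtered = methylcall.filter_sites(
                other_sites, peak_list, min_coverage=config.min_coverage
            )
            other_pm = peaks_mod.peak_mean_methylation(peak_list, other_filtered)
            counts, labels = peaks_mod.quadrant_counts(
                pm, other_pm, threshold=config.quadrant_threshold
            )
            qdf = pd.DataFrame(
                [(pid, lab) for pid, lab in sorted(labels.items())],
                columns=["peak", "quadrant"],
            )
            qdf.to_csv(outdir / "quadrants.tsv", sep="\t", index=False)
            result.tables["quadrants"] = qdf
            log(stage, **dict(counts))

        stage = "qc"
        hist, frag_summary = peaks_mod.fragment_length_histogram(fragments)
        qc_df = pd.DataFrame(
            sorted(hist.items()), columns=["fragment_length", "count"]
        )
        qc_df.to_csv(outdir / "qc.tsv", sep="\t", index=False)
        result.tables["fragment_lengths"] = qc_df
        log(stage, **{k: round(v, 2) for k, v in frag_summary.items()})

        if config.motif_pfm is not None:
            stage = "motif_analysis"
            matrix = motifs.read_jaspar_pfm(config.motif_pfm)
            threshold = motifs.pwm_score_threshold(
                matrix, pvalue=config.motif_pvalue
            )
            hits = motifs.scan_motifs(genome, peak_list, matrix, threshold)
            hits_df = pd.DataFrame(
                [
                    (
                        h.contig,
                        h.start0,
                        h.end0,
                        h.strand,
                        round(h.score, 4),
                        ";".join(f"{k}:{c}" for k, c in h.cpg_offsets),
                    )
                    for h in hits
                ],
                columns=["contig", "start", "end", "strand", "score", "cpg_offsets"],
            )
            hits_df.to_csv(outdir / "hits.tsv", sep="\t", index=False)
            result.tables["hits"] = hits_df

            posmeth = motifs.position_methylation(
                hits, filtered, offsets=config.motif_offsets
            )
            result.tables["position_methylation"] = posmeth
            cometh = motifs.pooled_comethylation(
                calls, hits, offsets=config.motif_offsets[:2]
            )
            cdf = pd.DataFrame(
                [
                    {
                        **cometh.counts(),
                        "observed_mm": cometh.observed_mm_fraction,
                        "expected_mm": cometh.expected_mm_fraction,
                        "chi_square": cometh.chi_square,
                        "pvalue": cometh.pvalue,
                    }
                ]
            )
            cdf.to_csv(outdir / "cometh.tsv", sep="\t", index=False)
            result.tables["cometh"] = cometh
            log(
                stage,
                threshold=round(threshold, 4),
                hits=len(hits),
                cometh_n=cometh.n,
            )
    except Exception as e:
        log_lines.append(f"FAILED at stage {stage}: {e}")
        (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e

    config.to_yaml(outdir / "config_used.yaml")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return result
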