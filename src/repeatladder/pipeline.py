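"""End-to-end orchestration: size, structure-check, allele-call, statistics.

A run is driven by a sample manifest (TSV) whose rows map FASTQ files to
donor, cell type, locus and role.  For every donor+locus the designated
``allele_reference`` sample (a non-expanding cell type) is sized first and
its two histogram modes define (N, M); the call is propagated to all
samples of that donor+locus.  Samples with an atypical tract structure
are re-sized against a rebuilt ladder before statistics.  Per-sample
failures are recorded and do not abort the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .alleles import (
    AlleleCall,
    AlleleCallError,
    AlleleCallParams,
    call_progenitor_lengths,
    detect_structure,
    resize_if_atypical,
)
from .cohort import CohortStatsError, GroupComparisonResult, compare_groups
from .locus import LadderReference, LocusTemplate, build_ladder
from .sizing import RepeatHistogram, SizingParams, iter_fastq, size_sample
from .stats import InstabilityStats, UndefinedStatisticError, compute_stats

log = logging.getLogger("repeatladder")

MANIFEST_COLUMNS = ["sample_id", "donor_id", "cell_type", "locus_id", "fastq_path", "role"]


@dataclass(frozen=True)
class PipelineConfig:
    sizing: SizingParams = SizingParams()
    alleles: AlleleCallParams = AlleleCallParams()
    check_structure: bool = True
    statistic: str = "mslg"  # statistic compared across cell types

    def to_dict(self) -> dict:
        return {
            "sizing": asdict(self.sizing),
            "alleles": asdict(self.alleles),
            "check_structure": self.check_structure,
            "statistic": self.statistic,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return cls(
            sizing=SizingParams(**data.get("sizing", {})),
            alleles=AlleleCallParams(**data.get("alleles", {})),
            check_structure=bool(data.get("check_structure", True)),
            statistic=data.get("statistic", "mslg"),
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            return cls.from_dict(yaml.safe_load(handle) or {})


@dataclass
class SampleFailure:
    sample_id: str
    stage: str
    reason: str


@dataclass
class RunReport:
    stats: list[InstabilityStats]
    allele_calls: dict[str, AlleleCall]  # "donor|locus" -> call
    comparisons: dict[str, GroupComparisonResult]  # locus -> result
    failures: list[SampleFailure]
    qc: dict[str, dict]
    provenance: dict


def read_manifest(path) -> pd.DataFrame:
    manifest = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    dupes = manifest["sample_id"][manifest["sample_id"].duplicated()]
    if len(dupes):
        raise ValueError(f"duplicate sample ids: {sorted(set(dupes))}")
    return manifest


def run_sample(
    fastq_path,
    ladder: LadderReference,
    allele_call: AlleleCall,
    config: PipelineConfig = PipelineConfig(),
    sample_id: str = "sample",
) -> tuple[InstabilityStats, RepeatHistogram]:
    """Size one sample and compute its instability statistics.

    The structure check runs on the sized reads; an atypical modal
    structure triggers re-sizing against a matching ladder before any
    statistic is computed.
    """
    t0 = time.perf_counter()
    hist, _ = size_sample(fastq_path, ladder, config.sizing, sample_id=sample_id)
    if config.check_structure:
        reads = list(iter_fastq(fastq_path))
        try:
            structure = detect_structure(reads, ladder.template, config.alleles)
        except AlleleCallError:
            structure = None  # too few parseable reads; keep canonical sizing
        if structure is not None and structure.atypical and not structure.conflicting:
            log.info("%s: atypical structure %s, re-sizing", sample_id,
                     structure.cassette_codon_counts)
            hist, _ = resize_if_atypical(
                reads, ladder.template, structure, hist, config.sizing
            )
    stats = compute_stats(hist, allele_call.N, allele_call.M)
    log.info(
        "%s: %d assigned / %d unassigned in %.1fs",
        sample_id, hist.n_assigned, hist.n_unassigned, time.perf_counter() - t0,
    )
    return stats, hist


def run_cohort(
    manifest: pd.DataFrame,
    templates: dict[str, LocusTemplate],
    config: PipelineConfig = PipelineConfig(),
) -> RunReport:
    """Run the full pipeline over a manifest.

    Phase 1 sizes every allele_reference sample and calls (N, M) per
    donor+locus; phase 2 sizes and scores all samples; phase 3 compares
    the chosen statistic across cell types within each locus.
    """
    manifest = manifest.sort_values("sample_id").reset_index(drop=True)
    ladders = {locus: build_ladder(t) for locus, t in templates.items()}
    failures: list[SampleFailure] = []
    allele_calls: dict[str, AlleleCall] = {}
    qc: dict[str, dict] = {}

    for (donor, locus), group in manifest.groupby(["donor_id", "locus_id"]):
        refs = group[group["role"] == "allele_reference"]
        key = f"{donor}|{locus}"
        if refs.empty:
            continue  # samples of this donor+locus fail below
        last_error = None
        for _, ref_row in refs.iterrows():
            try:
                hist, _ = size_sample(
                    ref_row["fastq_path"],
                    ladders[locus],
                    config.sizing,
                    sample_id=ref_row["sample_id"],
                )
                allele_calls[key] = call_progenitor_lengths(hist, config.alleles)
                break
            except (AlleleCallError, OSError, ValueError) as exc:
                last_error = exc
        if key not in allele_calls and last_error is not None:
            failures.append(
                SampleFailure(str(refs.iloc[0]["sample_id"]), "allele_call", str(last_error))
            )

    all_stats: list[InstabilityStats] = []
    for _, row in manifest.iterrows():
        key = f"{row['donor_id']}|{row['locus_id']}"
        call = allele_calls.get(key)
        if call is None:
            failures.append(
                SampleFailure(
                    row["sample_id"],
                    "allele_call",
                    f"no allele_reference call for donor {row['donor_id']} "
                    f"at locus {row['locus_id']}",
                )
            )
            continue
        try:
            stats, hist = run_sample(
                row["fastq_path"],
                ladders[row["locus_id"]],
                call,
                config,
                sample_id=row["sample_id"],
            )
        except (UndefinedStatisticError, AlleleCallError, OSError, ValueError) as exc:
            failures.append(SampleFailure(row["sample_id"], "stats", str(exc)))
            continue
        all_stats.append(stats)
        qc[row["sample_id"]] = {
            "n_assigned": hist.n_assigned,
            "n_unassigned": hist.n_unassigned,
            "unassigned_reasons": dict(hist.unassigned_reasons),
            "intermediate_reads": stats.n_intermediate_reads,
        }

    comparisons: dict[str, GroupComparisonResult] = {}
    by_sample = {s.sample_id: s for s in all_stats}
    for locus, group in manifest.groupby("locus_id"):
        scored = group[
            (group["role"] == "sample") & group["sample_id"].isin(by_sample)
        ]
        values: dict[str, list[float]] = {}
        for cell_type, sub in scored.groupby("cell_type"):
            values[cell_type] = [
                getattr(by_sample[sid], config.statistic) for sid in sub["sample_id"]
            ]
        values = {k: v for k, v in values.items() if len(v) >= 2}
        if len(values) >= 2:
            try:
                comparisons[locus] = compare_groups(values)
            except CohortStatsError as exc:
                log.warning("%s: cohort comparison failed: %s", locus, exc)

    config_hash = hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:16]
    return RunReport(
        stats=all_stats,
        allele_calls=allele_calls,
        comparisons=comparisons,
        failures=failures,
        qc=qc,
        provenance={
            "version": __version__,
            "config": config.to_dict(),
            "config_hash": config_hash,
            "n_samples": int(len(manifest)),
        },
    )


# ---------------------------------------------------------------------------
# Report serialization

def stats_frame(report: RunReport) -> pd.DataFrame:
    rows = [
        {
            "sample_id": s.sample_id,
            "locus_id": s.locus_id,
            "N": s.N,
            "M": s.M,
            "rose_normal": s.rose_normal,
            "rose_mutant": s.rose_mutant,
            "mslg": s.mslg,
            "n_mutant_reads": s.n_mutant_reads,
            "n_normal_reads": s.n_normal_reads,
            "n_intermediate_reads": s.n_intermediate_reads,
            "n_assigned": s.n_assigned,
            "n_unassigned": s.n_unassigned,
        }
        for s in report.stats
    ]
    return pd.DataFrame(rows)


def write_report(report: RunReport, out_dir) -> None:
    """Write stats TSV, normalized histograms TSV, and a JSON report."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stats_frame(report).to_csv(out_dir / "stats.tsv", sep="\t", index=False)
    hist_rows = [
        {"sample_id": s.sample_id, "i": i, "normalized_count": c}
        for s in report.stats
        for i, c in sorted(s.normalized_hist.items())
    ]
    pd.DataFrame(hist_rows).to_csv(
        out_dir / "normalized_histograms.tsv", sep="\t", index=False
    )
    payload = {
        "provenance": report.provenance,
        "allele_calls": {
            key: {"N": c.N, "M": c.M, "source_sample_id": c.source_sample_id}
            for key, c in report.allele_calls.items()
        },
        "comparisons": {
            locus: {
                "F": r.F,
                "p_overall": r.p_overall,
                "p_underflow": r.p_underflow,
                "pairwise": [
                    {
                        "pair": list(p.pair),
                        "raw_p": p.raw_p,
                        "adjusted_p": p.adjusted_p,
                        "t": p.t,
                    }
                    for p in r.pairwise
                ],
                "groups": r.groups,
            }
            for locus, r in report.comparisons.items()
        },
        "failures": [asdict(f) for f in report.failures],
        "qc": report.qc,
    }
    with open(out_dir / "report.json", "w") as handle:
        json.dump(payload, handle, indent=2)
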