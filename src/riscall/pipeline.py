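"""End-to-end orchestration: trim -> align -> filter -> call -> annotate -> report.

Per-query alignment lists are processed independently (a streaming
group-by-query pass), so memory stays bounded by the largest per-query
group rather than the whole alignment table. A run manifest records the
config snapshot, input digests and per-stage record counts, making the
read funnel auditable: every input read ends up as exactly one unique-
site contributor, repeat/in-range member, or filter-reason entry.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from riscall.alignment import ReferenceSet, align
from riscall.annotation_stats import (
    ChiSquareResult,
    IntegrationSummary,
    ProximityReport,
    annotate_site,
    summarize,
)
from riscall.config import PipelineConfig
from riscall.filtering_calling import (
    CandidateRIS,
    UniqueRIS,
    call_unique_ris,
    select_candidates,
)
from riscall.formats_io import (
    GeneModel,
    GenomicFeature,
    SequenceRead,
    write_chisq_csv,
    write_reports,
)
from riscall.random_sites import RandomSiteRequest, random_control_run
from riscall.trimming import FilterReason, Query, trim_batch


@dataclass
class PipelineResult:
    queries: List[Query]
    filter_reasons: List[FilterReason]  # all stages, pipeline order
    candidates: List[CandidateRIS]
    unique_ris: List[UniqueRIS]
    annotations: Dict[Tuple[str, str, int], ProximityReport]
    summary: Optional[IntegrationSummary]
    chisq: List[Tuple[str, ChiSquareResult]]
    manifest: dict
    written: Dict[str, Path] = field(default_factory=dict)


def _digest(reads: Sequence[SequenceRead]) -> str:
    h = hashlib.sha256()
    for r in reads:
        h.update(r.read_id.encode())
        h.update(b"\x00")
        h.update(r.sequence.encode())
        h.update(b"\n")
    return h.hexdigest()


def run_pipeline(
    reads: Sequence[SequenceRead],
    ltr: str,
    refs: ReferenceSet,
    *,
    lc: Optional[str] = None,
    genes: Sequence[GeneModel] = (),
    feature_lists: Optional[Dict[str, Sequence[GenomicFeature]]] = None,
    cfg: Optional[PipelineConfig] = None,
    backend: str = "builtin",
    blast8_path=None,
    command_template: Optional[str] = None,
    random_req: Optional[RandomSiteRequest] = None,
    out_dir=None,
) -> PipelineResult:
    """Run the full integration-site pipeline on a read set.

    Stages, in order: junction trimming; alignment to genome + vector
    via the chosen backend; initial + ambiguity filtering into candidate
    sites; clustering into unique sites; gene/TSS/feature annotation;
    optional random-control comparison (``random_req``); CSV + manifest
    output when ``out_dir`` is given.
    """
    cfg = cfg or PipelineConfig()

    queries, trim_reasons = trim_batch(reads, ltr, lc, cfg)
    records = align(
        queries,
        refs,
        backend=backend,
        blast8_path=blast8_path,
        command_template=command_template,
    )
    candidates, align_reasons = select_candidates(
        records, [q.read_id for q in queries], cfg, refs.vector_name
    )
    unique = call_unique_ris(candidates, cfg)

    annotations: Dict[Tuple[str, str, int], ProximityReport] = {}
    observed_reports: List[ProximityReport] = []
    if genes or feature_lists:
        for ris in unique:
            rep = annotate_site(
                ris.chrom, ris.strand, ris.position, genes, feature_lists, cfg
            )
            annotations[(ris.chrom, ris.strand, ris.position)] = rep
            observed_reports.append(rep)

    summary: Optional[IntegrationSummary] = None
    chisq: List[Tuple[str, ChiSquareResult]] = []
    random_reports: Optional[List[ProximityReport]] = None
    if observed_reports:
        if random_req is not None:
            random_reports, _, _ = random_control_run(
                refs, genes, feature_lists, random_req, cfg
            )
        summary, chisq = summarize(observed_reports, random_reports, cfg)

    all_reasons = trim_reasons + align_reasons
    reason_counts: Dict[str, int] = {}
    for fr in all_reasons:
        reason_counts[fr.reason] = reason_counts.get(fr.reason, 0) + 1
    manifest = {
        "config": cfg.to_dict(),
        "inputs": {
            "reads_sha256": _digest(reads),
            "n_reads": len(reads),
            "ltr": ltr,
            "lc": lc or "",
            "backend": backend,
        },
        "counts": {
            "reads_in": len(reads),
            "queries": len(queries),
            "alignments": len(records),
            "candidates": len(candidates),
            "unique_ris": len(unique),
            "eliminations": reason_counts,
        },
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    # conservation identities, asserted at run time
    assert len(reads) == len(queries) + len(trim_reasons)
    assert len(queries) == len(candidates) + len(align_reasons)
    assert sum(r.frequency for r in unique) == len(candidates)

    result = PipelineResult(
        queries=queries,
        filter_reasons=all_reasons,
        candidates=candidates,
        unique_ris=unique,
        annotations=annotations,
        summary=summary,
        chisq=chisq,
        manifest=manifest,
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        summary_dict = None
        if summary is not None:
            summary_dict = {
                "n_unique": summary.n_unique,
                "pct_in_genes": f"{summary.pct_in_genes:.2f}",
                "n_within_5kb": summary.n_within_5kb,
                **{
                    f"within_{name}": count
                    for name, count in summary.feature_within_counts.items()
                },
            }
        result.written = write_reports(
            unique, all_reasons, summary_dict, out_dir, annotations=annotations
        )
        if chisq:
            chisq_path = out_dir / "chisq.csv"
            write_chisq_csv(chisq, chisq_path)
            result.written["chisq"] = chisq_path
        manifest_path = out_dir / "manifest.json"
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        result.written["manifest"] = manifest_path
    return result
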