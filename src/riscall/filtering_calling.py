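"""Alignment filtering, candidate selection, and unique-site clustering.

A trimmed query's alignments go through, in order:

1. the initial filter — minimum score, minimum percent identity, and a
   cap on how far into the query the alignment may start;
2. retention of the top-k (default 5) greatest-scoring alignments;
3. the ambiguity filters — best hit to the vector, second-best score too
   close to the best (95 % tier for best scores >= 100, 90 % below), or
   best-hit identity below 95 %.

A query surviving all three contributes one candidate integration site:
the genomic coordinate paired with the first query base (the junction
base) of its best alignment. Candidates within +/-5 bp on the same
chromosome and strand are clustered; the greatest-scoring candidate in
each cluster is the unique site, co-clustered candidates at the exact
coordinate are "repeat" members and the rest "in range" members. The
cluster's frequency (total reads) and span count (distinct distal
fragment endpoints, i.e. shear sites) together distinguish PCR
duplication from clonal expansion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple, Union

from riscall.config import PipelineConfig
from riscall.formats_io import AlignmentRecord
from riscall.trimming import FilterReason


@dataclass(frozen=True)
class CandidateRIS:
    """The best unambiguous genomic placement of one read.

    ``position`` is the coordinate of the LTR-proximal junction base
    (t_start of the best alignment, on either strand); ``far_end`` is
    the distal aligned base (t_end), the shear/linker side.
    """

    read_id: str
    chrom: str
    strand: str
    position: int
    far_end: int
    score: float
    percent_identity: float


@dataclass
class UniqueRIS:
    """A clustered unique integration site.

    ``members`` holds (candidate, label) pairs; exactly one member is
    labelled "unique" (the representative), same-coordinate members are
    "repeat_ris" and the rest "in_range_ris".
    """

    chrom: str
    strand: str
    position: int
    score: float
    members: List[Tuple[CandidateRIS, str]] = field(default_factory=list)

    @property
    def frequency(self) -> int:
        return len(self.members)

    @property
    def span_count(self) -> int:
        return len({c.far_end for c, _ in self.members})


def initial_filter(
    records: Iterable[AlignmentRecord], cfg: PipelineConfig
) -> List[AlignmentRecord]:
    """Drop alignments below the score/identity floors or starting more
    than ``max_qstart_offset`` bp into the query (q_start - 1 > offset)."""
    return [
        r
        for r in records
        if r.score >= cfg.min_score
        and r.percent_identity >= cfg.min_identity_initial
        and (r.q_start - 1) <= cfg.max_qstart_offset
    ]


def top_k_per_query(
    records: Iterable[AlignmentRecord], cfg: PipelineConfig
) -> Dict[str, List[AlignmentRecord]]:
    """Retain the top-k greatest-scoring alignments per query.

    Sorted by score descending; ties broken by (target_id, t_start)
    ascending so truncation at rank k is deterministic.
    """
    grouped: Dict[str, List[AlignmentRecord]] = {}
    for rec in records:
        grouped.setdefault(rec.query_id, []).append(rec)
    return {
        qid: sorted(recs, key=lambda r: (-r.score, r.target_id, r.t_start))[: cfg.top_k]
        for qid, recs in grouped.items()
    }


def classify_query(
    top_list: Sequence[AlignmentRecord],
    cfg: PipelineConfig,
    vector_name: str,
) -> Union[CandidateRIS, FilterReason]:
    """Apply the ambiguity filters to a query's score-sorted top list.

    In order: (a) best hit targets the vector; (b) second-best score
    exceeds the tier threshold as a percentage of the best (vector
    second hits included — a strong vector runner-up still signals
    ambiguity); (c) best-hit percent identity below the floor. A query
    passing all three yields a CandidateRIS from its best alignment.
    """
    if not top_list:
        raise ValueError("classify_query requires a non-empty top list")
    best = top_list[0]
    if best.target_id == vector_name:
        return FilterReason(best.query_id, "vector_best")
    if len(top_list) > 1:
        second = top_list[1]
        threshold = (
            cfg.ratio_hi if best.score >= cfg.ratio_score_boundary else cfg.ratio_lo
        )
        if best.score > 0 and 100.0 * second.score / best.score > threshold:
            return FilterReason(best.query_id, "ambiguous_second_best")
    if best.percent_identity < cfg.min_best_identity:
        return FilterReason(best.query_id, "low_best_identity")
    return CandidateRIS(
        read_id=best.query_id,
        chrom=best.target_id,
        strand=best.strand,
        position=best.t_start,
        far_end=best.t_end,
        score=best.score,
        percent_identity=best.percent_identity,
    )


def select_candidates(
    records: Iterable[AlignmentRecord],
    query_ids: Iterable[str],
    cfg: PipelineConfig,
    vector_name: str,
) -> Tuple[List[CandidateRIS], List[FilterReason]]:
    """Full filtering funnel: initial filter, top-k, ambiguity filters.

    Queries with no alignment surviving the initial filter are reported
    as ``no_passing_alignment``. Output order follows the input query
    order.
    """
    surviving = initial_filter(records, cfg)
    per_query = top_k_per_query(surviving, cfg)
    candidates: List[CandidateRIS] = []
    reasons: List[FilterReason] = []
    for qid in query_ids:
        top = per_query.get(qid)
        if not top:
            reasons.append(FilterReason(qid, "no_passing_alignment"))
            continue
        result = classify_query(top, cfg, vector_name)
        if isinstance(result, CandidateRIS):
            candidates.append(result)
        else:
            reasons.append(result)
    return candidates, reasons


def call_unique_ris(
    candidates: Iterable[CandidateRIS], cfg: PipelineConfig
) -> List[UniqueRIS]:
    """Cluster candidates into unique sites within a +/-halfwidth window.

    Greedy, per (chrom, strand): repeatedly promote the greatest-scoring
    unassigned candidate (ties: lowest position, then read_id) to a
    unique site and absorb every unassigned candidate within
    ``cluster_halfwidth`` bp of it. Same-coordinate members are labelled
    repeat_ris, others in_range_ris. The result is sorted by
    (chrom, position, strand) and is independent of input order.
    """
    buckets: Dict[Tuple[str, str], List[CandidateRIS]] = {}
    for cand in candidates:
        buckets.setdefault((cand.chrom, cand.strand), []).append(cand)

    result: List[UniqueRIS] = []
    for (chrom, strand), group in buckets.items():
        pending = sorted(group, key=lambda c: (-c.score, c.position, c.read_id))
        while pending:
            rep = pending[0]
            members = [
                c for c in pending if abs(c.position - rep.position) <= cfg.cluster_halfwidth
            ]
            ris = UniqueRIS(chrom=chrom, strand=strand, position=rep.position, score=rep.score)
            for c in members:
                if c is rep:
                    label = "unique"
                elif c.position == rep.position:
                    label = "repeat_ris"
                else:
                    label = "in_range_ris"
                ris.members.append((c, label))
            result.append(ris)
            assigned = set(map(id, members))
            pending = [c for c in pending if id(c) not in assigned]
    result.sort(key=lambda r: (r.chrom, r.position, r.strand))
    return result
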