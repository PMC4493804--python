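"""LTR-chromosome junction detection and query trimming.

LTR-primed sequencing of integration libraries yields reads laid out as
LTR + genomic flank (+ optional linker cassette, LC, for LAM-PCR). The
genomic portion between the LTR and the LC is the alignment query; its
first base defines the integration site. Trimming is exact substring
matching, applied in a fixed order:

1. find the LTR; no LTR -> the read is eliminated (reason ``no_ltr``);
2. optionally find the LC within the query and truncate before it;
3. truncate before any run of >= ``n_run_limit`` consecutive Ns;
4. eliminate queries shorter than ``min_query_len`` (reason ``too_short``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, List, Optional, Tuple, Union

from riscall.config import PipelineConfig
from riscall.formats_io import SequenceRead

FILTER_REASONS = (
    "no_ltr",
    "too_short",
    "vector_best",
    "ambiguous_second_best",
    "low_best_identity",
    "no_passing_alignment",
)


@dataclass(frozen=True)
class Query:
    """A trimmed genomic query ready for alignment."""

    read_id: str
    sequence: str
    ltr_end_in_read: int  # 0-based offset in the read where genomic sequence begins
    lc_found: bool = False
    truncated_at_n_run: bool = False


@dataclass(frozen=True)
class FilterReason:
    """Why a read or query was eliminated; exactly one reason per read."""

    read_id: str
    reason: str

    def __post_init__(self) -> None:
        if self.reason not in FILTER_REASONS:
            raise ValueError(f"unknown filter reason {self.reason!r}")


def find_ltr(read: SequenceRead, ltr: str) -> Optional[int]:
    """Locate the LTR in a read; return the 0-based offset of the first
    genomic base (the base after the first LTR occurrence), or None.

    Matching is exact and case-insensitive; only the first occurrence
    counts, keeping the genomic portion maximal.
    """
    if not ltr:
        raise ValueError("LTR sequence must be non-empty")
    idx = read.sequence.upper().find(ltr.upper())
    if idx < 0:
        return None
    return idx + len(ltr)


def _first_n_run(seq: str, run_len: int) -> Optional[int]:
    """0-based start of the first run of >= run_len consecutive Ns."""
    m = re.search("N" * run_len, seq)
    return m.start() if m else None


def trim_read(
    read: SequenceRead,
    ltr: str,
    lc: Optional[str],
    cfg: PipelineConfig,
) -> Union[Query, FilterReason]:
    """Trim one read to its genomic query, or eliminate it.

    The length check applies to the final query after LC and N-run
    truncation, so a long read can still fail as ``too_short``.
    """
    seq = read.sequence.upper()
    offset = find_ltr(read, ltr)
    if offset is None:
        return FilterReason(read.read_id, "no_ltr")
    query = seq[offset:]

    lc_found = False
    if lc:
        lc_idx = query.find(lc.upper())
        if lc_idx >= 0:
            lc_found = True
            query = query[:lc_idx]

    truncated = False
    n_idx = _first_n_run(query, cfg.n_run_limit)
    if n_idx is not None:
        truncated = True
        query = query[:n_idx]

    if len(query) < cfg.min_query_len:
        return FilterReason(read.read_id, "too_short")
    return Query(
        read_id=read.read_id,
        sequence=query,
        ltr_end_in_read=offset,
        lc_found=lc_found,
        truncated_at_n_run=truncated,
    )


def trim_batch(
    reads: Iterable[SequenceRead],
    ltr: str,
    lc: Optional[str],
    cfg: PipelineConfig,
) -> Tuple[List[Query], List[FilterReason]]:
    """Trim a batch of reads into (queries, filter_reasons).

    Every read yields exactly one Query or one FilterReason, preserving
    input order within each list. Duplicate read ids are an error since
    ids key all downstream joins.
    """
    queries: List[Query] = []
    reasons: List[FilterReason] = []
    seen = set()
    for read in reads:
        if read.read_id in seen:
            raise ValueError(f"duplicate read id {read.read_id!r}")
        seen.add(read.read_id)
        result = trim_read(read, ltr, lc, cfg)
        if isinstance(result, Query):
            queries.append(result)
        else:
            reasons.append(result)
    return queries, reasons
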