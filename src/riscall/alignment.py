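"""Alignment backends producing blast8 records for queries vs genome + vector.

Three backends:

``builtin``
    A deterministic, exhaustive, ungapped seed-and-extend aligner. It is
    a test oracle and toy-genome workhorse, not a BLAT replacement: it
    reports full-length ungapped placements of each query on both
    strands of every reference sequence. With the default seed length it
    finds every placement at >= 92 % identity for queries >= 30 bp
    (pigeonhole: such a placement always contains an exact 10-mer).
``blast8_file``
    Pre-computed alignments (e.g. from BLAT ``-out=blast8``) loaded
    from disk.
``external_command``
    A user-supplied shell template that must write blast8.
"""

from __future__ import annotations

import shlex
import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

from riscall.formats_io import AlignmentRecord, read_blast8, write_fasta
from riscall.trimming import Query

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _qpair(query) -> tuple:
    """(id, sequence) from a Query, SequenceRead, or plain pair."""
    if hasattr(query, "read_id"):
        return query.read_id, query.sequence
    return tuple(query)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReferenceSet:
    """Named genome sequences plus the vector sequence.

    The vector is aligned alongside the chromosomes so that reads whose
    best placement is internal vector sequence can be filtered out.
    """

    genome: Dict[str, str]
    vector: str = ""
    vector_name: str = "vector"

    def __post_init__(self) -> None:
        if self.vector and self.vector_name in self.genome:
            raise ValueError(
                f"vector name {self.vector_name!r} collides with a chromosome name"
            )

    @property
    def targets(self) -> Dict[str, str]:
        """All alignment targets: chromosomes, then the vector (if any)."""
        t = dict(self.genome)
        if self.vector:
            t[self.vector_name] = self.vector
        return t


# score calibration: a perfect 30 bp ungapped alignment scores exactly 60,
# matching the coupling between the 30 bp minimum query length and the
# alignment-score cutoff of 60.
MATCH_SCORE = 2.0
MISMATCH_PENALTY = 6.0
DEFAULT_MIN_SEED = 10
DEFAULT_MIN_REPORT_IDENTITY = 90.0


def _placement_record(
    query_id: str,
    qseq: str,
    target_id: str,
    tseq: str,
    offset: int,
    strand: str,
) -> Optional[AlignmentRecord]:
    """Score the full-length ungapped placement of qseq at 0-based offset.

    On '-' the caller passes the reverse-complemented query; coordinates
    are reported in target space with t_start > t_end.
    """
    L = len(qseq)
    window = tseq[offset : offset + L]
    mism = sum(1 for a, b in zip(qseq, window) if a != b or a == "N")
    matches = L - mism
    identity = 100.0 * matches / L
    score = MATCH_SCORE * matches - MISMATCH_PENALTY * mism
    if strand == "+":
        t_start, t_end = offset + 1, offset + L
    else:
        t_start, t_end = offset + L, offset + 1
    return AlignmentRecord(
        query_id=query_id,
        target_id=target_id,
        percent_identity=round(identity, 2),
        aln_length=L,
        mismatches=mism,
        gap_openings=0,
        q_start=1,
        q_end=L,
        t_start=t_start,
        t_end=t_end,
        e_value=0.0,
        score=score,
    )


def _seed_index(tseq: str, k: int) -> Dict[str, List[int]]:
    index: Dict[str, List[int]] = {}
    for i in range(len(tseq) - k + 1):
        kmer = tseq[i : i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)
    return index


def builtin_align(
    query,
    refs: ReferenceSet,
    min_seed: int = DEFAULT_MIN_SEED,
    min_identity: float = DEFAULT_MIN_REPORT_IDENTITY,
    _indexes: Optional[Dict[str, Dict[str, List[int]]]] = None,
) -> List[AlignmentRecord]:
    """Exhaustively align one query (Query or (id, seq) pair), both strands.

    Every full-length ungapped placement sharing an exact ``min_seed``-mer
    with the target and reaching ``min_identity`` percent identity is
    reported. Records are ordered by (target, t_start position) on '+'
    before '-' at the same locus, deterministically.
    """
    qid, qseq = _qpair(query)
    qseq = qseq.upper()
    if len(qseq) < min_seed:
        raise ValueError(
            f"query {qid!r} shorter ({len(qseq)}) than the seed length ({min_seed})"
        )
    records: List[AlignmentRecord] = []
    for target_id in sorted(refs.targets):
        tseq = refs.targets[target_id]
        if len(tseq) < len(qseq):
            continue
        if _indexes is not None:
            index = _indexes[target_id]
        else:
            index = _seed_index(tseq, min_seed)
        hits = []
        for strand, oriented in (("+", qseq), ("-", reverse_complement(qseq))):
            offsets = set()
            for j in range(len(oriented) - min_seed + 1):
                kmer = oriented[j : j + min_seed]
                for pos in index.get(kmer, ()):
                    off = pos - j
                    if 0 <= off <= len(tseq) - len(oriented):
                        offsets.add(off)
            for off in sorted(offsets):
                rec = _placement_record(qid, oriented, target_id, tseq, off, strand)
                if rec is not None and rec.percent_identity >= min_identity:
                    hits.append((off, 0 if strand == "+" else 1, rec))
        hits.sort(key=lambda h: (h[0], h[1]))
        records.extend(h[2] for h in hits)
    return records


def align(
    queries: Sequence,
    refs: Optional[ReferenceSet] = None,
    backend: str = "builtin",
    blast8_path=None,
    command_template: Optional[str] = None,
    min_seed: int = DEFAULT_MIN_SEED,
    min_identity: float = DEFAULT_MIN_REPORT_IDENTITY,
) -> List[AlignmentRecord]:
    """Align queries against a reference set via the chosen backend.

    backend='builtin' runs the exhaustive ungapped aligner; 'blast8_file'
    loads pre-computed records from ``blast8_path``; 'external_command'
    substitutes {queries}, {reference} and {output} into
    ``command_template``, runs it, and reads the blast8 it wrote.
    Records referencing query ids not in ``queries`` trigger a warning
    but are kept.
    """
    query_ids = {_qpair(q)[0] for q in queries}

    if backend == "builtin":
        if refs is None:
            raise ValueError("builtin backend requires a ReferenceSet")
        indexes = {t: _seed_index(s, min_seed) for t, s in refs.targets.items()}
        records: List[AlignmentRecord] = []
        for q in queries:
            records.extend(
                builtin_align(q, refs, min_seed, min_identity, _indexes=indexes)
            )
        return records

    if backend == "blast8_file":
        if blast8_path is None:
            raise ValueError("blast8_file backend requires blast8_path")
        records = read_blast8(blast8_path)
    elif backend == "external_command":
        if command_template is None or refs is None:
            raise ValueError(
                "external_command backend requires command_template and a ReferenceSet"
            )
        records = _run_external(queries, refs, command_template)
    else:
        raise ValueError(f"unknown backend {backend!r}")

    unknown = {r.query_id for r in records} - query_ids
    if unknown:
        warnings.warn(
            f"blast8 references {len(unknown)} unknown query id(s), e.g. "
            f"{sorted(unknown)[:3]}; records kept",
            stacklevel=2,
        )
    return records


def _run_external(queries, refs: ReferenceSet, template: str) -> List[AlignmentRecord]:
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        qpath, rpath, opath = tmp / "queries.fa", tmp / "reference.fa", tmp / "out.blast8"
        pairs = [_qpair(q) for q in queries]
        write_fasta(pairs, qpath)
        write_fasta(list(refs.targets.items()), rpath)
        cmd = template.format(queries=qpath, reference=rpath, output=opath)
        proc = subprocess.run(shlex.split(cmd), capture_output=True, text=True)
        if proc.returncode != 0:
            raise RuntimeError(
                f"external aligner failed with exit status {proc.returncode}: "
                f"{proc.stderr.strip()[:500]}"
            )
        if not opath.exists():
            raise RuntimeError("external aligner wrote no output file")
        return read_blast8(opath)
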