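"""Readers and writers for the external formats the pipeline touches.

Internal genomic coordinates are 1-based inclusive throughout (the native
convention of blast8 alignment records); BED and genePred/refFlat inputs,
which use 0-based half-open starts, are converted at this boundary.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Union

from Bio import SeqIO

PathLike = Union[str, os.PathLike]

VALID_BASES = set("ACGTN")


@dataclass(frozen=True)
class SequenceRead:
    """A raw FASTA read; sequence is stored uppercased."""

    read_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.read_id:
            raise ValueError("read_id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"read {self.read_id!r}: empty sequence")


@dataclass(frozen=True)
class AlignmentRecord:
    """One 12-column blast8 (BLAST tabular) row.

    Coordinates are 1-based inclusive. A target interval given with
    t_start > t_end encodes a minus-strand alignment; the raw order is
    preserved so records round-trip losslessly.
    """

    query_id: str
    target_id: str
    percent_identity: float
    aln_length: int
    mismatches: int
    gap_openings: int
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    e_value: float
    score: float

    @property
    def strand(self) -> str:
        """'+' if t_start <= t_end else '-'."""
        return "+" if self.t_start <= self.t_end else "-"

    def to_blast8_line(self) -> str:
        return "\t".join(
            [
                self.query_id,
                self.target_id,
                _fmt_float(self.percent_identity),
                str(self.aln_length),
                str(self.mismatches),
                str(self.gap_openings),
                str(self.q_start),
                str(self.q_end),
                str(self.t_start),
                str(self.t_end),
                repr(self.e_value),
                _fmt_float(self.score),
            ]
        )


def _fmt_float(x: float) -> str:
    # blast8 prints identity/score with 2 decimals; keep full precision
    # when the value is not representable that way.
    if round(x, 2) == x:
        return f"{x:.2f}"
    return repr(x)


@dataclass(frozen=True)
class GeneModel:
    """A strand-aware gene with transcription bounds, 1-based inclusive."""

    gene_name: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_name!r}: bad strand {self.strand!r}")
        if self.tx_start > self.tx_end:
            raise ValueError(f"gene {self.gene_name!r}: tx_start > tx_end")

    @property
    def tss(self) -> int:
        """Transcription start site: tx_start on '+', tx_end on '-'."""
        return self.tx_start if self.strand == "+" else self.tx_end

    @property
    def span(self) -> int:
        return self.tx_end - self.tx_start + 1


@dataclass(frozen=True)
class GenomicFeature:
    """A generic genomic interval, 1-based inclusive."""

    feature_name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"feature {self.feature_name!r}: start > end")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# readers


def read_fasta(path: PathLike) -> List[SequenceRead]:
    """Read a FASTA file into SequenceReads, order preserved, uppercased.

    Raises ParseError naming the record index on an empty sequence or a
    header-less record.
    """
    reads: List[SequenceRead] = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        seq = str(rec.seq).upper()
        if not rec.id:
            raise ParseError(f"record {i}: missing identifier")
        if not seq:
            raise ParseError(f"record {i} ({rec.id!r}): empty sequence")
        reads.append(SequenceRead(rec.id, seq))
    return reads


def read_blast8(path: PathLike) -> List[AlignmentRecord]:
    """Parse 12-column BLAST tabular ("blast8") alignments.

    Field-exact: t_start > t_end (minus strand) is preserved, not
    normalised. A line with the wrong column count raises ParseError
    with the 1-based line number.
    """
    records: List[AlignmentRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise ParseError(
                    f"line {lineno}: expected 12 tab-separated columns, got {len(cols)}"
                )
            try:
                rec = AlignmentRecord(
                    query_id=cols[0],
                    target_id=cols[1],
                    percent_identity=float(cols[2]),
                    aln_length=int(cols[3]),
                    mismatches=int(cols[4]),
                    gap_openings=int(cols[5]),
                    q_start=int(cols[6]),
                    q_end=int(cols[7]),
                    t_start=int(cols[8]),
                    t_end=int(cols[9]),
                    e_value=float(cols[10]),
                    score=float(cols[11]),
                )
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
            records.append(rec)
    return records


def write_blast8(records: Iterable[AlignmentRecord], path: PathLike) -> None:
    """Write records as 12-column blast8, one per line."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(rec.to_blast8_line() + "\n")


# genePred: name chrom strand txStart txEnd cdsStart cdsEnd exonCount ...
# refFlat:  geneName name chrom strand txStart txEnd ...
_GENE_DIALECTS = {
    "genePred": {"name": 0, "chrom": 1, "strand": 2, "tx_start": 3, "tx_end": 4, "min_cols": 5},
    "refFlat": {"name": 0, "chrom": 2, "strand": 3, "tx_start": 4, "tx_end": 5, "min_cols": 6},
}


def read_genes(path: PathLike, dialect: str = "refFlat") -> List[GeneModel]:
    """Read gene annotations in genePred or refFlat dialect.

    Transcription bounds are converted from the dialects' 0-based
    half-open starts to 1-based inclusive coordinates; the TSS is then
    tx_start on '+' genes and tx_end on '-' genes.
    """
    if dialect not in _GENE_DIALECTS:
        raise ValueError(
            f"unknown gene dialect {dialect!r}; choose from {sorted(_GENE_DIALECTS)}"
        )
    d = _GENE_DIALECTS[dialect]
    genes: List[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < d["min_cols"]:
                raise ParseError(
                    f"line {lineno}: {dialect} needs >= {d['min_cols']} columns, got {len(cols)}"
                )
            strand = cols[d["strand"]]
            if strand not in ("+", "-"):
                raise ParseError(f"line {lineno}: unknown strand symbol {strand!r}")
            tx_start0 = int(cols[d["tx_start"]])
            tx_end_excl = int(cols[d["tx_end"]])
            genes.append(
                GeneModel(
                    gene_name=cols[d["name"]],
                    chrom=cols[d["chrom"]],
                    strand=strand,
                    tx_start=tx_start0 + 1,
                    tx_end=tx_end_excl,
                )
            )
    return genes


def read_features_bed(path: PathLike) -> List[GenomicFeature]:
    """Read BED3+ features, converting to 1-based inclusive coordinates.

    Unnamed intervals get auto-generated names "feature_<n>". BED rows
    with start >= end are rejected (zero-length intervals carry no
    genomic extent).
    """
    feats: List[GenomicFeature] = []
    with open(path) as fh:
        n = 0
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(f"line {lineno}: BED needs >= 3 columns")
            start0, end_excl = int(cols[1]), int(cols[2])
            if start0 >= end_excl:
                raise ParseError(
                    f"line {lineno}: BED start ({start0}) must be < end ({end_excl})"
                )
            n += 1
            name = cols[3] if len(cols) > 3 and cols[3] else f"feature_{n}"
            feats.append(
                GenomicFeature(
                    feature_name=name, chrom=cols[0], start=start0 + 1, end=end_excl
                )
            )
    return feats


def read_reference_fasta(path: PathLike) -> dict:
    """Read a reference FASTA into an {name: uppercase sequence} dict."""
    seqs = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ParseError(f"duplicate reference sequence name {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(entries: Iterable, path: PathLike) -> None:
    """Write (id, sequence) pairs or SequenceReads as FASTA, 70-col wrap."""
    with open(path, "w") as fh:
        for entry in entries:
            if isinstance(entry, SequenceRead):
                name, seq = entry.read_id, entry.sequence
            else:
                name, seq = entry
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# report writing

CONCISE_COLUMNS = [
    "chrom",
    "position",
    "strand",
    "frequency",
    "span_count",
    "score",
    "in_gene",
    "nearest_gene",
    "gene_distance",
    "gene_side",
    "nearest_tss_gene",
    "tss_distance",
]

MEMBER_COLUMNS = ["read_id", "chrom", "position", "strand", "label", "unique_position"]


def write_reports(
    unique_ris: Sequence,
    filter_reasons: Sequence,
    summary: Optional[dict],
    out_dir: PathLike,
    annotations: Optional[dict] = None,
) -> dict:
    """Write the concise and complete CSV results.

    concise.csv holds one row per unique RIS (plus gene/TSS annotation
    columns when ``annotations`` maps a (chrom, strand, position) key to
    a ProximityReport). The complete output adds members.csv, labelling
    every contributing read as unique / repeat_ris / in_range_ris, and
    one filtered_<reason>.csv per elimination reason that occurred.
    Returns {logical name: path} for everything written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}

    concise_path = out_dir / "concise.csv"
    with open(concise_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(CONCISE_COLUMNS)
        for ris in unique_ris:
            ann = (annotations or {}).get((ris.chrom, ris.strand, ris.position))
            if ann is None:
                gene_cols = ["", "", "", "", "", ""]
            else:
                gene_cols = [
                    str(ann.in_gene).lower(),
                    ann.gene_name or "",
                    "" if ann.gene_distance is None else ann.gene_distance,
                    ann.gene_side or "",
                    ann.tss_gene_name or "",
                    "" if ann.tss_distance is None else ann.tss_distance,
                ]
            w.writerow(
                [
                    ris.chrom,
                    ris.position,
                    ris.strand,
                    ris.frequency,
                    ris.span_count,
                    _fmt_float(ris.score),
                ]
                + gene_cols
            )
    written["concise"] = concise_path

    members_path = out_dir / "members.csv"
    with open(members_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(MEMBER_COLUMNS)
        for ris in unique_ris:
            for cand, label in ris.members:
                w.writerow(
                    [cand.read_id, cand.chrom, cand.position, cand.strand, label, ris.position]
                )
    written["members"] = members_path

    by_reason: dict = {}
    for fr in filter_reasons:
        by_reason.setdefault(fr.reason, []).append(fr)
    for reason, items in sorted(by_reason.items()):
        path = out_dir / f"filtered_{reason}.csv"
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["read_id", "reason"])
            for fr in items:
                w.writerow([fr.read_id, fr.reason])
        written[f"filtered_{reason}"] = path

    if summary is not None:
        path = out_dir / "summary.csv"
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["key", "value"])
            for key, value in summary.items():
                w.writerow([key, value])
        written["summary"] = path

    return written


def write_chisq_csv(results: Sequence, path: PathLike) -> None:
    """Write chi-squared goodness-of-fit results, one row per category."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["test", "category", "observed", "expected", "statistic", "df", "p_value"])
        for name, res in results:
            for cat, obs, exp in zip(res.categories, res.observed, res.expected):
                w.writerow(
                    [name, cat, obs, f"{exp:.6g}", f"{res.statistic:.10g}", res.dof, f"{res.p_value:.6g}"]
                )
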