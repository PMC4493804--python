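"""Random integration-site controls.

A random-integration null means uniform positional density genome-wide,
so chromosomes are chosen with probability proportional to the number of
valid start positions (length - site_length + 1), not uniformly per
chromosome. The extracted site sequences are then pushed through the
same alignment, filtering and annotation code as real reads — imparting
the same mapping biases — except the trimming stage, which they skip
because they carry no LTR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from riscall.alignment import ReferenceSet, align, reverse_complement
from riscall.annotation_stats import (
    ProximityReport,
    annotate_site,
    proportions_from_reports,
)
from riscall.config import PipelineConfig
from riscall.filtering_calling import select_candidates
from riscall.formats_io import GeneModel, GenomicFeature, SequenceRead

MAX_REDRAW_FACTOR = 100  # bound on N-containing site redraws: 100 * n_sites


@dataclass(frozen=True)
class RandomSiteRequest:
    """How many random sites to draw, how long, and from which seed."""

    n_sites: int
    site_length: int
    seed: int = 0

    def validate(self, cfg: PipelineConfig) -> None:
        n_lo, n_hi = cfg.random_n_bounds
        l_lo, l_hi = cfg.random_len_bounds
        if not (n_lo <= self.n_sites <= n_hi):
            raise ValueError(
                f"n_sites must be within [{n_lo}, {n_hi}], got {self.n_sites}"
            )
        if not (l_lo <= self.site_length <= l_hi):
            raise ValueError(
                f"site_length must be within [{l_lo}, {l_hi}] bp, got {self.site_length}"
            )


def generate_random_sites(
    genome: Dict[str, str],
    req: RandomSiteRequest,
    cfg: Optional[PipelineConfig] = None,
) -> Tuple[List[SequenceRead], List[Tuple[str, str, int, str]]]:
    """Draw random sites from a genome; returns (sequences, truth table).

    Each site picks a chromosome proportionally to its valid-start
    count, a uniform start, and a uniform strand; minus-strand sites are
    reverse-complemented. Sites containing any N are redrawn (bounded at
    100x the requested count). The truth table rows are
    (site_id, chrom, start, strand) with 1-based starts; for '-' sites
    the start is the junction-equivalent base, i.e. the higher
    coordinate of the extracted interval.
    """
    cfg = cfg or PipelineConfig()
    req.validate(cfg)
    chroms = sorted(genome)
    valid = np.array([len(genome[c]) - req.site_length + 1 for c in chroms], dtype=float)
    if np.any(valid < 1):
        short = [c for c, v in zip(chroms, valid) if v < 1]
        raise ValueError(
            f"chromosome(s) shorter than site_length {req.site_length}: {short}"
        )
    probs = valid / valid.sum()
    rng = np.random.default_rng(req.seed)

    sites: List[SequenceRead] = []
    truth: List[Tuple[str, str, int, str]] = []
    attempts = 0
    max_attempts = MAX_REDRAW_FACTOR * req.n_sites
    while len(sites) < req.n_sites:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"exhausted {max_attempts} draws redrawing N-containing sites"
            )
        attempts += 1
        ci = int(rng.choice(len(chroms), p=probs))
        chrom = chroms[ci]
        start0 = int(rng.integers(0, int(valid[ci])))
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        seq = genome[chrom][start0 : start0 + req.site_length]
        if "N" in seq:
            continue
        if strand == "-":
            seq = reverse_complement(seq)
            junction = start0 + req.site_length  # 1-based higher coordinate
        else:
            junction = start0 + 1
        sid = f"random_{len(sites) + 1}"
        sites.append(SequenceRead(sid, seq))
        truth.append((sid, chrom, junction, strand))
    return sites, truth


def random_control_run(
    genome: Union[Dict[str, str], ReferenceSet],
    genes: Sequence[GeneModel],
    features: Optional[Dict[str, Sequence[GenomicFeature]]],
    req: RandomSiteRequest,
    cfg: Optional[PipelineConfig] = None,
) -> Tuple[List[ProximityReport], Dict[str, float], Dict[str, float]]:
    """Generate, align, filter and annotate random control sites.

    The sites enter the pipeline at the alignment stage (they have no
    LTR to trim) and pass through the identical filtering and annotation
    functions as real queries. Returns the surviving sites' proximity
    reports plus their gene-category and per-feature-list proportions —
    the expected values for the chi-squared goodness-of-fit tests.
    """
    cfg = cfg or PipelineConfig()
    refs = genome if isinstance(genome, ReferenceSet) else ReferenceSet(genome=genome)
    sites, _truth = generate_random_sites(refs.genome, req, cfg)
    records = align(sites, refs, backend="builtin")
    candidates, _reasons = select_candidates(
        records, [s.read_id for s in sites], cfg, refs.vector_name
    )
    if not candidates:
        raise RuntimeError("every random control site was filtered out")
    reports = [
        annotate_site(c.chrom, c.strand, c.position, genes, features, cfg)
        for c in candidates
    ]
    gene_props, feat_props = proportions_from_reports(reports)
    return reports, gene_props, feat_props
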