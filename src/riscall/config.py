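"""Pipeline configuration: every numeric threshold in one overridable place."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Tuple


@dataclass
class PipelineConfig:
    """All tunable thresholds of the integration-site pipeline.

    The defaults are the recommended settings for LTR-primed junction
    libraries aligned with a BLAT-like local aligner emitting blast8
    records; every field may be overridden per run.

    Attributes
    ----------
    min_query_len : int
        Minimum trimmed query length in bp. Shorter queries cannot reach
        the alignment score cutoff and are eliminated before alignment.
    n_run_limit : int
        A run of at least this many consecutive ambiguous bases (N)
        truncates the query at the start of the run.
    min_score : float
        Minimum alignment score (blast8 column 12) for an alignment to
        be considered at all.
    min_identity_initial : float
        Minimum percent identity for the initial alignment filter.
    max_qstart_offset : int
        Maximum number of query bases allowed upstream of the alignment
        start; an alignment starting more than this many bp into the
        query is discarded (the junction base would be unaccounted for).
    top_k : int
        Number of greatest-scoring alignments retained per query for the
        ambiguity filters.
    ratio_hi : float
        Second-best/best score percentage above which a query is deemed
        ambiguous, applied when the best score is >= ratio_score_boundary.
    ratio_lo : float
        The stricter percentage used for lower-scoring alignments
        (best score < ratio_score_boundary).
    ratio_score_boundary : float
        Score separating the two second-best ratio tiers.
    min_best_identity : float
        Minimum percent identity of the best alignment for the query to
        yield a candidate site.
    cluster_halfwidth : int
        Candidate sites within +/- this many bp on the same chromosome
        and strand are grouped into one unique site (10 bp window).
    gene_max_dist : int
        Maximum distance in bp for reporting the nearest gene when a
        site falls outside all genes (5 kb).
    random_n_default : int
        Default number of random control sites.
    random_len_bounds : tuple
        Permitted (min, max) random-site length in bp.
    random_n_bounds : tuple
        Permitted (min, max) number of random sites.
    seed : int
        Seed for every source of randomness in a run.
    """

    min_query_len: int = 30
    n_run_limit: int = 3
    min_score: float = 60.0
    min_identity_initial: float = 92.0
    max_qstart_offset: int = 3
    top_k: int = 5
    ratio_hi: float = 95.0
    ratio_lo: float = 90.0
    ratio_score_boundary: float = 100.0
    min_best_identity: float = 95.0
    cluster_halfwidth: int = 5
    gene_max_dist: int = 5000
    random_n_default: int = 100_000
    random_len_bounds: Tuple[int, int] = (30, 1000)
    random_n_bounds: Tuple[int, int] = (1, 100_000)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "min_query_len",
            "n_run_limit",
            "min_score",
            "min_identity_initial",
            "top_k",
            "ratio_hi",
            "ratio_lo",
            "ratio_score_boundary",
            "min_best_identity",
            "cluster_halfwidth",
            "gene_max_dist",
            "random_n_default",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.max_qstart_offset < 0:
            raise ValueError("max_qstart_offset must be >= 0")
        for name in ("random_len_bounds", "random_n_bounds"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must satisfy 0 < lo <= hi, got ({lo}, {hi})")

    def replace(self, **kwargs) -> "PipelineConfig":
        """Return a copy with the given fields overridden."""
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("random_len_bounds", "random_n_bounds"):
            if key in d and not isinstance(d[key], tuple):
                d[key] = tuple(d[key])
        return cls(**d)
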