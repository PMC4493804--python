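"""Gene/TSS/feature proximity annotation and enrichment statistics.

Proximity to genes is determined in two phases. First, is the site
within a gene body (transcription bounds)? If not, the distance to the
nearest gene end is reported, up to 5 kb. Second — independently,
because a provirus inside one gene can sit closer to the transcription
start site (TSS) of another — the nearest TSS over all genes on the
chromosome is found, with a signed distance (negative upstream of the
TSS in gene orientation, positive downstream). Position relative to a
gene matters mechanistically: integration upstream of a promoter can
activate it via the LTR enhancer, while intragenic integration can cause
premature polyadenylation.

Observed site proportions are compared against random-control
proportions with a Pearson chi-squared goodness-of-fit test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from riscall.config import PipelineConfig
from riscall.formats_io import GeneModel, GenomicFeature

GENE_CATEGORIES = ("in_gene", "within_5kb_not_in_gene", "beyond")


@dataclass
class ProximityReport:
    """Gene, TSS, and custom-feature proximity of one site."""

    chrom: str
    strand: str
    position: int
    in_gene: bool = False
    gene_name: Optional[str] = None
    gene_distance: Optional[int] = None  # 0 if within; unsigned otherwise
    gene_side: Optional[str] = None  # upstream/downstream of the gene, strand-aware
    tss_gene_name: Optional[str] = None
    tss_distance: Optional[int] = None  # signed; negative upstream of the TSS
    features: Dict[str, Tuple[bool, Optional[str], Optional[int]]] = field(
        default_factory=dict
    )  # list name -> (within, nearest_name, distance)


@dataclass(frozen=True)
class ChiSquareResult:
    """Pearson chi-squared goodness of fit against expected proportions."""

    categories: Tuple[str, ...]
    observed: Tuple[int, ...]
    expected: Tuple[float, ...]
    statistic: float
    dof: int
    p_value: float


@dataclass(frozen=True)
class IntegrationSummary:
    n_unique: int
    pct_in_genes: float
    n_within_5kb: int  # within 5 kb of a gene but not inside one
    feature_within_counts: Dict[str, int] = field(default_factory=dict)


def _genes_by_chrom(genes: Iterable[GeneModel]) -> Dict[str, List[GeneModel]]:
    by: Dict[str, List[GeneModel]] = {}
    for g in genes:
        by.setdefault(g.chrom, []).append(g)
    return by


def annotate_gene(
    report: ProximityReport, genes: Sequence[GeneModel], cfg: PipelineConfig
) -> ProximityReport:
    """Phase 1: containment in a gene body, else nearest gene within 5 kb.

    Containment ties go to the smallest transcription span, then name;
    nearest-gene ties to the smallest distance, then name. The side of
    the gene (upstream/downstream in gene orientation) is recorded for
    non-contained hits.
    """
    pos = report.position
    chrom_genes = [g for g in genes if g.chrom == report.chrom]

    containing = [g for g in chrom_genes if g.tx_start <= pos <= g.tx_end]
    if containing:
        best = min(containing, key=lambda g: (g.span, g.gene_name))
        report.in_gene = True
        report.gene_name = best.gene_name
        report.gene_distance = 0
        report.gene_side = "within"
        return report

    nearest: Optional[Tuple[int, str, GeneModel]] = None
    for g in chrom_genes:
        dist = g.tx_start - pos if pos < g.tx_start else pos - g.tx_end
        key = (dist, g.gene_name)
        if nearest is None or key < (nearest[0], nearest[1]):
            nearest = (dist, g.gene_name, g)
    if nearest is not None and nearest[0] <= cfg.gene_max_dist:
        dist, _, g = nearest
        report.gene_name = g.gene_name
        report.gene_distance = dist
        before_gene = pos < g.tx_start
        # 5' side of a '+' gene (or 3' side of a '-' gene) is "upstream"
        report.gene_side = (
            "upstream" if before_gene == (g.strand == "+") else "downstream"
        )
    return report


def annotate_tss(report: ProximityReport, genes: Sequence[GeneModel]) -> ProximityReport:
    """Phase 2: nearest transcription start site over all chromosome genes.

    Distance is signed in gene orientation: negative when the site lies
    upstream of the TSS, positive downstream, 0 at the TSS. Ties on
    |distance| are broken by gene name.
    """
    pos = report.position
    best: Optional[Tuple[int, str, int]] = None
    for g in genes:
        if g.chrom != report.chrom:
            continue
        signed = pos - g.tss if g.strand == "+" else g.tss - pos
        key = (abs(signed), g.gene_name)
        if best is None or key < (best[0], best[1]):
            best = (abs(signed), g.gene_name, signed)
    if best is not None:
        report.tss_gene_name = best[1]
        report.tss_distance = best[2]
    return report


def annotate_features(
    report: ProximityReport,
    feature_lists: Dict[str, Sequence[GenomicFeature]],
) -> ProximityReport:
    """Containment in, or unsigned distance to, the closest custom feature.

    One result per named feature list; no distance cap. Equidistant
    features tie-break on name.
    """
    pos = report.position
    for list_name, feats in feature_lists.items():
        chrom_feats = [f for f in feats if f.chrom == report.chrom]
        best: Optional[Tuple[int, str]] = None
        for f in chrom_feats:
            if f.start <= pos <= f.end:
                dist = 0
            elif pos < f.start:
                dist = f.start - pos
            else:
                dist = pos - f.end
            key = (dist, f.feature_name)
            if best is None or key < best:
                best = key
        if best is None:
            report.features[list_name] = (False, None, None)
        else:
            report.features[list_name] = (best[0] == 0, best[1], best[0])
    return report


def annotate_site(
    chrom: str,
    strand: str,
    position: int,
    genes: Sequence[GeneModel],
    feature_lists: Optional[Dict[str, Sequence[GenomicFeature]]],
    cfg: PipelineConfig,
) -> ProximityReport:
    """Run all annotation phases on one site.

    This single code path serves both observed unique sites and random
    control sites, so the enrichment comparison sees identical logic.
    """
    report = ProximityReport(chrom=chrom, strand=strand, position=position)
    annotate_gene(report, genes, cfg)
    annotate_tss(report, genes)
    if feature_lists:
        annotate_features(report, feature_lists)
    return report


def gene_category(report: ProximityReport) -> str:
    """Classify a report into in_gene / within_5kb_not_in_gene / beyond."""
    if report.in_gene:
        return "in_gene"
    if report.gene_name is not None:
        return "within_5kb_not_in_gene"
    return "beyond"


def chisq_gof(
    observed: Sequence[int],
    expected_props: Sequence[float],
    categories: Optional[Sequence[str]] = None,
) -> ChiSquareResult:
    """Pearson chi-squared goodness of fit.

    ``expected_props`` are proportions summing to 1; they are scaled to
    the observed total N, the statistic is sum((obs - N*p)^2 / (N*p)),
    and the p-value comes from the upper tail of the chi-squared
    distribution with k-1 degrees of freedom.
    """
    obs = np.asarray(observed, dtype=float)
    props = np.asarray(expected_props, dtype=float)
    if obs.shape != props.shape or obs.size < 2:
        raise ValueError("observed and expected_props must match, with >= 2 categories")
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError(f"expected proportions must sum to 1, got {props.sum()!r}")
    n = obs.sum()
    expected = n * props
    if np.any((expected <= 0) & (obs > 0)):
        raise ValueError(
            "a category with zero expected proportion has nonzero observed "
            "count; merge sparse categories before testing"
        )
    if np.any(expected <= 0):
        raise ValueError("all expected counts must be positive; merge empty categories")
    statistic = float(np.sum((obs - expected) ** 2 / expected))
    dof = obs.size - 1
    p = float(stats.chi2.sf(statistic, dof))
    if categories is None:
        categories = tuple(f"cat_{i}" for i in range(obs.size))
    return ChiSquareResult(
        categories=tuple(categories),
        observed=tuple(int(x) for x in observed),
        expected=tuple(float(x) for x in expected),
        statistic=statistic,
        dof=dof,
        p_value=p,
    )


def proportions_from_reports(
    reports: Sequence[ProximityReport],
) -> Tuple[Dict[str, float], Dict[str, float]]:
    """Gene-category and per-feature-list 'within' proportions of a set."""
    n = len(reports)
    if n == 0:
        raise ValueError("cannot compute proportions of an empty report set")
    gene_counts = {cat: 0 for cat in GENE_CATEGORIES}
    for r in reports:
        gene_counts[gene_category(r)] += 1
    gene_props = {cat: gene_counts[cat] / n for cat in GENE_CATEGORIES}
    feat_props: Dict[str, float] = {}
    for list_name in reports[0].features:
        within = sum(1 for r in reports if r.features[list_name][0])
        feat_props[list_name] = within / n
    return gene_props, feat_props


def summarize(
    observed_reports: Sequence[ProximityReport],
    random_reports: Optional[Sequence[ProximityReport]],
    cfg: PipelineConfig,
) -> Tuple[IntegrationSummary, List[Tuple[str, ChiSquareResult]]]:
    """Summary statistics plus chi-squared tests against random controls.

    The gene test compares the 3-way split {in gene, within 5 kb but not
    in a gene, beyond}; each custom feature list gets a 2-way
    {within, not within} test. Expected proportions come from the random
    set, which must be annotated with the identical gene/feature inputs.
    With no random set, the summary is returned without tests.
    """
    n = len(observed_reports)
    n_in = sum(1 for r in observed_reports if r.in_gene)
    n_near = sum(1 for r in observed_reports if gene_category(r) == "within_5kb_not_in_gene")
    feat_counts = {}
    if observed_reports:
        for list_name in observed_reports[0].features:
            feat_counts[list_name] = sum(
                1 for r in observed_reports if r.features[list_name][0]
            )
    summary = IntegrationSummary(
        n_unique=n,
        pct_in_genes=(100.0 * n_in / n) if n else 0.0,
        n_within_5kb=n_near,
        feature_within_counts=feat_counts,
    )

    tests: List[Tuple[str, ChiSquareResult]] = []
    if not random_reports or n == 0:
        return summary, tests

    gene_props, feat_props = proportions_from_reports(random_reports)
    obs_gene = [
        sum(1 for r in observed_reports if gene_category(r) == cat)
        for cat in GENE_CATEGORIES
    ]
    props = [gene_props[cat] for cat in GENE_CATEGORIES]
    # drop categories absent from both sets so expected counts stay positive
    keep = [i for i in range(len(props)) if props[i] > 0 or obs_gene[i] > 0]
    if len(keep) >= 2:
        tests.append(
            (
                "gene_proximity",
                chisq_gof(
                    [obs_gene[i] for i in keep],
                    _renormalise([props[i] for i in keep]),
                    [GENE_CATEGORIES[i] for i in keep],
                ),
            )
        )
    for list_name, p_within in feat_props.items():
        obs_within = feat_counts.get(list_name, 0)
        obs = [obs_within, n - obs_within]
        if 0.0 < p_within < 1.0:
            tests.append(
                (
                    f"feature:{list_name}",
                    chisq_gof(obs, [p_within, 1.0 - p_within], ["within", "not_within"]),
                )
            )
    return summary, tests


def _renormalise(props: Sequence[float]) -> List[float]:
    total = sum(props)
    if total <= 0:
        raise ValueError("cannot renormalise all-zero proportions")
    return [p / total for p in props]
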