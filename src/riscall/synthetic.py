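"""Deterministic simulation of toy genomes and integration-read datasets.

The generator emulates what an LTR-primed junction library (e.g.
LAM-PCR) looks like after sequencing: a toy genome, planted proviruses,
and reads laid out as LTR + genomic flank (+ linker cassette), with PCR
duplicates, distinct shear endpoints, substitution errors and ambiguous
bases. Every planted site is recorded in a truth table with its expected
read frequency and shear-span count, so end-to-end recovery is exactly
checkable.

Planted flanks are screened to be genome-unique at 40 bp (both strands),
guaranteeing unambiguous mapping for truth reads; ambiguity-filter tests
should instead plant flanks inside deliberately duplicated segments.
Genes are placed on a regular grid so in-gene/near-gene truth fractions
have closed form. The generator does not model read qualities, indels,
or restriction-site bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from riscall.alignment import reverse_complement
from riscall.formats_io import GeneModel, SequenceRead, write_fasta

# lentiviral-style U5 LTR end and a LAM-PCR-style linker, fixed defaults
DEFAULT_LTR = "TGTGGAAAATCTCTAGCAGT"
DEFAULT_LC = "GATCCTGCAGGTCGAC"

FLANK_UNIQUE_LEN = 40  # planted flanks must be genome-unique at this length


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one simulated dataset.

    genome_length is per chromosome. gene_density is genes per kb (each
    gene spans 1 kb on an alternating-strand grid). reads_per_site sets
    the PCR-duplicate multiplicity; shear_spread is the bp range of
    fragment-length variation that creates distinct distal endpoints.
    """

    genome_length: int = 20_000
    n_chromosomes: int = 2
    gene_density: float = 0.1
    n_integrations: int = 20
    reads_per_site: int = 3
    shear_spread: int = 20
    min_fragment: int = 40
    error_rate: float = 0.0
    n_rate: float = 0.0
    ltr_seq: str = DEFAULT_LTR
    lc_seq: str = DEFAULT_LC
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("error_rate", "n_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.genome_length < 2 * (self.min_fragment + self.shear_spread + FLANK_UNIQUE_LEN):
            raise ValueError("genome too short to host integrations")
        if self.n_integrations < 0 or self.reads_per_site < 1:
            raise ValueError("need n_integrations >= 0 and reads_per_site >= 1")


@dataclass
class PlantedSite:
    site_id: str
    chrom: str
    position: int  # 1-based junction base
    strand: str
    expected_frequency: int
    expected_span_count: int


@dataclass
class SimulatedDataset:
    genome: Dict[str, str]
    vector: str
    genes: List[GeneModel]
    reads: List[SequenceRead]
    truth: List[PlantedSite]
    spec: SimulationSpec


GENE_LENGTH = 1000


def _make_genes(spec: SimulationSpec, chroms: List[str]) -> List[GeneModel]:
    if spec.gene_density <= 0:
        return []
    period = max(int(round(1000 / spec.gene_density)), GENE_LENGTH + 1)
    genes: List[GeneModel] = []
    n = 0
    for chrom in chroms:
        start = period // 2
        while start + GENE_LENGTH - 1 <= spec.genome_length:
            n += 1
            genes.append(
                GeneModel(
                    gene_name=f"gene{n}",
                    chrom=chrom,
                    strand="+" if n % 2 else "-",
                    tx_start=start,
                    tx_end=start + GENE_LENGTH - 1,
                )
            )
            start += period
    return genes


def _is_unique_flank(flank: str, genome: Dict[str, str]) -> bool:
    rc = reverse_complement(flank)
    count = 0
    for seq in genome.values():
        count += seq.count(flank) + seq.count(rc)
        if count > 1:
            return False
    return count == 1


def simulate_dataset(spec: SimulationSpec) -> SimulatedDataset:
    """Generate a toy genome, genes, planted proviruses and their reads.

    Deterministic under spec.seed: identical specs yield byte-identical
    datasets. Raises if unique placements cannot be found (e.g. the
    genome is too small for the requested integration count).
    """
    rng = np.random.default_rng(spec.seed)
    bases = np.array(list("ACGT"))
    chroms = [f"chr{i + 1}" for i in range(spec.n_chromosomes)]
    genome = {
        c: "".join(rng.choice(bases, size=spec.genome_length)) for c in chroms
    }
    vector = spec.ltr_seq + "".join(rng.choice(bases, size=400)) + spec.ltr_seq
    genes = _make_genes(spec, chroms)

    max_frag = spec.min_fragment + spec.shear_spread
    margin = max_frag + FLANK_UNIQUE_LEN
    min_separation = 2 * max_frag  # keep clusters of different sites disjoint

    truth: List[PlantedSite] = []
    reads: List[SequenceRead] = []
    placed: Dict[str, List[int]] = {c: [] for c in chroms}
    attempts, max_attempts = 0, 200 * max(spec.n_integrations, 1)
    while len(truth) < spec.n_integrations:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {spec.n_integrations} integrations after "
                f"{max_attempts} attempts; enlarge the genome"
            )
        attempts += 1
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        pos = int(rng.integers(margin, spec.genome_length - margin))  # 1-based
        if any(abs(pos - p) < min_separation for p in placed[chrom]):
            continue
        flank = _extract_flank(genome[chrom], pos, strand, FLANK_UNIQUE_LEN)
        if "N" in flank or not _is_unique_flank(flank, genome):
            continue
        placed[chrom].append(pos)
        site_id = f"site{len(truth) + 1}"
        frag_lens = [
            spec.min_fragment + int(rng.integers(0, spec.shear_spread + 1))
            for _ in range(spec.reads_per_site)
        ]
        for j, flen in enumerate(frag_lens, start=1):
            frag = _extract_flank(genome[chrom], pos, strand, flen)
            frag = _mutate(frag, spec, rng)
            reads.append(
                SequenceRead(f"{site_id}_read{j}", spec.ltr_seq + frag + spec.lc_seq)
            )
        truth.append(
            PlantedSite(
                site_id=site_id,
                chrom=chrom,
                position=pos,
                strand=strand,
                expected_frequency=spec.reads_per_site,
                expected_span_count=len(set(frag_lens)),
            )
        )
    return SimulatedDataset(
        genome=genome, vector=vector, genes=genes, reads=reads, truth=truth, spec=spec
    )


def _extract_flank(chrom_seq: str, pos: int, strand: str, length: int) -> str:
    """Genomic flank of `length` bp starting at the junction base `pos`
    and running away from the LTR: rightwards on '+', leftwards
    (reverse-complemented) on '-'."""
    if strand == "+":
        return chrom_seq[pos - 1 : pos - 1 + length]
    return reverse_complement(chrom_seq[pos - length : pos])


def _mutate(frag: str, spec: SimulationSpec, rng: np.random.Generator) -> str:
    if spec.error_rate == 0.0 and spec.n_rate == 0.0:
        return frag
    out = list(frag)
    for i, base in enumerate(out):
        r = rng.random()
        if r < spec.n_rate:
            out[i] = "N"
        elif r < spec.n_rate + spec.error_rate:
            choices = [b for b in "ACGT" if b != base]
            out[i] = choices[int(rng.integers(0, 3))]
    return "".join(out)


def write_dataset(ds: SimulatedDataset, out_dir) -> Dict[str, Path]:
    """Write the dataset as standard files: genome/vector/reads FASTA,
    refFlat genes, and a truth CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out_dir / "genome.fa",
        "vector": out_dir / "vector.fa",
        "reads": out_dir / "reads.fa",
        "genes": out_dir / "genes.refFlat",
        "truth": out_dir / "truth.csv",
    }
    write_fasta(sorted(ds.genome.items()), paths["genome"])
    write_fasta([("vector", ds.vector)], paths["vector"])
    write_fasta(ds.reads, paths["reads"])
    with open(paths["genes"], "w") as fh:
        for g in ds.genes:
            # refFlat: geneName name chrom strand txStart txEnd cds... exons
            fh.write(
                "\t".join(
                    [
                        g.gene_name,
                        g.gene_name,
                        g.chrom,
                        g.strand,
                        str(g.tx_start - 1),
                        str(g.tx_end),
                        str(g.tx_start - 1),
                        str(g.tx_end),
                        "1",
                        f"{g.tx_start - 1},",
                        f"{g.tx_end},",
                    ]
                )
                + "\n"
            )
    with open(paths["truth"], "w") as fh:
        fh.write("site_id,chrom,position,strand,expected_frequency,expected_span_count\n")
        for s in ds.truth:
            fh.write(
                f"{s.site_id},{s.chrom},{s.position},{s.strand},"
                f"{s.expected_frequency},{s.expected_span_count}\n"
            )
    return paths
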