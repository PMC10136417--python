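"""Miniature genome model for desk-scale pipeline runs.

A real clinical array covers ~3.1 Gb; full-genome simulation is pointless for
testing the calling and filtration logic, so the model here is a handful of
chromosome analogues of tens of Mb each, with procedurally generated
ISCN-style cytobands (p/q arms, two-level numbering), a gene track and a few
curated clinical regions.  Scale is configurable; everything downstream is
coordinate-generic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import ClinicalRegion, CytobandRecord, GeneRecord, ValidationError


@dataclass(slots=True)
class GenomeModel:
    """Chromosome lengths plus cytoband / gene / clinical-region tracks."""

    chromosomes: list[tuple[str, int]]
    cytobands: list[CytobandRecord] = field(default_factory=list)
    genes: list[GeneRecord] = field(default_factory=list)
    clinical_regions: list[ClinicalRegion] = field(default_factory=list)

    def chromosome_length(self, name: str) -> int:
        for chrom, length in self.chromosomes:
            if chrom == name:
                return length
        raise KeyError(f"unknown chromosome {name!r}")

    @property
    def chromosome_names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    def validate(self) -> None:
        """Check structural invariants; raises ValidationError on failure."""
        lengths = dict(self.chromosomes)
        for chrom, length in self.chromosomes:
            if length <= 0:
                raise ValidationError(f"chromosome {chrom}: non-positive length")
            bands = [b for b in self.cytobands if b.chromosome == chrom]
            if bands:
                _check_band_tiling(chrom, length, bands)
        for gene in self.genes:
            if gene.chromosome not in lengths:
                raise ValidationError(f"gene {gene.symbol}: unknown chromosome")
            if not (1 <= gene.start and gene.end <= lengths[gene.chromosome]):
                raise ValidationError(f"gene {gene.symbol}: outside chromosome bounds")
        for region in self.clinical_regions:
            if region.chromosome not in lengths:
                raise ValidationError(f"region {region.syndrome}: unknown chromosome")
            if not (1 <= region.start and region.end <= lengths[region.chromosome]):
                raise ValidationError(f"region {region.syndrome}: outside chromosome bounds")


def _check_band_tiling(chrom: str, length: int, bands: list[CytobandRecord]) -> None:
    bands = sorted(bands, key=lambda b: b.start)
    if bands[0].start != 1:
        raise ValidationError(f"{chrom}: first band starts at {bands[0].start}, not 1")
    if bands[-1].end != length:
        raise ValidationError(f"{chrom}: last band ends at {bands[-1].end}, not {length}")
    for prev, nxt in zip(bands, bands[1:]):
        if nxt.start != prev.end + 1:
            kind = "overlap" if nxt.start <= prev.end else "gap"
            raise ValidationError(
                f"{chrom}: {kind} between bands {prev.band} and {nxt.band}"
            )
    arms = [b.arm for b in bands]
    if arms != sorted(arms):  # 'p' < 'q'
        raise ValidationError(f"{chrom}: p bands must precede q bands")


def _band_labels(arm: str, n: int, rng: np.random.Generator) -> list[str]:
    """Generate ``n`` ISCN-style band labels for one arm, in coordinate order.

    Labels walk upward from 11 in ISCN numbering (11, 12, 21.1, 21.2, ...);
    for a p arm the walk is reversed so numbers decrease toward the
    centromere, as on a real ideogram.
    """
    major, minor = 1, 1
    labels: list[str] = []
    use_sub = rng.random() < 0.7
    sub = 0
    for _ in range(n):
        if use_sub and rng.random() < 0.4:
            sub += 1
            labels.append(f"{arm}{major}{minor}.{sub}")
            if sub >= 3:
                sub = 0
                minor += 1
        else:
            if sub:
                sub = 0
                minor += 1
            labels.append(f"{arm}{major}{minor}")
            minor += 1
        if minor > 5:
            major += 1
            minor = 1
    if arm == "p":
        labels = labels[::-1]
    return labels


def _make_bands(chrom: str, length: int, rng: np.random.Generator) -> list[CytobandRecord]:
    centromere = int(length * rng.uniform(0.3, 0.7))
    records: list[CytobandRecord] = []
    stains = ["gneg", "gpos25", "gpos50", "gpos75"]
    for arm, lo, hi in (("p", 1, centromere), ("q", centromere + 1, length)):
        span = hi - lo + 1
        n_bands = max(2, min(8, span // 5_000_000 + 2))
        cuts = np.sort(rng.choice(np.arange(1, span), size=n_bands - 1, replace=False))
        edges = [lo] + [lo + int(c) for c in cuts] + [hi + 1]
        labels = _band_labels(arm, n_bands, rng)
        for i, label in enumerate(labels):
            records.append(
                CytobandRecord(chrom, edges[i], edges[i + 1] - 1, label,
                               stains[i % len(stains)])
            )
    return records


def make_genome_model(n_chromosomes: int, seed: int, *,
                      min_length: int = 30_000_000,
                      max_length: int = 60_000_000,
                      gene_density_bp: int = 300_000) -> GenomeModel:
    """Build a deterministic miniature genome.

    Parameters
    ----------
    n_chromosomes
        Total chromosome count; the last one is the sex-chromosome analogue
        ``X``, the rest are autosomes named ``1``, ``2``, ...
    seed
        Seed for all randomness; identical seeds give identical models.
    min_length, max_length
        Per-chromosome length range in bp.
    gene_density_bp
        Roughly one gene per this many bp.
    """
    if n_chromosomes < 1:
        raise ValueError(f"n_chromosomes must be >= 1, got {n_chromosomes}")
    rng = np.random.default_rng(seed)

    names = [str(i + 1) for i in range(n_chromosomes - 1)] + ["X"]
    if n_chromosomes == 1:
        names = ["X"]
    chromosomes = [
        (name, int(rng.integers(min_length, max_length + 1))) for name in names
    ]

    model = GenomeModel(chromosomes=chromosomes)
    for chrom, length in chromosomes:
        model.cytobands.extend(_make_bands(chrom, length, rng))

    # Genes: non-overlapping intervals laid down left to right with random
    # jitter; ~30% flagged OMIM.
    gene_idx = 0
    for chrom, length in chromosomes:
        pos = 1
        n_target = max(1, length // gene_density_bp)
        mean_gap = max(1, length // n_target)
        while pos < length - 10_000:
            gap = int(rng.integers(mean_gap // 2, mean_gap + mean_gap // 2))
            start = pos + gap
            size = int(rng.integers(5_000, 200_000))
            end = min(start + size - 1, length)
            if start >= length:
                break
            gene_idx += 1
            model.genes.append(
                GeneRecord(chrom, start, end, f"GENE{gene_idx:05d}",
                           bool(rng.random() < 0.3))
            )
            pos = end
    # A few curated clinical regions per genome, 0.5-5 Mb, alternating class.
    region_idx = 0
    for chrom, length in chromosomes:
        for _ in range(int(rng.integers(1, 3))):
            size = int(rng.integers(500_000, 5_000_000))
            start = int(rng.integers(1, max(2, length - size)))
            region_idx += 1
            label = "pathogenic" if region_idx % 2 else "VUS"
            covered = tuple(
                g.symbol for g in model.genes
                if g.chromosome == chrom and g.start <= start + size - 1 and g.end >= start
            )[:6]
            model.clinical_regions.append(
                ClinicalRegion(chrom, start, start + size - 1,
                               f"SYN-{chrom}-{region_idx}", label, covered)
            )
    model.validate()
    return model
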