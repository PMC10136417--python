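"""Synthetic data generators: every input the pipeline consumes.

The generators emulate the two Agilent-style whole-genome CGH designs
(median probe spacing 8.9 kb for the 244K format, 5.3 kb for the 400K),
probe-level samples with planted gains/losses/aneuploidies under Gaussian
log2 noise, a DGV-style benign-CNV population database, and qPCR plates
obeying the Livak model (Ct = base - log2(template) + noise).

A cohort-scale cascade fixture co-constructs a CNV list with the database,
gene track and clinical-region table so that every record fails the
filtration cascade first at a designated stage (or survives); the designated
category of every record is retained as hidden truth for auditing.

All generators are deterministic in their seed; a single global seed fans
out to per-generator child seeds by fixed offsets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genome import GenomeModel
from .qpcr import QpcrWell
from .records import (
    AneuploidyCall,
    BenignCnvRecord,
    ClinicalRegion,
    CnvCall,
    GeneRecord,
    ProbeMeasurement,
    ValidationError,
)

#: median probe spacing targets in bp per array format
DESIGN_SPACING = {"244K": 8_900, "400K": 5_300}

#: fixed offsets fanning one global seed out to independent child streams
SEED_OFFSETS = {
    "genome": 11,
    "design": 23,
    "sample": 37,
    "benign": 53,
    "cascade": 71,
    "qpcr": 89,
}


def child_seed(seed: int, generator: str) -> int:
    """Derive a per-generator child seed (< 2**31) from the global seed."""
    return (seed * 1_000_003 + SEED_OFFSETS[generator]) % (2**31 - 1)


@dataclass(frozen=True, slots=True)
class ArrayDesign:
    """An array layout: sorted probes and the realized median spacing."""

    label: str  # 244K | 400K
    probes: tuple[tuple[str, int, str], ...]  # (chromosome, position, probe_id)
    median_spacing_bp: int


@dataclass(frozen=True, slots=True)
class PlantedEvent:
    """A ground-truth copy-number event used when simulating a sample."""

    chromosome: str
    start: int
    end: int
    true_copy_number: int  # >= 0; autosomal baseline is 2
    whole_chromosome: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError("planted event: start > end")
        if self.true_copy_number < 0:
            raise ValidationError("planted event: copy number < 0")

    @property
    def expected_log2(self) -> float:
        """log2(CN/2); copy number zero is floored at -4 (arrays saturate)."""
        if self.true_copy_number == 0:
            return -4.0
        return math.log2(self.true_copy_number / 2.0)


@dataclass(frozen=True, slots=True)
class NoiseModel:
    """Per-probe Gaussian noise on the log2 scale."""

    sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValidationError("noise sd must be >= 0")


@dataclass(frozen=True, slots=True)
class CohortFixtureSpec:
    """Per-category record counts for the cascade fixture.

    Categories follow the fixed cascade stage order; ``n_pathogenic_or_vus``
    records survive all five filters.
    """

    n_aneuploidy: int = 5
    n_small: int = 1211
    n_benign_pop: int = 951
    n_no_gene: int = 249
    n_not_significant: int = 97
    n_pathogenic_or_vus: int = 24

    def __post_init__(self) -> None:
        for name in ("n_aneuploidy", "n_small", "n_benign_pop", "n_no_gene",
                     "n_not_significant", "n_pathogenic_or_vus"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    @property
    def total(self) -> int:
        return (self.n_aneuploidy + self.n_small + self.n_benign_pop
                + self.n_no_gene + self.n_not_significant
                + self.n_pathogenic_or_vus)


@dataclass(slots=True)
class CascadeFixture:
    """A co-constructed cohort: calls plus the tables the cascade filters on.

    ``truth`` is the designated category of each call (parallel to
    ``calls``): one of aneuploidy / size / benign_pop / no_gene /
    not_significant / kept.
    """

    calls: list[CnvCall]
    aneuploidy: list[AneuploidyCall]
    benign_db: list[BenignCnvRecord]
    genes: list[GeneRecord]
    clinical_regions: list[ClinicalRegion]
    truth: list[str] = field(default_factory=list)


def make_design(model: GenomeModel, label: str, seed: int) -> ArrayDesign:
    """Lay probes over the genome at the format's target median spacing.

    Inter-probe steps are drawn uniformly in [0.5, 1.5] times the target
    spacing, so the realized median lands on the target (within a few
    percent at desk scale) and probe density scales with genome size.
    """
    if label not in DESIGN_SPACING:
        raise ValueError(f"unknown design label {label!r}; expected one of {sorted(DESIGN_SPACING)}")
    target = DESIGN_SPACING[label]
    rng = np.random.default_rng(child_seed(seed, "design"))
    probes: list[tuple[str, int, str]] = []
    gaps: list[int] = []
    idx = 0
    for chrom, length in model.chromosomes:
        pos = int(rng.integers(1, target + 1))
        prev = None
        while pos <= length:
            idx += 1
            probes.append((chrom, pos, f"P{label}_{idx:06d}"))
            if prev is not None:
                gaps.append(pos - prev)
            prev = pos
            pos += int(rng.integers(int(0.5 * target), int(1.5 * target) + 1))
    median_spacing = int(np.median(gaps)) if gaps else 0
    return ArrayDesign(label=label, probes=tuple(probes),
                       median_spacing_bp=median_spacing)


def _check_events_disjoint(events: list[PlantedEvent]) -> None:
    by_chrom: dict[str, list[PlantedEvent]] = {}
    for ev in events:
        by_chrom.setdefault(ev.chromosome, []).append(ev)
    for chrom, evs in by_chrom.items():
        evs = sorted(evs, key=lambda e: e.start)
        for a, b in zip(evs, evs[1:]):
            if b.start <= a.end:
                raise ValidationError(
                    f"planted events overlap on {chrom}: "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )


def simulate_sample(design: ArrayDesign, events: list[PlantedEvent],
                    noise: NoiseModel) -> list[ProbeMeasurement]:
    """Emit one sample's probe table: event log2 plus Gaussian noise.

    Each probe's expected log2 is that of the covering planted event (0
    when none covers it); probe order follows the design.
    """
    _check_events_disjoint(events)
    rng = np.random.default_rng(child_seed(noise.seed, "sample"))
    noise_values = (rng.normal(0.0, noise.sd, size=len(design.probes))
                    if noise.sd > 0 else np.zeros(len(design.probes)))
    out: list[ProbeMeasurement] = []
    for (chrom, pos, pid), eps in zip(design.probes, noise_values):
        expected = 0.0
        for ev in events:
            if ev.chromosome == chrom and ev.start <= pos <= ev.end:
                expected = ev.expected_log2
                break
        out.append(ProbeMeasurement(chrom, pos, pid, expected + float(eps)))
    return out


def make_benign_db(model: GenomeModel, n_records: int, seed: int
                   ) -> list[BenignCnvRecord]:
    """Random DGV-style population CNVs, 10-500 kb, within chromosome bounds."""
    if n_records < 0:
        raise ValueError("n_records must be >= 0")
    rng = np.random.default_rng(child_seed(seed, "benign"))
    states = ["gain", "loss", "either"]
    out: list[BenignCnvRecord] = []
    for _ in range(n_records):
        chrom, length = model.chromosomes[int(rng.integers(len(model.chromosomes)))]
        size = int(rng.integers(10_000, 500_000))
        start = int(rng.integers(1, max(2, length - size)))
        out.append(BenignCnvRecord(
            chrom, start, start + size - 1,
            states[int(rng.integers(3))],
            float(np.round(rng.uniform(0.01, 0.5), 4)),
        ))
    return out


# --- cascade fixture ---------------------------------------------------------

def _loss_gain_pattern(n: int, loss_count: int) -> list[str]:
    """Interleave ``loss_count`` losses among ``n`` records."""
    states = ["loss"] * loss_count + ["gain"] * (n - loss_count)
    # deterministic interleave: spread gains evenly
    order = sorted(range(n), key=lambda i: (i * 977) % n)
    return [states[i] for i in order]


def _mk_call(sample: str, chrom: str, start: int, end: int, state: str,
             spacing: int = 8_000) -> CnvCall:
    mean = -1.0 if state == "loss" else 0.585
    n_probes = max(3, (end - start + 1) // spacing)
    return CnvCall(sample_id=sample, chromosome=chrom, start=start, end=end,
                   n_probes=n_probes, mean_log2=mean, copy_state=state,
                   copy_number=1 if state == "loss" else 3)


def make_cascade_fixture(spec: CohortFixtureSpec, model: GenomeModel, seed: int,
                         *, pathogenic_fraction: float = 13 / 24,
                         loss_fraction: float = 14 / 24) -> CascadeFixture:
    """Plant a cohort of CNV records that fail the cascade at designated stages.

    Records of the removable categories are laid into disjoint per-category
    pools of genomic slots on the autosomes (sample ids cycle, so loci are
    reused within a category); each surviving record gets its own slot with
    a matching gene and clinical region.  Aneuploidy records are
    whole-chromosome calls on the sex-chromosome analogue.  The construction
    guarantees, and asserts, that each record's first failing filter is its
    designated category.
    """
    rng = np.random.default_rng(child_seed(seed, "cascade"))
    autosomes = [(c, l) for c, l in model.chromosomes if c != "X"]
    if not autosomes:
        raise ValidationError("cascade fixture needs at least one autosome")
    sex_chrom = "X" if any(c == "X" for c, _ in model.chromosomes) else autosomes[-1][0]

    pool_cap = 25
    pools = {
        "size": min(spec.n_small, pool_cap),
        "benign_pop": min(spec.n_benign_pop, pool_cap),
        "no_gene": min(spec.n_no_gene, pool_cap),
        "not_significant": min(spec.n_not_significant, pool_cap),
        "kept": spec.n_pathogenic_or_vus,
    }
    n_slots = sum(pools.values())
    total_bp = sum(l for _, l in autosomes)
    # +8 leaves headroom for per-chromosome remainder losses
    slot_width = min(1_000_000, total_bp // (n_slots + 8)) if n_slots else 1_000_000
    if n_slots and slot_width < 700_000:
        raise ValidationError(
            f"genome too small for cascade fixture: {n_slots} slots need "
            f">= 700 kb each, only {slot_width} bp available"
        )

    # enumerate slots across autosomes
    slot_list: list[tuple[str, int]] = []
    for chrom, length in autosomes:
        start = 1
        while start + slot_width - 1 <= length and len(slot_list) < n_slots:
            slot_list.append((chrom, start))
            start += slot_width
        if len(slot_list) >= n_slots:
            break
    if len(slot_list) < n_slots:
        raise ValidationError("not enough genomic slots for the cascade fixture")

    cursor = 0
    slot_of: dict[str, list[tuple[str, int]]] = {}
    for cat in ("size", "benign_pop", "no_gene", "not_significant", "kept"):
        slot_of[cat] = slot_list[cursor:cursor + pools[cat]]
        cursor += pools[cat]

    calls: list[CnvCall] = []
    truth: list[str] = []
    aneuploidy: list[AneuploidyCall] = []
    benign_db: list[BenignCnvRecord] = []
    genes: list[GeneRecord] = []
    regions: list[ClinicalRegion] = []

    # aneuploidy: whole sex-chromosome calls, one per synthetic sample
    sex_len = model.chromosome_length(sex_chrom)
    for i in range(spec.n_aneuploidy):
        state = "gain" if i % 2 == 0 else "loss"
        call = _mk_call(f"AN{i + 1:02d}", sex_chrom, 1, sex_len, state)
        call.from_aneuploidy = True
        calls.append(call)
        truth.append("aneuploidy")
        aneuploidy.append(AneuploidyCall(call.sample_id, sex_chrom, state, 1.0))

    # sub-300 kb records: removed by the size filter before anything else
    for i in range(spec.n_small):
        chrom, base = slot_of["size"][i % len(slot_of["size"])]
        width = 50_000 + (i % 5) * 40_000  # 50-210 kb, all < 300 kb
        start = base + 1_000
        calls.append(_mk_call(f"S{i % 40:03d}", chrom, start, start + width - 1,
                              "loss" if i % 2 else "gain"))
        truth.append("size")

    # benign-population records: >= 300 kb and identical to a database CNV
    benign_states = {}
    for j, (chrom, base) in enumerate(slot_of["benign_pop"]):
        width = 300_000 + (j % 7) * 40_000
        state = "loss" if j % 2 else "gain"
        benign_states[j] = (chrom, base + 1_000, base + 1_000 + width - 1, state)
        benign_db.append(BenignCnvRecord(chrom, base + 1_000,
                                         base + 1_000 + width - 1, state,
                                         float(np.round(rng.uniform(0.05, 0.4), 4))))
    for i in range(spec.n_benign_pop):
        j = i % len(slot_of["benign_pop"])
        chrom, start, end, state = benign_states[j]
        calls.append(_mk_call(f"S{i % 40:03d}", chrom, start, end, state))
        truth.append("benign_pop")

    # gene-desert records: >= 300 kb, no database match, no overlapping gene
    for i in range(spec.n_no_gene):
        chrom, base = slot_of["no_gene"][i % len(slot_of["no_gene"])]
        width = 300_000 + (i % 7) * 40_000
        start = base + 1_000
        calls.append(_mk_call(f"S{i % 40:03d}", chrom, start, start + width - 1,
                              "loss" if i % 3 else "gain"))
        truth.append("no_gene")

    # not-clinically-significant: gene present but no curated region overlap
    for j, (chrom, base) in enumerate(slot_of["not_significant"]):
        genes.append(GeneRecord(chrom, base + 50_000, base + 80_000,
                                f"NSG{j + 1:04d}", bool(j % 3 == 0)))
    for i in range(spec.n_not_significant):
        j = i % len(slot_of["not_significant"])
        chrom, base = slot_of["not_significant"][j]
        width = 300_000 + (i % 7) * 40_000
        start = base + 1_000
        calls.append(_mk_call(f"S{i % 40:03d}", chrom, start, start + width - 1,
                              "loss" if i % 2 else "gain"))
        truth.append("not_significant")

    # survivors: gene plus a matching clinical region (pathogenic/VUS split)
    n_kept = spec.n_pathogenic_or_vus
    n_path = round(pathogenic_fraction * n_kept)
    n_loss = round(loss_fraction * n_kept)
    states = _loss_gain_pattern(n_kept, n_loss) if n_kept else []
    for i, (chrom, base) in enumerate(slot_of["kept"]):
        width = 310_000 + (i % 9) * 35_000
        start = base + 1_000
        end = start + width - 1
        call = _mk_call(f"K{i % 13:02d}", chrom, start, end, states[i])
        calls.append(call)
        truth.append("kept")
        genes.append(GeneRecord(chrom, start + 40_000, start + 90_000,
                                f"KG{i + 1:04d}", True))
        label = "pathogenic" if i < n_path else "VUS"
        regions.append(ClinicalRegion(chrom, start, end, f"SYN-F{i + 1:02d}",
                                      label, (f"KG{i + 1:04d}",)))

    # generator self-audit: no stray gene may overlap a no-gene slot
    for chrom, base in slot_of["no_gene"]:
        for g in genes:
            if g.chromosome == chrom and g.start <= base + slot_width - 1 and g.end >= base:
                raise ValidationError(
                    "fixture invariant violated: gene overlaps a no-gene slot"
                )

    order = rng.permutation(len(calls))
    calls = [calls[i] for i in order]
    truth = [truth[i] for i in order]
    return CascadeFixture(calls=calls, aneuploidy=aneuploidy,
                          benign_db=benign_db, genes=genes,
                          clinical_regions=regions, truth=truth)


# --- qPCR plates -------------------------------------------------------------

def make_qpcr_plate(gene_truths: list[tuple[str, int]], seed: int, *,
                    ct_sd: float = 0.05, n_replicates: int = 3,
                    control_gene: str = "GAPDH") -> list[QpcrWell]:
    """Simulate a SYBR-style plate in triplicate for patient and calibrator.

    Ct follows the Livak model: Ct = base - log2(template) + N(0, ct_sd),
    with the patient's target template proportional to CN/2, the
    calibrator's to 1, and the endogenous control at 1 on both arms.  A
    planted CN of 0 is rejected (its Ct would be unbounded).
    """
    for gene, cn in gene_truths:
        if cn < 1:
            raise ValueError(f"gene {gene}: planted copy number must be >= 1, got {cn}")
    rng = np.random.default_rng(child_seed(seed, "qpcr"))
    wells: list[QpcrWell] = []

    def emit(arm: str, gene: str, role: str, base: float, template: float) -> None:
        for rep in range(1, n_replicates + 1):
            noise = float(rng.normal(0.0, ct_sd)) if ct_sd > 0 else 0.0
            wells.append(QpcrWell(arm, gene, role, rep,
                                  base - math.log2(template) + noise))

    base_control = float(rng.uniform(18, 24))
    for arm in ("patient", "calibrator"):
        emit(arm, control_gene, "endogenous_control", base_control, 1.0)
    for gene, cn in gene_truths:
        base_target = float(rng.uniform(22, 30))
        emit("patient", gene, "target", base_target, cn / 2.0)
        emit("calibrator", gene, "target", base_target, 1.0)
    return wells
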