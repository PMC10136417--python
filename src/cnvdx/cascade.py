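"""Five-stage pathogenic/VUS filtration cascade and clinical classification.

Stages are applied in a fixed order — aneuploidy, size (< 300 kb), benign
population database, gene content, clinical significance — and every record
is removed at its FIRST failing stage, so the per-stage removal counts
partition the input: |input| = |kept| + sum(stage counts).

Survivors are labelled pathogenic or VUS by their best-overlapping curated
clinical region and carry the overlapping gene symbols and an ISCN string.
"""

from __future__ import annotations

from dataclasses import dataclass

from intervaltree import IntervalTree

from .iscn import to_iscn
from .records import (
    AneuploidyCall,
    BenignCnvRecord,
    ClassifiedCnv,
    ClinicalRegion,
    CnvCall,
    CytobandRecord,
    GeneRecord,
    overlap_length,
)

STAGES = ("aneuploidy", "size", "benign_pop", "no_gene", "not_significant")


@dataclass(frozen=True, slots=True)
class CascadeParams:
    """Thresholds of the removable stages.

    min_size_bp
        Calls strictly smaller than this are excluded (< 300 kb rule).
    benign_reciprocal_overlap
        Fraction for the two-sided (reciprocal) overlap with a
        state-compatible population CNV.
    clinical_min_call_overlap
        Call-side overlap fraction required to match a curated region
        (one-sided: curated syndrome regions may far exceed the call).
    """

    min_size_bp: int = 300_000
    benign_reciprocal_overlap: float = 0.5
    clinical_min_call_overlap: float = 0.5


DEFAULT_CASCADE_PARAMS = CascadeParams()


@dataclass(slots=True)
class CascadeResult:
    kept: list[ClassifiedCnv]
    removed: list[tuple[CnvCall, str]]
    stage_counts: dict[str, int]

    @property
    def n_input(self) -> int:
        return len(self.kept) + len(self.removed)


def _tree_index(records, get_chrom=lambda r: r.chromosome,
                get_start=lambda r: r.start, get_end=lambda r: r.end
                ) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for rec in records:
        trees.setdefault(get_chrom(rec), IntervalTree()).addi(
            get_start(rec), get_end(rec) + 1, rec)  # half-open tree coords
    return trees


def filter_size(calls: list[CnvCall], min_size_bp: int = 300_000
                ) -> tuple[list[CnvCall], list[CnvCall]]:
    """Partition calls by the size rule: < min_size_bp fails (strict)."""
    passed = [c for c in calls if c.size_bp >= min_size_bp]
    failed = [c for c in calls if c.size_bp < min_size_bp]
    return passed, failed


def _benign_match(call: CnvCall, trees: dict[str, IntervalTree],
                  threshold: float) -> bool:
    tree = trees.get(call.chromosome)
    if tree is None:
        return False
    for iv in tree.overlap(call.start, call.end + 1):
        rec: BenignCnvRecord = iv.data
        if rec.state not in ("either", call.copy_state):
            continue
        olen = overlap_length(call.start, call.end, rec.start, rec.end)
        call_len = call.size_bp
        db_len = rec.end - rec.start + 1
        if olen / call_len >= threshold and olen / db_len >= threshold:
            return True
    return False


def filter_benign_pop(calls: list[CnvCall], db: list[BenignCnvRecord],
                      min_reciprocal_overlap: float = 0.5
                      ) -> tuple[list[CnvCall], list[CnvCall]]:
    """Drop calls reciprocally matching a state-compatible population CNV."""
    trees = _tree_index(db)
    passed, failed = [], []
    for call in calls:
        (failed if _benign_match(call, trees, min_reciprocal_overlap)
         else passed).append(call)
    return passed, failed


def overlapping_genes(call: CnvCall, trees: dict[str, IntervalTree]
                      ) -> tuple[str, ...]:
    tree = trees.get(call.chromosome)
    if tree is None:
        return ()
    hits = sorted((iv.data for iv in tree.overlap(call.start, call.end + 1)),
                  key=lambda g: (g.start, g.symbol))
    return tuple(g.symbol for g in hits)


def filter_gene_content(calls: list[CnvCall], genes: list[GeneRecord]
                        ) -> tuple[list[tuple[CnvCall, tuple[str, ...]]],
                                   list[CnvCall]]:
    """Keep calls overlapping >= 1 gene by >= 1 bp; attach the symbols."""
    trees = _tree_index(genes)
    passed, failed = [], []
    for call in calls:
        symbols = overlapping_genes(call, trees)
        if symbols:
            passed.append((call, symbols))
        else:
            failed.append(call)
    return passed, failed


def classify_clinical(calls: list[CnvCall], regions: list[ClinicalRegion],
                      min_call_overlap: float = 0.5
                      ) -> tuple[list[tuple[CnvCall, ClinicalRegion]],
                                 list[CnvCall]]:
    """Match calls to curated regions by call-side overlap.

    The best region wins: largest overlap length, then pathogenic over VUS,
    then region input order.  Calls matching nothing are not clinically
    significant.
    """
    region_order = {id(r): i for i, r in enumerate(regions)}
    trees = _tree_index(regions)
    classified, not_significant = [], []
    for call in calls:
        tree = trees.get(call.chromosome)
        best: tuple | None = None
        if tree is not None:
            for iv in tree.overlap(call.start, call.end + 1):
                region: ClinicalRegion = iv.data
                olen = overlap_length(call.start, call.end, region.start, region.end)
                if olen / call.size_bp < min_call_overlap:
                    continue
                key = (-olen, 0 if region.class_label == "pathogenic" else 1,
                       region_order[id(region)])
                if best is None or key < best[0]:
                    best = (key, region)
        if best is None:
            not_significant.append(call)
        else:
            classified.append((call, best[1]))
    return classified, not_significant


def run_cascade(calls: list[CnvCall], aneuploidy: list[AneuploidyCall],
                db: list[BenignCnvRecord], genes: list[GeneRecord],
                regions: list[ClinicalRegion],
                params: CascadeParams = DEFAULT_CASCADE_PARAMS, *,
                cytobands: list[CytobandRecord] | None = None,
                build: str = "synth") -> CascadeResult:
    """Run the full filtration in the fixed stage order.

    When ``cytobands`` are supplied the kept records carry ISCN strings for
    the given genome build; otherwise the iscn field is left empty.
    """
    removed: list[tuple[CnvCall, str]] = []
    stage_counts = {stage: 0 for stage in STAGES}

    aneu_keys = {(a.sample_id, a.chromosome, a.copy_state) for a in aneuploidy}
    surviving = []
    for call in calls:
        if call.from_aneuploidy or (
                (call.sample_id, call.chromosome, call.copy_state) in aneu_keys):
            removed.append((call, "aneuploidy"))
        else:
            surviving.append(call)

    surviving, failed = filter_size(surviving, params.min_size_bp)
    removed.extend((c, "size") for c in failed)

    surviving, failed = filter_benign_pop(surviving, db,
                                          params.benign_reciprocal_overlap)
    removed.extend((c, "benign_pop") for c in failed)

    with_genes, failed = filter_gene_content(surviving, genes)
    removed.extend((c, "no_gene") for c in failed)

    gene_symbols = {id(c): syms for c, syms in with_genes}
    classified, failed = classify_clinical([c for c, _ in with_genes], regions,
                                           params.clinical_min_call_overlap)
    removed.extend((c, "not_significant") for c in failed)

    kept: list[ClassifiedCnv] = []
    for call, region in classified:
        iscn_str = to_iscn(call, cytobands, build=build) if cytobands else ""
        kept.append(ClassifiedCnv(call=call, class_label=region.class_label,
                                  syndrome=region.syndrome,
                                  genes=gene_symbols[id(call)], iscn=iscn_str))

    for _, stage in removed:
        stage_counts[stage] += 1
    assert len(calls) == len(kept) + sum(stage_counts.values())
    return CascadeResult(kept=kept, removed=removed, stage_counts=stage_counts)
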