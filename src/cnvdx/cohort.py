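"""Cohort-level reporting: diagnostic yields, gain/loss prevalence, size bins,
and array-vs-karyotype concordance.

Percentage conventions follow clinical reporting practice: diagnostic yields
are rounded half-up to two decimals (10/63 prints as 15.87), gain/loss
prevalences half-up to whole percent (14/24 and 10/24 print as 58 and 42).
Size bins are half-open on Mb with edges at 5, 10, 20 and 25.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .records import AneuploidyCall, ClassifiedCnv, CnvCall, KaryotypeRecord

SIZE_BINS = ("<5", "5-10", "10-20", "20-25", ">25")
_BIN_EDGES_MB = (5.0, 10.0, 20.0, 25.0)


def _round_half_up(x: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def diagnostic_yield(n_abnormal: int, n_total: int) -> float:
    """Percentage of diagnosed patients, rounded half-up to 2 decimals."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not 0 <= n_abnormal <= n_total:
        raise ValueError(f"need 0 <= n_abnormal <= n_total, got {n_abnormal}/{n_total}")
    return _round_half_up(100.0 * n_abnormal / n_total, 2)


def _as_call(c) -> CnvCall:
    return c.call if isinstance(c, ClassifiedCnv) else c


def gain_loss_prevalence(calls: list) -> tuple[int, int]:
    """(loss %, gain %) over kept calls, each rounded half-up to integers."""
    if not calls:
        raise ValueError("prevalence undefined for an empty call set")
    states = [_as_call(c).copy_state for c in calls]
    n = len(states)
    n_loss = states.count("loss")
    return (int(_round_half_up(100.0 * n_loss / n, 0)),
            int(_round_half_up(100.0 * (n - n_loss) / n, 0)))


def size_bin_distribution(calls: list) -> dict[str, int]:
    """Counts per half-open Mb size bin: [0,5), [5,10), [10,20), [20,25), [25,inf)."""
    counts = {b: 0 for b in SIZE_BINS}
    for c in calls:
        mb = _as_call(c).size_bp / 1e6
        for edge, label in zip(_BIN_EDGES_MB, SIZE_BINS):
            if mb < edge:
                counts[label] += 1
                break
        else:
            counts[SIZE_BINS[-1]] += 1
    return counts


def size_bin_percentages(calls: list, *, bp_weighted: bool = False
                         ) -> dict[str, float]:
    """Per-bin percentages, count-weighted by default or bp-weighted.

    Both weightings are offered because published size distributions do not
    always state which was used; each is rounded half-up to one decimal.
    """
    if not calls:
        raise ValueError("percentages undefined for an empty call set")
    weights = {b: 0.0 for b in SIZE_BINS}
    total = 0.0
    for c in calls:
        call = _as_call(c)
        w = call.size_bp if bp_weighted else 1.0
        mb = call.size_bp / 1e6
        for edge, label in zip(_BIN_EDGES_MB, SIZE_BINS):
            if mb < edge:
                weights[label] += w
                break
        else:
            weights[SIZE_BINS[-1]] += w
        total += w
    return {b: _round_half_up(100.0 * w / total, 1) for b, w in weights.items()}


@dataclass(slots=True)
class KaryotypeComparison:
    """2x2 concordance of karyotype vs array abnormality, with listings."""

    both_abnormal: int
    karyotype_only: int
    array_only: int
    both_normal: int
    array_only_samples: list[str] = field(default_factory=list)
    karyotype_only_samples: list[str] = field(default_factory=list)


def compare_karyotype(karyo: list[KaryotypeRecord],
                      array_abnormal: list[str]) -> KaryotypeComparison:
    """Cross-tabulate G-banding abnormality against array abnormality.

    ``array_abnormal`` lists sample ids flagged abnormal by the array; any
    id absent from the karyotype table is an orphan and rejected.
    """
    karyo_ids = {r.sample_id for r in karyo}
    orphans = sorted(set(array_abnormal) - karyo_ids)
    if orphans:
        raise ValueError(f"array samples missing from karyotype table: {orphans}")
    array_set = set(array_abnormal)
    cells = {"bb": 0, "ko": 0, "ao": 0, "nn": 0}
    array_only, karyo_only = [], []
    for rec in karyo:
        in_array = rec.sample_id in array_set
        if rec.abnormal and in_array:
            cells["bb"] += 1
        elif rec.abnormal:
            cells["ko"] += 1
            karyo_only.append(rec.sample_id)
        elif in_array:
            cells["ao"] += 1
            array_only.append(rec.sample_id)
        else:
            cells["nn"] += 1
    return KaryotypeComparison(cells["bb"], cells["ko"], cells["ao"], cells["nn"],
                               array_only, karyo_only)


@dataclass(slots=True)
class CohortReport:
    """The cohort summary; percentages always recompute from its own counts."""

    n_patients: int
    n_abnormal_array: int
    n_abnormal_karyotype: int
    yield_array_pct: float
    yield_karyotype_pct: float
    n_cnvs_kept: int
    n_loss: int
    n_gain: int
    loss_pct: int
    gain_pct: int
    size_bins: dict[str, int]
    n_aneuploid_patients: int


def build_cohort_report(n_patients: int, kept: list[ClassifiedCnv],
                        aneuploidy: list[AneuploidyCall],
                        karyotype: list[KaryotypeRecord]) -> CohortReport:
    """Assemble the report from pipeline outputs.

    A patient counts as array-abnormal when they carry at least one kept
    pathogenic call or an aneuploidy.
    """
    pathogenic_samples = {cc.call.sample_id for cc in kept
                          if cc.class_label == "pathogenic"}
    aneuploid_samples = {a.sample_id for a in aneuploidy}
    abnormal_array = pathogenic_samples | aneuploid_samples
    abnormal_karyo = sum(1 for r in karyotype if r.abnormal)
    n_loss = sum(1 for cc in kept if cc.call.copy_state == "loss")
    loss_pct, gain_pct = gain_loss_prevalence(kept) if kept else (0, 0)
    return CohortReport(
        n_patients=n_patients,
        n_abnormal_array=len(abnormal_array),
        n_abnormal_karyotype=abnormal_karyo,
        yield_array_pct=diagnostic_yield(len(abnormal_array), n_patients),
        yield_karyotype_pct=diagnostic_yield(abnormal_karyo, n_patients),
        n_cnvs_kept=len(kept),
        n_loss=n_loss,
        n_gain=len(kept) - n_loss,
        loss_pct=loss_pct,
        gain_pct=gain_pct,
        size_bins=size_bin_distribution(kept),
        n_aneuploid_patients=len(aneuploid_samples),
    )
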