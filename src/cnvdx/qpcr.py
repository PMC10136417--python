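"""Relative copy-number quantification from qPCR threshold cycles (Livak).

The Livak (ddCt) model assumes exact doubling per cycle.  For each arm
(patient, calibrator) the target gene's mean Ct is referenced to an
endogenous control (e.g. GAPDH): dCt = Ct_target - Ct_control.  The
patient-vs-calibrator difference ddCt = dCt_patient - dCt_calibrator gives
the relative quantity RQ = 2**-ddCt; on genomic DNA a diploid calibrator
makes 2*RQ the patient's copy-number estimate (RQ 0.5 = heterozygous
deletion, RQ 1.5 = single-copy gain).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .records import ClassifiedCnv, CnvdxError, GeneRecord, ValidationError


class IncompletePlateError(CnvdxError):
    """A required (arm, gene, role) well group is missing from the plate."""


@dataclass(frozen=True, slots=True)
class QpcrWell:
    """One well: arm (patient/calibrator), gene, role, replicate index, Ct."""

    sample_arm: str  # patient | calibrator
    gene: str
    role: str  # target | endogenous_control
    replicate: int
    ct: float

    def __post_init__(self) -> None:
        if self.sample_arm not in ("patient", "calibrator"):
            raise ValidationError(f"sample_arm must be patient/calibrator, got {self.sample_arm!r}")
        if self.role not in ("target", "endogenous_control"):
            raise ValidationError(f"role must be target/endogenous_control, got {self.role!r}")
        if self.ct <= 0:
            raise ValidationError(f"Ct must be positive, got {self.ct}")


@dataclass(frozen=True, slots=True)
class ReplicateStats:
    mean_ct: float
    sd_ct: float
    n: int
    high_variance: bool  # sample sd above 0.5 cycles


@dataclass(frozen=True, slots=True)
class QpcrQuant:
    """Per-gene Livak quantities and the derived integer copy number."""

    gene: str
    delta_ct_patient: float
    delta_ct_calibrator: float
    delta_delta_ct: float
    rq: float
    copy_number_estimate: int
    direction: str  # decrease | no_change | increase
    p_value: float  # two-sample t-test on per-replicate dCt, patient vs calibrator


def _wells(wells: list[QpcrWell], arm: str, role: str, gene: str | None = None
           ) -> list[QpcrWell]:
    out = [w for w in wells
           if w.sample_arm == arm and w.role == role
           and (gene is None or w.gene == gene)]
    if not out:
        what = f"{arm}/{role}" + (f"/{gene}" if gene else "")
        raise IncompletePlateError(f"no wells for {what}")
    return out


def replicate_stats(wells: list[QpcrWell], gene: str, arm: str, role: str
                    ) -> ReplicateStats:
    """Mean and sample sd of the replicate Cts for one well group."""
    group = _wells(wells, arm, role, gene)
    cts = np.array([w.ct for w in group])
    sd = float(cts.std(ddof=1)) if len(cts) > 1 else 0.0
    return ReplicateStats(float(cts.mean()), sd, len(cts), sd > 0.5)


def quantify(wells: list[QpcrWell], gene: str, *,
             decrease_below: float = 0.75, increase_above: float = 1.25) -> QpcrQuant:
    """Livak ddCt quantification of one target gene.

    Requires target and endogenous-control wells on both arms.  Direction is
    called on RQ against the ``decrease_below``/``increase_above`` bounds.
    The reported p-value is a two-sample t-test comparing per-replicate
    dCt values (each target replicate referenced to its arm's mean control
    Ct) between arms; it accompanies the call but does not gate it.
    """
    d_ct = {}
    d_ct_reps = {}
    for arm in ("patient", "calibrator"):
        target = _wells(wells, arm, "target", gene)
        control = _wells(wells, arm, "endogenous_control")
        control_mean = float(np.mean([w.ct for w in control]))
        reps = np.array([w.ct - control_mean for w in target])
        d_ct[arm] = float(reps.mean())
        d_ct_reps[arm] = reps

    ddct = d_ct["patient"] - d_ct["calibrator"]
    rq = 2.0 ** -ddct
    cn = max(0, math.floor(2.0 * rq + 0.5))
    if rq < decrease_below:
        direction = "decrease"
    elif rq > increase_above:
        direction = "increase"
    else:
        direction = "no_change"

    if len(d_ct_reps["patient"]) > 1 and len(d_ct_reps["calibrator"]) > 1 and (
            d_ct_reps["patient"].std() > 0 or d_ct_reps["calibrator"].std() > 0):
        p_value = float(stats.ttest_ind(d_ct_reps["patient"],
                                        d_ct_reps["calibrator"]).pvalue)
    else:
        p_value = float("nan")

    return QpcrQuant(gene, d_ct["patient"], d_ct["calibrator"], ddct, rq, cn,
                     direction, p_value)


def concordance(quants: list[QpcrQuant], calls: list[ClassifiedCnv],
                gene_track: list[GeneRecord]) -> pd.DataFrame:
    """Score qPCR directions against the array calls covering each gene.

    A gene confirms its array call when the directions agree: loss with
    decrease, gain with increase.  Returns a table with one row per
    quantified gene.
    """
    by_symbol = {g.symbol: g for g in gene_track}
    rows = []
    for q in quants:
        if q.gene not in by_symbol:
            raise LookupError(f"gene {q.gene!r} not present in the gene track")
        gene = by_symbol[q.gene]
        array_state = None
        for cc in calls:
            c = cc.call
            if (c.chromosome == gene.chromosome
                    and c.start <= gene.end and c.end >= gene.start):
                array_state = c.copy_state
                break
        concordant = (array_state == "loss" and q.direction == "decrease") or \
                     (array_state == "gain" and q.direction == "increase")
        rows.append({"gene": q.gene, "array_state": array_state,
                     "qpcr_direction": q.direction, "rq": q.rq,
                     "concordant": bool(concordant)})
    return pd.DataFrame(rows, columns=["gene", "array_state", "qpcr_direction",
                                       "rq", "concordant"])
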