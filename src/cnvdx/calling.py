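"""Probe-level CNV calling.

A segment is reportable when at least ``min_probes`` consecutive same-sign
probes have a mean |log2 ratio| of at least the candidate threshold (0.25 by
default).  Full single-copy dosage is a second tier: a segment mean > 0.58
(~log2 3/2) is a full gain, < -1 (log2 1/2) a full loss; reportable segments
between the two tiers are retained but flagged as sub-integer dosage
(possible mosaics).  A chromosome is aneuploid when nearly all of its design
probes are covered by same-direction calls.

Segmentation is a run rule, not a change-point optimisation: probes are
partitioned into maximal sign-consistent runs (a zero or opposite-sign probe
terminates a run), run ends are trimmed of probes individually below the
candidate threshold, and the surviving run is gated on length and mean.  The
end trim keeps breakpoints on the aberrant probes themselves instead of
letting low-level same-sign noise at the flanks drag them outward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from itertools import groupby

import numpy as np

from .records import AneuploidyCall, CnvCall, ProbeMeasurement, ValidationError


@dataclass(frozen=True, slots=True)
class CallingParams:
    """Thresholds for segment calling and dosage assignment.

    min_probes
        Minimum consecutive probes per reportable segment.
    candidate_threshold
        Minimum |mean log2| for a reportable aberration (two-sided).
    gain_threshold / loss_threshold
        Full single-copy dosage tiers: mean > gain_threshold is a full
        gain, mean < loss_threshold a full loss (log2(3/2) and log2(1/2)).
    aneuploidy_fraction
        Fraction of a chromosome's probes that must be covered by
        same-direction calls to declare aneuploidy.
    """

    min_probes: int = 3
    candidate_threshold: float = 0.25
    gain_threshold: float = 0.58
    loss_threshold: float = -1.0
    aneuploidy_fraction: float = 0.9

    def __post_init__(self) -> None:
        if self.min_probes < 1:
            raise ValidationError("min_probes must be >= 1")
        if not 0 < self.candidate_threshold <= self.gain_threshold:
            raise ValidationError("need 0 < candidate_threshold <= gain_threshold")
        if self.loss_threshold > -self.candidate_threshold:
            raise ValidationError("need loss_threshold <= -candidate_threshold")
        if not 0 < self.aneuploidy_fraction <= 1:
            raise ValidationError("aneuploidy_fraction must be in (0, 1]")


DEFAULT_PARAMS = CallingParams()


def copy_number_from_log2(mean_log2: float) -> int:
    """Integer copy number from a diploid baseline: round(2 * 2**log2), >= 0.

    Rounding is half-up so e.g. a mean of exactly log2(1.25) maps to CN 3.
    """
    return max(0, math.floor(2.0 * 2.0 ** mean_log2 + 0.5))


def _dosage_flag(mean_log2: float, params: CallingParams) -> str:
    if mean_log2 > params.gain_threshold or mean_log2 < params.loss_threshold:
        return "full"
    return "sub-integer"


def assign_copy_state(call: CnvCall, params: CallingParams = DEFAULT_PARAMS,
                      sex_context: str = "autosome") -> CnvCall:
    """Assign copy state, integer copy number and the dosage flag.

    The baseline is uniformly diploid — sex chromosomes are hybridised
    against a sex-matched reference, so a doubled X in 47,XXY reads as
    log2(4/2) and is annotated x4, exactly like an autosomal event.
    ``sex_context`` is accepted for interface completeness but does not
    change the arithmetic.
    """
    if call.mean_log2 == 0:
        raise ValidationError("segment mean of 0 cannot be dosage-typed")
    return replace(
        call,
        copy_state="gain" if call.mean_log2 > 0 else "loss",
        copy_number=copy_number_from_log2(call.mean_log2),
        dosage_flag=_dosage_flag(call.mean_log2, params),
    )


def _check_sorted(probes: list[ProbeMeasurement]) -> None:
    for prev, nxt in zip(probes, probes[1:]):
        if prev.chromosome == nxt.chromosome and prev.position >= nxt.position:
            raise ValidationError(
                f"probes not sorted: {prev.chromosome}:{prev.position} before "
                f"{nxt.chromosome}:{nxt.position}"
            )


def call_segments(probes: list[ProbeMeasurement],
                  params: CallingParams = DEFAULT_PARAMS,
                  sample_id: str = "sample") -> list[CnvCall]:
    """Call aberrant segments from a single sample's sorted probe list.

    Returns non-overlapping calls whose boundaries are the first and last
    retained probe positions; each call already carries copy state, integer
    copy number and dosage flag.
    """
    _check_sorted(probes)
    calls: list[CnvCall] = []
    for chrom, group in groupby(probes, key=lambda p: p.chromosome):
        chrom_probes = list(group)
        values = np.array([p.log2_ratio for p in chrom_probes])
        signs = np.sign(values)
        idx = 0
        for sign, run in groupby(range(len(values)), key=lambda i: signs[i]):
            run_idx = list(run)
            idx += len(run_idx)
            if sign == 0:
                continue
            lo, hi = run_idx[0], run_idx[-1]
            # trim flanking probes individually below the candidate tier
            while lo <= hi and abs(values[lo]) < params.candidate_threshold:
                lo += 1
            while hi >= lo and abs(values[hi]) < params.candidate_threshold:
                hi -= 1
            n = hi - lo + 1
            if n < params.min_probes:
                continue
            mean = float(values[lo:hi + 1].mean())
            if abs(mean) < params.candidate_threshold:
                continue
            call = CnvCall(
                sample_id=sample_id,
                chromosome=chrom,
                start=chrom_probes[lo].position,
                end=chrom_probes[hi].position,
                n_probes=n,
                mean_log2=mean,
                copy_state="gain" if mean > 0 else "loss",
                copy_number=0,
            )
            calls.append(assign_copy_state(call, params))
    return calls


def detect_aneuploidy(calls: list[CnvCall], design, params: CallingParams = DEFAULT_PARAMS
                      ) -> list[AneuploidyCall]:
    """Flag chromosomes whose probes are nearly fully covered by one-direction calls.

    ``design`` is an :class:`~cnvdx.synthetic.ArrayDesign`.  For every
    chromosome, the fraction of its design probes falling inside gain
    (resp. loss) calls is computed; at or above ``aneuploidy_fraction`` the
    chromosome is declared aneuploid and the contributing calls are marked
    ``from_aneuploidy`` in place.
    """
    if not calls:
        return []
    sample_id = calls[0].sample_id
    positions: dict[str, np.ndarray] = {}
    for chrom, pos, _pid in design.probes:
        positions.setdefault(chrom, []).append(pos)  # type: ignore[arg-type]
    positions = {c: np.asarray(p) for c, p in positions.items()}

    out: list[AneuploidyCall] = []
    for chrom, pos in positions.items():
        for state in ("gain", "loss"):
            contributing = [c for c in calls
                            if c.chromosome == chrom and c.copy_state == state]
            if not contributing:
                continue
            covered = np.zeros(len(pos), dtype=bool)
            for c in contributing:
                lo = np.searchsorted(pos, c.start, side="left")
                hi = np.searchsorted(pos, c.end, side="right")
                covered[lo:hi] = True
            fraction = float(covered.mean())
            if fraction >= params.aneuploidy_fraction:
                out.append(AneuploidyCall(sample_id, chrom, state, fraction))
                for c in contributing:
                    c.from_aneuploidy = True
    return out
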