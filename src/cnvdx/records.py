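"""Core record types shared across the pipeline.

All genomic intervals are 1-based and inclusive at both ends, matching the
coordinate pairs printed in ISCN microarray strings such as
``arr[hg18] 11q24.2q25(123615752_134432324)x1``.  The only on-disk format
using a different convention is the UCSC cytoBand file (0-based half-open),
which is converted on read (see :mod:`cnvdx.io`).

Interval size is ``end - start + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class CnvdxError(Exception):
    """Base class for all package errors."""


class ValidationError(CnvdxError, ValueError):
    """An input violated a structural invariant (rejected, not repaired)."""


@dataclass(frozen=True, slots=True)
class ProbeMeasurement:
    """A single array probe: genomic position and log2(test/reference) ratio."""

    chromosome: str
    position: int  # bp, 1-based
    probe_id: str
    log2_ratio: float

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(
                f"probe {self.probe_id}: position must be >= 1, got {self.position}"
            )


@dataclass(frozen=True, slots=True)
class GeneRecord:
    """A gene interval; ``is_omim`` marks OMIM-annotated disease genes."""

    chromosome: str
    start: int
    end: int
    symbol: str
    is_omim: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"gene {self.symbol}: start {self.start} > end {self.end}"
            )


@dataclass(frozen=True, slots=True)
class BenignCnvRecord:
    """A CNV seen in healthy controls (a DGV-style population record).

    ``state`` is the copy direction of the population variant; ``either``
    matches both gains and losses.  ``frequency`` is the population allele
    or carrier frequency, in [0, 1].
    """

    chromosome: str
    start: int
    end: int
    state: str  # gain | loss | either
    frequency: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"benign record {self.chromosome}:{self.start}-{self.end}: start > end"
            )
        if self.state not in ("gain", "loss", "either"):
            raise ValidationError(f"benign record state must be gain/loss/either, got {self.state!r}")
        if not 0.0 <= self.frequency <= 1.0:
            raise ValidationError(f"benign record frequency {self.frequency} outside [0, 1]")


@dataclass(frozen=True, slots=True)
class CytobandRecord:
    """One Giemsa band, 1-based inclusive in memory (e.g. band ``q24.2``)."""

    chromosome: str
    start: int
    end: int
    band: str  # e.g. "q24.2"
    stain: str = "gneg"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"cytoband {self.chromosome}{self.band}: start {self.start} > end {self.end}"
            )

    @property
    def arm(self) -> str:
        return self.band[0]


@dataclass(frozen=True, slots=True)
class ClinicalRegion:
    """A curated syndrome interval with a fixed pathogenic/VUS class label."""

    chromosome: str
    start: int
    end: int
    syndrome: str
    class_label: str  # pathogenic | VUS
    genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"clinical region {self.syndrome}: start > end")
        if self.class_label not in ("pathogenic", "VUS"):
            raise ValidationError(
                f"clinical region class must be pathogenic/VUS, got {self.class_label!r}"
            )


@dataclass(slots=True)
class CnvCall:
    """A contiguous aberrant segment called from probe-level log2 ratios.

    ``dosage_flag`` is ``"full"`` when the segment mean clears the full
    single-copy dosage thresholds (> 0.58 for gains, < -1 for losses,
    i.e. log2(3/2) and log2(1/2)) and ``"sub-integer"`` for reportable
    aberrations whose mean sits between the +/-0.25 candidate tier and full
    dosage — possible mosaics, retained but flagged.
    """

    sample_id: str
    chromosome: str
    start: int
    end: int
    n_probes: int
    mean_log2: float
    copy_state: str  # gain | loss
    copy_number: int
    size_bp: int = 0
    dosage_flag: str = "full"
    from_aneuploidy: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"call {self.chromosome}:{self.start}-{self.end}: start > end")
        if self.copy_state not in ("gain", "loss"):
            raise ValidationError(f"copy_state must be gain/loss, got {self.copy_state!r}")
        if self.size_bp == 0:
            self.size_bp = self.end - self.start + 1


@dataclass(frozen=True, slots=True)
class AneuploidyCall:
    """A whole-chromosome dosage change (e.g. trisomy, monosomy X)."""

    sample_id: str
    chromosome: str
    copy_state: str  # gain | loss
    fraction_aberrant: float


@dataclass(slots=True)
class ClassifiedCnv:
    """A cascade survivor: the call plus clinical annotation and ISCN string."""

    call: CnvCall
    class_label: str  # pathogenic | VUS
    syndrome: str
    genes: tuple[str, ...] = ()
    iscn: str = ""


@dataclass(frozen=True, slots=True)
class KaryotypeRecord:
    """A G-banding result; the ISCN karyotype string is opaque metadata."""

    sample_id: str
    gband_string: str
    abnormal: bool


def overlap_length(start_a: int, end_a: int, start_b: int, end_b: int) -> int:
    """Overlap in bp between two 1-based inclusive intervals (0 if disjoint)."""
    return max(0, min(end_a, end_b) - max(start_a, start_b) + 1)
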