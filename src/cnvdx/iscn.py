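"""ISCN-style microarray nomenclature: rendering, parsing, size convention.

A microarray result is written ``arr[<build>] <chrom><band_start><band_end>
(<start>_<end>)x<copy number>``, e.g. ``arr[hg18] 11q24.2q25
(123615752_134432324)x1``; the end band is omitted when the call lies within
a single band.  Sizes are reported in Mb truncated (not rounded) to one
decimal, the convention that reproduces printed clinical report sizes such
as 10.8, 3.7 and 38.5 Mb from their coordinate pairs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .records import CnvCall, CnvdxError, CytobandRecord


class IscnParseError(CnvdxError, ValueError):
    """A nomenclature string could not be parsed; message carries position."""


@dataclass(frozen=True, slots=True)
class IscnCall:
    genome_build: str
    chromosome: str
    band_start: str
    band_end: str
    start: int
    end: int
    copy_number: int


def band_for_position(cytobands: list[CytobandRecord], chromosome: str,
                      position: int) -> str:
    """Name of the unique band containing ``position`` on ``chromosome``."""
    for band in cytobands:
        if band.chromosome == chromosome and band.start <= position <= band.end:
            return band.band
    raise LookupError(
        f"position {chromosome}:{position} falls in no cytoband"
    )


def to_iscn(call: CnvCall, cytobands: list[CytobandRecord],
            build: str = "hg18") -> str:
    """Render a call as an ISCN microarray string."""
    band_start = band_for_position(cytobands, call.chromosome, call.start)
    band_end = band_for_position(cytobands, call.chromosome, call.end)
    bands = band_start if band_start == band_end else band_start + band_end
    return (f"arr[{build}] {call.chromosome}{bands}"
            f"({call.start}_{call.end})x{call.copy_number}")


_ISCN_RE = re.compile(
    r"^arr\[(?P<build>[^\]]+)\]\s*"
    r"(?P<chrom>\d+|X|Y)\s*"
    r"(?P<band1>[pq]\d+(?:\.\d+)?)\s*-?\s*"
    r"(?P<band2>[pq]\d+(?:\.\d+)?)?\s*"
    r"\(\s*(?P<start>\d+)\s*_\s*(?P<end>\d+)\s*\)\s*"
    r"x(?P<cn>\d+)$"
)


def parse_iscn(s: str) -> IscnCall:
    """Parse an ISCN microarray string, tolerating stray internal spaces.

    Raises :class:`IscnParseError` naming the offending position for a
    missing coordinate separator, missing ``x<n>`` suffix, or malformed
    band labels.
    """
    text = s.strip()
    if not text:
        raise IscnParseError("empty nomenclature string")
    paren = re.search(r"\(([^)]*)\)", text)
    if paren and "_" not in paren.group(1):
        raise IscnParseError(
            f"missing '_' coordinate separator at position {paren.start(1)}: "
            f"{paren.group(1)!r}"
        )
    if paren and not re.search(r"\)\s*x\d+", text):
        raise IscnParseError("missing copy-number suffix 'x<n>' after coordinates")
    m = _ISCN_RE.match(text)
    if not m:
        raise IscnParseError(f"malformed ISCN string: {s!r}")
    band1 = m.group("band1")
    band2 = m.group("band2") or band1
    start, end = int(m.group("start")), int(m.group("end"))
    return IscnCall(genome_build=m.group("build"), chromosome=m.group("chrom"),
                    band_start=band1, band_end=band2, start=start, end=end,
                    copy_number=int(m.group("cn")))


def span_mb(start: int, end: int) -> float:
    """Interval span in Mb, truncated to one decimal: floor(size/1e5)/10.

    Truncation (not rounding) is the reporting convention: a 3,764,485 bp
    interval prints as 3.7 Mb, not 3.8.
    """
    if start > end:
        raise ValueError(f"start {start} > end {end}")
    return ((end - start + 1) // 100_000) / 10


def aneuploidy_to_iscn(chromosome: str, copy_number: int,
                       cytobands: list[CytobandRecord],
                       build: str = "hg18") -> tuple[str, str]:
    """Render a whole-chromosome event as one arm-spanning line per arm.

    Mirrors clinical reports where e.g. monosomy X appears as an
    ``Xp22.33p11.1(...)x1`` / ``Xq11.1q28(...)x1`` pair; the gap between
    the two lines is the centromeric region taken from the cytoband table.
    """
    bands = sorted((b for b in cytobands if b.chromosome == chromosome),
                   key=lambda b: b.start)
    if not bands:
        raise LookupError(f"no cytobands for chromosome {chromosome}")
    lines = []
    for arm in ("p", "q"):
        arm_bands = [b for b in bands if b.arm == arm]
        if not arm_bands:
            continue
        first, last = arm_bands[0], arm_bands[-1]
        # p-arm labels descend toward the centromere, so the distal band
        # comes first in the printed pair for both arms
        lines.append(f"arr[{build}] {chromosome}{first.band}{last.band}"
                     f"({first.start}_{last.end})x{copy_number}")
    return tuple(lines)  # type: ignore[return-value]
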