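"""Readers and writers for every on-disk table the pipeline touches.

All tables are tab-delimited text with a header row.  In-memory coordinates
are 1-based inclusive everywhere; the single on-disk exception is the UCSC
cytoBand dialect (0-based half-open, no header), which is converted on
read/write.  Every 1-based file starts with the comment line
``# coordinates: 1-based inclusive`` so the convention travels with the
data.  Readers reject coordinate violations (end < start, gaps/overlaps in
band tilings); they never repair them.
"""

from __future__ import annotations

import math
import warnings
from importlib import resources
from pathlib import Path

from .qpcr import QpcrWell
from .records import (
    BenignCnvRecord,
    ClassifiedCnv,
    ClinicalRegion,
    CnvCall,
    CnvdxError,
    CytobandRecord,
    GeneRecord,
    KaryotypeRecord,
    ProbeMeasurement,
    ValidationError,
)

COORD_COMMENT = "# coordinates: 1-based inclusive"


class ParseError(CnvdxError, ValueError):
    """A malformed row; the message names the file and 1-based line number."""


def _norm_chrom(name: str) -> str:
    """Strip a leading 'chr' prefix; tables in the wild mix both styles."""
    return name[3:] if name.lower().startswith("chr") else name


def _chrom_sort_key(name: str) -> tuple[int, int | str]:
    return (0, int(name)) if name.isdigit() else (1, name)


def _rows(path: str | Path, expected_header: list[str] | None):
    """Yield (line_number, fields) for data rows; validates the header."""
    path = Path(path)
    with path.open() as fh:
        header_seen = expected_header is None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if not header_seen:
                if fields != expected_header:
                    raise ParseError(
                        f"{path}:{lineno}: expected header {expected_header}, "
                        f"got {fields}"
                    )
                header_seen = True
                continue
            yield lineno, fields
        if not header_seen:
            raise ParseError(f"{path}: empty file, header missing")


def _parse_int(value: str, path, lineno: int, what: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: non-integer {what}: {value!r}") from None


def _parse_float(value: str, path, lineno: int, what: str) -> float:
    try:
        x = float(value)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: non-numeric {what}: {value!r}") from None
    if not math.isfinite(x):
        raise ParseError(f"{path}:{lineno}: non-finite {what}: {value!r}")
    return x


# --- probe tables ------------------------------------------------------------

PROBE_HEADER = ["chromosome", "position", "probe_id", "log2_ratio"]


def write_probe_table(probes: list[ProbeMeasurement], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write(COORD_COMMENT + "\n")
        fh.write("\t".join(PROBE_HEADER) + "\n")
        for p in probes:
            fh.write(f"{p.chromosome}\t{p.position}\t{p.probe_id}\t"
                     f"{p.log2_ratio!r}\n")


def read_probe_table(path: str | Path) -> list[ProbeMeasurement]:
    """Read a probe table; output is sorted by (chromosome, position).

    Unsorted input is sorted with a warning; duplicate positions on a
    chromosome are rejected.
    """
    out: list[ProbeMeasurement] = []
    for lineno, fields in _rows(path, PROBE_HEADER):
        if len(fields) != 4:
            raise ParseError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
        chrom = _norm_chrom(fields[0])
        pos = _parse_int(fields[1], path, lineno, "position")
        log2 = _parse_float(fields[3], path, lineno, "log2_ratio")
        out.append(ProbeMeasurement(chrom, pos, fields[2], log2))
    key = lambda p: (_chrom_sort_key(p.chromosome), p.position)
    if any(key(a) > key(b) for a, b in zip(out, out[1:])):
        warnings.warn(f"{path}: probe table not sorted; sorting", stacklevel=2)
        out.sort(key=key)
    seen: set[tuple[str, int]] = set()
    for p in out:
        if (p.chromosome, p.position) in seen:
            raise ValidationError(
                f"{path}: duplicate probe position {p.chromosome}:{p.position}"
            )
        seen.add((p.chromosome, p.position))
    return out


# --- cytobands (UCSC dialect) ------------------------------------------------

def read_cytobands(path: str | Path) -> list[CytobandRecord]:
    """Read a UCSC cytoBand file (5 columns, 0-based half-open, no header).

    Coordinates become 1-based inclusive in memory.  Bands must tile each
    chromosome without gaps or overlaps, p bands before q bands.
    """
    records: list[CytobandRecord] = []
    for lineno, fields in _rows(path, None):
        if len(fields) != 5:
            raise ParseError(f"{path}:{lineno}: expected 5 columns, got {len(fields)}")
        start0 = _parse_int(fields[1], path, lineno, "start")
        end0 = _parse_int(fields[2], path, lineno, "end")
        if end0 <= start0:
            raise ValidationError(f"{path}:{lineno}: empty or inverted band interval")
        records.append(CytobandRecord(_norm_chrom(fields[0]), start0 + 1, end0,
                                      fields[3], fields[4]))
    by_chrom: dict[str, list[CytobandRecord]] = {}
    for rec in records:
        by_chrom.setdefault(rec.chromosome, []).append(rec)
    for chrom, bands in by_chrom.items():
        bands.sort(key=lambda b: b.start)
        if bands[0].start != 1:
            raise ValidationError(f"{path}: {chrom}: first band does not start at 1")
        for prev, nxt in zip(bands, bands[1:]):
            if nxt.start != prev.end + 1:
                kind = "overlap" if nxt.start <= prev.end else "gap"
                raise ValidationError(
                    f"{path}: {chrom}: {kind} between bands {prev.band} and {nxt.band}"
                )
        arms = [b.arm for b in bands]
        if arms != sorted(arms):
            raise ValidationError(f"{path}: {chrom}: p bands must precede q bands")
    return records


def write_cytobands(bands: list[CytobandRecord], path: str | Path) -> None:
    """Write bands in the UCSC dialect (adds 'chr', 0-based half-open)."""
    ordered = sorted(bands, key=lambda b: (_chrom_sort_key(b.chromosome), b.start))
    with Path(path).open("w") as fh:
        for b in ordered:
            fh.write(f"chr{b.chromosome}\t{b.start - 1}\t{b.end}\t{b.band}\t{b.stain}\n")


def load_hg18_region_cytobands() -> list[CytobandRecord]:
    """Packaged hg18-region cytoband fixture.

    A synthetic reconstruction, not a UCSC download: band boundaries were
    chosen to be mutually consistent with the band/coordinate pairs of
    published hg18 clinical microarray calls and with the real hg18
    chromosome lengths, so nomenclature can be rendered and round-tripped
    for those regions.  Only chromosomes needed by the fixture are present.
    """
    ref = resources.files("cnvdx.data").joinpath("hg18_cytobands_synthetic.txt")
    with resources.as_file(ref) as path:
        return read_cytobands(path)


# --- BED-derived interval tracks ---------------------------------------------

GENE_HEADER = ["chromosome", "start", "end", "symbol", "is_omim"]
BENIGN_HEADER = ["chromosome", "start", "end", "state", "frequency"]
REGION_HEADER = ["chromosome", "start", "end", "syndrome", "class_label", "genes"]


def write_gene_track(genes: list[GeneRecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write(COORD_COMMENT + "\n")
        fh.write("\t".join(GENE_HEADER) + "\n")
        for g in genes:
            fh.write(f"chr{g.chromosome}\t{g.start}\t{g.end}\t{g.symbol}\t"
                     f"{int(g.is_omim)}\n")


def read_gene_track(path: str | Path) -> list[GeneRecord]:
    out = []
    for lineno, fields in _rows(path, GENE_HEADER):
        start = _parse_int(fields[1], path, lineno, "start")
        end = _parse_int(fields[2], path, lineno, "end")
        if end < start:
            raise ValidationError(f"{path}:{lineno}: end < start")
        out.append(GeneRecord(_norm_chrom(fields[0]), start, end, fields[3],
                              bool(int(fields[4]))))
    return out


def write_benign_track(db: list[BenignCnvRecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write(COORD_COMMENT + "\n")
        fh.write("\t".join(BENIGN_HEADER) + "\n")
        for r in db:
            fh.write(f"chr{r.chromosome}\t{r.start}\t{r.end}\t{r.state}\t"
                     f"{r.frequency}\n")


def read_benign_track(path: str | Path) -> list[BenignCnvRecord]:
    out = []
    for lineno, fields in _rows(path, BENIGN_HEADER):
        start = _parse_int(fields[1], path, lineno, "start")
        end = _parse_int(fields[2], path, lineno, "end")
        if end < start:
            raise ValidationError(f"{path}:{lineno}: end < start")
        out.append(BenignCnvRecord(_norm_chrom(fields[0]), start, end, fields[3],
                                   _parse_float(fields[4], path, lineno, "frequency")))
    return out


def write_clinical_regions(regions: list[ClinicalRegion], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write(COORD_COMMENT + "\n")
        fh.write("\t".join(REGION_HEADER) + "\n")
        for r in regions:
            fh.write(f"chr{r.chromosome}\t{r.start}\t{r.end}\t{r.syndrome}\t"
                     f"{r.class_label}\t{','.join(r.genes)}\n")


def read_clinical_regions(path: str | Path) -> list[ClinicalRegion]:
    out = []
    for lineno, fields in _rows(path, REGION_HEADER):
        start = _parse_int(fields[1], path, lineno, "start")
        end = _parse_int(fields[2], path, lineno, "end")
        if end < start:
            raise ValidationError(f"{path}:{lineno}: end < start")
        genes = tuple(g for g in fields[5].split(",") if g)
        out.append(ClinicalRegion(_norm_chrom(fields[0]), start, end, fields[3],
                                  fields[4], genes))
    return out


# --- classified calls --------------------------------------------------------

CALLS_HEADER = ["sample", "chromosome", "start", "end", "size_bp", "n_probes",
                "mean_log2", "copy_state", "copy_number", "iscn", "class",
                "syndrome", "genes", "excluded_reason"]


def write_calls(calls: list[ClassifiedCnv], path: str | Path,
                removed: list[tuple[CnvCall, str]] = ()) -> None:
    """Write kept (and optionally removed) calls as one TSV.

    Kept rows have an empty ``excluded_reason``; removed rows carry their
    exclusion stage and empty clinical columns.  Round-trips losslessly
    through :func:`read_calls`.
    """
    with Path(path).open("w") as fh:
        fh.write(COORD_COMMENT + "\n")
        fh.write("\t".join(CALLS_HEADER) + "\n")
        for cc in calls:
            c = cc.call
            fh.write("\t".join([
                c.sample_id, c.chromosome, str(c.start), str(c.end),
                str(c.size_bp), str(c.n_probes), repr(c.mean_log2),
                c.copy_state, str(c.copy_number), cc.iscn, cc.class_label,
                cc.syndrome, ",".join(cc.genes), "",
            ]) + "\n")
        for c, stage in removed:
            fh.write("\t".join([
                c.sample_id, c.chromosome, str(c.start), str(c.end),
                str(c.size_bp), str(c.n_probes), repr(c.mean_log2),
                c.copy_state, str(c.copy_number), "", "", "", "", stage,
            ]) + "\n")


def read_calls(path: str | Path
               ) -> tuple[list[ClassifiedCnv], list[tuple[CnvCall, str]]]:
    kept: list[ClassifiedCnv] = []
    removed: list[tuple[CnvCall, str]] = []
    for lineno, fields in _rows(path, CALLS_HEADER):
        if len(fields) != len(CALLS_HEADER):
            raise ParseError(f"{path}:{lineno}: expected {len(CALLS_HEADER)} "
                             f"columns, got {len(fields)}")
        call = CnvCall(
            sample_id=fields[0], chromosome=_norm_chrom(fields[1]),
            start=_parse_int(fields[2], path, lineno, "start"),
            end=_parse_int(fields[3], path, lineno, "end"),
            n_probes=_parse_int(fields[5], path, lineno, "n_probes"),
            mean_log2=_parse_float(fields[6], path, lineno, "mean_log2"),
            copy_state=fields[7],
            copy_number=_parse_int(fields[8], path, lineno, "copy_number"),
            size_bp=_parse_int(fields[4], path, lineno, "size_bp"),
        )
        if fields[13]:
            removed.append((call, fields[13]))
        else:
            kept.append(ClassifiedCnv(
                call=call, class_label=fields[10], syndrome=fields[11],
                genes=tuple(g for g in fields[12].split(",") if g),
                iscn=fields[9]))
    return kept, removed


# --- qPCR plates -------------------------------------------------------------

PLATE_HEADER = ["sample", "gene", "role", "arm", "replicate", "ct"]


def write_qpcr_plate(wells: list[QpcrWell], path: str | Path,
                     sample: str = "case") -> None:
    with Path(path).open("w") as fh:
        fh.write("\t".join(PLATE_HEADER) + "\n")
        for w in wells:
            fh.write(f"{sample}\t{w.gene}\t{w.role}\t{w.sample_arm}\t"
                     f"{w.replicate}\t{w.ct!r}\n")


def read_qpcr_plate(path: str | Path) -> list[QpcrWell]:
    out = []
    for lineno, fields in _rows(path, PLATE_HEADER):
        out.append(QpcrWell(
            sample_arm=fields[3], gene=fields[1], role=fields[2],
            replicate=_parse_int(fields[4], path, lineno, "replicate"),
            ct=_parse_float(fields[5], path, lineno, "ct")))
    return out


# --- karyotype tables --------------------------------------------------------

KARYO_HEADER = ["sample", "gband_string", "abnormal"]


def write_karyotype_table(records: list[KaryotypeRecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("\t".join(KARYO_HEADER) + "\n")
        for r in records:
            fh.write(f"{r.sample_id}\t{r.gband_string}\t{int(r.abnormal)}\n")


def read_karyotype_table(path: str | Path) -> list[KaryotypeRecord]:
    out = []
    for lineno, fields in _rows(path, KARYO_HEADER):
        out.append(KaryotypeRecord(fields[0], fields[1], bool(int(fields[2]))))
    return out
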