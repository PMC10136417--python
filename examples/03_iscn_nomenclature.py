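"""Render and parse ISCN microarray nomenclature; compute reported sizes.

Uses the packaged hg18-region cytoband table (a synthetic reconstruction of
band/coordinate pairs consistent with published clinical calls) to write an
``arr[hg18] ...`` string for a Jacobsen-syndrome-scale deletion, parse it
back, and print its size under the truncate-to-one-decimal Mb convention.
"""

from cnvdx import CnvCall, parse_iscn, span_mb, to_iscn
from cnvdx.io import load_hg18_region_cytobands

bands = load_hg18_region_cytobands()

call = CnvCall(sample_id="DEMO-02", chromosome="11",
               start=123_615_752, end=134_432_324,
               n_probes=1500, mean_log2=-1.0, copy_state="loss", copy_number=1)

s = to_iscn(call, bands, build="hg18")
print("rendered:", s)

parsed = parse_iscn(s)
print(f"parsed back: chr{parsed.chromosome} "
      f"{parsed.band_start}..{parsed.band_end} "
      f"{parsed.start}-{parsed.end} x{parsed.copy_number}")

print(f"span: {span_mb(call.start, call.end)} Mb "
      "(truncated, not rounded, to one decimal)")
# A subtelomeric 11q24.2q25 deletion of 10,816,573 bp prints as 10.8 Mb;
# rounding would have said 10.8 too, but e.g. 3,764,485 bp prints 3.7 (not 3.8).
print(f"18q23 example: {span_mb(72_346_539, 76_111_023)} Mb")
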