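"""Simulate an array-CGH sample with a planted deletion and call it back.

Builds a miniature genome, lays a 400K-style probe design over it (target
median spacing 5.3 kb), plants a heterozygous 2 Mb deletion (CN 1, expected
log2 = -1) under 0.15-sd probe noise, and runs segment calling.  The printed
call should land its breakpoints within about one probe spacing of the
planted event.
"""

from cnvdx import (
    NoiseModel,
    PlantedEvent,
    call_segments,
    make_design,
    make_genome_model,
    simulate_sample,
)

model = make_genome_model(5, seed=7)
design = make_design(model, "400K", seed=1)
print(f"design: {len(design.probes)} probes, "
      f"median spacing {design.median_spacing_bp} bp")

chrom = model.chromosomes[0][0]
event = PlantedEvent(chrom, 5_000_000, 7_000_000, true_copy_number=1)
probes = simulate_sample(design, [event], NoiseModel(sd=0.15, seed=3))

calls = call_segments(probes, sample_id="DEMO-01")
large = [c for c in calls if c.size_bp >= 300_000]
small = [c for c in calls if c.size_bp < 300_000]
print(f"{len(calls)} raw calls; {len(small)} are sub-300 kb probe-noise runs "
      "(the size filter's job downstream)")
for c in large:
    print(f"call: chr{c.chromosome}:{c.start}-{c.end}  "
          f"{c.copy_state} x{c.copy_number}  mean log2 {c.mean_log2:+.3f}  "
          f"{c.n_probes} probes  ({c.dosage_flag} dosage)")
print(f"planted: chr{chrom}:{event.start}-{event.end} CN 1 "
      f"(expected log2 {event.expected_log2:+.3f})")
# The surviving call's copy state (loss) and integer copy number (1) recover
# the planted truth; breakpoint error is bounded by the local probe spacing.
# At realistic probe noise, short spurious runs are expected — on a real
# clinical array they are the bulk of raw calls and are removed by the
# < 300 kb exclusion, never by tuning the segmentation itself.
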