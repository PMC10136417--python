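"""Generator correctness: determinism, planted truths, design geometry."""

import math

import numpy as np
import pytest

from cnvdx import (
    CohortFixtureSpec,
    NoiseModel,
    PlantedEvent,
    ValidationError,
    make_benign_db,
    make_cascade_fixture,
    make_design,
    make_genome_model,
    make_qpcr_plate,
    quantify,
    simulate_sample,
)


class TestGenomeModel:
    def test_single_chromosome_bands_tile_exactly(self):
        model = make_genome_model(1, seed=7)
        (chrom, length), = model.chromosomes
        bands = sorted((b for b in model.cytobands), key=lambda b: b.start)
        assert bands[0].start == 1 and bands[-1].end == length
        assert all(n.start == p.end + 1 for p, n in zip(bands, bands[1:]))

    def test_deterministic_for_fixed_seed(self):
        a, b = make_genome_model(4, seed=7), make_genome_model(4, seed=7)
        assert a.chromosomes == b.chromosomes
        assert a.cytobands == b.cytobands
        assert a.genes == b.genes
        assert a.clinical_regions == b.clinical_regions

    def test_every_feature_within_chromosome_bounds(self):
        model = make_genome_model(4, seed=7)
        lengths = dict(model.chromosomes)
        for gene in model.genes:  # exhaustive containment scan
            assert 1 <= gene.start <= gene.end <= lengths[gene.chromosome]
        for region in model.clinical_regions:
            assert 1 <= region.start <= region.end <= lengths[region.chromosome]

    def test_includes_sex_chromosome_analogue(self):
        assert "X" in make_genome_model(3, seed=0).chromosome_names

    def test_rejects_zero_chromosomes(self):
        with pytest.raises(ValueError):
            make_genome_model(0, seed=1)


class TestArrayDesign:
    @pytest.mark.parametrize("label,lo,hi", [
        ("400K", 4_240, 6_360),  # 5.3 kb +/- 20%
        ("244K", 7_120, 10_680),  # 8.9 kb +/- 20%
    ])
    def test_median_spacing_on_target(self, model, label, lo, hi):
        design = make_design(model, label, seed=1)
        assert lo <= design.median_spacing_bp <= hi
        # recompute realized median from the probe list itself
        gaps = []
        for (c1, p1, _), (c2, p2, _) in zip(design.probes, design.probes[1:]):
            if c1 == c2:
                gaps.append(p2 - p1)
        assert lo <= np.median(gaps) <= hi

    def test_probes_sorted_and_unique(self, design_400k):
        seen = set()
        for (c1, p1, _), (c2, p2, _) in zip(design_400k.probes,
                                            design_400k.probes[1:]):
            if c1 == c2:
                assert p1 < p2
        for chrom, pos, _ in design_400k.probes:
            assert (chrom, pos) not in seen
            seen.add((chrom, pos))

    def test_deterministic(self, model):
        assert make_design(model, "400K", 3).probes == make_design(model, "400K", 3).probes

    def test_unknown_label_rejected(self, model):
        with pytest.raises(ValueError):
            make_design(model, "1M", seed=0)


class TestSimulateSample:
    def test_null_sample_is_all_zero(self, small_design):
        probes = simulate_sample(small_design, [], NoiseModel(sd=0.0, seed=0))
        assert all(p.log2_ratio == 0.0 for p in probes)
        assert [p.probe_id for p in probes] == [pid for _, _, pid in small_design.probes]

    def test_noise_free_gain_hits_closed_form(self, small_design, small_model):
        chrom, length = small_model.chromosomes[0]
        ev = PlantedEvent(chrom, 1_000_000, 2_000_000, 3)
        probes = simulate_sample(small_design, [ev], NoiseModel(sd=0.0, seed=0))
        covered = [p.log2_ratio for p in probes if 1_000_000 <= p.position <= 2_000_000]
        assert covered and all(v == pytest.approx(math.log2(1.5)) for v in covered)
        outside = [p.log2_ratio for p in probes if not 1_000_000 <= p.position <= 2_000_000]
        assert all(v == 0.0 for v in outside)

    def test_copy_zero_floored_at_minus_four(self, small_design, small_model):
        chrom, _ = small_model.chromosomes[0]
        ev = PlantedEvent(chrom, 1_000_000, 1_500_000, 0)
        probes = simulate_sample(small_design, [ev], NoiseModel(sd=0.0, seed=0))
        covered = [p.log2_ratio for p in probes if 1_000_000 <= p.position <= 1_500_000]
        assert covered and all(v == -4.0 for v in covered)

    def test_noisy_loss_mean_recovers_expectation(self, small_design, small_model):
        chrom, _ = small_model.chromosomes[0]
        sd = 0.05
        ev = PlantedEvent(chrom, 1_000_000, 3_000_000, 1)
        probes = simulate_sample(small_design, [ev], NoiseModel(sd=sd, seed=42))
        covered = np.array([p.log2_ratio for p in probes
                            if 1_000_000 <= p.position <= 3_000_000])
        assert abs(covered.mean() + 1.0) < 3 * sd / math.sqrt(len(covered))

    def test_overlapping_events_rejected(self, small_design, small_model):
        chrom, _ = small_model.chromosomes[0]
        with pytest.raises(ValidationError):
            simulate_sample(small_design,
                            [PlantedEvent(chrom, 1, 100_000, 1),
                             PlantedEvent(chrom, 50_000, 200_000, 3)],
                            NoiseModel(sd=0.0, seed=0))


class TestBenignDb:
    def test_empty_and_count(self, model):
        assert make_benign_db(model, 0, 1) == []
        db = make_benign_db(model, 100, 1)
        assert len(db) == 100
        lengths = dict(model.chromosomes)
        assert all(1 <= r.start <= r.end <= lengths[r.chromosome] for r in db)

    def test_seed_sensitivity(self, model):
        assert make_benign_db(model, 20, 1) != make_benign_db(model, 20, 2)


def _audit_first_failure(call, fixture, params_min_size=300_000, t=0.5):
    """Independently evaluate every filter with plain loops (no trees)."""
    if call.from_aneuploidy:
        return "aneuploidy"
    if call.size_bp < params_min_size:
        return "size"
    for rec in fixture.benign_db:
        if rec.chromosome != call.chromosome or rec.state not in ("either", call.copy_state):
            continue
        olen = max(0, min(call.end, rec.end) - max(call.start, rec.start) + 1)
        if olen / call.size_bp >= t and olen / (rec.end - rec.start + 1) >= t:
            return "benign_pop"
    if not any(g.chromosome == call.chromosome and g.start <= call.end
               and g.end >= call.start for g in fixture.genes):
        return "no_gene"
    for r in fixture.clinical_regions:
        if r.chromosome != call.chromosome:
            continue
        olen = max(0, min(call.end, r.end) - max(call.start, r.start) + 1)
        if olen / call.size_bp >= t:
            return "kept"
    return "not_significant"


class TestCascadeFixture:
    def test_figure_scale_fixture_emits_exact_total(self, model):
        spec = CohortFixtureSpec(5, 1211, 951, 249, 97, 24)
        fx = make_cascade_fixture(spec, model, seed=3)
        assert len(fx.calls) == 2537 == spec.total
        assert len(fx.truth) == 2537

    def test_all_kept_spec_produces_only_survivors(self, model):
        fx = make_cascade_fixture(CohortFixtureSpec(0, 0, 0, 0, 0, 9), model, 3)
        assert all(t == "kept" for t in fx.truth)
        assert all(_audit_first_failure(c, fx) == "kept" for c in fx.calls)

    def test_per_record_first_failure_matches_designated_category(self, model):
        spec = CohortFixtureSpec(3, 40, 30, 25, 20, 12)
        fx = make_cascade_fixture(spec, model, seed=9)
        for call, designated in zip(fx.calls, fx.truth):
            assert _audit_first_failure(call, fx) == designated

    def test_deterministic(self, model):
        spec = CohortFixtureSpec(2, 10, 10, 10, 10, 6)
        a = make_cascade_fixture(spec, model, seed=5)
        b = make_cascade_fixture(spec, model, seed=5)
        assert a.calls == b.calls and a.truth == b.truth
        assert a.benign_db == b.benign_db and a.genes == b.genes


class TestQpcrPlate:
    def test_calibrator_equal_case_gives_zero_ddct(self):
        plate = make_qpcr_plate([("G1", 2)], seed=1, ct_sd=0.0)
        q = quantify(plate, "G1")
        assert q.delta_delta_ct == pytest.approx(0.0)
        assert q.rq == pytest.approx(1.0) and q.copy_number_estimate == 2

    def test_halved_template_gives_plus_one_ddct(self):
        plate = make_qpcr_plate([("G1", 1)], seed=1, ct_sd=0.0)
        q = quantify(plate, "G1")
        assert q.delta_delta_ct == pytest.approx(1.0)
        assert q.rq == pytest.approx(0.5) and q.copy_number_estimate == 1

    def test_noisy_triplicate_recovers_single_copy_gain(self):
        plate = make_qpcr_plate([("G1", 3)], seed=11, ct_sd=0.05)
        q = quantify(plate, "G1")  # rerun Livak on the emitted plate
        assert 1.3 <= q.rq <= 1.7

    def test_copy_zero_rejected(self):
        with pytest.raises(ValueError):
            make_qpcr_plate([("G1", 0)], seed=1)
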