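"""Segmentation, dosage typing and aneuploidy detection.

The segmentation contract: within each maximal sign-consistent probe run,
the called segment spans from the first to the last probe individually at or
above the candidate threshold, and is reported when it has >= min_probes
probes and |mean log2| >= the candidate threshold.  An independent
brute-force enumerator over all O(n^2) intervals re-derives that selection
and must agree exactly.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnvdx import (
    CallingParams,
    CnvCall,
    NoiseModel,
    PlantedEvent,
    ValidationError,
    assign_copy_state,
    call_segments,
    copy_number_from_log2,
    detect_aneuploidy,
    simulate_sample,
)
from cnvdx.records import ProbeMeasurement


def _probes(values, chrom="1"):
    return [ProbeMeasurement(chrom, 1000 * (i + 1), f"P{i}", v)
            for i, v in enumerate(values)]


def oracle_segments(values, min_probes=3, cand=0.25):
    """Brute-force run finder: enumerate all intervals, select per the rule."""
    n = len(values)
    sign = lambda v: (v > 0) - (v < 0)
    out = []
    for i in range(n):
        for j in range(i, n):
            signs = {sign(v) for v in values[i:j + 1]}
            if len(signs) != 1 or 0 in signs:
                continue
            sg = next(iter(signs))
            if i > 0 and sign(values[i - 1]) == sg:
                continue  # extendable left: not a maximal run
            if j < n - 1 and sign(values[j + 1]) == sg:
                continue
            above = [k for k in range(i, j + 1) if abs(values[k]) >= cand]
            if not above:
                continue
            lo, hi = min(above), max(above)
            if hi - lo + 1 < min_probes:
                continue
            mean = float(np.mean(values[lo:hi + 1]))
            if abs(mean) < cand:
                continue
            out.append((lo, hi, hi - lo + 1, mean))
    return out


def _as_tuples(calls, positions):
    idx = {pos: i for i, pos in enumerate(positions)}
    return [(idx[c.start], idx[c.end], c.n_probes, c.mean_log2) for c in calls]


class TestCallSegments:
    def test_flat_sample_yields_no_calls(self):
        assert call_segments(_probes([0.0] * 20)) == []

    def test_five_probe_gain_flanked_by_zeros(self):
        values = [0.0] * 3 + [0.6] * 5 + [0.0] * 3
        (call,) = call_segments(_probes(values))
        assert (call.n_probes, call.copy_state) == (5, "gain")
        assert call.mean_log2 == pytest.approx(0.6)
        assert call.start == 4000 and call.end == 8000

    def test_two_probe_run_too_short(self):
        assert call_segments(_probes([0.0, -1.5, -1.5, 0.0])) == []

    def test_three_probes_below_candidate_threshold(self):
        assert call_segments(_probes([-0.20, -0.20, -0.20])) == []

    def test_three_probes_at_exact_threshold_accepted(self):
        (call,) = call_segments(_probes([0.25, 0.25, 0.25]))
        assert call.n_probes == 3

    def test_opposite_sign_probe_terminates_run(self):
        values = [0.6, 0.6, 0.6, -0.1, 0.6, 0.6, 0.6]
        calls = call_segments(_probes(values))
        assert [(c.start, c.end) for c in calls] == [(1000, 3000), (5000, 7000)]

    def test_unsorted_input_rejected(self):
        probes = _probes([0.6] * 5)
        with pytest.raises(ValidationError):
            call_segments(list(reversed(probes)))

    def test_calls_split_per_chromosome(self):
        probes = _probes([0.6] * 3, chrom="1") + _probes([0.6] * 3, chrom="2")
        calls = call_segments(probes)
        assert [c.chromosome for c in calls] == ["1", "2"]

    @given(st.lists(
        st.one_of(
            st.sampled_from([0.0, 0.1, -0.1, 0.25, -0.25, 0.3, -0.3,
                             0.6, -0.6, -1.0, 1.0]),
            st.floats(-2, 2, allow_nan=False, allow_infinity=False)),
        max_size=50))
    @settings(max_examples=200, derandomize=True)
    def test_matches_brute_force_enumeration(self, values):
        probes = _probes(values)
        positions = [p.position for p in probes]
        got = _as_tuples(call_segments(probes), positions)
        expected = oracle_segments(values)
        assert [(a, b, n) for a, b, n, _ in got] == [(a, b, n) for a, b, n, _ in expected]
        for (_, _, _, m1), (_, _, _, m2) in zip(got, expected):
            assert m1 == pytest.approx(m2)


class TestDosage:
    @pytest.mark.parametrize("mean,state,cn,flag", [
        (0.585, "gain", 3, "full"),     # log2(3/2): single-copy gain
        (-1.0, "loss", 1, "sub-integer"),  # log2(1/2): boundary is strict
        (-1.01, "loss", 1, "full"),
        (1.0, "gain", 4, "full"),       # doubled dosage annotates as x4
        (-4.0, "loss", 0, "full"),      # saturated floor: round(2*2^-4) = 0
        (0.3, "gain", 2, "sub-integer"),
    ])
    def test_copy_state_examples(self, mean, state, cn, flag):
        call = CnvCall("s", "1", 100, 200, 5, mean, "gain", 0)
        call = assign_copy_state(call, CallingParams())
        assert (call.copy_state, call.copy_number, call.dosage_flag) == (state, cn, flag)

    def test_zero_mean_rejected(self):
        call = CnvCall("s", "1", 100, 200, 5, 0.0, "gain", 0)
        with pytest.raises(ValidationError):
            assign_copy_state(call)

    def test_copy_number_non_decreasing_in_mean(self):
        means = np.linspace(-4, 2, 400)
        cns = [copy_number_from_log2(m) for m in means]
        assert cns == sorted(cns)

    def test_thresholds_are_dosage_ratios(self):
        params = CallingParams()
        assert round(math.log2(3 / 2), 2) == params.gain_threshold
        assert math.log2(1 / 2) == params.loss_threshold


class TestRecovery:
    def test_planted_events_recovered_within_one_probe(self, small_design):
        """>= 99/100 replicates: breakpoints within one probe spacing."""
        chrom = small_design.probes[0][0]
        positions = [p for c, p, _ in small_design.probes if c == chrom]
        n = len(positions)
        successes = 0
        for rep in range(100):
            rng = np.random.default_rng(rep)
            width = int(rng.integers(3, 40))
            i0 = int(rng.integers(5, n - width - 5))
            i1 = i0 + width - 1
            cn = 1 if rep % 2 else 3  # |log2| of 1.0 / 0.585, both >= 0.35
            event = PlantedEvent(chrom, positions[i0], positions[i1], cn)
            probes = simulate_sample(small_design, [event],
                                     NoiseModel(sd=0.05, seed=1000 + rep))
            calls = call_segments(probes)
            hits = [c for c in calls
                    if c.start <= event.end and c.end >= event.start]
            if len(hits) != 1:
                continue
            idx = {pos: i for i, pos in enumerate(positions)}
            if abs(idx[hits[0].start] - i0) <= 1 and abs(idx[hits[0].end] - i1) <= 1:
                successes += 1
        assert successes >= 99

    def test_false_positive_rate_below_one_percent(self, small_design):
        with_calls = sum(
            bool(call_segments(simulate_sample(small_design, [],
                                               NoiseModel(sd=0.05, seed=5000 + rep))))
            for rep in range(100))
        assert with_calls < 1  # < 1% of replicates


class TestAneuploidy:
    def test_whole_chromosome_trisomy_detected(self, small_design, small_model):
        chrom, length = small_model.chromosomes[0]
        probes = simulate_sample(small_design,
                                 [PlantedEvent(chrom, 1, length, 3,
                                               whole_chromosome=True)],
                                 NoiseModel(sd=0.0, seed=0))
        calls = call_segments(probes)
        (aneu,) = detect_aneuploidy(calls, small_design)
        assert (aneu.chromosome, aneu.copy_state) == (chrom, "gain")
        assert aneu.fraction_aberrant == pytest.approx(1.0)
        assert all(c.from_aneuploidy for c in calls if c.chromosome == chrom)

    def test_half_chromosome_gain_is_not_aneuploidy(self, small_design, small_model):
        chrom, length = small_model.chromosomes[0]
        probes = simulate_sample(small_design,
                                 [PlantedEvent(chrom, 1, length // 2, 3)],
                                 NoiseModel(sd=0.0, seed=0))
        calls = call_segments(probes)
        assert detect_aneuploidy(calls, small_design) == []
        assert not any(c.from_aneuploidy for c in calls)

    def test_monosomy_x_analogue(self, model, design_400k):
        length = model.chromosome_length("X")
        probes = simulate_sample(design_400k,
                                 [PlantedEvent("X", 1, length, 1,
                                               whole_chromosome=True)],
                                 NoiseModel(sd=0.0, seed=0))
        calls = call_segments(probes, sample_id="45X")
        aneu = detect_aneuploidy(calls, design_400k)
        assert [(a.chromosome, a.copy_state) for a in aneu] == [("X", "loss")]
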