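import numpy as np
import pytest

from snsvta import axon
from snsvta.axon import (NODE, MYSA, FLUT, STIN, NoActivationError, PulseTrain,
                         build_axon, find_threshold, fires_one_to_one,
                         simulate_axon, simulate_axon_recorded)

from conftest import point_source_unit_potentials

THREE_PULSES = PulseTrain(14.0, 1.0, 0.21, 214.0)


class TestMorphology:
    def test_full_length_fibre_has_201_nodes(self, morph_full):
        assert morph_full.n_nodes == 201
        assert morph_full.n_compartments == 201 + 200 * 10

    def test_internode_sequence(self, morph_short):
        types = morph_short.comp_type
        nodes = morph_short.node_indices
        between = types[nodes[0] + 1:nodes[1]]
        assert list(between) == [MYSA, FLUT] + [STIN] * 6 + [FLUT, MYSA]

    def test_starts_and_ends_on_node(self, morph_short):
        assert morph_short.comp_type[0] == NODE
        assert morph_short.comp_type[-1] == NODE

    def test_compartment_lengths_sum_to_total_within_one_internode(self, morph_full):
        total = morph_full.length_um.sum() / 1000.0
        assert abs(total - 100.0) <= 0.5

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            build_axon(5.7, 0.0)

    def test_unsupported_diameter_rejected_naming_supported(self):
        with pytest.raises(ValueError, match="5.7"):
            build_axon(10.0, 100.0)


class TestRestingState:
    def test_no_drive_no_spikes_and_small_drift(self, morph_short):
        train = PulseTrain(14.0, 0.0, 0.21, 200.0)
        spikes, t, vm = simulate_axon_recorded(
            morph_short, np.zeros(morph_short.n_compartments), train, [40])
        assert len(spikes) == 0
        sel = t <= 50.0
        drift = np.abs(vm[sel, 0] - vm[0, 0]).max()
        assert drift < 0.1

    def test_rest_net_membrane_current_negligible(self, morph_short):
        # residual capacitive current at rest vs the peak during an AP
        cab = axon._cable(morph_short)
        rest = axon._rest_state(morph_short)
        train = PulseTrain(14.0, 0.3, 0.21, 71.0)
        ve = point_source_unit_potentials(morph_short, 2.0)
        _, t, vm = simulate_axon_recorded(morph_short, ve, train, [40], dt=0.005)
        rec = morph_short.node_indices[40]
        c_rec = cab["cm"][rec]
        i_peak = c_rec * np.abs(np.diff(vm[:, 0]) / np.diff(t)).max()
        # rest: advance 1 ms with no drive and measure the same quantity
        tr0 = PulseTrain(14.0, 0.0, 0.21, 1.0)
        _, t0, vm0 = simulate_axon_recorded(
            morph_short, np.zeros(morph_short.n_compartments), tr0, [40], dt=0.005)
        i_rest = c_rec * np.abs(np.diff(vm0[:, 0]) / np.diff(t0)).max()
        assert i_rest < 1e-3 * i_peak


class TestFiring:
    def test_one_to_one_at_twice_threshold(self, morph_short):
        ve = point_source_unit_potentials(morph_short, 2.0)
        thr = find_threshold(morph_short, ve, THREE_PULSES, tol=0.02)
        train = PulseTrain(14.0, 2.0 * thr, 0.21, 214.0)
        spikes = simulate_axon(morph_short, ve, train)
        assert fires_one_to_one(spikes, train)
        assert len(spikes) == 3
        for onset, s in zip(train.onset_times_ms, spikes):
            assert onset < s <= onset + 2.0

    def test_action_potential_overshoot_band(self, morph_short):
        ve = point_source_unit_potentials(morph_short, 2.0)
        thr = find_threshold(morph_short, ve, THREE_PULSES, tol=0.02)
        train = PulseTrain(14.0, 1.2 * thr, 0.21, 71.0)
        # probe a node well away from the drive and the sealed ends
        _, t, vm = simulate_axon_recorded(morph_short, ve, train, [60])
        peak = vm[:, 0].max()
        assert -10.0 < peak < 50.0

    def test_conduction_velocity_finite_and_uniform(self, morph_short):
        ve = point_source_unit_potentials(morph_short, 1.5, x0_mm=5.0)
        thr = find_threshold(morph_short, ve, THREE_PULSES, tol=0.02)
        train = PulseTrain(14.0, 1.3 * thr, 0.21, 71.0)
        probes = [30, 40, 50, 60, 70]
        _, t, vm = simulate_axon_recorded(morph_short, ve, train, probes)
        times = []
        for q in range(len(probes)):
            cross = np.nonzero((vm[:-1, q] < -20.0) & (vm[1:, q] >= -20.0))[0]
            assert len(cross) > 0
            times.append(t[cross[0] + 1])
        times = np.array(times)
        dx = 0.5 * 10.0   # 10 internodes at 0.5 mm, in mm
        vels = dx / np.diff(times) / 1000.0 * 1000.0   # mm/ms = m/s
        assert (vels > 0).all()
        assert vels.max() - vels.min() < 0.1 * vels.mean()

    def test_refractoriness_blocks_closely_spaced_second_pulse(self, morph_short):
        # the transcribed kinetics give an absolute refractory period just
        # under 1 ms at 36 C; a pulse pair 0.8 ms apart at 1.1x threshold
        # elicits a single spike
        ve = point_source_unit_potentials(morph_short, 2.0)
        thr = find_threshold(morph_short, ve, THREE_PULSES, tol=0.02)
        pair = PulseTrain(1250.0, 1.1 * thr, 0.21, 1.6)
        assert pair.n_pulses() == 2
        spikes = simulate_axon(morph_short, ve, pair)
        assert len(spikes) < 2

    def test_invalid_dt_rejected(self, morph_short):
        ve = point_source_unit_potentials(morph_short, 2.0)
        with pytest.raises(ValueError):
            simulate_axon(morph_short, ve, THREE_PULSES, dt=0.05)
        with pytest.raises(ValueError):
            simulate_axon(morph_short, ve, THREE_PULSES, dt=0.0)

    def test_compartment_count_mismatch_rejected(self, morph_short):
        with pytest.raises(ValueError, match="per compartment"):
            simulate_axon(morph_short, np.zeros(10), THREE_PULSES)


class TestThreshold:
    def test_monotone_with_distance(self, morph_short):
        thrs = [find_threshold(morph_short,
                               point_source_unit_potentials(morph_short, d),
                               THREE_PULSES, tol=0.02)
                for d in (2.0, 3.0, 4.0)]
        assert thrs[0] <= thrs[1] <= thrs[2]
        assert thrs[0] < thrs[2]

    def test_strength_duration_monotone_in_pulse_width(self, morph_short):
        ve = point_source_unit_potentials(morph_short, 2.0)
        thrs = []
        for pw in (0.1, 0.25, 0.5):
            tr = PulseTrain(14.0, 1.0, pw, 214.0)
            thrs.append(find_threshold(morph_short, ve, tr, tol=0.02))
        assert thrs[0] > thrs[1] > thrs[2]

    def test_returned_value_activates_and_tol_below_does_not(self, morph_short):
        ve = point_source_unit_potentials(morph_short, 2.0)
        tol = 0.05
        thr = find_threshold(morph_short, ve, THREE_PULSES, tol=tol)
        tr_hi = PulseTrain(14.0, thr, 0.21, 214.0)
        tr_lo = PulseTrain(14.0, thr - tol, 0.21, 214.0)
        assert fires_one_to_one(simulate_axon(morph_short, ve, tr_hi), tr_hi)
        assert not fires_one_to_one(simulate_axon(morph_short, ve, tr_lo), tr_lo)

    def test_zero_potentials_signal_no_activation(self, morph_short):
        with pytest.raises(NoActivationError):
            find_threshold(morph_short, np.zeros(morph_short.n_compartments),
                           THREE_PULSES)


class TestOneToOneCriterion:
    def test_duration_invariance_of_periodic_response(self, morph_short):
        # the 1:1 outcome for 3 pulses predicts the 14-pulse outcome
        ve = point_source_unit_potentials(morph_short, 2.0)
        thr = find_threshold(morph_short, ve, THREE_PULSES, tol=0.02)
        short = PulseTrain(14.0, 1.5 * thr, 0.21, 214.0)
        full = PulseTrain(14.0, 1.5 * thr, 0.21, 1000.0)
        assert full.n_pulses() == 14
        ok3 = fires_one_to_one(simulate_axon(morph_short, ve, short), short)
        ok14 = fires_one_to_one(simulate_axon(morph_short, ve, full), full)
        assert ok3 == ok14 is True

    @pytest.mark.parametrize("spikes,n_onsets,expected", [
        ([2.0, 73.0, 145.0], 3, True),            # one spike per window
        ([2.0, 73.0], 3, False),                  # missed pulse
        ([2.0, 3.5, 73.0, 145.0], 3, False),      # doublet after first pulse
        ([], 3, False),
    ])
    def test_window_counting(self, spikes, n_onsets, expected):
        train = PulseTrain(14.0, 1.0, 0.21, 214.0)
        assert train.n_pulses() == n_onsets
        assert fires_one_to_one(np.array(spikes), train) is expected

    def test_fourteen_spikes_for_fourteen_pulses(self):
        train = PulseTrain(14.0, 1.0, 0.21, 1000.0)
        spikes = train.onset_times_ms + 1.7
        assert fires_one_to_one(spikes, train)
        assert not fires_one_to_one(spikes[::2], train)
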