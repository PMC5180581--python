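"""GRN controller: sensor encoding, expression cascade, dosage dynamics."""
from __future__ import annotations

import types

import numpy as np
import pytest

from grnswarm.config import GrnConfig, SensorConfig, default_config
from grnswarm.genome import ArtificialGenome, init_genome
from grnswarm.grn import (
    ACTUATORS, CHANNELS, N_ACTUATORS, ActuatorVector, GRNState, SensorReadings,
    SensorVector, activate_signalling, actuator_outputs, build_network,
    channel_signature, channel_signatures, controller_step, encode_sensors,
    transduce, update_concentrations,
)

CFG = default_config()
ALPHA = "0123"


def comp(seq: str) -> str:
    return "".join(ALPHA[3 - ALPHA.index(c)] for c in seq)


def gene(kind: str, site: str, signature: str, wiring: str = "01", value: str = "33") -> str:
    """Hand-built gene: promoter | type | site(5) | payload(9)."""
    tfield = {"signalling": "00", "regulatory": "01", "structural": "02"}[kind]
    payload = signature + wiring + value
    assert len(site) == 5 and len(payload) == 9
    return "0101" + tfield + site + payload


def hand_genome(*genes: str, pad: int = 6) -> ArtificialGenome:
    body = ("2" * pad).join(genes) + "22"
    return ArtificialGenome.from_strings([body], ALPHA)


FOOD_HERE = CHANNELS.index("food_here")
FOOD_SIG = channel_signature(FOOD_HERE, ALPHA, 5)


def sensors(**kw) -> SensorVector:
    return encode_sensors(SensorReadings(**kw), CFG.sensors)


class TestEncodeSensors:
    def test_all_zero_readings_give_all_zero_channels(self):
        sv = sensors()
        assert np.all(sv.values == 0.0)

    def test_deterministic(self):
        a = sensors(n_robots=3, n_food_here=1, energy=120.0, age=17)
        b = sensors(n_robots=3, n_food_here=1, energy=120.0, age=17)
        assert np.array_equal(a.values, b.values)

    def test_channels_bounded(self):
        sv = sensors(n_robots=999, n_food_here=50, n_food=999, energy=1e9,
                     attacks=99, defences=99, replications=99, feedings=99, age=12)
        assert np.all(sv.values >= 0.0) and np.all(sv.values <= 1.0)

    def test_channel_signatures_injective(self):
        sigs = channel_signatures(ALPHA, CFG.genome.binding_len)
        assert len(set(sigs)) == len(CHANNELS)

    def test_rhythm_starts_at_zero_and_peaks_mid_cycle(self):
        period = CFG.sensors.rhythm_period
        assert sensors(age=0).values[-1] == 0.0
        assert sensors(age=period // 2).values[-1] == pytest.approx(1.0)


class TestActivateSignalling:
    def test_genome_without_signalling_genes_yields_nothing(self):
        g = hand_genome(gene("structural", "33333", "33333", "02", "33"))
        net = build_network(g, CFG.genome, CFG.grn)
        st = GRNState(net)
        agents = activate_signalling(sensors(n_food_here=2), st, CFG.grn)
        assert agents == []

    def test_single_matching_gene_gives_one_agent(self):
        g = hand_genome(gene("signalling", comp(FOOD_SIG), "31313"))
        net = build_network(g, CFG.genome, CFG.grn)
        st = GRNState(net)
        agents = activate_signalling(sensors(n_food_here=2), st, CFG.grn)
        assert len(agents) == 1
        assert agents[0].kind == "signalling"
        assert agents[0].concentration > 0

    def test_inactive_channel_produces_no_agent(self):
        g = hand_genome(gene("signalling", comp(FOOD_SIG), "31313"))
        net = build_network(g, CFG.genome, CFG.grn)
        st = GRNState(net)
        assert activate_signalling(sensors(), st, CFG.grn) == []


def cascade_genome(with_repressor: bool = False) -> ArtificialGenome:
    """signalling -> regulatory -> structural(eat, +1), optionally repressed."""
    sig_signature = "31313"
    reg_signature = "12321"
    genes = [
        gene("signalling", comp(FOOD_SIG), sig_signature),
        gene("regulatory", comp(sig_signature), reg_signature, wiring="01"),
        # actuator index: wiring "02" -> 2 == eat; value "33" -> +1
        gene("structural", comp(reg_signature), "23232", wiring="02", value="33"),
    ]
    if with_repressor:
        # same signature as the activator, but repressor wiring ("00" -> code 0)
        genes.append(gene("regulatory", comp(sig_signature), reg_signature, wiring="00"))
    return hand_genome(*genes)


class TestTransduce:
    def test_empty_state_is_unchanged(self):
        g = cascade_genome()
        st = GRNState(build_network(g, CFG.genome, CFG.grn))
        before = st.c.copy()
        transduce(st, CFG.grn)
        assert np.array_equal(st.c, before)

    def test_single_path_hand_trace(self):
        """Follow the documented expression formula through one cascade."""
        g = cascade_genome()
        net = build_network(g, CFG.genome, CFG.grn)
        st = GRNState(net)
        grn = CFG.grn
        sv = sensors(n_food_here=1)  # channel value 0.5, floored to c_init
        activate_signalling(sv, st, grn)
        c_sig = max(0.5 * 1.0, grn.c_init)
        transduce(st, grn)  # expresses the regulatory gene
        transduce(st, grn)  # expresses the structural gene
        c_reg = c_sig / (1 + c_sig)
        c_struct = c_reg / (1 + c_reg)
        struct = [a for a in st.agents if a.kind == "structural"]
        assert len(struct) == 1
        assert struct[0].concentration == pytest.approx(c_struct, rel=1e-5)
        assert struct[0].actuator == ACTUATORS.index("eat")
        assert struct[0].value == pytest.approx(1.0)

    def test_repressor_blocks_expression(self):
        g = cascade_genome(with_repressor=True)
        net = build_network(g, CFG.genome, CFG.grn)
        st = GRNState(net)
        grn = CFG.grn
        activate_signalling(sensors(n_food_here=1), st, grn)
        for _ in range(4):
            transduce(st, grn)
        assert not any(a.kind == "structural" for a in st.agents)


def stub_state(concentrations, actuators, values):
    """Synthetic structural-only network for output-math tests."""
    n = len(concentrations)
    va = np.zeros((n, N_ACTUATORS), dtype=np.float32)
    ma = np.zeros((n, N_ACTUATORS), dtype=np.float32)
    for i, (a, v) in enumerate(zip(actuators, values)):
        va[i, a] = v
        ma[i, a] = 1.0
    net = types.SimpleNamespace(n=n, va=va, ma=ma)
    st = GRNState.__new__(GRNState)
    st.network = net
    st.c = np.asarray(concentrations, dtype=np.float32)
    return st


class TestActuatorOutputs:
    def test_single_contributor_passes_value_through(self):
        st = stub_state([0.37], [2], [0.8])
        assert actuator_outputs(st)["eat"] == pytest.approx(0.8)

    def test_equal_concentrations_average(self):
        st = stub_state([1.0, 1.0], [2, 2], [0.2, 0.6])
        assert actuator_outputs(st)["eat"] == pytest.approx(0.4)

    def test_concentration_weighted_mean(self):
        st = stub_state([1.0, 1.0, 2.0], [3, 3, 3], [0.0, 0.0, 1.0])
        assert actuator_outputs(st)["attack"] == pytest.approx(0.5)

    def test_no_contributor_is_neutral(self):
        st = stub_state([1.0], [2], [0.9])
        out = actuator_outputs(st)
        assert out["move"] == 0.0 and out["replicate"] == 0.0

    def test_outputs_bounded_by_contributor_range(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            k = int(rng.integers(1, 6))
            vals = rng.uniform(-1, 1, k)
            st = stub_state(rng.uniform(0.01, 5.0, k), [1] * k, vals)
            out = actuator_outputs(st)["move"]
            assert vals.min() - 1e-6 <= out <= vals.max() + 1e-6


class TestUpdateConcentrations:
    def test_pure_decay(self):
        st = stub_state([1.0], [0], [1.0])
        cfg = GrnConfig(decay=0.1, c_min=0.0001)
        update_concentrations(st, 0.0, cfg)
        assert st.c[0] == pytest.approx(0.9)

    def test_agent_below_minimum_is_deleted(self):
        st = stub_state([0.12], [0], [1.0])
        cfg = GrnConfig(decay=0.1, c_min=0.2)
        update_concentrations(st, 0.0, cfg)
        assert st.c[0] == 0.0

    def test_positive_feedback_boosts_concentration(self):
        a = stub_state([1.0], [0], [1.0])
        b = stub_state([1.0], [0], [1.0])
        cfg = GrnConfig(decay=0.1)
        update_concentrations(a, 10.0, cfg)
        update_concentrations(b, 0.0, cfg)
        assert a.c[0] > b.c[0]


class TestControllerStep:
    def test_empty_genome_is_neutral_forever(self):
        g = ArtificialGenome.from_strings(["2" * 400], ALPHA)
        st = GRNState(build_network(g, CFG.genome, CFG.grn))
        for _ in range(5):
            out, _ = controller_step(sensors(n_food_here=2, energy=100), st, 0.0, CFG.grn)
            assert np.all(out.values == 0.0)

    def test_deterministic_for_identical_inputs(self):
        g = init_genome(77, 2, 2000, ALPHA)
        outs = []
        for _ in range(2):
            st = GRNState(build_network(g, CFG.genome, CFG.grn))
            series = []
            for t in range(30):
                sv = sensors(n_robots=1, n_food_here=t % 2, energy=100, age=t)
                out, _ = controller_step(sv, st, 0.0, CFG.grn)
                series.append(out.values.copy())
            outs.append(np.array(series))
        assert np.array_equal(outs[0], outs[1])

    def test_constant_context_reaches_stationary_total_concentration(self):
        g = init_genome(5, 2, 3000, ALPHA)
        st = GRNState(build_network(g, CFG.genome, CFG.grn))
        sv = sensors(n_robots=1, n_food_here=1, energy=100, age=7)
        totals = []
        for _ in range(200):
            controller_step(sv, st, 0.0, CFG.grn)
            totals.append(st.total_concentration)
        tail = np.array(totals[-20:])
        assert np.all(np.abs(np.diff(tail)) < 1e-3 * max(tail.max(), 1.0))

    def test_no_agent_survives_below_c_min(self):
        g = init_genome(9, 2, 3000, ALPHA)
        st = GRNState(build_network(g, CFG.genome, CFG.grn))
        rng = np.random.default_rng(0)
        for t in range(100):
            sv = sensors(n_robots=int(rng.integers(0, 4)),
                         n_food_here=int(rng.integers(0, 2)),
                         energy=float(rng.uniform(0, 300)), age=t)
            controller_step(sv, st, float(rng.normal(0, 3)), CFG.grn)
            live = st.c[st.c > 0]
            if live.size:
                assert live.min() >= CFG.grn.c_min - 1e-7

    def test_controller_never_modifies_genome(self):
        g = init_genome(13, 2, 2000, ALPHA)
        snapshot = [c.copy() for c in g.chromosomes]
        st = GRNState(build_network(g, CFG.genome, CFG.grn))
        for t in range(50):
            controller_step(sensors(n_food_here=1, energy=50, age=t), st, -1.0, CFG.grn)
        assert all(np.array_equal(a, b) for a, b in zip(snapshot, g.chromosomes))


class TestFastPathEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    def test_compiled_kernel_matches_reference(self, seed):
        g = init_genome(3000 + seed, 2, 4000, ALPHA)
        net = build_network(g, CFG.genome, CFG.grn)
        ref = GRNState(net)
        fast = GRNState(net)
        rng = np.random.default_rng(seed)
        for t in range(40):
            sv = sensors(n_robots=int(rng.integers(0, 5)),
                         n_food_here=int(rng.integers(0, 3)),
                         n_food=int(rng.integers(0, 6)),
                         energy=float(rng.uniform(0, 400)), age=t)
            fb = float(rng.normal(0, 5))
            out_ref, _ = controller_step(sv, ref, fb, CFG.grn)
            out_fast = fast.fast_step(sv.values, fb, CFG.grn)
            np.testing.assert_allclose(out_fast, out_ref.values, atol=2e-3)
            np.testing.assert_allclose(fast.c, ref.c, atol=2e-3)


class TestStateCheckpoint:
    def test_round_trip_resumes_identically(self):
        g = init_genome(55, 2, 3000, ALPHA)
        net = build_network(g, CFG.genome, CFG.grn)
        st = GRNState(net)
        for t in range(25):
            controller_step(sensors(n_food_here=t % 2, energy=90, age=t), st, 0.0, CFG.grn)
        restored = GRNState.from_text(st.to_text(), net)
        np.testing.assert_allclose(restored.c, st.c, rtol=1e-6)
        a, _ = controller_step(sensors(energy=90, age=25), st, 0.0, CFG.grn)
        b, _ = controller_step(sensors(energy=90, age=25), restored, 0.0, CFG.grn)
        np.testing.assert_allclose(a.values, b.values, atol=1e-6)

    def test_mismatched_network_rejected(self):
        g = init_genome(56, 1, 2000, ALPHA)
        net = build_network(g, CFG.genome, CFG.grn)
        st = GRNState(net)
        other = build_network(init_genome(57, 1, 1500, ALPHA), CFG.genome, CFG.grn)
        if other.n != net.n:
            with pytest.raises(ValueError):
                GRNState.from_text(st.to_text(), other)
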