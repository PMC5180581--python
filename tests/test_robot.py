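"""Robot layer: action mapping, eating, predation, replication, upkeep, aggregates."""
from __future__ import annotations

import numpy as np
import pytest

from grnswarm.config import EnergyConfig, FoodConfig, FoodTypeConfig, WorldConfig
from grnswarm.grn import ACTUATORS, ActuatorVector
from grnswarm.robot import (
    ActionDecision, Aggregate, Robot, attack, decide_actions, direction_octant,
    eat, joint_actuators, replication_ledger, upkeep,
)
from grnswarm.world import WorldGrid

SCHED = EnergyConfig(
    basic_cost=1.0, move_cost=1.0, attack_cost=5.0, defend_cost=3.0,
    defence_bonus=25.0, replicate_cost=20.0, replicate_threshold=150.0,
    endowment=50.0, aggregate_upkeep=1.0, prey_transfer=0.8,
)


def vec(**kw) -> ActuatorVector:
    values = np.zeros(len(ACTUATORS), dtype=np.float32)
    for name, v in kw.items():
        values[ACTUATORS.index(name)] = v
    return ActuatorVector(values)


def robot(energy=100.0, x=3, y=3, rid=0) -> Robot:
    return Robot(rid, x, y, energy, controller=None)


def food_world(per_cell: dict | None = None, types=None) -> WorldGrid:
    fcfg = FoodConfig(
        types=types or [
            FoodTypeConfig(0.0, 20.0, 0),
            FoodTypeConfig(30.0, 40.0, 0),
            FoodTypeConfig(60.0, 80.0, 0),
        ],
        r0=0.0, reseed_rate=0.0,
    )
    w = WorldGrid(WorldConfig(size=8), fcfg, np.random.default_rng(0))
    for (ti, x, y), count in (per_cell or {}).items():
        w.food[ti, x, y] = count
    return w


class TestDecideActions:
    def test_all_neutral_is_idle(self):
        d = decide_actions(ActuatorVector.neutral(), 0.5, -0.5, -0.5)
        assert d.actions == frozenset() and d.action is None

    def test_eat_beats_move(self):
        d = decide_actions(vec(eat=0.9, move=0.9), 0.5, -0.5, 0.5)
        assert d.actions == frozenset({"eat"})

    def test_eat_beats_attack(self):
        d = decide_actions(vec(eat=0.9, attack=0.9), 0.5)
        assert "eat" in d and "attack" not in d

    def test_attack_beats_defend(self):
        d = decide_actions(vec(attack=0.9, defend=0.9), 0.5)
        assert "attack" in d and "defend" not in d

    def test_replicate_coexists_with_eat(self):
        d = decide_actions(vec(eat=0.9, replicate=0.9), 0.5, -0.5, 0.5)
        assert "eat" in d and "replicate" in d

    def test_move_compatible_only_with_replicate(self):
        d = decide_actions(vec(move=0.9, replicate=0.9), 0.5, -0.5, 0.5)
        assert "move" in d and "replicate" in d
        d = decide_actions(vec(move=0.9, defend=0.9), 0.5, -0.5, 0.5)
        assert "move" not in d and "defend" in d

    @pytest.mark.parametrize("name", ["eat", "attack", "defend", "aggregate"])
    def test_sweeping_one_gate_flips_exactly_that_action(self, name):
        below = decide_actions(vec(**{name: 0.49}), 0.5, -0.5, 0.5)
        above = decide_actions(vec(**{name: 0.51}), 0.5, -0.5, 0.5)
        assert name not in below and name in above
        others = set(ACTUATORS[1:]) - {name, "move"}
        assert all(o not in above for o in others)

    def test_move_gate_uses_its_own_negative_threshold(self):
        below = decide_actions(vec(move=-0.6), 0.5, -0.5, 0.5)
        above = decide_actions(vec(move=-0.4), 0.5, -0.5, 0.5)
        assert "move" not in below and "move" in above

    def test_exactly_neutral_channel_never_fires(self):
        d = decide_actions(vec(move=0.0, replicate=0.0), 0.5, -0.5, -0.5)
        assert d.action is None

    def test_direction_octants_cover_range(self):
        assert direction_octant(-1.0) == 0
        assert direction_octant(1.0) == 7
        assert len({direction_octant(v) for v in np.linspace(-1, 1, 33)}) == 8


class TestEat:
    def test_inaccessible_food_is_not_eaten(self):
        w = food_world({(1, 3, 3): 1})  # threshold 30
        r = robot(energy=10.0)
        assert eat(r, w, SCHED) == 0.0
        assert w.food[1, 3, 3] == 1

    def test_greedy_choice_takes_richest_accessible(self):
        w = food_world({(0, 3, 3): 1, (2, 3, 3): 1})
        r = robot(energy=100.0)
        gained = eat(r, w, SCHED)
        assert gained == 80.0
        assert r.energy == 180.0
        assert w.food[2, 3, 3] == 0 and w.food[0, 3, 3] == 1
        assert r.feedings == 1

    def test_empty_cell_is_noop(self):
        w = food_world()
        r = robot()
        assert eat(r, w, SCHED) == 0.0
        assert r.energy == 100.0

    def test_dead_robot_cannot_eat(self):
        w = food_world({(0, 3, 3): 1})
        r = robot()
        r.alive = False
        with pytest.raises(ValueError):
            eat(r, w, SCHED)


class TestAttack:
    def test_successful_prey_hand_ledger(self):
        a, d = robot(100.0, rid=1), robot(40.0, rid=2)
        out = attack(a, d, SCHED, defender_defending=False)
        assert out.preyed
        # attacker pays 5, gains 0.8 * 40 = 32
        assert a.energy == pytest.approx(100 - 5 + 32)
        assert out.waste == pytest.approx(8.0)
        assert not d.alive and d.energy == 0.0
        assert a.attacks == 1

    def test_weaker_attacker_is_repelled(self):
        a, d = robot(40.0, rid=1), robot(100.0, rid=2)
        out = attack(a, d, SCHED, defender_defending=False)
        assert not out.preyed
        assert a.energy == pytest.approx(35.0)
        assert d.energy == pytest.approx(97.0)
        assert d.alive and d.defences == 1

    def test_tie_favours_defender(self):
        a, d = robot(80.0, rid=1), robot(80.0, rid=2)
        assert not attack(a, d, SCHED, defender_defending=False).preyed

    def test_defence_bonus_applies_only_when_defending(self):
        a, d = robot(100.0, rid=1), robot(90.0, rid=2)
        assert not attack(a, d, SCHED, defender_defending=True).preyed  # 90 + 25 > 100
        a2, d2 = robot(100.0, rid=3), robot(90.0, rid=4)
        assert attack(a2, d2, SCHED, defender_defending=False).preyed

    def test_cross_cell_attack_is_a_contract_violation(self):
        a = robot(100.0, x=0, y=0, rid=1)
        d = robot(50.0, x=1, y=0, rid=2)
        with pytest.raises(ValueError):
            attack(a, d, SCHED, defender_defending=False)

    def test_dead_participants_rejected(self):
        a, d = robot(rid=1), robot(rid=2)
        d.alive = False
        with pytest.raises(ValueError):
            attack(a, d, SCHED, defender_defending=False)


class TestReplicationLedger:
    def test_below_threshold_yields_none(self):
        assert replication_ledger(149.9, SCHED) is None

    def test_energy_arithmetic(self):
        parent_after, child = replication_ledger(200.0, SCHED)
        assert parent_after == pytest.approx(130.0)
        assert child == pytest.approx(50.0)

    def test_total_conserved_up_to_cost(self):
        parent_after, child = replication_ledger(321.0, SCHED)
        assert parent_after + child == pytest.approx(321.0 - SCHED.replicate_cost)


class TestUpkeep:
    def test_cannot_cover_debit_dies(self):
        r = robot(5.0)
        assert not upkeep(r, 5.0, 1.0)
        assert not r.alive

    def test_exact_zero_survives(self):
        r = robot(6.0)
        assert upkeep(r, 5.0, 1.0)
        assert r.alive and r.energy == 0.0

    def test_zero_extras_reproduce_baseline(self):
        r = robot(10.0)
        upkeep(r, 1.0, 0.0)
        assert r.energy == 9.0


class TestAggregates:
    def test_identical_outputs_average_to_same(self):
        v = vec(move=0.4, eat=0.2)
        joint = joint_actuators([v, v])
        assert np.allclose(joint.values, v.values)

    def test_mean_of_two_channels(self):
        joint = joint_actuators([vec(eat=0.2), vec(eat=0.8)])
        assert joint["eat"] == pytest.approx(0.5)

    def test_energy_sharing_equalizes(self):
        r1, r2 = robot(100.0, rid=1), robot(20.0, rid=2)
        agg = Aggregate(7, [r1, r2])
        agg.share_energy()
        assert r1.energy == r2.energy == pytest.approx(60.0)

    def test_member_death_dissolves_below_two(self):
        r1, r2 = robot(rid=1), robot(rid=2)
        agg = Aggregate(8, [r1, r2])
        r2.alive = False
        released = agg.prune()
        assert released == [r1]
        assert r1.aggregate_id is None and not agg.members

    def test_single_member_rejected_at_construction(self):
        with pytest.raises(ValueError):
            Aggregate(9, [robot(rid=1)])
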