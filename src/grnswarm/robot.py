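"""Robot life cycle: actions, energy accounting, predation, replication, aggregation.

A robot is a grid-dwelling digital organism.  Selection is purely energetic:
there is no explicit fitness function — a robot that cannot cover its basic
living cost dies and is removed the same step.  Continuous actuator outputs
are mapped to at most one discrete action per step by gate thresholds and a
fixed priority (eat > attack > defend > replicate > aggregate > move).

Predation ("prey behaviour") requires predator and target in the same cell;
the attack succeeds only when the attacker is strictly stronger (strength =
energy, plus a defence bonus if the target's defend gate fired this step), in
which case a fraction ``phi`` of the victim's energy transfers to the
attacker and the rest dissipates.  A repelled attack costs both sides energy.

Aggregates are fused robotic organisms: every member's controller keeps
running on its own sensors, the organism is steered by the unweighted mean of
the members' outputs, and members share pooled energy equally each step.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .config import EnergyConfig
from .grn import ACTUATORS, ActuatorVector

__all__ = [
    "ACTIONS", "ActionDecision", "IDLE", "Robot", "Aggregate", "AttackOutcome",
    "decide_actions", "direction_octant", "DIRECTIONS", "eat", "attack",
    "replication_ledger", "joint_actuators", "upkeep",
]

# Gate actuators in execution priority order; move_dir is the heading channel.
ACTIONS = ("eat", "attack", "defend", "replicate", "aggregate", "move")

# 8-way headings, octant order starting east, counter-clockwise.
DIRECTIONS = ((1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1))


@dataclass(frozen=True)
class ActionDecision:
    """The set of compatible discrete actions one controller output maps to."""

    actions: frozenset[str]          # subset of ACTIONS; empty = idle
    direction: Optional[int] = None  # octant index, set when "move" is selected

    @property
    def action(self) -> Optional[str]:
        """Highest-priority selected action (None when idling)."""
        for name in ACTIONS:
            if name in self.actions:
                return name
        return None

    def __contains__(self, name: str) -> bool:
        return name in self.actions


IDLE = ActionDecision(frozenset())


def direction_octant(value: float) -> int:
    """Map a [-1, 1] heading output onto one of 8 compass octants."""
    v = min(max(float(value), -1.0), 1.0)
    return min(int((v + 1.0) / 2.0 * 8.0), 7)


def decide_actions(actuators: ActuatorVector, gate_threshold: float = 0.5,
                   move_threshold: float | None = None,
                   replicate_threshold: float | None = None) -> ActionDecision:
    """Threshold the gate channels and resolve exclusive pairs by fixed priority.

    A gate fires when its output strictly exceeds its threshold.  Fired gates
    that are compatible all execute this step; mutually exclusive pairs are
    resolved in the fixed priority order eat > attack > defend > replicate >
    aggregate > move:

    * eat and attack exclude each other (eat wins);
    * defend excludes attack (attack wins when both fire);
    * movement excludes the in-place actions (eat, attack, defend,
      aggregate) but is compatible with replication — offspring are dropped
      in the parent's cell as it leaves;
    * replicate and aggregate are compatible with eating and defending.

    The move and replicate gates carry their own (negative by default)
    thresholds: robots with *any* live movement drive above the move
    threshold keep moving (basal motility), and reproduction fires whenever
    a live replication drive is not actively suppressed — the energy
    precondition is the effective gate.  A robot stops (or withholds
    reproduction) either by suppressing the drive below the threshold or by
    expressing nothing onto the actuator (an exactly neutral channel never
    fires).  With no gate fired the robot idles.
    """
    if move_threshold is None:
        move_threshold = gate_threshold
    if replicate_threshold is None:
        replicate_threshold = gate_threshold
    vals = actuators.values
    fired = {
        name: float(vals[ACTUATORS.index(name)]) > gate_threshold
        for name in ACTIONS
    }
    mv = float(vals[ACTUATORS.index("move")])
    fired["move"] = mv > move_threshold and mv != 0.0
    rp = float(vals[ACTUATORS.index("replicate")])
    fired["replicate"] = rp > replicate_threshold and rp != 0.0
    chosen: set[str] = set()
    if fired["eat"]:
        chosen.add("eat")
    elif fired["attack"]:
        chosen.add("attack")
    if fired["defend"] and "attack" not in chosen:
        chosen.add("defend")
    if fired["replicate"]:
        chosen.add("replicate")
    if fired["aggregate"]:
        chosen.add("aggregate")
    if fired["move"] and not (chosen - {"replicate"}):
        chosen.add("move")
        return ActionDecision(
            frozenset(chosen),
            direction_octant(vals[ACTUATORS.index("move_dir")]),
        )
    return ActionDecision(frozenset(chosen)) if chosen else IDLE


class Robot:
    """One digital organism: position, energy, controller state, action counters."""

    __slots__ = (
        "id", "x", "y", "energy", "controller", "genome",
        "attacks", "defences", "replications", "feedings",
        "recent_attacks", "recent_defences", "recent_replications", "recent_feedings",
        "alive", "aggregate_id", "last_energy", "decision", "moved", "birth_step",
    )

    def __init__(self, rid: int, x: int, y: int, energy: float, controller, genome=None,
                 birth_step: int = 0):
        self.id = rid
        self.x = x
        self.y = y
        self.energy = float(energy)
        self.controller = controller
        self.genome = genome
        self.attacks = 0
        self.defences = 0
        self.replications = 0
        self.feedings = 0
        self.recent_attacks = 0.0
        self.recent_defences = 0.0
        self.recent_replications = 0.0
        self.recent_feedings = 0.0
        self.alive = True
        self.aggregate_id: Optional[int] = None
        self.last_energy = float(energy)
        self.decision = IDLE
        self.moved = False
        self.birth_step = birth_step

    @property
    def position(self) -> tuple[int, int]:
        return self.x, self.y

    def decay_recent(self, factor: float) -> None:
        self.recent_attacks *= factor
        self.recent_defences *= factor
        self.recent_replications *= factor
        self.recent_feedings *= factor


class Aggregate:
    """A fused organism of >= 2 co-located robots with pooled energy."""

    __slots__ = ("id", "members")

    def __init__(self, aid: int, members: list[Robot]):
        if len(members) < 2:
            raise ValueError("an aggregate needs at least two members")
        self.id = aid
        self.members = members
        for m in members:
            m.aggregate_id = aid

    @property
    def pooled_energy(self) -> float:
        return sum(m.energy for m in self.members)

    def share_energy(self) -> None:
        """Equal redistribution of the pooled energy among live members."""
        live = [m for m in self.members if m.alive]
        if not live:
            return
        share = sum(m.energy for m in live) / len(live)
        for m in live:
            m.energy = share

    def prune(self) -> list[Robot]:
        """Drop dead members; a 1-member aggregate dissolves. Returns released robots."""
        self.members = [m for m in self.members if m.alive]
        if len(self.members) >= 2:
            return []
        released = self.members
        for m in released:
            m.aggregate_id = None
        self.members = []
        return released


def joint_actuators(outputs: Sequence[ActuatorVector]) -> ActuatorVector:
    """Unweighted per-channel mean of member controller outputs."""
    if not outputs:
        raise ValueError("no member outputs")
    vals = np.mean([o.values for o in outputs], axis=0).astype(np.float32)
    return ActuatorVector(vals)


# -- single-action semantics ------------------------------------------------

def eat(robot: Robot, world, schedule: EnergyConfig) -> float:
    """Consume the highest-value accessible food source in the robot's cell.

    Accessibility requires robot energy >= the source's access threshold.
    Returns the energy gained (0 when nothing accessible).
    """
    if not robot.alive:
        raise ValueError("dead robots do not act")
    best = world.best_accessible_food(robot.x, robot.y, robot.energy)
    if best is None:
        return 0.0
    world.remove_food(best.index, robot.x, robot.y)
    robot.energy += best.energy_content
    robot.feedings += 1
    robot.recent_feedings += 1.0
    return best.energy_content


@dataclass(frozen=True)
class AttackOutcome:
    preyed: bool
    energy_gained: float = 0.0
    waste: float = 0.0              # the (1 - phi) share lost on a kill
    attack_cost_paid: float = 0.0
    defend_cost_paid: float = 0.0


def attack(
    attacker: Robot,
    defender: Robot,
    schedule: EnergyConfig,
    defender_defending: bool,
    attacker_strength: float | None = None,
    defender_strength: float | None = None,
) -> AttackOutcome:
    """Resolve a same-cell attack; ties favour the defender.

    Strength defaults to current energy (pooled energy may be supplied for
    aggregates); a defending target gains ``defence_bonus``.  On a kill the
    attacker gains ``prey_transfer`` of the victim's energy and the remainder
    dissipates; otherwise the attack is repelled and the defender pays the
    defence cost.  The attack cost is paid in both cases.
    """
    if not (attacker.alive and defender.alive):
        raise ValueError("dead robots neither attack nor defend")
    if (attacker.x, attacker.y) != (defender.x, defender.y):
        raise ValueError("attack requires predator and target in the same cell")
    a = attacker.energy if attacker_strength is None else attacker_strength
    d = defender.energy if defender_strength is None else defender_strength
    if defender_defending:
        d += schedule.defence_bonus
    atk_paid = min(schedule.attack_cost, attacker.energy)
    attacker.energy -= atk_paid
    if a > d:
        loot = schedule.prey_transfer * defender.energy
        waste = defender.energy - loot
        attacker.energy += loot
        defender.energy = 0.0
        defender.alive = False
        attacker.attacks += 1
        attacker.recent_attacks += 1.0
        return AttackOutcome(True, energy_gained=loot, waste=waste, attack_cost_paid=atk_paid)
    def_paid = min(schedule.defend_cost, defender.energy)
    defender.energy -= def_paid
    defender.defences += 1
    defender.recent_defences += 1.0
    return AttackOutcome(False, attack_cost_paid=atk_paid, defend_cost_paid=def_paid)


def replication_ledger(parent_energy: float, schedule: EnergyConfig) -> tuple[float, float] | None:
    """Energy arithmetic of replication: (parent energy after, offspring energy).

    ``None`` below the replication threshold.  The parent pays the
    replication cost (dissipated) and transfers the endowment to the
    offspring, conserving the remainder.
    """
    if parent_energy < schedule.replicate_threshold:
        return None
    return parent_energy - schedule.replicate_cost - schedule.endowment, schedule.endowment


def upkeep(robot: Robot, basic_cost: float, seasonal_extra: float) -> bool:
    """Debit end-of-step living costs; returns the alive flag.

    Death occurs only when the debit cannot be covered; landing exactly on
    zero energy leaves the robot alive (it dies next step unless it gains).
    """
    debit = basic_cost + seasonal_extra
    if robot.energy < debit:
        robot.alive = False
        return False
    robot.energy -= debit
    return True
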