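"""Simulation engine: the frozen step pipeline, replicate experiments, logging.

Step pipeline (any reordering is a breaking change):

1. every live robot senses the *frozen* start-of-step world and its controller
   decides an action;
2. actions execute in a seeded random unit order (aggregates act as single
   units steered by the mean of member outputs);
3. upkeep is debited (basic + seasonal survival cost + aggregate upkeep) and
   robots that cannot pay die; aggregates share energy and dissolve below two
   members;
4. food grows (density-dependent) and scheduled restorations fire;
5. the season clock advances; metrics are sampled every ``metrics_interval``
   steps.

A run terminates at extinction (population strictly below the threshold,
default 100) or at ``max_steps``.  A run is a pure function of
``(SimConfig, seed)``: all randomness derives from one ``SeedSequence`` split
into independent child streams (initialisation, action order, world growth,
reproduction), so identical inputs give bit-identical logs.

Energy bookkeeping is exact: robot energy + food energy on the grid +
cumulative dissipated costs − cumulative injected food energy is invariant
over a run (audited in tests).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .ann import AnnController
from .config import ConfigError, SimConfig
from .genome import ArtificialGenome, MutationRates, init_genome, replicate_genome
from ._fast import HAVE_NUMBA, grn_step_kernel
from .grn import GRNState, SensorVector, build_network
from .robot import (
    ActionDecision, Aggregate, IDLE, Robot, attack,
    direction_octant, eat, replication_ledger, upkeep, DIRECTIONS,
)
from .world import WorldGrid, moore_sum, season_costs

__all__ = ["RunLog", "ExperimentSummary", "Simulation", "run_simulation", "run_experiment"]

METRIC_COLUMNS = (
    "step", "population", "food", "preys", "aggregations",
    "neighbour_sum", "mean_energy",
)


@dataclass
class RunLog:
    """Per-interval metric records plus the terminal (extinction) record."""

    seed: int
    controller: str
    records: list[dict] = field(default_factory=list)
    extinct: bool = False
    extinction_step: int | None = None
    food_at_extinction: int | None = None
    steps: int = 0
    final_population: int = 0
    events: list[tuple] | None = None

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.records, columns=METRIC_COLUMNS)
        return df.astype({"step": int, "population": int, "food": int,
                          "preys": int, "aggregations": int, "neighbour_sum": int})

    def to_csv_text(self) -> str:
        return self.frame().to_csv(index=False, float_format="%.6f")

    def summary(self) -> dict:
        return {
            "seed": self.seed,
            "controller": self.controller,
            "steps": self.steps,
            "extinct": self.extinct,
            "extinction_step": self.extinction_step,
            "food_at_extinction": self.food_at_extinction,
            "final_population": self.final_population,
        }


class Simulation:
    """One run: builds the world and population, then steps to termination."""

    def __init__(self, config: SimConfig, seed: int, audit: bool = False):
        config.validate()
        self.cfg = config
        self.seed = int(seed)
        self.audit = audit
        ss = np.random.SeedSequence(self.seed)
        init_ss, order_ss, world_ss, repro_ss = ss.spawn(4)
        self.order_rng = np.random.default_rng(order_ss)
        self.world_rng = np.random.default_rng(world_ss)
        self.repro_rng = np.random.default_rng(repro_ss)
        init_rng = np.random.default_rng(init_ss)

        self.world = WorldGrid(config.world, config.food, self.world_rng)
        self.rates = MutationRates(
            config.mutation.point_rate,
            config.mutation.duplication_rate,
            config.mutation.duplication_mean_length,
        )
        self.t = 0
        self.next_id = 0
        self.next_aggregate_id = 0
        self.robots: list[Robot] = []
        self.cells: dict[tuple[int, int], list[Robot]] = {}
        self.aggregates: dict[int, Aggregate] = {}
        self.dissipated = 0.0
        self.injected = 0.0
        self.window_preys = 0
        self.window_aggregations = 0
        self._decision_cache: dict = {}
        self.events: list[tuple] | None = [] if audit else None
        self.log = RunLog(seed=self.seed, controller=config.controller,
                          events=self.events)

        size = config.world.size
        e0 = config.population.initial_energy
        spread = config.population.initial_energy_spread
        for _ in range(config.population.initial):
            x = int(init_rng.integers(0, size))
            y = int(init_rng.integers(0, size))
            energy = e0 if spread == 0 else float(init_rng.uniform(e0 - spread, e0 + spread))
            self._spawn_robot(x, y, energy, init_rng)
        self.initial_energy_total = (
            sum(r.energy for r in self.robots) + self.world.total_food_energy
        )

    # -- population bookkeeping --------------------------------------------
    def _make_controller(self, rng: np.random.Generator, parent: Robot | None = None):
        cfg = self.cfg
        if cfg.controller == "grn":
            if parent is None:
                genome = init_genome(
                    int(rng.integers(0, 2**31 - 1)),
                    cfg.genome.n_chromosomes, cfg.genome.chrom_length, cfg.genome.alphabet,
                )
            else:
                genome = replicate_genome(parent.genome, self.rates, rng)
            state = GRNState(build_network(genome, cfg.genome, cfg.grn))
            return state, genome
        if parent is None:
            return AnnController.random(cfg.ann, rng), None
        return parent.controller.spawn_child(rng), None

    def _spawn_robot(self, x: int, y: int, energy: float,
                     rng: np.random.Generator, parent: Robot | None = None) -> Robot:
        controller, genome = self._make_controller(rng, parent)
        r = Robot(self.next_id, x, y, energy, controller, genome, birth_step=self.t)
        self.next_id += 1
        self.robots.append(r)
        self.cells.setdefault((x, y), []).append(r)
        self.world.robot_count[x, y] += 1
        return r

    def _remove_robot(self, r: Robot) -> None:
        self.cells[(r.x, r.y)].remove(r)
        self.world.robot_count[r.x, r.y] -= 1

    def _move_robot(self, r: Robot, nx: int, ny: int) -> None:
        self.cells[(r.x, r.y)].remove(r)
        self.world.robot_count[r.x, r.y] -= 1
        r.x, r.y = nx, ny
        self.cells.setdefault((nx, ny), []).append(r)
        self.world.robot_count[nx, ny] += 1

    def _event(self, rid: int, action: str, outcome: str, delta: float) -> None:
        if self.events is not None:
            self.events.append((self.t, rid, action, outcome, round(delta, 9)))

    def _sensor_matrix(self, r3: np.ndarray, f3: np.ndarray) -> np.ndarray:
        """Bounded [0, 1] channel values for every live robot, vectorized.

        Row layout matches :data:`grnswarm.grn.CHANNELS`; numerically
        identical to :func:`grnswarm.grn.encode_sensors` per robot.
        """
        cfg = self.cfg.sensors
        robots = self.robots
        n = len(robots)
        xs = np.fromiter((r.x for r in robots), np.int64, n)
        ys = np.fromiter((r.y for r in robots), np.int64, n)
        fh = self.world.food[:, xs, ys].sum(axis=0).astype(np.float32)
        chans = np.empty((n, 9), dtype=np.float32)
        cap = np.float32(cfg.count_cap)
        np.clip((r3[xs, ys] - 1).astype(np.float32), 0, cap, out=chans[:, 0])
        chans[:, 0] /= cap
        np.clip(fh, 0, np.float32(cfg.food_here_cap), out=chans[:, 1])
        chans[:, 1] /= np.float32(cfg.food_here_cap)
        np.clip((f3[xs, ys] - fh).astype(np.float32), 0, cap, out=chans[:, 2])
        chans[:, 2] /= cap
        energies = np.fromiter((r.energy for r in robots), np.float64, n)
        np.clip(energies.astype(np.float32), 0, np.float32(cfg.energy_scale), out=chans[:, 3])
        chans[:, 3] /= np.float32(cfg.energy_scale)
        ccap = np.float32(cfg.counter_cap)
        for col, name in ((4, "recent_attacks"), (5, "recent_defences"),
                          (6, "recent_replications"), (7, "recent_feedings")):
            vals = np.fromiter((getattr(r, name) for r in robots), np.float64, n)
            np.clip(vals.astype(np.float32), 0, ccap, out=chans[:, col])
            chans[:, col] /= ccap
        ages = self.t - np.fromiter((r.birth_step for r in robots), np.int64, n)
        frac = (ages % cfg.rhythm_period) / cfg.rhythm_period
        chans[:, 8] = np.where(frac < 0.5, 2.0 * frac, 2.0 * (1.0 - frac)).astype(np.float32)
        return chans

    def _decide(self, values: np.ndarray) -> ActionDecision:
        """Interned, allocation-free equivalent of :func:`decide_actions`."""
        acfg = self.cfg.actions
        thr = acfg.gate_threshold
        eat_f = values[2] > thr
        attack_f = (not eat_f) and values[3] > thr
        defend_f = (not attack_f) and values[4] > thr
        rp = float(values[5])
        repl_f = rp > acfg.replicate_threshold and rp != 0.0
        aggr_f = values[6] > thr
        mv = float(values[1])
        move_f = mv > acfg.move_threshold and mv != 0.0
        stationary = eat_f or attack_f or defend_f or aggr_f
        direction = direction_octant(float(values[0])) if (move_f and not stationary) else -1
        key = (eat_f, attack_f, defend_f, repl_f, aggr_f,
               move_f and not stationary, direction)
        dec = self._decision_cache.get(key)
        if dec is None:
            chosen = set()
            if eat_f:
                chosen.add("eat")
            if attack_f:
                chosen.add("attack")
            if defend_f:
                chosen.add("defend")
            if repl_f:
                chosen.add("replicate")
            if aggr_f:
                chosen.add("aggregate")
            if move_f and not stationary:
                chosen.add("move")
                dec = ActionDecision(frozenset(chosen), direction)
            else:
                dec = ActionDecision(frozenset(chosen)) if chosen else IDLE
            self._decision_cache[key] = dec
        return dec

    # -- one step ------------------------------------------------------------
    def step(self) -> None:
        cfg = self.cfg
        world = self.world
        grn_cfg = cfg.grn
        is_grn = cfg.controller == "grn"
        # 1. frozen sensing + decisions
        r3 = moore_sum(world.robot_count, world.sensing_radius, world.torus)
        f3 = moore_sum(world.food_total_grid, world.sensing_radius, world.torus)
        chans = self._sensor_matrix(r3, f3)
        outputs: dict[int, np.ndarray] = {}
        use_kernel = is_grn and HAVE_NUMBA
        c_init = np.float32(grn_cfg.c_init)
        c_max = np.float32(grn_cfg.c_max)
        c_min = np.float32(grn_cfg.c_min)
        rounds = grn_cfg.cascade_rounds
        decay_keep = 1.0 - grn_cfg.decay
        gain = grn_cfg.feedback_gain
        scale = grn_cfg.feedback_scale
        for i, r in enumerate(self.robots):
            feedback = r.energy - r.last_energy
            if use_kernel:
                st = r.controller
                net = st.network
                if net.n == 0:
                    raw = st._out
                else:
                    if feedback > 0:
                        factor = decay_keep * (1.0 + gain * min(feedback / scale, 1.0))
                    elif feedback < 0:
                        factor = decay_keep * (1.0 - gain * min(-feedback / scale, 1.0))
                    else:
                        factor = decay_keep
                    grn_step_kernel(
                        st.c, net.chan_q,
                        net.route_indptr, net.route_indices, net.route_data,
                        net.rep_idx, net.block_indptr, net.block_indices,
                        net.struct_idx, net.struct_act, net.struct_val,
                        chans[i], c_init, c_max, c_min, np.float32(factor),
                        rounds, st._out,
                    )
                    raw = st._out
            elif is_grn:
                raw = r.controller.fast_step(chans[i], feedback, grn_cfg)
            else:
                raw = r.controller.forward(SensorVector(chans[i])).values
                r.controller.feedback(feedback)
            outputs[r.id] = raw
            r.decision = self._decide(raw)
            r.moved = False

        # aggregate units decide jointly from the mean of member outputs
        unit_decisions: dict[int, ActionDecision] = {}
        for aid, agg in self.aggregates.items():
            joint = np.mean([outputs[m.id] for m in agg.members], axis=0).astype(np.float32)
            unit_decisions[aid] = self._decide(joint)

        # 2. execute in seeded random unit order
        units: list[tuple[str, object]] = [
            ("robot", r) for r in self.robots if r.aggregate_id is None
        ] + [("agg", a) for a in self.aggregates.values()]
        order = self.order_rng.permutation(len(units))
        _, move_extra = season_costs(self.t, cfg.seasons)
        for idx in order:
            kind, unit = units[idx]
            if kind == "robot":
                r = unit
                if not r.alive:
                    continue
                self._execute(r, r.decision, move_extra, solo=True)
            else:
                agg = unit
                agg.members = [m for m in agg.members if m.alive]
                if len(agg.members) < 2:
                    continue
                self._execute_aggregate(agg, unit_decisions[agg.id], move_extra)

        # 3. upkeep and deaths
        surv_extra, _ = season_costs(self.t, cfg.seasons)
        for r in self.robots:
            if not r.alive:
                continue
            extra = surv_extra + (cfg.energy.aggregate_upkeep if r.aggregate_id is not None else 0.0)
            before = r.energy
            if upkeep(r, cfg.energy.basic_cost, extra):
                self.dissipated += before - r.energy
            else:
                self.dissipated += before  # corpse energy dissipates
                r.energy = 0.0
                self._event(r.id, "death", "starved", -before)
        for aid in list(self.aggregates):
            agg = self.aggregates[aid]
            agg.share_energy()
            agg.prune()
            if not agg.members:
                del self.aggregates[aid]
        dead = [r for r in self.robots if not r.alive]
        for r in dead:
            self._remove_robot(r)
        if dead:
            self.robots = [r for r in self.robots if r.alive]

        # 4. food growth and scheduled restoration
        grown = world.grow_food(self.world_rng)
        reseeded = world.reseed(self.world_rng)
        restored = world.restore_food(self.t, self.world_rng)
        for ft in world.food_types:
            self.injected += (int(grown[ft.index]) + int(reseeded[ft.index])
                              + int(restored[ft.index])) * ft.energy_content

        # 5. advance clock; end-of-step robot state
        self.t += 1
        decay = cfg.sensors.counter_decay
        for r in self.robots:
            r.last_energy = r.energy
            r.decay_recent(decay)

    # -- action execution ----------------------------------------------------
    def _execute(self, r: Robot, decision: ActionDecision, move_extra: float,
                 solo: bool) -> None:
        cfg = self.cfg
        if "eat" in decision:
            gained = eat(r, self.world, cfg.energy)
            if gained:
                self._event(r.id, "eat", "fed", gained)
        elif "attack" in decision and r.energy >= cfg.energy.attack_cost:
            target = self._pick_target(r)
            if target is not None:
                self._resolve_attack(r, target, attacker_strength=r.energy)
                if not r.alive:
                    return
        # "defend" is a stance; its bonus applies when attacked this step
        if "replicate" in decision:
            self._replicate(r)
        if "aggregate" in decision and solo:
            self._try_aggregate(r)
        if "move" in decision:
            self._move_unit([r], decision.direction, move_extra)

    def _execute_aggregate(self, agg: Aggregate, decision: ActionDecision,
                           move_extra: float) -> None:
        cfg = self.cfg
        lead = max(agg.members, key=lambda m: m.energy)
        if "eat" in decision:
            gained = eat(lead, self.world, cfg.energy)
            if gained:
                self._event(lead.id, "eat", "fed", gained)
        elif "attack" in decision and agg.pooled_energy >= cfg.energy.attack_cost:
            target = self._pick_target(lead)
            if target is not None:
                self._resolve_attack(lead, target, attacker_strength=agg.pooled_energy)
        if "replicate" in decision:
            self._replicate(lead)
        if "move" in decision:
            self._move_unit(list(agg.members), decision.direction, move_extra)

    def _pick_target(self, attacker: Robot) -> Robot | None:
        """Random co-located robot outside the attacker's own aggregate."""
        occupants = [
            o for o in self.cells.get((attacker.x, attacker.y), ())
            if o.alive and o is not attacker
            and (attacker.aggregate_id is None or o.aggregate_id != attacker.aggregate_id)
        ]
        if not occupants:
            return None
        return occupants[int(self.order_rng.integers(0, len(occupants)))]

    def _defending(self, target: Robot) -> bool:
        if target.aggregate_id is not None:
            agg = self.aggregates.get(target.aggregate_id)
            if agg is not None and len(agg.members) >= 2:
                # the organism defends as a unit only if its joint gate fired;
                # approximated by any member's defend decision
                return any("defend" in m.decision for m in agg.members)
        return "defend" in target.decision

    def _resolve_attack(self, attacker: Robot, target: Robot,
                        attacker_strength: float) -> None:
        cfg = self.cfg
        defender_strength = target.energy
        if target.aggregate_id is not None:
            agg = self.aggregates.get(target.aggregate_id)
            if agg is not None and len(agg.members) >= 2:
                defender_strength = agg.pooled_energy
        outcome = attack(
            attacker, target, cfg.energy,
            defender_defending=self._defending(target),
            attacker_strength=attacker_strength,
            defender_strength=defender_strength,
        )
        self.dissipated += outcome.attack_cost_paid + outcome.defend_cost_paid + outcome.waste
        if outcome.preyed:
            self.window_preys += 1
            self._remove_robot(target)
            self.robots.remove(target)
            self._event(attacker.id, "attack", "prey", outcome.energy_gained)
            self._event(target.id, "death", "preyed", 0.0)
        else:
            self._event(attacker.id, "attack", "repelled", -outcome.attack_cost_paid)

    def _replicate(self, parent: Robot) -> None:
        ledger = replication_ledger(parent.energy, self.cfg.energy)
        if ledger is None:
            return
        parent_after, child_energy = ledger
        self.dissipated += self.cfg.energy.replicate_cost
        parent.energy = parent_after
        parent.replications += 1
        parent.recent_replications += 1.0
        child = self._spawn_robot(parent.x, parent.y, child_energy, self.repro_rng, parent=parent)
        self._event(parent.id, "replicate", f"child={child.id}", -self.cfg.energy.replicate_cost)

    def _try_aggregate(self, r: Robot) -> None:
        """Join a co-located aggregate, or fuse with a co-located consenting robot."""
        if r.aggregate_id is not None:
            return  # already recruited earlier this step
        cell = self.cells.get((r.x, r.y), ())
        for o in cell:
            if o is r or not o.alive:
                continue
            if o.aggregate_id is not None:
                self.aggregates[o.aggregate_id].members.append(r)
                r.aggregate_id = o.aggregate_id
                self.window_aggregations += 1
                self._event(r.id, "aggregate", f"joined={o.aggregate_id}", 0.0)
                return
        for o in cell:
            if o is r or not o.alive or o.aggregate_id is not None:
                continue
            if "aggregate" in o.decision:
                agg = Aggregate(self.next_aggregate_id, [r, o])
                self.next_aggregate_id += 1
                self.aggregates[agg.id] = agg
                self.window_aggregations += 1
                self._event(r.id, "aggregate", f"formed={agg.id}", 0.0)
                return

    def _heading(self, r: Robot, octant: int) -> int | None:
        """Resolve the relative direction octant onto the grid (food taxis).

        The heading frame is anchored on the local food gradient: octant
        offset 0 points at the Moore-ring cell holding the most food, so a
        neutral direction output climbs the gradient.  When the robot's own
        cell is the local food maximum and the direction output is neutral,
        the climb terminates: ``None`` (no displacement).  With no food in
        sight the frame falls back to a per-robot idiosyncratic base heading,
        giving straight-line exploration.  ``direction_octant`` maps the
        neutral output 0 to octant 4, hence the ``- 4`` rotation.
        """
        world = self.world
        food = world.food_total_grid
        best = -1
        anchor = -1
        for k, (dx, dy) in enumerate(DIRECTIONS):
            cx, cy = world.wrap(r.x + dx, r.y + dy)
            if (cx, cy) == (r.x, r.y):
                continue
            f = int(food[cx, cy])
            if f > best and f > 0:
                best = f
                anchor = k
        here = int(food[r.x, r.y])
        if here > 0 and here >= best and octant == 4:
            return None  # standing on the local food maximum
        if anchor < 0:
            anchor = (r.id * 5 + 3) % 8
        return (anchor + octant - 4) % 8

    def _move_unit(self, members: list[Robot], direction: int, move_extra: float) -> None:
        cfg = self.cfg
        lead = members[0]
        heading = self._heading(lead, direction)
        if heading is None:
            return
        dx, dy = DIRECTIONS[heading]
        cost = cfg.energy.move_cost + move_extra
        for r in members:
            if r.energy < cost:
                continue
            nx, ny = self.world.wrap(r.x + dx, r.y + dy)
            if (nx, ny) == (r.x, r.y):
                continue  # bounded-world edge: no motion, no cost
            r.energy -= cost
            self.dissipated += cost
            self._move_robot(r, nx, ny)
            r.moved = True

    # -- metrics / audit -----------------------------------------------------
    def _record_metrics(self) -> None:
        r3 = moore_sum(self.world.robot_count, self.world.sensing_radius, self.world.torus)
        nsum = 0
        esum = 0.0
        for r in self.robots:
            nsum += int(r3[r.x, r.y]) - 1
            esum += r.energy
        n = len(self.robots)
        self.log.records.append({
            "step": self.t,
            "population": n,
            "food": self.world.total_food,
            "preys": self.window_preys,
            "aggregations": self.window_aggregations,
            "neighbour_sum": nsum,
            "mean_energy": esum / n if n else 0.0,
        })
        self.window_preys = 0
        self.window_aggregations = 0

    def energy_balance(self) -> float:
        """Robots + food + dissipated − injected; constant over a run."""
        robots = sum(r.energy for r in self.robots)
        return robots + self.world.total_food_energy + self.dissipated - self.injected

    def check_invariants(self) -> None:
        """Audit occupancy bookkeeping and the energy ledger (tests call this)."""
        count = np.zeros_like(self.world.robot_count)
        for r in self.robots:
            assert r.alive
            count[r.x, r.y] += 1
            in_cell = self.cells.get((r.x, r.y), ())
            assert r in in_cell
        assert np.array_equal(count, self.world.robot_count)
        balance = self.energy_balance()
        assert abs(balance - self.initial_energy_total) < 1e-6 * max(
            1.0, self.initial_energy_total
        ), (balance, self.initial_energy_total)

    # -- run loop ------------------------------------------------------------
    def extinct(self) -> bool:
        return len(self.robots) < self.cfg.extinction_threshold

    def run(self, step_callback=None) -> RunLog:
        log = self.log
        if self.extinct():
            log.extinct = True
            log.extinction_step = 0
            log.food_at_extinction = self.world.total_food
            log.final_population = len(self.robots)
            return log
        while self.t < self.cfg.max_steps:
            self.step()
            if step_callback is not None:
                step_callback(self)
            if self.extinct():
                log.extinct = True
                log.extinction_step = self.t
                log.food_at_extinction = self.world.total_food
                break
            if self.t % self.cfg.metrics_interval == 0:
                self._record_metrics()
        log.steps = self.t
        log.final_population = len(self.robots)
        return log


def run_simulation(config: SimConfig, seed: int, audit: bool = False,
                   step_callback=None) -> RunLog:
    """Run one simulation to termination; bit-identical logs for identical inputs."""
    if not isinstance(config, SimConfig):
        raise ConfigError("config must be a SimConfig")
    return Simulation(config, seed, audit=audit).run(step_callback=step_callback)


@dataclass
class ExperimentSummary:
    """Replicated two-arm comparison (GRN vs ANN) on food-at-extinction."""

    runs: pd.DataFrame
    grn_food: list[float]
    ann_food: list[float]
    mean_grn: float
    mean_ann: float
    t_statistic: float
    p_value: float
    logs: dict[str, list[RunLog]]

    def summary(self) -> dict:
        return {
            "n_grn": len(self.grn_food),
            "n_ann": len(self.ann_food),
            "mean_food_at_extinction_grn": self.mean_grn,
            "mean_food_at_extinction_ann": self.mean_ann,
            "welch_t": self.t_statistic,
            "welch_p": self.p_value,
        }


def run_experiment(config: SimConfig, n_replicates: int, base_seed: int,
                   keep_logs: bool = True, progress=None) -> ExperimentSummary:
    """Run ``n_replicates`` per arm with disjoint seeds and compare the arms.

    GRN-arm seeds are ``base_seed .. base_seed+n-1`` and ANN-arm seeds
    ``base_seed+n .. base_seed+2n-1``, disjoint by construction.  The group
    comparison (Welch two-sample t-test on food-at-extinction) uses runs that
    actually went extinct.
    """
    if n_replicates < 2:
        raise ConfigError("need >= 2 replicates per arm for group statistics")
    rows = []
    logs: dict[str, list[RunLog]] = {"grn": [], "ann": []}
    for arm_index, arm in enumerate(("grn", "ann")):
        arm_cfg = config.replace(controller=arm)
        for i in range(n_replicates):
            seed = base_seed + arm_index * n_replicates + i
            log = run_simulation(arm_cfg, seed)
            if keep_logs:
                logs[arm].append(log)
            rows.append({"arm": arm, **log.summary()})
            if progress is not None:
                progress(arm, i, log)
    runs = pd.DataFrame(rows)
    grn_food = [float(v) for v in runs.query("arm == 'grn' and extinct").food_at_extinction]
    ann_food = [float(v) for v in runs.query("arm == 'ann' and extinct").food_at_extinction]
    if len(grn_food) >= 2 and len(ann_food) >= 2:
        comp = _metrics.compare_extinction_food(grn_food, ann_food)
        mean_grn, mean_ann = comp.mean_a, comp.mean_b
        t_stat, p_val = comp.t_statistic, comp.p_value
    else:  # too few extinct runs for a group comparison
        mean_grn = float(np.mean(grn_food)) if grn_food else float("nan")
        mean_ann = float(np.mean(ann_food)) if ann_food else float("nan")
        t_stat = p_val = float("nan")
    return ExperimentSummary(
        runs=runs, grn_food=grn_food, ann_food=ann_food,
        mean_grn=mean_grn, mean_ann=mean_ann,
        t_statistic=t_stat, p_value=p_val, logs=logs,
    )
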