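"""The 90x90 grid world: typed food sources, density-dependent regrowth, seasons.

Food lives on the same lattice as the robots.  Each source belongs to a type
with an *access threshold* (minimum robot energy required to consume it) and
an *energy content*.  Every step each source independently replicates into a
uniformly chosen neighbouring cell with probability
``r0 * max(0, 1 - k / K)`` where ``k`` is the number of other sources in its
radius-1 Moore neighbourhood — the denser the patch, the slower the growth.

Seasons are 100-step blocks cycling through a cost table: in harsher seasons
every robot pays extra energy for survival and movement.

The boundary is toroidal by default (configurable to bounded), so density
statistics carry no edge artifacts.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import FoodConfig, SeasonConfig, WorldConfig

__all__ = ["FoodType", "WorldGrid", "season_costs", "moore_sum"]


@dataclass(frozen=True)
class FoodType:
    """One food class: index, access threshold, delivered energy."""

    index: int
    access_threshold: float
    energy_content: float

    def __post_init__(self):
        if self.energy_content <= 0:
            raise ValueError("energy_content must be positive")


def moore_sum(grid: np.ndarray, radius: int, torus: bool) -> np.ndarray:
    """Per-cell sum of ``grid`` over the (2r+1)^2 Moore block centred on each cell."""
    if torus:
        acc = np.zeros_like(grid)
        for dx in range(-radius, radius + 1):
            for dy in range(-radius, radius + 1):
                acc += np.roll(np.roll(grid, dx, axis=0), dy, axis=1)
        return acc
    padded = np.pad(grid, radius, mode="constant")
    acc = np.zeros_like(grid)
    n, m = grid.shape
    for dx in range(2 * radius + 1):
        for dy in range(2 * radius + 1):
            acc += padded[dx : dx + n, dy : dy + m]
    return acc


class WorldGrid:
    """Toroidal (or bounded) square lattice holding food counts and robot occupancy.

    Food is stored as per-type integer count grids; robot occupancy as an
    integer count grid maintained by the engine.  All sensing is Chebyshev
    (Moore) neighbourhood based.
    """

    def __init__(self, wcfg: WorldConfig, fcfg: FoodConfig, rng: np.random.Generator):
        self.size = wcfg.size
        self.torus = wcfg.torus
        self.sensing_radius = wcfg.sensing_radius
        self.food_types = tuple(
            FoodType(i, t.threshold, t.energy) for i, t in enumerate(fcfg.types)
        )
        self.r0 = fcfg.r0
        self.K = fcfg.K
        self.reseed_rate = fcfg.reseed_rate
        self.restore_schedule = dict(fcfg.restore_schedule)
        self._initial_mix = np.array([t.initial for t in fcfg.types], dtype=float)
        self.food = np.zeros((len(self.food_types), self.size, self.size), dtype=np.int64)
        self.robot_count = np.zeros((self.size, self.size), dtype=np.int64)
        for ti, t in enumerate(fcfg.types):
            self._scatter(ti, t.initial, rng)

    # -- bookkeeping --------------------------------------------------------
    def _scatter(self, type_index: int, count: int, rng: np.random.Generator) -> None:
        if count <= 0:
            return
        cells = rng.integers(0, self.size, size=(count, 2))
        np.add.at(self.food[type_index], (cells[:, 0], cells[:, 1]), 1)

    def wrap(self, x: int, y: int) -> tuple[int, int]:
        if self.torus:
            return x % self.size, y % self.size
        return min(max(x, 0), self.size - 1), min(max(y, 0), self.size - 1)

    def in_bounds(self, x: int, y: int) -> bool:
        return 0 <= x < self.size and 0 <= y < self.size

    @property
    def food_total_grid(self) -> np.ndarray:
        return self.food.sum(axis=0)

    @property
    def total_food(self) -> int:
        return int(self.food.sum())

    @property
    def total_food_energy(self) -> float:
        return float(
            sum(self.food[t.index].sum() * t.energy_content for t in self.food_types)
        )

    # -- sensing ------------------------------------------------------------
    def neighbourhood(self, position: tuple[int, int], radius: int) -> tuple[int, int]:
        """(robot count, food count) in the Moore neighbourhood of ``position``.

        Counts cover every cell within Chebyshev distance <= radius including
        the focal cell, but the focal robot itself is excluded: if a robot
        stands at ``position`` one robot is subtracted, so the caller sees
        only *other* robots (co-located ones included).
        """
        x, y = position
        if radius < 1:
            raise ValueError("radius must be >= 1")
        if not self.in_bounds(x, y):
            raise ValueError(f"position {position} outside the {self.size}x{self.size} grid")
        robots = 0
        food = 0
        for dx in range(-radius, radius + 1):
            for dy in range(-radius, radius + 1):
                if self.torus:
                    cx, cy = (x + dx) % self.size, (y + dy) % self.size
                else:
                    cx, cy = x + dx, y + dy
                    if not self.in_bounds(cx, cy):
                        continue
                robots += int(self.robot_count[cx, cy])
                food += int(self.food[:, cx, cy].sum())
        if self.robot_count[x, y] > 0:
            robots -= 1
        return robots, food

    # -- dynamics -----------------------------------------------------------
    def grow_food(self, rng: np.random.Generator) -> np.ndarray:
        """Density-dependent replication of every food source.

        Each source spawns at most one offspring of its own type, into a
        uniformly chosen cell of its 8-cell surrounding neighbourhood, with
        probability ``r0 * max(0, 1 - k/K)`` where ``k`` counts the *other*
        sources within its radius-1 Moore block.  Food never decreases here.
        Returns the per-type spawn counts.
        """
        spawned = np.zeros(self.food.shape[0], dtype=np.int64)
        if self.r0 <= 0 or self.total_food == 0:
            return spawned
        total = self.food_total_grid
        block = moore_sum(total, 1, self.torus)
        offsets = _RING_OFFSETS
        for t in range(self.food.shape[0]):
            grid = self.food[t]
            cells = np.argwhere(grid > 0)
            if cells.size == 0:
                continue
            counts = grid[cells[:, 0], cells[:, 1]]
            k = block[cells[:, 0], cells[:, 1]] - 1  # other sources around each source
            p = self.r0 * np.maximum(0.0, 1.0 - k / self.K)
            births = rng.binomial(counts, p)
            for (cx, cy), b in zip(cells, births):
                for _ in range(int(b)):
                    dx, dy = offsets[rng.integers(0, len(offsets))]
                    nx, ny = cx + dx, cy + dy
                    if self.torus:
                        nx, ny = nx % self.size, ny % self.size
                    elif not self.in_bounds(nx, ny):
                        continue
                    self.food[t, nx, ny] += 1
                    spawned[t] += 1
        return spawned

    def reseed(self, rng: np.random.Generator) -> np.ndarray:
        """Background seed-bank influx: Poisson number of new sources per step,
        scattered uniformly, type mix following the initial proportions."""
        per_type = np.zeros(len(self.food_types), dtype=np.int64)
        if self.reseed_rate <= 0:
            return per_type
        count = int(rng.poisson(self.reseed_rate))
        if count == 0:
            return per_type
        mix = self._initial_mix
        if mix.sum() <= 0:
            mix = np.ones(len(self.food_types))
        per_type = rng.multinomial(count, mix / mix.sum()).astype(np.int64)
        for ti, c in enumerate(per_type):
            self._scatter(ti, int(c), rng)
        return per_type

    def restore_food(self, t: int, rng: np.random.Generator) -> np.ndarray:
        """Scheduled restoration: scatter the configured number of new sources.

        The type mix follows the initial per-type proportions.  Returns the
        per-type counts added (all zero when step ``t`` is unscheduled).
        """
        per_type = np.zeros(len(self.food_types), dtype=np.int64)
        count = self.restore_schedule.get(t, 0)
        if count <= 0:
            return per_type
        mix = self._initial_mix
        if mix.sum() <= 0:
            mix = np.ones(len(self.food_types))
        probs = mix / mix.sum()
        per_type = rng.multinomial(count, probs).astype(np.int64)
        for ti, c in enumerate(per_type):
            self._scatter(ti, int(c), rng)
        return per_type

    def best_accessible_food(self, x: int, y: int, energy: float) -> FoodType | None:
        """Highest-energy food source in the cell accessible at ``energy``."""
        best = None
        for t in sorted(self.food_types, key=lambda f: -f.energy_content):
            if self.food[t.index, x, y] > 0 and energy >= t.access_threshold:
                best = t
                break
        return best

    def remove_food(self, type_index: int, x: int, y: int) -> None:
        if self.food[type_index, x, y] <= 0:
            raise ValueError("no such food source to remove")
        self.food[type_index, x, y] -= 1


_RING_OFFSETS = tuple(
    (dx, dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1) if (dx, dy) != (0, 0)
)


def season_costs(t: int, scfg: SeasonConfig) -> tuple[float, float]:
    """(extra survival cost, extra movement cost) at timestep ``t``.

    Piecewise constant over ``length``-step blocks, cycling through the
    season table.
    """
    if t < 0:
        raise ValueError("timestep must be >= 0")
    idx = (t // scfg.length) % len(scfg.survival_costs)
    return scfg.survival_costs[idx], scfg.movement_costs[idx]
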