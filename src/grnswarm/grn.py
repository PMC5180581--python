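"""Agent-based GRN controller: the environment-activated slice of the genome.

The genome encodes the *full* regulatory network; at runtime only the part
switched on by current sensor inputs is instantiated, as a population of
*agents* — the gene products.  Three agent kinds mirror the three gene types:

* signalling agents translate active sensor channels into signal values;
* regulatory agents are expressed when a live agent's signature binds a
  regulatory gene's binding site (complement match within tolerance) and in
  turn activate or repress further genes;
* structural agents are expressed from structural genes bound by activating
  regulators and push output values to the robot's actuators.

Each agent carries a concentration ("dosage").  Per step the concentration
decays and is modulated by fitness feedback (the robot's net energy change);
an agent whose concentration falls below ``c_min`` is deleted that same step.
Each actuator's control value is the concentration-weighted mean of the
output values of the structural agents targeting it, so dosage directly
weights behavioural influence.

The controller never modifies the genome: deactivated genes remain encoded
and can be re-expressed when their environmental context returns.

Implementation note: for speed, the expressed network is compiled once per
genome into dense binding-quality matrices (``GenomeNetwork``), pruned to the
subnetwork reachable from sensor channels; per-step dynamics are then a
handful of small matrix-vector products over the concentration vector.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import GrnConfig, SensorConfig, GenomeConfig
from .genome import (
    ArtificialGenome, GeneLayout, GeneLocus, scan_genes,
    SIGNALLING, REGULATORY, STRUCTURAL, encode, decode,
)

__all__ = [
    "ACTUATORS", "CHANNELS", "Agent", "SensorReadings", "SensorVector",
    "ActuatorVector", "GenomeNetwork", "GRNState", "channel_signature",
    "channel_signatures", "encode_sensors", "activate_signalling",
    "transduce", "actuator_outputs", "update_concentrations", "controller_step",
    "build_network", "layout_from_config",
]

# Actuator channels, in fixed order.  move_dir is continuous (8-way heading);
# the remainder are gates compared against a firing threshold.
ACTUATORS = ("move_dir", "move", "eat", "attack", "defend", "replicate", "aggregate")
N_ACTUATORS = len(ACTUATORS)

# Sensor channels: external (neighbour robots, food in the robot's own cell,
# food elsewhere within sensing range) and internal (energy level, recent
# successful attacks / defences / replications / feedings, and an ultradian
# rhythm — a triangle wave over the robot's age that lets genomes express
# time-alternating behaviour such as move/feed cycles).
CHANNELS = ("neighbours", "food_here", "food", "energy", "attacks", "defences",
            "replications", "feedings", "rhythm")
N_CHANNELS = len(CHANNELS)


@dataclass(frozen=True)
class SensorReadings:
    """Raw per-step readings before bounded encoding."""

    n_robots: int = 0
    n_food_here: int = 0
    n_food: int = 0
    energy: float = 0.0
    attacks: float = 0.0
    defences: float = 0.0
    replications: float = 0.0
    feedings: float = 0.0
    age: int = 0


@dataclass(frozen=True)
class SensorVector:
    """Bounded [0, 1] channel values in ``CHANNELS`` order."""

    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.float32))
        if self.values.shape != (N_CHANNELS,):
            raise ValueError(f"expected {N_CHANNELS} channels")


@dataclass(frozen=True)
class ActuatorVector:
    """One bounded control value per actuator; neutral is 0 everywhere."""

    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.float32))
        if self.values.shape != (N_ACTUATORS,):
            raise ValueError(f"expected {N_ACTUATORS} actuators")

    def __getitem__(self, name: str) -> float:
        return float(self.values[ACTUATORS.index(name)])

    @classmethod
    def neutral(cls) -> "ActuatorVector":
        return cls(np.zeros(N_ACTUATORS, dtype=np.float32))


@dataclass(frozen=True)
class Agent:
    """A live gene product: introspection view of one network node."""

    kind: str
    locus: GeneLocus
    signature: str
    concentration: float
    actuator: int | None = None   # structural agents only
    value: float | None = None    # structural agents only


def channel_signature(channel: int, alphabet: str, length: int) -> str:
    """Deterministic, injective signature for a sensor channel.

    Channels are mapped onto codes by an affine step coprime with the code
    space, then written as base-``len(alphabet)`` digits.
    """
    A = len(alphabet)
    space = A ** length
    code = (37 * channel + 11) % space
    digits = []
    for _ in range(length):
        digits.append(alphabet[code % A])
        code //= A
    return "".join(reversed(digits))


def channel_signatures(alphabet: str, length: int) -> tuple[str, ...]:
    return tuple(channel_signature(k, alphabet, length) for k in range(N_CHANNELS))


def layout_from_config(gcfg: GenomeConfig) -> GeneLayout:
    return GeneLayout(
        promoter=gcfg.promoter,
        type_len=gcfg.type_len,
        binding_len=gcfg.binding_len,
        payload_len=gcfg.payload_len,
    )


def encode_sensors(readings: SensorReadings, cfg: SensorConfig) -> SensorVector:
    """Deterministic bounded encoding of raw readings onto [0, 1] channels."""
    cap = float(cfg.count_cap)
    ccap = float(cfg.counter_cap)
    vals = np.array(
        [
            min(max(readings.n_robots, 0), cap) / cap,
            min(max(readings.n_food_here, 0), cfg.food_here_cap) / cfg.food_here_cap,
            min(max(readings.n_food, 0), cap) / cap,
            min(max(readings.energy, 0.0), cfg.energy_scale) / cfg.energy_scale,
            min(max(readings.attacks, 0.0), ccap) / ccap,
            min(max(readings.defences, 0.0), ccap) / ccap,
            min(max(readings.replications, 0.0), ccap) / ccap,
            min(max(readings.feedings, 0.0), ccap) / ccap,
            _triangle(readings.age, cfg.rhythm_period),
        ],
        dtype=np.float32,
    )
    return SensorVector(vals)


def _triangle(age: int, period: int) -> float:
    """Symmetric 0 -> 1 -> 0 wave over ``period`` steps; 0 at age 0."""
    frac = (age % period) / period
    return 2.0 * frac if frac < 0.5 else 2.0 * (1.0 - frac)


class GenomeNetwork:
    """Compiled binding structure of one genome, pruned to the sensor-reachable part.

    ``quality[i, j]`` is the graded match strength ``(L_b - mismatches)/L_b``
    with which product *i*'s signature binds gene *j*'s site (zero beyond the
    mismatch tolerance).  Activation is routed signalling -> regulatory ->
    (regulatory | structural); repressor regulators block rather than route.
    """

    __slots__ = (
        "_genome", "_layout", "_keep", "_loci", "kinds", "repressor",
        "actuator", "value", "chan_q", "va", "ma", "n",
        "rep_idx", "struct_idx", "struct_act", "struct_val",
        "route_indptr", "route_indices", "route_data",
        "block_indptr", "block_indices",
        "_route_dense", "_block_dense",
    )

    def __init__(self, genome: ArtificialGenome, gcfg: GenomeConfig, grn_cfg: GrnConfig):
        from .genome import scan_arrays

        layout = layout_from_config(gcfg)
        self._genome = genome
        self._layout = layout
        self._loci = None
        arrs = scan_arrays(genome, layout)
        alphabet = genome.alphabet
        A = len(alphabet)
        Lb = layout.binding_len
        n_all = len(arrs["start"])
        if n_all == 0:
            self._empty()
            return

        kinds = (arrs["type_value"] % 3).astype(np.int8)
        sites = arrs["sites"]
        pay = arrs["payloads"]
        sigs = pay[:, :Lb]
        wiring = pay[:, Lb].astype(np.int64) * A + pay[:, Lb + 1]
        # output value: sign from one payload character, magnitude in
        # [0.5, 1] from the next — structural products push decisively
        # rather than hovering near neutral
        sign = np.where(pay[:, Lb + 2] >= (A + 1) // 2, 1.0, -1.0)
        mag = 0.5 + 0.5 * pay[:, Lb + 3].astype(np.float64) / (A - 1)
        value = sign * mag
        repressor = (kinds == 1) & (wiring % 4 == grn_cfg.repressor_code)
        actuator = wiring % N_ACTUATORS

        comp = (A - 1 - sites).astype(np.uint8)  # complement of each site
        tol = gcfg.match_tolerance

        # product-signature x binding-site mismatch counts, accumulated as
        # per-position outer comparisons (avoids a large 3-D temporary)
        mism = np.zeros((n_all, n_all), dtype=np.uint8)
        for k in range(Lb):
            mism += sigs[:, k : k + 1] != comp[None, :, k]
        bound = mism <= tol

        # sensor channel signatures binding signalling-gene sites
        ch_sigs = np.stack([encode(s, alphabet) for s in channel_signatures(alphabet, Lb)])
        ch_mism = (ch_sigs[:, None, :] != comp[None, :, :]).sum(axis=2, dtype=np.int16)
        ch_quality = np.where((ch_mism <= tol) & (kinds[None, :] == 0), (Lb - ch_mism) / Lb, 0.0)

        # reachability from channel-matched signalling genes through routing
        # and blocking edges; unreachable genes can never be expressed
        routable_src = (kinds == 0) | ((kinds == 1) & ~repressor)
        adj = (bound & routable_src[:, None] & (kinds[None, :] > 0)).astype(np.float32)
        reach = ch_quality.sum(axis=0) > 0
        frontier = reach.astype(np.float32)
        while True:
            nxt = ((frontier @ adj) > 0) & ~reach
            if not nxt.any():
                break
            reach |= nxt
            frontier = nxt.astype(np.float32)
        keep = np.flatnonzero(reach)
        if keep.size == 0:
            self._empty()
            return

        self._keep = keep
        self.n = keep.size
        self.kinds = kinds[keep]
        self.repressor = repressor[keep]
        self.actuator = actuator[keep]
        self.value = value[keep]
        self.chan_q = np.ascontiguousarray(ch_quality[:, keep], dtype=np.float32)
        m = np.ascontiguousarray(mism[keep][:, keep])
        b = m <= tol
        q = np.where(b, (Lb - m.astype(np.float32)) / Lb, np.float32(0.0))
        src_act = (self.kinds == 0) | ((self.kinds == 1) & ~self.repressor)
        # signalling routes only into regulatory genes; activating regulators
        # route into regulatory and structural genes
        tgt_ok = np.where(self.kinds[None, :] == 1, True, (self.kinds[None, :] == 2)
                          & (self.kinds[:, None] == 1))
        route_mask = src_act[:, None] & tgt_ok & b & (self.kinds[None, :] > 0)
        # row-compressed (CSR) storage: binding is ~10% dense, and the
        # per-step kernel touches only nonzero routes of live agents
        rows, cols = np.nonzero(route_mask)
        self.route_indptr = np.zeros(self.n + 1, dtype=np.int64)
        np.add.at(self.route_indptr, rows + 1, 1)
        np.cumsum(self.route_indptr, out=self.route_indptr)
        self.route_indices = cols.astype(np.int64)
        self.route_data = q[rows, cols].astype(np.float32)
        self.rep_idx = np.flatnonzero(self.repressor).astype(np.int64)
        block_mask = b[self.rep_idx] & (self.kinds[None, :] > 0)
        brows, bcols = np.nonzero(block_mask)
        self.block_indptr = np.zeros(len(self.rep_idx) + 1, dtype=np.int64)
        np.add.at(self.block_indptr, brows + 1, 1)
        np.cumsum(self.block_indptr, out=self.block_indptr)
        self.block_indices = bcols.astype(np.int64)
        va = np.zeros((self.n, N_ACTUATORS), dtype=np.float32)
        ma = np.zeros((self.n, N_ACTUATORS), dtype=np.float32)
        structs = np.flatnonzero(self.kinds == 2)
        va[structs, self.actuator[structs]] = self.value[structs]
        ma[structs, self.actuator[structs]] = 1.0
        self.va = va
        self.ma = ma
        self.struct_idx = structs.astype(np.int64)
        self.struct_act = self.actuator[structs].astype(np.int64)
        self.struct_val = self.value[structs].astype(np.float32)
        self._route_dense = None
        self._block_dense = None

    @property
    def route_q(self) -> np.ndarray:
        """Dense routing-quality matrix (reference path and tests)."""
        if self._route_dense is None:
            dense = np.zeros((self.n, self.n), dtype=np.float32)
            for i in range(self.n):
                lo, hi = self.route_indptr[i], self.route_indptr[i + 1]
                dense[i, self.route_indices[lo:hi]] = self.route_data[lo:hi]
            self._route_dense = dense
        return self._route_dense

    @property
    def block(self) -> np.ndarray:
        """Dense repressor-blocking matrix (reference path and tests)."""
        if self._block_dense is None:
            dense = np.zeros((self.n, self.n), dtype=np.float32)
            for r, i in enumerate(self.rep_idx):
                lo, hi = self.block_indptr[r], self.block_indptr[r + 1]
                dense[i, self.block_indices[lo:hi]] = 1.0
            self._block_dense = dense
        return self._block_dense

    @property
    def loci(self) -> list[GeneLocus]:
        """Introspection view: the (kept) gene loci backing this network."""
        if self._loci is None:
            full = scan_genes(self._genome, self._layout)
            self._loci = [full[i] for i in self._keep]
        return self._loci

    def _empty(self) -> None:
        self._keep = np.empty(0, dtype=np.int64)
        self._loci = []
        self.n = 0
        self.kinds = np.zeros(0, dtype=np.int8)
        self.repressor = np.zeros(0, dtype=bool)
        self.actuator = np.zeros(0, dtype=np.int64)
        self.value = np.zeros(0)
        self.chan_q = np.zeros((N_CHANNELS, 0), dtype=np.float32)
        self.va = np.zeros((0, N_ACTUATORS), dtype=np.float32)
        self.ma = np.zeros((0, N_ACTUATORS), dtype=np.float32)
        self.rep_idx = np.zeros(0, dtype=np.int64)
        self.struct_idx = np.zeros(0, dtype=np.int64)
        self.struct_act = np.zeros(0, dtype=np.int64)
        self.struct_val = np.zeros(0, dtype=np.float32)
        self.route_indptr = np.zeros(1, dtype=np.int64)
        self.route_indices = np.zeros(0, dtype=np.int64)
        self.route_data = np.zeros(0, dtype=np.float32)
        self.block_indptr = np.zeros(1, dtype=np.int64)
        self.block_indices = np.zeros(0, dtype=np.int64)
        self._route_dense = np.zeros((0, 0), dtype=np.float32)
        self._block_dense = np.zeros((0, 0), dtype=np.float32)


def build_network(genome: ArtificialGenome, gcfg: GenomeConfig, grn_cfg: GrnConfig) -> GenomeNetwork:
    """Compile (and cache per genome) the runtime network."""
    key = ("network", layout_from_config(gcfg), gcfg.match_tolerance, grn_cfg.repressor_code)
    net = genome._cache.get(key)
    if net is None:
        net = GenomeNetwork(genome, gcfg, grn_cfg)
        genome._cache[key] = net
    return net


class GRNState:
    """Mutable per-robot controller state: the live agent concentrations."""

    __slots__ = ("network", "c", "_out")

    def __init__(self, network: GenomeNetwork):
        self.network = network
        self.c = np.zeros(network.n, dtype=np.float32)
        self._out = np.zeros(N_ACTUATORS, dtype=np.float32)

    def fast_step(self, sensor_values: np.ndarray, feedback: float,
                  cfg: GrnConfig) -> np.ndarray:
        """Compiled equivalent of :func:`controller_step`; returns raw outputs.

        Falls back to the numpy reference path when numba is unavailable.
        """
        from ._fast import HAVE_NUMBA, grn_step_kernel

        net = self.network
        if net.n == 0:
            self._out[:] = 0.0
            return self._out
        if not HAVE_NUMBA:
            out, _ = controller_step(SensorVector(sensor_values), self, feedback, cfg)
            return out.values
        sgn = 0.0 if feedback == 0 else (1.0 if feedback > 0 else -1.0)
        factor = (1.0 - cfg.decay) * (
            1.0 + cfg.feedback_gain * sgn * min(abs(feedback) / cfg.feedback_scale, 1.0)
        )
        grn_step_kernel(
            self.c, net.chan_q,
            net.route_indptr, net.route_indices, net.route_data,
            net.rep_idx, net.block_indptr, net.block_indices,
            net.struct_idx, net.struct_act, net.struct_val,
            np.asarray(sensor_values, dtype=np.float32),
            np.float32(cfg.c_init), np.float32(cfg.c_max), np.float32(cfg.c_min),
            np.float32(factor), cfg.cascade_rounds, self._out,
        )
        return self._out

    @property
    def agents(self) -> list[Agent]:
        net = self.network
        out = []
        for i in np.flatnonzero(self.c > 0):
            kind = ("signalling", "regulatory", "structural")[net.kinds[i]]
            locus = net.loci[i]
            out.append(
                Agent(
                    kind=kind,
                    locus=locus,
                    signature=locus.payload[: len(locus.binding_site)],
                    concentration=float(self.c[i]),
                    actuator=int(net.actuator[i]) if kind == "structural" else None,
                    value=float(net.value[i]) if kind == "structural" else None,
                )
            )
        return out

    @property
    def total_concentration(self) -> float:
        return float(self.c.sum())

    # -- checkpointing ------------------------------------------------------
    def to_text(self) -> str:
        """Structured-text snapshot of the live agent concentrations.

        The genome itself is persisted separately (``save_genome``); a state
        restored against the same genome and configuration resumes exactly.
        """
        live = np.flatnonzero(self.c > 0)
        lines = ["#grnswarm-grn-state n=%d" % self.network.n]
        lines += [f"{int(i)} {float(self.c[i]):.8g}" for i in live]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str, network: GenomeNetwork) -> "GRNState":
        lines = [l for l in text.splitlines() if l.strip()]
        if not lines or not lines[0].startswith("#grnswarm-grn-state"):
            raise ValueError("not a controller-state snapshot")
        n = int(lines[0].split("n=")[1])
        if n != network.n:
            raise ValueError("snapshot does not match the compiled network size")
        state = cls(network)
        for line in lines[1:]:
            idx, val = line.split()
            state.c[int(idx)] = np.float32(val)
        return state


def _activate_signalling_values(sensors: SensorVector, state: GRNState,
                                cfg: GrnConfig) -> np.ndarray | None:
    """Fast path of :func:`activate_signalling`: returns the expressed mask or None."""
    net = state.network
    if net.n == 0:
        return None
    lvl = sensors.values @ net.chan_q
    nz = lvl > 0
    if not nz.any():
        return None
    lvl = np.where(nz, np.minimum(np.maximum(lvl, cfg.c_init), cfg.c_max), 0.0)
    state.c = np.maximum(state.c, lvl.astype(np.float32))
    return nz


def activate_signalling(sensors: SensorVector, state: GRNState, cfg: GrnConfig) -> list[Agent]:
    """Express signalling agents for every (active channel x matching gene).

    The expression level is channel magnitude x match quality, floored at
    ``c_init``; re-expression of a live agent adds to its concentration,
    capped at ``c_max``.  Returns the introspection view of the expressed
    signalling agents.
    """
    nz = _activate_signalling_values(sensors, state, cfg)
    if nz is None:
        return []
    net = state.network
    loci = net.loci
    return [
        Agent(
            kind=SIGNALLING,
            locus=loci[i],
            signature=loci[i].payload[: len(loci[i].binding_site)],
            concentration=float(state.c[i]),
        )
        for i in np.flatnonzero(nz)
    ]


def transduce(state: GRNState, cfg: GrnConfig) -> GRNState:
    """One round of signal transduction through the expressed network.

    Live signalling/activating-regulatory agents express the genes they
    bind.  The expression level saturates with the total bound activator
    drive, ``S / (1 + S)`` with ``S`` the sum of binder concentration x
    match quality — dosage tracks regulatory occupancy instead of
    integrating it, so concentrations stay on [0, 1] and remain sensitive
    to the sensor context.  Expression *refreshes* a live agent (concentration
    rises to the drive level, never above ``c_max``); a gene bound by any
    live repressor is blocked this step regardless of co-binding activators.
    """
    net = state.network
    if net.n == 0:
        return state
    c = state.c
    if not c.any():
        return state
    blocked = ((c > 0).astype(np.float32) @ net.block) > 0
    s = c @ net.route_q
    level = s / (1.0 + s)
    level[blocked] = 0.0
    state.c = np.maximum(c, np.minimum(level, cfg.c_max).astype(np.float32))
    return state


def actuator_outputs(state: GRNState) -> ActuatorVector:
    """Concentration-weighted mean of structural agents' output values, per actuator."""
    net = state.network
    if net.n == 0:
        return ActuatorVector.neutral()
    c = state.c
    den = c @ net.ma
    num = c @ net.va
    out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0).astype(np.float32)
    return ActuatorVector(out)


def update_concentrations(state: GRNState, feedback: float, cfg: GrnConfig) -> GRNState:
    """Decay + fitness modulation; agents below ``c_min`` do not survive the update.

    c <- c * (1 - d) * (1 + beta * sign(feedback) * min(|feedback|/F, 1))
    """
    if state.network.n == 0:
        return state
    sgn = 0.0 if feedback == 0 else (1.0 if feedback > 0 else -1.0)
    factor = (1.0 - cfg.decay) * (
        1.0 + cfg.feedback_gain * sgn * min(abs(feedback) / cfg.feedback_scale, 1.0)
    )
    c = state.c * np.float32(factor)
    c[c < cfg.c_min] = 0.0
    state.c = c
    return state


def controller_step(
    sensors: SensorVector,
    state: GRNState,
    feedback: float,
    cfg: GrnConfig,
) -> tuple[ActuatorVector, GRNState]:
    """One controller tick: sense -> express -> transduce -> act -> update dosage.

    Transduction runs ``cascade_rounds`` times so a fresh sensor signal can
    propagate signalling -> regulatory -> structural within a single
    behavioural step.
    """
    _activate_signalling_values(sensors, state, cfg)
    for _ in range(cfg.cascade_rounds):
        transduce(state, cfg)
    out = actuator_outputs(state)
    update_concentrations(state, feedback, cfg)
    return out, state
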