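"""ANN reference controller: fixed-topology feed-forward net with per-edge RL.

The baseline against which the GRN controller is compared.  The network maps
the same sensor channels to the same actuator channels (sensors -> hidden ->
actuators, tanh squashing, no biases so the all-zero input is neutral).
Weights are heritable: an ANN robot's "genome" is the flat real vector of
edge weights, mutated with Gaussian noise at replication.

Within a lifetime the only plasticity is reward-modulated per-edge learning:
each edge keeps an eligibility trace of its recent pre x post activity and is
nudged along trace x reward; structural rewiring is restricted to *zeroing* —
an edge whose signal contribution stays below a threshold for ``zero_window``
consecutive steps is set to zero and stays zero for the rest of the robot's
life (replication re-randomizes zeroed edges).
"""
from __future__ import annotations

import numpy as np

from .config import AnnConfig
from .grn import ActuatorVector, N_ACTUATORS, N_CHANNELS, SensorVector

__all__ = ["AnnController", "ann_forward", "ann_feedback"]


class AnnController:
    """Per-robot ANN state: weights, masks, eligibility traces, idle counters."""

    __slots__ = ("cfg", "w1", "w2", "m1", "m2", "e1", "e2", "i1", "i2", "_x", "_h", "_y")

    def __init__(self, cfg: AnnConfig, w1: np.ndarray, w2: np.ndarray):
        h = cfg.hidden
        if w1.shape != (h, N_CHANNELS) or w2.shape != (N_ACTUATORS, h):
            raise ValueError("weight shapes do not match the topology")
        self.cfg = cfg
        self.w1 = w1.astype(np.float32).copy()
        self.w2 = w2.astype(np.float32).copy()
        self.m1 = np.ones_like(self.w1, dtype=bool)   # True = edge still alive
        self.m2 = np.ones_like(self.w2, dtype=bool)
        self.e1 = np.zeros_like(self.w1)
        self.e2 = np.zeros_like(self.w2)
        self.i1 = np.zeros(self.w1.shape, dtype=np.int32)  # consecutive idle steps
        self.i2 = np.zeros(self.w2.shape, dtype=np.int32)
        self._x = np.zeros(N_CHANNELS, dtype=np.float32)
        self._h = np.zeros(h, dtype=np.float32)
        self._y = np.zeros(N_ACTUATORS, dtype=np.float32)

    # -- construction -------------------------------------------------------
    @classmethod
    def random(cls, cfg: AnnConfig, rng: np.random.Generator) -> "AnnController":
        w1 = rng.uniform(-1.0, 1.0, size=(cfg.hidden, N_CHANNELS))
        w2 = rng.uniform(-1.0, 1.0, size=(N_ACTUATORS, cfg.hidden))
        return cls(cfg, w1, w2)

    def spawn_child(self, rng: np.random.Generator) -> "AnnController":
        """Heritable replication: Gaussian weight noise; zeroed edges re-randomized."""
        s = self.cfg.mutation_sigma

        def inherit(w: np.ndarray, mask: np.ndarray) -> np.ndarray:
            child = w + rng.normal(0.0, s, size=w.shape)
            fresh = rng.uniform(-1.0, 1.0, size=w.shape)
            return np.where(mask, child, fresh)

        return AnnController(self.cfg, inherit(self.w1, self.m1), inherit(self.w2, self.m2))

    # -- runtime ------------------------------------------------------------
    def forward(self, sensors: SensorVector) -> ActuatorVector:
        """Deterministic feed-forward pass; records activities for the RL update."""
        x = sensors.values
        h = np.tanh(self.w1 @ x)
        y = np.tanh(self.w2 @ h)
        self._x, self._h, self._y = x, h, y
        return ActuatorVector(y)

    def feedback(self, reward: float) -> None:
        """Reward-modulated eligibility update plus idle-edge zeroing.

        ``reward`` is the robot's net energy change last step, squashed to
        [-1, 1].  Eligibility accumulates post x pre activity; weights move
        by ``eta * reward * trace``.  An edge whose absolute signal
        contribution |w * pre| stays below ``zero_threshold`` for
        ``zero_window`` consecutive steps is zeroed permanently (until
        replication re-randomizes it).
        """
        cfg = self.cfg
        r = float(np.tanh(reward))
        lam = cfg.trace_decay
        self.e1 = lam * self.e1 + np.outer(self._h, self._x)
        self.e2 = lam * self.e2 + np.outer(self._y, self._h)
        if r != 0.0:
            self.w1 += (cfg.eta * r) * self.e1
            self.w2 += (cfg.eta * r) * self.e2
        # contribution-based zeroing (rewiring restricted to zeroing)
        c1 = np.abs(self.w1) * np.abs(self._x)[None, :]
        c2 = np.abs(self.w2) * np.abs(self._h)[None, :]
        self.i1 = np.where(c1 < cfg.zero_threshold, self.i1 + 1, 0)
        self.i2 = np.where(c2 < cfg.zero_threshold, self.i2 + 1, 0)
        self.m1 &= self.i1 < cfg.zero_window
        self.m2 &= self.i2 < cfg.zero_window
        self.w1 *= self.m1
        self.w2 *= self.m2

    @property
    def live_edges(self) -> int:
        return int(self.m1.sum() + self.m2.sum())


def ann_forward(controller: AnnController, sensors: SensorVector) -> ActuatorVector:
    return controller.forward(sensors)


def ann_feedback(controller: AnnController, reward: float) -> AnnController:
    controller.feedback(reward)
    return controller
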