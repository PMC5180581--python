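"""Optional numba-compiled kernel for the per-robot GRN update.

Numerically equivalent (up to float summation order) to the reference numpy
path in :mod:`grnswarm.grn`; the engine uses it when numba is importable and
falls back to the numpy path otherwise.  Tests assert the two paths agree.

The routing and blocking structures arrive in row-compressed (CSR) form:
binding is sparse, and only the nonzero routes of live agents are touched.
"""
from __future__ import annotations

import numpy as np

try:  # pragma: no cover - environment dependent
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn
        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True, fastmath=False)
def grn_step_kernel(
    c: np.ndarray,             # (n,) float32 concentrations, updated in place
    chan_q: np.ndarray,        # (C, n) channel->signalling quality
    route_indptr: np.ndarray,  # (n+1,) CSR row pointers for activation routing
    route_indices: np.ndarray,
    route_data: np.ndarray,
    rep_idx: np.ndarray,       # (R,) indices of repressor nodes
    block_indptr: np.ndarray,  # (R+1,) CSR row pointers for blocking targets
    block_indices: np.ndarray,
    struct_idx: np.ndarray,    # (S,) structural node indices
    struct_act: np.ndarray,    # (S,) actuator index per structural node
    struct_val: np.ndarray,    # (S,) output value per structural node
    sensors: np.ndarray,       # (C,) float32 channel values
    c_init: float,
    c_max: float,
    c_min: float,
    factor: float,             # decay x feedback multiplier
    rounds: int,               # transduction rounds per step
    out: np.ndarray,           # (A,) float32 actuator outputs, filled
) -> None:
    n = c.shape[0]
    C = chan_q.shape[0]
    A = out.shape[0]
    # signalling expression from active sensor channels (refresh semantics)
    for j in range(n):
        lvl = np.float32(0.0)
        for k in range(C):
            lvl += sensors[k] * chan_q[k, j]
        if lvl > 0.0:
            if lvl < c_init:
                lvl = np.float32(c_init)
            if lvl > c_max:
                lvl = np.float32(c_max)
            if lvl > c[j]:
                c[j] = lvl
    # transduction: saturating drive from live activators, vetoed by live
    # repressors; several rounds let a fresh signal cross the cascade
    expr = np.zeros(n, dtype=np.float32)
    for _ in range(rounds):
        for j in range(n):
            expr[j] = 0.0
        for i in range(n):
            ci = c[i]
            if ci > 0.0:
                for p in range(route_indptr[i], route_indptr[i + 1]):
                    expr[route_indices[p]] += ci * route_data[p]
        for r in range(rep_idx.shape[0]):
            if c[rep_idx[r]] > 0.0:
                for p in range(block_indptr[r], block_indptr[r + 1]):
                    expr[block_indices[p]] = np.float32(0.0)
        for j in range(n):
            if expr[j] > 0.0:
                lvl = expr[j] / (np.float32(1.0) + expr[j])
                if lvl > c_max:
                    lvl = np.float32(c_max)
                if lvl > c[j]:
                    c[j] = lvl
    # actuator outputs: concentration-weighted mean over structural agents
    den = np.zeros(A, dtype=np.float32)
    for a in range(A):
        out[a] = 0.0
    for s in range(struct_idx.shape[0]):
        ci = c[struct_idx[s]]
        if ci > 0.0:
            a = struct_act[s]
            out[a] += ci * struct_val[s]
            den[a] += ci
    for a in range(A):
        out[a] = out[a] / den[a] if den[a] > 0.0 else np.float32(0.0)
    # decay + feedback, deletion below the survival floor
    for j in range(n):
        cj = c[j] * factor
        c[j] = cj if cj >= c_min else np.float32(0.0)
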