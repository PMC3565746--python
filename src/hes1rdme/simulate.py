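"""Exact stochastic sampling of the reaction–diffusion master equation.

Two samplers are provided.

``simulate_nsm``
    The next subvolume method (NSM): an event-driven, statistically exact
    sampler of the RDME.  Every voxel keeps the sum of its local reaction
    propensities plus the total outbound diffusion rate; the next event time
    of each voxel lives in an indexed binary min-heap; the earliest voxel
    fires; reaction versus diffusion is chosen proportionally to the two
    group sums, the specific channel / species / destination proportionally
    within the group; the fired (and, for a hop, the receiving) voxel's rates
    are recomputed and fresh exponential waiting times are drawn.  Re-drawing
    after every state change is statistically exact by memorylessness and
    keeps the bookkeeping simple; heap updates make event dispatch
    O(log V).  The event loop is compiled with numba.

``ssa_wellmixed``
    Gillespie's direct method on the same seven channels with no spatial
    structure, written independently of the NSM code path so it can serve as
    an oracle: on a single-voxel mesh the two samplers target identical
    processes and their sampled distributions must agree.

Trajectories record whole-cell copy-number totals on a fixed time grid
(state between events is piecewise constant, so grid sampling is exact).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numba import njit

from .geometry import JumpRateTable, Mesh
from .model import MRNA, PF, PO, PROTEIN, SPECIES, ParameterSet, ReactionSystem, SystemState

__all__ = ["Trajectory", "simulate_nsm", "ssa_wellmixed", "SimulationError"]


class SimulationError(RuntimeError):
    """Internal simulator failure (negative count or invalid propensity)."""


# ---------------------------------------------------------------------------
# indexed binary min-heap + event loop (numba)
# ---------------------------------------------------------------------------


@njit(inline="always")
def _sift_up(ht, hv, pos, i):
    while i > 0:
        p = (i - 1) // 2
        if ht[i] < ht[p]:
            ht[i], ht[p] = ht[p], ht[i]
            hv[i], hv[p] = hv[p], hv[i]
            pos[hv[i]] = i
            pos[hv[p]] = p
            i = p
        else:
            break


@njit(inline="always")
def _sift_down(ht, hv, pos, i, n):
    while True:
        l = 2 * i + 1
        r = l + 1
        m = i
        if l < n and ht[l] < ht[m]:
            m = l
        if r < n and ht[r] < ht[m]:
            m = r
        if m == i:
            break
        ht[i], ht[m] = ht[m], ht[i]
        hv[i], hv[m] = hv[m], hv[i]
        pos[hv[i]] = i
        pos[hv[m]] = m
        i = m


@njit(inline="always")
def _voxel_rates(x, v, c, react1, react2, qout, out):
    """Reaction-group and diffusion-group total rates of voxel v."""
    R = c.shape[1]
    S = qout.shape[0]
    rsum = 0.0
    for r in range(R):
        cv = c[v, r]
        if cv > 0.0:
            f = float(x[v, react1[r]])
            if react2[r] >= 0:
                f *= float(x[v, react2[r]])
            rsum += cv * f
    dsum = 0.0
    for s in range(S):
        if x[v, s] > 0 and qout[s, v] > 0.0:
            dsum += float(x[v, s]) * qout[s, v]
    out[0] = rsum
    out[1] = dsum


@njit
def _nsm_loop(
    x,  # (V, S) int64, modified in place
    t_end,
    record_times,  # (T,) float64, strictly increasing
    stoich,  # (R, S) int64
    react1,  # (R,) int64
    react2,  # (R,) int64
    c,  # (V, R) float64 per-voxel rate constants
    edge_rates,  # (S, E) float64
    indptr,  # (V+1,) int64
    indices,  # (E,) int64
    qout,  # (S, V) float64 total outbound rate constant
    snapshot_times,  # (K,) float64
    seed,
):
    np.random.seed(seed)
    V, S = x.shape
    R = stoich.shape[0]
    T = record_times.shape[0]
    K = snapshot_times.shape[0]

    totals = np.zeros(S, dtype=np.int64)
    for v in range(V):
        for s in range(S):
            totals[s] += x[v, s]

    rec = np.zeros((T, S), dtype=np.int64)
    snaps = np.zeros((K, V, S), dtype=np.int64)
    ri = 0
    ki = 0

    # per-voxel group sums and heap
    rsum = np.zeros(V)
    dsum = np.zeros(V)
    ht = np.empty(V)
    hv = np.empty(V, dtype=np.int64)
    pos = np.empty(V, dtype=np.int64)
    tmp = np.zeros(2)
    for v in range(V):
        _voxel_rates(x, v, c, react1, react2, qout, tmp)
        rsum[v] = tmp[0]
        dsum[v] = tmp[1]
        tot = tmp[0] + tmp[1]
        ht[v] = np.random.exponential(1.0 / tot) if tot > 0.0 else np.inf
        hv[v] = v
        pos[v] = v
    for i in range(V // 2 - 1, -1, -1):
        _sift_down(ht, hv, pos, i, V)

    n_events = 0
    while True:
        t = ht[0]
        v = hv[0]
        if t >= t_end:
            break
        # flush samples falling strictly before this event
        while ri < T and record_times[ri] < t:
            for s in range(S):
                rec[ri, s] = totals[s]
            ri += 1
        while ki < K and snapshot_times[ki] < t:
            for vv in range(V):
                for s in range(S):
                    snaps[ki, vv, s] = x[vv, s]
            ki += 1

        total = rsum[v] + dsum[v]
        u = np.random.random() * total
        other = -1
        if u < rsum[v]:
            # reaction event: pick the channel
            acc = 0.0
            hit = R - 1
            for r in range(R):
                cv = c[v, r]
                if cv > 0.0:
                    f = float(x[v, react1[r]])
                    if react2[r] >= 0:
                        f *= float(x[v, react2[r]])
                    acc += cv * f
                    if u < acc:
                        hit = r
                        break
            for s in range(S):
                d = stoich[hit, s]
                if d != 0:
                    x[v, s] += d
                    totals[s] += d
                    if x[v, s] < 0:
                        return rec, snaps, -1, n_events
        else:
            # diffusion event: pick species, then destination edge
            u -= rsum[v]
            sp = -1
            for s in range(S):
                if x[v, s] > 0 and qout[s, v] > 0.0:
                    w = float(x[v, s]) * qout[s, v]
                    if u < w:
                        sp = s
                        break
                    u -= w
            if sp < 0:  # numerical slack: attribute to last eligible species
                for s in range(S - 1, -1, -1):
                    if x[v, s] > 0 and qout[s, v] > 0.0:
                        sp = s
                        break
                if sp < 0:
                    return rec, snaps, -2, n_events
            xs = float(x[v, sp])
            dest = -1
            for e in range(indptr[v], indptr[v + 1]):
                w = xs * edge_rates[sp, e]
                if u < w:
                    dest = indices[e]
                    break
                u -= w
            if dest < 0:
                dest = indices[indptr[v + 1] - 1]
            x[v, sp] -= 1
            x[dest, sp] += 1
            other = dest

        n_events += 1
        # recompute rates and redraw next-event times for affected voxels
        _voxel_rates(x, v, c, react1, react2, qout, tmp)
        rsum[v] = tmp[0]
        dsum[v] = tmp[1]
        tot = tmp[0] + tmp[1]
        nt = t + np.random.exponential(1.0 / tot) if tot > 0.0 else np.inf
        i = pos[v]
        ht[i] = nt
        _sift_up(ht, hv, pos, i)
        _sift_down(ht, hv, pos, i, V)
        if other >= 0:
            _voxel_rates(x, other, c, react1, react2, qout, tmp)
            rsum[other] = tmp[0]
            dsum[other] = tmp[1]
            tot = tmp[0] + tmp[1]
            nt = t + np.random.exponential(1.0 / tot) if tot > 0.0 else np.inf
            i = pos[other]
            ht[i] = nt
            _sift_up(ht, hv, pos, i)
            _sift_down(ht, hv, pos, i, V)

    # constant tail after the last event
    while ri < T:
        for s in range(S):
            rec[ri, s] = totals[s]
        ri += 1
    while ki < K:
        for vv in range(V):
            for s in range(S):
                snaps[ki, vv, s] = x[vv, s]
        ki += 1
    return rec, snaps, 0, n_events


# ---------------------------------------------------------------------------
# trajectory container
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Whole-cell copy-number totals sampled on a fixed time grid."""

    times: np.ndarray  # (T,) minutes
    totals: np.ndarray  # (T, S) int64, column order == SPECIES
    seed: int
    params: dict = field(default_factory=dict)
    snapshots: Optional[np.ndarray] = None  # (K, V, S)
    snapshot_times: Optional[np.ndarray] = None
    n_events: int = 0

    @property
    def mrna(self) -> np.ndarray:
        return self.totals[:, MRNA]

    @property
    def protein(self) -> np.ndarray:
        return self.totals[:, PROTEIN]

    @property
    def pf(self) -> np.ndarray:
        return self.totals[:, PF]

    @property
    def po(self) -> np.ndarray:
        return self.totals[:, PO]

    def value_at(self, t: float, species: int = PROTEIN) -> int:
        """Copy number at time ``t`` (nearest recorded sample)."""
        if not (self.times[0] <= t <= self.times[-1]):
            raise ValueError(f"t={t} outside trajectory span")
        return int(self.totals[np.argmin(np.abs(self.times - t)), species])

    def to_csv(self, path) -> None:
        """CSV with JSON-encoded parameters and seed in ``#`` header lines."""
        header = {"seed": int(self.seed), "params": self.params}
        with open(path, "w") as fh:
            fh.write("# " + json.dumps(header) + "\n")
            fh.write("time_min,mRNA_total,protein_total,Pf,Po\n")
            for i, t in enumerate(self.times):
                m, p, pf, po = self.totals[i]
                fh.write(f"{t:g},{m},{p},{pf},{po}\n")

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        meta = {"seed": -1, "params": {}}
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    try:
                        meta = json.loads(line[1:])
                    except json.JSONDecodeError:
                        pass
                    continue
                if line.startswith("time_min"):
                    continue
                rows.append([float(x) for x in line.split(",")])
        arr = np.asarray(rows)
        return cls(
            times=arr[:, 0],
            totals=arr[:, 1:5].astype(np.int64),
            seed=int(meta.get("seed", -1)),
            params=meta.get("params", {}),
        )


# ---------------------------------------------------------------------------
# public samplers
# ---------------------------------------------------------------------------


def _record_grid(t_end: float, record_dt: float) -> np.ndarray:
    n = int(round(t_end / record_dt))
    return np.linspace(0.0, n * record_dt, n + 1)


def simulate_nsm(
    system: ReactionSystem,
    jumps: JumpRateTable,
    init: SystemState,
    t_end: float,
    record_dt: float = 1.0,
    seed: int = 0,
    snapshot_times: Optional[Sequence[float]] = None,
) -> Trajectory:
    """Sample one RDME trajectory with the next subvolume method.

    Parameters are taken from ``system`` (reaction channels with per-voxel
    rates) and ``jumps`` (per-edge diffusion rates).  Identical inputs and
    seed reproduce the trajectory bit for bit.
    """
    if t_end <= 0 or record_dt <= 0:
        raise ValueError("t_end and record_dt must be positive")
    mesh = system.mesh
    x = init.counts.astype(np.int64).copy()
    record_times = _record_grid(t_end, record_dt)
    snap_t = np.asarray(snapshot_times if snapshot_times is not None else [], dtype=float)

    stoich = np.ascontiguousarray(system.stoichiometric_matrix().T)  # (R, S)
    react1 = np.array([ch.reactants[0] for ch in system.channels], dtype=np.int64)
    react2 = np.array([ch.reactants[1] for ch in system.channels], dtype=np.int64)
    c = np.ascontiguousarray(
        np.stack([ch.rate_per_voxel for ch in system.channels], axis=1)
    )
    qout = np.zeros((len(SPECIES), mesh.n_voxels))
    for v in range(mesh.n_voxels):
        sl = slice(mesh.adjacency_indptr[v], mesh.adjacency_indptr[v + 1])
        qout[:, v] = jumps.edge_rates[:, sl].sum(axis=1)

    rec, snaps, status, n_events = _nsm_loop(
        x,
        float(t_end),
        record_times,
        stoich,
        react1,
        react2,
        c,
        np.ascontiguousarray(jumps.edge_rates),
        mesh.adjacency_indptr,
        mesh.adjacency_indices,
        qout,
        snap_t,
        np.uint32(seed & 0x7FFFFFFF),
    )
    if status != 0:
        raise SimulationError(f"NSM aborted with status {status} after {n_events} events")
    return Trajectory(
        times=record_times,
        totals=rec,
        seed=int(seed),
        params=system.params.to_dict(),
        snapshots=snaps if len(snap_t) else None,
        snapshot_times=snap_t if len(snap_t) else None,
        n_events=int(n_events),
    )


def ssa_wellmixed(
    params: ParameterSet,
    volume: float,
    init_totals: Sequence[int] = (10, 60, 1, 0),
    t_end: float = 1200.0,
    record_dt: float = 1.0,
    seed: int = 0,
) -> Trajectory:
    """Gillespie direct method on the well-stirred seven-channel Hes1 model.

    No spatial structure: transcription and translation are unrestricted and
    the bimolecular binding rate is converted with the full ``volume`` (μm³).
    Written independently of the NSM path as a validation oracle.
    """
    from .model import convert_bimolecular_rate  # local to keep namespace light

    if t_end <= 0 or record_dt <= 0:
        raise ValueError("t_end and record_dt must be positive")
    rng = np.random.default_rng(seed)
    c1 = convert_bimolecular_rate(params.k1, volume)
    k2, am, g = params.k2, params.alpha_m, params.gamma
    ap, mm, mp = params.alpha_p, params.mu_m, params.mu_p

    m, p, pf, po = (int(v) for v in init_totals)
    record_times = _record_grid(t_end, record_dt)
    rec = np.zeros((len(record_times), 4), dtype=np.int64)
    ri = 0
    t = 0.0
    # stoichiometry per channel: (dm, dp, dpf, dpo)
    sto = (
        (0, -1, -1, +1),
        (0, +1, +1, -1),
        (+1, 0, 0, 0),
        (+1, 0, 0, 0),
        (0, +1, 0, 0),
        (-1, 0, 0, 0),
        (0, -1, 0, 0),
    )
    while True:
        a = (c1 * p * pf, k2 * po, am * pf, (am / g) * po, ap * m, mm * m, mp * p)
        a0 = sum(a)
        t_next = t + rng.exponential(1.0 / a0) if a0 > 0 else np.inf
        while ri < len(record_times) and record_times[ri] < t_next:
            rec[ri] = (m, p, pf, po)
            ri += 1
        if t_next >= t_end:
            break
        t = t_next
        u = rng.random() * a0
        acc = 0.0
        hit = len(a) - 1
        for r, ar in enumerate(a):
            acc += ar
            if u < acc:
                hit = r
                break
        dm, dp, dpf, dpo = sto[hit]
        m += dm
        p += dp
        pf += dpf
        po += dpo
    while ri < len(record_times):
        rec[ri] = (m, p, pf, po)
        ri += 1
    return Trajectory(
        times=record_times, totals=rec, seed=int(seed), params=params.to_dict()
    )
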