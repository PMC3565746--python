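"""In-silico experiments: wild-type ensembles, parameter sweeps, drug treatments.

Each experiment runs an ensemble of independent NSM trajectories (trajectory
``i`` uses seed ``base_seed + i``; comparison arms use disjoint seed blocks),
summarises every trajectory (time-mean copy numbers, first mRNA-peak time,
wavelet mean period, persistent-expression label, differentiation fate) and
returns an :class:`ExperimentResult` that is fully re-creatable from its
configuration echo.

The two drug treatments mirror classic perturbations of the Hes1 loop:

* proteasome inhibition — protein degradation ``mu_p`` cut 100-fold for a
  240-min run; mRNA rises to an early peak and then settles low while
  protein saturates high.  The summary statistic is the mean first-peak
  time of total mRNA.
* translation inhibition — ``alpha_p`` cut 100-fold for a 300-min run;
  repression is lifted so mRNA climbs several-fold over the matched
  wild-type arm.  The summary statistic is the grand mean (average over
  trajectories of per-trajectory time-mean) total mRNA.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import numpy as np

from .analysis import (
    PERSISTENT_EXPRESSION,
    WaveletConfig,
    classify_differentiation,
    classify_pe,
    estimate_period,
)
from .geometry import (
    ConfigurationError,
    Mesh,
    build_spherical_cell_mesh,
    compute_jump_rates,
    select_gene_voxel,
)
from .model import ParameterSet, build_reaction_system, initial_state
from .simulate import Trajectory, simulate_nsm

__all__ = [
    "SweepSpec",
    "TrajectorySummary",
    "ExperimentResult",
    "run_ensemble",
    "run_wildtype_ensemble",
    "run_sweep",
    "run_proteasome_inhibition",
    "run_translation_inhibition",
    "mrna_peak_time",
]

logger = logging.getLogger(__name__)

DEFAULT_CELL_RADIUS = 7.5
DEFAULT_NUCLEUS_RADIUS = 3.0


@lru_cache(maxsize=8)
def _cached_mesh(cell_radius: float, nucleus_radius: float, voxel_edge: float) -> Mesh:
    mesh = build_spherical_cell_mesh(cell_radius, nucleus_radius, voxel_edge)
    logger.info(mesh.summary())
    return mesh


def _mesh_for(params: ParameterSet, voxel_edge: float,
              cell_radius: float = DEFAULT_CELL_RADIUS,
              nucleus_radius: float = DEFAULT_NUCLEUS_RADIUS) -> Mesh:
    mesh = _cached_mesh(cell_radius, nucleus_radius, voxel_edge)
    gene = select_gene_voxel(mesh, params.r)
    if gene != mesh.gene_voxel:
        mesh = dataclasses.replace(mesh, gene_voxel=gene)
    return mesh


def mrna_peak_time(traj: Trajectory, smooth_window: float = 0.0) -> float:
    """First time at which the total mRNA series attains its maximum.

    With ``smooth_window`` > 0 (minutes) a centred moving average of that
    width is applied first; raw count maxima are noisy, so a 5-min window is
    a useful alternative reading.
    """
    y = traj.mrna.astype(float)
    if smooth_window > 0:
        dt = float(traj.times[1] - traj.times[0])
        k = max(1, int(round(smooth_window / dt)))
        y = np.convolve(y, np.ones(k) / k, mode="same")
    return float(traj.times[int(np.argmax(y))])


@dataclass
class TrajectorySummary:
    seed: int
    mean_mrna: float
    mean_protein: float
    mrna_peak_time: float
    mean_period: Optional[float] = None  # None when analysis skipped; nan = no period
    label: Optional[str] = None
    differentiation: Optional[str] = None
    protein_at_decision: Optional[int] = None


@dataclass
class ExperimentResult:
    """Ensemble summary plus the configuration echo that reproduces it."""

    config: dict
    summaries: list
    control: Optional["ExperimentResult"] = None

    @property
    def n(self) -> int:
        return len(self.summaries)

    @property
    def seeds(self) -> list:
        return [s.seed for s in self.summaries]

    @property
    def mean_periods(self) -> np.ndarray:
        """Mean period per trajectory (nan where the series had no oscillation)."""
        return np.array(
            [np.nan if s.mean_period is None else s.mean_period for s in self.summaries]
        )

    @property
    def oscillatory_periods(self) -> np.ndarray:
        return np.array(
            [s.mean_period for s in self.summaries
             if s.label is not None and s.label != PERSISTENT_EXPRESSION]
        )

    @property
    def pe_count(self) -> int:
        return sum(1 for s in self.summaries if s.label == PERSISTENT_EXPRESSION)

    @property
    def pe_fraction(self) -> float:
        return self.pe_count / self.n

    @property
    def grand_mean_mrna(self) -> float:
        return float(np.mean([s.mean_mrna for s in self.summaries]))

    @property
    def grand_mean_protein(self) -> float:
        return float(np.mean([s.mean_protein for s in self.summaries]))

    @property
    def mean_mrna_peak_time(self) -> float:
        return float(np.mean([s.mrna_peak_time for s in self.summaries]))

    def to_json(self, path) -> None:
        doc = {
            "config": self.config,
            "summaries": [dataclasses.asdict(s) for s in self.summaries],
            "pe_count": self.pe_count,
            "grand_mean_mrna": self.grand_mean_mrna,
            "grand_mean_protein": self.grand_mean_protein,
            "mean_mrna_peak_time": self.mean_mrna_peak_time,
        }
        if self.control is not None:
            doc["control"] = {
                "config": self.control.config,
                "grand_mean_mrna": self.control.grand_mean_mrna,
            }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, default=float)

    def periods_csv(self, path) -> None:
        """Per-trajectory mean periods (histogram source data)."""
        with open(path, "w") as fh:
            fh.write("trajectory,seed,mean_period_min,label\n")
            for i, s in enumerate(self.summaries):
                mp = "" if s.mean_period is None or np.isnan(s.mean_period) else f"{s.mean_period:.2f}"
                fh.write(f"{i},{s.seed},{mp},{s.label or ''}\n")


@dataclass(frozen=True)
class SweepSpec:
    """One-parameter sweep: baseline values everywhere except ``parameter``."""

    parameter: str
    values: tuple
    n: int = 100
    horizon: float = 1200.0
    base_seed: int = 1
    voxel_edge: float = 1.0
    record_dt: float = 1.0

    def __post_init__(self):
        if len(self.values) == 0:
            raise ConfigurationError("sweep value grid must be non-empty")
        if self.parameter not in ParameterSet().to_dict():
            raise ConfigurationError(f"unknown parameter name: {self.parameter}")


def run_ensemble(
    params: Optional[ParameterSet] = None,
    n: int = 100,
    horizon: float = 1200.0,
    base_seed: int = 1,
    voxel_edge: float = 1.0,
    record_dt: float = 1.0,
    analyze: bool = True,
    wavelet: Optional[WaveletConfig] = None,
    decision_time: float = 900.0,
    peak_smooth_window: float = 0.0,
    keep_trajectories: bool = False,
):
    """Run ``n`` independent NSM trajectories and summarise each one.

    Returns an :class:`ExperimentResult`; with ``keep_trajectories`` the raw
    :class:`Trajectory` objects are attached as ``result.trajectories``.
    """
    if n < 1:
        raise ConfigurationError("need n >= 1 trajectories")
    if horizon <= 0:
        raise ConfigurationError("horizon must be positive")
    params = params or ParameterSet()
    wavelet = wavelet or WaveletConfig()
    mesh = _mesh_for(params, voxel_edge)
    system = build_reaction_system(params, mesh)
    jumps = compute_jump_rates(
        mesh, {"mRNA": params.D, "protein": params.D, "P_f": 0.0, "P_o": 0.0}
    )
    if analyze:
        # fail fast on horizons too short for the wavelet band
        probe_n = int(round(horizon / record_dt)) + 1
        span = (probe_n - 1) * record_dt
        if span <= 2 * wavelet.coi_widths(record_dt)[0]:
            raise ConfigurationError(
                f"horizon {horizon} min too short for period analysis over "
                f"periods >= {wavelet.period_min} min"
            )

    summaries = []
    trajectories = []
    for i in range(int(n)):
        seed = int(base_seed) + i
        init = initial_state(mesh, seed=seed)
        traj = simulate_nsm(system, jumps, init, horizon, record_dt, seed=seed)
        assert np.all(traj.pf + traj.po == 1), "promoter count not conserved"
        summary = TrajectorySummary(
            seed=seed,
            mean_mrna=float(traj.mrna.mean()),
            mean_protein=float(traj.protein.mean()),
            mrna_peak_time=mrna_peak_time(traj, peak_smooth_window),
        )
        if analyze:
            est = estimate_period(traj.protein, dt=record_dt, config=wavelet)
            summary.mean_period = est.mean_period
            summary.label = classify_pe(est)
            if traj.times[0] <= decision_time <= traj.times[-1]:
                summary.differentiation = classify_differentiation(traj, decision_time)
                summary.protein_at_decision = traj.value_at(decision_time)
        summaries.append(summary)
        if keep_trajectories:
            trajectories.append(traj)

    config = {
        "params": params.to_dict(),
        "n": int(n),
        "horizon": float(horizon),
        "base_seed": int(base_seed),
        "voxel_edge": float(voxel_edge),
        "record_dt": float(record_dt),
        "cell_radius": DEFAULT_CELL_RADIUS,
        "nucleus_radius": DEFAULT_NUCLEUS_RADIUS,
        "analyze": analyze,
        "wavelet": dataclasses.asdict(wavelet) if analyze else None,
        "decision_time": decision_time,
        "peak_smooth_window": peak_smooth_window,
    }
    result = ExperimentResult(config=config, summaries=summaries)
    if keep_trajectories:
        result.trajectories = trajectories  # type: ignore[attr-defined]
    return result


def run_wildtype_ensemble(
    n: int = 100, horizon: float = 1200.0, base_seed: int = 1, **kwargs
) -> ExperimentResult:
    """Baseline-parameter ensemble with period analysis and fate calls."""
    return run_ensemble(ParameterSet(), n=n, horizon=horizon, base_seed=base_seed, **kwargs)


def run_sweep(spec: SweepSpec, wavelet: Optional[WaveletConfig] = None, **kwargs):
    """One :class:`ExperimentResult` per grid value; disjoint seed blocks."""
    results = []
    for j, value in enumerate(spec.values):
        params = ParameterSet().with_overrides(**{spec.parameter: float(value)})
        results.append(
            run_ensemble(
                params,
                n=spec.n,
                horizon=spec.horizon,
                base_seed=spec.base_seed + j * spec.n,
                voxel_edge=spec.voxel_edge,
                record_dt=spec.record_dt,
                wavelet=wavelet,
                **kwargs,
            )
        )
    return results


def run_proteasome_inhibition(
    n: int = 100,
    base_seed: int = 1,
    horizon: float = 240.0,
    peak_smooth_window: float = 0.0,
    **kwargs,
) -> ExperimentResult:
    """Proteasome-inhibition ensemble: ``mu_p`` divided by 100, 240-min runs.

    The headline statistic is ``result.mean_mrna_peak_time`` — the average
    over trajectories of the first time total mRNA attains its maximum.
    """
    base = ParameterSet()
    treated = base.with_overrides(mu_p=base.mu_p / 100.0)
    return run_ensemble(
        treated,
        n=n,
        horizon=horizon,
        base_seed=base_seed,
        analyze=False,
        peak_smooth_window=peak_smooth_window,
        **kwargs,
    )


def run_translation_inhibition(
    n: int = 100,
    base_seed: int = 1,
    horizon: float = 300.0,
    with_control: bool = True,
    **kwargs,
) -> ExperimentResult:
    """Translation-inhibition ensemble: ``alpha_p`` divided by 100, 300-min runs.

    The headline statistic is ``result.grand_mean_mrna``; when
    ``with_control`` is set, a matched wild-type arm (equal size and horizon,
    disjoint seed block) is attached as ``result.control`` for the
    treated/wild-type mRNA comparison.
    """
    base = ParameterSet()
    treated_params = base.with_overrides(alpha_p=base.alpha_p / 100.0)
    treated = run_ensemble(
        treated_params, n=n, horizon=horizon, base_seed=base_seed, analyze=False, **kwargs
    )
    if with_control:
        treated.control = run_ensemble(
            ParameterSet(), n=n, horizon=horizon, base_seed=base_seed + n,
            analyze=False, **kwargs
        )
    return treated
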