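"""Monte Carlo model of a single dynamic-OCT pixel and compression sweeps.

The per-pixel signal is an additive three-component model:

    S(t_i) = cn * fn(t_i) + cm * fm(t_i) + 1,      i = 0 .. N-1,

where ``fn`` is unit-variance white Gaussian noise, the constant offset 1
represents stationary scatterers, and ``fm`` models motile scatterers as a
moving average of i.i.d. standard normals over a window of ``p`` sampling
points (memory time ``p * ts``), scaled by sqrt(p) so Var[fm] = 1:

    fm(t_i) = sqrt(p) * (1/p) * sum_{j=i}^{i+p-1} X(t_j),  X ~ N(0, 1).

Under this model the population moments are Gamma(0) = cn^2 + cm^2 + 1,
Gamma(ts) ~= cm^2 * (p-1)/p + 1 (the lag-1 autocorrelation of a length-p
moving average is (p-1)/p), and Sbar = 1 — so the motility amplitude is
approximately cm, with a deficit that grows as p shrinks relative to N.

``compression_sweep`` reproduces the fidelity study: at each motile weight
on a grid, mean M is estimated from the same simulated series both
uncompressed and under each compressed scheme (paired sub-sampling of one
acquisition), and compressed-vs-uncompressed means are summarized by a
through-origin regression slope.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .schedules import Method, SamplingSchedule, full_schedule, make_schedule
from .stats import slope_through_origin
from . import estimators


@dataclass(frozen=True)
class SimulationConfig:
    """Weights, memory length and bookkeeping for the per-pixel model.

    Parameters
    ----------
    cn, cm : float
        White-noise and motile-scatterer weights relative to the stationary
        offset of 1 (both >= 0).  ``cn`` sets an effective inverse SNR.
    p : int
        Memory (persistence) length of the motile component in sampling
        points, >= 1; the memory time is ``p * ts``.
    n_frames : int
        Series length N, >= 2.
    replicates : int
        Number of independent series per condition, >= 1.
    seed : int
        Master RNG seed; every replicate derives an independent child stream.
    """

    cn: float
    cm: float
    p: int
    n_frames: int = 100
    replicates: int = 6000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cn < 0 or self.cm < 0 or not np.isfinite([self.cn, self.cm]).all():
            raise ValueError("weights cn, cm must be finite and non-negative")
        if self.p < 1:
            raise ValueError(f"memory length p must be >= 1, got {self.p}")
        if self.n_frames < 2:
            raise ValueError(f"series length must be >= 2, got {self.n_frames}")
        if self.replicates < 1:
            raise ValueError(f"replicates must be >= 1, got {self.replicates}")


def _rng(seed: int, replicate_index: int) -> np.random.Generator:
    # One child stream per replicate: compressed and uncompressed estimates
    # share the identical series, and replicates are mutually independent.
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(replicate_index,)))


def motile_component(rng: np.random.Generator, n_frames: int, p: int) -> np.ndarray:
    """Draw fm: sqrt(p)-scaled length-p moving average of fresh N(0,1) draws.

    Uses n_frames + p - 1 draws so every output point is a full p-term
    average (no truncated windows at either end).
    """
    x = rng.standard_normal(n_frames + p - 1)
    return np.sqrt(p) * np.convolve(x, np.full(p, 1.0 / p), mode="valid")


def simulate_series(cfg: SimulationConfig, replicate_index: int = 0) -> np.ndarray:
    """One simulated pixel series on the full (uncompressed) sampling grid."""
    rng = _rng(cfg.seed, replicate_index)
    fn = rng.standard_normal(cfg.n_frames)
    fm = motile_component(rng, cfg.n_frames, cfg.p)
    return cfg.cn * fn + cfg.cm * fm + 1.0


def simulated_mean_M(cfg: SimulationConfig, schedule: SamplingSchedule | None = None) -> float:
    """Replicate-averaged motility amplitude under a sampling schedule.

    Each replicate is simulated on the full grid, sub-sampled to the
    schedule's retained slots, run through the scheme's estimator, and the
    resulting M values are averaged — mirroring how a spheroid-averaged M is
    formed from its pixels.
    """
    if schedule is None:
        schedule = full_schedule(cfg.n_frames)
    if schedule.n_frames != cfg.n_frames:
        raise ValueError(
            f"schedule N={schedule.n_frames} inconsistent with config N={cfg.n_frames}"
        )
    idx = np.asarray(schedule.indices)
    total = 0.0
    for i in range(cfg.replicates):
        series = simulate_series(cfg, i)[idx]
        total += estimators.motility_from_series(series, schedule).m
    return total / cfg.replicates


@dataclass(frozen=True)
class SweepResult:
    """Compression-fidelity sweep over a grid of motile weights.

    ``m_compressed`` and ``slopes`` are keyed by ``(method_value, r)``, e.g.
    ``("nuts", 8)``.  Slopes are through-origin fits of compressed vs.
    uncompressed mean M across the grid.
    """

    cm_grid: np.ndarray
    m_uncompressed: np.ndarray
    m_compressed: dict[tuple[str, int], np.ndarray]
    slopes: dict[tuple[str, int], float]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (cm, method, r) with mean M and slope."""
        rows = [
            {"cm": cm, "method": "full", "r": 1, "mean_M": m, "slope": 1.0}
            for cm, m in zip(self.cm_grid, self.m_uncompressed)
        ]
        for (method, r), values in self.m_compressed.items():
            rows += [
                {"cm": cm, "method": method, "r": r, "mean_M": m, "slope": self.slopes[(method, r)]}
                for cm, m in zip(self.cm_grid, values)
            ]
        return pd.DataFrame(rows)


def default_cm_grid(n_points: int = 11, cm_max: float = 0.5) -> np.ndarray:
    """Evenly spaced motile-weight grid, 0 to cm_max inclusive."""
    return np.linspace(0.0, cm_max, n_points)


def compression_sweep(
    cfg_template: SimulationConfig,
    cm_grid=None,
    schemes: list[tuple[str, int]] = (("nuts", 2), ("nuts", 4), ("nuts", 8), ("nuts", 16)),
) -> SweepResult:
    """Paired compressed-vs-uncompressed mean-M sweep over a cm grid.

    For every grid point, ``cfg_template.replicates`` series are simulated on
    the full grid; each compressed estimate sub-samples the *same* series its
    uncompressed partner used.  Grid points use independent RNG streams
    derived from the master seed.  Returns per-scheme through-origin slopes.
    """
    cm_grid = default_cm_grid() if cm_grid is None else np.asarray(cm_grid, dtype=float)
    if cm_grid.size == 0:
        raise ValueError("cm_grid must be non-empty")
    n = cfg_template.n_frames
    full = full_schedule(n)
    scheds = {(m, r): make_schedule(Method(m), n, r) for m, r in schemes}
    # Independent sub-seed per grid point, kept below 2^31.
    point_seeds = [
        int(s) & 0x7FFFFFFF
        for s in np.random.SeedSequence(cfg_template.seed).generate_state(cm_grid.size)
    ]

    m_unc = np.empty(cm_grid.size)
    m_comp = {key: np.empty(cm_grid.size) for key in scheds}
    for gi, cm in enumerate(cm_grid):
        cfg = replace(cfg_template, cm=float(cm), seed=point_seeds[gi])
        acc_full = 0.0
        acc = dict.fromkeys(scheds, 0.0)
        for rep in range(cfg.replicates):
            series = simulate_series(cfg, rep)
            acc_full += estimators.motility_from_series(series, full).m
            for key, sched in scheds.items():
                sub = series[np.asarray(sched.indices)]
                acc[key] += estimators.motility_from_series(sub, sched).m
        m_unc[gi] = acc_full / cfg.replicates
        for key in scheds:
            m_comp[key][gi] = acc[key] / cfg.replicates

    slopes = {key: slope_through_origin(m_unc, vals) for key, vals in m_comp.items()}
    return SweepResult(cm_grid=cm_grid, m_uncompressed=m_unc, m_compressed=m_comp, slopes=slopes)
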