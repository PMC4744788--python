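"""Synthetic groundwater plume simulator and monitoring-design sampler.

The "true" concentration field solves the 2-D advection–diffusion equation

    ∂y/∂t = D (∂²y/∂s1² + ∂²y/∂s2²) + ψ1(s1,s2) ∂y/∂s1 + ψ2(s1,s2) ∂y/∂s2

on the unit square for t ∈ [0, 1], with zero-flux boundaries.  With the
advection terms entering with a positive sign, the solute drifts along −ψ;
taking ψ as the gradient of a groundwater-head surface therefore gives the
physically expected down-gradient drift.  The default head surface is a
smooth tilted plane plus two bumps producing a south-east → north-west
drift, standing in for observed groundwater levels.

The solver is an explicit finite-difference scheme: conservative central
differences for diffusion (zero-flux ghost nodes) and first-order upwind
differences for advection, with automatic sub-stepping under a CFL-style
bound.  The solution is stored on a regular (s1, s2, t) output grid
(100 × 100 × 100 by default) and interpolated wherever observations or
evaluations need it.

Monitoring designs mirror three archetypes: a sparse clustered network of
29 wells sampled densely and irregularly in time (1402 observations), a
dense network of 280 random wells sampled rarely (1402 observations), and
the sparse network sampled only 100 times in total (~4 samples per well).
Measurement noise is multiplicative: on the log scale it is the sum of a
shared per-well effect and independent error, with total SD set by a
signal-to-noise ratio of 10:1 and within-well correlation 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .data import MonitoringDataset, ResponseTransform

__all__ = [
    "FlowField",
    "PlumeTruth",
    "SamplingScenario",
    "NoiseModel",
    "default_flow",
    "gaussian_initial",
    "solve_plume",
    "make_scenario",
    "sample_observations",
    "simulate_dataset",
    "default_truth",
]

#: seed of the packaged reference monitoring design (well layout, shared
#: sampling campaigns).  The design is fixed, mirroring how a real site's
#: network is fixed; replicate-level noise uses independent seeds.
DEFAULT_DESIGN_SEED = 33

#: number of shared sampling campaigns (site-wide sampling events) over the
#: monitoring period; wells are sampled on a subset of these dates
DEFAULT_N_CAMPAIGNS = 80

SCENARIO_SIZES = {1: (29, 1402), 2: (280, 1402), 3: (29, 100)}


@dataclass(frozen=True)
class FlowField:
    """Diffusion constant and advection field of the transport equation."""

    diffusion: float = 0.004
    psi1: Callable[[np.ndarray, np.ndarray], np.ndarray] = None  # type: ignore[assignment]
    psi2: Callable[[np.ndarray, np.ndarray], np.ndarray] = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.diffusion < 0:
            raise ValueError("diffusion constant must be >= 0")
        if self.psi1 is None or self.psi2 is None:
            f = default_flow(diffusion=self.diffusion)
            object.__setattr__(self, "psi1", f.psi1)
            object.__setattr__(self, "psi2", f.psi2)


def default_flow(
    diffusion: float = 0.004,
    slope: float = 0.35,
    bump_amp: float = 0.05,
    bump_width: float = 0.25,
) -> FlowField:
    """ψ = ∇(head) for a tilted two-bump head surface, high in the SE.

    The induced drift −ψ points roughly south-east → north-west with speed
    ≈ slope·√2, modulated by the bumps.
    """
    c1, c2 = (0.3, 0.4), (0.7, 0.6)

    def _bump_grad(s1, s2, cx, cy, sign):
        g = sign * bump_amp * np.exp(
            -((s1 - cx) ** 2 + (s2 - cy) ** 2) / (2.0 * bump_width**2)
        )
        return (
            g * -(s1 - cx) / bump_width**2,
            g * -(s2 - cy) / bump_width**2,
        )

    def psi1(s1, s2):
        d1a, _ = _bump_grad(s1, s2, *c1, +1.0)
        d1b, _ = _bump_grad(s1, s2, *c2, -1.0)
        return slope + d1a + d1b

    def psi2(s1, s2):
        _, d2a = _bump_grad(s1, s2, *c1, +1.0)
        _, d2b = _bump_grad(s1, s2, *c2, -1.0)
        return -slope + d2a + d2b

    return FlowField(diffusion=diffusion, psi1=psi1, psi2=psi2)


def gaussian_initial(
    center: tuple[float, float] = (0.75, 0.25),
    sd: float = 0.04,
    amplitude: float = 100.0,
) -> Callable[[np.ndarray, np.ndarray], np.ndarray]:
    """Gaussian solute release, by default in the south-east quadrant."""

    def init(s1, s2):
        return amplitude * np.exp(
            -((s1 - center[0]) ** 2 + (s2 - center[1]) ** 2) / (2.0 * sd**2)
        )

    return init


@dataclass
class PlumeTruth:
    """Gridded space–time concentration field from the PDE solver."""

    s1: np.ndarray
    s2: np.ndarray
    t: np.ndarray
    values: np.ndarray  # (n_t, n_s1, n_s2), >= 0
    flow: FlowField
    dt_internal: float
    _interp: RegularGridInterpolator | None = field(default=None, repr=False)

    def interpolator(self) -> RegularGridInterpolator:
        if self._interp is None:
            self._interp = RegularGridInterpolator(
                (self.s1, self.s2, self.t),
                np.moveaxis(self.values, 0, -1),
                bounds_error=True,
            )
        return self._interp

    def interp(self, s1, s2, t) -> np.ndarray:
        pts = np.column_stack(
            [np.atleast_1d(np.asarray(v, float)) for v in (s1, s2, t)]
        )
        return self.interpolator()(pts)


def _step(y, D, p1, p2, h, dt):
    """One explicit step: conservative diffusion + upwind advection."""
    # zero-flux ghost nodes: ghost equals the edge value
    ym1 = np.vstack([y[:1], y[:-1]])
    yp1 = np.vstack([y[1:], y[-1:]])
    lap = ym1 + yp1 - 2.0 * y
    ym2 = np.hstack([y[:, :1], y[:, :-1]])
    yp2 = np.hstack([y[:, 1:], y[:, -1:]])
    lap += ym2 + yp2 - 2.0 * y
    out = y + dt * D / h**2 * lap
    # upwind: forward difference where ψ > 0, backward where ψ < 0
    fwd1 = yp1 - y
    bwd1 = y - ym1
    out += dt / h * np.where(p1 > 0, p1 * fwd1, p1 * bwd1)
    fwd2 = yp2 - y
    bwd2 = y - ym2
    out += dt / h * np.where(p2 > 0, p2 * fwd2, p2 * bwd2)
    return out


def solve_plume(
    flow: FlowField,
    initial: Callable[[np.ndarray, np.ndarray], np.ndarray] | np.ndarray = None,
    grid_n: tuple[int, int] = (100, 100),
    n_t_out: int = 100,
    t_span: tuple[float, float] = (0.0, 1.0),
    cfl_safety: float = 0.8,
    max_refinements: int = 4,
) -> PlumeTruth:
    """Solve the advection–diffusion equation on a regular output grid."""
    n1, n2 = grid_n
    if n1 < 3 or n2 < 3 or n_t_out < 2:
        raise ValueError("grid too small")
    if n1 != n2:
        raise ValueError("solver assumes a square grid (equal spacing)")
    s1 = np.linspace(0.0, 1.0, n1)
    s2 = np.linspace(0.0, 1.0, n2)
    h = s1[1] - s1[0]
    S1, S2 = np.meshgrid(s1, s2, indexing="ij")
    if initial is None:
        initial = gaussian_initial()
    y0 = np.asarray(initial(S1, S2) if callable(initial) else initial, dtype=float)
    if y0.shape != (n1, n2):
        raise ValueError("initial condition shape mismatch")
    if np.any(y0 < 0):
        raise ValueError("initial concentrations must be >= 0")

    p1 = np.asarray(flow.psi1(S1, S2), dtype=float)
    p2 = np.asarray(flow.psi2(S1, S2), dtype=float)
    if not (np.all(np.isfinite(p1)) and np.all(np.isfinite(p2))):
        raise ValueError("advection field not finite on the grid")

    rate = 4.0 * flow.diffusion / h**2 + (np.abs(p1) + np.abs(p2)).max() / h
    dt0 = cfl_safety / rate if rate > 0 else (t_span[1] - t_span[0])
    t_out = np.linspace(t_span[0], t_span[1], n_t_out)
    cap = 10.0 * max(y0.max(), 1.0)

    dt = dt0
    for attempt in range(max_refinements + 1):
        values = np.empty((n_t_out, n1, n2))
        values[0] = y0
        y = y0.copy()
        ok = True
        for i in range(1, n_t_out):
            span = t_out[i] - t_out[i - 1]
            nsub = max(1, math.ceil(span / dt))
            sub = span / nsub
            for _ in range(nsub):
                y = _step(y, flow.diffusion, p1, p2, h, sub)
            if not np.all(np.isfinite(y)) or np.abs(y).max() > cap:
                ok = False
                break
            values[i] = y
        if ok:
            np.clip(values, 0.0, None, out=values)
            return PlumeTruth(
                s1=s1, s2=s2, t=t_out, values=values, flow=flow, dt_internal=dt
            )
        dt /= 2.0
    raise RuntimeError(
        f"solver unstable even at internal step {dt:.3g}; "
        f"a step below {dt:.3g} would be required"
    )


@dataclass
class SamplingScenario:
    """A monitoring design: well layout plus per-observation sample times."""

    scenario_id: int
    well_names: np.ndarray
    wells: np.ndarray  # (n_wells, 2)
    obs_well_index: np.ndarray  # (n_obs,)
    sample_times: np.ndarray  # (n_obs,)

    @property
    def n_wells(self) -> int:
        return len(self.wells)

    @property
    def n_obs(self) -> int:
        return len(self.sample_times)


def _scenario_wells_sparse(rng: np.random.Generator) -> np.ndarray:
    """29 wells: source and mid-plume clusters plus a perimeter ring.

    The layout mimics a contaminated-site network: most wells crowd the
    source area and plume track, a few guard wells sit at the site
    boundary, leaving large hull-interior regions without data support —
    the "sparse design" that makes smoothing-parameter selection hard.
    """
    a = rng.normal(loc=(0.70, 0.28), scale=0.05, size=(12, 2))
    b = rng.normal(loc=(0.48, 0.52), scale=0.07, size=(8, 2))
    ring = np.array(
        [
            [0.05, 0.05], [0.05, 0.50], [0.08, 0.93], [0.50, 0.95],
            [0.93, 0.92], [0.95, 0.50], [0.92, 0.07], [0.50, 0.06],
            [0.25, 0.75],
        ]
    )
    ring = ring + rng.normal(0.0, 0.02, size=ring.shape)
    return np.clip(np.vstack([a, b, ring]), 0.02, 0.98)


def make_scenario(
    scenario_id: int,
    design_seed: int = DEFAULT_DESIGN_SEED,
    n_campaigns: int = DEFAULT_N_CAMPAIGNS,
) -> SamplingScenario:
    """Construct one of the three monitoring designs (deterministic per seed).

    Sample dates follow shared site-wide campaigns: each well is sampled on
    its own irregular subset of the campaign dates, so wells share dates the
    way real monitoring rounds do.  Scenarios 1 and 3 share one well layout.
    """
    if scenario_id not in SCENARIO_SIZES:
        raise ValueError("scenario must be 1, 2 or 3")
    n_wells, n_obs = SCENARIO_SIZES[scenario_id]
    rng = np.random.default_rng(design_seed)
    wells_sparse = _scenario_wells_sparse(rng)
    campaigns = np.sort(rng.uniform(0.0, 1.0, size=n_campaigns))
    if scenario_id == 2:
        wells = rng.uniform(0.02, 0.98, size=(n_wells, 2))
    else:
        wells = wells_sparse

    # irregular per-well sample counts: at least one each, uneven remainder,
    # capped at one visit per campaign (excess redistributed)
    weights = rng.uniform(0.5, 1.5, size=n_wells)
    counts = np.ones(n_wells, dtype=int)
    counts += rng.multinomial(n_obs - n_wells, weights / weights.sum())
    counts = np.minimum(counts, n_campaigns)
    short = n_obs - counts.sum()
    while short > 0:
        room = np.where(counts < n_campaigns)[0]
        counts[room[rng.integers(0, len(room))]] += 1
        short -= 1

    idx_parts, time_parts = [], []
    for w in range(n_wells):
        sel = rng.choice(n_campaigns, size=counts[w], replace=False)
        idx_parts.append(np.full(counts[w], w))
        time_parts.append(campaigns[sel])
    idx = np.concatenate(idx_parts)
    times = np.concatenate(time_parts)
    names = np.asarray([f"W{i:03d}" for i in range(n_wells)], dtype=object)
    return SamplingScenario(
        scenario_id=scenario_id,
        well_names=names,
        wells=wells,
        obs_well_index=idx,
        sample_times=times,
    )


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative log-scale noise: shared well effect + independent error.

    Total log-scale noise SD is SD(log-signal)/snr; the shared well effect
    carries a fraction rho of the variance, so same-well pairs have
    correlation rho and different-well pairs are uncorrelated.
    """

    snr: float = 10.0
    rho: float = 0.05
    seed: int | None = None

    def __post_init__(self):
        if not (self.snr > 0 or math.isinf(self.snr)):
            raise ValueError("snr must be positive (inf for noise-free)")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("need 0 <= rho < 1")


def sample_observations(
    truth: PlumeTruth,
    scenario: SamplingScenario,
    noise: NoiseModel = NoiseModel(),
    seed: int | None = None,
    transform: ResponseTransform | None = None,
) -> MonitoringDataset:
    """Draw a monitoring dataset from the truth field under the noise model."""
    transform = transform or ResponseTransform()
    if np.any(scenario.wells < truth.s1.min()) or np.any(scenario.wells > truth.s1.max()):
        raise ValueError("scenario wells outside the solved domain")
    s1 = scenario.wells[scenario.obs_well_index, 0]
    s2 = scenario.wells[scenario.obs_well_index, 1]
    t = scenario.sample_times
    signal = truth.interp(s1, s2, t)

    if math.isinf(noise.snr):
        raw = signal
    else:
        # multiplicative errors: raw = signal·exp(well effect + independent),
        # so exact zeros stay exactly zero; the log-scale noise SD is set from
        # the observed spread of the (offset-)log signal and the stated SNR
        g = transform.forward(signal)
        rng = np.random.default_rng(seed if seed is not None else noise.seed)
        sigma = float(np.std(g)) / noise.snr
        u = rng.normal(0.0, sigma * math.sqrt(noise.rho), size=scenario.n_wells)
        e = rng.normal(0.0, sigma * math.sqrt(1.0 - noise.rho), size=scenario.n_obs)
        raw = signal * np.exp(u[scenario.obs_well_index] + e)
    return MonitoringDataset.from_raw(
        well=scenario.well_names[scenario.obs_well_index],
        s1=s1,
        s2=s2,
        t=t,
        raw=raw,
        transform=transform,
    )


_TRUTH_CACHE: dict[tuple, PlumeTruth] = {}


def default_truth(
    grid_n: tuple[int, int] = (100, 100), n_t_out: int = 100
) -> PlumeTruth:
    """Default-flow truth field, cached per grid size."""
    key = (grid_n, n_t_out)
    if key not in _TRUTH_CACHE:
        _TRUTH_CACHE[key] = solve_plume(
            default_flow(), gaussian_initial(), grid_n=grid_n, n_t_out=n_t_out
        )
    return _TRUTH_CACHE[key]


def simulate_dataset(
    scenario_id: int,
    seed: int,
    noise: NoiseModel = NoiseModel(),
    truth: PlumeTruth | None = None,
    design_seed: int = DEFAULT_DESIGN_SEED,
) -> tuple[MonitoringDataset, PlumeTruth, SamplingScenario]:
    """Convenience wrapper: cached truth field + design + noisy sampling."""
    truth = truth or default_truth()
    scenario = make_scenario(scenario_id, design_seed=design_seed)
    data = sample_observations(truth, scenario, noise=noise, seed=seed)
    return data, truth, scenario
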