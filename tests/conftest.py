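"""Shared fixtures: random monitoring datasets and dense linear-algebra oracles.

The dense oracles deliberately avoid the package's decomposition path: they
assemble B'B + λD'D explicitly and use numpy's dense solvers, so agreement
with the fast path is a genuine two-route check.
"""

from __future__ import annotations

import numpy as np
import pytest

from plumespline.basis import BasisSpec, build_tensor_design
from plumespline.data import MonitoringDataset
from plumespline.penalty import build_difference_penalty


def make_data(
    rng: np.random.Generator,
    n: int = 120,
    n_wells: int = 8,
    y_from=None,
    scatter: bool = False,
) -> MonitoringDataset:
    """Random irregular monitoring dataset on the unit cube.

    By default observations cluster at well locations (realistic geometry);
    ``scatter=True`` spreads them uniformly, giving a well-conditioned
    design suited to tight numerical-oracle comparisons.
    """
    wells = np.asarray([f"W{i:02d}" for i in range(n_wells)], dtype=object)
    widx = rng.integers(0, n_wells, size=n)
    if scatter:
        s1 = rng.uniform(0.0, 1.0, size=n)
        s2 = rng.uniform(0.0, 1.0, size=n)
    else:
        coords = rng.uniform(0.0, 1.0, size=(n_wells, 2))
        s1 = np.clip(coords[widx, 0] + rng.normal(0, 0.01, n), 0, 1)
        s2 = np.clip(coords[widx, 1] + rng.normal(0, 0.01, n), 0, 1)
    t = rng.uniform(0.0, 1.0, size=n)
    if y_from is None:
        y = rng.normal(0.0, 1.0, size=n)
    else:
        y = y_from(s1, s2, t) + rng.normal(0.0, 0.1, size=n)
    return MonitoringDataset(well=wells[widx], s1=s1, s2=s2, t=t, y=y)


def smooth_signal(s1, s2, t):
    return np.sin(3.0 * s1) + np.cos(2.0 * s2) + 0.5 * t + s1 * s2


def small_problem(seed: int, sizes=(4, 4, 3), n: int = 150, order: int = 1):
    """Smooth-signal dataset + design + penalty, small enough for dense oracles."""
    rng = np.random.default_rng(seed)
    data = make_data(rng, n=n, y_from=smooth_signal)
    spec = BasisSpec.from_data(data, sizes)
    design = build_tensor_design(data, spec)
    pen = build_difference_penalty(spec, order=order)
    return data, spec, design, pen


def mid_targets(spec, k: int = 10):
    """k target points strictly inside the basis domains."""
    axes = []
    for lo, hi in spec.domains:
        pad = 0.1 * (hi - lo)
        axes.append(np.linspace(lo + pad, hi - pad, k))
    return tuple(axes)


def dense_profile(design, pen, y, lam):
    """Dense-route α̂, penalized RSS, plain RSS, edf, logdet at one λ."""
    B = design.B.toarray()
    P = pen.DtD.toarray()
    C = B.T @ B
    A = C + lam * P
    alpha = np.linalg.solve(A, B.T @ y)
    rss_pen = float(y @ y - y @ B @ alpha)
    resid = y - B @ alpha
    rss_plain = float(resid @ resid)
    edf = float(np.trace(B @ np.linalg.solve(A, B.T)))
    logdet = float(np.linalg.slogdet(A)[1])
    return alpha, rss_pen, rss_plain, edf, logdet


def dense_log_posterior(design, pen, y, prior, lams):
    """Dense evaluation of the marginal λ posterior kernel (up to constant)."""
    out = []
    for lam in np.atleast_1d(lams):
        _, rss_pen, _, _, logdet = dense_profile(design, pen, y, lam)
        out.append(
            0.5 * pen.rank * np.log(lam)
            - 0.5 * logdet
            - (prior.a + 0.5 * len(y)) * np.log(2 * prior.b + rss_pen)
        )
    return np.asarray(out)


@pytest.fixture(scope="session")
def cached_truth():
    """Coarse plume truth shared across tests (cheap to solve, adequate)."""
    from plumespline.simulate import default_truth

    return default_truth(grid_n=(100, 100), n_t_out=100)
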