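"""Scoring fitted surfaces against simulator truth.

The headline score is the integrated squared error (ISE)

    ∫∫∫ (m̂(s1,s2,t) − m(s1,s2,t))² ds1 ds2 dt

computed by a Riemann sum over a regular evaluation grid restricted to the
convex hull of the monitoring wells crossed with the sampled time range,
on the transformed (log) scale — the scale on which the model is fitted.

``compare_selectors`` runs the full replicate-level method comparison: one
noisy dataset per replicate, every selector scored on the identical dataset
(asserted by checksum), means and standard errors across replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .basis import BasisSpec, build_tensor_design
from .criteria import cv_select, select_classical
from .data import MonitoringDataset
from .model import (
    NIGPrior,
    default_lambda_grid,
    lambda_posterior,
    precompute,
)
from .penalty import build_difference_penalty
from .simulate import NoiseModel, default_truth, make_scenario, sample_observations

__all__ = [
    "convex_hull_mask",
    "integrated_squared_error",
    "evaluation_grid",
    "compare_selectors",
    "ComparisonResult",
    "deletion_change",
]

ALL_SELECTORS = ("map", "average", "aicc", "gcv", "bic", "cv-obs", "cv-well")


def convex_hull_mask(
    wells: np.ndarray,
    t_range: tuple[float, float],
    grid: tuple[np.ndarray, np.ndarray, np.ndarray],
    tol: float = 1e-9,
) -> np.ndarray:
    """Boolean mask over a regular (s1, s2, t) grid: inside the closed hull.

    A node is flagged iff its spatial coordinates lie in the closed convex
    hull of the well locations and its time lies within ``t_range``.
    """
    wells = np.asarray(wells, dtype=float)
    if wells.ndim != 2 or wells.shape[1] != 2 or len(wells) < 3:
        raise ValueError("need at least 3 wells as an (n, 2) array")
    try:
        hull = ConvexHull(wells)
    except QhullError as exc:
        raise ValueError(f"degenerate well layout (collinear?): {exc}") from exc
    s1, s2, t = (np.asarray(g, dtype=float) for g in grid)
    P1, P2 = np.meshgrid(s1, s2, indexing="ij")
    pts = np.column_stack([P1.ravel(), P2.ravel(), np.ones(P1.size)])
    inside2d = np.all(pts @ hull.equations.T <= tol, axis=1).reshape(P1.shape)
    t_in = (t >= t_range[0] - tol) & (t <= t_range[1] + tol)
    return inside2d[:, :, None] & t_in[None, None, :]


def integrated_squared_error(
    fitted: np.ndarray,
    truth: np.ndarray,
    mask: np.ndarray,
    cell_volume: float,
) -> float:
    """Numerical ISE of fitted vs truth over the masked grid nodes.

    Trapezoidal node weights (half weight on domain-boundary nodes per
    dimension) remove the O(1/k) edge bias of a plain node-count sum; the
    hull mask simply zeroes excluded nodes.
    """
    fitted = np.asarray(fitted, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if fitted.shape != truth.shape or fitted.shape != mask.shape:
        raise ValueError(
            f"grid mismatch: fitted {fitted.shape}, truth {truth.shape}, "
            f"mask {mask.shape}"
        )
    w = np.ones(fitted.shape)
    for axis, k in enumerate(fitted.shape):
        shape = [1, 1, 1]
        shape[axis] = k
        edge = np.ones(k)
        if k > 1:
            edge[0] = edge[-1] = 0.5
        w *= edge.reshape(shape)
    return float(np.sum(((fitted - truth) ** 2) * w * mask) * cell_volume)


def evaluation_grid(
    spec: BasisSpec, shape: tuple[int, int, int] = (50, 50, 20)
) -> tuple[tuple[np.ndarray, np.ndarray, np.ndarray], np.ndarray, float]:
    """Regular grid over the basis domains: axes, flattened points, cell volume."""
    axes = tuple(
        np.linspace(lo, hi, k) for (lo, hi), k in zip(spec.domains, shape)
    )
    G1, G2, G3 = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([G1.ravel(), G2.ravel(), G3.ravel()])
    vol = float(np.prod([(hi - lo) / (k - 1) for (lo, hi), k in zip(spec.domains, shape)]))
    return axes, pts, vol


@dataclass
class ComparisonResult:
    """Replicate-level method comparison: summary table + per-replicate records."""

    table: pd.DataFrame
    replicates: pd.DataFrame
    scenario_id: int
    n_replicates: int

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _selector_lambda(name, ctx, post, data, spec, penalty_order, grid, k, seed):
    """λ chosen by a selector (None means model averaging over the grid)."""
    if name == "map":
        return post.map_lambda
    if name == "average":
        return None
    if name in ("aicc", "gcv", "bic"):
        return select_classical(ctx, grid, name).lambda_opt
    if name in ("cv-obs", "cv-well"):
        grouping = "well" if name == "cv-well" else "observation"
        return cv_select(
            data, spec, penalty_order, grid, k=k, grouping=grouping, seed=seed
        ).lambda_opt
    raise ValueError(f"unknown selector {name!r}")


def compare_selectors(
    n_replicates: int,
    scenario_id: int,
    selectors=ALL_SELECTORS,
    base_seed: int = 0,
    n_basis: tuple[int, int, int] = (14, 8, 5),
    degree: int = 2,
    penalty_order: int = 1,
    prior: NIGPrior | None = None,
    lambda_grid: np.ndarray | None = None,
    noise: NoiseModel = NoiseModel(),
    eval_shape: tuple[int, int, int] = (50, 50, 20),
    cv_folds: int = 10,
    truth=None,
) -> ComparisonResult:
    """Mean and standard error of ISE per selector over seeded replicates.

    The truth field and the monitoring design are fixed; replicates differ
    only in the measurement noise.  All selectors within a replicate score
    the identical dataset (checksum recorded per row).
    """
    unknown = set(selectors) - set(ALL_SELECTORS)
    if unknown:
        raise ValueError(f"unknown selectors: {sorted(unknown)}")
    prior = prior or NIGPrior()
    grid = default_lambda_grid() if lambda_grid is None else np.asarray(lambda_grid, float)
    truth = truth or default_truth()
    scenario = make_scenario(scenario_id)

    # design is noise-free: build it (and its decomposition) once
    probe = sample_observations(truth, scenario, noise=noise, seed=base_seed)
    spec = BasisSpec.from_data(probe, n_basis, degree=degree)
    design = build_tensor_design(probe, spec)
    pen = build_difference_penalty(spec, order=penalty_order)
    ctx = precompute(design, pen, probe.y)

    axes, pts, vol = evaluation_grid(spec, eval_shape)
    mask = convex_hull_mask(scenario.wells, spec.domain_t, axes)
    B_eval = design.rows_at(pts[:, 0], pts[:, 1], pts[:, 2])
    truth_vals = probe.transform.forward(
        truth.interp(pts[:, 0], pts[:, 1], pts[:, 2])
    ).reshape(eval_shape)

    records = []
    for r in range(n_replicates):
        seed_r = base_seed + r
        data = sample_observations(truth, scenario, noise=noise, seed=seed_r)
        checksum = data.checksum()
        ctx.set_response(data.y)
        post = lambda_posterior(ctx, prior, grid)
        for name in selectors:
            try:
                lam = _selector_lambda(
                    name, ctx, post, data, spec, penalty_order, grid, cv_folds, seed_r
                )
                if lam is None:
                    coef = np.zeros(ctx.m)
                    for w, g in zip(post.weights, post.grid):
                        if w > 1e-12:
                            coef += w * ctx.coefficients(g)
                    lam_rec = np.nan
                else:
                    coef = ctx.coefficients(lam)
                    lam_rec = lam
                surf = np.asarray(B_eval @ coef).reshape(eval_shape)
                ise = integrated_squared_error(surf, truth_vals, mask, vol)
                records.append(
                    dict(replicate=r, seed=seed_r, selector=name, ise=ise,
                         lam=lam_rec, checksum=checksum, error="")
                )
            except Exception as exc:  # a replicate failure is recorded, not fatal
                warnings.warn(
                    f"replicate {r}, selector {name} failed: {exc}", stacklevel=2
                )
                records.append(
                    dict(replicate=r, seed=seed_r, selector=name, ise=np.nan,
                         lam=np.nan, checksum=checksum, error=str(exc))
                )

    reps = pd.DataFrame.from_records(records)
    rows = []
    for name in selectors:
        vals = reps.loc[(reps.selector == name) & reps.ise.notna(), "ise"].to_numpy()
        mean = float(np.mean(vals)) if len(vals) else np.nan
        se = float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
        rows.append(dict(selector=name, mean_ise=mean, se=se, n_ok=len(vals)))
    table = pd.DataFrame(rows)
    return ComparisonResult(
        table=table, replicates=reps, scenario_id=scenario_id,
        n_replicates=n_replicates,
    )


def deletion_change(
    data: MonitoringDataset,
    spec: BasisSpec,
    penalty_order: int,
    lambda_grid: np.ndarray,
    prior: NIGPrior,
    eval_points: np.ndarray,
    n_drop: int = 4,
    seed: int = 0,
) -> dict[str, float]:
    """Max absolute prediction change after deleting low-value wells.

    Deletes ``n_drop`` wells chosen at random (seeded) among the wells with
    below-median mean response, refits, and reports the largest absolute
    change of the predicted surface at ``eval_points`` for the MAP-selected
    and the AICc-selected smoothing parameters.  The basis domains are kept
    global, so predictions before and after are directly comparable.
    """
    rng = np.random.default_rng(seed)
    wells = data.wells.astype(str)
    means = np.array(
        [data.y[np.asarray([str(w) for w in data.well]) == w].mean() for w in wells]
    )
    low = wells[means <= np.median(means)]
    if len(low) < n_drop:
        low = wells[np.argsort(means)[: max(n_drop, len(low))]]
    drop = rng.choice(low, size=n_drop, replace=False)

    pen = build_difference_penalty(spec, order=penalty_order)

    def _fit_preds(d):
        design = build_tensor_design(d, spec)
        ctx = precompute(design, pen, d.y)
        post = lambda_posterior(ctx, prior, lambda_grid)
        lam_map = post.map_lambda
        lam_aicc = select_classical(ctx, lambda_grid, "aicc").lambda_opt
        Bt = design.rows_at(eval_points[:, 0], eval_points[:, 1], eval_points[:, 2])
        return {
            "map": np.asarray(Bt @ ctx.coefficients(lam_map)),
            "aicc": np.asarray(Bt @ ctx.coefficients(lam_aicc)),
            "lam_map": lam_map,
            "lam_aicc": lam_aicc,
        }

    full = _fit_preds(data)
    reduced = _fit_preds(data.drop_wells(drop))
    return {
        "map": float(np.abs(full["map"] - reduced["map"]).max()),
        "aicc": float(np.abs(full["aicc"] - reduced["aicc"]).max()),
        "lam_map_full": full["lam_map"],
        "lam_aicc_full": full["lam_aicc"],
        "dropped": [str(w) for w in drop],
    }
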