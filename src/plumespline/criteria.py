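"""Classical smoothing-parameter selectors: AICc, GCV, BIC and k-fold CV.

All information criteria are computed from the same (RSS(λ), edf(λ))
profile as the Bayesian fit, using the Gaussian profile-likelihood forms:

    GCV(λ)  = n RSS / (n − edf)²
    AIC(λ)  = n log(RSS/n) + 2 edf
    AICc(λ) = AIC + 2 edf (edf + 1) / (n − edf − 1)
    BIC(λ)  = n log(RSS/n) + log(n) edf

Cross-validation refits the model on k seeded folds; folds either shuffle
individual observations or remove entire wells (grouped CV), the latter
respecting the clustered sampling design of monitoring networks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .basis import BasisSpec, build_tensor_design
from .data import MonitoringDataset
from .model import FitContext, precompute
from .penalty import build_difference_penalty

__all__ = [
    "SelectorResult",
    "gcv",
    "aicc",
    "bic",
    "select_classical",
    "cv_profile",
    "cv_score",
    "cv_select",
    "make_folds",
]


@dataclass
class SelectorResult:
    """Per-λ criterion values with the minimizing λ."""

    name: str
    grid: np.ndarray
    values: np.ndarray
    seed: int | None = None
    folds: list | None = None
    skipped_folds: int = 0

    @property
    def argmin_index(self) -> int:
        return int(np.argmin(self.values))

    @property
    def lambda_opt(self) -> float:
        return float(self.grid[self.argmin_index])


def _profile(ctx: FitContext, lam):
    lam = np.asarray(lam, dtype=float)
    return ctx.rss(lam), ctx.edf(lam), ctx.n


def gcv(ctx: FitContext, lam):
    """Generalized cross-validation score n·RSS/(n − edf)²."""
    rss, edf, n = _profile(ctx, lam)
    denom = (n - edf) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(edf < n, n * rss / denom, np.inf)
    if np.any(edf >= n):
        warnings.warn("edf >= n: GCV undefined, returning +inf", stacklevel=2)
    return out if out.ndim else float(out)


def aic(ctx: FitContext, lam):
    rss, edf, n = _profile(ctx, lam)
    return n * np.log(rss / n) + 2.0 * edf


def aicc(ctx: FitContext, lam):
    """Bias-corrected AIC (Hurvich–Tsai small-sample correction)."""
    rss, edf, n = _profile(ctx, lam)
    denom = n - edf - 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.where(denom > 0, 2.0 * edf * (edf + 1.0) / denom, np.inf)
    if np.any(denom <= 0):
        warnings.warn("edf >= n - 1: AICc undefined, returning +inf", stacklevel=2)
    return n * np.log(rss / n) + 2.0 * edf + corr


def bic(ctx: FitContext, lam):
    rss, edf, n = _profile(ctx, lam)
    return n * np.log(rss / n) + np.log(n) * edf


_CLASSICAL = {"gcv": gcv, "aicc": aicc, "bic": bic, "aic": aic}


def select_classical(ctx: FitContext, grid, name: str) -> SelectorResult:
    grid = np.asarray(grid, dtype=float)
    try:
        fn = _CLASSICAL[name]
    except KeyError:
        raise ValueError(f"unknown criterion {name!r}") from None
    return SelectorResult(name=name, grid=grid, values=np.asarray(fn(ctx, grid)))


def make_folds(
    data: MonitoringDataset, k: int, grouping: str, seed: int
) -> list[np.ndarray]:
    """Seeded k-fold partition of observation indices.

    ``observation`` grouping shuffles rows; ``well`` grouping shuffles whole
    wells so each fold removes entire wells.
    """
    if k < 2:
        raise ValueError("need k >= 2 folds")
    rng = np.random.default_rng(seed)
    if grouping == "observation":
        idx = rng.permutation(data.n)
        return [np.sort(part) for part in np.array_split(idx, k)]
    if grouping == "well":
        wells = data.wells.astype(str)
        if len(wells) < k:
            raise ValueError(f"well-based CV needs >= {k} wells, have {len(wells)}")
        perm = rng.permutation(len(wells))
        labels = np.asarray([str(w) for w in data.well])
        folds = []
        for part in np.array_split(perm, k):
            held = set(wells[part])
            folds.append(np.where(np.isin(labels, list(held)))[0])
        return folds
    raise ValueError("grouping must be 'observation' or 'well'")


def cv_profile(
    data: MonitoringDataset,
    spec: BasisSpec,
    penalty_order: int,
    grid,
    k: int = 10,
    grouping: str = "observation",
    seed: int = 0,
) -> SelectorResult:
    """Mean held-out squared error per λ over seeded k-fold refits.

    Each fold reuses the shared decomposition machinery on its training
    subset; held-out predictions use the global basis domains, so removed
    wells are always inside the basis support.
    """
    grid = np.asarray(grid, dtype=float)
    folds = make_folds(data, k, grouping, seed)
    pen = build_difference_penalty(spec, order=penalty_order)
    sq_err = np.zeros(len(grid))
    n_used = 0
    skipped = 0
    for held in folds:
        if len(held) == 0:
            continue
        mask = np.ones(data.n, dtype=bool)
        mask[held] = False
        train = data.subset(mask)
        test = data.subset(held)
        try:
            design = build_tensor_design(train, spec)
            ctx = precompute(design, pen, train.y)
        except np.linalg.LinAlgError as exc:
            warnings.warn(f"fold skipped (singular training system): {exc}", stacklevel=2)
            skipped += 1
            continue
        Bt = design.rows_at(test.s1, test.s2, test.t)
        coefs = np.column_stack([ctx.coefficients(lam) for lam in grid])
        pred = Bt @ coefs  # (n_test, n_lambda)
        sq_err += np.sum((pred - test.y[:, None]) ** 2, axis=0)
        n_used += len(held)
    if n_used == 0:
        raise RuntimeError("all CV folds failed")
    return SelectorResult(
        name=f"cv-{grouping}",
        grid=grid,
        values=sq_err / n_used,
        seed=seed,
        folds=folds,
        skipped_folds=skipped,
    )


def cv_score(
    data: MonitoringDataset,
    spec: BasisSpec,
    penalty_order: int,
    lam: float,
    k: int = 10,
    grouping: str = "observation",
    seed: int = 0,
) -> float:
    """Mean squared held-out prediction error at a single λ."""
    res = cv_profile(
        data, spec, penalty_order, np.asarray([float(lam)]), k=k,
        grouping=grouping, seed=seed,
    )
    return float(res.values[0])


def cv_select(
    data: MonitoringDataset,
    spec: BasisSpec,
    penalty_order: int,
    grid,
    k: int = 10,
    grouping: str = "observation",
    seed: int = 0,
) -> SelectorResult:
    """k-fold CV selector: λ minimizing the held-out squared error."""
    return cv_profile(data, spec, penalty_order, grid, k=k, grouping=grouping, seed=seed)
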