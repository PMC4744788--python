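"""Conjugate Bayesian P-spline fit with a cheap profile over the smoothing parameter.

Model
-----
On the transformed scale, ``y = B α + ε`` with ``ε ~ N(0, σ² I)`` and the
normal–inverse-gamma prior ``α, σ² ~ NIG(0, (λ D'D)^{-1}, a, b)``.  The
penalty cross-product ``D'D`` is rank deficient; its null space carries a
flat improper prior while the orthogonal complement carries a proper
Gaussian prior.  The marginal posterior over the smoothing parameter is

    f(λ | y) ∝ λ^{rank(D'D)/2} |B'B + λ D'D|^{-1/2}
               [2b + y'(I − B (B'B + λD'D)^{-1} B') y]^{-(a + n/2)} f(λ)

up to a λ-free constant, with a flat improper prior on λ by default.  λ is
either fixed at its MAP over a log-spaced grid or integrated out numerically
(model averaging).

Computation
-----------
All λ-dependent quantities are obtained from a single decomposition.  With
Z an orthonormal basis of null(D) and X its complement, the null-space
component of the fit is projected out (thin QR of BZ), the penalized
component is whitened by S^{-1/2} where S = X'(D'D)X, and the whitened
cross-product is diagonalized by one dense symmetric eigendecomposition —
the only dense O(m³) step, everything before it sparse.  Afterwards RSS(λ),
the generalized log-determinant, the effective degrees of freedom, the log
posterior and the coefficient posterior all cost O(m) arithmetic per λ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .basis import BasisSpec, TensorDesign, build_tensor_design
from .data import MonitoringDataset, ResponseTransform
from .penalty import PenaltyMatrix, build_difference_penalty

__all__ = [
    "NIGPrior",
    "ModelSizeError",
    "FitContext",
    "LambdaPosterior",
    "PredictionGrid",
    "FitResult",
    "default_lambda_grid",
    "precompute",
    "log_lambda_posterior",
    "lambda_posterior",
    "select_map",
    "effective_df",
    "predict",
    "model_average_predict",
    "fit",
]

#: default guardrail on the number of tensor coefficients: 25 basis functions
#: per dimension already implies a 15,625 × 15,625 cross-product matrix,
#: beyond what this desk-scale implementation will factorize without an
#: explicit override.
MAX_COEFFICIENTS = 10_000

_SPECTRUM_FLOOR = 1e-12  # relative floor below which spectrum values count as 0


class ModelSizeError(ValueError):
    """Raised when the coefficient space exceeds the configured guardrail."""

    def __init__(self, m: int, max_m: int):
        self.m = m
        self.max_m = max_m
        super().__init__(
            f"model has m = {m} tensor coefficients, implying an {m} x {m} "
            f"cross-product matrix; this exceeds the guardrail of {max_m}. "
            "Reduce the basis sizes or pass allow_large=True."
        )


@dataclass(frozen=True)
class NIGPrior:
    """Normal–inverse-gamma hyperparameters for (α, σ²); a = b = 1e-4 default."""

    a: float = 1e-4
    b: float = 1e-4

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("prior shape and scale must be positive")


def default_lambda_grid(lo: float = 1e-6, hi: float = 1e8, size: int = 81) -> np.ndarray:
    """Log-spaced grid of candidate smoothing parameters."""
    return np.logspace(np.log10(lo), np.log10(hi), size)


class FitContext:
    """One-time decomposition of a penalized spline problem.

    Built by :func:`precompute`; exposes O(m)-per-λ evaluation of all the
    quantities the λ profile needs.
    """

    def __init__(self, design: TensorDesign, pen: PenaltyMatrix, y: np.ndarray):
        B = design.B
        n, m = B.shape
        y = np.asarray(y, dtype=float)
        if len(y) != n:
            raise ValueError("response length does not match design rows")
        self.design = design
        self.penalty = pen
        self.n = n
        self.m = m
        q = pen.null_dim
        self.q = q
        self.rank_dtd = pen.rank

        # orthonormal split of coefficient space: Z spans null(D), X its
        # complement; the whitener Linv is penalty-only and cached there
        Z, X, Linv = pen.whitened_split()
        self._Z = Z
        self._X = X

        F = np.asarray(B @ Z)  # n x q, unpenalized directions in data space
        Qf, Rf = np.linalg.qr(F)
        rdiag = np.abs(np.diag(Rf))
        tol = 1e-10 * max(rdiag.max(initial=0.0), 1.0)
        deficient = rdiag.size < q or (rdiag.size > 0 and rdiag.min() <= tol)
        if deficient:
            bad = [i for i in range(q) if i >= rdiag.size or rdiag[i] <= tol]
            raise np.linalg.LinAlgError(
                "penalized system singular for every λ: the data do not "
                f"identify unpenalized (null-space) direction(s) {bad}"
            )
        self._F = F
        self._Qf = Qf

        G = np.asarray(B @ X)  # n x (m-q)
        Gt = G - Qf @ (Qf.T @ G)  # project out unpenalized fit

        M = Linv.T @ (Gt.T @ Gt) @ Linv
        M = 0.5 * (M + M.T)
        s2, V = np.linalg.eigh(M)  # the only dense O(m^3) step
        s2 = np.clip(s2, 0.0, None)
        if s2.size:
            s2[s2 < _SPECTRUM_FLOOR * s2.max()] = 0.0
        self.spectrum = s2  # length m - q
        self._T = Linv @ V  # maps diagonal coords δ to penalized coords γ
        self._G = G
        self._Gt = Gt
        self._A11 = F.T @ F
        self._lazy: dict[str, np.ndarray] = {}

        self.rank_b = q + int(np.count_nonzero(s2))
        self._dense_solve_count = 0  # instrumentation: dense path touches
        self.set_response(y)

    # prediction-only pieces, formed on first use (fits that never predict
    # with intervals — e.g. CV folds — skip these dense products entirely)
    @property
    def _W(self) -> np.ndarray:
        if "W" not in self._lazy:
            self._lazy["W"] = self._X @ self._T
        return self._lazy["W"]

    @property
    def _Hw(self) -> np.ndarray:
        if "Hw" not in self._lazy:
            self._lazy["Hw"] = self._Gt @ self._T
        return self._lazy["Hw"]

    @property
    def _A12(self) -> np.ndarray:
        if "A12" not in self._lazy:
            self._lazy["A12"] = (self._F.T @ self._G) @ self._T
        return self._lazy["A12"]

    @property
    def _J(self) -> np.ndarray:
        if "J" not in self._lazy:
            self._lazy["J"] = np.linalg.solve(self._A11, self._A12)
        return self._lazy["J"]

    # -- response-dependent pieces (cheap; reusable decomposition) ----------
    def set_response(self, y: np.ndarray) -> "FitContext":
        y = np.asarray(y, dtype=float)
        if len(y) != self.n:
            raise ValueError("response length mismatch")
        self.y = y
        yt = y - self._Qf @ (self._Qf.T @ y)
        self._yty_tilde = float(yt @ yt)
        c = self._T.T @ (self._Gt.T @ yt)
        c[self.spectrum == 0.0] = 0.0
        self._c = c
        self._Fty = self._F.T @ y
        return self

    # -- O(m)-per-λ profile quantities --------------------------------------
    def rss(self, lam):
        """Plain residual sum of squares ‖y − ŷ(λ)‖² (classical criteria)."""
        lam = np.asarray(lam, dtype=float)
        s2 = self.spectrum
        num = self._c**2 * (s2 + 2.0 * lam[..., None])
        den = (s2 + lam[..., None]) ** 2
        out = self._yty_tilde - np.sum(num / den, axis=-1)
        return np.maximum(out, 0.0)

    def rss_penalized(self, lam):
        """Minimized penalized objective y'(I − B(B'B+λD'D)^{-1}B')y.

        Equals ‖y − ŷ‖² + λ‖Dα̂‖²; this is the quantity in the posterior
        kernel and in the NIG posterior scale b_n.
        """
        lam = np.asarray(lam, dtype=float)
        out = self._yty_tilde - np.sum(
            self._c**2 / (self.spectrum + lam[..., None]), axis=-1
        )
        return np.maximum(out, 0.0)

    def edf(self, lam):
        """Effective degrees of freedom tr(B (B'B+λD'D)^{-1} B')."""
        lam = np.asarray(lam, dtype=float)
        if np.any(lam < 0):
            raise ValueError("λ must be >= 0")
        s2 = self.spectrum
        pos = s2 > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(pos, s2 / (s2 + lam[..., None]), 0.0)
        return self.q + np.sum(frac, axis=-1)

    def logdet_gen(self, lam):
        """log|B'B + λD'D| up to a λ-free additive constant."""
        lam = np.asarray(lam, dtype=float)
        return np.sum(np.log(self.spectrum + lam[..., None]), axis=-1)

    def coefficients(self, lam: float) -> np.ndarray:
        """Posterior mean of α at a fixed λ (= penalized LS estimate)."""
        lam = float(lam)
        if lam < 0:
            raise ValueError("λ must be >= 0")
        denom = self.spectrum + lam
        with np.errstate(invalid="ignore", divide="ignore"):
            delta = np.where(denom > 0, self._c / np.where(denom > 0, denom, 1.0), 0.0)
        beta = np.linalg.solve(self._A11, self._Fty - self._A12 @ delta)
        return self._Z @ beta + self._X @ (self._T @ delta)

    def quad_forms(self, rows_z: np.ndarray, rows_v: np.ndarray, lam: float) -> np.ndarray:
        """x'(B'B+λD'D)^{-1}x for target rows given their split coordinates."""
        base = np.einsum(
            "ij,ij->i", rows_z, np.linalg.solve(self._A11, rows_z.T).T
        )
        g = rows_z @ self._J - rows_v
        return base + np.sum(g**2 / (self.spectrum + lam), axis=1)

    def target_coordinates(self, Bt):
        """Split a sparse target design into (null, diagonalized) coordinates."""
        rows_z = np.asarray(Bt @ self._Z)
        rows_v = np.asarray(Bt @ self._W)
        return rows_z, rows_v

    # -- marginal posterior of λ --------------------------------------------
    def log_posterior(self, lam, prior: NIGPrior, log_prior_lambda=None):
        """Log marginal posterior kernel of λ, up to a λ-free constant."""
        lam = np.asarray(lam, dtype=float)
        if np.any(lam <= 0):
            raise ValueError("λ must be > 0")
        rss = self.rss_penalized(lam)
        lp = (
            0.5 * self.rank_dtd * np.log(lam)
            - 0.5 * self.logdet_gen(lam)
            - (prior.a + 0.5 * self.n) * np.log(2.0 * prior.b + rss)
        )
        if log_prior_lambda is not None:
            lp = lp + log_prior_lambda(lam)
        if not np.all(np.isfinite(lp)):
            bad = np.atleast_1d(lam)[~np.isfinite(np.atleast_1d(lp))]
            raise FloatingPointError(f"non-finite log posterior at λ = {bad[:3]}")
        return lp


@dataclass
class LambdaPosterior:
    """Discrete posterior of the smoothing parameter over a log-spaced grid."""

    grid: np.ndarray
    log_posterior: np.ndarray
    map_index: int
    weights: np.ndarray

    @property
    def map_lambda(self) -> float:
        return float(self.grid[self.map_index])


@dataclass
class PredictionGrid:
    """Predictions with pointwise credible bounds at the stated level."""

    s1: np.ndarray
    s2: np.ndarray
    t: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float
    in_hull: np.ndarray | None = None


def precompute(
    design: TensorDesign,
    pen: PenaltyMatrix,
    y: np.ndarray,
    *,
    max_m: int = MAX_COEFFICIENTS,
    allow_large: bool = False,
) -> FitContext:
    """One-time decomposition; refuses oversized coefficient spaces by default."""
    m = design.m
    if m != pen.m:
        raise ValueError("design and penalty dimensions differ")
    if m > max_m and not allow_large:
        raise ModelSizeError(m, max_m)
    return FitContext(design, pen, y)


def log_lambda_posterior(
    ctx: FitContext, prior: NIGPrior, lam, log_prior_lambda=None
):
    """Log marginal posterior of λ (flat improper prior on λ by default)."""
    return ctx.log_posterior(lam, prior, log_prior_lambda)


def lambda_posterior(
    ctx: FitContext, prior: NIGPrior, grid: np.ndarray, log_prior_lambda=None
) -> LambdaPosterior:
    """Evaluate the λ profile on a grid and normalize to posterior masses."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty λ grid")
    if np.any(np.diff(grid) < 0):
        raise ValueError("λ grid must be sorted ascending")
    lp = ctx.log_posterior(grid, prior, log_prior_lambda)
    shifted = lp - lp.max()
    w = np.exp(shifted)
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        raise FloatingPointError("posterior weights degenerate on this grid")
    return LambdaPosterior(
        grid=grid,
        log_posterior=lp,
        map_index=int(np.argmax(lp)),
        weights=w / total,
    )


def select_map(
    ctx: FitContext,
    prior: NIGPrior,
    grid: np.ndarray,
    strict: bool = False,
    log_prior_lambda=None,
) -> tuple[float, LambdaPosterior]:
    """MAP smoothing parameter from the gridded posterior profile."""
    post = lambda_posterior(ctx, prior, grid, log_prior_lambda)
    i = post.map_index
    if i in (0, len(post.grid) - 1):
        msg = (
            f"posterior maximum at grid boundary (λ = {post.grid[i]:.3g}); "
            "consider extending the grid"
        )
        if strict and len(post.grid) > 1:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
    return post.map_lambda, post


def effective_df(ctx: FitContext, lam) -> np.ndarray | float:
    """Effective degrees of freedom at λ (trace of the smoother matrix)."""
    out = ctx.edf(lam)
    return float(out) if np.ndim(out) == 0 else out


def _posterior_scale(ctx: FitContext, prior: NIGPrior, lam: float, qf: np.ndarray):
    a_n = prior.a + 0.5 * ctx.n
    b_n = prior.b + 0.5 * float(ctx.rss_penalized(np.asarray(lam)))
    return a_n, b_n, np.sqrt(np.maximum(qf, 0.0) * b_n / a_n)


def predict(
    ctx: FitContext,
    lam: float,
    targets,
    level: float = 0.95,
    prior: NIGPrior | None = None,
    extrapolate: bool = False,
    transform: ResponseTransform | None = None,
) -> PredictionGrid:
    """Posterior mean surface and pointwise credible bounds at fixed λ.

    ``targets`` is a tuple of (s1, s2, t) arrays.  Credible bounds come from
    the marginal Student-t implied by the NIG posterior, with 2(a + n/2)
    degrees of freedom.  If ``transform`` is given, mean and bounds are
    mapped back to concentration units (monotone, so quantiles carry over).
    """
    prior = prior or NIGPrior()
    if not 0.0 <= level < 1.0:
        raise ValueError("credible level must be in [0, 1)")
    s1, s2, t = (np.atleast_1d(np.asarray(v, dtype=float)) for v in targets)
    Bt = ctx.design.rows_at(s1, s2, t, extrapolate=extrapolate)
    mean = Bt @ ctx.coefficients(lam)
    rows_z, rows_v = ctx.target_coordinates(Bt)
    qf = ctx.quad_forms(rows_z, rows_v, float(lam))
    a_n, _, scale = _posterior_scale(ctx, prior, lam, qf)
    tq = stats.t.ppf(0.5 + level / 2.0, df=2.0 * a_n) if level > 0 else 0.0
    lower = mean - tq * scale
    upper = mean + tq * scale
    if transform is not None:
        mean, lower, upper = (transform.inverse(v) for v in (mean, lower, upper))
    return PredictionGrid(s1=s1, s2=s2, t=t, mean=mean, lower=lower, upper=upper, level=level)


def model_average_predict(
    ctx: FitContext,
    prior: NIGPrior,
    grid: np.ndarray,
    targets,
    level: float | None = 0.95,
    weight_floor: float = 1e-10,
    extrapolate: bool = False,
    transform: ResponseTransform | None = None,
) -> PredictionGrid:
    """Model-averaged prediction, numerically integrating out λ.

    Posterior weights are the normalized masses on the λ grid (discrete
    quadrature).  The predictive mean is the weighted mean over λ; credible
    bounds are quantiles of the mixture of marginal Student-t distributions,
    found by vectorized bisection on the mixture CDF.  ``level=None`` skips
    the bounds (mean only).
    """
    post = lambda_posterior(ctx, prior, grid)
    s1, s2, t = (np.atleast_1d(np.asarray(v, dtype=float)) for v in targets)
    Bt = ctx.design.rows_at(s1, s2, t, extrapolate=extrapolate)
    keep = np.where(post.weights > weight_floor)[0]
    w = post.weights[keep]
    w = w / w.sum()
    lams = post.grid[keep]
    means = np.empty((len(keep), Bt.shape[0]))
    for i, lam in enumerate(lams):
        means[i] = Bt @ ctx.coefficients(lam)
    mix_mean = w @ means

    if level is None or level == 0.0:
        mean_out, lo_out, hi_out = mix_mean, mix_mean.copy(), mix_mean.copy()
        if transform is not None:
            mean_out, lo_out, hi_out = (
                transform.inverse(v) for v in (mean_out, lo_out, hi_out)
            )
        return PredictionGrid(
            s1=s1, s2=s2, t=t, mean=mean_out, lower=lo_out, upper=hi_out,
            level=float(level or 0.0),
        )

    rows_z, rows_v = ctx.target_coordinates(Bt)
    a_n = prior.a + 0.5 * ctx.n
    df = 2.0 * a_n
    scales = np.empty_like(means)
    for i, lam in enumerate(lams):
        qf = ctx.quad_forms(rows_z, rows_v, float(lam))
        _, _, scales[i] = _posterior_scale(ctx, prior, lam, qf)
    scales = np.maximum(scales, 1e-300)

    tq = stats.t.ppf(0.5 + level / 2.0, df=df)
    lo = np.min(means - 1.5 * tq * scales - 1e-12, axis=0)
    hi = np.max(means + 1.5 * tq * scales + 1e-12, axis=0)

    def mixture_cdf(x):
        z = (x[None, :] - means) / scales
        return w @ stats.t.cdf(z, df=df)

    def mixture_quantile(p):
        a, b_ = lo.copy(), hi.copy()
        for _ in range(80):
            mid = 0.5 * (a + b_)
            below = mixture_cdf(mid) < p
            a = np.where(below, mid, a)
            b_ = np.where(below, b_, mid)
        return 0.5 * (a + b_)

    lower = mixture_quantile(0.5 - level / 2.0)
    upper = mixture_quantile(0.5 + level / 2.0)
    lower = np.minimum(lower, mix_mean)
    upper = np.maximum(upper, mix_mean)
    if transform is not None:
        mix_mean, lower, upper = (transform.inverse(v) for v in (mix_mean, lower, upper))
    return PredictionGrid(
        s1=s1, s2=s2, t=t, mean=mix_mean, lower=lower, upper=upper, level=level
    )


@dataclass
class FitResult:
    """Fitted model: context, λ posterior, selection, and per-λ summaries."""

    ctx: FitContext
    prior: NIGPrior
    posterior: LambdaPosterior
    selector: str
    selected_lambda: float | None  # None for model averaging
    edf_profile: np.ndarray = field(repr=False)
    rss_profile: np.ndarray = field(repr=False)
    transform: ResponseTransform | None = None

    @property
    def a_n(self) -> float:
        return self.prior.a + 0.5 * self.ctx.n

    def b_n(self, lam: float) -> float:
        return self.prior.b + 0.5 * float(self.ctx.rss_penalized(np.asarray(lam)))

    @property
    def edf_selected(self) -> float:
        lam = self.selected_lambda
        if lam is None:
            return float(self.posterior.weights @ self.edf_profile)
        return float(self.ctx.edf(np.asarray(lam)))

    def predict(
        self, targets, level: float = 0.95, back_transform: bool = False,
        extrapolate: bool = False,
    ) -> PredictionGrid:
        tr = self.transform if back_transform else None
        if self.selected_lambda is None:
            return model_average_predict(
                self.ctx, self.prior, self.posterior.grid, targets,
                level=level, extrapolate=extrapolate, transform=tr,
            )
        return predict(
            self.ctx, self.selected_lambda, targets, level=level,
            prior=self.prior, extrapolate=extrapolate, transform=tr,
        )

    def summary(self) -> dict:
        """JSON-serializable report of the fit."""
        sel = self.selected_lambda
        return {
            "n_obs": self.ctx.n,
            "m_coefficients": self.ctx.m,
            "basis": {
                "sizes": list(self.ctx.design.spec.sizes),
                "degree": self.ctx.design.spec.degree,
                "domains": [list(d) for d in self.ctx.design.spec.domains],
            },
            "penalty_order": self.ctx.penalty.order,
            "prior": {"a": self.prior.a, "b": self.prior.b},
            "selector": self.selector,
            "selected_lambda": None if sel is None else float(sel),
            "map_lambda": self.posterior.map_lambda,
            "edf_selected": self.edf_selected,
            "a_n": self.a_n,
            "b_n_at_map": self.b_n(self.posterior.map_lambda),
            "lambda_grid": self.posterior.grid.tolist(),
            "log_posterior": self.posterior.log_posterior.tolist(),
        }


def fit(
    data: MonitoringDataset,
    n_basis: tuple[int, int, int] = (14, 8, 5),
    degree: int = 2,
    penalty_order: int = 1,
    prior: NIGPrior | None = None,
    lambda_grid: np.ndarray | None = None,
    selector: str = "map",
    cv_folds: int = 10,
    seed: int = 0,
    spec: BasisSpec | None = None,
    max_m: int = MAX_COEFFICIENTS,
    allow_large: bool = False,
) -> FitResult:
    """Fit the spatiotemporal P-spline model and select its smoothing parameter.

    ``selector`` is one of ``map``, ``average``, ``aicc``, ``gcv``, ``bic``,
    ``cv-obs``, ``cv-well``.
    """
    prior = prior or NIGPrior()
    grid = default_lambda_grid() if lambda_grid is None else np.asarray(lambda_grid, float)
    spec = spec or BasisSpec.from_data(data, n_basis, degree=degree)
    design = build_tensor_design(data, spec)
    pen = build_difference_penalty(spec, order=penalty_order)
    ctx = precompute(design, pen, data.y, max_m=max_m, allow_large=allow_large)
    post = lambda_posterior(ctx, prior, grid)

    if selector in ("map", "average"):
        lam = None if selector == "average" else post.map_lambda
    elif selector in ("aicc", "gcv", "bic"):
        from .criteria import select_classical

        lam = select_classical(ctx, grid, selector).lambda_opt
    elif selector in ("cv-obs", "cv-well"):
        from .criteria import cv_select

        grouping = "well" if selector == "cv-well" else "observation"
        lam = cv_select(
            data, spec, penalty_order, grid, k=cv_folds, grouping=grouping,
            seed=seed,
        ).lambda_opt
    else:
        raise ValueError(f"unknown selector {selector!r}")

    return FitResult(
        ctx=ctx,
        prior=prior,
        posterior=post,
        selector=selector,
        selected_lambda=lam,
        edf_profile=ctx.edf(grid),
        rss_profile=ctx.rss(grid),
        transform=data.transform,
    )
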