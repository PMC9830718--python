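"""Least-trimmed-squares regression of pseudo-values on group and covariates.

For each gene k the model

    E[theta_tilde_ik | Z_i, X_i] = alpha_k + beta_k Z_i + gamma_k1 X_i1 + ...

is fitted robustly by least trimmed squares (LTS): minimise the sum of the h
smallest squared residuals, h = floor(n * coverage_fraction). The optimum is
located FAST-LTS style — random elemental starts followed by concentration
steps (each C-step refits OLS on the current h best-fitting observations,
which never increases the objective), with full convergence on the best
candidates.

Inference on beta_k follows the reweighted-LTS recipe of the robustbase
ltsReg estimator: the trimmed residual scale is rescaled by the normal-model
consistency factor, observations within 2.5 sigma of the LTS fit are
retained, and classical OLS standard errors / t-tests (df = n_retained - d)
on the retained set give the p-value for H0: beta_k = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .containers import PseudoValueMatrix

__all__ = ["LTSConfig", "DesignMatrix", "LTSFit", "GeneRegressionResult", "fit_lts", "prana_regression"]


@dataclass(frozen=True)
class LTSConfig:
    """FAST-LTS search settings.

    coverage_fraction is h/n, the fraction of observations whose squared
    residuals enter the objective; 1.0 reduces LTS to OLS. Values in
    (0.5, 1] keep the estimator's breakdown point meaningful. The search is
    deterministic given ``seed``.
    """

    coverage_fraction: float = 0.75
    n_subsets: int = 500
    n_keep: int = 10
    n_initial_csteps: int = 2
    max_csteps: int = 50
    reweight_threshold: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.5 < self.coverage_fraction <= 1.0:
            raise ValueError("coverage_fraction must be in (0.5, 1]")


@dataclass
class DesignMatrix:
    """Group indicator plus optional numeric covariates, row-aligned with the
    pseudo-value matrix. The group is coded 0/1 internally; only beta's test
    is invariant to that choice, the intercept is not."""

    z: np.ndarray
    x: np.ndarray | None = None
    sample_ids: list[str] | None = None
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        uniq = np.unique(self.z)
        if uniq.size > 2:
            raise ValueError("group indicator must be binary")
        if uniq.size == 2:
            self.z = (self.z == uniq.max()).astype(float)
        if self.x is None:
            self.x = np.empty((self.z.shape[0], 0))
        self.x = np.asarray(self.x, dtype=float)
        if self.x.ndim == 1:
            self.x = self.x[:, None]
        if self.x.shape[0] != self.z.shape[0]:
            raise ValueError("covariates and group indicator length mismatch")
        if not np.all(np.isfinite(self.x)) or not np.all(np.isfinite(self.z)):
            raise ValueError("design matrix must be finite (no missing values)")
        if not self.covariate_names:
            self.covariate_names = [f"x{j + 1}" for j in range(self.x.shape[1])]

    @property
    def n(self) -> int:
        return self.z.shape[0]

    @property
    def q(self) -> int:
        return self.x.shape[1]

    def full_matrix(self) -> np.ndarray:
        return np.column_stack([np.ones(self.n), self.z, self.x])


@dataclass
class LTSFit:
    """Raw LTS solution plus the reweighted inference actually reported."""

    raw_coef: np.ndarray          # minimiser of the trimmed objective
    coef: np.ndarray              # reweighted-OLS coefficients (inference)
    se: np.ndarray
    t_stat: np.ndarray
    p_value: np.ndarray
    h_subset: np.ndarray          # indices of the h retained observations
    objective: float              # sum of h smallest squared residuals
    scale: float                  # consistency-corrected residual scale
    df: int
    n_reweighted: int


@dataclass
class GeneRegressionResult:
    gene_id: str
    alpha: float
    beta: float
    gamma: np.ndarray
    se_beta: float
    t_stat: float
    p_value: float
    q_value: float | None = None
    error: str | None = None


def _batched_ols(xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """OLS coefficients for a batch of (h x d) designs; pinv fallback."""
    gram = np.einsum("cij,cik->cjk", xs, xs)
    rhs = np.einsum("cij,ci->cj", xs, ys)
    try:
        return np.linalg.solve(gram, rhs[..., None])[..., 0]
    except np.linalg.LinAlgError:
        # singular subsets (e.g. elemental draws with a constant group column)
        return np.einsum("cjk,ck->cj", np.linalg.pinv(gram), rhs)


def _trimmed_objective(coefs: np.ndarray, x: np.ndarray, y: np.ndarray, h: int):
    resid = y[None, :] - coefs @ x.T
    part = np.argpartition(np.abs(resid), h - 1, axis=1)[:, :h]
    obj = np.take_along_axis(resid, part, axis=1) ** 2
    return obj.sum(axis=1), part


def _consistency_factor(alpha: float) -> float:
    # E[Z^2 | central alpha mass] / 1 for a standard normal
    if alpha >= 1.0:
        return 1.0
    q = stats.norm.ppf((1.0 + alpha) / 2.0)
    return 1.0 - 2.0 * q * stats.norm.pdf(q) / alpha


def _rejection_consistency(q: float) -> float:
    # variance retained by a normal after hard rejection at |z| > q
    p = 2.0 * stats.norm.cdf(q) - 1.0
    return 1.0 - 2.0 * q * stats.norm.pdf(q) / p


def fit_lts(y, design: DesignMatrix, config: LTSConfig | None = None) -> LTSFit:
    """FAST-LTS fit of y on [1, z, covariates] with reweighted inference."""
    config = config or LTSConfig()
    y = np.asarray(y, dtype=float)
    x = design.full_matrix()
    n, d = x.shape
    h = int(np.floor(n * config.coverage_fraction))
    if h < d:
        raise ValueError("h must be at least the number of parameters (q + 2)")
    if np.linalg.matrix_rank(x) < d:
        raise ValueError("singular design")
    rng = np.random.default_rng(config.seed)

    if h == n:
        raw, *_ = np.linalg.lstsq(x, y, rcond=None)
    else:
        # elemental starts (+ the full OLS solution as one candidate)
        subsets = np.stack(
            [rng.choice(n, size=d, replace=False) for _ in range(config.n_subsets)]
        )
        coefs = _batched_ols(x[subsets], y[subsets])
        ols_full, *_ = np.linalg.lstsq(x, y, rcond=None)
        coefs = np.vstack([coefs, ols_full])
        for _ in range(config.n_initial_csteps):
            _, part = _trimmed_objective(coefs, x, y, h)
            coefs = _batched_ols(x[part], y[part])
        obj, _ = _trimmed_objective(coefs, x, y, h)
        keep = np.argsort(obj)[: config.n_keep]
        coefs = coefs[keep]
        # concentrate the survivors to local convergence
        prev = None
        for _ in range(config.max_csteps):
            obj, part = _trimmed_objective(coefs, x, y, h)
            part_sorted = np.sort(part, axis=1)
            if prev is not None and np.array_equal(part_sorted, prev):
                break
            prev = part_sorted
            coefs = _batched_ols(x[part], y[part])
        obj, _ = _trimmed_objective(coefs, x, y, h)
        raw = coefs[np.argmin(obj)]

    resid = y - x @ raw
    order = np.argsort(np.abs(resid), kind="stable")
    h_subset = np.sort(order[:h])
    objective = float(np.sum(resid[h_subset] ** 2))

    # consistency- and df-corrected scale from the trimmed residuals, with a
    # finite-sample factor (~ (1 - 3/n)^-1) for the small-n downward bias of
    # the trimmed scale under normal errors
    factor = _consistency_factor(h / n)
    scale = float(np.sqrt(objective / max(h - d, 1) / factor))
    if h < n and n > 6:
        scale /= 1.0 - 3.0 / n

    if h == n or scale == 0:
        weights = np.ones(n, dtype=bool)  # coverage 1: plain OLS, no trimming
    else:
        weights = np.abs(resid) <= config.reweight_threshold * scale
    if weights.sum() < d:
        weights = np.zeros(n, dtype=bool)
        weights[h_subset] = True
    xw, yw = x[weights], y[weights]
    nw = int(weights.sum())
    coef, *_ = np.linalg.lstsq(xw, yw, rcond=None)
    df = nw - d
    rss = float(np.sum((yw - xw @ coef) ** 2))
    xtx_inv = np.linalg.pinv(xw.T @ xw)
    if df > 0:
        s2 = rss / df
        if nw < n:  # residual variance lost to the 2.5-sigma rejection step
            s2 /= _rejection_consistency(config.reweight_threshold)
        se = np.sqrt(np.maximum(s2 * np.diag(xtx_inv), 0.0))
    else:
        se = np.zeros(d)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = np.where(se > 0, coef / se, np.where(np.abs(coef) > 1e-12, np.inf, 0.0))
    t_stat = np.where(np.isfinite(t_stat), t_stat, np.sign(coef) * np.inf)
    p_value = np.where(
        np.isinf(t_stat),
        0.0,
        2.0 * stats.t.sf(np.abs(t_stat), max(df, 1)),
    )
    p_value = np.where((se == 0) & (np.abs(coef) <= 1e-12), 1.0, p_value)
    return LTSFit(
        raw_coef=raw,
        coef=coef,
        se=se,
        t_stat=t_stat,
        p_value=np.clip(p_value, 0.0, 1.0),
        h_subset=h_subset,
        objective=objective,
        scale=scale,
        df=max(df, 0),
        n_reweighted=nw,
    )


def prana_regression(
    pv: PseudoValueMatrix, design: DesignMatrix, config: LTSConfig | None = None
) -> list[GeneRegressionResult]:
    """One LTS fit per gene; per-gene sub-seeds derive from ``config.seed``.

    Genes whose fit fails are recorded with an error message rather than
    aborting the batch. q-values are filled in by the multiple-testing step.
    """
    config = config or LTSConfig()
    if pv.values.shape[0] != design.n:
        raise ValueError("pseudo-value matrix and design are not row-aligned")
    seeds = np.random.SeedSequence(config.seed).generate_state(pv.values.shape[1])
    results: list[GeneRegressionResult] = []
    for k, gene in enumerate(pv.gene_ids):
        cfg_k = LTSConfig(
            coverage_fraction=config.coverage_fraction,
            n_subsets=config.n_subsets,
            n_keep=config.n_keep,
            n_initial_csteps=config.n_initial_csteps,
            max_csteps=config.max_csteps,
            reweight_threshold=config.reweight_threshold,
            seed=int(seeds[k]),
        )
        try:
            fit = fit_lts(pv.values[:, k], design, cfg_k)
        except (ValueError, np.linalg.LinAlgError) as exc:
            results.append(
                GeneRegressionResult(
                    gene, np.nan, np.nan, np.full(design.q, np.nan),
                    np.nan, np.nan, np.nan, error=str(exc),
                )
            )
            continue
        results.append(
            GeneRegressionResult(
                gene_id=gene,
                alpha=float(fit.coef[0]),
                beta=float(fit.coef[1]),
                gamma=fit.coef[2:].copy(),
                se_beta=float(fit.se[1]),
                t_stat=float(fit.t_stat[1]),
                p_value=float(fit.p_value[1]),
            )
        )
    return results
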