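"""Mutual-information association networks from expression profiles.

The association between each pair of genes is measured by mutual information
(MI), estimated with the Gaussian-kernel plug-in estimator used by ARACNE:
profiles are first copula-transformed (rank-mapped to (0, 1), which makes the
estimate invariant to monotone reparameterisation of each gene), the joint and
marginal densities are estimated by kernel density estimation at the observed
points, and

    I_hat_jk = (1/n) sum_i log f(g_ij, g_ik) / (f(g_ij) f(g_ik)).

Negative plug-in estimates are clipped to zero so that total connectivity is
monotone in edge strength. Optional data-processing-inequality (DPI) pruning
removes the weakest edge of each triangle, as in ARACNE proper.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .containers import AssociationMatrix, ExpressionMatrix

__all__ = ["MIConfig", "copula_transform", "estimate_mi_matrix", "apply_dpi"]

_SQRT2PI = np.sqrt(2.0 * np.pi)


@dataclass(frozen=True)
class MIConfig:
    """Settings for MI-matrix estimation.

    copula: apply the rank transform internally (assumed already applied if False).
    joint_bw_exponent / marginal_bw_exponent: normal-reference bandwidths
        h = sd * n**exponent per dimension (-1/6 bivariate, -1/5 univariate).
    dpi: apply DPI pruning to the association matrix; off by default, so the
        total-connectivity pipeline sums the raw MI matrix.
    """

    copula: bool = True
    joint_bw_exponent: float = -1.0 / 6.0
    marginal_bw_exponent: float = -1.0 / 5.0
    dpi: bool = False
    dpi_tolerance: float = 0.0


def copula_transform(expr):
    """Map each gene column to its empirical ranks scaled by 1/(n+1).

    Average ranks are used for ties, keeping all outputs strictly inside
    (0, 1). A constant column collapses to 0.5 everywhere (with a warning)
    since ranks carry no information there.

    Accepts and returns either an :class:`ExpressionMatrix` or a plain array.
    """
    if isinstance(expr, ExpressionMatrix):
        u = copula_transform(expr.values)
        return ExpressionMatrix(u, expr.sample_ids, expr.gene_ids)
    values = np.asarray(expr, dtype=float)
    n = values.shape[0]
    constant = np.ptp(values, axis=0) == 0
    if np.any(constant):
        warnings.warn(
            "constant expression column(s) collapse to 0.5 under the copula transform",
            UserWarning,
            stacklevel=2,
        )
    ranks = rankdata(values, axis=0, method="average")
    return ranks / (n + 1.0)


def _mi_from_uniform(u: np.ndarray, config: MIConfig) -> np.ndarray:
    """Kernel plug-in MI for every gene pair of copula-transformed data."""
    n, p = u.shape
    sd = u.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)  # constant column: any bandwidth, MI clips to 0
    h_joint = sd * n**config.joint_bw_exponent
    h_marg = sd * n**config.marginal_bw_exponent

    # diff[i, l, j] = u[i, j] - u[l, j]
    diff = u[:, None, :] - u[None, :, :]
    # per-column kernel matrices with the bivariate bandwidth: K[j, i, l]
    kern = np.exp(-0.5 * (diff / h_joint) ** 2) / (_SQRT2PI * h_joint)
    kern = np.moveaxis(kern, -1, 0)
    # marginal density of column j at its own points, univariate bandwidth
    marg = np.exp(-0.5 * (diff / h_marg) ** 2).mean(axis=1) / (_SQRT2PI * h_marg)

    # joint density of pair (j, k) at point i: (1/n) sum_l K[j,i,l] * K[k,i,l]
    joint = np.einsum("jil,kil->jki", kern, kern) / n
    log_marg_mean = np.log(marg).mean(axis=0)  # length p
    mi = (
        np.log(joint).mean(axis=2)
        - log_marg_mean[:, None]
        - log_marg_mean[None, :]
    )
    mi = np.maximum(mi, 0.0)
    np.fill_diagonal(mi, 0.0)
    return 0.5 * (mi + mi.T)


def estimate_mi_matrix(expr, config: MIConfig | None = None) -> AssociationMatrix:
    """Estimate the p x p MI association matrix of an expression matrix.

    Requires n >= 3 samples and finite input. The diagonal is zeroed and
    negative plug-in estimates are clipped at zero.
    """
    config = config or MIConfig()
    if isinstance(expr, ExpressionMatrix):
        values = expr.values
        gene_ids = expr.gene_ids
    else:
        values = np.asarray(expr, dtype=float)
        gene_ids = [f"G{j + 1}" for j in range(values.shape[1])]
    if values.ndim != 2 or values.shape[1] < 2:
        raise ValueError("expression matrix must be 2-D with at least 2 genes")
    if values.shape[0] < 3:
        raise ValueError("insufficient samples: MI estimation requires n >= 3")
    if not np.all(np.isfinite(values)):
        raise ValueError("expression values must be finite")

    u = copula_transform(values) if config.copula else values
    mi = _mi_from_uniform(u, config)
    if config.dpi:
        mi = _dpi_values(mi, config.dpi_tolerance)
    return AssociationMatrix(mi, list(gene_ids))


def _dpi_values(a: np.ndarray, tolerance: float) -> np.ndarray:
    # weakest edge of triangle (i, j, k) is dropped when it is below
    # (1 - tolerance) times the smaller of the other two edges
    indirect = np.minimum(a[:, None, :], a[None, :, :]).max(axis=2)
    pruned = a.copy()
    pruned[(a > 0) & (a < (1.0 - tolerance) * indirect)] = 0.0
    return pruned


def apply_dpi(assoc: AssociationMatrix, tolerance: float = 0.0) -> AssociationMatrix:
    """Data-processing-inequality pruning of an association matrix.

    For every triangle the weakest edge w is zeroed when
    w < (1 - tolerance) * min(other two). ``tolerance=1`` disables pruning.
    Removal decisions are made on the input matrix simultaneously, which makes
    the operation idempotent and never increases any entry.
    """
    if not 0.0 <= tolerance <= 1.0:
        raise ValueError("tolerance must be in [0, 1]")
    return AssociationMatrix(_dpi_values(assoc.values, tolerance), assoc.gene_ids)
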