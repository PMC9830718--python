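"""Total connectivity and leave-one-out jackknife pseudo-values.

For gene k the total connectivity is the column sum of the MI association
matrix, theta_k = sum_j I_hat_jk — a continuous analogue of degree centrality.
The jackknife pseudo-value for sample i converts this group-level network
statistic into a per-sample response:

    theta_tilde_ik = n * theta_k - (n - 1) * theta_k(i),

where theta_k(i) is recomputed from scratch (including re-ranking in the
copula transform) on the data without sample i. Pseudo-values are obtained
separately within each of the two comparison groups.
"""

from __future__ import annotations

import numpy as np

from .containers import (
    AssociationMatrix,
    ConnectivityVector,
    ExpressionMatrix,
    PseudoValueMatrix,
)
from .mi import MIConfig, estimate_mi_matrix

__all__ = ["total_connectivity", "jackknife_pseudovalues", "pseudovalues_by_group"]


def total_connectivity(assoc: AssociationMatrix, group_label=None) -> ConnectivityVector:
    """Column sums of the association matrix: theta_k = sum_j I_hat_jk."""
    theta = assoc.values.sum(axis=0)
    return ConnectivityVector(theta, assoc.gene_ids, group_label)


def _theta(values: np.ndarray, config: MIConfig) -> np.ndarray:
    return estimate_mi_matrix(values, config).values.sum(axis=0)


def jackknife_pseudovalues(
    expr_group: ExpressionMatrix, config: MIConfig | None = None
) -> PseudoValueMatrix:
    """Leave-one-out jackknife pseudo-values for one group's samples.

    The MI matrix is fully re-estimated on each n-1 subsample (ranks are
    recomputed, not reused), so each row i reflects sample i's contribution
    to every gene's total connectivity. Requires at least 3 samples so that
    each leave-one-out fit retains >= 2.
    """
    config = config or MIConfig()
    n = expr_group.n_samples
    if n < 4:
        # leave-one-out must itself satisfy the n >= 3 MI requirement
        raise ValueError("jackknife requires at least 4 samples per group")
    theta_full = _theta(expr_group.values, config)
    pv = np.empty((n, expr_group.n_genes))
    for i in range(n):
        theta_i = _theta(np.delete(expr_group.values, i, axis=0), config)
        pv[i] = n * theta_full - (n - 1) * theta_i
    return PseudoValueMatrix(
        pv,
        expr_group.sample_ids,
        expr_group.gene_ids,
        np.repeat(None, n),
    )


def pseudovalues_by_group(
    expr: ExpressionMatrix, groups, config: MIConfig | None = None
) -> PseudoValueMatrix:
    """Group-wise jackknife pseudo-values, rows in the input sample order.

    ``groups`` must take exactly two distinct values; each group needs at
    least 4 samples. Computation within a group never sees the other group's
    samples, so relabelling the groups leaves the matrix unchanged.
    """
    groups = np.asarray(groups)
    if groups.shape[0] != expr.n_samples:
        raise ValueError("groups must have one label per sample")
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError(f"expected exactly two groups, found {labels.size}")
    pv = np.empty((expr.n_samples, expr.n_genes))
    for lab in labels:
        idx = np.flatnonzero(groups == lab)
        sub = jackknife_pseudovalues(expr.subset_samples(idx), config)
        pv[idx] = sub.values
    return PseudoValueMatrix(pv, expr.sample_ids, expr.gene_ids, groups)
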