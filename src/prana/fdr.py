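"""Multiplicity adjustment of per-gene p-values and DC-gene calling.

Two adjustments are available behind one interface:

* ``bh`` (default) — the Benjamini–Hochberg step-up procedure.
* ``ebs`` — an empirical-Bayes screening: p-values are probit-transformed
  (null p-values map to a standard normal), the marginal density of the
  transformed values is estimated nonparametrically (Gaussian KDE), and each
  gene's posterior null probability (local false discovery rate)
  pi0 * f0(z) / f(z) is converted to a q-value-like adjusted value by
  averaging the sorted local fdrs, so that flagging adjusted < alpha controls
  the expected FDR of the flagged set at alpha.

A gene is called differentially connected (DC) when its adjusted p-value is
strictly below alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["AdjustedPValues", "adjust_pvalues", "call_dc_genes"]


@dataclass
class AdjustedPValues:
    raw: np.ndarray
    adjusted: np.ndarray
    method: str
    alpha: float = 0.05


def _ebs_adjust(raw: np.ndarray) -> np.ndarray:
    eps = 1e-16  # keep the probit finite without flattening extreme signals
    z = stats.norm.ppf(np.clip(raw, eps, 1.0 - eps))
    f0 = stats.norm.pdf(z)
    if np.ptp(z) == 0:
        f = np.full_like(z, np.inf)  # degenerate: all identical p-values
        lfdr = np.ones_like(z)
    else:
        f = stats.gaussian_kde(z)(z)
        pi0 = min(1.0, 2.0 * np.mean(raw > 0.5))
        with np.errstate(divide="ignore", invalid="ignore"):
            lfdr = np.clip(pi0 * f0 / f, 0.0, 1.0)
    order = np.argsort(lfdr, kind="stable")
    running = np.cumsum(lfdr[order]) / np.arange(1, lfdr.size + 1)
    adjusted = np.empty_like(running)
    adjusted[order] = running
    return adjusted


def adjust_pvalues(raw, method: str = "bh", alpha: float = 0.05) -> AdjustedPValues:
    """Adjust raw p-values for multiplicity (``method`` in {"bh", "ebs"})."""
    raw = np.asarray(raw, dtype=float)
    if np.any((raw < 0) | (raw > 1) | ~np.isfinite(raw)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bh":
        adjusted = multipletests(raw, alpha=alpha, method="fdr_bh")[1]
    elif method == "ebs":
        adjusted = _ebs_adjust(raw)
    else:
        raise ValueError(f"unknown adjustment method: {method!r}")
    return AdjustedPValues(raw=raw, adjusted=adjusted, method=method, alpha=alpha)


def call_dc_genes(adj: AdjustedPValues) -> np.ndarray:
    """Boolean flags: adjusted p-value strictly below alpha."""
    return adj.adjusted < adj.alpha
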