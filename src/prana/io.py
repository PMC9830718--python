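"""Tabular I/O and the end-to-end pipeline entry point.

Expression tables are TSV/CSV with the first column holding sample IDs and
the remaining columns genes (set ``genes_in_rows=True`` for the transposed
layout). Phenotype tables have one row per sample with a binary group column
and optional covariate columns; samples are aligned to the expression matrix
by ID join, not row order. Categorical covariates are one-hot encoded with
the alphabetically first level as reference; missing cells are a hard error.
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import ExpressionMatrix, PseudoValueMatrix
from .fdr import adjust_pvalues, call_dc_genes
from .lts import DesignMatrix, GeneRegressionResult, LTSConfig, prana_regression
from .mi import MIConfig, estimate_mi_matrix
from .pseudovalues import pseudovalues_by_group

__all__ = ["RunConfig", "read_expression", "read_phenotype", "run_prana", "results_to_dataframe"]


@dataclass
class RunConfig:
    expr_path: str
    pheno_path: str
    group_column: str
    covariate_columns: list[str] = field(default_factory=list)
    fdr_method: str = "bh"
    alpha: float = 0.05
    coverage_fraction: float = 0.75
    dpi: bool = False
    dpi_tolerance: float = 0.0
    seed: int = 0
    genes_in_rows: bool = False
    out_dir: str | None = None


def _read_table(path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, index_col=0)


def read_expression(path, genes_in_rows: bool = False) -> ExpressionMatrix:
    df = _read_table(path)
    if genes_in_rows:
        df = df.T
    return ExpressionMatrix.from_dataframe(df)


def read_phenotype(path) -> pd.DataFrame:
    df = _read_table(path)
    df.index = df.index.map(str)
    return df


def _encode_covariates(pheno: pd.DataFrame, columns: list[str]) -> tuple[np.ndarray, list[str]]:
    if not columns:
        return np.empty((len(pheno), 0)), []
    sub = pheno[columns]
    if sub.isna().any().any():
        bad = sub.columns[sub.isna().any()].tolist()
        raise ValueError(f"missing covariate values in column(s): {bad}")
    encoded = pd.get_dummies(sub, drop_first=True, dtype=float)
    return encoded.to_numpy(dtype=float), list(encoded.columns)


def run_prana(config: RunConfig):
    """Full pipeline: expression + phenotype in, per-gene DC results out.

    Returns (results DataFrame, pseudo-value matrix, log dict); writes
    results.tsv, pseudovalues.tsv and run_log.json when out_dir is set.
    """
    t0 = time.time()
    expr = read_expression(config.expr_path, config.genes_in_rows)
    pheno = read_phenotype(config.pheno_path)

    missing = [s for s in expr.sample_ids if s not in pheno.index]
    extra = [s for s in pheno.index if s not in expr.sample_ids]
    if missing or extra:
        raise ValueError(
            "sample-ID mismatch between expression and phenotype; "
            f"missing from phenotype: {missing[:5]}; missing from expression: {extra[:5]}"
        )
    pheno = pheno.loc[expr.sample_ids]

    groups = pheno[config.group_column].to_numpy()
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError(f"group column {config.group_column!r} must be binary")
    counts = [(groups == lab).sum() for lab in labels]
    if min(counts) < 4:
        raise ValueError("each group needs at least 4 samples for the jackknife")

    mi_config = MIConfig(dpi=config.dpi, dpi_tolerance=config.dpi_tolerance)
    pv = pseudovalues_by_group(expr, groups, mi_config)

    x, cov_names = _encode_covariates(pheno, config.covariate_columns)
    design = DesignMatrix(
        z=(groups == labels.max()).astype(float),
        x=x,
        sample_ids=expr.sample_ids,
        covariate_names=cov_names,
    )
    lts = LTSConfig(coverage_fraction=config.coverage_fraction, seed=config.seed)
    results = prana_regression(pv, design, lts)

    pvals = np.array([r.p_value for r in results])
    ok = np.isfinite(pvals)
    if ok.any():
        adj = adjust_pvalues(pvals[ok], method=config.fdr_method, alpha=config.alpha)
        qvals = np.full(len(results), np.nan)
        qvals[ok] = adj.adjusted
        for r, q in zip(results, qvals):
            r.q_value = None if np.isnan(q) else float(q)

    table = results_to_dataframe(results, config.alpha)
    log = {
        "package": "prana",
        "version": __version__,
        "config": {k: v for k, v in vars(config).items()},
        "n_samples": expr.n_samples,
        "n_genes": expr.n_genes,
        "group_sizes": {str(lab): int(c) for lab, c in zip(labels, counts)},
        "covariates": cov_names,
        "n_dc_genes": int(table["dc_flag"].sum()),
        "elapsed_seconds": round(time.time() - t0, 3),
    }
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "results.tsv", sep="\t", index=False)
        pv.to_dataframe().to_csv(out / "pseudovalues.tsv", sep="\t")
        for lab in labels:
            assoc = estimate_mi_matrix(
                expr.subset_samples(np.flatnonzero(groups == lab)), mi_config
            )
            assoc.to_dataframe().to_csv(out / f"association_group{lab}.tsv", sep="\t")
        (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    print(f"prana: {log['n_dc_genes']}/{expr.n_genes} genes flagged DC "
          f"(alpha={config.alpha}, fdr={config.fdr_method})", file=sys.stderr)
    return table, pv, log


def results_to_dataframe(results: list[GeneRegressionResult], alpha: float = 0.05) -> pd.DataFrame:
    rows = []
    q_len = max((len(r.gamma) for r in results if r.error is None), default=0)
    for r in results:
        row = {
            "gene_id": r.gene_id,
            "alpha": r.alpha,
            "beta": r.beta,
        }
        for j in range(q_len):
            row[f"gamma_{j + 1}"] = r.gamma[j] if r.error is None and j < len(r.gamma) else np.nan
        row.update(
            se_beta=r.se_beta,
            t_stat=r.t_stat,
            p_value=r.p_value,
            q_value=np.nan if r.q_value is None else r.q_value,
            dc_flag=bool(r.q_value is not None and r.q_value < alpha),
            error=r.error or "",
        )
        rows.append(row)
    return pd.DataFrame(rows)
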