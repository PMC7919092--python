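"""Differential abundance of relative-abundance features between cohorts.

The procedure: drop features present in fewer than 20% of samples unless a
Fisher-exact test shows their presence/absence pattern is cohort-specific
(BH-FDR < 0.05, the "rescue"); replace zeros with half the smallest
non-zero value per feature; log10-transform; fit one ordinary-least-squares
model per feature with age, sex, cohort, and treatment as fixed effects;
report cohort contrasts vs the control reference with BH correction across
features within each contrast.

All features share a single design matrix, so the per-feature fits are
solved jointly as one multi-response least-squares problem.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import SampleMetadata, ValidationError

__all__ = [
    "bh_adjust",
    "prevalence_filter",
    "transform",
    "fit_feature_models",
    "degenerate_treatment_cells",
    "diff_abundance_pipeline",
]

REFERENCE_LEVELS = {"cohort": "control", "treatment": "none", "sex": "male"}


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def prevalence_filter(
    rel_abundance: pd.DataFrame,
    metadata: SampleMetadata,
    min_prev: float = 0.20,
    rescue_fdr: float = 0.05,
) -> tuple[list, pd.DataFrame]:
    """Keep prevalent features; rescue cohort-specific absent ones.

    Features (rows) present in >= ``min_prev`` of samples pass outright.
    Low-prevalence features are kept anyway when their presence/absence
    pattern is specific to the control or the pooled disease cohorts
    (two-sided Fisher exact on the presence x disease-status table, BH-FDR
    across the low-prevalence candidates < ``rescue_fdr``).

    Returns the kept feature list (input order) and a per-feature report
    with prevalence, rescue p/q, and kept/rescued flags.
    """
    if rel_abundance.empty:
        raise ValidationError("empty abundance table")
    meta = metadata.frame.loc[rel_abundance.columns]
    present = rel_abundance.to_numpy(dtype=float) > 0
    prevalence = present.mean(axis=1)
    prevalent = prevalence >= min_prev

    is_disease = (meta["cohort"] != "control").to_numpy()
    low_idx = np.flatnonzero(~prevalent)
    fisher_p = np.full(len(rel_abundance), np.nan)
    for i in low_idx:
        pres = present[i]
        table = [
            [int((pres & is_disease).sum()), int((pres & ~is_disease).sum())],
            [int((~pres & is_disease).sum()), int((~pres & ~is_disease).sum())],
        ]
        fisher_p[i] = stats.fisher_exact(table, alternative="two-sided")[1]
    fisher_q = np.full(len(rel_abundance), np.nan)
    if len(low_idx):
        fisher_q[low_idx] = bh_adjust(fisher_p[low_idx])
    rescued = ~prevalent & (fisher_q < rescue_fdr) & (prevalence > 0)

    report = pd.DataFrame(
        {
            "prevalence": prevalence,
            "rescue_p": fisher_p,
            "rescue_q": fisher_q,
            "rescued": rescued,
            "kept": prevalent | rescued,
        },
        index=rel_abundance.index.copy(),
    )
    return report.index[report["kept"]].tolist(), report


def transform(rel_abundance: pd.DataFrame, kept_features) -> pd.DataFrame:
    """Half-minimum zero replacement then log10, per feature."""
    sub = rel_abundance.loc[list(kept_features)].to_numpy(dtype=float).copy()
    mins = np.where(sub > 0, sub, np.inf).min(axis=1)
    if np.isinf(mins).any():
        bad = [f for f, m in zip(kept_features, mins) if np.isinf(m)]
        raise ValidationError(f"kept features with no non-zero value: {bad[:5]}")
    sub = np.where(sub > 0, sub, (mins / 2.0)[:, None])
    return pd.DataFrame(
        np.log10(sub), index=pd.Index(kept_features, name=rel_abundance.index.name), columns=rel_abundance.columns.copy()
    )


def _build_design(
    meta: pd.DataFrame, terms: list[str]
) -> tuple[np.ndarray, list[str], dict[str, list[str]]]:
    """Design matrix with intercept; categorical terms dummy-coded vs reference."""
    cols = [np.ones(len(meta))]
    names = ["Intercept"]
    term_cols: dict[str, list[str]] = {}
    for term in terms:
        if term not in meta.columns:
            raise ValidationError(f"model term {term!r} not in metadata")
        col = meta[term]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.to_numpy(dtype=float))
            names.append(term)
            term_cols[term] = [term]
        else:
            ref = REFERENCE_LEVELS.get(term)
            levels = [l for l in pd.unique(col.dropna().astype(str)) if l != ref]
            levels.sort()
            term_cols[term] = []
            for level in levels:
                cols.append((col.astype(str) == level).to_numpy(dtype=float))
                name = f"{term}[{level}]"
                names.append(name)
                term_cols[term].append(name)
    return np.column_stack(cols), names, term_cols


def degenerate_treatment_cells(metadata: SampleMetadata) -> pd.DataFrame:
    """Treatment categories observed in only one cohort (confound report)."""
    meta = metadata.frame
    tab = pd.crosstab(meta["treatment"], meta["cohort"])
    degenerate = tab[(tab > 0).sum(axis=1) == 1]
    return degenerate


def fit_feature_models(
    log_table: pd.DataFrame,
    metadata: SampleMetadata,
    terms: list[str] | None = None,
    contrast_term: str = "cohort",
) -> pd.DataFrame:
    """Per-feature OLS with covariates; cohort contrasts vs the reference.

    ``log_table`` is features x samples on the log10 scale. One model per
    feature: y ~ intercept + terms (default age + sex + cohort + treatment).
    For every non-reference level of ``contrast_term`` the coefficient, its
    standard error, t, p (two-sided), and BH q across features within that
    contrast are reported.
    """
    terms = terms if terms is not None else ["age", "sex", "cohort", "treatment"]
    if contrast_term not in terms:
        raise ValidationError(f"contrast term {contrast_term!r} must be among the model terms")
    meta = metadata.frame.loc[log_table.columns]
    x, names, term_cols = _build_design(meta, terms)
    n, p = x.shape
    rank = int(np.linalg.matrix_rank(x))
    if rank < p:
        _, r = np.linalg.qr(x)
        diag = np.abs(np.diag(r))
        aliased = [names[j] for j in np.flatnonzero(diag <= 1e-10 * max(1.0, diag.max()))]
        raise ValidationError(f"rank-deficient design; aliased columns: {aliased}")
    if n <= p:
        raise ValidationError("more model parameters than samples")

    y = log_table.to_numpy(dtype=float).T  # samples x features
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y  # p x features
    resid = y - x @ beta
    df_res = n - p
    sigma2 = (resid**2).sum(axis=0) / df_res
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    with np.errstate(invalid="ignore", divide="ignore"):
        tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_res)

    rows = []
    ref = REFERENCE_LEVELS.get(contrast_term)
    for col_name in term_cols[contrast_term]:
        j = names.index(col_name)
        level = col_name[col_name.index("[") + 1 : -1] if "[" in col_name else col_name
        contrast = f"{level} vs {ref}" if ref else level
        q = bh_adjust(pvals[j])
        for f_i, feature in enumerate(log_table.index):
            rows.append(
                (feature, contrast, beta[j, f_i], se[j, f_i], tvals[j, f_i], pvals[j, f_i], q[f_i])
            )
    return pd.DataFrame(
        rows, columns=["feature_id", "contrast", "coef", "se", "t", "p", "q"]
    )


def diff_abundance_pipeline(
    rel_abundance: pd.DataFrame,
    metadata: SampleMetadata,
    min_prev: float = 0.20,
    rescue_fdr: float = 0.05,
    terms: list[str] | None = None,
    contrast_term: str = "cohort",
) -> pd.DataFrame:
    """Filter, transform, and fit in one call; attaches prevalence and rescue flags."""
    kept, report = prevalence_filter(rel_abundance, metadata, min_prev, rescue_fdr)
    if not kept:
        raise ValidationError("no features pass the prevalence filter")
    log_table = transform(rel_abundance, kept)
    result = fit_feature_models(log_table, metadata, terms, contrast_term)
    result = result.merge(
        report[["prevalence", "rescued"]], left_on="feature_id", right_index=True
    )
    return result
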