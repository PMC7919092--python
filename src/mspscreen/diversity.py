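"""Community diversity: Shannon, Bray-Curtis, PCoA, and sequential PERMANOVA.

The PERMANOVA here implements the distance-based sequential (Type I)
partition of McArdle & Anderson on the Gower-centered matrix, with a
model-selection step that orders covariates by their single-term partial
R-squared before fitting the joint sequential model. Permutation p-values
use free permutation of sample labels with the +1 correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io import SampleMetadata, ValidationError

__all__ = [
    "DistanceMatrix",
    "PermanovaResult",
    "shannon",
    "bray_curtis",
    "pcoa",
    "order_covariates",
    "permanova",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise sample dissimilarities with a zero diagonal."""

    sample_ids: pd.Index
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] != len(self.sample_ids):
            raise ValidationError("distance matrix shape does not match sample ids")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal must be zero")
        if (d < -1e-12).any():
            raise ValidationError("distances must be non-negative")
        self.d = d

    def to_skbio(self):
        from skbio import DistanceMatrix as SkbioDM

        return SkbioDM(self.d, ids=[str(s) for s in self.sample_ids])


@dataclass
class PermanovaResult:
    """Sequential PERMANOVA table plus the residual/total partition."""

    terms: pd.DataFrame  # index term; columns df, ss, r2, pseudo_F, p
    residual_ss: float
    total_ss: float
    n_permutations: int
    seed: int

    def __post_init__(self) -> None:
        part = self.terms["ss"].sum() + self.residual_ss
        if not np.isclose(part, self.total_ss, rtol=1e-9, atol=1e-12):
            raise ValidationError("term + residual SS do not reconstruct the total SS")


def shannon(rel_abundance) -> float:
    """Shannon index H = -sum p_i ln p_i (natural log) after renormalization."""
    p = np.asarray(rel_abundance, dtype=float)
    if (p < 0).any():
        raise ValidationError("abundances must be non-negative")
    total = p.sum()
    if total <= 0:
        raise ValidationError("Shannon index undefined for an all-zero profile")
    p = p[p > 0] / total
    return float(-(p * np.log(p)).sum())


def bray_curtis(abundance: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between sample columns of an abundance table.

    d_ij = sum_k |x_ik - x_jk| / sum_k (x_ik + x_jk).
    """
    if abundance.shape[1] < 2:
        raise ValidationError("need at least two samples")
    arr = abundance.to_numpy(dtype=float).T  # samples x features
    if (arr < 0).any():
        raise ValidationError("abundances must be non-negative")
    zero = arr.sum(axis=1) == 0
    if zero.sum() >= 2:
        bad = abundance.columns[zero].tolist()
        raise ValidationError(f"Bray-Curtis undefined between all-zero samples: {bad[:5]}")
    return DistanceMatrix(abundance.columns.copy(), squareform(pdist(arr, metric="braycurtis")))


def pcoa(dm: DistanceMatrix, k: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical principal-coordinate analysis.

    Returns sample coordinates on the first k axes (ordered by decreasing
    eigenvalue) and the full eigenvalue spectrum. Axes beyond the positive
    eigenvalues are dropped with a warning.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    from skbio.stats.ordination import pcoa as skbio_pcoa

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # skbio warns about negative eigenvalues
        res = skbio_pcoa(dm.to_skbio(), method="eigh")
    eigvals = res.eigvals.to_numpy()
    n_pos = int((eigvals > 1e-12).sum())
    if k > n_pos:
        warnings.warn(
            f"requested {k} axes but only {n_pos} positive eigenvalues; truncating",
            stacklevel=2,
        )
        k = max(n_pos, 1)
    coords = res.samples.iloc[:, :k].copy()
    coords.index = dm.sample_ids
    coords.columns = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return coords, eigvals


# ---------------------------------------------------------------------------
# PERMANOVA


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    row = a.mean(axis=1, keepdims=True)
    return a - row - row.T + a.mean()


def _term_design(metadata: pd.DataFrame, term: str) -> np.ndarray:
    """Columns for one covariate: centered numeric, or reference-dropped dummies."""
    col = metadata[term]
    if pd.api.types.is_numeric_dtype(col):
        x = col.to_numpy(dtype=float)[:, None]
    else:
        x = pd.get_dummies(col.astype(str), drop_first=True).to_numpy(dtype=float)
    return x


def _hat(x: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(x)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    q = q[:, keep]
    return q @ q.T


def order_covariates(
    dm: DistanceMatrix, metadata: SampleMetadata, covariates: list[str]
) -> tuple[list[str], pd.DataFrame]:
    """Model selection: rank covariates by single-term partial R-squared.

    Each covariate is fit alone against the distance matrix; covariates are
    ordered by that R-squared, descending, ties broken by input order.
    Constant covariates are excluded with a warning. Returns the ordered
    list and a table with each covariate's single-term R-squared.
    """
    meta = metadata.frame.loc[dm.sample_ids]
    g = _gower_center(dm.d)
    total = np.trace(g)
    rows = []
    for term in covariates:
        if term not in meta.columns:
            raise ValidationError(f"covariate {term!r} not in metadata")
        if meta[term].nunique(dropna=False) < 2:
            warnings.warn(f"covariate {term!r} is constant; excluded", stacklevel=2)
            continue
        x = np.column_stack([np.ones(len(meta)), _term_design(meta, term)])
        h = _hat(x)
        r2 = float(np.sum(h * g) / total)
        rows.append((term, r2))
    table = pd.DataFrame(rows, columns=["covariate", "single_term_r2"]).set_index("covariate")
    order = table["single_term_r2"].sort_values(ascending=False, kind="stable").index.tolist()
    return order, table


def permanova(
    dm: DistanceMatrix,
    metadata: SampleMetadata,
    covariates: list[str],
    n_perm: int = 1000,
    seed: int = 0,
) -> PermanovaResult:
    """Sequential PERMANOVA over an ordered covariate list.

    Terms enter in the given order; each term's sum of squares is the gain
    in explained (Gower-centered) distance variation over the preceding
    terms. p-values come from free permutation of sample labels:
    p = (1 + #{permuted F >= observed F}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    meta = metadata.frame.loc[dm.sample_ids]
    n = len(meta)
    g = _gower_center(dm.d)
    total = float(np.trace(g))

    blocks = []
    for term in covariates:
        if term not in meta.columns:
            raise ValidationError(f"covariate {term!r} not in metadata")
        blocks.append(_term_design(meta, term))

    hats: list[np.ndarray] = []
    dfs: list[int] = []
    x = np.ones((n, 1))
    prev_rank = 1
    for block in blocks:
        x = np.column_stack([x, block])
        rank = int(np.linalg.matrix_rank(x))
        hats.append(_hat(x))
        dfs.append(rank - prev_rank)
        prev_rank = rank
    df_res = n - prev_rank
    if df_res < 1:
        raise ValidationError("model has as many degrees of freedom as samples")

    def seq_f(gp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        explained = np.array([np.sum(h * gp) for h in hats])
        ss = np.diff(explained, prepend=0.0)
        ss_res = np.trace(gp) - explained[-1]
        f = (ss / np.array(dfs)) / (ss_res / df_res)
        return ss, f

    ss_obs, f_obs = seq_f(g)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(hats))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        _, f_perm = seq_f(g[np.ix_(perm, perm)])
        exceed += f_perm >= f_obs
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    terms = pd.DataFrame(
        {
            "df": dfs,
            "ss": ss_obs,
            "r2": ss_obs / total,
            "pseudo_F": f_obs,
            "p": pvals,
        },
        index=pd.Index(covariates, name="term"),
    )
    return PermanovaResult(
        terms=terms,
        residual_ss=total - float(ss_obs.sum()),
        total_ss=total,
        n_permutations=n_perm,
        seed=seed,
    )
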