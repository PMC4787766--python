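"""MARA-style motif activity inference and target scoring.

The linear model explains promoter expression from motif site counts
times unknown sample-specific motif activities:

    E_ps  ~=  sum_m  N_pm * A_ms

with ``E`` the log size-factor-normalized expression (pseudocount 1),
row- and column-centered, and ``N`` the promoter x motif site-count
matrix, column-centered.  Activities are estimated per sample by ridge
regression, A_.s = (N'N + lambda I)^-1 N' E_.s, and centered across
samples per motif.  Per-motif significance is summarized by the z-value
z_m = sqrt(mean_s (A_ms / sigma_ms)^2) with sigma from the ridge
covariance and the residual variance.

The strength of regulation of promoter p by motif m is the increase in
model misfit when the motif's sites are removed from that promoter with
activities held fixed (S_pm, scaled by the residual variance so scores
are dimensionless); the per-gene score S_m takes the maximum over the
gene's promoters, giving one score per target.  Motifs with z < 2 and
genes with S_m below the score threshold are filtered from the
strongly-regulated table.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from pip3scope.core_io import Dataset, GeneSetCollection
from pip3scope.de_engine import estimate_size_factors


@dataclasses.dataclass
class MotifModel:
    activities: pd.DataFrame  # motifs x samples
    activity_se: pd.DataFrame  # motifs x samples
    z_values: pd.Series
    ridge_lambda: float
    fitted: np.ndarray  # promoters x samples
    residuals: np.ndarray
    residual_variance: float
    sites_centered: np.ndarray


@dataclasses.dataclass
class TargetScores:
    s_pm: pd.DataFrame  # promoters x motifs
    s_m: pd.DataFrame | None = None  # one row per (gene, motif) wide: genes x motifs
    promoter_of_gene: pd.Series | None = None


def promoter_expression(
    dataset: Dataset, promoter_map: pd.Series, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Promoter x sample expression: log(normalized gene count + 1).

    Each promoter inherits the expression of the gene it controls (counts
    are gene-level); multi-promoter genes contribute one identical row
    per promoter.
    """
    sf = estimate_size_factors(dataset.counts, pseudo_reference=True)
    norm = dataset.counts / sf
    missing = set(promoter_map) - set(norm.index)
    if missing:
        raise ValueError(f"promoters map to unknown genes: {sorted(missing)[:5]}")
    E = np.log(norm.loc[promoter_map.to_numpy()].to_numpy() + pseudocount)
    return pd.DataFrame(E, index=promoter_map.index, columns=norm.columns)


def _double_center(E: np.ndarray) -> np.ndarray:
    E = E - E.mean(axis=1, keepdims=True)
    return E - E.mean(axis=0, keepdims=True)


def _ridge_fit(Nc: np.ndarray, E: np.ndarray, lam: float):
    M = Nc.shape[1]
    G = Nc.T @ Nc + lam * np.eye(M)
    Ginv = np.linalg.inv(G)
    A = Ginv @ Nc.T @ E  # motifs x samples
    return A, Ginv


def _cv_lambda(Nc, E, lambdas, n_folds=5, seed=0):
    """Promoter-wise K-fold cross-validation of the ridge penalty."""
    rng = np.random.default_rng(seed)
    P = Nc.shape[0]
    fold = rng.integers(0, n_folds, size=P)
    errs = []
    for lam in lambdas:
        sse = 0.0
        for f in range(n_folds):
            tr, te = fold != f, fold == f
            A, _ = _ridge_fit(Nc[tr], E[tr], lam)
            resid = E[te] - Nc[te] @ A
            sse += (resid**2).sum()
        errs.append(sse)
    return float(lambdas[int(np.argmin(errs))])


def fit_motif_activities(
    E: pd.DataFrame,
    sites: pd.DataFrame,
    ridge_lambda="cv",
    cv_seed: int = 0,
) -> MotifModel:
    """Fit sample-wise motif activities by ridge regression.

    ``E`` is promoters x samples expression (will be row- and
    column-centered); ``sites`` the aligned promoter x motif site-count
    matrix (columns centered internally).  ``ridge_lambda`` is a positive
    number or ``"cv"`` for 5-fold promoter-wise cross-validation on a
    logarithmic grid.
    """
    if not E.index.equals(sites.index):
        sites = sites.loc[E.index]
    Em = _double_center(E.to_numpy(dtype=float))
    N = sites.to_numpy(dtype=float)
    Nc = N - N.mean(axis=0, keepdims=True)
    if ridge_lambda == "cv":
        grid = np.logspace(-2, 4, 13) * max(Nc.shape[0], 1)
        lam = _cv_lambda(Nc, Em, grid, seed=cv_seed)
    else:
        lam = float(ridge_lambda)
        if lam <= 0:
            raise ValueError("ridge penalty must be positive")
    A, Ginv = _ridge_fit(Nc, Em, lam)
    A = A - A.mean(axis=1, keepdims=True)  # center activities per motif
    fitted = Nc @ A
    resid = Em - fitted
    P, S = Em.shape
    df_eff = float(np.trace(Nc @ Ginv @ Nc.T))
    denom = max(P - df_eff, 1.0)
    resvar_s = (resid**2).sum(axis=0) / denom  # per-sample residual variance
    cov_diag = np.diag(Ginv @ (Nc.T @ Nc) @ Ginv)
    se = np.sqrt(np.maximum(np.outer(cov_diag, resvar_s), 1e-300))
    z = np.sqrt(np.mean((A / se) ** 2, axis=1))
    return MotifModel(
        activities=pd.DataFrame(A, index=sites.columns, columns=E.columns),
        activity_se=pd.DataFrame(se, index=sites.columns, columns=E.columns),
        z_values=pd.Series(z, index=sites.columns, name="z"),
        ridge_lambda=lam,
        fitted=fitted,
        residuals=resid,
        residual_variance=float(resvar_s.mean()),
        sites_centered=Nc,
    )


def target_scores(model: MotifModel, sites: pd.DataFrame) -> TargetScores:
    """Per-promoter strength of regulation S_pm.

    S_pm is the increase in residual sum of squares when motif m's sites
    are removed from promoter p, activities held fixed; clipped at zero
    and scaled by the residual variance.  Promoters without sites score
    exactly zero.
    """
    N = sites.to_numpy(dtype=float)
    A = model.activities.to_numpy()
    R = model.residuals  # promoters x samples
    # removing N_pm shifts promoter p's prediction by -N_pm * A_m. ; the
    # RSS difference expands to 2 N_pm (r_p . A_m) + N_pm^2 |A_m|^2
    cross = R @ A.T  # promoters x motifs
    a_norm2 = (A**2).sum(axis=1)  # motifs
    raw = 2.0 * N * cross + (N**2) * a_norm2[None, :]
    raw = np.maximum(raw, 0.0)
    raw[N == 0] = 0.0
    scaled = raw / max(model.residual_variance, 1e-300)
    return TargetScores(
        s_pm=pd.DataFrame(scaled, index=sites.index, columns=sites.columns)
    )


def dedup_to_genes(scores: TargetScores, promoter_map: pd.Series) -> TargetScores:
    """Per-gene score S_m: the maximum S_pm over the gene's promoters."""
    missing = scores.s_pm.index.difference(promoter_map.index)
    if len(missing):
        raise ValueError(f"promoters without gene mapping: {list(missing[:5])}")
    genes = promoter_map.loc[scores.s_pm.index]
    s_m = scores.s_pm.groupby(genes.to_numpy()).max()
    s_m.index.name = "gene_id"
    # which promoter won, per gene (for reporting): promoter of max total score
    best = scores.s_pm.sum(axis=1).groupby(genes.to_numpy()).idxmax()
    return TargetScores(s_pm=scores.s_pm, s_m=s_m, promoter_of_gene=best)


def strongly_regulated(
    scores: TargetScores,
    model: MotifModel,
    gene_sets: GeneSetCollection | None = None,
    s_threshold: float = 20.0,
    z_threshold: float = 2.0,
) -> pd.DataFrame:
    """The strongly-regulated table: (motif, gene, S_m, set labels).

    Keeps motifs with z >= z_threshold and genes with S_m strictly above
    s_threshold, sorted by motif then descending score.  The absolute
    default threshold of 20 is only meaningful on a comparable score
    scale; a quantile-based threshold can be passed instead by computing
    it from ``scores.s_m`` beforehand.
    """
    if scores.s_m is None:
        raise ValueError("run dedup_to_genes first")
    keep_motifs = [
        m
        for m in model.z_values.index[model.z_values >= z_threshold]
        if m in scores.s_m.columns
    ]
    rows = []
    for m in keep_motifs:
        col = scores.s_m[m]
        hits = col[col > s_threshold].sort_values(ascending=False)
        for gene, s in hits.items():
            labels = ""
            if gene_sets is not None:
                labels = ",".join(
                    sorted(lab for lab, members in gene_sets.sets.items() if gene in members)
                )
            rows.append((m, gene, float(s), labels))
    return pd.DataFrame(rows, columns=["motif", "gene_id", "s_m", "gene_sets"])
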