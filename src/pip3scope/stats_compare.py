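"""Comparison and enrichment statistics, plus sample-level QC.

Two-sample Kolmogorov–Smirnov and Mann–Whitney tests compare the
distributions of per-gene motif target scores S_m between gene sets;
term enrichment uses the classical one-sided Fisher (hypergeometric
upper tail); QC provides the Pearson sample-correlation matrix and a PCA
of the samples.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from pip3scope.core_io import GeneSetCollection


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample KS: D = sup |ECDF_x - ECDF_y|, asymptotic p.

    The p-value uses the Kolmogorov distribution with effective sample
    size n_x n_y / (n_x + n_y).
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Mann–Whitney U of sample x (pairs won, ties half); two-sided p.

    The p-value uses the normal approximation with tie-corrected
    variance and continuity correction.
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


@dataclasses.dataclass
class ComparisonResult:
    """Per-motif distribution tests of S_m between two gene sets."""

    table: pd.DataFrame  # motif, n_a, n_b, ks_d, ks_p, mw_u, mw_p (sorted by ks_d desc)
    skipped: list[str]


def compare_sm_distributions(
    scores,
    set_a: set[str],
    set_b: set[str],
    model,
    z_threshold: float = 2.0,
    min_targets: int = 5,
) -> ComparisonResult:
    """Test S_m score distributions between two gene sets per motif.

    For each motif with z >= z_threshold, the S_m scores of its targets
    (S_m > 0) inside set_a and inside set_b are compared with both the KS
    and Mann–Whitney tests; motifs with fewer than ``min_targets``
    targets in either set are skipped.  Results are sorted by descending
    KS D (the degree of difference between the distributions).
    """
    if scores.s_m is None:
        raise ValueError("gene-level scores required; run dedup_to_genes first")
    overlap = set_a & set_b
    if overlap:
        warnings.warn(f"{len(overlap)} genes shared by both sets", stacklevel=2)
    s_m = scores.s_m
    idx_a = [g for g in s_m.index if g in set_a]
    idx_b = [g for g in s_m.index if g in set_b]
    motifs = model.z_values.index[model.z_values >= z_threshold]
    rows, skipped = [], []
    for m in motifs:
        a = s_m.loc[idx_a, m]
        b = s_m.loc[idx_b, m]
        a = a[a > 0].to_numpy()
        b = b[b > 0].to_numpy()
        if len(a) < min_targets or len(b) < min_targets:
            skipped.append(m)
            continue
        d, ks_p = ks_two_sample(a, b)
        u, mw_p = mann_whitney_u(a, b)
        rows.append((m, len(a), len(b), d, ks_p, u, mw_p))
    if not rows:
        warnings.warn("no motif has enough targets in both sets", stacklevel=2)
    table = pd.DataFrame(
        rows, columns=["motif", "n_a", "n_b", "ks_d", "ks_p", "mw_u", "mw_p"]
    ).sort_values("ks_d", ascending=False, ignore_index=True)
    return ComparisonResult(table=table, skipped=skipped)


def fisher_enrichment(
    gene_set: set[str],
    universe: set[str],
    term_annotation: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Classical one-sided Fisher (hypergeometric upper-tail) enrichment.

    ``term_annotation`` maps gene_id to a list of term ids.  Terms with
    no members in the universe are skipped.  Returns per-term overlap
    counts, raw p, BH-adjusted p, and a significance flag at ``alpha``
    on the raw p (matching the classical procedure); a stricter report
    can be derived by filtering on the returned p-values.
    """
    stray = gene_set - universe
    if stray:
        raise ValueError(f"gene set members outside universe: {sorted(stray)[:5]}")
    ann = term_annotation.loc[[g for g in term_annotation.index if g in universe]]
    term_members: dict[str, set[str]] = {}
    for gene, terms in ann.items():
        for t in terms:
            term_members.setdefault(t, set()).add(gene)
    M = len(universe)
    N = len(gene_set)
    rows = []
    for term, members in sorted(term_members.items()):
        n = len(members)
        if n == 0:
            continue
        k = len(members & gene_set)
        p = float(stats.hypergeom.sf(k - 1, M, n, N))
        rows.append((term, k, N, n, M, p))
    table = pd.DataFrame(
        rows, columns=["term", "overlap", "set_size", "term_size", "universe_size", "pvalue"]
    )
    if len(table):
        from pip3scope.de_engine import bh_adjust

        table["padj"] = bh_adjust(table["pvalue"].to_numpy())
        table["significant"] = table["pvalue"] < alpha
        table = table.sort_values("pvalue", ignore_index=True)
    return table


def sample_correlation_matrix(matrix) -> pd.DataFrame:
    """Pairwise Pearson correlation of sample columns (unit diagonal).

    Zero-variance columns yield NaN entries with a warning.
    """
    df = matrix if isinstance(matrix, pd.DataFrame) else pd.DataFrame(np.asarray(matrix))
    if df.shape[0] < 2:
        raise ValueError("need >= 2 genes")
    X = df.to_numpy(dtype=float)
    sd = X.std(axis=0)
    if (sd == 0).any():
        warnings.warn("zero-variance sample column(s); correlations set to NaN", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(corr, np.where(sd > 0, 1.0, np.nan))
    return pd.DataFrame(corr, index=df.columns, columns=df.columns)


def pca_samples(matrix, n_components: int | None = None):
    """PCA of samples via SVD of the column-centered matrix.

    Returns (coordinates: samples x components, variance fractions
    summing to 1 over all components).
    """
    df = matrix if isinstance(matrix, pd.DataFrame) else pd.DataFrame(np.asarray(matrix))
    X = df.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    Xc = (X - X.mean(axis=1, keepdims=True)).T  # samples x genes, gene-centered
    Xc = Xc - Xc.mean(axis=0, keepdims=True)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    frac = var / var.sum() if var.sum() > 0 else var
    coords = U * s
    if n_components is not None:
        coords = coords[:, :n_components]
        frac_out = frac[:n_components]
    else:
        frac_out = frac
    coords = pd.DataFrame(
        coords,
        index=df.columns,
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    return coords, frac_out
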