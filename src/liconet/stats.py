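"""Over-representation and correlation statistics for the target pipeline.

Enrichment of a study gene set against term annotations uses the exact
hypergeometric upper tail ``P(X ≥ k)`` with Benjamini–Hochberg adjustment;
a term is significant when both ``p < 0.01`` and ``q < 0.01`` (strict, both
configurable).  The co-expression screen reports the Pearson correlation of
every gene against a query gene, with a two-sided p-value from the exact
t transform on ``S − 2`` degrees of freedom and a BH column, mirroring the
``Query / Statistic / p-Value / FDR (BH)`` report layout.
"""

from __future__ import annotations

import logging
from fractions import Fraction
from math import comb, sqrt
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .targets import GeneSet

logger = logging.getLogger(__name__)

DEFAULT_P_CUTOFF = 0.01
DEFAULT_Q_CUTOFF = 0.01


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Exact upper-tail ``P(X ≥ k)`` for X ~ Hypergeometric(N, K, n).

    *k* study hits, *K* annotated genes in the universe, *n* study size,
    *N* universe size.  Summed exactly over rationals before converting to
    float, so small tails lose no precision to cancellation.
    """
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"need 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if K > N or n > N:
        raise ValueError(f"need K <= N and n <= N; got K={K}, n={n}, N={N}")
    total = comb(N, n)
    tail = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1))
    return float(Fraction(tail, total))


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, input order preserved.

    ``q_(i) = min_{j >= i} p_(j) * m / j`` over the ascending order
    statistics, capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    # divide first so the top rank's factor is exactly 1 and q >= p holds
    ranked = p[order] * (m / np.arange(1, m + 1))
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def enrich(
    study: GeneSet,
    annotation: Mapping[str, GeneSet | frozenset[str] | set[str]],
    universe: GeneSet,
    p_cutoff: float = DEFAULT_P_CUTOFF,
    q_cutoff: float = DEFAULT_Q_CUTOFF,
) -> pd.DataFrame:
    """Hypergeometric over-representation of *study* in each annotation term.

    Terms and the study set are intersected with the universe first (a study
    gene outside the universe is dropped with a warning).  Only terms with at
    least one study hit are reported; rows are sorted by p-value and flagged
    ``significant`` when both cut-offs are passed strictly.
    """
    if len(universe) == 0:
        raise ValueError("enrichment universe is empty")
    uni = universe.genes
    study_genes = study.genes & uni
    dropped = len(study.genes) - len(study_genes)
    if dropped:
        logger.warning("%d study genes outside the universe were dropped", dropped)
    n, N = len(study_genes), len(uni)
    rows = []
    for term, genes in annotation.items():
        term_genes = (genes.genes if isinstance(genes, GeneSet) else frozenset(genes)) & uni
        k, K = len(term_genes & study_genes), len(term_genes)
        if k < 1:
            continue
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N})
    df = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N"])
    if df.empty:
        df["p"], df["q"], df["significant"] = [], [], []
        return df
    df["p"] = [hypergeom_pvalue(r.k, r.K, r.n, r.N) for r in df.itertuples()]
    df["q"] = bh_adjust(df["p"].to_numpy())
    df["significant"] = (df["p"] < p_cutoff) & (df["q"] < q_cutoff)
    return df.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)


def _pearson_pvalue(r: float, n_samples: int) -> float:
    """Two-sided p from the t transform, ``t = r sqrt((S−2)/(1−r²))``."""
    if abs(r) >= 1.0:
        return 0.0
    dof = n_samples - 2
    t = r * sqrt(dof / (1.0 - r * r))
    return float(2.0 * sps.t.sf(abs(t), dof))


def correlation_screen(expr: pd.DataFrame, query: str) -> pd.DataFrame:
    """Pearson correlation of every gene against *query* across samples.

    ``expr`` is samples × genes.  Zero-variance genes are reported with
    ``excluded=True`` and take no part in the BH adjustment.  Rows are
    sorted by descending correlation, so the query itself (r = 1) leads.
    """
    if query not in expr.columns:
        raise KeyError(f"query gene {query!r} not in expression matrix")
    S = expr.shape[0]
    if S < 4:
        raise ValueError(f"correlation screen requires >= 4 samples, got {S}")
    X = expr.to_numpy(dtype=float)
    genes = list(expr.columns)
    qv = expr[query].to_numpy(dtype=float)
    if np.std(qv) == 0:
        raise ValueError("query gene has zero variance")
    sd = X.std(axis=0)
    centered = X - X.mean(axis=0)
    qc = qv - qv.mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (centered.T @ qc) / (S * sd * qc.std())
    r = np.clip(r, -1.0, 1.0)
    excluded = sd == 0
    pvals = np.array(
        [np.nan if excl else _pearson_pvalue(ri, S) for ri, excl in zip(r, excluded)]
    )
    df = pd.DataFrame(
        {"gene": genes, "r": r, "p": pvals, "excluded": excluded}
    )
    df.loc[df["gene"] == query, "r"] = 1.0
    fdr = np.full(len(df), np.nan)
    mask = ~df["excluded"].to_numpy()
    fdr[mask] = bh_adjust(df.loc[mask, "p"].to_numpy())
    df["fdr"] = fdr
    df = df.sort_values(["r", "gene"], ascending=[False, True], kind="mergesort")
    is_query = df["gene"] == query
    df = pd.concat([df[is_query], df[~is_query]]).reset_index(drop=True)
    return df


def correlation_table(screen: pd.DataFrame) -> pd.DataFrame:
    """Reshape a correlation screen into the published report layout."""
    kept = screen[~screen["excluded"]]
    return pd.DataFrame(
        {
            "Query": kept["gene"],
            "Statistic": kept["r"].round(3),
            "p-Value": kept["p"],
            "FDR (BH)": kept["fdr"],
        }
    ).reset_index(drop=True)


def read_annotation(path) -> dict[str, GeneSet]:
    """Two-column TSV ``term``, ``gene`` → term gene sets."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {
        str(term): GeneSet.from_iterable(sub["gene"], label=str(term))
        for term, sub in df.groupby("term", sort=True)
    }


def read_expression(path, orientation: str = "samples_x_genes") -> pd.DataFrame:
    """Expression TSV with sample ids in the first column (or transposed)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if orientation == "genes_x_samples":
        df = df.T
    elif orientation != "samples_x_genes":
        raise ValueError(f"unknown orientation {orientation!r}")
    return df
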