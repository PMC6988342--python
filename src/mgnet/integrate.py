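"""Gene-side selection cascade, CLR transform, the gene-by-taxon Spearman
screen, and Storey q-value control.

Genes entering the screen are size-factor-normalized counts; Spearman is
rank-based so any monotone per-sample-consistent transform of expression
gives identical results.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from mgnet.tables import FeatureTable, ValidationError
from mgnet.abundance import DifferentialResult, bh_adjust

__all__ = [
    "PairCorrelation",
    "select_genes",
    "clr_transform",
    "spearman_screen",
    "qvalues",
    "estimate_pi0",
    "attach_qvalues",
    "significant_pairs",
    "pairs_to_frame",
]


@dataclass(frozen=True)
class PairCorrelation:
    gene_id: str
    taxon_id: str
    rho: float
    p: float
    q: float = float("nan")
    flag: str = ""


def pairs_to_frame(pairs: Sequence[PairCorrelation]) -> pd.DataFrame:
    return pd.DataFrame([vars(p) for p in pairs])


# ---------------------------------------------------------------------------
# Gene selection
# ---------------------------------------------------------------------------

def select_genes(de: Sequence[DifferentialResult], pathway_genes: set[str],
                 fdr: float = 0.05, min_abs_lfc: float = 0.35) -> set[str]:
    """Significant DE genes restricted to a pathway set with
    |log2fc| strictly greater than ``min_abs_lfc``."""
    return {r.feature_id for r in de
            if r.q < fdr
            and r.feature_id in pathway_genes
            and abs(r.log2fc) > min_abs_lfc}


# ---------------------------------------------------------------------------
# CLR transform
# ---------------------------------------------------------------------------

def clr_transform(table: FeatureTable, pseudocount: float = 1.0
                  ) -> pd.DataFrame:
    """Centered log-ratio per sample: ln(x_i + pc) minus its column mean.

    Returns a taxa-by-samples DataFrame whose columns each sum to 0.
    """
    vals = table.values
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    if pseudocount == 0 and (vals == 0).any():
        raise ValidationError(
            "zero counts present: a positive pseudocount is required")
    x = np.log(vals + pseudocount)
    clr = x - x.mean(axis=0, keepdims=True)
    return pd.DataFrame(clr, index=table.feature_ids,
                        columns=table.sample_ids)


# ---------------------------------------------------------------------------
# Spearman screen
# ---------------------------------------------------------------------------

@lru_cache(maxsize=16)
def _exact_rho_null(n: int) -> np.ndarray:
    """All n! tie-free Spearman rho values against a fixed ordering."""
    base = np.arange(1, n + 1)
    perms = np.array(list(itertools.permutations(base)))
    d2 = ((perms - base) ** 2).sum(axis=1)
    return 1.0 - 6.0 * d2 / (n * (n ** 2 - 1.0))


def _exact_p(rho: float, n: int) -> float:
    null = _exact_rho_null(n)
    return float(np.mean(np.abs(null) >= abs(rho) - 1e-12))


def _t_approx_p(rho: np.ndarray, n: int) -> np.ndarray:
    r = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.where(np.abs(r) >= 1.0, 0.0, np.clip(p, 0.0, 1.0))


def spearman_screen(gene_expr: FeatureTable, clr: pd.DataFrame,
                    exact_max_n: int = 9) -> list[PairCorrelation]:
    """Tie-aware Spearman correlation for every gene-by-taxon pair.

    rho is Pearson on mid-ranks.  p is two-sided from the t approximation
    with df = n - 2, or the exact permutation null for n <= ``exact_max_n``
    when neither vector has ties.  Constant vectors yield rho = 0, p = 1,
    flagged.  Samples are aligned by ID intersection.
    """
    shared = [s for s in gene_expr.sample_ids if s in clr.columns]
    if len(shared) < 4:
        raise ValidationError(
            f"need >= 4 shared samples, got {len(shared)}")
    n = len(shared)
    G = gene_expr.data[shared].to_numpy()
    T = clr[shared].to_numpy()
    g_ranks = np.apply_along_axis(stats.rankdata, 1, G)
    t_ranks = np.apply_along_axis(stats.rankdata, 1, T)

    def _standardize(r):
        c = r - r.mean(axis=1, keepdims=True)
        sd = c.std(axis=1, keepdims=True)
        const = sd[:, 0] == 0
        sd[sd == 0] = 1.0
        return c / sd, const

    gz, g_const = _standardize(g_ranks)
    tz, t_const = _standardize(t_ranks)
    rho = (gz @ tz.T) / n
    pmat = np.column_stack([_t_approx_p(rho[:, j], n)
                            for j in range(rho.shape[1])])
    g_ties = np.array([len(np.unique(row)) < n for row in G])
    t_ties = np.array([len(np.unique(row)) < n for row in T])
    results = []
    for i, gid in enumerate(gene_expr.feature_ids):
        for j, tid in enumerate(clr.index):
            if g_const[i] or t_const[j]:
                results.append(PairCorrelation(gid, tid, 0.0, 1.0,
                                               flag="constant input"))
                continue
            r = float(np.clip(rho[i, j], -1.0, 1.0))
            if n <= exact_max_n and not (g_ties[i] or t_ties[j]):
                p = _exact_p(r, n)
            else:
                p = float(pmat[i, j])
            results.append(PairCorrelation(gid, tid, r,
                                           max(p, np.finfo(float).tiny)))
    return results


# ---------------------------------------------------------------------------
# Storey q-values
# ---------------------------------------------------------------------------

def estimate_pi0(p: np.ndarray,
                 lambdas: np.ndarray | None = None) -> float:
    """Storey's smoother estimate of the null proportion pi0.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) over the default grid
    0.05..0.95; a cubic polynomial smoother is evaluated at the largest
    lambda.  Unstable fits (outside (0, 1]) fall back to 1 (BH).
    """
    p = np.asarray(p, dtype=float)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.951, 0.05)
    m = p.size
    pi0_lambda = np.array([(p > lam).sum() / (m * (1.0 - lam))
                           for lam in lambdas])
    try:
        coef = np.polyfit(lambdas, pi0_lambda, 3)
        pi0 = float(np.polyval(coef, lambdas.max()))
    except np.linalg.LinAlgError:
        pi0 = 1.0
    if not (0.0 < pi0 <= 1.0):
        pi0 = 1.0
    return pi0


def qvalues(pvalues, pi0: float | None = None) -> np.ndarray:
    """Storey q-values: BH step-up scaled by the estimated null proportion.

    With ``pi0`` forced to 1 the result equals Benjamini-Hochberg exactly.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValidationError("p-values must lie in (0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0(p)
    if not (0.0 < pi0 <= 1.0):
        raise ValidationError(f"pi0 {pi0} outside (0, 1]")
    return np.minimum(pi0 * bh_adjust(p), 1.0)


def attach_qvalues(pairs: Sequence[PairCorrelation],
                   pi0: float | None = None) -> list[PairCorrelation]:
    q = qvalues([pr.p for pr in pairs], pi0=pi0)
    return [replace(pr, q=float(qv)) for pr, qv in zip(pairs, q)]


def significant_pairs(pairs: Sequence[PairCorrelation],
                      q_threshold: float = 0.1) -> list[PairCorrelation]:
    """Pairs with q strictly below threshold, sorted by |rho| descending."""
    kept = [pr for pr in pairs if pr.q < q_threshold]
    return sorted(kept, key=lambda pr: -abs(pr.rho))
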