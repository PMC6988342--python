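"""Rarefaction-based alpha diversity, beta-diversity distances, PCoA, and
PERMANOVA.

Alpha diversity averages each metric over repeated rarefactions (default
100 draws at the minimum sample depth); beta diversity offers Bray-Curtis
and both UniFrac variants; group structure is tested with a permutation
pseudo-F (Adonis-style PERMANOVA).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skbio import TreeNode

from mgnet.tables import (
    FeatureTable,
    SampleMetadata,
    ValidationError,
    condition_groups,
)

__all__ = [
    "AlphaDiversityResult",
    "DistanceMatrix",
    "PermanovaResult",
    "rarefy",
    "alpha_diversity",
    "alpha_group_test",
    "beta_diversity",
    "pcoa",
    "permanova",
    "chao1",
    "observed_otus",
    "shannon",
]

ALPHA_METRICS = ("chao1", "observed_otus", "shannon")
BETA_METRICS = ("bray_curtis", "unweighted_unifrac", "weighted_unifrac")


# ---------------------------------------------------------------------------
# Result types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlphaDiversityResult:
    sample_id: str
    metric: str
    value: float
    n_resamples: int
    depth: int


class DistanceMatrix:
    """Symmetric non-negative distance matrix keyed by sample ID."""

    def __init__(self, matrix, sample_ids: Sequence[str], metric: str = ""):
        m = np.asarray(matrix, dtype=float)
        ids = list(sample_ids)
        if m.shape != (len(ids), len(ids)):
            raise ValidationError("matrix shape does not match sample_ids")
        if np.isnan(m).any():
            raise ValidationError("NaN in distance matrix")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValidationError("distance matrix not symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal not zero")
        if (m < -1e-12).any():
            raise ValidationError("negative distances")
        self.data = pd.DataFrame(np.clip(m, 0.0, None), index=ids, columns=ids)
        self.metric = metric

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def filter(self, sample_ids: Sequence[str]) -> "DistanceMatrix":
        ids = list(sample_ids)
        return DistanceMatrix(self.data.loc[ids, ids].to_numpy(), ids,
                              self.metric)

    def to_tsv(self, path) -> None:
        df = self.data.copy()
        df.index.name = "#SampleID"
        df.to_csv(path, sep="\t", float_format="%.12g")

    @classmethod
    def from_tsv(cls, path, metric: str = "") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(), [str(s) for s in df.columns], metric)


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    R2: float
    p: float
    n_permutations: int


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------

def rarefy(table: FeatureTable, depth: int,
           seed: int | np.random.Generator = 0) -> FeatureTable:
    """Subsample each column without replacement to exactly ``depth``."""
    counts = table.values
    if not np.allclose(counts, np.round(counts)):
        raise ValidationError("rarefaction requires integer counts")
    counts = np.round(counts).astype(np.int64)
    sums = counts.sum(axis=0)
    short = sums < depth
    if short.any():
        bad = list(np.asarray(table.sample_ids)[short])
        raise ValidationError(
            f"depth {depth} exceeds column sums for samples: {bad}")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    out = np.empty_like(counts)
    for j in range(counts.shape[1]):
        out[:, j] = rng.multivariate_hypergeometric(counts[:, j], depth)
    return FeatureTable(out.astype(float), "counts",
                        feature_ids=table.feature_ids,
                        sample_ids=table.sample_ids)


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

def observed_otus(x: np.ndarray) -> float:
    return float((np.asarray(x) > 0).sum())


def chao1(x: np.ndarray) -> float:
    """S_obs + F1(F1-1) / (2(F2+1)) with singleton/doubleton counts."""
    x = np.round(np.asarray(x)).astype(np.int64)
    s_obs = float((x > 0).sum())
    f1 = float((x == 1).sum())
    f2 = float((x == 2).sum())
    return s_obs + f1 * (f1 - 1.0) / (2.0 * (f2 + 1.0))


def shannon(x: np.ndarray) -> float:
    """Shannon entropy with natural log."""
    x = np.asarray(x, dtype=float)
    total = x.sum()
    if total == 0:
        return 0.0
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


_ALPHA_FUNCS = {"chao1": chao1, "observed_otus": observed_otus,
                "shannon": shannon}


def alpha_diversity(table: FeatureTable, metric: str, depth: int,
                    n_resamples: int = 100,
                    seed: int = 0) -> list[AlphaDiversityResult]:
    """Mean of ``metric`` over repeated independent rarefactions.

    A single master seed spawns one child stream per draw, so results are
    reproducible and draws are independent.
    """
    if metric not in _ALPHA_FUNCS:
        raise ValidationError(
            f"unknown alpha metric {metric!r}; choose from {ALPHA_METRICS}")
    if n_resamples < 1:
        raise ValidationError("n_resamples must be >= 1")
    func = _ALPHA_FUNCS[metric]
    children = np.random.SeedSequence(seed).spawn(n_resamples)
    acc = np.zeros(len(table.sample_ids))
    for child in children:
        sub = rarefy(table, depth, np.random.default_rng(child))
        vals = sub.values
        acc += np.array([func(vals[:, j]) for j in range(vals.shape[1])])
    acc /= n_resamples
    return [AlphaDiversityResult(sid, metric, float(v), n_resamples, depth)
            for sid, v in zip(table.sample_ids, acc)]


def alpha_group_test(results: Sequence[AlphaDiversityResult],
                     meta: Sequence[SampleMetadata]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum between the two conditions.

    Exact null when combined n <= 20 with no ties; otherwise normal
    approximation with tie correction.
    """
    values = {r.sample_id: r.value for r in results}
    groups = condition_groups(meta, sample_ids=list(values))
    if len(groups) != 2:
        raise ValidationError(
            f"need exactly 2 condition groups, got {sorted(groups)}")
    (ga, ids_a), (gb, ids_b) = sorted(groups.items())
    xa = [values[s] for s in ids_a]
    xb = [values[s] for s in ids_b]
    if min(len(xa), len(xb)) < 2:
        raise ValidationError("each group needs >= 2 samples")
    pooled = xa + xb
    no_ties = len(set(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(xa, xb, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Beta diversity
# ---------------------------------------------------------------------------

def _bray_curtis(values: np.ndarray) -> np.ndarray:
    n = values.shape[1]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            x, y = values[:, i], values[:, j]
            denom = (x + y).sum()
            d[i, j] = d[j, i] = (np.abs(x - y).sum() / denom
                                 if denom > 0 else 0.0)
    return d


def _branch_table(tree: TreeNode, feature_ids: Sequence[str]
                  ) -> tuple[np.ndarray, np.ndarray]:
    """(branch x feature indicator matrix, branch lengths) for all non-root
    branches; errors if any feature is missing from the tree."""
    idx = {f: i for i, f in enumerate(feature_ids)}
    tips = {t.name for t in tree.tips()}
    missing = [f for f in feature_ids if f not in tips]
    if missing:
        raise ValidationError(f"features missing from tree: {missing}")
    rows, lengths = [], []
    for node in tree.postorder(include_self=False):
        row = np.zeros(len(feature_ids), dtype=bool)
        relevant = False
        for tip in ([node] if node.is_tip() else node.tips()):
            if tip.name in idx:
                row[idx[tip.name]] = True
                relevant = True
        if relevant:
            rows.append(row)
            lengths.append(node.length or 0.0)
    return np.array(rows), np.asarray(lengths, dtype=float)


def _unifrac(values: np.ndarray, tree: TreeNode,
             feature_ids: Sequence[str], weighted: bool,
             normalized: bool = True) -> np.ndarray:
    U, b = _branch_table(tree, feature_ids)
    n = values.shape[1]
    totals = values.sum(axis=0)
    if (totals == 0).any():
        raise ValidationError("all-zero sample in UniFrac input")
    if weighted:
        A = (U.astype(float) @ values) / totals          # branch proportions
    else:
        P = U @ (values > 0)                             # branch presence
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if weighted:
                num = (b * np.abs(A[:, i] - A[:, j])).sum()
                den = (b * (A[:, i] + A[:, j])).sum()
                d[i, j] = d[j, i] = (num / den if normalized and den > 0
                                     else num)
            else:
                either = P[:, i] | P[:, j]
                unique = P[:, i] ^ P[:, j]
                den = b[either].sum()
                d[i, j] = d[j, i] = (b[unique].sum() / den if den > 0
                                     else 0.0)
    return d


def beta_diversity(table: FeatureTable, metric: str,
                   tree: TreeNode | None = None,
                   unifrac_normalized: bool = True) -> DistanceMatrix:
    """Pairwise sample distances.

    bray_curtis = sum|x-y| / sum(x+y); unweighted_unifrac = unique branch
    length / covered branch length over presence; weighted_unifrac is the
    normalized abundance-weighted variant (raw with
    ``unifrac_normalized=False``).
    """
    if metric not in BETA_METRICS:
        raise ValidationError(
            f"unknown beta metric {metric!r}; choose from {BETA_METRICS}")
    if metric == "bray_curtis":
        d = _bray_curtis(table.values)
    else:
        if tree is None:
            raise ValidationError(f"{metric} requires a phylogenetic tree")
        d = _unifrac(table.values, tree, table.feature_ids,
                     weighted=(metric == "weighted_unifrac"),
                     normalized=unifrac_normalized)
    return DistanceMatrix(d, table.sample_ids, metric)


# ---------------------------------------------------------------------------
# Ordination and PERMANOVA
# ---------------------------------------------------------------------------

def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d ** 2
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def pcoa(dm: DistanceMatrix) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Classical scaling of a distance matrix.

    Returns (coordinates over positive axes, all eigenvalues in descending
    order, percent variance over the positive eigenvalues).  Negative
    eigenvalues are reported, not corrected.
    """
    b = _gower_center(dm.values)
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > max(1e-12, 1e-12 * abs(eigvals).max())
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    axes = [f"PC{i + 1}" for i in range(pos.sum())]
    coords = pd.DataFrame(coords, index=dm.sample_ids, columns=axes)
    pct = 100.0 * eigvals[pos] / eigvals[pos].sum()
    return coords, eigvals, pct


def _pseudo_f(d2: np.ndarray, labels: np.ndarray) -> float:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    groups = np.unique(labels)
    for g in groups:
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    a = len(groups)
    ss_between = ss_total - ss_within
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def permanova(dm: DistanceMatrix, meta: Sequence[SampleMetadata],
              grouping: str = "condition", n_permutations: int = 999,
              seed: int = 0) -> PermanovaResult:
    """Permutation test of group separation (Adonis-style pseudo-F).

    Labels are permuted freely; p = (1 + #{F_perm >= F_obs}) /
    (1 + n_permutations).
    """
    by_id = {m.sample_id: m for m in meta}
    labels = []
    for sid in dm.sample_ids:
        if sid not in by_id:
            raise ValidationError(f"sample {sid!r} missing from metadata")
        labels.append(getattr(by_id[sid], grouping))
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValidationError("PERMANOVA needs >= 2 groups")
    if (counts == 0).any():
        raise ValidationError("empty group")
    d2 = dm.values ** 2
    f_obs = _pseudo_f(d2, labels)
    n = len(labels)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    a = len(uniq)
    # back out R2 from F: R2 = SSB/SST with F = (SSB/(a-1))/(SSW/(n-a))
    r2 = f_obs * (a - 1) / (f_obs * (a - 1) + (n - a))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        if _pseudo_f(d2, perm) >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    del ss_total
    return PermanovaResult(pseudo_F=float(f_obs), R2=float(r2), p=float(p),
                           n_permutations=n_permutations)
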