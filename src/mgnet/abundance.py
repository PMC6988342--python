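"""Taxonomic agglomeration, prevalence/abundance filtering, and
differential-abundance tests shared by OTU and gene count tables.

The negative-binomial stage is a deliberately simplified stand-in for a
DESeq2-style analysis: median-of-ratios size factors (with a positive-count
fallback for sparse tables), method-of-moments dispersions shrunk toward a
log-log mean-dispersion trend, an NB GLM fitted by IRLS, and either a Wald
test on the condition coefficient or a likelihood-ratio test across
genotype categories.  No Cox-Reid adjustment, no fold-change shrinkage, no
outlier or independent filtering — per-feature results will differ from
DESeq2 even on identical input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from mgnet.tables import (
    RANKS,
    RANK_PREFIXES,
    FeatureTable,
    SampleMetadata,
    TaxonomyMap,
    ValidationError,
    condition_groups,
    metadata_by_id,
)

__all__ = [
    "DifferentialResult",
    "bh_adjust",
    "agglomerate",
    "prevalence_abundance_filter",
    "size_factors",
    "nb_wald",
    "nb_lrt",
    "wilcoxon_feature_test",
    "de_summary",
    "results_to_frame",
]

_MIN_DISPERSION = 1e-8
_MAX_DISPERSION = 100.0


@dataclass(frozen=True)
class DifferentialResult:
    feature_id: str
    base_mean: float
    log2fc: float
    se: float
    statistic: float
    p: float
    q: float
    test: str
    flag: str = ""


def results_to_frame(results: Sequence[DifferentialResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# Agglomeration and filtering
# ---------------------------------------------------------------------------

def _glom_label(key: tuple[str, ...]) -> str:
    """Human-readable label for an agglomeration key: the deepest assigned
    label, with its rank prefix if not already present."""
    for depth in range(len(key) - 1, -1, -1):
        if key[depth]:
            label = key[depth]
            prefix = RANK_PREFIXES[RANKS[depth]] + "__"
            return label if label.startswith(prefix) else prefix + label
    return "Unassigned"


def agglomerate(table: FeatureTable, taxonomy: TaxonomyMap,
                rank: str) -> FeatureTable:
    """Sum features sharing the lineage prefix down to ``rank``.

    Features unassigned at ``rank`` are grouped by their last characterized
    level ("collapse at the genus level or the last characterized level"):
    the grouping key is the full assigned lineage prefix, labeled
    ``<rank-prefix>__<name>``.
    """
    if rank not in RANKS:
        raise ValidationError(f"unknown rank {rank!r}; choose from {RANKS}")
    missing = [f for f in table.feature_ids if f not in taxonomy]
    if missing:
        raise ValidationError(f"taxonomy missing features: {missing[:5]}")
    k = RANKS.index(rank) + 1
    keys: dict[str, tuple[str, ...]] = {}
    for fid in table.feature_ids:
        prefix = taxonomy.lineage_at(fid, rank)
        if not prefix[-1]:
            # unassigned at rank: fall back to deepest assigned prefix
            full = taxonomy[fid]
            depth = max((i for i, lab in enumerate(full) if lab), default=-1)
            prefix = full[:depth + 1] + ("",) * (k - depth - 1)
        keys[fid] = prefix
    # stable group order: first appearance in the table
    groups: dict[tuple[str, ...], list[str]] = {}
    for fid in table.feature_ids:
        groups.setdefault(keys[fid], []).append(fid)
    labels, seen = [], {}
    for key in groups:
        label = _glom_label(key)
        if label in seen:            # same label, different lineage
            label = label + "|" + ";".join(x for x in key if x)
        seen[label] = key
        labels.append(label)
    mat = np.vstack([table.data.loc[fids].to_numpy().sum(axis=0)
                     for fids in groups.values()])
    return FeatureTable(mat, table.kind, feature_ids=labels,
                        sample_ids=table.sample_ids)


def prevalence_abundance_filter(table: FeatureTable,
                                meta: Sequence[SampleMetadata],
                                min_rel_abund: float = 0.001) -> FeatureTable:
    """Keep features at >= ``min_rel_abund`` relative abundance in at least
    half (ceil) of the samples of the smaller condition group."""
    if not (0 < min_rel_abund < 1):
        raise ValidationError(f"min_rel_abund {min_rel_abund} outside (0,1)")
    groups = condition_groups(meta, sample_ids=table.sample_ids)
    if len(groups) != 2:
        raise ValidationError(
            f"need exactly 2 conditions, got {sorted(groups)}")
    n_min = min(len(ids) for ids in groups.values())
    needed = math.ceil(n_min / 2)
    sample_ids = [s for ids in groups.values() for s in ids]
    sub = table.data[sample_ids]
    rel = sub / sub.sum(axis=0)
    keep = (rel >= min_rel_abund).sum(axis=1) >= needed
    return FeatureTable(table.data.loc[keep.index[keep], sample_ids],
                        table.kind)


# ---------------------------------------------------------------------------
# Size factors
# ---------------------------------------------------------------------------

def size_factors(table: FeatureTable, fallback: bool = True) -> pd.Series:
    """Median-of-ratios size factors (DESeq convention).

    Uses features with all-positive counts; when none exist and
    ``fallback`` is true, geometric means are taken over positive entries
    only ("poscounts").  A single-sample table gets s = 1.
    """
    counts = table.values
    if counts.shape[1] == 1:
        return pd.Series([1.0], index=table.sample_ids)
    with np.errstate(divide="ignore"):
        logc = np.log(counts)
    all_pos = np.isfinite(logc).all(axis=1)
    if all_pos.any():
        log_geo = logc[all_pos].mean(axis=1)
        ratios = logc[all_pos] - log_geo[:, None]
    elif fallback:
        pos = np.isfinite(logc)
        n_pos = pos.sum(axis=1)
        usable = n_pos > 0
        if not usable.any():
            raise ValidationError("empty table: no positive counts at all")
        log_geo = np.where(usable,
                           np.where(pos, logc, 0.0).sum(axis=1)
                           / np.maximum(n_pos, 1), np.nan)
        ratios = np.where(pos, logc - log_geo[:, None], np.nan)[usable]
    else:
        raise ValidationError(
            "no feature has all-positive counts; enable the poscounts "
            "fallback or filter samples")
    s = np.exp(np.nanmedian(ratios, axis=0))
    if not (np.isfinite(s).all() and (s > 0).all()):
        raise ValidationError("degenerate size factors")
    return pd.Series(s, index=table.sample_ids)


# ---------------------------------------------------------------------------
# NB GLM machinery
# ---------------------------------------------------------------------------

def _irls_nb(y: np.ndarray, X: np.ndarray, offset: np.ndarray,
             alpha: float, max_iter: int = 100,
             tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray, bool]:
    """Fit log mu = X beta + offset for NB with known dispersion alpha.

    Returns (beta, covariance of beta, converged).
    """
    # init from ridge-ish log counts
    z0 = np.log(y + 0.5) - offset
    beta, *_ = np.linalg.lstsq(X, z0, rcond=None)
    for _ in range(max_iter):
        eta = X @ beta + offset
        eta = np.clip(eta, -30, 30)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (y - mu) / mu
        xtw = X.T * w
        try:
            new = np.linalg.solve(xtw @ X, xtw @ z)
        except np.linalg.LinAlgError:
            return beta, np.full((X.shape[1], X.shape[1]), np.nan), False
        if not np.isfinite(new).all():
            return beta, np.full((X.shape[1], X.shape[1]), np.nan), False
        step = np.abs(new - beta).max()
        beta = new
        if step < tol:
            eta = np.clip(X @ beta + offset, -30, 30)
            mu = np.exp(eta)
            w = mu / (1.0 + alpha * mu)
            cov = np.linalg.inv((X.T * w) @ X)
            return beta, cov, True
    eta = np.clip(X @ beta + offset, -30, 30)
    mu = np.exp(eta)
    w = mu / (1.0 + alpha * mu)
    try:
        cov = np.linalg.inv((X.T * w) @ X)
    except np.linalg.LinAlgError:
        cov = np.full((X.shape[1], X.shape[1]), np.nan)
    return beta, cov, False


def _nb_deviance(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    inv = 1.0 / alpha
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(y / mu), 0.0)
    term2 = (y + inv) * np.log((1.0 + alpha * y) / (1.0 + alpha * mu))
    return float(2.0 * (term1 - term2).sum())


def _moment_dispersions(counts: np.ndarray, sf: np.ndarray,
                        group_idx: list[np.ndarray]) -> np.ndarray:
    """Per-feature method-of-moments dispersion, pooling within-group
    residuals.

    Solves E[(q - m)^2] = m/s + alpha m^2 per design cell with two
    small-sample corrections: residual sums are scaled by n_g/(n_g - 1),
    and Var(m-hat) is subtracted from the squared-mean denominator so the
    estimator is approximately unbiased at small n.
    """
    q = counts / sf[None, :]
    num = np.zeros(counts.shape[0])
    den = np.zeros(counts.shape[0])
    poisson_part = np.zeros(counts.shape[0])
    for idx in group_idx:
        ng = len(idx)
        m = q[:, idx].mean(axis=1)
        rss = ((q[:, idx] - m[:, None]) ** 2).sum(axis=1)
        if ng > 1:
            num += rss * ng / (ng - 1)
            den += ng * (m ** 2 - rss / (ng * (ng - 1)))
        else:
            den += m ** 2
        poisson_part += m * np.sum(1.0 / sf[idx])
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (num - poisson_part) / den
    alpha = np.where(np.isfinite(alpha) & (den > 0), alpha, _MIN_DISPERSION)
    return np.clip(alpha, _MIN_DISPERSION, _MAX_DISPERSION)


def _shrink_dispersions(alpha_mom: np.ndarray,
                        base_mean: np.ndarray) -> np.ndarray:
    """50/50 log-space shrinkage toward a log-log mean-dispersion trend."""
    usable = (alpha_mom > _MIN_DISPERSION * 10) & (base_mean > 0)
    if usable.sum() >= 10:
        x = np.log(base_mean[usable])
        yv = np.log(alpha_mom[usable])
        slope, intercept = np.polyfit(x, yv, 1)
        with np.errstate(divide="ignore"):
            trend = np.exp(intercept + slope * np.log(
                np.maximum(base_mean, 1e-8)))
        trend = np.clip(trend, _MIN_DISPERSION, _MAX_DISPERSION)
        out = np.exp(0.5 * np.log(np.maximum(alpha_mom, _MIN_DISPERSION))
                     + 0.5 * np.log(trend))
    else:
        out = alpha_mom
    return np.clip(out, _MIN_DISPERSION, _MAX_DISPERSION)


def _design_condition(table: FeatureTable, meta: Sequence[SampleMetadata]
                      ) -> tuple[np.ndarray, list[np.ndarray]]:
    groups = condition_groups(meta, sample_ids=table.sample_ids)
    if len(groups) != 2:
        raise ValidationError(
            f"need exactly 2 conditions, got {sorted(groups)}")
    for cond, ids in groups.items():
        if len(ids) < 2:
            raise ValidationError(f"condition {cond!r} has < 2 samples")
    by_id = metadata_by_id(meta)
    x = np.array([1.0 if by_id[s].condition == "CF" else 0.0
                  for s in table.sample_ids])
    X = np.column_stack([np.ones_like(x), x])
    group_idx = [np.flatnonzero(x == 0), np.flatnonzero(x == 1)]
    return X, group_idx


def nb_wald(table: FeatureTable, meta: Sequence[SampleMetadata],
            sf: pd.Series | None = None) -> list[DifferentialResult]:
    """Per-feature NB Wald test of CF vs Healthy.

    log2fc is the CF coefficient divided by ln 2; two-sided normal p on
    z = beta1 / SE; BH-adjusted q across all features.
    """
    if sf is None:
        sf = size_factors(table)
    sf = sf.loc[table.sample_ids]
    X, group_idx = _design_condition(table, meta)
    counts = table.values
    s = sf.to_numpy()
    offset = np.log(s)
    base_mean = (counts / s[None, :]).mean(axis=1)
    alpha_mom = _moment_dispersions(counts, s, group_idx)
    alphas = _shrink_dispersions(alpha_mom, np.maximum(base_mean, 1e-8))
    ln2 = np.log(2.0)
    rows = []
    for i, fid in enumerate(table.feature_ids):
        y = counts[i]
        flag = ""
        if (y == 0).all():
            rows.append((fid, 0.0, 0.0, np.nan, 0.0, 1.0, "all zero"))
            continue
        # one-group-all-zero: 0.5-count ridge keeps the fit finite
        if any((y[idx] == 0).all() for idx in group_idx):
            y = y + 0.5
            flag = "zero group (ridged)"
        beta, cov, converged = _irls_nb(y, X, offset, alphas[i])
        if not converged and flag == "":
            flag = "non-convergence"
        se = float(np.sqrt(cov[1, 1])) if np.isfinite(cov[1, 1]) else np.nan
        if not np.isfinite(se) or se <= 0:
            rows.append((fid, base_mean[i], 0.0, np.nan, 0.0, 1.0,
                         flag or "degenerate fit"))
            continue
        z = beta[1] / se
        p = 1.0 if flag == "non-convergence" else float(
            2.0 * stats.norm.sf(abs(z)))
        rows.append((fid, base_mean[i], float(beta[1] / ln2),
                     se / ln2, float(z), max(p, np.finfo(float).tiny), flag))
    q = bh_adjust([r[5] for r in rows])
    return [DifferentialResult(fid, bm, lfc, se, zstat, p, float(qv),
                               "wald", flag)
            for (fid, bm, lfc, se, zstat, p, flag), qv in zip(rows, q)]


def nb_lrt(table: FeatureTable, meta: Sequence[SampleMetadata],
           sf: pd.Series | None = None) -> list[DifferentialResult]:
    """NB likelihood-ratio test across the three genotype categories
    (full ~genotype vs reduced ~1, shared per-feature dispersion).

    The deviance difference is referred to F(df, n - p_full) via LR/df
    rather than the asymptotic chi-square: with estimated dispersions at
    these sample sizes the chi-square reference is anticonservative, and
    the F reference restores null calibration.
    """
    if sf is None:
        sf = size_factors(table)
    sf = sf.loc[table.sample_ids]
    by_id = metadata_by_id(meta)
    levels = ("Healthy", "CF_df508", "CF_other")
    genotypes = []
    for sid in table.sample_ids:
        rec = by_id.get(sid)
        if rec is None or rec.is_negative_control:
            raise ValidationError(f"sample {sid!r} not a typed true sample")
        genotypes.append(rec.genotype)
    counts_per = {g: genotypes.count(g) for g in levels}
    bad = [g for g, c in counts_per.items() if c < 2]
    if bad:
        raise ValidationError(f"genotype categories with < 2 samples: {bad}")
    g_codes = np.array([levels.index(g) for g in genotypes])
    X_full = np.column_stack([np.ones(len(g_codes)),
                              (g_codes == 1).astype(float),
                              (g_codes == 2).astype(float)])
    X_red = X_full[:, :1]
    group_idx = [np.flatnonzero(g_codes == k) for k in range(3)]
    counts = table.values
    s = sf.to_numpy()
    offset = np.log(s)
    base_mean = (counts / s[None, :]).mean(axis=1)
    alpha_mom = _moment_dispersions(counts, s, group_idx)
    alphas = _shrink_dispersions(alpha_mom, np.maximum(base_mean, 1e-8))
    df = X_full.shape[1] - X_red.shape[1]
    rows = []
    for i, fid in enumerate(table.feature_ids):
        y = counts[i]
        flag = ""
        if (y == 0).all():
            rows.append((fid, 0.0, 0.0, np.nan, 0.0, 1.0, "all zero"))
            continue
        if any((y[idx] == 0).all() for idx in group_idx):
            y = y + 0.5
            flag = "zero group (ridged)"
        bf, _, conv_f = _irls_nb(y, X_full, offset, alphas[i])
        br, _, conv_r = _irls_nb(y, X_red, offset, alphas[i])
        if not (conv_f and conv_r):
            rows.append((fid, base_mean[i], 0.0, np.nan, 0.0, 1.0,
                         flag or "non-convergence"))
            continue
        mu_f = np.exp(np.clip(X_full @ bf + offset, -30, 30))
        mu_r = np.exp(np.clip(X_red @ br + offset, -30, 30))
        lr = _nb_deviance(y, mu_r, alphas[i]) - _nb_deviance(y, mu_f,
                                                             alphas[i])
        lr = max(lr, 0.0)
        p = float(stats.f.sf(lr / df, df, len(y) - X_full.shape[1]))
        # report the largest genotype contrast as the effect size
        lfc = float(max(bf[1], bf[2], 0.0, key=abs) / np.log(2.0))
        rows.append((fid, base_mean[i], lfc, np.nan, float(lr),
                     max(p, np.finfo(float).tiny), flag))
    q = bh_adjust([r[5] for r in rows])
    return [DifferentialResult(fid, bm, lfc, se, statv, p, float(qv),
                               "lrt", flag)
            for (fid, bm, lfc, se, statv, p, flag), qv in zip(rows, q)]


# ---------------------------------------------------------------------------
# Wilcoxon test for relative-abundance tables
# ---------------------------------------------------------------------------

def wilcoxon_feature_test(rel_table: FeatureTable,
                          meta: Sequence[SampleMetadata],
                          min_rel_abund: float = 0.001,
                          min_fraction: float = 0.5
                          ) -> list[DifferentialResult]:
    """Filter + per-feature two-sided Wilcoxon rank-sum + BH.

    Unlike the OTU filter, prevalence here is over *all* samples: keep a
    feature iff its relative abundance exceeds ``min_rel_abund`` (strict)
    in at least ``ceil(min_fraction * n_samples)`` samples.
    """
    if rel_table.kind != "relative":
        raise ValidationError(
            "wilcoxon_feature_test expects a relative-abundance table; "
            "normalize counts first (FeatureTable.to_relative)")
    groups = condition_groups(meta, sample_ids=rel_table.sample_ids)
    if len(groups) != 2:
        raise ValidationError(
            f"need exactly 2 conditions, got {sorted(groups)}")
    sample_ids = [s for ids in groups.values() for s in ids]
    sub = rel_table.data[sample_ids]
    needed = math.ceil(min_fraction * len(sample_ids))
    keep = (sub > min_rel_abund).sum(axis=1) >= needed
    sub = sub.loc[keep.index[keep]]
    (ca, ids_a), (cb, ids_b) = sorted(groups.items())
    rows = []
    for fid in sub.index:
        xa = sub.loc[fid, ids_a].to_numpy()
        xb = sub.loc[fid, ids_b].to_numpy()
        pooled = np.concatenate([xa, xb])
        if np.all(pooled == pooled[0]):
            stat, p = 0.0, 1.0
        else:
            no_ties = len(np.unique(pooled)) == len(pooled)
            method = ("exact" if (len(pooled) <= 20 and no_ties)
                      else "asymptotic")
            res = stats.mannwhitneyu(xa, xb, alternative="two-sided",
                                     method=method)
            stat, p = float(res.statistic), float(res.pvalue)
        # effect direction on log2 scale of group medians (pseudo 1e-9)
        med_a = float(np.median(xa)) + 1e-9
        med_b = float(np.median(xb)) + 1e-9
        lfc = math.log2(med_b / med_a) if ca == "CF" else math.log2(
            med_a / med_b)
        rows.append((fid, float(pooled.mean()), lfc, stat, min(p, 1.0)))
    q = bh_adjust([r[4] for r in rows])
    return [DifferentialResult(fid, bm, lfc, float("nan"), statv, p,
                               float(qv), "wilcoxon")
            for (fid, bm, lfc, statv, p), qv in zip(rows, q)]


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def de_summary(results: Sequence[DifferentialResult],
               alpha: float = 0.05) -> dict:
    """Counts and up/down split of significant features.

    ``pct_up_display`` follows the truncating integer-percent convention
    common in results text (919/1543 -> 59)."""
    sig = [r for r in results if r.q < alpha]
    n_up = sum(1 for r in sig if r.log2fc > 0)
    n_down = sum(1 for r in sig if r.log2fc < 0)
    n = len(sig)
    pct_up = 100.0 * n_up / n if n else float("nan")
    pct_down = 100.0 * n_down / n if n else float("nan")
    return {
        "n_significant": n,
        "n_up": n_up,
        "n_down": n_down,
        "pct_up": pct_up,
        "pct_down": pct_down,
        "pct_up_display": int(pct_up) if n else None,
        "pct_down_display": int(pct_down) if n else None,
        "alpha": alpha,
    }
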