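"""From-scratch SparCC basis correlations, permutation pseudo-p-values,
and assembly of the mixed gene-taxon network.

SparCC estimates correlations between latent ("basis") abundances from
compositional counts: per estimation iteration, fractions are drawn from a
per-sample Dirichlet posterior, the pairwise log-ratio variance matrix is
formed, basis variances are solved under the sparsity assumption
(correlations approximately zero), and strongly correlated pairs are
iteratively excluded from the system.  The final correlation is the median
over estimation iterations.  Defaults (20 estimation iterations, 10
exclusion rounds, exclusion threshold 0.1, Dirichlet alpha = counts + 1,
median aggregation) follow the original algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from mgnet.tables import FeatureTable, Network, NetworkEdge, ValidationError
from mgnet.integrate import PairCorrelation

__all__ = [
    "SparccConfig",
    "SparccResult",
    "sparcc",
    "sparcc_pseudo_p",
    "build_network",
    "network_stats",
    "sparcc_to_frame",
]


@dataclass(frozen=True)
class SparccConfig:
    n_estimation_iters: int = 20
    n_exclusion_iters: int = 10
    exclusion_threshold: float = 0.1
    n_null: int = 100
    seed: int = 0

    def __post_init__(self):
        if min(self.n_estimation_iters, self.n_exclusion_iters,
               self.n_null) < 1:
            raise ValidationError("iteration counts must be positive")
        if not (0 < self.exclusion_threshold < 1):
            raise ValidationError("exclusion_threshold must be in (0, 1)")


@dataclass(frozen=True)
class SparccResult:
    taxon_i: str
    taxon_j: str
    r: float
    pseudo_p: float = float("nan")
    n_null: int = 0


def sparcc_to_frame(results: Sequence[SparccResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


# ---------------------------------------------------------------------------
# Core estimation
# ---------------------------------------------------------------------------

def _variation_matrix(log_fracs: np.ndarray) -> np.ndarray:
    """t_ij = Var over samples of ln(f_i / f_j), from the covariance of
    log fractions."""
    cov = np.cov(log_fracs)
    v = np.diag(cov)
    return v[:, None] + v[None, :] - 2.0 * cov


def _solve_basis(T: np.ndarray, M: np.ndarray,
                 t_vec: np.ndarray) -> np.ndarray:
    return np.linalg.solve(M, t_vec)


def _correlation_from_basis(T: np.ndarray, omega: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = 2.0 * np.sqrt(np.outer(omega, omega))
        r = (omega[:, None] + omega[None, :] - T) / denom
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def _one_iteration(T: np.ndarray, cfg: SparccConfig) -> np.ndarray:
    """Solve the basis system with iterative strong-pair exclusion.

    Components whose solved basis variance goes non-positive are dropped
    from the system; their correlations come back as NaN.
    """
    D = T.shape[0]
    active = np.ones(D, dtype=bool)
    excluded_pairs: set[tuple[int, int]] = set()

    def solve_active() -> np.ndarray:
        idx = np.flatnonzero(active)
        d = len(idx)
        if d < 4:
            return np.full(D, np.nan)
        Ts = T[np.ix_(idx, idx)]
        M = np.ones((d, d)) + np.diag(np.full(d, d - 2.0))
        t_vec = Ts.sum(axis=1)
        pos = {g: k for k, g in enumerate(idx)}
        for (i, j) in excluded_pairs:
            if i in pos and j in pos:
                a, b = pos[i], pos[j]
                M[a, a] -= 1.0
                M[b, b] -= 1.0
                M[a, b] -= 1.0
                M[b, a] -= 1.0
                t_vec[a] -= Ts[a, b]
                t_vec[b] -= Ts[a, b]
        omega_s = _solve_basis(Ts, M, t_vec)
        omega = np.full(D, np.nan)
        omega[idx] = omega_s
        return omega

    def resolve() -> np.ndarray:
        # drop components until all solved variances are positive
        while True:
            omega = solve_active()
            bad = np.flatnonzero(active & ~(omega > 0))
            if len(bad) == 0 or active.sum() < 4:
                return omega
            # drop the worst offender and re-solve
            worst = bad[np.nanargmin(omega[bad])]
            active[worst] = False

    omega = resolve()
    r = _correlation_from_basis(T, omega)
    for _ in range(cfg.n_exclusion_iters):
        cand = np.abs(r.copy())
        np.fill_diagonal(cand, 0.0)
        for (i, j) in excluded_pairs:
            cand[i, j] = cand[j, i] = 0.0
        inactive = np.flatnonzero(~active)
        cand[inactive, :] = 0.0
        cand[:, inactive] = 0.0
        i, j = np.unravel_index(np.nanargmax(cand), cand.shape)
        if not cand[i, j] > cfg.exclusion_threshold:
            break
        excluded_pairs.add((min(i, j), max(i, j)))
        omega = resolve()
        r = _correlation_from_basis(T, omega)
    r[~active, :] = np.nan
    r[:, ~active] = np.nan
    np.fill_diagonal(r, 1.0)
    return r


def _sparcc_r(counts: np.ndarray, cfg: SparccConfig,
              rng: np.random.Generator) -> np.ndarray:
    """Median SparCC correlation matrix over estimation iterations."""
    D, n = counts.shape
    mats = np.empty((cfg.n_estimation_iters, D, D))
    for it in range(cfg.n_estimation_iters):
        fracs = rng.standard_gamma(counts + 1.0)
        fracs /= fracs.sum(axis=0, keepdims=True)
        T = _variation_matrix(np.log(fracs))
        mats[it] = _one_iteration(T, cfg)
    # pairs dropped in every iteration legitimately yield NaN medians
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmedian(mats, axis=0)


def sparcc(table: FeatureTable,
           cfg: SparccConfig = SparccConfig()) -> list[SparccResult]:
    """SparCC basis correlations for every taxon pair (i < j)."""
    D, n = table.shape
    if D < 4:
        raise ValidationError(
            f"SparCC needs >= 4 taxa (basis system under-determined), got {D}")
    rng = np.random.default_rng([cfg.seed, 11])
    r = _sparcc_r(table.values, cfg, rng)
    taxa = table.feature_ids
    out = []
    for i in range(D):
        for j in range(i + 1, D):
            out.append(SparccResult(taxa[i], taxa[j], float(r[i, j])))
    return out


def sparcc_pseudo_p(table: FeatureTable, observed: Sequence[SparccResult],
                    cfg: SparccConfig = SparccConfig()) -> list[SparccResult]:
    """Two-sided permutation pseudo-p-values.

    Each null dataset permutes every taxon's counts across samples
    independently (breaking associations, preserving marginals); SparCC is
    re-run per null set and pseudo_p = (1 + #{|r_null| >= |r_obs|}) /
    (1 + n_null).
    """
    taxa = table.feature_ids
    idx = {t: i for i, t in enumerate(taxa)}
    D, n = table.shape
    r_obs = np.full((D, D), np.nan)
    for res in observed:
        i, j = idx[res.taxon_i], idx[res.taxon_j]
        r_obs[i, j] = r_obs[j, i] = res.r
    rng = np.random.default_rng([cfg.seed, 13])
    exceed = np.zeros((D, D))
    counts = table.values
    for _ in range(cfg.n_null):
        null = np.empty_like(counts)
        for i in range(D):
            null[i] = counts[i, rng.permutation(n)]
        r_null = _sparcc_r(null, cfg, rng)
        with np.errstate(invalid="ignore"):
            exceed += (np.abs(r_null) >= np.abs(r_obs)).astype(float)
    pmat = (1.0 + exceed) / (1.0 + cfg.n_null)
    return [replace(res, pseudo_p=float(pmat[idx[res.taxon_i],
                                             idx[res.taxon_j]]),
                    n_null=cfg.n_null)
            for res in observed]


# ---------------------------------------------------------------------------
# Network assembly
# ---------------------------------------------------------------------------

def build_network(gene_taxon: Sequence[PairCorrelation],
                  taxon_taxon: Sequence[SparccResult],
                  q_threshold: float = 0.1,
                  r_threshold: float = 0.1,
                  p_threshold: float = 0.05) -> Network:
    """Mixed network of significant edges.

    Gene-taxon edges require q strictly below ``q_threshold``; taxon-taxon
    edges require |r| >= ``r_threshold`` (inclusive) AND pseudo-p strictly
    below ``p_threshold``.  Nodes are exactly the endpoints of retained
    edges.  NaN correlations never become edges.
    """
    node_types: dict[str, str] = {}
    edges: list[NetworkEdge] = []

    def set_type(nid: str, ntype: str):
        if node_types.get(nid, ntype) != ntype:
            raise ValidationError(
                f"node {nid!r} typed both gene and taxon")
        node_types[nid] = ntype

    for pr in gene_taxon:
        if np.isnan(pr.q) or not pr.q < q_threshold or np.isnan(pr.rho):
            continue
        set_type(pr.gene_id, "gene")
        set_type(pr.taxon_id, "taxon")
        edges.append(NetworkEdge(pr.gene_id, pr.taxon_id, "gene_taxon",
                                 pr.rho, pr.q))
    for sr in taxon_taxon:
        if (np.isnan(sr.r) or np.isnan(sr.pseudo_p)
                or abs(sr.r) < r_threshold
                or not sr.pseudo_p < p_threshold):
            continue
        set_type(sr.taxon_i, "taxon")
        set_type(sr.taxon_j, "taxon")
        edges.append(NetworkEdge(sr.taxon_i, sr.taxon_j, "taxon_taxon",
                                 sr.r, sr.pseudo_p))
    return Network(node_types, edges)


def network_stats(net: Network) -> pd.DataFrame:
    """Per-node degree and positive/negative edge counts, the quantities
    behind hub statements; empty network gives an empty frame."""
    rows: dict[str, dict] = {}
    for nid, ntype in net.node_types.items():
        rows[nid] = {"node_id": nid, "node_type": ntype, "degree": 0,
                     "n_positive": 0, "n_negative": 0}
    for e in net.edges:
        for nid in (e.source, e.target):
            rows[nid]["degree"] += 1
            if e.weight >= 0:
                rows[nid]["n_positive"] += 1
            else:
                rows[nid]["n_negative"] += 1
    df = pd.DataFrame(list(rows.values()),
                      columns=["node_id", "node_type", "degree",
                               "n_positive", "n_negative"])
    return df


def mean_degree_by_type(stats_frame: pd.DataFrame) -> dict[str, float]:
    if stats_frame.empty:
        return {}
    return stats_frame.groupby("node_type")["degree"].mean().to_dict()
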