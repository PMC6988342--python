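"""Paired synthetic host-expression / microbiome data with known truth.

The generative model mirrors the structure the analysis assumes:

* gene counts are negative binomial with per-sample size factors and
  condition fold changes;
* microbial counts are logistic-normal + multinomial: per-sample log basis
  abundances are multivariate normal with a planted correlation structure,
  exponentiated, normalized, and multinomially sampled at the sequencing
  depth;
* contaminant taxa are enriched in negative-control columns and nearly
  absent from true samples;
* gene-taxon links are planted by re-drawing a gene's counts with its NB
  mean tied to the linked taxon's standardized log-basis abundance, with
  the coupling coefficient read from a simulation-calibrated lookup so the
  expected Spearman correlation matches the requested strength.

All randomness flows from ``SimulationConfig.seed`` through fixed
per-operation child streams (PCG64 via :func:`numpy.random.default_rng`),
so a fixed seed reproduces every table bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from mgnet.tables import (
    FeatureTable,
    SampleMetadata,
    TaxonomyMap,
    ValidationError,
)

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "make_truth",
    "make_metadata",
    "simulate_gene_counts",
    "simulate_microbiome",
    "simulate_negative_controls",
    "spike_contaminants",
    "plant_gene_taxon_links",
    "simulate_dataset",
    "link_beta_for_strength",
]

# fixed sub-stream labels so each operation has an independent,
# reproducible generator derived from the one user-facing seed
_STREAM = {"genes": 1, "microbiome": 2, "controls": 3, "links": 4,
           "metadata": 5, "spike": 6}


def _rng(cfg: "SimulationConfig", op: str) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, _STREAM[op]])


@dataclass(frozen=True)
class SimulationConfig:
    """Sizes, depths and dispersion for one synthetic dataset.

    Defaults mirror the study scale (10 CF, 12 healthy, 2 blank controls,
    minimum depth 9551) so filters are exercised at realistic sparsity.
    """

    n_cf: int = 10
    n_healthy: int = 12
    n_controls: int = 2
    n_genes: int = 500
    n_taxa: int = 35
    seq_depth_range: tuple[int, int] = (9551, 30000)
    nb_dispersion: float = 0.2
    seed: int = 0
    # baseline gene expression drawn log-normal(meanlog, sdlog) as a
    # fraction of library size
    gene_mean_log: float = -7.0
    gene_mean_sd: float = 1.2

    def __post_init__(self):
        if min(self.n_cf, self.n_healthy, self.n_genes, self.n_taxa) < 1:
            raise ValidationError("all sizes must be >= 1")
        if self.n_controls < 0:
            raise ValidationError("n_controls must be >= 0")
        lo, hi = self.seq_depth_range
        if not (0 < lo <= hi):
            raise ValidationError("seq_depth_range must satisfy 0 < min <= max")
        if self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion must be positive")

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(1, self.n_genes + 1)]

    @property
    def taxon_ids(self) -> list[str]:
        return [f"T{i:03d}" for i in range(1, self.n_taxa + 1)]

    @property
    def cf_ids(self) -> list[str]:
        return [f"CF{i:02d}" for i in range(1, self.n_cf + 1)]

    @property
    def healthy_ids(self) -> list[str]:
        return [f"H{i:02d}" for i in range(1, self.n_healthy + 1)]

    @property
    def control_ids(self) -> list[str]:
        return [f"NC{i:02d}" for i in range(1, self.n_controls + 1)]

    @property
    def sample_ids(self) -> list[str]:
        return self.cf_ids + self.healthy_ids


@dataclass
class SyntheticTruth:
    """Planted structure; the downstream acceptance oracle."""

    de_genes: list[tuple[str, float]] = field(default_factory=list)
    da_taxa: list[tuple[str, float]] = field(default_factory=list)
    contaminants: list[str] = field(default_factory=list)
    basis_correlation: np.ndarray | None = None
    gene_taxon_links: list[tuple[str, str, float]] = field(default_factory=list)

    def validate(self, cfg: SimulationConfig) -> None:
        genes = set(cfg.gene_ids)
        taxa = set(cfg.taxon_ids)
        for g, _ in self.de_genes:
            if g not in genes:
                raise ValidationError(f"de gene {g!r} not in gene set")
        for t, _ in self.da_taxa:
            if t not in taxa:
                raise ValidationError(f"da taxon {t!r} not in taxon set")
        for g, t, s in self.gene_taxon_links:
            if g not in genes or t not in taxa:
                raise ValidationError(f"link ({g},{t}) references unknown IDs")
            if abs(s) >= 1:
                raise ValidationError(f"link strength {s} not in (-1, 1)")
        if self.basis_correlation is not None:
            c = np.asarray(self.basis_correlation, dtype=float)
            if c.shape != (cfg.n_taxa, cfg.n_taxa):
                raise ValidationError(
                    f"basis_correlation shape {c.shape} != "
                    f"({cfg.n_taxa}, {cfg.n_taxa})")
            if not np.allclose(c, c.T):
                raise ValidationError("basis_correlation not symmetric")
            if not np.allclose(np.diag(c), 1.0):
                raise ValidationError("basis_correlation diagonal must be 1")
            off = c[~np.eye(len(c), dtype=bool)]
            if len(off) and np.abs(off).max() >= 1:
                raise ValidationError("off-diagonal |correlation| must be < 1")
            w = np.linalg.eigvalsh(c)
            if w.min() < -1e-10:
                raise ValidationError(
                    f"basis_correlation not PSD (smallest eigenvalue "
                    f"{w.min():.3e})")

    def to_json(self) -> dict:
        return {
            "de_genes": [[g, f] for g, f in self.de_genes],
            "da_taxa": [[t, f] for t, f in self.da_taxa],
            "contaminants": list(self.contaminants),
            "basis_correlation": (
                None if self.basis_correlation is None
                else np.asarray(self.basis_correlation).tolist()),
            "gene_taxon_links": [[g, t, s]
                                 for g, t, s in self.gene_taxon_links],
        }

    @classmethod
    def from_json(cls, doc: dict) -> "SyntheticTruth":
        return cls(
            de_genes=[(g, float(f)) for g, f in doc["de_genes"]],
            da_taxa=[(t, float(f)) for t, f in doc["da_taxa"]],
            contaminants=list(doc["contaminants"]),
            basis_correlation=(
                None if doc["basis_correlation"] is None
                else np.asarray(doc["basis_correlation"], dtype=float)),
            gene_taxon_links=[(g, t, float(s))
                              for g, t, s in doc["gene_taxon_links"]],
        )


def make_truth(cfg: SimulationConfig,
               n_de_genes: int = 50,
               de_log2fc: float = 2.0,
               n_da_taxa: int = 6,
               da_log2fc: float = 1.5,
               n_contaminants: int = 3,
               n_links: int = 10,
               link_strength: float = 0.75,
               basis_pairs: Sequence[tuple[int, int, float]] = ((0, 1, 0.8),),
               ) -> SyntheticTruth:
    """Assemble a default planted-structure record.

    DE genes alternate up/down; DA taxa alternate enriched/depleted;
    ``basis_pairs`` plants taxon-taxon basis correlations by index.
    Linked genes are drawn from the DE set (so they survive the gene
    selection cascade) and linked taxa from the non-DA tail.
    """
    rng = np.random.default_rng([cfg.seed, 7])
    genes, taxa = cfg.gene_ids, cfg.taxon_ids
    de = [(genes[i], de_log2fc * (1 if i % 2 == 0 else -1))
          for i in range(min(n_de_genes, cfg.n_genes))]
    da = [(taxa[i], da_log2fc * (1 if i % 2 == 0 else -1))
          for i in range(min(n_da_taxa, cfg.n_taxa))]
    corr = np.eye(cfg.n_taxa)
    for i, j, r in basis_pairs:
        corr[i, j] = corr[j, i] = r
    # links: spread over non-DA taxa, alternating sign
    link_taxa = [t for t in taxa if t not in {x for x, _ in da}] or taxa
    links = []
    for k in range(n_links):
        g = de[k % len(de)][0] if de else genes[k % len(genes)]
        t = link_taxa[k % len(link_taxa)]
        links.append((g, t, link_strength * (1 if k % 2 == 0 else -1)))
    contaminants = [f"C{i:02d}" for i in range(1, n_contaminants + 1)]
    truth = SyntheticTruth(de_genes=de, da_taxa=da, contaminants=contaminants,
                           basis_correlation=corr, gene_taxon_links=links)
    truth.validate(cfg)
    del rng  # reserved for future randomized truth layouts
    return truth


def make_metadata(cfg: SimulationConfig) -> list[SampleMetadata]:
    """CF samples split between df508-homozygous and other genotypes."""
    records = []
    for i, sid in enumerate(cfg.cf_ids):
        geno = "CF_df508" if i < (cfg.n_cf + 1) // 2 else "CF_other"
        records.append(SampleMetadata(sid, "CF", geno, False))
    for sid in cfg.healthy_ids:
        records.append(SampleMetadata(sid, "Healthy", "Healthy", False))
    for sid in cfg.control_ids:
        records.append(SampleMetadata(sid, None, None, True))
    return records


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    """NB with var = mean + dispersion * mean^2 (gamma-Poisson mixture)."""
    mean = np.asarray(mean, dtype=float)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def simulate_gene_counts(cfg: SimulationConfig,
                         truth: SyntheticTruth) -> FeatureTable:
    """NB gene counts with condition fold changes.

    counts_ij ~ NB(mean = s_j * mu_i * 2^(log2fc_i * [j is CF]),
    dispersion = cfg.nb_dispersion); size factors s_j are log-uniform over
    the configured depth range.  The returned table carries the generating
    parameters in ``table.params`` for downstream link planting.
    """
    truth.validate(cfg)
    rng = _rng(cfg, "genes")
    genes, samples = cfg.gene_ids, cfg.sample_ids
    lo, hi = cfg.seq_depth_range
    s = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(samples)))
    mu = np.exp(rng.normal(cfg.gene_mean_log, cfg.gene_mean_sd,
                           size=len(genes)))
    lfc = pd.Series(0.0, index=genes)
    for g, f in truth.de_genes:
        lfc[g] = f
    is_cf = np.array([sid in set(cfg.cf_ids) for sid in samples], dtype=float)
    mean = (mu[:, None] * s[None, :]
            * np.power(2.0, np.outer(lfc.to_numpy(), is_cf)))
    counts = _nb_draw(rng, mean, cfg.nb_dispersion)
    table = FeatureTable(counts.astype(float), "counts",
                         feature_ids=genes, sample_ids=samples)
    table.params = {
        "mu": pd.Series(mu, index=genes),
        "size_factors": pd.Series(s, index=samples),
        "log2fc": lfc,
    }
    return table


def _random_tree(taxon_ids: Sequence[str],
                 rng: np.random.Generator) -> TreeNode:
    """Random coalescent-style rooted bifurcating tree over the taxa."""
    nodes = [TreeNode(name=t, length=float(rng.exponential(0.1)))
             for t in taxon_ids]
    if len(nodes) == 1:
        root = TreeNode(children=nodes)
        return root
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = TreeNode(length=float(rng.exponential(0.1)),
                          children=[a, b])
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


def _make_taxonomy(taxon_ids: Sequence[str]) -> TaxonomyMap:
    """Unique genus per taxon under a small shared upper hierarchy."""
    lineages = {}
    for i, t in enumerate(taxon_ids):
        lineages[t] = (
            "k__Bacteria",
            f"p__Phylum{i % 4 + 1}",
            f"c__Class{i % 8 + 1}",
            f"o__Order{i % 12 + 1}",
            f"f__Family{i % 16 + 1}",
            f"g__Genus_{t}",
        )
    return TaxonomyMap(lineages)


def simulate_microbiome(cfg: SimulationConfig, truth: SyntheticTruth,
                        return_basis: bool = False):
    """Logistic-normal + multinomial OTU counts with planted correlations.

    Returns ``(counts, taxonomy, tree)``; with ``return_basis=True`` a
    fourth element holds the latent log-basis matrix (taxa x samples) used
    for gene-taxon link planting.  Taxonomy and tree also cover the
    contaminant taxa so downstream phylogenetic steps stay well defined.
    """
    truth.validate(cfg)
    corr = (np.eye(cfg.n_taxa) if truth.basis_correlation is None
            else np.asarray(truth.basis_correlation, dtype=float))
    w = np.linalg.eigvalsh(corr)
    if w.min() < -1e-10:
        raise ValidationError(
            f"basis_correlation not PSD (smallest eigenvalue {w.min():.3e})")
    rng = _rng(cfg, "microbiome")
    taxa, samples = cfg.taxon_ids, cfg.sample_ids
    # heterogeneous baseline abundances on the log scale
    base = rng.normal(0.0, 1.5, size=cfg.n_taxa)
    shift = pd.Series(0.0, index=taxa)
    for t, f in truth.da_taxa:
        shift[t] = f * np.log(2.0)
    is_cf = np.array([sid in set(cfg.cf_ids) for sid in samples], dtype=float)
    # sample latent log-basis: mvn with the planted correlation structure
    chol = np.linalg.cholesky(corr + 1e-10 * np.eye(cfg.n_taxa))
    z = rng.standard_normal((cfg.n_taxa, len(samples)))
    resid = chol @ z
    # remove the chance association between taxa and condition: center the
    # latent residual within each condition group so condition shifts are
    # exactly the planted da_taxa effects (within-group correlation
    # structure is unchanged)
    for mask in (is_cf > 0.5, is_cf <= 0.5):
        if mask.sum() > 1:
            resid[:, mask] -= resid[:, mask].mean(axis=1, keepdims=True)
    log_basis = (base[:, None] + resid
                 + np.outer(shift.to_numpy(), is_cf))
    fractions = np.exp(log_basis - log_basis.max(axis=0))
    fractions /= fractions.sum(axis=0)
    lo, hi = cfg.seq_depth_range
    depths = rng.integers(lo, hi + 1, size=len(samples))
    counts = np.column_stack([
        rng.multinomial(depths[j], fractions[:, j])
        for j in range(len(samples))
    ]).astype(float)
    table = FeatureTable(counts, "counts", feature_ids=taxa,
                         sample_ids=samples)
    all_taxa = list(taxa) + list(truth.contaminants)
    taxonomy = _make_taxonomy(all_taxa)
    tree = _random_tree(all_taxa, rng)
    if return_basis:
        basis = pd.DataFrame(log_basis, index=taxa, columns=samples)
        return table, taxonomy, tree, basis
    return table, taxonomy, tree


def simulate_negative_controls(cfg: SimulationConfig,
                               truth: SyntheticTruth) -> FeatureTable:
    """Control-sample counts: contaminants nearly always present, real taxa
    leaking in only through low-rate cross-talk."""
    if cfg.n_controls > 0 and not truth.contaminants:
        raise ValidationError(
            "n_controls > 0 requires at least one contaminant taxon")
    rng = _rng(cfg, "controls")
    all_taxa = list(cfg.taxon_ids) + list(truth.contaminants)
    counts = np.zeros((len(all_taxa), cfg.n_controls))
    contaminant_set = set(truth.contaminants)
    for i, t in enumerate(all_taxa):
        if t in contaminant_set:
            present = rng.random(cfg.n_controls) < 0.97
            counts[i, present] = rng.poisson(80, present.sum()) + 1
        else:
            present = rng.random(cfg.n_controls) < 0.03
            counts[i, present] = rng.poisson(2, present.sum()) + 1
    return FeatureTable(counts, "counts", feature_ids=all_taxa,
                        sample_ids=cfg.control_ids)


def spike_contaminants(otu_table: FeatureTable, cfg: SimulationConfig,
                       truth: SyntheticTruth) -> FeatureTable:
    """Append contaminant rows to a true-sample table at low prevalence
    (each contaminant present in <= 15% of samples with small counts)."""
    rng = _rng(cfg, "spike")
    n = len(otu_table.sample_ids)
    rows = {}
    for t in truth.contaminants:
        row = np.zeros(n)
        present = rng.random(n) < 0.10
        row[present] = rng.poisson(3, present.sum()) + 1
        rows[t] = row
    extra = pd.DataFrame(rows, index=otu_table.sample_ids).T
    data = pd.concat([otu_table.data, extra])
    return FeatureTable(data, "counts")


# ---------------------------------------------------------------------------
# Gene-taxon link planting
# ---------------------------------------------------------------------------

def _load_link_lookup() -> tuple[np.ndarray, np.ndarray]:
    ref = resources.files("mgnet") / "data" / "link_lookup.json"
    doc = json.loads(ref.read_text())
    return (np.asarray(doc["beta"], dtype=float),
            np.asarray(doc["mean_spearman"], dtype=float))


def link_beta_for_strength(strength: float) -> float:
    """Coupling coefficient achieving a target expected Spearman rho.

    Inverts a simulation-calibrated monotone lookup (beta grid vs mean
    realized Spearman between NB counts and the latent covariate); sign
    follows the requested strength.
    """
    if abs(strength) >= 1:
        raise ValidationError(f"requested |strength| {abs(strength)} >= 1")
    if strength == 0:
        return 0.0
    beta_grid, rho_grid = _load_link_lookup()
    target = min(abs(strength), rho_grid.max())
    beta = float(np.interp(target, rho_grid, beta_grid))
    return beta if strength > 0 else -beta


def _expected_spearman(beta: float, base_mean: np.ndarray, z: np.ndarray,
                       dispersion: float, rng: np.random.Generator,
                       reps: int = 200) -> float:
    """Monte-Carlo expected Spearman between NB counts with mean
    base_mean * exp(beta z - beta^2/2) and z itself."""
    from scipy import stats as _stats
    mean = base_mean * np.exp(beta * z - beta ** 2 / 2.0)
    counts = _nb_draw(rng, np.broadcast_to(mean, (reps, mean.size)),
                      dispersion)
    cr = _stats.rankdata(counts, axis=1).astype(float)
    cr -= cr.mean(axis=1, keepdims=True)
    sd = cr.std(axis=1)
    zr = _stats.rankdata(z).astype(float)
    zr -= zr.mean()
    rho = (cr @ zr) / np.maximum(sd, 1e-12) / zr.std() / z.size
    rho[sd == 0] = 0.0
    return float(rho.mean())


def _calibrate_beta(target: float, base_mean: np.ndarray, z: np.ndarray,
                    dispersion: float, rng: np.random.Generator) -> float:
    """Monotone bisection for the coupling coefficient whose expected
    Spearman (given the gene's actual means, including any condition fold
    change, and the taxon's actual z vector) matches |target|."""
    lo, hi = 0.0, 3.0
    if _expected_spearman(hi, base_mean, z, dispersion, rng) < abs(target):
        return hi if target > 0 else -hi
    for _ in range(12):
        mid = 0.5 * (lo + hi)
        if _expected_spearman(mid, base_mean, z, dispersion, rng) < abs(target):
            lo = mid
        else:
            hi = mid
    beta = 0.5 * (lo + hi)
    return beta if target > 0 else -beta


def plant_gene_taxon_links(gene_table: FeatureTable,
                           basis: pd.DataFrame,
                           cfg: SimulationConfig,
                           truth: SyntheticTruth) -> FeatureTable:
    """Re-draw linked genes' counts with NB mean tied to the linked taxon.

    The new mean is the original NB mean times exp(beta * z) / exp(beta^2/2)
    with z the standardized log-basis abundance of the linked taxon; the
    exp(beta^2/2) factor keeps the marginal mean (and hence the planted DE
    structure) unchanged in expectation.  beta starts from the shipped
    monotone lookup and is refined per link by Monte-Carlo bisection against
    the gene's actual generating parameters, so the expected Spearman
    matches the requested strength even for strongly DE genes.
    """
    if not hasattr(gene_table, "params"):
        raise ValidationError(
            "gene_table must come from simulate_gene_counts (params missing)")
    for g, t, s in truth.gene_taxon_links:
        if g not in gene_table.data.index:
            raise ValidationError(f"linked gene {g!r} missing from table")
        if t not in basis.index:
            raise ValidationError(f"linked taxon {t!r} missing from basis")
        if abs(s) >= 1:
            raise ValidationError(f"link strength {s} not in (-1, 1)")
    rng = _rng(cfg, "links")
    params = gene_table.params
    samples = gene_table.sample_ids
    s_j = params["size_factors"].loc[samples].to_numpy()
    is_cf = np.array([sid in set(cfg.cf_ids) for sid in samples], dtype=float)
    data = gene_table.data.copy()
    for g, t, strength in truth.gene_taxon_links:
        if strength == 0.0 or link_beta_for_strength(strength) == 0.0:
            continue
        zb = basis.loc[t, samples].to_numpy()
        z = (zb - zb.mean()) / zb.std(ddof=0)
        base_mean = (params["mu"][g] * s_j
                     * np.power(2.0, params["log2fc"][g] * is_cf))
        beta = _calibrate_beta(strength, base_mean, z, cfg.nb_dispersion,
                               rng)
        mean = base_mean * np.exp(beta * z - beta ** 2 / 2.0)
        data.loc[g] = _nb_draw(rng, mean, cfg.nb_dispersion).astype(float)
    out = FeatureTable(data, "counts")
    out.params = params
    return out


# ---------------------------------------------------------------------------
# Whole-dataset convenience
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    genes: FeatureTable          # genes x true samples (links planted)
    otus: FeatureTable           # taxa+contaminants x true samples + controls
    taxonomy: TaxonomyMap
    tree: TreeNode
    metadata: list[SampleMetadata]
    basis: pd.DataFrame          # latent log-basis, taxa x true samples
    truth: SyntheticTruth
    config: SimulationConfig


def simulate_dataset(cfg: SimulationConfig,
                     truth: SyntheticTruth | None = None) -> SyntheticDataset:
    """Generate the full paired dataset: gene counts with planted links,
    an OTU table with spiked contaminants plus negative-control columns,
    taxonomy, tree, metadata, and the truth record."""
    if truth is None:
        truth = make_truth(cfg)
    truth.validate(cfg)
    genes = simulate_gene_counts(cfg, truth)
    otus, taxonomy, tree, basis = simulate_microbiome(cfg, truth,
                                                      return_basis=True)
    genes = plant_gene_taxon_links(genes, basis, cfg, truth)
    otus = spike_contaminants(otus, cfg, truth)
    if cfg.n_controls > 0:
        controls = simulate_negative_controls(cfg, truth)
        data = pd.concat([otus.data, controls.data], axis=1).fillna(0.0)
        otus = FeatureTable(data, "counts")
    metadata = make_metadata(cfg)
    return SyntheticDataset(genes=genes, otus=otus, taxonomy=taxonomy,
                            tree=tree, metadata=metadata, basis=basis,
                            truth=truth, config=cfg)


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    from mgnet.tables import write_feature_table, write_metadata, write_taxonomy
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_feature_table(ds.genes, outdir / "gene.tsv")
    write_feature_table(ds.otus, outdir / "otu.tsv")
    write_taxonomy(ds.taxonomy, outdir / "taxonomy.tsv")
    ds.tree.write(str(outdir / "tree.nwk"), format="newick")
    write_metadata(ds.metadata, outdir / "metadata.tsv")
    (outdir / "truth.json").write_text(
        json.dumps(ds.truth.to_json(), indent=1))
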