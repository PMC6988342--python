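"""Data model and readers/writers for feature tables, metadata, taxonomy,
trees, and mixed gene-taxon networks.

Canonical on-disk table format is TSV with a ``#FeatureID`` header cell;
BIOM-style JSON (format version 1.0) is accepted read-only.  All tables are
indexed by string ID, never by position.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "FeatureTable",
    "SampleMetadata",
    "TaxonomyMap",
    "Network",
    "NetworkEdge",
    "read_feature_table",
    "write_feature_table",
    "read_metadata",
    "write_metadata",
    "read_taxonomy",
    "write_taxonomy",
    "read_tree",
    "write_network",
    "read_network",
]

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")
RANK_PREFIXES = dict(zip(RANKS, "kpcofg"))

CONDITIONS = ("CF", "Healthy")
GENOTYPES = ("Healthy", "CF_df508", "CF_other")


class ValidationError(ValueError):
    """A table or record violates a domain-type invariant."""


# ---------------------------------------------------------------------------
# FeatureTable
# ---------------------------------------------------------------------------

class FeatureTable:
    """Non-negative feature-by-sample matrix with string IDs.

    Parameters
    ----------
    data
        DataFrame with feature rows and sample columns, or a 2-D array
        combined with ``feature_ids`` / ``sample_ids``.
    kind
        ``"counts"`` (non-negative integers) or ``"relative"`` (columns sum
        to 1).
    """

    def __init__(self, data, kind: str = "counts", feature_ids=None,
                 sample_ids=None):
        if not isinstance(data, pd.DataFrame):
            data = pd.DataFrame(np.asarray(data, dtype=float),
                                index=list(feature_ids),
                                columns=list(sample_ids))
        else:
            data = data.astype(float)
            data.index = data.index.astype(str)
            data.columns = data.columns.astype(str)
        self.data = data
        self.kind = kind
        self._validate()

    # -- validation ---------------------------------------------------------
    def _validate(self) -> None:
        if self.kind not in ("counts", "relative"):
            raise ValidationError(f"unknown table kind {self.kind!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique()
            raise ValidationError(f"duplicate feature IDs: {list(dups)}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique()
            raise ValidationError(f"duplicate sample IDs: {list(dups)}")
        vals = self.data.to_numpy()
        if not np.isfinite(vals).all():
            raise ValidationError("non-finite values in table")
        if (vals < 0).any():
            i, j = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative value at feature {self.data.index[i]!r}, "
                f"sample {self.data.columns[j]!r}")
        if self.kind == "relative" and self.data.shape[1] > 0:
            sums = vals.sum(axis=0)
            bad = np.abs(sums - 1.0) > 1e-9
            if bad.any():
                raise ValidationError(
                    "relative-abundance columns must sum to 1: "
                    f"{list(self.data.columns[bad])}")

    # -- accessors ----------------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def __eq__(self, other) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return (self.kind == other.kind
                and self.feature_ids == other.feature_ids
                and self.sample_ids == other.sample_ids
                and np.allclose(self.values, other.values, rtol=1e-12,
                                atol=0.0))

    def __repr__(self) -> str:
        return (f"FeatureTable(kind={self.kind!r}, "
                f"n_features={self.shape[0]}, n_samples={self.shape[1]})")

    # -- derived tables -----------------------------------------------------
    def select_samples(self, sample_ids: Sequence[str]) -> "FeatureTable":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        return FeatureTable(self.data.loc[:, list(sample_ids)], self.kind)

    def select_features(self, feature_ids: Sequence[str]) -> "FeatureTable":
        missing = [f for f in feature_ids if f not in self.data.index]
        if missing:
            raise KeyError(f"features not in table: {missing}")
        return FeatureTable(self.data.loc[list(feature_ids)], self.kind)

    def to_relative(self) -> "FeatureTable":
        """Normalize each sample column to sum to 1."""
        sums = self.data.sum(axis=0)
        if (sums <= 0).any():
            bad = list(sums.index[sums <= 0])
            raise ValidationError(f"all-zero sample columns: {bad}")
        return FeatureTable(self.data / sums, "relative")


def read_feature_table(path, kind: str = "counts") -> FeatureTable:
    """Read a feature table from TSV (``#FeatureID`` convention) or
    BIOM-style JSON (sniffed from content)."""
    path = Path(path)
    text_head = path.open().read(1).strip()
    if text_head == "{":
        return _read_biom_json(path, kind)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index.name = None
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric cell in {path}: {exc}") from exc
    if df.isna().any().any():
        raise ValidationError(f"missing/ragged values in {path}")
    return FeatureTable(df, kind)


def _read_biom_json(path: Path, kind: str) -> FeatureTable:
    doc = json.loads(path.read_text())
    feature_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    mat = np.zeros((len(feature_ids), len(sample_ids)))
    if doc.get("matrix_type") == "sparse":
        for i, j, v in doc["data"]:
            mat[i, j] = v
    else:
        mat[:] = np.asarray(doc["data"], dtype=float)
    return FeatureTable(mat, kind, feature_ids=feature_ids,
                        sample_ids=sample_ids)


def write_feature_table(table: FeatureTable, path) -> None:
    df = table.data.copy()
    df.index.name = "#FeatureID"
    # counts stored as integers when exactly integral, keeping fixtures tidy
    vals = df.to_numpy()
    if table.kind == "counts" and np.allclose(vals, np.round(vals)):
        df = df.astype(np.int64)
    df.to_csv(path, sep="\t", float_format="%.12g")


# ---------------------------------------------------------------------------
# SampleMetadata
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample condition, genotype category and negative-control flag."""

    sample_id: str
    condition: str | None
    genotype: str | None
    is_negative_control: bool = False

    def __post_init__(self):
        if self.is_negative_control:
            return  # controls carry no condition requirement
        if self.condition not in CONDITIONS:
            raise ValidationError(
                f"{self.sample_id}: unknown condition {self.condition!r}")
        if self.genotype not in GENOTYPES:
            raise ValidationError(
                f"{self.sample_id}: unknown genotype {self.genotype!r}")
        if (self.genotype == "Healthy") != (self.condition == "Healthy"):
            raise ValidationError(
                f"{self.sample_id}: genotype {self.genotype!r} inconsistent "
                f"with condition {self.condition!r}")


_BOOL = {"true": True, "false": False, "1": True, "0": False,
         "yes": True, "no": False}


def read_metadata(path) -> list[SampleMetadata]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"sample_id", "condition", "genotype", "is_negative_control"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"metadata missing columns: {sorted(missing)}")
    if len(df) == 0:
        raise ValidationError("no samples in metadata file")
    records = []
    for row in df.itertuples(index=False):
        flag = str(row.is_negative_control).strip().lower()
        if flag not in _BOOL:
            raise ValidationError(
                f"{row.sample_id}: bad is_negative_control {flag!r}")
        records.append(SampleMetadata(
            sample_id=str(row.sample_id),
            condition=row.condition or None,
            genotype=row.genotype or None,
            is_negative_control=_BOOL[flag]))
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate sample IDs in metadata")
    return records


def write_metadata(records: Sequence[SampleMetadata], path) -> None:
    rows = [{"sample_id": r.sample_id,
             "condition": r.condition or "",
             "genotype": r.genotype or "",
             "is_negative_control": str(r.is_negative_control).lower()}
            for r in records]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def metadata_by_id(records: Iterable[SampleMetadata]) -> dict[str, SampleMetadata]:
    return {r.sample_id: r for r in records}


def condition_groups(records: Iterable[SampleMetadata],
                     sample_ids: Sequence[str] | None = None,
                     ) -> dict[str, list[str]]:
    """Map condition -> sample IDs, excluding negative controls.

    When ``sample_ids`` is given, restrict (and order) by that list.
    """
    by_id = metadata_by_id(records)
    if sample_ids is None:
        sample_ids = [r.sample_id for r in records]
    groups: dict[str, list[str]] = {}
    for sid in sample_ids:
        rec = by_id.get(sid)
        if rec is None or rec.is_negative_control:
            continue
        groups.setdefault(rec.condition, []).append(sid)
    return groups


# ---------------------------------------------------------------------------
# TaxonomyMap
# ---------------------------------------------------------------------------

class TaxonomyMap:
    """feature_id -> ordered lineage over (kingdom..genus).

    Unassigned ranks are empty strings; an assigned rank may never follow an
    unassigned one (prefix property).
    """

    def __init__(self, lineages: Mapping[str, Sequence[str]]):
        self._lineages: dict[str, tuple[str, ...]] = {}
        for fid, lineage in lineages.items():
            lineage = tuple(str(x).strip() for x in lineage)
            if len(lineage) > len(RANKS):
                raise ValidationError(
                    f"{fid}: lineage longer than {len(RANKS)} ranks")
            lineage = lineage + ("",) * (len(RANKS) - len(lineage))
            seen_empty = False
            for label in lineage:
                if label == "":
                    seen_empty = True
                elif seen_empty:
                    raise ValidationError(
                        f"{fid}: assigned rank below an unassigned one")
            self._lineages[str(fid)] = lineage

    def __getitem__(self, fid: str) -> tuple[str, ...]:
        return self._lineages[fid]

    def __contains__(self, fid: str) -> bool:
        return fid in self._lineages

    def __len__(self) -> int:
        return len(self._lineages)

    def __iter__(self):
        return iter(self._lineages)

    def items(self):
        return self._lineages.items()

    def lineage_at(self, fid: str, rank: str) -> tuple[str, ...]:
        """Lineage prefix down to ``rank`` (inclusive)."""
        if rank not in RANKS:
            raise ValidationError(f"unknown rank {rank!r}")
        k = RANKS.index(rank) + 1
        return self._lineages[fid][:k]

    def last_characterized(self, fid: str) -> tuple[str, str]:
        """(rank, label) of the deepest assigned rank; kingdom fallback."""
        lineage = self._lineages[fid]
        for rank, label in zip(reversed(RANKS), reversed(lineage)):
            if label:
                return rank, label
        return "kingdom", "Unassigned"


def read_taxonomy(path) -> TaxonomyMap:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "#FeatureID" in df.columns:
        df = df.set_index("#FeatureID")
    else:
        df = df.set_index(df.columns[0])
    cols = [c for c in RANKS if c in df.columns]
    if not cols:
        raise ValidationError(
            f"taxonomy file needs rank columns {RANKS}, got {list(df.columns)}")
    return TaxonomyMap({fid: [df.at[fid, c] for c in cols] for fid in df.index})


def write_taxonomy(tax: TaxonomyMap, path) -> None:
    rows = [{"#FeatureID": fid, **dict(zip(RANKS, lineage))}
            for fid, lineage in tax.items()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PhyloTree
# ---------------------------------------------------------------------------

def read_tree(path) -> TreeNode:
    """Read a rooted newick tree and validate tip labels and lengths."""
    tree = TreeNode.read(str(path), format="newick")
    tips = [t.name for t in tree.tips()]
    if len(set(tips)) != len(tips):
        raise ValidationError("duplicate tip labels in tree")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
        if not math.isfinite(node.length) or node.length < 0:
            raise ValidationError(f"bad branch length on {node.name!r}")
    return tree


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkEdge:
    source: str
    target: str
    edge_type: str          # gene_taxon | taxon_taxon
    weight: float           # rho or SparCC r
    significance: float     # q (gene_taxon) or pseudo-p (taxon_taxon)

    @property
    def sign(self) -> int:
        return 1 if self.weight >= 0 else -1


@dataclass
class Network:
    """Mixed gene-taxon correlation network."""

    node_types: dict[str, str] = field(default_factory=dict)
    edges: list[NetworkEdge] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for nid, ntype in self.node_types.items():
            if ntype not in ("gene", "taxon"):
                raise ValidationError(f"node {nid!r}: bad type {ntype!r}")
        for e in self.edges:
            if abs(e.weight) > 1 + 1e-12:
                raise ValidationError(f"edge {e.source}-{e.target}: |weight|>1")
            st = (self.node_types.get(e.source), self.node_types.get(e.target))
            if None in st:
                raise ValidationError(
                    f"edge {e.source}-{e.target}: endpoint missing from nodes")
            if e.edge_type == "gene_taxon":
                if sorted(st) != ["gene", "taxon"]:
                    raise ValidationError(
                        f"gene_taxon edge {e.source}-{e.target} joins {st}")
            elif e.edge_type == "taxon_taxon":
                if st != ("taxon", "taxon") or e.source == e.target:
                    raise ValidationError(
                        f"taxon_taxon edge {e.source}-{e.target} invalid")
            else:
                raise ValidationError(f"unknown edge_type {e.edge_type!r}")

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for nid, ntype in self.node_types.items():
            g.add_node(nid, node_type=ntype)
        for e in self.edges:
            g.add_edge(e.source, e.target, edge_type=e.edge_type,
                       weight=e.weight, sign=e.sign,
                       significance=e.significance)
        return g


EDGE_COLUMNS = ["source", "target", "edge_type", "weight", "significance",
                "source_type", "target_type"]


def write_network(net: Network, path, format: str = "edge_list") -> None:
    """Write a network as a TSV edge list or GraphML; both carry node types,
    weights and significance so a read-back reproduces the network."""
    if format == "edge_list":
        rows = [{"source": e.source, "target": e.target,
                 "edge_type": e.edge_type,
                 "weight": f"{e.weight:.12g}",
                 "significance": f"{e.significance:.12g}",
                 "source_type": net.node_types[e.source],
                 "target_type": net.node_types[e.target]}
                for e in net.edges]
        pd.DataFrame(rows, columns=EDGE_COLUMNS).to_csv(
            path, sep="\t", index=False)
    elif format == "graphml":
        nx.write_graphml(net.to_graph(), str(path))
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path, format: str = "edge_list") -> Network:
    if format == "edge_list":
        df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
        node_types: dict[str, str] = {}
        edges = []
        for row in df.itertuples(index=False):
            node_types[row.source] = row.source_type
            node_types[row.target] = row.target_type
            edges.append(NetworkEdge(row.source, row.target, row.edge_type,
                                     float(row.weight),
                                     float(row.significance)))
        return Network(node_types, edges)
    elif format == "graphml":
        g = nx.read_graphml(str(path))
        node_types = {n: d["node_type"] for n, d in g.nodes(data=True)}
        edges = [NetworkEdge(u, v, d["edge_type"], float(d["weight"]),
                             float(d["significance"]))
                 for u, v, d in g.edges(data=True)]
        return Network(node_types, edges)
    raise ValueError(f"unknown network format {format!r}")
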