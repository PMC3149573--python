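"""File formats and run configuration.

On-disk conventions
-------------------
* Expression matrices are tab-delimited text with probesets in rows and
  samples in columns (the array convention).  In memory they are always
  pandas DataFrames with samples in rows and probesets in columns; the
  transpose happens exactly once, here.
* Phenotypes are CSV with columns ``sample, sex, breed`` followed by one
  numeric column per metabolite.  Missing metabolite values are allowed
  (a sample missing trait *t* is dropped for trait *t* only).
* Gene sets use the GMT format (name, description, tab-separated members).
* Networks are written as GraphML plus a TSV edge list.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("qttnet")

#: phenotype columns that are not metabolite traits
COVARIATE_COLUMNS = ("sex", "breed")


class FormatError(ValueError):
    """Malformed input file; the message locates the offending record."""


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Thresholds and sizes shared by the pipeline stages.

    Defaults are the study's analysis choices: QTT at nominal p < 0.01 with
    a 20-permutation FDR, GSEA with 1000 permutations and weight exponent 1,
    soft thresholds scanned over 1..20 against a scale-free fit cut of 0.8,
    modules of at least 30 nodes, the top 10% of intramodular connectivity
    as hubs, and multi-tissue edges at nominal p < 1e-4 with FDR < 0.05.
    """

    qtt_alpha: float = 0.01
    n_qtt_permutations: int = 20
    gsea_permutations: int = 1000
    gsea_weight_exponent: float = 1.0
    beta_candidates: tuple[int, ...] = tuple(range(1, 21))
    scale_free_r2_cut: float = 0.8
    min_module_size: int = 30
    hub_fraction: float = 0.10
    edge_alpha: float = 1e-4
    edge_fdr: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("qtt_alpha", "edge_alpha", "edge_fdr"):
            p = getattr(self, name)
            if not 0.0 < p < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {p!r}")
        for name in ("n_qtt_permutations", "gsea_permutations", "min_module_size"):
            c = getattr(self, name)
            if not (isinstance(c, (int, np.integer)) and c >= 1):
                raise ValueError(f"{name} must be a count >= 1, got {c!r}")
        if not self.beta_candidates:
            raise ValueError("beta_candidates must be non-empty")
        if any(int(b) != b or b < 1 for b in self.beta_candidates):
            raise ValueError("beta_candidates must be positive integers")
        if not 0.0 <= self.scale_free_r2_cut <= 1.0:
            raise ValueError("scale_free_r2_cut must be in [0, 1]")
        if not 0.0 < self.hub_fraction <= 1.0:
            raise ValueError("hub_fraction must be in (0, 1]")

    def child_rng(self, *labels: object) -> np.random.Generator:
        return child_rng(self.rng_seed, *labels)

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, rng_seed=int(seed))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "beta_candidates" in raw:
            raw = dict(raw, beta_candidates=tuple(raw["beta_candidates"]))
        return cls(**raw)


def child_rng(seed: int, *labels: object) -> np.random.Generator:
    """Deterministic per-operation random stream.

    One global seed; each randomized operation derives its own stream from
    (seed, label...) so stages are order-independent and reproducible.
    """
    words = [int(seed) & 0x7FFFFFFF]
    words += [zlib.crc32(str(lab).encode()) for lab in labels]
    return np.random.default_rng(np.random.SeedSequence(words))


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression(path) -> pd.DataFrame:
    """Read a tissue expression matrix.

    Returns a samples x probesets DataFrame of finite floats (the file
    stores probesets in rows; see module docstring).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate probeset ids {dups[:5]}")
    mat = df.transpose()
    mat.index.name = "sample"
    mat.columns.name = "probeset"
    numeric = mat.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~mat.isna()
    if bad.to_numpy().any():
        s, p = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric value {mat.iat[s, p]!r} for "
            f"probeset {mat.columns[p]!r}, sample {mat.index[s]!r}"
        )
    if numeric.isna().to_numpy().any():
        s, p = np.argwhere(numeric.isna().to_numpy())[0]
        raise FormatError(
            f"{path}: missing value for probeset {mat.columns[p]!r}, "
            f"sample {mat.index[s]!r}"
        )
    return numeric.astype(float)


def write_expression(expr: pd.DataFrame, path) -> None:
    """Write samples x probesets matrix in the on-disk (transposed) layout."""
    expr.transpose().to_csv(path, sep="\t", float_format="%.6f")


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def validate_phenotypes(pheno: pd.DataFrame, source: str = "<memory>") -> pd.DataFrame:
    for col in COVARIATE_COLUMNS:
        if col not in pheno.columns:
            raise FormatError(f"{source}: missing required column {col!r}")
    traits = trait_names(pheno)
    if not traits:
        raise FormatError(f"{source}: no metabolite columns found")
    n_sex = pheno["sex"].nunique()
    if n_sex != 2:
        raise FormatError(
            f"{source}: sex must have exactly 2 levels, found {n_sex} "
            f"({sorted(pheno['sex'].unique())}); sex effect unestimable"
        )
    if pheno["breed"].nunique() < 2:
        raise FormatError(f"{source}: breed must have >= 2 levels")
    for t in traits:
        pheno[t] = pd.to_numeric(pheno[t], errors="raise")
    return pheno


def read_phenotypes(path) -> pd.DataFrame:
    """Read the per-sample phenotype table (sex, breed, metabolites).

    Index is the sample id; sex must have exactly two levels and breed at
    least two (otherwise the covariate model is rank deficient).
    """
    pheno = pd.read_csv(path, index_col=0)
    pheno.index = pheno.index.astype(str)
    pheno.index.name = "sample"
    return validate_phenotypes(pheno, str(path))


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, index_label="sample")


def trait_names(pheno: pd.DataFrame) -> list[str]:
    """Metabolite columns of a phenotype table (everything but sex/breed)."""
    return [c for c in pheno.columns if c not in COVARIATE_COLUMNS]


# ---------------------------------------------------------------------------
# gene sets and probeset->gene maps
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets, GMT-style: name -> (description, members)."""

    sets: dict[str, tuple[str, tuple[str, ...]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_desc, members) in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise ValueError(f"gene set {name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def members(self, name: str) -> tuple[str, ...]:
        return self.sets[name][1]

    def description(self, name: str) -> str:
        return self.sets[name][0]


def read_gmt(path) -> GeneSetCollection:
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated "
                    f"fields (name, description, members), got {len(fields)}"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            deduped = tuple(dict.fromkeys(members))
            if not deduped:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets[name] = (desc, deduped)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in collection:
            desc = collection.description(name)
            fh.write("\t".join([name, desc, *collection.members(name)]) + "\n")


def read_probeset_map(path) -> pd.Series:
    """TSV probeset -> gene symbol map (many probesets may share a gene)."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (probeset, gene)")
    probes, genes = df.iloc[:, 0], df.iloc[:, 1]
    if probes.duplicated().any():
        amb = probes[probes.duplicated()].unique().tolist()
        raise FormatError(f"{path}: probesets mapped more than once: {amb[:5]}")
    mapping = pd.Series(genes.values, index=probes.values, name="gene")
    mapping.index.name = "probeset"
    return mapping


def write_probeset_map(mapping: pd.Series, path) -> None:
    mapping.rename("gene").to_csv(path, sep="\t", index_label="probeset")


# ---------------------------------------------------------------------------
# network output
# ---------------------------------------------------------------------------

def write_network(net, edge_threshold: float, path_prefix) -> int:
    """Write a co-expression network as GraphML plus a TSV edge list.

    Only edges with adjacency >= ``edge_threshold`` are emitted.  ``net``
    is any object with ``node_ids``, ``adjacency`` (symmetric, unit
    diagonal), ``correlations`` and per-node attribute mappings ``tissue``
    and ``module`` (either may be None).  Returns the number of edges
    written.
    """
    if edge_threshold < 0:
        raise ValueError("edge_threshold must be >= 0")
    nodes = list(net.node_ids)
    adj = np.asarray(net.adjacency, dtype=float)
    cor = np.asarray(net.correlations, dtype=float)
    tissue = getattr(net, "tissue", None)
    module = getattr(net, "module", None)

    graph = nx.Graph()
    for k, node in enumerate(nodes):
        attrs = {}
        if tissue is not None:
            attrs["tissue"] = str(tissue[k] if not isinstance(tissue, str) else tissue)
        if module is not None:
            attrs["module"] = int(module[k])
        graph.add_node(str(node), **attrs)

    iu, ju = np.triu_indices(len(nodes), k=1)
    keep = adj[iu, ju] >= edge_threshold
    path_prefix = str(path_prefix)
    with open(path_prefix + ".edges.tsv", "w") as fh:
        fh.write("node1\tnode2\tadjacency\tsign\n")
        for i, j in zip(iu[keep], ju[keep]):
            sign = "+" if cor[i, j] >= 0 else "-"
            graph.add_edge(str(nodes[i]), str(nodes[j]),
                           adjacency=float(adj[i, j]), sign=sign)
            fh.write(f"{nodes[i]}\t{nodes[j]}\t{adj[i, j]:.6f}\t{sign}\n")
    nx.write_graphml(graph, path_prefix + ".graphml")
    return int(keep.sum())
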