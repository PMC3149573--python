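"""End-to-end pipeline: simulate/load -> metabolites -> QTT -> overlap ->
GSEA -> single-tissue networks -> multi-tissue network.

A run is described by one YAML file::

    seed: 1
    multi_tissue_trait: NEFA
    simulate:                 # either this block or `inputs`
      n_probesets: 500
      qtt_traits: [NEFA]
    inputs:                   # paths to user data (alternative to simulate)
      phenotypes: pheno.csv
      expression: {FATB: fatb.tsv, ...}
      probeset_map: map.tsv   # optional; enables GSEA
      gene_sets: sets.gmt     # optional; enables GSEA
    config:                   # RunConfig overrides (qtt_alpha, ...)
      n_qtt_permutations: 20

Stages cache by config hash: outputs already present under the same hash
are not recomputed.  Reruns with the same config and seed are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .gsea import GSEA, collapse_probesets
from .io import (RunConfig, logger, read_expression, read_gmt,
                 read_phenotypes, read_probeset_map, trait_names,
                 write_expression, write_gmt, write_network, write_phenotypes,
                 write_probeset_map)
from .metabolites import (SexBreedModel, breed_dendrogram,
                          breed_trait_profiles, trait_correlations)
from .multitissue import MultiTissueNetwork
from .network import CoexpressionNetwork
from .overlap import overlap_scan, overlap_table
from .qtt import QTTModel, residualize
from .simulate import SimulationDesign, random_probeset_gene_map, simulate_cohort, simulate_gene_sets

STAGES = ("simulate", "metabolites", "qtt", "overlap", "gsea",
          "network", "multinet")
_TOP_KEYS = {"seed", "multi_tissue_trait", "simulate", "inputs", "config",
             "gsea_traits", "n_decoy_sets", "edge_threshold"}


@dataclass
class RunManifest:
    """What a run produced: config snapshot, seed, stage outputs, timings."""

    config: dict
    seed: int
    version: str = __version__
    outputs: dict[str, list[str]] = field(default_factory=dict)
    status: dict[str, str] = field(default_factory=dict)

    def record(self, stage: str, paths: list[Path], status: str = "ok") -> None:
        self.outputs[stage] = [str(p) for p in paths]
        self.status[stage] = status

    def write(self, path: Path) -> None:
        payload = {"config": self.config, "seed": self.seed,
                   "version": self.version, "outputs": self.outputs,
                   "status": self.status}
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def load_run_spec(config_path) -> dict:
    with open(config_path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_run_spec(raw)


def validate_run_spec(raw: dict) -> dict:
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if ("simulate" in raw) == ("inputs" in raw):
        raise ValueError("config needs exactly one of `simulate` or `inputs`")
    if "inputs" in raw:
        inputs = raw["inputs"]
        for key in ("phenotypes", "expression"):
            if key not in inputs:
                raise ValueError(f"inputs block missing {key!r}")
    RunConfig.from_dict(raw.get("config", {}))   # strict key check
    return raw


def _config_hash(spec: dict, seed: int) -> str:
    blob = json.dumps({"spec": spec, "seed": seed, "version": __version__},
                      sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def make_table2(qtt_sets: dict[tuple[str, str], object]) -> pd.DataFrame:
    """Traits x tissues grid 'observed (mean permuted)' of QTT counts."""
    tissues = sorted({t for t, _ in qtt_sets})
    traits = sorted({tr for _, tr in qtt_sets})
    grid = pd.DataFrame(index=traits, columns=tissues, dtype=object)
    for (tissue, trait), qs in qtt_sets.items():
        if qs.permuted_mean_count is None:
            grid.loc[trait, tissue] = str(qs.n_observed)
        else:
            grid.loc[trait, tissue] = f"{qs.n_observed} ({qs.permuted_mean_count:.1f})"
    grid.index.name = "trait"
    return grid


class Pipeline:
    """Stage runner bound to one config, seed and output directory."""

    def __init__(self, spec: dict, outdir, seed: int | None = None):
        self.spec = validate_run_spec(dict(spec))
        self.seed = int(seed if seed is not None else self.spec.get("seed", 0))
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.config = RunConfig.from_dict(self.spec.get("config", {})).with_seed(self.seed)
        self.hash = _config_hash(self.spec, self.seed)
        self.manifest = RunManifest(config=self.spec, seed=self.seed)
        # in-memory state shared between stages
        self.pheno = None
        self.expression: dict[str, pd.DataFrame] = {}
        self.truth = None
        self.probe_map = None
        self.gene_sets = None
        self.residuals: dict[str, pd.DataFrame] = {}
        self.qtt_sets: dict[tuple[str, str], object] = {}

    # -- helpers ---------------------------------------------------------
    def _stage_dir(self, stage: str) -> Path:
        d = self.outdir / stage
        d.mkdir(exist_ok=True)
        return d

    def _cached(self, stage: str, paths: list[Path]) -> bool:
        marker = self._stage_dir(stage) / ".hash"
        return (marker.exists() and marker.read_text().strip() == self.hash
                and all(p.exists() for p in paths))

    def _mark(self, stage: str) -> None:
        (self._stage_dir(stage) / ".hash").write_text(self.hash + "\n")

    @property
    def multi_trait(self) -> str:
        return self.spec.get("multi_tissue_trait", "NEFA")

    # -- stages ----------------------------------------------------------
    def stage_data(self) -> None:
        """Simulate a cohort or load user inputs into memory (+ disk copy)."""
        if self.pheno is not None:
            return
        t0 = time.time()
        if "simulate" in self.spec:
            design = SimulationDesign(**{k: tuple(v) if isinstance(v, list) else v
                                         for k, v in self.spec["simulate"].items()})
            self.pheno, self.expression, self.truth = simulate_cohort(design, self.seed)
            probes = list(next(iter(self.expression.values())).columns)
            n_genes = max(1, int(0.75 * len(probes)))
            self.probe_map = random_probeset_gene_map(probes, n_genes, self.seed)
            self.gene_sets = simulate_gene_sets(
                self.truth, self.probe_map,
                n_decoy_sets=int(self.spec.get("n_decoy_sets", 20)),
                seed=self.seed)
            d = self._stage_dir("simulate")
            paths = [d / "phenotypes.csv", d / "probeset_map.tsv",
                     d / "gene_sets.gmt"]
            if not self._cached("simulate", paths):
                write_phenotypes(self.pheno, paths[0])
                write_probeset_map(self.probe_map, paths[1])
                write_gmt(self.gene_sets, paths[2])
                for tissue, mat in self.expression.items():
                    p = d / f"expression_{tissue}.tsv"
                    write_expression(mat, p)
                    paths.append(p)
                self._mark("simulate")
            self.manifest.record("simulate", paths)
        else:
            inputs = self.spec["inputs"]
            self.pheno = read_phenotypes(inputs["phenotypes"])
            self.expression = {t: read_expression(p)
                               for t, p in inputs["expression"].items()}
            if "probeset_map" in inputs:
                self.probe_map = read_probeset_map(inputs["probeset_map"])
            if "gene_sets" in inputs:
                self.gene_sets = read_gmt(inputs["gene_sets"])
        logger.info("stage data: %d samples, %d tissues (%.1fs)",
                    len(self.pheno), len(self.expression), time.time() - t0)

    def stage_metabolites(self) -> list[Path]:
        self.stage_data()
        d = self._stage_dir("metabolites")
        paths = [d / "effects.tsv", d / "trait_correlations.tsv",
                 d / "breed_dendrogram.newick"]
        if not self._cached("metabolites", paths):
            res = SexBreedModel(self.pheno).fit()
            res.summary().to_csv(paths[0], sep="\t")
            corr, _flags = trait_correlations(self.pheno)
            corr.to_csv(paths[1], sep="\t")
            dend = breed_dendrogram(breed_trait_profiles(self.pheno))
            paths[2].write_text(dend.to_newick() + "\n")
            self._mark("metabolites")
        self.manifest.record("metabolites", paths)
        return paths

    def stage_qtt(self) -> list[Path]:
        self.stage_data()
        d = self._stage_dir("qtt")
        for tissue, expr in self.expression.items():
            self.residuals[tissue] = residualize(expr, self.pheno)
            results = QTTModel(expr, self.pheno, tissue).fit(config=self.config)
            for trait, qs in results.sets.items():
                self.qtt_sets[(tissue, trait)] = qs
        paths = [d / "table2.tsv", d / "summary.tsv"]
        if not self._cached("qtt", paths):
            make_table2(self.qtt_sets).to_csv(paths[0], sep="\t")
            rows = []
            for (tissue, trait), qs in sorted(self.qtt_sets.items()):
                rows.append({"tissue": tissue, "trait": trait,
                             "n_qtt": qs.n_observed,
                             "permuted_mean": qs.permuted_mean_count,
                             "fdr": qs.fdr_estimate})
                member = qs.member_table()
                if len(member):
                    member.to_csv(d / f"qtt_{tissue}_{trait}.tsv", sep="\t")
            pd.DataFrame(rows).to_csv(paths[1], sep="\t", index=False)
            self._mark("qtt")
        logger.info("stage qtt: %s",
                    {t: sum(q.n_observed for (ti, _), q in self.qtt_sets.items() if ti == t)
                     for t in self.expression})
        self.manifest.record("qtt", paths)
        return paths

    def stage_overlap(self) -> list[Path]:
        if not self.qtt_sets:
            self.stage_qtt()
        d = self._stage_dir("overlap")
        universe = next(iter(self.expression.values())).shape[1]
        results = overlap_scan(self.qtt_sets, universe)
        path = d / "overlap.tsv"
        if not self._cached("overlap", [path]):
            overlap_table(results).to_csv(path, sep="\t", index=False)
            self._mark("overlap")
        self.manifest.record("overlap", [path])
        return [path]

    def stage_gsea(self) -> list[Path]:
        self.stage_data()
        if self.probe_map is None or self.gene_sets is None:
            self.manifest.record("gsea", [], status="skipped (no gene sets)")
            return []
        d = self._stage_dir("gsea")
        traits = self.spec.get("gsea_traits", [self.multi_trait])
        paths = []
        cached = self._cached("gsea", [d / f"gsea_{t}_{tr}.tsv"
                                       for t in self.expression for tr in traits])
        for tissue, expr in self.expression.items():
            gene_expr = collapse_probesets(expr, self.probe_map)
            for trait in traits:
                p = d / f"gsea_{tissue}_{trait}.tsv"
                if not cached:
                    res = GSEA(gene_expr, self.pheno, trait, self.gene_sets).fit(
                        n_perm=self.config.gsea_permutations,
                        weight_exponent=self.config.gsea_weight_exponent,
                        seed=self.config.child_rng("gsea", tissue, trait))
                    res.summary().to_csv(p, sep="\t", index=False)
                paths.append(p)
        if not cached:
            self._mark("gsea")
        self.manifest.record("gsea", paths)
        return paths

    def stage_network(self) -> list[Path]:
        if not self.residuals:
            self.stage_qtt()
        d = self._stage_dir("network")
        trait = self.multi_trait
        paths = []
        done = True
        for tissue in sorted(self.expression):
            qs = self.qtt_sets[(tissue, trait)]
            base = [d / f"{tissue}_scale_free.tsv", d / f"{tissue}_modules.tsv",
                    d / f"{tissue}_connectivity.tsv"]
            paths += base
            if self._cached("network", base):
                continue
            done = False
            members = qs.members
            if len(members) < 3:
                for p in base:
                    p.write_text("# too few QTT for a network\n")
                continue
            resid = self.residuals[tissue][members]
            result = CoexpressionNetwork(resid, tissue).fit(self.config)
            if result.scale_free is not None:
                result.scale_free.table.to_csv(base[0], sep="\t")
            result.modules.to_csv(base[1], sep="\t")
            result.connectivity_profile.to_csv(base[2], sep="\t")
            write_network(result, 0.5, d / f"{tissue}_network")
            logger.info("stage network[%s]: beta=%d, %d modules", tissue,
                        result.beta, int(result.modules.max()))
        if not done:
            self._mark("network")
        self.manifest.record("network", paths)
        return paths

    def stage_multinet(self) -> list[Path]:
        if not self.residuals:
            self.stage_qtt()
        d = self._stage_dir("multinet")
        trait = self.multi_trait
        paths = [d / "nodes.tsv", d / "tissue_pairs.tsv",
                 d / "module_tissue_enrichment.tsv", d / "hub_edges.tsv"]
        if not self._cached("multinet", paths):
            qtt = {t: self.qtt_sets[(t, trait)] for t in self.expression}
            model = MultiTissueNetwork(qtt, self.residuals, pheno=self.pheno)
            result = model.fit(self.config)
            result.node_table.to_csv(paths[0], sep="\t")
            result.tissue_pair_strength.to_csv(paths[1], sep="\t")
            result.module_enrichment.to_csv(paths[2], sep="\t", index=False)
            result.hub_edges.to_csv(paths[3], sep="\t", index=False)
            write_network(result, 0.5, d / "multitissue_network")
            logger.info("stage multinet: %d nodes, %d modules, %d hub edges",
                        result.n_nodes, int(result.modules.max()),
                        len(result.hub_edges))
            self._mark("multinet")
        self.manifest.record("multinet", paths)
        return paths

    def run(self, stages=("metabolites", "qtt", "overlap", "gsea",
                          "network", "multinet")) -> RunManifest:
        for stage in stages:
            getattr(self, f"stage_{stage}")()
        self.manifest.write(self.outdir / "manifest.json")
        return self.manifest


def run_all(config_path, outdir, seed: int | None = None) -> RunManifest:
    """Execute every stage from a YAML config; returns the run manifest."""
    spec = load_run_spec(config_path)
    return Pipeline(spec, outdir, seed=seed).run()
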