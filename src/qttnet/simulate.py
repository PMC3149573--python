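"""Synthetic multi-breed, multi-tissue cohorts with known planted structure.

The generator emulates the study design this package analyses: a small pig
cohort (default 16 animals = 4 breeds x ~2 sexes) profiled in five endocrine
tissues on a log-scale expression array, with 12 plasma metabolites per
animal.  Three kinds of structure are planted and recorded as ground truth:

* **breed and sex effects** on every trait and transcript, so that the
  covariate-adjusted analyses are the correct analyses;
* **co-expression modules**: blocks of probesets sharing a latent factor,
  with expected pairwise correlation equal to ``within_module_correlation``
  (latent-factor construction: module factor + idiosyncratic noise, which
  is O(N) and gives exact control of the expected correlation);
* **trait-associated probesets (true QTT)**: probeset and trait share a
  latent factor scaled so the partial correlation (given sex and breed)
  equals ``qtt_partial_correlation`` in expectation.  Association is
  planted through the shared factor *after* breed/sex effects are added.

Expression values mimic log2 array intensities: per-probeset baseline
Uniform(2, 12) plus effects, with unit-variance stochastic structure scaled
by ``noise_sd``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GeneSetCollection, child_rng

DEFAULT_TISSUES = ("FATB", "GONA", "AHYP", "THYG", "HYPO")
DEFAULT_TRAITS = (
    "Glucose", "HydroxyButyrate", "NEFA", "Cholesterol", "HDL-C", "LDL-C",
    "Triglyceride", "TotalProtein", "ALT", "ALP", "Haptoglobin", "PigMAP",
)


@dataclass(frozen=True)
class SimulationDesign:
    """Cohort layout and planted effect sizes.

    ``sex_counts`` gives (males, females) per breed; the default mirrors a
    balanced 2M/2F design with one hybrid line at 3M/1F.  ``qtt_traits``
    names the traits that receive ``n_true_qtt`` truly associated probesets
    in every tissue at partial correlation ``qtt_partial_correlation``; the
    remaining traits are null.
    """

    n_breeds: int = 4
    samples_per_breed: int = 4
    sex_counts: tuple[tuple[int, int], ...] | None = None
    n_tissues: int = 5
    n_probesets: int = 2000
    n_traits: int = 12
    qtt_traits: tuple[str, ...] = ("NEFA",)
    n_true_qtt: int = 50
    qtt_partial_correlation: float = 0.85
    n_modules: int = 3
    module_sizes: tuple[int, ...] | None = None
    within_module_correlation: float = 0.7
    noise_sd: float = 0.5
    breed_effect_sd: float = 0.3
    sex_effect_sd: float = 0.2
    tissues: tuple[str, ...] | None = None
    trait_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.qtt_partial_correlation < 1.0:
            raise ValueError("qtt_partial_correlation must be in [0, 1)")
        if not 0.0 <= self.within_module_correlation < 1.0:
            raise ValueError("within_module_correlation must be in [0, 1)")
        if sum(self.resolved_module_sizes()) > self.n_probesets:
            raise ValueError("module sizes exceed n_probesets")

    # -- resolved (defaulted) pieces ------------------------------------
    def resolved_sex_counts(self) -> tuple[tuple[int, int], ...]:
        if self.sex_counts is not None:
            if len(self.sex_counts) != self.n_breeds:
                raise ValueError("sex_counts must have one entry per breed")
            return self.sex_counts
        counts = []
        for b in range(self.n_breeds):
            n = self.samples_per_breed
            if b == self.n_breeds - 1 and n >= 2:
                counts.append((n - n // 2 + (1 if n % 2 == 0 else 0), n // 2 - (1 if n % 2 == 0 else 0)))
            else:
                counts.append((n - n // 2, n // 2))
        return tuple(counts)

    def resolved_module_sizes(self) -> tuple[int, ...]:
        if self.module_sizes is not None:
            return self.module_sizes
        size = min(50, max(1, self.n_probesets // max(1, 2 * self.n_modules)))
        return tuple([size] * self.n_modules)

    def resolved_tissues(self) -> tuple[str, ...]:
        if self.tissues is not None:
            return self.tissues
        if self.n_tissues <= len(DEFAULT_TISSUES):
            return DEFAULT_TISSUES[: self.n_tissues]
        return tuple(f"TIS{k + 1}" for k in range(self.n_tissues))

    def resolved_traits(self) -> tuple[str, ...]:
        if self.trait_names is not None:
            return self.trait_names
        if self.n_traits <= len(DEFAULT_TRAITS):
            return DEFAULT_TRAITS[: self.n_traits]
        return tuple(f"trait{k + 1}" for k in range(self.n_traits))

    @property
    def n_samples(self) -> int:
        return sum(m + f for m, f in self.resolved_sex_counts())


@dataclass
class GroundTruth:
    """What was planted, for downstream power/recovery checks."""

    qtt: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)
    modules: dict[str, dict[str, int]] = field(default_factory=dict)
    trait_breed_effects: pd.DataFrame | None = None
    trait_sex_effects: pd.Series | None = None

    def true_probesets(self, tissue: str, trait: str) -> set[str]:
        return set(self.qtt.get((tissue, trait), {}))


def _unit_mix(shared: np.ndarray, rho: float, rng: np.random.Generator,
              n_cols: int) -> np.ndarray:
    """Columns sqrt(rho)*shared + sqrt(1-rho)*noise, unit variance."""
    n = shared.shape[0]
    noise = rng.standard_normal((n, n_cols))
    return np.sqrt(rho) * shared[:, None] + np.sqrt(1.0 - rho) * noise


def simulate_cohort(design: SimulationDesign, seed: int
                    ) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], GroundTruth]:
    """Generate (phenotypes, tissue -> expression, ground truth).

    Deterministic for a fixed seed.  Raises ``ValueError`` for infeasible
    designs (more planted QTT than free probesets).
    """
    tissues = design.resolved_tissues()
    traits = design.resolved_traits()
    sex_counts = design.resolved_sex_counts()
    module_sizes = design.resolved_module_sizes()
    n = design.n_samples

    n_module_probes = sum(module_sizes)
    n_free = design.n_probesets - n_module_probes
    needed = design.n_true_qtt * len(design.qtt_traits)
    if needed > n_free:
        raise ValueError(
            f"design infeasible: {needed} true QTT requested per tissue but "
            f"only {n_free} probesets free outside modules"
        )
    unknown = set(design.qtt_traits) - set(traits)
    if unknown:
        raise ValueError(f"qtt_traits not in trait list: {sorted(unknown)}")

    # -- samples ---------------------------------------------------------
    breeds, sexes = [], []
    for b, (males, females) in enumerate(sex_counts):
        breeds += [f"B{b + 1}"] * (males + females)
        sexes += ["M"] * males + ["F"] * females
    samples = [f"S{i + 1:02d}" for i in range(n)]

    # -- traits ----------------------------------------------------------
    rng_t = child_rng(seed, "traits")
    breed_levels = sorted(set(breeds))
    breed_eff = pd.DataFrame(
        rng_t.normal(0.0, design.breed_effect_sd, (len(breed_levels), len(traits))),
        index=breed_levels, columns=list(traits),
    )
    sex_eff = pd.Series(rng_t.normal(0.0, design.sex_effect_sd, len(traits)),
                        index=list(traits))
    trait_factors = {t: rng_t.standard_normal(n) for t in design.qtt_traits}

    r = design.qtt_partial_correlation
    pheno = pd.DataFrame(index=pd.Index(samples, name="sample"))
    pheno["sex"] = sexes
    pheno["breed"] = breeds
    breed_part = breed_eff.loc[breeds].to_numpy()
    sex_part = np.where(np.array(sexes) == "M", 1.0, -1.0)[:, None] * sex_eff.to_numpy()
    for k, t in enumerate(traits):
        base = breed_part[:, k] + sex_part[:, k]
        if t in trait_factors and r > 0:
            y = np.sqrt(r) * trait_factors[t] + np.sqrt(1.0 - r) * rng_t.standard_normal(n)
        else:
            y = rng_t.standard_normal(n)
        pheno[t] = base + y

    truth = GroundTruth(trait_breed_effects=breed_eff, trait_sex_effects=sex_eff)

    # -- expression per tissue -------------------------------------------
    # One shared probeset universe across tissues (same array); the planted
    # QTT positions for a trait are likewise shared, so truly associated
    # probesets overlap across tissues as the cross-tissue analyses assume.
    probes = [f"p{j + 1:05d}" for j in range(design.n_probesets)]
    free = np.arange(n_module_probes, design.n_probesets)
    rng_pick = child_rng(seed, "qtt-positions")
    picked = (rng_pick.choice(free, size=needed, replace=False)
              if needed else np.array([], int))
    qtt_idx = {t: picked[k * design.n_true_qtt:(k + 1) * design.n_true_qtt]
               for k, t in enumerate(design.qtt_traits)}

    expression: dict[str, pd.DataFrame] = {}
    rho = design.within_module_correlation
    for tissue in tissues:
        rng_e = child_rng(seed, "expr", tissue)
        z = rng_e.standard_normal((n, design.n_probesets))

        module_of: dict[str, int] = {}
        start = 0
        for m, size in enumerate(module_sizes, start=1):
            factor = rng_e.standard_normal(n)
            z[:, start:start + size] = _unit_mix(factor, rho, rng_e, size)
            for j in range(start, start + size):
                module_of[probes[j]] = m
            start += size
        truth.modules[tissue] = module_of

        for t in design.qtt_traits:
            idx = qtt_idx[t]
            if r > 0 and len(idx):
                z[:, idx] = _unit_mix(trait_factors[t], r, rng_e, len(idx))
                truth.qtt[(tissue, t)] = {probes[j]: r for j in idx}
            else:
                truth.qtt[(tissue, t)] = {}

        baseline = rng_e.uniform(2.0, 12.0, design.n_probesets)
        b_eff = rng_e.normal(0.0, design.breed_effect_sd, (len(breed_levels), design.n_probesets))
        s_eff = rng_e.normal(0.0, design.sex_effect_sd, design.n_probesets)
        breed_idx = np.array([breed_levels.index(b) for b in breeds])
        values = (baseline[None, :] + b_eff[breed_idx, :]
                  + np.where(np.array(sexes) == "M", 1.0, -1.0)[:, None] * s_eff[None, :]
                  + design.noise_sd * z)
        expression[tissue] = pd.DataFrame(values, index=pheno.index,
                                          columns=pd.Index(probes, name="probeset"))
    return pheno, expression, truth


def random_probeset_gene_map(probeset_ids, n_genes: int, seed: int) -> pd.Series:
    """Many-to-one probeset -> gene map with exactly ``n_genes`` genes.

    The first ``n_genes`` probesets seed one gene each; the rest are
    assigned uniformly, mimicking arrays where some genes carry several
    probesets.
    """
    probeset_ids = list(probeset_ids)
    if n_genes > len(probeset_ids):
        raise ValueError("n_genes cannot exceed the number of probesets")
    rng = child_rng(seed, "probe-gene-map")
    genes = [f"GENE{g + 1:05d}" for g in range(n_genes)]
    assigned = genes + list(rng.choice(genes, size=len(probeset_ids) - n_genes))
    mapping = pd.Series(assigned, index=probeset_ids, name="gene")
    mapping.index.name = "probeset"
    return mapping


def simulate_gene_sets(truth: GroundTruth, mapping: pd.Series,
                       n_decoy_sets: int, seed: int,
                       decoy_size: int = 40,
                       true_fill_fraction: float = 0.1) -> GeneSetCollection:
    """Gene sets for enrichment testing: planted "true" sets plus decoys.

    Each planted (tissue, trait) signal yields a set holding all its truly
    associated genes plus a ``true_fill_fraction`` of random fillers (so
    >= 80% of members are truly associated); decoys are uniform draws from
    the gene universe.
    """
    rng = child_rng(seed, "gene-sets")
    universe = sorted(set(mapping.values))
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    for (tissue, trait), members in sorted(truth.qtt.items()):
        if not members:
            continue
        genes = sorted({mapping[p] for p in members if p in mapping.index})
        if not genes:
            continue
        n_fill = int(np.floor(true_fill_fraction * len(genes)))
        fillers = [g for g in universe if g not in set(genes)]
        fill = list(rng.choice(fillers, size=min(n_fill, len(fillers)), replace=False))
        sets[f"TRUE_{tissue}_{trait}"] = (
            f"planted {trait} signal in {tissue}", tuple(genes + sorted(fill)))
    for d in range(n_decoy_sets):
        size = min(decoy_size, len(universe))
        members = sorted(rng.choice(universe, size=size, replace=False))
        sets[f"DECOY_{d + 1:03d}"] = ("random decoy set", tuple(members))
    return GeneSetCollection(sets)
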