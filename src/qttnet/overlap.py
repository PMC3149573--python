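"""Cross-tissue QTT overlap statistics.

For a metabolite and two tissues, tests whether the number of probesets
called QTT in both tissues exceeds the random expectation |A||B|/N, where
N is the shared probeset universe (all probesets on the array).  The
one-sided p-value is the hypergeometric upper tail, identical to a
one-sided Fisher's exact test on the 2x2 table; Bonferroni correction is
applied across all (trait, tissue-pair) tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd
from scipy import stats

from .qtt import QTTSet

__all__ = ["OverlapResult", "overlap_test", "overlap_scan"]


@dataclass
class OverlapResult:
    trait: str
    tissue_pair: tuple[str, str]
    observed: int
    expected: float
    fold: float | None       # None when expected == 0
    p_raw: float
    p_bonferroni: float
    universe: int

    def as_row(self) -> dict:
        return {
            "trait": self.trait, "tissue1": self.tissue_pair[0],
            "tissue2": self.tissue_pair[1], "observed": self.observed,
            "expected": self.expected, "fold": self.fold,
            "p_raw": self.p_raw, "p_bonferroni": self.p_bonferroni,
        }


def overlap_test(set_a: QTTSet, set_b: QTTSet, universe: int,
                 n_tests: int = 1) -> OverlapResult:
    """Hypergeometric enrichment test of the overlap of two QTT sets.

    ``universe`` is the number of probesets both sets were drawn from.
    """
    a, b = set(set_a.members), set(set_b.members)
    if len(a) > universe or len(b) > universe:
        raise ValueError("set size exceeds universe")
    observed = len(a & b)
    expected = len(a) * len(b) / universe if universe else 0.0
    fold = observed / expected if expected > 0 else None
    # P(X >= observed), X ~ Hypergeom(N=universe, K=|A|, n=|B|)
    p_raw = float(stats.hypergeom.sf(observed - 1, universe, len(a), len(b)))
    return OverlapResult(
        trait=set_a.trait, tissue_pair=(set_a.tissue, set_b.tissue),
        observed=observed, expected=expected, fold=fold, p_raw=p_raw,
        p_bonferroni=min(1.0, p_raw * n_tests), universe=universe,
    )


def overlap_counts_test(size_a: int, size_b: int, observed: int, universe: int,
                        n_tests: int = 1, trait: str = "",
                        pair: tuple[str, str] = ("", "")) -> OverlapResult:
    """overlap_test from summary counts alone (e.g. published QTT counts)."""
    if size_a > universe or size_b > universe:
        raise ValueError("set size exceeds universe")
    if observed > min(size_a, size_b):
        raise ValueError("observed overlap exceeds the smaller set")
    expected = size_a * size_b / universe if universe else 0.0
    fold = observed / expected if expected > 0 else None
    p_raw = float(stats.hypergeom.sf(observed - 1, universe, size_a, size_b))
    return OverlapResult(trait, pair, observed, expected, fold, p_raw,
                         min(1.0, p_raw * n_tests), universe)


def overlap_scan(qtt_sets: dict[tuple[str, str], QTTSet], universe: int,
                 report_threshold: float = 1.0) -> list[OverlapResult]:
    """All (trait, unordered tissue pair) overlap tests, Bonferroni-corrected.

    ``qtt_sets`` maps (tissue, trait) -> QTTSet.  The Bonferroni family is
    n_traits x C(n_tissues, 2); results are sorted by raw p and filtered at
    ``p_bonferroni <= report_threshold``.
    """
    tissues = sorted({t for t, _ in qtt_sets})
    traits = sorted({tr for _, tr in qtt_sets})
    if len(tissues) < 2:
        raise ValueError("need >= 2 tissues")
    pairs = list(combinations(tissues, 2))
    n_tests = len(traits) * len(pairs)
    results = []
    for trait in traits:
        for t1, t2 in pairs:
            if (t1, trait) not in qtt_sets or (t2, trait) not in qtt_sets:
                continue
            res = overlap_test(qtt_sets[(t1, trait)], qtt_sets[(t2, trait)],
                               universe, n_tests)
            results.append(res)
    results.sort(key=lambda r: r.p_raw)
    return [r for r in results if r.p_bonferroni <= report_threshold]


def overlap_table(results: list[OverlapResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in results])
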