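"""Exact multinomial test for per-codon variant-type skew.

A codon can mutate to nine possible single-nucleotide variants (three
substitutions at each of its three bases). Under the null that the nine are
equally likely (probability 1/9 each), the patient counts across them are
multinomial. The test statistic is the chi-square discrepancy from the
uniform expectation, and the p-value is the exact multinomial tail: the total
probability of all ordered 9-category outcomes with the same total whose
statistic is at least the observed one (ties included — the conservative
convention). Enumeration runs over integer partitions with multiplicity
weights; beyond the enumeration cap a seeded Monte Carlo estimate is used.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from functools import lru_cache
from math import factorial
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .variants import VariantRecord

__all__ = [
    "N_CATEGORIES",
    "CodonObservation",
    "chisq_stat",
    "exact_multinomial_pvalue",
    "hotspot_scan",
]

N_CATEGORIES = 9  # single-nucleotide variants per codon
_TIE_TOL = 1e-9
DEFAULT_ENUM_CAP = 25


@dataclass(frozen=True)
class CodonObservation:
    """Per-variant patient counts at one residue (≤ 9 distinct variants)."""

    residue: int
    variant_counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.variant_counts) <= N_CATEGORIES:
            raise ValueError("between 1 and 9 distinct variants per codon")
        if any(c < 1 for c in self.variant_counts):
            raise ValueError("every observed variant needs at least one patient")

    @property
    def n(self) -> int:
        return sum(self.variant_counts)

    def padded(self) -> tuple[int, ...]:
        return tuple(self.variant_counts) + (0,) * (
            N_CATEGORIES - len(self.variant_counts)
        )


def chisq_stat(counts9: Sequence[int]) -> float:
    """Chi-square statistic against the equal-1/9 expectation."""
    counts = np.asarray(counts9, dtype=float)
    if counts.size != N_CATEGORIES:
        raise ValueError(f"expected {N_CATEGORIES} category counts")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    n = counts.sum()
    if n == 0:
        raise ValueError("all-zero counts")
    expected = n / N_CATEGORIES
    return float(np.sum((counts - expected) ** 2) / expected)


def _partitions(n: int, max_parts: int, largest: Optional[int] = None) -> Iterator[tuple[int, ...]]:
    """Integer partitions of n into at most `max_parts` parts, non-increasing."""
    if n == 0:
        yield ()
        return
    if max_parts == 0:
        return
    largest = n if largest is None else min(largest, n)
    for first in range(largest, 0, -1):
        for rest in _partitions(n - first, max_parts - 1, first):
            yield (first,) + rest


@lru_cache(maxsize=None)
def _partition_table(n: int) -> tuple[tuple[tuple[int, ...], float, float], ...]:
    """(padded partition, statistic, total probability of its orderings)."""
    out = []
    log9 = np.log(9.0)
    for part in _partitions(n, N_CATEGORIES):
        padded = tuple(part) + (0,) * (N_CATEGORIES - len(part))
        stat = chisq_stat(padded)
        # multinomial coefficient n!/prod(c_i!) times the number of distinct
        # orderings of the padded vector, at probability (1/9)^n each
        log_coeff = float(np.log(float(factorial(n))))
        for c in padded:
            log_coeff -= float(np.log(float(factorial(c))))
        mult = factorial(N_CATEGORIES)
        for rep in Counter(padded).values():
            mult //= factorial(rep)
        prob = float(np.exp(log_coeff + np.log(float(mult)) - n * log9))
        out.append((padded, stat, prob))
    return tuple(out)


def exact_multinomial_pvalue(
    counts9: Sequence[int],
    enum_cap: int = DEFAULT_ENUM_CAP,
    seed: int = 0,
    n_draws: int = 1_000_000,
) -> tuple[float, str]:
    """Exact (or Monte Carlo) multinomial tail probability of the statistic.

    Returns ``(p, method)`` with method ``"enum"`` for complete enumeration
    (n ≤ enum_cap) or ``"mc"`` for the seeded Monte Carlo fallback.
    """
    observed = chisq_stat(counts9)
    n = int(np.asarray(counts9).sum())
    if n <= enum_cap:
        table = _partition_table(n)
        p = sum(prob for _, stat, prob in table if stat >= observed - _TIE_TOL)
        return min(float(p), 1.0), "enum"
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n, np.full(N_CATEGORIES, 1 / N_CATEGORIES), size=n_draws)
    expected = n / N_CATEGORIES
    stats = ((draws - expected) ** 2).sum(axis=1) / expected
    return float(np.mean(stats >= observed - _TIE_TOL)), "mc"


def _split_evenly(total: int, k: int) -> list[int]:
    """Split `total` patients over k categories as evenly as possible, largest first."""
    base, extra = divmod(total, k)
    return [base + 1 if i < extra else base for i in range(k)]


def hotspot_scan(
    records: Sequence[VariantRecord],
    alpha: float = 0.05,
    enum_cap: int = DEFAULT_ENUM_CAP,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-residue exact multinomial test over all mutated residues.

    Distinct variants are counted at cDNA granularity; when one table row
    carries several cDNA descriptors its patients are split across them as
    evenly as possible (the row does not say which patient carries which
    nucleotide change). The protein-level tabulation is reported alongside.
    Splice records are ignored; more than nine distinct variants at one
    residue is impossible under the single-nucleotide model and raises.
    """
    by_residue: dict[int, list[VariantRecord]] = {}
    for r in records:
        if r.consequence == "splice":
            continue
        by_residue.setdefault(r.residue_position, []).append(r)

    rows = []
    for residue in sorted(by_residue):
        recs = by_residue[residue]
        nt_counts: list[int] = []
        for r in recs:
            k = max(len(r.cdna_changes), 1)
            nt_counts.extend(_split_evenly(r.n_patients, k))
        aa_counts = sorted((r.n_patients for r in recs), reverse=True)
        if len(nt_counts) > N_CATEGORIES:
            raise ValueError(
                f"residue {residue}: {len(nt_counts)} distinct variants exceed "
                f"the {N_CATEGORIES}-outcome single-nucleotide model"
            )
        obs = CodonObservation(residue=residue, variant_counts=tuple(sorted(nt_counts, reverse=True)))
        stat = chisq_stat(obs.padded())
        p, method = exact_multinomial_pvalue(obs.padded(), enum_cap=enum_cap, seed=seed)
        rows.append(
            {
                "residue": residue,
                "n": obs.n,
                "pattern_nt": "/".join(map(str, obs.variant_counts)),
                "pattern_aa": "/".join(map(str, aa_counts)),
                "chisq": stat,
                "p_exact": p,
                "method": method,
                "significant": p < alpha,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "residue", "n", "pattern_nt", "pattern_aa",
            "chisq", "p_exact", "method", "significant",
        ],
    )
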