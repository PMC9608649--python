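"""Pairwise agreement between categorical variant-effect predictors.

Predictor vocabularies ("Probably Damaging", "Deleterious", "Disease
Causing", ...) are first collapsed to a binary benign/effect call through a
user-editable recoding scheme; each unordered pair of predictors is then
summarised by its 2×2 concordance table, percent agreement, Cohen's kappa and
McNemar's test of marginal homogeneity (asymptotic, without continuity
correction). Missing calls drop a variant from the pairs that involve them
only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

__all__ = [
    "RatingMatrix",
    "PairAgreement",
    "load_rating_matrix",
    "recode_binary",
    "cohen_kappa",
    "mcnemar_test",
    "pairwise_concordance",
]

EFFECT, BENIGN = 1, 0


@dataclass
class RatingMatrix:
    """Variants × predictors categorical calls plus a binary recoding scheme."""

    calls: pd.DataFrame  # index: variant ids; columns: predictor names; NaN = missing
    scheme: Mapping[str, str]  # label -> "benign" | "effect"

    @property
    def variants(self) -> list[str]:
        return list(self.calls.index)

    @property
    def raters(self) -> list[str]:
        return list(self.calls.columns)


@dataclass(frozen=True)
class PairAgreement:
    rater_a: str
    rater_b: str
    a: int  # both effect
    b: int  # A effect, B benign
    c: int  # A benign, B effect
    d: int  # both benign
    percent_agreement: float
    kappa: Optional[float]  # None when chance agreement is exactly 1
    mcnemar_stat: Optional[float]  # None when no discordant pairs
    mcnemar_p: Optional[float]

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def load_rating_matrix(path: str | Path, scheme_path: str | Path) -> RatingMatrix:
    """Read a TSV rating matrix (first column variant id) and a scheme JSON."""
    calls = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    with open(scheme_path) as fh:
        scheme = json.load(fh)
    return RatingMatrix(calls=calls, scheme=scheme)


def recode_binary(matrix: RatingMatrix) -> pd.DataFrame:
    """Map every non-missing label to 1 (effect) / 0 (benign).

    Raises on any observed label absent from the scheme, naming it.
    """
    out = pd.DataFrame(index=matrix.calls.index, columns=matrix.calls.columns, dtype=float)
    for col in matrix.calls.columns:
        for idx, label in matrix.calls[col].items():
            if pd.isna(label) or label == "":
                out.loc[idx, col] = np.nan
                continue
            mapped = matrix.scheme.get(str(label))
            if mapped not in ("benign", "effect"):
                raise KeyError(
                    f"label {label!r} (rater {col!r}) has no benign/effect mapping"
                )
            out.loc[idx, col] = EFFECT if mapped == "effect" else BENIGN
    return out


def cohen_kappa(a: int, b: int, c: int, d: int) -> Optional[float]:
    """Chance-corrected agreement κ = (p_o − p_e) / (1 − p_e) for a 2×2 table.

    Returns None (undefined) when expected chance agreement p_e equals 1,
    which happens when both raters are unanimous.
    """
    n = a + b + c + d
    if n < 1:
        raise ValueError("empty 2x2 table")
    p_o = (a + d) / n
    p_e = ((a + b) * (a + c) + (c + d) * (b + d)) / n**2
    if p_e == 1.0:
        return None
    return (p_o - p_e) / (1 - p_e)


def mcnemar_test(b: int, c: int) -> tuple[Optional[float], Optional[float]]:
    """Asymptotic McNemar statistic (b−c)²/(b+c) and its χ²₁ upper tail.

    No continuity correction. With no discordant pairs (b + c = 0) the test
    is not computable and (None, None) is returned.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    if b + c == 0:
        return None, None
    stat = (b - c) ** 2 / (b + c)
    return float(stat), float(chi2.sf(stat, df=1))


def pairwise_concordance(matrix: RatingMatrix) -> list[PairAgreement]:
    """One PairAgreement per unordered predictor pair, in rater-list order.

    Each pair uses only the variants rated by both predictors; all-missing
    columns contribute no complete pairs and yield empty tables, which are
    skipped.
    """
    binary = recode_binary(matrix)
    raters = list(binary.columns)
    if len(raters) < 2:
        raise ValueError("need at least two raters")
    out: list[PairAgreement] = []
    for ia in range(len(raters)):
        for ib in range(ia + 1, len(raters)):
            ra, rb = raters[ia], raters[ib]
            sub = binary[[ra, rb]].dropna()
            if sub.empty:
                continue
            va = sub[ra].to_numpy()
            vb = sub[rb].to_numpy()
            a = int(np.sum((va == EFFECT) & (vb == EFFECT)))
            b = int(np.sum((va == EFFECT) & (vb == BENIGN)))
            c = int(np.sum((va == BENIGN) & (vb == EFFECT)))
            d = int(np.sum((va == BENIGN) & (vb == BENIGN)))
            stat, p = mcnemar_test(b, c)
            out.append(
                PairAgreement(
                    rater_a=ra,
                    rater_b=rb,
                    a=a, b=b, c=c, d=d,
                    percent_agreement=(a + d) / (a + b + c + d),
                    kappa=cohen_kappa(a, b, c, d),
                    mcnemar_stat=stat,
                    mcnemar_p=p,
                )
            )
    return out
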