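"""Nonrandom mutation clustering (NMC) by order-statistic spacings.

Under the null that patient mutation events fall independently and uniformly
on a protein of length N, the spacing between the i-th and j-th order
statistics of m events (rescaled to the unit interval) follows a
Beta(j−i, m−(j−i)+1) distribution. A run of co-located or tightly packed
events therefore yields an improbably small spacing, and its lower Beta tail
is the cluster p-value. The scan tests every pair i<j and controls the false
discovery rate over the m(m−1)/2 tests with Benjamini–Hochberg.

Span convention: a pair of events at residues x_i ≤ x_j occupies
(x_j − x_i + 1)/N of the sequence, so events tied at one residue — the typical
disease hotspot — get span 1/N rather than a degenerate 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import beta as beta_dist
from statsmodels.stats.multitest import multipletests

from .domains import DomainSet
from .variants import MutationProfile

__all__ = [
    "ClusterResult",
    "spacing_pvalue",
    "bh_adjust",
    "nmc_scan",
    "single_residue_clusters",
]


@dataclass(frozen=True)
class ClusterResult:
    """One tested pair of ordered mutation events."""

    i: int  # 1-based order-statistic indices, i < j
    j: int
    start_residue: int
    end_residue: int
    d: int  # j - i
    span: float  # fraction of protein length covered
    n_samples: int  # events inside [start_residue, end_residue]
    raw_p: float
    adj_p: float

    @property
    def single_residue(self) -> bool:
        return self.start_residue == self.end_residue


def spacing_pvalue(d: int, m: int, span: float) -> float:
    """Lower Beta(d, m−d+1) tail of an order-statistic spacing.

    Parameters
    ----------
    d : rank gap j − i between the two order statistics (1 ≤ d < m).
    m : total number of events.
    span : observed spacing as a fraction of protein length, in (0, 1].
    """
    if not 1 <= d < m:
        raise ValueError(f"need 1 <= d < m, got d={d}, m={m}")
    if not 0.0 < span <= 1.0:
        raise ValueError(f"span must lie in (0, 1], got {span}")
    return float(beta_dist.cdf(span, d, m - d + 1))


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, capped at 1."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def nmc_scan(profile: MutationProfile) -> list[ClusterResult]:
    """Score every pair of ordered events against the uniform null.

    Requires at least two events; splice variants must already be excluded
    (profiles built by `residue_patient_counts` never contain them).
    """
    x = np.sort(np.asarray(profile.events, dtype=int))
    m = int(x.size)
    if m < 2:
        raise ValueError("NMC needs at least two mutation events")
    N = profile.protein_length

    iu, ju = np.triu_indices(m, k=1)
    d = ju - iu
    start = x[iu]
    end = x[ju]
    span = (end - start + 1) / N
    raw = beta_dist.cdf(span, d, m - d + 1)
    adj = bh_adjust(raw)

    # events inside [start, end] — vectorised via the sorted positions
    lo = np.searchsorted(x, start, side="left")
    hi = np.searchsorted(x, end, side="right")
    n_samples = hi - lo

    return [
        ClusterResult(
            i=int(iu[k]) + 1,
            j=int(ju[k]) + 1,
            start_residue=int(start[k]),
            end_residue=int(end[k]),
            d=int(d[k]),
            span=float(span[k]),
            n_samples=int(n_samples[k]),
            raw_p=float(raw[k]),
            adj_p=float(adj[k]),
        )
        for k in range(len(iu))
    ]


def single_residue_clusters(
    results: Sequence[ClusterResult],
    alpha: float = 0.05,
    domains: Optional[DomainSet] = None,
) -> list[dict]:
    """Significant clusters spanning exactly one residue (mutation hotspots).

    For each residue with at least two events, the representative pair is the
    one covering all events at the residue (first event to last event, the
    largest rank gap among same-residue pairs); it is reported iff its
    adjusted p is below ``alpha``. Output is ordered by adjusted p, then by
    residue, and annotated against ``domains`` when provided.
    """
    best: dict[int, ClusterResult] = {}
    for r in results:
        if r.single_residue:
            cur = best.get(r.start_residue)
            if cur is None or r.d > cur.d:
                best[r.start_residue] = r
    rows = []
    for residue, cluster in best.items():
        if cluster.adj_p < alpha:
            rows.append(
                {
                    "residue": residue,
                    "n_samples": cluster.n_samples,
                    "raw_p": cluster.raw_p,
                    "adj_p": cluster.adj_p,
                    "domains": domains.annotate(residue) if domains else "",
                }
            )
    rows.sort(key=lambda row: (row["adj_p"], row["residue"]))
    return rows
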