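"""Synthetic data with the statistical structure the pipeline assumes.

Three generators mirror the three nulls under test: patient mutation events
uniform on a protein (optionally enriched at hotspot residues), per-codon
variant-type counts multinomial with equal 1/9 probabilities (optionally
skewed), and paired binary predictor calls with controllable marginal effect
rates and percent agreement. Defaults reproduce the study conditions of the
CK2α analysis: a 391-residue protein carrying 121 patient events, with the
hotspot alternative placing a 24/121 fraction at residue 198.

Every generator draws integers from a `numpy` Generator seeded through a
single root `SeedSequence`, so runs are reproducible and stages are
independently re-seedable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .codon import exact_multinomial_pvalue
from .nmc import nmc_scan, single_residue_clusters
from .variants import MutationProfile, VariantRecord

__all__ = [
    "SimulationConfig",
    "RaterModel",
    "simulate_event_table",
    "simulate_codon_counts",
    "simulate_rating_pairs",
    "calibration_harness",
]

# one-letter codes used to synthesise parseable missense descriptors
_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "E": "Glu",
    "Q": "Gln", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val",
}
_AAS = sorted(_AA3)


@dataclass(frozen=True)
class RaterModel:
    p_effect_a: float = 0.8
    p_effect_b: float = 0.8
    agreement: float = 0.9

    def cell_probabilities(self) -> tuple[float, float, float, float]:
        """(p11, p10, p01, p00) of the paired-call table, validated feasible."""
        pa, pb, agree = self.p_effect_a, self.p_effect_b, self.agreement
        for name, v in [("p_effect_a", pa), ("p_effect_b", pb), ("agreement", agree)]:
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        lo = abs(1.0 - pa - pb)
        hi = 1.0 - abs(pa - pb)
        if not lo - 1e-12 <= agree <= hi + 1e-12:
            raise ValueError(
                f"agreement {agree} infeasible for marginals ({pa}, {pb}); "
                f"feasible interval is [{lo:.4f}, {hi:.4f}]"
            )
        p11 = (agree + pa + pb - 1.0) / 2.0
        p00 = agree - p11
        p10 = pa - p11
        p01 = pb - p11
        return tuple(max(0.0, p) for p in (p11, p10, p01, p00))


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic variant table."""

    protein_length: int = 391
    m: int = 121
    hotspots: list[dict] = field(default_factory=list)  # [{"residue": r, "weight": w}]
    codon_skew: Optional[Sequence[float]] = None  # default: uniform 1/9
    rater_model: RaterModel = field(default_factory=RaterModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.protein_length < 1 or self.m < 0:
            raise ValueError("protein_length must be >= 1 and m >= 0")
        total = sum(h["weight"] for h in self.hotspots)
        if total > 1.0 + 1e-12:
            raise ValueError("hotspot weights must sum to at most 1")
        for h in self.hotspots:
            if not 1 <= h["residue"] <= self.protein_length:
                raise ValueError(f"hotspot residue {h['residue']} out of range")
        if self.codon_skew is not None:
            skew = np.asarray(self.codon_skew, dtype=float)
            if skew.size != 9 or abs(skew.sum() - 1.0) > 1e-9 or np.any(skew < 0):
                raise ValueError("codon_skew must be 9 non-negative values summing to 1")


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_event_positions(config: SimulationConfig) -> np.ndarray:
    """Residue position of each patient event (sorted, 1-based)."""
    (rng,) = _streams(config.seed, 1)
    weights = np.array([h["weight"] for h in config.hotspots], dtype=float)
    residues = np.array([h["residue"] for h in config.hotspots], dtype=int)
    background = 1.0 - weights.sum()
    choice = rng.choice(
        len(residues) + 1,
        size=config.m,
        p=np.append(weights, background) if len(residues) else [1.0],
    )
    positions = np.where(
        choice < len(residues),
        residues[np.minimum(choice, max(len(residues) - 1, 0))] if len(residues) else 0,
        rng.integers(1, config.protein_length + 1, size=config.m),
    )
    return np.sort(positions.astype(int))


def simulate_event_table(config: SimulationConfig) -> list[VariantRecord]:
    """Synthetic variant records in the same dialect the parsers read.

    Each patient event lands on a hotspot residue with its weight and
    uniformly otherwise; events sharing a residue merge into one missense
    record with an ``n_patients`` count and a synthesised, parseable
    protein-change descriptor. Deterministic under a fixed seed.
    """
    positions = simulate_event_positions(config)
    (rng,) = _streams(config.seed + 1, 1)
    records = []
    for residue, count in zip(*np.unique(positions, return_counts=True)):
        ref, alt = [_AAS[i] for i in rng.choice(len(_AAS), size=2, replace=False)]
        records.append(
            VariantRecord(
                gene="SYN",
                residue_position=int(residue),
                cdna_changes=(f"c.{3 * int(residue) - 1}N>N",),
                protein_change=f"p.{_AA3[ref]}{int(residue)}{_AA3[alt]}",
                consequence="missense",
                ref_aa=ref,
                alt_aa=alt,
                n_patients=int(count),
                sources=("synthetic",),
            )
        )
    return records


def simulate_codon_counts(
    n: int, codon_skew: Optional[Sequence[float]] = None, seed: int = 0
) -> np.ndarray:
    """One multinomial draw of per-codon variant-type counts."""
    if n < 1:
        raise ValueError("n must be >= 1")
    probs = (
        np.full(9, 1 / 9) if codon_skew is None else np.asarray(codon_skew, dtype=float)
    )
    return np.random.default_rng(seed).multinomial(n, probs)


def simulate_rating_pairs(
    n: int, rater_model: RaterModel, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Paired binary calls whose expected agreement matches the model."""
    probs = np.asarray(rater_model.cell_probabilities(), dtype=float)
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    cells = rng.choice(4, size=n, p=probs)
    calls_a = np.isin(cells, (0, 1)).astype(int)
    calls_b = np.isin(cells, (0, 2)).astype(int)
    return calls_a, calls_b


def _nmc_replicate(config: SimulationConfig, alpha: float) -> list[dict]:
    positions = simulate_event_positions(config)
    profile = MutationProfile(
        gene="SYN", protein_length=config.protein_length, events=positions
    )
    return single_residue_clusters(nmc_scan(profile), alpha=alpha)


def calibration_harness(
    stage: str,
    scenarios: Sequence[dict],
    replicates: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Empirical rejection rates of the NMC or multinomial stage.

    Each scenario dict configures one condition; the harness reports the
    fraction of replicates with a significant call at ``alpha``:

    - stage ``"nmc"``: keys ``protein_length``, ``m``, ``hotspots``; a
      replicate rejects if any single-residue cluster is significant, and
      ``detected`` additionally tracks the first listed hotspot residue.
    - stage ``"multinomial"``: keys ``n``, ``codon_skew``; a replicate
      rejects if the exact test of a fresh multinomial draw is significant.
    """
    if stage not in ("nmc", "multinomial"):
        raise ValueError(f"unknown calibration stage {stage!r}")
    seeds = np.random.SeedSequence(seed).spawn(len(scenarios))
    rows = []
    for scenario, ss in zip(scenarios, seeds):
        child_ints = ss.generate_state(replicates, dtype=np.uint32) >> 1
        hits = 0
        detected = 0
        for rep in range(replicates):
            rep_seed = int(child_ints[rep])
            if stage == "nmc":
                cfg = SimulationConfig(
                    protein_length=scenario.get("protein_length", 391),
                    m=scenario.get("m", 121),
                    hotspots=scenario.get("hotspots", []),
                    seed=rep_seed,
                )
                significant = _nmc_replicate(cfg, alpha)
                if significant:
                    hits += 1
                    if cfg.hotspots and any(
                        row["residue"] == cfg.hotspots[0]["residue"]
                        for row in significant
                    ):
                        detected += 1
            else:
                counts = simulate_codon_counts(
                    scenario.get("n", 10), scenario.get("codon_skew"), seed=rep_seed
                )
                observed = counts[counts > 0]
                padded = np.zeros(9, dtype=int)
                padded[: observed.size] = -np.sort(-observed)
                p, _ = exact_multinomial_pvalue(padded)
                if p < alpha:
                    hits += 1
        rows.append(
            {
                "stage": stage,
                "scenario": scenario.get("name", ""),
                "replicates": replicates,
                "reject_rate": hits / replicates,
                "detect_rate": detected / replicates,
            }
        )
    return pd.DataFrame(rows)
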