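"""Functional/structural residue sets and per-domain mutation density.

Domains are named residue sets built from closed 1-based ranges and explicit
residue lists; they may be discontiguous and may overlap (the activation
segment contains the P+1 loop, for instance). Overlap is preserved — a patient
event inside two domains counts in both rows. The "interdomain" region is the
complement of the union of every listed set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

from .variants import MutationProfile

__all__ = [
    "Domain",
    "DomainSet",
    "DensityRow",
    "load_domain_config",
    "domain_density",
    "interdomain_complement",
]


@dataclass(frozen=True)
class Domain:
    name: str
    residues: frozenset[int]

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"domain {self.name!r} has an empty residue set")
        if min(self.residues) < 1:
            raise ValueError(f"domain {self.name!r} has residues below 1")


@dataclass
class DomainSet:
    gene: str
    domains: list[Domain] = field(default_factory=list)

    def union(self) -> frozenset[int]:
        out: set[int] = set()
        for d in self.domains:
            out |= d.residues
        return frozenset(out)

    def annotate(self, residue: int) -> str:
        """Semicolon-joined names of every domain containing `residue`."""
        names = [d.name for d in self.domains if residue in d.residues]
        return "; ".join(names) if names else "Interdomain"


@dataclass(frozen=True)
class DensityRow:
    name: str
    n_residues: int
    n_patients: int
    density: float

    @property
    def density_display(self) -> str:
        """Half-up 2-decimal rounding, matching conventional table formatting."""
        return str(
            Decimal(self.n_patients / self.n_residues).quantize(
                Decimal("0.01"), rounding=ROUND_HALF_UP
            )
        )


def _residues_from_spec(spec: Mapping[str, object]) -> frozenset[int]:
    residues: set[int] = set(int(r) for r in spec.get("residues", []))
    for a, b in spec.get("ranges", []):
        if b < a:
            raise ValueError(f"inverted range [{a}, {b}] in domain {spec.get('name')!r}")
        residues.update(range(int(a), int(b) + 1))
    return frozenset(residues)


def load_domain_config(
    path: str | Path, protein_length: int | None = None
) -> DomainSet:
    """Load a domain-definition JSON: {gene, domains: [{name, ranges, residues}]}."""
    with open(path) as fh:
        cfg = json.load(fh)
    domains = [
        Domain(name=str(d["name"]), residues=_residues_from_spec(d))
        for d in cfg["domains"]
    ]
    dset = DomainSet(gene=str(cfg["gene"]), domains=domains)
    if protein_length is not None:
        out_of_range = [r for r in dset.union() if r > protein_length]
        if out_of_range:
            raise ValueError(
                f"domain residues beyond protein length {protein_length}: "
                f"{sorted(out_of_range)[:5]}..."
            )
    return dset


def domain_density(profile: MutationProfile, domain_set: DomainSet) -> list[DensityRow]:
    """Patients-per-residue density for every domain in the set.

    The profile must already exclude splice variants (it always does when
    built by `residue_patient_counts`).
    """
    counts = profile.counts()
    rows = []
    for d in domain_set.domains:
        n_pat = sum(counts.get(r, 0) for r in d.residues)
        rows.append(
            DensityRow(
                name=d.name,
                n_residues=len(d.residues),
                n_patients=n_pat,
                density=n_pat / len(d.residues),
            )
        )
    return rows


def interdomain_complement(domain_set: DomainSet, protein_length: int) -> frozenset[int]:
    """Residues of [1, protein_length] outside every listed domain.

    Single-residue rows (e.g. phosphorylation sites) count as domains, so they
    are excluded from the interdomain region too.
    """
    return frozenset(range(1, protein_length + 1)) - domain_set.union()


def interdomain_density(
    profile: MutationProfile, domain_set: DomainSet
) -> DensityRow:
    """Density row for the interdomain complement of `domain_set`."""
    residues = interdomain_complement(domain_set, profile.protein_length)
    counts = profile.counts()
    n_pat = sum(counts.get(r, 0) for r in residues)
    return DensityRow(
        name="Interdomain",
        n_residues=len(residues),
        n_patients=n_pat,
        density=n_pat / len(residues) if residues else 0.0,
    )
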