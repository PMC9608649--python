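"""Patient variant tables: loading, validation, classification, aggregation.

A variant table is a UTF-8 TSV with header
``gene  residue  cdna  protein_change  n_patients  source``; one row per
distinct protein-level variant, possibly carrying several coding-DNA
descriptors in one cell (space separated) when different nucleotide changes
produce the same amino acid change. Patient counting is per row; variant
counting is per distinct cDNA change.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .hgvs import CONSEQUENCES, HgvsParseError, parse_protein_change

__all__ = [
    "VariantRecord",
    "MutationProfile",
    "VariantTableError",
    "load_variant_table",
    "write_variant_table",
    "summarize_variant_classes",
    "residue_patient_counts",
    "POINT_CLASSES",
]

REQUIRED_COLUMNS = ("gene", "residue", "cdna", "protein_change", "n_patients", "source")

#: Consequence classes that carry a residue position and enter every
#: downstream statistic. Splice variants never do.
POINT_CLASSES = frozenset(
    {"missense", "nonsense", "frameshift", "start_loss", "inframe_dup"}
)


class VariantTableError(ValueError):
    """Raised when a variant table fails validation; lists offending rows."""


@dataclass(frozen=True)
class VariantRecord:
    """One parsed table row: a protein-level variant with its patient count."""

    gene: str
    residue_position: int
    cdna_changes: tuple[str, ...]
    protein_change: str
    consequence: str
    ref_aa: Optional[str]
    alt_aa: Optional[str]
    n_patients: int
    sources: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if self.consequence != "splice" and self.residue_position < 1:
            raise ValueError("residue_position must be >= 1")
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        if self.consequence == "missense" and (
            self.ref_aa is None or self.alt_aa is None or self.ref_aa == self.alt_aa
        ):
            raise ValueError(
                "missense record requires distinct ref and alt amino acids"
            )


@dataclass
class MutationProfile:
    """Per-residue patient events for one protein.

    ``events`` holds one 1-based residue position per patient (a multiset
    stored sorted), so hotspots appear as runs of equal positions.
    """

    gene: str
    protein_length: int
    events: np.ndarray
    class_filter: frozenset[str] = field(default_factory=lambda: POINT_CLASSES)

    def __post_init__(self) -> None:
        self.events = np.sort(np.asarray(self.events, dtype=int))
        if self.protein_length < 1:
            raise ValueError("protein_length must be positive")
        if self.events.size and (
            self.events[0] < 1 or self.events[-1] > self.protein_length
        ):
            raise ValueError("event positions must lie in [1, protein_length]")

    @property
    def n_events(self) -> int:
        return int(self.events.size)

    def counts(self) -> dict[int, int]:
        """Mapping residue -> number of patient events at that residue."""
        positions, n = np.unique(self.events, return_counts=True)
        return dict(zip(positions.tolist(), n.tolist()))


_CDNA_POS = re.compile(r"^c?\.?\s*(\d+)")


def _split_cdna_cell(cell: str) -> tuple[str, ...]:
    """Split a cDNA cell into descriptors; several are space separated.

    Source tables occasionally print a stray space inside one descriptor
    ("c. 245T>A"), so a dangling "c."/"c" token is re-joined with the token
    that follows it.
    """
    tokens = [t for t in cell.split(" ") if t]
    out: list[str] = []
    for token in tokens:
        if out and out[-1].rstrip(".").lower() == "c":
            out[-1] += token
        else:
            out.append(token)
    return tuple(out)


def _cdna_first_position(descriptor: str) -> Optional[int]:
    m = _CDNA_POS.match(descriptor.strip())
    return int(m.group(1)) if m else None


def load_variant_table(
    path: str | Path, gene_config: Mapping[str, object]
) -> list[VariantRecord]:
    """Load and validate a variant TSV against a gene configuration.

    ``gene_config`` supplies ``gene`` and ``protein_length``. Rows whose cDNA
    cell holds several descriptors yield a single record with several
    ``cdna_changes``. Positional inconsistencies between the cDNA and protein
    descriptors (present verbatim in some source tables) raise a warning, not
    an error.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise VariantTableError(f"missing required column(s): {', '.join(missing)}")

    length = int(gene_config["protein_length"])
    gene = str(gene_config["gene"])
    records: list[VariantRecord] = []
    problems: list[str] = []
    seen: set[tuple] = set()

    for idx, row in frame.iterrows():
        line = idx + 2  # 1-based, after header
        try:
            change = parse_protein_change(row["protein_change"])
        except HgvsParseError as exc:
            problems.append(f"line {line}: {exc}")
            continue
        cdna = _split_cdna_cell(str(row["cdna"]))
        sources = tuple(s.strip() for s in str(row["source"]).split(";") if s.strip())
        n_patients = int(row["n_patients"])
        if n_patients < 1:
            problems.append(f"line {line}: n_patients must be >= 1 in a fixture table")
            continue
        if change.consequence != "splice" and not (1 <= change.position <= length):
            problems.append(
                f"line {line}: residue {change.position} outside [1, {length}]"
            )
            continue
        key = (row["gene"], row["protein_change"].strip(), cdna)
        if key in seen:
            problems.append(f"line {line}: duplicate row for {key}")
            continue
        seen.add(key)
        if row["gene"] != gene:
            problems.append(
                f"line {line}: gene {row['gene']!r} does not match config {gene!r}"
            )
            continue
        for descriptor in cdna:
            pos = _cdna_first_position(descriptor)
            if pos is not None and change.consequence in ("missense", "nonsense"):
                implied = (pos - 1) // 3 + 1
                if implied != change.position:
                    warnings.warn(
                        f"{row['protein_change']}: cDNA {descriptor} implies residue "
                        f"{implied}, table says {change.position} (kept verbatim)",
                        stacklevel=2,
                    )
        records.append(
            VariantRecord(
                gene=gene,
                residue_position=change.position,
                cdna_changes=cdna,
                protein_change=row["protein_change"].strip(),
                consequence=change.consequence,
                ref_aa=change.ref_aa,
                alt_aa=change.alt_aa,
                n_patients=n_patients,
                sources=sources,
            )
        )

    if problems:
        raise VariantTableError(
            "variant table failed validation:\n  " + "\n  ".join(problems)
        )
    return records


def write_variant_table(records: Iterable[VariantRecord], path: str | Path) -> None:
    """Write records back to the TSV dialect `load_variant_table` reads."""
    rows = [
        {
            "gene": r.gene,
            "residue": r.residue_position,
            "cdna": " ".join(r.cdna_changes),
            "protein_change": r.protein_change,
            "n_patients": r.n_patients,
            "source": ";".join(r.sources),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def summarize_variant_classes(records: Sequence[VariantRecord]) -> dict[str, int]:
    """Count variants per consequence class at nucleotide granularity.

    A record with k cDNA descriptors contributes k to its class count, so an
    amino acid change reachable by two distinct nucleotide substitutions counts
    twice; patient counts are untouched.
    """
    counts: Counter[str] = Counter()
    for record in records:
        counts[record.consequence] += max(len(record.cdna_changes), 1)
    return {c: counts.get(c, 0) for c in CONSEQUENCES if counts.get(c, 0) > 0} or {
        c: 0 for c in CONSEQUENCES
    }


def residue_patient_counts(
    records: Sequence[VariantRecord],
    protein_length: int,
    class_filter: Iterable[str] = POINT_CLASSES,
    gene: str = "",
) -> tuple[MutationProfile, dict[int, int]]:
    """Aggregate patient counts per residue into a mutation profile.

    The count at residue r is the sum of ``n_patients`` over included records
    anchored at r. Splice records never contribute, whatever the filter.
    """
    included = frozenset(class_filter) - {"splice"}
    unknown = included - set(CONSEQUENCES)
    if unknown:
        raise ValueError(f"unknown consequence class(es): {sorted(unknown)}")
    events: list[int] = []
    for record in records:
        if record.consequence in included:
            events.extend([record.residue_position] * record.n_patients)
    gene = gene or (records[0].gene if records else "")
    profile = MutationProfile(
        gene=gene,
        protein_length=protein_length,
        events=np.asarray(events, dtype=int),
        class_filter=included,
    )
    return profile, profile.counts()
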