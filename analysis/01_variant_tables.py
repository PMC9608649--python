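#!/usr/bin/env python
"""Load the curated CK2α/CK2β variant tables; tally classes and hotspots.

Writes per-gene class tallies and per-residue patient counts (the data behind
the mutation histograms) to results/.
"""

import warnings
from pathlib import Path

import pandas as pd

import mutclust as mc
from mutclust.data import fixture_path, load_gene_config

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)


def run(gene_key: str, label: str) -> None:
    cfg = load_gene_config(gene_key)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # known verbatim typos in the source tables
        records = mc.load_variant_table(fixture_path(f"{gene_key}_variants.tsv"), cfg)
    patients = sum(r.n_patients for r in records)
    classes = mc.summarize_variant_classes(records)
    print(f"{label}: {len(records)} table rows, {patients} patients")
    print(f"  nucleotide-level class tallies: {classes}")

    _, by_residue = mc.residue_patient_counts(records, cfg["protein_length"])
    hist = pd.DataFrame(sorted(by_residue.items()), columns=["residue", "n_patients"])
    hist.to_csv(RESULTS / f"{gene_key}_residue_counts.tsv", sep="\t", index=False)
    top = hist.nlargest(3, "n_patients")
    print(f"  busiest residues: "
          + ", ".join(f"{r.residue} ({r.n_patients} patients)" for r in top.itertuples()))
    pd.Series(classes).rename("n").to_csv(RESULTS / f"{gene_key}_class_tallies.tsv", sep="\t")


if __name__ == "__main__":
    run("csnk2a1", "CK2a (CSNK2A1, 391 aa)")
    run("csnk2b", "CK2b (CSNK2B, 215 aa)")
    print("wrote results/<gene>_residue_counts.tsv and _class_tallies.tsv")
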