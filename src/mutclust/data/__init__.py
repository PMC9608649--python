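"""Packaged fixtures: curated CK2α/CK2β variant tables and domain configs."""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

__all__ = ["fixture_path", "load_gene_config", "CK2A", "CK2B"]

CK2A = "csnk2a1"
CK2B = "csnk2b"


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged data file."""
    return Path(resources.files(__package__).joinpath(name))


def load_gene_config(gene: str) -> dict:
    """Gene configuration ({gene, uniprot_accession, protein_length}) by key."""
    with open(fixture_path(f"{gene}_gene.json")) as fh:
        return json.load(fh)
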