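"""Lenient parser for HGVS-style protein change descriptors.

Published OCNDS/POBINDS variant tables mix notation dialects freely: one- and
three-letter amino acid codes, ``Ter``/``*`` for stop codons, ``fs*``/``fsTer``
for frameshifts, and inconsistent ``p.``/``P.`` prefixes with stray whitespace.
This module normalises all of them to a single tuple
``(consequence, position, ref_aa, alt_aa)``.
"""

from __future__ import annotations

import re
from typing import NamedTuple, Optional

from Bio.SeqUtils import IUPACData

__all__ = [
    "CONSEQUENCES",
    "HgvsParseError",
    "ProteinChange",
    "parse_protein_change",
]

#: Recognised consequence classes, in no particular order.
CONSEQUENCES = (
    "missense",
    "nonsense",
    "frameshift",
    "start_loss",
    "inframe_dup",
    "splice",
    "other",
)

_THREE_TO_ONE = {k.upper(): v for k, v in IUPACData.protein_letters_3to1.items()}
_ONE_LETTERS = set(IUPACData.protein_letters)


class HgvsParseError(ValueError):
    """Raised when a protein-change descriptor cannot be interpreted."""


class ProteinChange(NamedTuple):
    consequence: str
    position: int
    ref_aa: Optional[str]
    alt_aa: Optional[str]


def _aa1(token: str, context: str) -> str:
    """Convert a one- or three-letter amino acid token to its one-letter code."""
    token = token.strip()
    if len(token) == 1:
        aa = token.upper()
        if aa not in _ONE_LETTERS:
            raise HgvsParseError(
                f"unknown amino acid code {token!r} in {context!r}"
            )
        return aa
    aa = _THREE_TO_ONE.get(token.upper())
    if aa is None:
        raise HgvsParseError(f"unknown amino acid code {token!r} in {context!r}")
    return aa


# Amino acid token: three letters, or a single one-letter code.
_AA = r"(?:[A-Za-z]{3}|[A-Z])"
_PREFIX = re.compile(r"^[pP]\.\s*")

_RE_START_LOSS = re.compile(rf"^({_AA})1\?$")
_RE_DUP = re.compile(rf"^({_AA})(\d+)(?:_({_AA})(\d+))?dup$")
_RE_FRAMESHIFT = re.compile(
    rf"^({_AA})(\d+)({_AA})?fs(?:(?:\*|[Tt]er)(\d+)?)?$"
)
_RE_SUBSTITUTION = re.compile(rf"^({_AA})(\d+)(\*|[Tt]er|{_AA})$")


def parse_protein_change(text: str) -> ProteinChange:
    """Parse a protein-change descriptor into its consequence and coordinates.

    Returns the anchored (first affected) residue position. Duplications are
    anchored at the first residue of the duplicated span; stop-gain, frameshift
    and start-loss changes carry no alternate amino acid.

    Raises
    ------
    HgvsParseError
        If the descriptor (or any amino acid token inside it) is not
        recognisable; the message names the offending token.
    """
    if not isinstance(text, str) or not text.strip():
        raise HgvsParseError("empty protein-change descriptor")
    raw = text.strip()
    body = _PREFIX.sub("", raw)

    m = _RE_START_LOSS.match(body)
    if m:
        ref = _aa1(m.group(1), raw)
        if ref != "M":
            raise HgvsParseError(f"start-loss descriptor {raw!r} must begin at Met")
        return ProteinChange("start_loss", 1, "M", None)

    m = _RE_DUP.match(body)
    if m:
        ref = _aa1(m.group(1), raw)
        pos = int(m.group(2))
        if m.group(4) is not None and int(m.group(4)) < pos:
            raise HgvsParseError(f"inverted duplication span in {raw!r}")
        return ProteinChange("inframe_dup", pos, ref, None)

    m = _RE_FRAMESHIFT.match(body)
    if m:
        ref = _aa1(m.group(1), raw)
        return ProteinChange("frameshift", int(m.group(2)), ref, None)

    m = _RE_SUBSTITUTION.match(body)
    if m:
        ref = _aa1(m.group(1), raw)
        pos = int(m.group(2))
        alt_token = m.group(3)
        if alt_token == "*" or alt_token.upper() == "TER":
            return ProteinChange("nonsense", pos, ref, None)
        alt = _aa1(alt_token, raw)
        if alt == ref:
            raise HgvsParseError(
                f"synonymous substitution {raw!r} is not a missense change"
            )
        return ProteinChange("missense", pos, ref, alt)

    raise HgvsParseError(f"unparseable protein-change descriptor {raw!r}")
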