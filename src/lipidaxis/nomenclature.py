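"""Lipid shorthand nomenclature: parsing, totals, and molecular geometry.

Lipid species exported by LipidSearch-style software carry shorthand names
such as ``DG(22:6/22:6)`` (subclass token followed by per-chain
``carbons:double_bonds`` specs) or sum-composition forms like ``PC(34:2)``
that only give totals. This module parses both dialects into a structured
:class:`LipidAnnotation` and classifies subclasses by molecular geometry
(cone / cylinder / inverted cone), which governs membrane curvature.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

__all__ = [
    "SUBCLASSES",
    "Chain",
    "LipidAnnotation",
    "LipidParseError",
    "parse_lipid_name",
    "format_lipid_name",
    "geometry_class",
]

#: Controlled vocabulary of supported subclass tokens (case-sensitive).
SUBCLASSES: frozenset[str] = frozenset(
    {
        "PC", "PE", "Cer", "LPE", "PA", "PG", "PI", "PS", "SM", "DG",
        "LPC", "So", "TG", "GM1", "LPA", "LPI", "LPG", "MG",
    }
)

#: Number of fatty-acyl (or long-chain base) chains a fully resolved
#: molecular species of each subclass carries.
EXPECTED_CHAINS: dict[str, int] = {
    "PC": 2, "PE": 2, "Cer": 2, "PA": 2, "PG": 2, "PI": 2, "PS": 2,
    "SM": 2, "DG": 2, "TG": 3, "MG": 1, "GM1": 2,
    "LPC": 1, "LPE": 1, "LPA": 1, "LPI": 1, "LPG": 1, "So": 1,
}

#: Subclasses annotated at class level only (no chain math); any chain
#: detail in the name is collapsed into the species totals.
TOTALS_ONLY: frozenset[str] = frozenset({"GM1"})

#: Molecular geometry by head-to-tail size ratio. Small head with two or
#: more tails packs as a cone; large head with two tails as a cylinder;
#: large head with a single tail as an inverted cone. Subclasses without
#: an established assignment are left unclassified.
GEOMETRY: dict[str, str] = {
    "DG": "cone", "PA": "cone", "TG": "cone",
    "PC": "cylinder", "PI": "cylinder",
    "LPI": "inverted_cone", "LPC": "inverted_cone",
}

_CHAIN_RE = re.compile(r"^(?P<prefix>[OP]-)?(?P<c>\d+):(?P<d>\d+)(?P<suffix>[ep])?$")
_HEAD_RE = re.compile(r"^\s*(?P<token>[A-Za-z][A-Za-z0-9]*)\s*\(")

_LINKAGE_BY_MARK = {"O-": "ether_o", "P-": "ether_p", "e": "ether_o", "p": "ether_p"}


class LipidParseError(ValueError):
    """Raised when a lipid shorthand name cannot be parsed."""


@dataclass(frozen=True)
class Chain:
    """One fatty-acyl chain: carbon count, double bonds, and linkage."""

    carbons: int
    double_bonds: int
    linkage: str = "ester"  # ester | ether_o | ether_p

    def __post_init__(self) -> None:
        if self.carbons < 0 or self.double_bonds < 0:
            raise ValueError("chain carbons and double bonds must be >= 0")
        if self.linkage not in ("ester", "ether_o", "ether_p"):
            raise ValueError(f"unknown linkage {self.linkage!r}")


@dataclass(frozen=True)
class LipidAnnotation:
    """Parsed structure of one lipid species.

    ``level`` is ``molecular_species`` when individual chains are resolved
    and ``species_total`` when the name only encodes summed composition
    (in which case a single pseudo-chain holds the totals).
    """

    raw_name: str
    subclass: str
    chains: tuple[Chain, ...]
    level: str  # species_total | molecular_species

    @property
    def total_carbons(self) -> int:
        return sum(c.carbons for c in self.chains)

    @property
    def total_double_bonds(self) -> int:
        return sum(c.double_bonds for c in self.chains)


def _parse_chain(spec: str, offset: int) -> Chain:
    spec = spec.strip()
    m = _CHAIN_RE.match(spec)
    if m is None:
        raise LipidParseError(
            f"malformed chain spec {spec!r} at position {offset}: "
            "expected '<carbons>:<double_bonds>' with optional O-/P- prefix "
            "or e/p suffix"
        )
    linkage = "ester"
    if m.group("prefix"):
        linkage = _LINKAGE_BY_MARK[m.group("prefix")]
    elif m.group("suffix"):
        linkage = _LINKAGE_BY_MARK[m.group("suffix")]
    return Chain(int(m.group("c")), int(m.group("d")), linkage)


def parse_lipid_name(name: str, vocabulary: Iterable[str] | None = None) -> LipidAnnotation:
    """Parse a shorthand lipid name into a :class:`LipidAnnotation`.

    Accepts sn-resolved (``/``) and unresolved (``_``) chain separators,
    optional whitespace after the subclass token, sum-composition forms,
    and ether/plasmalogen chain marks (``O-``/``P-`` prefixes or ``e``/``p``
    suffixes).

    Parameters
    ----------
    name:
        Shorthand name, e.g. ``"DG(22:6/22:6)"`` or ``"PC(34:2)"``.
    vocabulary:
        Optional replacement subclass vocabulary (defaults to
        :data:`SUBCLASSES`).

    Raises
    ------
    LipidParseError
        On an unknown subclass token or a malformed chain spec (message
        carries the character position of the offending chunk).
    """
    vocab = frozenset(vocabulary) if vocabulary is not None else SUBCLASSES
    if not name or not name.strip():
        raise LipidParseError("empty lipid name")
    stripped = name.strip()
    m = _HEAD_RE.match(stripped)
    if m is None:
        raise LipidParseError(
            f"cannot locate subclass token and '(' in {stripped!r}"
        )
    token = m.group("token")
    if token not in vocab:
        raise LipidParseError(f"unknown subclass {token!r} in {stripped!r}")
    if not stripped.endswith(")"):
        raise LipidParseError(f"missing closing ')' in {stripped!r}")
    inner = stripped[m.end():-1]
    if not inner.strip():
        raise LipidParseError(f"empty chain specification in {stripped!r}")

    parts = re.split(r"[/_]", inner)
    chains = []
    offset = m.end()
    for part in parts:
        chains.append(_parse_chain(part, offset))
        offset += len(part) + 1

    expected = EXPECTED_CHAINS.get(token, 2)
    if token in TOTALS_ONLY:
        level = "species_total"
        chains = [
            Chain(
                sum(c.carbons for c in chains),
                sum(c.double_bonds for c in chains),
            )
        ]
    elif len(chains) == 1 and expected > 1:
        level = "species_total"
    else:
        level = "molecular_species"
    return LipidAnnotation(stripped, token, tuple(chains), level)


def format_lipid_name(annotation: LipidAnnotation, separator: str = "/") -> str:
    """Render an annotation back into shorthand form.

    Molecular species round-trip through :func:`parse_lipid_name`;
    ``species_total`` annotations render as sum compositions.
    """
    if annotation.level == "species_total":
        return (
            f"{annotation.subclass}"
            f"({annotation.total_carbons}:{annotation.total_double_bonds})"
        )
    marks = {"ester": "", "ether_o": "O-", "ether_p": "P-"}
    body = separator.join(
        f"{marks[c.linkage]}{c.carbons}:{c.double_bonds}" for c in annotation.chains
    )
    return f"{annotation.subclass}({body})"


def geometry_class(subclass: str) -> str:
    """Molecular geometry of a lipid subclass.

    Returns one of ``cone``, ``cylinder``, ``inverted_cone`` or
    ``unclassified``; the mapping is total over any input.
    """
    return GEOMETRY.get(subclass, "unclassified")
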