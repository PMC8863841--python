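"""Small set-overlap and composition utilities.

Used to express statements like "the majority of altered viruses belong
to one order" or "two-thirds of a subclass's species are shared across
brain regions" as reproducible computations on explicit sets.
"""

from __future__ import annotations

from typing import Collection, Hashable

__all__ = ["shared_species", "proportion_percent", "member_percent"]


def shared_species(a: Collection[Hashable], b: Collection[Hashable]) -> set:
    """Species present in both collections."""
    return set(a) & set(b)


def proportion_percent(numerator: int, denominator: int) -> float:
    """``100 * numerator / denominator`` with domain checks."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator < 0 or numerator > denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    return 100.0 * numerator / denominator


def member_percent(members: Collection[Hashable], universe: Collection[Hashable]) -> float:
    """Percentage of ``universe`` items that belong to ``members``."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    return proportion_percent(len(set(members) & universe), len(universe))
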