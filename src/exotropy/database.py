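"""Ligand–receptor interaction database container.

Schema follows CellChatDB-style catalogues: each interaction pairs a ligand
with a receptor, and either side may be a multimeric complex encoded as an
ordered tuple of gene-encoded subunits (written ``"ITGAV+ITGB3"`` on disk).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from exotropy.exceptions import ParseError

SUBUNIT_SEP = "+"


def parse_subunits(cell: str, pair_id: str = "?") -> tuple[str, ...]:
    """Split a '+'-joined subunit cell into a normalized gene tuple."""
    parts = tuple(p.strip().upper() for p in str(cell).split(SUBUNIT_SEP))
    if not parts or any(p == "" for p in parts):
        raise ParseError(
            f"malformed subunit list {cell!r} in pair {pair_id!r}"
        )
    return parts


def format_subunits(subunits: tuple[str, ...]) -> str:
    return SUBUNIT_SEP.join(subunits)


@dataclass(frozen=True)
class LRPair:
    """One ligand–receptor interaction, possibly multimeric on either side."""

    pair_id: str
    ligand_subunits: tuple[str, ...]
    receptor_subunits: tuple[str, ...]

    @property
    def ligand_id(self) -> str:
        return format_subunits(self.ligand_subunits)

    @property
    def receptor_id(self) -> str:
        return format_subunits(self.receptor_subunits)


@dataclass
class LRDatabase:
    """Catalogue of ligand–receptor pairs with convenience gene-set views."""

    pairs: list[LRPair] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for p in self.pairs:
            if p.pair_id in seen:
                raise ParseError(f"duplicate pair id {p.pair_id!r}")
            seen.add(p.pair_id)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    @property
    def receptor_units(self) -> set[tuple[str, ...]]:
        """Distinct receptor sides (subunit tuples)."""
        return {p.receptor_subunits for p in self.pairs}

    @property
    def receptor_genes(self) -> set[str]:
        """Union of all receptor subunit genes."""
        return {g for p in self.pairs for g in p.receptor_subunits}

    @property
    def ligand_units(self) -> set[tuple[str, ...]]:
        return {p.ligand_subunits for p in self.pairs}

    @property
    def ligand_genes(self) -> set[str]:
        return {g for p in self.pairs for g in p.ligand_subunits}
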