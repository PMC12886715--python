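"""Membrane-localization filter and receptor-side intersection.

The commonly up-regulated exosomal protein set is reduced to
membrane-annotated genes, then intersected with the receptor side of the
ligand–receptor database. A multimeric receptor complex counts as a
candidate when at least one subunit is present in the membrane set; the
``complete`` flag records whether every subunit was detected (a complex
with an undetected subunit — the ITGA2B case — is retained, not
discarded).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

from exotropy.database import LRDatabase, format_subunits

logger = logging.getLogger(__name__)


def normalize_symbol(gene: str) -> str:
    """Gene-symbol normalization: trim and uppercase (no alias mapping)."""
    return str(gene).strip().upper()


def filter_membrane(genes: Iterable[str], annotation: Mapping[str, bool]) -> set[str]:
    """Subset of ``genes`` annotated as membrane-localized.

    Genes absent from the annotation are dropped with a warning (absence
    of an annotation is not an error).
    """
    norm_annotation = {normalize_symbol(g): bool(v) for g, v in annotation.items()}
    out: set[str] = set()
    unannotated = []
    for gene in genes:
        g = normalize_symbol(gene)
        if g not in norm_annotation:
            unannotated.append(g)
        elif norm_annotation[g]:
            out.add(g)
    if unannotated:
        logger.warning(
            "%d gene(s) absent from the membrane annotation were dropped: %s",
            len(unannotated),
            ", ".join(sorted(unannotated)[:10]),
        )
    return out


@dataclass(frozen=True)
class ReceptorCandidate:
    """A receptor unit supported by membrane-set evidence.

    ``receptor_unit`` is the subunit tuple as catalogued; ``evidence_genes``
    the (non-empty) subset of subunits found in the membrane set;
    ``complete`` whether all subunits were found.
    """

    receptor_unit: tuple[str, ...]
    evidence_genes: frozenset[str]
    complete: bool

    @property
    def receptor_id(self) -> str:
        return format_subunits(self.receptor_unit)


def intersect_receptors(
    membrane_set: Iterable[str], lrdb: LRDatabase
) -> list[ReceptorCandidate]:
    """Receptor units of ``lrdb`` evidenced by the membrane set.

    A monomeric receptor is a candidate iff its gene is in the membrane
    set; a multimeric receptor iff at least one subunit is, with
    ``complete=True`` when all subunits are present. Candidates are
    returned sorted by receptor id for stable output.
    """
    mem = {normalize_symbol(g) for g in membrane_set}
    candidates = []
    for unit in sorted(lrdb.receptor_units):
        evidence = frozenset(g for g in unit if g in mem)
        if evidence:
            candidates.append(
                ReceptorCandidate(
                    receptor_unit=unit,
                    evidence_genes=evidence,
                    complete=len(evidence) == len(unit),
                )
            )
    return candidates
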