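"""Tissue-specific ligand assignment and organ-tropism mapping.

Ligands from the interaction database are assigned to the single tissue in
which their (complex-aggregated) nTPM expression is maximal; genes whose
expression never reaches the nTPM threshold in any tissue are excluded
first. Receptor candidates from the exosomal membrane set are then joined
with tissue-assigned ligands to produce per-organ ligand–receptor edge
lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from exotropy.database import LRDatabase, format_subunits
from exotropy.exceptions import ExotropyError
from exotropy.membrane import ReceptorCandidate

TIE_RTOL = 1e-9

REASON_ASSIGNED = "assigned"
REASON_TIE = "tie"
REASON_BELOW = "below_threshold"
REASON_MISSING = "missing_gene"


def filter_expressed(atlas: pd.DataFrame, min_ntpm: float = 1.0) -> pd.DataFrame:
    """Remove genes whose maximum nTPM across all tissues is below threshold.

    Retained genes keep all tissue values intact; the threshold is
    inclusive (a gene peaking exactly at ``min_ntpm`` is kept).
    """
    if atlas.empty:
        raise ExotropyError("empty tissue atlas")
    keep = atlas.max(axis=1) >= min_ntpm
    return atlas.loc[keep]


def aggregate_multimer(
    atlas: pd.DataFrame, ligand_subunits: tuple[str, ...], rule: str = "min"
) -> pd.Series:
    """Per-tissue expression of a (possibly multimeric) ligand.

    For a complex the per-tissue value is the minimum across subunit rows
    (a complex cannot exceed its limiting subunit); ``rule="mean"`` is
    available as an alternative aggregation. A monomer returns its own
    row.
    """
    if not ligand_subunits:
        raise ExotropyError("empty ligand subunit list")
    missing = [g for g in ligand_subunits if g not in atlas.index]
    if missing:
        raise KeyError(f"subunit(s) absent from atlas: {missing}")
    rows = atlas.loc[list(ligand_subunits)]
    if rule == "min":
        return rows.min(axis=0)
    if rule == "mean":
        return rows.mean(axis=0)
    raise ExotropyError(f"unknown aggregation rule {rule!r}")


@dataclass
class LigandAssignment:
    """Tissue-specificity call for one ligand."""

    ligand_id: str
    subunits: tuple[str, ...]
    expression: pd.Series | None
    assigned_tissue: str | None
    reason: str


@dataclass
class LigandAssignments:
    """All ligand calls plus the atlas tissue vocabulary."""

    assignments: dict[str, LigandAssignment]
    tissues: list[str]

    def __getitem__(self, ligand_id: str) -> LigandAssignment:
        return self.assignments[ligand_id]

    def __iter__(self):
        return iter(self.assignments.values())

    def assigned_to(self, tissue: str) -> list[LigandAssignment]:
        return [a for a in self if a.assigned_tissue == tissue]

    def counts_by_reason(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for a in self:
            out[a.reason] = out.get(a.reason, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lid in sorted(self.assignments):
            a = self.assignments[lid]
            rows.append(
                {
                    "ligand": lid,
                    "subunits": format_subunits(a.subunits),
                    "assigned_tissue": a.assigned_tissue or "",
                    "reason": a.reason,
                    "max_ntpm": float(a.expression.max()) if a.expression is not None else np.nan,
                }
            )
        return pd.DataFrame(rows)


def assign_tissue_specificity(
    atlas: pd.DataFrame,
    lrdb: LRDatabase,
    removed_genes: set[str] | None = None,
    rule: str = "min",
) -> LigandAssignments:
    """Assign every database ligand to its tissue of maximal expression.

    ``atlas`` must already be threshold-filtered (:func:`filter_expressed`).
    A ligand whose maximum is attained in two or more tissues (within
    relative tolerance 1e-9) is a tie and stays unassigned; a ligand with
    a subunit absent from the filtered atlas is ``below_threshold`` when
    the gene was removed by the filter (``removed_genes``) and
    ``missing_gene`` otherwise.
    """
    removed = removed_genes or set()
    tissues = list(atlas.columns)
    assignments: dict[str, LigandAssignment] = {}
    for unit in sorted(lrdb.ligand_units):
        lid = format_subunits(unit)
        if lid in assignments:
            continue
        absent = [g for g in unit if g not in atlas.index]
        if absent:
            reason = REASON_BELOW if any(g in removed for g in absent) else REASON_MISSING
            assignments[lid] = LigandAssignment(lid, unit, None, None, reason)
            continue
        expr = aggregate_multimer(atlas, unit, rule=rule)
        vals = expr.to_numpy(dtype=float)
        order = np.argsort(vals)[::-1]
        top, second = vals[order[0]], vals[order[1]] if len(vals) > 1 else -np.inf
        if len(vals) > 1 and np.isclose(top, second, rtol=TIE_RTOL, atol=0.0):
            assignments[lid] = LigandAssignment(lid, unit, expr, None, REASON_TIE)
        else:
            assignments[lid] = LigandAssignment(
                lid, unit, expr, tissues[order[0]], REASON_ASSIGNED
            )
    return LigandAssignments(assignments=assignments, tissues=tissues)


@dataclass(frozen=True)
class TropismEdge:
    """One organ-specific receptor–ligand interaction with evidence."""

    receptor_unit: tuple[str, ...]
    ligand_id: str
    ligand_tissue_ntpm: float

    @property
    def receptor_id(self) -> str:
        return format_subunits(self.receptor_unit)


@dataclass
class TropismMap:
    """Per-organ ligand–receptor edges inferred for the exosomal receptors."""

    edges: dict[str, list[TropismEdge]] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        return {organ: len(e) for organ, e in self.edges.items()}

    def all_edges(self) -> list[tuple[str, TropismEdge]]:
        return [(organ, e) for organ in self.edges for e in self.edges[organ]]


def _canonical_tissue(organ: str, tissues: list[str]) -> str:
    """Case-insensitive, trimmed organ-name match against atlas tissues."""
    key = organ.strip().lower()
    for t in tissues:
        if t.strip().lower() == key:
            return t
    raise ExotropyError(
        f"unknown organ {organ!r}; valid tissues: {', '.join(sorted(tissues))}"
    )


def map_interactions(
    receptor_candidates: list[ReceptorCandidate],
    assignment: LigandAssignments,
    lrdb: LRDatabase,
    organs: list[str],
) -> TropismMap:
    """Organ-specific edges: candidate receptor x ligand assigned to organ.

    For each requested organ the edges are all database pairs whose
    receptor side is an evidenced candidate and whose ligand is assigned
    to that organ; the edge carries the ligand's aggregated nTPM in the
    organ.
    """
    candidate_units = {c.receptor_unit for c in receptor_candidates}
    tmap = TropismMap(edges={})
    for organ in organs:
        tissue = _canonical_tissue(organ, assignment.tissues)
        edges = []
        for pair in lrdb:
            if pair.receptor_subunits not in candidate_units:
                continue
            a = assignment.assignments.get(pair.ligand_id)
            if a is None or a.assigned_tissue != tissue:
                continue
            edges.append(
                TropismEdge(
                    receptor_unit=pair.receptor_subunits,
                    ligand_id=pair.ligand_id,
                    ligand_tissue_ntpm=float(a.expression[tissue]),
                )
            )
        tmap.edges[organ] = edges
    return tmap


def export_edges(tropism_map: TropismMap, path: str | Path) -> Path:
    """Write the edge list as a lexicographically sorted, byte-stable TSV."""
    rows = [
        (organ, e.receptor_id, e.ligand_id, f"{e.ligand_tissue_ntpm:.6g}")
        for organ, e in tropism_map.all_edges()
    ]
    rows.sort()
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("organ\treceptor\tligand\tligand_tissue_ntpm\n")
        for r in rows:
            fh.write("\t".join(r) + "\n")
    return path
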