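"""End-to-end pipeline: differential abundance -> membrane/receptor filter
-> organ-tropism mapping, plus the biomarker panel, driven by a run
configuration and producing a machine-readable manifest."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

import exotropy
from exotropy import io as eio
from exotropy.diffabund import log2_transform, diff_test, significant_sets, common_altered
from exotropy.exceptions import ConfigError
from exotropy.membrane import filter_membrane, intersect_receptors
from exotropy.panel import (
    roc_auc,
    fit_logistic_panel,
    normalize_per_particle,
    validate_panel,
)
from exotropy.tropism import (
    assign_tissue_specificity,
    export_edges,
    filter_expressed,
    map_interactions,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths, thresholds and panel settings for one pipeline run."""

    intensity_path: str
    group_map_path: str
    annotation_path: str
    lrdb_path: str
    atlas_path: str
    outdir: str
    cohort_path: str | None = None
    parental_group: str = "parental"
    fc_threshold: float = 2.0
    p_threshold: float = 0.05
    min_ntpm: float = 1.0
    organs: list[str] = field(default_factory=lambda: ["brain", "liver"])
    markers: list[str] = field(default_factory=lambda: ["ITGB3", "L1CAM"])
    positive_label: str = "stage4_BrM"
    cv_folds: int = 5
    n_boot: int = 2000
    seed: int = 0

    def __post_init__(self):
        if self.fc_threshold <= 1:
            raise ConfigError("fc_threshold must be > 1")
        if self.p_threshold <= 0 or self.min_ntpm < 0:
            raise ConfigError("thresholds must be positive")
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be an integer")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def to_jsonable(self) -> dict:
        return dataclasses.asdict(self)

    def validate_paths(self) -> None:
        paths = [self.intensity_path, self.group_map_path, self.annotation_path,
                 self.lrdb_path, self.atlas_path]
        if self.cohort_path:
            paths.append(self.cohort_path)
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise ConfigError(f"missing input path(s): {missing}")


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write the result bundle plus manifest.

    Returns the manifest dictionary. Outputs (all under ``config.outdir``):
    ``altered_sets.json``, ``receptor_candidates.tsv``,
    ``ligand_assignment.tsv``, ``tropism_edges.tsv``, ``tropism_counts.json``,
    ``panel.json`` (if a cohort is given) and ``manifest.json``. Rerunning
    with the same configuration and inputs is byte-identical.
    """
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_jsonable(),
        "version": exotropy.__version__,
        "stages": {},
    }

    # differential abundance
    matrix = eio.read_intensity_matrix(config.intensity_path, config.group_map_path)
    log2m = log2_transform(matrix)
    groups = [g for g in log2m.group_names if g != config.parental_group]
    if config.parental_group not in log2m.group_names:
        raise ConfigError(f"parental group {config.parental_group!r} not in group map")
    sets = {}
    for g in groups:
        result = diff_test(log2m, config.parental_group, g)
        sets[g] = significant_sets(
            result, fc_threshold=config.fc_threshold, p_threshold=config.p_threshold
        )
        logger.info(
            "diff %s vs %s: %d up, %d down",
            g, config.parental_group, len(sets[g][0]), len(sets[g][1]),
        )
    altered = common_altered(sets)
    _dump_json(altered.to_jsonable(), outdir / "altered_sets.json")
    manifest["stages"]["differential_abundance"] = {
        "n_proteins": len(log2m.proteins),
        "n_samples": len(log2m.samples),
        "common_up": len(altered.common_up),
        "common_down": len(altered.common_down),
    }

    # membrane + receptor intersection
    annotation = eio.annotation_to_mapping(eio.read_annotation(config.annotation_path))
    membrane_set = filter_membrane(altered.common_up, annotation)
    lrdb = eio.read_lr_database(config.lrdb_path)
    candidates = intersect_receptors(membrane_set, lrdb)
    cand_rows = "\n".join(
        f"{c.receptor_id}\t{'+'.join(sorted(c.evidence_genes))}\t{str(c.complete).lower()}"
        for c in candidates
    )
    (outdir / "receptor_candidates.tsv").write_text(
        "receptor\tevidence_genes\tcomplete\n" + (cand_rows + "\n" if cand_rows else "")
    )
    manifest["stages"]["membrane_receptor_filter"] = {
        "membrane_genes": len(membrane_set),
        "receptor_candidates": len(candidates),
    }

    # tropism
    atlas = eio.read_tissue_atlas(config.atlas_path)
    filtered = filter_expressed(atlas, min_ntpm=config.min_ntpm)
    removed = set(atlas.index) - set(filtered.index)
    logger.info("nTPM filter removed %d of %d genes", len(removed), len(atlas))
    assignment = assign_tissue_specificity(filtered, lrdb, removed_genes=removed)
    assignment.to_frame().to_csv(
        outdir / "ligand_assignment.tsv", sep="\t", index=False, float_format="%.6g"
    )
    tmap = map_interactions(candidates, assignment, lrdb, config.organs)
    export_edges(tmap, outdir / "tropism_edges.tsv")
    _dump_json(tmap.counts, outdir / "tropism_counts.json")
    manifest["stages"]["tropism_inference"] = {
        "atlas_genes": len(atlas),
        "atlas_genes_expressed": len(filtered),
        "ligand_reasons": assignment.counts_by_reason(),
        "edge_counts": tmap.counts,
    }

    # biomarker panel
    if config.cohort_path:
        cohort = eio.read_cohort(config.cohort_path, markers=config.markers)
        panel_out: dict = {}
        pos = config.positive_label
        other_groups = [g for g in dict.fromkeys(cohort["group"]) if g != pos]
        for g in other_groups:
            sub = cohort[cohort["group"].isin([g, pos])].reset_index(drop=True)
            comp: dict = {}
            sub = normalize_per_particle(sub, config.markers)
            for mk in config.markers:
                r = roc_auc(
                    sub[mk + "_per_particle"].to_numpy(),
                    sub["group"].to_numpy(),
                    pos,
                    n_boot=config.n_boot,
                    seed=config.seed,
                )
                comp[mk] = {k: v for k, v in r.to_jsonable().items()
                            if k not in ("fpr", "tpr")}
            res = fit_logistic_panel(sub, config.markers, pos)
            r = res.roc(n_boot=config.n_boot, seed=config.seed)
            comp["combined"] = {k: v for k, v in r.to_jsonable().items()
                                if k not in ("fpr", "tpr")}
            comp["validation"] = validate_panel(
                sub, config.markers, pos,
                k=config.cv_folds, n_boot=config.n_boot, seed=config.seed,
            ).to_jsonable()
            del comp["validation"]["seed"]  # already in config
            panel_out[f"{g}_vs_{pos}"] = comp
        _dump_json(panel_out, outdir / "panel.json")
        manifest["stages"]["biomarker_panel"] = {
            "n_patients": len(cohort),
            "comparisons": sorted(panel_out),
        }

    _dump_json(manifest, outdir / "manifest.json")
    return manifest
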