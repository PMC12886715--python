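"""Synthetic pipeline inputs with planted, machine-readable ground truth.

Emulates the five measured inputs of the organotropism/biomarker chain:

* a label-free exosome proteomics intensity matrix (parental line plus
  EMT-resistant lines, replicated), with planted up/down-regulated
  proteins — some concordant across all resistant lines, some
  line-specific;
* a CellChatDB-style ligand–receptor pair catalogue with monomeric and
  multimeric sides, in which a configurable number of organ-specific
  pairs have their receptor planted among the concordantly up-regulated
  membrane proteins;
* an HPA-consensus-style gene x tissue nTPM atlas in which planted
  organ-pair ligands peak strictly in their designated tissue and a
  configurable fraction of background genes falls below the nTPM
  exclusion threshold;
* a gene -> membrane-localization annotation table;
* a patient serum cohort whose per-particle marker loads follow a
  correlated binormal model calibrated to target AUCs
  (mean shift delta = sqrt(2) * Phi^{-1}(AUC)).

One integer seed drives every sub-generator through independently spawned
streams, so the full fixture set is reproducible from a single number.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from exotropy.database import LRDatabase, LRPair
from exotropy.diffabund import IntensityMatrix
from exotropy.exceptions import ConfigError

# stream indices for SeedSequence.spawn — fixed so each generator is
# reproducible when called on its own
_STREAM_PROTEOMICS = 0
_STREAM_LRDB = 1
_STREAM_ATLAS = 2
_STREAM_COHORT = 3

_SAFE_TISSUE_PREFIX = "tissue"


def _default_organ_pairs() -> dict[str, int]:
    # three receptors against five brain-specific and four liver-specific
    # ligands is the funnel shape the pipeline is built to resolve
    return {"brain": 5, "liver": 4}


def _default_cohort_sizes() -> dict[str, int]:
    return {"stage1": 27, "stage4_nonBrM": 27, "stage4_BrM": 27}


def _default_marker_auc() -> dict[str, float]:
    return {"ITGB3": 0.80, "L1CAM": 0.73}


@dataclass
class SimulationConfig:
    """All knobs of the five synthetic inputs, with study-scale defaults.

    Proteomics: ``n_groups`` counts parental plus resistant lines;
    ``planted_common`` proteins are altered concordantly in every
    resistant line (half up, half down), while ``planted_up`` /
    ``planted_down`` are additionally altered in exactly one line each.
    ``effect_log2fc`` is the planted shift in log2 units (>= 1 keeps the
    plant detectable at a two-fold threshold); ``noise_sd_log2`` the
    replicate noise; ``missing_rate`` the completely-at-random missingness
    probability.

    Database/atlas: ``planted_organ_pairs`` maps organ -> number of
    tissue-specific ligand–receptor pairs whose receptor is drawn from
    ``n_planted_receptors`` concordantly up-regulated membrane proteins.
    ``fraction_below_1`` of background atlas genes never reach nTPM 1.

    Cohort: per-marker target AUC (brain-metastasis group versus the
    rest) realized as a mean shift delta = sqrt(2) * Phi^{-1}(AUC) on the
    log scale; ``marker_correlation`` couples markers through a Gaussian
    copula before exponentiation; ``particle_marker_dependence`` adds an
    optional dependence of per-particle loads on particle counts
    (0 = independent).
    """

    # proteomics
    n_proteins: int = 1500
    n_replicates_per_group: int = 3
    n_groups: int = 3
    planted_common: int = 744
    planted_up: int = 50
    planted_down: int = 50
    effect_log2fc: float = 2.0
    noise_sd_log2: float = 0.4
    missing_rate: float = 0.1
    base_mean_log2: float = 18.0
    base_sd_log2: float = 2.0
    # ligand-receptor database
    n_ligands: int = 621
    n_receptors: int = 780
    n_pairs: int = 900
    n_multimeric_ligands: int = 12
    n_multimeric_receptors: int = 30
    n_planted_receptors: int = 7
    planted_organ_pairs: dict[str, int] = field(default_factory=_default_organ_pairs)
    # membrane annotation
    membrane_fraction: float = 0.3
    background_membrane_fraction: float = 0.25
    # tissue atlas
    n_tissues: int = 40
    n_atlas_genes: int = 20141
    fraction_below_1: float = 0.1
    ligand_below_threshold_frac: float = 0.02
    ligand_missing_frac: float = 0.01
    # cohort
    cohort_sizes: dict[str, int] = field(default_factory=_default_cohort_sizes)
    positive_group: str = "stage4_BrM"
    marker_target_auc: dict[str, float] = field(default_factory=_default_marker_auc)
    marker_correlation: float = 0.5
    particle_mean_log10: float = 9.5
    particle_sd_log10: float = 0.3
    particle_marker_dependence: float = 0.0
    per_particle_scale: float = 1e-8
    seed: int = 0

    def __post_init__(self):
        if self.n_groups < 2:
            raise ConfigError("n_groups must include parental plus >= 1 resistant line")
        n_resistant = self.n_groups - 1
        planted_total = self.planted_common + n_resistant * (
            self.planted_up + self.planted_down
        )
        if planted_total > self.n_proteins:
            raise ConfigError(
                f"planted proteins ({planted_total}) exceed n_proteins ({self.n_proteins})"
            )
        for name in ("missing_rate", "membrane_fraction", "background_membrane_fraction",
                     "fraction_below_1", "ligand_below_threshold_frac",
                     "ligand_missing_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if not -1.0 <= self.marker_correlation <= 1.0:
            raise ConfigError("marker_correlation must be in [-1, 1]")
        for m, a in self.marker_target_auc.items():
            if not 0.5 <= a < 1.0:
                raise ConfigError(
                    f"marker_target_auc[{m!r}] must be in [0.5, 1), got {a}"
                )
        if self.n_tissues < 2:
            raise ConfigError("n_tissues must be >= 2")
        n_planted_pairs = sum(self.planted_organ_pairs.values())
        if self.n_pairs < n_planted_pairs:
            raise ConfigError("n_pairs smaller than the planted organ pairs")
        if n_planted_pairs + self.n_planted_receptors > self.n_ligands:
            raise ConfigError("not enough ligands for planted and decoy pairs")
        if self.n_planted_receptors > self.planted_common // 2:
            raise ConfigError("n_planted_receptors exceeds the planted common-up set")
        if len(self.planted_organ_pairs) > self.n_tissues - 1:
            raise ConfigError("need at least one non-organ tissue for decoy ligands")
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigError("seed must be an integer")

    # -- derived structure (deterministic, no RNG) --------------------------

    @property
    def resistant_lines(self) -> list[str]:
        return [f"resistant{i}" for i in range(1, self.n_groups)]

    @property
    def group_names(self) -> list[str]:
        return ["parental"] + self.resistant_lines

    @property
    def tissue_names(self) -> list[str]:
        organs = list(self.planted_organ_pairs)
        extra = self.n_tissues - len(organs)
        return organs + [f"{_SAFE_TISSUE_PREFIX}{i:02d}" for i in range(1, extra + 1)]

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(4)[stream])

    def to_jsonable(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class GroundTruth:
    """Machine-readable record of everything the generators planted."""

    up_by_line: dict[str, list[str]] = field(default_factory=dict)
    down_by_line: dict[str, list[str]] = field(default_factory=dict)
    common_up: list[str] = field(default_factory=list)
    common_down: list[str] = field(default_factory=list)
    membrane_genes: list[str] = field(default_factory=list)
    planted_receptors: list[str] = field(default_factory=list)
    organ_edges: list[dict] = field(default_factory=list)
    decoy_ligands: list[str] = field(default_factory=list)
    marker_delta: dict[str, float] = field(default_factory=dict)
    marker_theoretical_auc: dict[str, float] = field(default_factory=dict)
    combined_theoretical_auc: float | None = None
    logistic_coefficients: dict[str, float] = field(default_factory=dict)

    def merge(self, other: "GroundTruth") -> "GroundTruth":
        out = GroundTruth()
        for f in dataclasses.fields(GroundTruth):
            a = getattr(self, f.name)
            b = getattr(other, f.name)
            if isinstance(a, dict):
                merged = dict(a)
                merged.update(b)
                setattr(out, f.name, merged)
            elif isinstance(a, list):
                setattr(out, f.name, list(a) + [x for x in b if x not in a])
            else:
                setattr(out, f.name, b if b is not None else a)
        return out

    def to_jsonable(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_jsonable(), indent=2, sort_keys=True) + "\n")
        return path

    @classmethod
    def load(cls, path) -> "GroundTruth":
        data = json.loads(Path(path).read_text())
        return cls(**data)


# ---------------------------------------------------------------------------
# Deterministic planted structure shared by generators


def _planted_proteins(config: SimulationConfig):
    """Deterministic allocation of planted protein identifiers.

    Proteins P00001..P<n>; the first ``planted_common`` ids are the
    concordant set (first half up, second half down), followed by
    line-specific up/down blocks. Planted receptors are the first
    ``n_planted_receptors`` concordant-up proteins.
    """
    names = [f"P{i:05d}" for i in range(1, config.n_proteins + 1)]
    n_cu = config.planted_common - config.planted_common // 2
    common_up = names[:n_cu]
    common_down = names[n_cu:config.planted_common]
    pos = config.planted_common
    up_by_line: dict[str, list[str]] = {}
    down_by_line: dict[str, list[str]] = {}
    for line in config.resistant_lines:
        up_by_line[line] = names[pos:pos + config.planted_up]
        pos += config.planted_up
        down_by_line[line] = names[pos:pos + config.planted_down]
        pos += config.planted_down
    receptors = common_up[: config.n_planted_receptors]
    return names, common_up, common_down, up_by_line, down_by_line, receptors


def _ligand_subunits(config: SimulationConfig) -> list[tuple[str, ...]]:
    """Ligand pool with evenly interleaved multimeric (2-subunit) ligands."""
    if config.n_multimeric_ligands > 0:
        step = max(1, -(-config.n_ligands // config.n_multimeric_ligands))
        multimeric = {i for i in range(0, config.n_ligands, step)}
        multimeric = set(sorted(multimeric)[: config.n_multimeric_ligands])
    else:
        multimeric = set()
    pool = []
    for i in range(config.n_ligands):
        if i in multimeric:
            pool.append((f"LIG{i + 1:04d}A", f"LIG{i + 1:04d}B"))
        else:
            pool.append((f"LIG{i + 1:04d}",))
    return pool


def _planted_structure(config: SimulationConfig):
    """The planted pair layout: organ pairs, decoy pairs, ligand roles."""
    _, _, _, _, _, receptors = _planted_proteins(config)
    ligand_pool = _ligand_subunits(config)
    organ_ligands: list[tuple[str, tuple[str, ...]]] = []  # (organ, ligand)
    idx = 0
    for organ, count in config.planted_organ_pairs.items():
        for _ in range(count):
            organ_ligands.append((organ, ligand_pool[idx]))
            idx += 1
    planted_pairs = [
        (organ, receptors[k % len(receptors)], lig)
        for k, (organ, lig) in enumerate(organ_ligands)
    ]
    used = {receptors[k % len(receptors)] for k in range(len(organ_ligands))}
    decoy_pairs = []
    for r in receptors:
        if r not in used:
            decoy_pairs.append((r, ligand_pool[idx]))
            idx += 1
    # unused planted receptors also get decoy ligands so every planted
    # receptor appears in the database; decoy ligands peak in a non-organ
    # tissue so they never create organ edges
    return planted_pairs, decoy_pairs, ligand_pool, idx


# ---------------------------------------------------------------------------
# Generators


def gen_proteomics(config: SimulationConfig) -> tuple[IntensityMatrix, GroundTruth]:
    """Log-normal intensity matrix with planted group shifts.

    Planted proteins are shifted by ±``effect_log2fc`` in the designated
    resistant line(s) on the log2 scale; replicate noise is Gaussian on
    log2; missing entries are injected completely at random.
    """
    rng = config._rng(_STREAM_PROTEOMICS)
    names, common_up, common_down, up_by_line, down_by_line, receptors = (
        _planted_proteins(config)
    )
    samples = [
        f"{g}_rep{r}"
        for g in config.group_names
        for r in range(1, config.n_replicates_per_group + 1)
    ]
    base = rng.normal(config.base_mean_log2, config.base_sd_log2, config.n_proteins)
    shift = pd.DataFrame(0.0, index=names, columns=config.group_names)
    for line in config.resistant_lines:
        shift.loc[common_up, line] += config.effect_log2fc
        shift.loc[common_down, line] -= config.effect_log2fc
        shift.loc[up_by_line[line], line] += config.effect_log2fc
        shift.loc[down_by_line[line], line] -= config.effect_log2fc
    log2 = np.empty((config.n_proteins, len(samples)))
    for j, s in enumerate(samples):
        g = s.rsplit("_rep", 1)[0]
        noise = rng.normal(0.0, config.noise_sd_log2, config.n_proteins) \
            if config.noise_sd_log2 > 0 else np.zeros(config.n_proteins)
        log2[:, j] = base + shift[g].to_numpy() + noise
    values = np.exp2(log2)
    if config.missing_rate > 0:
        mask = rng.random(values.shape) < config.missing_rate
        values = np.where(mask, np.nan, values)
    matrix = IntensityMatrix(
        values=pd.DataFrame(values, index=names, columns=samples),
        groups=pd.Series(
            {s: s.rsplit("_rep", 1)[0] for s in samples}, name="group"
        ),
        log2=False,
    )
    truth = GroundTruth(
        up_by_line={l: sorted(set(common_up) | set(up_by_line[l])) for l in up_by_line},
        down_by_line={
            l: sorted(set(common_down) | set(down_by_line[l])) for l in down_by_line
        },
        common_up=list(common_up),
        common_down=list(common_down),
        planted_receptors=list(receptors),
    )
    return matrix, truth


def gen_membrane_annotation(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Gene -> membrane-localization table over the proteomics universe.

    Planted receptors are always membrane; a ``membrane_fraction`` of the
    other concordant-up proteins and a background fraction of the rest
    are membrane too (the 74 -> 7 funnel needs up-regulated membrane
    genes that are *not* receptors).
    """
    rng = config._rng(_STREAM_LRDB).spawn(2)[1]
    names, common_up, _, _, _, receptors = _planted_proteins(config)
    receptor_set = set(receptors)
    membrane = {}
    for g in names:
        if g in receptor_set:
            membrane[g] = True
        elif g in set(common_up):
            membrane[g] = bool(rng.random() < config.membrane_fraction)
        else:
            membrane[g] = bool(rng.random() < config.background_membrane_fraction)
    table = pd.DataFrame(
        {
            "gene": names,
            "is_membrane": [membrane[g] for g in names],
            "localization": [
                "plasma membrane" if membrane[g] else "cytoplasm" for g in names
            ],
        }
    )
    truth = GroundTruth(
        membrane_genes=sorted(g for g, v in membrane.items() if v),
        planted_receptors=list(receptors),
    )
    return table, truth


def gen_lr_database(config: SimulationConfig) -> tuple[LRDatabase, GroundTruth]:
    """CellChatDB-style pair catalogue with planted organ-specific pairs.

    Planted pairs connect planted (up-regulated, membrane) receptors to
    designated organ-specific ligands; decoy pairs give every planted
    receptor at least one database entry; background pairs connect the
    remaining ligands to background receptors, with multimeric receptor
    complexes interleaved.
    """
    rng = config._rng(_STREAM_LRDB).spawn(2)[0]
    planted_pairs, decoy_pairs, ligand_pool, next_ligand = _planted_structure(config)

    n_bg_receptors = config.n_receptors - config.n_planted_receptors
    bg_receptors: list[tuple[str, ...]] = []
    for i in range(n_bg_receptors):
        if i < config.n_multimeric_receptors:
            bg_receptors.append((f"REC{i + 1:04d}A", f"REC{i + 1:04d}B"))
        else:
            bg_receptors.append((f"REC{i + 1:04d}",))

    pairs: list[LRPair] = []
    organ_edges = []
    for organ, receptor, ligand in planted_pairs:
        pid = f"LR{len(pairs) + 1:05d}"
        pairs.append(LRPair(pid, ligand, (receptor,)))
        organ_edges.append(
            {"organ": organ, "receptor": receptor, "ligand": "+".join(ligand)}
        )
    decoy_ligands = []
    for receptor, ligand in decoy_pairs:
        pid = f"LR{len(pairs) + 1:05d}"
        pairs.append(LRPair(pid, ligand, (receptor,)))
        decoy_ligands.append("+".join(ligand))
    while len(pairs) < config.n_pairs and next_ligand < len(ligand_pool):
        ligand = ligand_pool[next_ligand]
        receptor = bg_receptors[int(rng.integers(0, len(bg_receptors)))]
        pairs.append(LRPair(f"LR{len(pairs) + 1:05d}", ligand, receptor))
        next_ligand += 1
    # reuse ligands with fresh background receptors if n_pairs > n_ligands
    while len(pairs) < config.n_pairs:
        ligand = ligand_pool[int(rng.integers(len(decoy_pairs) + len(planted_pairs),
                                              len(ligand_pool)))]
        receptor = bg_receptors[int(rng.integers(0, len(bg_receptors)))]
        pairs.append(LRPair(f"LR{len(pairs) + 1:05d}", ligand, receptor))

    _, _, _, _, _, receptors = _planted_proteins(config)
    truth = GroundTruth(
        planted_receptors=list(receptors),
        organ_edges=organ_edges,
        decoy_ligands=decoy_ligands,
    )
    return LRDatabase(pairs=pairs), truth


def gen_tissue_atlas(config: SimulationConfig) -> pd.DataFrame:
    """Gene x tissue nTPM atlas with planted tissue-specific ligands.

    Planted organ-pair ligand subunits peak strictly in their designated
    organ; decoy ligands peak in a dedicated non-organ tissue; background
    ligands and genes have broad low-level expression, with an exact
    ``fraction_below_1`` of background genes never reaching nTPM 1. A
    small fraction of background ligands is forced below threshold or
    left out of the atlas to exercise the exclusion paths.
    """
    rng = config._rng(_STREAM_ATLAS)
    tissues = config.tissue_names
    n_t = len(tissues)
    planted_pairs, decoy_pairs, ligand_pool, next_ligand = _planted_structure(config)

    rows: dict[str, np.ndarray] = {}

    def plant_specific(subunits: tuple[str, ...], tissue: str):
        t_idx = tissues.index(tissue)
        for g in subunits:
            vals = rng.uniform(0.1, 3.0, n_t)
            vals[t_idx] = rng.uniform(20.0, 100.0)
            rows[g] = vals

    for organ, _receptor, ligand in planted_pairs:
        plant_specific(ligand, organ)
    safe_tissue = tissues[len(config.planted_organ_pairs)]
    for _receptor, ligand in decoy_pairs:
        plant_specific(ligand, safe_tissue)

    background_ligands = ligand_pool[next_ligand:]
    n_bg_lig = len(background_ligands)
    n_below = int(round(config.ligand_below_threshold_frac * n_bg_lig))
    n_missing = int(round(config.ligand_missing_frac * n_bg_lig))
    for k, subunits in enumerate(background_ligands):
        if k < n_below:
            for g in subunits:
                rows[g] = rng.uniform(0.01, 0.95, n_t)
        elif k < n_below + n_missing:
            continue  # absent from the atlas entirely
        else:
            for g in subunits:
                vals = rng.uniform(0.1, 5.0, n_t)
                vals[int(rng.integers(0, n_t))] = rng.uniform(1.5, 30.0)
                rows[g] = vals

    n_background = max(0, config.n_atlas_genes - len(rows))
    n_bg_below = int(round(config.fraction_below_1 * n_background))
    for i in range(n_background):
        g = f"BG{i + 1:05d}"
        if i < n_bg_below:
            rows[g] = rng.uniform(0.01, 0.95, n_t)
        else:
            vals = rng.uniform(0.1, 5.0, n_t)
            vals[int(rng.integers(0, n_t))] = rng.uniform(1.5, 30.0)
            rows[g] = vals

    atlas = pd.DataFrame.from_dict(rows, orient="index", columns=tissues)
    atlas.index.name = "gene"
    return atlas


def gen_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Patient cohort with binormal per-particle markers calibrated to AUC.

    Latent per-marker scores are unit-variance Gaussians correlated by
    ``marker_correlation``; the positive (brain-metastasis) group is
    shifted by delta_m = sqrt(2) * Phi^{-1}(AUC_m), so each marker's
    theoretical AUC against any comparison group is exactly its target.
    Scores are exponentiated to positive per-particle loads; particle
    concentrations are log-normal; marker concentrations (pg/ml) are
    per-particle load times particle count, so per-particle normalization
    recovers the calibrated scale exactly.
    """
    for g, n in config.cohort_sizes.items():
        if n < 2:
            raise ConfigError(f"cohort group {g!r} needs >= 2 patients")
    if config.positive_group not in config.cohort_sizes:
        raise ConfigError(f"positive group {config.positive_group!r} not in cohort_sizes")
    rng = config._rng(_STREAM_COHORT)
    markers = list(config.marker_target_auc)
    m = len(markers)
    delta = np.array(
        [np.sqrt(2.0) * stats.norm.ppf(config.marker_target_auc[mk]) for mk in markers]
    )
    corr = np.full((m, m), config.marker_correlation)
    np.fill_diagonal(corr, 1.0)
    # eigen factor handles the singular rho = +/-1 cases that Cholesky cannot
    w, v = np.linalg.eigh(corr)
    factor = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))

    rows = []
    pid = 0
    for group, n in config.cohort_sizes.items():
        z = rng.standard_normal((n, m)) @ factor.T
        if group == config.positive_group:
            z = z + delta
        log10_particles = rng.normal(config.particle_mean_log10, config.particle_sd_log10, n)
        if config.particle_marker_dependence != 0:
            standardized = (log10_particles - config.particle_mean_log10) / config.particle_sd_log10
            z = z + config.particle_marker_dependence * standardized[:, None]
        particles = np.power(10.0, log10_particles)
        per_particle = np.exp(z) * config.per_particle_scale
        for i in range(n):
            pid += 1
            row = {
                "patient_id": f"PT{pid:04d}",
                "group": group,
                "particle_concentration": particles[i],
            }
            for j, mk in enumerate(markers):
                row[mk] = per_particle[i, j] * particles[i]  # pg/ml
            rows.append(row)
    table = pd.DataFrame(rows)

    inv = np.linalg.pinv(corr)
    mahal = float(delta @ inv @ delta)
    combined_auc = float(stats.norm.cdf(np.sqrt(mahal) / np.sqrt(2.0)))
    beta = inv @ delta
    truth = GroundTruth(
        marker_delta={mk: float(d) for mk, d in zip(markers, delta)},
        marker_theoretical_auc={
            mk: float(stats.norm.cdf(d / np.sqrt(2.0))) for mk, d in zip(markers, delta)
        },
        combined_theoretical_auc=combined_auc,
        logistic_coefficients={mk: float(b) for mk, b in zip(markers, beta)},
    )
    return table, truth


def generate_all(config: SimulationConfig):
    """All five inputs plus merged ground truth.

    Returns ``(matrix, annotation, lrdb, atlas, cohort, truth)``.
    """
    matrix, t1 = gen_proteomics(config)
    annotation, t2 = gen_membrane_annotation(config)
    lrdb, t3 = gen_lr_database(config)
    atlas = gen_tissue_atlas(config)
    cohort, t4 = gen_cohort(config)
    truth = t1.merge(t2).merge(t3).merge(t4)
    return matrix, annotation, lrdb, atlas, cohort, truth
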