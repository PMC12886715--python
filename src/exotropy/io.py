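"""TSV readers and writers for the five pipeline inputs.

All files are UTF-8 TSV with a header row and "." decimals; multimeric
subunit lists are "+"-joined (``ITGA2B+ITGB3``). Empty cells and ``NA``
in intensity matrices are missing values, never zeros. Schema violations
raise :class:`~exotropy.exceptions.ParseError` with the offending line or
column.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from exotropy.database import LRDatabase, LRPair, parse_subunits, format_subunits
from exotropy.diffabund import IntensityMatrix
from exotropy.exceptions import ParseError

NA_VALUES = ["", "NA"]


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"input file not found: {path}")
    try:
        return pd.read_csv(
            path, sep="\t", na_values=NA_VALUES, keep_default_na=False, **kwargs
        )
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")


# -- intensity matrix -------------------------------------------------------


def read_intensity_matrix(path, group_map_path) -> IntensityMatrix:
    """Read proteins x samples intensities plus a sample -> group sidecar."""
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected gene column plus sample columns")
    gene_col = df.columns[0]
    genes = df[gene_col].astype(str)
    dup = genes[genes.duplicated()]
    if len(dup):
        raise ParseError(f"{path}: duplicate gene {dup.iloc[0]!r}")
    values = df.drop(columns=[gene_col])
    for col in values.columns:
        try:
            values[col] = pd.to_numeric(values[col]).astype(float)
        except (ValueError, TypeError) as exc:
            bad = values[col][pd.to_numeric(values[col], errors="coerce").isna()
                              & values[col].notna()]
            line = int(bad.index[0]) + 2 if len(bad) else "?"
            raise ParseError(
                f"{path}: non-numeric cell in column {col!r}, line {line}"
            ) from exc
    values.index = pd.Index(genes.to_numpy(), name=None)

    gm = _read_tsv(group_map_path)
    _require_columns(gm, ["sample", "group"], group_map_path)
    groups = pd.Series(
        gm["group"].astype(str).to_numpy(), index=gm["sample"].astype(str), name="group"
    )
    return IntensityMatrix(values=values, groups=groups, log2=False)


def write_intensity_matrix(matrix: IntensityMatrix, path, group_map_path) -> None:
    out = matrix.values.copy()
    out.insert(0, "gene", out.index)
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")
    gm = pd.DataFrame(
        {"sample": matrix.groups.index, "group": matrix.groups.to_numpy()}
    )
    gm.to_csv(group_map_path, sep="\t", index=False)


# -- ligand-receptor database ----------------------------------------------


def read_lr_database(path) -> LRDatabase:
    df = _read_tsv(path, dtype=str)
    _require_columns(df, ["pair_id", "ligand", "receptor"], path)
    pairs = []
    for i, row in df.iterrows():
        pid = str(row["pair_id"])
        for col in ("ligand", "receptor"):
            if pd.isna(row[col]):
                raise ParseError(f"{path}: empty {col} in pair {pid!r} (line {i + 2})")
        pairs.append(
            LRPair(
                pair_id=pid,
                ligand_subunits=parse_subunits(row["ligand"], pid),
                receptor_subunits=parse_subunits(row["receptor"], pid),
            )
        )
    return LRDatabase(pairs=pairs)


def write_lr_database(lrdb: LRDatabase, path) -> None:
    df = pd.DataFrame(
        {
            "pair_id": [p.pair_id for p in lrdb],
            "ligand": [format_subunits(p.ligand_subunits) for p in lrdb],
            "receptor": [format_subunits(p.receptor_subunits) for p in lrdb],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# -- tissue atlas -----------------------------------------------------------


def read_tissue_atlas(path) -> pd.DataFrame:
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected gene column plus tissue columns")
    gene_col = df.columns[0]
    genes = df[gene_col].astype(str)
    if genes.duplicated().any():
        dup = genes[genes.duplicated()].iloc[0]
        raise ParseError(f"{path}: duplicate gene {dup!r}")
    atlas = df.drop(columns=[gene_col]).astype(float)
    atlas.index = genes
    if atlas.columns.duplicated().any():
        raise ParseError(f"{path}: duplicate tissue column")
    if (atlas.to_numpy() < 0).any():
        gi, ti = np.argwhere(atlas.to_numpy() < 0)[0]
        raise ParseError(
            f"{path}: negative nTPM for gene {atlas.index[gi]!r}, "
            f"tissue {atlas.columns[ti]!r}"
        )
    return atlas


def write_tissue_atlas(atlas: pd.DataFrame, path) -> None:
    out = atlas.copy()
    out.insert(0, "gene", out.index)
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


# -- membrane annotation ----------------------------------------------------

_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False,
             "yes": True, "no": False}


def read_annotation(path) -> pd.DataFrame:
    df = _read_tsv(path, dtype=str)
    _require_columns(df, ["gene", "is_membrane"], path)
    genes = df["gene"].astype(str).str.strip().str.upper()
    if genes.duplicated().any():
        dup = genes[genes.duplicated()].iloc[0]
        raise ParseError(f"{path}: duplicate gene {dup!r} after symbol normalization")
    flags = []
    for i, v in enumerate(df["is_membrane"]):
        key = str(v).strip().lower()
        if key not in _BOOL_MAP:
            raise ParseError(
                f"{path}: column 'is_membrane' has non-boolean value {v!r} (line {i + 2})"
            )
        flags.append(_BOOL_MAP[key])
    out = pd.DataFrame({"gene": genes, "is_membrane": flags})
    if "localization" in df.columns:
        out["localization"] = df["localization"]
    return out


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index=False)


def annotation_to_mapping(annotation: pd.DataFrame) -> dict[str, bool]:
    return dict(zip(annotation["gene"], annotation["is_membrane"]))


# -- cohort -----------------------------------------------------------------


def read_cohort(path, markers: list[str] | None = None) -> pd.DataFrame:
    df = _read_tsv(path)
    _require_columns(df, ["patient_id", "group", "particle_concentration"], path)
    if df["patient_id"].duplicated().any():
        dup = df["patient_id"][df["patient_id"].duplicated()].iloc[0]
        raise ParseError(f"{path}: duplicate patient id {dup!r}")
    particles = pd.to_numeric(df["particle_concentration"], errors="coerce")
    bad = df.index[~(particles > 0)]
    if len(bad):
        raise ParseError(
            f"{path}: non-positive particle_concentration "
            f"for patient {df['patient_id'].iloc[bad[0]]!r} (line {bad[0] + 2})"
        )
    df["particle_concentration"] = particles
    marker_cols = markers or [
        c for c in df.columns
        if c not in ("patient_id", "group", "particle_concentration")
    ]
    for m in marker_cols:
        if m not in df.columns:
            raise ParseError(f"{path}: missing marker column {m!r}")
        vals = pd.to_numeric(df[m], errors="coerce")
        neg = df.index[vals < 0]
        if len(neg):
            raise ParseError(
                f"{path}: negative concentration in column {m!r} (line {neg[0] + 2})"
            )
        df[m] = vals
    return df


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False, float_format="%.10g")
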