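"""Differential exosomal protein abundance.

Label-free LC-MS/MS intensities (proteins x samples) are log2-transformed;
each resistant line is compared against the parental line with a two-sided
Welch t test per protein, fold change is the difference of log2 group means
(a geometric-mean ratio), and proteins passing ``|log2fc| >= log2(2)`` and
``p <= 0.05`` form per-comparison up/down sets. Proteins altered
concordantly in every comparison form the common sets; the Venn region
counts over the union of altered proteins reproduce the intersection
diagram of the funnel's first stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from exotropy.exceptions import ConfigError, ExotropyError

STATUS_TESTED = "tested"
STATUS_INSUFFICIENT = "insufficient_data"


@dataclass
class IntensityMatrix:
    """Proteins x samples label-free intensity matrix with group labels.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows are proteins (unique identifiers), columns are samples
        (unique identifiers). Missing observations are ``NaN``. Raw
        intensities must be non-negative; log2-scale matrices (after
        :func:`log2_transform`) may contain negative values.
    groups : pandas.Series
        Sample identifier -> group label; must cover every sample column.
    log2 : bool
        Whether ``values`` is on the log2 scale.
    """

    values: pd.DataFrame
    groups: pd.Series
    log2: bool = False

    def __post_init__(self):
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ExotropyError(f"duplicate protein identifier {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ExotropyError(f"duplicate sample identifier {dup!r}")
        missing_groups = [s for s in self.values.columns if s not in self.groups.index]
        if missing_groups:
            raise ExotropyError(f"samples without group label: {missing_groups}")
        if not self.log2:
            vals = self.values.to_numpy(dtype=float)
            if np.nanmin(vals, initial=np.inf) < 0:
                raise ExotropyError("raw intensities must be non-negative")

    @property
    def proteins(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_of(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]

    @property
    def group_names(self) -> list[str]:
        seen: list[str] = []
        for s in self.values.columns:
            g = self.groups[s]
            if g not in seen:
                seen.append(g)
        return seen


def log2_transform(matrix: IntensityMatrix) -> IntensityMatrix:
    """Elementwise log2 of a raw intensity matrix; missing stays missing.

    Zero or negative intensities are a data error (label-free peak
    intensities are strictly positive where observed) and are reported
    with the offending protein/sample cell.
    """
    if matrix.log2:
        raise ExotropyError("matrix is already on the log2 scale")
    vals = matrix.values.to_numpy(dtype=float)
    bad = np.argwhere(np.nan_to_num(vals, nan=1.0) <= 0)
    if bad.size:
        i, j = bad[0]
        raise ExotropyError(
            "non-positive intensity at protein "
            f"{matrix.values.index[i]!r}, sample {matrix.values.columns[j]!r}"
        )
    out = pd.DataFrame(
        np.log2(vals), index=matrix.values.index, columns=matrix.values.columns
    )
    return IntensityMatrix(values=out, groups=matrix.groups, log2=True)


def _welch(mean_a, var_a, n_a, mean_b, var_b, n_b):
    """Welch t statistic, Satterthwaite df and two-sided p, vectorized.

    Degenerate zero-variance rows (both groups constant) get p = 1 when the
    means agree and p = 0 when they differ — the limiting behaviour of the
    statistic.
    """
    n_a = np.maximum(n_a, 1)
    n_b = np.maximum(n_b, 1)
    se2 = var_a / n_a + var_b / n_b
    diff = mean_b - mean_a
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        df = se2**2 / (
            (var_a / n_a) ** 2 / (n_a - 1) + (var_b / n_b) ** 2 / (n_b - 1)
        )
        p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = se2 == 0
    p = np.where(degenerate, np.where(diff == 0, 1.0, 0.0), p)
    with np.errstate(invalid="ignore"):
        t = np.where(degenerate, np.where(diff == 0, 0.0, np.inf * np.sign(diff)), t)
    return t, p


def diff_test(
    matrix: IntensityMatrix,
    group_a: str,
    group_b: str,
    min_obs: int = 2,
) -> pd.DataFrame:
    """Per-protein differential test of ``group_b`` versus ``group_a``.

    Returns a DataFrame indexed by protein with columns ``log2fc``
    (mean log2 of b minus mean log2 of a over observed values),
    ``p_value`` (two-sided Welch t), ``n_obs_a``, ``n_obs_b`` and
    ``status``. Proteins with fewer than ``min_obs`` observed values in
    either group are flagged ``insufficient_data`` (log2fc and p are NaN),
    never silently dropped.
    """
    if not matrix.log2:
        raise ExotropyError("diff_test requires a log2-scale matrix")
    for g in (group_a, group_b):
        samples = matrix.samples_of(g)
        if not samples:
            raise ExotropyError(f"group {g!r} not present in group map")
        if len(samples) < 2:
            raise ExotropyError(f"group {g!r} has fewer than 2 samples")
    if min_obs < 2:
        raise ConfigError("min_obs must be >= 2 (variance needs 2 observations)")

    A = matrix.values[matrix.samples_of(group_a)].to_numpy(dtype=float)
    B = matrix.values[matrix.samples_of(group_b)].to_numpy(dtype=float)
    n_a = np.sum(~np.isnan(A), axis=1)
    n_b = np.sum(~np.isnan(B), axis=1)
    mean_a, var_a = _nanmoments(A, n_a)
    mean_b, var_b = _nanmoments(B, n_b)
    tested = (n_a >= min_obs) & (n_b >= min_obs)
    _, p = _welch(mean_a, var_a, n_a, mean_b, var_b, n_b)
    log2fc = mean_b - mean_a
    log2fc = np.where(tested, log2fc, np.nan)
    p = np.where(tested, p, np.nan)
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "p_value": p,
            "n_obs_a": n_a,
            "n_obs_b": n_b,
            "status": np.where(tested, STATUS_TESTED, STATUS_INSUFFICIENT),
        },
        index=matrix.values.index,
    )


def _nanmoments(X, n):
    """NaN-ignoring row mean and sample variance (ddof=1) without warnings.

    Mean is 0 and variance 0 where too few observations exist; such rows
    are flagged insufficient by the caller.
    """
    n_safe = np.maximum(n, 1)
    mean = np.nansum(X, axis=1) / n_safe
    dev2 = np.nansum((X - mean[:, None]) ** 2, axis=1)
    var = np.where(n >= 2, dev2 / np.maximum(n - 1, 1), 0.0)
    return mean, var


def significant_sets(
    result: pd.DataFrame,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    adjust: str = "none",
) -> tuple[set[str], set[str]]:
    """Up/down sets at inclusive fold-change and p thresholds.

    up = {log2fc >= log2(fc_threshold) and p <= p_threshold}; down is
    symmetric with log2fc <= -log2(fc_threshold). ``adjust="bh"`` applies
    Benjamini–Hochberg to the tested p-values before thresholding.
    """
    if fc_threshold <= 1:
        raise ConfigError("fc_threshold must be > 1")
    if adjust not in ("none", "bh"):
        raise ConfigError(f"unknown adjust method {adjust!r}")
    tested = result[result["status"] == STATUS_TESTED]
    p = tested["p_value"].to_numpy()
    if adjust == "bh" and len(p):
        p = stats.false_discovery_control(p, method="bh")
    lfc = tested["log2fc"].to_numpy()
    cut = math.log2(fc_threshold)
    up = set(tested.index[(lfc >= cut) & (p <= p_threshold)])
    down = set(tested.index[(lfc <= -cut) & (p <= p_threshold)])
    return up, down


@dataclass
class AlteredSets:
    """Per-comparison and concordant-common altered protein sets.

    ``venn`` maps each non-empty comparison subset (frozenset of names) to
    the number of proteins altered (up or down) in exactly those
    comparisons; the exclusive regions partition the union of all altered
    proteins.
    """

    per_comparison: dict[str, tuple[set[str], set[str]]]
    common_up: set[str] = field(default_factory=set)
    common_down: set[str] = field(default_factory=set)
    discordant: set[str] = field(default_factory=set)
    venn: dict[frozenset, int] = field(default_factory=dict)

    @property
    def common_total(self) -> int:
        return len(self.common_up) + len(self.common_down)

    def to_jsonable(self) -> dict:
        return {
            "per_comparison": {
                name: {"up": sorted(up), "down": sorted(down)}
                for name, (up, down) in sorted(self.per_comparison.items())
            },
            "common_up": sorted(self.common_up),
            "common_down": sorted(self.common_down),
            "discordant": sorted(self.discordant),
            "venn": {
                "|".join(sorted(k)): v
                for k, v in sorted(self.venn.items(), key=lambda kv: sorted(kv[0]))
            },
        }


def common_altered(sets_per_comparison: dict[str, tuple[set[str], set[str]]]) -> AlteredSets:
    """Concordant intersection of per-comparison up/down sets.

    common_up is the intersection of all up-sets (and symmetrically for
    down); a protein up in one comparison and down in another is
    discordant and excluded from both common sets. Venn region counts are
    direction-agnostic (altered = up or down).
    """
    if len(sets_per_comparison) < 2:
        raise ExotropyError("common_altered requires >= 2 comparisons")
    names = list(sets_per_comparison)
    ups = [sets_per_comparison[n][0] for n in names]
    downs = [sets_per_comparison[n][1] for n in names]
    common_up = set.intersection(*ups)
    common_down = set.intersection(*downs)
    any_up = set.union(*ups)
    any_down = set.union(*downs)
    discordant = any_up & any_down
    common_up -= discordant
    common_down -= discordant

    altered = {n: sets_per_comparison[n][0] | sets_per_comparison[n][1] for n in names}
    union = set.union(*altered.values())
    venn: dict[frozenset, int] = {}
    for protein in union:
        key = frozenset(n for n in names if protein in altered[n])
        venn[key] = venn.get(key, 0) + 1
    return AlteredSets(
        per_comparison=dict(sets_per_comparison),
        common_up=common_up,
        common_down=common_down,
        discordant=discordant,
        venn=venn,
    )
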