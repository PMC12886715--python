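"""Serum-exosome biomarker panel: per-particle normalization, ROC, and
logistic combination with internal validation.

ELISA marker concentrations (pg/ml) are normalized to exosome particle
counts (particles/ml), giving per-particle marker loads (pg/particle).
Discrimination of the brain-metastasis group is quantified by the rank
(Mann–Whitney) AUC estimator with half-credit ties; the two-marker panel
is combined through a maximum-likelihood logistic model whose per-patient
predicted probabilities feed the combined ROC. Internal validation uses
stratified k-fold cross-validation (pooled held-out probabilities) and
stratified bootstrap resampling (percentile CI and Harrell's
optimism-corrected AUC).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from exotropy.exceptions import ConfigError, ConvergenceError, ExotropyError

PER_PARTICLE_SUFFIX = "_per_particle"


def normalize_per_particle(
    table: pd.DataFrame,
    markers: list[str],
    particle_col: str = "particle_concentration",
) -> pd.DataFrame:
    """Add per-particle marker columns: concentration / particle count.

    Marker concentrations are pg/ml, particle concentrations particles/ml;
    the derived value is pg/particle. Zero or negative particle counts are
    a row-level data error.
    """
    if particle_col not in table.columns:
        raise ExotropyError(f"missing column {particle_col!r}")
    particles = table[particle_col].to_numpy(dtype=float)
    bad = np.flatnonzero(~(particles > 0))
    if bad.size:
        raise ExotropyError(
            f"non-positive particle concentration in row(s) {list(table.index[bad])}"
        )
    out = table.copy()
    for m in markers:
        if m not in table.columns:
            raise ExotropyError(f"missing marker column {m!r}")
        out[m + PER_PARTICLE_SUFFIX] = table[m].to_numpy(dtype=float) / particles
    return out


# ---------------------------------------------------------------------------
# ROC / AUC


@dataclass
class ROCResult:
    """Rank-estimator ROC with bootstrap CI and Mann–Whitney p-value."""

    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    ci_low: float | None
    ci_high: float | None
    p_value: float
    n_pos: int
    n_neg: int

    def to_jsonable(self) -> dict:
        return {
            "auc": self.auc,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "fpr": [float(x) for x in self.fpr],
            "tpr": [float(x) for x in self.tpr],
        }


def _rank_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Mann–Whitney AUC with half-credit for ties, via midranks."""
    n_pos, n_neg = len(pos), len(neg)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> float:
    """DeLong variance of the rank AUC via placement values."""
    m, n = len(pos), len(neg)
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_auc(
    values,
    labels,
    positive_label,
    n_boot: int = 2000,
    seed: int | None = None,
    ci_level: float = 0.95,
    p_method: str = "mannwhitney",
) -> ROCResult:
    """ROC curve and AUC of ``values`` for discriminating the positive class.

    AUC uses the rank (Mann–Whitney) estimator (ties count 1/2); the curve
    is traced over sorted unique thresholds and anchored at (0,0) and
    (1,1). The p-value tests AUC = 0.5 by the tie-corrected normal
    approximation of the Mann–Whitney statistic (``p_method="delong"``
    switches to a DeLong-variance z test). The CI is a stratified
    percentile bootstrap with ``n_boot`` replicates (``n_boot=0`` skips
    it). AUC is reported as-is for the declared positive class, never
    flipped.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    is_pos = labels == positive_label
    pos, neg = values[is_pos], values[~is_pos]
    if len(pos) == 0 or len(neg) == 0:
        raise ExotropyError("both classes must be present for ROC analysis")
    auc = _rank_auc(pos, neg)

    fpr, tpr, _ = _sk_roc_curve(is_pos.astype(int), values, drop_intermediate=False)

    if np.all(values == values[0]):
        p_value = 1.0
    elif p_method == "mannwhitney":
        p_value = float(
            stats.mannwhitneyu(pos, neg, alternative="two-sided", method="asymptotic").pvalue
        )
    elif p_method == "delong":
        var = _delong_variance(pos, neg)
        if var <= 0:
            p_value = 0.0 if auc != 0.5 else 1.0
        else:
            z = (auc - 0.5) / np.sqrt(var)
            p_value = float(2.0 * stats.norm.sf(abs(z)))
    else:
        raise ConfigError(f"unknown p_method {p_method!r}")

    ci_low = ci_high = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            bp = pos[rng.integers(0, len(pos), len(pos))]
            bn = neg[rng.integers(0, len(neg), len(neg))]
            boots[b] = _rank_auc(bp, bn)
        alpha = (1.0 - ci_level) / 2.0
        ci_low = float(np.quantile(boots, alpha))
        ci_high = float(np.quantile(boots, 1.0 - alpha))
    return ROCResult(
        auc=float(auc),
        fpr=fpr,
        tpr=tpr,
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=p_value,
        n_pos=int(len(pos)),
        n_neg=int(len(neg)),
    )


# ---------------------------------------------------------------------------
# Logistic panel model


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def _newton_logistic(X, y, ridge=1e-6, max_iter=100, tol=1e-8):
    """Ridge-stabilized Newton–Raphson MLE for logistic regression.

    Ridge applies to the non-intercept coefficients only. Returns
    (beta, convergence record, inverse Hessian).
    """
    n, p = X.shape
    beta = np.zeros(p)
    penalty = np.full(p, ridge)
    penalty[0] = 0.0  # no shrinkage on the intercept
    grad_norm = np.inf
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = _sigmoid(eta)
        grad = X.T @ (y - mu) - penalty * beta
        grad_norm = float(np.max(np.abs(grad)))
        if grad_norm < tol:
            break
        w = mu * (1.0 - mu)
        hess = (X.T * w) @ X + np.diag(penalty)
        beta = beta + np.linalg.solve(hess, grad)
    record = {"iterations": it, "grad_norm": grad_norm, "converged": grad_norm < tol}
    if not record["converged"]:
        raise ConvergenceError(
            f"logistic fit did not converge in {max_iter} iterations "
            f"(gradient norm {grad_norm:.3e})",
            record=record,
        )
    mu = _sigmoid(X @ beta)
    w = mu * (1.0 - mu)
    hess = (X.T * w) @ X + np.diag(penalty)
    return beta, record, np.linalg.inv(hess)


class BiomarkerPanel:
    """Logistic combination model for a multi-marker exosomal panel.

    The model is built from a cohort table (one row per patient) and fitted
    by maximum likelihood on z-score-standardized per-particle marker
    values; standardization leaves predicted probabilities (hence the
    combined ROC) unchanged but makes coefficients unit-free.

    Parameters
    ----------
    table : pandas.DataFrame
        Cohort rows with a group column, particle concentrations and raw
        marker concentrations (or precomputed per-particle columns).
    markers : list of str
        Marker names; per-particle columns ``<marker>_per_particle`` are
        derived if absent.
    positive_label : str
        Group treated as the positive class (brain metastasis).
    """

    def __init__(
        self,
        table: pd.DataFrame,
        markers: list[str],
        positive_label: str,
        group_col: str = "group",
        particle_col: str = "particle_concentration",
    ):
        if group_col not in table.columns:
            raise ExotropyError(f"missing group column {group_col!r}")
        need_norm = any(m + PER_PARTICLE_SUFFIX not in table.columns for m in markers)
        if need_norm:
            table = normalize_per_particle(table, markers, particle_col)
        self.table = table
        self.markers = list(markers)
        self.positive_label = positive_label
        self.group_col = group_col
        y = (table[group_col] == positive_label).to_numpy(dtype=float)
        if y.sum() < 2 or (1 - y).sum() < 2:
            raise ExotropyError("need >= 2 patients per class")
        self.y = y
        self.X_raw = table[[m + PER_PARTICLE_SUFFIX for m in markers]].to_numpy(dtype=float)

    @classmethod
    def from_dataframe(cls, table, markers, positive_label, **kwargs):
        return cls(table, markers, positive_label, **kwargs)

    def fit(self, max_iter: int = 100, tol: float = 1e-8, ridge: float = 1e-6):
        """Fit by Newton–Raphson; returns :class:`PanelResults`."""
        mean = self.X_raw.mean(axis=0)
        sd = self.X_raw.std(axis=0, ddof=0)
        sd = np.where(sd == 0, 1.0, sd)
        Z = (self.X_raw - mean) / sd
        X = np.column_stack([np.ones(len(Z)), Z])
        beta, record, cov = _newton_logistic(
            X, self.y, ridge=ridge, max_iter=max_iter, tol=tol
        )
        prob = _sigmoid(X @ beta)
        return PanelResults(
            model=self,
            intercept=float(beta[0]),
            coefficients=pd.Series(beta[1:], index=self.markers),
            standard_errors=pd.Series(np.sqrt(np.diag(cov)), index=["intercept"] + self.markers),
            standardization=(mean, sd),
            predicted_prob=pd.Series(prob, index=self.table.index),
            convergence=record,
        )


@dataclass
class PanelResults:
    """Fitted panel: coefficients, per-patient probabilities, diagnostics."""

    model: BiomarkerPanel
    intercept: float
    coefficients: pd.Series
    standard_errors: pd.Series
    standardization: tuple[np.ndarray, np.ndarray]
    predicted_prob: pd.Series
    convergence: dict

    @property
    def params(self) -> pd.Series:
        return pd.concat(
            [pd.Series({"intercept": self.intercept}), self.coefficients]
        )

    def predict(self, table: pd.DataFrame) -> pd.Series:
        """Predicted positive-class probability for new cohort rows."""
        m = self.model
        need = [mk for mk in m.markers if mk + PER_PARTICLE_SUFFIX not in table.columns]
        if need:
            table = normalize_per_particle(table, m.markers)
        X_raw = table[[mk + PER_PARTICLE_SUFFIX for mk in m.markers]].to_numpy(dtype=float)
        mean, sd = self.standardization
        Z = (X_raw - mean) / sd
        eta = self.intercept + Z @ self.coefficients.to_numpy()
        return pd.Series(_sigmoid(eta), index=table.index)

    def roc(self, n_boot: int = 2000, seed: int | None = None) -> ROCResult:
        """Combined-panel ROC of the in-sample predicted probabilities."""
        return roc_auc(
            self.predicted_prob.to_numpy(),
            self.model.table[self.model.group_col].to_numpy(),
            self.model.positive_label,
            n_boot=n_boot,
            seed=seed,
        )

    def summary(self) -> str:
        """Plain-text coefficient table in the spirit of statsmodels."""
        lines = [
            "Biomarker panel logistic model",
            f"  positive class: {self.model.positive_label}",
            f"  n = {len(self.predicted_prob)} "
            f"(pos {int(self.model.y.sum())}, neg {int((1 - self.model.y).sum())})",
            f"  converged in {self.convergence['iterations']} Newton iterations "
            f"(grad {self.convergence['grad_norm']:.2e})",
            "",
            f"  {'term':<14}{'coef':>10}{'std err':>10}",
            f"  {'intercept':<14}{self.intercept:>10.4f}"
            f"{self.standard_errors['intercept']:>10.4f}",
        ]
        for mk in self.coefficients.index:
            lines.append(
                f"  {mk:<14}{self.coefficients[mk]:>10.4f}"
                f"{self.standard_errors[mk]:>10.4f}"
            )
        auc = roc_auc(
            self.predicted_prob.to_numpy(),
            self.model.table[self.model.group_col].to_numpy(),
            self.model.positive_label,
            n_boot=0,
        ).auc
        lines += ["", f"  combined in-sample AUC: {auc:.3f}"]
        return "\n".join(lines)


def fit_logistic_panel(
    table: pd.DataFrame,
    markers: list[str],
    positive_label: str,
    **fit_kwargs,
) -> PanelResults:
    """Convenience wrapper: build a :class:`BiomarkerPanel` and fit it."""
    return BiomarkerPanel(table, markers, positive_label).fit(**fit_kwargs)


def combined_roc(results: PanelResults, n_boot: int = 2000, seed: int | None = None) -> ROCResult:
    """ROC of the fitted panel's predicted probabilities."""
    return results.roc(n_boot=n_boot, seed=seed)


# ---------------------------------------------------------------------------
# Internal validation


@dataclass
class ValidationReport:
    """Cross-validation and bootstrap validation of the combined panel."""

    apparent_auc: float
    cv_fold_aucs: list[float]
    cv_pooled_auc: float
    k: int
    n_boot: int
    seed: int
    bootstrap_aucs: list[float] = field(default_factory=list)
    ci_low: float | None = None
    ci_high: float | None = None
    optimism: float | None = None
    optimism_corrected_auc: float | None = None

    def to_jsonable(self) -> dict:
        return {
            "apparent_auc": self.apparent_auc,
            "cv_fold_aucs": self.cv_fold_aucs,
            "cv_pooled_auc": self.cv_pooled_auc,
            "k": self.k,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "bootstrap_ci": [self.ci_low, self.ci_high],
            "optimism": self.optimism,
            "optimism_corrected_auc": self.optimism_corrected_auc,
        }


def validate_panel(
    table: pd.DataFrame,
    markers: list[str],
    positive_label: str,
    k: int = 5,
    n_boot: int = 2000,
    seed: int = 0,
    group_col: str = "group",
) -> ValidationReport:
    """Stratified k-fold CV and stratified bootstrap of the logistic panel.

    Held-out predicted probabilities from the k folds are pooled into one
    ROC (the honest analogue of the apparent combined ROC). Bootstrap
    replicates refit the panel on stratified resamples: the replicate AUCs
    (fit and evaluated on the bootstrap sample) give a percentile CI, and
    Harrell's optimism — mean of (bootstrap-sample AUC minus the
    bootstrap model's AUC on the original cohort) — corrects the apparent
    AUC. ``n_boot=0`` reports cross-validation only.
    """
    table = normalize_per_particle(table, markers) if any(
        m + PER_PARTICLE_SUFFIX not in table.columns for m in markers
    ) else table
    y = (table[group_col] == positive_label).to_numpy(dtype=int)
    n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
    if min(n_pos, n_neg) < k:
        raise ExotropyError(f"k={k} exceeds the smaller class count {min(n_pos, n_neg)}")

    labels = table[group_col].to_numpy()
    apparent = fit_logistic_panel(table, markers, positive_label)
    apparent_auc = roc_auc(
        apparent.predicted_prob.to_numpy(), labels, positive_label, n_boot=0
    ).auc

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**32))
    pooled = np.empty(len(y))
    fold_aucs = []
    for train, test in skf.split(np.zeros(len(y)), y):
        res = fit_logistic_panel(table.iloc[train], markers, positive_label)
        probs = res.predict(table.iloc[test]).to_numpy()
        pooled[test] = probs
        fold_aucs.append(
            roc_auc(probs, labels[test], positive_label, n_boot=0).auc
        )
    cv_pooled = roc_auc(pooled, labels, positive_label, n_boot=0).auc

    report = ValidationReport(
        apparent_auc=float(apparent_auc),
        cv_fold_aucs=[float(a) for a in fold_aucs],
        cv_pooled_auc=float(cv_pooled),
        k=k,
        n_boot=n_boot,
        seed=seed,
    )
    if n_boot <= 0:
        return report

    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    boot_aucs = np.empty(n_boot)
    optimisms = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate(
            [
                pos_idx[rng.integers(0, n_pos, n_pos)],
                neg_idx[rng.integers(0, n_neg, n_neg)],
            ]
        )
        boot_table = table.iloc[idx].reset_index(drop=True)
        res_b = fit_logistic_panel(boot_table, markers, positive_label)
        auc_boot = roc_auc(
            res_b.predicted_prob.to_numpy(),
            boot_table[group_col].to_numpy(),
            positive_label,
            n_boot=0,
        ).auc
        auc_orig = roc_auc(
            res_b.predict(table).to_numpy(), labels, positive_label, n_boot=0
        ).auc
        boot_aucs[b] = auc_boot
        optimisms[b] = auc_boot - auc_orig
    report.bootstrap_aucs = [float(a) for a in boot_aucs]
    report.ci_low = float(np.quantile(boot_aucs, 0.025))
    report.ci_high = float(np.quantile(boot_aucs, 0.975))
    report.optimism = float(np.mean(optimisms))
    report.optimism_corrected_auc = float(apparent_auc - report.optimism)
    return report


# ---------------------------------------------------------------------------
# Cohort summary


def _format_count_pct(count: int, total: int) -> str:
    """``"n (p)"`` with one-decimal half-up percentage, Table-1 style."""
    pct = (Decimal(count) * 100 / Decimal(total)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP
    )
    return f"{count} ({pct})"


def cohort_summary(
    table: pd.DataFrame,
    variables: list[str],
    group_col: str = "group",
) -> pd.DataFrame:
    """Per-group counts and percentages for categorical cohort variables.

    Boolean variables yield one row counting ``True``; categorical
    variables yield one row per level. Cells are formatted
    ``"n (p)"`` with the percentage of the group size at one decimal,
    half-up rounding.
    """
    if group_col not in table.columns:
        raise ExotropyError(f"missing group column {group_col!r}")
    groups = list(dict.fromkeys(table[group_col]))
    sizes = {g: int((table[group_col] == g).sum()) for g in groups}
    rows = []
    index = []
    for var in variables:
        if var not in table.columns:
            raise ExotropyError(f"unknown variable {var!r}")
        col = table[var]
        if col.dtype == bool:
            levels = [True]
        else:
            levels = sorted(col.dropna().unique().tolist(), key=str)
        for level in levels:
            cells = {}
            for g in groups:
                count = int(((table[group_col] == g) & (col == level)).sum())
                cells[g] = _format_count_pct(count, sizes[g])
            rows.append(cells)
            index.append(var if col.dtype == bool else f"{var}={level}")
    return pd.DataFrame(rows, index=index, columns=groups)
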