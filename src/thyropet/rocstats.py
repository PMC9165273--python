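"""Rule-out threshold analysis: ROC curves, cut-off selection, and
diagnostic-accuracy tables with exact binomial confidence intervals.

The clinical logic: a useful rule-out test for indeterminate thyroid nodules
needs sensitivity >= 95% (NPV comparable to benign cytology); at the chosen
SUV cut-off the benign call rate — the fraction of test-negative cases — is
the potential surgery-avoidance yield. Higher SUV means more suspicious, so a
case is test-positive iff its value >= cut-off. All proportions carry exact
Clopper–Pearson 95% intervals; AUCs carry DeLong intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


def clopper_pearson(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial CI from beta quantiles, returned in percent."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    alpha = 1.0 - level
    low = 0.0 if successes == 0 else stats.beta.ppf(alpha / 2, successes, n - successes + 1)
    high = 1.0 if successes == n else stats.beta.ppf(1 - alpha / 2, successes + 1, n - successes)
    return 100.0 * float(low), 100.0 * float(high)


@dataclass
class Proportion:
    """A percentage with its exact binomial CI; undefined if the denominator is 0."""

    numerator: int
    denominator: int
    level: float = 0.95

    @property
    def defined(self) -> bool:
        return self.denominator > 0

    @property
    def percent(self) -> float | None:
        if not self.defined:
            return None
        return 100.0 * self.numerator / self.denominator

    @property
    def ci(self) -> tuple[float, float] | None:
        if not self.defined:
            return None
        return clopper_pearson(self.numerator, self.denominator, self.level)

    def formatted(self, decimals: int = 1) -> str:
        if not self.defined:
            return "n/a"
        lo, hi = self.ci
        return f"{self.percent:.{decimals}f} ({lo:.{decimals}f}-{hi:.{decimals}f})"


@dataclass
class DiagnosticTable:
    """2x2 counts and the five rule-out accuracy measures with exact CIs."""

    tp: int
    fp: int
    tn: int
    fn: int
    stratum: str = "all"
    cut_off: float | None = None
    level: float = 0.95

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        if self.n < 1:
            raise ValueError("empty table")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> Proportion:
        return Proportion(self.tp, self.tp + self.fn, self.level)

    @property
    def specificity(self) -> Proportion:
        return Proportion(self.tn, self.tn + self.fp, self.level)

    @property
    def npv(self) -> Proportion:
        return Proportion(self.tn, self.tn + self.fn, self.level)

    @property
    def ppv(self) -> Proportion:
        return Proportion(self.tp, self.tp + self.fp, self.level)

    @property
    def benign_call_rate(self) -> Proportion:
        return Proportion(self.tn + self.fn, self.n, self.level)

    def to_row(self) -> dict:
        row: dict = {
            "stratum": self.stratum,
            "cut_off": self.cut_off,
            "n": self.n,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
        }
        for name in ("sensitivity", "specificity", "npv", "ppv", "benign_call_rate"):
            prop: Proportion = getattr(self, name)
            row[name] = prop.percent
            row[f"{name}_ci_low"], row[f"{name}_ci_high"] = prop.ci if prop.defined else (None, None)
        return row


def diagnostic_table(
    labels, test_positive, stratum: str = "all", cut_off: float | None = None
) -> DiagnosticTable:
    """Build the 2x2 table from per-case outcome labels and test calls."""
    y = np.asarray(labels).astype(bool)
    t = np.asarray(test_positive).astype(bool)
    if y.shape != t.shape:
        raise ValueError("labels and test calls differ in length")
    return DiagnosticTable(
        tp=int((y & t).sum()),
        fp=int((~y & t).sum()),
        tn=int((~y & ~t).sum()),
        fn=int((y & ~t).sum()),
        stratum=stratum,
        cut_off=cut_off,
    )


def find_cutoff(values, labels, min_sensitivity: float = 0.95, rounded: bool = False):
    """Largest cut-off (test-positive iff value >= cut-off) with sensitivity
    >= ``min_sensitivity``.

    Candidates are the observed values (rounded to one decimal when
    ``rounded``, matching published presentation); among cut-offs of equal
    sensitivity the largest maximises specificity. If no finite cut-off
    reaches the required sensitivity, the minimum value is returned with a
    warning (every case test-positive).
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels).astype(bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    candidates = np.unique(np.round(v, 1) if rounded else v)
    pos = v[y]
    best = None
    for c in candidates:  # ascending
        sens = (pos >= c).mean()
        if sens >= min_sensitivity:
            best = c  # keep the largest satisfying candidate
    if best is None:
        warnings.warn("no cut-off reaches the required sensitivity; returning minimum value")
        best = candidates[0]
    return float(best)


@dataclass
class RocResult:
    """Empirical ROC curve with trapezoidal AUC and DeLong CI."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    metric: str = ""
    stratum: str = "all"
    tables: list = field(default_factory=list, repr=False)


def _delong_variance(values: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """DeLong AUC and its variance via midrank placements."""
    pos, neg = values[y], values[~y]
    m, n = len(pos), len(neg)
    all_v = np.concatenate([pos, neg])
    rank_all = stats.rankdata(all_v)
    rank_pos = stats.rankdata(pos)
    rank_neg = stats.rankdata(neg)
    v10 = (rank_all[:m] - rank_pos) / n  # placement of each positive
    v01 = 1.0 - (rank_all[m:] - rank_neg) / m  # placement of each negative
    auc = v10.mean()
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def roc_with_auc(values, labels, metric: str = "", stratum: str = "all", level: float = 0.95) -> RocResult:
    """Full empirical ROC with trapezoidal AUC (equal to the rank AUC) and
    DeLong confidence interval."""
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels).astype(bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    thresholds = np.concatenate([[-np.inf], np.unique(v), [np.inf]])
    sens = np.array([(v[y] >= t).mean() for t in thresholds])
    spec = np.array([(v[~y] < t).mean() for t in thresholds])
    # trapezoid over (1-spec, sens), sorted by increasing false-positive rate
    # (and by sensitivity within tied FPR, so vertical ROC jumps add no area)
    fpr = 1.0 - spec
    order = np.lexsort((sens, fpr))
    auc = float(np.trapezoid(sens[order], fpr[order]))
    d_auc, var = _delong_variance(v, y)
    z = stats.norm.ppf(1 - (1 - level) / 2)
    half = z * np.sqrt(var)
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        auc_ci=(float(np.clip(d_auc - half, 0, 1)), float(np.clip(d_auc + half, 0, 1))),
        metric=metric,
        stratum=stratum,
    )


SUV_METRICS = ("suv_max", "suv_peak", "suv_max_ratio", "suv_peak_ratio")


def stratified_analysis(
    cohort_frame,
    metrics=SUV_METRICS,
    min_sensitivity: float = 0.95,
    strata: dict | None = None,
):
    """Per-stratum, per-metric threshold analysis in the published layout.

    ``cohort_frame`` needs columns: label (or is_malignant boolean),
    cytology_group, visual_positive and the SUV metric columns. Default
    strata: all, non-Hürthle, Hürthle, FDG-positive non-Hürthle. Returns
    {stratum: {"tables": [DiagnosticTable...], "roc": {metric: RocResult}}}.
    """
    frame = cohort_frame.copy()
    if "is_malignant" not in frame.columns:
        frame["is_malignant"] = frame["label"] == "malignant_or_borderline"
    hurthle = frame["cytology_group"] == "HCN/SHCN"
    if strata is None:
        strata = {
            "all": np.ones(len(frame), dtype=bool),
            "non_hurthle": ~hurthle.to_numpy(),
            "hurthle": hurthle.to_numpy(),
            "fdg_positive_non_hurthle": (~hurthle & frame["visual_positive"]).to_numpy(),
        }
    results: dict = {}
    for name, sel in strata.items():
        sub = frame[sel]
        if len(sub) == 0:
            warnings.warn(f"stratum {name!r} is empty; skipped")
            continue
        y = sub["is_malignant"].to_numpy()
        tables = []
        rocs = {}
        if "visual_positive" in sub.columns:
            tables.append(
                diagnostic_table(y, sub["visual_positive"].to_numpy(), stratum=f"{name}/visual")
            )
        single_class = bool(y.all() or not y.any())
        for metric in metrics:
            vals = sub[metric].to_numpy()
            if single_class:
                warnings.warn(f"stratum {name!r} single-class: no ROC for {metric}")
                continue
            cut = find_cutoff(vals, y, min_sensitivity)
            tables.append(
                diagnostic_table(y, vals >= cut, stratum=f"{name}/{metric}", cut_off=cut)
            )
            rocs[metric] = roc_with_auc(vals, y, metric=metric, stratum=name)
        results[name] = {"tables": tables, "roc": rocs}
    return results


def tables_to_frame(results: dict):
    """Flatten a stratified_analysis result into a tidy DataFrame."""
    import pandas as pd

    rows = []
    for name, block in results.items():
        for table in block["tables"]:
            row = table.to_row()
            for metric, roc in block["roc"].items():
                if row["stratum"].endswith("/" + metric):
                    row["auc"] = roc.auc
                    row["auc_ci_low"], row["auc_ci_high"] = roc.auc_ci
            rows.append(row)
    return pd.DataFrame(rows)
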