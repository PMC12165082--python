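"""Slide-level diagnostic model and cohort statistics.

A slide is summarized by its tumor-cell percentage, ETC% = 100 x (predicted
tumor cells) / (QC-passed cells), and called positive when ETC% reaches the
operating cutoff (0.2% by default, boundary inclusive). Cohort-level
evaluation uses standard 2x2 contingency tables: sensitivity, specificity,
PPV and NPV with exact Clopper-Pearson 95% intervals (configurable to
Wald), rank-based ROC AUC with a Wald interval, optimal-cutoff discovery,
sensitivity-corrected proportions, and nonparametric group comparisons.

Percentages are reported to one decimal, round-half-up.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import config

log = logging.getLogger("lessel.diagnosis")


def round1(x: float) -> float:
    """Round to one decimal, half away from zero (table convention)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# slide-level model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SlideResult:
    """Per-slide totals and the binary diagnostic call."""

    slide_id: str
    n_total_cells: int
    n_predicted_etc: int
    etc_percent: float
    call: bool

    def __post_init__(self) -> None:
        if not (0 <= self.n_predicted_etc <= max(self.n_total_cells, 0)):
            raise ValueError("predicted tumor cells must be within [0, total]")


def etc_fraction(n_etc: int, n_total: int) -> float:
    """Tumor-cell percentage of a slide."""
    if n_total <= 0:
        raise ValueError("total cell count must be positive")
    return 100.0 * n_etc / n_total


def slide_call(etc_percent: float, cutoff: float = config.ETC_CUTOFF_PCT) -> bool:
    """Positive when the tumor-cell percentage reaches the cutoff
    (boundary counts as positive)."""
    return etc_percent >= cutoff


# ---------------------------------------------------------------------------
# contingency metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_calls(cls, calls: Sequence[bool | int], truths: Sequence[bool | int]) -> "ConfusionTable":
        c = np.asarray(calls).astype(bool)
        t = np.asarray(truths).astype(bool)
        if c.shape != t.shape:
            raise ValueError("calls and truths must align")
        return cls(int((c & t).sum()), int((c & ~t).sum()),
                   int((~c & t).sum()), int((~c & ~t).sum()))


@dataclass(frozen=True)
class MetricCI:
    value: float | None            # percent; None when the margin is zero
    lo: float | None = None
    hi: float | None = None


@dataclass(frozen=True)
class MetricsWithCI:
    sensitivity: MetricCI
    specificity: MetricCI
    ppv: MetricCI
    npv: MetricCI


def proportion_ci(k: int, n: int, method: str = "clopper-pearson",
                  level: float = 0.95) -> tuple[float, float]:
    """95% CI of a binomial proportion, in percent."""
    if n == 0:
        raise ValueError("empty margin")
    a = 1.0 - level
    if method == "clopper-pearson":
        lo = 0.0 if k == 0 else stats.beta.ppf(a / 2, k, n - k + 1)
        hi = 1.0 if k == n else stats.beta.ppf(1 - a / 2, k + 1, n - k)
    elif method == "wald":
        p = k / n
        z = stats.norm.ppf(1 - a / 2)
        se = np.sqrt(p * (1 - p) / n)
        lo, hi = max(0.0, p - z * se), min(1.0, p + z * se)
    else:
        raise ValueError(f"unknown CI method: {method}")
    return 100.0 * lo, 100.0 * hi


def _metric(k: int, n: int, ci_method: str) -> MetricCI:
    if n == 0:
        return MetricCI(None)
    lo, hi = proportion_ci(k, n, ci_method)
    return MetricCI(100.0 * k / n, lo, hi)


def confusion_metrics(table: ConfusionTable,
                      ci_method: str = "clopper-pearson") -> MetricsWithCI:
    """Sensitivity, specificity, PPV, NPV (percent) with 95% CIs.

    A metric whose margin is zero is reported as undefined (None) rather
    than raising.
    """
    return MetricsWithCI(
        sensitivity=_metric(table.tp, table.tp + table.fn, ci_method),
        specificity=_metric(table.tn, table.tn + table.fp, ci_method),
        ppv=_metric(table.tp, table.tp + table.fp, ci_method),
        npv=_metric(table.tn, table.tn + table.fn, ci_method),
    )


def corrected_proportion(observed_percent: float, sensitivity_percent: float) -> float:
    """Scale an observed tumor-cell proportion by the detector's sensitivity.

    corrected = 100 * observed / sensitivity, capped at 100 with a warning
    (an observed proportion can exceed sensitivity only through false
    positives).
    """
    if sensitivity_percent <= 0:
        raise ValueError("sensitivity must be positive")
    corrected = 100.0 * observed_percent / sensitivity_percent
    if corrected > 100.0:
        log.warning("corrected proportion %.1f%% exceeds 100%%; capping", corrected)
        return 100.0
    return corrected


# ---------------------------------------------------------------------------
# cutoff discovery and ROC
# ---------------------------------------------------------------------------

def find_cutoff(etc_percents: Sequence[float], truths: Sequence[int],
                rule: str = "max-sens-at-max-spec") -> dict:
    """Pick the slide-level operating cutoff from discovery data.

    Candidates are midpoints between sorted unique values (plus sentinels
    just outside the range). The default rule keeps the candidates with the
    highest achievable specificity and among them maximizes sensitivity;
    the 'youden' rule maximizes sensitivity + specificity - 1. Ties resolve
    to the smallest qualifying cutoff. Returns the cutoff, its operating
    sensitivity/specificity and the rule applied.
    """
    x = np.asarray(etc_percents, dtype=float)
    t = np.asarray(truths).astype(int)
    if len(set(t.tolist())) < 2:
        raise ValueError("both classes required to pick a cutoff")
    u = np.unique(x)
    if len(u) == 1:
        log.warning("degenerate cutoff search: a single distinct value")
        candidates = np.array([u[0]])
    else:
        candidates = np.concatenate([[u[0] - 1e-9], (u[:-1] + u[1:]) / 2, [u[-1] + 1e-9]])
    sens = np.array([(x[t == 1] >= c).mean() for c in candidates])
    spec = np.array([(x[t == 0] < c).mean() for c in candidates])
    if rule == "max-sens-at-max-spec":
        best_spec = spec.max()
        pool = np.flatnonzero(spec == best_spec)
        k = pool[np.argmax(sens[pool])]
    elif rule == "youden":
        k = int(np.argmax(sens + spec - 1.0))
    else:
        raise ValueError(f"unknown cutoff rule: {rule}")
    return {"cutoff": float(candidates[k]), "sensitivity": float(100 * sens[k]),
            "specificity": float(100 * spec[k]), "rule": rule}


@dataclass(frozen=True)
class AucWithCI:
    auc: float
    lo: float
    hi: float


def roc_auc(scores: Sequence[float], labels: Sequence[int],
            level: float = 0.95) -> AucWithCI:
    """Rank-based ROC AUC (equals the trapezoidal area) with a Wald CI.

    AUC is the normalized Mann-Whitney statistic (ties count half); the CI
    uses the Hanley-McNeil variance estimate, clipped to [0, 1].
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n1, n0 = int((y == 1).sum()), int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required for ROC analysis")
    ranks = stats.rankdata(s)
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    q1 = auc / (2 - auc)
    q2 = 2 * auc ** 2 / (1 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc ** 2)
           + (n0 - 1) * (q2 - auc ** 2)) / (n1 * n0)
    z = stats.norm.ppf(1 - (1 - level) / 2)
    half = z * np.sqrt(max(var, 0.0))
    return AucWithCI(float(auc), float(max(0.0, auc - half)), float(min(1.0, auc + half)))


def roc_points(scores: Sequence[float], labels: Sequence[int]) -> pd.DataFrame:
    """ROC curve points (fpr, tpr, threshold), thresholds descending."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    thresholds = np.concatenate([[np.inf], np.unique(s)[::-1]])
    rows = [(float((s[y == 0] >= t).mean()), float((s[y == 1] >= t).mean()), float(t))
            for t in thresholds]
    return pd.DataFrame(rows, columns=["fpr", "tpr", "threshold"])


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def compare_groups(x, y=None, kind: str = "mann-whitney") -> tuple[float, float]:
    """Two-sided nonparametric comparisons used in cohort reporting.

    kind: 'mann-whitney' (two independent groups), 'wilcoxon-paired'
    (paired measurements; identical vectors return p = 1 by convention),
    or 'chi-square' (x is a 2x2 table). Returns (statistic, p).
    """
    if kind == "mann-whitney":
        if min(len(x), len(y)) < 2:
            raise ValueError("groups too small for a Mann-Whitney test")
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
    elif kind == "wilcoxon-paired":
        d = np.asarray(x, float) - np.asarray(y, float)
        if np.all(d == 0):
            return 0.0, 1.0
        res = stats.wilcoxon(x, y, alternative="two-sided")
    elif kind == "chi-square":
        res = stats.chi2_contingency(np.asarray(x))
        return float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown test kind: {kind}")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# cohort report
# ---------------------------------------------------------------------------

def cohort_report(
    slide_results: pd.DataFrame,
    ci_method: str = "clopper-pearson",
) -> dict:
    """Model-vs-cytology cohort evaluation.

    ``slide_results`` needs columns patient_id, truth (1 = cancer), call
    (model positive) and optionally cytology_result, stage, subtype. The
    report carries confusion tables and metrics for the model (and
    cytology when present), sensitivity stratified by stage/subtype, the
    model's detection rate among cytology-negative cancer patients, and the
    percent increase in positive findings over cytology.
    """
    df = slide_results
    model = ConfusionTable.from_calls(df["call"], df["truth"])
    report: dict = {
        "model_table": model,
        "model_metrics": confusion_metrics(model, ci_method),
        "n_patients": len(df),
    }
    if "cytology_result" in df.columns:
        cyto = ConfusionTable.from_calls(df["cytology_result"], df["truth"])
        report["cytology_table"] = cyto
        report["cytology_metrics"] = confusion_metrics(cyto, ci_method)
        cancer = df[df["truth"].astype(bool)]
        cyto_pos = cancer[cancer["cytology_result"].astype(bool)]
        cyto_neg = cancer[~cancer["cytology_result"].astype(bool)]
        report["detected_of_cytology_positive"] = (
            int(cyto_pos["call"].sum()), len(cyto_pos))
        report["detected_of_cytology_negative"] = (
            int(cyto_neg["call"].sum()), len(cyto_neg))
        n_cyto_pos = int(df["cytology_result"].astype(bool).sum())
        n_model_pos = int(df["call"].astype(bool).sum())
        report["positive_increase_pct"] = (
            100.0 * (n_model_pos - n_cyto_pos) / n_cyto_pos if n_cyto_pos else None)
    for col in ("stage", "subtype"):
        if col in df.columns:
            strat = {}
            cancer = df[df["truth"].astype(bool)]
            for val, grp in cancer.groupby(col):
                strat[val] = (int(grp["call"].sum()), len(grp))
            report[f"sensitivity_by_{col}"] = strat
    return report


def metrics_to_frame(m: MetricsWithCI) -> pd.DataFrame:
    rows = []
    for name in ("sensitivity", "specificity", "ppv", "npv"):
        mc: MetricCI = getattr(m, name)
        rows.append((name,
                     None if mc.value is None else round1(mc.value),
                     None if mc.lo is None else round1(mc.lo),
                     None if mc.hi is None else round1(mc.hi)))
    return pd.DataFrame(rows, columns=["metric", "percent", "ci_lo", "ci_hi"])
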