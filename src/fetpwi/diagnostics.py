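"""Diagnostic-performance statistics for progression-vs-treatment-change calls.

Positive class throughout is POD (progression of disease); negative is TRC
(treatment-related change). The module provides:

* ROC analysis with orientation handling (metrics for which *low* values
  indicate progression, such as late-window slopes and time-to-peak, are
  sign-flipped internally so every ROC assumes higher => more POD-like,
  and reported cutoffs are mapped back to the original scale);
* Hanley-McNeil closed-form AUC standard errors, 95% CIs and one-sided
  tests of AUC > 0.5;
* cutoff optimization by the geometric mean of sensitivity and
  specificity over midpoint candidate thresholds;
* contingency-table summary statistics with report-style rounding;
* the Hanley paired (correlated) AUC comparison;
* Benjamini-Hochberg multiplicity adjustment;
* rule-based PET / perfusion-MRI calls and their concordance accounting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm, rankdata
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score, roc_curve as _sk_roc_curve
from statsmodels.stats.multitest import multipletests

__all__ = [
    "POD",
    "TRC",
    "MetricOrientation",
    "RocCurve",
    "Cutoff",
    "ContingencyTable",
    "ThresholdRules",
    "ThresholdDecision",
    "HanleyComparison",
    "ConcordanceSummary",
    "roc_curve",
    "auc_ci",
    "optimal_cutoff",
    "contingency_metrics",
    "format_performance",
    "apply_thresholds",
    "hanley_compare",
    "benjamini_hochberg",
    "concordance_summary",
    "mann_whitney_auc",
    "CutoffClassifier",
    "ThresholdRuleClassifier",
]

POD = "POD"
TRC = "TRC"

#: Metrics for which smaller values indicate progression by default.
LOWER_INDICATES_POD = frozenset(
    {"suv_slope", "tbr_slope", "ttp_s", "ttp", "slope"}
)


@dataclass(frozen=True)
class MetricOrientation:
    """Direction in which a metric points toward progression."""

    name: str
    higher_indicates_pod: bool = True

    @classmethod
    def default_for(cls, name: str) -> "MetricOrientation":
        return cls(name, higher_indicates_pod=name not in LOWER_INDICATES_POD)

    def transform(self, scores: np.ndarray) -> np.ndarray:
        """Map scores so that larger transformed values are more POD-like."""
        scores = np.asarray(scores, dtype=float)
        return scores if self.higher_indicates_pod else -scores

    @property
    def inequality(self) -> str:
        return ">" if self.higher_indicates_pod else "<"


def _binary_labels(labels: Sequence[str]) -> np.ndarray:
    arr = np.asarray(labels)
    bad = set(np.unique(arr)) - {POD, TRC}
    if bad:
        raise ValueError(f"labels must be POD/TRC, found {sorted(bad)}")
    return (arr == POD).astype(int)


def mann_whitney_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """AUC as the Mann-Whitney concordance statistic (half credit for ties).

    ``y`` is 1 for POD, 0 for TRC; ``scores`` are already oriented so
    higher means more POD-like.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    n1 = int(y.sum())
    n0 = int(y.size - n1)
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


@dataclass
class RocCurve:
    """ROC coordinates plus Hanley-McNeil AUC inference for one metric."""

    metric: str
    orientation: MetricOrientation
    thresholds: np.ndarray  # transformed scale (higher => POD)
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_se: float
    ci95: tuple[float, float]
    p_auc_gt_half: float
    n_pod: int
    n_trc: int
    # raw material kept for cutoff optimization
    scores_transformed: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)


def hanley_mcneil_se(auc: float, n_pod: int, n_trc: int) -> float:
    """Closed-form standard error of a trapezoidal AUC (Hanley-McNeil 1982)."""
    if n_pod < 1 or n_trc < 1:
        raise ValueError("both classes need at least one observation")
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pod - 1) * (q1 - auc * auc)
        + (n_trc - 1) * (q2 - auc * auc)
    ) / (n_pod * n_trc)
    return float(np.sqrt(max(var, 0.0)))


def auc_ci(
    auc: float, n_pod: int, n_trc: int
) -> tuple[float, float, tuple[float, float]]:
    """Hanley-McNeil SE, one-sided p for AUC > 0.5, and a truncated 95% CI.

    Returns ``(se, ci95, p_auc_gt_half)`` packed as ``(se, (lo, hi), p)``.
    """
    se = hanley_mcneil_se(auc, n_pod, n_trc)
    lo = max(0.0, auc - 1.96 * se)
    hi = min(1.0, auc + 1.96 * se)
    if se == 0.0:
        p = 0.0 if auc > 0.5 else (0.5 if auc == 0.5 else 1.0)
    else:
        p = float(norm.sf((auc - 0.5) / se))
    return se, (lo, hi), p


def roc_curve(
    scores: Sequence[float],
    labels: Sequence[str],
    orientation: MetricOrientation | None = None,
    metric: str = "score",
) -> RocCurve:
    """Empirical ROC over all distinct score thresholds.

    Sensitivity is the fraction of POD cases detected; specificity the
    fraction of TRC cases correctly rejected.
    """
    if orientation is None:
        orientation = MetricOrientation.default_for(metric)
    scores = np.asarray(scores, dtype=float)
    if np.any(np.isnan(scores)):
        raise ValueError("scores contain missing values; drop them upstream")
    y = _binary_labels(labels)
    n_pod = int(y.sum())
    n_trc = int(y.size - n_pod)
    if n_pod == 0 or n_trc == 0:
        raise ValueError("ROC needs both POD and TRC cases")
    t = orientation.transform(scores)
    fpr, tpr, thresholds = _sk_roc_curve(y, t)
    auc = float(roc_auc_score(y, t))
    se, ci, p = auc_ci(auc, n_pod, n_trc)
    return RocCurve(
        metric=metric,
        orientation=orientation,
        thresholds=thresholds,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        auc=auc,
        auc_se=se,
        ci95=ci,
        p_auc_gt_half=p,
        n_pod=n_pod,
        n_trc=n_trc,
        scores_transformed=t,
        y=y,
    )


@dataclass(frozen=True)
class Cutoff:
    """An operating point on the original metric scale.

    ``direction`` is ``">"`` when values above the threshold call POD and
    ``"<"`` when values below it do.
    """

    threshold: float
    direction: str
    sensitivity: float
    specificity: float
    gmean: float

    def call(self, value: float) -> str:
        if self.direction == ">":
            return POD if value > self.threshold else TRC
        return POD if value < self.threshold else TRC


def optimal_cutoff(roc: RocCurve) -> Cutoff:
    """Threshold maximizing the geometric mean of sensitivity and specificity.

    Candidates are midpoints between adjacent distinct (transformed)
    scores plus +/-infinity sentinels; ties resolve to the smallest
    transformed threshold. The returned threshold is mapped back to the
    original metric scale with the matching inequality direction.
    """
    t = roc.scores_transformed
    y = roc.y
    distinct = np.unique(t)
    candidates = np.concatenate(
        [[-np.inf], (distinct[:-1] + distinct[1:]) / 2.0, [np.inf]]
    )
    n_pod = y.sum()
    n_trc = y.size - n_pod
    best = None
    for c in candidates:  # ascending, so ties keep the smallest threshold
        pred = t > c
        sens = (pred & (y == 1)).sum() / n_pod
        spec = (~pred & (y == 0)).sum() / n_trc
        g = np.sqrt(sens * spec)
        if best is None or g > best[0] + 1e-12:
            best = (g, c, sens, spec)
    g, c, sens, spec = best
    if roc.orientation.higher_indicates_pod:
        threshold, direction = float(c), ">"
    else:
        threshold, direction = float(-c), "<"
    return Cutoff(
        threshold=threshold,
        direction=direction,
        sensitivity=float(sens),
        specificity=float(spec),
        gmean=float(g),
    )


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 diagnostic table against the reference-standard POD/TRC labels."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        if self.n == 0:
            raise ValueError("contingency table is empty")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_calls(
        cls, calls: Sequence[str], truth: Sequence[str]
    ) -> "ContingencyTable":
        calls = np.asarray(calls)
        truth = np.asarray(truth)
        if calls.shape != truth.shape:
            raise ValueError("calls and truth must have equal length")
        return cls(
            tp=int(((calls == POD) & (truth == POD)).sum()),
            fp=int(((calls == POD) & (truth == TRC)).sum()),
            tn=int(((calls == TRC) & (truth == TRC)).sum()),
            fn=int(((calls == TRC) & (truth == POD)).sum()),
        )


def _safe_div(num: float, den: float) -> float | None:
    return num / den if den > 0 else None


def contingency_metrics(t: ContingencyTable) -> dict[str, float | None]:
    """Standard diagnostic summary statistics as raw proportions/ratios.

    Metrics whose denominator is zero are reported as ``None``
    (undefined) rather than raising.
    """
    sens = _safe_div(t.tp, t.tp + t.fn)
    spec = _safe_div(t.tn, t.tn + t.fp)
    out: dict[str, float | None] = {
        "accuracy": _safe_div(t.tp + t.tn, t.n),
        "sensitivity": sens,
        "specificity": spec,
        "ppv": _safe_div(t.tp, t.tp + t.fp),
        "npv": _safe_div(t.tn, t.tn + t.fn),
        "plr": None,
        "nlr": None,
        "fpr": _safe_div(t.fp, t.fp + t.tn),
        "fnr": _safe_div(t.fn, t.fn + t.tp),
    }
    if sens is not None and spec is not None:
        if spec < 1:
            out["plr"] = sens / (1.0 - spec)
        if spec > 0:
            out["nlr"] = (1.0 - sens) / spec
    return out


def _round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


_PERCENT_KEYS = ("accuracy", "sensitivity", "specificity", "ppv", "npv", "fpr", "fnr")


def format_performance(metrics: Mapping[str, float | None]) -> dict[str, str]:
    """Report-style formatting: percentages rounded half-up to integers,
    likelihood ratios to their customary 1 (positive) / 2 (negative)
    decimals. Undefined metrics render as ``"NA"``."""
    out: dict[str, str] = {}
    for key in _PERCENT_KEYS:
        v = metrics.get(key)
        out[key] = "NA" if v is None else f"{_round_half_up(100 * v, 0):.0f}%"
    plr = metrics.get("plr")
    nlr = metrics.get("nlr")
    out["plr"] = "NA" if plr is None else f"{_round_half_up(plr, 1):.1f}"
    out["nlr"] = "NA" if nlr is None else f"{_round_half_up(nlr, 2):.2f}"
    return out


@dataclass(frozen=True)
class ThresholdRules:
    """Literature/institutional decision rules.

    Each rule is ``(metric, inequality, threshold)`` with strict
    comparison; the modality calls POD when any of its rules fires.
    Defaults are the institutional criteria: PET fires on
    ``tbr_max > 2.5``, perfusion MRI on ``rcbv > 3`` or
    ``ktrans > 0.26``. Discordant PET/MRI calls resolve to the PET call
    (flagged) under the default ``"pet"`` fusion policy.
    """

    pet_rules: tuple[tuple[str, str, float], ...] = (("tbr_max", ">", 2.5),)
    mri_rules: tuple[tuple[str, str, float], ...] = (
        ("rcbv", ">", 3.0),
        ("ktrans", ">", 0.26),
    )
    fusion: str = "pet"  # discordance resolution policy


@dataclass(frozen=True)
class ThresholdDecision:
    pet_call: str
    mri_call: str
    hybrid_call: str
    discordant: bool
    fired: Mapping[str, bool]


def _rule_fires(metrics: Mapping[str, float], rule: tuple[str, str, float]) -> bool:
    name, op, threshold = rule
    if name not in metrics or metrics[name] is None or np.isnan(metrics[name]):
        raise ValueError(f"metric '{name}' required by threshold rule is missing")
    value = metrics[name]
    if op == ">":
        return value > threshold
    if op == "<":
        return value < threshold
    raise ValueError(f"unsupported inequality {op!r}")


def apply_thresholds(
    metrics: Mapping[str, float],
    rules: ThresholdRules | None = None,
) -> ThresholdDecision:
    """Rule-based PET, MRI and hybrid calls for one patient.

    All comparisons are strict, so a value exactly at its threshold does
    not fire (a lesion "more than" the cutoff is required).
    """
    rules = rules or ThresholdRules()
    fired: dict[str, bool] = {}
    pet_pos = False
    for rule in rules.pet_rules:
        hit = _rule_fires(metrics, rule)
        fired[f"pet:{rule[0]}{rule[1]}{rule[2]}"] = hit
        pet_pos = pet_pos or hit
    mri_pos = False
    for rule in rules.mri_rules:
        hit = _rule_fires(metrics, rule)
        fired[f"mri:{rule[0]}{rule[1]}{rule[2]}"] = hit
        mri_pos = mri_pos or hit
    pet_call = POD if pet_pos else TRC
    mri_call = POD if mri_pos else TRC
    discordant = pet_call != mri_call
    if not discordant:
        hybrid = pet_call
    elif rules.fusion == "pet":
        hybrid = pet_call
    elif rules.fusion == "mri":
        hybrid = mri_call
    else:
        raise ValueError(f"unknown fusion policy {rules.fusion!r}")
    return ThresholdDecision(
        pet_call=pet_call,
        mri_call=mri_call,
        hybrid_call=hybrid,
        discordant=discordant,
        fired=fired,
    )


@dataclass(frozen=True)
class HanleyComparison:
    auc_a: float
    auc_b: float
    r: float
    z: float
    p: float
    alternative: str


def _within_class_corr(a: np.ndarray, b: np.ndarray, y: np.ndarray) -> float:
    rs = []
    for cls in (1, 0):
        av, bv = a[y == cls], b[y == cls]
        if av.size >= 2 and np.std(av) > 0 and np.std(bv) > 0:
            rs.append(float(np.corrcoef(av, bv)[0, 1]))
    return float(np.mean(rs)) if rs else 0.0


def hanley_compare(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[str],
    orientation_a: MetricOrientation | None = None,
    orientation_b: MetricOrientation | None = None,
    alternative: str = "greater",
    r: float | None = None,
) -> HanleyComparison:
    """Paired comparison of two AUCs measured on the same patients.

    ``z = (A_a - A_b) / sqrt(se_a^2 + se_b^2 - 2 r se_a se_b)`` with the
    Hanley-McNeil closed-form SEs and the AUC correlation ``r`` estimated
    as the mean of the within-class Pearson correlations of the two score
    vectors (pass ``r`` explicitly to override; ``r=0`` recovers the
    unpaired comparison). ``alternative="greater"`` tests overperformance
    of metric a.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = _binary_labels(labels)
    if not (a.shape == b.shape == y.shape):
        raise ValueError("paired comparison needs equal-length score vectors")
    n_pod = int(y.sum())
    n_trc = int(y.size - n_pod)
    if n_pod == 0 or n_trc == 0:
        raise ValueError("both classes must be present")
    ta = (orientation_a or MetricOrientation("a")).transform(a)
    tb = (orientation_b or MetricOrientation("b")).transform(b)
    auc_a = mann_whitney_auc(ta, y)
    auc_b = mann_whitney_auc(tb, y)
    se_a = hanley_mcneil_se(auc_a, n_pod, n_trc)
    se_b = hanley_mcneil_se(auc_b, n_pod, n_trc)
    if r is None:
        r = _within_class_corr(ta, tb, y)
    var = se_a**2 + se_b**2 - 2.0 * r * se_a * se_b
    diff = auc_a - auc_b
    if var <= 0:
        # Degenerate (e.g. identical score vectors): no evidence of difference.
        z = 0.0 if diff == 0 else np.sign(diff) * np.inf
        p = 1.0 if diff == 0 else (0.0 if (diff > 0) == (alternative == "greater") else 1.0)
        if alternative == "two-sided" and diff != 0:
            p = 0.0
        return HanleyComparison(auc_a, auc_b, r, float(z), float(p), alternative)
    z = diff / np.sqrt(var)
    if alternative == "greater":
        p = float(norm.sf(z))
    elif alternative == "two-sided":
        p = float(2.0 * norm.sf(abs(z)))
    else:
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    return HanleyComparison(auc_a, auc_b, r, float(z), p, alternative)


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class ConcordanceSummary:
    """PET/MRI agreement accounting against the reference diagnosis."""

    n_concordant: int
    concordant_correct: int
    concordant_accuracy: float | None
    n_discordant: int
    pet_correct_when_discordant_n: int
    pet_correct_when_discordant: float | None
    mri_correct_when_discordant_n: int
    mri_correct_when_discordant: float | None


def concordance_summary(
    pet_calls: Sequence[str],
    mri_calls: Sequence[str],
    truth: Sequence[str],
) -> ConcordanceSummary:
    """Split patients by PET/MRI agreement and score each stratum.

    On concordant cases the shared call is scored against the reference
    standard; on discordant cases each modality is scored separately.
    """
    pet = np.asarray(pet_calls)
    mri = np.asarray(mri_calls)
    y = np.asarray(truth)
    if not (pet.shape == mri.shape == y.shape):
        raise ValueError("call and truth vectors must have equal length")
    for vec, name in ((pet, "pet"), (mri, "mri"), (y, "truth")):
        bad = set(np.unique(vec)) - {POD, TRC}
        if bad:
            raise ValueError(f"{name} calls must be POD/TRC, found {sorted(bad)}")
    conc = pet == mri
    n_conc = int(conc.sum())
    conc_correct = int((pet[conc] == y[conc]).sum())
    n_disc = int((~conc).sum())
    pet_correct = int((pet[~conc] == y[~conc]).sum())
    mri_correct = int((mri[~conc] == y[~conc]).sum())
    return ConcordanceSummary(
        n_concordant=n_conc,
        concordant_correct=conc_correct,
        concordant_accuracy=(conc_correct / n_conc) if n_conc else None,
        n_discordant=n_disc,
        pet_correct_when_discordant_n=pet_correct,
        pet_correct_when_discordant=(pet_correct / n_disc) if n_disc else None,
        mri_correct_when_discordant_n=mri_correct,
        mri_correct_when_discordant=(mri_correct / n_disc) if n_disc else None,
    )


class CutoffClassifier(BaseEstimator, ClassifierMixin):
    """Single-metric POD/TRC classifier with a ROC-learned threshold.

    ``fit`` runs the ROC analysis and stores the geometric-mean-optimal
    operating point; ``predict`` applies it.

    Parameters
    ----------
    higher_indicates_pod:
        Metric orientation; ``None`` resolves the default for
        ``metric_name``.
    """

    def __init__(self, metric_name: str = "score", higher_indicates_pod: bool | None = None):
        self.metric_name = metric_name
        self.higher_indicates_pod = higher_indicates_pod

    def _orientation(self) -> MetricOrientation:
        if self.higher_indicates_pod is None:
            return MetricOrientation.default_for(self.metric_name)
        return MetricOrientation(self.metric_name, self.higher_indicates_pod)

    def fit(self, X, y):
        scores = np.asarray(X, dtype=float).reshape(-1)
        self.roc_ = roc_curve(scores, y, self._orientation(), metric=self.metric_name)
        self.cutoff_ = optimal_cutoff(self.roc_)
        self.auc_ = self.roc_.auc
        self.classes_ = np.array([POD, TRC])
        return self

    def predict(self, X):
        scores = np.asarray(X, dtype=float).reshape(-1)
        return np.array([self.cutoff_.call(v) for v in scores])


class ThresholdRuleClassifier(BaseEstimator, ClassifierMixin):
    """Rule-based hybrid PET/MRI classifier (no fitting: fixed clinical rules).

    ``predict`` consumes a DataFrame-like mapping of metric columns and
    returns the hybrid call per row; per-modality calls are exposed via
    :meth:`decide`.
    """

    def __init__(self, rules: ThresholdRules | None = None):
        self.rules = rules

    def fit(self, X=None, y=None):
        self.rules_ = self.rules or ThresholdRules()
        return self

    def decide(self, rows: Sequence[Mapping[str, float]]) -> list[ThresholdDecision]:
        if not hasattr(self, "rules_"):
            self.fit()
        return [apply_thresholds(dict(row), self.rules_) for row in rows]

    def predict(self, X):
        import pandas as pd

        if isinstance(X, pd.DataFrame):
            rows = X.to_dict("records")
        else:
            rows = list(X)
        return np.array([d.hybrid_call for d in self.decide(rows)])
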