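"""Diagnostic-accuracy and agreement statistics.

These operate on :class:`~lcsleep.signal_io.StudyRecord` rows — either the
bundled pilot-study tables or records produced by running the pipeline on
new data. The positive class is always ``abnormal`` (AHI >= 5). Severity
is scored on three classes with moderate and severe collapsed, per study
night: the predicted class comes from the per-night predicted AHI
(censored "<5" counts as normal) and the actual class from the
gold-standard AHI, falling back to a recorded severity label when no
numeric AHI is available.

Agreement statistics (Bland-Altman bias and limits, median absolute
error, Pearson correlation) use only study nights where both AHI values
are numeric; censored rows carry no numeric estimate to compare.
Differences are oriented actual - predicted, so a positive bias means the
device underestimates, and the limits of agreement use the population SD
with the conventional 1.96 multiplier.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
from scipy import stats

from .errors import ValidationError
from .osa_model import severity_from_ahi, severity_of
from .signal_io import StudyRecord
from .types import Category, Setting, Severity

Scope = Literal["all", "clinic", "home"]


def _in_scope(rec: StudyRecord, scope: Scope) -> bool:
    if scope == "all":
        return True
    if scope == "clinic":
        return rec.setting is Setting.CLINIC_PSG
    if scope == "home":
        return rec.setting in (Setting.HOME_HSAT, Setting.HOME_LC_ONLY)
    raise ValidationError(f"unknown scope {scope!r}")


def round_half_up(x: float, digits: int = 1) -> float:
    """Decimal rounding as printed in clinical reports (0.05 -> 0.1)."""
    q = 10.0 ** digits
    return math.floor(abs(x) * q + 0.5) / q * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class ConfusionMetrics:
    """Binary screening metrics; percentages on 0-100 scale."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp)

    @property
    def ppv(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fp)

    @property
    def npv(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fn)

    def summary(self) -> dict[str, float]:
        return {
            "accuracy": round_half_up(self.accuracy),
            "sensitivity": round_half_up(self.sensitivity),
            "specificity": round_half_up(self.specificity),
            "ppv": round_half_up(self.ppv),
            "npv": round_half_up(self.npv),
        }


@dataclass(frozen=True)
class AgreementStats:
    n_pairs: int
    bias: float                 # mean(actual - predicted), events/h
    lower_limit: float          # bias - 1.96 * population SD
    upper_limit: float
    median_abs_error: float
    pearson_r: float


def confusion_metrics(records: Iterable[StudyRecord], scope: Scope = "all") -> ConfusionMetrics:
    """Per-study-night normal/abnormal confusion counts and rates.

    Studies without both an actual and a predicted category (e.g. the
    zero-duration clinic night) are excluded.
    """
    tp = fp = tn = fn = 0
    for r in records:
        if not _in_scope(r, scope):
            continue
        if r.actual_category is None or r.predicted_category is None:
            continue
        actual_pos = r.actual_category is Category.ABNORMAL
        pred_pos = r.predicted_category is Category.ABNORMAL
        if actual_pos and pred_pos:
            tp += 1
        elif actual_pos:
            fn += 1
        elif pred_pos:
            fp += 1
        else:
            tn += 1
    if tp + fp + tn + fn == 0:
        raise ValidationError(f"no scorable records in scope {scope!r}")
    return ConfusionMetrics(tp, fp, tn, fn)


def _actual_severity(r: StudyRecord) -> Severity | None:
    if r.actual_ahi is not None:
        return severity_from_ahi(r.actual_ahi)
    return r.actual_severity


def _predicted_severity(r: StudyRecord) -> Severity | None:
    if r.predicted_ahi is not None:
        return severity_of(r.predicted_ahi)
    return r.predicted_severity


def severity_accuracy(records: Iterable[StudyRecord], scope: Scope = "all") -> float:
    """Percentage of study nights with matching 3-class severity."""
    ok = total = 0
    for r in records:
        if not _in_scope(r, scope) or not r.has_result:
            continue
        actual, predicted = _actual_severity(r), _predicted_severity(r)
        if actual is None or predicted is None:
            continue
        total += 1
        ok += actual is predicted
    if total == 0:
        raise ValidationError(f"no severity-scorable records in scope {scope!r}")
    return 100.0 * ok / total


def agreement(records: Iterable[StudyRecord]) -> AgreementStats:
    """Bland-Altman agreement over numerically paired AHI estimates."""
    pairs = [
        (r.actual_ahi, r.predicted_ahi.value)
        for r in records
        if r.actual_ahi is not None
        and r.predicted_ahi is not None
        and not r.predicted_ahi.is_censored
    ]
    if len(pairs) < 2:
        raise ValidationError("agreement needs >= 2 numeric AHI pairs")
    actual = np.array([a for a, _ in pairs])
    predicted = np.array([p for _, p in pairs])
    d = actual - predicted
    bias = float(d.mean())
    half_width = 1.96 * float(d.std(ddof=0))
    r = float(stats.pearsonr(actual, predicted).statistic)
    return AgreementStats(
        n_pairs=len(pairs),
        bias=bias,
        lower_limit=bias - half_width,
        upper_limit=bias + half_width,
        median_abs_error=float(np.median(np.abs(d))),
        pearson_r=r,
    )


def subject_level_confusion(records: Iterable[StudyRecord]) -> ConfusionMetrics:
    """Subject-level screening metrics under the max rule.

    A subject is actually abnormal if any gold-standard night was scored
    abnormal, and predicted abnormal if the device called any night
    abnormal — the multi-night "highest AHI" aggregation viewed as a
    binary test. Only records carrying results are counted.
    """
    by_subject: dict[str, list[StudyRecord]] = {}
    for r in records:
        if r.has_result:
            by_subject.setdefault(r.subject_id, []).append(r)
    if not by_subject:
        raise ValidationError("no scored subjects")
    tp = fp = tn = fn = 0
    for nights in by_subject.values():
        actual_pos = any(n.actual_category is Category.ABNORMAL for n in nights)
        pred_pos = any(n.predicted_category is Category.ABNORMAL for n in nights)
        if actual_pos and pred_pos:
            tp += 1
        elif actual_pos:
            fn += 1
        elif pred_pos:
            fp += 1
        else:
            tn += 1
    return ConfusionMetrics(tp, fp, tn, fn)


def compare_hsat_effect(
    hsat_records: Iterable[StudyRecord],
    lc_only_records: Iterable[StudyRecord],
    censored_value: float = 2.5,
):
    """Paired t-test: does wearing HSAT sensors change the device's AHI?

    Per-subject mean predicted AHI on HSAT-monitored nights is compared
    with the mean on load-cell-only nights. Censored "<5" estimates enter
    as ``censored_value`` (midpoint of the normal range) — the handling
    of censored nights is a documented convention, not a measured fact.

    Returns
    -------
    (t, p) : tuple of float
        Two-sided paired t statistic and p-value.
    """

    def per_subject(records: Iterable[StudyRecord]) -> dict[str, float]:
        acc: dict[str, list[float]] = {}
        for r in records:
            if r.predicted_ahi is None:
                continue
            acc.setdefault(r.subject_id, []).append(
                r.predicted_ahi.numeric(censored_as=censored_value)
            )
        return {s: float(np.mean(v)) for s, v in acc.items()}

    a, b = per_subject(hsat_records), per_subject(lc_only_records)
    common = sorted(set(a) & set(b))
    if len(common) < 3:
        raise ValidationError("paired comparison needs >= 3 subjects in both arms")
    res = stats.ttest_rel([a[s] for s in common], [b[s] for s in common])
    return float(res.statistic), float(res.pvalue)


def evaluation_report(clinic: list[StudyRecord], hsat: list[StudyRecord],
                      lc_only: list[StudyRecord] | None = None) -> dict:
    """All headline metrics as one nested dict (see the CLI's --json)."""
    both = clinic + hsat
    ba = agreement(both)
    report = {
        "detection": {
            "all": confusion_metrics(both, "all").summary(),
            "clinic": confusion_metrics(both, "clinic").summary(),
            "home": confusion_metrics(both, "home").summary(),
        },
        "severity_accuracy": {
            "all": round_half_up(severity_accuracy(both, "all")),
            "clinic": round_half_up(severity_accuracy(both, "clinic")),
            "home": round_half_up(severity_accuracy(both, "home")),
        },
        "agreement": {
            "n_pairs": ba.n_pairs,
            "bias": round_half_up(ba.bias, 2),
            "lower_limit": round_half_up(ba.lower_limit, 2),
            "upper_limit": round_half_up(ba.upper_limit, 2),
            "median_abs_error": round_half_up(ba.median_abs_error, 2),
            "pearson_r": round_half_up(ba.pearson_r, 2),
        },
        "subject_level": subject_level_confusion(both).summary(),
    }
    if lc_only is not None:
        t, p = compare_hsat_effect(hsat, lc_only)
        report["hsat_effect"] = {"t": round_half_up(t, 2), "p": round_half_up(p, 2)}
    return report
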