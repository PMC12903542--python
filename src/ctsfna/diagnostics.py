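"""Diagnostic-accuracy statistics for paired slide-level tests.

Cross-tabulates index-test calls against the reference diagnosis
(permanent-section histopathology), excluding inadequate slides from the
2x2 table while counting them in the insufficiency rate over all submitted
slides.  Provides exact (binomial) McNemar for paired accuracy comparison
and the Mann-Whitney U test for intensity contrasts, plus per-category
concordance and group intensity summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ctsfna.images import InputError

#: default mapping of PAP-style comparator levels to binary index calls;
#: "atypical" counts as test-negative (the only mapping consistent with the
#: printed specificity arithmetic), configurable per call.
DEFAULT_COMPARATOR_MAPPING: dict[str, str] = {
    "malignant_suspicious": "positive",
    "atypical": "negative",
    "benign": "negative",
    "inadequate": "inadequate",
}

REFERENCE_LEVELS = ("malignant", "benign_normal")
CALL_LEVELS = ("positive", "negative", "inadequate")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero at ``ndigits`` decimals (printed-table style)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class SlideOutcome:
    """One slide's index call, reference diagnosis and optional extras."""

    slide_id: str
    index_call: str  # positive | negative | inadequate
    reference: str  # malignant | benign_normal
    comparator_call: str | None = None
    red_intensity: float | None = None

    def __post_init__(self) -> None:
        if self.reference not in REFERENCE_LEVELS:
            raise InputError(f"unknown reference level {self.reference!r}")
        if self.index_call not in CALL_LEVELS:
            raise InputError(f"unknown index call {self.index_call!r}")


@dataclass
class ConfusionSummary:
    """2x2 counts (+ inadequates) with derived metrics, full precision.

    ``accuracy`` and companions use evaluable slides only;
    ``insufficiency_rate`` uses all submitted slides.  ``rounded()`` gives
    the 1-decimal half-up percentages as printed in reports.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    n_inadequate: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn + self.n_inadequate

    @property
    def n_evaluable(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @staticmethod
    def _pct(num: int, den: int) -> float:
        return 100.0 * num / den if den else float("nan")

    @property
    def sensitivity(self) -> float:
        return self._pct(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self._pct(self.tn, self.tn + self.fp)

    @property
    def accuracy(self) -> float:
        return self._pct(self.tp + self.tn, self.n_evaluable)

    @property
    def ppv(self) -> float:
        return self._pct(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float:
        return self._pct(self.tn, self.tn + self.fn)

    @property
    def insufficiency_rate(self) -> float:
        return self._pct(self.n_inadequate, self.total)

    def rounded(self, ndigits: int = 1) -> dict[str, float]:
        return {
            name: round_half_up(getattr(self, name), ndigits)
            for name in (
                "sensitivity",
                "specificity",
                "accuracy",
                "ppv",
                "npv",
                "insufficiency_rate",
            )
        }

    def as_dict(self) -> dict:
        d = {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "n_inadequate": self.n_inadequate,
            "n_evaluable": self.n_evaluable,
            "total": self.total,
        }
        d.update(self.rounded())
        return d


def confusion(
    outcomes: Sequence[SlideOutcome],
    mapping: dict[str, str] | None = None,
    use_comparator: bool = False,
) -> ConfusionSummary:
    """Cross-tabulate calls against the reference.

    With ``use_comparator=True`` the comparator column is evaluated through
    ``mapping`` (default: malignant/suspicious positive, atypical and
    benign negative, inadequate excluded) instead of the index call.
    """
    if use_comparator and mapping is None:
        mapping = DEFAULT_COMPARATOR_MAPPING
    tp = fp = fn = tn = n_inad = 0
    for o in outcomes:
        if use_comparator:
            if o.comparator_call is None:
                raise InputError(f"slide {o.slide_id}: comparator_call missing")
            if o.comparator_call not in mapping:
                raise InputError(
                    f"slide {o.slide_id}: comparator level {o.comparator_call!r} "
                    "not covered by mapping"
                )
            call = mapping[o.comparator_call]
        else:
            call = o.index_call
        if call == "inadequate":
            n_inad += 1
        elif call == "positive":
            if o.reference == "malignant":
                tp += 1
            else:
                fp += 1
        else:
            if o.reference == "malignant":
                fn += 1
            else:
                tn += 1
    return ConfusionSummary(tp=tp, fp=fp, fn=fn, tn=tn, n_inadequate=n_inad)


def per_category_accuracy(
    categories: Sequence[int], references: Sequence[str]
) -> pd.DataFrame:
    """Concordance per flow-chart category.

    Category 4 is concordant with a malignant reference; categories 1-3
    with a benign/normal reference.  Returns one row per category present:
    (category, n, n_concordant, accuracy_pct).
    """
    if len(categories) != len(references):
        raise InputError("categories and references differ in length")
    rows = []
    cats = np.asarray(categories)
    refs = np.asarray(references)
    for cat in sorted(set(cats.tolist())):
        sel = cats == cat
        n = int(sel.sum())
        want = "malignant" if cat == 4 else "benign_normal"
        n_conc = int((refs[sel] == want).sum())
        rows.append(
            {
                "category": int(cat),
                "n": n,
                "n_concordant": n_conc,
                "accuracy_pct": round_half_up(100.0 * n_conc / n) if n else float("nan"),
            }
        )
    return pd.DataFrame(rows)


class McNemarResult(NamedTuple):
    b: int
    c: int
    p_value: float
    degenerate: bool


def mcnemar_exact(
    paired: Iterable[tuple[bool, bool]], method: str = "exact"
) -> McNemarResult:
    """Exact (binomial) McNemar test on paired correctness indicators.

    ``paired`` yields (test_A_correct, test_B_correct) per slide; slides
    inadequate under either test should be excluded upstream.  ``b`` counts
    A-only-correct and ``c`` B-only-correct discordant pairs; the exact
    two-sided p is min(1, 2 * BinomCDF(min(b, c); b + c, 1/2)).  With
    ``method="chi2"`` the continuity-corrected chi-square p is returned.
    """
    b = c = 0
    for a_ok, b_ok in paired:
        if a_ok and not b_ok:
            b += 1
        elif b_ok and not a_ok:
            c += 1
    n = b + c
    if n == 0:
        return McNemarResult(0, 0, 1.0, True)
    if method == "chi2":
        statistic = (abs(b - c) - 1) ** 2 / n if abs(b - c) > 1 else 0.0
        p = float(stats.chi2.sf(statistic, df=1)) if statistic > 0 else 1.0
    elif method == "exact":
        p = min(1.0, 2.0 * float(stats.binom.cdf(min(b, c), n, 0.5)))
    else:
        raise InputError(f"unknown method {method!r}")
    return McNemarResult(b, c, p, False)


class MannWhitneyResult(NamedTuple):
    U: float
    p_value: float
    method: str


def mann_whitney(
    group_a: Sequence[float], group_b: Sequence[float], method: str = "auto"
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    U is the rank-sum statistic for ``group_a`` with mid-ranks for ties.
    ``method="auto"`` uses exact enumeration when n_a + n_b <= 20 and the
    data are tie-free, otherwise the normal approximation with tie and
    continuity corrections.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if method == "auto":
        method = "exact" if (a.size + b.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return MannWhitneyResult(float(res.statistic), float(res.pvalue), method)


def intensity_contrast(
    outcomes: Sequence[SlideOutcome],
) -> dict:
    """Red-intensity contrast between reference classes.

    Returns per-class descriptive summaries (n, median, IQR), the
    Mann-Whitney comparison of malignant vs benign/normal intensities, and
    the slide ids misclassified by the index test (the marked points of an
    intensity scatter).
    """
    with_int = [o for o in outcomes if o.red_intensity is not None]
    if not with_int:
        raise InputError("no red_intensity values present")
    groups: dict[str, list[float]] = {lvl: [] for lvl in REFERENCE_LEVELS}
    misclassified = []
    for o in with_int:
        groups[o.reference].append(float(o.red_intensity))
        correct = (o.index_call == "positive") == (o.reference == "malignant")
        if o.index_call != "inadequate" and not correct:
            misclassified.append(o.slide_id)
    summaries = {}
    for lvl, vals in groups.items():
        if vals:
            arr = np.asarray(vals)
            q1, med, q3 = np.percentile(arr, [25, 50, 75])
            summaries[lvl] = {
                "n": int(arr.size),
                "median": float(med),
                "iqr": [float(q1), float(q3)],
            }
        else:
            summaries[lvl] = {"n": 0, "median": float("nan"), "iqr": [float("nan")] * 2}
    result: dict = {"groups": summaries, "misclassified": misclassified}
    if all(summaries[lvl]["n"] > 0 for lvl in REFERENCE_LEVELS):
        mw = mann_whitney(groups["malignant"], groups["benign_normal"])
        result["mann_whitney"] = {"U": mw.U, "p_value": mw.p_value, "method": mw.method}
    return result


# ---------------------------------------------------------------------------
# Table I/O


def outcomes_from_frame(frame: pd.DataFrame) -> list[SlideOutcome]:
    """Build outcomes from a table with columns slide_id, index_call,
    reference and optional comparator_call / red_intensity."""
    outcomes = []
    has_comp = "comparator_call" in frame.columns
    has_int = "red_intensity" in frame.columns
    for r in frame.itertuples():
        outcomes.append(
            SlideOutcome(
                slide_id=str(r.slide_id),
                index_call=str(r.index_call),
                reference=str(r.reference),
                comparator_call=(
                    str(r.comparator_call)
                    if has_comp and not pd.isna(r.comparator_call)
                    else None
                ),
                red_intensity=(
                    float(r.red_intensity)
                    if has_int and not pd.isna(r.red_intensity)
                    else None
                ),
            )
        )
    return outcomes
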