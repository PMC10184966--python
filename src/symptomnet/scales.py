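"""Scoring and descriptive statistics for the GAD-7 and PSQI instruments.

The seven-item Generalized Anxiety Disorder scale (GAD-7) and the seven
component scores of the Pittsburgh Sleep Quality Index (PSQI) are both coded
0-3 per item, summed to 0-21 totals.  Clinical conventions implemented here:

* anxiety screen positive  <=>  GAD-7 total >= 5
* poor sleep quality       <=>  PSQI global > 7
* clinical sleep problems  <=>  PSQI global >= 10
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .errors import ValidationError

GAD_ITEMS = [f"gad{i}" for i in range(1, 8)]
PSQI_ITEMS = [f"psqi{i}" for i in range(1, 8)]
ALL_ITEMS = GAD_ITEMS + PSQI_ITEMS

GAD_LABELS = {
    "gad1": "Nervousness",
    "gad2": "Uncontrollable worry",
    "gad3": "Excessive worry",
    "gad4": "Trouble relaxing",
    "gad5": "Restlessness",
    "gad6": "Irritability",
    "gad7": "Feeling afraid",
}
PSQI_LABELS = {
    "psqi1": "Subjective sleep quality",
    "psqi2": "Sleep latency",
    "psqi3": "Sleep duration",
    "psqi4": "Sleep efficiency",
    "psqi5": "Sleep disturbance",
    "psqi6": "Use of sleep medication",
    "psqi7": "Daytime dysfunction",
}

GAD7_ANXIETY_CUTOFF = 5
PSQI_POOR_SLEEP_CUTOFF = 7  # poor sleep iff global > 7
PSQI_CLINICAL_CUTOFF = 10  # clinical iff global >= 10


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention used for reported %)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _check_items(values: Sequence, what: str) -> np.ndarray:
    vals = list(values)
    if len(vals) != 7:
        raise ValidationError(f"{what}: expected 7 item scores, got {len(vals)}")
    out = np.empty(7, dtype=int)
    for i, v in enumerate(vals):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ValidationError(f"{what}: item {i + 1} is missing")
        iv = int(v)
        if iv != v or iv not in (0, 1, 2, 3):
            raise ValidationError(
                f"{what}: item {i + 1} has value {v!r}, expected an integer in 0..3"
            )
        out[i] = iv
    return out


@dataclass(frozen=True)
class GadResponse:
    """A scored GAD-7 response."""

    items: tuple
    total: int
    anxiety: bool


@dataclass(frozen=True)
class PsqiComponents:
    """A scored PSQI response at component level."""

    components: tuple
    global_score: int
    poor_sleep: bool
    clinical: bool


@dataclass(frozen=True)
class PrevalenceEstimate:
    count: int
    n: int
    proportion: float
    ci_low: float
    ci_high: float
    level: float
    method: str


def score_gad7(items: Sequence) -> GadResponse:
    """Score seven GAD-7 items (each 0-3); anxiety flag at total >= 5."""
    vals = _check_items(items, "GAD-7")
    total = int(vals.sum())
    return GadResponse(tuple(vals), total, total >= GAD7_ANXIETY_CUTOFF)


def score_psqi(components: Sequence) -> PsqiComponents:
    """Score seven PSQI components (each 0-3).

    ``poor_sleep`` flags global > 7; ``clinical`` flags global >= 10.
    """
    vals = _check_items(components, "PSQI")
    total = int(vals.sum())
    return PsqiComponents(
        tuple(vals),
        total,
        total > PSQI_POOR_SLEEP_CUTOFF,
        total >= PSQI_CLINICAL_CUTOFF,
    )


def describe_items(data: pd.DataFrame, items: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-item n, mean, sample SD, adjusted skewness and excess kurtosis.

    Constant columns get SD 0 and NaN skewness/kurtosis (undefined marker)
    rather than raising.
    """
    if items is None:
        items = [c for c in ALL_ITEMS if c in data.columns]
        if not items:
            items = list(data.columns)
    rows = []
    for col in items:
        x = pd.to_numeric(data[col], errors="coerce").dropna().to_numpy(float)
        n = x.size
        if n < 2:
            raise ValidationError(f"item {col!r}: need >= 2 complete observations, got {n}")
        sd = float(np.std(x, ddof=1))
        if sd == 0.0:
            skew = kurt = float("nan")
        else:
            skew = float(stats.skew(x, bias=False))
            kurt = float(stats.kurtosis(x, fisher=True, bias=False))
        rows.append(
            {
                "item": col,
                "label": GAD_LABELS.get(col, PSQI_LABELS.get(col, col)),
                "n": n,
                "mean": float(np.mean(x)),
                "sd": sd,
                "skewness": skew,
                "kurtosis": kurt,
            }
        )
    return pd.DataFrame(rows).set_index("item")


def prevalence_ci(
    count: int, n: int, level: float = 0.95, method: str = "wald"
) -> PrevalenceEstimate:
    """Binomial proportion with a Wald (default) or Wilson interval.

    The interval is clipped to [0, 1].
    """
    if n <= 0:
        raise ValidationError("prevalence_ci: n must be positive")
    if not 0 <= count <= n:
        raise ValidationError(f"prevalence_ci: count {count} outside 0..{n}")
    sm_method = {"wald": "normal", "wilson": "wilson"}.get(method)
    if sm_method is None:
        raise ValidationError(f"prevalence_ci: unknown method {method!r}")
    lo, hi = proportion_confint(count, n, alpha=1 - level, method=sm_method)
    return PrevalenceEstimate(
        count=int(count),
        n=int(n),
        proportion=count / n,
        ci_low=float(np.clip(lo, 0.0, 1.0)),
        ci_high=float(np.clip(hi, 0.0, 1.0)),
        level=level,
        method=method,
    )


def group_rates(
    flags: Sequence[bool] | pd.Series,
    grouping: Sequence | pd.Series,
    missing_label: str = "Missing",
) -> pd.DataFrame:
    """Cross-tabulate flagged cases by group, column-wise.

    The denominator for each percentage is the total number of flagged
    respondents, so the percentages describe how flagged cases distribute
    across groups (the column-wise convention of demographic tables).
    Missing group values form their own category.
    """
    flags = pd.Series(np.asarray(flags, dtype=bool)).reset_index(drop=True)
    grp = pd.Series(grouping).reset_index(drop=True)
    if len(flags) != len(grp):
        raise ValidationError("group_rates: flags and grouping lengths differ")
    grp = grp.astype(object).where(grp.notna() & (grp.astype(str).str.strip() != ""), missing_label)
    total_flagged = int(flags.sum())
    counts = grp[flags].value_counts()
    rows = []
    for cat in grp.unique():
        c = int(counts.get(cat, 0))
        pct = 0.0 if total_flagged == 0 else round_half_up(100.0 * c / total_flagged, 2)
        rows.append({"group": cat, "count": c, "denominator": total_flagged, "percent": pct})
    return pd.DataFrame(rows).set_index("group")
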