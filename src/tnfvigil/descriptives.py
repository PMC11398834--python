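"""Cohort description: demographics, outcome proportions, time to onset.

Reproduces the standard "Table 1" layout of spontaneous-report studies:
per-drug counts and percentages for sex, weight bins (<50, 50-100,
>100 kg), age bins (<=17, 18-64, 65-85, >=86 years), reporter occupation
and top reporting countries, with missing values pooled under
"uncertain".  Percentages are 100*count/N rounded half-up to one
decimal, so each printed cell reconstructs exactly from its count and N.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping

import numpy as np
import pandas as pd

from .ingest import TTO_MAX_DAYS

__all__ = [
    "percent",
    "bin_age",
    "bin_weight",
    "summarize_demographics",
    "summarize_outcomes_tto",
    "demographics_frame",
]

AGE_BIN_LABELS = ("<=17", "18-64", "65-85", ">=86", "uncertain")
WEIGHT_BIN_LABELS = ("<50", "50-100", ">100", "uncertain")
SEX_LABELS = ("female", "male", "uncertain")


def percent(count: int, n: int) -> float:
    """100*count/n rounded half-up to one decimal (as printed)."""
    if n == 0:
        return float("nan")
    return float(
        (Decimal(100 * count) / Decimal(n)).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )


def bin_age(age_years) -> str:
    """Integer-year inclusive bins; fractional ages floored; NaN 'uncertain'."""
    if age_years is None or (isinstance(age_years, float) and np.isnan(age_years)):
        return "uncertain"
    y = int(np.floor(age_years))
    if y <= 17:
        return "<=17"
    if y <= 64:
        return "18-64"
    if y <= 85:
        return "65-85"
    return ">=86"


def bin_weight(weight_kg) -> str:
    if weight_kg is None or (isinstance(weight_kg, float) and np.isnan(weight_kg)):
        return "uncertain"
    if weight_kg < 50:
        return "<50"
    if weight_kg <= 100:
        return "50-100"
    return ">100"


def _block(series: pd.Series, labels, n: int) -> dict[str, tuple[int, float]]:
    counts = series.value_counts()
    return {lab: (int(counts.get(lab, 0)), percent(int(counts.get(lab, 0)), n)) for lab in labels}


def summarize_demographics(
    reports: pd.DataFrame, top_k_countries: int = 5
) -> dict[str, dict]:
    """Per-drug Table 1-style summary.

    Returns {drug: {"n": N, "sex": {...}, "weight": {...}, "age": {...},
    "reporter": {...}, "countries": [(country, count, pct), ...]}} where
    every categorical cell is a (count, percent) pair.  Empty input gives
    an empty dict with a warning.
    """
    import warnings

    if len(reports) == 0:
        warnings.warn("no reports to summarize", stacklevel=2)
        return {}
    out: dict[str, dict] = {}
    for drug, grp in reports.groupby("ps_drug", sort=True):
        n = len(grp)
        sex = grp["sex"].map({"female": "female", "male": "male"}).fillna("uncertain")
        summary = {
            "n": n,
            "sex": _block(sex, SEX_LABELS, n),
            "weight": _block(grp["weight_kg"].map(bin_weight), WEIGHT_BIN_LABELS, n),
            "age": _block(grp["age_years"].map(bin_age), AGE_BIN_LABELS, n),
            "reporter": _block(
                grp["reporter"], sorted(grp["reporter"].unique()), n
            ),
            "countries": [
                (country, int(cnt), percent(int(cnt), n))
                for country, cnt in grp["country"].value_counts().head(top_k_countries).items()
            ],
        }
        out[drug] = summary
    return out


def demographics_frame(summary: Mapping[str, dict]) -> pd.DataFrame:
    """Tidy long-format view of :func:`summarize_demographics` output."""
    rows = []
    for drug, s in summary.items():
        for block in ("sex", "weight", "age", "reporter"):
            for label, (count, pct) in s[block].items():
                rows.append((drug, block, label, count, pct))
        for country, count, pct in s["countries"]:
            rows.append((drug, "country", country, count, pct))
    return pd.DataFrame(rows, columns=["drug", "block", "category", "count", "percent"])


def summarize_outcomes_tto(reports: pd.DataFrame, by_sex: bool = False) -> pd.DataFrame:
    """Outcome proportions and onset-time quartiles per drug (and sex).

    The outcome denominator is the number of reports with at least one
    recorded outcome; a report with several outcome categories counts
    once in each, so proportions may sum past 100.  Onset summaries use
    only valid gaps (present, nonnegative, <= 720 days).
    """
    keys = ["ps_drug"] + (["sex"] if by_sex else [])
    rows = []
    for key, grp in reports.groupby(keys, sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        with_outcome = grp[grp["outcomes"].map(len) > 0]
        denom = len(with_outcome)
        oc_counts: dict[str, int] = {}
        for ocs in with_outcome["outcomes"]:
            for oc in ocs:
                oc_counts[oc] = oc_counts.get(oc, 0) + 1
        tto = grp.loc[grp["tto_valid"], "tto_days"]
        base = dict(zip(keys, key))
        base.update(
            n=len(grp),
            n_with_outcome=denom,
            tto_n=len(tto),
            tto_median=float(tto.median()) if len(tto) else np.nan,
            tto_q1=float(tto.quantile(0.25)) if len(tto) else np.nan,
            tto_q3=float(tto.quantile(0.75)) if len(tto) else np.nan,
        )
        for oc, cnt in sorted(oc_counts.items()):
            base[f"outcome_{oc}_count"] = cnt
            base[f"outcome_{oc}_pct"] = percent(cnt, denom)
        rows.append(base)
    return pd.DataFrame(rows)
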