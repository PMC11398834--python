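"""2x2 contingency construction for drug-event disproportionality.

For each (drug, event, stratum) the four cells count *reports*:

    a  reports with the drug and the event
    b  reports with the drug, without the event
    c  comparator reports with the event
    d  comparator reports without the event

The comparator is every cleaned report whose PS drug is not the target
drug.  A report contributes at most once to ``a`` no matter how many
times the event term is recorded on it.  Strata are "all", "female" and
"male"; unknown-sex reports appear only in "all".
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = ["build_tables", "write_tables"]

STRATA = ("all", "female", "male")


def _pair_frame(reports: pd.DataFrame) -> pd.DataFrame:
    """One row per (report, distinct event term)."""
    return (
        reports[["ps_drug", "sex", "events"]]
        .explode("events")
        .dropna(subset=["events"])
        .rename(columns={"events": "event"})
    )


def build_tables(
    reports: pd.DataFrame,
    background: pd.DataFrame,
    stratify_by_sex: bool = True,
    drugs: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Build all 2x2 tables for the target drugs.

    ``reports`` is the cleaned study-drug extract, ``background`` the
    comparator reports (non-target PS drugs).  One table is emitted per
    (drug, event observed with that drug, stratum), as a tidy frame with
    columns drug, event, stratum, a, b, c, d.

    Raises ``ValueError`` on an empty comparator set — the reporting odds
    ratio is undefined without one.
    """
    if len(background) == 0 and reports["ps_drug"].nunique() < 2:
        raise ValueError("empty background: ROR is undefined without comparators")
    if drugs is None:
        drugs = sorted(reports["ps_drug"].unique())

    db = pd.concat([reports, background], ignore_index=True)
    strata = STRATA if stratify_by_sex else ("all",)
    out = []
    for stratum in strata:
        sub = db if stratum == "all" else db[db["sex"] == stratum]
        n_total = len(sub)
        if n_total == 0:
            continue
        pairs = _pair_frame(sub)
        event_totals = pairs.groupby("event").size()
        for drug in drugs:
            n_drug = int((sub["ps_drug"] == drug).sum())
            a = pairs[pairs["ps_drug"] == drug].groupby("event").size()
            if a.empty:
                continue
            tab = pd.DataFrame(
                {
                    "drug": drug,
                    "event": a.index,
                    "stratum": stratum,
                    "a": a.to_numpy(),
                }
            )
            tab["b"] = n_drug - tab["a"]
            tab["c"] = event_totals.reindex(a.index).to_numpy() - tab["a"].to_numpy()
            tab["d"] = n_total - n_drug - tab["c"]
            out.append(tab)
    if not out:
        return pd.DataFrame(columns=["drug", "event", "stratum", "a", "b", "c", "d"])
    result = pd.concat(out, ignore_index=True)
    for col in ("a", "b", "c", "d"):
        result[col] = result[col].astype(int)
    return result.sort_values(["drug", "stratum", "event"], kind="stable").reset_index(
        drop=True
    )


def write_tables(tables: pd.DataFrame, path: str | Path) -> None:
    tables.to_csv(path, sep="\t", index=False)
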