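"""Reading, deduplication, drug-name normalization and inclusion filtering.

The analysis-ready unit is the *report*: one row per spontaneous report,
with demographics, exactly one primary-suspect (PS) drug, the set of
coded event terms, outcome codes, therapy-start / event dates and the
indication set.  Reports are held in a pandas DataFrame whose set-valued
columns (``events``, ``outcomes``, ``indications``) store sorted tuples.

Cleaning follows standard spontaneous-reporting practice: collapse
duplicate case versions keeping the latest, map trade-name spellings to
canonical drug names, then retain reports whose sole indication is
rheumatoid arthritis, whose PS drug is a study drug, and whose reporter
is a health professional.  Every stage is logged so the case attrition
is auditable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .synthetic import RawTables, STUDY_DRUGS

__all__ = [
    "SynonymDictionary",
    "FilterLog",
    "FilterResult",
    "InclusionConfig",
    "read_raw_tables",
    "assemble_reports",
    "deduplicate",
    "normalize_drug",
    "time_to_onset",
    "apply_inclusion_filters",
    "RA_TERM",
    "TTO_MAX_DAYS",
]

RA_TERM = "rheumatoid arthritis"
#: events more than this many days after therapy start are excluded from
#: time-to-onset analyses (the report itself is retained)
TTO_MAX_DAYS = 720

_OCCP_MAP = {
    "MD": "physician",
    "PH": "pharmacist",
    "OT": "other_health_professional",
    "HP": "other_health_professional",
    "RN": "other_health_professional",
    "CN": "consumer",
    "LW": "lawyer",
}

_OUTC_MAP = {
    "DE": "death",
    "LT": "life_threatening",
    "HO": "hospitalization",
    "DS": "disability",
    "CA": "congenital_anomaly",
    "RI": "required_intervention",
    "OT": "other",
}

HEALTH_PROFESSIONALS = frozenset(
    {"physician", "pharmacist", "other_health_professional"}
)


class SynonymDictionary:
    """Case-insensitive term -> canonical drug-name mapping.

    The mapping is a function (no term maps to two canonicals) and every
    canonical name maps to itself.
    """

    def __init__(self, mapping: Mapping[str, str]):
        norm: dict[str, str] = {}
        for term, canon in mapping.items():
            t = term.strip().lower()
            c = canon.strip().lower()
            if t in norm and norm[t] != c:
                raise ValueError(f"term {t!r} maps to both {norm[t]!r} and {c!r}")
            norm[t] = c
        for canon in set(norm.values()):
            if norm.get(canon, canon) != canon:
                raise ValueError(f"canonical {canon!r} does not map to itself")
            norm.setdefault(canon, canon)
        self.mapping = norm

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SynonymDictionary":
        df = pd.read_csv(path, sep="\t")
        return cls(dict(zip(df["term"], df["canonical"])))

    @classmethod
    def default(cls) -> "SynonymDictionary":
        with resources.as_file(
            resources.files("tnfvigil.data") / "drug_synonyms.tsv"
        ) as p:
            return cls.from_tsv(p)

    def lookup(self, raw_name: str) -> str | None:
        return self.mapping.get(str(raw_name).strip().lower())


def normalize_drug(raw_name: str, dictionary: SynonymDictionary) -> str | None:
    """Map a raw drug spelling to its canonical name.

    Case-insensitive, whitespace-trimmed.  Returns ``None`` for an
    unmatched name — callers decide what to do with it; nothing is
    silently dropped here.
    """
    return dictionary.lookup(raw_name)


def _default_indication_synonyms() -> dict[str, str]:
    with resources.as_file(
        resources.files("tnfvigil.data") / "indication_synonyms.tsv"
    ) as p:
        df = pd.read_csv(p, sep="\t")
    return {t.strip().lower(): c.strip().lower() for t, c in zip(df["term"], df["canonical"])}


def read_raw_tables(directory: str | Path, dialect: str = "auto") -> RawTables:
    """Read the six relations from ``directory``.

    ``dialect`` is ``"faers"`` ("$"-separated, DEMO.txt ...), ``"tsv"``
    (tab-separated, demo.tsv ...) or ``"auto"`` to detect from the files
    present.
    """
    directory = Path(directory)
    if dialect == "auto":
        dialect = "faers" if (directory / "DEMO.txt").exists() else "tsv"
    if dialect == "faers":
        sep, pattern = "$", "{}.txt"
        names = {n: n.upper() for n in RawTables._NAMES}
    elif dialect == "tsv":
        sep, pattern = "\t", "{}.tsv"
        names = {n: n for n in RawTables._NAMES}
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    frames = {}
    for attr, fname in names.items():
        path = directory / pattern.format(fname)
        if not path.exists():
            raise FileNotFoundError(f"missing relation file {path}")
        frames[attr] = pd.read_csv(path, sep=sep, dtype={"pt": str}, keep_default_na=True)
    return RawTables(**frames)


def _parse_dates(col: pd.Series) -> pd.Series:
    s = col.astype("string").str.replace(r"\.0$", "", regex=True)
    return pd.to_datetime(s, format="%Y%m%d", errors="coerce")


def assemble_reports(
    raw: RawTables,
    synonyms: SynonymDictionary | None = None,
    indication_synonyms: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Join the six relations into one row per raw report (pre-dedup).

    The PS drug name is normalized through the synonym dictionary; an
    unmatched name keeps its lower-cased raw spelling and is marked in
    ``ps_drug_matched`` so it can be audited rather than silently lost.
    """
    if synonyms is None:
        synonyms = SynonymDictionary.default()
    if indication_synonyms is None:
        indication_synonyms = _default_indication_synonyms()

    demo = raw.demo.copy()
    pid = "primaryid"

    ps = raw.drug[raw.drug["role_cod"] == "PS"]
    ps_counts = ps.groupby(pid).size()
    bad = ps_counts[ps_counts != 1]
    if len(bad):
        raise ValueError(
            f"{len(bad)} report(s) do not have exactly one primary-suspect drug row"
        )
    ps = ps.set_index(pid)["drugname"]

    def _agg_sets(df: pd.DataFrame, col: str, transform=None) -> pd.Series:
        vals = df[[pid, col]].dropna()
        if transform is not None:
            vals = vals.assign(**{col: vals[col].map(transform)})
        return vals.groupby(pid)[col].agg(lambda s: tuple(sorted(set(s))))

    events = _agg_sets(raw.reac, "pt", lambda s: str(s).strip().lower())
    outcomes = _agg_sets(
        raw.outc, "outc_cod", lambda s: _OUTC_MAP.get(str(s).strip().upper(), "other")
    )
    indi_norm = lambda s: indication_synonyms.get(
        str(s).strip().lower(), str(s).strip().lower()
    )
    indications = _agg_sets(raw.indi, "indi_pt", indi_norm)
    ther_start = _parse_dates(raw.ther.set_index(pid)["start_dt"]).groupby(level=0).min()

    out = pd.DataFrame(
        {
            "case_id": demo["caseid"].astype(str).to_numpy(),
            "version": demo["caseversion"].astype(int).to_numpy(),
            "sex": demo["sex"].map({"F": "female", "M": "male"})
            .fillna("unknown").to_numpy(),
            "age_years": pd.to_numeric(demo["age"], errors="coerce").to_numpy(),
            "weight_kg": pd.to_numeric(demo["wt"], errors="coerce").to_numpy(),
            "country": demo["occr_country"].fillna("unknown").to_numpy(),
            "reporter": demo["occp_cod"].map(_OCCP_MAP).fillna("unknown").to_numpy(),
            "event_date": _parse_dates(demo["event_dt"]).to_numpy(),
        },
        index=pd.Index(demo[pid].to_numpy(), name=pid),
    )
    raw_ps = ps.reindex(out.index)
    canon = raw_ps.map(lambda s: synonyms.lookup(s) if pd.notna(s) else None)
    out["ps_drug_raw"] = raw_ps.to_numpy()
    out["ps_drug_matched"] = canon.notna().to_numpy()
    out["ps_drug"] = np.where(
        canon.notna(), canon, raw_ps.astype(str).str.strip().str.lower()
    )
    out["events"] = events.reindex(out.index).apply(
        lambda v: v if isinstance(v, tuple) else ()
    ).to_numpy()
    out["outcomes"] = outcomes.reindex(out.index).apply(
        lambda v: v if isinstance(v, tuple) else ()
    ).to_numpy()
    out["indications"] = indications.reindex(out.index).apply(
        lambda v: v if isinstance(v, tuple) else ()
    ).to_numpy()
    out["therapy_start"] = ther_start.reindex(out.index).to_numpy()
    out = out.reset_index().rename(columns={pid: "primaryid"})
    out = time_to_onset(out)
    return out


def deduplicate(reports: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate case versions: one row per ``case_id``.

    The retained row is the one with the highest ``version`` (ties broken
    by last occurrence in input order); output order is stable by first
    appearance of each ``case_id``.  Idempotent.
    """
    df = reports.reset_index(drop=True)
    order = df.groupby("case_id", sort=False).ngroup()
    keep = (
        df.assign(_order=order)
        .sort_values("version", kind="stable")
        .groupby("case_id", sort=False)
        .tail(1)
        .sort_values("_order", kind="stable")
        .drop(columns="_order")
    )
    return keep.reset_index(drop=True)


def time_to_onset(reports: pd.DataFrame) -> pd.DataFrame:
    """Attach time-to-onset columns.

    ``tto_days`` is event date minus therapy start in whole days (NaN if
    either date is missing).  ``tto_valid`` marks values usable in
    onset-time summaries: present, nonnegative and at most 720 days.
    Negative gaps are data errors; longer gaps are excluded from onset
    analyses only — the report stays in the disproportionality set.
    """
    df = reports.copy()
    delta = (df["event_date"] - df["therapy_start"]).dt.days
    df["tto_days"] = delta
    df["tto_valid"] = delta.notna() & (delta >= 0) & (delta <= TTO_MAX_DAYS)
    return df


@dataclass
class InclusionConfig:
    study_drugs: Sequence[str] = STUDY_DRUGS
    require_ra_only: bool = True
    health_professional_only: bool = True
    ra_term: str = RA_TERM


@dataclass
class FilterLog:
    """Per-criterion attrition in application order."""

    input_count: int
    removed: dict[str, int] = field(default_factory=dict)
    retained_count: int = 0

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "input_count": self.input_count,
                "removed": self.removed,
                "retained_count": self.retained_count,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


@dataclass
class FilterResult:
    retained: pd.DataFrame
    background: pd.DataFrame
    log: FilterLog


def apply_inclusion_filters(
    reports: pd.DataFrame, config: InclusionConfig | None = None
) -> FilterResult:
    """Apply the study inclusion criteria to deduplicated reports.

    Criteria, in order: (1) PS drug is a study drug; (2) the normalized
    indication set is exactly {rheumatoid arthritis}; (3) the reporter is
    a physician, pharmacist or other health professional.  The returned
    ``background`` frame holds reports failing only the drug criterion
    (they satisfy the indication and reporter criteria), i.e. the cleaned
    same-population extract usable as the disproportionality comparator.

    An empty retained set is a warning, not an error.
    """
    import warnings

    if config is None:
        config = InclusionConfig()
    df = reports.reset_index(drop=True)
    log = FilterLog(input_count=len(df))

    drug_ok = df["ps_drug"].isin(set(config.study_drugs))
    if config.require_ra_only:
        indi_ok = df["indications"].map(lambda t: t == (config.ra_term,))
    else:
        indi_ok = pd.Series(True, index=df.index)
    if config.health_professional_only:
        rep_ok = df["reporter"].isin(HEALTH_PROFESSIONALS)
    else:
        rep_ok = pd.Series(True, index=df.index)

    # sequential attrition accounting: each report is charged to the first
    # criterion it fails
    log.removed["ps_drug_not_study_drug"] = int((~drug_ok).sum())
    log.removed["indication_not_ra_only"] = int((drug_ok & ~indi_ok).sum())
    log.removed["reporter_not_health_professional"] = int(
        (drug_ok & indi_ok & ~rep_ok).sum()
    )
    retained = df[drug_ok & indi_ok & rep_ok].reset_index(drop=True)
    background = df[~drug_ok & indi_ok & rep_ok].reset_index(drop=True)
    log.retained_count = len(retained)
    if len(retained) == 0:
        warnings.warn("inclusion filters retained no reports", stacklevel=2)
    return FilterResult(retained=retained, background=background, log=log)
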