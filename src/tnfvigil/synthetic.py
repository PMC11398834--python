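"""Synthetic spontaneous-report generator with known ground truth.

Emulates the structure of FAERS quarterly ASCII extracts: six delimited
relations (DEMO, DRUG, REAC, OUTC, THER, INDI) sharing case/report keys.
Each simulated case has demographics, exactly one primary-suspect (PS)
drug, one or more coded event terms, outcome codes, therapy-start and
event dates, a reporter occupation and indication strings.  Nuisance
processes — duplicate case versions, missing demographics, trade-name
spellings of the PS drug — are injected at configurable rates so the
cleaning stages downstream have something real to do.

Signal structure is planted multiplicatively: for an injected
(drug, event, lift) triple the per-draw probability of that event given
the PS drug is ``lift`` times its background weight, renormalized over
the event vocabulary.  That is exactly the elevated-reporting-rate
alternative that disproportionality statistics (ROR, BCPNN-IC) are
designed to detect, so every injected pair is a recoverable ground-truth
signal.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "InjectedSignal",
    "SynthScenario",
    "RawTables",
    "ScenarioError",
    "generate",
    "default_scenario",
    "recovery_scenario",
    "null_scenario",
    "injected_event_probability",
    "STUDY_DRUGS",
    "COMMON_SIGNAL_EVENTS",
]

STUDY_DRUGS = (
    "adalimumab",
    "golimumab",
    "certolizumab",
    "etanercept",
    "infliximab",
)

#: events planted in every study drug by the default scenario, mirroring a
#: class effect shared across the whole drug family
COMMON_SIGNAL_EVENTS = (
    "pulmonary tuberculosis",
    "infection",
    "hypersensitivity",
    "herpes zoster",
)

# FAERS occupation codes for the reporter field
_OCCP_CODES = ("MD", "OT", "PH", "CN", "LW")

_OUTCOME_CODES = {
    "death": "DE",
    "life_threatening": "LT",
    "hospitalization": "HO",
    "disability": "DS",
    "other": "OT",
}


class ScenarioError(ValueError):
    """Raised when a scenario field fails validation; names the field."""


@dataclass(frozen=True)
class InjectedSignal:
    """One planted (drug, event) association.

    ``lift`` multiplies the event's background weight for reports whose PS
    drug matches; ``sex_lift_female`` / ``sex_lift_male`` further scale the
    lift within a sex stratum (1.0 = no modification, 0.0 = signal absent
    in that sex).
    """

    drug: str
    event: str
    lift: float
    sex_lift_female: float = 1.0
    sex_lift_male: float = 1.0


@dataclass
class SynthScenario:
    """Parameters of one simulated reporting universe.

    ``drugs`` maps canonical drug name -> marginal probability of being the
    PS drug of a report (must sum to 1 within tolerance); ``events`` maps
    event term -> strictly positive background weight (weights are
    renormalized per draw).  All rates are probabilities in [0, 1].
    """

    n_reports: int
    drugs: Mapping[str, float]
    events: Mapping[str, float]
    injected_signals: Sequence[InjectedSignal] = ()
    duplicate_rate: float = 0.05
    missing_sex_rate: float = 0.08
    missing_age_rate: float = 0.30
    missing_weight_rate: float = 0.70
    missing_date_rate: float = 0.10
    synonym_noise_rate: float = 0.30
    ra_only_fraction: float = 0.80
    female_fraction: float = 0.75
    events_per_report_mean: float = 2.0
    max_events_per_report: int = 10
    # per-drug lognormal (meanlog, sdlog) of the therapy-start-to-event gap
    # in days; key "*" is the fallback
    tto_days: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"*": (4.6, 1.0)}
    )
    tto_tail_rate: float = 0.05  # fraction of gaps forced beyond 720 days
    outcome_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "none": 0.30,
            "other": 0.30,
            "hospitalization": 0.25,
            "death": 0.08,
            "disability": 0.04,
            "life_threatening": 0.03,
        }
    )
    reporter_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "MD": 0.55,
            "OT": 0.18,
            "PH": 0.08,
            "CN": 0.17,
            "LW": 0.02,
        }
    )
    country_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "US": 0.60,
            "JP": 0.08,
            "CA": 0.06,
            "GB": 0.05,
            "DE": 0.05,
            "FR": 0.04,
            "CO": 0.02,
            "CZ": 0.02,
            "TW": 0.02,
            "OTHER": 0.06,
        }
    )
    duplicate_perturb_rate: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if not (isinstance(self.n_reports, (int, np.integer)) and self.n_reports > 0):
            raise ScenarioError("n_reports must be a positive integer")
        if not self.drugs:
            raise ScenarioError("drugs must be non-empty")
        if not self.events:
            raise ScenarioError("events must be non-empty")
        if abs(sum(self.drugs.values()) - 1.0) > 1e-6:
            raise ScenarioError("drugs probabilities must sum to 1")
        if any(p < 0 for p in self.drugs.values()):
            raise ScenarioError("drugs probabilities must be nonnegative")
        if any(w <= 0 for w in self.events.values()):
            raise ScenarioError("events background weights must be strictly positive")
        for rate_name in (
            "duplicate_rate",
            "missing_sex_rate",
            "missing_age_rate",
            "missing_weight_rate",
            "missing_date_rate",
            "synonym_noise_rate",
            "ra_only_fraction",
            "female_fraction",
            "tto_tail_rate",
            "duplicate_perturb_rate",
        ):
            v = getattr(self, rate_name)
            if not 0.0 <= v <= 1.0:
                raise ScenarioError(f"{rate_name} must be in [0, 1]")
        for sig in self.injected_signals:
            if sig.drug not in self.drugs:
                raise ScenarioError(
                    f"injected_signals: drug {sig.drug!r} not in drugs vocabulary"
                )
            if sig.event not in self.events:
                raise ScenarioError(
                    f"injected_signals: event {sig.event!r} not in events vocabulary"
                )
            if sig.lift < 1.0:
                raise ScenarioError("injected_signals: lift must be >= 1")
            if sig.sex_lift_female < 0 or sig.sex_lift_male < 0:
                raise ScenarioError("injected_signals: sex lifts must be >= 0")
        for dist_name in ("outcome_probs", "reporter_probs", "country_probs"):
            dist = getattr(self, dist_name)
            if abs(sum(dist.values()) - 1.0) > 1e-6:
                raise ScenarioError(f"{dist_name} must sum to 1")
        if "*" not in self.tto_days:
            raise ScenarioError('tto_days must provide a "*" fallback entry')

    def replace(self, **kwargs) -> "SynthScenario":
        return dataclasses.replace(self, **kwargs)


@dataclass
class RawTables:
    """The six FAERS-like relations; keys are ``primaryid`` / ``caseid``."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame
    ther: pd.DataFrame
    indi: pd.DataFrame

    _NAMES = ("demo", "drug", "reac", "outc", "ther", "indi")

    def write(self, directory: str | Path, dialect: str = "faers") -> None:
        """Write the six relations as delimited text.

        ``dialect="faers"`` uses the "$"-separated ASCII layout with
        upper-case file names (DEMO.txt, ...); ``dialect="tsv"`` writes
        plain tab-separated files (demo.tsv, ...).
        """
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        if dialect == "faers":
            sep, suffix, upper = "$", ".txt", True
        elif dialect == "tsv":
            sep, suffix, upper = "\t", ".tsv", False
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
        for name in self._NAMES:
            df: pd.DataFrame = getattr(self, name)
            fname = (name.upper() if upper else name) + suffix
            df.to_csv(directory / fname, sep=sep, index=False)


def injected_event_probability(
    scenario: SynthScenario, drug: str, event: str, sex: str = "unknown"
) -> float:
    """Closed-form per-draw probability of ``event`` given PS ``drug``.

    This is the target the generator realizes: the event's background
    weight multiplied by the (sex-modified) lift, renormalized over the
    whole vocabulary.  Used as the independent oracle for injection
    fidelity.
    """
    weights = dict(scenario.events)
    lifted = dict(weights)
    for sig in scenario.injected_signals:
        if sig.drug != drug:
            continue
        lift = sig.lift
        if sex == "female":
            lift *= sig.sex_lift_female
        elif sex == "male":
            lift *= sig.sex_lift_male
        lifted[sig.event] = weights[sig.event] * lift
    return lifted[event] / sum(lifted.values())


def report_event_probability(
    scenario: SynthScenario, drug: str, event: str, sex: str = "unknown"
) -> float:
    """P(event term appears at least once in a report | PS drug, sex).

    Event draws are with replacement (then de-duplicated into a set), so
    with K draws the inclusion probability is 1 - (1-p)^K, marginalized
    over the truncated-geometric K.
    """
    p = injected_event_probability(scenario, drug, event, sex)
    q = 1.0 / scenario.events_per_report_mean
    kmax = scenario.max_events_per_report
    pk = np.array([(1 - q) ** (k - 1) * q for k in range(1, kmax + 1)])
    pk[-1] = 1.0 - pk[:-1].sum()  # truncation mass on kmax
    ks = np.arange(1, kmax + 1)
    return float(np.sum(pk * (1.0 - (1.0 - p) ** ks)))


def _truncated_geometric(rng: np.random.Generator, n: int, mean: float, kmax: int):
    k = rng.geometric(p=1.0 / mean, size=n)
    return np.minimum(k, kmax)


def _load_trade_names() -> dict[str, list[str]]:
    from .ingest import SynonymDictionary

    syn = SynonymDictionary.default()
    out: dict[str, list[str]] = {}
    for term, canon in syn.mapping.items():
        if term != canon:
            out.setdefault(canon, []).append(term)
    for v in out.values():
        v.sort()
    return out


def generate(scenario: SynthScenario) -> RawTables:
    """Simulate raw FAERS-like tables from a scenario.

    Deterministic given ``scenario.seed``.  Raises :class:`ScenarioError`
    on an invalid scenario.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_reports

    drug_names = list(scenario.drugs)
    drug_probs = np.array([scenario.drugs[d] for d in drug_names], dtype=float)
    drug_probs = drug_probs / drug_probs.sum()
    event_names = list(scenario.events)
    event_w = np.array([scenario.events[e] for e in event_names], dtype=float)
    event_idx = {e: i for i, e in enumerate(event_names)}
    drug_idx_map = {d: i for i, d in enumerate(drug_names)}

    caseid = np.arange(10_000_001, 10_000_001 + n)
    version = np.ones(n, dtype=int)

    ps_drug_i = rng.choice(len(drug_names), size=n, p=drug_probs)

    # sex: 0=female, 1=male, 2=unknown
    sex_code = np.where(rng.random(n) < scenario.female_fraction, 0, 1)
    sex_code = np.where(rng.random(n) < scenario.missing_sex_rate, 2, sex_code)

    age = np.clip(np.round(rng.normal(55, 16, size=n)), 5, 95)
    age_missing = rng.random(n) < scenario.missing_age_rate
    weight = np.clip(np.round(rng.normal(74, 16, size=n), 1), 35, 160)
    weight_missing = rng.random(n) < scenario.missing_weight_rate

    countries = list(scenario.country_probs)
    country = rng.choice(
        countries, size=n, p=np.array(list(scenario.country_probs.values()))
    )
    occp = rng.choice(
        list(scenario.reporter_probs),
        size=n,
        p=np.array(list(scenario.reporter_probs.values())),
    )

    # indications: RA-only / RA+another / other diagnosis entirely
    u = rng.random(n)
    ra_only = u < scenario.ra_only_fraction
    rest = 1.0 - scenario.ra_only_fraction
    ra_plus = (~ra_only) & (u < scenario.ra_only_fraction + rest / 2)
    other_indis = ["Psoriasis", "Crohn's disease", "Ankylosing spondylitis",
                   "Ulcerative colitis", "Psoriatic arthropathy"]
    extra_indi = rng.choice(other_indis, size=n)

    # events: draws with replacement from the (drug, sex)-specific lifted
    # distribution, de-duplicated into the report's event set
    k_events = _truncated_geometric(
        rng, n, scenario.events_per_report_mean, scenario.max_events_per_report
    )
    injected_drugs = {drug_idx_map[s.drug] for s in scenario.injected_signals}
    events_per_report: list[list[str]] = [None] * n  # type: ignore[list-item]
    base_p = event_w / event_w.sum()
    for di in range(len(drug_names)):
        for sc, sex_name in ((0, "female"), (1, "male"), (2, "unknown")):
            mask = (ps_drug_i == di) & (sex_code == sc)
            m = int(mask.sum())
            if m == 0:
                continue
            if di in injected_drugs:
                w = event_w.copy()
                for sig in scenario.injected_signals:
                    if drug_idx_map[sig.drug] != di:
                        continue
                    lift = sig.lift
                    if sex_name == "female":
                        lift *= sig.sex_lift_female
                    elif sex_name == "male":
                        lift *= sig.sex_lift_male
                    w[event_idx[sig.event]] = scenario.events[sig.event] * lift
                p = w / w.sum()
            else:
                p = base_p
            ks = k_events[mask]
            draws = rng.choice(len(event_names), size=int(ks.sum()), p=p)
            offsets = np.concatenate(([0], np.cumsum(ks)))
            rows = np.flatnonzero(mask)
            for j, r in enumerate(rows):
                chunk = draws[offsets[j]:offsets[j + 1]]
                events_per_report[r] = [event_names[i] for i in dict.fromkeys(chunk)]

    # outcomes
    oc_names = list(scenario.outcome_probs)
    oc_draw = rng.choice(
        oc_names, size=n, p=np.array(list(scenario.outcome_probs.values()))
    )
    extra_hosp = (oc_draw == "death") & (rng.random(n) < 0.5)

    # dates: therapy start uniform over a 20-quarter window; event date =
    # start + lognormal gap, with a configurable tail beyond 720 days
    window_start = np.datetime64("2018-10-01")
    window_days = 1826  # 2018-10-01 .. 2023-09-30
    start_offset = rng.integers(0, window_days, size=n)
    start_date = window_start + start_offset.astype("timedelta64[D]")
    gap = np.empty(n)
    for di, dname in enumerate(drug_names):
        mask = ps_drug_i == di
        meanlog, sdlog = scenario.tto_days.get(dname, scenario.tto_days["*"])
        gap[mask] = rng.lognormal(meanlog, sdlog, size=int(mask.sum()))
    gap = np.maximum(0, np.round(gap)).astype(int)
    tail = rng.random(n) < scenario.tto_tail_rate
    gap[tail] = rng.integers(721, 1500, size=int(tail.sum()))
    event_date = start_date + gap.astype("timedelta64[D]")
    date_missing = rng.random(n) < scenario.missing_date_rate

    # PS drug spelling: trade-name synonym noise + occasional upper-casing
    trade = _load_trade_names()
    ps_name_raw = np.array([drug_names[i] for i in ps_drug_i], dtype=object)
    noise = rng.random(n) < scenario.synonym_noise_rate
    for r in np.flatnonzero(noise):
        cands = trade.get(ps_name_raw[r])
        if cands:
            ps_name_raw[r] = cands[rng.integers(0, len(cands))]
    upper = rng.random(n) < 0.3
    for r in np.flatnonzero(upper):
        ps_name_raw[r] = str(ps_name_raw[r]).upper()

    # duplicates: re-report a subset of cases under version 2, with an
    # optional +-1 kg weight perturbation
    dup_mask = rng.random(n) < scenario.duplicate_rate
    dup_rows = np.flatnonzero(dup_mask)

    def _fmt_date(dates, missing):
        s = pd.Series(dates).dt.strftime("%Y%m%d").astype(object)
        return s.where(~pd.Series(missing), "").to_numpy(dtype=object)

    sex_str = np.array(["F", "M", ""], dtype=object)[sex_code]
    age_str = np.where(age_missing, "", age.astype(int).astype(str)).astype(object)
    wt_str = np.where(weight_missing, "", np.char.mod("%.1f", weight)).astype(object)

    primaryid = caseid * 10 + version

    demo = pd.DataFrame(
        {
            "primaryid": primaryid,
            "caseid": caseid,
            "caseversion": version,
            "sex": sex_str,
            "age": age_str,
            "age_cod": "YR",
            "wt": wt_str,
            "wt_cod": "KG",
            "occr_country": country,
            "occp_cod": occp,
            "event_dt": _fmt_date(pd.to_datetime(event_date), date_missing),
        }
    )

    drug_rows = {
        "primaryid": primaryid,
        "caseid": caseid,
        "drug_seq": np.ones(n, dtype=int),
        "role_cod": np.full(n, "PS", dtype=object),
        "drugname": ps_name_raw,
    }
    drug_df = pd.DataFrame(drug_rows)
    # concomitant rows: common RA co-medication, role C
    conco = rng.random(n) < 0.5
    conco_rows = np.flatnonzero(conco)
    conco_names = rng.choice(
        ["methotrexate", "prednisone", "folic acid", "hydroxychloroquine"],
        size=len(conco_rows),
    )
    drug_c = pd.DataFrame(
        {
            "primaryid": primaryid[conco_rows],
            "caseid": caseid[conco_rows],
            "drug_seq": 2,
            "role_cod": "C",
            "drugname": conco_names,
        }
    )
    drug_df = pd.concat([drug_df, drug_c], ignore_index=True)

    reac_pid, reac_cid, reac_pt = [], [], []
    for r in range(n):
        for ev in events_per_report[r]:
            reac_pid.append(primaryid[r])
            reac_cid.append(caseid[r])
            reac_pt.append(ev)
    reac = pd.DataFrame({"primaryid": reac_pid, "caseid": reac_cid, "pt": reac_pt})

    outc_rows = []
    for r in range(n):
        if oc_draw[r] != "none":
            outc_rows.append((primaryid[r], caseid[r], _OUTCOME_CODES[oc_draw[r]]))
        if extra_hosp[r]:
            outc_rows.append((primaryid[r], caseid[r], "HO"))
    outc = pd.DataFrame(outc_rows, columns=["primaryid", "caseid", "outc_cod"])

    ther = pd.DataFrame(
        {
            "primaryid": primaryid,
            "caseid": caseid,
            "dsg_drug_seq": np.ones(n, dtype=int),
            "start_dt": _fmt_date(pd.to_datetime(start_date), date_missing),
        }
    )

    indi_rows = []
    for r in range(n):
        if ra_only[r]:
            indi_rows.append((primaryid[r], caseid[r], 1, "Rheumatoid arthritis"))
        elif ra_plus[r]:
            indi_rows.append((primaryid[r], caseid[r], 1, "Rheumatoid arthritis"))
            indi_rows.append((primaryid[r], caseid[r], 1, extra_indi[r]))
        else:
            indi_rows.append((primaryid[r], caseid[r], 1, extra_indi[r]))
    indi = pd.DataFrame(
        indi_rows, columns=["primaryid", "caseid", "indi_drug_seq", "indi_pt"]
    )

    if len(dup_rows):
        dup_version = version[dup_rows] + 1
        dup_pid = caseid[dup_rows] * 10 + dup_version
        ddemo = demo.iloc[dup_rows].copy()
        ddemo["primaryid"] = dup_pid
        ddemo["caseversion"] = dup_version
        perturb = rng.random(len(dup_rows)) < scenario.duplicate_perturb_rate
        signs = rng.choice([-1.0, 1.0], size=len(dup_rows))
        wt = ddemo["wt"].to_numpy(dtype=object)
        for j in np.flatnonzero(perturb):
            if wt[j] != "":
                wt[j] = "%.1f" % (float(wt[j]) + signs[j])
        ddemo["wt"] = wt
        demo = pd.concat([demo, ddemo], ignore_index=True)

        pid_map = dict(zip(primaryid[dup_rows], dup_pid))

        def _dup(df: pd.DataFrame) -> pd.DataFrame:
            sub = df[df["primaryid"].isin(pid_map)].copy()
            sub["primaryid"] = sub["primaryid"].map(pid_map)
            return pd.concat([df, sub], ignore_index=True)

        drug_df = _dup(drug_df)
        reac = _dup(reac)
        outc = _dup(outc)
        ther = _dup(ther)
        indi = _dup(indi)

    return RawTables(demo=demo, drug=drug_df, reac=reac, outc=outc, ther=ther, indi=indi)


def default_scenario(n_reports: int = 50_000, seed: int = 0) -> SynthScenario:
    """The study-shaped default scenario.

    Five TNF-alpha inhibitors as study drugs with marginal reporting
    probabilities proportional to their real per-drug report counts
    (adalimumab : golimumab : certolizumab : etanercept : infliximab
    = 3441 : 918 : 1190 : 15730 : 1432), together occupying half of all
    reports; ten common RA co-medications share the other half.  Four
    class-effect events are planted in all five drugs and two unique
    events per drug, so the downstream set decomposition has a known
    4-common / 2-unique-per-drug ground truth.
    """
    tnfi_counts = {
        "adalimumab": 3441,
        "golimumab": 918,
        "certolizumab": 1190,
        "etanercept": 15730,
        "infliximab": 1432,
    }
    total = sum(tnfi_counts.values())
    drugs = {d: 0.5 * c / total for d, c in tnfi_counts.items()}
    background_drugs = [
        "methotrexate", "prednisone", "hydroxychloroquine", "leflunomide",
        "sulfasalazine", "tocilizumab", "rituximab", "abatacept",
        "tofacitinib", "naproxen",
    ]
    for d in background_drugs:
        drugs[d] = 0.5 / len(background_drugs)

    common_events = [
        "arthralgia", "drug ineffective", "headache", "nausea", "fatigue",
        "rash", "pain", "pyrexia", "injection site reaction", "diarrhoea",
        "dizziness", "dyspnoea", "pruritus", "cough", "vomiting",
        "infusion related reaction", "urticaria", "back pain", "malaise",
        "pneumonia", "oedema peripheral", "alopecia", "weight decreased",
        "insomnia", "anaemia", "paraesthesia", "chest pain", "psoriasis",
        "abdominal pain", "condition aggravated", "sinusitis",
        "upper respiratory tract infection", "muscle spasms", "asthenia",
        "hypertension", "joint swelling", "bronchitis", "influenza",
        "urinary tract infection", "myalgia",
    ]
    unique_events = {
        "adalimumab": ["lower respiratory tract inflammation", "vascular dementia"],
        "golimumab": ["pneumonia cryptococcal", "device deployment issue"],
        "certolizumab": ["maternal exposure before pregnancy", "premature delivery"],
        "etanercept": ["joint destruction", "chondrolysis"],
        "infliximab": ["hodgkin's disease", "metastatic neoplasm"],
    }
    # Zipf-ish background weights for the common vocabulary; rare background
    # weight for the signal events so that their lifts stand out
    events: dict[str, float] = {
        e: 1.0 / (i + 1) for i, e in enumerate(common_events)
    }
    for e in COMMON_SIGNAL_EVENTS:
        events[e] = 0.02
    for evs in unique_events.values():
        for e in evs:
            events[e] = 0.015

    injected: list[InjectedSignal] = []
    for d in tnfi_counts:
        for e in COMMON_SIGNAL_EVENTS:
            injected.append(InjectedSignal(d, e, lift=10.0))
    lifts = {"adalimumab": (20.0, 15.0), "golimumab": (25.0, 12.0),
             "certolizumab": (18.0, 12.0), "etanercept": (15.0, 14.0),
             "infliximab": (15.0, 12.0)}
    for d, evs in unique_events.items():
        l1, l2 = lifts[d]
        injected.append(InjectedSignal(d, evs[0], lift=l1))
        injected.append(InjectedSignal(d, evs[1], lift=l2))
    # one sex-differential signal to exercise stratified recovery
    injected.append(
        InjectedSignal("etanercept", "joint stiffness", lift=12.0,
                       sex_lift_female=1.0, sex_lift_male=0.1)
    )
    events.setdefault("joint stiffness", 0.02)

    tto = {"*": (4.8, 1.0), "golimumab": (4.2, 1.0), "certolizumab": (4.2, 1.0),
           "etanercept": (4.3, 1.0)}
    return SynthScenario(
        n_reports=n_reports,
        drugs=drugs,
        events=events,
        injected_signals=injected,
        tto_days=tto,
        seed=seed,
    )


def recovery_scenario(n_reports: int = 50_000, seed: int = 0) -> SynthScenario:
    """Power-study scenario: per-drug unique injections only.

    Each planted (drug, event) pair is injected into exactly one drug, so
    the comparator for that pair carries only the event's background rate
    and the planted lift is the true reporting-rate contrast the
    disproportionality statistics should recover.  All lifts are >= 10
    and per-drug report counts are large enough that the expected
    with-drug event count is >= 10.
    """
    base = default_scenario(n_reports=n_reports, seed=seed)
    unique_only = [
        s
        for s in base.injected_signals
        if s.event not in COMMON_SIGNAL_EVENTS and s.sex_lift_male == 1.0
    ]
    return base.replace(injected_signals=tuple(unique_only))


def null_scenario(n_reports: int = 50_000, seed: int = 0) -> SynthScenario:
    """No planted signals: every flagged pair is a false positive."""
    base = default_scenario(n_reports=n_reports, seed=seed)
    return base.replace(injected_signals=())
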