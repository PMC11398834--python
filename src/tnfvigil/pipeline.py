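"""End-to-end orchestration: simulate/read -> clean -> 2x2 tables ->
signal statistics -> shared/unique sets -> descriptives, with a manifest
recording configuration and per-stage record counts for reproducibility.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from . import contingency, descriptives, ingest, sets, stats
from .synthetic import (
    InjectedSignal,
    RawTables,
    SynthScenario,
    STUDY_DRUGS,
    default_scenario,
    generate,
)

__all__ = ["RunConfig", "RunArtifacts", "run", "load_config"]


@dataclass
class RunConfig:
    """One pipeline run.  Exactly one of ``input_dir`` / ``scenario``."""

    input_dir: str | None = None
    dialect: str = "auto"
    scenario: SynthScenario | None = None
    study_drugs: Sequence[str] = STUDY_DRUGS
    synonym_file: str | None = None  # defaults to the packaged dictionary
    require_ra_only: bool = True
    health_professional_only: bool = True
    background: str = "ra_extract"  # or "other_study_drugs"
    stratify_by_sex: bool = True
    count_threshold: int = 3
    alpha: float = 0.05
    ic_variant: str = "noren"
    require_significance: bool = False
    top_k: int = 30
    out_dir: str | None = None
    seed: int | None = None  # overrides scenario.seed when set

    def validate(self) -> None:
        if (self.input_dir is None) == (self.scenario is None):
            raise ValueError("exactly one of input_dir / scenario must be given")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.count_threshold < 0:
            raise ValueError("count_threshold must be nonnegative")
        if self.background not in ("ra_extract", "other_study_drugs"):
            raise ValueError("background must be ra_extract or other_study_drugs")

    def to_jsonable(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        if self.scenario is not None:
            d["scenario"] = dataclasses.asdict(self.scenario)
            d["scenario"]["injected_signals"] = [
                dataclasses.asdict(s) for s in self.scenario.injected_signals
            ]
        d["study_drugs"] = list(self.study_drugs)
        return d


@dataclass
class RunArtifacts:
    reports: pd.DataFrame
    background: pd.DataFrame
    filter_log: ingest.FilterLog
    tables: pd.DataFrame
    signals: pd.DataFrame
    set_summary: sets.SignalSetSummary | None
    demographics: dict
    outcomes_tto: pd.DataFrame
    manifest: dict


def _config_hash(config: RunConfig) -> str:
    canonical = json.dumps(config.to_jsonable(), sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()


def _input_checksums(directory: Path) -> dict[str, str]:
    out = {}
    for p in sorted(directory.iterdir()):
        if p.is_file():
            out[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    return out


def run(config: RunConfig) -> RunArtifacts:
    """Execute the full pipeline; deterministic given config and seed."""
    config.validate()
    manifest: dict[str, Any] = {
        "config_hash": _config_hash(config),
        "stages": {},
    }

    if config.scenario is not None:
        scenario = config.scenario
        if config.seed is not None:
            scenario = scenario.replace(seed=config.seed)
        raw = generate(scenario)
        manifest["input"] = {"mode": "scenario", "seed": scenario.seed}
    else:
        in_dir = Path(config.input_dir)
        if not in_dir.exists():
            raise FileNotFoundError(f"input directory {in_dir} does not exist")
        raw = ingest.read_raw_tables(in_dir, dialect=config.dialect)
        manifest["input"] = {
            "mode": "files",
            "directory": str(in_dir),
            "checksums": _input_checksums(in_dir),
        }
    manifest["stages"]["raw_demo_rows"] = len(raw.demo)

    synonyms = (
        ingest.SynonymDictionary.from_tsv(config.synonym_file)
        if config.synonym_file
        else ingest.SynonymDictionary.default()
    )
    assembled = ingest.assemble_reports(raw, synonyms)
    manifest["stages"]["assembled_reports"] = len(assembled)

    deduped = ingest.deduplicate(assembled)
    manifest["stages"]["deduplicated_reports"] = len(deduped)
    manifest["stages"]["duplicates_removed"] = len(assembled) - len(deduped)

    fres = ingest.apply_inclusion_filters(
        deduped,
        ingest.InclusionConfig(
            study_drugs=config.study_drugs,
            require_ra_only=config.require_ra_only,
            health_professional_only=config.health_professional_only,
        ),
    )
    manifest["stages"]["retained_reports"] = len(fres.retained)
    manifest["stages"]["background_reports"] = len(fres.background)
    manifest["stages"]["filter_log"] = {
        "input_count": fres.log.input_count,
        "removed": fres.log.removed,
        "retained_count": fres.log.retained_count,
    }

    # comparator for drug X is always "everything in the combined frame
    # whose PS drug is not X"; the config switch decides whether the
    # non-study-drug RA extract joins that pool or only the other study
    # drugs do
    background = (
        fres.background
        if config.background == "ra_extract"
        else fres.background.iloc[0:0]
    )
    tables = contingency.build_tables(
        fres.retained,
        background,
        stratify_by_sex=config.stratify_by_sex,
        drugs=list(config.study_drugs),
    )
    manifest["stages"]["contingency_tables"] = len(tables)

    signals = stats.evaluate_signals(
        tables,
        count_threshold=config.count_threshold,
        alpha=config.alpha,
        ic_variant=config.ic_variant,
        require_significance=config.require_significance,
    )
    pos = signals[signals["is_signal"] & (signals["stratum"] == "all")]
    manifest["stages"]["positive_signals_all_stratum"] = int(len(pos))
    manifest["stages"]["positive_signals_per_drug"] = (
        pos.groupby("drug").size().to_dict()
    )

    per_drug_sets = {
        d: set(grp["event"]) for d, grp in pos.groupby("drug")
    }
    for d in config.study_drugs:
        per_drug_sets.setdefault(d, set())
    set_summary = (
        sets.decompose(per_drug_sets) if len(per_drug_sets) >= 2 else None
    )
    if set_summary is not None:
        manifest["stages"]["common_all_count"] = len(set_summary.common_all)
        manifest["stages"]["unique_counts"] = {
            d: len(s) for d, s in set_summary.unique.items()
        }

    demographics = descriptives.summarize_demographics(fres.retained)
    outcomes_tto = descriptives.summarize_outcomes_tto(fres.retained)

    artifacts = RunArtifacts(
        reports=fres.retained,
        background=fres.background,
        filter_log=fres.log,
        tables=tables,
        signals=signals,
        set_summary=set_summary,
        demographics=demographics,
        outcomes_tto=outcomes_tto,
        manifest=manifest,
    )
    if config.out_dir is not None:
        _write_artifacts(artifacts, Path(config.out_dir), config)
    return artifacts


def _write_artifacts(art: RunArtifacts, out_dir: Path, config: RunConfig) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    art.signals.to_csv(out_dir / "signals.tsv", sep="\t", index=False)
    contingency.write_tables(art.tables, out_dir / "contingency.tsv")
    stats.top_k_by_ror(art.signals, k=config.top_k).to_csv(
        out_dir / "forest_topk.tsv", sep="\t", index=False
    )
    art.filter_log.to_json(out_dir / "filter_log.json")
    if art.set_summary is not None:
        art.set_summary.to_json(out_dir / "signal_sets.json")
        art.set_summary.membership_matrix().to_csv(
            out_dir / "signal_membership.tsv", sep="\t"
        )
    descriptives.demographics_frame(art.demographics).to_csv(
        out_dir / "demographics.tsv", sep="\t", index=False
    )
    art.outcomes_tto.to_csv(out_dir / "outcomes_tto.tsv", sep="\t", index=False)
    (out_dir / "manifest.json").write_text(json.dumps(art.manifest, indent=2, default=str))


def _scenario_from_mapping(m: Mapping[str, Any]) -> SynthScenario:
    m = dict(m)
    if m.pop("default", False):
        base = default_scenario(
            n_reports=m.pop("n_reports", 50_000), seed=m.pop("seed", 0)
        )
        return base.replace(**m) if m else base
    if "injected_signals" in m:
        m["injected_signals"] = [
            InjectedSignal(**s) if isinstance(s, Mapping) else s
            for s in m["injected_signals"]
        ]
    if "tto_days" in m:
        m["tto_days"] = {k: tuple(v) for k, v in m["tto_days"].items()}
    return SynthScenario(**m)


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML or JSON file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if "scenario" in data and data["scenario"] is not None:
        data["scenario"] = _scenario_from_mapping(data["scenario"])
    return RunConfig(**data)
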