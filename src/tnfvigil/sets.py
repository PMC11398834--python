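"""Shared / unique decomposition of per-drug signal sets (UpSet semantics).

Given each drug's set of positive-signal event terms, partition the union
of all terms by *exact* membership pattern: an event counted under the
pattern {A, B} belongs to A's and B's sets and no other.  Patterns are
therefore disjoint and their counts sum to the size of the union — the
same decomposition an UpSet plot displays.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Set

import pandas as pd

__all__ = ["SignalSetSummary", "decompose"]

_WS = re.compile(r"\s+")


def _norm_term(term: str) -> str:
    return _WS.sub(" ", str(term).strip().lower())


@dataclass
class SignalSetSummary:
    per_drug: dict[str, frozenset[str]]
    common_all: frozenset[str]
    unique: dict[str, frozenset[str]]
    #: exact-membership pattern -> sorted events; keys ordered by
    #: (degree desc, count desc, lexical)
    intersections: dict[frozenset[str], tuple[str, ...]]

    @property
    def intersection_counts(self) -> dict[frozenset[str], int]:
        return {k: len(v) for k, v in self.intersections.items()}

    def membership_matrix(self) -> pd.DataFrame:
        """Boolean events x drugs matrix suitable for UpSet plotting."""
        drugs = sorted(self.per_drug)
        union = sorted(set().union(*self.per_drug.values())) if self.per_drug else []
        return pd.DataFrame(
            {d: [e in self.per_drug[d] for e in union] for d in drugs}, index=union
        )

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "per_drug": {d: sorted(s) for d, s in self.per_drug.items()},
                "common_all": sorted(self.common_all),
                "unique": {d: sorted(s) for d, s in self.unique.items()},
                "intersections": [
                    {"drugs": sorted(k), "count": len(v), "events": list(v)}
                    for k, v in self.intersections.items()
                ],
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def decompose(per_drug: Mapping[str, Set[str]]) -> SignalSetSummary:
    """Exact-membership decomposition of per-drug event sets.

    Event terms are matched across drugs by case-folded,
    whitespace-normalized string equality.  Requires at least two drugs.
    """
    if len(per_drug) < 2:
        raise ValueError("decompose needs at least two drugs")
    sets = {d: frozenset(_norm_term(e) for e in s) for d, s in per_drug.items()}
    drugs = sorted(sets)
    union = set().union(*sets.values())

    pattern_events: dict[frozenset[str], list[str]] = {}
    for event in union:
        members = frozenset(d for d in drugs if event in sets[d])
        pattern_events.setdefault(members, []).append(event)

    ordered = sorted(
        pattern_events.items(),
        key=lambda kv: (-len(kv[0]), -len(kv[1]), tuple(sorted(kv[0]))),
    )
    intersections = {k: tuple(sorted(v)) for k, v in ordered}

    common_all = frozenset(e for e in union if all(e in sets[d] for d in drugs))
    unique = {
        d: frozenset(
            e for e in sets[d] if not any(e in sets[o] for o in drugs if o != d)
        )
        for d in drugs
    }
    return SignalSetSummary(
        per_drug=sets,
        common_all=common_all,
        unique=unique,
        intersections=intersections,
    )
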