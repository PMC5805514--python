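"""End-to-end orchestration: the reference cohort fixture, cohort
simulation/classification runs and JSON/CSV report assembly."""

from __future__ import annotations

import json
import logging
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .classifier import MOES, MOECall, RuleVote, classify_case, majority_vote
from .config import RunConfig
from .io import CaseBundle
from .sim import build_scenario, simulate_case

log = logging.getLogger(__name__)

__all__ = [
    "load_reference_cohort_votes",
    "reference_cohort_calls",
    "call_to_report",
    "run_simulated_cohort",
]


def _parse_vote_cell(rule_id: int, cell: str) -> RuleVote:
    cell = cell.strip()
    if cell in {"-", ""}:
        return RuleVote(rule_id, frozenset(), False, "not applicable")
    if " or " in cell:
        return RuleVote(rule_id, frozenset(), False, f"ambiguous: {cell}")
    votes = frozenset(v.strip().upper() for v in cell.split(",") if v.strip())
    return RuleVote(rule_id, votes)


def load_reference_cohort_votes() -> pd.DataFrame:
    """The bundled 13-case reference cohort: per-rule vote sets, printed
    conclusions, and the per-case rule restriction (applied to the case
    whose polyp and cancer likely arose from independent clones)."""
    with resources.files("moevo.data").joinpath("reference_cohort_votes.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str).fillna("")
    return df


def reference_cohort_calls() -> list:
    """Run majority vote on the bundled reference-cohort vote sets.

    Returns one MOECall per case; cases with a rule restriction are
    low-confidence by construction.
    """
    calls = []
    for row in load_reference_cohort_votes().itertuples(index=False):
        votes = [
            _parse_vote_cell(rid, getattr(row, f"rule{rid}")) for rid in range(1, 6)
        ]
        restrict = None
        independent = False
        if row.restrict_rules:
            restrict = {int(x) for x in row.restrict_rules.split(",")}
            independent = True
        calls.append(
            majority_vote(
                votes,
                restrict_to_rules=restrict,
                independent_origin=independent,
                case_id=row.case_id,
            )
        )
    return calls


def _clusterset_repr(cs) -> Optional[dict]:
    if cs is None:
        return None
    return {
        "n_afs": cs.n_afs,
        "has_gap": cs.has_gap,
        "clusters": [
            {"mode": c.mode, "weight": c.weight, "interval": list(c.interval)}
            for c in cs.clusters
        ],
        "gaps": [list(g) for g in cs.gaps],
    }


def call_to_report(call: MOECall, config: Optional[RunConfig] = None) -> dict:
    """JSON-serializable report of one call, carrying every rule vote, the
    tally, the features and the thresholds used (for auditability)."""
    report = {
        "case_id": call.case_id,
        "final": call.final_as_str(),
        "confidence": call.confidence,
        "independent_origin": call.independent_origin,
        "tally": {m: call.tally.get(m, 0) for m in MOES},
        "rules": [
            {
                "rule_id": v.rule_id,
                "votes": sorted(v.votes, key=MOES.index),
                "applicable": v.applicable,
                "note": v.note,
            }
            for v in call.rule_votes
        ],
    }
    if call.features:
        f = dict(call.features)
        for key in ("union_clusters", "shared_clusters", "private_clusters"):
            if key in f:
                f[key] = {k: _clusterset_repr(v) for k, v in f[key].items()}
        report["features"] = f
    if config is not None:
        report["config"] = config.to_dict()
    return report


def run_simulated_cohort(
    moes: Sequence[str] = MOES,
    reps: int = 5,
    base_seed: int = 1,
    config: Optional[RunConfig] = None,
    overrides: Optional[dict] = None,
    out_dir: Optional[str] = None,
) -> pd.DataFrame:
    """Simulate ``reps`` cases per mode, classify each, and return the
    cohort summary (one row per case). With ``out_dir`` set, per-case JSON
    reports and the cohort CSV are written there; reruns with the same
    seeds produce byte-identical outputs."""
    cfg = config or RunConfig()
    rows = []
    counter = 0
    for moe in moes:
        for _ in range(reps):
            seed = base_seed + counter
            counter += 1
            bundle = simulate_case(build_scenario(moe, overrides or {}, seed=seed))
            call = classify_case(bundle, cfg)
            rows.append(
                {
                    "case_id": bundle.case_id,
                    "true_moe": moe,
                    "final": call.final_as_str(),
                    "recovered": (not call.unclassifiable) and moe in call.final,
                    "confidence": call.confidence,
                    **{f"tally_{m.lower()}": call.tally[m] for m in MOES},
                }
            )
            if out_dir is not None:
                out = Path(out_dir)
                out.mkdir(parents=True, exist_ok=True)
                report = call_to_report(call, cfg)
                (out / f"{bundle.case_id}.json").write_text(
                    json.dumps(report, indent=2, sort_keys=True, default=float)
                )
    summary = pd.DataFrame(rows)
    if out_dir is not None:
        summary.to_csv(Path(out_dir) / "cohort_summary.csv", index=False)
    return summary
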