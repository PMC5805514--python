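"""Rule-based mode-of-evolution (MOE) classification by majority vote.

Four archetypal adenoma-to-cancer trajectories are considered:

* ``S`` stepwise — gradual accumulation with selection; a selected subclone
  of the polyp founds the cancer.
* ``P`` parallel — polyp and cancer branch early and evolve independently;
  most mutations are private and clonal within their own compartment.
* ``N`` neutral — no selection; essentially all mutations are shared and the
  subclonal tail follows the 1/f law.
* ``E`` eruptive — an early burst fixes the shared clonal structure in the
  polyp, followed by stasis.

Each of five rules inspects one feature (private/shared fractions, AF gaps,
private-cluster position, shared-AF substructure, aneuploidy timing) and
votes for the set of modes compatible with what it sees. The final call is
the argmax set of the per-mode tally over applicable rules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .af import (
    AFClusterSet,
    AFPartition,
    cluster_afs,
    estimate_purity,
    flag_independent_origin,
    partition_snvs,
    relative_position,
)
from .config import RunConfig

log = logging.getLogger(__name__)

MOES = ("S", "P", "N", "E")

__all__ = [
    "MOES",
    "RuleVote",
    "MOECall",
    "rule1_fractions",
    "rule2_gaps",
    "rule3_positions",
    "rule4_shared_structure",
    "rule5_aneuploidy_timing",
    "majority_vote",
    "classify_case",
]


@dataclass
class RuleVote:
    """One rule's vote: the subset of modes compatible with its feature."""

    rule_id: int
    votes: frozenset
    applicable: bool = True
    note: str = ""

    def __post_init__(self) -> None:
        self.votes = frozenset(self.votes)
        if not self.votes <= set(MOES):
            raise ValueError(f"votes {set(self.votes)} not a subset of {MOES}")


@dataclass
class MOECall:
    """Final majority-vote call for one case."""

    case_id: str
    tally: dict
    final: object  # frozenset of modes, or the string "unclassifiable"
    confidence: str = "normal"
    independent_origin: bool = False
    rule_votes: list = field(default_factory=list)
    features: dict = field(default_factory=dict)

    @property
    def unclassifiable(self) -> bool:
        return self.final == "unclassifiable"

    def final_as_str(self) -> str:
        if self.unclassifiable:
            return "unclassifiable"
        return ",".join(sorted(self.final, key=MOES.index)).lower()


def rule1_fractions(partition: AFPartition, cfg: Optional[RunConfig] = None) -> RuleVote:
    """Rule 1 — fraction of private SNVs relative to shared SNVs."""
    cfg = cfg or RunConfig()
    f_s, f_p, f_c = partition.f_shared, partition.f_polyp, partition.f_cancer
    votes = set()
    if (
        f_c >= cfg.rule1_s_private_min
        and f_p >= cfg.rule1_s_private_min
        and f_s >= cfg.rule1_s_shared_min
    ):
        votes.add("S")
    if f_c >= cfg.rule1_p_private_min or f_p >= cfg.rule1_p_private_min:
        votes.add("P")
    if f_c < cfg.rule1_n_private_max and f_p < cfg.rule1_n_private_max:
        votes.add("N")
    if (
        f_c < cfg.rule1_e_cancer_max
        and f_p >= cfg.rule1_e_polyp_min
        and f_s >= cfg.rule1_e_shared_min
    ):
        votes.add("E")
    note = "" if votes else "matches no MOE"
    return RuleVote(1, frozenset(votes), True, note)


def rule2_gaps(
    polyp_has_gap: Optional[bool],
    cancer_has_gap: Optional[bool],
    eruptive_gap_in: str = "cancer",
) -> RuleVote:
    """Rule 2 — presence of a gap in the AF distribution (polyp/cancer).

    gap/gap -> {S, P}; no/no -> {N}; the single-gap patterns depend on which
    compartment carries the eruptive gap: with the normative reading
    (``eruptive_gap_in='cancer'``) no-polyp-gap/cancer-gap -> {E} and the
    reverse pattern matches no mode (the signature of an independently
    arisen cancer).
    """
    if polyp_has_gap is None or cancer_has_gap is None:
        return RuleVote(2, frozenset(), False, "gap not assessable")
    if polyp_has_gap and cancer_has_gap:
        return RuleVote(2, frozenset({"S", "P"}))
    if not polyp_has_gap and not cancer_has_gap:
        return RuleVote(2, frozenset({"N"}))
    eruptive_pattern = cancer_has_gap if eruptive_gap_in == "cancer" else polyp_has_gap
    if eruptive_pattern:
        return RuleVote(2, frozenset({"E"}))
    return RuleVote(2, frozenset(), True, "matches no MOE")


def rule3_positions(polyp_private_pos: str, cancer_private_pos: str) -> RuleVote:
    """Rule 3 — position of private SNV clusters relative to the shared one."""
    for pos in (polyp_private_pos, cancer_private_pos):
        if pos not in {"lower", "equal", "higher", "none"}:
            raise ValueError(f"invalid position {pos!r}")
    votes = set()
    note = ""
    if polyp_private_pos == "none" and cancer_private_pos == "none":
        votes.add("N")
    if polyp_private_pos == "lower":
        votes.add("S")
        if cancer_private_pos == "lower":
            votes.add("E")
    if polyp_private_pos == "equal" and cancer_private_pos == "equal":
        votes.add("P")
    if "higher" in (polyp_private_pos, cancer_private_pos):
        note = "private cluster above shared cluster: polyclonal-origin suspicion"
    if not votes and not note:
        note = "matches no MOE"
    return RuleVote(3, frozenset(votes), True, note)


def rule4_shared_structure(
    shared_afs_polyp: Sequence[float],
    shared_afs_cancer: Sequence[float],
    cfg: Optional[RunConfig] = None,
) -> RuleVote:
    """Rule 4 — are early shared and later shared SNVs indistinguishable?

    Indistinguishable means the shared-SNV AFs form a single cluster in both
    compartments (no internal substructure), which is the signature of
    selection-free shared history -> {N, E}; any substructure -> {S, P}.
    """
    cfg = cfg or RunConfig()
    kwargs = dict(
        bandwidth=cfg.kde_bandwidth,
        min_cluster_weight=cfg.min_cluster_weight,
        min_gap_width=cfg.min_gap_width,
        density_ratio=cfg.density_ratio,
        detection_limit=cfg.detection_limit,
        min_afs=cfg.min_afs_for_clustering,
    )
    cs_p = cluster_afs(shared_afs_polyp, "polyp", **kwargs)
    cs_c = cluster_afs(shared_afs_cancer, "cancer", **kwargs)
    if not cs_p.assessable or not cs_c.assessable:
        return RuleVote(4, frozenset(), False, "too few shared SNVs")
    single_both = len(cs_p.clusters) == 1 and len(cs_c.clusters) == 1
    if single_both:
        return RuleVote(4, frozenset({"N", "E"}))
    return RuleVote(4, frozenset({"S", "P"}))


def rule5_aneuploidy_timing(
    polyp_profile,
    cancer_profile,
    genome_fraction_threshold: float = 0.10,
    margin: float = 0.02,
) -> RuleVote:
    """Rule 5 — compartment in which numerous aneuploidies first appear.

    Profiles expose ``autosomal_altered_fraction``. A sample is aneuploid
    when the altered fraction exceeds the threshold. Aneuploid polyp (early
    onset) -> {N, E}; aneuploid cancer only (late onset) -> {S, P, N};
    neither -> inapplicable. Neutral evolution always stays in the vote set
    when aneuploidies are observable because drift can fix them at any time.
    A polyp fraction within ``margin`` of the threshold makes the timing
    ambiguous and the rule inapplicable.
    """
    if polyp_profile is None or cancer_profile is None:
        return RuleVote(5, frozenset(), False, "no CNA profiles")
    f_p = polyp_profile.autosomal_altered_fraction
    f_c = cancer_profile.autosomal_altered_fraction
    if abs(f_p - genome_fraction_threshold) <= margin:
        return RuleVote(5, frozenset(), False, "ambiguous timing: n,e or s,p,n")
    if f_p > genome_fraction_threshold:
        return RuleVote(5, frozenset({"N", "E"}))
    if f_c > genome_fraction_threshold:
        return RuleVote(5, frozenset({"S", "P", "N"}))
    return RuleVote(5, frozenset(), False, "no significant aneuploidies")


def majority_vote(
    rule_votes: Iterable[RuleVote],
    restrict_to_rules: Optional[Iterable[int]] = None,
    independent_origin: bool = False,
    case_id: str = "",
) -> MOECall:
    """Combine per-rule vote sets into the final call.

    Each applicable rule contributes one tally unit to every mode in its
    vote set; the final call is the set of modes attaining the maximum
    tally. When the independent-origin flag is set the vote is restricted to
    the fraction and aneuploidy-timing rules (1 and 5), the only rules whose
    features remain meaningful for a cancer that did not grow out of the
    polyp clone, and confidence is low.
    """
    votes = list(rule_votes)
    if independent_origin and restrict_to_rules is None:
        restrict_to_rules = {1, 5}
    restrict = set(restrict_to_rules) if restrict_to_rules is not None else None

    applicable = [
        v for v in votes if v.applicable and (restrict is None or v.rule_id in restrict)
    ]
    tally = {m: 0 for m in MOES}
    for v in applicable:
        for m in v.votes:
            tally[m] += 1

    top = max(tally.values()) if tally else 0
    if not applicable or top == 0:
        final: object = "unclassifiable"
    else:
        final = frozenset(m for m in MOES if tally[m] == top)
    confidence = "low" if (independent_origin or len(applicable) < 3) else "normal"
    return MOECall(
        case_id=case_id,
        tally=tally,
        final=final,
        confidence=confidence,
        independent_origin=independent_origin,
        rule_votes=votes,
    )


def _detected_afs(snvs, sample: str, limit: float) -> np.ndarray:
    return np.array(
        [snv.af_by_sample[sample] for snv in snvs if snv.detected_in(sample, limit)],
        dtype=float,
    )


def classify_case(bundle, config: Optional[RunConfig] = None) -> MOECall:
    """Run the full per-case pipeline: partition, clustering, rules 1-5,
    independent-origin check, majority vote.

    ``bundle`` is a :class:`~moevo.io.CaseBundle` (or anything exposing
    ``case_id``, ``snvs``, ``polyp_sample_id``, ``cancer_sample_id`` and
    ``cna_profiles``). All intermediate features are attached to the
    returned call for reporting.
    """
    cfg = config or RunConfig()
    limit = cfg.detection_limit
    polyp = bundle.polyp_sample_id
    cancer = bundle.cancer_sample_id

    partition = partition_snvs(bundle.snvs, polyp, cancer, limit)

    kwargs = dict(
        bandwidth=cfg.kde_bandwidth,
        min_cluster_weight=cfg.min_cluster_weight,
        min_gap_width=cfg.min_gap_width,
        density_ratio=cfg.density_ratio,
        detection_limit=limit,
        min_afs=cfg.min_afs_for_clustering,
    )

    union = partition.shared + partition.polyp_private + partition.cancer_private
    union_p = cluster_afs(_detected_afs(union, polyp, limit), polyp, **kwargs)
    union_c = cluster_afs(_detected_afs(union, cancer, limit), cancer, **kwargs)

    shared_afs_p = _detected_afs(partition.shared, polyp, limit)
    shared_afs_c = _detected_afs(partition.shared, cancer, limit)
    shared_cs_p = cluster_afs(shared_afs_p, polyp, **kwargs)
    shared_cs_c = cluster_afs(shared_afs_c, cancer, **kwargs)

    # Private-cluster positions; a compartment with < min_private_fraction of
    # the union is treated as having no private mutations at all.
    def private_position(private_snvs, fraction, sample, shared_cs):
        if fraction < cfg.min_private_fraction_for_position:
            return "none", None
        afs = _detected_afs(private_snvs, sample, limit)
        cs = cluster_afs(afs, sample, **kwargs)
        if not cs.assessable:
            return "none", cs
        return relative_position(cs, shared_cs, cfg.position_delta), cs

    pos_p, priv_cs_p = private_position(
        partition.polyp_private, partition.f_polyp, polyp, shared_cs_p
    )
    pos_c, priv_cs_c = private_position(
        partition.cancer_private, partition.f_cancer, cancer, shared_cs_c
    )

    drivers = [
        s
        for s in union
        if s.is_driver or (s.gene is not None and s.gene in cfg.driver_genes)
    ]
    indep, evidence = flag_independent_origin(
        drivers, polyp, cancer, cfg.kappa, limit, cfg.driver_min_polyp_af
    )

    votes = [
        rule1_fractions(partition, cfg),
        rule2_gaps(union_p.has_gap, union_c.has_gap, cfg.eruptive_gap_in),
        rule3_positions(pos_p, pos_c),
        rule4_shared_structure(shared_afs_p, shared_afs_c, cfg),
        rule5_aneuploidy_timing(
            bundle.cna_profiles.get(polyp),
            bundle.cna_profiles.get(cancer),
            cfg.aneuploidy_threshold,
            cfg.aneuploidy_margin,
        ),
    ]
    for v in votes:
        log.debug("case %s rule %d -> %s (%s)", bundle.case_id, v.rule_id, set(v.votes), v.note)

    call = majority_vote(votes, independent_origin=indep, case_id=bundle.case_id)
    call.features = {
        "fractions": {
            "shared": partition.f_shared,
            "polyp_private": partition.f_polyp,
            "cancer_private": partition.f_cancer,
        },
        "n_union": partition.n_union,
        "has_gap": {"polyp": union_p.has_gap, "cancer": union_c.has_gap},
        "union_clusters": {"polyp": union_p, "cancer": union_c},
        "shared_clusters": {"polyp": shared_cs_p, "cancer": shared_cs_c},
        "private_clusters": {"polyp": priv_cs_p, "cancer": priv_cs_c},
        "private_position": {"polyp": pos_p, "cancer": pos_c},
        "purity_estimate": {
            "polyp": estimate_purity(shared_afs_p, **kwargs),
            "cancer": estimate_purity(shared_afs_c, **kwargs),
        },
        "independent_origin_evidence": evidence,
        "aneuploid_fraction": {
            s: (p.autosomal_altered_fraction if p is not None else None)
            for s, p in bundle.cna_profiles.items()
        },
    }
    return call
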