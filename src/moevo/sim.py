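"""Synthetic clonal-evolution generator for paired polyp/cancer cases.

The generator works in cancer-cell-fraction (CCF) space: every SNV belongs
to a cluster with a CCF in each compartment (0 = absent), placed according
to one of four archetypes:

* stepwise (S): a clonal shared cluster, a polyp subclone that founded the
  cancer (subclonal in polyp, clonal in cancer), a low-CCF polyp-private
  subclone and a cancer-private subclone swept upward by selection;
* parallel (P): a small shared clonal cluster and compartment-private
  lineages that are clonal within their own compartment, each with a
  subclone;
* neutral (N): a shared clonal cluster plus a shared subclonal tail whose
  frequencies follow the 1/f power law, and a handful of private SNVs;
* eruptive (E): the shared clonal cluster plus several early subclonal
  clusters present in both compartments (a dense CCF ladder in the polyp,
  collapsed to a low-CCF block in the cancer), a polyp-private cluster and
  almost no cancer-private SNVs.

Observed allele fractions follow a heterozygous-diploid observation model:
expected AF = purity x CCF / 2, read depth is Poisson, the read count
carrying the variant is binomial, and an SNV whose observed AF falls below
the detection limit is undetected in that sample. CNA-overlapping SNVs are
not AF-adjusted: large aneuploidies are mostly subclonal and shift shared
and private SNVs together, so they do not change the relative AF pattern
the rules read.

Cluster CCF placements are package choices (no published quantitative
values exist for them), fixed so that each archetype expresses its defining
gap/position features at the default purity and depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from ._genome import GRCH37_AUTOSOMES
from .af import SomaticSNV
from .cna import CNAProfile, genotype_filter
from .io import CaseBundle, Sample
from .spectra import N_CHANNELS, channel_of, decode_channel, _revcomp

__all__ = [
    "SimScenario",
    "TOY_SIGNATURES",
    "build_scenario",
    "sample_neutral_subclonal_afs",
    "apply_observation_model",
    "simulate_cna_profiles",
    "simulate_case",
    "simulate_cohort",
]


def _make_toy_signatures() -> dict:
    flat = np.full(N_CHANNELS, 1.0 / N_CHANNELS)

    # Spontaneous-deamination-like: C>T at NpCpG dominates.
    deam = np.full(N_CHANNELS, 0.2 / N_CHANNELS)
    ct = 2 * 16  # C>T block
    for five in range(4):
        deam[ct + five * 4 + 2] += 0.8 / 4  # 3' base G
    deam /= deam.sum()

    # Mismatch-repair-deficiency-like: broad C>T with a C>A component.
    mmr = np.full(N_CHANNELS, 0.2 / N_CHANNELS)
    mmr[2 * 16 : 3 * 16] += 0.5 / 16
    mmr[0:16] += 0.3 / 16
    mmr /= mmr.sum()

    return {"flat": flat, "deamination-like": deam, "mmr-like": mmr}


#: Built-in toy spectra; stand-ins shaped like common mutational processes,
#: not fitted signature vectors. Users may supply their own 96-vectors.
TOY_SIGNATURES: dict = _make_toy_signatures()


@dataclass
class SimScenario:
    """Parameters of one simulated polyp/cancer case."""

    moe_label: str
    n_shared: int
    n_polyp_private: int
    n_cancer_private: int
    purity_polyp: float = 0.85
    purity_cancer: float = 0.85
    depth: float = 100.0
    detection_limit: float = 0.05
    selection_shift: float = 0.0
    neutral_fmin: float = 0.15
    neutral_fmax: float = 0.5
    aneuploidy_timing: str = "cancer"
    n_cna_events: int = 5
    signature_weights: dict = field(
        default_factory=lambda: {"deamination-like": 0.6, "flat": 0.4}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.moe_label not in {"S", "P", "N", "E"}:
            raise ValueError(f"unknown MOE label {self.moe_label!r}")
        for name in ("n_shared", "n_polyp_private", "n_cancer_private", "n_cna_events"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("purity_polyp", "purity_cancer"):
            if not 0.0 < getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")
        if not 0.0 < self.detection_limit < 1.0:
            raise ValueError("detection_limit must lie in (0, 1)")
        if not 0.0 < self.neutral_fmin < self.neutral_fmax <= 0.5:
            raise ValueError("need 0 < neutral_fmin < neutral_fmax <= 0.5")
        if self.aneuploidy_timing not in {"none", "polyp", "cancer", "random"}:
            raise ValueError(f"invalid aneuploidy_timing {self.aneuploidy_timing!r}")

    @property
    def n_total(self) -> int:
        return self.n_shared + self.n_polyp_private + self.n_cancer_private


# Per-archetype defaults. Counts give union fractions of 0.55/0.15/0.30 (S),
# 0.20/0.25/0.55 (P), 0.97/0.015/0.015 (N) and 0.85/0.12/0.03 (E), each
# satisfying its own mode's fraction-rule condition.
_MOE_DEFAULTS = {
    "S": dict(
        n_shared=1100,
        n_polyp_private=300,
        n_cancer_private=600,
        aneuploidy_timing="cancer",
        selection_shift=0.10,
    ),
    "P": dict(
        n_shared=400,
        n_polyp_private=500,
        n_cancer_private=1100,
        aneuploidy_timing="cancer",
    ),
    "N": dict(
        n_shared=1940,
        n_polyp_private=30,
        n_cancer_private=30,
        aneuploidy_timing="random",
    ),
    "E": dict(
        n_shared=1700,
        n_polyp_private=240,
        n_cancer_private=60,
        aneuploidy_timing="polyp",
    ),
}


def build_scenario(moe_label: str, overrides: Optional[dict] = None, seed: int = 0) -> SimScenario:
    """Scenario with archetype defaults for ``moe_label``, optionally
    overridden field by field."""
    if moe_label not in _MOE_DEFAULTS:
        raise ValueError(
            f"unknown MOE label {moe_label!r}; expected one of S, P, N, E"
        )
    params = dict(_MOE_DEFAULTS[moe_label])
    params.update(overrides or {})
    return SimScenario(moe_label=moe_label, seed=seed, **params)


def sample_neutral_subclonal_afs(
    n: int, f_min: float, f_max: float, seed=None
) -> np.ndarray:
    """Draw subclonal frequencies from the neutral 1/f power law.

    The density is proportional to 1/f^2 on [f_min, f_max], so the number of
    mutations above frequency f grows linearly in 1/f. Sampling is by exact
    inverse-CDF transform and is deterministic under a fixed seed.
    """
    if not (0.0 < f_min < f_max <= 0.5):
        raise ValueError("need 0 < f_min < f_max <= 0.5")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.random(n)
    inv_min, inv_max = 1.0 / f_min, 1.0 / f_max
    return 1.0 / (inv_min - u * (inv_min - inv_max))


def apply_observation_model(
    true_cell_fraction: float,
    purity: float,
    depth: float,
    detection_limit: float = 0.05,
    seed=None,
) -> Optional[float]:
    """Observe one heterozygous-diploid variant at finite depth.

    Expected AF = purity x CCF / 2; depth is Poisson (truncated at >= 1) and
    the variant read count binomial. Returns the observed AF, or None when
    it falls below the detection limit ("undetected").
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    af = _observe(np.array([true_cell_fraction]), purity, depth, detection_limit, rng)[0]
    return None if np.isnan(af) else float(af)


def _observe(
    ccf: np.ndarray, purity: float, depth: float, detection_limit: float, rng
) -> np.ndarray:
    """Vectorized observation model; nan marks undetected."""
    expected = purity * ccf / 2.0
    d = rng.poisson(depth, size=ccf.shape)
    d[d == 0] = 1
    k = rng.binomial(d, np.clip(expected, 0.0, 1.0))
    af = k / d
    af[af < detection_limit] = np.nan
    return af


# Archetype cluster tables: (polyp CCF, cancer CCF, relative weight) within
# each of the shared / polyp-private / cancer-private categories. The
# neutral shared tail is the special entry "tail".
def _archetype_clusters(sc: SimScenario) -> dict:
    if sc.moe_label == "S":
        return {
            "shared": [(1.0, 1.0, 0.545), (0.20, 1.0, 0.455)],
            "polyp": [(0.20, 0.0, 1.0)],
            "cancer": [(0.0, min(1.0, 0.18 + sc.selection_shift), 1.0)],
        }
    if sc.moe_label == "P":
        return {
            "shared": [(1.0, 1.0, 1.0)],
            "polyp": [(1.0, 0.0, 0.6), (0.26, 0.0, 0.4)],
            "cancer": [(0.0, 1.0, 0.636), (0.0, 0.26, 0.364)],
        }
    if sc.moe_label == "N":
        return {
            "shared": [(1.0, 1.0, 0.361), ("tail", "tail", 0.639)],
            "polyp": [(0.30, 0.0, 1.0)],
            "cancer": [(0.0, 0.30, 1.0)],
        }
    # eruptive: dense early ladder in the polyp, low block in the cancer
    return {
        "shared": [
            (1.0, 1.0, 0.4353),
            (0.75, 0.25, 0.1412),
            (0.55, 0.22, 0.1412),
            (0.40, 0.20, 0.1412),
            (0.28, 0.24, 0.1411),
        ],
        "polyp": [(0.25, 0.0, 1.0)],
        "cancer": [(0.0, 0.24, 1.0)],
    }


def _category_ccfs(sc: SimScenario, category: str, n: int, rng) -> tuple:
    """CCF arrays (polyp, cancer) for ``n`` SNVs of one category."""
    clusters = _archetype_clusters(sc)[category]
    weights = np.array([w for _, _, w in clusters])
    idx = rng.choice(len(clusters), size=n, p=weights / weights.sum())
    ccf_p = np.empty(n)
    ccf_c = np.empty(n)
    for i, (cp, cc, _) in enumerate(clusters):
        mask = idx == i
        if cp == "tail":
            f = sample_neutral_subclonal_afs(
                int(mask.sum()), sc.neutral_fmin, sc.neutral_fmax, rng
            )
            ccf = 2.0 * f  # tail frequencies are AF-like (clonal at 0.5)
            ccf_p[mask] = ccf
            ccf_c[mask] = ccf
        else:
            ccf_p[mask] = cp
            ccf_c[mask] = cc
    return ccf_p, ccf_c


_ARM_SPLIT = 0.4  # p-arm fraction of chromosome length used for arm events
_EVENT_CHROMS = tuple(list(GRCH37_AUTOSOMES)[:12])  # the 12 largest autosomes


def simulate_cna_profiles(
    timing: str,
    n_events: int,
    seed=None,
    arm_prob: float = 0.3,
    genome: Optional[dict] = None,
) -> tuple:
    """Simulate aneuploidy-scale CNA profiles for a polyp/cancer pair.

    Events are whole-chromosome or arm-scale deletions/duplications on
    distinct large autosomes. ``timing='polyp'`` puts identical events in
    both profiles (early onset), ``'cancer'`` in the cancer only,
    ``'random'`` flips a coin per event, ``'none'`` leaves both empty.
    Returns ``(polyp_profile, cancer_profile, polyp_segments,
    cancer_segments)`` with the raw segment tables carrying simulated tumor
    and matched-normal copy numbers.
    """
    if timing not in {"none", "polyp", "cancer", "random"}:
        raise ValueError(f"invalid timing {timing!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genome = dict(genome) if genome is not None else dict(GRCH37_AUTOSOMES)

    polyp_rows: list = []
    cancer_rows: list = []
    if timing != "none" and n_events > 0:
        chroms = rng.choice(
            _EVENT_CHROMS, size=min(n_events, len(_EVENT_CHROMS)), replace=False
        )
        for chrom in chroms:
            length = genome[chrom]
            if rng.random() < arm_prob:
                # larger (q-like) arm
                start, end = int(_ARM_SPLIT * length), length
            else:
                start, end = 0, length
            state_dup = rng.random() < 0.5
            tumor_cn = (3.0 if state_dup else 1.0) + rng.normal(0.0, 0.05)
            normal_cn = 2.0 + rng.normal(0.0, 0.03)
            row = {
                "chrom": chrom,
                "start": start,
                "end": end,
                "tumor_cn": round(float(tumor_cn), 3),
                "normal_cn": round(float(normal_cn), 3),
            }
            in_polyp = timing == "polyp" or (timing == "random" and rng.random() < 0.5)
            cancer_rows.append(row)
            if in_polyp:
                polyp_rows.append(dict(row))

    cols = ["chrom", "start", "end", "tumor_cn", "normal_cn"]
    polyp_segments = pd.DataFrame(polyp_rows, columns=cols)
    cancer_segments = pd.DataFrame(cancer_rows, columns=cols)
    polyp_profile = genotype_filter(polyp_segments, "polyp", genome)
    cancer_profile = genotype_filter(cancer_segments, "cancer", genome)
    return polyp_profile, cancer_profile, polyp_segments, cancer_segments


def _draw_contexts(sc: SimScenario, n: int, rng) -> list:
    """(ref, alt, context) triplets drawn from the scenario's signature
    mixture, stored on a random strand."""
    mix = np.zeros(N_CHANNELS)
    for name, w in sc.signature_weights.items():
        vec = TOY_SIGNATURES[name] if isinstance(name, str) else np.asarray(name)
        mix += w * vec
    mix /= mix.sum()
    channels = rng.choice(N_CHANNELS, size=n, p=mix)
    flip = rng.random(n) < 0.5
    out = []
    for ch, fl in zip(channels, flip):
        ref, alt, ctx = decode_channel(int(ch))
        if fl:
            ref, alt, ctx = (
                {"C": "G", "T": "A"}[ref],
                {"A": "T", "C": "G", "G": "C", "T": "A"}[alt],
                _revcomp(ctx),
            )
        out.append((ref, alt, ctx))
    return out


def _draw_positions(n: int, rng, genome: dict) -> list:
    chroms = list(genome)
    lengths = np.array([genome[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    seen = set()
    out = []
    while len(out) < n:
        ci = rng.choice(len(chroms), p=probs)
        pos = int(rng.integers(1, genome[chroms[ci]]))
        key = (chroms[ci], pos)
        if key in seen:
            continue
        seen.add(key)
        out.append(key)
    return out


def simulate_case(scenario: SimScenario, case_id: Optional[str] = None) -> CaseBundle:
    """Simulate one polyp/cancer case bundle from a scenario.

    Deterministic under a fixed scenario (including its seed). SNVs
    undetected in both compartments are dropped, exactly as a finite-
    sensitivity pipeline would never report them.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    case_id = case_id or f"sim-{sc.moe_label}-{sc.seed}"
    polyp_id, cancer_id = f"{case_id}_polyp", f"{case_id}_cancer"

    parts = []
    for category, n in (
        ("shared", sc.n_shared),
        ("polyp", sc.n_polyp_private),
        ("cancer", sc.n_cancer_private),
    ):
        if n > 0:
            parts.append(_category_ccfs(sc, category, n, rng))
    if not parts:
        raise ValueError("scenario has zero SNVs")
    ccf_p = np.concatenate([p for p, _ in parts])
    ccf_c = np.concatenate([c for _, c in parts])

    af_p = _observe(ccf_p, sc.purity_polyp, sc.depth, sc.detection_limit, rng)
    af_c = _observe(ccf_c, sc.purity_cancer, sc.depth, sc.detection_limit, rng)

    n_total = ccf_p.size
    contexts = _draw_contexts(sc, n_total, rng)
    positions = _draw_positions(n_total, rng, GRCH37_AUTOSOMES)

    snvs = []
    for i in range(n_total):
        detected = {}
        if not np.isnan(af_p[i]):
            detected[polyp_id] = round(float(af_p[i]), 6)
        if not np.isnan(af_c[i]):
            detected[cancer_id] = round(float(af_c[i]), 6)
        if not detected:
            continue
        ref, alt, ctx = contexts[i]
        chrom, pos = positions[i]
        snvs.append(
            SomaticSNV(
                chrom=chrom, pos=pos, ref=ref, alt=alt,
                af_by_sample=detected, context=ctx,
            )
        )

    profile_p, profile_c, seg_p, seg_c = simulate_cna_profiles(
        sc.aneuploidy_timing, sc.n_cna_events, rng
    )
    profile_p = replace_sample_id(profile_p, polyp_id)
    profile_c = replace_sample_id(profile_c, cancer_id)

    bundle = CaseBundle(
        case_id=case_id,
        samples=[Sample(polyp_id, "villous"), Sample(cancer_id, "cancer")],
        snvs=snvs,
        cna_profiles={polyp_id: profile_p, cancer_id: profile_c},
        cna_segments={polyp_id: seg_p, cancer_id: seg_c},
        provenance=[f"simulated: moe={sc.moe_label} seed={sc.seed} depth={sc.depth}"],
        true_moe=sc.moe_label,
    )
    return bundle


def replace_sample_id(profile: CNAProfile, sample_id: str) -> CNAProfile:
    return CNAProfile(sample_id=sample_id, events=profile.events, genome=profile.genome)


def simulate_cohort(
    moes=("S", "P", "N", "E"),
    reps: int = 5,
    base_seed: int = 1,
    overrides: Optional[dict] = None,
) -> list:
    """One bundle per (MOE, repetition), seeded reproducibly: repetition
    ``r`` of mode ``m`` uses seed ``base_seed + index``."""
    bundles = []
    counter = 0
    for moe in moes:
        for _ in range(reps):
            sc = build_scenario(moe, overrides or {}, seed=base_seed + counter)
            bundles.append(simulate_case(sc))
            counter += 1
    return bundles
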