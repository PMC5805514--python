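"""Allele-frequency features for paired polyp/cancer somatic SNV sets.

This module turns raw per-sample allele fractions into the features the
mode-of-evolution rules consume: the shared/private partition of the SNV
union, the 1D cluster-and-gap structure of each compartment's AF
distribution, the position of private clusters relative to the shared clonal
cluster, a purity estimate, and the independent-origin flag raised when
shared driver mutations lose allele fraction from polyp to cancer.

All detection semantics are uniform: an SNV is "detected" in a sample iff it
carries an AF >= the detection limit there. SNVs re-quantified below the
limit in the other compartment therefore count as private, which mirrors how
a finite-sensitivity calling pipeline sees the data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.stats import gaussian_kde

log = logging.getLogger(__name__)

__all__ = [
    "SomaticSNV",
    "AFPartition",
    "AFCluster",
    "AFClusterSet",
    "partition_snvs",
    "cluster_afs",
    "relative_position",
    "estimate_purity",
    "flag_independent_origin",
]

_BASES = set("ACGT")


@dataclass(frozen=True)
class SomaticSNV:
    """One somatic substitution with per-sample allele fractions.

    ``af_by_sample`` maps sample id -> allele fraction in [0, 1]; a sample
    absent from the map was not genotyped/detected at all. ``context`` is the
    reference-strand 3-mer centred on the position (middle base == ref).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    af_by_sample: dict = field(default_factory=dict)
    context: Optional[str] = None
    gene: Optional[str] = None
    is_driver: bool = False

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(f"ref/alt must be single bases, got {self.ref}>{self.alt}")
        for sample, af in self.af_by_sample.items():
            if not 0.0 <= af <= 1.0:
                raise ValueError(f"AF {af} for sample {sample} outside [0, 1]")
        if self.context is not None:
            if len(self.context) != 3 or self.context[1] != self.ref:
                raise ValueError(
                    f"context {self.context!r} must be a 3-mer with middle base {self.ref}"
                )

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    def af(self, sample: str) -> Optional[float]:
        return self.af_by_sample.get(sample)

    def detected_in(self, sample: str, detection_limit: float) -> bool:
        af = self.af_by_sample.get(sample)
        return af is not None and af >= detection_limit


@dataclass
class AFPartition:
    """Shared vs private split of the SNV union of one polyp/cancer pair."""

    shared: list
    polyp_private: list
    cancer_private: list
    f_shared: float
    f_polyp: float
    f_cancer: float

    @property
    def n_union(self) -> int:
        return len(self.shared) + len(self.polyp_private) + len(self.cancer_private)


@dataclass(frozen=True)
class AFCluster:
    """One AF cluster: modal AF, fraction of SNVs it holds, AF interval."""

    mode: float
    weight: float
    interval: tuple


@dataclass
class AFClusterSet:
    """Cluster/gap decomposition of one sample's AF distribution.

    ``has_gap`` is True/False when assessable and None when fewer than the
    minimum number of AF values were available.
    """

    sample_id: str
    clusters: list
    gaps: list
    has_gap: Optional[bool]
    n_afs: int

    @property
    def assessable(self) -> bool:
        return self.has_gap is not None

    def dominant_mode(self) -> Optional[float]:
        """Modal AF of the weight-dominant cluster (None if no clusters)."""
        if not self.clusters:
            return None
        return max(self.clusters, key=lambda c: (c.weight, c.mode)).mode


def partition_snvs(
    snvs: Iterable[SomaticSNV],
    polyp_sample: str,
    cancer_sample: str,
    detection_limit: float = 0.05,
) -> AFPartition:
    """Split the SNV union into shared, polyp-private and cancer-private sets.

    An SNV detected (AF >= ``detection_limit``) in both compartments is
    shared; detected in exactly one, private to it; detected in neither it
    does not enter the union. Fractions are over the union size.
    """
    shared: list = []
    polyp_private: list = []
    cancer_private: list = []
    for snv in snvs:
        in_p = snv.detected_in(polyp_sample, detection_limit)
        in_c = snv.detected_in(cancer_sample, detection_limit)
        if in_p and in_c:
            shared.append(snv)
        elif in_p:
            polyp_private.append(snv)
        elif in_c:
            cancer_private.append(snv)
    n = len(shared) + len(polyp_private) + len(cancer_private)
    if n == 0:
        raise ValueError(
            f"empty SNV union for samples {polyp_sample!r}/{cancer_sample!r}"
        )
    return AFPartition(
        shared=shared,
        polyp_private=polyp_private,
        cancer_private=cancer_private,
        f_shared=len(shared) / n,
        f_polyp=len(polyp_private) / n,
        f_cancer=len(cancer_private) / n,
    )


def _contiguous_runs(mask: np.ndarray) -> list:
    """Index ranges [i, j] (inclusive) of True runs in a boolean array."""
    runs = []
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return runs
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    ends = np.concatenate((idx[breaks], [idx[-1]]))
    return list(zip(starts, ends))


def cluster_afs(
    afs: Sequence[float],
    sample_id: str = "",
    *,
    bandwidth: float = 0.03,
    min_cluster_weight: float = 0.05,
    min_gap_width: float = 0.08,
    density_ratio: float = 0.10,
    detection_limit: float = 0.05,
    min_afs: int = 20,
    grid_step: float = 0.002,
) -> AFClusterSet:
    """Decompose a 1D AF distribution into clusters and gaps.

    A Gaussian KDE with fixed absolute bandwidth is evaluated on
    [detection_limit, 1]; clusters are maximal regions where the density is
    at least ``density_ratio`` of the global maximum and that retain at least
    ``min_cluster_weight`` of the SNVs. Threshold regions separated by less
    than ``min_gap_width`` merge into a single cluster, so the remaining
    inter-cluster intervals are the gaps and ``has_gap`` is simply whether
    at least two clusters survive.

    With fewer than ``min_afs`` values the result is "not assessable"
    (``has_gap is None``) rather than an exception.
    """
    values = np.asarray(list(afs), dtype=float)
    n = values.size
    if n < min_afs:
        return AFClusterSet(sample_id, [], [], None, n)

    grid = np.arange(detection_limit, 1.0 + grid_step, grid_step)
    spread = values.std(ddof=1) if n > 1 else 0.0
    if spread < 1e-9:
        mode = float(values.mean())
        cluster = AFCluster(mode, 1.0, (mode - bandwidth, mode + bandwidth))
        return AFClusterSet(sample_id, [cluster], [], False, n)

    kde = gaussian_kde(values, bw_method=bandwidth / spread)
    density = kde(grid)
    threshold = density_ratio * density.max()

    regions = _contiguous_runs(density >= threshold)
    kept = []
    for i, j in regions:
        lo, hi = grid[i], grid[j]
        weight = float(np.mean((values >= lo - grid_step / 2) & (values <= hi + grid_step / 2)))
        if weight >= min_cluster_weight:
            kept.append((i, j, weight))

    # Merge threshold regions closer than min_gap_width: sub-gap dips are not gaps.
    merged: list = []
    for i, j, w in kept:
        if merged and grid[i] - grid[merged[-1][1]] < min_gap_width:
            pi, pj, pw = merged[-1]
            merged[-1] = (pi, j, pw + w)
        else:
            merged.append((i, j, w))

    clusters = []
    for i, j, w in merged:
        k = i + int(np.argmax(density[i : j + 1]))
        clusters.append(AFCluster(float(grid[k]), w, (float(grid[i]), float(grid[j]))))

    gaps = [
        (clusters[k].interval[1], clusters[k + 1].interval[0])
        for k in range(len(clusters) - 1)
    ]
    return AFClusterSet(sample_id, clusters, gaps, len(clusters) >= 2, n)


def relative_position(
    private_clusters: Optional[AFClusterSet],
    shared_clusters: Optional[AFClusterSet],
    delta: float = 0.10,
) -> str:
    """Position of the dominant private cluster relative to the dominant
    shared cluster on the same sample axis: 'lower', 'equal', 'higher' or
    'none' (no private cluster).
    """
    if private_clusters is None or not private_clusters.clusters:
        return "none"
    if shared_clusters is None or not shared_clusters.clusters:
        return "none"
    m_p = private_clusters.dominant_mode()
    m_s = shared_clusters.dominant_mode()
    if m_s - m_p > delta:
        return "lower"
    if m_p - m_s > delta:
        return "higher"
    return "equal"


def estimate_purity(
    shared_afs_in_sample: Sequence[float],
    **cluster_kwargs,
) -> Optional[float]:
    """Estimate sample purity as twice the modal AF of the highest-AF shared
    cluster (clonal heterozygous diploid SNVs sit at AF = purity/2).

    Returns None when too few shared AFs are available. For distributions
    whose subclonal tail merges into the clonal cluster, the single merged
    cluster's mode can sit below the clonal mode and the estimate degrades;
    the relative-position rules are unaffected by this because they only use
    AFs within one sample.
    """
    cs = cluster_afs(shared_afs_in_sample, **cluster_kwargs)
    if not cs.assessable or not cs.clusters:
        return None
    top = max(cs.clusters, key=lambda c: c.mode)
    return min(1.0, 2.0 * top.mode)


def flag_independent_origin(
    driver_snvs: Iterable[SomaticSNV],
    polyp_sample: str,
    cancer_sample: str,
    kappa: float = 0.5,
    detection_limit: float = 0.05,
    min_polyp_af: float = 0.25,
) -> tuple:
    """Flag cases whose cancer likely arose from a different clone than the
    adjacent polyp.

    A driver SNV triggers the flag when it is well represented in the polyp
    (AF >= ``min_polyp_af``) but its cancer AF is below ``kappa`` times its
    polyp AF — or it is undetected in the cancer altogether. Returns
    ``(flag, evidence)`` with one evidence record per triggering SNV.
    """
    evidence = []
    for snv in driver_snvs:
        p_af = snv.af(polyp_sample)
        if p_af is None or p_af < min_polyp_af:
            continue
        c_af = snv.af(cancer_sample)
        undetected = c_af is None or c_af < detection_limit
        if undetected or c_af < kappa * p_af:
            evidence.append(
                {
                    "snv": snv.key,
                    "gene": snv.gene,
                    "polyp_af": p_af,
                    "cancer_af": None if c_af is None else c_af,
                    "reason": "undetected_in_cancer" if undetected else "af_drop",
                }
            )
    return (len(evidence) > 0, evidence)
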