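"""Copy-number aberration profiles, the pairwise genome similarity metric M,
chromosome recurrence testing and UPGMA clustering.

The similarity metric is a per-chromosome Jaccard coefficient over
deletion/duplication intervals, matched by state: shared duplicated bp plus
shared deleted bp, over the union of altered bp in the pair. Summing the
per-chromosome scores over the 22 autosomes gives the genome score
M in [0, 22]. Chromosomes X and Y are excluded so the metric is comparable
across genders.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import wilcoxon
from statsmodels.stats.multitest import multipletests

from ._genome import GRCH37_AUTOSOMES, is_sex_chrom, normalize_chrom

log = logging.getLogger(__name__)

STATES = ("del", "dup")

__all__ = [
    "CNAProfile",
    "SimilarityMatrix",
    "genotype_filter",
    "chromosome_similarity",
    "genome_similarity",
    "similarity_matrix",
    "recurrence_test",
    "upgma_cluster",
]


def merge_intervals(intervals: Iterable[tuple]) -> list:
    """Union of half-open intervals as a sorted, non-overlapping list."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    merged: list = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def total_length(intervals: Sequence[tuple]) -> int:
    return sum(e - s for s, e in intervals)


def intersect_length(a: Sequence[tuple], b: Sequence[tuple]) -> int:
    """Overlap length of two sorted non-overlapping interval lists."""
    i = j = 0
    out = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if hi > lo:
            out += hi - lo
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


@dataclass
class CNAProfile:
    """Genotype-filtered deletion/duplication intervals of one sample.

    ``events`` maps chromosome -> {"del": [...], "dup": [...]} with merged,
    non-overlapping half-open bp intervals.
    """

    sample_id: str
    events: dict = field(default_factory=dict)
    genome: dict = field(default_factory=lambda: dict(GRCH37_AUTOSOMES))

    def intervals(self, chrom: str, state: str) -> list:
        return self.events.get(chrom, {}).get(state, [])

    def chroms_with_events(self) -> list:
        return [
            c
            for c, ev in self.events.items()
            if total_length(ev.get("del", [])) + total_length(ev.get("dup", [])) > 0
        ]

    def altered_length(self, chrom: str) -> int:
        merged = merge_intervals(
            self.intervals(chrom, "del") + self.intervals(chrom, "dup")
        )
        return total_length(merged)

    @property
    def autosomal_altered_fraction(self) -> float:
        altered = sum(self.altered_length(c) for c in self.genome)
        return altered / sum(self.genome.values())

    def chrom_altered_fraction(self, chrom: str) -> float:
        return self.altered_length(chrom) / self.genome[chrom]


def genotype_filter(
    segments: pd.DataFrame,
    sample_id: str = "",
    genome: Optional[dict] = None,
    normal_band: tuple = (1.75, 2.25),
    min_diff: float = 0.2,
) -> CNAProfile:
    """Filter raw CNA segments into a clean profile.

    Keeps segments whose matched-normal copy number lies strictly inside
    ``normal_band`` and whose |tumor - normal| difference exceeds
    ``min_diff``; state is dup if tumor > normal else del. Chromosomes X/Y
    are dropped. Malformed rows (start >= end, negative coordinates) are
    rejected row-wise with a log entry.

    ``segments`` needs columns chrom, start, end, tumor_cn, normal_cn
    (half-open 0-based coordinates).
    """
    genome = dict(genome) if genome is not None else dict(GRCH37_AUTOSOMES)
    events: dict = {}
    for row in segments.itertuples(index=False):
        chrom = normalize_chrom(row.chrom)
        if is_sex_chrom(chrom):
            continue
        start, end = int(row.start), int(row.end)
        if start < 0 or start >= end:
            log.warning(
                "rejected malformed segment %s:%s-%s in %s", chrom, start, end, sample_id
            )
            continue
        normal = float(row.normal_cn)
        tumor = float(row.tumor_cn)
        if not (normal_band[0] < normal < normal_band[1]):
            continue
        if abs(tumor - normal) <= min_diff:
            continue
        state = "dup" if tumor > normal else "del"
        events.setdefault(chrom, {"del": [], "dup": []})[state].append((start, end))
    for chrom, ev in events.items():
        for state in STATES:
            ev[state] = merge_intervals(ev[state])
    return CNAProfile(sample_id=sample_id, events=events, genome=genome)


def chromosome_similarity(profile1: CNAProfile, profile2: CNAProfile, chrom: str) -> float:
    """State-matched Jaccard similarity of two samples' events on one
    chromosome, in [0, 1]; 0 when neither sample has events there.
    """
    shared = 0
    union_terms = 0
    for state in STATES:
        a = profile1.intervals(chrom, state)
        b = profile2.intervals(chrom, state)
        inter = intersect_length(a, b)
        shared += inter
        union_terms += total_length(a) + total_length(b) - inter
    if union_terms == 0:
        return 0.0
    return shared / union_terms


def genome_similarity(profile1: CNAProfile, profile2: CNAProfile) -> float:
    """Genome score M: sum of per-chromosome similarities over autosomes."""
    chroms = set(profile1.genome) | set(profile2.genome)
    return float(
        sum(
            chromosome_similarity(profile1, profile2, c)
            for c in chroms
            if not is_sex_chrom(c)
        )
    )


@dataclass
class SimilarityMatrix:
    """Pairwise similarity of a profile set: per-chromosome and genome-wide."""

    sample_ids: list
    per_chrom: dict  # chrom -> DataFrame (samples x samples)
    M: pd.DataFrame  # genome score matrix


def similarity_matrix(profiles: Sequence[CNAProfile]) -> SimilarityMatrix:
    ids = [p.sample_id for p in profiles]
    chroms = sorted(
        {c for p in profiles for c in p.genome if not is_sex_chrom(c)},
        key=lambda c: (len(c), c),
    )
    per_chrom = {}
    n = len(profiles)
    M = np.zeros((n, n))
    for chrom in chroms:
        mat = np.zeros((n, n))
        for i in range(n):
            for j in range(i, n):
                s = chromosome_similarity(profiles[i], profiles[j], chrom)
                mat[i, j] = mat[j, i] = s
        per_chrom[chrom] = pd.DataFrame(mat, index=ids, columns=ids)
        M += mat
    return SimilarityMatrix(ids, per_chrom, pd.DataFrame(M, index=ids, columns=ids))


def recurrence_test(
    profiles: Sequence[CNAProfile],
    tissue_label: str = "",
    mode: str = "pairs",
) -> pd.DataFrame:
    """Per-chromosome recurrence of aneuploidies within one tissue type.

    For each autosome the observations are paired against the mean over the
    other autosomes and tested with a one-sided Wilcoxon signed-rank test
    (alternative: greater). With ``mode='pairs'`` the paired unit is the
    sample pair and the observable is the pairwise chromosome similarity;
    with ``mode='samples'`` the unit is the sample and the observable is the
    altered fraction of the chromosome. Raw p-values are primary;
    Benjamini-Hochberg-adjusted values are reported alongside.
    """
    if len(profiles) < 5:
        raise ValueError("recurrence_test requires at least 5 profiles")
    if mode not in {"pairs", "samples"}:
        raise ValueError("mode must be 'pairs' or 'samples'")
    chroms = sorted(
        {c for p in profiles for c in p.genome if not is_sex_chrom(c)},
        key=lambda c: (len(c), c),
    )
    if mode == "pairs":
        units = list(itertools.combinations(range(len(profiles)), 2))
        scores = np.array(
            [
                [chromosome_similarity(profiles[i], profiles[j], c) for c in chroms]
                for i, j in units
            ]
        )
    else:
        scores = np.array(
            [[p.chrom_altered_fraction(c) for c in chroms] for p in profiles]
        )

    rows = []
    k = len(chroms)
    for ci, chrom in enumerate(chroms):
        others = np.delete(np.arange(k), ci)
        diffs = scores[:, ci] - scores[:, others].mean(axis=1)
        note = ""
        if np.allclose(diffs, 0.0):
            p = 1.0
            stat = 0.0
            note = "all paired differences zero"
        else:
            stat, p = wilcoxon(diffs, alternative="greater", zero_method="wilcox")
        rows.append(
            {
                "tissue": tissue_label,
                "chrom": chrom,
                "statistic": float(stat),
                "p_value": float(p),
                "median_diff": float(np.median(diffs)),
                "note": note,
            }
        )
    out = pd.DataFrame(rows)
    out["p_bh"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def upgma_cluster(
    matrix,
    labels: Optional[Sequence[str]] = None,
    kind: str = "distance",
) -> tuple:
    """Average-linkage (UPGMA) agglomeration of a symmetric matrix.

    ``kind='similarity'`` converts to distances via d = max(s) - s before
    linking. Returns ``(Z, labels)`` with a scipy linkage matrix; merge
    order on exact ties follows lowest leaf index (scipy's deterministic
    ordering).
    """
    if isinstance(matrix, pd.DataFrame):
        if labels is None:
            labels = list(matrix.index)
        matrix = matrix.to_numpy(dtype=float)
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(matrix, matrix.T, atol=1e-10):
        raise ValueError("matrix must be symmetric")
    if kind == "similarity":
        matrix = matrix.max() - matrix
    elif kind != "distance":
        raise ValueError("kind must be 'distance' or 'similarity'")
    dist = matrix.copy()
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    if labels is None:
        labels = [str(i) for i in range(matrix.shape[0])]
    return Z, list(labels)
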