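"""96-channel trinucleotide substitution spectra.

Somatic substitutions are folded onto the pyrimidine reference strand and
binned into 6 substitution classes (C>A, C>G, C>T, T>A, T>C, T>G) times 16
flanking-base contexts. Channel ordering is lexicographic:
``index = class * 16 + 4 * index(5' base) + index(3' base)`` with bases in
A, C, G, T order, so channel 0 is A[C>A]A and channel 95 is T[T>G]T.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

__all__ = [
    "SUB_CLASSES",
    "N_CHANNELS",
    "SpectrumVector",
    "channel_of",
    "channel_label",
    "decode_channel",
    "spectrum",
    "spectrum_correlation",
    "cluster_spectra",
    "match_signatures",
    "spectra_to_frame",
]

SUB_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = "ACGT"
N_CHANNELS = 96

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def channel_of(ref: str, alt: str, context: str) -> int:
    """Map a substitution with its reference-strand 3-mer context to its
    channel index 0-95. Purine references are complemented (and the context
    reverse-complemented) first, so strand-equivalent inputs share a channel.
    """
    if ref == alt:
        raise ValueError("ref == alt is not a substitution")
    if ref not in BASES or alt not in BASES:
        raise ValueError(f"invalid bases {ref!r}>{alt!r}")
    if len(context) != 3 or any(b not in BASES for b in context):
        raise ValueError(f"context must be a 3-mer over ACGT, got {context!r}")
    if context[1] != ref:
        raise ValueError(f"context middle base {context[1]!r} != ref {ref!r}")
    if ref in "AG":
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        context = _revcomp(context)
    cls = SUB_CLASSES.index(f"{ref}>{alt}")
    return cls * 16 + BASES.index(context[0]) * 4 + BASES.index(context[2])


def decode_channel(index: int) -> tuple:
    """Inverse of :func:`channel_of` on the pyrimidine strand:
    returns (ref, alt, context)."""
    if not 0 <= index < N_CHANNELS:
        raise ValueError(f"channel index {index} out of range")
    cls, rest = divmod(index, 16)
    five, three = divmod(rest, 4)
    ref, alt = SUB_CLASSES[cls].split(">")
    return ref, alt, BASES[five] + ref + BASES[three]


def channel_label(index: int) -> str:
    ref, alt, ctx = decode_channel(index)
    return f"{ctx[0]}[{ref}>{alt}]{ctx[2]}"


@dataclass
class SpectrumVector:
    """Normalized 96-channel spectrum of one sample.

    ``flagged`` marks spectra built from all of a sample's SNVs because too
    few compartment-specific SNVs were available (the asterisk convention).
    """

    weights: np.ndarray
    n_snvs: int
    sample_id: str = ""
    flagged: bool = False

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (N_CHANNELS,):
            raise ValueError(f"spectrum must have {N_CHANNELS} channels")
        if (w < 0).any():
            raise ValueError("spectrum weights must be non-negative")
        total = w.sum()
        if total <= 0:
            raise ValueError("spectrum has zero total weight")
        self.weights = w / total


def spectrum(
    snvs: Iterable,
    sample: str,
    exclude_sample: Optional[str] = None,
    detection_limit: float = 0.05,
    min_snvs: int = 50,
    fallback_to_all: bool = True,
) -> SpectrumVector:
    """Build the spectrum of SNVs detected in ``sample``.

    With ``exclude_sample`` set, only SNVs NOT detected there are used
    (e.g. cancer-specific = cancer minus polyp, ensuring mutual
    exclusivity). If fewer than ``min_snvs`` remain and ``fallback_to_all``
    is enabled, all of the sample's SNVs are used instead and the spectrum
    is flagged.
    """
    snvs = list(snvs)
    in_sample = [s for s in snvs if s.detected_in(sample, detection_limit)]
    if exclude_sample is not None:
        selected = [
            s for s in in_sample if not s.detected_in(exclude_sample, detection_limit)
        ]
    else:
        selected = in_sample
    flagged = False
    if exclude_sample is not None and len(selected) < min_snvs and fallback_to_all:
        selected = in_sample
        flagged = True

    counts = np.zeros(N_CHANNELS)
    used = 0
    for s in selected:
        if s.context is None:
            continue
        counts[channel_of(s.ref, s.alt, s.context)] += 1
        used += 1
    if used == 0:
        raise ValueError(f"no usable SNVs with context for sample {sample!r}")
    return SpectrumVector(counts, n_snvs=used, sample_id=sample, flagged=flagged)


def spectrum_correlation(s1, s2) -> float:
    """Pearson correlation of two spectra across the 96 channels.

    Accepts SpectrumVector or raw 96-vectors (counts or proportions —
    Pearson is scale invariant). Returns nan for a zero-variance vector.
    """
    a = s1.weights if isinstance(s1, SpectrumVector) else np.asarray(s1, dtype=float)
    b = s2.weights if isinstance(s2, SpectrumVector) else np.asarray(s2, dtype=float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(pearsonr(a, b)[0])


def cluster_spectra(spectra: Sequence[SpectrumVector]) -> tuple:
    """UPGMA dendrogram over spectra with distance 1 - Pearson r.

    Returns ``(Z, labels)`` as in :func:`moevo.cna.upgma_cluster`.
    """
    from .cna import upgma_cluster

    if len(spectra) < 2:
        raise ValueError("need at least 2 spectra to cluster")
    n = len(spectra)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = spectrum_correlation(spectra[i], spectra[j])
            if np.isnan(r):
                raise ValueError("zero-variance spectrum cannot be clustered")
            dist[i, j] = dist[j, i] = 1.0 - r
    labels = [
        s.sample_id + ("*" if s.flagged else "") or str(i)
        for i, s in enumerate(spectra)
    ]
    return upgma_cluster(dist, labels=labels, kind="distance")


def match_signatures(spec: SpectrumVector, signature_matrix: pd.DataFrame) -> tuple:
    """Cosine similarity of a spectrum against user-supplied signature
    columns (96 rows x k signatures). Returns ``(per_signature, best)``.
    """
    mat = signature_matrix.to_numpy(dtype=float)
    if mat.shape[0] != N_CHANNELS:
        raise ValueError(f"signature matrix must have {N_CHANNELS} rows")
    w = spec.weights
    sims = {}
    for name, col in zip(signature_matrix.columns, mat.T):
        denom = np.linalg.norm(w) * np.linalg.norm(col)
        sims[name] = float(w @ col / denom) if denom > 0 else 0.0
    series = pd.Series(sims)
    return series, series.idxmax()


def spectra_to_frame(spectra: Sequence[SpectrumVector]) -> pd.DataFrame:
    """Long-form table mirroring the 6-class x 16-context heatmap layout,
    one weight column per sample plus its (log-scale-ready) SNV count."""
    rows = []
    for i in range(N_CHANNELS):
        ref, alt, ctx = decode_channel(i)
        rows.append(
            {"channel": channel_label(i), "class": f"{ref}>{alt}", "context": ctx}
        )
    frame = pd.DataFrame(rows)
    for s in spectra:
        name = s.sample_id + ("*" if s.flagged else "")
        frame[name] = s.weights
        frame.attrs[f"n_snvs:{name}"] = s.n_snvs
    return frame
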