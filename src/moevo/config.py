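"""Run configuration: every threshold the classification pipeline uses, in one place.

The defaults encode the published qualitative rule thresholds (fractions of
private/shared SNVs, the 10% aneuploid-genome cutoff) together with the
operational parameters this package had to choose itself (KDE bandwidth, gap
width, cluster-position delta). All of them can be overridden from YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import yaml


@dataclass
class RunConfig:
    """Thresholds and knobs for the MOE classification pipeline.

    Attributes
    ----------
    detection_limit
        Minimum observable allele fraction; an SNV with AF below this in a
        sample counts as undetected there.
    consensus_min_callers
        ``k`` of the ``k``-of-``n`` caller consensus merge.
    kde_bandwidth, density_ratio, min_cluster_weight, min_gap_width
        Parameters of the 1D AF cluster/gap detector: Gaussian KDE bandwidth
        (absolute, AF units); clusters are maximal regions with density at
        least ``density_ratio`` times the global maximum, retaining at least
        ``min_cluster_weight`` of the SNVs; inter-cluster intervals narrower
        than ``min_gap_width`` are not gaps (the flanking clusters merge).
    min_afs_for_clustering
        Below this many AF values the gap flag is "not assessable".
    position_delta
        Modal-AF difference below which private and shared clusters count as
        "equal" in the cluster-position rule.
    rule1_*
        Fraction thresholds of the private/shared-fraction rule.
    min_private_fraction_for_position
        Private fraction of the union below which a compartment is treated as
        having effectively no private mutations (position "none").
    kappa, driver_min_polyp_af
        Independent-origin flag: a driver SNV with polyp AF >= the minimum
        whose cancer AF drops below ``kappa`` times the polyp AF (or vanishes)
        is evidence that polyp and cancer arose from different clones.
    aneuploidy_threshold, aneuploidy_margin
        A sample is aneuploid when more than ``aneuploidy_threshold`` of its
        autosomal genome is altered; a polyp fraction within
        ``aneuploidy_margin`` of the threshold makes aneuploidy timing
        ambiguous and the rule inapplicable.
    eruptive_gap_in
        Which compartment carries the AF gap under the eruptive mode:
        "cancer" (normative) or "polyp" (the alternative reading).
    driver_genes
        Gene symbols treated as drivers when SNVs are not explicitly flagged.
    """

    detection_limit: float = 0.05
    consensus_min_callers: int = 3

    kde_bandwidth: float = 0.03
    density_ratio: float = 0.10
    min_cluster_weight: float = 0.05
    min_gap_width: float = 0.08
    min_afs_for_clustering: int = 20

    position_delta: float = 0.10

    rule1_s_private_min: float = 0.10
    rule1_s_shared_min: float = 0.40
    rule1_p_private_min: float = 0.50
    rule1_n_private_max: float = 0.05
    rule1_e_cancer_max: float = 0.05
    rule1_e_polyp_min: float = 0.10
    rule1_e_shared_min: float = 0.80

    min_private_fraction_for_position: float = 0.05

    kappa: float = 0.5
    driver_min_polyp_af: float = 0.25

    aneuploidy_threshold: float = 0.10
    aneuploidy_margin: float = 0.02

    eruptive_gap_in: str = "cancer"
    driver_genes: tuple[str, ...] = ("APC", "KRAS", "TP53")

    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name in (
            "detection_limit",
            "density_ratio",
            "min_cluster_weight",
            "min_gap_width",
            "position_delta",
            "rule1_s_private_min",
            "rule1_s_shared_min",
            "rule1_p_private_min",
            "rule1_n_private_max",
            "rule1_e_cancer_max",
            "rule1_e_polyp_min",
            "rule1_e_shared_min",
            "min_private_fraction_for_position",
            "kappa",
            "driver_min_polyp_af",
            "aneuploidy_threshold",
            "aneuploidy_margin",
        ):
            value = getattr(self, name)
            if not 0.0 <= float(value) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
        if self.eruptive_gap_in not in {"cancer", "polyp"}:
            raise ValueError("eruptive_gap_in must be 'cancer' or 'polyp'")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["driver_genes"] = list(self.driver_genes)
        return d

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "driver_genes" in data:
            data["driver_genes"] = tuple(data["driver_genes"])
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
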