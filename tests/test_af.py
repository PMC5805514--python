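"""AF features: shared/private partition, cluster/gap detection, cluster
positions, purity estimation and the independent-origin flag."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from moevo import (
    SomaticSNV,
    build_scenario,
    cluster_afs,
    estimate_purity,
    flag_independent_origin,
    partition_snvs,
    relative_position,
    simulate_case,
)


def snv(i, afs, **kw):
    return SomaticSNV("chr1", i + 1, "C", "T", af_by_sample=afs, **kw)


class TestSomaticSNV:
    def test_rejects_identity_substitution(self):
        with pytest.raises(ValueError):
            SomaticSNV("chr1", 1, "C", "C")

    def test_rejects_out_of_range_af(self):
        with pytest.raises(ValueError):
            snv(0, {"a": 1.2})

    def test_rejects_context_ref_mismatch(self):
        with pytest.raises(ValueError):
            SomaticSNV("chr1", 1, "C", "T", context="ATA")


class TestPartition:
    def test_counting(self):
        snvs = (
            [snv(i, {"p": 0.4, "c": 0.4}) for i in range(40)]
            + [snv(100 + i, {"p": 0.2}) for i in range(30)]
            + [snv(200 + i, {"c": 0.2}) for i in range(30)]
        )
        part = partition_snvs(snvs, "p", "c", 0.05)
        assert (part.f_shared, part.f_polyp, part.f_cancer) == (0.4, 0.3, 0.3)

    def test_all_shared(self):
        snvs = [snv(i, {"p": 0.5, "c": 0.5}) for i in range(10)]
        assert partition_snvs(snvs, "p", "c", 0.05).f_shared == 1.0

    def test_below_limit_counts_as_private(self):
        # re-quantified below the detection limit in the other compartment
        part = partition_snvs([snv(0, {"p": 0.3, "c": 0.02})], "p", "c", 0.05)
        assert len(part.polyp_private) == 1 and not part.shared

    def test_empty_union_rejected(self):
        with pytest.raises(ValueError, match="empty SNV union"):
            partition_snvs([snv(0, {"p": 0.01})], "p", "c", 0.05)

    def test_simulated_eruptive_case_has_few_cancer_private(self, default_bundles, cfg):
        b = default_bundles["E"]
        part = partition_snvs(
            b.snvs, b.polyp_sample_id, b.cancer_sample_id, cfg.detection_limit
        )
        assert part.f_cancer < 0.05

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.tuples(st.booleans(), st.booleans()).filter(lambda t: any(t)),
            min_size=1,
            max_size=60,
        )
    )
    def test_partition_is_disjoint_cover_of_union(self, flags):
        snvs = [
            snv(i, {**({"p": 0.3} if in_p else {}), **({"c": 0.3} if in_c else {})})
            for i, (in_p, in_c) in enumerate(flags)
        ]
        part = partition_snvs(snvs, "p", "c", 0.05)
        groups = [part.shared, part.polyp_private, part.cancer_private]
        keys = [s.key for g in groups for s in g]
        assert len(keys) == len(set(keys)) == len(snvs)
        assert part.f_shared + part.f_polyp + part.f_cancer == pytest.approx(1.0)
        # order independence
        part2 = partition_snvs(list(reversed(snvs)), "p", "c", 0.05)
        assert {s.key for s in part2.shared} == {s.key for s in part.shared}


class TestClusterAfs:
    def test_two_well_separated_modes(self, rng):
        afs = np.r_[rng.normal(0.25, 0.02, 250), rng.normal(0.5, 0.02, 250)]
        cs = cluster_afs(afs)
        assert len(cs.clusters) == 2 and cs.has_gap is True
        modes = sorted(c.mode for c in cs.clusters)
        assert modes[0] == pytest.approx(0.25, abs=0.02)
        assert modes[1] == pytest.approx(0.50, abs=0.02)
        assert len(cs.gaps) == 1

    def test_uniform_has_no_gap(self, rng):
        cs = cluster_afs(rng.uniform(0.05, 0.5, 500))
        assert len(cs.clusters) == 1 and cs.has_gap is False

    def test_too_few_values_not_assessable(self, rng):
        cs = cluster_afs(rng.uniform(0.1, 0.5, 10))
        assert cs.has_gap is None and not cs.assessable

    def test_single_tight_cluster(self, rng):
        cs = cluster_afs(rng.normal(0.4, 0.005, 300))
        assert len(cs.clusters) == 1 and cs.has_gap is False

    def test_degenerate_identical_values(self):
        cs = cluster_afs(np.full(30, 0.4))
        assert len(cs.clusters) == 1 and cs.has_gap is False
        assert cs.clusters[0].mode == pytest.approx(0.4)

    def test_cluster_weights_sum_below_one(self, rng):
        afs = np.r_[rng.normal(0.2, 0.02, 240), rng.normal(0.5, 0.02, 260)]
        cs = cluster_afs(afs)
        total = sum(c.weight for c in cs.clusters)
        assert 0.9 <= total <= 1.0 + 1e-9

    def test_sub_gap_dips_merge_into_one_cluster(self, rng):
        # two modes closer than min_gap_width must not count as a gap
        afs = np.r_[rng.normal(0.40, 0.015, 250), rng.normal(0.46, 0.015, 250)]
        cs = cluster_afs(afs)
        assert cs.has_gap is False and len(cs.gaps) == 0


class TestRelativePosition:
    def make(self, *mode_weight):
        clusters = [
            type("C", (), {"mode": m, "weight": w, "interval": (m - 0.05, m + 0.05)})()
            for m, w in mode_weight
        ]
        cs = cluster_afs(np.repeat([m for m, _ in mode_weight], 30))
        cs.clusters = clusters
        return cs

    def test_lower_equal_higher(self):
        shared = self.make((0.45, 0.8))
        assert relative_position(self.make((0.15, 1.0)), shared, 0.1) == "lower"
        assert relative_position(self.make((0.42, 1.0)), shared, 0.1) == "equal"
        assert relative_position(self.make((0.60, 1.0)), shared, 0.1) == "higher"

    def test_none_without_private_clusters(self):
        assert relative_position(None, self.make((0.45, 1.0)), 0.1) == "none"

    def test_dominant_cluster_decides(self):
        private = self.make((0.15, 0.3), (0.44, 0.7))
        assert relative_position(private, self.make((0.45, 1.0)), 0.1) == "equal"

    def test_invariant_to_common_purity_scaling(self, rng):
        # scaling all AFs of one sample by a purity factor preserves the
        # qualitative relative pattern
        shared = rng.normal(0.5, 0.02, 300)
        private_low = rng.normal(0.12, 0.02, 300)
        private_eq = rng.normal(0.5, 0.02, 300)
        for factor in (1.0, 0.8, 0.6):
            assert relative_position(
                cluster_afs(private_low * factor), cluster_afs(shared * factor)
            ) == "lower"
            assert relative_position(
                cluster_afs(private_eq * factor), cluster_afs(shared * factor)
            ) == "equal"


class TestEstimatePurity:
    def test_formula_on_clean_clusters(self, rng):
        assert estimate_purity(rng.normal(0.5, 0.01, 200)) == pytest.approx(1.0, abs=0.05)
        assert estimate_purity(rng.normal(0.3, 0.01, 200)) == pytest.approx(0.6, abs=0.05)

    def test_too_few_values(self):
        assert estimate_purity([0.5] * 5) is None

    def test_invariant_to_subclonal_snvs_below_clonal_cluster(self, rng):
        clonal = rng.normal(0.35, 0.02, 400)
        with_tail = np.r_[clonal, rng.uniform(0.06, 0.15, 150)]
        assert estimate_purity(with_tail) == pytest.approx(
            estimate_purity(clonal), abs=0.02
        )

    def test_recovers_simulated_cancer_purity(self, cfg):
        sc = build_scenario(
            "S", {"purity_cancer": 0.7, "depth": 200, "n_shared": 2000}, 5
        )
        bundle = simulate_case(sc)
        cancer = bundle.cancer_sample_id
        part_afs = [
            s.af_by_sample[cancer]
            for s in bundle.snvs
            if s.detected_in(cancer, cfg.detection_limit)
            and s.detected_in(bundle.polyp_sample_id, cfg.detection_limit)
        ]
        assert estimate_purity(part_afs) == pytest.approx(0.7, abs=0.05)


class TestIndependentOrigin:
    def drivers(self):
        return [
            SomaticSNV("chr17", 7577121, "C", "T",
                       {"villous": 0.471, "cancer": 0.167}, gene="TP53", is_driver=True),
            SomaticSNV("chr17", 7578406, "C", "A",
                       {"villous": 0.424, "cancer": 0.028}, gene="TP53", is_driver=True),
            SomaticSNV("chr12", 25398284, "C", "A",
                       {"villous": 0.261}, gene="KRAS", is_driver=True),
        ]

    # the second case's cancer AF (0.028) sits below the detection limit,
    # so it is evidence of the "undetected" kind rather than an AF drop
    @pytest.mark.parametrize("idx,reason", [(0, "af_drop"), (1, "undetected_in_cancer"),
                                            (2, "undetected_in_cancer")])
    def test_driver_af_collapse_triggers_flag(self, idx, reason):
        flag, evidence = flag_independent_origin(
            [self.drivers()[idx]], "villous", "cancer"
        )
        assert flag and evidence[0]["reason"] == reason

    def test_stable_driver_does_not_trigger(self):
        stable = SomaticSNV("chr17", 100, "C", "T",
                            {"villous": 0.45, "cancer": 0.40}, gene="TP53")
        flag, evidence = flag_independent_origin([stable], "villous", "cancer")
        assert not flag and evidence == []

    def test_no_drivers_no_flag(self):
        assert flag_independent_origin([], "villous", "cancer") == (False, [])

    def test_low_polyp_af_driver_ignored(self):
        low = SomaticSNV("chr17", 100, "C", "T",
                         {"villous": 0.10, "cancer": 0.02}, gene="TP53")
        flag, _ = flag_independent_origin([low], "villous", "cancer")
        assert not flag
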