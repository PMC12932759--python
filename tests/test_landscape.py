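"""Tumor-level burdens, landscape scores, CSiN/ioTNL and heterogeneity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neoprecis.landscape import (
    CSIN_CUTOFFS,
    CloneCluster,
    TumorProfile,
    clonality_summaries,
    csin,
    dual_score,
    gini,
    heterogeneity_class,
    iotnl,
    landscape_ccf,
    landscape_clone,
    landscape_sum,
    mutation_burdens,
    tumor_gini,
)
from neoprecis.mutation_metrics import MutationRecord


def mut(mid, np_i=0.5, np_ii=0.5, ccf=1.0, cluster=None, phbr_i=1.0, dna_af=0.5,
        pmhc_ranks=(1.0,)):
    return MutationRecord(
        mutation_id=mid, np_immuno_i=np_i, np_immuno_ii=np_ii, ccf=ccf,
        cluster_id=cluster, phbr_i=phbr_i, dna_af=dna_af,
        pmhc_ranks=list(pmhc_ranks),
    )


def profile(mutations, clusters=None, pid="P0"):
    return TumorProfile(
        patient_id=pid, hla_i=["A1"], hla_ii=["D1"],
        mutations=mutations, clusters=clusters or [],
    )


class TestBurdens:
    def test_npb_threshold_arithmetic(self):
        p = profile([
            mut("m1", 0.5, 0.5),   # 0.25 passes
            mut("m2", 0.3, 0.4),   # 0.12 fails
            mut("m3", 0.4, 0.4),   # 0.16 passes (non-strict)
        ])
        assert mutation_burdens(p)[2] == 2

    def test_tnb_counts_phbr_binders(self):
        p = profile([mut("m1", phbr_i=1.5), mut("m2", phbr_i=2.0), mut("m3", phbr_i=3.0)])
        assert mutation_burdens(p)[1] == 2

    def test_empty_tumor(self):
        assert mutation_burdens(profile([])) == (0, 0, 0)


class TestDualScore:
    def test_methods(self):
        assert dual_score(0.5, 0.4, "product") == pytest.approx(0.2)
        assert dual_score(0.7, 0.0, "product") == 0.0
        assert dual_score(0.5, 0.4, "max") == 0.5
        assert dual_score(0.5, 0.4, "sum") == pytest.approx(0.9)
        with pytest.raises(ValueError):
            dual_score(0.5, 0.4, "geometric")


class TestLandscapeSum:
    def test_hand_computed(self):
        # dual scores 0.5, 0.2, 0.3 -> log10(2)
        p = profile([mut("a", 0.5, 1.0), mut("b", 0.2, 1.0), mut("c", 0.3, 1.0)])
        assert landscape_sum(p) == pytest.approx(math.log10(2.0))

    def test_empty_is_zero(self):
        assert landscape_sum(profile([])) == 0.0

    def test_zero_dual_mutation_is_neutral(self):
        base = [mut("a", 0.5, 1.0)]
        with_zero = base + [mut("b", 0.0, 0.9)]
        assert landscape_sum(profile(with_zero)) == landscape_sum(profile(base))


class TestLandscapeCCF:
    def test_hand_computed(self):
        p = profile([mut("a", 0.5, 1.0, ccf=1.0), mut("b", 0.2, 1.0, ccf=0.4)])
        assert landscape_ccf(p) == pytest.approx(math.log10(1.58))

    def test_reduces_to_sum_at_full_ccf(self):
        p = profile([mut("a", 0.5, 0.7, ccf=1.0), mut("b", 0.3, 0.9, ccf=1.0)])
        assert landscape_ccf(p) == pytest.approx(landscape_sum(p))

    def test_zero_ccf_gives_zero(self):
        p = profile([mut("a", 0.5, 0.7, ccf=0.0)])
        assert landscape_ccf(p) == 0.0

    def test_never_exceeds_sum(self):
        rng = np.random.default_rng(0)
        muts = [mut(f"m{i}", rng.random(), rng.random(), ccf=rng.random())
                for i in range(30)]
        p = profile(muts)
        assert landscape_ccf(p) <= landscape_sum(p) + 1e-12


class TestLandscapeClone:
    def test_two_cluster_hand_case(self):
        # cluster scores C = 3.0 (prev 1.0) and 1.0 (prev 0.5):
        # log10(1 + (3 + 0.5) / 1.5) = log10(10/3)
        clusters = [CloneCluster("c0", 1.0, {"a"}), CloneCluster("c1", 0.5, {"b"})]
        muts = [mut("a", 2.0, 1.5, cluster="c0"), mut("b", 1.0, 1.0, cluster="c1")]
        p = profile(muts, clusters)
        assert landscape_clone(p) == pytest.approx(math.log10(10 / 3))

    def test_single_cluster_product(self):
        clusters = [CloneCluster("c0", 1.0, {"a", "b"})]
        muts = [mut("a", 1.5, 0.25, cluster="c0"), mut("b", 0.5, 0.25, cluster="c0")]
        # np_i sum 2, np_ii sum 0.5 -> product 1.0 -> log10(2)
        assert landscape_clone(profile(muts, clusters)) == pytest.approx(math.log10(2.0))

    def test_zero_prevalence_cluster_contributes_nothing(self):
        clusters = [CloneCluster("c0", 1.0, {"a"}), CloneCluster("c1", 0.0, {"b"})]
        muts = [mut("a", 1.0, 1.0, cluster="c0"), mut("b", 9.0, 9.0, cluster="c1")]
        assert landscape_clone(profile(muts, clusters)) == pytest.approx(math.log10(2.0))

    def test_all_zero_prevalence_degenerate(self):
        clusters = [CloneCluster("c0", 0.0, {"a"})]
        p = profile([mut("a", cluster="c0")], clusters)
        assert landscape_clone(p) == 0.0

    def test_single_full_cluster_closed_form(self):
        rng = np.random.default_rng(1)
        muts = [mut(f"m{i}", rng.random(), rng.random(), cluster="c0") for i in range(10)]
        clusters = [CloneCluster("c0", 1.0, {m.mutation_id for m in muts})]
        expected = math.log10(1 + sum(m.np_immuno_i for m in muts)
                              * sum(m.np_immuno_ii for m in muts))
        assert landscape_clone(profile(muts, clusters)) == pytest.approx(expected)


class TestCSiN:
    def test_homogeneous_landscape_is_zero(self):
        muts = [mut(f"m{i}", dna_af=0.3, pmhc_ranks=[0.2, 1.0, 3.0]) for i in range(5)]
        assert csin(muts) == pytest.approx(0.0)

    def test_low_vaf_excluded(self):
        low = mut("low", dna_af=0.04, pmhc_ranks=[0.1])
        rest = [mut(f"m{i}", dna_af=0.3, pmhc_ranks=[0.2]) for i in range(3)]
        assert csin([low] + rest) == pytest.approx(csin(rest))

    def test_matches_brute_force_oracle(self):
        # independent re-implementation with explicit loops
        muts = [
            mut("a", dna_af=0.40, pmhc_ranks=[0.1, 0.3, 1.2, 5.0]),
            mut("b", dna_af=0.10, pmhc_ranks=[0.7, 0.9]),
            mut("c", dna_af=0.25, pmhc_ranks=[1.9, 2.5, 0.4]),
        ]
        terms = []
        for c in CSIN_CUTOFFS:
            included = [m for m in muts if min(m.pmhc_ranks) < c]
            if not included:
                continue
            V = [m.dna_af for m in included]
            L = [sum(1 for r in m.pmhc_ranks if r < c) for m in included]
            vbar, lbar = sum(V) / len(V), sum(L) / len(L)
            inner = [(v / vbar) * (l / lbar) for v, l in zip(V, L)]
            terms.append(math.log(sum(inner) / len(inner)))
        expected = sum(terms) / len(terms)
        assert csin(muts) == pytest.approx(expected, abs=1e-12)

    def test_vaf_cap_keeps_highest(self):
        rng = np.random.default_rng(0)
        muts = [mut(f"m{i}", dna_af=float(v), pmhc_ranks=[0.5])
                for i, v in enumerate(rng.uniform(0.05, 1.0, 40))]
        top = sorted(muts, key=lambda m: -m.dna_af)[:10]
        assert csin(muts, max_mutations=10) == pytest.approx(csin(top))


class TestIoTNL:
    def test_hand_cases(self):
        assert iotnl([5.0], [10], [1.0]) == pytest.approx(5.0)   # 0.5 < 1.4
        assert iotnl([20.0], [10], [1.0]) == pytest.approx(0.0)  # 2.0 > 1.4
        assert iotnl([5.0], [10], [1.0], e=0.0) == 0.0

    def test_monotone_in_cutoff(self):
        loads, sizes, ccfs = [5.0, 8.0, 1.0], [10, 5, 4], [1.0, 0.5, 0.2]
        values = [iotnl(loads, sizes, ccfs, e=e) for e in (0.0, 0.4, 1.0, 1.7, 10.0)]
        assert values == sorted(values)

    def test_zero_size_cluster_skipped(self):
        assert iotnl([5.0, 3.0], [0, 10], [1.0, 1.0]) == pytest.approx(3.0)


class TestGini:
    @pytest.mark.parametrize(
        "values,expected",
        [([1, 1, 1, 1], 0.0), ([0, 0, 0, 1], 0.75), ([1, 3], 0.25)],
    )
    def test_closed_forms(self, values, expected):
        assert gini(values) == pytest.approx(expected)

    def test_degenerate_all_zero(self):
        assert gini([0.0, 0.0]) == 0.0

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1e3), min_size=1, max_size=15),
        st.floats(min_value=0.01, max_value=100),
    )
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance_and_bounds(self, values, c):
        if sum(values) == 0:
            return
        g = gini(values)
        assert 0 <= g <= 1 - 1 / len(values) + 1e-9
        assert gini([c * v for v in values]) == pytest.approx(g, abs=1e-9)


class TestHeterogeneity:
    def test_boundary_patient_is_heterogeneous(self):
        labels = heterogeneity_class([0.2, 0.2, 0.4], [0.3, 0.3, 0.5])
        assert labels[0] == "heterogeneous"  # exactly at both medians

    def test_quadrants_and_mixed(self):
        labels = heterogeneity_class([0.1, 0.9, 0.1, 0.9], [0.1, 0.9, 0.9, 0.1])
        assert labels == ["heterogeneous", "homogeneous", "mixed", "mixed"]

    def test_identical_patients_share_labels(self):
        labels = heterogeneity_class([0.3, 0.3], [0.4, 0.4])
        assert labels[0] == labels[1]

    def test_single_patient_rejected(self):
        with pytest.raises(ValueError):
            heterogeneity_class([0.1], [0.1])

    def test_single_cluster_tumor_has_zero_ginis(self):
        clusters = [CloneCluster("c0", 1.0, {"a", "b"})]
        p = profile([mut("a", cluster="c0"), mut("b", cluster="c0")], clusters)
        assert tumor_gini(p) == (0.0, 0.0)


class TestClonalitySummaries:
    def test_hand_computed_fractions(self):
        p = profile([mut("a", ccf=0.9), mut("b", ccf=0.5)])
        pct_clonal, _ = clonality_summaries(p)
        assert pct_clonal == pytest.approx(0.5)

    def test_all_binding(self):
        p = profile([mut("a", phbr_i=1.0), mut("b", phbr_i=2.0)])
        assert clonality_summaries(p)[1] == pytest.approx(1.0)

    def test_all_clonal(self):
        p = profile([mut("a", ccf=0.85), mut("b", ccf=1.0)])
        assert clonality_summaries(p)[0] == pytest.approx(1.0)

    def test_empty_profile(self):
        assert clonality_summaries(profile([])) == (0.0, 0.0)


def test_scores_permutation_invariant():
    rng = np.random.default_rng(3)
    muts = [mut(f"m{i}", rng.random(), rng.random(), ccf=rng.random(),
                cluster=f"c{i % 3}", dna_af=rng.uniform(0.05, 0.9),
                pmhc_ranks=list(rng.uniform(0.1, 5, 4)))
            for i in range(12)]
    clusters = [CloneCluster(f"c{j}", prev, {m.mutation_id for m in muts if m.cluster_id == f"c{j}"})
                for j, prev in enumerate([1.0, 0.6, 0.3])]
    p1 = profile(muts, clusters)
    p2 = profile(muts[::-1], clusters[::-1])
    assert landscape_sum(p1) == pytest.approx(landscape_sum(p2))
    assert landscape_ccf(p1) == pytest.approx(landscape_ccf(p2))
    assert landscape_clone(p1) == pytest.approx(landscape_clone(p2))
    assert csin(p1.mutations) == pytest.approx(csin(p2.mutations))
    assert tumor_gini(p1)[0] == pytest.approx(tumor_gini(p2)[0])
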