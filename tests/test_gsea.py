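import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import crmimic as cm
from crmimic.errors import (
    DegenerateSampleError,
    SignatureNotRepresentedError,
    ValidationError,
)
from crmimic.gsea import RankedProfile, _call, rank_sample

from conftest import build_study
from oracles import exhaustive_permutation_pvalues, running_sum_extremes


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------


class TestRankSample:
    def test_forced_ordering(self, tiny_study):
        ranked = rank_sample(tiny_study, "t1")
        # sample (5,3,1) - control means (1,3,5) -> scores (+4, 0, -4)
        assert list(ranked.probe_ids) == ["p1", "p2", "p3"]
        np.testing.assert_array_equal(ranked.scores, [4.0, 0.0, -4.0])

    def test_all_ties_ordered_by_probe_id(self):
        study = build_study(
            values={"p3": [1, 1, 2], "p1": [5, 5, 6], "p2": [3, 3, 4]},
            probe_gene={"p1": "G1", "p2": "G2", "p3": "G3"},
            groups={"c1": "CTRL", "c2": "CTRL", "t1": "TRT"},
            control_of={"TRT": "CTRL"},
            samples=["c1", "c2", "t1"],
        )
        ranked = rank_sample(study, "t1")
        assert list(ranked.probe_ids) == ["p1", "p2", "p3"]

    def test_all_missing_sample_is_degenerate(self):
        study = build_study(
            values={"p1": [1, 1, np.nan], "p2": [3, 3, np.nan]},
            probe_gene={"p1": "G1", "p2": "G2"},
            groups={"c1": "CTRL", "c2": "CTRL", "t1": "TRT"},
            control_of={"TRT": "CTRL"},
            samples=["c1", "c2", "t1"],
        )
        with pytest.raises(DegenerateSampleError, match="0/2"):
            rank_sample(study, "t1")

    def test_probe_missing_in_sample_excluded_and_counted(self):
        study = build_study(
            values={"p1": [1, 1, 5], "p2": [3, 3, np.nan], "p3": [2, 2, 4], "p4": [0, 0, 1]},
            probe_gene={"p1": "G1", "p2": "G2", "p3": "G3", "p4": "G4"},
            groups={"c1": "CTRL", "c2": "CTRL", "t1": "TRT"},
            control_of={"TRT": "CTRL"},
            samples=["c1", "c2", "t1"],
        )
        ranked = rank_sample(study, "t1")
        assert ranked.n_excluded == 1
        assert "p2" not in ranked.probe_ids

    def test_unresolvable_control_group_is_error(self, tiny_study):
        with pytest.raises(ValidationError, match="control"):
            rank_sample(tiny_study, "c1")


# ---------------------------------------------------------------------------
# enrichment scores
# ---------------------------------------------------------------------------


class TestEnrichmentScores:
    @pytest.mark.parametrize("weight_exponent", [0, 1])
    def test_single_hit_at_top_rank(self, toy_ranked, toy_probe_gene, weight_exponent):
        # running sum 1, 2/3, 1/3, 0
        es_pos, es_neg = cm.enrichment_scores(toy_ranked, ["G1"], toy_probe_gene,
                                              weight_exponent)
        assert es_pos == pytest.approx(1.0, abs=1e-15)
        assert es_neg == 0.0

    @pytest.mark.parametrize("weight_exponent", [0, 1])
    def test_single_hit_at_bottom_rank(self, toy_ranked, toy_probe_gene, weight_exponent):
        # running sum -1/3, -2/3, -1, 0
        es_pos, es_neg = cm.enrichment_scores(toy_ranked, ["G4"], toy_probe_gene,
                                              weight_exponent)
        assert es_pos == 0.0
        assert es_neg == pytest.approx(-1.0, abs=1e-15)

    def test_signature_covering_all_probes_is_degenerate(self, toy_ranked, toy_probe_gene):
        with pytest.raises(ValidationError, match="every probe"):
            cm.enrichment_scores(toy_ranked, ["G1", "G2", "G3", "G4"], toy_probe_gene)

    def test_unrepresented_signature_is_error(self, toy_ranked, toy_probe_gene):
        with pytest.raises(SignatureNotRepresentedError):
            cm.enrichment_scores(toy_ranked, ["NOT_A_GENE"], toy_probe_gene)

    def test_zero_hit_weights_fall_back_to_uniform_increments(self, toy_probe_gene):
        ranked = RankedProfile("s", np.array(["p1", "p2", "p3", "p4"]),
                               np.array([2.0, 0.0, 0.0, -2.0]))
        weighted = cm.enrichment_scores(ranked, ["G2", "G3"], toy_probe_gene, 1)
        uniform = cm.enrichment_scores(ranked, ["G2", "G3"], toy_probe_gene, 0)
        assert weighted == uniform

    def test_unannotated_probes_never_hit(self):
        ranked = RankedProfile("s", np.array(["p1", "p2", "p3"]),
                               np.array([3.0, 2.0, 1.0]))
        pg = {"p1": cm.UNANNOTATED, "p2": "G2", "p3": cm.UNANNOTATED}
        with pytest.raises(SignatureNotRepresentedError):
            cm.enrichment_scores(ranked, [cm.UNANNOTATED], pg)

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("weight_exponent", [0, 1])
    def test_matches_stepwise_oracle_on_random_lists(self, seed, weight_exponent):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 30))
        scores = np.sort(rng.normal(0, 1, n))[::-1].copy()
        k = int(rng.integers(1, min(6, n)))
        hit_pos = np.sort(rng.choice(n, k, replace=False))
        probes = np.array([f"p{i:03d}" for i in range(n)])
        pg = {p: (f"HIT{i}" if i in set(hit_pos) else f"BG{i}")
              for i, p in enumerate(probes)}
        ranked = RankedProfile("s", probes, scores)
        genes = [f"HIT{i}" for i in hit_pos]
        got = cm.enrichment_scores(ranked, genes, pg, weight_exponent)
        want = running_sum_extremes(scores, hit_pos, weight_exponent)
        assert got == pytest.approx(want, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_antisymmetry_under_list_reversal(self, seed):
        """Reversing the ranked list and negating scores swaps
        (ES+, ES-) -> (-ES-, -ES+) under uniform weighting."""
        rng = np.random.default_rng(seed)
        n = 12
        scores = np.sort(rng.normal(0, 1, n))[::-1].copy()
        probes = np.array([f"p{i:02d}" for i in range(n)])
        hit_pos = np.sort(rng.choice(n, 3, replace=False))
        pg = {p: (f"HIT{i}" if i in set(hit_pos) else f"BG{i}")
              for i, p in enumerate(probes)}
        genes = [f"HIT{i}" for i in hit_pos]
        fwd = cm.enrichment_scores(RankedProfile("s", probes, scores), genes, pg, 0)
        rev = cm.enrichment_scores(
            RankedProfile("s", probes[::-1].copy(), -scores[::-1].copy()), genes, pg, 0
        )
        assert rev[0] == pytest.approx(-fwd[1], abs=1e-12)
        assert rev[1] == pytest.approx(-fwd[0], abs=1e-12)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.data())
    def test_scores_bounded_one_sided(self, data):
        n = data.draw(st.integers(4, 15))
        k = data.draw(st.integers(1, n - 1))
        raw = data.draw(st.lists(
            st.floats(-5, 5, allow_nan=False), min_size=n, max_size=n))
        scores = np.sort(np.asarray(raw))[::-1].copy()
        hit_pos = sorted(data.draw(
            st.sets(st.integers(0, n - 1), min_size=k, max_size=k)))
        probes = np.array([f"p{i:02d}" for i in range(n)])
        pg = {p: (f"HIT{i}" if i in set(hit_pos) else f"BG{i}")
              for i, p in enumerate(probes)}
        genes = [f"HIT{i}" for i in hit_pos]
        we = data.draw(st.sampled_from([0, 1]))
        es_pos, es_neg = cm.enrichment_scores(
            RankedProfile("s", probes, scores), genes, pg, we)
        assert 0.0 <= es_pos <= 1.0 + 1e-12
        assert -1.0 - 1e-12 <= es_neg <= 0.0


def test_cross_check_against_gseapy_prerank():
    """The running-sum statistic agrees with an independent GSEA implementation."""
    gseapy = pytest.importorskip("gseapy")
    rng = np.random.default_rng(7)
    n = 60
    scores = np.sort(rng.normal(0, 1, n))[::-1].copy()
    scores[:6] += 2.0  # clear positive enrichment for the planted set
    genes = [f"g{i:03d}" for i in range(n)]
    gene_set = genes[:6]
    probes = np.array(genes)
    pg = dict(zip(genes, (g.upper() for g in genes)))
    ours_pos, ours_neg = cm.enrichment_scores(
        RankedProfile("s", probes, scores), [g.upper() for g in gene_set], pg, 1)
    rnk = pd.DataFrame({"gene": genes, "score": scores})
    res = gseapy.prerank(rnk=rnk, gene_sets={"SET": gene_set}, permutation_num=4,
                         min_size=1, max_size=100, outdir=None, seed=1,
                         threads=1, no_plot=True, weight=1.0)
    theirs = float(res.res2d.loc[res.res2d["Term"] == "SET", "ES"].iloc[0])
    assert theirs == pytest.approx(ours_pos, abs=1e-6)


# ---------------------------------------------------------------------------
# permutation p-values
# ---------------------------------------------------------------------------


class TestPermutationPvalues:
    def test_worked_example_top_rank(self, toy_ranked, toy_probe_gene):
        """Exhaustive null over the 4 placements: P(ES+ >= 1) = 1/4;
        P(ES- <= 0) = 1 (every placement has ES- <= 0)."""
        p_pos, p_neg = cm.permutation_pvalues(toy_ranked, ["G1"], toy_probe_gene,
                                              n_perm=20000, seed=2)
        se = np.sqrt(0.25 * 0.75 / 20000)
        assert abs(p_pos - 0.25) <= 3 * se + 2 / 20001
        assert p_neg == 1.0

    def test_zero_permutations_rejected(self, toy_ranked, toy_probe_gene):
        with pytest.raises(ValidationError, match="n_perm"):
            cm.permutation_pvalues(toy_ranked, ["G1"], toy_probe_gene, n_perm=0)

    def test_deterministic_given_seed(self, toy_ranked, toy_probe_gene):
        a = cm.permutation_pvalues(toy_ranked, ["G1"], toy_probe_gene, n_perm=5000, seed=42)
        b = cm.permutation_pvalues(toy_ranked, ["G1"], toy_probe_gene, n_perm=5000, seed=42)
        assert a == b

    def test_pvalues_never_zero_or_above_one(self, toy_ranked, toy_probe_gene):
        p_pos, p_neg = cm.permutation_pvalues(toy_ranked, ["G1"], toy_probe_gene,
                                              n_perm=10, seed=0)
        assert 0 < p_pos <= 1 and 0 < p_neg <= 1

    @pytest.mark.parametrize("n,k,weight_exponent", [
        (5, 1, 1), (6, 2, 1), (7, 3, 0), (8, 2, 1),
    ])
    def test_agrees_with_exhaustive_enumeration(self, n, k, weight_exponent):
        rng = np.random.default_rng(n * 10 + k)
        scores = np.sort(rng.normal(0, 1, n))[::-1].copy()
        hit_pos = np.sort(rng.choice(n, k, replace=False))
        probes = np.array([f"p{i}" for i in range(n)])
        pg = {p: (f"HIT{i}" if i in set(hit_pos) else f"BG{i}")
              for i, p in enumerate(probes)}
        genes = [f"HIT{i}" for i in hit_pos]
        ranked = RankedProfile("s", probes, scores)
        exact_pos, exact_neg = exhaustive_permutation_pvalues(scores, hit_pos,
                                                              weight_exponent)
        n_perm = 30000
        mc_pos, mc_neg = cm.permutation_pvalues(ranked, genes, pg, n_perm=n_perm,
                                                seed=5, weight_exponent=weight_exponent)
        for mc, exact in ((mc_pos, exact_pos), (mc_neg, exact_neg)):
            se = np.sqrt(exact * (1 - exact) / n_perm)
            assert abs(mc - exact) <= 3 * se + 2 / (n_perm + 1)


# ---------------------------------------------------------------------------
# ternary calls
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("p_pos,p_neg,expected", [
    (0.01, 0.80, 1),
    (0.30, 0.30, 0),
    (0.02, 0.02, 0),    # both significant, exact tie -> no call
    (0.80, 0.01, -1),
    (0.01, 0.03, 1),    # both significant, smaller p wins
    (0.03, 0.01, -1),
    (0.05, 1.00, 1),    # boundary: p == alpha is significant
])
def test_ternary_call_rule(p_pos, p_neg, expected):
    assert _call(p_pos, p_neg, alpha=0.05) == expected


def test_call_signature_validates_alpha():
    result = cm.EnrichmentResult("S", 0.5, -0.1, 0.01, 0.9, 1000, 1)
    assert cm.call_signature(result, alpha=0.05) == 1
    with pytest.raises(ValidationError):
        cm.call_signature(result, alpha=1.5)


# ---------------------------------------------------------------------------
# study-level scoring
# ---------------------------------------------------------------------------


def _signal_study(seed=0, n_probes=40, n_hit=6, shift=2.0):
    rng = np.random.default_rng(seed)
    probes = [f"p{i:03d}" for i in range(n_probes)]
    pg = {p: f"G{i:03d}" for i, p in enumerate(probes)}
    base = rng.normal(7, 1, n_probes)
    cols = {}
    for s in ("c1", "c2", "c3"):
        cols[s] = base + rng.normal(0, 0.25, n_probes)
    for s in ("t1", "t2"):
        eff = np.zeros(n_probes)
        eff[:n_hit] = shift
        cols[s] = base + eff + rng.normal(0, 0.25, n_probes)
    values = pd.DataFrame(cols, index=probes)
    study = cm.ExpressionStudy(
        values=values,
        probe_gene=pd.Series(pg),
        groups=pd.Series({"c1": "CTRL", "c2": "CTRL", "c3": "CTRL",
                          "t1": "TRT", "t2": "TRT"}),
        control_of={"TRT": "CTRL"},
    )
    sigs = cm.SignatureSet({
        "UP_SET": tuple(f"G{i:03d}" for i in range(n_hit)),
        "NULL_SET": tuple(f"G{i:03d}" for i in range(10, 10 + n_hit)),
        "ABSENT_SET": ("ZZ1", "ZZ2", "ZZ3", "ZZ4", "ZZ5"),
    })
    return study, sigs


class TestScoreStudy:
    def test_profile_cardinality_and_order(self):
        study, sigs = _signal_study()
        result = cm.score_study(study, sigs, n_perm=500, seed=1)
        assert [p.sample for p in result.profiles] == ["t1", "t2"]
        for p in result.profiles:
            assert p.signature_names == ("UP_SET", "NULL_SET", "ABSENT_SET")

    def test_planted_signature_called_induced(self):
        study, sigs = _signal_study()
        result = cm.score_study(study, sigs, n_perm=2000, seed=1)
        for p in result.profiles:
            assert p.results[0].call == 1

    def test_rerun_is_bit_identical(self):
        study, sigs = _signal_study()
        a = cm.score_study(study, sigs, n_perm=1000, seed=9)
        b = cm.score_study(study, sigs, n_perm=1000, seed=9)
        assert a.profiles == b.profiles

    def test_unrepresented_signature_isolated_with_flag(self):
        study, sigs = _signal_study()
        result = cm.score_study(study, sigs, n_perm=500, seed=1)
        for p in result.profiles:
            absent = p.results[2]
            assert absent.flag == "not_represented"
            assert absent.call == 0 and absent.p_pos == 1.0

    def test_sample_null_sharing_keeps_scores_and_determinism(self):
        study, sigs = _signal_study()
        per_sig = cm.score_study(study, sigs, n_perm=1000, seed=3,
                                 null_sharing="signature")
        shared_a = cm.score_study(study, sigs, n_perm=1000, seed=3,
                                  null_sharing="sample")
        shared_b = cm.score_study(study, sigs, n_perm=1000, seed=3,
                                  null_sharing="sample")
        assert shared_a.profiles == shared_b.profiles
        # observed scores identical across modes; p-values are both MC
        # estimates of the same null tail
        for p1, p2 in zip(per_sig.profiles, shared_a.profiles):
            for r1, r2 in zip(p1.results, p2.results):
                assert r1.es_pos == r2.es_pos and r1.es_neg == r2.es_neg
                assert abs(r1.p_pos - r2.p_pos) < 0.05
                assert abs(r1.p_neg - r2.p_neg) < 0.05

    def test_all_samples_failing_raises(self):
        study, sigs = _signal_study()
        study.values.loc[:, ["t1", "t2"]] = np.nan
        with pytest.raises(ValidationError, match="all treated samples"):
            cm.score_study(study, sigs, n_perm=100, seed=1)

    def test_partial_failure_reported_not_fatal(self):
        study, sigs = _signal_study()
        study.values.loc[:, "t2"] = np.nan
        result = cm.score_study(study, sigs, n_perm=100, seed=1)
        assert [p.sample for p in result.profiles] == ["t1"]
        assert "t2" in result.failures
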