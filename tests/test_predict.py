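import numpy as np
import pytest

from nogoa.gaf import GeneTermMatrix
from nogoa.predict import (
    alpha_sweep,
    baseline_ec,
    baseline_lf,
    baseline_random,
    baseline_sr,
    combine_scores,
    expand_descendants,
    select_q_noisy,
    threshold_predict,
)
from nogoa.sparse_sim import VoteMatrix

from .conftest import ROOT, T1, T2, T3, make_dag


def gtm(arr, terms, genes=None, form="propagated-binary"):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    return GeneTermMatrix(genes=genes, terms=terms, values=arr, form=form)


def votes(arr, terms, genes=None, kind="V_SR", alpha=None):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    return VoteMatrix(genes=genes, terms=terms, values=arr, kind=kind,
                      alpha=alpha)


TERMS = [T1, T2, T3]


class TestCombineScores:
    def test_alpha_zero_is_evidence_only(self):
        v = votes([[0.3, 0.7, 0.1]], TERMS)
        a = gtm([[1.0, 0.5, 1.0]], TERMS, form="propagated-weighted")
        fused = combine_scores(v, a, alpha=0.0)
        assert np.allclose(fused.values, a.toarray())

    def test_alpha_one_is_votes_only(self):
        v = votes([[0.3, 0.7, 0.1]], TERMS)
        a = gtm([[1.0, 0.5, 1.0]], TERMS, form="propagated-weighted")
        fused = combine_scores(v, a, alpha=1.0)
        assert np.allclose(fused.values, v.values)

    def test_affine_arithmetic(self):
        v = votes([[0.5]], [T1])
        a = gtm([[1.0]], [T1], form="propagated-weighted")
        fused = combine_scores(v, a, alpha=0.2)
        assert fused.values[0, 0] == pytest.approx(0.9)

    def test_alpha_range_checked(self):
        v = votes([[0.5]], [T1])
        a = gtm([[1.0]], [T1])
        with pytest.raises(ValueError, match="alpha"):
            combine_scores(v, a, alpha=1.5)


class TestSelectQNoisy:
    def fused(self):
        return votes([[0.9, 0.1, 0.5]], TERMS, kind="fused", alpha=0.2)

    def test_q_zero_selects_nothing(self):
        A = gtm([[1, 1, 1]], TERMS)
        preds = select_q_noisy(self.fused(), A, {"g0": 0})
        assert preds[0].selected == set()

    def test_q_equal_to_annotated_selects_all(self):
        A = gtm([[1, 1, 1]], TERMS)
        preds = select_q_noisy(self.fused(), A, {"g0": 3})
        assert preds[0].selected == set(TERMS)

    def test_argmin_selected(self):
        A = gtm([[1, 1, 1]], TERMS)
        preds = select_q_noisy(self.fused(), A, {"g0": 1})
        assert preds[0].direct == [T2]  # score 0.1

    def test_only_annotated_terms_ranked(self):
        A = gtm([[1, 0, 1]], TERMS)
        preds = select_q_noisy(self.fused(), A, {"g0": 1})
        assert [t for t, _ in preds[0].ranked] == [T3, T1]

    def test_q_above_annotated_count_selects_all(self):
        A = gtm([[1, 0, 1]], TERMS)
        preds = select_q_noisy(self.fused(), A, {"g0": 7})
        assert preds[0].selected == {T1, T3}

    def test_tie_breaks_lexicographically(self):
        f = votes([[0.5, 0.5, 0.5]], TERMS, kind="fused")
        A = gtm([[1, 1, 1]], TERMS)
        preds = select_q_noisy(f, A, {"g0": 2})
        assert preds[0].direct == sorted(TERMS)[:2]

    def test_lowering_a_score_never_deselects_it(self):
        A = gtm([[1, 1, 1]], TERMS)
        base = select_q_noisy(self.fused(), A, {"g0": 2})[0].selected
        lowered = votes([[0.9, 0.05, 0.5]], TERMS, kind="fused")
        after = select_q_noisy(lowered, A, {"g0": 2})[0].selected
        assert T2 in base and T2 in after


class TestExpandDescendants:
    def test_expansion_adds_annotated_descendants(self, diamond_dag):
        A = gtm([[1, 1, 1]], TERMS)
        f = votes([[0.1, 0.9, 0.8]], TERMS, kind="fused")
        preds = select_q_noisy(f, A, {"g0": 1})
        expanded = expand_descendants(preds, A, diamond_dag)
        assert expanded[0].direct == [T1]
        assert expanded[0].inherited == {T3}

    def test_no_annotated_descendants_unchanged(self, diamond_dag):
        A = gtm([[1, 1, 1]], TERMS)
        f = votes([[0.9, 0.8, 0.1]], TERMS, kind="fused")
        preds = select_q_noisy(f, A, {"g0": 1})  # selects leaf T3
        expanded = expand_descendants(preds, A, diamond_dag)
        assert expanded[0].inherited == set()

    def test_idempotent(self, diamond_dag):
        A = gtm([[1, 1, 1]], TERMS)
        f = votes([[0.1, 0.9, 0.8]], TERMS, kind="fused")
        preds = select_q_noisy(f, A, {"g0": 2})
        once = expand_descendants(preds, A, diamond_dag)
        twice = expand_descendants(once, A, diamond_dag)
        for a, b in zip(once, twice):
            assert a.direct == b.direct and a.inherited == b.inherited


class TestThresholdPredict:
    def test_low_fused_score_flagged(self):
        # theta-weighted evidence 0.5 and weak votes 0.2:
        # V = 0.2*0.2 + 0.8*0.5 = 0.44 < 0.45
        v_sr = votes([[0.2]], [T1])
        a_ec = gtm([[0.5]], [T1], form="propagated-weighted")
        fused = combine_scores(v_sr, a_ec, alpha=0.2)
        assert fused.values[0, 0] == pytest.approx(0.44)
        A = gtm([[1]], [T1])
        preds = threshold_predict(fused, A)
        assert preds[0].selected == {T1}

    def test_full_weight_entries_never_flagged(self):
        # A_ec = 1 bounds V below by 0.8 regardless of votes
        v_sr = votes([[0.0]], [T1])
        a_ec = gtm([[1.0]], [T1], form="propagated-weighted")
        fused = combine_scores(v_sr, a_ec, alpha=0.2)
        preds = threshold_predict(fused, gtm([[1]], [T1]))
        assert preds[0].selected == set()

    def test_empty_matrix_gives_empty_predictions(self):
        fused = votes(np.zeros((1, 3)), TERMS, kind="fused")
        preds = threshold_predict(fused, gtm(np.zeros((1, 3)), TERMS))
        assert preds[0].selected == set()

    def test_cut_validated(self):
        fused = votes([[0.5]], [T1], kind="fused")
        with pytest.raises(ValueError, match="v_cut"):
            threshold_predict(fused, gtm([[1]], [T1]), v_cut=-0.1)


class TestBaselines:
    def test_random_full_q_is_everything(self):
        A = gtm([[1, 1, 1]], TERMS)
        for seed in (0, 1, 2):
            preds = baseline_random(A, {"g0": 3}, seed=seed)
            assert preds[0].selected == set(TERMS)

    def test_random_is_seed_deterministic(self):
        A = gtm([[1, 1, 1], [1, 1, 0]], TERMS)
        a = baseline_random(A, {"g0": 1, "g1": 1}, seed=7)
        b = baseline_random(A, {"g0": 1, "g1": 1}, seed=7)
        assert [p.direct for p in a] == [p.direct for p in b]

    def test_random_is_uniform(self):
        A = gtm(np.ones((1, 4)), [T1, T2, T3, ROOT])
        counts = {t: 0 for t in [T1, T2, T3, ROOT]}
        for seed in range(10_000):
            pick = baseline_random(A, {"g0": 1}, seed=seed)[0].direct[0]
            counts[pick] += 1
        for c in counts.values():
            assert abs(c / 10_000 - 0.25) <= 0.02

    def test_lf_picks_lowest_frequency(self):
        A = gtm([[1, 1, 1], [1, 0, 1], [1, 0, 1], [1, 0, 0], [1, 0, 0]],
                TERMS)  # column sums 5, 1, 3
        preds = baseline_lf(A, {g: 1 for g in A.genes}, seed=0)
        assert preds[0].direct == [T2]

    def test_lf_q2_takes_two_rarest(self):
        A = gtm([[1, 1, 1], [1, 0, 1], [1, 0, 1], [1, 0, 0], [1, 0, 0]],
                TERMS)
        preds = baseline_lf(A, {g: 2 if g == "g0" else 0 for g in A.genes},
                            seed=0)
        assert set(preds[0].direct) == {T2, T3}

    def test_lf_ties_are_seeded(self):
        A = gtm([[1, 1, 1]], TERMS)
        a = baseline_lf(A, {"g0": 1}, seed=3)
        b = baseline_lf(A, {"g0": 1}, seed=3)
        assert a[0].direct == b[0].direct


class TestSpecialCaseEquivalence:
    def build(self, seed=0):
        rng = np.random.default_rng(seed)
        A = gtm((rng.random((6, 5)) < 0.6).astype(float),
                [T1, T2, T3, "GO:9000007", "GO:9000008"])
        v_sr = votes(rng.random((6, 5)), A.terms)
        a_ec = gtm(rng.choice([0.5, 1.0], size=(6, 5)) * A.toarray(),
                   A.terms, genes=A.genes, form="propagated-weighted")
        return A, v_sr, a_ec

    @pytest.mark.parametrize("seed", range(3))
    def test_alpha_zero_equals_ec_baseline(self, seed):
        A, v_sr, a_ec = self.build(seed)
        q = {g: 2 for g in A.genes}
        fused = combine_scores(v_sr, a_ec, alpha=0.0)
        via_fusion = select_q_noisy(fused, A, q)
        via_baseline = baseline_ec(a_ec, A, q)
        for a, b in zip(via_fusion, via_baseline):
            assert a.ranked == b.ranked
            assert a.direct == b.direct

    @pytest.mark.parametrize("seed", range(3))
    def test_alpha_one_equals_sr_baseline(self, seed):
        A, v_sr, a_ec = self.build(seed)
        q = {g: 2 for g in A.genes}
        fused = combine_scores(v_sr, a_ec, alpha=1.0)
        via_fusion = select_q_noisy(fused, A, q)
        via_baseline = baseline_sr(v_sr, A, q)
        for a, b in zip(via_fusion, via_baseline):
            assert a.ranked == b.ranked
            assert a.direct == b.direct


def test_selection_invariant_to_input_order():
    rng = np.random.default_rng(4)
    terms = [T1, T2, T3]
    A_arr = (rng.random((5, 3)) < 0.7).astype(float)
    V_arr = rng.random((5, 3))
    A = gtm(A_arr, terms)
    f = votes(V_arr, terms, kind="fused")
    q = {g: 1 for g in A.genes}
    base = {p.gene: p.selected for p in select_q_noisy(f, A, q)}

    perm_g, perm_t = rng.permutation(5), rng.permutation(3)
    A2 = GeneTermMatrix(
        genes=[A.genes[i] for i in perm_g], terms=[terms[j] for j in perm_t],
        values=A_arr[np.ix_(perm_g, perm_t)], form="propagated-binary",
    )
    f2 = VoteMatrix(genes=A2.genes, terms=A2.terms,
                    values=V_arr[np.ix_(perm_g, perm_t)], kind="fused")
    shuffled = {p.gene: p.selected for p in select_q_noisy(f2, A2, q)}
    assert base == shuffled


def test_alpha_sweep_covers_grid_and_endpoints():
    rng = np.random.default_rng(6)
    A = gtm((rng.random((4, 3)) < 0.8).astype(float), TERMS)
    v_sr = votes(rng.random((4, 3)), TERMS)
    a_ec = gtm(A.toarray() * 0.5, TERMS, genes=A.genes,
               form="propagated-weighted")
    q = {g: 1 for g in A.genes}
    sweep = alpha_sweep(v_sr, a_ec, A, q)
    assert set(sweep) == {round(0.1 * k, 1) for k in range(11)}
    ec = baseline_ec(a_ec, A, q)
    assert [p.direct for p in sweep[0.0]] == [p.direct for p in ec]
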