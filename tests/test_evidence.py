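import numpy as np
import pandas as pd
import pytest

from nogoa.evidence import (
    assign_code_weights,
    average_ratios,
    estimate_noise_ratio,
    propagate_weights,
    weight_direct_matrix,
)
from nogoa.gaf import build_direct_matrix, propagate_true_path
from nogoa.simulate import SimConfig, generate_annotations, generate_dag, \
    make_release_pair

from .conftest import ROOT, T1, T2, T3, record

SHARED = {ROOT, T1, T2, T3}
TERMS = [ROOT, T1, T2, T3]


def ratio_table(**r):
    """Hand-built averaged table: code -> r_tilde, all observed."""
    codes = sorted(r)
    return pd.DataFrame({
        "n": 10, "n_noisy": 0, "r": [r[c] for c in codes],
        "r_tilde": [r[c] for c in codes], "observed": True,
    }, index=pd.Index(codes, name="code"))


class TestEstimateNoiseRatio:
    def test_simple_ratio(self):
        old = [record(f"g{i}", T1, "IEA") for i in range(10)]
        new = [record(f"g{i}", T1, "IEA") for i in range(8)]  # 2 removed
        table = estimate_noise_ratio(old, new, SHARED)
        assert table.loc["IEA", "n"] == 10
        assert table.loc["IEA", "n_noisy"] == 2
        assert table.loc["IEA", "r"] == pytest.approx(0.2)

    def test_no_removal_gives_zero_ratios(self):
        old = [record("g1", T1, "IDA"), record("g2", T2, "IEA")]
        table = estimate_noise_ratio(old, old + [record("g3", T3)], SHARED)
        assert (table["r"] == 0).all()

    def test_evidence_code_change_is_not_noise(self):
        # pair present in both releases, but re-curated IEA -> IDA
        old = [record("g1", T1, "IEA")]
        new = [record("g1", T1, "IDA")]
        table = estimate_noise_ratio(old, new, SHARED)
        assert table.loc["IEA", "n_noisy"] == 0

    def test_restricted_to_shared_terms(self):
        old = [record("g1", T1, "IEA"), record("g1", "GO:9999999", "IEA")]
        table = estimate_noise_ratio(old, [], {T1})
        assert table.loc["IEA", "n"] == 1

    def test_unobserved_codes_flagged(self):
        table = estimate_noise_ratio([record("g1", T1, "IEA")], [], SHARED)
        assert not table.loc["IDA", "observed"]
        assert table.loc["IDA", "r"] == 0.0
        assert len(table) == 21

    def test_binomial_parameter_recovery(self):
        """Estimated ratios recover injected per-code removal rates."""
        cfg = SimConfig(
            n_terms=600, n_layers=4, n_genes=800, directs_per_gene=9,
            n_clusters=4, profile_noise=0.0,
            code_mix={"IEA": 1 / 3, "IDA": 1 / 3, "TAS": 1 / 3},
            removal_rates={"IEA": 0.2, "IDA": 0.05, "TAS": 0.1},
            seed=42,
        )
        dag = generate_dag(cfg)
        ann = generate_annotations(dag, cfg)
        hist, recent, _ = make_release_pair(ann.records, cfg)
        table = estimate_noise_ratio(hist, recent, dag.terms)
        for code, p in cfg.removal_rates.items():
            n = table.loc[code, "n"]
            assert n >= 2000
            tol = 3 * np.sqrt(p * (1 - p) / n)
            assert abs(table.loc[code, "r"] - p) <= tol


class TestAverageRatios:
    def test_single_table_is_identity(self):
        t = estimate_noise_ratio([record("g1", T1, "IEA")], [], SHARED)
        avg = average_ratios([t], l=1)
        assert (avg["r_tilde"] == t["r"]).all()

    def test_mean_of_two(self):
        t1 = estimate_noise_ratio(
            [record(f"g{i}", T1, "IEA") for i in range(10)],
            [record(f"g{i}", T1, "IEA") for i in range(9)], SHARED)
        t2 = estimate_noise_ratio(
            [record(f"g{i}", T1, "IEA") for i in range(10)],
            [record(f"g{i}", T1, "IEA") for i in range(7)], SHARED)
        avg = average_ratios([t1, t2], l=2)
        assert avg.loc["IEA", "r_tilde"] == pytest.approx((0.1 + 0.3) / 2)

    def test_window_takes_last_l(self):
        tables = []
        for removed in (0, 3, 3):
            old = [record(f"g{i}", T1, "IEA") for i in range(10)]
            tables.append(estimate_noise_ratio(old, old[removed:], SHARED))
        avg = average_ratios(tables, l=3)
        assert avg.loc["IEA", "r_tilde"] == pytest.approx(0.2)
        avg2 = average_ratios(tables, l=2)
        assert avg2.loc["IEA", "r_tilde"] == pytest.approx(0.3)

    def test_l_larger_than_history_rejected(self):
        t = estimate_noise_ratio([record("g1", T1)], [], SHARED)
        with pytest.raises(ValueError, match="l="):
            average_ratios([t], l=2)


class TestAssignCodeWeights:
    def test_threshold_is_mean_of_observed(self):
        table = ratio_table(IEA=0.2, IDA=0.0)
        w = assign_code_weights(table, theta=0.5)
        assert w.tau == pytest.approx(0.1)
        assert w.weight("IEA") == 0.5
        assert w.weight("IDA") == 1.0

    def test_tie_at_threshold_gets_theta(self):
        table = ratio_table(IEA=0.3, IDA=0.3, TAS=0.3)
        w = assign_code_weights(table, theta=0.5)
        assert all(w.weight(c) == 0.5 for c in ("IEA", "IDA", "TAS"))

    def test_single_code_gets_theta(self):
        w = assign_code_weights(ratio_table(IEA=0.12), theta=0.4)
        assert w.tau == pytest.approx(0.12)
        assert w.weight("IEA") == 0.4

    def test_unobserved_codes_keep_weight_one(self):
        table = estimate_noise_ratio(
            [record(f"g{i}", T1, "IEA") for i in range(10)],
            [record(f"g{i}", T1, "IEA") for i in range(8)], SHARED)
        w = assign_code_weights(average_ratios([table], 1), theta=0.5)
        assert w.weight("IDA") == 1.0
        assert w.weight("IEA") == 0.5  # the only observed code: r_tilde = tau

    def test_theta_validated(self):
        with pytest.raises(ValueError, match="theta"):
            assign_code_weights(ratio_table(IEA=0.1), theta=1.5)

    def test_tsv_round_trip(self, tmp_path):
        w = assign_code_weights(ratio_table(IEA=0.2, IDA=0.0), theta=0.5)
        path = tmp_path / "weights.tsv"
        w.to_tsv(path)
        back = type(w).from_tsv(path, theta=0.5)
        assert back.weights == w.weights
        assert back.tau == pytest.approx(w.tau)


class TestWeightDirectMatrix:
    def test_max_over_codes(self):
        recs = [record("g1", T3, "IEA"), record("g1", T3, "IDA"),
                record("g2", T1, "IEA")]
        direct = build_direct_matrix(recs, TERMS)
        w = assign_code_weights(ratio_table(IEA=0.2, IDA=0.0), theta=0.5)
        weighted = weight_direct_matrix(direct, w)
        d = weighted.toarray()
        # IEA(0.5) + IDA(1) -> 1; lone IEA -> 0.5; zero entries stay zero
        assert d[0, TERMS.index(T3)] == 1.0
        assert d[1, TERMS.index(T1)] == 0.5
        assert weighted.values.nnz == 2

    def test_rejects_wrong_form(self, diamond_dag):
        direct = build_direct_matrix([record("g1", T3)], TERMS)
        prop = propagate_true_path(direct, diamond_dag)
        w = assign_code_weights(ratio_table(IEA=0.1), theta=0.5)
        with pytest.raises(ValueError, match="direct-binary"):
            weight_direct_matrix(prop, w)


class TestPropagateWeights:
    def weights(self):
        return assign_code_weights(ratio_table(IEA=0.5, IDA=0.0), theta=0.5)

    def test_chain_propagates_single_weight(self, chain_dag):
        direct = build_direct_matrix([record("g1", T2, "IEA")],
                                     [ROOT, T1, T2])
        a_ec = propagate_weights(weight_direct_matrix(direct, self.weights()),
                                 chain_dag)
        row = dict(zip(a_ec.terms, a_ec.toarray()[0]))
        assert row[T2] == 0.5 and row[T1] == 0.5
        assert ROOT not in a_ec.terms

    def test_direct_ancestor_keeps_its_own_weight(self, chain_dag):
        # T1 direct with weight 1 and also ancestor of T2 (weight 0.5)
        recs = [record("g1", T2, "IEA"), record("g1", T1, "IDA")]
        direct = build_direct_matrix(recs, [ROOT, T1, T2])
        a_ec = propagate_weights(weight_direct_matrix(direct, self.weights()),
                                 chain_dag)
        row = dict(zip(a_ec.terms, a_ec.toarray()[0]))
        assert row[T1] == 1.0 and row[T2] == 0.5

    def test_diamond_takes_max_of_contributors(self, diamond_dag):
        # two leaves would be needed; here T3's two parents share it
        recs = [record("g1", T3, "IEA"), record("g1", T1, "IDA")]
        direct = build_direct_matrix(recs, TERMS)
        a_ec = propagate_weights(weight_direct_matrix(direct, self.weights()),
                                 diamond_dag)
        row = dict(zip(a_ec.terms, a_ec.toarray()[0]))
        assert row[T1] == 1.0  # max(direct 1.0, inherited 0.5)
        assert row[T2] == 0.5  # only inherited from T3

    def test_monotone_closure_and_support_on_random_fixture(self):
        cfg = SimConfig(n_terms=80, n_layers=4, n_genes=30,
                        directs_per_gene=4, n_clusters=3, seed=5)
        dag = generate_dag(cfg)
        ann = generate_annotations(dag, cfg)
        direct = build_direct_matrix(ann.records, sorted(dag.terms))
        w = assign_code_weights(
            ratio_table(IEA=0.4, IDA=0.05, TAS=0.1), theta=0.5)
        d_ec = weight_direct_matrix(direct, w)
        a_ec = propagate_weights(d_ec, dag)
        prop = propagate_true_path(direct, dag)
        assert a_ec.terms == prop.terms
        # support preservation
        assert np.array_equal(a_ec.toarray() > 0, prop.toarray() > 0)
        # ancestor weight >= descendant direct weight
        dense_ec = a_ec.toarray()
        tidx = a_ec.term_index
        d = d_ec.toarray()
        for (gene, term), _ in direct.evidence_map.items():
            i = direct.gene_index[gene]
            wd = d[i, direct.term_index[term]]
            for s in dag.ancestors(term):
                if s in tidx:
                    assert dense_ec[i, tidx[s]] >= wd - 1e-12
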