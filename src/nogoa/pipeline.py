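"""End-to-end wiring: matrices -> similarity -> weights -> predictions.

Two entry points:

* :func:`benchmark_seed` / :func:`synthetic_benchmark` — the synthetic
  study: generate an ontology and two annotation release pairs (one to
  estimate evidence-code noise ratios, one to evaluate on), run the fused
  detector and the Random/LF/SR/EC baselines with the oracle per-gene q,
  and score everything against the release-derived labels.
* :func:`run_from_files` — the production path behind ``nogoa predict``:
  OBO + GAF releases in, flagged-annotation TSV out.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .evaluate import (
    EvalResult,
    NoiseLabels,
    derive_noise_labels,
    evaluate_predictions,
)
from .evidence import (
    EvidenceWeightTable,
    assign_code_weights,
    average_ratios,
    estimate_noise_ratio,
    propagate_weights,
    weight_direct_matrix,
)
from .gaf import (
    GeneTermMatrix,
    build_direct_matrix,
    parse_gaf,
    propagate_true_path,
    write_predictions,
)
from .ontology import OntologyDAG, parse_obo, shared_terms
from .predict import (
    baseline_ec,
    baseline_lf,
    baseline_random,
    baseline_sr,
    combine_scores,
    expand_descendants,
    select_q_noisy,
    threshold_predict,
)
from .simulate import SimConfig, generate_annotations, generate_dag, \
    make_release_pair
from .sparse_sim import aggregate_votes, build_similarity

METHODS = ("NoGOA", "SR", "EC", "Random", "LF")


@dataclass
class SeedRun:
    """Everything one synthetic benchmark seed produced."""

    dag: OntologyDAG
    A_hist: GeneTermMatrix
    A_recent: GeneTermMatrix
    A_ec: GeneTermMatrix
    labels: NoiseLabels
    weights: EvidenceWeightTable
    results: dict[str, EvalResult]
    predictions: dict[str, list]


def build_release_matrices(records_hist, records_recent, dag,
                           term_order=None):
    """Direct + propagated matrices for a release pair on one term universe."""
    if term_order is None:
        term_order = sorted(dag.terms)
    direct_hist = build_direct_matrix(records_hist, term_order)
    A_hist = propagate_true_path(direct_hist, dag)
    direct_recent = build_direct_matrix(records_recent, term_order)
    A_recent = propagate_true_path(direct_recent, dag)
    return direct_hist, A_hist, A_recent


def benchmark_seed(
    seed: int,
    cfg: SimConfig | None = None,
    alpha: float = 0.2,
    theta: float = 0.5,
    lam: float = 0.5,
    methods: tuple[str, ...] = METHODS,
) -> SeedRun:
    """Run the full synthetic study for one seed.

    Evidence-code ratios are estimated from an independent release pair
    (same configuration, a different sub-seed) standing in for the archive
    pair preceding the prediction release, so estimation never sees the
    evaluation pair. q per gene is the oracle true noisy count.
    """
    base = cfg if cfg is not None else SimConfig()
    cfg_eval = replace(base, seed=2 * seed)
    cfg_ratio = replace(base, seed=2 * seed + 1)

    dag = generate_dag(cfg_eval)

    # ratio-estimation pair
    ann_r = generate_annotations(dag, cfg_ratio)
    hist_r, recent_r, _ = make_release_pair(ann_r.records, cfg_ratio,
                                            ann_r.off_profile)
    ratios = estimate_noise_ratio(hist_r, recent_r, dag.terms)
    weights = assign_code_weights(
        average_ratios([ratios], l=1), theta=theta, branch=base.branch, l=1,
    )

    # evaluation pair
    ann = generate_annotations(dag, cfg_eval)
    hist, recent, _ = make_release_pair(ann.records, cfg_eval,
                                        ann.off_profile)
    direct_hist, A_hist, A_recent = build_release_matrices(hist, recent, dag)
    labels = derive_noise_labels(A_hist, A_recent)
    q = {g: labels.q_true(g) for g in A_hist.genes}

    a_d_ec = weight_direct_matrix(direct_hist, weights)
    a_ec = propagate_weights(a_d_ec, dag)
    sim = build_similarity(A_hist, lam)
    v_sr = aggregate_votes(sim, A_hist)
    fused = combine_scores(v_sr, a_ec, alpha)

    predictions = {}
    if "NoGOA" in methods:
        predictions["NoGOA"] = expand_descendants(
            select_q_noisy(fused, A_hist, q), A_hist, dag
        )
    if "SR" in methods:
        predictions["SR"] = baseline_sr(v_sr, A_hist, q, dag)
    if "EC" in methods:
        predictions["EC"] = baseline_ec(a_ec, A_hist, q, dag)
    if "Random" in methods:
        predictions["Random"] = baseline_random(A_hist, q, seed=cfg_eval.seed,
                                                dag=dag)
    if "LF" in methods:
        predictions["LF"] = baseline_lf(A_hist, q, seed=cfg_eval.seed,
                                        dag=dag)

    results = {m: evaluate_predictions(p, labels)
               for m, p in predictions.items()}
    return SeedRun(
        dag=dag, A_hist=A_hist, A_recent=A_recent, A_ec=a_ec, labels=labels,
        weights=weights, results=results, predictions=predictions,
    )


def synthetic_benchmark(
    seeds,
    cfg: SimConfig | None = None,
    alpha: float = 0.2,
    theta: float = 0.5,
    lam: float = 0.5,
    methods: tuple[str, ...] = METHODS,
) -> pd.DataFrame:
    """Per-seed, per-method precision/recall/F1 table over many seeds."""
    rows = []
    for seed in seeds:
        run = benchmark_seed(seed, cfg=cfg, alpha=alpha, theta=theta,
                             lam=lam, methods=methods)
        for method, res in run.results.items():
            rows.append({
                "seed": seed, "method": method,
                "precision": res.precision, "recall": res.recall,
                "f1": res.f1, "n_genes": len(res.per_gene),
            })
    return pd.DataFrame(rows)


def run_from_files(
    obo_old,
    obo_new,
    gaf_old,
    gaf_new,
    branch: str,
    gaf_history: tuple = (),
    alpha: float = 0.2,
    theta: float = 0.5,
    lam: float = 0.5,
    mode: str = "q",
    v_cut: float = 0.45,
    vsr_cut: float = 0.25,
    seed: int = 0,
    out=None,
):
    """File-level pipeline: two GO releases + GAF releases -> predictions.

    Noise ratios are estimated from consecutive pairs of
    ``gaf_history + [gaf_old]`` when a history is supplied (the archive
    setup, in which estimation precedes the prediction release), otherwise
    from the (gaf_old, gaf_new) pair itself. In q-mode the
    per-gene q is the number of release-derived noise labels; threshold mode
    flags annotated entries with fused score below ``v_cut``.
    """
    dag_old = parse_obo(obo_old, branch)
    dag_new = parse_obo(obo_new, branch)
    shared = shared_terms(dag_old, dag_new)
    term_order = sorted(shared)

    def load(path):
        return parse_gaf(path, branch, allowed_terms=shared,
                         resolve=dag_old.resolve)

    records_old = load(gaf_old)
    records_new = load(gaf_new)
    if gaf_history:
        releases = [load(p) for p in gaf_history] + [records_old]
        pairs = list(zip(releases[:-1], releases[1:]))
    else:
        pairs = [(records_old, records_new)]
    tables = [estimate_noise_ratio(a, b, shared) for a, b in pairs]
    weights = assign_code_weights(
        average_ratios(tables, l=len(tables)), theta=theta, branch=branch,
        l=len(tables),
    )

    direct_old, A_old, A_new = build_release_matrices(
        records_old, records_new, dag_old, term_order
    )
    a_ec = propagate_weights(weight_direct_matrix(direct_old, weights),
                             dag_old)
    sim = build_similarity(A_old, lam)
    fused = combine_scores(aggregate_votes(sim, A_old), a_ec, alpha)

    labels = derive_noise_labels(A_old, A_new)
    if mode == "q":
        q = {g: labels.q_true(g) for g in A_old.genes}
        preds = expand_descendants(select_q_noisy(fused, A_old, q),
                                   A_old, dag_old)
    elif mode == "threshold":
        preds = threshold_predict(fused, A_old, v_cut=v_cut,
                                  vsr_cut=vsr_cut, dag=dag_old)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if out is not None:
        write_predictions(preds, out)
    return {
        "predictions": preds, "labels": labels, "weights": weights,
        "A_old": A_old, "A_new": A_new, "A_ec": a_ec, "dag": dag_old,
        "evaluation": evaluate_predictions(preds, labels),
    }
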