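"""Noisy-annotation selection from fused scores.

The fused score of an annotated entry is

    V(i, t) = alpha * V_SR(i, t) + (1 - alpha) * A_ec(i, t),

combining the neighbourhood vote V_SR with the evidence weight A_ec. Within
a gene, annotated terms with the smallest V are the most likely noisy
annotations. Two selection modes are provided: q-mode (the evaluation
protocol — take the q lowest-scoring annotated terms per gene) and threshold
mode (the production protocol — flag every annotated entry with V below a
cut, 0.45 by default). Either way, annotated descendants of a selected term
are flagged too: by the true path rule a term cannot hold once its ancestor
is removed.

alpha = 0 reduces to the evidence-only ranking (EC); alpha = 1 to the
sparse-representation ranking (SR). The Random and LF (lowest global term
frequency) baselines share the same selection-and-expansion protocol.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .gaf import GeneTermMatrix
from .ontology import OntologyDAG
from .sparse_sim import VoteMatrix

logger = logging.getLogger(__name__)


@dataclass
class NoisePrediction:
    """Ranked annotated terms and the selected noisy set for one gene."""

    gene: str
    ranked: list[tuple[str, float]]  # annotated terms, score ascending
    direct: list[str]  # directly selected terms, selection order
    inherited: set[str] = field(default_factory=set)
    q: int | None = None
    alpha: float | None = None

    @property
    def selected(self) -> set[str]:
        return set(self.direct) | self.inherited


def combine_scores(
    v_sr: VoteMatrix, a_ec: GeneTermMatrix, alpha: float
) -> VoteMatrix:
    """Fuse neighbourhood votes and evidence weights elementwise."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    if v_sr.genes != a_ec.genes or v_sr.terms != a_ec.terms:
        raise ValueError("gene/term orders of V_SR and A_ec differ")
    values = alpha * v_sr.values + (1.0 - alpha) * a_ec.toarray()
    return VoteMatrix(
        genes=list(v_sr.genes), terms=list(v_sr.terms), values=values,
        kind="fused", alpha=alpha,
    )


def _rank_annotated(
    scores: np.ndarray, A: GeneTermMatrix, gene_row: int
) -> list[tuple[str, float]]:
    """Annotated terms of one gene ordered by (score asc, term id)."""
    cols = A.values.getrow(gene_row).indices
    pairs = [(A.terms[j], float(scores[gene_row, j])) for j in cols]
    pairs.sort(key=lambda p: (p[1], p[0]))
    return pairs


def select_q_noisy(
    fused: VoteMatrix,
    A: GeneTermMatrix,
    q_per_gene: dict[str, int],
) -> list[NoisePrediction]:
    """Per gene, select the q annotated terms with the smallest fused score.

    Only terms with A(i, t) = 1 are ranked (so poorly connected genes are
    not penalised for globally low votes). Ties break lexicographically by
    term id. q larger than the annotated count selects everything (logged).
    """
    if fused.genes != A.genes or fused.terms != A.terms:
        raise ValueError("gene/term orders of scores and A differ")
    predictions = []
    for i, gene in enumerate(A.genes):
        q = q_per_gene.get(gene)
        if q is None:
            raise KeyError(f"q_per_gene has no entry for gene {gene!r}")
        if q < 0:
            raise ValueError(f"negative q for gene {gene!r}")
        ranked = _rank_annotated(fused.values, A, i)
        if q > len(ranked):
            logger.info(
                "gene %s: q=%d exceeds %d annotated terms; selecting all",
                gene, q, len(ranked),
            )
            q = len(ranked)
        predictions.append(NoisePrediction(
            gene=gene, ranked=ranked, direct=[t for t, _ in ranked[:q]],
            q=q, alpha=fused.alpha,
        ))
    return predictions


def expand_descendants(
    selection: list[NoisePrediction],
    A: GeneTermMatrix,
    dag: OntologyDAG,
) -> list[NoisePrediction]:
    """Add annotated descendants of each directly selected term (idempotent).

    Expanded terms are flagged ``inherited`` so evaluation can count them
    separately from direct selections.
    """
    out = []
    for pred in selection:
        annotated = set(t for t, _ in pred.ranked)
        inherited = set(pred.inherited)
        for term in pred.direct:
            inherited |= dag.descendants(term) & annotated
        inherited -= set(pred.direct)
        out.append(NoisePrediction(
            gene=pred.gene, ranked=list(pred.ranked),
            direct=list(pred.direct), inherited=inherited,
            q=pred.q, alpha=pred.alpha,
        ))
    return out


def threshold_predict(
    fused: VoteMatrix,
    A: GeneTermMatrix,
    v_cut: float = 0.45,
    vsr_cut: float = 0.25,
    dag: OntologyDAG | None = None,
) -> list[NoisePrediction]:
    """Flag annotated entries with fused score V < v_cut.

    Under the default parameterisation (alpha = 0.2, theta = 0.5) this is
    equivalent to flagging entries at the gene's lowest evidence weight with
    V_SR < 0.25, since alpha*V_SR spans [0, 0.2] and (1-alpha)*A_ec spans
    {0.4, 0.8}; the V-cut is taken as the primary rule for all other
    parameters and ``vsr_cut`` is kept for reference only. Descendant
    expansion is applied when a DAG is supplied.
    """
    for name, cut in (("v_cut", v_cut), ("vsr_cut", vsr_cut)):
        if not 0.0 <= cut <= 2.0:
            raise ValueError(f"{name} out of range: {cut}")
    predictions = []
    for i, gene in enumerate(A.genes):
        ranked = _rank_annotated(fused.values, A, i)
        direct = [t for t, s in ranked if s < v_cut]
        predictions.append(NoisePrediction(
            gene=gene, ranked=ranked, direct=direct, alpha=fused.alpha,
        ))
    if dag is not None:
        predictions = expand_descendants(predictions, A, dag)
    return predictions


def baseline_random(
    A: GeneTermMatrix,
    q_per_gene: dict[str, int],
    seed: int,
    dag: OntologyDAG | None = None,
) -> list[NoisePrediction]:
    """Uniformly random choice of q annotated terms per gene (seeded)."""
    rng = np.random.default_rng(seed)
    predictions = []
    for i, gene in enumerate(A.genes):
        cols = A.values.getrow(i).indices
        terms = sorted(A.terms[j] for j in cols)
        order = rng.permutation(len(terms))
        ranked = [(terms[k], float(pos)) for pos, k in enumerate(order)]
        q = min(q_per_gene.get(gene, 0), len(ranked))
        predictions.append(NoisePrediction(
            gene=gene, ranked=ranked, direct=[t for t, _ in ranked[:q]], q=q,
        ))
    if dag is not None:
        predictions = expand_descendants(predictions, A, dag)
    return predictions


def baseline_lf(
    A: GeneTermMatrix,
    q_per_gene: dict[str, int],
    seed: int,
    dag: OntologyDAG | None = None,
) -> list[NoisePrediction]:
    """Lowest-frequency baseline: select the annotated terms with the
    smallest column sums of A; ties broken uniformly at random (seeded)."""
    rng = np.random.default_rng(seed)
    freq = np.asarray(A.values.sum(axis=0)).ravel()
    predictions = []
    for i, gene in enumerate(A.genes):
        cols = A.values.getrow(i).indices
        jitter = rng.random(len(cols))
        order = sorted(
            range(len(cols)), key=lambda k: (freq[cols[k]], jitter[k])
        )
        ranked = [(A.terms[cols[k]], float(freq[cols[k]])) for k in order]
        q = min(q_per_gene.get(gene, 0), len(ranked))
        predictions.append(NoisePrediction(
            gene=gene, ranked=ranked, direct=[t for t, _ in ranked[:q]], q=q,
        ))
    if dag is not None:
        predictions = expand_descendants(predictions, A, dag)
    return predictions


def baseline_sr(
    v_sr: VoteMatrix,
    A: GeneTermMatrix,
    q_per_gene: dict[str, int],
    dag: OntologyDAG | None = None,
) -> list[NoisePrediction]:
    """Sparse-representation-only ranking (the alpha = 1 special case)."""
    fused = VoteMatrix(
        genes=list(v_sr.genes), terms=list(v_sr.terms),
        values=np.asarray(v_sr.values, dtype=float), kind="fused", alpha=1.0,
    )
    preds = select_q_noisy(fused, A, q_per_gene)
    return expand_descendants(preds, A, dag) if dag is not None else preds


def baseline_ec(
    a_ec: GeneTermMatrix,
    A: GeneTermMatrix,
    q_per_gene: dict[str, int],
    dag: OntologyDAG | None = None,
) -> list[NoisePrediction]:
    """Evidence-weight-only ranking (the alpha = 0 special case)."""
    fused = VoteMatrix(
        genes=list(a_ec.genes), terms=list(a_ec.terms),
        values=a_ec.toarray(), kind="fused", alpha=0.0,
    )
    preds = select_q_noisy(fused, A, q_per_gene)
    return expand_descendants(preds, A, dag) if dag is not None else preds


def alpha_sweep(
    v_sr: VoteMatrix,
    a_ec: GeneTermMatrix,
    A: GeneTermMatrix,
    q_per_gene: dict[str, int],
    dag: OntologyDAG | None = None,
    alphas=None,
) -> dict[float, list[NoisePrediction]]:
    """q-mode predictions over a grid of fusion weights (default 0..1 by 0.1)."""
    if alphas is None:
        alphas = [round(0.1 * k, 1) for k in range(11)]
    out = {}
    for alpha in alphas:
        fused = combine_scores(v_sr, a_ec, alpha)
        preds = select_q_noisy(fused, A, q_per_gene)
        if dag is not None:
            preds = expand_descendants(preds, A, dag)
        out[alpha] = preds
    return out
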