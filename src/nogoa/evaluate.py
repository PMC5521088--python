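"""Evaluation of noisy-annotation predictions and the downstream demo.

Ground-truth noise labels come from release pairs: an annotation present in
the historical propagated matrix but absent from the recent one is labelled
noisy. Per-gene precision/recall are averaged over evaluated genes (those
with at least one label), F1 is the mean of per-gene harmonic means, and a
CAFA2-style bootstrap (85% of evaluated genes, 500 replicates) gives mean
and standard deviation.

The downstream experiment scores a majority-vote function predictor — a
gene's score for a term is the fraction of its interaction partners
annotated with the term — before and after noisy-annotation removal, with
the usual protein-function metrics (micro/macro F1, term-averaged precision
and AUROC, Fmax, Smin).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.metrics import (
    average_precision_score,
    f1_score,
    roc_auc_score,
)

from .gaf import GeneTermMatrix
from .predict import NoisePrediction

logger = logging.getLogger(__name__)


@dataclass
class NoiseLabels:
    """Per-gene sets of terms labelled noisy by release comparison."""

    labels: dict[str, set[str]]

    def q_true(self, gene: str) -> int:
        return len(self.labels.get(gene, set()))

    @property
    def genes(self) -> list[str]:
        return sorted(self.labels)

    def q_per_gene(self) -> dict[str, int]:
        return {g: len(s) for g, s in self.labels.items()}


def derive_noise_labels(
    A_hist: GeneTermMatrix,
    A_recent: GeneTermMatrix,
    shared: set[str] | None = None,
) -> NoiseLabels:
    """Label (gene, term) noisy iff annotated historically but not recently.

    Both matrices must live on the same (shared) term universe. Genes present
    only in the recent release are ignored; a historical gene absent from the
    recent release has lost all its annotations.
    """
    if set(A_hist.terms) != set(A_recent.terms):
        raise ValueError("historical and recent matrices use different "
                         "term universes")
    if shared is not None:
        extra = set(A_hist.terms) - shared
        if extra:
            raise ValueError(f"matrices contain non-shared terms: "
                             f"{sorted(extra)[:5]}")
    recent_sets = {
        g: set(A_recent.annotated_terms(g)) for g in A_recent.genes
    }
    labels = {}
    for gene in A_hist.genes:
        hist_terms = set(A_hist.annotated_terms(gene))
        labels[gene] = hist_terms - recent_sets.get(gene, set())
    return NoiseLabels(labels=labels)


def score_gene(
    selected: set[str], labels: set[str]
) -> tuple[int, int, int, float, float, float]:
    """Confusion counts and P/R/F1 for one gene's selection."""
    tp = len(selected & labels)
    fp = len(selected - labels)
    fn = len(labels - selected)
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return tp, fp, fn, p, r, f1


@dataclass
class EvalResult:
    """Per-gene scores plus full-sample and bootstrap aggregates."""

    per_gene: pd.DataFrame
    precision: float
    recall: float
    f1: float
    bootstrap: dict[str, tuple[float, float]] = field(default_factory=dict)

    def summary_row(self, method: str, branch: str = "BP") -> dict:
        bs = self.bootstrap
        return {
            "method": method, "branch": branch,
            "precision_mean": bs.get("precision", (self.precision, 0.0))[0],
            "precision_sd": bs.get("precision", (self.precision, 0.0))[1],
            "recall_mean": bs.get("recall", (self.recall, 0.0))[0],
            "recall_sd": bs.get("recall", (self.recall, 0.0))[1],
            "f1_mean": bs.get("f1", (self.f1, 0.0))[0],
            "f1_sd": bs.get("f1", (self.f1, 0.0))[1],
        }


def _per_gene_table(
    predictions: list[NoisePrediction], labels: NoiseLabels
) -> pd.DataFrame:
    """Scores for evaluated genes (q_true > 0) with a prediction."""
    by_gene = {p.gene: p for p in predictions}
    rows = []
    for gene, lab in labels.labels.items():
        if not lab or gene not in by_gene:
            continue
        tp, fp, fn, p, r, f1 = score_gene(by_gene[gene].selected, lab)
        rows.append((gene, tp, fp, fn, p, r, f1))
    return pd.DataFrame(
        rows, columns=["gene", "tp", "fp", "fn", "p", "r", "f1"]
    )


def evaluate_predictions(
    predictions: list[NoisePrediction], labels: NoiseLabels
) -> EvalResult:
    """Plain (non-bootstrap) per-gene averages over evaluated genes.

    Genes without any noise label are excluded: the evaluation protocol sets
    q from the true noisy count, so such genes make no predictions and their
    precision is undefined.
    """
    table = _per_gene_table(predictions, labels)
    if table.empty:
        return EvalResult(per_gene=table, precision=0.0, recall=0.0, f1=0.0)
    return EvalResult(
        per_gene=table,
        precision=float(table["p"].mean()),
        recall=float(table["r"].mean()),
        f1=float(table["f1"].mean()),
    )


def bootstrap_evaluate(
    predictions: list[NoisePrediction],
    labels: NoiseLabels,
    fraction: float = 0.85,
    reps: int = 500,
    seed: int = 0,
) -> EvalResult:
    """Bootstrap the per-gene averages over subsamples of evaluated genes.

    Each replicate draws floor(fraction * N) evaluated genes without
    replacement and averages their per-gene P/R/F1; reported as mean +/- sd
    over replicates.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    result = evaluate_predictions(predictions, labels)
    table = result.per_gene
    n = len(table)
    if n == 0:
        return result
    size = max(1, int(np.floor(fraction * n)))
    rng = np.random.default_rng(seed)
    stats = {"precision": [], "recall": [], "f1": []}
    cols = table[["p", "r", "f1"]].to_numpy()
    for _ in range(reps):
        idx = rng.choice(n, size=size, replace=False)
        sub = cols[idx]
        stats["precision"].append(sub[:, 0].mean())
        stats["recall"].append(sub[:, 1].mean())
        stats["f1"].append(sub[:, 2].mean())
    result.bootstrap = {
        k: (float(np.mean(v)), float(np.std(v))) for k, v in stats.items()
    }
    return result


def read_ppi(path) -> list[tuple[str, str]]:
    """Read a 2-column TSV of interacting gene pairs (extra columns ignored)."""
    edges = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "!")):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) >= 2 and cols[0] != cols[1]:
                edges.append((cols[0], cols[1]))
    return edges


def majority_vote_predict(
    ppi_edges: list[tuple[str, str]], A: GeneTermMatrix
) -> np.ndarray:
    """Majority-vote function prediction over a PPI network.

    score(i, t) = (# partners of gene i annotated with t) / degree(i);
    isolated genes score 0 everywhere. Edges mentioning genes outside A are
    dropped.
    """
    gene_idx = A.gene_index
    pairs = [
        (gene_idx[a], gene_idx[b]) for a, b in ppi_edges
        if a in gene_idx and b in gene_idx and a != b
    ]
    if not pairs:
        raise ValueError("PPI gene ids do not intersect the matrix genes")
    n = len(A.genes)
    rows = [i for i, j in pairs] + [j for i, j in pairs]
    cols = [j for i, j in pairs] + [i for i, j in pairs]
    adj = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    adj.data[:] = 1.0  # collapse duplicate edges
    adj.sum_duplicates()
    adj.data[:] = np.minimum(adj.data, 1.0)
    degree = np.asarray(adj.sum(axis=1)).ravel()
    counts = np.asarray((adj @ A.values).todense(), dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(degree[:, None] > 0, counts / degree[:, None], 0.0)
    return scores


def function_pred_metrics(
    scores: np.ndarray, truth: GeneTermMatrix | np.ndarray
) -> dict[str, float]:
    """Standard protein-function metrics for a score matrix against truth.

    Micro/macro F1 at score threshold 0.5; average precision and AUROC
    averaged per term; Fmax = max over thresholds of the protein-centric F1
    (precision over proteins with >= 1 prediction, recall over proteins with
    >= 1 true term); Smin = min over thresholds of sqrt(ru^2 + mi^2) with
    term information content -log(term frequency in truth). Terms never
    annotated in the truth are dropped from per-term averages.
    """
    Y = truth.toarray() if isinstance(truth, GeneTermMatrix) else \
        np.asarray(truth, dtype=float)
    S = np.asarray(scores, dtype=float)
    if S.shape != Y.shape:
        raise ValueError("score and truth shapes differ")
    Y = (Y > 0).astype(float)

    col_pos = Y.sum(axis=0)
    keep = col_pos > 0
    if (~keep).any():
        logger.warning(
            "%d terms have no positive gene in the truth; dropped from "
            "per-term averages", int((~keep).sum()),
        )
    Yk, Sk = Y[:, keep], S[:, keep]
    n_genes = Y.shape[0]

    pred05 = (Sk >= 0.5).astype(float)
    micro = f1_score(Yk.ravel(), pred05.ravel(), zero_division=0)
    macro = f1_score(Yk, pred05, average="macro", zero_division=0)

    ap, auroc = [], []
    for j in range(Yk.shape[1]):
        y = Yk[:, j]
        ap.append(average_precision_score(y, Sk[:, j]))
        if 0 < y.sum() < n_genes:  # AUROC needs both classes
            auroc.append(roc_auc_score(y, Sk[:, j]))
    avg_prec = float(np.mean(ap)) if ap else 0.0
    avg_roc = float(np.mean(auroc)) if auroc else 0.0

    # protein-centric Fmax and Smin over a threshold grid
    ic = -np.log(Yk.sum(axis=0) / n_genes)
    has_truth = Yk.sum(axis=1) > 0
    fmax, smin = 0.0, np.inf
    for tau in np.arange(0.0, 1.0001, 0.01):
        P = Sk >= tau
        tp = (P * Yk).sum(axis=1)
        npred = P.sum(axis=1)
        ntrue = Yk.sum(axis=1)
        covered = npred > 0
        prec = float((tp[covered] / npred[covered]).mean()) if covered.any() \
            else 0.0
        rec = float((tp[has_truth] / ntrue[has_truth]).mean()) if \
            has_truth.any() else 0.0
        if prec + rec > 0:
            fmax = max(fmax, 2 * prec * rec / (prec + rec))
        fn_ic = ((~P) * Yk * ic).sum(axis=1)
        fp_ic = (P * (1 - Yk) * ic).sum(axis=1)
        ru = float(fn_ic.mean())
        mi = float(fp_ic.mean())
        smin = min(smin, float(np.hypot(ru, mi)))

    return {
        "micro_f1": float(micro),
        "macro_f1": float(macro),
        "avg_prec": avg_prec,
        "avg_roc": avg_roc,
        "fmax": float(fmax),
        "smin": float(smin),
    }
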