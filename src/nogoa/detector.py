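"""Estimator-style front end for noisy-annotation detection.

Two scikit-learn-compatible classes wrap the functional modules:

* :class:`SparseRepresentationSimilarity` — a transformer mapping a
  genes x terms annotation matrix to the genes x genes nonnegative
  similarity matrix derived from sparse codes.
* :class:`NoisyAnnotationDetector` — a transductive detector (in the spirit
  of ``LocalOutlierFactor``): ``fit`` on the propagated annotation matrix
  computes fused scores for every annotated entry of that same matrix, and
  ``fit_predict`` returns a boolean mask of flagged entries.

Both follow the sklearn parameter conventions (``get_params``/``set_params``
via ``BaseEstimator``; fitted attributes carry a trailing underscore), so
they compose with sklearn model selection.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin

from . import predict as _predict
from .gaf import GeneTermMatrix
from .ontology import OntologyDAG
from .sparse_sim import VoteMatrix, aggregate_votes, build_similarity


def _as_gene_term_matrix(X, genes=None, terms=None,
                         form="propagated-binary") -> GeneTermMatrix:
    if isinstance(X, GeneTermMatrix):
        return X
    X = sp.csr_matrix(np.asarray(X, dtype=float) if not sp.issparse(X) else X)
    n, t = X.shape
    genes = list(genes) if genes is not None else [f"g{i}" for i in range(n)]
    terms = list(terms) if terms is not None else [f"t{j}" for j in range(t)]
    return GeneTermMatrix(genes=genes, terms=terms, values=X, form=form)


class SparseRepresentationSimilarity(TransformerMixin, BaseEstimator):
    """Nonnegative sparse-coding similarity between the rows of X.

    Parameters
    ----------
    lam : float, default 0.5
        l1 regularisation weight of the per-row nonnegative lasso.
    """

    def __init__(self, lam: float = 0.5):
        self.lam = lam

    def fit(self, X, y=None):
        gtm = _as_gene_term_matrix(X)
        self.n_features_in_ = len(gtm.terms)
        sim = build_similarity(gtm, self.lam)
        self.genes_ = sim.genes
        self.similarity_ = sim.values
        return self

    def transform(self, X):
        """Similarity matrix of the rows of X (stateless apart from lam)."""
        gtm = _as_gene_term_matrix(X)
        return build_similarity(gtm, self.lam).values

    def fit_transform(self, X, y=None, **fit_params):
        self.fit(X)
        return self.similarity_


class NoisyAnnotationDetector(BaseEstimator):
    """Transductive detector of noisy entries in an annotation matrix.

    Parameters
    ----------
    alpha : float, default 0.2
        Fusion weight of the similarity votes against the evidence weights;
        0 is evidence-only, 1 is votes-only.
    lam : float, default 0.5
        Sparse-coding regularisation.
    mode : {"q", "threshold"}, default "threshold"
        ``fit_predict`` selection rule: per-gene q lowest scores, or a
        global score cut.
    v_cut : float, default 0.45
        Fused-score cut for threshold mode.

    Attributes
    ----------
    similarity_ : ndarray of shape (n_genes, n_genes)
    votes_ : ndarray — similarity-aggregated votes V_SR.
    scores_ : ndarray — fused scores V of the fitted matrix.
    """

    def __init__(self, alpha: float = 0.2, lam: float = 0.5,
                 mode: str = "threshold", v_cut: float = 0.45):
        self.alpha = alpha
        self.lam = lam
        self.mode = mode
        self.v_cut = v_cut

    def fit(self, X, y=None, *, evidence_weights=None,
            dag: OntologyDAG | None = None):
        """Compute similarity, votes and fused scores for X.

        ``evidence_weights`` is the propagated evidence-weighted matrix
        A_ec aligned with X; when omitted every annotation weighs 1 and the
        detector degrades gracefully to the votes-only ranking blended with
        the binary matrix.
        """
        if self.mode not in ("q", "threshold"):
            raise ValueError(f"unknown mode {self.mode!r}")
        A = _as_gene_term_matrix(X)
        if evidence_weights is None:
            a_ec = GeneTermMatrix(
                genes=list(A.genes), terms=list(A.terms),
                values=A.values.copy(), form="propagated-weighted",
            )
        else:
            a_ec = _as_gene_term_matrix(
                evidence_weights, genes=A.genes, terms=A.terms,
                form="propagated-weighted",
            )
        sim = build_similarity(A, self.lam)
        v_sr = aggregate_votes(sim, A)
        fused = _predict.combine_scores(v_sr, a_ec, self.alpha)

        self._A = A
        self._dag = dag
        self.genes_ = list(A.genes)
        self.terms_ = list(A.terms)
        self.n_features_in_ = len(A.terms)
        self.similarity_ = sim.values
        self.votes_ = v_sr.values
        self.scores_ = fused.values
        return self

    def _fused(self) -> VoteMatrix:
        return VoteMatrix(
            genes=self.genes_, terms=self.terms_, values=self.scores_,
            kind="fused", alpha=self.alpha,
        )

    def predict_noisy(self, q_per_gene: dict[str, int] | None = None):
        """NoisePrediction list, q-mode if ``q_per_gene`` given else cut."""
        if not hasattr(self, "scores_"):
            raise AttributeError("detector is not fitted")
        if q_per_gene is not None:
            preds = _predict.select_q_noisy(self._fused(), self._A,
                                            q_per_gene)
            if self._dag is not None:
                preds = _predict.expand_descendants(preds, self._A, self._dag)
            return preds
        return _predict.threshold_predict(
            self._fused(), self._A, v_cut=self.v_cut, dag=self._dag,
        )

    def fit_predict(self, X, y=None, *, evidence_weights=None,
                    dag: OntologyDAG | None = None,
                    q_per_gene: dict[str, int] | None = None) -> np.ndarray:
        """Boolean mask of flagged (gene, term) entries of X."""
        self.fit(X, evidence_weights=evidence_weights, dag=dag)
        if self.mode == "q" and q_per_gene is None:
            raise ValueError("q mode needs q_per_gene")
        preds = self.predict_noisy(
            q_per_gene if self.mode == "q" else None
        )
        mask = np.zeros((len(self.genes_), len(self.terms_)), dtype=bool)
        gidx = {g: i for i, g in enumerate(self.genes_)}
        tidx = {t: j for j, t in enumerate(self.terms_)}
        for p in preds:
            i = gidx[p.gene]
            for t in p.selected:
                mask[i, tidx[t]] = True
        return mask
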