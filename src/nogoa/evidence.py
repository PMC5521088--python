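"""Evidence-code reliability estimated from successive GOA releases.

Annotations carry evidence codes recording their provenance (IEA =
electronically inferred, IDA = direct assay, TAS = traceable author
statement, ...). Codes differ in stability: comparing a release with a later
one, the fraction of direct (gene, term) annotations tagged with code c that
disappeared,

    r_ec(c) = N_noisy(c) / N(c),

estimates the noise ratio of c. Ratios averaged over l prior release pairs
(r~) are thresholded at their own mean tau: codes with r~ >= tau are
unstable and their annotations down-weighted to theta < 1, all others keep
weight 1. Weights are applied to direct annotations (maximum over a pair's
codes) and propagated to ancestors with the maximum rule, so an ancestor
annotation is never weighted below any of its descendants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .gaf import EVIDENCE_CODES, AnnotationRecord, GeneTermMatrix
from .ontology import OntologyDAG

logger = logging.getLogger(__name__)

RATIO_COLUMNS = ["n", "n_noisy", "r", "observed"]


def estimate_noise_ratio(
    records_old: list[AnnotationRecord],
    records_new: list[AnnotationRecord],
    shared: set[str],
) -> pd.DataFrame:
    """Per-code noisy-annotation ratios from one release pair.

    A direct (gene, term, code) annotation of the old release, restricted to
    the shared term universe, is noisy iff the (gene, term) pair is absent
    from the new release's direct pairs — presence is code-agnostic, so an
    annotation that merely changed evidence code is not counted as noisy.

    Returns a DataFrame indexed by all 21 evidence codes with columns
    ``n``, ``n_noisy``, ``r`` and ``observed`` (n > 0); unobserved codes get
    r = 0.
    """
    new_pairs = {(r.gene, r.term) for r in records_new if r.term in shared}
    triples = {(r.gene, r.term, r.evidence)
               for r in records_old if r.term in shared}

    codes = sorted(EVIDENCE_CODES)
    n = {c: 0 for c in codes}
    n_noisy = {c: 0 for c in codes}
    for gene, term, code in triples:
        n[code] += 1
        if (gene, term) not in new_pairs:
            n_noisy[code] += 1

    df = pd.DataFrame({
        "n": [n[c] for c in codes],
        "n_noisy": [n_noisy[c] for c in codes],
    }, index=pd.Index(codes, name="code"))
    df["observed"] = df["n"] > 0
    df["r"] = np.where(df["n"] > 0, df["n_noisy"] / df["n"].where(df["n"] > 0, 1), 0.0)
    return df[RATIO_COLUMNS]


def average_ratios(ratio_tables: list[pd.DataFrame], l: int) -> pd.DataFrame:
    """Average per-code ratios over the last ``l`` release pairs.

    Codes unobserved in some tables contribute their flagged zero entries to
    the mean. The returned table also carries the most recent pair's counts
    for reporting.
    """
    if l < 1:
        raise ValueError("l must be a positive integer")
    if len(ratio_tables) < l:
        raise ValueError(
            f"requested averaging over l={l} version pairs but only "
            f"{len(ratio_tables)} tables are available"
        )
    window = ratio_tables[-l:]
    codes = window[0].index
    r_tilde = sum(t["r"].reindex(codes, fill_value=0.0) for t in window) / l
    observed = pd.concat(
        [t["observed"].reindex(codes, fill_value=False) for t in window],
        axis=1,
    ).any(axis=1)
    last = window[-1]
    out = pd.DataFrame({
        "n": last["n"].reindex(codes, fill_value=0),
        "n_noisy": last["n_noisy"].reindex(codes, fill_value=0),
        "r": last["r"].reindex(codes, fill_value=0.0),
        "r_tilde": r_tilde,
        "observed": observed,
    })
    out.index.name = "code"
    return out


@dataclass
class EvidenceWeightTable:
    """Per-branch evidence-code weights with their estimation table."""

    branch: str
    table: pd.DataFrame  # columns n, n_noisy, r, r_tilde, observed, w
    tau: float
    theta: float
    l: int = 1
    weights: dict[str, float] = field(default_factory=dict)

    def weight(self, code: str) -> float:
        """Weight of a code; codes outside the table default to 1."""
        return self.weights.get(code, 1.0)

    def to_tsv(self, path) -> None:
        df = self.table.reset_index()
        df.insert(0, "branch", self.branch)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, theta: float, l: int = 1) -> "EvidenceWeightTable":
        df = pd.read_csv(path, sep="\t")
        branch = df["branch"].iloc[0]
        table = df.drop(columns=["branch"]).set_index("code")
        obs = table[table["observed"]]
        tau = float(obs["r_tilde"].mean()) if len(obs) else 0.0
        return cls(
            branch=branch, table=table, tau=tau, theta=theta, l=l,
            weights=table["w"].to_dict(),
        )


def assign_code_weights(
    r_tilde: pd.DataFrame,
    theta: float = 0.5,
    branch: str = "BP",
    l: int = 1,
) -> EvidenceWeightTable:
    """Threshold averaged ratios into binary code weights.

    tau is the mean of r~ over codes actually observed (n > 0); observed
    codes with r~ >= tau get weight theta, the rest weight 1. Unobserved
    codes get weight 1 by convention (with a warning): nothing is known
    about their stability.
    """
    if not 0 < theta < 1:
        raise ValueError(f"theta must lie in (0, 1), got {theta}")
    if len(r_tilde) == 0:
        raise ValueError("empty ratio table")
    table = r_tilde.copy()
    if "r_tilde" not in table.columns:  # accept a raw single-pair table
        table["r_tilde"] = table["r"]
    observed = table["observed"]
    if not observed.any():
        raise ValueError("no evidence code was observed in any release pair")
    tau = float(table.loc[observed, "r_tilde"].mean())
    unobserved = table.index[~observed]
    if len(unobserved):
        logger.warning(
            "%d evidence codes unobserved in %s; they keep weight 1: %s",
            len(unobserved), branch, ", ".join(unobserved),
        )
    w = np.where(observed & (table["r_tilde"] >= tau), theta, 1.0)
    table = table.assign(w=w)
    return EvidenceWeightTable(
        branch=branch, table=table, tau=tau, theta=theta, l=l,
        weights=table["w"].to_dict(),
    )


def weight_direct_matrix(
    direct: GeneTermMatrix, weights: EvidenceWeightTable
) -> GeneTermMatrix:
    """Weight direct annotations by their evidence codes (A^d_ec).

    A pair supported by several codes takes the maximal weight — accumulated
    evidence from independent sources makes an annotation more, not less,
    trustworthy.
    """
    if direct.form != "direct-binary":
        raise ValueError(f"expected a direct-binary matrix, got {direct.form}")
    if direct.values.nnz != len(direct.evidence_map):
        raise ValueError("evidence map does not cover every direct entry")
    gene_idx = direct.gene_index
    term_idx = direct.term_index
    rows, cols, vals = [], [], []
    for (gene, term), codes in direct.evidence_map.items():
        if not codes:
            raise ValueError(f"no evidence codes recorded for ({gene}, {term})")
        rows.append(gene_idx[gene])
        cols.append(term_idx[term])
        vals.append(max(weights.weight(c) for c in codes))
    values = sp.csr_matrix(
        (vals, (rows, cols)),
        shape=(len(direct.genes), len(direct.terms)),
    )
    return GeneTermMatrix(
        genes=list(direct.genes), terms=list(direct.terms), values=values,
        form="direct-weighted", evidence_map=dict(direct.evidence_map),
    )


def propagate_weights(
    direct_weighted: GeneTermMatrix, dag: OntologyDAG
) -> GeneTermMatrix:
    """Propagate evidence weights to ancestors with the maximum rule (A_ec).

    A_ec(i, s) is the maximum weight over direct annotations t of gene i
    with t = s or s an ancestor of t; the branch root is dropped. The
    nonzero pattern therefore equals that of the propagated binary matrix.
    """
    if direct_weighted.form != "direct-weighted":
        raise ValueError(
            f"expected a direct-weighted matrix, got {direct_weighted.form}"
        )
    terms = direct_weighted.terms
    term_idx = direct_weighted.term_index
    csc = direct_weighted.values.tocsc()

    # contributors of target column s: s itself plus its descendants
    from .gaf import _drop_roots

    n_genes = len(direct_weighted.genes)
    keep = _drop_roots(terms, dag)
    out_cols = []
    for j in keep:
        t = terms[j]
        if t not in dag.terms:
            raise ValueError(f"term {t} missing from the {dag.branch} DAG")
        cols = [j] + [term_idx[d] for d in dag.descendants(t) if d in term_idx]
        block = csc[:, cols]
        out_cols.append(sp.csr_matrix(block.max(axis=1)))
    values = sp.hstack(out_cols, format="csr") if out_cols else \
        sp.csr_matrix((n_genes, 0))
    return GeneTermMatrix(
        genes=list(direct_weighted.genes),
        terms=[terms[j] for j in keep],
        values=values,
        form="propagated-weighted",
    )
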