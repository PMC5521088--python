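"""GAF 2.x parsing and gene-term association matrices.

The central container is :class:`GeneTermMatrix`, a sparse genes x terms
matrix in one of four forms:

* ``direct-binary`` (A^d): 1 iff the GAF file directly pairs the gene with
  the term; carries an evidence map (gene, term) -> set of evidence codes.
* ``propagated-binary`` (A): true-path closure of A^d — a gene annotated
  with a term is annotated with all its ancestors.
* ``direct-weighted`` (A^d_ec) and ``propagated-weighted`` (A_ec): the same
  supports with per-annotation evidence-code weights in [0, 1].

Branch roots are excluded from propagated matrices: every annotated gene
would trivially hit its branch root, and a root can never be a meaningful
noisy annotation.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .ontology import BRANCH_ROOTS, OntologyDAG

logger = logging.getLogger(__name__)

#: the 21 GO evidence codes, by category
EVIDENCE_CODES = frozenset({
    # experimental
    "EXP", "IDA", "IPI", "IMP", "IGI", "IEP",
    # computational
    "ISS", "ISO", "ISA", "ISM", "IGC", "IBA", "IBD", "IKR", "IRD", "RCA",
    # author statement
    "TAS", "NAS",
    # curatorial / electronic
    "IC", "ND", "IEA",
})

_ASPECT_TO_BRANCH = {"P": "BP", "C": "CC", "F": "MF"}


@dataclass(frozen=True)
class AnnotationRecord:
    """One direct gene-term annotation from a GAF file."""

    gene: str
    term: str
    evidence: str
    aspect: str
    qualifier: str = ""


@dataclass
class GeneTermMatrix:
    """Sparse genes x terms association matrix (see module docstring)."""

    genes: list[str]
    terms: list[str]
    values: sp.csr_matrix
    form: str
    evidence_map: dict[tuple[str, str], frozenset[str]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        if self.values.shape != (len(self.genes), len(self.terms)):
            raise ValueError("matrix shape does not match gene/term lists")

    @property
    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    @property
    def term_index(self) -> dict[str, int]:
        return {t: j for j, t in enumerate(self.terms)}

    def toarray(self) -> np.ndarray:
        return self.values.toarray()

    def density(self) -> float:
        n = self.values.shape[0] * self.values.shape[1]
        return self.values.nnz / n if n else 0.0

    def annotated_terms(self, gene: str) -> list[str]:
        """Terms with a nonzero entry for ``gene`` (matrix order)."""
        i = self.gene_index[gene]
        row = self.values.getrow(i)
        return [self.terms[j] for j in row.indices]


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def parse_gaf(
    path,
    branch: str,
    allowed_terms: set[str] | None = None,
    *,
    drop_not: bool = True,
    drop_nd: bool = True,
    resolve=None,
) -> list[AnnotationRecord]:
    """Parse a GAF 2.0/2.1/2.2 file into annotation records of one branch.

    Parameters
    ----------
    allowed_terms:
        If given, records whose term is outside this set are dropped (the
        shared-term filter across ontology releases). ``None`` keeps all.
    drop_not:
        Drop records whose qualifier contains ``NOT`` (negative annotations
        are not annotations in the association-matrix sense).
    drop_nd:
        Drop ND-evidence records (they annotate branch roots only).
    resolve:
        Optional callable mapping alias term ids to primary ids
        (e.g. ``dag.resolve``) applied before the allowed-term filter.
    """
    records: list[AnnotationRecord] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 15:
                logger.warning(
                    "%s:%d: %d columns (expected >= 15); line skipped",
                    path, lineno, len(cols),
                )
                continue
            qualifier, term, evidence, aspect = (
                cols[3], cols[4], cols[6], cols[8]
            )
            if _ASPECT_TO_BRANCH.get(aspect) != branch:
                continue
            if drop_not and "NOT" in qualifier.split("|"):
                continue
            if evidence not in EVIDENCE_CODES:
                logger.warning(
                    "%s:%d: unknown evidence code %r; record dropped",
                    path, lineno, evidence,
                )
                continue
            if drop_nd and evidence == "ND":
                continue
            if resolve is not None:
                term = resolve(term)
            if allowed_terms is not None and term not in allowed_terms:
                continue
            records.append(AnnotationRecord(
                gene=cols[1], term=term, evidence=evidence,
                aspect=branch, qualifier=qualifier,
            ))
    return records


def build_direct_matrix(
    records: list[AnnotationRecord],
    term_order: list[str],
) -> GeneTermMatrix:
    """Assemble the direct-binary matrix A^d with its evidence map.

    Duplicate gene-term pairs collapse to one entry carrying the union of
    their evidence codes. Gene order is sorted-unique gene ids; term order
    is the caller's (typically the sorted shared-term universe).
    """
    if not records:
        raise ValueError("cannot build a matrix from an empty record list")
    term_idx = {t: j for j, t in enumerate(term_order)}
    missing = {r.term for r in records} - set(term_idx)
    if missing:
        raise ValueError(f"records mention terms outside term_order: "
                         f"{sorted(missing)[:5]}...")
    genes = sorted({r.gene for r in records})
    gene_idx = {g: i for i, g in enumerate(genes)}

    evidence_map: dict[tuple[str, str], set[str]] = {}
    for r in records:
        evidence_map.setdefault((r.gene, r.term), set()).add(r.evidence)

    rows, cols = [], []
    for gene, term in evidence_map:
        rows.append(gene_idx[gene])
        cols.append(term_idx[term])
    values = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)),
        shape=(len(genes), len(term_order)),
    )
    return GeneTermMatrix(
        genes=genes, terms=list(term_order), values=values,
        form="direct-binary",
        evidence_map={k: frozenset(v) for k, v in evidence_map.items()},
    )


def _closure_matrix(terms: list[str], dag: OntologyDAG) -> sp.csr_matrix:
    """|T| x |T| boolean matrix C with C[t, s] = 1 iff s == t or s in anc(t),
    restricted to the given term universe."""
    term_idx = {t: j for j, t in enumerate(terms)}
    rows, cols = [], []
    for t in terms:
        if t not in dag.terms:
            raise ValueError(f"term {t} missing from the {dag.branch} DAG")
        j = term_idx[t]
        rows.append(j)
        cols.append(j)
        for s in dag.ancestors(t):
            if s in term_idx:
                rows.append(j)
                cols.append(term_idx[s])
    n = len(terms)
    return sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )


def _drop_roots(terms: list[str], dag: OntologyDAG) -> list[int]:
    roots = set(BRANCH_ROOTS.values()) | {dag.root}
    return [j for j, t in enumerate(terms) if t not in roots]


def propagate_true_path(
    direct: GeneTermMatrix, dag: OntologyDAG
) -> GeneTermMatrix:
    """True-path closure of a direct-binary matrix.

    A(i, s) = 1 iff s is a direct term of gene i or an ancestor of one.
    The branch root is removed from the term list.
    """
    if direct.form != "direct-binary":
        raise ValueError(f"expected a direct-binary matrix, got {direct.form}")
    closure = _closure_matrix(direct.terms, dag)
    prop = (direct.values @ closure) > 0
    keep = _drop_roots(direct.terms, dag)
    return GeneTermMatrix(
        genes=list(direct.genes),
        terms=[direct.terms[j] for j in keep],
        values=sp.csr_matrix(prop[:, keep], dtype=float),
        form="propagated-binary",
    )


PREDICTION_COLUMNS = ["gene", "term", "score", "rank", "flag"]


def write_predictions(predictions, path) -> None:
    """Write noisy-annotation predictions as a deterministic TSV.

    One row per flagged (gene, term): gene, term, fused score V(i, t), rank
    of the term within the gene's ascending-score ranking, and a flag
    ``direct`` (selected) or ``inherited`` (descendant-expanded). Rows are
    ordered by gene id, then score ascending, then term id.
    """
    rows = []
    for pred in predictions:
        score = dict(pred.ranked)
        rank = {t: k + 1 for k, (t, _) in enumerate(pred.ranked)}
        for term in pred.direct:
            rows.append((pred.gene, term, score[term], rank[term], "direct"))
        for term in pred.inherited:
            rows.append((pred.gene, term, score[term], rank[term],
                         "inherited"))
    rows.sort(key=lambda r: (r[0], r[2], r[1]))
    df = pd.DataFrame(rows, columns=PREDICTION_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_predictions(path) -> pd.DataFrame:
    """Read a prediction TSV written by :func:`write_predictions`."""
    return pd.read_csv(path, sep="\t", dtype={"gene": str, "term": str})
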