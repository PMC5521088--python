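"""Per-branch Gene Ontology DAGs with ancestor/descendant queries.

The three GO branches (biological_process, cellular_component,
molecular_function) are handled independently: a :class:`OntologyDAG` holds
the terms of a single branch and the containment relations between them
(``is_a`` and, by default, ``part_of``). Regulates-type relations are not
containment relations and are ignored. Obsolete terms are recorded but carry
no edges and never enter annotation matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

#: branch code -> OBO namespace
BRANCH_NAMESPACES = {
    "BP": "biological_process",
    "CC": "cellular_component",
    "MF": "molecular_function",
}

#: branch code -> canonical GO root term
BRANCH_ROOTS = {
    "BP": "GO:0008150",
    "CC": "GO:0005575",
    "MF": "GO:0003674",
}

DEFAULT_RELATIONS = ("is_a", "part_of")


class OboFormatError(ValueError):
    """Raised when an OBO file violates the DAG contract (e.g. a cycle)."""


@dataclass
class OntologyDAG:
    """Terms of one GO branch with child->parent containment edges.

    Parameters
    ----------
    branch:
        One of ``"BP"``, ``"CC"``, ``"MF"``.
    graph:
        Directed graph with edges pointing child -> parent. Ancestors of a
        term are therefore the nodes *reachable from* it.
    root:
        The branch root term (the unique term with no parents).
    obsolete:
        Term ids marked obsolete; they are members of neither ``graph`` nor
        ``terms``.
    alt_ids:
        Alias term id -> primary term id.
    """

    branch: str
    graph: nx.DiGraph
    root: str
    obsolete: set[str] = field(default_factory=set)
    alt_ids: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.branch not in BRANCH_NAMESPACES:
            raise ValueError(f"unknown branch code {self.branch!r}")
        if not nx.is_directed_acyclic_graph(self.graph):
            raise OboFormatError("ontology graph contains a cycle")

    @property
    def terms(self) -> set[str]:
        """Non-obsolete terms of the branch."""
        return set(self.graph.nodes)

    def _check(self, term: str) -> None:
        if term not in self.graph:
            raise KeyError(f"unknown term {term!r} in {self.branch} DAG")

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable from ``term`` via is_a/part_of, excluding it."""
        self._check(term)
        # edges point child -> parent, so graph-descendants are GO-ancestors
        return nx.descendants(self.graph, term)

    def descendants(self, term: str) -> set[str]:
        """All terms from which ``term`` is reachable, excluding itself."""
        self._check(term)
        return nx.ancestors(self.graph, term)

    def resolve(self, term: str) -> str:
        """Map an alt_id alias to its primary term id (identity otherwise)."""
        return self.alt_ids.get(term, term)


def parse_obo(
    path,
    branch: str,
    relations: tuple[str, ...] = DEFAULT_RELATIONS,
) -> OntologyDAG:
    """Parse an OBO 1.2/1.4 file into the DAG of one branch.

    Terms whose namespace does not match ``branch`` are skipped (cross-branch
    ``part_of`` edges are dropped with them); terms with no namespace at all
    are skipped with a warning. Obsolete terms are recorded in
    ``OntologyDAG.obsolete`` and excluded from the graph.
    """
    if branch not in BRANCH_NAMESPACES:
        raise ValueError(f"unknown branch code {branch!r}")
    namespace = BRANCH_NAMESPACES[branch]

    raw = obonet.read_obo(path, ignore_obsolete=False)

    obsolete: set[str] = set()
    alt_ids: dict[str, str] = {}
    keep: set[str] = set()
    for term, data in raw.nodes(data=True):
        ns = data.get("namespace")
        if ns is None:
            logger.warning("term %s has no namespace; skipped", term)
            continue
        if ns != namespace:
            continue
        if str(data.get("is_obsolete", "")).lower() == "true":
            obsolete.add(term)
            continue
        keep.add(term)
        for alias in data.get("alt_id", []):
            alt_ids[alias] = term

    graph = nx.DiGraph()
    graph.add_nodes_from(keep)
    for child, parent, rel in raw.edges(keys=True):
        if rel not in relations:
            continue
        if child in keep and parent in keep:
            graph.add_edge(child, parent, relation=rel)

    if not nx.is_directed_acyclic_graph(graph):
        raise OboFormatError(f"cycle detected in {branch} branch of {path}")

    roots = [t for t in graph.nodes if graph.out_degree(t) == 0]
    canonical = BRANCH_ROOTS[branch]
    if canonical in graph:
        root = canonical
    elif len(roots) == 1:
        root = roots[0]
    elif roots:
        # several parentless terms: pick deterministically, warn
        root = min(roots)
        logger.warning(
            "%s branch has %d parentless terms; using %s as root",
            branch, len(roots), root,
        )
    else:
        raise OboFormatError(f"{branch} branch of {path} has no root term")

    return OntologyDAG(branch=branch, graph=graph, root=root,
                       obsolete=obsolete, alt_ids=alt_ids)


def ancestors(dag: OntologyDAG, term: str) -> set[str]:
    """Ancestor set of ``term`` (true-path closure, term excluded)."""
    return dag.ancestors(term)


def descendants(dag: OntologyDAG, term: str) -> set[str]:
    """Descendant set of ``term`` (term excluded)."""
    return dag.descendants(term)


def shared_terms(dag_old: OntologyDAG, dag_new: OntologyDAG) -> set[str]:
    """Non-obsolete terms present in both releases of the same branch.

    Mirrors the CAFA-style protocol of retaining only terms that exist in
    both the historical and recent ontology files, so evaluation is not
    confounded by ontology evolution.
    """
    if dag_old.branch != dag_new.branch:
        raise ValueError(
            f"branch mismatch: {dag_old.branch} vs {dag_new.branch}"
        )
    return dag_old.terms & dag_new.terms
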