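import textwrap

import networkx as nx
import pytest

from nogoa.gaf import AnnotationRecord
from nogoa.ontology import OntologyDAG

ROOT = "GO:9000000"
T1, T2, T3 = "GO:9000001", "GO:9000002", "GO:9000003"


def make_dag(edges, root=ROOT, branch="BP", obsolete=()):
    g = nx.DiGraph()
    g.add_node(root)
    for child, parent in edges:
        g.add_edge(child, parent, relation="is_a")
    return OntologyDAG(branch=branch, graph=g, root=root,
                       obsolete=set(obsolete))


@pytest.fixture
def diamond_dag():
    """t3 is_a t1, t3 is_a t2, t1/t2 is_a root."""
    return make_dag([(T1, ROOT), (T2, ROOT), (T3, T1), (T3, T2)])


@pytest.fixture
def chain_dag():
    """root <- t1 <- t2."""
    return make_dag([(T1, ROOT), (T2, T1)])


@pytest.fixture
def diamond_obo(tmp_path):
    text = textwrap.dedent(f"""\
        format-version: 1.2
        ontology: fixture

        [Term]
        id: {ROOT}
        name: root
        namespace: biological_process

        [Term]
        id: {T1}
        name: branch a
        namespace: biological_process
        is_a: {ROOT} ! root

        [Term]
        id: {T2}
        name: branch b
        namespace: biological_process
        is_a: {ROOT} ! root

        [Term]
        id: {T3}
        name: leaf
        namespace: biological_process
        is_a: {T1} ! branch a
        is_a: {T2} ! branch b

        [Term]
        id: GO:9000009
        name: retired
        namespace: biological_process
        is_obsolete: true

        [Term]
        id: GO:9000010
        name: elsewhere
        namespace: molecular_function
    """)
    path = tmp_path / "diamond.obo"
    path.write_text(text)
    return path


@pytest.fixture
def toy_gaf(tmp_path):
    """3 usable BP lines, 1 MF line, 1 NOT-qualified, 1 ND, 1 malformed."""
    rows = [
        ["SIM", "g1", "g1", "", T3, "REF:1", "IDA", "", "P", "", "",
         "protein", "taxon:0000", "20150501", "SIM", "", ""],
        ["SIM", "g1", "g1", "", T3, "REF:1", "IEA", "", "P", "", "",
         "protein", "taxon:0000", "20150501", "SIM", "", ""],
        ["SIM", "g2", "g2", "", T1, "REF:1", "TAS", "", "P", "", "",
         "protein", "taxon:0000", "20150501", "SIM", "", ""],
        ["SIM", "g2", "g2", "", T2, "REF:1", "IDA", "", "F", "", "",
         "protein", "taxon:0000", "20150501", "SIM", "", ""],
        ["SIM", "g3", "g3", "NOT|involved_in", T1, "REF:1", "IDA", "", "P",
         "", "", "protein", "taxon:0000", "20150501", "SIM", "", ""],
        ["SIM", "g3", "g3", "", ROOT, "REF:1", "ND", "", "P", "", "",
         "protein", "taxon:0000", "20150501", "SIM", "", ""],
    ]
    lines = ["!gaf-version: 2.1"]
    lines += ["\t".join(r) for r in rows]
    lines.append("SIM\tbroken line")
    path = tmp_path / "toy.gaf"
    path.write_text("\n".join(lines) + "\n")
    return path


def record(gene, term, evidence="IDA", aspect="BP"):
    return AnnotationRecord(gene=gene, term=term, evidence=evidence,
                            aspect=aspect)
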