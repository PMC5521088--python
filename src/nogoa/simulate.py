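"""Synthetic ontologies, annotation releases and injected noise.

The generator emulates the archived-release setting the method is built for:

* a layered is_a DAG standing in for one GO branch;
* genes grouped into functional clusters, each owning a coherent subset of
  deep terms — the neighbourhood structure the sparse-representation votes
  rely on; a configurable fraction of direct annotations is swapped for an
  off-profile term (the injected "true noise"), tagged with a noisier
  evidence-code mix;
* a "recent" release produced from the "historical" one by removing each
  direct annotation independently, with a per-evidence-code probability and
  an elevated probability for off-profile records, coupling injected noise
  with removal exactly as archived GOA pairs couple instability with
  disappearance.

All randomness flows from ``SimConfig.seed``; outputs are byte-identical
across runs and round-trip through the OBO/GAF parsers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import networkx as nx
import numpy as np

from .gaf import EVIDENCE_CODES, AnnotationRecord
from .ontology import OntologyDAG

logger = logging.getLogger(__name__)

_ASPECT_LETTER = {"BP": "P", "CC": "C", "MF": "F"}


def _default_code_mix() -> dict[str, float]:
    return {"IDA": 0.4, "TAS": 0.3, "IEA": 0.3}


def _default_noise_code_mix() -> dict[str, float]:
    return {"IEA": 0.7, "IDA": 0.15, "TAS": 0.15}


def _default_removal_rates() -> dict[str, float]:
    return {"IEA": 0.2, "IDA": 0.05, "TAS": 0.1}


@dataclass
class SimConfig:
    """Knobs of the synthetic study (defaults are the study conditions)."""

    n_terms: int = 400
    n_layers: int = 5
    parents_per_term: int = 2
    n_genes: int = 300
    directs_per_gene: int = 8
    n_clusters: int = 10
    code_mix: dict[str, float] = field(default_factory=_default_code_mix)
    noise_code_mix: dict[str, float] = field(
        default_factory=_default_noise_code_mix
    )
    removal_rates: dict[str, float] = field(
        default_factory=_default_removal_rates
    )
    profile_noise: float = 0.1
    offprofile_removal_rate: float = 0.9
    ppi_within: float = 0.25
    ppi_between: float = 0.002
    branch: str = "BP"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_layers < 2:
            raise ValueError("n_layers must be >= 2")
        if self.n_terms < self.n_layers:
            raise ValueError("n_terms must be >= n_layers")
        if self.parents_per_term < 1:
            raise ValueError("parents_per_term must be >= 1")
        for name in ("profile_noise", "offprofile_removal_rate",
                     "ppi_within", "ppi_between"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for mix_name in ("code_mix", "noise_code_mix"):
            mix = getattr(self, mix_name)
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"{mix_name} probabilities must sum to 1")
            unknown = set(mix) - EVIDENCE_CODES
            if unknown:
                raise ValueError(f"{mix_name} has unknown codes: {unknown}")
        for code, rate in self.removal_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"removal rate for {code} outside [0, 1]")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one named sub-stream of the seed."""
        return np.random.default_rng([self.seed, stream])


def _term_id(k: int) -> str:
    return f"GO:9{k:06d}"


def generate_dag(cfg: SimConfig) -> OntologyDAG:
    """Layered random is_a DAG: 1 root, geometric layer growth, each term
    drawing 1..parents_per_term parents from the layer above."""
    rng = cfg.rng(0)
    inner = cfg.n_layers - 1
    weights = np.array([2.0 ** k for k in range(inner)])
    sizes = np.maximum(
        1, np.round((cfg.n_terms - 1) * weights / weights.sum()).astype(int)
    )
    sizes[-1] += (cfg.n_terms - 1) - sizes.sum()  # exact total
    if sizes[-1] < 1:
        raise ValueError("infeasible DAG shape: empty bottom layer")

    graph = nx.DiGraph()
    root = _term_id(0)
    graph.add_node(root)
    layers = [[root]]
    next_id = 1
    for size in sizes:
        prev = layers[-1]
        layer = []
        for _ in range(size):
            term = _term_id(next_id)
            next_id += 1
            n_par = int(rng.integers(1, cfg.parents_per_term + 1))
            parents = rng.choice(
                len(prev), size=min(n_par, len(prev)), replace=False
            )
            graph.add_node(term)
            for p in sorted(parents):
                graph.add_edge(term, prev[p], relation="is_a")
            layer.append(term)
        layers.append(layer)
    return OntologyDAG(branch=cfg.branch, graph=graph, root=root)


class SimAnnotations(NamedTuple):
    """Direct annotations with their cluster structure and injected noise."""

    records: list[AnnotationRecord]
    gene_cluster: dict[str, int]
    cluster_pools: list[list[str]]
    off_profile: set[tuple[str, str]]


def _draw_code(rng: np.random.Generator, mix: dict[str, float]) -> str:
    codes = sorted(mix)
    probs = np.array([mix[c] for c in codes])
    return codes[rng.choice(len(codes), p=probs / probs.sum())]


def generate_annotations(dag: OntologyDAG, cfg: SimConfig) -> SimAnnotations:
    """Cluster-structured direct annotations with off-profile noise.

    Leaf terms are partitioned into ``n_clusters`` pools; each gene draws
    ``directs_per_gene`` distinct terms from its cluster's pool, replacing
    each draw with probability ``profile_noise`` by a term from another
    cluster's pool (recorded as injected noise and tagged with the noisier
    code mix).
    """
    rng = cfg.rng(1)
    leaves = sorted(t for t in dag.terms if not dag.descendants(t))
    if len(leaves) < cfg.n_clusters:
        raise ValueError("fewer leaf terms than clusters")
    perm = rng.permutation(len(leaves))
    pools: list[list[str]] = [[] for _ in range(cfg.n_clusters)]
    for pos, k in enumerate(perm):
        pools[pos % cfg.n_clusters].append(leaves[k])
    pools = [sorted(p) for p in pools]
    if min(len(p) for p in pools) < cfg.directs_per_gene:
        raise ValueError(
            "cluster pools smaller than directs_per_gene; increase n_terms "
            "or decrease n_clusters/directs_per_gene"
        )

    records: list[AnnotationRecord] = []
    gene_cluster: dict[str, int] = {}
    off_profile: set[tuple[str, str]] = set()
    for g in range(cfg.n_genes):
        gene = f"SIMG{g:05d}"
        cl = g % cfg.n_clusters
        gene_cluster[gene] = cl
        pool = pools[cl]
        picks = rng.choice(len(pool), size=cfg.directs_per_gene,
                           replace=False)
        terms = {pool[k] for k in sorted(picks)}
        final_terms: list[tuple[str, bool]] = []
        used = set(terms)
        for term in sorted(terms):
            if rng.random() < cfg.profile_noise:
                other = [t for c2, p2 in enumerate(pools) if c2 != cl
                         for t in p2 if t not in used]
                swap = other[int(rng.integers(len(other)))]
                used.add(swap)
                final_terms.append((swap, True))
            else:
                final_terms.append((term, False))
        for term, noisy in final_terms:
            mix = cfg.noise_code_mix if noisy else cfg.code_mix
            code = _draw_code(rng, mix)
            records.append(AnnotationRecord(
                gene=gene, term=term, evidence=code, aspect=cfg.branch,
            ))
            if noisy:
                off_profile.add((gene, term))
    return SimAnnotations(records, gene_cluster, pools, off_profile)


def make_release_pair(
    records: list[AnnotationRecord],
    cfg: SimConfig,
    off_profile: set[tuple[str, str]] | None = None,
) -> tuple[list[AnnotationRecord], list[AnnotationRecord],
           list[AnnotationRecord]]:
    """Historical/recent release pair by per-code stochastic removal.

    Each record is removed independently with ``removal_rates[code]``;
    records flagged off-profile are removed with the elevated
    ``offprofile_removal_rate`` instead, coupling injected noise with
    disappearance. Returns (historical, recent, removed).
    """
    rng = cfg.rng(2)
    seen_codes = {r.evidence for r in records}
    for code in cfg.removal_rates:
        if code not in seen_codes:
            logger.warning(
                "removal rate given for code %s absent from the records; "
                "ignored", code,
            )
    off_profile = off_profile or set()
    historical = list(records)
    recent, removed = [], []
    for r in historical:
        if (r.gene, r.term) in off_profile:
            rate = cfg.offprofile_removal_rate
        else:
            rate = cfg.removal_rates.get(r.evidence, 0.0)
        if rng.random() < rate:
            removed.append(r)
        else:
            recent.append(r)
    return historical, recent, removed


def generate_ppi(
    gene_cluster: dict[str, int], cfg: SimConfig
) -> list[tuple[str, str]]:
    """Random cluster-assortative PPI edges (within-cluster enriched)."""
    rng = cfg.rng(3)
    genes = sorted(gene_cluster)
    edges = []
    for i, a in enumerate(genes):
        for b in genes[i + 1:]:
            p = cfg.ppi_within if gene_cluster[a] == gene_cluster[b] \
                else cfg.ppi_between
            if rng.random() < p:
                edges.append((a, b))
    return edges


def write_obo(dag: OntologyDAG, path) -> None:
    """Serialise a DAG as a minimal OBO 1.2 file (deterministic order)."""
    from .ontology import BRANCH_NAMESPACES

    ns = BRANCH_NAMESPACES[dag.branch]
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: sim\n")
        for term in sorted(dag.terms):
            fh.write(f"\n[Term]\nid: {term}\nname: {term}\n")
            fh.write(f"namespace: {ns}\n")
            for parent in sorted(dag.graph.successors(term)):
                rel = dag.graph.edges[term, parent].get("relation", "is_a")
                if rel == "is_a":
                    fh.write(f"is_a: {parent} ! {parent}\n")
                else:
                    fh.write(f"relationship: {rel} {parent} ! {parent}\n")
        for term in sorted(dag.obsolete):
            fh.write(f"\n[Term]\nid: {term}\nname: {term}\n")
            fh.write(f"namespace: {ns}\nis_obsolete: true\n")


def write_gaf(records: list[AnnotationRecord], path,
              date: str = "20160501") -> None:
    """Serialise records as a GAF 2.1 file with placeholder DB ``SIM``."""
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.1\n")
        for r in sorted(records, key=lambda r: (r.gene, r.term, r.evidence)):
            cols = [
                "SIM", r.gene, r.gene, r.qualifier, r.term, "SIM_REF:0000001",
                r.evidence, "", _ASPECT_LETTER[r.aspect], r.gene, "",
                "protein", "taxon:0000", date, "SIM", "", "",
            ]
            fh.write("\t".join(cols) + "\n")


def write_dataset(out_dir, cfg: SimConfig) -> dict:
    """Generate a full dataset and write it under ``out_dir``.

    Writes ``ontology.obo``, ``historical.gaf``, ``recent.gaf``,
    ``truth_noise.tsv`` (injected off-profile pairs) and
    ``truth_removed.tsv`` (records removed in the recent release).
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dag = generate_dag(cfg)
    ann = generate_annotations(dag, cfg)
    historical, recent, removed = make_release_pair(
        ann.records, cfg, ann.off_profile
    )
    write_obo(dag, out / "ontology.obo")
    write_gaf(historical, out / "historical.gaf")
    write_gaf(recent, out / "recent.gaf")
    with open(out / "truth_noise.tsv", "w") as fh:
        fh.write("gene\tterm\n")
        for gene, term in sorted(ann.off_profile):
            fh.write(f"{gene}\t{term}\n")
    with open(out / "truth_removed.tsv", "w") as fh:
        fh.write("gene\tterm\tevidence\n")
        for r in sorted(removed, key=lambda r: (r.gene, r.term, r.evidence)):
            fh.write(f"{r.gene}\t{r.term}\t{r.evidence}\n")
    return {
        "dag": dag, "annotations": ann, "historical": historical,
        "recent": recent, "removed": removed,
    }
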