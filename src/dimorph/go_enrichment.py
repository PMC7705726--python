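"""GO over-representation analysis with ontology-depth filtering.

The candidate gene set is tested term-by-term with the upper-tail
hypergeometric probability against an annotated background population,
adjusted by Benjamini–Hochberg within the tested namespace.  Terms are
additionally filtered by their hierarchical depth — the length of the
longest is_a path from the namespace root (root = 0) — keeping only broad
terms near the top of the DAG (depth ≤ 3 by default).  Only is_a edges are
used, both for annotation propagation (true-path rule) and for depth;
part_of is deliberately ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import obonet
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .model import AnnotationSet

logger = logging.getLogger(__name__)

NAMESPACES = {
    "BP": "biological_process",
    "MF": "molecular_function",
    "CC": "cellular_component",
}


@dataclass
class OntologyDAG:
    """is_a-only view of a parsed OBO ontology.

    ``graph`` holds one directed edge child → parent per is_a relation;
    ``alt_ids`` maps secondary ids to their primary term.
    """

    graph: nx.DiGraph
    names: dict[str, str]
    namespaces: dict[str, str]
    alt_ids: dict[str, str] = field(default_factory=dict)

    def resolve(self, term: str) -> str:
        return self.alt_ids.get(term, term)

    def __contains__(self, term: str) -> bool:
        return self.resolve(term) in self.graph

    def parents(self, term: str) -> set[str]:
        return set(self.graph.successors(self.resolve(term)))

    def ancestors(self, term: str) -> set[str]:
        """All is_a ancestors (excluding the term itself)."""
        return nx.descendants(self.graph, self.resolve(term))

    def terms_in_namespace(self, namespace: str) -> list[str]:
        ns = NAMESPACES.get(namespace, namespace)
        return [t for t, n in self.namespaces.items() if n == ns]


def parse_obo(path: str | Path) -> OntologyDAG:
    """Parse an OBO 1.2 file into an is_a DAG.

    part_of and other relationship edges are dropped; obsolete terms are
    excluded; alt_id entries resolve to their primary term.  A cycle in the
    is_a graph is an error naming one of its members.
    """
    multi = obonet.read_obo(str(path))
    graph = nx.DiGraph()
    names: dict[str, str] = {}
    namespaces: dict[str, str] = {}
    alt_ids: dict[str, str] = {}
    for node, data in multi.nodes(data=True):
        graph.add_node(node)
        names[node] = data.get("name", node)
        namespaces[node] = data.get("namespace", "")
        for alt in data.get("alt_id", []):
            alt_ids[alt] = node
    for child, parent, key in multi.edges(keys=True):
        if key == "is_a":
            graph.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise ValueError(f"is_a cycle detected involving term {cycle[0][0]}")
    return OntologyDAG(graph=graph, names=names, namespaces=namespaces, alt_ids=alt_ids)


def term_depth(dag: OntologyDAG, term: str) -> int:
    """Length of the longest is_a path from the namespace root (root = 0)."""
    return _depths(dag)[0][dag_resolve_checked(dag, term)]


def term_level(dag: OntologyDAG, term: str) -> int:
    """Length of the shortest is_a path from the namespace root."""
    return _depths(dag)[1][dag_resolve_checked(dag, term)]


def dag_resolve_checked(dag: OntologyDAG, term: str) -> str:
    resolved = dag.resolve(term)
    if resolved not in dag.graph:
        raise KeyError(f"unknown GO term {term!r}")
    return resolved


def _depths(dag: OntologyDAG) -> tuple[dict[str, int], dict[str, int]]:
    # memoised on the dag object; edges never change after parsing
    cached = getattr(dag, "_depth_cache", None)
    if cached is not None:
        return cached
    depth: dict[str, int] = {}
    level: dict[str, int] = {}
    for term in nx.topological_sort(dag.graph.reverse(copy=False)):
        parents = list(dag.graph.successors(term))
        if not parents:
            depth[term] = 0
            level[term] = 0
        else:
            depth[term] = 1 + max(depth[p] for p in parents)
            level[term] = 1 + min(level[p] for p in parents)
    dag._depth_cache = (depth, level)
    return depth, level


def propagate_annotations(annotations: AnnotationSet, dag: OntologyDAG) -> AnnotationSet:
    """Annotate every gene to all is_a ancestors of its direct terms.

    Term ids absent from the ontology are dropped (a count is logged).
    Idempotent: propagating a propagated set changes nothing.
    """
    dropped = 0
    out: dict[str, set[str]] = {}
    for gene, terms in annotations.gene_to_terms.items():
        full: set[str] = set()
        for term in terms:
            resolved = dag.resolve(term)
            if resolved not in dag.graph:
                dropped += 1
                continue
            full.add(resolved)
            full |= dag.ancestors(resolved)
        out[gene] = full
    if dropped:
        logger.warning("dropped %d annotation(s) to terms absent from the ontology", dropped)
    return AnnotationSet(gene_to_terms=out, population_size=annotations.population_size)


def hypergeom_enrich(
    study: set[str],
    annotations: AnnotationSet,
    dag: OntologyDAG,
    namespace: str = "BP",
) -> pd.DataFrame:
    """Hypergeometric over-representation test for every term hit by the study.

    For a term annotating ``pop_count`` of ``pop_n`` population genes, the
    raw p-value is the upper-tail probability of drawing ≥ ``study_count``
    annotated genes in ``study_n`` draws without replacement.  BH adjustment
    runs over all tested terms (study_count ≥ 1) in the namespace.
    """
    if not study:
        raise ValueError("empty study set")
    pop_genes = set(annotations.gene_to_terms)
    study_in = study & pop_genes
    if len(study_in) < len(study):
        logger.warning(
            "dropped %d study gene(s) absent from the annotated population",
            len(study) - len(study_in),
        )
    if not study_in:
        raise ValueError("no study genes are in the annotated population")
    study_n = len(study_in)
    pop_n = annotations.population_size

    ns_terms = set(dag.terms_in_namespace(namespace))
    pop_count: dict[str, int] = {}
    study_count: dict[str, int] = {}
    for gene, terms in annotations.gene_to_terms.items():
        in_study = gene in study_in
        for term in terms:
            if term not in ns_terms:
                continue
            pop_count[term] = pop_count.get(term, 0) + 1
            if in_study:
                study_count[term] = study_count.get(term, 0) + 1

    rows = []
    for term, k in study_count.items():
        K = pop_count[term]
        p_raw = float(hypergeom.sf(k - 1, pop_n, K, study_n))
        rows.append(
            {
                "go_id": term,
                "term": dag.names.get(term, term),
                "study_count": k,
                "study_n": study_n,
                "pop_count": K,
                "pop_n": pop_n,
                "depth": term_depth(dag, term),
                "level": term_level(dag, term),
                "p_raw": min(p_raw, 1.0),
            }
        )
    result = pd.DataFrame(
        rows,
        columns=[
            "go_id", "term", "study_count", "study_n", "pop_count", "pop_n",
            "depth", "level", "p_raw",
        ],
    )
    if len(result):
        result["p_fdr"] = multipletests(result["p_raw"], method="fdr_bh")[1]
        result = result.sort_values(["p_fdr", "go_id"], kind="mergesort").reset_index(drop=True)
    else:
        result["p_fdr"] = []
    return result


def filter_significant(
    results: pd.DataFrame, max_fdr: float = 0.05, max_depth: int = 3
) -> pd.DataFrame:
    """Keep terms with FDR strictly below ``max_fdr`` and depth ≤ ``max_depth``."""
    keep = (results["p_fdr"] < max_fdr) & (results["depth"] <= max_depth)
    return results[keep].reset_index(drop=True)
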