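"""Hypergeometric GO over-representation with true-path propagation and masking.

Annotations are first closed under the true-path rule (a gene annotated to a
term is annotated to all its ``is_a`` ancestors), then each term annotating
at least ``min_term_size`` universe genes is tested with the upper-tail
hypergeometric probability

    p = P(X >= k),  X ~ Hypergeom(N, K, n)

where N is the universe size, K the universe genes carrying the term, n the
study-set size and k the study-set genes carrying the term. BH q-values are
computed over the tested terms and significance tiers assigned at q < 0.05
("*") and q < 0.01 ("**"). Development-GO masking mirrors the gene-level
procedure: terms enriched in both between-genotype control-light DE sets are
removed from each within-genotype term list.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import networkx as nx
import obonet
import pandas as pd
from scipy.stats import hypergeom

from .diffexpr import bh_adjust
from .expression_qc import ValidationError


class DagError(ValueError):
    pass


class GODag:
    """Minimal GO DAG: term ids, names, and ``is_a`` parents."""

    def __init__(self, graph: nx.MultiDiGraph):
        undefined = [n for n, d in graph.nodes(data=True) if "name" not in d]
        if undefined:
            raise DagError(f"is_a references undefined terms: {sorted(undefined)}")
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise DagError(f"cycle in is_a hierarchy: {cycle}")
        self.graph = graph

    @classmethod
    def from_dict(cls, dag: Mapping[str, Mapping]) -> "GODag":
        g = nx.MultiDiGraph()
        for term, info in dag.items():
            g.add_node(term, name=info.get("name", term))
        for term, info in dag.items():
            for parent in info.get("parents", ()):
                g.add_edge(term, parent)
        return cls(g)

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def name(self, term: str) -> str:
        return self.graph.nodes[term].get("name", term)

    def parents(self, term: str) -> set[str]:
        return set(self.graph.successors(term))

    def children(self, term: str) -> set[str]:
        return set(self.graph.predecessors(term))

    def ancestors(self, term: str) -> set[str]:
        """All is_a ancestors of ``term`` (term itself excluded)."""
        if term not in self.graph:
            raise ValidationError(f"unknown GO term {term!r}")
        return set(nx.descendants(self.graph, term))

    def roots(self) -> set[str]:
        return {n for n in self.graph if self.graph.out_degree(n) == 0}


def parse_obo_lite(path) -> GODag:
    """Parse an OBO file consuming only id/name/is_a; obsolete stanzas skipped."""
    graph = obonet.read_obo(path, ignore_obsolete=True)
    return GODag(graph)


def propagate_annotations(
    gene2terms: Mapping[str, Iterable[str]], dag: GODag
) -> dict[str, set[str]]:
    """Close every gene's term set under is_a ancestors (true-path rule)."""
    closure_cache: dict[str, set[str]] = {}
    out: dict[str, set[str]] = {}
    for gene, terms in gene2terms.items():
        closed: set[str] = set()
        for term in terms:
            if term not in closure_cache:
                closure_cache[term] = {term} | dag.ancestors(term)
            closed |= closure_cache[term]
        out[gene] = closed
    return out


def enrich(
    study: set[str],
    universe: set[str],
    annotations: Mapping[str, set[str]],
    dag: GODag | None = None,
    min_term_size: int = 3,
    q_cutoffs: tuple[float, float] = (0.05, 0.01),
) -> pd.DataFrame:
    """Hypergeometric over-representation of every sufficiently annotated term.

    ``annotations`` must already be propagated. Terms annotating fewer than
    ``min_term_size`` universe genes are not tested.
    """
    if not study <= universe:
        raise ValidationError("study set must be a subset of the universe")
    n, big_n = len(study), len(universe)
    term_universe: dict[str, int] = {}
    term_study: dict[str, int] = {}
    for gene in universe:
        for term in annotations.get(gene, ()):
            term_universe[term] = term_universe.get(term, 0) + 1
            if gene in study:
                term_study[term] = term_study.get(term, 0) + 1
    rows = []
    for term in sorted(term_universe):
        big_k = term_universe[term]
        if big_k < min_term_size:
            continue
        k = term_study.get(term, 0)
        p = float(hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append(
            {
                "term_id": term,
                "name": dag.name(term) if dag is not None else term,
                "k": k,
                "K": big_k,
                "n": n,
                "N": big_n,
                "p_value": min(p, 1.0),
            }
        )
    result = pd.DataFrame(
        rows, columns=["term_id", "name", "k", "K", "n", "N", "p_value"]
    )
    if len(result):
        result["q_value"] = bh_adjust(result["p_value"].to_numpy())
        relaxed, strict = max(q_cutoffs), min(q_cutoffs)
        result["tier"] = [
            "**" if q < strict else ("*" if q < relaxed else "")
            for q in result["q_value"]
        ]
        result = result.sort_values(["p_value", "term_id"], kind="stable").reset_index(drop=True)
    else:
        result["q_value"] = pd.Series(dtype=float)
        result["tier"] = pd.Series(dtype=str)
    return result


def significant_terms(result: pd.DataFrame, q_cutoff: float) -> set[str]:
    if not len(result):
        return set()
    return set(result.loc[result["q_value"] < q_cutoff, "term_id"])


def development_go_set(terms_a: set[str], terms_b: set[str]) -> set[str]:
    """Terms enriched in both between-genotype control-light comparisons."""
    return set(terms_a) & set(terms_b)


def mask_go(
    within_terms: set[str], terms_a: set[str], terms_b: set[str]
) -> set[str]:
    """Remove development-attributed GO terms from a within-genotype term set."""
    return set(within_terms) - development_go_set(terms_a, terms_b)


def load_go_map(path) -> dict[str, set[str]]:
    """Read a gene TAB comma-separated-terms map."""
    gene2go: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            gene = parts[0]
            terms = parts[1].split(",") if len(parts) > 1 and parts[1] else []
            gene2go[gene] = {t for t in terms if t}
    return gene2go
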