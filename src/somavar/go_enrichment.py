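"""GO-term enrichment: OBO DAG, true-path propagation, hypergeometric test.

The classic per-term one-sided hypergeometric (Fisher) test is used;
multiple-testing correction is Benjamini-Hochberg by default with
Bonferroni available. Namespaces are tested separately.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping

import networkx as nx
from scipy.stats import hypergeom

from .variant_io import _open_text

log = logging.getLogger(__name__)

__all__ = [
    "GODag",
    "EnrichmentRow",
    "read_obo",
    "read_annotations",
    "propagate_annotations",
    "expected_count",
    "bh_adjust",
    "bonferroni_adjust",
    "enrich_terms",
]

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")


class GODag:
    """Ontology terms plus is_a edges (child -> parent), acyclic."""

    def __init__(self) -> None:
        self.graph = nx.DiGraph()
        self.names: dict[str, str] = {}
        self.namespaces: dict[str, str] = {}

    def add_term(self, term_id: str, name: str = "", namespace: str = "") -> None:
        self.graph.add_node(term_id)
        self.names[term_id] = name
        self.namespaces[term_id] = namespace

    def add_is_a(self, child: str, parent: str) -> None:
        self.graph.add_edge(child, parent)

    def validate(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("ontology graph contains a cycle")

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.graph

    def ancestors(self, term_id: str) -> set[str]:
        """All is_a ancestors of a term (excluding the term itself)."""
        return set(nx.descendants(self.graph, term_id))

    def terms(self) -> list[str]:
        return sorted(self.graph.nodes)


def read_obo(path) -> GODag:
    """Parse an OBO 1.2 ontology file into a GODag (is_a edges only)."""
    dag = GODag()
    edges: list[tuple[str, str]] = []
    current: dict | None = None

    def flush(stanza: dict | None) -> None:
        if not stanza or stanza.get("obsolete"):
            return
        tid = stanza.get("id")
        if tid is None:
            return
        dag.add_term(tid, stanza.get("name", ""), stanza.get("namespace", ""))
        for parent in stanza.get("is_a", []):
            edges.append((tid, parent))

    with _open_text(path) as fh:
        in_term = False
        for raw in fh:
            line = raw.strip()
            if line.startswith("["):
                flush(current if in_term else None)
                in_term = line == "[Term]"
                current = {} if in_term else None
                continue
            if not in_term or current is None or not line:
                continue
            if line.startswith("id:"):
                current["id"] = line[3:].strip()
            elif line.startswith("name:"):
                current["name"] = line[5:].strip()
            elif line.startswith("namespace:"):
                current["namespace"] = line[10:].strip()
            elif line.startswith("is_a:"):
                current.setdefault("is_a", []).append(
                    line[5:].strip().split("!")[0].strip())
            elif line.startswith("is_obsolete:") and "true" in line:
                current["obsolete"] = True
        flush(current if in_term else None)
    for child, parent in edges:
        if parent in dag:
            dag.add_is_a(child, parent)
        else:
            log.warning("is_a parent %s not defined; edge skipped", parent)
    dag.validate()
    return dag


def read_annotations(path) -> dict[str, set[str]]:
    """Read gene -> term annotations from 2-column TSV or GAF-like rows.

    Rows with >= 5 tab-separated fields are treated as GAF (gene from
    column 2, term from column 5); comment lines start with '!' or '#'.
    """
    ann: dict[str, set[str]] = {}
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("!", "#")):
                continue
            fields = line.split("\t")
            if len(fields) >= 5:
                gene, term = fields[1], fields[4]
            elif len(fields) >= 2:
                gene, term = fields[0], fields[1]
            else:
                continue
            ann.setdefault(gene, set()).add(term)
    return ann


def propagate_annotations(direct: Mapping[str, set[str]],
                          dag: GODag) -> dict[str, set[str]]:
    """True-path propagation: each gene inherits all ancestors of its terms."""
    cache: dict[str, set[str]] = {}
    out: dict[str, set[str]] = {}
    for gene, terms in direct.items():
        full: set[str] = set()
        for t in terms:
            if t not in dag:
                log.warning("annotation term %s not in ontology; skipped", t)
                continue
            if t not in cache:
                cache[t] = dag.ancestors(t) | {t}
            full |= cache[t]
        out[gene] = full
    return out


def expected_count(annotated: int, study_size: int, universe_size: int) -> float:
    """annotated * study_size / universe_size, rounded half-up to 2 dp."""
    if universe_size <= 0:
        raise ValueError("universe_size must be positive")
    if annotated > universe_size:
        raise ValueError("annotated cannot exceed universe_size")
    value = Decimal(annotated) * Decimal(study_size) / Decimal(universe_size)
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def bh_adjust(p_values: Iterable[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    ps = list(p_values)
    for p in ps:
        if not (0 <= p <= 1):
            raise ValueError(f"p-value out of [0, 1]: {p}")
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        i = order[rank_from_top]
        value = min(1.0, ps[i] * m / (rank_from_top + 1))
        running_min = min(running_min, value)
        adjusted[i] = running_min
    return adjusted


def bonferroni_adjust(p_values: Iterable[float]) -> list[float]:
    ps = list(p_values)
    for p in ps:
        if not (0 <= p <= 1):
            raise ValueError(f"p-value out of [0, 1]: {p}")
    return [min(1.0, p * len(ps)) for p in ps]


@dataclass(frozen=True)
class EnrichmentRow:
    term_id: str
    name: str
    namespace: str
    annotated: int
    significant: int
    expected: float
    p_value: float
    corrected_p: float


def enrich_terms(study: set[str], universe: set[str],
                 annotations: Mapping[str, set[str]], dag: GODag,
                 namespace: str | None = None,
                 correction: str = "bh") -> list[EnrichmentRow]:
    """Per-term upper-tail hypergeometric enrichment of ``study`` genes.

    ``annotations`` must already be propagated. Only genes in ``universe``
    contribute to counts; rows are sorted by raw p ascending.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    if not study <= universe:
        raise ValueError("study genes must be a subset of the universe")
    term_genes: dict[str, set[str]] = {}
    for gene in universe:
        for t in annotations.get(gene, ()):
            if namespace and dag.namespaces.get(t) != namespace:
                continue
            term_genes.setdefault(t, set()).add(gene)
    n_universe = len(universe)
    n_study = len(study)
    rows = []
    for term, genes in term_genes.items():
        annotated = len(genes)
        significant = len(genes & study)
        p = float(hypergeom.sf(significant - 1, n_universe, annotated, n_study))
        rows.append((term, annotated, significant, min(1.0, p)))
    rows.sort(key=lambda r: (r[3], r[0]))
    raw_ps = [r[3] for r in rows]
    if correction == "bh":
        corrected = bh_adjust(raw_ps)
    elif correction == "bonferroni":
        corrected = bonferroni_adjust(raw_ps)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return [
        EnrichmentRow(
            term_id=term,
            name=dag.names.get(term, ""),
            namespace=dag.namespaces.get(term, ""),
            annotated=annotated,
            significant=significant,
            expected=expected_count(annotated, n_study, n_universe),
            p_value=p,
            corrected_p=cp,
        )
        for (term, annotated, significant, p), cp in zip(rows, corrected)
    ]


def enrichment_tsv(rows: Iterable[EnrichmentRow]) -> str:
    lines = ["GO.ID\tTerm\tNamespace\tAnnotated\tSignificant\tExpected\tP-value\tCorrected P"]
    for r in rows:
        lines.append(f"{r.term_id}\t{r.name}\t{r.namespace}\t{r.annotated}\t"
                     f"{r.significant}\t{r.expected:.2f}\t{r.p_value:.3g}\t"
                     f"{r.corrected_p:.3g}")
    return "\n".join(lines) + "\n"
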