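"""Ontology handling and information-content based semantic similarity.

A medical ontology (MeSH-like) is modelled as a DAG of terms with
child -> parent edges and a designated set of *top-level headings*
(disease areas).  An annotation corpus assigns each term a direct usage
count; a term's probability is the cumulative count of the term and all
its descendants divided by the corpus total, and its information content
is ``IC(t) = -ln p(t)``.

Two classic pairwise similarities are derived from IC:

* Resnik: IC of the most informative common ancestor (MICA);
* Lin: ``2 * IC(MICA) / (IC(a) + IC(b))``.

The combined score averages Lin with a rescaled Resnik: Resnik values
are multiplied by the zero-intercept least-squares slope of Lin on
Resnik (capped at 1) so that both components share the [0, 1] range
before averaging.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd


class OntologyError(ValueError):
    """Structural problem with an ontology or similarity input."""


@dataclass(frozen=True)
class AnnotationCorpus:
    """Direct annotation counts per term; drives information content."""

    counts: Mapping[str, int]

    def __post_init__(self):
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("annotation counts must be non-negative")

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))

    @classmethod
    def from_tsv(cls, path) -> "AnnotationCorpus":
        df = pd.read_csv(path, sep="\t", dtype={"term": str, "count": int})
        if list(df.columns) != ["term", "count"]:
            raise OntologyError(f"corpus file {path} must have columns term, count")
        return cls(counts=dict(zip(df["term"], df["count"])))

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"term": list(self.counts), "count": list(self.counts.values())}
        ).to_csv(path, sep="\t", index=False)


class Ontology:
    """Validated DAG of terms with child->parent edges.

    Parameters
    ----------
    edges
        Iterable of ``(child, parent)`` pairs; duplicates are collapsed.
    top_level
        Terms designated as top-level headings (disease areas).
    """

    def __init__(self, edges: Iterable[tuple[str, str]], top_level: Iterable[str] = ()):
        g = nx.DiGraph()
        for child, parent in edges:
            g.add_edge(str(child), str(parent))
        if g.number_of_nodes() == 0:
            raise OntologyError("ontology has no terms")
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise OntologyError(
                f"ontology contains a cycle involving term {cycle[0][0]!r}"
            )
        self.graph = g
        self.terms: list[str] = sorted(g.nodes)
        self._index = {t: i for i, t in enumerate(self.terms)}
        self.roots = frozenset(t for t in self.terms if g.out_degree(t) == 0)
        top = frozenset(str(t) for t in top_level)
        unknown = top - set(self.terms)
        if unknown:
            raise OntologyError(f"unknown top-level terms: {sorted(unknown)}")
        self.top_level = top
        self._anc: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term: str) -> bool:
        return term in self._index

    @property
    def ancestor_matrix(self) -> np.ndarray:
        """Boolean (n, n) matrix; entry [i, j] true iff j is an
        ancestor-or-self of i.  Built once via topological accumulation."""
        if self._anc is None:
            n = len(self.terms)
            anc = np.zeros((n, n), dtype=bool)
            # edges point child->parent, so reversed topological order of
            # the graph visits parents before their children; a node's
            # ancestor set is itself plus the union of its parents' sets
            for t in reversed(list(nx.topological_sort(self.graph))):
                i = self._index[t]
                for _, parent in self.graph.out_edges(t):
                    anc[i] |= anc[self._index[parent]]
                anc[i, i] = True
            self._anc = anc
        return self._anc

    def index(self, term: str) -> int:
        try:
            return self._index[term]
        except KeyError:
            raise OntologyError(f"unknown term {term!r}") from None

    def ancestors(self, term: str, include_self: bool = True) -> frozenset[str]:
        row = self.ancestor_matrix[self.index(term)]
        out = {self.terms[j] for j in np.flatnonzero(row)}
        if not include_self:
            out.discard(term)
        return frozenset(out)

    def top_level_headings(self, term: str) -> frozenset[str]:
        """All designated top-level ancestors of ``term`` (self counts)."""
        return self.ancestors(term) & self.top_level

    @classmethod
    def from_tsv(cls, path, top_level_ids: Iterable[str] = ()) -> "Ontology":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if list(df.columns) != ["child", "parent"]:
            raise OntologyError(f"ontology file {path} must have columns child, parent")
        if df.empty:
            raise OntologyError(f"ontology file {path} is empty")
        return cls(edges=df.itertuples(index=False), top_level=top_level_ids)

    def to_tsv(self, path) -> None:
        rows = sorted(self.graph.edges)
        pd.DataFrame(rows, columns=["child", "parent"]).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_obo(cls, path, top_level_ids: Iterable[str] = ()) -> "Ontology":
        """Convenience ingestion of an OBO file via obonet (``is_a`` edges)."""
        import obonet

        g = obonet.read_obo(path)
        edges = [
            (child, parent)
            for child, parent, key in g.edges(keys=True)
            if key == "is_a"
        ]
        return cls(edges=edges, top_level=top_level_ids)


def load_ontology(edge_tsv, top_level_ids: Iterable[str] = ()) -> Ontology:
    """Load a ``child<TAB>parent`` edge table into a validated Ontology."""
    return Ontology.from_tsv(edge_tsv, top_level_ids)


def information_content(
    onto: Ontology, corpus: AnnotationCorpus, smooth: bool = True
) -> dict[str, float]:
    """IC(t) = -ln(cumulative count of t and descendants / corpus total).

    With ``smooth`` (default), Laplace add-one smoothing is applied to the
    direct count of every ontology term, so every term has a defined IC.
    Without smoothing, terms with zero cumulative count are omitted from
    the result (their IC is undefined).
    """
    n = len(onto)
    direct = np.zeros(n, dtype=float)
    for term, count in corpus.counts.items():
        if term in onto:
            direct[onto.index(term)] += count
    if smooth:
        direct += 1.0
    total = direct.sum()
    if total <= 0:
        raise ValueError("annotation corpus total must be positive")
    # cumulative[j] = sum of direct counts over descendants-or-self of j
    cumulative = onto.ancestor_matrix.T.astype(float) @ direct
    ic: dict[str, float] = {}
    for j, term in enumerate(onto.terms):
        if cumulative[j] > 0:
            ic[term] = -math.log(cumulative[j] / total)
    return ic


def _ic_vector(onto: Ontology, ic: Mapping[str, float]) -> np.ndarray:
    v = np.full(len(onto), np.nan)
    for t, val in ic.items():
        if t in onto:
            v[onto.index(t)] = val
    return v


def resnik(a: str, b: str, ic: Mapping[str, float], onto: Ontology) -> float:
    """IC of the most informative common ancestor (a term is its own
    ancestor); 0 when the terms share no ancestor."""
    if a not in ic or b not in ic:
        raise ValueError(f"IC undefined for {a!r} or {b!r}")
    common = onto.ancestor_matrix[onto.index(a)] & onto.ancestor_matrix[onto.index(b)]
    best = 0.0
    for j in np.flatnonzero(common):
        val = ic.get(onto.terms[j])
        if val is not None and val > best:
            best = val
    return best


def lin(a: str, b: str, ic: Mapping[str, float], onto: Ontology) -> float:
    """Lin similarity 2*IC(MICA)/(IC(a)+IC(b)), clamped to [0, 1].

    The 0/0 case is 1 for a root paired with itself and 0 otherwise.
    """
    mica = resnik(a, b, ic, onto)
    denom = ic[a] + ic[b]
    if denom == 0:
        return 1.0 if (a == b and a in onto.roots) else 0.0
    return min(1.0, max(0.0, 2.0 * mica / denom))


@dataclass
class SimilarityMatrix:
    """Symmetric combined similarity over a fixed term list, in [0, 1]."""

    terms: list[str]
    values: np.ndarray
    multiplier: float = float("nan")
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.terms)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix shape does not match term list")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("similarity matrix must be symmetric")
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("similarity values must lie in [0, 1]")
        self.index = {t: i for i, t in enumerate(self.terms)}

    def __contains__(self, term: str) -> bool:
        return term in self.index

    def sim(self, a: str, b: str) -> float:
        return float(self.values[self.index[a], self.index[b]])

    def submatrix(self, rows: Iterable[str], cols: Iterable[str]) -> np.ndarray:
        ri = [self.index[t] for t in rows]
        ci = [self.index[t] for t in cols]
        return self.values[np.ix_(ri, ci)]

    def to_tsv(self, path) -> None:
        """Write upper triangle (including diagonal) plus the multiplier."""
        iu, ju = np.triu_indices(len(self.terms))
        df = pd.DataFrame(
            {
                "term_a": [self.terms[i] for i in iu],
                "term_b": [self.terms[j] for j in ju],
                "sim": np.round(self.values[iu, ju], 10),
            }
        )
        with open(path, "w") as fh:
            fh.write(f"# resnik_multiplier\t{self.multiplier:.10g}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SimilarityMatrix":
        multiplier = float("nan")
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("# resnik_multiplier"):
                multiplier = float(first.rsplit("\t", 1)[1])
            else:
                fh.seek(0)
            df = pd.read_csv(fh, sep="\t", dtype={"term_a": str, "term_b": str})
        terms = sorted(set(df["term_a"]) | set(df["term_b"]))
        idx = {t: i for i, t in enumerate(terms)}
        vals = np.zeros((len(terms), len(terms)))
        ia = df["term_a"].map(idx).to_numpy()
        ib = df["term_b"].map(idx).to_numpy()
        vals[ia, ib] = df["sim"].to_numpy()
        vals[ib, ia] = df["sim"].to_numpy()
        return cls(terms=terms, values=vals, multiplier=multiplier)


def _pairwise_lin_resnik(onto: Ontology, ic: Mapping[str, float]):
    """Dense Lin and Resnik matrices over the ontology's term order.

    Terms without defined IC get NaN rows/columns (excluded downstream).
    """
    n = len(onto)
    icv = _ic_vector(onto, ic)
    anc = onto.ancestor_matrix
    ic_row = np.where(np.isnan(icv), -np.inf, icv)
    mica = np.zeros((n, n))
    for i in range(n):
        # common ancestors of i with every other term, best IC among them
        common = anc & anc[i]
        masked = np.where(common, ic_row[None, :], -np.inf)
        best = masked.max(axis=1)
        mica[i] = np.where(np.isfinite(best), np.maximum(best, 0.0), 0.0)
    res = mica
    denom = icv[:, None] + icv[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        lin_m = np.where(denom > 0, 2.0 * res / denom, 0.0)
    lin_m = np.clip(lin_m, 0.0, 1.0)
    # 0/0 self-pair convention: roots get Lin 1 with themselves
    for r in onto.roots:
        i = onto.index(r)
        if icv[i] == 0:
            lin_m[i, i] = 1.0
    undef = np.isnan(icv)
    lin_m[undef, :] = np.nan
    lin_m[:, undef] = np.nan
    res[undef, :] = np.nan
    res[:, undef] = np.nan
    return lin_m, res


def combine_similarities(
    lin_matrix: np.ndarray, resnik_matrix: np.ndarray, terms: list[str]
) -> SimilarityMatrix:
    """Average Lin with multiplier-rescaled Resnik into the combined score.

    Both scores are clamped at a minimum of 0; the multiplier m is the
    zero-intercept least-squares slope of Lin on Resnik over all term
    pairs (upper triangle, diagonal included); rescaled Resnik is capped
    at 1; the combined score is the mean of the two components.
    """
    lin_m = np.clip(np.asarray(lin_matrix, dtype=float), 0.0, None)
    res_m = np.clip(np.asarray(resnik_matrix, dtype=float), 0.0, None)
    iu, ju = np.triu_indices(len(terms))
    lv, rv = lin_m[iu, ju], res_m[iu, ju]
    keep = ~(np.isnan(lv) | np.isnan(rv))
    lv, rv = lv[keep], rv[keep]
    denom = float(np.sum(rv * rv))
    if denom == 0:
        raise OntologyError(
            "all Resnik similarities are 0; enrich the annotation corpus "
            "so terms have non-zero information content"
        )
    m = float(np.sum(lv * rv) / denom)
    combined = 0.5 * (lin_m + np.minimum(1.0, m * res_m))
    combined = np.clip(np.nan_to_num(combined, nan=0.0), 0.0, 1.0)
    combined = 0.5 * (combined + combined.T)
    return SimilarityMatrix(terms=list(terms), values=combined, multiplier=m)


def pairwise_similarity(
    onto: Ontology, corpus: AnnotationCorpus, smooth: bool = True
) -> SimilarityMatrix:
    """End-to-end combined Lin-Resnik similarity for all term pairs."""
    ic = information_content(onto, corpus, smooth=smooth)
    lin_m, res_m = _pairwise_lin_resnik(onto, ic)
    return combine_similarities(lin_m, res_m, onto.terms)
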