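"""Hypergeometric term enrichment of differentially expressed gene sets.

For a term annotating K of the N annotated background genes, with k hits
among the n annotated DE genes, the enrichment p-value is the upper tail

    p = sum_{j >= k} C(K, j) * C(N-K, n-j) / C(N, n),

i.e. the probability of drawing at least k term members when sampling n
genes without replacement from the background.  The background is the
annotated portion of the reference transcriptome: genes without any term
cannot contribute to a term count and are excluded from both N and n.

Multiple testing is corrected within each annotation namespace (each
ontology category or the pathway set) separately; Benjamini-Hochberg by
default, Bonferroni optionally.  A term is enriched when its corrected
p-value is at or below alpha (default 0.05).  Supplied annotations are
tested as-is: no ancestor-term propagation is performed.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom

from .dgestat import bh_fdr

DEFAULT_NAMESPACE = "default"


@dataclass
class AnnotationMap:
    """gene_id -> set of term ids, plus a namespace label per term."""

    gene_terms: dict[str, set[str]] = field(default_factory=dict)
    term_namespace: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, terms in self.gene_terms.items():
            if not terms:
                raise ValueError(f"annotated gene {gene!r} has no terms")
            for t in terms:
                if not t:
                    raise ValueError("term ids must be non-empty")
                self.term_namespace.setdefault(t, DEFAULT_NAMESPACE)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AnnotationMap":
        """Load (gene_id, term_id[, namespace]) rows; a header is allowed."""
        gene_terms: dict[str, set[str]] = defaultdict(set)
        term_ns: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if not parts or not parts[0] or parts[0] == "gene_id":
                    continue
                gene, term = parts[0], parts[1]
                gene_terms[gene].add(term)
                term_ns[term] = parts[2] if len(parts) > 2 and parts[2] else DEFAULT_NAMESPACE
        return cls(dict(gene_terms), term_ns)

    @property
    def genes(self) -> set[str]:
        return set(self.gene_terms)


def hypergeom_enrichment(
    de_genes: Iterable[str],
    background_genes: Iterable[str],
    annotation: AnnotationMap,
    alpha: float = 0.05,
    correction: str = "bh",
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a DE gene set.

    Only terms observed in the DE set (k >= 1) are tested.  Returns one
    row per term: term_id, namespace, k, n, K, N, p_value, corrected_p,
    enriched — sorted by namespace then corrected_p.  Results do not
    depend on the order of the input gene collections.
    """
    de = set(de_genes)
    background = set(background_genes)
    if not de <= background:
        extra = sorted(de - background)[:5]
        raise ValueError(f"DE genes not in background: {extra}")
    if not annotation.gene_terms:
        raise ValueError("empty annotation map")

    annotated_bg = background & annotation.genes
    annotated_de = de & annotation.genes
    if not annotated_de:
        raise ValueError("no annotated DE genes to test")
    n_bg = len(annotated_bg)
    n_de = len(annotated_de)

    term_bg: dict[str, int] = defaultdict(int)
    term_de: dict[str, int] = defaultdict(int)
    for gene in annotated_bg:
        for term in annotation.gene_terms[gene]:
            term_bg[term] += 1
            if gene in annotated_de:
                term_de[term] += 1

    rows = []
    for term, k in sorted(term_de.items()):
        if k < 1:
            continue
        K = term_bg[term]
        p = float(hypergeom.sf(k - 1, n_bg, K, n_de))
        rows.append(
            (term, annotation.term_namespace.get(term, DEFAULT_NAMESPACE),
             k, n_de, K, n_bg, min(max(p, 5e-324), 1.0))
        )
    df = pd.DataFrame(
        rows, columns=["term_id", "namespace", "k", "n", "K", "N", "p_value"]
    )
    if df.empty:
        df["corrected_p"] = []
        df["enriched"] = []
        return df

    corrected = pd.Series(index=df.index, dtype=float)
    for ns, grp in df.groupby("namespace"):
        if correction == "bh":
            corrected.loc[grp.index] = bh_fdr(grp["p_value"].to_numpy())
        elif correction == "bonferroni":
            corrected.loc[grp.index] = (grp["p_value"] * len(grp)).clip(upper=1.0)
        else:
            raise ValueError(f"unknown correction {correction!r}")
    df["corrected_p"] = corrected
    df["enriched"] = df["corrected_p"] <= alpha
    return df.sort_values(["namespace", "corrected_p", "term_id"]).reset_index(drop=True)
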