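"""Tag-to-gene mapping, TPM quantification, and library-level summaries.

Clean tags are matched against the reference tag index in two tiers: exact
hits first; a tag with no exact hit is compared at Hamming distance 1 (a
single substitution anywhere in the 21-mer, anchor included — sequencing
error does not respect the restriction site).  At its matching tier a tag
whose hits span more than one gene is discarded as ambiguous; a tag with
no hit at either tier is unknown.  Every clean distinct tag therefore lands
in exactly one of {assigned, ambiguous, unknown}, and distinct/total counts
are conserved.

Per-gene sense and antisense tag counts are normalised to TPM (tags per
million) against the clean-tag total of the library.  The module also
produces the bidirectional-transcription summary, a depth-subsampling
saturation curve, and the histogram of assigned tags by the 3'-rank of
their matched reference CATG site.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from ._util import pct_half_up
from .tagproc import CLEAN, TagLibrary
from .tagref import ANTISENSE, SENSE, TAG_LENGTH, RefTagIndex

EXACT = "exact"
MM1 = "mm1"

_BASES = "ACGT"


@dataclass(frozen=True)
class TagAssignment:
    """One clean distinct tag assigned to a single gene."""

    tag: str
    gene_id: str
    strand: str
    match_type: str
    count: int
    ref_rank: int  # smallest (most 3') rank among matched reference tags


@dataclass
class MappingResult:
    """Partition of a clean library into assigned / ambiguous / unknown tags."""

    library_id: str
    assignments: list[TagAssignment]
    ambiguous: TagLibrary
    unknown: TagLibrary
    ambiguous_gene_hits: set[str] = field(default_factory=set)
    n_genes_total: int = 0

    @property
    def assigned_distinct(self) -> int:
        return len(self.assignments)

    @property
    def assigned_total(self) -> int:
        return sum(a.count for a in self.assignments)


def _neighbors(tag: str) -> Iterator[str]:
    """All 63 Hamming-1 neighbors of a 21-mer."""
    for i, base in enumerate(tag):
        for alt in _BASES:
            if alt != base:
                yield tag[:i] + alt + tag[i + 1 :]


def _resolve(tag: str, hits: list[tuple[str, str, int]], count: int, match_type: str) -> TagAssignment:
    gene = hits[0][0]
    strands = {s for _, s, _ in hits}
    strand = SENSE if SENSE in strands else ANTISENSE
    rank = min(r for _, s, r in hits if s == strand)
    return TagAssignment(tag, gene, strand, match_type, count, rank)


def map_tags(clean: TagLibrary, index: RefTagIndex) -> MappingResult:
    """Two-tier (exact, then 1-mismatch) mapping of a clean library.

    Exact hits take strict priority: a tag with any exact reference hit
    never consults its mismatch neighborhood, so anchor-breaking neighbors
    cannot displace true matches.  Within one gene a sense hit is preferred
    over an antisense hit of the same tag.
    """
    if len(index) == 0:
        raise ValueError("empty reference tag index")
    assignments: list[TagAssignment] = []
    ambiguous: dict[str, int] = {}
    unknown: dict[str, int] = {}
    amb_genes: set[str] = set()
    for tag, count in clean.counts.items():
        hits = index.entries.get(tag)
        match_type = EXACT
        if hits is None:
            match_type = MM1
            hits = []
            for nb in _neighbors(tag):
                hits.extend(index.entries.get(nb, ()))
        if not hits:
            unknown[tag] = count
            continue
        genes = {g for g, _, _ in hits}
        if len(genes) > 1:
            ambiguous[tag] = count
            amb_genes |= genes
            continue
        assignments.append(_resolve(tag, hits, count, match_type))
    return MappingResult(
        library_id=clean.library_id,
        assignments=assignments,
        ambiguous=TagLibrary(clean.library_id + ":ambiguous", ambiguous, CLEAN),
        unknown=TagLibrary(clean.library_id + ":unknown", unknown, CLEAN),
        ambiguous_gene_hits=amb_genes,
        n_genes_total=index.n_genes_total,
    )


@dataclass
class ExpressionTable:
    """Per-gene sense/antisense tag counts and TPM for one library.

    ``data`` is indexed by gene_id with columns sense_count,
    antisense_count, sense_tpm, antisense_tpm.  ``summary`` carries the
    mapping accounting with standard report row names.
    """

    library_id: str
    clean_total: int
    data: pd.DataFrame
    summary: dict

    def gene_counts(self, strand: str = SENSE) -> pd.Series:
        col = "sense_count" if strand == SENSE else "antisense_count"
        return self.data[col]


def expression_table(
    result: MappingResult,
    clean: TagLibrary,
    tpm_denominator: str = "clean",
) -> ExpressionTable:
    """Aggregate assignments into per-gene counts and TPM.

    ``tpm_denominator`` selects the normalisation total: ``"clean"`` (the
    default — all clean tags of the library) or ``"mapped"`` (assigned
    tags only).  Raises on an empty clean library.
    """
    clean_total = clean.tag_total
    if clean_total == 0:
        raise ValueError("clean library has zero tags")
    sense: dict[str, int] = defaultdict(int)
    anti: dict[str, int] = defaultdict(int)
    for a in result.assignments:
        if a.strand == SENSE:
            sense[a.gene_id] += a.count
        else:
            anti[a.gene_id] += a.count
    genes = sorted(set(sense) | set(anti))
    denom = clean_total if tpm_denominator == "clean" else max(result.assigned_total, 1)
    data = pd.DataFrame(
        {
            "sense_count": [sense.get(g, 0) for g in genes],
            "antisense_count": [anti.get(g, 0) for g in genes],
        },
        index=pd.Index(genes, name="gene_id"),
    )
    data["sense_tpm"] = data["sense_count"] / denom * 1e6
    data["antisense_tpm"] = data["antisense_count"] / denom * 1e6

    mapped_d = result.assigned_distinct + result.ambiguous.distinct_total
    mapped_t = result.assigned_total + result.ambiguous.tag_total
    all_mapped_genes = set(genes) | result.ambiguous_gene_hits
    n_total = result.n_genes_total
    cd, ct = clean.distinct_total, clean_total
    summary = {
        "Mapping to Unigene": {
            "distinct": mapped_d, "distinct_pct": pct_half_up(mapped_d, cd),
            "total": mapped_t, "total_pct": pct_half_up(mapped_t, ct),
        },
        "Unknown Tag": {
            "distinct": result.unknown.distinct_total,
            "distinct_pct": pct_half_up(result.unknown.distinct_total, cd),
            "total": result.unknown.tag_total,
            "total_pct": pct_half_up(result.unknown.tag_total, ct),
        },
        "Unambiguous Mapping": {
            "distinct": result.assigned_distinct,
            "distinct_pct": pct_half_up(result.assigned_distinct, cd),
            "total": result.assigned_total,
            "total_pct": pct_half_up(result.assigned_total, ct),
        },
        "All Tag-mapped Genes": {
            "count": len(all_mapped_genes),
            "pct": pct_half_up(len(all_mapped_genes), n_total),
        },
        "Unambiguous Tag-mapped Genes": {
            "count": len(genes),
            "pct": pct_half_up(len(genes), n_total),
        },
        "tpm_denominator": tpm_denominator,
    }
    return ExpressionTable(result.library_id, clean_total, data, summary)


def write_expression(table: ExpressionTable, path) -> None:
    """Write an expression TSV; library id and clean total ride in a comment header."""
    with open(path, "w") as fh:
        fh.write(f"# library_id={table.library_id}\tclean_total={table.clean_total}\n")
        table.data.to_csv(fh, sep="\t")


def read_expression(path) -> ExpressionTable:
    """Read an expression TSV written by :func:`write_expression`."""
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing expression header line")
        meta = dict(
            part.split("=", 1) for part in header.lstrip("#").strip().split("\t")
        )
        data = pd.read_csv(fh, sep="\t", index_col="gene_id")
    return ExpressionTable(
        meta["library_id"], int(meta["clean_total"]), data, summary={}
    )


def antisense_summary(*tables: ExpressionTable) -> pd.DataFrame:
    """Bidirectional-transcription accounting across libraries.

    Per library: counts (and percentages of detectable genes) of genes with
    sense-only, antisense-only and bidirectional signal, plus the global
    sense:antisense total-tag ratio (inf when no antisense tags at all).
    """
    if not tables:
        raise ValueError("at least one expression table required")
    rows = []
    for t in tables:
        s = t.data["sense_count"] > 0
        a = t.data["antisense_count"] > 0
        detectable = int((s | a).sum())
        bidir = int((s & a).sum())
        s_only = int((s & ~a).sum())
        a_only = int((~s & a).sum())
        s_tot = int(t.data["sense_count"].sum())
        a_tot = int(t.data["antisense_count"].sum())
        ratio = float("nan") if s_tot == 0 and a_tot == 0 else (
            float("inf") if a_tot == 0 else s_tot / a_tot
        )
        rows.append(
            (
                t.library_id, detectable, s_only, pct_half_up(s_only, detectable),
                a_only, pct_half_up(a_only, detectable),
                bidir, pct_half_up(bidir, detectable),
                s_tot, a_tot, ratio,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "library_id", "detectable_genes",
            "sense_only", "sense_only_pct",
            "antisense_only", "antisense_only_pct",
            "bidirectional", "bidirectional_pct",
            "sense_total", "antisense_total", "sense_antisense_ratio",
        ],
    )


def saturation_curve(
    clean: TagLibrary, index: RefTagIndex, step: int, seed: int = 0
) -> pd.DataFrame:
    """Gene and distinct-tag discovery as a function of subsampled depth.

    Tags are expanded to unit copies, permuted once with a fixed seed, and
    scanned at cumulative depths step, 2*step, ..., tag_total (the final
    point always covers the full library, so it equals full-library
    mapping).  Returns columns (sampled_tags, genes_identified,
    distinct_tags); both curves are non-decreasing in depth.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    total = clean.tag_total
    if step > total:
        raise ValueError(f"step {step} exceeds library size {total}")
    tags = list(clean.counts)
    counts = np.array([clean.counts[t] for t in tags], dtype=np.int64)
    # gene index per distinct tag: -1 when not assigned to a single gene
    result = map_tags(clean, index)
    gene_ids = {a.tag: a.gene_id for a in result.assignments}
    gene_code = {g: i for i, g in enumerate(sorted(set(gene_ids.values())))}
    tag_gene = np.array([gene_code.get(gene_ids.get(t, ""), -1) for t in tags])

    rng = np.random.default_rng(seed)
    units = np.repeat(np.arange(len(tags)), counts)
    rng.shuffle(units)

    # first-occurrence position of each distinct tag in the permuted stream
    first_pos = np.full(len(tags), total, dtype=np.int64)
    rev = units[::-1]
    first_pos[rev] = total - 1 - np.arange(total)

    depths = list(range(step, total + 1, step))
    if depths[-1] != total:
        depths.append(total)
    depths_arr = np.array(depths)

    order = np.sort(first_pos)
    distinct_at = np.searchsorted(order, depths_arr, side="right")

    assigned = tag_gene >= 0
    if assigned.any():
        gene_first = np.full(len(gene_code), total, dtype=np.int64)
        np.minimum.at(gene_first, tag_gene[assigned], first_pos[assigned])
        gorder = np.sort(gene_first)
        genes_at = np.searchsorted(gorder, depths_arr, side="right")
    else:
        genes_at = np.zeros(len(depths_arr), dtype=np.int64)

    return pd.DataFrame(
        {
            "sampled_tags": depths_arr,
            "genes_identified": genes_at,
            "distinct_tags": distinct_at,
        }
    )


def tag_position_distribution(
    assignments: Iterable[TagAssignment], max_rank: int = 10
) -> pd.Series:
    """Histogram of assigned total tag counts by matched reference 3'-rank.

    Ranks above ``max_rank`` are pooled into a single ``"10+"``-style bin.
    Empty assignments yield an empty series.
    """
    hist: dict[str, int] = defaultdict(int)
    for a in assignments:
        key = str(a.ref_rank) if a.ref_rank <= max_rank else f"{max_rank}+"
        hist[key] += a.count
    if not hist:
        return pd.Series(dtype=np.int64, name="tag_count")

    def _order(k: str) -> int:
        return max_rank + 1 if k.endswith("+") else int(k)

    keys = sorted(hist, key=_order)
    return pd.Series([hist[k] for k in keys], index=keys, name="tag_count")
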