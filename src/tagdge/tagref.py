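"""Reference tag extraction and indexing.

In NlaIII/MmeI tag profiling, every transcript is represented by 21-nt
"CATG+17" tags: NlaIII recognises CATG, and MmeI cleaves 17 bp downstream
of the site, so a tag is the CATG anchor plus the following 17 bases.  To
map sequenced tags back to genes, we pre-compute the catalogue of all such
tags extractable from a reference transcript set, on both strands (tags on
the reverse complement reveal antisense transcription).  A tag sequence
shared by more than one gene is *ambiguous* and is excluded from
quantification downstream.

Coordinates are 0-based half-open internally; the reported ``rank_3prime``
is the 1-based index of the tag's source CATG site counted from the 3' end
of the strand the tag lives on (rank 1 = the 3'-most taggable site, the one
the bead-capture chemistry preferentially observes).
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import pct_half_up, revcomp

TAG_LENGTH = 21
ANCHOR = "CATG"

SENSE = "sense"
ANTISENSE = "antisense"


@dataclass(frozen=True)
class Transcript:
    """A reference gene unit (unigene): id plus 5'->3' sense sequence."""

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("transcript gene_id must be non-empty")
        if not self.sequence:
            raise ValueError(f"transcript {self.gene_id!r} has an empty sequence")


@dataclass(frozen=True)
class RefTag:
    """One CATG-anchored 21-mer extractable from a reference transcript."""

    tag: str
    gene_id: str
    strand: str
    rank_3prime: int

    def __post_init__(self) -> None:
        if len(self.tag) != TAG_LENGTH or not self.tag.startswith(ANCHOR):
            raise ValueError(f"invalid reference tag {self.tag!r}")
        if self.rank_3prime < 1:
            raise ValueError("rank_3prime is 1-based")


def _strand_tags(seq: str) -> list[tuple[str, int]]:
    """All (tag, rank_3prime) on one strand; N-containing tags are skipped.

    Ranks are assigned over taggable sites only (CATG with >=17 following
    bases and no N in the window), counted from the strand's 3' end.
    """
    sites: list[int] = []
    start = seq.find(ANCHOR)
    while start != -1:
        if start + TAG_LENGTH <= len(seq):
            window = seq[start : start + TAG_LENGTH]
            if "N" not in window:
                sites.append(start)
        start = seq.find(ANCHOR, start + 1)
    n = len(sites)
    # 3'-most site (largest offset) gets rank 1
    return [(seq[i : i + TAG_LENGTH], n - k) for k, i in enumerate(sites)]


def extract_ref_tags(transcript: Transcript) -> list[RefTag]:
    """All CATG+17 tags of a transcript, sense and antisense.

    A transcript without any taggable CATG site yields an empty list.
    """
    seq = transcript.sequence.upper()
    out = [
        RefTag(tag, transcript.gene_id, SENSE, rank)
        for tag, rank in _strand_tags(seq)
    ]
    out.extend(
        RefTag(tag, transcript.gene_id, ANTISENSE, rank)
        for tag, rank in _strand_tags(revcomp(seq))
    )
    return out


@dataclass
class RefTagIndex:
    """Lookup from tag sequence to its reference hits.

    ``entries`` maps each distinct tag sequence to the list of
    (gene_id, strand, rank_3prime) occurrences.  Ambiguity is defined at
    the distinct-sequence level over gene ids: a tag hitting one gene on
    both strands, or at several positions, stays unambiguous.
    """

    entries: dict[str, list[tuple[str, str, int]]] = field(default_factory=dict)
    n_genes_total: int = 0

    @property
    def n_ref_tags(self) -> int:
        """Distinct reference tag sequences."""
        return len(self.entries)

    @property
    def n_ref_tag_occurrences(self) -> int:
        return sum(len(v) for v in self.entries.values())

    def genes_of(self, tag: str) -> set[str]:
        return {g for g, _, _ in self.entries.get(tag, ())}

    def is_ambiguous(self, tag: str) -> bool:
        return len(self.genes_of(tag)) > 1

    @property
    def n_unambiguous(self) -> int:
        return sum(1 for hits in self.entries.values() if len({g for g, _, _ in hits}) == 1)

    @property
    def n_genes_with_tags(self) -> int:
        return len({g for hits in self.entries.values() for g, _, _ in hits})

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (tag, gene, strand, rank, len({g for g, _, _ in hits}) > 1)
            for tag, hits in self.entries.items()
            for gene, strand, rank in hits
        ]
        return pd.DataFrame(
            rows, columns=["tag", "gene_id", "strand", "rank_3prime", "ambiguous"]
        )


def build_index(transcripts: Iterable[Transcript]) -> RefTagIndex:
    """Build the reference tag index over a transcript set.

    Raises ``ValueError`` on duplicate gene ids.
    """
    entries: dict[str, list[tuple[str, str, int]]] = defaultdict(list)
    seen: set[str] = set()
    n_total = 0
    for tr in transcripts:
        if tr.gene_id in seen:
            raise ValueError(f"duplicate gene_id {tr.gene_id!r}")
        seen.add(tr.gene_id)
        n_total += 1
        for rt in extract_ref_tags(tr):
            entries[rt.tag].append((rt.gene_id, rt.strand, rt.rank_3prime))
    return RefTagIndex(entries=dict(entries), n_genes_total=n_total)


def summarize_tag_totals(
    n_ref_tags: int,
    n_unambiguous: int,
    n_genes_with_tags: int,
    n_genes_total: int,
) -> dict:
    """Report-style percentages (2 dp, half-up) from index totals.

    An empty index reports 0 percentages with an explanatory note rather
    than dividing by zero.
    """
    summary = {
        "n_ref_tags": n_ref_tags,
        "n_unambiguous": n_unambiguous,
        "pct_unambiguous": pct_half_up(n_unambiguous, n_ref_tags),
        "n_genes_with_tags": n_genes_with_tags,
        "n_genes_total": n_genes_total,
        "pct_genes_with_tags": pct_half_up(n_genes_with_tags, n_genes_total),
    }
    if n_ref_tags == 0:
        summary["note"] = "empty index"
    return summary


def index_stats(index: RefTagIndex) -> dict:
    """Summary totals and percentages for a built index."""
    s = summarize_tag_totals(
        index.n_ref_tags,
        index.n_unambiguous,
        index.n_genes_with_tags,
        index.n_genes_total,
    )
    s["n_ref_tag_occurrences"] = index.n_ref_tag_occurrences
    return s


def read_transcripts_fasta(path: str | Path) -> list[Transcript]:
    """Read transcripts from FASTA; the record id (first token) is the gene id."""
    return [
        Transcript(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_transcripts_fasta(transcripts: Sequence[Transcript], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(t.sequence), id=t.gene_id, description="")
        for t in transcripts
    ]
    SeqIO.write(records, str(path), "fasta")


def write_index(index: RefTagIndex, tsv_path: str | Path, summary_path: str | Path | None = None) -> None:
    """Write the index as TSV (tag, gene_id, strand, rank_3prime, ambiguous) plus a JSON summary."""
    index.to_frame().to_csv(tsv_path, sep="\t", index=False)
    if summary_path is not None:
        Path(summary_path).write_text(json.dumps(index_stats(index), indent=2) + "\n")
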