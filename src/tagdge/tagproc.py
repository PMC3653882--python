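"""Raw tag-library filtering with a full removal ledger.

A raw DGE library is a multiset of sequenced tags.  Before mapping, four
defect classes are removed, each distinct tag being charged to exactly one
category in fixed precedence:

1. ``adaptor``     — the tag contains an adaptor sequence (empty tags, which
                     are adaptor-only reads, fall here too);
2. ``low_quality`` — the tag contains an ambiguous base (N) or any
                     non-A/C/G/T character;
3. ``length``      — the tag is not exactly 21 nt;
4. ``copy_lt_2``   — the tag survives the sequence filters but has copy
                     number 1, the signature of sequencing error.

The :class:`FilterLedger` records, per category, the distinct-tag and
total-tag counts removed, and satisfies exact conservation: raw = clean +
sum(removed) for both distinct and total counts.  Percentages are expressed
against the raw library (2 dp, half-up), as in standard library-accounting
tables; copy-number bins of the clean library re-anchor to the clean totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._util import pct_half_up
from .tagref import TAG_LENGTH

RAW = "raw"
CLEAN = "clean"

#: filter categories in precedence order
CATEGORIES = ("adaptor", "low_quality", "length", "copy_lt_2")

#: report row names for ledger output
ROW_NAMES = {
    "adaptor": "Adaptor Tag",
    "low_quality": "Low Quality Tag",
    "length": "Length!=21 Tag",
    "copy_lt_2": "Tag CopyNum<2",
}

_VALID_BASES = frozenset("ACGT")


@dataclass
class TagLibrary:
    """A tag -> count multiset for one sequencing library."""

    library_id: str
    counts: dict[str, int] = field(default_factory=dict)
    status: str = RAW

    @property
    def distinct_total(self) -> int:
        return len(self.counts)

    @property
    def tag_total(self) -> int:
        return sum(self.counts.values())

    @classmethod
    def from_tsv(cls, path: str | Path, library_id: str | None = None, status: str = RAW) -> "TagLibrary":
        """Load a two-column (tag, count) TSV; a header line 'tag\\tcount' is allowed."""
        counts: dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                tag, _, cnt = line.partition("\t")
                if tag == "tag" and cnt == "count":
                    continue
                counts[tag] = counts.get(tag, 0) + int(cnt)
        return cls(library_id or Path(path).stem, counts, status)

    @classmethod
    def from_reads(cls, reads: Iterable[str], library_id: str, status: str = RAW) -> "TagLibrary":
        """Build from a plain list of tag reads, inferring counts."""
        counts: dict[str, int] = {}
        for r in reads:
            r = r.strip().upper()
            counts[r] = counts.get(r, 0) + 1
        return cls(library_id, counts, status)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("tag\tcount\n")
            for tag in sorted(self.counts):
                fh.write(f"{tag}\t{self.counts[tag]}\n")


@dataclass
class FilterLedger:
    """Category-by-category accounting of one filtering pass.

    ``removed`` maps category -> (distinct, total).  The conservation
    identities raw_distinct - sum(distinct removed) = clean_distinct and
    raw_total - sum(total removed) = clean_total hold exactly.
    """

    raw_distinct: int
    raw_total: int
    removed: dict[str, tuple[int, int]]
    clean_distinct: int
    clean_total: int

    @classmethod
    def from_counts(
        cls,
        raw_distinct: int,
        raw_total: int,
        removed: Mapping[str, tuple[int, int]],
    ) -> "FilterLedger":
        """Derive the clean counts from raw and per-category removal counts."""
        removed = {c: tuple(removed.get(c, (0, 0))) for c in CATEGORIES}
        rd = sum(d for d, _ in removed.values())
        rt = sum(t for _, t in removed.values())
        if rd > raw_distinct or rt > raw_total:
            raise ValueError("removed counts exceed raw library size")
        return cls(raw_distinct, raw_total, removed, raw_distinct - rd, raw_total - rt)

    def check(self) -> None:
        rd = sum(d for d, _ in self.removed.values())
        rt = sum(t for _, t in self.removed.values())
        assert self.raw_distinct - rd == self.clean_distinct
        assert self.raw_total - rt == self.clean_total

    def percentages(self) -> dict[str, tuple[float, float]]:
        """Per-row (distinct %, total %) of the raw library, 2 dp half-up."""
        out = {"Raw Data": (pct_half_up(self.raw_distinct, self.raw_distinct),
                            pct_half_up(self.raw_total, self.raw_total))}
        for cat in CATEGORIES:
            d, t = self.removed[cat]
            out[ROW_NAMES[cat]] = (
                pct_half_up(d, self.raw_distinct),
                pct_half_up(t, self.raw_total),
            )
        out["Clean Tag"] = (
            pct_half_up(self.clean_distinct, self.raw_distinct),
            pct_half_up(self.clean_total, self.raw_total),
        )
        return out

    def to_frame(self) -> pd.DataFrame:
        pct = self.percentages()
        rows = [("Raw Data", self.raw_distinct, pct["Raw Data"][0],
                 self.raw_total, pct["Raw Data"][1])]
        for cat in CATEGORIES:
            d, t = self.removed[cat]
            name = ROW_NAMES[cat]
            rows.append((name, d, pct[name][0], t, pct[name][1]))
        rows.append(("Clean Tag", self.clean_distinct, pct["Clean Tag"][0],
                     self.clean_total, pct["Clean Tag"][1]))
        return pd.DataFrame(
            rows,
            columns=["row", "distinct", "distinct_pct", "total", "total_pct"],
        )


def _classify(tag: str, count: int, adaptor_seqs: Sequence[str]) -> str | None:
    """Assign a tag to its removal category, or None if retained."""
    if not tag or any(a and a in tag for a in adaptor_seqs):
        return "adaptor"
    if not set(tag) <= _VALID_BASES:
        return "low_quality"
    if len(tag) != TAG_LENGTH:
        return "length"
    if count < 2:
        return "copy_lt_2"
    return None


def filter_tags(
    raw: TagLibrary, adaptor_seqs: Sequence[str] = ()
) -> tuple[TagLibrary, FilterLedger]:
    """Filter a raw library into clean 21-nt tags with copy number >= 2.

    Raises ``ValueError`` if the input library is already marked clean
    (re-filtering a clean library is a pipeline wiring error, even though
    the operation itself is idempotent on the counts).
    """
    if raw.status == CLEAN:
        raise ValueError(f"library {raw.library_id!r} is already clean")
    removed = {c: [0, 0] for c in CATEGORIES}
    kept: dict[str, int] = {}
    for tag, count in raw.counts.items():
        cat = _classify(tag.upper(), count, adaptor_seqs)
        if cat is None:
            kept[tag.upper()] = count
        else:
            removed[cat][0] += 1
            removed[cat][1] += count
    ledger = FilterLedger.from_counts(
        raw.distinct_total,
        raw.tag_total,
        {c: (d, t) for c, (d, t) in removed.items()},
    )
    clean = TagLibrary(raw.library_id, kept, CLEAN)
    assert clean.distinct_total == ledger.clean_distinct
    assert clean.tag_total == ledger.clean_total
    return clean, ledger


#: copy-number bin labels and predicates, in report order
COPY_BINS = (
    ("CopyNum>=2", 1),
    ("CopyNum>5", 5),
    ("CopyNum>10", 10),
    ("CopyNum>20", 20),
    ("CopyNum>50", 50),
    ("CopyNum>100", 100),
)


def library_summary(clean: TagLibrary) -> pd.DataFrame:
    """Copy-number distribution of a clean library.

    Each row counts tags with copy number strictly above the threshold
    (the first row, >=2, is the whole clean library) with percentages of
    the clean distinct/total counts.
    """
    cd, ct = clean.distinct_total, clean.tag_total
    rows = []
    for label, thr in COPY_BINS:
        d = sum(1 for c in clean.counts.values() if c > thr)
        t = sum(c for c in clean.counts.values() if c > thr)
        rows.append((label, d, pct_half_up(d, cd), t, pct_half_up(t, ct)))
    return pd.DataFrame(
        rows, columns=["bin", "distinct", "distinct_pct", "total", "total_pct"]
    )
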