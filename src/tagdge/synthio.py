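"""Synthetic transcriptomes and tag libraries with known expression truth.

The generator emulates the anatomy of an NlaIII/MmeI tag-profiling
experiment at desk scale so every downstream stage (filtering, mapping,
TPM, differential calling) can be validated against a known truth:

* random A/C/G/T transcripts at a chosen length range and GC content,
  each guaranteed taggable (a CATG site with >=17 nt downstream is
  implanted when the random sequence lacks one);
* per-gene baseline abundances drawn log-normally (a heavy-tailed
  expression profile, as in real tag libraries where a small fraction of
  genes carries most of the tag mass), with a chosen fraction of genes
  differentially expressed at a fixed log2 fold-change magnitude in the
  treatment libraries;
* per-molecule tag sampling: gene proportional to abundance x 2^lfc,
  then a CATG rank drawn geometrically from the 3' end (the bead-capture
  chemistry observes the 3'-most sites far more often), then strand
  (a configurable antisense fraction), then per-base substitution error;
* filterable noise: tags carrying an ambiguous base (N) and singleton
  random CATG+17 tags of copy number 1, mimicking sequencing error.

All randomness flows from one integer seed.  The transcriptome/truth use
the base stream; each library uses a substream derived from (seed,
library index), so libraries are independent but jointly reproducible.
Total emitted tag count equals ``depth_per_library`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .tagproc import RAW, TagLibrary
from .tagref import ANCHOR, SENSE, TAG_LENGTH, Transcript, extract_ref_tags

_ASCII = np.frombuffer(b"ACGTN", dtype=np.uint8)
_TRUTH_STREAM = 65536  # substream key reserved for truth generation


class EmptyDesignError(ValueError):
    """Raised when a simulation design contains no genes."""


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for one synthetic experiment.

    Defaults describe a desk-scale two-library experiment: 2,000 genes,
    10% differentially expressed at |log2FC| = 2, one million tags per
    library, 0.5% per-base substitution error, with N-containing and
    singleton noise tags at the few-percent level and a moderate
    antisense fraction.
    """

    n_genes: int = 2000
    length_range: tuple[int, int] = (200, 2000)
    gc_content: float = 0.40
    n_libraries: int = 2
    depth_per_library: int = 1_000_000
    de_fraction: float = 0.10
    log2fc_magnitude: float = 2.0
    error_rate: float = 0.005
    n_rate: float = 0.005
    singleton_rate: float = 0.02
    antisense_fraction: float = 0.30
    rank_bias: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gc_content", "de_fraction", "error_rate", "n_rate",
                     "singleton_rate", "antisense_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.rank_bias <= 1.0:
            raise ValueError("rank_bias must be in (0, 1]")
        if self.depth_per_library < 1:
            raise ValueError("depth_per_library must be >= 1")
        lo, hi = self.length_range
        if lo < TAG_LENGTH or hi < lo:
            raise ValueError(f"length_range must satisfy {TAG_LENGTH} <= min <= max")
        if self.n_libraries < 1:
            raise ValueError("n_libraries must be >= 1")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        if "length_range" in raw:
            raw["length_range"] = tuple(raw["length_range"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["length_range"] = list(d["length_range"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


@dataclass
class SimTruth:
    """Per-gene ground truth: baseline weight, per-library log2FC, DE label.

    ``frame`` is indexed by gene_id with columns baseline,
    log2fc_lib0..log2fc_lib{L-1}, de_flag, direction.  Library 0 is the
    control: its fold-change column is identically zero, as are the
    columns of non-DE genes.
    """

    frame: pd.DataFrame

    @property
    def genes(self) -> list[str]:
        return list(self.frame.index)

    @property
    def n_libraries(self) -> int:
        return sum(1 for c in self.frame.columns if c.startswith("log2fc_lib"))

    def baseline(self) -> np.ndarray:
        return self.frame["baseline"].to_numpy()

    def log2fc(self, library_index: int) -> np.ndarray:
        return self.frame[f"log2fc_lib{library_index}"].to_numpy()

    def de_genes(self) -> set[str]:
        return set(self.frame.index[self.frame["de_flag"]])


def generate_truth(config: SimConfig) -> SimTruth:
    """Draw baseline abundances and assign DE genes.

    Baselines are log-normal(0, 1); round(de_fraction * n_genes) genes
    are flagged DE with sign chosen uniformly, and their fold change of
    +-log2fc_magnitude applies to every treatment library (index >= 1).
    """
    if config.n_genes == 0:
        raise EmptyDesignError("empty design: n_genes must be >= 1")
    rng = np.random.default_rng([config.seed, _TRUTH_STREAM])
    g = config.n_genes
    ids = [f"gene_{i+1:05d}" for i in range(g)]
    baseline = rng.lognormal(mean=0.0, sigma=1.0, size=g)
    n_de = int(round(config.de_fraction * g))
    de_idx = rng.choice(g, size=n_de, replace=False)
    up = rng.random(n_de) < 0.5
    lfc = np.zeros(g)
    lfc[de_idx] = np.where(up, config.log2fc_magnitude, -config.log2fc_magnitude)
    de_flag = np.zeros(g, dtype=bool)
    de_flag[de_idx] = True
    direction = np.full(g, "none", dtype=object)
    direction[de_idx] = np.where(up, "up", "down")
    cols = {"baseline": baseline}
    for lib in range(config.n_libraries):
        cols[f"log2fc_lib{lib}"] = lfc if lib >= 1 else np.zeros(g)
    cols["de_flag"] = de_flag
    cols["direction"] = direction
    frame = pd.DataFrame(cols, index=pd.Index(ids, name="gene_id"))
    return SimTruth(frame)


def generate_transcriptome(config: SimConfig) -> list[Transcript]:
    """Random taggable transcripts, deterministic for a fixed seed.

    Every transcript is an A/C/G/T string within ``length_range``; a CATG
    site with a full 17-nt downstream window is implanted wherever the
    random draw produced none, so all genes are observable by tags.
    """
    if config.n_genes == 0:
        raise EmptyDesignError("empty design: n_genes must be >= 1")
    rng = np.random.default_rng(config.seed)
    gc = config.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    lo, hi = config.length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    codes = rng.choice(4, size=int(lengths.sum()), p=probs).astype(np.uint8)
    out: list[Transcript] = []
    offset = 0
    for i, length in enumerate(lengths):
        seq = _ASCII[codes[offset : offset + length]].tobytes().decode()
        offset += int(length)
        # taggable = CATG starting at a position with >= 17 nt downstream
        if ANCHOR not in seq[: length - TAG_LENGTH + len(ANCHOR)]:
            pos = int(rng.integers(0, length - TAG_LENGTH + 1))
            seq = seq[:pos] + ANCHOR + seq[pos + len(ANCHOR) :]
        out.append(Transcript(f"gene_{i+1:05d}", seq))
    return out


def _tag_arrays(transcripts: Sequence[Transcript]):
    """Flat rank-ordered tag matrices per strand with per-gene offsets."""
    sense_rows: list[str] = []
    anti_rows: list[str] = []
    sense_off, sense_n, anti_off, anti_n = [], [], [], []
    for tr in transcripts:
        tags = extract_ref_tags(tr)
        s = sorted((t for t in tags if t.strand == SENSE), key=lambda t: t.rank_3prime)
        a = sorted((t for t in tags if t.strand != SENSE), key=lambda t: t.rank_3prime)
        if not s:
            raise ValueError(f"transcript {tr.gene_id!r} has no sense reference tag")
        sense_off.append(len(sense_rows))
        sense_n.append(len(s))
        sense_rows.extend(t.tag for t in s)
        anti_off.append(len(anti_rows))
        anti_n.append(len(a))
        anti_rows.extend(t.tag for t in a)

    def encode(rows: list[str]) -> np.ndarray:
        if not rows:
            return np.zeros((0, TAG_LENGTH), dtype=np.uint8)
        buf = np.frombuffer("".join(rows).encode(), dtype=np.uint8)
        lut = np.zeros(256, dtype=np.uint8)
        lut[np.frombuffer(b"ACGT", dtype=np.uint8)] = np.arange(4)
        return lut[buf].reshape(len(rows), TAG_LENGTH)

    return (
        encode(sense_rows), np.array(sense_off), np.array(sense_n),
        encode(anti_rows), np.array(anti_off), np.array(anti_n),
    )


def _truncated_geometric(rng: np.random.Generator, r: np.ndarray, bias: float) -> np.ndarray:
    """Ranks 1..r with P(j) proportional to bias*(1-bias)^(j-1), renormalised."""
    if bias >= 1.0:
        return np.ones_like(r)
    q = 1.0 - bias
    u = rng.random(r.shape[0])
    j = np.ceil(np.log1p(-u * (1.0 - q ** r)) / np.log(q)).astype(np.int64)
    return np.clip(j, 1, r)


def simulate_tag_library(
    transcripts: Sequence[Transcript],
    truth: SimTruth,
    library_index: int,
    config: SimConfig,
) -> TagLibrary:
    """Emit one raw tag library of exactly ``depth_per_library`` tags.

    Sampling is per molecule: gene proportional to baseline x 2^log2fc,
    CATG rank geometric from the 3' end (``rank_bias``), strand by
    ``antisense_fraction`` (falling back to sense for genes without
    antisense tags), then independent per-base substitution at
    ``error_rate`` and N-injection at ``n_rate``.  ``singleton_rate`` of
    the depth is emitted as random CATG+17 tags of copy number 1.
    """
    gene_ids = [t.gene_id for t in transcripts]
    if gene_ids != truth.genes:
        raise ValueError("truth and transcript gene sets do not match")
    rng = np.random.default_rng([config.seed, library_index])
    depth = config.depth_per_library
    n_single = int(round(config.singleton_rate * depth))
    n_main = depth - n_single

    s_mat, s_off, s_n, a_mat, a_off, a_n = _tag_arrays(transcripts)
    weights = truth.baseline() * np.exp2(truth.log2fc(library_index))
    p = weights / weights.sum()

    gene = rng.choice(len(gene_ids), size=n_main, p=p)
    anti = rng.random(n_main) < config.antisense_fraction
    anti &= a_n[gene] > 0
    n_ranks = np.where(anti, a_n[gene], s_n[gene])
    rank = _truncated_geometric(rng, n_ranks, config.rank_bias)
    row = np.where(anti, a_off[gene], s_off[gene]) + rank - 1

    mat = np.empty((n_main, TAG_LENGTH), dtype=np.uint8)
    if anti.any():
        mat[anti] = a_mat[row[anti]]
    mat[~anti] = s_mat[row[~anti]]

    if config.error_rate > 0:
        mask = rng.random(mat.shape) < config.error_rate
        shift = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
        mat[mask] = (mat[mask] + shift) % 4
    if config.n_rate > 0:
        sel = np.flatnonzero(rng.random(n_main) < config.n_rate)
        pos = rng.integers(0, TAG_LENGTH, size=sel.size)
        mat[sel, pos] = 4  # code for N

    tags = _ASCII[mat].view(f"S{TAG_LENGTH}").ravel()
    uniq, counts = np.unique(tags, return_counts=True)
    table = {t.decode(): int(c) for t, c in zip(uniq, counts)}

    if n_single:
        body = rng.integers(0, 4, size=(n_single, TAG_LENGTH - len(ANCHOR))).astype(np.uint8)
        suffixes = _ASCII[body].view(f"S{TAG_LENGTH - len(ANCHOR)}").ravel()
        for suf in suffixes:
            tag = ANCHOR + suf.decode()
            table[tag] = table.get(tag, 0) + 1

    lib = TagLibrary(f"lib{library_index}", table, RAW)
    assert lib.tag_total == depth
    return lib


def write_truth(truth: SimTruth, path: str | Path) -> None:
    """Write the truth table as TSV; round-trips losslessly via read_truth."""
    truth.frame.to_csv(path, sep="\t")


def read_truth(path: str | Path) -> SimTruth:
    frame = pd.read_csv(path, sep="\t", index_col="gene_id")
    if len(frame) == 0:
        frame = frame.astype({"baseline": float})
    return SimTruth(frame)
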