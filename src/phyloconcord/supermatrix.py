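"""Locus bookkeeping and supermatrix construction.

Implements the three matrix-construction regimes used to explore tree
space over a UCE-style locus collection:

* completeness thresholds — keep loci present in at least floor(frac * N)
  taxa (for N = 37 the ten standard fractions 1.0 ... 0.15 give minimum
  taxon counts 37, 35, 31, 27, 24, 20, 16, 12, 9, 5);
* length deciles — sort loci by length and split into equal-size groups;
* random subsamples — repeated uniform draws of k loci without
  replacement.

Concatenation pads taxa missing from a locus with '?' and records 1-based
inclusive character-set intervals per locus, the convention RAxML/NEXUS
partition files expect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "LocusAlignment",
    "LocusStats",
    "Supermatrix",
    "locus_stats",
    "filter_by_completeness",
    "completeness_threshold",
    "bin_by_length",
    "random_subsets",
    "concatenate",
    "read_fasta",
    "write_fasta",
    "read_locus_dir",
]

_NUCLEOTIDES = frozenset("ACGT")


@dataclass(frozen=True)
class LocusAlignment:
    """One aligned locus: equal-length sequences keyed by taxon label."""

    locus_id: str
    sequences: dict[str, str]

    def __post_init__(self):
        if not self.sequences:
            raise ValueError(f"locus {self.locus_id}: empty alignment")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValueError(
                f"locus {self.locus_id}: unequal sequence lengths {lengths}")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def taxon_count(self) -> int:
        return len(self.sequences)

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(self.sequences)


@dataclass(frozen=True)
class LocusStats:
    length: int
    variable: int
    informative: int

    def __post_init__(self):
        if not self.informative <= self.variable <= self.length:
            raise ValueError("expected informative <= variable <= length")

    @property
    def constant(self) -> int:
        return self.length - self.variable

    @property
    def variable_uninformative(self) -> int:
        return self.variable - self.informative


def locus_stats(locus: LocusAlignment) -> LocusStats:
    """Count variable and parsimony-informative columns.

    A column is *variable* if >= 2 distinct non-missing nucleotide states
    occur, and *parsimony-informative* if >= 2 states each occur in >= 2
    sequences.  Gaps, N and ambiguity codes are treated as missing.
    """
    if locus.taxon_count < 2:
        raise ValueError("site statistics need >= 2 taxa")
    seqs = [s.upper() for s in locus.sequences.values()]
    variable = informative = 0
    for col in zip(*seqs):
        counts: dict[str, int] = {}
        for ch in col:
            if ch in _NUCLEOTIDES:
                counts[ch] = counts.get(ch, 0) + 1
        if len(counts) >= 2:
            variable += 1
            if sum(1 for c in counts.values() if c >= 2) >= 2:
                informative += 1
    return LocusStats(length=locus.length, variable=variable,
                      informative=informative)


def completeness_threshold(frac: float, n_taxa: int) -> int:
    """Minimum taxon count for a completeness fraction: floor(frac * N)."""
    if not 0 < frac <= 1:
        raise ValueError("completeness fraction must be in (0, 1]")
    return math.floor(frac * n_taxa + 1e-9)


def filter_by_completeness(loci: Iterable[LocusAlignment], frac: float,
                           n_taxa: int) -> list[LocusAlignment]:
    """Keep loci present in at least floor(frac * n_taxa) taxa."""
    t = completeness_threshold(frac, n_taxa)
    return [l for l in loci if l.taxon_count >= t]


def bin_by_length(loci: Sequence[LocusAlignment], n_bins: int = 10
                  ) -> list[list[LocusAlignment]]:
    """Sort loci by (length, locus_id) and split into ``n_bins`` contiguous
    groups whose sizes differ by at most one (larger groups first)."""
    loci = sorted(loci, key=lambda l: (l.length, l.locus_id))
    m = len(loci)
    if n_bins > m:
        raise ValueError(f"cannot make {n_bins} bins from {m} loci")
    base, extra = divmod(m, n_bins)
    bins, start = [], 0
    for i in range(n_bins):
        size = base + (1 if i < extra else 0)
        bins.append(loci[start:start + size])
        start += size
    return bins


def random_subsets(loci: Sequence[LocusAlignment], k: int = 365,
                   reps: int = 100, seed: int = 0) -> list[list[str]]:
    """``reps`` independent uniform samples of ``k`` locus ids without
    replacement (within a replicate); reproducible for a fixed seed."""
    ids = sorted(l.locus_id for l in loci)
    if k > len(ids):
        raise ValueError(f"cannot sample {k} loci from {len(ids)}")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(reps):
        pick = rng.choice(len(ids), size=k, replace=False)
        out.append(sorted(ids[i] for i in pick))
    return out


@dataclass
class Supermatrix:
    """Concatenated loci: per-taxon sequence plus 1-based inclusive
    character-set intervals in locus order."""

    sequences: dict[str, str]
    charsets: dict[str, tuple[int, int]]

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    def write_phylip(self, path: str | Path) -> None:
        taxa = sorted(self.sequences)
        with open(path, "w") as fh:
            fh.write(f"{len(taxa)} {self.length}\n")
            for t in taxa:
                fh.write(f"{t}  {self.sequences[t]}\n")

    def write_raxml_partitions(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for locus_id, (start, end) in self.charsets.items():
                fh.write(f"DNA, {locus_id} = {start}-{end}\n")

    def write_nexus(self, path: str | Path) -> None:
        taxa = sorted(self.sequences)
        with open(path, "w") as fh:
            fh.write("#NEXUS\nbegin data;\n")
            fh.write(f"  dimensions ntax={len(taxa)} nchar={self.length};\n")
            fh.write("  format datatype=dna missing=? gap=-;\n  matrix\n")
            for t in taxa:
                fh.write(f"    {t}  {self.sequences[t]}\n")
            fh.write("  ;\nend;\nbegin sets;\n")
            for locus_id, (start, end) in self.charsets.items():
                fh.write(f"  charset {locus_id} = {start}-{end};\n")
            fh.write("end;\n")


def concatenate(loci: Sequence[LocusAlignment]) -> Supermatrix:
    """Concatenate loci in the given order, padding absent taxa with '?'."""
    if not loci:
        raise ValueError("cannot concatenate zero loci")
    ids = [l.locus_id for l in loci]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate locus_id in concatenation")
    taxa = sorted(set().union(*(l.taxa for l in loci)))
    parts: dict[str, list[str]] = {t: [] for t in taxa}
    charsets: dict[str, tuple[int, int]] = {}
    pos = 0
    for l in loci:
        charsets[l.locus_id] = (pos + 1, pos + l.length)
        for t in taxa:
            parts[t].append(l.sequences.get(t, "?" * l.length))
        pos += l.length
    return Supermatrix(sequences={t: "".join(p) for t, p in parts.items()},
                       charsets=charsets)


def summarize_matrices(loci: Sequence[LocusAlignment],
                       fractions: Sequence[float], n_taxa: int):
    """Completeness-spectrum summary table (one row per matrix): minimum
    taxon count, loci retained, informative / variable-uninformative site
    totals, and concatenated length."""
    import pandas as pd

    rows = []
    for frac in fractions:
        subset = filter_by_completeness(loci, frac, n_taxa)
        stats = [locus_stats(l) for l in subset]
        rows.append({
            "matrix_pct": int(round(frac * 100)),
            "min_taxa": completeness_threshold(frac, n_taxa),
            "n_loci": len(subset),
            "informative": sum(s.informative for s in stats),
            "variable_uninformative": sum(s.variable_uninformative for s in stats),
            "length": sum(s.length for s in stats),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# FASTA I/O (one file per locus)


def read_fasta(path: str | Path, locus_id: str | None = None) -> LocusAlignment:
    from Bio import SeqIO

    path = Path(path)
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise ValueError(f"no sequences in {path}")
    return LocusAlignment(locus_id=locus_id or path.stem, sequences=seqs)


def write_fasta(locus: LocusAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for taxon in sorted(locus.sequences):
            fh.write(f">{taxon}\n{locus.sequences[taxon]}\n")


def read_locus_dir(directory: str | Path,
                   pattern: str = "*.fasta") -> list[LocusAlignment]:
    paths = sorted(Path(directory).glob(pattern))
    if not paths:
        raise ValueError(f"no {pattern} files in {directory}")
    return [read_fasta(p) for p in paths]
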