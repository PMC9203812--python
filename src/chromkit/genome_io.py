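"""Genomic coordinate model, interval algebra and plain-text readers/writers.

All coordinates are 0-based, half-open ``[start, end)`` — the BED convention —
throughout the package.  Any 1-based input dialect must be converted at the
reader boundary.  Chromosome names are compared by exact string match; no
``chr`` aliasing is performed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "GenomeModel",
    "read_intervals",
    "write_intervals",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_fasta",
    "write_fasta",
    "overlap_pairs",
    "classify_location",
]

STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic region ``[start, end)`` on a named chromosome.

    ``strand`` is one of ``+``, ``-`` or ``.`` (unstranded, the default);
    ``score`` may be absent (``None``).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two half-open intervals share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    @property
    def tss(self) -> int:
        """5' end: ``start`` on the plus strand, ``end - 1`` on the minus.

        Unstranded records are treated as plus-strand.
        """
        return self.end - 1 if self.strand == "-" else self.start


def _sort_key(iv: GenomicInterval):
    return (iv.chrom, iv.start, iv.end)


class IntervalSet:
    """An ordered, overlap-queryable collection of :class:`GenomicInterval`.

    Intervals are kept sorted by ``(chrom, start, end)``.  Duplicates are
    permitted but flagged via :attr:`has_duplicates`.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        label: str = "",
        sample_id: str | None = None,
        antibody: str | None = None,
    ) -> None:
        self.intervals: tuple[GenomicInterval, ...] = tuple(
            sorted(intervals, key=_sort_key)
        )
        self.label = label
        self.sample_id = sample_id
        self.antibody = antibody
        self._arrays: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None
        self._merged: "IntervalSet" | None = None

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def __repr__(self) -> str:
        lab = f" {self.label!r}" if self.label else ""
        return f"<IntervalSet{lab} n={len(self)}>"

    @property
    def has_duplicates(self) -> bool:
        seen = set()
        for iv in self.intervals:
            key = (iv.chrom, iv.start, iv.end)
            if key in seen:
                return True
            seen.add(key)
        return False

    @property
    def chroms(self) -> list[str]:
        return sorted({iv.chrom for iv in self.intervals})

    def lengths(self) -> np.ndarray:
        return np.array([iv.length for iv in self.intervals], dtype=np.int64)

    # -- bulk overlap machinery --------------------------------------------
    def _chrom_arrays(self) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends, original indices), start-sorted."""
        if self._arrays is None:
            arrays: dict[str, list[list[int]]] = {}
            for i, iv in enumerate(self.intervals):
                arrays.setdefault(iv.chrom, [[], [], []])
                arrays[iv.chrom][0].append(iv.start)
                arrays[iv.chrom][1].append(iv.end)
                arrays[iv.chrom][2].append(i)
            self._arrays = {
                c: (
                    np.asarray(v[0], dtype=np.int64),
                    np.asarray(v[1], dtype=np.int64),
                    np.asarray(v[2], dtype=np.int64),
                )
                for c, v in arrays.items()
            }
        return self._arrays

    def merged(self) -> "IntervalSet":
        """Union footprint: overlapping or book-ended-by-overlap intervals
        collapsed into maximal runs (>= 1 shared base chains; abutting
        intervals are NOT merged)."""
        if self._merged is not None:
            return self._merged
        out: list[GenomicInterval] = []
        cur: GenomicInterval | None = None
        for iv in self.intervals:
            if cur is not None and iv.chrom == cur.chrom and iv.start < cur.end:
                if iv.end > cur.end:
                    cur = replace(cur, end=iv.end)
            else:
                if cur is not None:
                    out.append(cur)
                cur = GenomicInterval(iv.chrom, iv.start, iv.end)
        if cur is not None:
            out.append(cur)
        self._merged = IntervalSet(out, label=self.label)
        return self._merged

    def total_bp(self) -> int:
        """Number of distinct bases covered by the set."""
        return int(sum(iv.length for iv in self.merged()))

    def overlaps_any(self, queries: "IntervalSet") -> np.ndarray:
        """Boolean array: does ``queries[i]`` overlap any interval of self?"""
        merged = self.merged()._chrom_arrays()
        out = np.zeros(len(queries), dtype=bool)
        for chrom, (qs, qe, qi) in queries._chrom_arrays().items():
            if chrom not in merged:
                continue
            fs, fe, _ = merged[chrom]
            # first feature whose end > query start
            j = np.searchsorted(fe, qs, side="right")
            hit = (j < len(fs)) & (fs[np.minimum(j, len(fs) - 1)] < qe)
            out[qi] = hit
        return out

    def count_overlapping(self, queries: "IntervalSet") -> int:
        return int(self.overlaps_any(queries).sum())


@dataclass
class GenomeModel:
    """Chromosome sizes plus optional annotation layers and sequence.

    The TSS of a minus-strand gene is its ``end - 1`` coordinate.  Every
    layer interval must lie within ``chrom_sizes``.
    """

    chrom_sizes: dict[str, int]
    genes: IntervalSet | None = None
    cpg_islands: IntervalSet = field(default_factory=IntervalSet)
    blacklist: IntervalSet = field(default_factory=IntervalSet)
    tfbs: dict[str, IntervalSet] = field(default_factory=dict)
    open_chromatin: IntervalSet | None = None
    sequence: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        layers = [self.cpg_islands, self.blacklist, *self.tfbs.values()]
        if self.genes is not None:
            layers.append(self.genes)
        if self.open_chromatin is not None:
            layers.append(self.open_chromatin)
        for layer in layers:
            for iv in layer:
                size = self.chrom_sizes.get(iv.chrom)
                if size is None:
                    raise ValueError(f"interval on unknown chromosome {iv.chrom!r}")
                if iv.end > size:
                    raise ValueError(
                        f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds "
                        f"chromosome size {size}"
                    )

    @property
    def total_size(self) -> int:
        return sum(self.chrom_sizes.values())

    def seq(self, chrom: str, start: int, end: int) -> str:
        if self.sequence is None:
            raise ValueError("genome has no sequence attached")
        return str(self.sequence[chrom][start:end])

    def tss_sites(self) -> IntervalSet:
        """1-bp TSS intervals for every gene, strand preserved."""
        if self.genes is None:
            raise ValueError("genome has no genes layer")
        out = []
        for g in self.genes:
            t = g.tss
            out.append(GenomicInterval(g.chrom, t, t + 1, g.strand, g.name))
        return IntervalSet(out, label="tss")

    def tss_windows(self, upstream: int, downstream: int) -> IntervalSet:
        """Strand-oriented windows ``[TSS-upstream, TSS+downstream)``.

        Clipped to chromosome bounds.
        """
        if self.genes is None:
            raise ValueError("genome has no genes layer")
        out = []
        for g in self.genes:
            t = g.tss
            if g.strand == "-":
                lo, hi = t - downstream + 1, t + upstream + 1
            else:
                lo, hi = t - upstream, t + downstream
            lo = max(0, lo)
            hi = min(self.chrom_sizes[g.chrom], hi)
            if lo < hi:
                out.append(GenomicInterval(g.chrom, lo, hi, g.strand, g.name))
        return IntervalSet(out, label="tss_windows")


# -- readers / writers ------------------------------------------------------

def read_intervals(path: str | Path, fmt: str = "bed", label: str = "") -> IntervalSet:
    """Read a BED3/BED6 (or headerless TSV, same columns) interval file.

    BED start/end are interpreted verbatim as 0-based half-open.  A malformed
    line raises :class:`ValueError` naming the line number.
    """
    if fmt not in ("bed", "tsv"):
        raise ValueError(f"unknown interval format {fmt!r}")
    path = Path(path)
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}: expected >=3 columns at line {lineno}")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: non-integer coordinate at line {lineno}"
                ) from exc
            if start < 0:
                raise ValueError(f"{path}: negative start at line {lineno}")
            if start >= end:
                raise ValueError(f"{path}: start >= end at line {lineno}")
            name = cols[3] if len(cols) > 3 else ""
            score: float | None = None
            if len(cols) > 4 and cols[4] not in (".", ""):
                score = float(cols[4])
            strand = cols[5] if len(cols) > 5 else "."
            out.append(GenomicInterval(cols[0], start, end, strand, name, score))
    return IntervalSet(out, label=label or path.stem)


def write_intervals(
    iset: IntervalSet | Sequence[GenomicInterval],
    path: str | Path,
    header: bool = False,
) -> None:
    """Write BED records, tab-separated, newline-terminated.

    BED6 columns are emitted when any record carries a name, score or strand;
    otherwise BED3.
    """
    ivs = list(iset)
    six = any(iv.name or iv.score is not None or iv.strand != "." for iv in ivs)
    with open(path, "w") as fh:
        if header:
            cols = ["chrom", "start", "end"] + (["name", "score", "strand"] if six else [])
            fh.write("#" + "\t".join(cols) + "\n")
        for iv in ivs:
            if six:
                score = "." if iv.score is None else format(iv.score, "g")
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                    f"{score}\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column TSV: chromosome name, length in bp."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ValueError(f"{path}: expected 2 columns at line {lineno}")
            sizes[cols[0]] = int(cols[1])
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into per-chromosome strings via pyfaidx."""
    from pyfaidx import Fasta

    fa = Fasta(str(path))
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# -- interval algebra -------------------------------------------------------

def overlap_pairs(
    a: IntervalSet, b: IntervalSet
) -> list[tuple[GenomicInterval, GenomicInterval]]:
    """All pairs ``(iv_a, iv_b)`` sharing >= 1 bp, by a sorted sweep.

    Symmetric in content: ``overlap_pairs(b, a)`` yields the flipped pairs.
    """
    pairs: list[tuple[GenomicInterval, GenomicInterval]] = []
    b_arr = b._chrom_arrays()
    for chrom, (a_s, a_e, a_i) in a._chrom_arrays().items():
        if chrom not in b_arr:
            continue
        b_s, b_e, b_i = b_arr[chrom]
        order = np.argsort(b_s, kind="stable")
        b_s, b_e, b_i = b_s[order], b_e[order], b_i[order]
        for s, e, ia in zip(a_s, a_e, a_i):
            lo = 0
            hi = np.searchsorted(b_s, e, side="left")
            for j in range(lo, hi):
                if b_e[j] > s:
                    pairs.append((a.intervals[ia], b.intervals[b_i[j]]))
    return pairs


def classify_location(
    peaks: IntervalSet,
    genome: GenomeModel,
    promoter_up: int = 1000,
    promoter_down: int = 500,
) -> list[str]:
    """Label each peak ``promoter`` / ``gene_body`` / ``intergenic``.

    The promoter window is ``[TSS - promoter_up, TSS + promoter_down)``
    oriented by gene strand; precedence is promoter > gene_body > intergenic.
    """
    if genome.genes is None:
        raise ValueError("genome has no genes layer")
    promoters = genome.tss_windows(promoter_up, promoter_down)
    in_prom = promoters.overlaps_any(peaks)
    in_body = genome.genes.overlaps_any(peaks)
    labels = []
    for p, b in zip(in_prom, in_body):
        labels.append("promoter" if p else ("gene_body" if b else "intergenic"))
    return labels
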