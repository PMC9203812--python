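"""Coverage tracks, normalization and metagene profiling.

Two normalizations are supported:

* **per-N-reads** — every bin is scaled by ``denominator / mapped_reads``
  (default denominator 1e8, i.e. "per 100 million reads").  The mapped-read
  count may be the library total or the total under peak regions; the
  caller chooses which count to pass.
* **ChIP-Rx** — reference-adjusted (exogenous spike-in) scaling.  With
  mapped read counts ``h_chip``/``s_chip`` (target and spike species in the
  ChIP library) and ``h_input``/``s_input`` (same in the input library),
  the factor is

      gamma = (s_input / h_input) / (s_chip / h_chip) * (1e8 / h_chip)

  so that samples prepared with the same true spike:target cell ratio
  become quantitatively comparable regardless of sequencing depth or IP
  efficiency.

Metagene profiles average a track over many genes on a common axis, either
TSS-centered or with the gene body length-scaled to a fixed number of bins;
minus-strand genes are coordinate-reversed so the axis always reads 5'->3'.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import GenomicInterval, IntervalSet

__all__ = [
    "CoverageTrack",
    "SpikeInStats",
    "ExpressionStratum",
    "MetageneProfile",
    "normalize_per_reads",
    "chiprx_factor",
    "normalize_chiprx",
    "stratify_by_expression",
    "metagene_profile",
    "read_bedgraph",
    "write_bedgraph",
]


@dataclass
class CoverageTrack:
    """Binned, per-chromosome signal with normalization provenance."""

    bin_size: int
    values: dict[str, np.ndarray]
    normalization: str = "raw"  # raw | per_reads | chiprx
    factor: float = 1.0
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        self.values = {c: np.asarray(v, dtype=float) for c, v in self.values.items()}

    def scaled(self, factor: float, normalization: str) -> "CoverageTrack":
        return CoverageTrack(
            self.bin_size,
            {c: v * factor for c, v in self.values.items()},
            normalization,
            self.factor * factor,
            self.sample_id,
        )

    def mean_over(self, iv: GenomicInterval) -> float:
        """Mean bin value over the bins the interval touches."""
        arr = self.values.get(iv.chrom)
        if arr is None:
            return 0.0
        lo = iv.start // self.bin_size
        hi = (iv.end - 1) // self.bin_size + 1
        lo, hi = max(0, lo), min(len(arr), hi)
        if lo >= hi:
            return 0.0
        return float(arr[lo:hi].mean())

    def genome_mean(self) -> float:
        return float(np.concatenate(list(self.values.values())).mean())


@dataclass(frozen=True)
class SpikeInStats:
    """Mapped read counts for ChIP-Rx: target ("h") and spike ("s") species
    in the ChIP and input libraries."""

    h_chip: int
    s_chip: int
    h_input: int
    s_input: int

    def __post_init__(self) -> None:
        if min(self.h_chip, self.s_chip, self.h_input, self.s_input) <= 0:
            raise ValueError("all spike-in read counts must be > 0")


def normalize_per_reads(
    track: CoverageTrack, mapped_reads: int, denominator: float = 1e8
) -> CoverageTrack:
    """Scale a raw track by ``denominator / mapped_reads``.

    Refuses to renormalize an already-normalized track.
    """
    if mapped_reads <= 0:
        raise ValueError("mapped_reads must be > 0")
    if track.normalization != "raw":
        raise ValueError(f"track already normalized ({track.normalization})")
    return track.scaled(denominator / mapped_reads, "per_reads")


def chiprx_factor(s: SpikeInStats, denominator: float = 1e8) -> float:
    """Reference-adjusted normalization factor gamma (see module docstring)."""
    return (s.s_input / s.h_input) / (s.s_chip / s.h_chip) * (denominator / s.h_chip)


def normalize_chiprx(
    track: CoverageTrack, s: SpikeInStats, denominator: float = 1e8
) -> CoverageTrack:
    if track.normalization != "raw":
        raise ValueError(f"track already normalized ({track.normalization})")
    return track.scaled(chiprx_factor(s, denominator), "chiprx")


# -- bedGraph ---------------------------------------------------------------

def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Emit one line per bin (runs of equal value are not collapsed)."""
    with open(path, "w") as fh:
        for chrom, arr in track.values.items():
            bs = track.bin_size
            for i, v in enumerate(arr):
                fh.write(f"{chrom}\t{i * bs}\t{(i + 1) * bs}\t{v:g}\n")


def read_bedgraph(
    path: str | Path, chrom_sizes: Mapping[str, int], bin_size: int
) -> CoverageTrack:
    """Rasterize a bedGraph into fixed bins by bp-weighted averaging."""
    sums = {c: np.zeros(-(-size // bin_size)) for c, size in chrom_sizes.items()}
    cover = {c: np.zeros_like(v) for c, v in sums.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise ValueError(f"{path}: expected 4 columns at line {lineno}")
            chrom, start, end, val = cols[0], int(cols[1]), int(cols[2]), float(cols[3])
            if chrom not in sums:
                continue
            b0, b1 = start // bin_size, (end - 1) // bin_size + 1
            for b in range(b0, min(b1, len(sums[chrom]))):
                lo = max(start, b * bin_size)
                hi = min(end, (b + 1) * bin_size)
                sums[chrom][b] += val * (hi - lo)
                cover[chrom][b] += hi - lo
    values = {
        c: np.divide(sums[c], cover[c], out=np.zeros_like(sums[c]),
                     where=cover[c] > 0)
        for c in sums
    }
    return CoverageTrack(bin_size, values)


# -- expression strata ------------------------------------------------------

@dataclass(frozen=True)
class ExpressionStratum:
    label: str
    gene_ids: tuple[str, ...]


def stratify_by_expression(
    expr: pd.DataFrame,
    mode: str = "status4",
    q: int = 5,
    threshold: float = 1.0,
    genes: Sequence[str] | None = None,
) -> list[ExpressionStratum]:
    """Partition genes by expression.

    ``expr`` is indexed by gene id.  ``status4`` uses the first two columns
    (cell types A and B) and a detection threshold, yielding the classes
    both_expressed / a_only / b_only / repressed.  ``quantiles`` ranks the
    detected genes (first column >= threshold) and splits them into ``q``
    equal-count bins, lowest first; ties at a boundary are broken by stable
    gene-id order so the partition is deterministic.  Genes below threshold
    form a ``not_expressed`` stratum (omitted when empty).
    """
    if genes is not None:
        missing = sorted(set(genes) - set(expr.index))
        if missing:
            raise ValueError(f"missing expression values for genes: {missing}")
        expr = expr.loc[list(genes)]
    if expr.isna().any().any():
        bad = sorted(expr.index[expr.isna().any(axis=1)])
        raise ValueError(f"missing expression values for genes: {bad}")
    if mode == "status4":
        if expr.shape[1] < 2:
            raise ValueError("status4 mode needs two expression columns")
        a = expr.iloc[:, 0] >= threshold
        b = expr.iloc[:, 1] >= threshold
        classes = {
            "both_expressed": a & b,
            "a_only": a & ~b,
            "b_only": ~a & b,
            "repressed": ~a & ~b,
        }
        return [
            ExpressionStratum(lab, tuple(expr.index[mask]))
            for lab, mask in classes.items()
        ]
    if mode == "quantiles":
        if q < 1:
            raise ValueError("q must be >= 1")
        col = expr.iloc[:, 0]
        detected = col[col >= threshold]
        order = sorted(detected.index, key=lambda g: (detected[g], g))
        out = [
            ExpressionStratum(f"q{i + 1}", tuple(chunk))
            for i, chunk in enumerate(np.array_split(np.array(order, dtype=object), q))
        ]
        rest = tuple(g for g in expr.index if g not in set(detected.index))
        if rest:
            out.append(ExpressionStratum("not_expressed", rest))
        return out
    raise ValueError(f"unknown mode {mode!r}")


# -- metagene ---------------------------------------------------------------

@dataclass
class MetageneProfile:
    positions: np.ndarray  # bin axis: bp offsets (tss_centered) or bin index
    mean_signal: np.ndarray
    group: str
    n_genes: int
    n_dropped: int = 0
    mode: str = "tss_centered"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.positions,
                "stratum": self.group,
                "mean": self.mean_signal,
                "n_genes": self.n_genes,
            }
        )


def _gene_rows_tss(
    track: CoverageTrack, genes: list[GenomicInterval], flank: int
) -> tuple[np.ndarray, int]:
    bs = track.bin_size
    nf = flank // bs
    rows = []
    dropped = 0
    for g in genes:
        arr = track.values.get(g.chrom)
        if arr is None:
            dropped += 1
            continue
        tbin = g.tss // bs
        lo, hi = tbin - nf, tbin + nf + 1
        if lo < 0 or hi > len(arr):
            dropped += 1
            continue
        row = arr[lo:hi]
        rows.append(row[::-1] if g.strand == "-" else row)
    return (np.array(rows) if rows else np.empty((0, 2 * nf + 1))), dropped


def _gene_rows_scaled(
    track: CoverageTrack, genes: list[GenomicInterval], flank: int, body_bins: int
) -> tuple[np.ndarray, int]:
    bs = track.bin_size
    nf = flank // bs
    rows = []
    dropped = 0
    for g in genes:
        arr = track.values.get(g.chrom)
        if arr is None or g.length < body_bins:
            dropped += 1
            continue
        lo_bp, hi_bp = g.start - flank, g.end + flank
        if lo_bp < 0 or hi_bp > len(arr) * bs:
            dropped += 1
            continue
        up = arr[(g.start - flank) // bs : g.start // bs][:nf]
        down = arr[-(-g.end // bs) : -(-g.end // bs) + nf]
        if len(up) < nf or len(down) < nf:
            dropped += 1
            continue
        # per-bp body signal, interpolated onto body_bins points
        body_bp = arr[np.arange(g.start, g.end) // bs]
        pts = np.linspace(0, len(body_bp) - 1, body_bins)
        body = np.interp(pts, np.arange(len(body_bp)), body_bp)
        row = np.concatenate([up, body, down])
        rows.append(row[::-1] if g.strand == "-" else row)
    width = 2 * nf + body_bins
    return (np.array(rows) if rows else np.empty((0, width))), dropped


def metagene_profile(
    track: CoverageTrack,
    genes: IntervalSet,
    mode: str = "tss_centered",
    flank: int = 2000,
    body_bins: int = 100,
    strata: list[ExpressionStratum] | None = None,
) -> list[MetageneProfile]:
    """Average a track over genes, per stratum, on a common 5'->3' axis.

    ``tss_centered``: one bin row per gene centred on its TSS, +/- flank.
    ``scaled_body``: upstream flank bins, the gene body interpolated to
    ``body_bins`` points, downstream flank bins.  Genes truncated by
    chromosome ends (or, in scaled mode, shorter than ``body_bins`` bp) are
    dropped and counted in ``n_dropped``.  A stratum with zero usable genes
    raises.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    if mode not in ("tss_centered", "scaled_body"):
        raise ValueError(f"unknown mode {mode!r}")
    by_name = {}
    for g in genes:
        by_name.setdefault(g.name, g)
    if strata is None:
        strata = [ExpressionStratum("all", tuple(by_name))]
    bs = track.bin_size
    nf = flank // bs
    out = []
    for stratum in strata:
        members = [by_name[g] for g in stratum.gene_ids if g in by_name]
        if mode == "tss_centered":
            rows, dropped = _gene_rows_tss(track, members, flank)
            positions = (np.arange(-nf, nf + 1)) * bs
        else:
            rows, dropped = _gene_rows_scaled(track, members, flank, body_bins)
            positions = np.arange(2 * nf + body_bins)
        if rows.shape[0] == 0:
            raise ValueError(f"stratum {stratum.label!r} has no usable genes")
        out.append(
            MetageneProfile(
                positions, rows.mean(axis=0), stratum.label, rows.shape[0],
                dropped, mode,
            )
        )
    return out
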