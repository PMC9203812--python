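"""Single-cell accessibility / expression analysis of relative locus activity.

The question this module answers: in which cells is a target locus (an
alpha-globin-like gene, HBA or HBM) silenced *relative to* an anchor locus
(the beta-globin-like gene HBB) that marks how far the cell has progressed
down the erythroid differentiation path?  A cell that is anchor-high but
shows an abnormally low target:anchor activity ratio is flagged as
stochastically silenced, and the case/control composition of the flagged
subpopulation is tested with Fisher's exact test.

QC mirrors the standard 10x workflows: ATAC cells require
``passed_filters > 500`` fragments and are randomly subsampled to exactly
4,000 per sample; RNA cells with more than 7.5% mitochondrial reads or a
detected-gene count outside [800, 4000] are excluded before subsampling to
4,400 per sample.  RNA counts are log-normalized (ln(1 + 1e4 * c / total));
ATAC gene activities are depth-normalized to counts per 10,000.

Because a visual t-SNE gate is not reproducible, the subpopulation is
defined by explicit, configurable thresholds: anchor-high means above the
control group's 75th percentile of anchor activity (ATAC) or a fixed
log-normalized anchor expression (RNA, default 8); the ratio cutoff is the
25th percentile of the control anchor-high cells' mean target:anchor ratio.
Ratios are computed on the linear normalized scale so a multiplicative
silencing effect maps proportionally onto the ratio.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .enrichment import ContingencyTable, EnrichmentResult, fisher_exact
from .genome_io import GenomicInterval, IntervalSet

__all__ = [
    "CellMatrix",
    "ScConfig",
    "qc_and_subsample",
    "gene_activity",
    "normalize_atac",
    "normalize_rna",
    "relative_activity",
    "subpopulation_enrichment",
    "read_cell_matrix",
    "write_cell_matrix",
]


@dataclass
class CellMatrix:
    """Sparse cells x features count matrix with feature metadata.

    ``feature_intervals`` (ordered like ``feature_ids``) carries genomic
    coordinates for accessibility features; RNA matrices use gene ids only.
    """

    counts: sp.csr_matrix
    cell_ids: list[str]
    feature_ids: list[str]
    modality: str  # atac_fragments | rna_umis
    feature_intervals: IntervalSet | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.cell_ids), len(self.feature_ids)):
            raise ValueError("counts shape does not match cell/feature ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell ids must be unique")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("feature ids must be unique")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")

    def subset_cells(self, cell_ids: Sequence[str]) -> "CellMatrix":
        idx = {c: i for i, c in enumerate(self.cell_ids)}
        rows = [idx[c] for c in cell_ids]
        return CellMatrix(
            self.counts[rows], list(cell_ids), self.feature_ids,
            self.modality, self.feature_intervals,
        )


@dataclass
class ScConfig:
    atac_min_passed_filters: int = 500
    atac_cells_per_sample: int = 4000
    rna_max_pct_mito: float = 7.5
    rna_min_features: int = 800
    rna_max_features: int = 4000
    rna_cells_per_sample: int = 4400
    rna_scale_factor: float = 10_000.0
    atac_scale_factor: float = 10_000.0
    gene_upstream_extension: int = 2000
    hbb_high_threshold: float = 8.0  # log-normalized anchor expression (RNA)
    anchor_high_quantile: float = 0.75  # control-group anchor quantile (ATAC)
    ratio_quantile: float = 0.25  # control anchor-high ratio cutoff
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.rna_min_features < self.rna_max_features):
            raise ValueError("need 0 < rna_min_features < rna_max_features")
        for v in (
            self.atac_cells_per_sample, self.rna_cells_per_sample,
            self.rna_scale_factor, self.atac_scale_factor,
        ):
            if v <= 0:
                raise ValueError("sizes and scale factors must be positive")


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(sample_id.encode())])


def qc_and_subsample(
    m: CellMatrix, ann: pd.DataFrame, cfg: ScConfig
) -> tuple[CellMatrix, pd.DataFrame]:
    """Modality-appropriate QC then a seeded exact-size subsample per sample.

    ATAC keeps cells with ``passed_filters`` strictly greater than the
    threshold; RNA keeps ``pct_mito <= max`` and ``min <= n_features <= max``
    (the stated exclusions are strict inequalities, so boundary cells are
    kept).  Deterministic under the config seed and invariant to input row
    order.  Raises when fewer cells survive QC than requested.
    """
    ann = ann.set_index("cell_id") if "cell_id" in ann.columns else ann
    ann = ann.loc[list(m.cell_ids)]
    if m.modality == "atac_fragments":
        ok = ann["passed_filters"] > cfg.atac_min_passed_filters
        target = cfg.atac_cells_per_sample
    elif m.modality == "rna_umis":
        ok = (
            (ann["pct_mito"] <= cfg.rna_max_pct_mito)
            & (ann["n_features"] >= cfg.rna_min_features)
            & (ann["n_features"] <= cfg.rna_max_features)
        )
        target = cfg.rna_cells_per_sample
    else:
        raise ValueError(f"unknown modality {m.modality!r}")
    keep: list[str] = []
    for sample in sorted(ann["sample_id"].unique()):
        cells = sorted(ann.index[(ann["sample_id"] == sample) & ok])
        if len(cells) < target:
            raise ValueError(
                f"sample {sample!r}: only {len(cells)} cells pass QC, "
                f"{target} requested"
            )
        rng = _sample_rng(cfg.seed, sample)
        chosen = rng.choice(len(cells), size=target, replace=False)
        keep.extend(cells[i] for i in sorted(chosen))
    m2 = m.subset_cells(keep)
    return m2, ann.loc[keep].reset_index().rename(columns={"index": "cell_id"})


def gene_activity(
    m: CellMatrix, genes: IntervalSet, cfg: ScConfig
) -> CellMatrix:
    """Per-cell, per-gene accessibility: fragment counts summed over
    features overlapping the gene body extended upstream (strand-aware) by
    ``gene_upstream_extension`` bp.  A feature overlapping a gene is counted
    once for that gene.
    """
    if m.feature_intervals is None:
        raise ValueError("matrix features carry no genomic coordinates")
    ext = cfg.gene_upstream_extension
    # align intervals with matrix columns by feature name, falling back to
    # the set's own order when names don't match the ids
    by_name = {iv.name: iv for iv in m.feature_intervals}
    if all(fid in by_name for fid in m.feature_ids):
        aligned = [by_name[fid] for fid in m.feature_ids]
    else:
        aligned = list(m.feature_intervals)
    if len(aligned) != len(m.feature_ids):
        raise ValueError("feature intervals do not align with matrix columns")
    f_chrom = np.array([iv.chrom for iv in aligned])
    f_start = np.array([iv.start for iv in aligned], dtype=np.int64)
    f_end = np.array([iv.end for iv in aligned], dtype=np.int64)
    cols = []
    gene_names = []
    for g in genes:
        if g.strand == "." and ext > 0:
            raise ValueError(f"unstranded gene {g.name!r} with upstream extension")
        if g.strand == "-":
            lo, hi = g.start, g.end + ext
        else:
            lo, hi = max(0, g.start - ext), g.end
        mask = (f_chrom == g.chrom) & (f_start < hi) & (f_end > lo)
        cols.append(np.asarray(m.counts[:, np.flatnonzero(mask)].sum(axis=1)).ravel())
        gene_names.append(g.name)
    counts = sp.csr_matrix(np.column_stack(cols)) if cols else sp.csr_matrix((len(m.cell_ids), 0))
    return CellMatrix(counts, list(m.cell_ids), gene_names, "atac_fragments", genes)


def _per_cell_totals(counts: sp.csr_matrix) -> np.ndarray:
    return np.asarray(counts.sum(axis=1)).ravel()


def normalize_atac(m: CellMatrix, cfg: ScConfig) -> pd.DataFrame:
    """Linear depth normalization of gene activities: counts per 10,000."""
    totals = _per_cell_totals(m.counts)
    if (totals == 0).any():
        raise ValueError("zero-total cell reached normalization")
    dense = np.asarray(m.counts.todense(), dtype=float)
    return pd.DataFrame(
        dense * (cfg.atac_scale_factor / totals[:, None]),
        index=m.cell_ids, columns=m.feature_ids,
    )


def normalize_rna(m: CellMatrix, cfg: ScConfig) -> pd.DataFrame:
    """Log-normalize UMIs: ln(1 + count * scale_factor / cell_total).

    When both HBA1 and HBA2 are present, a ``sumHBA`` column is added:
    the log-normalized value of their summed counts (summing on the count
    scale keeps the quantity a single locus-level expression).
    """
    totals = _per_cell_totals(m.counts)
    if (totals == 0).any():
        raise ValueError("zero-total cell reached normalization")
    dense = np.asarray(m.counts.todense(), dtype=float)
    norm = np.log1p(dense * (cfg.rna_scale_factor / totals[:, None]))
    df = pd.DataFrame(norm, index=m.cell_ids, columns=m.feature_ids)
    if "HBA1" in df.columns and "HBA2" in df.columns:
        i1 = m.feature_ids.index("HBA1")
        i2 = m.feature_ids.index("HBA2")
        summed = dense[:, i1] + dense[:, i2]
        df["sumHBA"] = np.log1p(summed * (cfg.rna_scale_factor / totals))
    return df


def relative_activity(
    activity: pd.DataFrame,
    ann: pd.DataFrame,
    anchor: str,
    targets: Sequence[str],
    cfg: ScConfig,
    modality: str = "atac",
) -> pd.DataFrame:
    """Per-cell anchor level, target levels, target:anchor ratios and the
    anchor-high partition.

    ``activity`` is linear (counts per 10,000) for ATAC and log-normalized
    for RNA.  Ratios are always linear, so a cell with anchor 0 gets an
    undefined ratio (NaN) and is excluded from ratio summaries.  Anchor-high
    is the control group's ``anchor_high_quantile`` of anchor level (ATAC)
    or a fixed log-normalized threshold (RNA).
    """
    for locus in [anchor, *targets]:
        if locus not in activity.columns:
            raise ValueError(f"locus {locus!r} missing from activity matrix")
    ann = ann.set_index("cell_id") if "cell_id" in ann.columns else ann.copy()
    ann = ann.loc[activity.index].copy()
    if modality == "rna":
        linear = np.expm1(activity[[anchor, *targets]])
        level = activity  # log scale
    elif modality == "atac":
        linear = activity[[anchor, *targets]]
        level = np.log1p(activity)
    else:
        raise ValueError(f"unknown modality {modality!r}")
    ann["anchor_level"] = level[anchor].to_numpy()
    anchor_lin = linear[anchor].to_numpy()
    ratio_cols = []
    with np.errstate(divide="ignore", invalid="ignore"):
        for t in targets:
            r = np.where(anchor_lin > 0, linear[t].to_numpy() / anchor_lin, np.nan)
            ann[f"{t}_level"] = level[t].to_numpy()
            ann[f"{t}_ratio"] = r
            ratio_cols.append(f"{t}_ratio")
    ann["ratio_mean"] = ann[ratio_cols].mean(axis=1)
    if modality == "rna":
        ann["anchor_high"] = ann["anchor_level"] > cfg.hbb_high_threshold
    else:
        ctrl = ann["group"] == "control"
        if not ctrl.any():
            raise ValueError("no control cells to anchor the quantile on")
        cut = float(np.quantile(ann.loc[ctrl, "anchor_level"], cfg.anchor_high_quantile))
        ann["anchor_high"] = ann["anchor_level"] > cut
    return ann.reset_index().rename(columns={"index": "cell_id"})


def subpopulation_enrichment(
    ann: pd.DataFrame,
    cfg: ScConfig,
    per_sample: bool = False,
) -> tuple[EnrichmentResult, list[str], dict[str, EnrichmentResult]]:
    """Flag the silenced-like subpopulation and test its group composition.

    A cell is flagged when it is anchor-high and its mean target:anchor
    ratio falls below the control anchor-high cells' ``ratio_quantile``.
    The 2x2 table is case/control x flagged/not; with ``per_sample`` the
    same table is additionally built for each case sample against all
    control cells.
    """
    ann = ann.set_index("cell_id") if "cell_id" in ann.columns else ann
    groups = ann["group"].unique()
    if len(groups) < 2:
        raise ValueError("need >= 2 groups (case and control)")
    for g in groups:
        if (ann["group"] == g).sum() == 0:  # pragma: no cover
            raise ValueError(f"group {g!r} has zero cells")
    ctrl_high = ann[(ann["group"] == "control") & ann["anchor_high"]]
    if len(ctrl_high) == 0:
        raise ValueError("no anchor-high control cells; cannot set ratio cutoff")
    cutoff = float(np.nanquantile(ctrl_high["ratio_mean"], cfg.ratio_quantile))
    flagged_mask = ann["anchor_high"] & (ann["ratio_mean"] < cutoff)
    flagged = list(ann.index[flagged_mask])
    case = ann["group"] == "case"
    a = int((case & flagged_mask).sum())
    b = int((case & ~flagged_mask).sum())
    c = int((~case & flagged_mask).sum())
    d = int((~case & ~flagged_mask).sum())
    fr = fisher_exact(ContingencyTable(a, b, c, d))
    result = EnrichmentResult.from_fisher(
        fr, {"ratio_cutoff": cutoff, "flagged": len(flagged)}
    )
    per: dict[str, EnrichmentResult] = {}
    if per_sample:
        ctrl_mask = ann["group"] == "control"
        for sample in sorted(ann.loc[case, "sample_id"].unique()):
            sm = ann["sample_id"] == sample
            t = ContingencyTable(
                int((sm & flagged_mask).sum()),
                int((sm & ~flagged_mask).sum()),
                int((ctrl_mask & flagged_mask).sum()),
                int((ctrl_mask & ~flagged_mask).sum()),
            )
            per[sample] = EnrichmentResult.from_fisher(
                fisher_exact(t), {"sample": sample, "ratio_cutoff": cutoff}
            )
    return result, flagged, per


# -- MTX + TSV triplet IO ---------------------------------------------------

def write_cell_matrix(m: CellMatrix, prefix: str | Path) -> None:
    """Write matrix.mtx + cells.tsv + features.tsv under a prefix directory."""
    from scipy.io import mmwrite

    prefix = Path(prefix)
    prefix.mkdir(parents=True, exist_ok=True)
    mmwrite(str(prefix / "matrix.mtx"), sp.coo_matrix(m.counts))
    (prefix / "cells.tsv").write_text("".join(c + "\n" for c in m.cell_ids))
    with open(prefix / "features.tsv", "w") as fh:
        if m.feature_intervals is not None:
            for fid, iv in zip(m.feature_ids, m.feature_intervals):
                fh.write(f"{fid}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\n")
        else:
            for fid in m.feature_ids:
                fh.write(fid + "\n")
    (prefix / "modality.txt").write_text(m.modality + "\n")


def read_cell_matrix(prefix: str | Path) -> CellMatrix:
    from scipy.io import mmread

    prefix = Path(prefix)
    counts = sp.csr_matrix(mmread(str(prefix / "matrix.mtx")))
    cells = (prefix / "cells.tsv").read_text().splitlines()
    intervals = None
    feature_ids = []
    rows = [l.split("\t") for l in (prefix / "features.tsv").read_text().splitlines()]
    if rows and len(rows[0]) >= 5:
        ivs = []
        for r in rows:
            feature_ids.append(r[0])
            ivs.append(GenomicInterval(r[1], int(r[2]), int(r[3]), r[4], r[0]))
        intervals = IntervalSet(ivs)
    else:
        feature_ids = [r[0] for r in rows]
    modality = (prefix / "modality.txt").read_text().strip()
    return CellMatrix(counts, cells, feature_ids, modality, intervals)
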