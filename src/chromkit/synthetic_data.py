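"""Synthetic genomes, peak replicates, spike-in libraries and single-cell
experiments with planted ground truth.

Every generator is deterministic under the configured seed (each consumes an
independent child stream, so regenerating one product never perturbs
another) and every planted object is recorded in a :class:`GroundTruth` so
downstream recovery can be scored exactly.

What is emulated, in brief:

* a random-nucleotide genome with non-overlapping genes (hence TSS), CpG
  islands, blacklist regions and planted G-quadruplex motifs;
* replicate peak calls: a latent "true" peak set, a tunable fraction of it
  centred on TSS, each replicate observing each latent peak independently
  with probability ``reproducibility`` plus Poisson spurious peaks placed
  away from the latent footprint;
* ChIP-Rx library pairs: identical binding biology at different sequencing
  depths, with a fixed spike-in cell ratio, summarized as four mapped-read
  counts per sample;
* paired single-cell ATAC/RNA experiments with a control and a case
  sample: per-cell depths are lognormal, locus rates scale with a per-cell
  differentiation rank (globin activity rises as cells mature), and in the
  case sample a fraction of the most mature cells has its HBA-like and
  HBM-like rates multiplied by an effect ``e < 1`` while the HBB-like
  anchor is untouched; RNA mirrors this with a constant HBA:HBB ratio
  outside the silenced cells.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .genome_io import GenomeModel, GenomicInterval, IntervalSet
from .single_cell import CellMatrix
from .tracks import CoverageTrack, SpikeInStats

__all__ = [
    "PeakParams",
    "SpikeInParams",
    "ScParams",
    "RnaParams",
    "SyntheticSpec",
    "GroundTruth",
    "ScExperiment",
    "make_genome",
    "make_peak_replicates",
    "make_chiprx_pair",
    "make_sc_experiment",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class PeakParams:
    n_peaks: int = 2000
    len_min: int = 200
    len_max: int = 400
    tss_fraction: float = 0.5  # fraction of latent peaks centred on a TSS
    reproducibility: float = 0.9  # per-sample observation probability
    n_samples: int = 6
    antibodies: tuple[str, ...] = ("ab1", "ab2")
    spurious_rate: float = 20.0  # Poisson mean of spurious peaks per sample
    min_gap: int = 50  # latent peaks never closer than this


@dataclass
class SpikeInParams:
    depths: tuple[int, int] = (5_000_000, 15_000_000)  # ChIP library sizes
    spike_cell_ratio: float = 0.25  # spike:target cells, 1:4
    spike_capture: float = 0.4  # library fraction factor for spike chromatin
    input_depth: int = 5_000_000
    enrichment: float = 5.0  # fold signal inside peaks vs background
    bin_size: int = 200


@dataclass
class ScParams:
    n_cells: int = 5000  # raw droplets per sample, before QC
    silenced_fraction: float = 0.2
    effect: float = 0.2  # rate multiplier at silenced target loci
    n_background: int = 50
    anchor_frac: tuple[float, float] = (0.002, 0.05)  # HBB rate vs maturity
    hba_rel: float = 1.0  # HBA rate relative to HBB
    hbm_rel: float = 0.6
    depth_meanlog: float = 8.5  # ~5000 fragments, typical 10x scATAC median
    depth_sdlog: float = 0.8
    maturity_tau: float = 0.02  # softness of the late-cell silencing bias


@dataclass
class RnaParams:
    n_cells: int = 5200
    hba_hbb_ratio: float = 1.0  # sumHBA : HBB expression ratio (mu)
    hbm_rel: float = 0.1
    hbb_frac: tuple[float, float] = (0.02, 0.45)  # HBB library fraction vs maturity
    n_background: int = 40
    depth_meanlog: float = 9.0  # ~8000 UMIs
    depth_sdlog: float = 0.5
    mito_alpha: float = 2.0  # Beta parameters for pct_mito
    mito_beta: float = 60.0
    nfeat_mean: float = 2000.0
    nfeat_sd: float = 700.0


@dataclass
class SyntheticSpec:
    seed: int = 0
    n_chroms: int = 2
    chrom_len: int = 3_500_000
    n_genes: int = 1200
    gene_len: tuple[int, int] = (600, 1200)
    gene_min_gap: int = 1500
    n_cpg: int = 300
    cpg_len: tuple[int, int] = (300, 1200)
    n_blacklist: int = 30
    blacklist_len: tuple[int, int] = (500, 2000)
    pqs_planted: int = 60
    peak_params: PeakParams = field(default_factory=PeakParams)
    spikein_params: SpikeInParams = field(default_factory=SpikeInParams)
    sc_params: ScParams = field(default_factory=ScParams)
    rna_params: RnaParams = field(default_factory=RnaParams)

    def __post_init__(self) -> None:
        for f in (self.peak_params.tss_fraction, self.peak_params.reproducibility,
                  self.sc_params.silenced_fraction):
            if not 0 <= f <= 1:
                raise ValueError("fractions must lie in [0, 1]")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent child generator for one product family."""
        return np.random.default_rng([self.seed, stream])


@dataclass
class GroundTruth:
    """Planted objects, one-to-one with generated records."""

    pqs: IntervalSet | None = None
    latent_peaks: IntervalSet | None = None
    peak_is_tss: np.ndarray | None = None
    spike_factors: list[float] | None = None
    silenced_atac: frozenset[str] | None = None
    silenced_rna: frozenset[str] | None = None


# -- placement helper -------------------------------------------------------

class _Placer:
    """Rejection-samples non-overlapping intervals with a minimum gap,
    avoiding an exclusion set, uniformly over the genome."""

    def __init__(
        self,
        chrom_sizes: dict[str, int],
        exclude: IntervalSet | None = None,
        min_gap: int = 1,
        edge_margin: int = 0,
    ) -> None:
        self.sizes = chrom_sizes
        self.min_gap = min_gap
        self.edge_margin = edge_margin
        self.blocked: dict[str, tuple[list[int], list[int]]] = {
            c: ([], []) for c in chrom_sizes
        }
        if exclude is not None:
            for iv in exclude.merged():
                self._insert(iv.chrom, iv.start, iv.end)
        self.chroms = list(chrom_sizes)
        sizes = np.array([chrom_sizes[c] for c in self.chroms], dtype=float)
        self.probs = sizes / sizes.sum()

    def _insert(self, chrom: str, start: int, end: int) -> None:
        starts, ends = self.blocked[chrom]
        i = bisect.bisect_left(starts, start)
        starts.insert(i, start)
        ends.insert(i, end)

    def _fits(self, chrom: str, start: int, end: int) -> bool:
        starts, ends = self.blocked[chrom]
        i = bisect.bisect_left(starts, start)
        if i < len(starts) and starts[i] < end + self.min_gap:
            return False
        if i > 0 and ends[i - 1] + self.min_gap > start:
            return False
        return True

    def reserve(self, chrom: str, start: int, end: int) -> None:
        self._insert(chrom, start, end)

    def try_place_at(self, chrom: str, start: int, length: int) -> bool:
        size = self.sizes[chrom]
        if start < self.edge_margin or start + length > size - self.edge_margin:
            return False
        if not self._fits(chrom, start, start + length):
            return False
        self._insert(chrom, start, start + length)
        return True

    def place(self, rng: np.random.Generator, length: int, tries: int = 500) -> GenomicInterval:
        for _ in range(tries):
            ci = rng.choice(len(self.chroms), p=self.probs)
            chrom = self.chroms[ci]
            size = self.sizes[chrom]
            hi = size - self.edge_margin - length
            if hi <= self.edge_margin:
                continue
            start = int(rng.integers(self.edge_margin, hi))
            if self.try_place_at(chrom, start, length):
                return GenomicInterval(chrom, start, start + length)
        raise ValueError(
            f"could not place an interval of length {length}: requested "
            "features do not fit the genome"
        )


# -- genome -----------------------------------------------------------------

def _random_pqs_motif(rng: np.random.Generator) -> str:
    """A guaranteed-match motif: four G3 runs with A/C/T loops of 1-7 nt."""
    parts = ["GGG"]
    for _ in range(3):
        ll = int(rng.integers(1, 8))
        loop = "".join(rng.choice(list("ACT"), size=ll))
        parts.append(loop + "GGG")
    return "".join(parts)


def make_genome(spec: SyntheticSpec) -> tuple[GenomeModel, GroundTruth]:
    """Random genome with planted PQS motifs, genes, CpG islands, blacklist.

    Genes are mutually separated by ``gene_min_gap`` bp (so TSS-anchored
    peaks never chain); CpG islands and blacklist regions avoid each other
    and the genes.  Planted motifs are padded with A on both sides so the
    scanner recovers each one.
    """
    rng = spec.rng(1)
    sizes = {f"chr{i + 1}": spec.chrom_len for i in range(spec.n_chroms)}
    seqs = {
        c: rng.integers(0, 4, size=n).astype(np.uint8) for c, n in sizes.items()
    }

    placer = _Placer(sizes, min_gap=spec.gene_min_gap, edge_margin=2000)
    genes = []
    for i in range(spec.n_genes):
        length = int(rng.integers(spec.gene_len[0], spec.gene_len[1] + 1))
        iv = placer.place(rng, length)
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GenomicInterval(iv.chrom, iv.start, iv.end, strand, f"gene{i + 1:05d}")
        )
    gene_set = IntervalSet(genes, label="genes")

    feat_placer = _Placer(sizes, exclude=gene_set, min_gap=600, edge_margin=1000)
    cpg = []
    for i in range(spec.n_cpg):
        length = int(rng.integers(spec.cpg_len[0], spec.cpg_len[1] + 1))
        iv = feat_placer.place(rng, length)
        cpg.append(GenomicInterval(iv.chrom, iv.start, iv.end, ".", f"cpg{i + 1:04d}"))
    blacklist = []
    for i in range(spec.n_blacklist):
        length = int(rng.integers(spec.blacklist_len[0], spec.blacklist_len[1] + 1))
        iv = feat_placer.place(rng, length)
        blacklist.append(
            GenomicInterval(iv.chrom, iv.start, iv.end, ".", f"bl{i + 1:03d}")
        )

    pqs = []
    for i in range(spec.pqs_planted):
        motif = _random_pqs_motif(rng)
        padded = "A" + motif + "A"
        iv = feat_placer.place(rng, len(padded))
        strand = "+" if rng.random() < 0.5 else "-"
        ins = padded if strand == "+" else _revcomp_str(padded)
        arr = np.frombuffer(ins.encode(), dtype="S1")
        idx = np.searchsorted(_BASES, arr)
        seqs[iv.chrom][iv.start : iv.end] = idx
        pqs.append(
            GenomicInterval(iv.chrom, iv.start + 1, iv.end - 1, strand, f"pqs{i + 1:03d}")
        )

    sequence = {c: _BASES[v].tobytes().decode() for c, v in seqs.items()}
    genome = GenomeModel(
        chrom_sizes=sizes,
        genes=gene_set,
        cpg_islands=IntervalSet(cpg, label="cpg_islands"),
        blacklist=IntervalSet(blacklist, label="blacklist"),
        sequence=sequence,
    )
    return genome, GroundTruth(pqs=IntervalSet(pqs, label="planted_pqs"))


def _revcomp_str(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


# -- peak replicates --------------------------------------------------------

def make_peak_replicates(
    genome: GenomeModel, spec: SyntheticSpec
) -> tuple[list[IntervalSet], GroundTruth]:
    """Latent true peaks observed by each replicate with probability ``r``.

    A fraction ``tss_fraction`` of latent peaks is centred on distinct gene
    TSS; the rest are uniform outside the blacklist and never overlap each
    other.  Spurious peaks are placed away from the latent footprint so
    they form their own components.  Antibody labels are assigned to the
    samples round-robin.
    """
    pp = spec.peak_params
    rng = spec.rng(2)
    n_tss = int(round(pp.n_peaks * pp.tss_fraction))
    genes = list(genome.genes) if genome.genes is not None else []
    if n_tss > len(genes):
        raise ValueError(f"tss_fraction needs {n_tss} genes, only {len(genes)} present")
    lengths = rng.integers(pp.len_min, pp.len_max + 1, size=pp.n_peaks)

    placer = _Placer(
        genome.chrom_sizes, exclude=genome.blacklist, min_gap=pp.min_gap,
        edge_margin=1000,
    )
    latent: list[GenomicInterval] = []
    is_tss = np.zeros(pp.n_peaks, dtype=bool)
    chosen = rng.choice(len(genes), size=n_tss, replace=False)
    for k, gi in enumerate(chosen):
        g = genes[gi]
        length = int(lengths[k])
        start = g.tss - length // 2
        if not placer.try_place_at(g.chrom, start, length):
            raise ValueError(
                f"TSS-centred peak at {g.chrom}:{start} does not fit; "
                "genome too crowded"
            )
        latent.append(GenomicInterval(g.chrom, start, start + length, ".", f"peak{k + 1:05d}"))
        is_tss[k] = True
    for k in range(n_tss, pp.n_peaks):
        iv = placer.place(rng, int(lengths[k]))
        latent.append(
            GenomicInterval(iv.chrom, iv.start, iv.end, ".", f"peak{k + 1:05d}")
        )
    latent_set = IntervalSet(latent, label="latent_peaks")

    samples: list[IntervalSet] = []
    for s in range(pp.n_samples):
        seen = rng.random(pp.n_peaks) < pp.reproducibility
        ivs = [latent[i] for i in np.flatnonzero(seen)]
        n_spur = int(rng.poisson(pp.spurious_rate))
        spur_placer = _Placer(
            genome.chrom_sizes,
            exclude=IntervalSet(list(genome.blacklist) + latent),
            min_gap=pp.min_gap,
            edge_margin=1000,
        )
        for j in range(n_spur):
            length = int(rng.integers(pp.len_min, pp.len_max + 1))
            iv = spur_placer.place(rng, length)
            ivs.append(
                GenomicInterval(iv.chrom, iv.start, iv.end, ".", f"spur_s{s}_{j}")
            )
        samples.append(
            IntervalSet(
                ivs,
                label=f"sample{s + 1}",
                sample_id=f"s{s + 1}",
                antibody=pp.antibodies[s % len(pp.antibodies)],
            )
        )
    truth = GroundTruth(latent_peaks=latent_set, peak_is_tss=is_tss)
    return samples, truth


# -- ChIP-Rx pair -----------------------------------------------------------

def make_chiprx_pair(
    genome: GenomeModel, spec: SyntheticSpec
) -> tuple[list[CoverageTrack], list[SpikeInStats], GroundTruth]:
    """Two ChIP-Rx samples with identical binding biology, different depths.

    The binding profile is enriched ``enrichment``-fold inside gene-TSS
    windows.  Per sample, the spike fraction of the ChIP library follows
    the (shared) spike cell ratio and capture factor, so reference-adjusted
    scaling must make the two tracks quantitatively equal.
    """
    sip = spec.spikein_params
    rng = spec.rng(3)
    bs = sip.bin_size
    windows = genome.tss_windows(500, 500)
    profile = {}
    for chrom, size in genome.chrom_sizes.items():
        nb = -(-size // bs)
        w = np.ones(nb)
        profile[chrom] = w
    for iv in windows:
        lo, hi = iv.start // bs, (iv.end - 1) // bs + 1
        profile[iv.chrom][lo:hi] = sip.enrichment
    total_w = sum(v.sum() for v in profile.values())

    phi = sip.spike_cell_ratio * sip.spike_capture / (
        1 + sip.spike_cell_ratio * sip.spike_capture
    )  # spike fraction of each ChIP library
    phi_input = sip.spike_cell_ratio / (1 + sip.spike_cell_ratio)

    tracks, stats = [], []
    factors = []
    for i, depth in enumerate(sip.depths):
        h_chip = int(rng.poisson(depth * (1 - phi)))
        s_chip = int(rng.poisson(depth * phi))
        h_input = int(rng.poisson(sip.input_depth * (1 - phi_input)))
        s_input = int(rng.poisson(sip.input_depth * phi_input))
        values = {
            c: rng.poisson(h_chip * w / total_w).astype(float)
            for c, w in profile.items()
        }
        tracks.append(CoverageTrack(bs, values, sample_id=f"rx{i + 1}"))
        st = SpikeInStats(h_chip, s_chip, h_input, s_input)
        stats.append(st)
        factors.append((s_input / h_input) / (s_chip / h_chip) * (1e8 / h_chip))
    return tracks, stats, GroundTruth(spike_factors=factors)


# -- single-cell experiment -------------------------------------------------

@dataclass
class ScExperiment:
    atac: CellMatrix
    atac_ann: pd.DataFrame
    atac_genes: IntervalSet
    rna: CellMatrix
    rna_ann: pd.DataFrame
    truth: GroundTruth


def _silence_mask(
    rng: np.random.Generator, maturity: np.ndarray, f_s: float, tau: float
) -> np.ndarray:
    """Bernoulli silencing concentrated in the most mature cells.

    The per-cell probability is a logistic ramp in maturity rank whose
    midpoint is solved so the expected silenced fraction equals ``f_s``.
    """
    if f_s <= 0:
        return np.zeros(len(maturity), dtype=bool)

    def frac(u0: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(maturity - u0) / tau))))

    lo, hi = -0.5, 1.5
    for _ in range(60):
        mid = (lo + hi) / 2
        if frac(mid) > f_s:
            lo = mid
        else:
            hi = mid
    p = 1.0 / (1.0 + np.exp(-(maturity - (lo + hi) / 2) / tau))
    return rng.random(len(maturity)) < p


def _sc_locus_annotation(n_background: int) -> IntervalSet:
    """Locus layout for the accessibility modality: anchor, targets and
    background genes spaced on one synthetic chromosome."""
    names = ["HBB", "HBA", "HBM"] + [f"bg{i + 1:03d}" for i in range(n_background)]
    out = []
    pos = 5000
    for name in names:
        out.append(GenomicInterval("scchr1", pos, pos + 2000, "+", name))
        pos += 8000
    return IntervalSet(out, label="sc_loci")


def make_sc_experiment(spec: SyntheticSpec) -> ScExperiment:
    """Control + case single-cell experiment with a planted silenced
    subpopulation in the case sample.

    ATAC counts are Poisson around per-locus rates that scale with a
    per-cell maturity rank; the silenced cells' HBA-like and HBM-like rates
    are multiplied by ``effect`` while HBB-like accessibility is unchanged.
    The RNA modality mirrors the design with HBA1+HBA2 expression
    proportional to HBB (ratio ``hba_hbb_ratio``) except in silenced cells.
    A warning is emitted when silencing is requested with no detectable
    effect (``effect >= 1``).
    """
    scp, rp = spec.sc_params, spec.rna_params
    if scp.silenced_fraction > 0 and scp.effect >= 1:
        import warnings

        warnings.warn("silenced_fraction > 0 with effect >= 1: no detectable effect")

    genes = _sc_locus_annotation(scp.n_background)
    gene_order = [g.name for g in genes]
    rng = spec.rng(4)
    bg_w = rng.dirichlet(np.full(scp.n_background, 20.0))

    # --- tiles: 3 per locus, inside the gene body
    tiles, tile_locus = [], []
    for g in genes:
        third = g.length // 3
        for t in range(3):
            lo = g.start + t * third
            hi = g.end if t == 2 else lo + third
            tiles.append(GenomicInterval(g.chrom, lo, hi, "+", f"{g.name}_t{t}"))
            tile_locus.append(g.name)
    tile_set = IntervalSet(tiles)
    tile_ids = [iv.name for iv in tiles]
    tile_w = np.array([0.5, 0.3, 0.2])

    cells, anns, silenced_ids = [], [], []
    blocks = []
    for sample, group in (("ctr", "control"), ("case", "case")):
        n = scp.n_cells
        depth = np.exp(rng.normal(scp.depth_meanlog, scp.depth_sdlog, size=n))
        depth = np.maximum(depth.astype(int), 50)
        maturity = (np.argsort(np.argsort(depth)) + 0.5) / n
        a0, a1 = scp.anchor_frac
        hbb = a0 + (a1 - a0) * maturity
        hba = scp.hba_rel * hbb
        hbm = scp.hbm_rel * hbb
        silenced = (
            _silence_mask(rng, maturity, scp.silenced_fraction, scp.maturity_tau)
            if group == "case"
            else np.zeros(n, dtype=bool)
        )
        eff = np.where(silenced, scp.effect, 1.0)
        special = np.column_stack([hbb, hba * eff, hbm * eff])
        bg = (1.0 - special.sum(axis=1))[:, None] * bg_w[None, :]
        locus_rates = np.column_stack([special, bg])  # order = gene_order
        lam = locus_rates * depth[:, None]
        # split each locus across its 3 tiles
        lam_tiles = (lam[:, :, None] * tile_w[None, None, :]).reshape(n, -1)
        counts = rng.poisson(lam_tiles)
        blocks.append(sp.csr_matrix(counts))
        ids = [f"{sample}_{i + 1:05d}" for i in range(n)]
        cells.extend(ids)
        silenced_ids.extend(np.array(ids)[silenced])
        anns.append(
            pd.DataFrame(
                {
                    "cell_id": ids,
                    "sample_id": sample,
                    "group": group,
                    "passed_filters": depth,
                    "maturity": maturity,
                    "silenced": silenced,
                }
            )
        )
    atac = CellMatrix(
        sp.vstack(blocks), cells, tile_ids, "atac_fragments", tile_set
    )
    atac_ann = pd.concat(anns, ignore_index=True)
    silenced_atac = frozenset(silenced_ids)

    # --- RNA modality
    rng_r = spec.rng(5)
    gene_names = ["HBB", "HBA1", "HBA2", "HBM"] + [
        f"rbg{i + 1:03d}" for i in range(rp.n_background)
    ]
    rbg_w = rng_r.dirichlet(np.full(rp.n_background, 20.0))
    r_cells, r_anns, r_blocks, r_silenced = [], [], [], []
    for sample, group in (("ctr", "control"), ("case", "case")):
        n = rp.n_cells
        depth = np.exp(rng_r.normal(rp.depth_meanlog, rp.depth_sdlog, size=n))
        depth = np.maximum(depth.astype(int), 200)
        maturity = (np.argsort(np.argsort(depth)) + 0.5) / n
        h0, h1 = rp.hbb_frac
        hbb = h0 + (h1 - h0) * maturity
        silenced = (
            _silence_mask(rng_r, maturity, scp.silenced_fraction, scp.maturity_tau)
            if group == "case"
            else np.zeros(n, dtype=bool)
        )
        eff = np.where(silenced, scp.effect, 1.0)
        hba_each = rp.hba_hbb_ratio * hbb / 2.0 * eff
        hbm = rp.hbm_rel * hbb * eff
        special = np.column_stack([hbb, hba_each, hba_each, hbm])
        bg = (1.0 - special.sum(axis=1))[:, None] * rbg_w[None, :]
        lam = np.column_stack([special, bg]) * depth[:, None]
        counts = rng_r.poisson(np.maximum(lam, 0))
        r_blocks.append(sp.csr_matrix(counts))
        ids = [f"{sample}_rna_{i + 1:05d}" for i in range(n)]
        r_cells.extend(ids)
        r_silenced.extend(np.array(ids)[silenced])
        pct_mito = 100.0 * rng_r.beta(rp.mito_alpha, rp.mito_beta, size=n)
        n_features = np.clip(
            rng_r.normal(rp.nfeat_mean, rp.nfeat_sd, size=n).astype(int), 50, 6000
        )
        r_anns.append(
            pd.DataFrame(
                {
                    "cell_id": ids,
                    "sample_id": sample,
                    "group": group,
                    "passed_filters": depth,
                    "pct_mito": pct_mito,
                    "n_features": n_features,
                    "maturity": maturity,
                    "silenced": silenced,
                }
            )
        )
    rna = CellMatrix(sp.vstack(r_blocks), r_cells, gene_names, "rna_umis")
    rna_ann = pd.concat(r_anns, ignore_index=True)

    truth = GroundTruth(
        silenced_atac=silenced_atac, silenced_rna=frozenset(r_silenced)
    )
    return ScExperiment(atac, atac_ann, genes, rna, rna_ann, truth)


def make_enrichment_peaks(
    genome: GenomeModel, spec: SyntheticSpec
) -> tuple[IntervalSet, np.ndarray]:
    """Peak set for enrichment-recovery experiments.

    A fraction ``tss_fraction`` of peaks is centred on distinct gene TSS;
    the rest are placed *independently* (mutual overlap allowed), uniformly
    over the placement space outside the blacklist — the same space the
    matched null draws from — so the TSS-overlap probability of a
    background peak is exactly the uniform placement probability.
    """
    pp = spec.peak_params
    rng = spec.rng(6)
    n_tss = int(round(pp.n_peaks * pp.tss_fraction))
    genes = list(genome.genes) if genome.genes is not None else []
    if n_tss > len(genes):
        raise ValueError(f"tss_fraction needs {n_tss} genes, only {len(genes)} present")
    lengths = rng.integers(pp.len_min, pp.len_max + 1, size=pp.n_peaks)
    out: list[GenomicInterval] = []
    is_tss = np.zeros(pp.n_peaks, dtype=bool)
    chosen = rng.choice(len(genes), size=n_tss, replace=False)
    for k, gi in enumerate(chosen):
        g = genes[gi]
        length = int(lengths[k])
        start = max(0, g.tss - length // 2)
        out.append(GenomicInterval(g.chrom, start, start + length, ".", f"pk{k + 1:05d}"))
        is_tss[k] = True
    if n_tss < pp.n_peaks:
        from .enrichment import matched_random_fragments

        proto = IntervalSet(
            [
                GenomicInterval("chr1", 0, int(l))
                for l in lengths[n_tss:]
            ]
        )
        uniform = matched_random_fragments(
            proto, genome, exclude=genome.blacklist, seed=rng
        )
        for j, iv in enumerate(uniform):
            out.append(
                GenomicInterval(iv.chrom, iv.start, iv.end, ".", f"pk{n_tss + j + 1:05d}")
            )
    return IntervalSet(out, label="enrichment_peaks"), is_tss
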