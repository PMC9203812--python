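"""Cross-sample consensus peak filtering.

A peak is retained in the final call only when it is reproduced across
samples: per-sample peak calls are pooled and chained into connected
components (>= 1 bp overlap links), and a component survives iff it
contains peaks from at least ``min_samples`` distinct samples and — when
antibody agreement is required — from at least two distinct antibody
labels.  Retained components overlapping a signal-artefact blacklist by
>= 1 bp are removed, as are components whose mean background (input / gDNA)
signal exceeds a threshold.  The reported footprint is the component union.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genome_io import GenomicInterval, IntervalSet
from .tracks import CoverageTrack

__all__ = [
    "ConsensusConfig",
    "ConsensusPeak",
    "consensus_filter",
    "consensus_monotonicity_report",
    "default_background_threshold",
]


@dataclass
class ConsensusConfig:
    min_samples: int = 3
    require_antibody_agreement: bool = False
    blacklist: IntervalSet = field(default_factory=IntervalSet)
    background_track: CoverageTrack | None = None
    background_threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")
        if self.background_threshold < 0:
            raise ValueError("background_threshold must be >= 0")


@dataclass(frozen=True)
class ConsensusPeak:
    interval: GenomicInterval  # union footprint of the component
    supporting_samples: tuple[str, ...]
    antibodies_supporting: frozenset[str]


def _components(
    per_sample: Sequence[IntervalSet],
) -> list[tuple[GenomicInterval, tuple[str, ...], frozenset[str]]]:
    """Pool all samples' peaks and chain them into >=1 bp overlap components."""
    ids = [s.sample_id or f"sample{i}" for i, s in enumerate(per_sample)]
    if len(set(ids)) != len(ids):
        raise ValueError("sample_ids must be unique")
    pooled: list[tuple[str, int, int, str, str]] = []
    for sid, s in zip(ids, per_sample):
        ab = s.antibody or ""
        for iv in s:
            pooled.append((iv.chrom, iv.start, iv.end, sid, ab))
    pooled.sort()
    comps = []
    cur: list | None = None
    for chrom, start, end, sid, ab in pooled:
        if cur is not None and chrom == cur[0] and start < cur[2]:
            cur[2] = max(cur[2], end)
            cur[3].add(sid)
            if ab:
                cur[4].add(ab)
        else:
            if cur is not None:
                comps.append(cur)
            cur = [chrom, start, end, {sid}, {ab} if ab else set()]
    if cur is not None:
        comps.append(cur)
    return [
        (
            GenomicInterval(c[0], c[1], c[2]),
            tuple(sorted(c[3])),
            frozenset(c[4]),
        )
        for c in comps
    ]


def consensus_filter(
    per_sample: Sequence[IntervalSet], cfg: ConsensusConfig
) -> list[ConsensusPeak]:
    """Apply the retention rules; output sorted by coordinate.

    Raises if antibody agreement is requested but fewer than two distinct
    antibody labels are present across the input samples.
    """
    if not per_sample:
        raise ValueError("need at least one sample peak set")
    if cfg.require_antibody_agreement:
        labels = {s.antibody for s in per_sample if s.antibody}
        if len(labels) < 2:
            raise ValueError(
                "antibody agreement requested but fewer than 2 distinct "
                "antibody labels present"
            )
    out: list[ConsensusPeak] = []
    candidates = []
    for iv, samples, abs_ in _components(per_sample):
        if len(samples) < cfg.min_samples:
            continue
        if cfg.require_antibody_agreement and len(abs_) < 2:
            continue
        candidates.append(ConsensusPeak(iv, samples, abs_))
    if candidates and len(cfg.blacklist):
        # components are produced in (chrom, start, end) order, so the
        # flags from the (sorted) IntervalSet align positionally
        keep = ~cfg.blacklist.overlaps_any(
            IntervalSet([p.interval for p in candidates])
        )
        candidates = [p for p, k in zip(candidates, keep) if k]
    if cfg.background_track is not None:
        candidates = [
            p
            for p in candidates
            if cfg.background_track.mean_over(p.interval) <= cfg.background_threshold
        ]
    out = sorted(
        candidates, key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end)
    )
    return out


def consensus_monotonicity_report(
    per_sample: Sequence[IntervalSet], cfg: ConsensusConfig
) -> dict[int, int]:
    """Retained component count for every min_samples value 1..n_samples.

    The count is non-increasing in ``min_samples``.
    """
    counts: dict[int, int] = {}
    for k in range(1, len(per_sample) + 1):
        cfg_k = ConsensusConfig(
            min_samples=k,
            require_antibody_agreement=cfg.require_antibody_agreement,
            blacklist=cfg.blacklist,
            background_track=cfg.background_track,
            background_threshold=cfg.background_threshold,
        )
        counts[k] = len(consensus_filter(per_sample, cfg_k))
    return counts


def default_background_threshold(
    track: CoverageTrack,
    n_bins: int = 1000,
    n_sd: float = 3.0,
    seed: int = 0,
) -> float:
    """Mean + ``n_sd`` standard deviations over random genomic bins."""
    rng = np.random.default_rng(seed)
    vals = []
    chroms = list(track.values)
    sizes = np.array([len(track.values[c]) for c in chroms], dtype=float)
    probs = sizes / sizes.sum()
    picks = rng.choice(len(chroms), size=n_bins, p=probs)
    for ci in picks:
        arr = track.values[chroms[ci]]
        vals.append(arr[rng.integers(0, len(arr))])
    vals = np.asarray(vals, dtype=float)
    return float(vals.mean() + n_sd * vals.std())
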