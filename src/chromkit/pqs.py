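"""Putative G-quadruplex sequence (PQS) scanning.

The motif is the canonical four-run rule used throughout the G4 literature:
``n_runs`` runs of at least ``min_run`` guanines separated by loops of
``loop_min``..``loop_max`` arbitrary (non-N) nucleotides, i.e. the pattern

    G{min_run,} ( [ACGT]{loop_min,loop_max} G{min_run,} ) x (n_runs - 1)

on the plus strand, and its reverse complement (a C-run pattern) on the
minus strand.  Matching is leftmost-greedy and maximal per strand, with the
exact backtracking semantics of a greedy regular expression: at each
candidate start the first run takes as many G as possible, each loop takes
as many bases as possible, and longer alternatives are preferred before
shorter ones.  ``N`` never matches; lowercase (soft-masked) bases never
match unless ``allow_lowercase`` is set.  Hit coordinates are 0-based
half-open on the plus strand regardless of hit strand.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome_io import GenomicInterval, IntervalSet

__all__ = ["PQSHit", "scan_pqs", "pqs_overlap_fraction", "revcomp"]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PQSHit:
    """One PQS match.

    ``g_run_lengths`` and ``loop_lengths`` describe the match in its own
    reading direction (5'->3' on the hit strand); the interval is always
    reported in plus-strand coordinates.  The interval length equals the sum
    of runs and loops.
    """

    interval: GenomicInterval
    g_run_lengths: tuple[int, ...]
    loop_lengths: tuple[int, ...]
    matched_sequence: str


def _validate(sequence: str) -> None:
    allowed = set("ACGTNacgtn")
    for i, ch in enumerate(sequence):
        if ch not in allowed:
            raise ValueError(f"invalid alphabet symbol {ch!r} at offset {i}")


def _scan_one_strand(
    seq: str, min_run: int, loop_min: int, loop_max: int, n_runs: int,
    allow_lowercase: bool,
) -> list[tuple[int, int, tuple[int, ...], tuple[int, ...]]]:
    """Greedy leftmost scan for the G-pattern on one strand.

    Returns (start, end, run_lengths, loop_lengths) tuples, non-overlapping.
    """
    if allow_lowercase:
        seq = seq.upper()
    n = len(seq)
    # g_run[i]: length of the maximal G-run starting at i (0 if seq[i] != G)
    g_run = [0] * (n + 1)
    for i in range(n - 1, -1, -1):
        if seq[i] == "G":
            g_run[i] = g_run[i + 1] + 1
    loop_ok = [c in "ACGT" for c in seq]
    # prefix sums of loop-valid flags for O(1) "all valid in [a,b)" checks
    pref = [0] * (n + 1)
    for i in range(n):
        pref[i + 1] = pref[i] + (1 if loop_ok[i] else 0)

    def all_loop_ok(a: int, b: int) -> bool:
        return pref[b] - pref[a] == b - a

    def match_from(pos: int, runs_left: int):
        """Greedy-with-backtracking match expecting a G-run at ``pos``.

        Returns (end, [run_lengths], [loop_lengths]) or None.
        """
        avail = g_run[pos]
        if avail < min_run:
            return None
        if runs_left == 1:
            return pos + avail, [avail], []
        for r in range(avail, min_run - 1, -1):
            base = pos + r
            hi = min(loop_max, n - base)
            for l in range(hi, loop_min - 1, -1):
                nxt = base + l
                if not all_loop_ok(base, nxt):
                    continue
                sub = match_from(nxt, runs_left - 1)
                if sub is not None:
                    end, runs, loops = sub
                    return end, [r] + runs, [l] + loops
        return None

    min_len = n_runs * min_run + (n_runs - 1) * loop_min
    hits = []
    i = 0
    limit = n - min_len
    while i <= limit:
        if g_run[i] >= min_run:
            m = match_from(i, n_runs)
            if m is not None:
                end, runs, loops = m
                hits.append((i, end, tuple(runs), tuple(loops)))
                i = end
                continue
            # no match can start inside this failed run's prefix either,
            # but shorter suffixes of the run may still seed one
        i += 1
    return hits


def scan_pqs(
    sequence: str,
    chrom: str = "",
    min_run: int = 3,
    loop_min: int = 1,
    loop_max: int = 7,
    n_runs: int = 4,
    allow_lowercase: bool = False,
) -> list[PQSHit]:
    """Scan both strands of ``sequence`` for PQS.

    Hits are maximal, non-overlapping per strand under leftmost-greedy
    scanning.  The result is sorted by plus-strand coordinate.
    """
    if min_run < 1 or loop_min < 1 or n_runs < 2 or loop_min > loop_max:
        raise ValueError("require min_run>=1, 1<=loop_min<=loop_max, n_runs>=2")
    _validate(sequence)
    n = len(sequence)
    hits: list[PQSHit] = []
    for start, end, runs, loops in _scan_one_strand(
        sequence, min_run, loop_min, loop_max, n_runs, allow_lowercase
    ):
        hits.append(
            PQSHit(
                GenomicInterval(chrom or "seq", start, end, "+", "G4", end - start),
                runs,
                loops,
                sequence[start:end],
            )
        )
    rc = revcomp(sequence)
    for start, end, runs, loops in _scan_one_strand(
        rc, min_run, loop_min, loop_max, n_runs, allow_lowercase
    ):
        # reflect back onto plus-strand coordinates
        ps, pe = n - end, n - start
        hits.append(
            PQSHit(
                GenomicInterval(chrom or "seq", ps, pe, "-", "G4", pe - ps),
                runs,
                loops,
                rc[start:end],
            )
        )
    hits.sort(key=lambda h: (h.interval.start, h.interval.end, h.interval.strand))
    return hits


def hits_to_intervals(hits: list[PQSHit], label: str = "pqs") -> IntervalSet:
    return IntervalSet([h.interval for h in hits], label=label)


def pqs_overlap_fraction(peaks: IntervalSet, hits: list[PQSHit] | IntervalSet) -> float:
    """Fraction of peaks overlapping >= 1 PQS hit, strand-blind.

    The merged PQS footprint is used, so nested or duplicated hits count a
    peak only once.
    """
    if len(peaks) == 0:
        return 0.0
    iset = hits if isinstance(hits, IntervalSet) else hits_to_intervals(hits)
    if len(iset) == 0:
        return 0.0
    return iset.merged().count_overlapping(peaks) / len(peaks)
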