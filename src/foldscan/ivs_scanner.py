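"""Detection of imperfect inverted repeats (IVS) in a reference window.

An IVS is a pair of same-strand segments (arms) where the downstream arm is
the reverse complement of the upstream one, separated by a spacer. Such
structures can fold back and self-pair during library preparation; any
imperfection in the pairing (a mismatched column or an unpaired bulge) is a
site where chimera repair writes the "perfecting" base, i.e. a predictable
artifact variant.

Detection operates on pairing anti-diagonals: positions p (arm 1) and q
(arm 2) pair in a gapless fold-back alignment iff p + q is constant, so a
candidate structure is a run of complementary columns on one anti-diagonal.
Runs of exact pairing are the seeds; runs separated by at most
``max_interrupt`` non-pairing columns are chained into one structure
(mismatch interruptions), and pairs of exact runs on anti-diagonals
differing by g <= ``max_interrupt`` are joined into single-gap structures
(bulge interruptions). This enumeration is complete for the structure
classes it reports, which is asserted against a brute-force oracle in the
test suite. Structures combining a gap with mismatches, or with more than
one gap, are not reported.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .genome_io import (
    GenomicInterval,
    ReferenceWindow,
    complement_base,
    left_align_indel,
    reverse_complement,
)

__all__ = [
    "IVSParams",
    "Interruption",
    "InvertedRepeat",
    "kmer_census",
    "scan_ivs",
    "ivs_blacklist",
]

MISMATCH = "mismatch"
GAP_ARM1 = "gap_arm1"  # unpaired (bulged) bases on arm 1
GAP_ARM2 = "gap_arm2"  # unpaired (bulged) bases on arm 2


@dataclass(frozen=True)
class IVSParams:
    """Detection and blacklist thresholds for inverted repeats.

    Default criteria: spacer >= 5 bp between the arms, per-arm aligned
    length >= 8 bp, and an interruption at least 2 bp from either end of
    the arm alignment before it is blacklisted.
    """

    min_spacer: int = 5
    min_arm: int = 8
    min_edge: int = 2
    seed_len: int = 8
    max_interrupt: int = 1
    max_spacer: int = 300
    kmin: int = 2
    kmax: int | None = None

    def __post_init__(self) -> None:
        if self.min_spacer < 0 or self.min_edge < 1 or self.max_interrupt < 1:
            raise ValueError("invalid IVS parameters")

    @property
    def effective_seed(self) -> int:
        """Exact-block length every reported structure must contain.

        Capped by the shortest exact block a qualifying structure can have
        (one interruption of ``max_interrupt`` splitting ``min_arm`` columns),
        so that seed-based detection stays complete for the thresholds.
        """
        guaranteed = max(1, math.ceil((self.min_arm - self.max_interrupt) / 2))
        return min(self.seed_len, guaranteed)


@dataclass(frozen=True)
class Interruption:
    """One imperfection in an arm alignment.

    For a mismatch run, ``arm1_off``/``arm2_off`` are the offsets (within
    arm1/arm2, left to right) of the leftmost base of the run on each arm;
    column i of the run pairs arm1 base (arm1_off + i) with arm2 base
    (arm2_off + length - 1 - i). For a gap, the offsets locate the bulge on
    the carrying arm and the insertion anchor (base left of the junction) on
    the partner arm. ``left_cols``/``right_cols`` count alignment columns
    flanking the interruption, used for the edge-distance criterion.
    """

    kind: str
    arm1_off: int
    arm2_off: int
    arm1_bases: str
    arm2_bases: str
    length: int
    left_cols: int
    right_cols: int


@dataclass(frozen=True)
class InvertedRepeat:
    arm1: GenomicInterval
    arm2: GenomicInterval
    spacer_len: int
    aligned_len: int
    interruptions: tuple[Interruption, ...]

    @property
    def structure_id(self) -> str:
        return (
            f"IVS:{self.arm1.chrom}:{self.arm1.start}-{self.arm1.end}"
            f"_{self.arm2.start}-{self.arm2.end}"
        )

    def contains(self, other: "InvertedRepeat") -> bool:
        return self.arm1.contains(other.arm1) and self.arm2.contains(other.arm2)


def kmer_census(seq: str, kmin: int, kmax: int) -> tuple[int, Counter]:
    """Enumerate every K-mer of the sequence for K in [kmin, kmax].

    The conceptual first step of the inverted-repeat workflow: a sequence of
    length L yields L - K + 1 K-mers per K, total sum over K of (L - K + 1).
    K may range over 2..L/2. Duplicate K-mers are retained (multiset).
    """
    L = len(seq)
    if kmin < 2 or kmin > kmax:
        raise ValueError("require 2 <= kmin <= kmax")
    if kmax > L // 2:
        raise ValueError(f"kmax {kmax} exceeds L/2 = {L // 2}")
    census: Counter = Counter()
    total = 0
    for K in range(kmin, kmax + 1):
        n = L - K + 1
        total += n
        for i in range(n):
            census[seq[i : i + K]] += 1
    return total, census


# ---------------------------------------------------------------------------
# pairing machinery

_CODE = np.zeros(256, dtype=np.int8)
for _i, _b in enumerate("ACGT", start=1):
    _CODE[ord(_b)] = _i
_PAIR_OF = np.zeros(5, dtype=np.int8)  # code of complement; 0 = N/unknown
_PAIR_OF[1], _PAIR_OF[2], _PAIR_OF[3], _PAIR_OF[4] = 4, 3, 2, 1


def _column_values(enc: np.ndarray, d: int, p_lo: int, p_hi: int) -> np.ndarray:
    """Per-column state on anti-diagonal d: 1 pair, 0 mismatch, -1 N."""
    ps = np.arange(p_lo, p_hi + 1)
    a = enc[ps]
    b = enc[d - ps]
    vals = np.where((a == 0) | (b == 0), -1, (_PAIR_OF[a] == b).astype(np.int8))
    return vals.astype(np.int8)


def _run_arrays(vals: np.ndarray, p_lo: int):
    """Maximal runs of equal state as numpy arrays (states, starts, ends),
    start/end columns inclusive."""
    n = len(vals)
    breaks = np.flatnonzero(vals[1:] != vals[:-1])
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [n - 1]))
    return vals[starts], starts + p_lo, ends + p_lo


def scan_ivs(window: ReferenceWindow, params: IVSParams) -> list[InvertedRepeat]:
    """Report maximal imperfect inverted repeats in the window.

    A reported structure satisfies: spacer in [min_spacer, max_spacer],
    aligned columns >= min_arm, every interruption <= max_interrupt bp, an
    exact block >= the effective seed length, arms exact reverse complements
    outside interruptions. Structures whose arms are both contained in
    another reported structure's arms are removed; output is sorted by
    (arm1.start, arm2.start).
    """
    seq = window.seq
    W = len(seq)
    results: list[InvertedRepeat] = []
    if W < 2:
        return results
    enc = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    eff_seed = params.effective_seed

    # perfect (exact pairing) runs per anti-diagonal, as numpy arrays
    perfect_runs: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    gapless: list[tuple[int, int, int, tuple[int, int] | None]] = []
    for d in range(1, 2 * W - 2):
        p_lo = max(0, d - W + 1)
        p_hi = (d - 1) // 2
        if p_hi < p_lo:
            continue
        vals = _column_values(enc, d, p_lo, p_hi)
        states, starts, ends = _run_arrays(vals, p_lo)
        ones = states == 1
        if ones.any():
            perfect_runs[d] = (starts[ones], ends[ones])
        lens = ends - starts + 1
        # lone exact runs as candidates (no interruption)
        lone = ones & (lens >= params.min_arm) & (lens >= eff_seed)
        lone &= (d - 2 * ends - 1 >= params.min_spacer) & (
            d - 2 * ends - 1 <= params.max_spacer
        )
        for i in np.flatnonzero(lone):
            gapless.append((d, int(starts[i]), int(ends[i]), None))
        # adjacent exact runs bridged by one mismatch run <= max_interrupt
        # (at most one interruption per structure, like the palindrome
        # scanner's one-mismatch rule; N runs are never bridged)
        n_runs = len(states)
        if n_runs >= 3:
            mid = np.arange(1, n_runs - 1)
            bridge = (
                (states[mid] == 0)
                & (lens[mid] <= params.max_interrupt)
                & (states[mid - 1] == 1)
                & (states[mid + 1] == 1)
            )
            p1s = starts[mid - 1]
            p2s = ends[mid + 1]
            aligned = p2s - p1s + 1
            maxblk = np.maximum(lens[mid - 1], lens[mid + 1])
            spacer = d - 2 * p2s - 1
            bridge &= (
                (aligned >= params.min_arm)
                & (maxblk >= eff_seed)
                & (spacer >= params.min_spacer)
                & (spacer <= params.max_spacer)
            )
            for i in np.flatnonzero(bridge):
                k = int(mid[i])
                gapless.append(
                    (d, int(p1s[i]), int(p2s[i]), (int(starts[k]), int(ends[k])))
                )

    structures: list[InvertedRepeat] = []
    seen: set[tuple] = set()
    win0 = window.interval.start
    chrom = window.interval.chrom

    def add(struct: InvertedRepeat) -> None:
        key = (struct.arm1, struct.arm2, tuple(struct.interruptions))
        if key not in seen:
            seen.add(key)
            structures.append(struct)

    # gapless (mismatch-interrupted) structures
    for d, p1, p2, mm_run in gapless:
        aligned = p2 - p1 + 1
        spacer = d - 2 * p2 - 1
        arm1 = GenomicInterval(chrom, win0 + p1, win0 + p2 + 1)
        arm2 = GenomicInterval(chrom, win0 + d - p2, win0 + d - p1 + 1)
        ints = []
        if mm_run is not None:
            s, e = mm_run
            m = e - s + 1
            ints.append(
                Interruption(
                    kind=MISMATCH,
                    arm1_off=s - p1,
                    arm2_off=(d - e) - (d - p2),
                    arm1_bases=seq[s : e + 1],
                    arm2_bases=seq[d - e : d - s + 1],
                    length=m,
                    left_cols=s - p1,
                    right_cols=p2 - e,
                )
            )
        add(InvertedRepeat(arm1, arm2, spacer, aligned, tuple(ints)))

    # single-gap structures: exact run on d joined with exact run on d +/- g
    for d, (s1, e1) in perfect_runs.items():
        l1max = int((e1 - s1).max()) + 1
        for g in range(1, params.max_interrupt + 1):
            for side, d_inner in ((GAP_ARM1, d + g), (GAP_ARM2, d - g)):
                inner = perfect_runs.get(d_inner)
                if inner is None:
                    continue
                s2, e2 = inner
                if l1max + int((e2 - s2).max()) + 1 < params.min_arm:
                    continue
                skip = g + 1 if side == GAP_ARM1 else 1
                # feasible partners: r2e >= r1s + skip and r2s <= r1e + skip
                los = np.searchsorted(e2, s1 + skip, side="left")
                his = np.searchsorted(s2, e1 + skip, side="right")
                for idx in np.flatnonzero(his > los):
                    r1s, r1e = int(s1[idx]), int(e1[idx])
                    for k in range(int(los[idx]), int(his[idx])):
                        r2s, r2e = int(s2[k]), int(e2[k])
                        j = max(r1s, r2s - skip)  # left-normalized junction
                        if j > r1e or j + skip > r2e:
                            continue
                        p1, p3 = r1s, r2e
                        outer_len = j - p1 + 1
                        inner_len = p3 - (j + skip) + 1
                        if inner_len < 1:
                            continue
                        aligned = outer_len + inner_len
                        spacer = d_inner - 2 * p3 - 1
                        if aligned < params.min_arm:
                            continue
                        if max(outer_len, inner_len) < eff_seed:
                            continue
                        if not (params.min_spacer <= spacer <= params.max_spacer):
                            continue
                        if side == GAP_ARM1:
                            arm1 = GenomicInterval(chrom, win0 + p1, win0 + p3 + 1)
                            arm2 = GenomicInterval(
                                chrom, win0 + d_inner - p3, win0 + d - p1 + 1
                            )
                            bulge = seq[j + 1 : j + g + 1]
                            intr = Interruption(
                                kind=GAP_ARM1,
                                arm1_off=j + 1 - p1,
                                arm2_off=(d - j - 1) - (d_inner - p3),
                                arm1_bases=bulge,
                                arm2_bases="",
                                length=g,
                                left_cols=outer_len,
                                right_cols=inner_len,
                            )
                        else:
                            arm1 = GenomicInterval(chrom, win0 + p1, win0 + p3 + 1)
                            arm2 = GenomicInterval(
                                chrom, win0 + d_inner - p3, win0 + d - p1 + 1
                            )
                            bulge = seq[d - j - g : d - j]
                            intr = Interruption(
                                kind=GAP_ARM2,
                                arm1_off=j - p1,
                                arm2_off=(d - j - g) - (d_inner - p3),
                                arm1_bases="",
                                arm2_bases=bulge,
                                length=g,
                                left_cols=outer_len,
                                right_cols=inner_len,
                            )
                        add(InvertedRepeat(arm1, arm2, spacer, aligned, (intr,)))

    # containment removal (overlaps kept)
    if not structures:
        return []
    a1s = np.array([s.arm1.start for s in structures])
    a1e = np.array([s.arm1.end for s in structures])
    a2s = np.array([s.arm2.start for s in structures])
    a2e = np.array([s.arm2.end for s in structures])
    kept: list[InvertedRepeat] = []
    for i, s in enumerate(structures):
        dominating = (
            (a1s <= a1s[i]) & (a1e >= a1e[i]) & (a2s <= a2s[i]) & (a2e >= a2e[i])
        )
        # strict containment: the container differs in at least one bound
        strict = dominating & (
            (a1s < a1s[i]) | (a1e > a1e[i]) | (a2s < a2s[i]) | (a2e > a2e[i])
        )
        if not strict.any():
            kept.append(s)
    kept.sort(key=lambda s: (s.arm1.start, s.arm2.start))
    return kept


# ---------------------------------------------------------------------------
# blacklist extraction

def ivs_blacklist(
    ivs_list: Iterable[InvertedRepeat],
    window: ReferenceWindow,
    params: IVSParams,
    roi: Iterable[GenomicInterval] | None = None,
):
    """Predicted artifact sites at IVS interruptions.

    A mismatch column yields entries at both genomic positions of the pair;
    the predicted artifact allele at each site is the complement of the
    partner arm's base (the base that would create perfect pairing). A gap
    of g bases yields a g-base deletion at the bulge and a g-base insertion
    at the mirrored site on the partner arm, left-normalized. Interruptions
    closer than ``min_edge`` columns to either alignment end emit nothing;
    sites outside the roi are dropped.
    """
    from .blacklist import BlacklistEntry

    roi = tuple(roi) if roi is not None else window.origins
    seq = window.seq
    win0 = window.interval.start
    chrom = window.interval.chrom

    def in_roi(start: int, end: int) -> bool:
        probe = GenomicInterval(chrom, start, max(end, start + 1))
        return any(probe.overlaps(o) for o in roi)

    entries = []

    def emit(start: int, end: int, ref: str, alt: str, sid: str) -> None:
        if "N" in ref or "N" in alt or ref == alt:
            return
        if not in_roi(start, end):
            return
        entries.append(
            BlacklistEntry(
                chrom=chrom, start=start, end=end, ref=ref, predicted_alt=alt,
                source="IVS", structure_id=sid,
            )
        )

    def emit_indel(pos_g: int, ref: str, alt: str, sid: str) -> None:
        off = pos_g - win0
        if off < 0:
            return
        noff, nref, nalt = left_align_indel(off, ref, alt, seq)
        emit(win0 + noff, win0 + noff + len(nref), nref, nalt, sid)

    for ivs in ivs_list:
        if ivs.spacer_len < params.min_spacer or ivs.aligned_len < params.min_arm:
            continue
        for intr in ivs.interruptions:
            if intr.left_cols < params.min_edge or intr.right_cols < params.min_edge:
                continue
            if intr.kind == MISMATCH:
                m = intr.length
                a1 = ivs.arm1.start + intr.arm1_off
                a2 = ivs.arm2.start + intr.arm2_off
                for i in range(m):
                    p = a1 + i  # pairs with arm2 base at a2 + m - 1 - i
                    q = a2 + m - 1 - i
                    bp, bq = seq[p - win0], seq[q - win0]
                    if bp == "N" or bq == "N":
                        continue
                    emit(p, p + 1, bp, complement_base(bq), ivs.structure_id)
                    emit(q, q + 1, bq, complement_base(bp), ivs.structure_id)
            else:
                g = intr.length
                if intr.kind == GAP_ARM1:
                    bulge0 = ivs.arm1.start + intr.arm1_off
                    anchor = ivs.arm2.start + intr.arm2_off
                    bulge = intr.arm1_bases
                else:
                    bulge0 = ivs.arm2.start + intr.arm2_off
                    anchor = ivs.arm1.start + intr.arm1_off
                    bulge = intr.arm2_bases
                if "N" in bulge:
                    continue
                # deletion of the bulge at its own site
                d0 = bulge0 - 1
                if d0 >= win0:
                    ref = seq[d0 - win0 : d0 - win0 + g + 1]
                    emit_indel(d0, ref, ref[0], ivs.structure_id)
                # insertion of the reverse-complement bulge on the partner arm
                a_off = anchor - win0
                if a_off >= 0:
                    base = seq[a_off]
                    emit_indel(
                        anchor, base, base + reverse_complement(bulge), ivs.structure_id
                    )

    # dedupe by site+allele, keep first structure id
    uniq: dict[tuple, object] = {}
    for e in entries:
        uniq.setdefault((e.chrom, e.start, e.end, e.predicted_alt), e)
    return sorted(uniq.values(), key=lambda e: (e.chrom, e.start, e.end, e.predicted_alt))
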