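"""Detection of imperfect palindromic sequences (PS) by central expansion.

A palindromic sequence reads as its own reverse complement around a center;
in odd-center form the center base is unpaired. Every position of the
window is treated as a candidate center and expanded outward, comparing the
base k to the left with the complement of the base k to the right. The
expansion records the first non-pairing column as the structure's internal
mismatch and halts immediately before the second one (or at a sequence
end), so a reported structure has at most one internal mismatched pair and
its longest continuously matched stretch is helix_len - 2 (one column lost
to the unpaired center, one to the mismatch).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .genome_io import GenomicInterval, ReferenceWindow, complement_base

__all__ = ["PSParams", "Palindrome", "expand_palindrome", "scan_ps", "ps_blacklist"]

_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass(frozen=True)
class PSParams:
    """Palindrome thresholds: minimum full span (helix) and the mismatch
    count at which expansion halts (default 2: the second mismatch
    terminates, so a structure carries at most one internal mismatch)."""

    min_helix: int = 17
    stop_mismatches: int = 2
    include_even_centers: bool = False

    def __post_init__(self) -> None:
        if self.min_helix < 3 or self.stop_mismatches < 1:
            raise ValueError("invalid PS parameters")


@dataclass(frozen=True)
class Palindrome:
    """An odd-center fold-back: ``span`` is the full structure, ``center``
    the genomic position of the unpaired center base. ``mismatches`` holds
    the internal non-pairing columns as (left_pos, right_pos, left_base,
    right_base); a base may be N (recorded for bookkeeping, never
    blacklisted). ``even`` marks between-base centers (center = left
    flanking position)."""

    center: int
    span: GenomicInterval
    helix_len: int
    mismatches: tuple[tuple[int, int, str, str], ...]
    matched_len: int
    even: bool = False

    @property
    def structure_id(self) -> str:
        c = f"{self.center}.5" if self.even else str(self.center)
        return f"PS:{self.span.chrom}:{c}"

    @property
    def mismatch(self):
        """The single internal mismatch pair, when exactly one is present."""
        return self.mismatches[0] if len(self.mismatches) == 1 else None


def _column(seq: str, left: int, right: int) -> bool:
    return (seq[left], seq[right]) in _PAIRS


def expand_palindrome(
    seq: str,
    center_index: int,
    stop_mismatches: int = 2,
    *,
    even: bool = False,
) -> Palindrome | None:
    """Expand a palindrome around one center of a plain sequence string.

    Coordinates in the returned structure are sequence offsets (callers
    embed them genomically). Returns None when not even the innermost
    column pairs and no mismatch can be internal (helix would be a bare
    center). An N in either base of a column counts as a mismatch for the
    stopping rule.
    """
    n = len(seq)
    if not (0 <= center_index < n):
        raise IndexError("center outside sequence")
    mms: list[tuple[int, int, str, str]] = []
    k_last = 0
    k = 1
    while True:
        left = center_index - k
        right = center_index + k - 1 if even else center_index + k
        if left < 0 or right >= n:
            break
        if _column(seq, left, right):
            k_last = k
        else:
            if len(mms) + 1 >= stop_mismatches:
                break  # halt immediately before this, the stopping mismatch
            mms.append((left, right, seq[left], seq[right]))
            k_last = k
        k += 1
    # trim a terminal mismatch: the outermost column must pair
    while mms and mms[-1][0] == center_index - k_last:
        mms.pop()
        k_last -= 1
    if k_last < 1:
        return None
    if even:
        span = (center_index - k_last, center_index + k_last)
        helix = 2 * k_last
    else:
        span = (center_index - k_last, center_index + k_last + 1)
        helix = 2 * k_last + 1
    matched = helix - 1 - len(mms) if not even else helix - len(mms)
    return Palindrome(
        center=center_index,
        span=GenomicInterval("*", span[0], span[1]),
        helix_len=helix,
        mismatches=tuple(mms),
        matched_len=matched,
        even=even,
    )


def scan_ps(window: ReferenceWindow, params: PSParams) -> list[Palindrome]:
    """Run central expansion at every position; keep structures with
    helix_len >= min_helix; drop structures wholly contained in a longer
    reported structure with the same mismatch pair; sort by center."""
    seq = window.seq
    chrom = window.interval.chrom
    win0 = window.interval.start
    found: list[Palindrome] = []
    centers: list[tuple[int, bool]] = [(i, False) for i in range(len(seq))]
    if params.include_even_centers:
        centers += [(i, True) for i in range(1, len(seq))]
    for i, even in centers:
        p = expand_palindrome(seq, i, params.stop_mismatches, even=even)
        if p is None or p.helix_len < params.min_helix:
            continue
        found.append(
            Palindrome(
                center=win0 + p.center,
                span=GenomicInterval(chrom, win0 + p.span.start, win0 + p.span.end),
                helix_len=p.helix_len,
                mismatches=tuple(
                    (win0 + l, win0 + r, bl, br) for l, r, bl, br in p.mismatches
                ),
                matched_len=p.matched_len,
                even=even,
            )
        )
    kept = []
    for p in found:
        mmkey = tuple((l, r) for l, r, *_ in p.mismatches)
        contained = any(
            o is not p
            and o.helix_len > p.helix_len
            and o.span.contains(p.span)
            and tuple((l, r) for l, r, *_ in o.mismatches) == mmkey
            for o in found
        )
        if not contained:
            kept.append(p)
    kept.sort(key=lambda p: (p.center, p.even))
    return kept


def ps_blacklist(
    ps_list: Iterable[Palindrome],
    window: ReferenceWindow,
    params: PSParams,
    roi: Iterable[GenomicInterval] | None = None,
):
    """Blacklist entries at both positions of each internal mismatched pair.

    The predicted artifact allele at each site is the complement of the
    partner column's base. Perfect palindromes and N-containing columns
    emit nothing; sites outside the roi are dropped.
    """
    from .blacklist import BlacklistEntry

    roi = tuple(roi) if roi is not None else window.origins
    chrom = window.interval.chrom

    def in_roi(pos: int) -> bool:
        return any(o.contains_pos(pos) for o in roi)

    entries = []
    for p in ps_list:
        for left, right, bl, br in p.mismatches:
            if bl == "N" or br == "N":
                continue
            for pos, ref, partner in ((left, bl, br), (right, br, bl)):
                if not in_roi(pos):
                    continue
                entries.append(
                    BlacklistEntry(
                        chrom=chrom,
                        start=pos,
                        end=pos + 1,
                        ref=ref,
                        predicted_alt=complement_base(partner),
                        source="PS",
                        structure_id=p.structure_id,
                    )
                )
    uniq: dict[tuple, object] = {}
    for e in entries:
        uniq.setdefault((e.chrom, e.start, e.end, e.predicted_alt), e)
    return sorted(uniq.values(), key=lambda e: (e.chrom, e.start, e.end, e.predicted_alt))
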