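"""Per-read predicates and transforms used by the QC pipelines.

Coordinates are 0-based half-open throughout.  Adaptor matching is pure
Hamming distance (no indels): the first and last 20 bases of each adaptor
are slid over the permitted region of the read and the lowest-mismatch,
leftmost hit within the allowance wins.  An ``N`` in the read always
counts as a mismatch; matching is case-insensitive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from .seqio import SequenceRead

ADAPTOR_WINDOW = 20  # terminal window length taken from each adaptor


class EmptyReadError(ValueError):
    """A trim removed every base; callers length-filter instead of emitting."""


@dataclass(frozen=True)
class QualityFilterParams:
    """High-quality read rule: at least ``min_fraction`` percent of the
    bases must score at or above ``cutoff_q``.

    The required count is the ceiling of ``min_fraction/100 * length`` —
    "at least this share of bases" read conservatively as an integer
    count of bases.
    """

    cutoff_q: int = 20
    min_fraction: float = 70.0

    def __post_init__(self) -> None:
        if not (0 <= self.cutoff_q <= 93):
            raise ValueError(f"cutoff_q {self.cutoff_q} outside 0..93")
        if not (0 < self.min_fraction <= 100):
            raise ValueError(f"min_fraction {self.min_fraction} outside (0, 100]")


@dataclass(frozen=True)
class AdaptorMatch:
    """Where and how an adaptor window matched a read."""

    adaptor_id: str
    read_start: int
    read_end: int
    mismatches: int
    end: str  # "first-20" | "last-20" | "whole"


@dataclass(frozen=True)
class HomopolymerHit:
    base: str
    start: int
    run_length: int


def passes_quality_filter(quals: Sequence, params: QualityFilterParams) -> bool:
    """True iff the read meets the HQ rule (see QualityFilterParams)."""
    n = len(quals)
    if n == 0:
        raise ValueError("empty read has no quality to filter on")
    needed = math.ceil(params.min_fraction * n / 100.0 - 1e-9)
    good = sum(1 for q in quals if q >= params.cutoff_q)
    return good >= needed


def _hamming(a: str, b: str) -> int:
    # read base N never matches anything
    return sum(1 for x, y in zip(a, b) if x != y or x == "N")


def _scan_window(
    seq: str, window: str, regions: Sequence
) -> Optional[tuple]:
    """Best (mismatches, start) of ``window`` over offset ranges ``regions``.

    Each region is an ``(lo, hi)`` range of permitted start offsets
    (half-open).  Ties in mismatch count break to the leftmost start.
    """
    w = len(window)
    best = None
    for lo, hi in regions:
        for start in range(lo, hi):
            d = _hamming(seq[start : start + w], window)
            if best is None or d < best[0]:
                best = (d, start)
    return best


def find_adaptor(
    seq: str,
    adaptor: str,
    allowance: int = 1,
    search_span: Optional[int] = None,
    adaptor_id: str = "adaptor",
) -> Optional[AdaptorMatch]:
    """Locate an adaptor's terminal 20-base windows in a read.

    With ``search_span=None`` the whole read is scanned (Illumina discard
    semantics).  With ``search_span=n`` a hit must lie entirely inside the
    first ``n`` or last ``n`` bases of the read (454 end-trimming
    semantics).  Adaptors shorter than 20 bases are matched in full as a
    single window.  Returns the lowest-mismatch, leftmost hit with at most
    ``allowance`` mismatches, or ``None``.
    """
    seq = seq.upper()
    adaptor = adaptor.upper()
    if len(adaptor) <= ADAPTOR_WINDOW:
        windows = [(adaptor, "whole")]
    else:
        windows = [
            (adaptor[:ADAPTOR_WINDOW], "first-20"),
            (adaptor[-ADAPTOR_WINDOW:], "last-20"),
        ]
    best: Optional[AdaptorMatch] = None
    for window, label in windows:
        w = len(window)
        if w > len(seq):
            continue
        if search_span is None:
            regions = [(0, len(seq) - w + 1)]
        else:
            head = (0, max(0, min(search_span, len(seq)) - w + 1))
            tail_lo = max(len(seq) - search_span, 0)
            tail = (max(tail_lo, head[1]), len(seq) - w + 1)
            regions = [r for r in (head, tail) if r[0] < r[1]]
        hit = _scan_window(seq, window, regions)
        if hit is None or hit[0] > allowance:
            continue
        cand = AdaptorMatch(adaptor_id, hit[1], hit[1] + w, hit[0], label)
        if (
            best is None
            or cand.mismatches < best.mismatches
            or (cand.mismatches == best.mismatches and cand.read_start < best.read_start)
        ):
            best = cand
    return best


def trim_adaptor_454(read: SequenceRead, match: AdaptorMatch, end_span: int = 50) -> SequenceRead:
    """Trim a read at the end where an adaptor window matched.

    A hit inside the first ``end_span`` bases removes everything from the
    read start through the match end; a hit inside the last ``end_span``
    bases removes everything from the match start onward.  Quality scores
    are trimmed in lockstep.  Removing every base raises
    :class:`EmptyReadError` so the caller can length-filter.
    """
    n = len(read)
    if match.read_end <= end_span:
        out = read.slice(match.read_end, n)
    elif match.read_start >= n - end_span:
        out = read.slice(0, match.read_start)
    else:
        raise ValueError(
            f"match span [{match.read_start}, {match.read_end}) lies in "
            f"neither terminal {end_span}-base region of a {n}-base read"
        )
    if len(out) == 0:
        raise EmptyReadError(read.id)
    return out


def find_homopolymer(seq: str, min_len: int) -> Optional[HomopolymerHit]:
    """Leftmost maximal single-base run of length >= ``min_len``.

    Runs of N do not count (they are missing calls, not miscalled
    homopolymers).
    """
    if min_len < 2:
        raise ValueError("homopolymer length threshold must be >= 2")
    seq = seq.upper()
    i, n = 0, len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len and seq[i] in "ACGT":
            return HomopolymerHit(seq[i], i, j - i)
        i = j
    return None


def trim_homopolymer(read: SequenceRead, min_len: int) -> SequenceRead:
    """Truncate at the first base of the leftmost qualifying homopolymer.

    Everything from the run's first base through the 3' end is removed;
    a run starting at position 0 leaves nothing and raises
    :class:`EmptyReadError`.
    """
    hit = find_homopolymer(read.seq, min_len)
    if hit is None:
        return read
    if hit.start == 0:
        raise EmptyReadError(read.id)
    return read.slice(0, hit.start)


def trim_fixed(read: SequenceRead, n5: int = 0, n3: int = 0) -> SequenceRead:
    """Remove fixed base counts from the 5' and 3' ends."""
    if n5 < 0 or n3 < 0:
        raise ValueError("trim counts must be non-negative")
    if n5 + n3 >= len(read):
        raise EmptyReadError(read.id)
    return read.slice(n5, len(read) - n3)


def trim_by_quality(read: SequenceRead, threshold: int) -> SequenceRead:
    """Remove the maximal 3' suffix in which every score is below ``threshold``.

    Trimming stops at the rightmost base scoring at or above the threshold;
    interior low-quality bases are untouched.
    """
    if read.quals is None:
        raise ValueError(f"read {read.id!r} has no quality scores")
    keep = len(read)
    while keep > 0 and read.quals[keep - 1] < threshold:
        keep -= 1
    if keep == 0:
        raise EmptyReadError(read.id)
    return read.slice(0, keep)


def passes_length_filter(read: SequenceRead, min_len: int) -> bool:
    return len(read) >= min_len


def mean_quality(quals: Sequence) -> float:
    if len(quals) == 0:
        raise ValueError("empty quality list has no mean")
    return sum(quals) / len(quals)


def load_adaptor_catalog(path) -> dict:
    """Read a plain-text catalog of ``name TAB sequence`` adaptor entries.

    Blank lines and ``#`` comments are ignored.
    """
    catalog = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            name, seq = line.split("\t")
        except ValueError:
            raise ValueError(
                f"{path}:{lineno}: expected 'name<TAB>sequence'"
            ) from None
        catalog[name.strip()] = seq.strip().upper()
    return catalog
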