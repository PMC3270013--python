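"""Read-set summary statistics and per-position distributions.

Everything is accumulated in a single pass and the accumulators merge, so
statistics computed chunk-by-chunk and summed equal the single-pass result
exactly — the property that makes chunk-parallel pipeline execution safe.

Conventions (the underlying formats leave these open, so they are pinned
here): the median of an even-count length multiset is the lower middle
value; the Nx statistic is the first length, scanning lengths in
decreasing order, at which the cumulative base count reaches x% of the
total; "HQ bases" counts bases scoring at or above the run's Phred cutoff
(default 20); overall average quality is base-weighted.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from .seqio import SequenceRead

DEFAULT_QUALITY_BINS = (0, 10, 20, 30)  # bin edges; last bin is open-ended


def n_statistic(lengths: Sequence, fraction: float) -> int:
    """Nx length: e.g. N50 is the length L such that reads of length >= L
    hold at least 50% of all bases.

    Lengths are scanned in decreasing order and the first length at which
    the running base total reaches ``fraction`` percent of the grand total
    is returned.
    """
    if not lengths:
        raise ValueError("empty length list")
    if not (0 < fraction < 100):
        raise ValueError(f"fraction {fraction} outside (0, 100)")
    total = sum(lengths)
    running = 0
    for length in sorted(lengths, reverse=True):
        running += length
        if running * 100 >= fraction * total:
            return length
    return min(lengths)  # unreachable; guards float fractions


@dataclass(frozen=True)
class DetailedStats:
    """The per-stream summary block of a QC report."""

    n_reads: int
    total_bases: int
    min_len: int
    max_len: int
    mean_len: float
    median_len: float
    n50_len: int
    hq_bases: int
    non_atcg_bases: int
    base_counts: Dict[str, int]
    gc_percent: float

    def as_rows(self) -> List[Tuple[str, object]]:
        rows = [
            ("Number of reads", self.n_reads),
            ("Total bases", self.total_bases),
            ("Minimum read length", self.min_len),
            ("Maximum read length", self.max_len),
            ("Mean read length", round(self.mean_len, 2)),
            ("Median read length", self.median_len),
            ("N50 read length", self.n50_len),
            ("Total HQ bases", self.hq_bases),
            ("Non-ATCG bases", self.non_atcg_bases),
            ("GC percent", round(self.gc_percent, 2)),
        ]
        for base in ("A", "C", "G", "T", "N"):
            rows.append((f"{base} count", self.base_counts.get(base, 0)))
        return rows


class ReadSetAccumulator:
    """Mergeable single-pass accumulator behind :class:`DetailedStats`.

    Keeps a length histogram (read lengths are small integers) so the
    median and N50 of merged accumulators are exact.
    """

    def __init__(self, cutoff_q: int = 20):
        self.cutoff_q = cutoff_q
        self.n_reads = 0
        self.total_bases = 0
        self.hq_bases = 0
        self.length_counts: Counter = Counter()
        self.base_counts: Counter = Counter()

    def add(self, read: SequenceRead) -> None:
        self.n_reads += 1
        self.total_bases += len(read)
        self.length_counts[len(read)] += 1
        for base in read.seq:
            self.base_counts[base if base in "ACGT" else "N"] += 1
        if read.quals is not None:
            self.hq_bases += sum(1 for q in read.quals if q >= self.cutoff_q)

    def merge(self, other: "ReadSetAccumulator") -> "ReadSetAccumulator":
        if other.cutoff_q != self.cutoff_q:
            raise ValueError("cannot merge accumulators with different cutoffs")
        self.n_reads += other.n_reads
        self.total_bases += other.total_bases
        self.hq_bases += other.hq_bases
        self.length_counts.update(other.length_counts)
        self.base_counts.update(other.base_counts)
        return self

    def _median(self) -> float:
        # lower-median from the length histogram
        target = (self.n_reads + 1) // 2
        seen = 0
        for length in sorted(self.length_counts):
            seen += self.length_counts[length]
            if seen >= target:
                return float(length)
        return 0.0

    def result(self) -> DetailedStats:
        if self.n_reads == 0:
            return DetailedStats(0, 0, 0, 0, 0.0, 0.0, 0, 0, 0, {}, 0.0)
        lengths = sorted(self.length_counts)
        expanded = [
            length
            for length in lengths
            for _ in range(self.length_counts[length])
        ]
        gc = self.base_counts.get("G", 0) + self.base_counts.get("C", 0)
        non_atcg = self.base_counts.get("N", 0)
        return DetailedStats(
            n_reads=self.n_reads,
            total_bases=self.total_bases,
            min_len=lengths[0],
            max_len=lengths[-1],
            mean_len=self.total_bases / self.n_reads,
            median_len=self._median(),
            n50_len=n_statistic(expanded, 50),
            hq_bases=self.hq_bases,
            non_atcg_bases=non_atcg,
            base_counts=dict(self.base_counts),
            gc_percent=100.0 * gc / self.total_bases,
        )


def summarize_reads(reads: Iterable[SequenceRead], cutoff_q: int = 20) -> DetailedStats:
    """Single-pass :class:`DetailedStats` over a read stream."""
    acc = ReadSetAccumulator(cutoff_q)
    for read in reads:
        acc.add(read)
    return acc.result()


@dataclass
class DistributionSet:
    """Per-position and per-read distributions behind the QC charts.

    Per-position series use position-specific denominators: a read shorter
    than position p contributes nothing at p.  ``quality_range_fractions``
    rows sum to 1 at every position with data.
    """

    per_position_mean_quality: np.ndarray
    position_counts: np.ndarray
    quality_range_fractions: np.ndarray  # positions x bins
    quality_bins: Tuple[int, ...]
    gc_histogram: np.ndarray  # 101 integer-percent bins
    mean_quality_histogram: np.ndarray  # per-read mean quality, floor-binned
    length_histogram: Dict[int, int]
    base_composition: Dict[str, int]


class DistributionAccumulator:
    def __init__(self, quality_bins: Sequence = DEFAULT_QUALITY_BINS):
        self.quality_bins = tuple(quality_bins)
        self._qual_sum = np.zeros(0, dtype=np.float64)
        self._count = np.zeros(0, dtype=np.int64)
        self._bin_counts = np.zeros((0, len(self.quality_bins)), dtype=np.int64)
        self.gc_histogram = np.zeros(101, dtype=np.int64)
        self.mean_quality_histogram = np.zeros(94, dtype=np.int64)
        self.length_histogram: Counter = Counter()
        self.base_composition: Counter = Counter()

    def _grow(self, n: int) -> None:
        if n <= len(self._count):
            return
        pad = n - len(self._count)
        self._qual_sum = np.concatenate([self._qual_sum, np.zeros(pad)])
        self._count = np.concatenate([self._count, np.zeros(pad, dtype=np.int64)])
        self._bin_counts = np.vstack(
            [self._bin_counts, np.zeros((pad, len(self.quality_bins)), dtype=np.int64)]
        )

    def add(self, read: SequenceRead) -> None:
        n = len(read)
        self.length_histogram[n] += 1
        for base in read.seq:
            self.base_composition[base if base in "ACGT" else "N"] += 1
        if n:
            gc = sum(1 for b in read.seq if b in "GC")
            self.gc_histogram[int(round(100.0 * gc / n))] += 1
        if read.quals is not None and n:
            self._grow(n)
            q = np.asarray(read.quals, dtype=np.float64)
            self._qual_sum[:n] += q
            self._count[:n] += 1
            bins = np.searchsorted(self.quality_bins, read.quals, side="right") - 1
            np.clip(bins, 0, len(self.quality_bins) - 1, out=bins)
            for pos, b in enumerate(bins):
                self._bin_counts[pos, b] += 1
            mean_q = int(q.mean())
            self.mean_quality_histogram[min(mean_q, 93)] += 1

    def merge(self, other: "DistributionAccumulator") -> "DistributionAccumulator":
        if other.quality_bins != self.quality_bins:
            raise ValueError("cannot merge accumulators with different bins")
        self._grow(len(other._count))
        n = len(other._count)
        self._qual_sum[:n] += other._qual_sum
        self._count[:n] += other._count
        self._bin_counts[:n] += other._bin_counts
        self.gc_histogram += other.gc_histogram
        self.mean_quality_histogram += other.mean_quality_histogram
        self.length_histogram.update(other.length_histogram)
        self.base_composition.update(other.base_composition)
        return self

    def result(self) -> DistributionSet:
        with np.errstate(invalid="ignore", divide="ignore"):
            means = np.where(self._count > 0, self._qual_sum / np.maximum(self._count, 1), 0.0)
            denom = self._count[:, None]
            fractions = np.where(
                denom > 0, self._bin_counts / np.maximum(denom, 1), 0.0
            )
        return DistributionSet(
            per_position_mean_quality=means,
            position_counts=self._count.copy(),
            quality_range_fractions=fractions,
            quality_bins=self.quality_bins,
            gc_histogram=self.gc_histogram.copy(),
            mean_quality_histogram=self.mean_quality_histogram.copy(),
            length_histogram=dict(self.length_histogram),
            base_composition=dict(self.base_composition),
        )


def accumulate_distributions(
    reads: Iterable[SequenceRead], quality_bins: Sequence = DEFAULT_QUALITY_BINS
) -> DistributionSet:
    acc = DistributionAccumulator(quality_bins)
    for read in reads:
        acc.add(read)
    return acc.result()


def avg_quality_report(qual_source) -> Tuple[List[Tuple[str, float]], float]:
    """Per-read mean quality plus the base-weighted overall mean.

    Input is a 454-style qual file.  The overall mean is total score sum
    over total base count, so long reads weigh more than short ones.
    """
    per_read: List[Tuple[str, float]] = []
    total = 0
    bases = 0
    from .seqio import _read_fasta_blocks

    for header, body in _read_fasta_blocks(qual_source):
        rid = header.split(None, 1)[0]
        vals = [int(tok) for tok in " ".join(body).split()]
        if not vals:
            raise ValueError(f"qual record {rid!r} has no values")
        per_read.append((rid, sum(vals) / len(vals)))
        total += sum(vals)
        bases += len(vals)
    if bases == 0:
        raise ValueError("qual file holds no records")
    return per_read, total / bases
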