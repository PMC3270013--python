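"""The Illumina QC workflow: HQ filtering, adaptor discard, paired-end
integrity.

A read is high-quality (HQ) when at least the configured fraction of its
bases score at or above the Phred cutoff.  Adaptor matching runs only on
reads that already passed the quality filter, so every discarded read is
attributed to exactly one step.  In paired-end mode both mates must
survive for the pair to be kept; a lone survivor is diverted to an
unpaired output rather than thrown away, preserving both pairing
integrity and data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import zip_longest
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

from .encodings import QualityEncoding, resolve_encoding, to_phred
from .filters import QualityFilterParams, find_adaptor, passes_quality_filter
from .seqio import FormatError, SequenceRead, read_fastq, write_fastq
from .stats import DetailedStats, ReadSetAccumulator

# stage keys, in pipeline order, for QC-statistics reports
STAGE_LOW_QUALITY = "low_quality"
STAGE_ADAPTOR = "adaptor"


@dataclass
class IlluminaQCParams:
    """User-tunable knobs of the Illumina workflow.

    ``adaptors`` is a list of ``(name, sequence)`` entries; when empty the
    contamination step is skipped.  ``variant_override`` pins the FASTQ
    dialect instead of auto-detecting it.
    """

    quality: QualityFilterParams = field(default_factory=QualityFilterParams)
    adaptors: Sequence[Tuple[str, str]] = ()
    variant_override: Union[QualityEncoding, str, None] = None
    adaptor_allowance: int = 1
    compress_output: bool = False


@dataclass
class QCRunStats:
    """Per-step filtering counters plus input/output summary statistics.

    ``stage_counts`` maps pipeline stage -> number of reads removed there,
    in stage order.  Accumulators are kept (not just their finalized
    snapshots) so chunk-wise runs can be merged exactly.
    """

    parameters: Dict[str, object] = field(default_factory=dict)
    input_reads: int = 0
    hq_reads: int = 0
    stage_counts: Dict[str, int] = field(default_factory=dict)
    pairs_in: int = 0
    paired_surviving: int = 0
    unpaired_surviving: int = 0
    input_acc: ReadSetAccumulator = field(default_factory=ReadSetAccumulator)
    output_acc: ReadSetAccumulator = field(default_factory=ReadSetAccumulator)

    @property
    def input_stats(self) -> DetailedStats:
        return self.input_acc.result()

    @property
    def output_stats(self) -> DetailedStats:
        return self.output_acc.result()

    @property
    def low_quality_discarded(self) -> int:
        return self.stage_counts.get(STAGE_LOW_QUALITY, 0)

    @property
    def adaptor_discarded(self) -> int:
        return self.stage_counts.get(STAGE_ADAPTOR, 0)

    @property
    def total_discarded(self) -> int:
        return sum(self.stage_counts.values())

    def count_stage(self, stage: str, n: int = 1) -> None:
        self.stage_counts[stage] = self.stage_counts.get(stage, 0) + n

    def merged_with(self, other: "QCRunStats") -> "QCRunStats":
        """Sum of two runs' counters and accumulators (chunk merge)."""
        out = QCRunStats(parameters=dict(self.parameters))
        out.input_reads = self.input_reads + other.input_reads
        out.hq_reads = self.hq_reads + other.hq_reads
        stages = list(self.stage_counts) + [
            s for s in other.stage_counts if s not in self.stage_counts
        ]
        out.stage_counts = {
            s: self.stage_counts.get(s, 0) + other.stage_counts.get(s, 0)
            for s in stages
        }
        out.pairs_in = self.pairs_in + other.pairs_in
        out.paired_surviving = self.paired_surviving + other.paired_surviving
        out.unpaired_surviving = self.unpaired_surviving + other.unpaired_surviving
        out.input_acc = ReadSetAccumulator(self.input_acc.cutoff_q)
        out.input_acc.merge(self.input_acc).merge(other.input_acc)
        out.output_acc = ReadSetAccumulator(self.output_acc.cutoff_q)
        out.output_acc.merge(self.output_acc).merge(other.output_acc)
        return out


def _new_stats(params: IlluminaQCParams, extra: Optional[dict] = None) -> QCRunStats:
    p = {
        "quality cutoff (Phred)": params.quality.cutoff_q,
        "minimum HQ base fraction (%)": params.quality.min_fraction,
        "adaptors": ", ".join(name for name, _ in params.adaptors) or "none",
        "adaptor mismatch allowance": params.adaptor_allowance,
    }
    if extra:
        p.update(extra)
    stats = QCRunStats(parameters=p)
    stats.stage_counts = {STAGE_LOW_QUALITY: 0, STAGE_ADAPTOR: 0}
    stats.input_acc = ReadSetAccumulator(params.quality.cutoff_q)
    stats.output_acc = ReadSetAccumulator(params.quality.cutoff_q)
    return stats


def _read_fate(
    read: SequenceRead,
    phred: Sequence,
    params: IlluminaQCParams,
) -> str:
    """"kept", STAGE_LOW_QUALITY or STAGE_ADAPTOR for one read."""
    if not passes_quality_filter(phred, params.quality):
        return STAGE_LOW_QUALITY
    for name, seq in params.adaptors:
        if find_adaptor(
            read.seq, seq, params.adaptor_allowance, None, adaptor_id=name
        ):
            return STAGE_ADAPTOR
    return "kept"


def _phred(read: SequenceRead, encoding: Optional[QualityEncoding]):
    if read.quals is None:
        raise FormatError(f"read {read.id!r} has no quality scores")
    if encoding is not None and encoding.is_solexa_scale:
        return to_phred(read.quals, encoding)
    return read.quals


def qc_single_end(
    reads: Iterable[SequenceRead],
    params: IlluminaQCParams,
    encoding: Optional[QualityEncoding] = None,
) -> Tuple[List[SequenceRead], QCRunStats]:
    """Filter a single-end stream; returns survivors and run statistics.

    ``encoding`` is only needed for Solexa-scaled input, whose decoded
    scores must be mapped to Phred before thresholding.
    """
    stats = _new_stats(params)
    kept: List[SequenceRead] = []
    for read in reads:
        stats.input_reads += 1
        stats.input_acc.add(read)
        fate = _read_fate(read, _phred(read, encoding), params)
        if fate == "kept":
            stats.hq_reads += 1
            stats.output_acc.add(read)
            kept.append(read)
        else:
            stats.count_stage(fate)
    return kept, stats


def qc_paired_end(
    forward: Iterable[SequenceRead],
    reverse: Iterable[SequenceRead],
    params: IlluminaQCParams,
    encoding: Optional[QualityEncoding] = None,
) -> Tuple[List[SequenceRead], List[SequenceRead], List[SequenceRead], QCRunStats]:
    """Filter mate streams together, preserving pairing integrity.

    Mates at the same ordinal must share a pairing key (an error names the
    offending ordinal otherwise).  Both mates HQ -> the pair is emitted at
    the same ordinal in both paired outputs; exactly one HQ -> the
    survivor goes to the unpaired output; neither -> both discarded.
    """
    stats = _new_stats(params)
    paired_f: List[SequenceRead] = []
    paired_r: List[SequenceRead] = []
    unpaired: List[SequenceRead] = []
    sentinel = object()
    for ordinal, (f, r) in enumerate(zip_longest(forward, reverse, fillvalue=sentinel), 1):
        if f is sentinel or r is sentinel:
            which = "forward" if f is sentinel else "reverse"
            raise FormatError(
                f"{which} file ended early: no mate at record ordinal {ordinal}"
            )
        if f.pairing_key != r.pairing_key:
            raise FormatError(
                f"mate identifiers disagree at record ordinal {ordinal}: "
                f"{f.id!r} vs {r.id!r}"
            )
        stats.pairs_in += 1
        stats.input_reads += 2
        stats.input_acc.add(f)
        stats.input_acc.add(r)
        fate_f = _read_fate(f, _phred(f, encoding), params)
        fate_r = _read_fate(r, _phred(r, encoding), params)
        if fate_f == "kept" and fate_r == "kept":
            stats.paired_surviving += 1
            stats.hq_reads += 2
            stats.output_acc.add(f)
            stats.output_acc.add(r)
            paired_f.append(f)
            paired_r.append(r)
            continue
        if fate_f == "kept":
            stats.unpaired_surviving += 1
            stats.hq_reads += 1
            stats.output_acc.add(f)
            unpaired.append(f)
        else:
            stats.count_stage(fate_f)
        if fate_r == "kept":
            stats.unpaired_surviving += 1
            stats.hq_reads += 1
            stats.output_acc.add(r)
            unpaired.append(r)
        else:
            stats.count_stage(fate_r)
    return paired_f, paired_r, unpaired, stats


def qc_single_end_chunked(
    reads: Sequence[SequenceRead],
    params: IlluminaQCParams,
    chunks: int,
    encoding: Optional[QualityEncoding] = None,
) -> Tuple[List[SequenceRead], QCRunStats]:
    """Split the input into ``chunks`` contiguous parts, QC each
    independently, concatenate the outputs and merge the statistics.

    By construction of the mergeable accumulators this equals the
    single-pass run exactly, for any chunk count — the contract behind
    multithreaded execution in the original tooling.
    """
    reads = list(reads)
    if chunks < 1:
        raise ValueError("chunk count must be >= 1")
    size = -(-len(reads) // chunks) if reads else 1
    merged: Optional[QCRunStats] = None
    kept: List[SequenceRead] = []
    for i in range(0, max(len(reads), 1), size):
        part, part_stats = qc_single_end(reads[i : i + size], params, encoding)
        kept.extend(part)
        merged = part_stats if merged is None else merged.merged_with(part_stats)
    assert merged is not None
    return kept, merged


def _out_path(in_path: Path, out_dir: Optional[Path], label: str, gz: bool) -> Path:
    base = in_path.name
    if base.endswith(".gz"):
        base = base[:-3]
    stem, dot, suffix = base.rpartition(".")
    name = f"{stem or suffix}_{label}.{suffix if stem else 'fastq'}"
    if gz:
        name += ".gz"
    return (out_dir or in_path.parent) / name


def run_illumina_se(
    input_path,
    params: Optional[IlluminaQCParams] = None,
    out_dir=None,
    chunks: int = 1,
) -> Tuple[QCRunStats, Dict[str, Path]]:
    """File-level single-end QC: detect the variant, filter, write outputs.

    Returns the run statistics and a map of output roles to paths
    (``filtered``, plus report files added by the caller).
    """
    params = params or IlluminaQCParams()
    input_path = Path(input_path)
    out_dir = Path(out_dir) if out_dir is not None else input_path.parent
    out_dir.mkdir(parents=True, exist_ok=True)
    detection = resolve_encoding(params.variant_override or "auto", input_path)
    enc = detection.encoding
    reads = read_fastq(input_path, enc)
    if chunks > 1:
        kept, stats = qc_single_end_chunked(list(reads), params, chunks, enc)
    else:
        kept, stats = qc_single_end(reads, params, enc)
    stats.parameters["input file"] = input_path.name
    stats.parameters["FASTQ variant"] = enc.name + (
        " (ambiguous)" if detection.ambiguous else ""
    )
    gz = params.compress_output
    out = _out_path(input_path, out_dir, "filtered", gz)
    write_fastq(kept, out, enc, compress=gz)
    return stats, {"filtered": out}


def run_illumina_pe(
    fwd_path,
    rev_path,
    params: Optional[IlluminaQCParams] = None,
    out_dir=None,
) -> Tuple[QCRunStats, Dict[str, Path]]:
    """File-level paired-end QC over two synchronized FASTQ files."""
    params = params or IlluminaQCParams()
    fwd_path, rev_path = Path(fwd_path), Path(rev_path)
    out_dir = Path(out_dir) if out_dir is not None else fwd_path.parent
    out_dir.mkdir(parents=True, exist_ok=True)
    detection = resolve_encoding(params.variant_override or "auto", fwd_path)
    enc = detection.encoding
    pf, pr, up, stats = qc_paired_end(
        read_fastq(fwd_path, enc), read_fastq(rev_path, enc), params, enc
    )
    stats.parameters["input files"] = f"{fwd_path.name}, {rev_path.name}"
    stats.parameters["FASTQ variant"] = enc.name + (
        " (ambiguous)" if detection.ambiguous else ""
    )
    gz = params.compress_output
    paths = {
        "filtered_forward": _out_path(fwd_path, out_dir, "filtered", gz),
        "filtered_reverse": _out_path(rev_path, out_dir, "filtered", gz),
        "unpaired": _out_path(fwd_path, out_dir, "unpaired", gz),
    }
    write_fastq(pf, paths["filtered_forward"], enc, compress=gz)
    write_fastq(pr, paths["filtered_reverse"], enc, compress=gz)
    write_fastq(up, paths["unpaired"], enc, compress=gz)
    return stats, paths
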