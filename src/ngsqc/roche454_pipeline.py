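"""The Roche 454 QC workflow for FASTA+qual reads, single- and paired-end.

Stage order, with a length filter after every stage:

1. input length filter;
2. optional homopolymer trimming (truncate at the first base of the
   leftmost run of the configured length — pyrosequencing miscalls long
   runs, so everything 3' of the run is suspect);
3. quality filter: mean read quality must reach the Phred cutoff;
4. adaptor end-trimming: the adaptor's terminal 20-base windows are
   matched against the first and last 50 bases of the read (1 mismatch
   allowed) and the contaminated end is cut off.

Paired-end 454 reads are one physical read with a linker joining the two
mates; ``split_by_linker`` recovers them before the stages run.  A pair
survives only if both mates survive; a lone survivor joins the unpaired
output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .filters import (
    EmptyReadError,
    find_adaptor,
    find_homopolymer,
    mean_quality,
    trim_adaptor_454,
)
from .illumina_pipeline import QCRunStats
from .seqio import FormatError, SequenceRead, read_fasta_qual, write_fasta_qual
from .stats import ReadSetAccumulator

STAGE_SHORT_INPUT = "short_input"
STAGE_HOMOPOLYMER = "homopolymer_trim_short"
STAGE_LOW_QUALITY = "low_quality"
STAGE_ADAPTOR_TRIM = "adaptor_trim_short"
STAGE_ORDER = (
    STAGE_SHORT_INPUT,
    STAGE_HOMOPOLYMER,
    STAGE_LOW_QUALITY,
    STAGE_ADAPTOR_TRIM,
)


@dataclass
class Roche454QCParams:
    """User-tunable knobs of the 454 workflow.

    ``min_len`` is re-applied after every stage.  ``homopolymer_len`` of
    ``None`` disables trimming (it is an aggressive option).  The quality
    filter is mean read quality >= ``quality_cutoff``.  ``end_span`` is
    how deep into each read end adaptor windows may match.
    """

    min_len: int = 50
    homopolymer_len: Optional[int] = None
    quality_cutoff: float = 20.0
    adaptors: Sequence[Tuple[str, str]] = ()
    adaptor_allowance: int = 1
    end_span: int = 50
    linker: Optional[str] = None
    linker_allowance: int = 2
    cutoff_q: int = 20  # base-level threshold for the HQ-bases statistic

    def __post_init__(self) -> None:
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")


@dataclass
class LinkerSplit:
    """Result of searching one 454 PE read for its linker.

    Either ``forward``/``reverse`` are set (with ``linker_span`` giving the
    0-based half-open linker location on the parent read), or ``unpaired``
    holds the whole read when no linker was found or one mate came out
    empty.
    """

    forward: Optional[SequenceRead] = None
    reverse: Optional[SequenceRead] = None
    linker_span: Optional[Tuple[int, int]] = None
    unpaired: Optional[SequenceRead] = None


def split_by_linker(
    read: SequenceRead, linker: str, allowance: int = 2
) -> LinkerSplit:
    """Split a PE 454 read at its best full-length linker match.

    The linker is matched whole (Hamming, no indels); the lowest-mismatch,
    leftmost hit within ``allowance`` splits the read, mate identifiers
    gaining ``/1`` and ``/2`` suffixes.  No hit, or a hit flush with a read
    end (one mate empty), leaves the read unpaired.
    """
    if not linker:
        raise ValueError("linker sequence must be non-empty")
    linker = linker.upper()
    n, w = len(read), len(linker)
    best: Optional[Tuple[int, int]] = None
    seq = read.seq
    for start in range(0, n - w + 1):
        d = sum(
            1 for x, y in zip(seq[start : start + w], linker) if x != y or x == "N"
        )
        if best is None or d < best[0]:
            best = (d, start)
    if best is None or best[0] > allowance:
        return LinkerSplit(unpaired=read)
    start = best[1]
    span = (start, start + w)
    fwd = read.slice(0, start)
    rev = read.slice(span[1], n)
    if len(fwd) == 0 or len(rev) == 0:
        survivor = rev if len(fwd) == 0 else fwd
        return LinkerSplit(unpaired=survivor, linker_span=span)
    fwd = SequenceRead(read.id + "/1", fwd.seq, fwd.quals, read.desc)
    rev = SequenceRead(read.id + "/2", rev.seq, rev.quals, read.desc)
    return LinkerSplit(forward=fwd, reverse=rev, linker_span=span)


def _process_one(
    read: SequenceRead, params: Roche454QCParams
) -> Tuple[str, Optional[SequenceRead]]:
    """Run the stage sequence on one read.

    Returns ``(fate, survivor)`` where fate is ``"kept"`` or the stage key
    at which the read was removed.
    """
    if read.quals is None:
        raise FormatError(f"read {read.id!r} has no quality scores (qual file required)")
    if len(read) < params.min_len:
        return STAGE_SHORT_INPUT, None
    if params.homopolymer_len is not None:
        hit = find_homopolymer(read.seq, params.homopolymer_len)
        if hit is not None:
            if hit.start < params.min_len:
                return STAGE_HOMOPOLYMER, None
            read = read.slice(0, hit.start)
    if mean_quality(read.quals) < params.quality_cutoff:
        return STAGE_LOW_QUALITY, None
    for name, adaptor in params.adaptors:
        match = find_adaptor(
            read.seq,
            adaptor,
            params.adaptor_allowance,
            search_span=params.end_span,
            adaptor_id=name,
        )
        if match is None:
            continue
        try:
            read = trim_adaptor_454(read, match, params.end_span)
        except EmptyReadError:
            return STAGE_ADAPTOR_TRIM, None
        if len(read) < params.min_len:
            return STAGE_ADAPTOR_TRIM, None
    return "kept", read


def _new_stats(params: Roche454QCParams, extra: Optional[dict] = None) -> QCRunStats:
    p = {
        "length cutoff": params.min_len,
        "homopolymer trimming": (
            f"runs >= {params.homopolymer_len}"
            if params.homopolymer_len is not None
            else "off"
        ),
        "mean quality cutoff": params.quality_cutoff,
        "adaptors": ", ".join(name for name, _ in params.adaptors) or "none",
        "adaptor mismatch allowance": params.adaptor_allowance,
    }
    if extra:
        p.update(extra)
    stats = QCRunStats(parameters=p)
    stats.stage_counts = {s: 0 for s in STAGE_ORDER}
    stats.input_acc = ReadSetAccumulator(params.cutoff_q)
    stats.output_acc = ReadSetAccumulator(params.cutoff_q)
    return stats


def qc_454(
    reads: Iterable[SequenceRead], params: Optional[Roche454QCParams] = None
) -> Tuple[List[SequenceRead], QCRunStats]:
    """Single-end 454 QC; returns survivors (possibly trimmed) and stats."""
    params = params or Roche454QCParams()
    stats = _new_stats(params)
    kept: List[SequenceRead] = []
    for read in reads:
        stats.input_reads += 1
        stats.input_acc.add(read)
        fate, survivor = _process_one(read, params)
        if fate == "kept":
            stats.hq_reads += 1
            stats.output_acc.add(survivor)
            kept.append(survivor)
        else:
            stats.count_stage(fate)
    return kept, stats


def qc_454_chunked(
    reads: Sequence[SequenceRead], params: Roche454QCParams, chunks: int
) -> Tuple[List[SequenceRead], QCRunStats]:
    """Chunk-wise 454 QC; equals the single-pass run exactly (merged stats)."""
    reads = list(reads)
    if chunks < 1:
        raise ValueError("chunk count must be >= 1")
    size = -(-len(reads) // chunks) if reads else 1
    merged: Optional[QCRunStats] = None
    kept: List[SequenceRead] = []
    for i in range(0, max(len(reads), 1), size):
        part, part_stats = qc_454(reads[i : i + size], params)
        kept.extend(part)
        merged = part_stats if merged is None else merged.merged_with(part_stats)
    assert merged is not None
    return kept, merged


def qc_454_pe(
    reads: Iterable[SequenceRead], params: Optional[Roche454QCParams] = None
) -> Tuple[List[SequenceRead], List[SequenceRead], List[SequenceRead], QCRunStats]:
    """Paired-end 454 QC: linker split first, then the stage sequence.

    Returns (paired forward, paired reverse, unpaired, stats).  The stats
    carry extra counters: ``pairs_in`` is the number of reads in which a
    linker was found.
    """
    params = params or Roche454QCParams()
    if not params.linker:
        raise ValueError("paired-end 454 QC requires a linker sequence")
    stats = _new_stats(params, {"linker": params.linker,
                                "linker mismatch allowance": params.linker_allowance})
    paired_f: List[SequenceRead] = []
    paired_r: List[SequenceRead] = []
    unpaired: List[SequenceRead] = []
    for read in reads:
        stats.input_reads += 1
        stats.input_acc.add(read)
        split = split_by_linker(read, params.linker, params.linker_allowance)
        if split.forward is not None and split.reverse is not None:
            stats.pairs_in += 1
            fate_f, surv_f = _process_one(split.forward, params)
            fate_r, surv_r = _process_one(split.reverse, params)
            if fate_f == "kept" and fate_r == "kept":
                stats.paired_surviving += 1
                stats.hq_reads += 2
                stats.output_acc.add(surv_f)
                stats.output_acc.add(surv_r)
                paired_f.append(surv_f)
                paired_r.append(surv_r)
                continue
            for fate, surv in ((fate_f, surv_f), (fate_r, surv_r)):
                if fate == "kept":
                    stats.unpaired_surviving += 1
                    stats.hq_reads += 1
                    stats.output_acc.add(surv)
                    unpaired.append(surv)
                else:
                    stats.count_stage(fate)
        else:
            fate, surv = _process_one(split.unpaired, params)
            if fate == "kept":
                stats.unpaired_surviving += 1
                stats.hq_reads += 1
                stats.output_acc.add(surv)
                unpaired.append(surv)
            else:
                stats.count_stage(fate)
    return paired_f, paired_r, unpaired, stats


def run_454(
    seq_path,
    qual_path,
    params: Optional[Roche454QCParams] = None,
    out_dir=None,
    chunks: int = 1,
) -> Tuple[QCRunStats, Dict[str, Path]]:
    """File-level single-end 454 QC over FASTA+qual inputs."""
    params = params or Roche454QCParams()
    seq_path, qual_path = Path(seq_path), Path(qual_path)
    out_dir = Path(out_dir) if out_dir is not None else seq_path.parent
    out_dir.mkdir(parents=True, exist_ok=True)
    reads = read_fasta_qual(seq_path, qual_path)
    if chunks > 1:
        kept, stats = qc_454_chunked(list(reads), params, chunks)
    else:
        kept, stats = qc_454(reads, params)
    stats.parameters["input files"] = f"{seq_path.name}, {qual_path.name}"
    stem = seq_path.stem
    paths = {
        "filtered_fna": out_dir / f"{stem}_filtered.fna",
        "filtered_qual": out_dir / f"{stem}_filtered.qual",
    }
    write_fasta_qual(kept, paths["filtered_fna"], paths["filtered_qual"])
    return stats, paths


def run_454_pe(
    seq_path,
    qual_path,
    params: Roche454QCParams,
    out_dir=None,
) -> Tuple[QCRunStats, Dict[str, Path]]:
    """File-level paired-end 454 QC; writes mate files plus unpaired output."""
    seq_path, qual_path = Path(seq_path), Path(qual_path)
    out_dir = Path(out_dir) if out_dir is not None else seq_path.parent
    out_dir.mkdir(parents=True, exist_ok=True)
    pf, pr, up, stats = qc_454_pe(read_fasta_qual(seq_path, qual_path), params)
    stats.parameters["input files"] = f"{seq_path.name}, {qual_path.name}"
    stem = seq_path.stem
    paths = {}
    for label, recs in (("1", pf), ("2", pr), ("unpaired", up)):
        fna = out_dir / f"{stem}_filtered_{label}.fna"
        qual = out_dir / f"{stem}_filtered_{label}.qual"
        write_fasta_qual(recs, fna, qual)
        paths[f"filtered_{label}_fna"] = fna
        paths[f"filtered_{label}_qual"] = qual
    return stats, paths
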