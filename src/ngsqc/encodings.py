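"""FASTQ quality-encoding variants: detection, decoding and conversion.

Three dialects are supported.  Sanger encodes Phred scores 0..93 at ASCII
offset 33.  Illumina 1.3+ encodes Phred scores 0..62 at offset 64.  Solexa
also uses offset 64 but its scores are log-odds, Q_solexa =
-10*log10(p/(1-p)), spanning -5..62; they are mapped to Phred via
``solexa_to_phred``.

Variant detection inspects the minimum and maximum ASCII codes over a
sample of quality lines.  Any code below 59 can only be Sanger; a minimum
in 59..63 can only be Solexa (Sanger data that high-quality is essentially
impossible and Illumina 1.3+ cannot go below 64); a minimum of 64 or more
is reported as Illumina 1.3+ with an ambiguity flag, because Solexa data
with no score below 0 cannot be excluded.  An explicit user override
always wins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence


class EncodingError(ValueError):
    """A quality score or character outside the encoding's legal range."""


@dataclass(frozen=True)
class QualityEncoding:
    """Descriptor of one FASTQ dialect.

    ``is_solexa_scale`` marks the one variant whose scores are log-odds
    rather than Phred; all arithmetic on decoded values must check it
    before treating scores as Phred.
    """

    name: str
    ascii_offset: int
    q_min: int
    q_max: int
    is_solexa_scale: bool = False

    def __post_init__(self) -> None:
        assert self.ascii_offset + self.q_min >= 33
        assert self.ascii_offset + self.q_max <= 126

    def decode(self, qual_string: str) -> list:
        """ASCII quality characters -> integer scores."""
        out = []
        for ch in qual_string:
            q = ord(ch) - self.ascii_offset
            if q < self.q_min or q > self.q_max:
                raise EncodingError(
                    f"quality character {ch!r} (code {ord(ch)}) outside "
                    f"{self.name} range"
                )
            out.append(q)
        return out

    def encode(self, quals: Sequence, context: str = "") -> str:
        """Integer scores -> ASCII quality string; out-of-range is an error."""
        chars = []
        for i, q in enumerate(quals):
            if q < self.q_min or q > self.q_max:
                where = f" in read {context!r}" if context else ""
                raise EncodingError(
                    f"score {q} at position {i}{where} not representable "
                    f"in {self.name} ({self.q_min}..{self.q_max})"
                )
            chars.append(chr(q + self.ascii_offset))
        return "".join(chars)


SANGER = QualityEncoding("sanger", 33, 0, 93)
SOLEXA = QualityEncoding("solexa", 64, -5, 62, is_solexa_scale=True)
ILLUMINA13 = QualityEncoding("illumina13", 64, 0, 62)

ENCODINGS = {e.name: e for e in (SANGER, SOLEXA, ILLUMINA13)}

DEFAULT_DETECTION_SAMPLE = 100_000


@dataclass(frozen=True)
class DetectionResult:
    encoding: QualityEncoding
    ambiguous: bool
    min_code: int
    max_code: int


def detect_variant(
    quality_strings: Iterable[str],
    sample_size: int = DEFAULT_DETECTION_SAMPLE,
) -> DetectionResult:
    """Classify the FASTQ dialect from a sample of quality lines.

    ``sample_size`` bounds the scan (0 means the whole input).  The decision
    depends only on the min/max ASCII codes observed, so it is deterministic
    and insensitive to record order within the sample.
    """
    lo, hi = 0x10FFFF, -1
    seen = 0
    for s in quality_strings:
        if not s:
            continue
        lo = min(lo, min(map(ord, s)))
        hi = max(hi, max(map(ord, s)))
        seen += 1
        if sample_size and seen >= sample_size:
            break
    if hi < 0:
        raise EncodingError("no non-empty quality strings to detect from")
    if lo < 33 or hi > 126:
        raise EncodingError(
            f"quality code {lo if lo < 33 else hi} outside printable FASTQ "
            "range 33..126; input is not FASTQ"
        )
    if lo < 59:
        return DetectionResult(SANGER, False, lo, hi)
    if lo < 64:
        return DetectionResult(SOLEXA, False, lo, hi)
    return DetectionResult(ILLUMINA13, True, lo, hi)


def solexa_to_phred(q_solexa: int) -> int:
    """Map a Solexa log-odds score to the nearest integer Phred score.

    Phred = 10*log10(10^(Q/10) + 1), rounded half away from zero (the
    domain is non-negative so this is round-half-up).  The mapping is
    monotone and converges to the identity for large Q.
    """
    if q_solexa < SOLEXA.q_min or q_solexa > SOLEXA.q_max:
        raise EncodingError(f"Solexa score {q_solexa} outside -5..62")
    phred = 10.0 * math.log10(10.0 ** (q_solexa / 10.0) + 1.0)
    return math.floor(phred + 0.5)


def _converted_read(record, quals, name):
    from .seqio import SequenceRead  # local import: seqio depends on this module

    return SequenceRead(record.id, record.seq, quals, record.desc)


def convert_sanger_to_illumina(record):
    """Re-encode a Sanger-scored read for the Illumina-1.3+ dialect.

    Numeric Phred scores are unchanged; only the ASCII offset shifts from
    33 to 64.  Scores above 62 do not exist in Illumina 1.3+ and raise an
    error naming the record and position — clamping would corrupt data.
    """
    if record.quals is None:
        raise EncodingError(f"read {record.id!r} has no quality scores")
    for i, q in enumerate(record.quals):
        if q > ILLUMINA13.q_max:
            raise EncodingError(
                f"read {record.id!r} position {i}: Phred {q} not "
                f"representable in illumina13 (max {ILLUMINA13.q_max})"
            )
    return _converted_read(record, record.quals, "illumina13")


def convert_solexa_to_illumina(record):
    """Map a Solexa-scored read to Phred scores on the Illumina-1.3+ scale."""
    if record.quals is None:
        raise EncodingError(f"read {record.id!r} has no quality scores")
    return _converted_read(
        record, [solexa_to_phred(q) for q in record.quals], "illumina13"
    )


def to_phred(quals: Sequence, encoding: QualityEncoding) -> list:
    """Decoded scores -> Phred scores (identity unless Solexa-scaled)."""
    if encoding.is_solexa_scale:
        return [solexa_to_phred(q) for q in quals]
    return list(quals)


def fastq_to_fasta(record, encoding: QualityEncoding):
    """Split a FASTQ record into a sequence-only read and Phred scores.

    Returns ``(sequence_record, phred_quals)`` ready for 454-style
    FASTA+qual output; Solexa input is mapped through ``solexa_to_phred``.
    """
    from .seqio import SequenceRead

    if record.quals is None:
        raise EncodingError(f"read {record.id!r} has no quality scores")
    phred = to_phred(record.quals, encoding)
    return SequenceRead(record.id, record.seq, None, record.desc), phred


def detect_variant_in_file(path, sample_size: int = DEFAULT_DETECTION_SAMPLE):
    """Detect the dialect of a FASTQ file (plain or gzip) from its bytes."""
    from .seqio import _open_read

    def quality_lines() -> Iterator[str]:
        fh = _open_read(path)
        while True:
            head = fh.readline()
            if not head or not head.strip():
                return
            fh.readline()
            fh.readline()
            yield fh.readline().rstrip("\n")

    return detect_variant(quality_lines(), sample_size)


def resolve_encoding(spec, path=None) -> DetectionResult:
    """Turn a user spec (``auto``, a name, or an encoding) into a decision."""
    if isinstance(spec, QualityEncoding):
        return DetectionResult(spec, False, -1, -1)
    if spec is None or spec == "auto":
        if path is None:
            raise ValueError("auto-detection needs an input file")
        return detect_variant_in_file(path)
    if spec in ENCODINGS:
        return DetectionResult(ENCODINGS[spec], False, -1, -1)
    raise ValueError(
        f"unknown FASTQ variant {spec!r}; expected auto, sanger, solexa or "
        "illumina13"
    )
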