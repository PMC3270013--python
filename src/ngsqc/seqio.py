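"""Streaming readers and writers for FASTQ and FASTA+qual files.

Both readers yield one :class:`SequenceRead` at a time so memory use is
bounded by a single record regardless of file size.  gzip compression is
detected on input by the two magic bytes ``1f 8b`` (never by filename) and
can be requested explicitly on output.

FASTQ records are the strict 4-line form (header, sequence, separator,
quality); multi-line FASTQ is deliberately unsupported.  454-style qual
files are FASTA-formatted blocks of whitespace-separated integer Phred
scores whose headers must agree, in order, with the companion sequence
file.
"""

from __future__ import annotations

import gzip
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional, Sequence, Union

from .encodings import QualityEncoding

GZIP_MAGIC = b"\x1f\x8b"

# trailing /1, /2 mate markers on the identifier token
_MATE_SUFFIX = re.compile(r"/[12]$")
# Casava 1.8 style mate field: first token of the description, e.g. "1:N:0:ACGT"
_CASAVA_MATE = re.compile(r"^[12]:[YN]:\d+:\S*$")

PathOrStream = Union[str, Path, IO]


class FormatError(ValueError):
    """A malformed FASTQ/FASTA/qual record."""


@dataclass
class SequenceRead:
    """One sequencing read: identifier, bases and optional per-base Phred scores.

    ``id`` is the first whitespace-delimited token of the header line and
    ``desc`` the remainder (may be empty).  ``quals`` holds one integer score
    per base, or ``None`` for sequence-only FASTA records.  Bases are
    uppercased on construction; non-ACGT (IUPAC ambiguity letters, N) are
    preserved verbatim because downstream statistics count them.
    """

    id: str
    seq: str
    quals: Optional[tuple] = None
    desc: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("read identifier must be non-empty")
        self.seq = self.seq.upper()
        if self.quals is not None:
            self.quals = tuple(self.quals)
            if len(self.quals) != len(self.seq):
                raise FormatError(
                    f"read {self.id!r}: {len(self.quals)} quality scores "
                    f"for {len(self.seq)} bases"
                )
            # Phred scores are non-negative; Solexa log-odds may reach -5
            if any(q < -5 for q in self.quals):
                raise FormatError(f"read {self.id!r}: quality score below -5")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def pairing_key(self) -> str:
        """Identifier with any trailing ``/1`` ``/2`` mate marker stripped.

        Casava-1.8 headers carry the mate number in the description instead,
        so the bare ``id`` token is already the pairing key there.
        """
        return _MATE_SUFFIX.sub("", self.id)

    @property
    def mate_number(self) -> Optional[int]:
        """1 or 2 when a mate marker is present (``/1``, ``/2`` or Casava)."""
        m = _MATE_SUFFIX.search(self.id)
        if m:
            return int(m.group(0)[1])
        first = self.desc.split(None, 1)[0] if self.desc else ""
        if _CASAVA_MATE.match(first):
            return int(first[0])
        return None

    @property
    def header(self) -> str:
        return f"{self.id} {self.desc}".rstrip()

    def slice(self, start: int, stop: int) -> "SequenceRead":
        """Sub-read over ``[start, stop)`` with quals taken in lockstep."""
        quals = self.quals[start:stop] if self.quals is not None else None
        return SequenceRead(self.id, self.seq[start:stop], quals, self.desc)


@dataclass
class ReadPair:
    """A forward/reverse mate pair whose pairing keys must agree."""

    forward: SequenceRead
    reverse: SequenceRead

    def __post_init__(self) -> None:
        if self.forward.pairing_key != self.reverse.pairing_key:
            raise FormatError(
                f"mate identifiers disagree: {self.forward.id!r} vs "
                f"{self.reverse.id!r}"
            )


def _open_read(source: PathOrStream) -> IO[str]:
    """Open ``source`` for text reading, transparently un-gzipping.

    gzip is recognised by magic bytes so a misnamed ``.fastq`` that is
    really compressed still parses.
    """
    if hasattr(source, "read"):
        raw = source
        if isinstance(raw.read(0), str):  # already a text stream
            return raw
        buffered = io.BufferedReader(raw) if not hasattr(raw, "peek") else raw
        if buffered.peek(2)[:2] == GZIP_MAGIC:
            return io.TextIOWrapper(gzip.GzipFile(fileobj=buffered))
        return io.TextIOWrapper(buffered)
    path = Path(source)
    fh = open(path, "rb")
    if fh.peek(2)[:2] == GZIP_MAGIC:
        return io.TextIOWrapper(gzip.GzipFile(fileobj=fh))
    return io.TextIOWrapper(fh)


def _open_write(dest: PathOrStream, compress: bool) -> IO[str]:
    if hasattr(dest, "write"):
        return dest
    if compress:
        # mtime pinned to 0 so identical runs produce identical bytes
        return io.TextIOWrapper(
            gzip.GzipFile(str(dest), mode="wb", mtime=0)
        )
    return open(dest, "w")


def _split_header(line: str) -> tuple:
    parts = line.split(None, 1)
    if not parts:
        raise FormatError("empty header line")
    return parts[0], (parts[1] if len(parts) > 1 else "")


def read_fastq(
    source: PathOrStream, encoding: QualityEncoding
) -> Iterator[SequenceRead]:
    """Yield reads from a 4-line-per-record FASTQ file, plain or gzipped.

    Quality characters are decoded to integer scores with ``encoding``
    (Solexa files yield Solexa log-odds scores, not Phred).  Malformed
    records raise :class:`FormatError` naming the record ordinal and line
    number; a quality character outside the encoding's legal range raises an
    error naming the character.
    """
    fh = _open_read(source)
    lineno = 0
    ordinal = 0
    while True:
        head = fh.readline()
        if not head:
            return
        lineno += 1
        ordinal += 1
        head = head.rstrip("\n")
        if not head.strip():
            # tolerate trailing blank lines only
            for rest in fh:
                if rest.strip():
                    raise FormatError(
                        f"record {ordinal}, line {lineno}: blank line inside file"
                    )
            return
        if not head.startswith("@"):
            raise FormatError(
                f"record {ordinal}, line {lineno}: expected '@', got {head[:1]!r}"
            )
        seq = fh.readline().rstrip("\n")
        plus = fh.readline().rstrip("\n")
        qual = fh.readline().rstrip("\n")
        lineno += 3
        if not plus.startswith("+"):
            raise FormatError(
                f"record {ordinal}, line {lineno - 1}: expected '+' separator"
            )
        if len(seq) != len(qual):
            raise FormatError(
                f"record {ordinal}, line {lineno}: sequence length {len(seq)} "
                f"!= quality length {len(qual)}"
            )
        rid, desc = _split_header(head[1:])
        quals = encoding.decode(qual)
        yield SequenceRead(rid, seq, quals, desc)


def write_fastq(
    records: Iterable[SequenceRead],
    dest: PathOrStream,
    encoding: QualityEncoding,
    compress: bool = False,
) -> int:
    """Write records as FASTQ, returning the record count.

    A score outside the encoding's representable range is a hard error;
    values are never silently clamped.
    """
    fh = _open_write(dest, compress)
    n = 0
    try:
        for rec in records:
            if rec.quals is None:
                raise FormatError(f"read {rec.id!r} has no quality scores")
            qual = encoding.encode(rec.quals, context=rec.id)
            fh.write(f"@{rec.header}\n{rec.seq}\n+\n{qual}\n")
            n += 1
    finally:
        if not hasattr(dest, "write"):
            fh.close()
    return n


def _read_fasta_blocks(source: PathOrStream) -> Iterator[tuple]:
    """Yield ``(header, body_lines)`` for each FASTA record."""
    fh = _open_read(source)
    header = None
    body: list = []
    for line in fh:
        line = line.rstrip("\n")
        if line.startswith(">"):
            if header is not None:
                yield header, body
            header = line[1:]
            body = []
        elif line.strip():
            if header is None:
                raise FormatError("sequence data before first '>' header")
            body.append(line.strip())
    if header is not None:
        yield header, body


def read_fasta_qual(
    seq_source: PathOrStream, qual_source: Optional[PathOrStream] = None
) -> Iterator[SequenceRead]:
    """Yield reads from a FASTA file, attaching scores from a 454 qual file.

    The qual file holds whitespace-separated integers under headers that
    must match the sequence file's headers in the same order; a mismatch is
    an error naming both headers.
    """
    seq_blocks = _read_fasta_blocks(seq_source)
    qual_blocks = _read_fasta_blocks(qual_source) if qual_source is not None else None
    for header, body in seq_blocks:
        rid, desc = _split_header(header)
        seq = "".join(body)
        quals = None
        if qual_blocks is not None:
            try:
                qheader, qbody = next(qual_blocks)
            except StopIteration:
                raise FormatError(
                    f"qual file ended before sequence record {rid!r}"
                ) from None
            if qheader != header:
                raise FormatError(
                    f"header mismatch: sequence file has {header!r}, "
                    f"qual file has {qheader!r}"
                )
            try:
                quals = [int(tok) for tok in " ".join(qbody).split()]
            except ValueError as exc:
                raise FormatError(f"record {rid!r}: non-integer quality value") from exc
            if any(q < 0 for q in quals):
                raise FormatError(f"record {rid!r}: negative quality value")
            if len(quals) != len(seq):
                raise FormatError(
                    f"record {rid!r}: {len(quals)} quality values for "
                    f"{len(seq)} bases"
                )
        yield SequenceRead(rid, seq, quals, desc)
    if qual_blocks is not None:
        try:
            qheader, _ = next(qual_blocks)
        except StopIteration:
            pass
        else:
            raise FormatError(
                f"qual record {qheader!r} has no matching sequence record"
            )


def _wrap(text: str, width: int) -> Iterator[str]:
    for i in range(0, len(text), width):
        yield text[i : i + width]


def write_fasta_qual(
    records: Iterable[SequenceRead],
    seq_dest: PathOrStream,
    qual_dest: Optional[PathOrStream] = None,
    width: int = 70,
    compress: bool = False,
) -> int:
    """Write FASTA (and optionally a companion qual file); returns the count.

    Sequence lines wrap at ``width`` columns; quality integers wrap so that
    at most ``width`` space-separated values share a line.
    """
    sfh = _open_write(seq_dest, compress)
    qfh = _open_write(qual_dest, compress) if qual_dest is not None else None
    n = 0
    try:
        for rec in records:
            sfh.write(f">{rec.header}\n")
            for chunk in _wrap(rec.seq, width) if rec.seq else [""]:
                sfh.write(chunk + "\n")
            if qfh is not None:
                if rec.quals is None:
                    raise FormatError(f"read {rec.id!r} has no quality scores")
                qfh.write(f">{rec.header}\n")
                vals = [str(q) for q in rec.quals]
                if not vals:
                    qfh.write("\n")
                for i in range(0, len(vals), width):
                    qfh.write(" ".join(vals[i : i + width]) + "\n")
            n += 1
    finally:
        if not hasattr(seq_dest, "write"):
            sfh.close()
        if qfh is not None and not hasattr(qual_dest, "write"):
            qfh.close()
    return n
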