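"""Deterministic synthetic-read generator with planted QC artifacts.

Every generated dataset comes with a manifest recording, per read, which
artifact was planted (none, low-quality, adaptor contamination with a
stated mismatch count, a homopolymer run, a paired-end linker) and the
fate the matching QC pipeline is expected to assign under the stated
parameters.  Running the pipeline and diffing against the manifest is the
end-to-end ground-truth check for the whole toolkit.

Plants are unambiguous by construction: low-quality reads sit far below
the Phred cutoff, high-quality backgrounds sit far above it with jitter
bounded away from the boundary, and backgrounds never contain single-base
runs long enough to trigger homopolymer trimming by accident.  The same
seed always yields byte-identical output.
"""

from __future__ import annotations

import csv
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

from .encodings import ENCODINGS
from .seqio import SequenceRead, write_fasta_qual, write_fastq

# Widely used public adaptor/linker sequences; both are free of runs >= 4
# so they never fake a homopolymer plant.
DEFAULT_ADAPTOR = "GATCGGAAGAGCACACGTCTGAACTCCAGT"
DEFAULT_LINKER = "GTTGGAACCGAAAGGGTTTGAATTCAAACCCTTTCGGTTCCAAC"

_BASES = "ACGT"
_MAX_BACKGROUND_RUN = 4  # backgrounds never reach a run of 5


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic dataset.

    Fractions are of ``n_reads`` (or of pairs, for the paired-end
    fractions) and must sum to at most 1.  ``adaptor_mismatches`` is
    cycled over successive adaptor plants.  ``read_length`` is either a
    fixed length or an inclusive ``(lo, hi)`` range.
    """

    platform: str = "illumina"  # "illumina" | "454"
    n_reads: int = 1000
    read_length: Union[int, Tuple[int, int]] = 100
    base_quality: int = 35
    quality_jitter: int = 2
    low_quality_q: int = 2
    frac_low_quality: float = 0.0
    frac_adaptor: float = 0.0
    adaptor: str = DEFAULT_ADAPTOR
    adaptor_mismatches: Tuple[int, ...] = (0,)
    frac_homopolymer: float = 0.0
    homopolymer_run: int = 8
    homopolymer_base: str = "A"
    frac_linker: float = 0.0
    frac_linker_fwd_fail: float = 0.0
    linker: str = DEFAULT_LINKER
    paired: bool = False
    frac_fwd_fail: float = 0.0
    frac_rev_fail: float = 0.0
    frac_both_fail: float = 0.0
    min_len: int = 50  # the length cutoff the 454 fates assume
    encoding: str = "sanger"
    seed: int = 0

    def validate(self) -> None:
        total = (
            self.frac_low_quality
            + self.frac_adaptor
            + self.frac_homopolymer
            + self.frac_linker
            + self.frac_linker_fwd_fail
            + self.frac_fwd_fail
            + self.frac_rev_fail
            + self.frac_both_fail
        )
        if total > 1.0 + 1e-9:
            raise ValueError(f"planted fractions sum to {total} > 1")
        if self.platform not in ("illumina", "454"):
            raise ValueError(f"unknown platform {self.platform!r}")
        length = self._min_length()
        if self.frac_adaptor and len(self.adaptor) > length:
            raise ValueError("adaptor longer than the shortest read")
        if self.frac_homopolymer and self.homopolymer_run > length:
            raise ValueError("homopolymer run longer than the shortest read")
        if self.paired and self.platform != "illumina":
            raise ValueError("paired mode is for the illumina platform; "
                             "454 pairs are linker plants")

    def _min_length(self) -> int:
        return (
            self.read_length
            if isinstance(self.read_length, int)
            else self.read_length[0]
        )


@dataclass(frozen=True)
class ManifestEntry:
    """Ground truth for one read (or one 454 parent read)."""

    read_id: str
    artifact: str  # none|low_quality|adaptor|homopolymer|linker|linker_fwd_fail|...
    detail: str  # e.g. "mismatches=1" or "run_start=62"
    expected_fate: str  # pipeline stage key, "kept", "pair", "unpaired", ...
    expected_length: Optional[int] = None


@dataclass
class FixtureResult:
    reads: List[SequenceRead]
    manifest: List[ManifestEntry]
    mates: Optional[Tuple[List[SequenceRead], List[SequenceRead]]] = None


def _background(rng: random.Random, n: int) -> str:
    """Random bases with no single-base run longer than 4."""
    out: List[str] = []
    run = 0
    for _ in range(n):
        if run >= _MAX_BACKGROUND_RUN:
            base = rng.choice([b for b in _BASES if b != out[-1]])
        else:
            base = rng.choice(_BASES)
        run = run + 1 if out and base == out[-1] else 1
        out.append(base)
    return "".join(out)


def _max_run(seq: str) -> int:
    best = run = 0
    prev = ""
    for b in seq:
        run = run + 1 if b == prev else 1
        prev = b
        best = max(best, run)
    return best


def _hq_quals(rng: random.Random, spec: FixtureSpec, n: int) -> List[int]:
    lo = spec.base_quality - spec.quality_jitter
    hi = spec.base_quality + spec.quality_jitter
    return [rng.randint(lo, hi) for _ in range(n)]


def _length(rng: random.Random, spec: FixtureSpec) -> int:
    if isinstance(spec.read_length, int):
        return spec.read_length
    return rng.randint(*spec.read_length)


def _mutate(rng: random.Random, window: str, k: int) -> str:
    """Substitute ``k`` distinct positions with a different base."""
    chars = list(window)
    for pos in rng.sample(range(len(chars)), k):
        chars[pos] = rng.choice([b for b in _BASES if b != chars[pos]])
    return "".join(chars)


def _class_assignment(rng: random.Random, spec: FixtureSpec) -> List[str]:
    """One artifact class per read index, shuffled deterministically."""
    n = spec.n_reads
    pairs = [
        ("low_quality", spec.frac_low_quality),
        ("adaptor", spec.frac_adaptor),
        ("homopolymer", spec.frac_homopolymer),
        ("linker", spec.frac_linker),
        ("linker_fwd_fail", spec.frac_linker_fwd_fail),
        ("fwd_fail", spec.frac_fwd_fail),
        ("rev_fail", spec.frac_rev_fail),
        ("both_fail", spec.frac_both_fail),
    ]
    classes: List[str] = []
    for name, frac in pairs:
        classes.extend([name] * int(round(frac * n)))
    if len(classes) > n:
        raise ValueError("planted fractions exceed the read count")
    classes.extend(["none"] * (n - len(classes)))
    rng.shuffle(classes)
    return classes


def _plant_window(
    rng: random.Random, seq: str, window: str, lo: int, hi: int
) -> Tuple[str, int]:
    """Overwrite ``window`` at a start drawn from ``[lo, hi]``."""
    start = rng.randint(lo, hi)
    return seq[:start] + window + seq[start + len(window):], start


def _plant_run(
    rng: random.Random, seq: str, base: str, run_len: int, start: int
) -> str:
    """Plant an exact single-base run, guarding both flanks with a
    different base so the run's start and length stay as recorded."""
    chars = list(seq[:start] + base * run_len + seq[start + run_len:])
    others = [b for b in _BASES if b != base]
    if start > 0 and chars[start - 1] == base:
        chars[start - 1] = rng.choice(others)
    end = start + run_len
    if end < len(chars) and chars[end] == base:
        chars[end] = rng.choice(others)
    return "".join(chars)


def _illumina_read(
    rng: random.Random, spec: FixtureSpec, rid: str, cls: str, mm_cycle: List[int]
) -> Tuple[SequenceRead, ManifestEntry]:
    n = _length(rng, spec)
    seq = _background(rng, n)
    quals = _hq_quals(rng, spec, n)
    if cls == "low_quality":
        quals = [spec.low_quality_q] * n
        entry = ManifestEntry(rid, cls, "", "low_quality", None)
    elif cls == "adaptor":
        k = mm_cycle.pop(0)
        mm_cycle.append(k)
        window = _mutate(rng, spec.adaptor[:20], k)
        seq, start = _plant_window(rng, seq, window, 0, n - 20)
        fate = "adaptor" if k <= 1 else "kept"
        entry = ManifestEntry(rid, cls, f"mismatches={k};start={start}", fate, None)
    elif cls == "homopolymer":
        # a run at position 0 would empty the read when trimmed
        start = rng.randint(1, n - spec.homopolymer_run)
        seq = _plant_run(rng, seq, spec.homopolymer_base, spec.homopolymer_run, start)
        entry = ManifestEntry(
            rid, cls, f"run_start={start};run_len={spec.homopolymer_run}",
            "kept", start,
        )
    else:
        entry = ManifestEntry(rid, "none", "", "kept", n)
    if cls != "homopolymer" and spec.frac_homopolymer:
        # rebuild any accidental qualifying run in a non-homopolymer read
        while _max_run(seq) >= spec.homopolymer_run:
            seq = _background(rng, n)  # pragma: no cover - vanishingly rare
    return SequenceRead(rid, seq, quals), entry


def _roche_read(
    rng: random.Random, spec: FixtureSpec, rid: str, cls: str, mm_cycle: List[int]
) -> Tuple[SequenceRead, ManifestEntry]:
    n = _length(rng, spec)
    seq = _background(rng, n)
    quals = _hq_quals(rng, spec, n)
    if cls == "low_quality":
        quals = [spec.low_quality_q] * n
        entry = ManifestEntry(rid, cls, "", "low_quality", None)
    elif cls == "adaptor":
        k = mm_cycle.pop(0)
        mm_cycle.append(k)
        window = _mutate(rng, spec.adaptor[:20], k)
        if rng.random() < 0.5:  # 5' end: window inside the first 50 bases
            seq, start = _plant_window(rng, seq, window, 0, min(30, n - 20))
            expected = n - (start + 20)
        else:  # 3' end: window inside the last 50 bases
            seq, start = _plant_window(rng, seq, window, max(n - 50, 0), n - 20)
            expected = start
        if k <= 1:
            fate = "kept" if expected >= spec.min_len else "adaptor_trim_short"
            entry = ManifestEntry(
                rid, cls, f"mismatches={k};start={start}", fate,
                expected if fate == "kept" else None,
            )
        else:
            entry = ManifestEntry(rid, cls, f"mismatches={k};start={start}", "kept", n)
    elif cls == "homopolymer":
        start = rng.randint(1, n - spec.homopolymer_run)
        seq = _plant_run(rng, seq, spec.homopolymer_base, spec.homopolymer_run, start)
        if start >= spec.min_len:
            entry = ManifestEntry(
                rid, cls, f"run_start={start}", "kept", start
            )
        else:
            entry = ManifestEntry(
                rid, cls, f"run_start={start}", "homopolymer_trim_short", None
            )
    elif cls in ("linker", "linker_fwd_fail"):
        flen = rng.randint(spec.min_len + 10, spec.min_len + 40)
        rlen = rng.randint(spec.min_len + 10, spec.min_len + 40)
        fwd = _background(rng, flen)
        rev = _background(rng, rlen)
        seq = fwd + spec.linker + rev
        quals = _hq_quals(rng, spec, len(seq))
        if cls == "linker_fwd_fail":
            quals[:flen] = [spec.low_quality_q] * flen
            fate = "unpaired_reverse"
        else:
            fate = "pair"
        entry = ManifestEntry(
            rid, cls, f"linker_span=({flen},{flen + len(spec.linker)})", fate, None
        )
    else:
        entry = ManifestEntry(rid, "none", "", "kept", n)
    if cls not in ("homopolymer", "linker", "linker_fwd_fail") and spec.frac_homopolymer:
        while _max_run(seq) >= spec.homopolymer_run:  # pragma: no cover
            seq = _background(rng, len(seq))
    return SequenceRead(rid, seq, quals), entry


def _paired_reads(
    rng: random.Random, spec: FixtureSpec
) -> FixtureResult:
    fwd: List[SequenceRead] = []
    rev: List[SequenceRead] = []
    manifest: List[ManifestEntry] = []
    classes = _class_assignment(rng, spec)
    for i, cls in enumerate(classes):
        key = f"pair{i:05d}"
        n = _length(rng, spec)
        f = SequenceRead(f"{key}/1", _background(rng, n), _hq_quals(rng, spec, n))
        r = SequenceRead(f"{key}/2", _background(rng, n), _hq_quals(rng, spec, n))
        if cls in ("fwd_fail", "both_fail"):
            f = SequenceRead(f.id, f.seq, [spec.low_quality_q] * n)
        if cls in ("rev_fail", "both_fail"):
            r = SequenceRead(r.id, r.seq, [spec.low_quality_q] * n)
        fate = {
            "none": "pair",
            "fwd_fail": "unpaired_reverse",
            "rev_fail": "unpaired_forward",
            "both_fail": "dropped",
        }.get(cls, "pair")
        manifest.append(ManifestEntry(key, cls, "", fate, None))
        fwd.append(f)
        rev.append(r)
    return FixtureResult(reads=fwd + rev, manifest=manifest, mates=(fwd, rev))


def generate_reads(spec: FixtureSpec) -> FixtureResult:
    """Build the reads and manifest for ``spec`` entirely in memory."""
    spec.validate()
    rng = random.Random(spec.seed)
    if spec.paired:
        return _paired_reads(rng, spec)
    mm_cycle = list(spec.adaptor_mismatches)
    make = _illumina_read if spec.platform == "illumina" else _roche_read
    reads: List[SequenceRead] = []
    manifest: List[ManifestEntry] = []
    for i, cls in enumerate(_class_assignment(rng, spec)):
        read, entry = make(rng, spec, f"read{i:05d}", cls, mm_cycle)
        reads.append(read)
        manifest.append(entry)
    return FixtureResult(reads=reads, manifest=manifest)


def write_manifest(manifest: Sequence[ManifestEntry], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["read_id", "artifact", "detail", "expected_fate",
                         "expected_length"])
        for e in manifest:
            writer.writerow([
                e.read_id, e.artifact, e.detail, e.expected_fate,
                "" if e.expected_length is None else e.expected_length,
            ])


def read_manifest(path) -> List[ManifestEntry]:
    entries = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            entries.append(
                ManifestEntry(
                    row["read_id"], row["artifact"], row["detail"],
                    row["expected_fate"],
                    int(row["expected_length"]) if row["expected_length"] else None,
                )
            )
    return entries


def generate(spec: FixtureSpec, out_dir) -> Dict[str, Path]:
    """Write the dataset and its manifest to ``out_dir``; returns the paths.

    Illumina datasets become FASTQ (one file, or two for paired mode);
    454 datasets become an fna + qual pair.  The same spec and seed always
    produce byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result = generate_reads(spec)
    enc = ENCODINGS[spec.encoding]
    paths: Dict[str, Path] = {}
    if spec.paired:
        assert result.mates is not None
        paths["forward"] = out_dir / "reads_1.fastq"
        paths["reverse"] = out_dir / "reads_2.fastq"
        write_fastq(result.mates[0], paths["forward"], enc)
        write_fastq(result.mates[1], paths["reverse"], enc)
    elif spec.platform == "illumina":
        paths["reads"] = out_dir / "reads.fastq"
        write_fastq(result.reads, paths["reads"], enc)
    else:
        paths["fna"] = out_dir / "reads.fna"
        paths["qual"] = out_dir / "reads.qual"
        write_fasta_qual(result.reads, paths["fna"], paths["qual"])
    paths["manifest"] = out_dir / "manifest.tsv"
    write_manifest(result.manifest, paths["manifest"])
    return paths
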