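"""Streaming FASTQ input/output with gzip auto-detection.

Parsing is delegated to Biopython's ``FastqGeneralIterator`` (fast,
title/seq/qual tuples, validates record structure); this module adds
gzip sniffing, base normalisation, quality-encoding detection and the
bounded preprocessing scan used to size the primer search window.
"""

from __future__ import annotations

import enum
import gzip
import logging
import warnings
from dataclasses import dataclass, replace
from typing import IO, Iterable, Iterator, Sequence

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import FastqFormatError

logger = logging.getLogger(__name__)

_GZIP_MAGIC = b"\x1f\x8b"
_VALID_BASES = frozenset("ACGTN")
_UPPER_N = {c: ("N" if c not in _VALID_BASES else c) for c in map(chr, range(65, 91))}


class QualityEncoding(enum.Enum):
    PHRED33 = 33
    PHRED64 = 64


@dataclass(frozen=True)
class SeqRecord:
    """One FASTQ record; quality kept as the raw ASCII string."""

    read_id: str
    sequence: str
    quality: str
    encoding: QualityEncoding = QualityEncoding.PHRED33

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise FastqFormatError(
                f"record {self.read_id!r}: sequence and quality lengths differ"
            )

    def phred_scores(self) -> list[int]:
        offset = self.encoding.value
        return [ord(c) - offset for c in self.quality]

    def sliced(self, start: int, end: int) -> "SeqRecord":
        """Sub-record keeping id and encoding; sequence and quality cut together."""
        return replace(self, sequence=self.sequence[start:end], quality=self.quality[start:end])


@dataclass(frozen=True)
class ScanSummary:
    max_read_len: int
    record_count: int
    encoding: QualityEncoding


def _open_text(path) -> IO[str]:
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == _GZIP_MAGIC:
        return gzip.open(path, "rt", encoding="ascii")
    return open(path, "rt", encoding="ascii")


def _normalise(seq: str, path, warned: list[bool]) -> str:
    seq = seq.upper()
    if set(seq) <= _VALID_BASES:
        return seq
    if not warned[0]:
        warned[0] = True
        warnings.warn(f"{path}: bases outside A/C/G/T/N mapped to N", stacklevel=3)
    return "".join(c if c in _VALID_BASES else "N" for c in seq)


def read_fastq(
    path, encoding: QualityEncoding = QualityEncoding.PHRED33
) -> Iterator[SeqRecord]:
    """Yield records from a plain or gzipped 4-line FASTQ file.

    Lowercase bases are uppercased; anything outside {A,C,G,T,N} becomes N
    with a one-time warning.  Truncated or inconsistent records raise
    :class:`FastqFormatError` naming the record ordinal.
    """
    warned = [False]
    ordinal = 0
    handle = _open_text(path)
    try:
        iterator = FastqGeneralIterator(handle)
        while True:
            try:
                title, seq, qual = next(iterator)
            except StopIteration:
                break
            except ValueError as exc:
                raise FastqFormatError(f"{path}: record {ordinal + 1}: {exc}") from exc
            ordinal += 1
            yield SeqRecord(title.split()[0], _normalise(seq, path, warned), qual, encoding)
    finally:
        handle.close()


def detect_quality_encoding(sample: Sequence[str]) -> QualityEncoding:
    """Classify Phred+33 vs Phred+64 from observed quality characters.

    Any code below 59 forces Phred+33 (such codes are illegal under +64);
    Phred+64 is called only when all codes are >= 64 and at least one is
    >= 75 (impossible under +33, whose ceiling is Q41); samples where
    every code is legal under both encodings default to Phred+33, the
    modern-platform convention.
    """
    if not sample:
        raise ValueError("cannot detect quality encoding from an empty sample")
    codes = [ord(c) for q in sample for c in q]
    if not codes:
        raise ValueError("cannot detect quality encoding from empty quality strings")
    if min(codes) < 59:
        return QualityEncoding.PHRED33
    if min(codes) >= 64 and max(codes) >= 75:
        return QualityEncoding.PHRED64
    return QualityEncoding.PHRED33


def prescan(paths: Iterable, sample_records: int = 10_000) -> ScanSummary:
    """Bounded preprocessing pass: max read length, record count, encoding.

    Reads at most ``sample_records`` records per file; the search window
    is sized by the primer lengths anyway, so an exact global maximum is
    not required.
    """
    max_len = 0
    count = 0
    quals: list[str] = []
    for path in paths:
        for i, rec in enumerate(read_fastq(path)):
            if i >= sample_records:
                break
            count += 1
            max_len = max(max_len, len(rec.sequence))
            if len(quals) < 1000:
                quals.append(rec.quality)
    if not quals:
        logger.warning("prescan saw no records; empty input?")
        return ScanSummary(0, 0, QualityEncoding.PHRED33)
    return ScanSummary(max_len, count, detect_quality_encoding(quals))


def write_fastq(records: Iterable[SeqRecord], path) -> None:
    """Write 4-line FASTQ; gzip-compressed iff ``path`` ends in ``.gz``."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt", encoding="ascii") as handle:
        for rec in records:
            handle.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{rec.quality}\n")
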