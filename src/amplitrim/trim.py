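"""Trimming engine: apply primer matches under the normal and read-through
geometries, quality filtering, and single/paired-end orchestration.

After the 5' primer is removed, the matched amplicon's insert length
decides the geometry: a remaining read longer than the insert must have
run through into the reverse complement of the partner primer (short
cfDNA-style amplicons on longer reads), so the 3' end is searched around
the expected boundary; otherwise only the 5' primer is present.
"""

from __future__ import annotations

import enum
import logging
import statistics
from dataclasses import dataclass, field

from .errors import AmplitrimError
from .fastq import SeqRecord
from .kmer_index import FIVE_PRIME_ROLES, KmerIndex, SeedRole
from .match import MatchParams, PrimerMatch, hamming_distance, locate_primer
from .panel import AmpliconPanel, AmpliconPrimer, reverse_complement

logger = logging.getLogger(__name__)

DEFAULT_READTHROUGH_SLACK = 5


class TrimStatus(enum.Enum):
    TRIMMED_NORMAL = "trimmed_normal"
    TRIMMED_READTHROUGH = "trimmed_readthrough"
    UNTRIMMED = "untrimmed"
    DROPPED_QUALITY = "dropped_quality"


@dataclass
class TrimParams:
    match_params: MatchParams = field(default_factory=MatchParams)
    min_qual: float = 0.0  # mean-quality threshold; 0 disables
    keep_untrimmed: bool = True
    readthrough_slack: int = DEFAULT_READTHROUGH_SLACK

    def __post_init__(self) -> None:
        if self.min_qual < 0 or self.readthrough_slack < 0:
            raise ValueError("min_qual and readthrough_slack must be >= 0")


@dataclass(frozen=True)
class TrimResult:
    record: SeqRecord
    status: TrimStatus
    match: PrimerMatch | None
    bases_removed_5p: int = 0
    bases_removed_3p: int = 0


def passes_quality(record: SeqRecord, min_qual: float) -> bool:
    """Mean Phred score of the full (untrimmed) read against the threshold."""
    if min_qual <= 0 or not record.sequence:
        return True
    return statistics.fmean(record.phred_scores()) >= min_qual


def find_readthrough_end(
    seq_after_5p: str,
    matched: AmpliconPrimer,
    which_end_primer: SeedRole,
    params: TrimParams,
) -> int | None:
    """Locate the 3' partner-primer boundary in a read-through read.

    The partner of a read that began with the forward primer is the
    reverse primer (and vice versa); its reverse complement is expected
    at offset ``insert_len`` of the 5'-trimmed read.  Offsets within
    ``readthrough_slack`` of that are scored by Hamming distance over the
    overlapping portion (>= k bases required; the primer may be truncated
    by the read end).  Ties go to the offset closest to the expected
    boundary, then to the smaller offset.
    """
    mp = params.match_params
    if which_end_primer is SeedRole.FORWARD_5P:
        partner_rc = reverse_complement(matched.reverse_seq)
    else:
        partner_rc = reverse_complement(matched.forward_seq)
    expected = matched.insert_len
    best: tuple[int, int, int] | None = None  # cost, |off-expected|, off
    for off in range(expected - params.readthrough_slack, expected + params.readthrough_slack + 1):
        if off < 0:
            continue
        overlap = min(len(partner_rc), len(seq_after_5p) - off)
        if overlap < mp.k:
            continue
        cost = hamming_distance(partner_rc[:overlap], seq_after_5p[off : off + overlap])
        key = (cost, abs(off - expected), off)
        if best is None or key < best:
            best = key
    if best is not None and best[0] <= mp.max_mismatch:
        return best[2]
    return None


def trim_single(
    record: SeqRecord,
    index: KmerIndex,
    panel: AmpliconPanel,
    params: TrimParams,
) -> TrimResult:
    """Trim one read: 5' primer removal, then geometry-driven 3' removal.

    A 5' match removes ``[0, match.read_end)`` — any junk bases before a
    shifted primer placement are not insert sequence and go with it.  The
    quality string is always cut at the same coordinates.
    """
    match = locate_primer(record.sequence, index, panel, params.match_params, FIVE_PRIME_ROLES)
    if match is None:
        return TrimResult(record, TrimStatus.UNTRIMMED, None)
    cut5 = match.read_end
    remaining = record.sliced(cut5, len(record.sequence))
    amplicon = panel.primers[match.primer_index]
    status = TrimStatus.TRIMMED_NORMAL
    removed3 = 0
    if len(remaining.sequence) > amplicon.insert_len:
        boundary = find_readthrough_end(remaining.sequence, amplicon, match.role, params)
        if boundary is not None:
            removed3 = len(remaining.sequence) - boundary
            remaining = remaining.sliced(0, boundary)
            status = TrimStatus.TRIMMED_READTHROUGH
    return TrimResult(remaining, status, match, cut5, removed3)


def _mate_prefix(read_id: str) -> str:
    for suffix in ("/1", "/2"):
        if read_id.endswith(suffix):
            return read_id[: -len(suffix)]
    return read_id


def process_pair(
    r1: SeqRecord,
    r2: SeqRecord,
    index: KmerIndex,
    panel: AmpliconPanel,
    params: TrimParams,
) -> tuple[TrimResult, TrimResult]:
    """Trim both mates independently; quality-drop them together.

    If either mate fails the mean-quality filter both are marked
    DROPPED_QUALITY so paired outputs never desynchronise.
    """
    if _mate_prefix(r1.read_id) != _mate_prefix(r2.read_id):
        logger.warning("mate id mismatch: %r vs %r", r1.read_id, r2.read_id)
    if not (passes_quality(r1, params.min_qual) and passes_quality(r2, params.min_qual)):
        return (
            TrimResult(r1, TrimStatus.DROPPED_QUALITY, None),
            TrimResult(r2, TrimStatus.DROPPED_QUALITY, None),
        )
    return (
        trim_single(r1, index, panel, params),
        trim_single(r2, index, panel, params),
    )


@dataclass
class RunSummary:
    """Trimming run accounting; categories partition ``total_reads``."""

    total_reads: int = 0
    trimmed_reads: int = 0
    readthrough_reads: int = 0
    untrimmed_reads: int = 0
    dropped_quality: int = 0
    per_amplicon: dict[str, int] = field(default_factory=dict)

    def record(self, result: TrimResult, panel: AmpliconPanel) -> None:
        self.total_reads += 1
        if result.status is TrimStatus.DROPPED_QUALITY:
            self.dropped_quality += 1
        elif result.status is TrimStatus.UNTRIMMED:
            self.untrimmed_reads += 1
        else:
            self.trimmed_reads += 1
            if result.status is TrimStatus.TRIMMED_READTHROUGH:
                self.readthrough_reads += 1
            amp_id = panel.primers[result.match.primer_index].amplicon_id
            self.per_amplicon[amp_id] = self.per_amplicon.get(amp_id, 0) + 1

    def check(self) -> None:
        if self.trimmed_reads + self.untrimmed_reads + self.dropped_quality != self.total_reads:
            raise AmplitrimError("run summary categories do not partition the total")
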