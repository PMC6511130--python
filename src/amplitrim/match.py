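"""Locate the best-matching primer at a read's 5' end.

Two search strategies, tried in order:

* k-mers model — exact hash lookups of the read's k-mers at shifted
  offsets (0..buffer_len); every seed hit implies a primer placement,
  which is verified by whole-primer Hamming distance.  O(1)-ish and
  handles substitutions, but an indel between seed and primer start
  breaks the placement arithmetic.
* dynamic model — fallback: tally k-mer hits per candidate primer over
  the whole search prefix, take the top candidate, and align it with a
  semi-global Needleman-Wunsch (match 0, mismatch -1, gap -1), accepting
  when the edit distance stays within the mismatch allowance.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .kmer_index import (
    DEFAULT_K,
    FIVE_PRIME_ROLES,
    KmerIndex,
    SeedRole,
    _ROLE_ORDER,
    role_sequence,
)
from .panel import AmpliconPanel, bases_match

DEFAULT_BUFFER_LEN = 12
DEFAULT_MAX_MISMATCH = 3


@dataclass
class MatchParams:
    """Knobs of the primer search.

    ``buffer_len`` is the number of extra read offsets tried when seeding
    (the read prefix searched is max primer length + buffer); ``max_mismatch``
    is the mismatch/edit-distance allowance shared by both models and the
    3' read-through check.
    """

    k: int = DEFAULT_K
    max_mismatch: int = DEFAULT_MAX_MISMATCH
    buffer_len: int = DEFAULT_BUFFER_LEN
    nw_match: int = 0
    nw_mismatch: int = -1
    nw_gap: int = -1

    def __post_init__(self) -> None:
        if self.max_mismatch < 0 or self.buffer_len < 0:
            raise ValueError("max_mismatch and buffer_len must be >= 0")


class MatchModel(enum.Enum):
    KMERS = "kmers"
    DYNAMIC = "dynamic"


@dataclass(frozen=True)
class PrimerMatch:
    primer_index: int
    role: SeedRole
    read_start: int  # inclusive
    read_end: int  # exclusive; the trim boundary
    cost: int
    model: MatchModel


def hamming_distance(primer_seg: str, read_seg: str) -> int:
    """Mismatch count under the N-wildcard policy (primer side first)."""
    if len(primer_seg) != len(read_seg):
        raise ValueError(
            f"unequal lengths: {len(primer_seg)} vs {len(read_seg)}"
        )
    return sum(not bases_match(p, r) for p, r in zip(primer_seg, read_seg))


def kmer_model_match(
    sequence: str,
    index: KmerIndex,
    panel: AmpliconPanel,
    params: MatchParams,
    roles: frozenset[SeedRole] = FIVE_PRIME_ROLES,
) -> PrimerMatch | None:
    """Seed-and-verify search over read offsets 0..buffer_len.

    Each seed hit implies ``read_start = offset_in_read - offset_in_primer``;
    negative placements and placements running past the read end are
    discarded; survivors are verified by whole-primer Hamming distance.
    Returns the minimum-cost placement when it is within the allowance,
    breaking ties toward the lower primer index.
    """
    k = index.k
    best: tuple[int, int, int, int] | None = None  # cost, primer_index, role order, start
    best_match: PrimerMatch | None = None
    seen: set[tuple[int, SeedRole, int]] = set()
    last_seed = min(params.buffer_len, len(sequence) - k)
    for s in range(last_seed + 1):
        for hit in index.query(sequence[s : s + k], roles):
            read_start = s - hit.offset
            if read_start < 0:
                continue
            placement = (hit.primer_index, hit.role, read_start)
            if placement in seen:
                continue
            seen.add(placement)
            primer_seq = role_sequence(panel.primers[hit.primer_index], hit.role)
            read_end = read_start + len(primer_seq)
            if read_end > len(sequence):
                continue  # primer would be truncated; not verifiable here
            cost = hamming_distance(primer_seq, sequence[read_start:read_end])
            key = (cost, hit.primer_index, _ROLE_ORDER[hit.role], read_start)
            if best is None or key < best:
                best = key
                best_match = PrimerMatch(
                    hit.primer_index, hit.role, read_start, read_end, cost, MatchModel.KMERS
                )
                if cost == 0:
                    return best_match  # globally minimal; stop early
    if best_match is not None and best_match.cost <= params.max_mismatch:
        return best_match
    return None


def nw_align(primer: str, text: str, params: MatchParams | None = None) -> tuple[int, int]:
    """Semi-global Needleman-Wunsch: primer end-to-end, anchored at text[0].

    The alignment must consume the whole primer and start at the first
    text position, but may end anywhere in the text (no penalty for the
    unaligned text suffix).  Scores: match 0, mismatch -1, gap -1, so the
    score equals minus the edit distance to the best-matching text prefix.

    Returns ``(score, text_end)`` with ties in score resolved toward the
    smallest ``text_end``.
    """
    if params is None:
        params = MatchParams()
    m, n = len(primer), len(text)
    if m == 0 or n == 0:
        raise ValueError("nw_align requires non-empty primer and text")
    gap, mis, mat = params.nw_gap, params.nw_mismatch, params.nw_match
    prev = list(range(0, -(n + 1), -1)) if gap == -1 else [j * gap for j in range(n + 1)]
    for i in range(1, m + 1):
        cur = [i * gap] + [0] * n
        p_base = primer[i - 1]
        for j in range(1, n + 1):
            sub = mat if bases_match(p_base, text[j - 1]) else mis
            cur[j] = max(prev[j - 1] + sub, prev[j] + gap, cur[j - 1] + gap)
        prev = cur
    best_j = 0
    for j in range(1, n + 1):
        if prev[j] > prev[best_j]:
            best_j = j
    return prev[best_j], best_j


def dynamic_model_match(
    sequence: str,
    index: KmerIndex,
    panel: AmpliconPanel,
    params: MatchParams,
    roles: frozenset[SeedRole] = FIVE_PRIME_ROLES,
) -> PrimerMatch | None:
    """Hit-count candidate selection followed by semi-global alignment.

    All k-mers of the search prefix (max primer length + buffer) vote for
    (primer, role) candidates; the top-voted candidate (ties to the lower
    primer index) is aligned end-to-end against the prefix and accepted
    when its edit distance is within the allowance.
    """
    k = index.k
    prefix = sequence[: panel.max_primer_len + params.buffer_len]
    counts: dict[tuple[int, SeedRole], int] = {}
    for s in range(len(prefix) - k + 1):
        for hit in index.query(prefix[s : s + k], roles):
            key = (hit.primer_index, hit.role)
            counts[key] = counts.get(key, 0) + 1
    if not counts:
        return None
    (primer_index, role), _ = min(
        counts.items(), key=lambda kv: (-kv[1], kv[0][0], _ROLE_ORDER[kv[0][1]])
    )
    primer_seq = role_sequence(panel.primers[primer_index], role)
    score, text_end = nw_align(primer_seq, prefix, params)
    cost = -score
    if cost > params.max_mismatch or text_end == 0:
        return None
    return PrimerMatch(primer_index, role, 0, text_end, cost, MatchModel.DYNAMIC)


def locate_primer(
    sequence: str,
    index: KmerIndex,
    panel: AmpliconPanel,
    params: MatchParams,
    roles: frozenset[SeedRole] = FIVE_PRIME_ROLES,
) -> PrimerMatch | None:
    """k-mers model first; on failure, the dynamic model; else ``None``."""
    match = kmer_model_match(sequence, index, panel, params, roles)
    if match is not None:
        return match
    return dynamic_model_match(sequence, index, panel, params, roles)
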