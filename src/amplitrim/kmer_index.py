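"""Hash index of all 1-base-shift k-mers of every primer in a panel.

Each primer contributes k-mers under four roles: the forward and reverse
primers as they appear at read 5' ends, and the reverse complements of
both, which appear at read 3' ends when a short insert lets the read run
through into the partner primer.  A query returns every (primer, role,
offset) whose indexed window equals the k-mer, so a seed hit immediately
implies a primer placement on the read.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

from .errors import IndexConfigError
from .panel import AmpliconPanel, AmpliconPrimer, reverse_complement

DEFAULT_K = 8


class SeedRole(enum.Enum):
    """Which primer sequence (or reverse complement) an indexed window belongs to."""

    FORWARD_5P = "forward_5p"
    REVERSE_5P = "reverse_5p"
    FORWARD_3P_RC = "forward_3p_rc"
    REVERSE_3P_RC = "reverse_3p_rc"


FIVE_PRIME_ROLES = frozenset({SeedRole.FORWARD_5P, SeedRole.REVERSE_5P})

_ROLE_ORDER = {role: i for i, role in enumerate(SeedRole)}


class SeedHit(NamedTuple):
    primer_index: int
    role: SeedRole
    offset: int  # 0-based start of the k-mer within the role's sequence


def role_sequence(primer: AmpliconPrimer, role: SeedRole) -> str:
    """The concrete sequence a role refers to for one panel entry."""
    if role is SeedRole.FORWARD_5P:
        return primer.forward_seq
    if role is SeedRole.REVERSE_5P:
        return primer.reverse_seq
    if role is SeedRole.FORWARD_3P_RC:
        return reverse_complement(primer.forward_seq)
    return reverse_complement(primer.reverse_seq)


@dataclass
class KmerIndex:
    k: int
    entries: dict[str, list[SeedHit]] = field(default_factory=dict)

    def query(self, kmer: str, roles: Iterable[SeedRole] | None = None) -> list[SeedHit]:
        """All seed hits for ``kmer``, optionally restricted to ``roles``.

        Results are ordered by (primer_index, role, offset) so downstream
        tie-breaking is deterministic.
        """
        if len(kmer) != self.k:
            raise ValueError(f"query k-mer has length {len(kmer)}, index k={self.k}")
        hits = self.entries.get(kmer, [])
        if roles is None:
            return list(hits)
        wanted = set(roles)
        return [h for h in hits if h.role in wanted]

    @property
    def n_entries(self) -> int:
        return sum(len(v) for v in self.entries.values())


def build_index(panel: AmpliconPanel, k: int = DEFAULT_K) -> KmerIndex:
    """Index every N-free k-mer window of every primer under all four roles."""
    if k < 4:
        raise IndexConfigError(f"k={k} is too small (minimum 4)")
    for p in panel:
        if min(len(p.forward_seq), len(p.reverse_seq)) < k:
            raise IndexConfigError(
                f"k={k} exceeds a primer length of amplicon {p.amplicon_id!r}"
            )
    entries: dict[str, list[SeedHit]] = {}
    for primer_index, primer in enumerate(panel):
        for role in SeedRole:
            seq = role_sequence(primer, role)
            for offset in range(len(seq) - k + 1):
                window = seq[offset : offset + k]
                if "N" in window:
                    continue
                entries.setdefault(window, []).append(SeedHit(primer_index, role, offset))
    for hits in entries.values():
        hits.sort(key=lambda h: (h.primer_index, _ROLE_ORDER[h.role], h.offset))
    return KmerIndex(k=k, entries=entries)
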