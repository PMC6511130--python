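"""Amplicon primer panel: parsing, validation and small sequence utilities.

A panel row describes one amplicon: the forward primer, the reverse primer
and the insert length (number of biological bases between the two primer
3' ends, primers excluded).  The on-disk dialect is tab-separated text with
an optional fourth identifier column and ``#`` comment lines.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import PanelFormatError, PanelValidationError

_VALID_SEQ = re.compile(r"^[ACGTN]+$")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}; N maps to N."""
    if not _VALID_SEQ.match(seq):
        raise ValueError(f"illegal characters in sequence {seq!r}")
    return seq.translate(_COMPLEMENT)[::-1]


def bases_match(primer_base: str, read_base: str) -> bool:
    """Single-base comparison with the N-wildcard policy.

    N in the primer matches any read base (panels legitimately carry N at
    degenerate positions); N in the read matches only an N in the primer,
    because an uncalled read base carries no evidence for the primer.
    """
    return primer_base == read_base or primer_base == "N"


@dataclass(frozen=True)
class AmpliconPrimer:
    """One amplicon panel entry."""

    amplicon_id: str
    forward_seq: str
    reverse_seq: str
    insert_len: int

    def __post_init__(self) -> None:
        for name, seq in (("forward", self.forward_seq), ("reverse", self.reverse_seq)):
            if not seq or not _VALID_SEQ.match(seq):
                raise PanelValidationError(
                    f"{self.amplicon_id}: {name} primer {seq!r} is empty or has "
                    "characters outside A/C/G/T/N"
                )
        if self.insert_len < 0:
            raise PanelValidationError(f"{self.amplicon_id}: negative insert length")


@dataclass
class AmpliconPanel:
    """Ordered collection of amplicon primers.

    Input order is preserved: the matcher breaks cost ties toward the
    lowest primer index, so order is part of reproducible behaviour.
    """

    primers: list[AmpliconPrimer] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for p in self.primers:
            if p.amplicon_id in seen:
                raise PanelValidationError(f"duplicate amplicon id {p.amplicon_id!r}")
            seen.add(p.amplicon_id)

    @property
    def max_primer_len(self) -> int:
        return max(
            (max(len(p.forward_seq), len(p.reverse_seq)) for p in self.primers),
            default=0,
        )

    @property
    def min_primer_len(self) -> int:
        return min(
            (min(len(p.forward_seq), len(p.reverse_seq)) for p in self.primers),
            default=0,
        )

    def __len__(self) -> int:
        return len(self.primers)

    def __iter__(self):
        return iter(self.primers)


def parse_primer_table(path) -> AmpliconPanel:
    """Parse a tab-separated primer table into an :class:`AmpliconPanel`.

    Columns: forward primer, reverse primer, insert length, optional
    amplicon id (default ``AMP{line_number}``).  Lines starting with ``#``
    and blank lines are skipped.  Sequences are uppercased.
    """
    primers: list[AmpliconPrimer] = []
    with open(path, "rt", encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) < 3:
                raise PanelFormatError(
                    f"line {lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            fwd, rev, ins_text = fields[0].upper(), fields[1].upper(), fields[2]
            try:
                insert_len = int(ins_text)
            except ValueError:
                raise PanelFormatError(
                    f"line {lineno}: insert length {ins_text!r} is not an integer"
                ) from None
            amp_id = fields[3] if len(fields) >= 4 and fields[3] else f"AMP{lineno}"
            try:
                primers.append(AmpliconPrimer(amp_id, fwd, rev, insert_len))
            except PanelValidationError as exc:
                raise PanelFormatError(f"line {lineno}: {exc}") from None
    return AmpliconPanel(primers)


def write_primer_table(panel: AmpliconPanel, path) -> None:
    """Write a panel in the same dialect :func:`parse_primer_table` reads."""
    with open(path, "wt", encoding="utf-8") as handle:
        handle.write("#forward\treverse\tinsert_len\tamplicon_id\n")
        for p in panel:
            handle.write(f"{p.forward_seq}\t{p.reverse_seq}\t{p.insert_len}\t{p.amplicon_id}\n")
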