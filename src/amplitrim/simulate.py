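"""Synthetic amplicon panels and reads with ground truth.

The generator emulates a multiplex amplicon sequencing run: every read
pair starts with its gene-specific primer, short inserts make reads run
through into the reverse complement of the partner primer, and a
configurable number of substitutions (optionally one 1-bp indel) is
planted in every primer copy, mimicking primer synthesis errors.  Insert
bases are left error-free so the benchmark isolates primer matching.
A fraction of primer-free uniform-random read pairs provides the
negative class for specificity.

Panels are rejection-sampled so that any two primers (either strand)
differ by more than twice the largest tested mismatch allowance at
offset 0, which makes the ground-truth assignment unambiguous.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .errors import SimulationError
from .fastq import SeqRecord, write_fastq
from .kmer_index import DEFAULT_K
from .panel import AmpliconPanel, AmpliconPrimer, reverse_complement, write_primer_table

_BASES = "ACGT"
_Q30 = "?"  # chr(30 + 33)
MAX_TESTED_MISMATCH = 5


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset.

    ``depth`` is read pairs per amplicon; ``errors_in_primer``
    substitutions are planted in every primer copy (with probability
    ``indel_prob`` one of them becomes a 1-bp indel instead);
    ``negative_fraction`` is the fraction of the TOTAL dataset made of
    primer-free pairs (1.0 emits only negatives).
    """

    n_amplicons: int = 50
    primer_len_range: tuple[int, int] = (18, 25)
    insert_len_range: tuple[int, int] = (90, 180)
    read_len: int = 150
    depth: int = 100
    errors_in_primer: int = 0
    indel_prob: float = 0.0
    negative_fraction: float = 0.10
    seed: int = 0
    k: int = DEFAULT_K  # used only to keep 3' overlaps verifiable

    def __post_init__(self) -> None:
        if not (0 <= self.negative_fraction <= 1):
            raise SimulationError("negative_fraction must be in [0, 1]")
        if not (0 <= self.errors_in_primer <= MAX_TESTED_MISMATCH):
            raise SimulationError(f"errors_in_primer must be in 0..{MAX_TESTED_MISMATCH}")
        if self.primer_len_range[0] <= self.k:
            raise SimulationError("minimum primer length must exceed k")


@dataclass(frozen=True)
class TruthRecord:
    read_id: str
    has_primer: bool
    amplicon_id: str | None = None
    primer_interval_5p: tuple[int, int] | None = None
    primer_interval_3p: tuple[int, int] | None = None
    true_insert_seq: str | None = None
    read_len: int = 0


def _random_seq(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(_BASES) for _ in range(length))


def _offset0_distance(a: str, b: str) -> int:
    n = min(len(a), len(b))
    return sum(a[i] != b[i] for i in range(n))


def _too_close(candidate: str, accepted: list[str]) -> bool:
    # offset-0 prefix distance is not symmetric for unequal lengths, so
    # both orientations of the reverse-complement comparison are checked
    limit = 2 * MAX_TESTED_MISMATCH
    rc_cand = reverse_complement(candidate)
    for other in accepted:
        if _offset0_distance(candidate, other) <= limit:
            return True
        if _offset0_distance(candidate, reverse_complement(other)) <= limit:
            return True
        if _offset0_distance(other, rc_cand) <= limit:
            return True
    return False


def _ambiguous_insert(insert_len: int, primer_lens: tuple[int, int], cfg: SimConfig) -> bool:
    # A 3' partner overlap of 1..k-1 bases is too short to verify, so
    # exact trimming would be impossible by construction; redraw those.
    for plen in primer_lens:
        overlap = cfg.read_len - plen - insert_len
        if 0 < overlap < cfg.k:
            return True
    return False


def simulate_panel(config: SimConfig) -> tuple[AmpliconPanel, dict[str, str]]:
    """Draw a well-separated panel and its insert sequences.

    Deterministic under ``config.seed``.  Raises
    :class:`SimulationError` if separation cannot be met in 1000 redraws
    (longer primers fix that).
    """
    rng = random.Random(config.seed)
    accepted: list[str] = []
    primers: list[AmpliconPrimer] = []
    inserts: dict[str, str] = {}
    lo, hi = config.primer_len_range
    for i in range(config.n_amplicons):
        pair: list[str] = []
        for _ in range(2):
            for attempt in range(1000):
                cand = _random_seq(rng, rng.randint(lo, hi))
                if not _too_close(cand, accepted + pair):
                    pair.append(cand)
                    break
            else:
                raise SimulationError(
                    "could not draw a sufficiently separated primer after 1000 "
                    "attempts; use longer primers or a smaller panel"
                )
        fwd, rev = pair
        accepted.extend(pair)
        ins_lo, ins_hi = config.insert_len_range
        for attempt in range(1000):
            insert_len = rng.randint(ins_lo, ins_hi)
            if not _ambiguous_insert(insert_len, (len(fwd), len(rev)), config):
                break
        else:
            raise SimulationError("could not draw an unambiguous insert length")
        amp_id = f"SIM{i + 1:03d}"
        primers.append(AmpliconPrimer(amp_id, fwd, rev, insert_len))
        inserts[amp_id] = _random_seq(rng, insert_len)
    return AmpliconPanel(primers), inserts


def _mutate_copy(seq: str, rng: random.Random, n_errors: int, indel_prob: float) -> str:
    """Plant exactly ``n_errors`` substitutions in ``seq``; with probability
    ``indel_prob`` one of them becomes a 1-bp indel instead."""
    if n_errors == 0 or not seq:
        return seq
    n = min(n_errors, len(seq))
    positions = rng.sample(range(len(seq)), n)
    indel_at = None
    if indel_prob > 0 and rng.random() < indel_prob:
        indel_at = positions[0]
    out = list(seq)
    for pos in positions:
        if pos == indel_at:
            continue
        out[pos] = rng.choice([b for b in _BASES if b != seq[pos]])
    if indel_at is not None:
        if rng.random() < 0.5:
            out[indel_at] = ""  # deletion
        else:
            out[indel_at] = rng.choice(_BASES) + out[indel_at]  # insertion
    return "".join(out)


def simulate_read_pairs(
    panel: AmpliconPanel, inserts: dict[str, str], config: SimConfig
) -> tuple[list[tuple[SeqRecord, SeqRecord]], list[TruthRecord]]:
    """Emit ``depth`` read pairs per amplicon plus negative pairs.

    read1 = forward primer + insert (+ revcomp(reverse primer) + random
    fill when the insert is short), truncated to ``read_len``; read2
    mirrors it from the other end.  All qualities are Q30.
    """
    rng = random.Random(config.seed + 1)
    pairs: list[tuple[SeqRecord, SeqRecord]] = []
    truth: list[TruthRecord] = []

    def build_read(p5: str, insert: str, partner: str) -> tuple[str, dict]:
        p5c = _mutate_copy(p5, rng, config.errors_in_primer, config.indel_prob)
        segments = [p5c, insert]
        pos3 = len(p5c) + len(insert)
        interval_3p = None
        if pos3 < config.read_len:
            avail = config.read_len - pos3
            present = reverse_complement(partner)[:avail]
            p3c = _mutate_copy(present, rng, config.errors_in_primer, config.indel_prob)
            segments.append(p3c)
            interval_3p = (pos3, min(config.read_len, pos3 + len(p3c)))
        read = "".join(segments)
        if len(read) < config.read_len:
            read += _random_seq(rng, config.read_len - len(read))
        read = read[: config.read_len]
        insert_present = insert[: max(0, config.read_len - len(p5c))]
        info = {
            "p5": (0, min(config.read_len, len(p5c))),
            "p3": interval_3p,
            "insert": insert_present,
        }
        return read, info

    only_negatives = config.negative_fraction >= 1.0
    for amp_index, primer in enumerate(panel):
        if only_negatives:
            break
        insert = inserts[primer.amplicon_id]
        for j in range(config.depth):
            base_id = f"sim{amp_index:03d}_{j:05d}"
            r1_seq, i1 = build_read(primer.forward_seq, insert, primer.reverse_seq)
            r2_seq, i2 = build_read(
                primer.reverse_seq, reverse_complement(insert), primer.forward_seq
            )
            r1 = SeqRecord(f"{base_id}/1", r1_seq, _Q30 * len(r1_seq))
            r2 = SeqRecord(f"{base_id}/2", r2_seq, _Q30 * len(r2_seq))
            pairs.append((r1, r2))
            for rec, info in ((r1, i1), (r2, i2)):
                truth.append(
                    TruthRecord(
                        rec.read_id,
                        True,
                        primer.amplicon_id,
                        info["p5"],
                        info["p3"],
                        info["insert"],
                        len(rec.sequence),
                    )
                )

    # negative_fraction is a fraction of the total dataset
    n_pos_pairs = len(pairs)
    if only_negatives:
        n_neg = config.n_amplicons * config.depth
    else:
        f = config.negative_fraction
        n_neg = round(f * n_pos_pairs / (1.0 - f))
    for j in range(n_neg):
        base_id = f"simneg_{j:05d}"
        recs = []
        for mate in (1, 2):
            seq = _random_seq(rng, config.read_len)
            rec = SeqRecord(f"{base_id}/{mate}", seq, _Q30 * len(seq))
            recs.append(rec)
            truth.append(TruthRecord(rec.read_id, False, read_len=len(seq)))
        pairs.append((recs[0], recs[1]))
    return pairs, truth


TRUTH_COLUMNS = [
    "read_id",
    "has_primer",
    "amplicon_id",
    "p5_start",
    "p5_end",
    "p3_start",
    "p3_end",
    "read_len",
    "true_insert",
]


def write_truth_table(truth: list[TruthRecord], path) -> None:
    with open(path, "wt", encoding="utf-8") as handle:
        handle.write("#" + "\t".join(TRUTH_COLUMNS) + "\n")
        for t in truth:
            p5 = t.primer_interval_5p or (".", ".")
            p3 = t.primer_interval_3p or (".", ".")
            handle.write(
                "\t".join(
                    str(x)
                    for x in (
                        t.read_id,
                        int(t.has_primer),
                        t.amplicon_id or ".",
                        p5[0],
                        p5[1],
                        p3[0],
                        p3[1],
                        t.read_len,
                        t.true_insert_seq if t.true_insert_seq is not None else ".",
                    )
                )
                + "\n"
            )


@dataclass(frozen=True)
class SimOutput:
    panel_path: Path
    read1_path: Path
    read2_path: Path
    truth_path: Path


def simulate_to_files(config: SimConfig, outdir, gzip_output: bool = False) -> SimOutput:
    """Run the full simulation and write panel, paired FASTQ and truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel, inserts = simulate_panel(config)
    pairs, truth = simulate_read_pairs(panel, inserts, config)
    suffix = ".fastq.gz" if gzip_output else ".fastq"
    out = SimOutput(
        outdir / "panel.tsv",
        outdir / f"reads_1{suffix}",
        outdir / f"reads_2{suffix}",
        outdir / "truth.tsv",
    )
    write_primer_table(panel, out.panel_path)
    write_fastq((p[0] for p in pairs), out.read1_path)
    write_fastq((p[1] for p in pairs), out.read2_path)
    write_truth_table(truth, out.truth_path)
    return out
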