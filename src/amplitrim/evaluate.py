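"""Score trimmed reads against simulator ground truth.

Metric definitions (per-read, joined on read id):

* TPR — fraction of primer-bearing reads with at least one base removed
  (partial credit: any trimming counts).
* TNR — fraction of primer-free reads left completely untouched.
* ACC — fraction of primer-bearing reads whose output sequence equals
  the true insert byte-for-byte (the truth insert is already truncated
  at the read end for normal-condition reads).

A class with no members yields NaN for its metric, never 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .errors import EvaluationError
from .fastq import read_fastq
from .simulate import TRUTH_COLUMNS, TruthRecord


@dataclass(frozen=True)
class Metrics:
    tpr: float
    tnr: float
    acc: float
    n_pos: int
    n_neg: int

    def as_row(self) -> dict:
        return {
            "tpr": self.tpr,
            "tnr": self.tnr,
            "acc": self.acc,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
        }


def evaluate(trimmed: Mapping[str, str], truth: Iterable[TruthRecord]) -> Metrics:
    """Compute TPR/TNR/ACC from output sequences keyed by read id.

    ``trimmed`` maps read id to the output sequence (reads written
    unchanged included); every truth record must be present.
    """
    n_pos = n_neg = 0
    tp = tn = exact = 0
    for t in truth:
        try:
            out_seq = trimmed[t.read_id]
        except KeyError:
            raise EvaluationError(f"read {t.read_id!r} missing from trimmed output") from None
        removed = t.read_len - len(out_seq)
        if removed < 0:
            raise EvaluationError(f"read {t.read_id!r} grew during trimming")
        if t.has_primer:
            n_pos += 1
            if removed >= 1:
                tp += 1
            if out_seq == (t.true_insert_seq or ""):
                exact += 1
        else:
            n_neg += 1
            if removed == 0:
                tn += 1
    tpr = tp / n_pos if n_pos else math.nan
    acc = exact / n_pos if n_pos else math.nan
    tnr = tn / n_neg if n_neg else math.nan
    return Metrics(tpr, tnr, acc, n_pos, n_neg)


def load_truth_table(path) -> list[TruthRecord]:
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        names=TRUTH_COLUMNS,
        dtype=str,
        keep_default_na=False,
    )
    records = []
    for row in df.itertuples(index=False):
        has_primer = row.has_primer == "1"
        records.append(
            TruthRecord(
                read_id=row.read_id,
                has_primer=has_primer,
                amplicon_id=None if row.amplicon_id == "." else row.amplicon_id,
                primer_interval_5p=None
                if row.p5_start == "."
                else (int(row.p5_start), int(row.p5_end)),
                primer_interval_3p=None
                if row.p3_start == "."
                else (int(row.p3_start), int(row.p3_end)),
                true_insert_seq=None if row.true_insert == "." else row.true_insert,
                read_len=int(row.read_len),
            )
        )
    return records


def evaluate_files(truth_path, *fastq_paths) -> Metrics:
    """Evaluate trimmed FASTQ file(s) against a truth table on disk."""
    trimmed: dict[str, str] = {}
    for path in fastq_paths:
        for rec in read_fastq(path):
            trimmed[rec.read_id] = rec.sequence
    return evaluate(trimmed, load_truth_table(truth_path))


def write_metrics(metrics: Metrics, path) -> None:
    pd.DataFrame([metrics.as_row()]).to_csv(path, sep="\t", index=False)
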