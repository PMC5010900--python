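"""Chimeric-scaffold quality control for candidate EBRs.

A candidate EBR inside a scaffold may be a genuine evolutionary junction or
an assembly artifact joining unrelated sequence.  Physical support is
summarised as the *minimum paired-read spanning coverage*: the minimum,
over bases of the EBR interval, of the number of read-pair inserts covering
that base.  Integer thresholds per sequencing-coverage class are calibrated
from examples labelled by independent verification (e.g. PCR across the
junction), minimising false positives + false negatives.

The direction of the criterion is configurable:

* ``reject_low_span``  (default) — a real junction in a correctly assembled
  scaffold is spanned by read pairs, so LOW support flags an artifact
  (EBR passes iff min_span >= t);
* ``reject_high_span`` — the opposite convention (EBR passes iff
  min_span <= t), for datasets where spanning support instead marks a
  suspect join.

Spanning input is a precomputed per-interval TSV
(species, scaffold, ebr_start, ebr_end, min_span, coverage_class), not a
BAM: computing it from mapped read pairs is an upstream step.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .formats import GenomicInterval, _data_lines

REJECT_LOW = "reject_low_span"
REJECT_HIGH = "reject_high_span"


@dataclass(frozen=True)
class SpanningRecord:
    species: str
    ebr: GenomicInterval
    min_span: int
    coverage_class: str

    def __post_init__(self) -> None:
        if self.min_span < 0:
            raise ValueError("min_span must be >= 0")


@dataclass(frozen=True)
class QCThreshold:
    coverage_class: str
    t: int
    est_fp: float
    est_fn: float
    direction: str = REJECT_LOW

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError("threshold must be >= 0")
        if self.direction not in (REJECT_LOW, REJECT_HIGH):
            raise ValueError(f"unknown direction {self.direction!r}")

    def passes(self, min_span: int) -> bool:
        if self.direction == REJECT_LOW:
            return min_span >= self.t
        return min_span <= self.t


def min_spanning_coverage(
    pair_intervals: Sequence[GenomicInterval],
    ebr: GenomicInterval,
    scaffold_length: int | None = None,
) -> int:
    """Minimum over EBR bases of the number of pair inserts containing the base."""
    if scaffold_length is not None and ebr.end > scaffold_length:
        raise ValueError(
            f"EBR {ebr} extends past scaffold end ({scaffold_length})"
        )
    n = ebr.length
    depth = np.zeros(n + 1, dtype=np.int64)
    for iv in pair_intervals:
        if iv.seq_id != ebr.seq_id:
            continue
        lo = max(iv.start, ebr.start) - ebr.start
        hi = min(iv.end, ebr.end) - ebr.start
        if hi > lo:
            depth[lo] += 1
            depth[hi] -= 1
    per_base = np.cumsum(depth[:-1])
    return int(per_base.min()) if n else 0


def calibrate_threshold(
    labelled: Sequence[tuple[int, bool]],
    coverage_class: str,
    direction: str = REJECT_LOW,
) -> QCThreshold:
    """Integer threshold minimising FP + FN on verification-labelled EBRs.

    ``labelled`` holds (min_span, verified_real) pairs.  Ties in the error
    count resolve to the smallest threshold.  est_fp is the fraction of
    artifacts accepted; est_fn the fraction of real EBRs rejected.
    """
    if direction not in (REJECT_LOW, REJECT_HIGH):
        raise ValueError(f"unknown direction {direction!r}")
    spans_real = [s for s, v in labelled if v]
    spans_fake = [s for s, v in labelled if not v]
    if not spans_real or not spans_fake:
        raise ValueError("cannot calibrate: need both verified and artifact examples")

    best_t, best_err, best_fp, best_fn = None, None, 0, 0
    for t in range(0, max(s for s, _ in labelled) + 2):
        probe = QCThreshold(coverage_class, t, 0.0, 0.0, direction)
        fp = sum(probe.passes(s) for s in spans_fake)
        fn = sum(not probe.passes(s) for s in spans_real)
        if best_err is None or fp + fn < best_err:
            best_t, best_err, best_fp, best_fn = t, fp + fn, fp, fn
    return QCThreshold(
        coverage_class=coverage_class,
        t=best_t,
        est_fp=best_fp / len(spans_fake),
        est_fn=best_fn / len(spans_real),
        direction=direction,
    )


def apply_qc(
    records: Iterable[SpanningRecord],
    thresholds: Mapping[str, QCThreshold],
) -> tuple[list[tuple[SpanningRecord, str]], list[tuple[SpanningRecord, str]]]:
    """Partition candidate EBRs into (pass, fail) with reasons."""
    passed: list[tuple[SpanningRecord, str]] = []
    failed: list[tuple[SpanningRecord, str]] = []
    for rec in records:
        thr = thresholds.get(rec.coverage_class)
        if thr is None:
            raise KeyError(f"no threshold for coverage class {rec.coverage_class!r}")
        reason = (
            f"min_span={rec.min_span} vs t={thr.t} ({thr.direction})"
        )
        if thr.passes(rec.min_span):
            passed.append((rec, reason))
        else:
            failed.append((rec, reason))
    return passed, failed


def read_spanning_tsv(path: str | Path) -> list[SpanningRecord]:
    records: list[SpanningRecord] = []
    with open(path) as handle:
        for lineno, fields in _data_lines(handle):
            if len(fields) < 6:
                raise ValueError(f"line {lineno}: expected 6 columns")
            try:
                start, end, span = int(fields[2]), int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-integer field") from exc
            records.append(
                SpanningRecord(
                    species=fields[0],
                    ebr=GenomicInterval(fields[1], start, end),
                    min_span=span,
                    coverage_class=fields[5],
                )
            )
    return records
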