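"""Accuracy scoring of alignments against simulation truth.

A read is counted correct when it is mapped to its origin sequence no more
than 30 bp from the true leftmost coordinate.  For each mapping-quality
threshold 1..60 the evaluator reports the confident fraction (mapped with
mapq at or above the threshold), the error fraction among confident reads,
and the unmapped fraction — the standard threshold-sweep view of aligner
accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pysam

from .simulate import TruthRecord

POSITION_TOLERANCE = 30
DEFAULT_THRESHOLDS = tuple(range(1, 61))


@dataclass(frozen=True)
class EvalSummary:
    """Accuracy summary at one mapping-quality threshold."""

    threshold: int
    n_reads: int
    confident: int
    errors: int
    unmapped: int

    @property
    def confident_fraction(self) -> float:
        return self.confident / self.n_reads if self.n_reads else 0.0

    @property
    def error_fraction(self) -> float:
        return self.errors / self.confident if self.confident else 0.0

    @property
    def unmapped_fraction(self) -> float:
        return self.unmapped / self.n_reads if self.n_reads else 0.0


class TruthMismatchError(KeyError):
    """SAM read names without truth records."""

    def __init__(self, offenders: Sequence[Tuple[str, int]]):
        self.offenders = list(offenders)
        shown = ", ".join(f"{n}/{m}" for n, m in self.offenders[:10])
        more = "" if len(self.offenders) <= 10 else f" (+{len(self.offenders) - 10} more)"
        super().__init__(f"reads without truth records: {shown}{more}")


def _mate_of(rec: "pysam.AlignedSegment") -> int:
    if not rec.is_paired:
        return 0
    return 1 if rec.is_read1 else 2


def alignment_correct(
    ref_name: Optional[str],
    position0: Optional[int],
    truth: TruthRecord,
    tolerance: int = POSITION_TOLERANCE,
) -> bool:
    """Correct iff on the origin sequence within ``tolerance`` bp of the truth."""
    if ref_name is None or position0 is None:
        return False
    return ref_name == truth.sequence and abs(position0 - truth.start) <= tolerance


def evaluate(
    sam_path: str,
    truth: Dict[Tuple[str, int], TruthRecord],
    thresholds: Sequence[int] = DEFAULT_THRESHOLDS,
    tolerance: int = POSITION_TOLERANCE,
    strict: bool = False,
) -> List[EvalSummary]:
    """Score a SAM file against truth records at each mapq threshold.

    ``strict`` demands mapq strictly above the threshold instead of at-or-above.
    Raises :class:`TruthMismatchError` listing any read name absent from the
    truth table.
    """
    per_read: List[Tuple[int, bool, bool]] = []  # (mapq, mapped, correct)
    offenders: List[Tuple[str, int]] = []
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_secondary or rec.is_supplementary:
                continue
            key = (rec.query_name, _mate_of(rec))
            t = truth.get(key)
            if t is None:
                offenders.append(key)
                continue
            if rec.is_unmapped:
                per_read.append((0, False, False))
            else:
                ok = alignment_correct(rec.reference_name, rec.reference_start, t, tolerance)
                per_read.append((rec.mapping_quality, True, ok))
    if offenders:
        raise TruthMismatchError(offenders)
    n = len(per_read)
    unmapped = sum(1 for _, mapped, _ in per_read if not mapped)
    out = []
    for thr in thresholds:
        if strict:
            conf = [(q, ok) for q, mapped, ok in per_read if mapped and q > thr]
        else:
            conf = [(q, ok) for q, mapped, ok in per_read if mapped and q >= thr]
        errors = sum(1 for _, ok in conf if not ok)
        out.append(EvalSummary(thr, n, len(conf), errors, unmapped))
    return out


def check_threshold_trend(summaries: Sequence[EvalSummary]) -> bool:
    """True when the sweep shows the expected trade-off.

    The error fraction among confident reads must be non-increasing and the
    not-confident fraction (below threshold or unmapped) non-decreasing as the
    threshold rises.
    """
    ordered = sorted(summaries, key=lambda s: s.threshold)
    for a, b in zip(ordered, ordered[1:]):
        if b.error_fraction > a.error_fraction + 1e-12:
            return False
        if b.confident_fraction > a.confident_fraction + 1e-12:
            return False
    return True


def write_summaries(summaries: Iterable[EvalSummary], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("threshold\tconfident_pct\terror_pct\tunmapped_pct\n")
        for s in summaries:
            fh.write(
                f"{s.threshold}\t{100 * s.confident_fraction:.4f}"
                f"\t{100 * s.error_fraction:.4f}\t{100 * s.unmapped_fraction:.4f}\n"
            )
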