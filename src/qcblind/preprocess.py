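"""Quality trimming and length filtering of raw reads.

Trimming follows leading/trailing semantics: bases are removed one at a time
from each end while the terminal base's quality is below the threshold, and
reads shorter than ``min_length`` after trimming are discarded.  An optional
fixed-cut mode removes a constant number of bases from each end instead.
When either mate of a pair is discarded the whole pair is dropped, because
the downstream assembler and mapper assume intact pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io_formats import ReadRecord, ReadSet, TruthTable


@dataclass
class TrimParams:
    quality_threshold: int = 3
    min_length: int = 50
    fixed_cut: int | None = None  # cut exactly this many bases from each end

    def __post_init__(self):
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.quality_threshold < 0:
            raise ValueError("quality_threshold must be >= 0")


DISCARD = None


def trim_read(read: ReadRecord, params: TrimParams) -> ReadRecord | None:
    """Trim one read; returns the trimmed record or ``None`` (discard)."""
    q = read.qualities
    n = len(q)
    if params.fixed_cut is not None:
        lo, hi = params.fixed_cut, n - params.fixed_cut
    else:
        t = params.quality_threshold
        lo = 0
        while lo < n and q[lo] < t:
            lo += 1
        hi = n
        while hi > lo and q[hi - 1] < t:
            hi -= 1
    if hi - lo < params.min_length:
        return DISCARD
    if lo == 0 and hi == n:
        return read
    return ReadRecord(read.read_id, read.sequence[lo:hi], q[lo:hi],
                      read.mate, read.pair_id)


@dataclass
class StageLedger:
    """Per-stage read accounting: reads (and truth-target reads) surviving.

    The first entry is the raw input; each later entry records the reads
    still represented after a named stage, so marginal and cumulative losses
    can both be derived.
    """

    stages: list[str] = field(default_factory=list)
    total: list[int] = field(default_factory=list)
    target: list[int | None] = field(default_factory=list)

    def record(self, stage: str, total: int, target: int | None = None) -> None:
        if self.total and total > self.total[-1]:
            raise ValueError(
                f"stage {stage}: surviving ({total}) exceeds entering ({self.total[-1]})"
            )
        self.stages.append(stage)
        self.total.append(int(total))
        self.target.append(None if target is None else int(target))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"stage": self.stages, "reads_total": self.total, "reads_target": self.target}
        )


def count_target(reads: ReadSet, truth: TruthTable | None) -> int | None:
    if truth is None:
        return None
    return sum(1 for r in reads if truth.is_target_read(r.read_id))


def trim_set(reads: ReadSet, params: TrimParams,
             truth: TruthTable | None = None,
             ledger: StageLedger | None = None) -> tuple[ReadSet, StageLedger]:
    """Trim a read set, dropping whole pairs when either mate is discarded."""
    if ledger is None:
        ledger = StageLedger()
    if not ledger.stages:
        ledger.record("raw", len(reads), count_target(reads, truth))

    out: list[ReadRecord] = []
    it = iter(reads)
    for r in it:
        if r.mate == "mate1":
            m2 = next(it)
            t1, t2 = trim_read(r, params), trim_read(m2, params)
            if t1 is not None and t2 is not None:
                out.extend((t1, t2))
        elif r.mate == "single":
            t = trim_read(r, params)
            if t is not None:
                out.append(t)
        else:  # stray mate2: treated as an orphan, dropped with its pair
            continue
    result = ReadSet(out)
    ledger.record("trim", len(result), count_target(result, truth))
    return result, ledger
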