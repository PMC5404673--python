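"""Run, sample and amplicon quality control.

Run yield is compared against control bounds of mean ± 2 standard deviations
over the previous ten runs of the same assay (a Westgard-style clinical QC
rule).  All checks are advisory: the software never passes or fails a run —
a laboratory user must sign the verdict off explicitly, and that sign-off is
audited.
"""

from __future__ import annotations

import csv
import math
import statistics
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

#: how many recent same-assay runs feed the control bounds
WESTGARD_WINDOW = 10

#: amplicon cells below this read count are reported
LOW_AMPLICON_READS = 100


class QCError(ValueError):
    pass


class PermissionError_(QCError):
    pass


@dataclass(frozen=True)
class YieldBounds:
    """Control limits for run read yield: mean ± 2 sample standard deviations."""

    mean: float
    sd: float
    n_history: int

    @property
    def lower(self) -> float:
        return self.mean - 2.0 * self.sd

    @property
    def upper(self) -> float:
        return self.mean + 2.0 * self.sd


def yield_bounds(history: Sequence[float]) -> YieldBounds:
    """Bounds from the most recent (≤10) same-assay run yields.

    ``history`` is ordered oldest→newest; only the last ten entries count.
    Requires at least two runs — with fewer, the sample standard deviation is
    undefined and the verdict can only be advisory.
    """
    window = list(history)[-WESTGARD_WINDOW:]
    if len(window) < 2:
        raise QCError(
            f"insufficient history ({len(window)} runs): need >=2 for bounds"
        )
    mean = statistics.fmean(window)
    sd = statistics.stdev(window)  # n-1 denominator
    return YieldBounds(mean=mean, sd=sd, n_history=len(window))


def check_run_yield(current: float, bounds: YieldBounds) -> str:
    """'within' | 'below' | 'above' — boundary values count as within."""
    if current < bounds.lower:
        return "below"
    if current > bounds.upper:
        return "above"
    return "within"


@dataclass
class AmpliconCounts:
    """Read-count matrix: rows are amplicons, columns samples.

    Non-template control columns are named in ``ntc_samples`` (by convention
    prefixed ``NTC_`` in the TSV interchange format).
    """

    amplicons: list[str]
    samples: list[str]
    counts: list[list[int]]  # amplicon-major
    ntc_samples: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for row in self.counts:
            if len(row) != len(self.samples):
                raise QCError("count row width != number of samples")
            if any(c < 0 for c in row):
                raise QCError("negative read count")

    @classmethod
    def from_tsv(cls, path: str) -> "AmpliconCounts":
        with open(path) as fh:
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader)
            samples = header[1:]
            amplicons, counts = [], []
            for row in reader:
                amplicons.append(row[0])
                counts.append([int(x) for x in row[1:]])
        ntc = {s for s in samples if s.startswith("NTC_")}
        return cls(amplicons, samples, counts, ntc)

    def to_tsv(self, path: str) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["amplicon"] + self.samples)
            for amp, row in zip(self.amplicons, self.counts):
                w.writerow([amp] + row)

    def cell(self, amplicon: str, sample: str) -> int:
        return self.counts[self.amplicons.index(amplicon)][self.samples.index(sample)]


@dataclass(frozen=True)
class LowAmpliconReport:
    low_cells: tuple[tuple[str, str, int], ...]  # (amplicon, sample, count)
    amplicon_means: dict[str, float]  # per-amplicon mean across non-NTC samples
    poor_amplicons: tuple[str, ...]  # lighter heatmap bands


def low_amplicons(counts: AmpliconCounts,
                  threshold: int = LOW_AMPLICON_READS) -> LowAmpliconReport:
    """Cells under the read threshold plus per-amplicon means for banding.

    NTC columns are excluded (they are expected to be empty).  An amplicon
    whose mean falls below half the median amplicon mean is reported as a
    poorly performing band.
    """
    if not counts.amplicons:
        raise QCError("empty count matrix")
    idx = [i for i, s in enumerate(counts.samples) if s not in counts.ntc_samples]
    low = []
    means: dict[str, float] = {}
    for amp, row in zip(counts.amplicons, counts.counts):
        vals = [row[i] for i in idx]
        means[amp] = statistics.fmean(vals) if vals else math.nan
        for i in idx:
            if row[i] < threshold:
                low.append((amp, counts.samples[i], row[i]))
    med = statistics.median(means.values())
    poor = tuple(a for a, m in means.items() if m < 0.5 * med)
    return LowAmpliconReport(tuple(low), means, poor)


def ntc_check(counts: AmpliconCounts) -> dict[str, bool]:
    """Per-NTC verdict: flagged (True) iff it contains any reads at all."""
    if not counts.ntc_samples:
        raise QCError("no non-template control designated in this run")
    out = {}
    for s in counts.ntc_samples:
        j = counts.samples.index(s)
        out[s] = any(row[j] > 0 for row in counts.counts)
    return out


@dataclass(frozen=True)
class SampleReadSummary:
    totals: dict[str, int]
    run_mean: float
    below_mean: tuple[str, ...]


def sample_read_report(counts: AmpliconCounts) -> SampleReadSummary:
    """Per-sample totals with below-run-mean highlights (NTCs excluded)."""
    idx = [(i, s) for i, s in enumerate(counts.samples) if s not in counts.ntc_samples]
    if not idx:
        raise QCError("no non-NTC samples in run")
    totals = {s: sum(row[i] for row in counts.counts) for i, s in idx}
    mean = statistics.fmean(totals.values())
    below = tuple(s for s, t in totals.items() if t < mean)
    return SampleReadSummary(totals, mean, below)


# ---------------------------------------------------------------------------
# sign-off

QC_SIGNOFF_ROLES = frozenset({"ROLE_LAB", "ROLE_ADMIN", "ROLE_DEV"})


@dataclass
class RunQCRecord:
    """QC state for one run (or, with sample_id set, one sample)."""

    run_id: str
    assay_id: str
    total_reads: int
    timestamp: float = field(default_factory=time.time)
    sample_id: str | None = None
    verdict: str = "pending"
    signed_by: str | None = None
    audit: list[dict] = field(default_factory=list)


def sign_off(record: RunQCRecord, verdict: str, user: str, role: str) -> RunQCRecord:
    """Record a user's pass/fail determination.

    Only laboratory (or admin) roles may sign; a record can be signed once.
    """
    if verdict not in ("passed", "failed"):
        raise QCError(f"verdict must be passed|failed, got {verdict!r}")
    if role not in QC_SIGNOFF_ROLES:
        raise PermissionError_(f"role {role} may not sign off QC")
    if record.verdict != "pending":
        raise QCError(f"record already signed ({record.verdict} by {record.signed_by})")
    record.verdict = verdict
    record.signed_by = user
    record.audit.append({
        "action": f"qc_{verdict}", "user": user, "role": role, "at": time.time(),
    })
    return record


# ---------------------------------------------------------------------------
# run-history store

def read_run_history(path: str, assay_id: str | None = None) -> list[dict]:
    """Append-only run-history TSV: run_id, assay_id, total_reads, date, verdict."""
    out = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            if assay_id is not None and row["assay_id"] != assay_id:
                continue
            row["total_reads"] = int(float(row["total_reads"]))
            out.append(row)
    return out


def append_run_history(path: str, run_id: str, assay_id: str,
                       total_reads: int, date: str, verdict: str = "pending") -> None:
    p = Path(path)
    new = not p.exists()
    with open(p, "a", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        if new:
            w.writerow(["run_id", "assay_id", "total_reads", "date", "verdict"])
        w.writerow([run_id, assay_id, total_reads, date, verdict])
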