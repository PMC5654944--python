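"""Copy-number segment and clinical-table I/O.

Two input dialects are supported, both tab-separated with a header and
1-based inclusive coordinates (converted to the package's internal 0-based
half-open convention on read):

* ``ACGH`` — aCGH-export style: ``patient_id, chrom, start, end, call``
  with optional ``log2_ratio`` and ``n_probes`` columns; ``call`` is
  ``GAIN`` or ``LOSS``.
* ``SEG`` — standard segmented copy-number format:
  ``Sample, Chromosome, Start, End, Num_Probes, Segment_Mean``. SEG rows
  carry no gain/loss call until thresholded with
  :func:`call_from_segment_mean`.

Clinical tables are tab-separated ``patient_id, outcome, follow_up_months,
cohort`` with outcome in {REC, NOREC}.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .genome import GenomeBuild, GenomicInterval, normalize_chrom

logger = logging.getLogger(__name__)

__all__ = [
    "GAIN",
    "LOSS",
    "REC",
    "NOREC",
    "UNID",
    "CNASegment",
    "PatientRecord",
    "Cohort",
    "read_segment_table",
    "write_segment_table",
    "call_from_segment_mean",
    "filter_min_probes",
    "read_clinical_table",
    "write_clinical_table",
]

GAIN = "GAIN"
LOSS = "LOSS"

# Outcome / class labels used throughout the package.
REC = "REC"      # recurrence/metastasis during follow-up
NOREC = "NOREC"  # no recurrence/metastasis during follow-up
UNID = "UNID"    # derived "unidentifiable" class (training-time construct)


@dataclass(frozen=True)
class CNASegment:
    """One called copy-number gain/loss interval for one patient."""

    patient_id: str
    interval: GenomicInterval
    call: str | None = None
    log2_ratio: float | None = None
    n_probes: int | None = None

    def __post_init__(self) -> None:
        if self.call is not None and self.call not in (GAIN, LOSS):
            raise ValueError(f"call must be GAIN or LOSS, got {self.call!r}")
        if self.n_probes is not None and self.n_probes < 1:
            raise ValueError(f"n_probes must be >= 1, got {self.n_probes}")


@dataclass(frozen=True)
class PatientRecord:
    """Clinical record: outcome label and follow-up for one patient."""

    patient_id: str
    outcome: str | None = None
    follow_up_months: float | None = None
    cohort: str = ""

    def __post_init__(self) -> None:
        if self.outcome is not None and self.outcome not in (REC, NOREC):
            raise ValueError(f"outcome must be REC or NOREC, got {self.outcome!r}")
        if self.follow_up_months is not None and self.follow_up_months < 0:
            raise ValueError("follow_up_months must be nonnegative")


def _merge_same_call(segments: Sequence[CNASegment]) -> list[CNASegment]:
    """Merge overlapping same-patient, same-call segments (reader losslessness:
    opposite-call overlaps are kept and resolved later at binning)."""
    groups: dict[tuple[str, str, str | None], list[CNASegment]] = {}
    for seg in segments:
        groups.setdefault((seg.patient_id, seg.interval.chrom, seg.call), []).append(seg)
    merged: list[CNASegment] = []
    for group in groups.values():
        group.sort(key=lambda s: (s.interval.start, s.interval.end))
        current = group[0]
        for nxt in group[1:]:
            if nxt.interval.start < current.interval.end:  # strict overlap
                new_iv = GenomicInterval(
                    current.interval.chrom,
                    current.interval.start,
                    max(current.interval.end, nxt.interval.end),
                )
                n_probes = (
                    None
                    if current.n_probes is None or nxt.n_probes is None
                    else current.n_probes + nxt.n_probes
                )
                current = replace(current, interval=new_iv, n_probes=n_probes)
            else:
                merged.append(current)
                current = nxt
        merged.append(current)
    return merged


@dataclass
class Cohort:
    """A set of patients with their called copy-number segments.

    Overlapping identical-call segments of one patient are merged at
    construction; GAIN/LOSS overlaps survive and are resolved by dominant
    overlap at binning time.
    """

    build: GenomeBuild
    patients: list[PatientRecord] = field(default_factory=list)
    segments: list[CNASegment] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate patient_id in cohort")
        known = set(ids)
        for seg in self.segments:
            if seg.patient_id not in known:
                raise ValueError(f"segment patient {seg.patient_id!r} not in clinical records")
            seg.interval.validate_against(self.build)
        self.segments = sorted(
            _merge_same_call(self.segments),
            key=lambda s: (
                s.patient_id,
                self.build.chrom_order(s.interval.chrom),
                s.interval.start,
                s.interval.end,
                s.call or "",
            ),
        )

    @property
    def patient_ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def outcomes(self) -> dict[str, str | None]:
        return {p.patient_id: p.outcome for p in self.patients}

    def segments_of(self, patient_id: str) -> list[CNASegment]:
        return [s for s in self.segments if s.patient_id == patient_id]


_ACGH_COLUMNS = ("patient_id", "chrom", "start", "end", "call")
_SEG_COLUMNS = ("Sample", "Chromosome", "Start", "End", "Num_Probes", "Segment_Mean")


def read_segment_table(
    path: str | Path,
    build: GenomeBuild,
    dialect: Literal["ACGH", "SEG"] = "ACGH",
) -> list[CNASegment]:
    """Read a tab-separated segment table in ACGH or SEG dialect.

    Input coordinates are 1-based inclusive; returned segments are 0-based
    half-open. ``chr`` prefixes are stripped. Rows on chromosomes absent from
    *build* are dropped (logged count), as are rows whose interval is empty
    after conversion (logged individually).

    Raises
    ------
    ValueError
        On a malformed row, naming the 1-based line number.
    """
    dialect = dialect.upper()
    if dialect not in ("ACGH", "SEG"):
        raise ValueError(f"unknown dialect {dialect!r}")
    segments: list[CNASegment] = []
    dropped_chrom = 0
    with open(path) as fh:
        header_line = fh.readline().rstrip("\n")
        header = header_line.split("\t")
        if dialect == "SEG":
            required = _SEG_COLUMNS
        else:
            required = _ACGH_COLUMNS
        missing = [c for c in required if c not in header]
        if missing:
            raise ValueError(f"{path}: line 1: missing column(s) {missing} for dialect {dialect}")
        idx = {c: header.index(c) for c in header}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < len(required):
                raise ValueError(f"{path}: line {lineno}: expected >= {len(required)} columns")
            try:
                if dialect == "SEG":
                    patient = fields[idx["Sample"]]
                    chrom = normalize_chrom(fields[idx["Chromosome"]])
                    start1, end1 = int(fields[idx["Start"]]), int(fields[idx["End"]])
                    n_probes = int(fields[idx["Num_Probes"]])
                    log2 = float(fields[idx["Segment_Mean"]])
                    call = None
                else:
                    patient = fields[idx["patient_id"]]
                    chrom = normalize_chrom(fields[idx["chrom"]])
                    start1, end1 = int(fields[idx["start"]]), int(fields[idx["end"]])
                    call = fields[idx["call"]].strip().upper()
                    if call not in (GAIN, LOSS):
                        raise ValueError(f"bad call {call!r}")
                    log2 = None
                    n_probes = None
                    if "log2_ratio" in idx and fields[idx["log2_ratio"]] not in ("", "NA"):
                        log2 = float(fields[idx["log2_ratio"]])
                    if "n_probes" in idx and fields[idx["n_probes"]] not in ("", "NA"):
                        n_probes = int(fields[idx["n_probes"]])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: malformed row ({exc})") from exc
            if chrom not in build:
                dropped_chrom += 1
                continue
            start, end = start1 - 1, end1  # 1-based inclusive -> 0-based half-open
            if start < 0 or start >= end:
                logger.warning("%s: line %d: empty/negative interval after conversion; row rejected",
                               path, lineno)
                continue
            segments.append(CNASegment(patient, GenomicInterval(chrom, start, end),
                                       call=call, log2_ratio=log2, n_probes=n_probes))
    if dropped_chrom:
        logger.info("%s: dropped %d row(s) on chromosomes absent from build %s",
                    path, dropped_chrom, build.name)
    return segments


def write_segment_table(
    segments: Iterable[CNASegment],
    path: str | Path,
    dialect: Literal["ACGH", "SEG"] = "ACGH",
) -> None:
    """Write segments in a dialect, converting back to 1-based inclusive
    coordinates so that a read/write round trip is lossless."""
    dialect = dialect.upper()
    with open(path, "w") as fh:
        if dialect == "SEG":
            fh.write("\t".join(_SEG_COLUMNS) + "\n")
            for s in segments:
                if s.log2_ratio is None:
                    raise ValueError(f"segment {s.patient_id} lacks log2_ratio; cannot write SEG")
                fh.write(
                    f"{s.patient_id}\t{s.interval.chrom}\t{s.interval.start + 1}\t"
                    f"{s.interval.end}\t{s.n_probes if s.n_probes is not None else ''}\t"
                    f"{s.log2_ratio!r}\n"
                )
        elif dialect == "ACGH":
            fh.write("\t".join(_ACGH_COLUMNS + ("log2_ratio", "n_probes")) + "\n")
            for s in segments:
                if s.call is None:
                    raise ValueError(f"segment {s.patient_id} lacks a call; cannot write ACGH")
                log2 = "" if s.log2_ratio is None else repr(s.log2_ratio)
                probes = "" if s.n_probes is None else str(s.n_probes)
                fh.write(
                    f"{s.patient_id}\t{s.interval.chrom}\t{s.interval.start + 1}\t"
                    f"{s.interval.end}\t{s.call}\t{log2}\t{probes}\n"
                )
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


def call_from_segment_mean(
    segments: Iterable[CNASegment],
    tau_gain: float = 0.2,
    tau_loss: float = -0.2,
) -> list[CNASegment]:
    """Threshold SEG ``Segment_Mean`` log2 ratios into GAIN/LOSS calls.

    ``log2 >= tau_gain`` is a GAIN, ``log2 <= tau_loss`` a LOSS (boundaries
    inclusive); segments strictly inside the neutral band are removed.
    """
    if not tau_loss < 0 < tau_gain:
        raise ValueError("need tau_loss < 0 < tau_gain")
    out: list[CNASegment] = []
    for seg in segments:
        if seg.log2_ratio is None:
            raise ValueError(f"segment for {seg.patient_id} lacks log2_ratio; cannot call")
        if seg.log2_ratio >= tau_gain:
            out.append(replace(seg, call=GAIN))
        elif seg.log2_ratio <= tau_loss:
            out.append(replace(seg, call=LOSS))
    return out


def filter_min_probes(segments: Iterable[CNASegment], min_probes: int = 3) -> list[CNASegment]:
    """Drop segments supported by fewer than *min_probes* consecutive probes.

    Segments without probe counts are retained — they are assumed to come
    from already-filtered upstream calls.
    """
    if min_probes < 1:
        raise ValueError("min_probes must be >= 1")
    return [s for s in segments if s.n_probes is None or s.n_probes >= min_probes]


def read_clinical_table(path: str | Path) -> list[PatientRecord]:
    """Read a tab-separated clinical table (patient_id, outcome,
    follow_up_months, cohort)."""
    records: list[PatientRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if "patient_id" not in header or "outcome" not in header:
            raise ValueError(f"{path}: line 1: need 'patient_id' and 'outcome' columns")
        idx = {c: header.index(c) for c in header}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            try:
                outcome = fields[idx["outcome"]].strip().upper() or None
                follow_up = None
                if "follow_up_months" in idx and fields[idx["follow_up_months"]] not in ("", "NA"):
                    follow_up = float(fields[idx["follow_up_months"]])
                cohort = fields[idx["cohort"]] if "cohort" in idx and len(fields) > idx["cohort"] else ""
                records.append(PatientRecord(fields[idx["patient_id"]], outcome, follow_up, cohort))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: line {lineno}: malformed row ({exc})") from exc
    return records


def write_clinical_table(patients: Iterable[PatientRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("patient_id\toutcome\tfollow_up_months\tcohort\n")
        for p in patients:
            fu = "" if p.follow_up_months is None else repr(p.follow_up_months)
            fh.write(f"{p.patient_id}\t{p.outcome or ''}\t{fu}\t{p.cohort}\n")
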