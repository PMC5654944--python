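import numpy as np
import pandas as pd
import pytest

from cnarec.genome import CytobandMap, GenomeBuild, GenomicInterval
from cnarec.segments import (
    GAIN, LOSS, NOREC, REC, CNASegment, Cohort, PatientRecord,
)


@pytest.fixture
def tiny_build():
    """Two short chromosomes for hand-checkable binning arithmetic."""
    return GenomeBuild(name="tiny", chromosomes=(("1", 200), ("2", 100)))


@pytest.fixture
def toy_map():
    """Two contiguous bands per chromosome of the tiny build."""
    return CytobandMap([
        (GenomicInterval("1", 0, 100), "p11"),
        (GenomicInterval("1", 100, 200), "q11"),
        (GenomicInterval("2", 0, 50), "p11"),
        (GenomicInterval("2", 50, 100), "q11"),
    ])


@pytest.fixture
def tiny_cohort(tiny_build):
    patients = [
        PatientRecord("A", REC, 24.0, "test"),
        PatientRecord("B", NOREC, 36.0, "test"),
        PatientRecord("C", NOREC, 12.0, "test"),
    ]
    segments = [
        CNASegment("A", GenomicInterval("1", 0, 50), GAIN),
        CNASegment("A", GenomicInterval("1", 120, 180), LOSS),
        CNASegment("B", GenomicInterval("2", 10, 90), LOSS),
    ]
    return Cohort(build=tiny_build, patients=patients, segments=segments)


def random_cohort(rng, n_patients=10, max_segments=5):
    """A random small cohort on the tiny build, for oracle comparisons."""
    build = GenomeBuild(name="tiny", chromosomes=(("1", 200), ("2", 100)))
    patients = [
        PatientRecord(f"P{i}", REC if rng.random() < 0.4 else NOREC)
        for i in range(n_patients)
    ]
    segments = []
    for p in patients:
        for _ in range(rng.integers(0, max_segments + 1)):
            chrom, length = build.chromosomes[rng.integers(len(build.chromosomes))]
            start = int(rng.integers(0, length - 1))
            end = int(rng.integers(start + 1, length + 1))
            call = GAIN if rng.random() < 0.5 else LOSS
            segments.append(CNASegment(p.patient_id, GenomicInterval(chrom, start, end), call))
    return Cohort(build=build, patients=patients, segments=segments)
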