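"""Synthetic cohort generator.

Emulates the statistical structure the pipeline assumes in a head-and-neck
cancer cohort, with no real data required:

* a cohort of ``n_patients`` (default 104) with recurrence prevalence
  ``rec_prevalence`` (default 0.385, i.e. 40/104);
* a small set of *informative regions* where the probability of carrying an
  alteration depends on class. Two kinds are planted by default: six
  "primary" regions enriched in recurrence (REC) patients, and five
  "resolving" regions altered at equal rates in both outcome groups but
  rarely in the ambiguous subpopulation (see below);
* genome-wide background alterations at ``background_rate`` per
  bin-equivalent window in every patient;
* an *ambiguous subpopulation* (default 10% of the non-recurrence class):
  patients labelled NOREC whose profile on the primary regions follows the
  REC distribution — emulating patients whose follow-up was too short for a
  recurrence to be recorded. On the resolving regions they are distinct,
  which is what ultimately lets the third classification phase separate them
  from true REC patients.

Alteration lengths are log-normal; informative segments are centred in their
region. Default regions are positioned at the centres of the bins the
pipeline is expected to derive (the expected per-chromosome mean alteration
size is computed in closed form from the configuration), so each planted
region maps essentially to one feature bin.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeBuild, GenomicInterval, toy_build
from .segments import (
    GAIN, LOSS, NOREC, REC,
    CNASegment, Cohort, PatientRecord,
    write_clinical_table, write_segment_table,
)

__all__ = [
    "InformativeRegion",
    "SimulationConfig",
    "SyntheticTruth",
    "default_informative_regions",
    "simulate_cohort",
    "write_fixtures",
]


@dataclass(frozen=True)
class InformativeRegion:
    """A planted class-informative region.

    ``p_alt_rec`` / ``p_alt_norec`` are the per-patient probabilities of an
    alteration for REC and (non-ambiguous) NOREC patients; ambiguous patients
    use ``p_alt_amb`` when given, otherwise the REC probability (the
    short-follow-up reading: their genome looks like the recurrence class).
    """

    interval: GenomicInterval
    call: str
    p_alt_rec: float
    p_alt_norec: float
    p_alt_amb: float | None = None

    def __post_init__(self) -> None:
        if self.call not in (GAIN, LOSS):
            raise ValueError(f"call must be GAIN or LOSS, got {self.call!r}")
        for p in (self.p_alt_rec, self.p_alt_norec,
                  self.p_alt_rec if self.p_alt_amb is None else self.p_alt_amb):
            if not 0 <= p <= 1:
                raise ValueError("alteration probabilities must be in [0, 1]")

    def p_for(self, is_rec: bool, is_ambiguous: bool) -> float:
        if is_ambiguous:
            return self.p_alt_rec if self.p_alt_amb is None else self.p_alt_amb
        return self.p_alt_rec if is_rec else self.p_alt_norec


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of a synthetic cohort.

    Log-normal length parameters are (log-scale mean, log-scale sd) in bp.
    ``background_rate`` is the per-patient alteration probability per
    ``background_window_bp`` window — the bin-equivalent granularity of
    background noise.
    """

    n_patients: int = 104
    rec_prevalence: float = 0.385
    informative_regions: tuple[InformativeRegion, ...] | None = None  # None -> defaults
    background_rate: float = 0.10
    background_window_bp: int = 2_000_000
    bg_length_log_mean: float = math.log(2_000_000)
    bg_length_log_sd: float = 0.05
    inf_length_log_mean: float = math.log(1_000_000)
    inf_length_log_sd: float = 0.05
    ambiguous_fraction: float = 0.10
    build: GenomeBuild = field(default_factory=toy_build)
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.rec_prevalence, self.background_rate, self.ambiguous_fraction):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")

    def regions(self) -> tuple[InformativeRegion, ...]:
        regs = (default_informative_regions(self)
                if self.informative_regions is None else self.informative_regions)
        by_chrom: dict[str, list[InformativeRegion]] = {}
        for r in regs:
            r.interval.validate_against(self.build)
            by_chrom.setdefault(r.interval.chrom, []).append(r)
        for items in by_chrom.values():
            items.sort(key=lambda r: r.interval.start)
            for a, b in zip(items, items[1:]):
                if a.interval.end > b.interval.start:
                    raise ValueError(
                        f"informative regions overlap on {a.interval.chrom}: "
                        f"{a.interval} and {b.interval}"
                    )
        return tuple(regs)

    def primary_regions(self) -> tuple[InformativeRegion, ...]:
        """Regions whose REC and NOREC probabilities differ (class signal)."""
        return tuple(r for r in self.regions() if r.p_alt_rec != r.p_alt_norec)

    def to_jsonable(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in ("n_patients", "rec_prevalence", "background_rate",
                      "background_window_bp", "bg_length_log_mean", "bg_length_log_sd",
                      "inf_length_log_mean", "inf_length_log_sd",
                      "ambiguous_fraction", "seed")
        }
        d["build"] = {"name": self.build.name, "chromosomes": list(self.build.chromosomes)}
        d["informative_regions"] = [
            {
                "chrom": r.interval.chrom, "start": r.interval.start, "end": r.interval.end,
                "call": r.call, "p_alt_rec": r.p_alt_rec, "p_alt_norec": r.p_alt_norec,
                "p_alt_amb": r.p_alt_amb,
            }
            for r in self.regions()
        ]
        return d


# Default planted layout: (chromosome, bin slot, kind). Primary slots carry the
# REC-enriched signal; resolving slots separate ambiguous patients from REC.
_PRIMARY_SLOTS = (("1", 2), ("1", 6), ("2", 2), ("2", 6), ("3", 2), ("4", 2))
_RESOLVING_SLOTS = (("1", 10), ("2", 10), ("3", 6), ("3", 10), ("4", 6))
_PRIMARY_P = (0.75, 0.15)          # p_alt_rec, p_alt_norec; ambiguous follow REC
_RESOLVING_P = (0.65, 0.65, 0.10)  # p_alt_rec, p_alt_norec, p_alt_amb
# Region half-width exceeds the largest plausible informative segment
# half-length (~0.5 Mb x e^{3 sigma}), so every bin touched by a planted
# segment overlaps its region; segments stay well inside one ~1.8 Mb bin.
_REGION_HALF_BP = 700_000


def _expected_bin_width(config: SimulationConfig) -> dict[str, float]:
    """Closed-form expectation of the per-chromosome mean alteration size.

    The pipeline will bin each chromosome by the realised mean segment
    length; this predicts it from the background/informative mixture so that
    default regions can be centred in the expected bins.
    """
    mean_bg = math.exp(config.bg_length_log_mean + config.bg_length_log_sd**2 / 2)
    mean_inf = math.exp(config.inf_length_log_mean + config.inf_length_log_sd**2 / 2)
    prev, amb = config.rec_prevalence, config.ambiguous_fraction
    # expected informative alterations per patient per chromosome slot
    exp_p: dict[str, float] = {c: 0.0 for c, _ in config.build.chromosomes}
    slots = [(c, _PRIMARY_P[0], _PRIMARY_P[1], None) for c, _ in _PRIMARY_SLOTS]
    slots += [(c, _RESOLVING_P[0], _RESOLVING_P[1], _RESOLVING_P[2]) for c, _ in _RESOLVING_SLOTS]
    for chrom, p_rec, p_norec, p_amb in slots:
        if chrom not in exp_p:
            continue
        p_amb_eff = p_rec if p_amb is None else p_amb
        exp_p[chrom] += (prev * p_rec
                         + (1 - prev) * ((1 - amb) * p_norec + amb * p_amb_eff))
    widths: dict[str, float] = {}
    for chrom, length in config.build.chromosomes:
        n_bg = math.ceil(length / config.background_window_bp) * config.background_rate
        n_inf = exp_p[chrom]
        widths[chrom] = (n_bg * mean_bg + n_inf * mean_inf) / (n_bg + n_inf)
    return widths


def default_informative_regions(config: SimulationConfig) -> tuple[InformativeRegion, ...]:
    """Six primary + five resolving regions centred in expected feature bins."""
    w0 = _expected_bin_width(config)
    regions: list[InformativeRegion] = []
    calls = {"1": LOSS, "2": GAIN, "3": LOSS, "4": GAIN}
    for chrom, k in _PRIMARY_SLOTS:
        if chrom not in dict(config.build.chromosomes):
            continue
        center = (k + 0.5) * w0[chrom]
        iv = GenomicInterval(chrom, int(center - _REGION_HALF_BP), int(center + _REGION_HALF_BP))
        regions.append(InformativeRegion(iv, calls.get(chrom, GAIN), *_PRIMARY_P))
    for chrom, k in _RESOLVING_SLOTS:
        if chrom not in dict(config.build.chromosomes):
            continue
        center = (k + 0.5) * w0[chrom]
        iv = GenomicInterval(chrom, int(center - _REGION_HALF_BP), int(center + _REGION_HALF_BP))
        regions.append(InformativeRegion(iv, GAIN, *_RESOLVING_P))
    return tuple(regions)


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated cohort.

    ``table`` has one row per patient: ``true_class`` (the clinical label,
    REC/NOREC) and ``ambiguous`` (True for NOREC-labelled patients drawn from
    the REC distribution on the primary regions). ``regions`` is the planted
    region list.
    """

    table: pd.DataFrame
    regions: tuple[InformativeRegion, ...]
    config: SimulationConfig

    @property
    def ambiguous_patients(self) -> list[str]:
        return list(self.table.index[self.table["ambiguous"]])

    def primary_regions(self) -> tuple[InformativeRegion, ...]:
        return tuple(r for r in self.regions if r.p_alt_rec != r.p_alt_norec)

    def recovered_primary_regions(self, selected_bins, scheme) -> int:
        """How many distinct primary regions are hit by the selected bins
        (a bin counts for a region when their intervals overlap)."""
        hit = 0
        for region in self.primary_regions():
            for name in selected_bins:
                if scheme.by_name(name).interval.overlap_bp(region.interval) > 0:
                    hit += 1
                    break
        return hit

    def to_table(self) -> pd.DataFrame:
        return self.table.copy()


def simulate_cohort(config: SimulationConfig = SimulationConfig()) -> tuple[Cohort, SyntheticTruth]:
    """Generate a cohort and its ground truth. Deterministic given
    ``config.seed``.

    When no explicit region list is configured, default regions are placed in
    two passes: a pilot cohort is simulated with the closed-form region guess,
    its realised per-chromosome mean alteration sizes (the bin widths the
    pipeline will derive) are measured, and the final regions are re-centred
    in the realised bins before the reported cohort is simulated. This keeps
    each planted region inside a single feature bin without hand-tuned
    coordinates.
    """
    if config.informative_regions is None:
        from .binning import mean_alteration_size

        pilot = replace(config, informative_regions=default_informative_regions(config),
                        seed=(config.seed + 1_000_003) % (2**31))
        pilot_cohort, _ = simulate_cohort(pilot)
        widths = mean_alteration_size(pilot_cohort)
        regions: list[InformativeRegion] = []
        calls = {"1": LOSS, "2": GAIN, "3": LOSS, "4": GAIN}
        chrom_set = dict(config.build.chromosomes)
        for slots, params in ((_PRIMARY_SLOTS, _PRIMARY_P), (_RESOLVING_SLOTS, _RESOLVING_P)):
            for chrom, k in slots:
                if chrom not in chrom_set:
                    continue
                center = (k + 0.5) * widths[chrom]
                iv = GenomicInterval(chrom, int(center - _REGION_HALF_BP),
                                     int(center + _REGION_HALF_BP))
                call = calls.get(chrom, GAIN) if params is _PRIMARY_P else GAIN
                regions.append(InformativeRegion(iv, call, *params))
        config = replace(config, informative_regions=tuple(regions))
    rng = np.random.default_rng(config.seed)
    regions = config.regions()
    n = config.n_patients
    ids = [f"P{i + 1:03d}" for i in range(n)]
    n_rec = int(round(config.rec_prevalence * n))
    is_rec = np.zeros(n, dtype=bool)
    is_rec[rng.permutation(n)[:n_rec]] = True
    norec_idx = np.flatnonzero(~is_rec)
    n_amb = int(round(config.ambiguous_fraction * len(norec_idx)))
    is_amb = np.zeros(n, dtype=bool)
    is_amb[rng.choice(norec_idx, size=n_amb, replace=False)] = True

    lengths = dict(config.build.chromosomes)
    segments: list[CNASegment] = []
    for i, pid in enumerate(ids):
        # planted informative alterations, centred in their region
        for region in regions:
            if rng.random() >= region.p_for(is_rec[i], is_amb[i]):
                continue
            L = rng.lognormal(config.inf_length_log_mean, config.inf_length_log_sd)
            c = (region.interval.start + region.interval.end) / 2
            chrom_len = lengths[region.interval.chrom]
            start = max(0, int(round(c - L / 2)))
            end = min(chrom_len, int(round(c + L / 2)))
            if end > start:
                segments.append(CNASegment(pid, GenomicInterval(region.interval.chrom, start, end),
                                           call=region.call))
        # genome-wide background
        for chrom, chrom_len in config.build.chromosomes:
            n_windows = math.ceil(chrom_len / config.background_window_bp)
            for w in range(n_windows):
                if rng.random() >= config.background_rate:
                    continue
                L = rng.lognormal(config.bg_length_log_mean, config.bg_length_log_sd)
                w_lo = w * config.background_window_bp
                w_hi = min(w_lo + config.background_window_bp, chrom_len)
                c = rng.uniform(w_lo, w_hi)
                start = max(0, int(round(c - L / 2)))
                end = min(chrom_len, int(round(c + L / 2)))
                if end <= start:
                    continue
                # keep informative regions' class-conditional probabilities
                # exactly as configured: background avoids planted regions and
                # a one-bin-scale buffer around them, so the feature bins that
                # host planted regions carry no background hits
                span = GenomicInterval(chrom, start, end)
                if any(
                    r.interval.chrom == chrom
                    and span.start < r.interval.end + config.background_window_bp
                    and span.end > r.interval.start - config.background_window_bp
                    for r in regions
                ):
                    continue
                call = GAIN if rng.random() < 0.5 else LOSS
                segments.append(CNASegment(pid, span, call=call))

    follow_up = np.where(
        is_amb, rng.uniform(6, 18, size=n), rng.uniform(6, 64, size=n)
    )  # ambiguous patients emulate short follow-up
    patients = [
        PatientRecord(pid, REC if is_rec[i] else NOREC,
                      float(round(follow_up[i], 1)), cohort="synthetic")
        for i, pid in enumerate(ids)
    ]
    cohort = Cohort(build=config.build, patients=patients, segments=segments)
    truth = SyntheticTruth(
        table=pd.DataFrame(
            {"true_class": np.where(is_rec, REC, NOREC), "ambiguous": is_amb},
            index=pd.Index(ids, name="patient_id"),
        ),
        regions=regions,
        config=config,
    )
    return cohort, truth


def write_fixtures(
    cohort: Cohort,
    directory: str | Path,
    truth: SyntheticTruth | None = None,
    seed: int = 0,
) -> dict[str, Path]:
    """Write a cohort as file fixtures in both input dialects.

    Emits ``segments.acgh.tsv`` (lossless round trip), ``segments.seg``
    (log2 ratios sampled consistently with the calls: gains around +0.4,
    losses around -0.5, magnitudes kept beyond the +/-0.2 calling thresholds
    by construction), ``clinical.tsv``, optionally ``truth.tsv``, and a
    ``config.json`` echo.
    """
    if not cohort.patients:
        raise ValueError("cohort is empty; nothing to write")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    paths = {
        "acgh": directory / "segments.acgh.tsv",
        "seg": directory / "segments.seg",
        "clinical": directory / "clinical.tsv",
    }
    write_segment_table(cohort.segments, paths["acgh"], dialect="ACGH")
    seg_rows = []
    for s in cohort.segments:
        if s.call == GAIN:
            log2 = max(0.25, rng.normal(0.4, 0.1))
        else:
            log2 = min(-0.25, rng.normal(-0.5, 0.1))
        n_probes = s.n_probes if s.n_probes is not None else max(3, s.interval.length // 10_000)
        seg_rows.append(replace(s, log2_ratio=round(float(log2), 4), n_probes=int(n_probes)))
    write_segment_table(seg_rows, paths["seg"], dialect="SEG")
    write_clinical_table(cohort.patients, paths["clinical"])
    if truth is not None:
        paths["truth"] = directory / "truth.tsv"
        truth.to_table().to_csv(paths["truth"], sep="\t")
        paths["config"] = directory / "config.json"
        with open(paths["config"], "w") as fh:
            json.dump(truth.config.to_jsonable(), fh, indent=1, sort_keys=True)
    return paths
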