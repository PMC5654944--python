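"""Per-chromosome binning of copy-number segments into a ternary feature matrix.

Variable-size per-patient segments are projected onto fixed genome bins whose
width, per chromosome, equals the cohort's mean alteration size on that
chromosome. Each (patient, bin) cell is +1 (gain), -1 (loss) or 0 (neutral);
when a patient has both gain and loss overlap in one bin the dominant overlap
(more covered bp) wins, with an exact nonzero tie resolved to +1.

The resulting ``BinMatrix`` is a plain :class:`pandas.DataFrame` (rows =
patients, columns = unique bin names ``"<chrom>:<start>-<end>"``) so it can be
fed directly to scikit-learn; the :class:`BinScheme` keeps the interval and
cytoband-range label of every column.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .genome import CytobandMap, GenomeBuild, GenomicInterval, band_label
from .segments import Cohort, GAIN, LOSS

__all__ = [
    "Bin",
    "BinScheme",
    "mean_alteration_size",
    "build_bin_scheme",
    "bin_scheme_from_cohort",
    "assign_to_bins",
    "frequency_profile",
    "plot_frequency_profile",
    "harmonize",
    "write_bin_matrix",
    "read_bin_matrix",
]


@dataclass(frozen=True)
class Bin:
    """One genome bin: interval, display label and genome-order index."""

    interval: GenomicInterval
    label: str
    index: int

    @property
    def name(self) -> str:
        """Unique coordinate name used as the matrix column id."""
        iv = self.interval
        return f"{iv.chrom}:{iv.start}-{iv.end}"

    @property
    def width(self) -> int:
        return self.interval.length


class BinScheme:
    """Per-chromosome tiling of a genome into fixed-width bins.

    For a chromosome of length ``L`` and width ``w`` there are ``ceil(L/w)``
    bins ``[0,w), [w,2w), ...`` with the last truncated to ``L``; their union
    is exactly ``[0, L)``.
    """

    def __init__(self, build: GenomeBuild, mean_alt_size: dict[str, int], bins: list[Bin]):
        self.build = build
        self.mean_alt_size = dict(mean_alt_size)
        self.bins = list(bins)
        self._by_chrom: dict[str, list[Bin]] = {}
        for b in self.bins:
            self._by_chrom.setdefault(b.interval.chrom, []).append(b)
        for chrom, items in self._by_chrom.items():
            pos = 0
            for b in items:
                if b.interval.start != pos:
                    raise ValueError(f"bins on {chrom} are not contiguous at {pos}")
                pos = b.interval.end
            if pos != build.length(chrom):
                raise ValueError(f"bins on {chrom} do not cover [0, {build.length(chrom)})")

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def names(self) -> list[str]:
        return [b.name for b in self.bins]

    @property
    def labels(self) -> list[str]:
        return [b.label for b in self.bins]

    def chrom_bins(self, chrom: str) -> list[Bin]:
        return list(self._by_chrom.get(chrom, []))

    def width(self, chrom: str) -> int:
        return self._by_chrom[chrom][0].interval.length if chrom in self._by_chrom else 0

    def by_name(self, name: str) -> Bin:
        for b in self.bins:
            if b.name == name:
                return b
        raise KeyError(name)

    def resolve(self, key: str) -> Bin:
        """Resolve a bin by unique name or by (unambiguous) cytoband label."""
        for b in self.bins:
            if b.name == key:
                return b
        hits = [b for b in self.bins if b.label == key]
        if not hits:
            raise KeyError(f"no bin named or labelled {key!r}")
        if len(hits) > 1:
            raise KeyError(f"label {key!r} is ambiguous; use coordinate names")
        return hits[0]

    def to_bed(self, path: str | Path) -> None:
        """Export bins as BED (0-based half-open; label in column 4)."""
        with open(path, "w") as fh:
            for b in self.bins:
                iv = b.interval
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{b.label}\n")


def mean_alteration_size(
    cohort: Cohort,
    default_width: int | None = None,
) -> dict[str, int]:
    """Mean segment length per chromosome, rounded half-up to >= 1 bp.

    Chromosomes without any alteration fall back to *default_width* (whole
    chromosome when None).
    """
    if not cohort.segments:
        raise ValueError("cohort has no segments; cannot derive bin widths")
    lengths: dict[str, list[int]] = {}
    for seg in cohort.segments:
        lengths.setdefault(seg.interval.chrom, []).append(seg.interval.length)
    sizes: dict[str, int] = {}
    for chrom, chrom_len in cohort.build.chromosomes:
        if chrom in lengths:
            mean = sum(lengths[chrom]) / len(lengths[chrom])
            sizes[chrom] = max(1, math.floor(mean + 0.5))  # round half up
        else:
            sizes[chrom] = chrom_len if default_width is None else min(default_width, chrom_len)
    return sizes


def build_bin_scheme(
    build: GenomeBuild,
    mean_sizes: dict[str, int],
    cytobands: CytobandMap | None = None,
) -> BinScheme:
    """Tile every chromosome of *build* with bins of its mean alteration size.

    Bin labels are cytoband-range labels when *cytobands* is given, otherwise
    the coordinate names.
    """
    bins: list[Bin] = []
    index = 0
    for chrom, length in build.chromosomes:
        w = int(mean_sizes[chrom])
        if w <= 0:
            raise ValueError(f"mean size for chromosome {chrom} must be positive")
        for start in range(0, length, w):
            iv = GenomicInterval(chrom, start, min(start + w, length))
            if cytobands is not None and chrom in cytobands:
                label = band_label(iv, cytobands)
            else:
                label = f"{iv.chrom}:{iv.start}-{iv.end}"
            bins.append(Bin(iv, label, index))
            index += 1
    return BinScheme(build, mean_sizes, bins)


def bin_scheme_from_cohort(
    cohort: Cohort,
    cytobands: CytobandMap | None = None,
    default_width: int | None = None,
) -> BinScheme:
    """Convenience: derive mean sizes from the cohort and build its scheme."""
    return build_bin_scheme(cohort.build, mean_alteration_size(cohort, default_width), cytobands)


def assign_to_bins(
    cohort: Cohort,
    scheme: BinScheme,
    min_overlap_fraction: float = 0.0,
) -> pd.DataFrame:
    """Project a cohort's segments onto a bin scheme.

    For each patient and bin, gain- and loss-covered base pairs are
    accumulated over all that patient's segments; a channel qualifies when its
    covered bp exceed ``min_overlap_fraction x bin_width`` (fraction 0 means
    any overlap of >= 1 bp). The cell is +1 when qualifying gain bp exceed
    loss bp, -1 for the converse, +1 on an exact nonzero tie, else 0.

    Returns a patients x bins DataFrame with values in {-1, 0, +1}; patients
    without segments keep an all-zero row.
    """
    if not 0 <= min_overlap_fraction <= 1:
        raise ValueError("min_overlap_fraction must be in [0, 1]")
    if scheme.build.chromosomes != cohort.build.chromosomes:
        raise ValueError(
            f"scheme build {scheme.build.name!r} does not match cohort build {cohort.build.name!r}"
        )
    patient_ids = cohort.patient_ids
    row_of = {p: i for i, p in enumerate(patient_ids)}
    n, m = len(patient_ids), scheme.n_bins
    gain_bp = np.zeros((n, m), dtype=np.int64)
    loss_bp = np.zeros((n, m), dtype=np.int64)
    col0 = {}  # chromosome -> (first column index, width, n_bins)
    for chrom, _ in scheme.build.chromosomes:
        cb = scheme.chrom_bins(chrom)
        if cb:
            col0[chrom] = (cb[0].index, cb[0].interval.length, len(cb))
    for seg in cohort.segments:
        chrom = seg.interval.chrom
        if chrom not in col0:
            raise ValueError(f"segment chromosome {chrom!r} missing from bin scheme")
        first, w, k = col0[chrom]
        b_lo = seg.interval.start // w
        b_hi = min((seg.interval.end - 1) // w, k - 1)
        target = gain_bp if seg.call == GAIN else loss_bp
        r = row_of[seg.patient_id]
        for b in range(b_lo, b_hi + 1):
            bin_iv = scheme.bins[first + b].interval
            target[r, first + b] += seg.interval.overlap_bp(bin_iv)
    widths = np.array([b.width for b in scheme.bins], dtype=np.int64)
    thresh = min_overlap_fraction * widths  # qualify when covered bp strictly exceed this
    g = np.where(gain_bp > thresh, gain_bp, 0)
    l = np.where(loss_bp > thresh, loss_bp, 0)
    values = np.zeros((n, m), dtype=np.int8)
    values[g > l] = 1
    values[l > g] = -1
    values[(g == l) & (g > 0)] = 1  # exact nonzero tie -> gain
    return pd.DataFrame(values, index=pd.Index(patient_ids, name="patient_id"),
                        columns=scheme.names)


def frequency_profile(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-bin fraction of patients with a gain and with a loss.

    Returns a DataFrame indexed by bin name with columns ``gain_fraction``
    and ``loss_fraction`` (each in [0, 1]; their sum never exceeds 1).
    """
    if matrix.shape[0] == 0:
        raise ValueError("empty matrix")
    n = matrix.shape[0]
    return pd.DataFrame(
        {
            "gain_fraction": (matrix.values == 1).sum(axis=0) / n,
            "loss_fraction": (matrix.values == -1).sum(axis=0) / n,
        },
        index=matrix.columns,
    )


def harmonize(
    second_cohort: Cohort,
    scheme: BinScheme,
    min_overlap_fraction: float = 0.0,
) -> pd.DataFrame:
    """Apply an existing (reference-cohort) scheme to a second cohort.

    Bin boundaries are *not* recomputed, so feature columns line up across
    cohorts and a model trained on the reference cohort can read the result.
    """
    if second_cohort.build.chromosomes != scheme.build.chromosomes:
        raise ValueError("second cohort is on a different build than the scheme")
    return assign_to_bins(second_cohort, scheme, min_overlap_fraction)


def plot_frequency_profile(profile: pd.DataFrame, scheme: BinScheme | None = None, ax=None):
    """Genome-wide gain/loss frequency plot (gains up in blue, losses down in
    red), one bar per bin in genome order. Requires matplotlib."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(12, 3))
    x = np.arange(len(profile))
    ax.bar(x, profile["gain_fraction"].values, width=1.0, color="tab:blue", label="gain")
    ax.bar(x, -profile["loss_fraction"].values, width=1.0, color="tab:red", label="loss")
    ax.axhline(0, color="black", linewidth=0.5)
    ax.set_ylabel("fraction of patients")
    ax.set_ylim(-1, 1)
    if scheme is not None and scheme.names == list(profile.index):
        edges, labels = [], []
        for chrom, _ in scheme.build.chromosomes:
            cb = scheme.chrom_bins(chrom)
            if cb:
                edges.append(cb[0].index)
                labels.append(chrom)
        for e in edges[1:]:
            ax.axvline(e - 0.5, color="grey", linewidth=0.5, linestyle=":")
        ax.set_xticks(edges)
        ax.set_xticklabels(labels)
        ax.set_xlabel("chromosome")
    else:
        ax.set_xlabel("bin")
    ax.legend(loc="upper right", frameon=False)
    return ax


def write_bin_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a patients x bins matrix as TSV (values -1/0/1)."""
    matrix.to_csv(path, sep="\t", index_label="patient_id")


def read_bin_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="patient_id")
    df.index = df.index.astype(str)
    return df.astype(np.int8)
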