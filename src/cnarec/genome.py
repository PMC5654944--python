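"""Genome builds, intervals and cytoband maps.

Coordinates are 0-based half-open throughout the package; file dialects that
use 1-based inclusive coordinates are converted on read (see :mod:`cnarec.segments`).

Chromosome names are stored without a ``chr`` prefix ("1".."22", "X", "Y"), the
convention used by cytogenetic band labels such as ``17p12-p11.2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "GenomeBuild",
    "GenomicInterval",
    "CytobandMap",
    "hg19",
    "toy_build",
    "read_cytobands",
    "band_label",
    "synthetic_cytobands",
    "bundled_synthetic_hg19_cytobands",
]

# Reference chromosome lengths for Human Genome build 19 (GRCh37).
_HG19_LENGTHS: tuple[tuple[str, int], ...] = (
    ("1", 249_250_621), ("2", 243_199_373), ("3", 198_022_430),
    ("4", 191_154_276), ("5", 180_915_260), ("6", 171_115_067),
    ("7", 159_138_663), ("8", 146_364_022), ("9", 141_213_431),
    ("10", 135_534_747), ("11", 135_006_516), ("12", 133_851_895),
    ("13", 115_169_878), ("14", 107_349_540), ("15", 102_531_392),
    ("16", 90_354_753), ("17", 81_195_210), ("18", 78_077_248),
    ("19", 59_128_983), ("20", 63_025_520), ("21", 48_129_895),
    ("22", 51_304_566), ("X", 155_270_560), ("Y", 59_373_566),
)


def normalize_chrom(name: str) -> str:
    """Strip a leading ``chr`` prefix and surrounding whitespace."""
    name = str(name).strip()
    if name.lower().startswith("chr"):
        name = name[3:]
    return name


@dataclass(frozen=True)
class GenomeBuild:
    """An ordered set of chromosomes with lengths.

    Parameters
    ----------
    name
        Build identifier, e.g. ``"hg19"``.
    chromosomes
        Ordered ``(chrom_name, length_bp)`` pairs. Names must be unique and
        lengths positive.
    """

    name: str = "hg19"
    chromosomes: tuple[tuple[str, int], ...] = _HG19_LENGTHS

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in build")
        for c, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {c!r} has non-positive length {length}")
        object.__setattr__(self, "chromosomes", tuple((str(c), int(l)) for c, l in self.chromosomes))

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.chromosomes)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def __contains__(self, chrom: str) -> bool:
        return normalize_chrom(chrom) in self.lengths

    def length(self, chrom: str) -> int:
        return self.lengths[normalize_chrom(chrom)]

    def chrom_order(self, chrom: str) -> int:
        """Genome-order rank of a chromosome (for sorting)."""
        return self.chrom_names.index(normalize_chrom(chrom))


def hg19() -> GenomeBuild:
    """The full hg19 build (chromosomes 1-22, X, Y)."""
    return GenomeBuild(name="hg19", chromosomes=_HG19_LENGTHS)


def toy_build(n_chrom: int = 4) -> GenomeBuild:
    """A small 4-chromosome genome (50-100 Mb each) used for simulation and tests."""
    lengths = (100_000_000, 90_000_000, 70_000_000, 50_000_000, 60_000_000, 80_000_000)
    if not 1 <= n_chrom <= len(lengths):
        raise ValueError(f"n_chrom must be in 1..{len(lengths)}")
    return GenomeBuild(name=f"toy{n_chrom}", chromosomes=tuple(
        (str(i + 1), lengths[i]) for i in range(n_chrom)
    ))


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end}) on {self.chrom}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def validate_against(self, build: GenomeBuild) -> None:
        if self.chrom not in build:
            raise ValueError(f"chromosome {self.chrom!r} not in build {build.name!r}")
        if self.end > build.length(self.chrom):
            raise ValueError(
                f"interval end {self.end} exceeds {self.chrom} length {build.length(self.chrom)}"
            )


class CytobandMap:
    """Cytogenetic band annotation: per chromosome, bands tile ``[0, L)``.

    Bands are ``(GenomicInterval, band_name)`` pairs, e.g. ``(17:0-3mb, "p13.3")``.
    The tiling invariant (no gaps, no overlaps, starts at 0) is enforced at
    construction.
    """

    def __init__(self, bands: Iterable[tuple[GenomicInterval, str]]):
        per_chrom: dict[str, list[tuple[GenomicInterval, str]]] = {}
        for iv, name in bands:
            per_chrom.setdefault(iv.chrom, []).append((iv, name))
        for chrom, items in per_chrom.items():
            items.sort(key=lambda t: t[0].start)
            if items[0][0].start != 0:
                raise ValueError(f"cytobands on {chrom} do not start at 0")
            for (a, _), (b, _) in zip(items, items[1:]):
                if a.end < b.start:
                    raise ValueError(f"gap in cytobands on {chrom} at {a.end}..{b.start}")
                if a.end > b.start:
                    raise ValueError(f"overlapping cytobands on {chrom} at {b.start}")
        self._bands = per_chrom

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._bands)

    def bands(self, chrom: str) -> list[tuple[GenomicInterval, str]]:
        return list(self._bands[normalize_chrom(chrom)])

    def __contains__(self, chrom: str) -> bool:
        return normalize_chrom(chrom) in self._bands

    def overlapping(self, interval: GenomicInterval) -> list[tuple[GenomicInterval, str]]:
        """Bands overlapping *interval*, in coordinate order."""
        if interval.chrom not in self._bands:
            raise KeyError(f"chromosome {interval.chrom!r} not annotated")
        return [
            (iv, name)
            for iv, name in self._bands[interval.chrom]
            if iv.overlap_bp(interval) > 0
        ]


def read_cytobands(path: str | Path, build: GenomeBuild | None = None) -> CytobandMap:
    """Read a UCSC ``cytoBand.txt``-format file (5 tab-separated columns,
    0-based half-open: chrom, start, end, band, stain).

    If *build* is given, chromosomes absent from it are skipped.
    """
    bands: list[tuple[GenomicInterval, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}: line {lineno}: expected >=4 tab-separated columns")
            chrom = normalize_chrom(fields[0])
            if build is not None and chrom not in build:
                continue
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates") from exc
            bands.append((GenomicInterval(chrom, start, end), fields[3]))
    return CytobandMap(bands)


def band_label(interval: GenomicInterval, cytobands: CytobandMap) -> str:
    """Cytoband-range label for an interval, e.g. ``"17p12-p11.2"``.

    The label is ``<chrom><first band>-<last band>`` over the bands the
    interval overlaps, collapsing to ``<chrom><band>`` when a single band is
    spanned.
    """
    hits = cytobands.overlapping(interval)
    if not hits:
        raise ValueError(
            f"interval {interval.chrom}:{interval.start}-{interval.end} overlaps no annotated band"
        )
    first, last = hits[0][1], hits[-1][1]
    if first == last:
        return f"{interval.chrom}{first}"
    return f"{interval.chrom}{first}-{last}"


def synthetic_cytobands(
    build: GenomeBuild,
    n_p_bands: int = 5,
    n_q_bands: int = 6,
    centromere_fraction: float = 0.4,
) -> CytobandMap:
    """Generate a SYNTHETIC band tiling for a build.

    This is a stand-in annotation for tests and simulations: band *names*
    follow cytogenetic conventions (p-arm bands numbered outward from the
    centromere, listed telomere-first), but band *coordinates* are an even
    tiling of each arm, not real staining boundaries.
    """
    bands: list[tuple[GenomicInterval, str]] = []
    for chrom, length in build.chromosomes:
        cen = int(length * centromere_fraction)
        # p arm: telomere -> centromere, names descend p<n> ... p11
        p_names = [f"p{n_p_bands + 10 - i}" for i in range(n_p_bands)]
        p_edges = [round(cen * i / n_p_bands) for i in range(n_p_bands + 1)]
        for name, s, e in zip(p_names, p_edges, p_edges[1:]):
            if e > s:
                bands.append((GenomicInterval(chrom, s, e), name))
        q_names = [f"q{11 + i}" for i in range(n_q_bands)]
        q_edges = [cen + round((length - cen) * i / n_q_bands) for i in range(n_q_bands + 1)]
        for name, s, e in zip(q_names, q_edges, q_edges[1:]):
            if e > s:
                bands.append((GenomicInterval(chrom, s, e), name))
    return CytobandMap(bands)


def write_cytobands(cytobands: CytobandMap, path: str | Path, stain: str = "gneg") -> None:
    """Write a map in UCSC cytoBand.txt format (no header)."""
    with open(path, "w") as fh:
        for chrom in cytobands.chromosomes:
            for iv, name in cytobands.bands(chrom):
                fh.write(f"chr{chrom}\t{iv.start}\t{iv.end}\t{name}\t{stain}\n")


def bundled_synthetic_hg19_cytobands() -> CytobandMap:
    """Load the bundled synthetic hg19 band annotation (24 chromosomes).

    The file is generated by :func:`synthetic_cytobands` over the real hg19
    chromosome lengths; band boundaries are synthetic.
    """
    ref = resources.files("cnarec").joinpath("data/cytobands.synthetic.hg19.tsv")
    with resources.as_file(ref) as path:
        return read_cytobands(path, build=hg19())
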