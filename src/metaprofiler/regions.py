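"""Genomic region handling: reading, validation, resizing, orientation, stratification.

Regions use 0-based half-open coordinates everywhere (BED-native). A
:class:`RegionGroup` is the unit of aggregation: a labelled, ordered set of
regions that, after resizing, share a common width so that per-region
coverage vectors can be stacked into a rectangular matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

log = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")


class RegionFileError(ValueError):
    """Raised when a region file cannot be parsed."""


@dataclass(frozen=True)
class GenomicRegion:
    """A strand-aware genomic interval, 0-based half-open.

    ``strand`` is ``"+"``, ``"-"`` or ``"."`` (unstranded). ``score`` is an
    optional numeric annotation (e.g. a peak signalValue or a CAGE level).
    """

    chrom: str
    start: int
    end: int
    name: str = ""
    score: float | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}; expected one of {STRANDS}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Midpoint, floor for odd widths."""
        return (self.start + self.end) // 2


@dataclass
class RegionGroup:
    """A labelled, ordered collection of regions aggregated together."""

    label: str
    regions: list[GenomicRegion] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def __getitem__(self, i):
        return self.regions[i]

    @property
    def width(self) -> int | None:
        """Common region width in bp, or None if widths differ or group is empty."""
        widths = {r.width for r in self.regions}
        return widths.pop() if len(widths) == 1 else None


def _parse_int(token: str, what: str, lineno: int, path) -> int:
    try:
        return int(token)
    except ValueError:
        raise RegionFileError(
            f"{path}, line {lineno}: non-integer {what} {token!r}"
        ) from None


def _make_region(chrom, start, end, name, score, strand, lineno, path) -> GenomicRegion:
    try:
        return GenomicRegion(chrom, start, end, name=name, score=score, strand=strand)
    except ValueError as exc:
        raise RegionFileError(f"{path}, line {lineno}: {exc}") from None


def read_bed(path, label: str | None = None) -> RegionGroup:
    """Read a 3-6 column BED file into a :class:`RegionGroup`.

    Coordinates are kept 0-based half-open as in the file. Missing name
    fields become ``region_<i>`` (1-based), a missing strand field means
    unstranded.
    """
    path = Path(path)
    regions: list[GenomicRegion] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise RegionFileError(
                    f"{path}, line {lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            chrom = fields[0]
            start = _parse_int(fields[1], "start", lineno, path)
            end = _parse_int(fields[2], "end", lineno, path)
            name = fields[3] if len(fields) > 3 and fields[3] not in ("", ".") else f"region_{len(regions) + 1}"
            score = None
            if len(fields) > 4 and fields[4] not in ("", "."):
                try:
                    score = float(fields[4])
                except ValueError:
                    raise RegionFileError(
                        f"{path}, line {lineno}: non-numeric score {fields[4]!r}"
                    ) from None
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            regions.append(_make_region(chrom, start, end, name, score, strand, lineno, path))
    return RegionGroup(label=label or path.stem, regions=regions)


def read_narrowpeak(path, label: str | None = None) -> RegionGroup:
    """Read an ENCODE narrowPeak (10 col) or broadPeak (9 col) file.

    Dispatches on column count; the signalValue column (7th) is stored as the
    region score in both formats.
    """
    path = Path(path)
    regions: list[GenomicRegion] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) not in (9, 10):
                raise RegionFileError(
                    f"{path}, line {lineno}: expected 10 (narrowPeak) or 9 (broadPeak) "
                    f"columns, got {len(fields)}"
                )
            chrom = fields[0]
            start = _parse_int(fields[1], "start", lineno, path)
            end = _parse_int(fields[2], "end", lineno, path)
            name = fields[3] if fields[3] not in ("", ".") else f"region_{len(regions) + 1}"
            strand = fields[5] if fields[5] in ("+", "-") else "."
            try:
                score = float(fields[6])  # signalValue
            except ValueError:
                raise RegionFileError(
                    f"{path}, line {lineno}: non-numeric signalValue {fields[6]!r}"
                ) from None
            regions.append(_make_region(chrom, start, end, name, score, strand, lineno, path))
    return RegionGroup(label=label or path.stem, regions=regions)


def write_bed(group: RegionGroup, path) -> None:
    """Write a group as 6-column BED (score 0 when unset)."""
    with open(path, "w") as fh:
        for r in group:
            score = 0 if r.score is None else r.score
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{score:g}\t{r.strand}\n")


def read_chrom_sizes(path) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>length`` file."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise RegionFileError(f"{path}, line {lineno}: expected 'chrom<TAB>length'")
            sizes[fields[0]] = _parse_int(fields[1], "length", lineno, path)
    return sizes


def resize_regions(
    group: RegionGroup, flank: int, chrom_sizes: Mapping[str, int]
) -> RegionGroup:
    """Re-center every region to ``[center - flank, center + flank)``.

    All output regions share width ``2 * flank``. Regions whose resized
    interval would extend below 0 or past the chromosome end are dropped with
    a warning: clamping would break the uniform-width matrix the profile
    arithmetic requires.
    """
    if flank <= 0:
        raise ValueError("flank must be > 0")
    kept: list[GenomicRegion] = []
    dropped = 0
    for r in group:
        c = r.center
        start, end = c - flank, c + flank
        limit = chrom_sizes.get(r.chrom)
        if start < 0 or limit is None or end > limit:
            dropped += 1
            continue
        kept.append(replace(r, start=start, end=end))
    if dropped:
        log.warning(
            "resize_regions(%s): dropped %d/%d regions exceeding chromosome bounds",
            group.label, dropped, len(group),
        )
    if not kept:
        raise ValueError(f"no regions remain in group {group.label!r} after resizing")
    return RegionGroup(label=group.label, regions=kept)


def orient_region_coverage(cov: np.ndarray, strand: str) -> np.ndarray:
    """Flip a per-region coverage vector into 5'->3' orientation.

    Minus-strand vectors are reversed; plus-strand and unstranded vectors are
    returned unchanged. Applying the operation twice is the identity.
    """
    cov = np.asarray(cov)
    if strand not in STRANDS:
        raise ValueError(f"invalid strand {strand!r}")
    return cov[::-1] if strand == "-" else cov


def stratify_by_score(
    group: RegionGroup,
    quantile_edges: Sequence[float] = (1 / 3, 2 / 3),
) -> dict[str, RegionGroup]:
    """Split a group into activity classes none/low/moderate/high by score.

    Regions with score exactly 0 form the "none" class. The remaining
    regions are ranked by score (stable with respect to input order, so
    ties split as evenly as possible) and cut at the given quantile edges of
    the rank distribution, defaulting to tertiles. Input order is preserved
    within each output class; the four classes partition the input.
    """
    scores = []
    for r in group:
        if r.score is None or r.score < 0:
            raise ValueError(f"region {r.name!r} lacks a non-negative score")
        scores.append(float(r.score))
    scores = np.asarray(scores)
    nonzero_idx = np.flatnonzero(scores > 0)
    if len(nonzero_idx) < 3:
        raise ValueError(
            f"need >=3 nonzero-score regions to stratify, got {len(nonzero_idx)}"
        )
    edges = sorted(quantile_edges)
    if len(edges) != 2 or not (0 < edges[0] < edges[1] < 1):
        raise ValueError("quantile_edges must be two fractions strictly inside (0, 1)")
    order = nonzero_idx[np.argsort(scores[nonzero_idx], kind="stable")]
    n = len(order)
    b1 = int(round(n * edges[0]))
    b2 = int(round(n * edges[1]))
    labels = {"low": order[:b1], "moderate": order[b1:b2], "high": order[b2:]}
    out: dict[str, RegionGroup] = {
        "none": RegionGroup("none", [group[i] for i in np.flatnonzero(scores == 0)])
    }
    for name, idx in labels.items():
        keep = sorted(idx)  # preserve input order inside each class
        out[name] = RegionGroup(name, [group[i] for i in keep])
    return out
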