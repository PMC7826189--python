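"""Breadth-of-coverage over labelled genomic region classes.

Answers the question "what fraction of the bases of each region class
(e.g. 'viral' vs 'nonviral') is covered by at least one aligned read?".
Depth is deliberately not computed — the quantity of interest is breadth.
Coverage is strand-agnostic; all coordinates are 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .core_io import Interval

logger = logging.getLogger("chromaforge")


def merge_intervals(ivs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals as a sorted disjoint list (sweep)."""
    s = sorted(ivs)
    out: list[tuple[int, int]] = []
    for start, end in s:
        if out and start <= out[-1][1]:
            if end > out[-1][1]:
                out[-1] = (out[-1][0], end)
        else:
            out.append((start, end))
    return out


def _intersect_length(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> int:
    """Total overlap of two disjoint sorted interval lists (two pointers)."""
    i = j = 0
    total = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo < hi:
            total += hi - lo
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return total


@dataclass
class RegionClassMap:
    """Labelled genomic intervals partitioned by class.

    Overlapping same-class intervals are unioned internally; classes need
    not tile the genome.
    """

    intervals: list[Interval]
    _by_class: dict[str, dict[str, list[tuple[int, int]]]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        grouped: dict[str, dict[str, list[tuple[int, int]]]] = {}
        for iv in self.intervals:
            if not iv.label:
                raise ValueError(f"region {iv.contig}:{iv.start}-{iv.end} lacks a class label")
            grouped.setdefault(iv.label, {}).setdefault(iv.contig, []).append(
                (iv.start, iv.end)
            )
        self._by_class = {
            cls: {contig: merge_intervals(ivs) for contig, ivs in per.items()}
            for cls, per in grouped.items()
        }

    @property
    def classes(self) -> list[str]:
        return sorted(self._by_class)

    @property
    def contigs(self) -> set[str]:
        return {iv.contig for iv in self.intervals}

    def class_intervals(self, cls: str) -> dict[str, list[tuple[int, int]]]:
        return self._by_class[cls]

    def total_bases(self, cls: str) -> int:
        return sum(e - s for ivs in self._by_class[cls].values() for s, e in ivs)


@dataclass
class ClassCoverage:
    total_bases: int
    covered_bases: int

    @property
    def fraction(self) -> float:
        return self.covered_bases / self.total_bases if self.total_bases else 0.0


@dataclass
class CoverageReport:
    """Per-class breadth of coverage for one alignment mode."""

    mode_label: str
    per_class: dict[str, ClassCoverage]


def breadth_per_class(
    regions: RegionClassMap,
    alignments: Sequence[Interval],
    mode_label: str = "default",
) -> CoverageReport:
    """Fraction of each region class's bases covered by >=1 alignment.

    Computed by sweep-line union of the alignments followed by two-pointer
    intersection with each class's unioned intervals. Alignments on contigs
    absent from the region map are logged and excluded.
    """
    known = regions.contigs
    per_contig: dict[str, list[tuple[int, int]]] = {}
    dropped = 0
    for iv in alignments:
        if iv.contig not in known:
            dropped += 1
            continue
        per_contig.setdefault(iv.contig, []).append((iv.start, iv.end))
    if dropped:
        logger.warning(
            "breadth_per_class: %d alignments on contigs absent from the region map", dropped
        )
    aln_union = {contig: merge_intervals(ivs) for contig, ivs in per_contig.items()}

    per_class: dict[str, ClassCoverage] = {}
    for cls in regions.classes:
        covered = 0
        for contig, class_ivs in regions.class_intervals(cls).items():
            covered += _intersect_length(aln_union.get(contig, []), class_ivs)
        per_class[cls] = ClassCoverage(
            total_bases=regions.total_bases(cls), covered_bases=covered
        )
    return CoverageReport(mode_label=mode_label, per_class=per_class)


def compare_classes(
    report_a: CoverageReport,
    report_b: CoverageReport,
    class_a: str | None = None,
    class_b: str | None = None,
) -> dict[str, float | str]:
    """Descriptive comparison of two class breadths (same alignment mode).

    Returns both fractions, their absolute difference and the ratio a/b
    (0 when a is 0; undefined -> nan when b is 0 and a > 0). No inferential
    statistic is attached.
    """
    if report_a.mode_label != report_b.mode_label:
        raise ValueError(
            f"mode labels differ: {report_a.mode_label!r} vs {report_b.mode_label!r}"
        )

    def pick(report: CoverageReport, cls: str | None) -> tuple[str, ClassCoverage]:
        if cls is None:
            if len(report.per_class) != 1:
                raise ValueError("class name required for a multi-class report")
            cls = next(iter(report.per_class))
        return cls, report.per_class[cls]

    name_a, cov_a = pick(report_a, class_a)
    name_b, cov_b = pick(report_b, class_b)
    fa, fb = cov_a.fraction, cov_b.fraction
    if fa == 0.0:
        ratio = 0.0
    elif fb == 0.0:
        ratio = float("nan")
    else:
        ratio = fa / fb
    return {
        "mode": report_a.mode_label,
        "class_a": name_a,
        "class_b": name_b,
        "fraction_a": fa,
        "fraction_b": fb,
        "ratio": ratio,
        "abs_difference": abs(fa - fb),
    }


def write_coverage_table(report: CoverageReport, path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("mode\tclass\ttotal_bases\tcovered_bases\tfraction\n")
        for cls in sorted(report.per_class):
            c = report.per_class[cls]
            fh.write(
                f"{report.mode_label}\t{cls}\t{c.total_bases}\t{c.covered_bases}\t{c.fraction:.6f}\n"
            )
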