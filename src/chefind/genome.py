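"""Genome annotation model, GTF/BED I/O, overlap engine and positional classification.

Internal coordinates are 0-based half-open throughout.  GTF I/O converts
from/to the 1-based inclusive GTF dialect; BED I/O is natively 0-based
half-open.  Overlap is computed on transcript spans: any two features sharing
at least one base are considered overlapping (exon-level overlap is available
as an option but off by default).
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence


class GtfParseError(ValueError):
    """Raised on a malformed GTF line; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


class AnnotationValidationError(ValueError):
    pass


@dataclass
class TranscriptModel:
    """A stranded, exon-structured genomic transcript.

    Coordinates are 0-based half-open; ``tss`` is the transcription start
    site: ``start`` on the + strand, ``end`` on the − strand.
    """

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    biotype: str = "other"
    annotated: bool = True
    gene_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise AnnotationValidationError(
                f"transcript {self.id}: start {self.start} >= end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationValidationError(
                f"transcript {self.id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.exons:
            self.exons = [(self.start, self.end)]
        self.exons = sorted(tuple(e) for e in self.exons)
        prev_end = None
        for (s, e) in self.exons:
            if s < self.start or e > self.end or s >= e:
                raise AnnotationValidationError(
                    f"transcript {self.id}: exon ({s},{e}) outside span "
                    f"({self.start},{self.end}) or empty"
                )
            if prev_end is not None and s < prev_end:
                raise AnnotationValidationError(
                    f"transcript {self.id}: overlapping exons at ({s},{e})"
                )
            prev_end = e

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class GenomeAnnotation:
    """A collection of transcripts plus chromosome sizes.

    ``coding_genes`` returns the protein_coding subset; ids are unique and
    all coordinates must fit the declared chromosome sizes (when given).
    """

    transcripts: dict[str, TranscriptModel]
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.chrom_sizes:
            for t in self.transcripts.values():
                size = self.chrom_sizes.get(t.chrom)
                if size is None:
                    raise AnnotationValidationError(
                        f"transcript {t.id}: chromosome {t.chrom} not in chrom_sizes"
                    )
                if t.end > size:
                    raise AnnotationValidationError(
                        f"transcript {t.id}: end {t.end} beyond {t.chrom} size {size}"
                    )

    @classmethod
    def from_transcripts(
        cls,
        transcripts: Iterable[TranscriptModel],
        chrom_sizes: Optional[dict[str, int]] = None,
    ) -> "GenomeAnnotation":
        index: dict[str, TranscriptModel] = {}
        for t in transcripts:
            if t.id in index:
                raise AnnotationValidationError(f"duplicate transcript id {t.id}")
            index[t.id] = t
        return cls(transcripts=index, chrom_sizes=chrom_sizes or {})

    @property
    def coding_genes(self) -> list[TranscriptModel]:
        return [t for t in self.transcripts.values() if t.biotype == "protein_coding"]

    def __len__(self) -> int:
        return len(self.transcripts)

    def __getitem__(self, tid: str) -> TranscriptModel:
        return self.transcripts[tid]


class PositionalClass(enum.Enum):
    """Positional class of an expressed transcript relative to coding genes."""

    SENSE_OVERLAP = "sense_overlap"
    ANTISENSE = "antisense"
    INTERGENIC = "intergenic"


# ---------------------------------------------------------------------------
# GTF I/O

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def read_gtf(path: str | Path) -> GenomeAnnotation:
    """Read transcript and exon features from a GTF file.

    GTF 1-based inclusive coordinates are converted to the internal 0-based
    half-open convention.  Each ``transcript`` feature becomes one
    :class:`TranscriptModel`; ``exon`` features are attached by
    ``transcript_id``.  The optional ``annotated "true|false"`` attribute
    carries the annotation status (default true); ``gene_biotype`` other than
    ``protein_coding`` maps to ``other``.
    """
    specs: dict[str, dict] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"expected 9 tab-separated fields, got {len(fields)}", lineno
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs_s = fields
            if feature not in ("transcript", "exon"):
                continue
            try:
                start = int(start_s) - 1  # 1-based inclusive -> 0-based half-open
                end = int(end_s)
            except ValueError:
                raise GtfParseError(f"non-integer coordinates {start_s!r}/{end_s!r}", lineno)
            attrs = _parse_attributes(attrs_s)
            tid = attrs.get("transcript_id")
            if tid is None:
                raise GtfParseError("missing transcript_id attribute", lineno)
            if feature == "transcript":
                specs[tid] = dict(
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    biotype=attrs.get("gene_biotype", "other"),
                    annotated=attrs.get("annotated", "true").lower() != "false",
                    gene_id=attrs.get("gene_id"),
                )
            else:
                exons.setdefault(tid, []).append((start, end))
    models = []
    for tid, sp in specs.items():
        ex = exons.get(tid, [])
        for (s, e) in ex:
            if s < sp["start"] or e > sp["end"]:
                raise AnnotationValidationError(
                    f"transcript {tid}: exon ({s},{e}) outside transcript span"
                )
        models.append(TranscriptModel(id=tid, exons=ex, **sp))
    return GenomeAnnotation.from_transcripts(models)


def write_gtf(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write transcripts and exons as GTF (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        for t in annotation.transcripts.values():
            gene_id = t.gene_id or t.id
            attrs = (
                f'gene_id "{gene_id}"; transcript_id "{t.id}"; '
                f'gene_biotype "{t.biotype}"; '
                f'annotated "{"true" if t.annotated else "false"}";'
            )
            fh.write(
                f"{t.chrom}\tchefind\ttranscript\t{t.start + 1}\t{t.end}\t.\t"
                f"{t.strand}\t.\t{attrs}\n"
            )
            for (s, e) in t.exons:
                fh.write(
                    f"{t.chrom}\tchefind\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# BED and chrom.sizes I/O


@dataclass
class BedInterval:
    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."


def read_bed(path: str | Path) -> list[BedInterval]:
    """Read BED3–BED6 intervals (native 0-based half-open)."""
    out = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append(
                BedInterval(
                    chrom=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    name=f[3] if len(f) > 3 else ".",
                    score=float(f[4]) if len(f) > 4 and f[4] != "." else 0.0,
                    strand=f[5] if len(f) > 5 else ".",
                )
            )
    return out


def write_bed(intervals: Sequence[BedInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.score:g}\t{iv.strand}\n"
            )


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, size = line.split()[:2]
            sizes[chrom] = int(size)
    return sizes


# ---------------------------------------------------------------------------
# Overlap engine


def _exon_overlap_bases(a: TranscriptModel, b: TranscriptModel) -> int:
    total = 0
    for (s1, e1) in a.exons:
        for (s2, e2) in b.exons:
            total += max(0, min(e1, e2) - max(s1, s2))
    return total


def overlaps(
    a: TranscriptModel,
    b: TranscriptModel,
    same_strand: bool = False,
    min_bases: int = 1,
    exon_level: bool = False,
) -> bool:
    """True iff the two transcripts share ``min_bases`` or more bases.

    Features sharing at least one base count as overlapping.  With
    ``same_strand`` the strands must also match.  Overlap is evaluated on
    transcript spans unless ``exon_level`` is set.
    """
    if min_bases < 1:
        raise ValueError("min_bases must be >= 1")
    if a.chrom != b.chrom:
        return False
    if same_strand and a.strand != b.strand:
        return False
    if exon_level:
        return _exon_overlap_bases(a, b) >= min_bases
    return min(a.end, b.end) - max(a.start, b.start) >= min_bases


def classify_position(
    t: TranscriptModel,
    coding: Sequence[TranscriptModel],
    exon_level: bool = False,
) -> PositionalClass:
    """Classify a transcript by position relative to the coding gene set.

    Rule order: sense_overlap if it overlaps any coding gene on the same
    strand by at least one base; else antisense if it overlaps any coding
    gene on the opposite strand; else intergenic.  The transcript is tested
    against all coding genes and the first matching rule wins.
    """
    if not coding:
        raise ValueError("coding set must be nonempty")
    any_opposite = False
    for g in coding:
        if g.id == t.id:
            continue
        if overlaps(t, g, same_strand=False, exon_level=exon_level):
            if g.strand == t.strand:
                return PositionalClass.SENSE_OVERLAP
            any_opposite = True
    # A coding transcript trivially sense-overlaps its own locus.
    if t.biotype == "protein_coding" and any(g.id == t.id for g in coding):
        return PositionalClass.SENSE_OVERLAP
    if any_opposite:
        return PositionalClass.ANTISENSE
    return PositionalClass.INTERGENIC


def classify_positions(
    transcripts: Iterable[TranscriptModel],
    coding: Sequence[TranscriptModel],
    exon_level: bool = False,
) -> dict[str, PositionalClass]:
    """Vector form of :func:`classify_position` over a transcript collection."""
    if not coding:
        raise ValueError("coding set must be nonempty")
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for g in coding:
        by_chrom.setdefault(g.chrom, []).append(g)
    out = {}
    for t in transcripts:
        local = by_chrom.get(t.chrom)
        if local:
            out[t.id] = classify_position(t, local, exon_level=exon_level)
        else:
            out[t.id] = PositionalClass.INTERGENIC
    return out


def flanking_genes(
    t: TranscriptModel,
    coding: Sequence[TranscriptModel],
    same_strand: bool = True,
) -> tuple[Optional[TranscriptModel], Optional[TranscriptModel]]:
    """Nearest non-overlapping coding gene on each side of an intergenic transcript.

    Upstream/downstream are in genomic coordinate order relative to the
    transcript's span; distance is the span gap.  Ties at equal gap break
    toward the smaller-coordinate gene.  Returns ``(upstream, downstream)``
    with ``None`` where a side has no candidate.
    """
    up_best: Optional[TranscriptModel] = None
    up_gap = None
    down_best: Optional[TranscriptModel] = None
    down_gap = None
    for g in coding:
        if g.chrom != t.chrom or g.id == t.id:
            continue
        if same_strand and g.strand != t.strand:
            continue
        if g.end <= t.start:
            gap = t.start - g.end
            if up_gap is None or gap < up_gap or (gap == up_gap and g.start < up_best.start):
                up_best, up_gap = g, gap
        elif g.start >= t.end:
            gap = g.start - t.end
            if down_gap is None or gap < down_gap or (gap == down_gap and g.start < down_best.start):
                down_best, down_gap = g, gap
        # genes overlapping t are not flanks
    return up_best, down_best
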