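"""Structural-motif enrichment (RR-score) and Fisher co-enrichment.

A transcript is annotated to a motif family if its span fully contains at
least one motif interval on the same strand (family motifs are short
relative to assembled transcripts, so full containment is required).  The
RR-score of a transcript set t against a family r within a noncoding
universe T is the ratio of observed and background annotated fractions:

    RR(t, r) = (|t ∩ r| / |t|) / (|T ∩ r| / |T|)

with membership meaning containment-annotation; RR > 1 marks an
overrepresented family.  Co-enrichment between two transcript sets over a
universe uses Fisher's exact test; the enrichment flag requires odds ratio
> 2 and p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from scipy import stats as _sps
from scipy.stats.contingency import odds_ratio as _odds_ratio

from chefind.genome import BedInterval, TranscriptModel, read_bed


@dataclass
class MotifFamilySet:
    """Stranded motif intervals belonging to one (super-)family."""

    family: str
    motifs: list[BedInterval] = field(default_factory=list)


@dataclass
class RRResult:
    family: str
    observed_fraction: float
    background_fraction: float
    rr: float
    n_target: int
    n_universe: int


@dataclass
class FisherResult:
    odds_ratio: float
    pvalue: float
    table: tuple[tuple[int, int], tuple[int, int]]
    enriched: bool


class UndefinedRRError(ValueError):
    pass


def read_motif_bed(
    path: str | Path, superfamilies: Optional[Mapping[str, str]] = None
) -> dict[str, MotifFamilySet]:
    """Read a family-labelled motif BED (name column = family).

    An optional two-column family -> super-family mapping collapses
    annotating families into super-families before scoring.
    """
    out: dict[str, MotifFamilySet] = {}
    for iv in read_bed(path):
        fam = iv.name
        if superfamilies is not None:
            fam = superfamilies.get(fam, fam)
        out.setdefault(fam, MotifFamilySet(family=fam)).motifs.append(iv)
    return out


def read_superfamily_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    return dict(zip(df[0].astype(str), df[1].astype(str)))


def annotate_by_containment(t: TranscriptModel, motifs: MotifFamilySet) -> bool:
    """True iff >=1 motif interval lies entirely within t's span, same strand.

    Boundaries are inclusive: a motif exactly coextensive with the
    transcript counts; a motif hanging over either end does not.
    """
    for m in motifs.motifs:
        if (
            m.chrom == t.chrom
            and (m.strand == "." or m.strand == t.strand)
            and t.start <= m.start
            and m.end <= t.end
        ):
            return True
    return False


def annotated_ids(
    transcripts: Iterable[TranscriptModel], motifs: MotifFamilySet
) -> set[str]:
    return {t.id for t in transcripts if annotate_by_containment(t, motifs)}


def rr_score(
    target_ids: Sequence[str],
    family: MotifFamilySet,
    universe: Sequence[TranscriptModel],
    annotated: Optional[set[str]] = None,
) -> RRResult:
    """RR-score of a transcript set against one motif family.

    ``target_ids`` must be a subset of the universe's ids.  ``annotated``
    may carry precomputed containment-annotated ids (else computed here).
    Counting is per transcript, not per motif instance.
    """
    universe_ids = {t.id for t in universe}
    target = set(target_ids)
    if not target:
        raise ValueError("target set is empty")
    if not target <= universe_ids:
        raise ValueError("target set must be a subset of the universe")
    if annotated is None:
        annotated = annotated_ids(universe, family)
    n_bg = len(annotated)
    if n_bg == 0:
        raise UndefinedRRError(
            f"no transcript in the universe contains a {family.family} motif"
        )
    obs = len(target & annotated) / len(target)
    bg = n_bg / len(universe_ids)
    return RRResult(
        family=family.family,
        observed_fraction=obs,
        background_fraction=bg,
        rr=obs / bg,
        n_target=len(target),
        n_universe=len(universe_ids),
    )


def rr_report(
    target_ids: Sequence[str],
    families: Mapping[str, MotifFamilySet],
    universe: Sequence[TranscriptModel],
) -> pd.DataFrame:
    """RR-scores for every family with a nonzero background fraction."""
    rows = []
    for fam in sorted(families):
        try:
            r = rr_score(target_ids, families[fam], universe)
        except UndefinedRRError:
            continue
        rows.append(
            (r.family, r.observed_fraction, r.background_fraction, r.rr)
        )
    return pd.DataFrame(
        rows, columns=["family", "observed_fraction", "background_fraction", "rr"]
    )


def fisher_co_enrichment(
    set_a: Sequence[str] | set[str],
    set_b: Sequence[str] | set[str],
    universe: Sequence[str] | set[str],
    or_threshold: float = 2.0,
    alpha: float = 0.05,
) -> FisherResult:
    """Fisher exact co-enrichment of two transcript sets over a universe.

    Builds the 2x2 table (A∩B, A\\B, B\\A, neither), computes the
    conditional-MLE odds ratio and the two-sided exact p-value, and flags
    enrichment when OR > 2 and p < 0.05.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("universe is empty")
    a = set(set_a) & uni
    b = set(set_b) & uni
    both = len(a & b)
    a_only = len(a - b)
    b_only = len(b - a)
    neither = len(uni) - both - a_only - b_only
    table = [[both, a_only], [b_only, neither]]
    p = float(_sps.fisher_exact(table, alternative="two-sided")[1])
    orr = float(_odds_ratio(table, kind="conditional").statistic)
    return FisherResult(
        odds_ratio=orr,
        pvalue=p,
        table=((both, a_only), (b_only, neither)),
        enriched=(orr > or_threshold) and (p < alpha),
    )
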