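"""Neighbor-gene expression correlation and relative-density curves.

Each intergenic transcript is paired with one of its two flanking
protein-coding genes on the same strand: the one with the highest absolute
Pearson correlation (PCC) of expression across all CPE and SNE samples.  The
distribution of pair PCCs is summarized as a relative density: the Gaussian
kernel density of the group's PCC values divided by the density of a control
in which each transcript is paired with a randomly selected coding gene.
The significance cutoff on PCC is +/-0.8.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from chefind.genome import GenomeAnnotation, TranscriptModel, flanking_genes

DENSITY_FLOOR = 1e-6


class UndefinedCorrelationError(ValueError):
    pass


@dataclass
class NeighborPair:
    rna_id: str
    gene_id: str
    side: str  # upstream | downstream
    pcc: float


@dataclass
class RelativeDensityCurve:
    grid: np.ndarray
    density_group: np.ndarray
    density_control: np.ndarray
    ratio: np.ndarray
    floored: np.ndarray  # True where the control hit the density floor

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "grid": self.grid,
                "density_group": self.density_group,
                "density_control": self.density_control,
                "ratio": self.ratio,
                "floored": self.floored,
            }
        )


def compute_pcc(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation coefficient of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("vectors must be 1-D and of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in at least one vector")
    return float(stats.pearsonr(x, y).statistic)


def pair_neighbor_gene(
    rna: TranscriptModel | str,
    flanks: tuple[Optional[TranscriptModel], Optional[TranscriptModel]],
    expr: Mapping[str, np.ndarray],
) -> Optional[NeighborPair]:
    """Choose the flanking gene with the largest |PCC| of expression.

    ``expr`` maps transcript/gene ids to expression vectors over all CPE and
    SNE samples.  A flank without expression (or with zero variance) is not
    a candidate; with no usable flank the pair is ``None``.  Ties at equal
    |PCC| break toward the downstream gene.
    """
    rna_id = rna if isinstance(rna, str) else rna.id
    if rna_id not in expr:
        return None
    x = np.asarray(expr[rna_id], dtype=float)
    candidates: list[NeighborPair] = []
    for side, gene in zip(("upstream", "downstream"), flanks):
        if gene is None or gene.id not in expr:
            continue
        try:
            r = compute_pcc(x, np.asarray(expr[gene.id], dtype=float))
        except (UndefinedCorrelationError, ValueError):
            continue
        candidates.append(NeighborPair(rna_id, gene.id, side, r))
    if not candidates:
        return None
    # max |PCC|; tie -> downstream (candidates list is upstream-first)
    best = max(candidates, key=lambda p: (abs(p.pcc), p.side == "downstream"))
    return best


def pair_all_neighbors(
    rnas: Iterable[TranscriptModel],
    annotation: GenomeAnnotation,
    expr: Mapping[str, np.ndarray],
    same_strand: bool = True,
) -> list[NeighborPair]:
    """Neighbor pairing for a collection of intergenic transcripts."""
    coding = annotation.coding_genes
    pairs = []
    for t in rnas:
        flanks = flanking_genes(t, coding, same_strand=same_strand)
        p = pair_neighbor_gene(t, flanks, expr)
        if p is not None:
            pairs.append(p)
    return pairs


def random_control_pairs(
    rnas: Sequence[TranscriptModel | str],
    coding_ids: Sequence[str],
    expr: Mapping[str, np.ndarray],
    seed: int,
) -> list[NeighborPair]:
    """Pair each transcript with a uniformly random coding gene (control).

    Genes are drawn without replacement when enough are available, matching
    the group size; the result feeds the denominator of the relative-density
    curve.
    """
    rng = np.random.default_rng(seed)
    ids = [r if isinstance(r, str) else r.id for r in rnas]
    usable = [g for g in coding_ids if g in expr]
    if not usable:
        return []
    replace = len(usable) < len(ids)
    chosen = rng.choice(np.asarray(usable, dtype=object), size=len(ids), replace=replace)
    out = []
    for rid, gid in zip(ids, chosen):
        if rid not in expr:
            continue
        try:
            r = compute_pcc(expr[rid], expr[gid])
        except (UndefinedCorrelationError, ValueError):
            continue
        out.append(NeighborPair(rid, str(gid), "random", r))
    return out


def relative_density(
    pccs_group: Sequence[float],
    pccs_control: Sequence[float],
    bandwidth: Optional[float | str] = "silverman",
    grid: Optional[np.ndarray] = None,
    floor: float = DENSITY_FLOOR,
) -> RelativeDensityCurve:
    """Density ratio of group PCC values over the random control.

    Gaussian kernel density of each collection evaluated on a common grid
    (default 201 points on [-1, 1], Silverman bandwidth); the ratio is
    group/control with the control floored at ``floor``.  Grid points where
    the control hit the floor are flagged.
    """
    g = np.asarray(pccs_group, dtype=float)
    c = np.asarray(pccs_control, dtype=float)
    if len(g) < 20 or len(c) < 20:
        raise ValueError("need at least 20 PCC values in each collection")
    if grid is None:
        grid = np.linspace(-1.0, 1.0, 201)
    kde_g = stats.gaussian_kde(g, bw_method=bandwidth)
    kde_c = stats.gaussian_kde(c, bw_method=bandwidth)
    dg = kde_g(grid)
    dc = kde_c(grid)
    floored = dc < floor
    ratio = dg / np.maximum(dc, floor)
    return RelativeDensityCurve(
        grid=np.asarray(grid), density_group=dg, density_control=dc,
        ratio=ratio, floored=floored,
    )


def fraction_beyond_cutoff(
    pairs: Sequence[NeighborPair] | Sequence[float], cutoff: float = 0.8
) -> tuple[float, float]:
    """Fractions of pairs with PCC >= cutoff and PCC <= -cutoff (inclusive)."""
    if len(pairs) == 0:
        raise ValueError("empty pair collection")
    pccs = np.asarray(
        [p.pcc if isinstance(p, NeighborPair) else float(p) for p in pairs]
    )
    return (
        float(np.mean(pccs >= cutoff)),
        float(np.mean(pccs <= -cutoff)),
    )


def pairs_to_frame(pairs: Sequence[NeighborPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.rna_id, p.gene_id, p.side, p.pcc) for p in pairs],
        columns=["rna_id", "gene_id", "side", "pcc"],
    )
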