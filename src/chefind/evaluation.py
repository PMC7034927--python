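"""Pipeline-comparison metrics: ROC/AUC, canonical-locus PPV, R1 specificity,
and the spike-in-normalized qPCR abundance.

The proxy gold standard for ROC evaluation is the set of transcripts called
by all compared methods; the default ranking statistic is the signed
-log10(FDR) from the enrichment stage (sign of the log2 fold-change), with
missing scores ranked below every present score.  PPV is the fraction of
canonical loci whose predicted chromatin class matches the expectation.  R1
is the fraction of a cell type's identifications found in no other cell
type.  RT-qPCR abundances are A = 2^(−ΔCq) with ΔCq = Cq − Cq_spike.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _roc_curve, auc as _auc

from chefind.genome import TranscriptModel


@dataclass
class ProxyGoldStandard:
    """Positives = ids called by all compared methods; universe = scored ids."""

    positive_ids: set[str]
    universe: set[str]

    def __post_init__(self) -> None:
        if not self.positive_ids <= self.universe:
            raise ValueError("positive ids must be a subset of the universe")

    @classmethod
    def from_calls(
        cls, calls_by_method: Mapping[str, set[str]], universe: set[str]
    ) -> "ProxyGoldStandard":
        sets = list(calls_by_method.values())
        common = set.intersection(*sets) if sets else set()
        return cls(positive_ids=common & universe, universe=universe)


@dataclass
class CanonicalLocusSet:
    """Canonical loci with experimentally expected chromatin classes."""

    expected: dict[str, str]  # locus id -> cheRNA | sneRNA | independent


@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    n_missing: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr})


def signed_score(calls: pd.DataFrame, direction: str = "cheRNA") -> pd.Series:
    """Default ROC ranking statistic: signed -log10(fdr) from enrichment calls.

    For ``direction='cheRNA'`` high scores mean confidently CPE-enriched;
    ``'sneRNA'`` negates the sign so SNE-enrichment ranks high.
    """
    eps = np.finfo(float).tiny
    s = -np.log10(np.maximum(calls["fdr"].to_numpy(float), eps)) * np.sign(
        calls["log2fc"].to_numpy(float)
    )
    if direction == "sneRNA":
        s = -s
    elif direction != "cheRNA":
        raise ValueError("direction must be 'cheRNA' or 'sneRNA'")
    return pd.Series(s, index=calls.index)


def roc_auc(scores: Mapping[str, float] | pd.Series, gs: ProxyGoldStandard) -> ROCResult:
    """ROC curve and trapezoid AUC of a ranking against the proxy gold standard.

    Every id in the universe is evaluated; ids without a score receive a
    worst (below-minimum) score and are counted in ``n_missing``.
    """
    scores = pd.Series(scores)
    universe = sorted(gs.universe)
    present = scores.reindex(universe)
    n_missing = int(present.isna().sum())
    worst = float(present.min() - 1.0) if present.notna().any() else -1.0
    y_score = present.fillna(worst).to_numpy()
    y_true = np.array([tid in gs.positive_ids for tid in universe], dtype=int)
    if y_true.sum() == 0 or y_true.sum() == len(y_true):
        raise ValueError("need both positives and negatives in the universe")
    fpr, tpr, thr = _roc_curve(y_true, y_score)
    return ROCResult(fpr=fpr, tpr=tpr, thresholds=thr, auc=float(_auc(fpr, tpr)),
                     n_missing=n_missing)


def ppv_canonical(
    calls: Mapping[str, str], truth: CanonicalLocusSet
) -> float:
    """Fraction of canonical loci predicted with the expected class.

    Loci without a prediction count as wrong.
    """
    if not truth.expected:
        raise ValueError("empty canonical locus set")
    correct = sum(
        1 for locus, exp in truth.expected.items() if calls.get(locus) == exp
    )
    return correct / len(truth.expected)


def r1_specificity(
    sets_by_celltype: Mapping[str, set[str]], focal: str
) -> float:
    """R1 = cell-type-exclusive identifications / all identifications (focal).

    Requires at least two cell types; the focal set must be nonempty.
    """
    if focal not in sets_by_celltype:
        raise ValueError(f"focal cell type {focal!r} not present")
    if len(sets_by_celltype) < 2:
        raise ValueError("need at least two cell types")
    focal_set = set(sets_by_celltype[focal])
    if not focal_set:
        raise ValueError("focal set is empty")
    others = set().union(
        *(s for ct, s in sets_by_celltype.items() if ct != focal)
    )
    return len(focal_set - others) / len(focal_set)


def deduplicate_across_celltypes(
    transcripts_by_celltype: Mapping[str, Sequence[TranscriptModel]],
    min_reciprocal: float = 0.5,
) -> dict[str, set[str]]:
    """Greedy coordinate-based id unification across cell types.

    Assembled coordinates of the same locus can differ slightly between cell
    types; transcripts from different cell types with reciprocal span
    overlap >= ``min_reciprocal`` (same chrom/strand) are assigned a shared
    id (that of the first cell type encountered) before R1 set arithmetic.
    """
    canonical: list[TranscriptModel] = []
    out: dict[str, set[str]] = {}
    for ct, transcripts in transcripts_by_celltype.items():
        ids = set()
        for t in transcripts:
            match = None
            for c in canonical:
                if c.chrom != t.chrom or c.strand != t.strand:
                    continue
                ov = min(c.end, t.end) - max(c.start, t.start)
                if ov >= min_reciprocal * t.length and ov >= min_reciprocal * c.length:
                    match = c
                    break
            if match is None:
                canonical.append(t)
                ids.add(t.id)
            else:
                ids.add(match.id)
        out[ct] = ids
    return out


def spike_normalized_abundance(cq: float, cq_spike: float) -> float:
    """qPCR abundance A = 2^(−ΔCq), ΔCq = Cq − Cq_spike (spike-in control)."""
    if not (np.isfinite(cq) and np.isfinite(cq_spike)):
        raise ValueError("Cq values must be finite")
    return float(2.0 ** (-(cq - cq_spike)))
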