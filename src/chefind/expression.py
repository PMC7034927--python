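"""Count normalization (CPM/FPKM) and the empirical noise filter.

Lowly expressed assembled transcripts are overwhelmingly experimental noise;
rather than a hard length cutoff, transcripts with CPM >= 1 in at least half
of the fractionated samples are defined as "expressed" and kept for all
downstream analyses.  Library sizes default to the column sums of the
supplied matrix; externally determined totals can be passed instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

VALID_FRACTIONS = ("CPE", "SNE")


@dataclass
class CountMatrix:
    """Raw read counts over transcripts x fractionated samples.

    ``counts`` is a transcripts-by-samples DataFrame of non-negative integers;
    ``sample_sheet`` is indexed by sample id with at least a ``fraction``
    column taking values CPE (chromatin pellet extract) or SNE (soluble
    nuclear extract), plus ``cell_type`` and ``replicate``.
    """

    counts: pd.DataFrame
    sample_sheet: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.columns.duplicated().any():
            raise ValueError("sample ids must be unique")
        if self.counts.index.duplicated().any():
            raise ValueError("transcript ids must be unique")
        missing = set(self.counts.columns) - set(self.sample_sheet.index)
        if missing:
            raise ValueError(f"samples missing from sample sheet: {sorted(missing)}")
        if "fraction" not in self.sample_sheet.columns:
            raise ValueError("sample sheet must have a 'fraction' column")
        bad = set(self.sample_sheet.loc[list(self.counts.columns), "fraction"]) - set(
            VALID_FRACTIONS
        )
        if bad:
            raise ValueError(f"unknown fraction labels: {sorted(bad)}")
        self.sample_sheet = self.sample_sheet.loc[list(self.counts.columns)]

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def fraction_samples(self, fraction: str) -> list[str]:
        return list(self.sample_sheet.index[self.sample_sheet["fraction"] == fraction])

    def subset(self, transcript_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(transcript_ids)], self.sample_sheet)

    def swap_fractions(self) -> "CountMatrix":
        """Return a copy with CPE and SNE labels exchanged (for symmetry checks)."""
        sheet = self.sample_sheet.copy()
        sheet["fraction"] = sheet["fraction"].map({"CPE": "SNE", "SNE": "CPE"})
        return CountMatrix(self.counts.copy(), sheet)

    @classmethod
    def from_tsv(cls, counts_path: str | Path, sheet_path: str | Path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0, comment="#")
        sheet = pd.read_csv(sheet_path, sep="\t", index_col=0, comment="#")
        return cls(counts, sheet)

    def to_tsv(self, counts_path: str | Path, sheet_path: str | Path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="transcript_id")
        self.sample_sheet.to_csv(sheet_path, sep="\t", index_label="sample_id")


@dataclass
class ExpressionSummary:
    cpm: pd.DataFrame
    fpkm: Optional[pd.DataFrame]
    expressed_ids: list[str]


def _library_sizes(
    counts: pd.DataFrame, lib_sizes: Optional[Sequence[float]]
) -> np.ndarray:
    if lib_sizes is None:
        sizes = counts.sum(axis=0).to_numpy(dtype=float)
    else:
        sizes = np.asarray(lib_sizes, dtype=float)
        if len(sizes) != counts.shape[1]:
            raise ValueError("lib_sizes length must match sample count")
    if (sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    return sizes


def compute_cpm(
    m: CountMatrix, lib_sizes: Optional[Sequence[float]] = None
) -> pd.DataFrame:
    """Counts per million: counts[i,j] / lib_size[j] * 1e6."""
    sizes = _library_sizes(m.counts, lib_sizes)
    return m.counts / sizes * 1e6


def compute_fpkm(
    m: CountMatrix,
    lengths: pd.Series | dict[str, float],
    lib_sizes: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped reads."""
    sizes = _library_sizes(m.counts, lib_sizes)
    lengths = pd.Series(lengths).reindex(m.counts.index)
    if lengths.isna().any():
        raise ValueError("lengths missing for some transcripts")
    if (lengths <= 0).any():
        raise ValueError("lengths must be >= 1")
    return m.counts.div(lengths / 1e3, axis=0) / (sizes / 1e6)


def filter_expressed(
    cpm: pd.DataFrame, threshold: float = 1.0, min_fraction: float = 0.5
) -> list[str]:
    """Transcripts with CPM >= threshold in at least ``min_fraction`` of samples.

    A transcript is kept iff the number of samples with CPM >= threshold is
    at least ``ceil(min_fraction * n_samples)``.  Defaults implement the
    empirical noise filter (CPM >= 1 in at least half of the samples).
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    need = math.ceil(min_fraction * cpm.shape[1])
    n_pass = (cpm >= threshold).sum(axis=1)
    return list(cpm.index[n_pass >= need])


def summarize_expression(
    m: CountMatrix,
    lengths: Optional[pd.Series | dict[str, float]] = None,
    threshold: float = 1.0,
    min_fraction: float = 0.5,
    lib_sizes: Optional[Sequence[float]] = None,
) -> ExpressionSummary:
    """CPM (and FPKM when lengths are given) plus the expressed subset."""
    cpm = compute_cpm(m, lib_sizes)
    fpkm = compute_fpkm(m, lengths, lib_sizes) if lengths is not None else None
    expressed = filter_expressed(cpm, threshold=threshold, min_fraction=min_fraction)
    return ExpressionSummary(cpm=cpm, fpkm=fpkm, expressed_ids=expressed)


def log_expression(
    values: pd.DataFrame, prior: float = 0.5, base: float = 2.0
) -> pd.DataFrame:
    """log-scale expression with a pseudocount prior (plots and correlations)."""
    return np.log(values + prior) / np.log(base)
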