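"""Chromatin signal tracks and metagene profiles.

A :class:`SignalTrack` holds per-base coverage (reads-per-million scale) per
chromosome.  Metagene profiles average ChIP-versus-input ratios either in a
fixed window centered at the TSS (oriented 5'->3', reversed on the − strand)
or across transcript bodies scaled to a fixed number of bins plus
fixed-width flanks.  Averaging is across transcripts of per-transcript
binned means, so long transcripts do not dominate.  Transcripts are grouped
high/low for a mark by whether their span, extended by a proximity margin on
both sides, touches at least one called peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from chefind._stats import significance_tier
from chefind.genome import BedInterval, TranscriptModel


@dataclass
class SignalTrack:
    """Per-base coverage arrays keyed by chromosome, with a mark label."""

    data: dict[str, np.ndarray]
    label: str = ""

    def __post_init__(self) -> None:
        self.data = {c: np.asarray(v, dtype=float) for c, v in self.data.items()}
        for c, v in self.data.items():
            if (v < 0).any():
                raise ValueError(f"negative coverage on {c}")

    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(v) for c, v in self.data.items()}

    def total(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))

    def scaled(self, factor: float) -> "SignalTrack":
        return SignalTrack({c: v * factor for c, v in self.data.items()}, self.label)

    def to_rpm(self, total_reads: Optional[float] = None) -> "SignalTrack":
        """Scale so coverage sums to 1e6 (or by an external read total)."""
        tot = self.total() if total_reads is None else float(total_reads)
        if tot <= 0:
            raise ValueError("cannot RPM-scale an empty track")
        return self.scaled(1e6 / tot)

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_bedgraph(
        cls, path: str | Path, chrom_sizes: dict[str, int], label: str = ""
    ) -> "SignalTrack":
        data = {c: np.zeros(n, dtype=float) for c, n in chrom_sizes.items()}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("track", "#")):
                    continue
                chrom, s, e, v = line.split()[:4]
                if chrom in data:
                    data[chrom][int(s): int(e)] = float(v)
        return cls(data, label)

    def to_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.data):
                v = self.data[chrom]
                # run-length encode constant stretches
                change = np.flatnonzero(np.diff(v)) + 1
                starts = np.concatenate(([0], change))
                ends = np.concatenate((change, [len(v)]))
                for s, e in zip(starts, ends):
                    if v[s] != 0:
                        fh.write(f"{chrom}\t{s}\t{e}\t{v[s]:.6g}\n")

    @classmethod
    def from_bigwig(
        cls, path: str | Path, chrom_sizes: Optional[dict[str, int]] = None,
        label: str = "",
    ) -> "SignalTrack":
        import pyBigWig  # optional dependency

        bw = pyBigWig.open(str(path))
        sizes = chrom_sizes or dict(bw.chroms())
        data = {}
        for chrom, n in sizes.items():
            vals = np.nan_to_num(
                np.asarray(bw.values(chrom, 0, n), dtype=float), nan=0.0
            )
            data[chrom] = vals
        bw.close()
        return cls(data, label)


@dataclass
class PeakSet:
    intervals: list[BedInterval]
    mark: str = ""

    def by_chrom(self) -> dict[str, list[tuple[int, int]]]:
        out: dict[str, list[tuple[int, int]]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for c in out:
            out[c].sort()
        return out


@dataclass
class MetageneProfile:
    bins: np.ndarray  # bp offsets (tss mode) or scaled positions (body mode)
    mean_ratio: np.ndarray
    n_transcripts: int
    n_dropped: int = 0
    mode: str = "tss"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin": self.bins, "mean_ratio": self.mean_ratio})


def signal_vs_input(
    chip: SignalTrack, input_track: SignalTrack, pseudocount: float = 1.0
) -> SignalTrack:
    """Per-base ratio (chip + pc) / (input + pc); both tracks RPM-scaled."""
    if set(chip.data) != set(input_track.data) or any(
        len(chip.data[c]) != len(input_track.data[c]) for c in chip.data
    ):
        raise ValueError("chip and input tracks cover different chromosome spaces")
    return SignalTrack(
        {
            c: (chip.data[c] + pseudocount) / (input_track.data[c] + pseudocount)
            for c in chip.data
        },
        label=f"{chip.label}_vs_input" if chip.label else "ratio",
    )


def _tss_window_values(
    track: SignalTrack, t: TranscriptModel, half_window: int
) -> Optional[np.ndarray]:
    arr = track.data.get(t.chrom)
    if arr is None:
        return None
    lo, hi = t.tss - half_window, t.tss + half_window
    if lo < 0 or hi > len(arr):
        return None
    w = arr[lo:hi]
    return w[::-1] if t.strand == "-" else w


def tss_profile(
    track: SignalTrack,
    transcripts: Iterable[TranscriptModel],
    half_window: int = 1000,
    bin_size: int = 50,
) -> MetageneProfile:
    """Average signal in a +/-half_window window centered at each TSS.

    Windows are oriented 5'->3' (reversed for − strand transcripts), binned
    by the mean within ``bin_size`` bp bins, then averaged across
    transcripts.  Transcripts whose window leaves the chromosome are dropped
    and counted.
    """
    if 2 * half_window % bin_size != 0:
        raise ValueError("window width must be a multiple of bin_size")
    n_bins = 2 * half_window // bin_size
    rows = []
    dropped = 0
    for t in transcripts:
        w = _tss_window_values(track, t, half_window)
        if w is None:
            dropped += 1
            continue
        rows.append(w.reshape(n_bins, bin_size).mean(axis=1))
    if not rows:
        raise ValueError("no usable transcripts for the TSS profile")
    offsets = np.arange(n_bins) * bin_size - half_window + bin_size // 2
    return MetageneProfile(
        bins=offsets,
        mean_ratio=np.vstack(rows).mean(axis=0),
        n_transcripts=len(rows),
        n_dropped=dropped,
        mode="tss",
    )


def _scaled_body_means(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Mean of per-base values over n_bins equal-width segments (exact, via cumsum)."""
    cs = np.concatenate(([0.0], np.cumsum(values)))
    bounds = np.linspace(0.0, len(values), n_bins + 1)
    ends = np.interp(bounds, np.arange(len(cs)), cs)
    widths = np.diff(bounds)
    return np.diff(ends) / widths


def body_profile(
    track: SignalTrack,
    transcripts: Iterable[TranscriptModel],
    n_bins: int = 100,
    flank: int = 1000,
    flank_bins: int = 10,
) -> MetageneProfile:
    """Average signal across transcript bodies scaled to ``n_bins`` bins.

    Each body is divided into ``n_bins`` equal-width segments (plus
    ``flank_bins`` fixed-width bins over each ``flank``-bp flank), the mean
    taken per segment, the layout reversed for − strand transcripts, and the
    result averaged across transcripts.  Transcripts shorter than ``n_bins``
    bases (or whose flanks leave the chromosome) are dropped and counted.
    """
    if flank and flank % flank_bins != 0:
        raise ValueError("flank must be a multiple of flank_bins")
    rows = []
    dropped = 0
    for t in transcripts:
        arr = track.data.get(t.chrom)
        if arr is None or t.length < n_bins:
            dropped += 1
            continue
        lo, hi = t.start - flank, t.end + flank
        if lo < 0 or hi > len(arr):
            dropped += 1
            continue
        left = arr[lo: t.start].reshape(flank_bins, -1).mean(axis=1) if flank else np.array([])
        body = _scaled_body_means(arr[t.start: t.end], n_bins)
        right = arr[t.end: hi].reshape(flank_bins, -1).mean(axis=1) if flank else np.array([])
        prof = np.concatenate([left, body, right])
        if t.strand == "-":
            prof = prof[::-1]
        rows.append(prof)
    if not rows:
        raise ValueError("no usable transcripts for the body profile")
    nb_flank = flank_bins if flank else 0
    positions = np.concatenate(
        [
            -flank + (np.arange(nb_flank) + 0.5) * (flank / max(nb_flank, 1)),
            (np.arange(n_bins) + 0.5) / n_bins * 100.0,  # percent of body
            100.0 + (np.arange(nb_flank) + 0.5) * (flank / max(nb_flank, 1)),
        ]
    )
    return MetageneProfile(
        bins=positions,
        mean_ratio=np.vstack(rows).mean(axis=0),
        n_transcripts=len(rows),
        n_dropped=dropped,
        mode="body",
    )


def group_by_mark(
    transcripts: Iterable[TranscriptModel],
    peaks: PeakSet,
    proximity: int = 1000,
) -> dict[str, list[TranscriptModel]]:
    """Partition transcripts into high/low groups for a chromatin mark.

    ``high``: the transcript span extended by ``proximity`` bp on both sides
    intersects at least one peak (>= 1 base); ``low``: the rest.  With
    proximity 0 this reduces to span overlap with peaks.
    """
    if not peaks.intervals:
        raise ValueError("peak set is empty")
    by_chrom = peaks.by_chrom()
    starts = {c: np.array([s for s, _ in ivs]) for c, ivs in by_chrom.items()}
    ends = {c: np.array([e for _, e in ivs]) for c, ivs in by_chrom.items()}
    high, low = [], []
    for t in transcripts:
        lo, hi = t.start - proximity, t.end + proximity
        s = starts.get(t.chrom)
        hit = bool(s is not None and np.any((s < hi) & (ends[t.chrom] > lo)))
        (high if hit else low).append(t)
    return {"high": high, "low": low}


@dataclass
class GroupComparison:
    values_a: np.ndarray
    values_b: np.ndarray
    pvalue: float
    tier: str


def compare_groups_at_tss(
    ratio_track: SignalTrack,
    group_a: Sequence[TranscriptModel],
    group_b: Sequence[TranscriptModel],
    half_window: int = 1000,
) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum comparison of per-transcript TSS signal.

    Each transcript contributes its mean signal-vs-input ratio within the
    +/-half_window TSS window; the two groups (each >= 5 usable transcripts)
    are compared with the rank-sum test and the p-value mapped to the legend
    significance tier.
    """

    def group_means(group: Sequence[TranscriptModel]) -> np.ndarray:
        vals = []
        for t in group:
            w = _tss_window_values(ratio_track, t, half_window)
            if w is not None:
                vals.append(w.mean())
        return np.asarray(vals)

    a = group_means(group_a)
    b = group_means(group_b)
    if len(a) < 5 or len(b) < 5:
        raise ValueError("each group needs >= 5 usable transcripts")
    p = float(stats.ranksums(a, b).pvalue)
    return GroupComparison(values_a=a, values_b=b, pvalue=p, tier=significance_tier(p))
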