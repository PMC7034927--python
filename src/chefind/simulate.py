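"""Synthetic fixture generator with known ground truth.

Emulates the statistical structure of a nuclear-fractionation RNA-seq study
on toy chromosomes: protein-coding genes spaced along each chromosome,
intergenic lncRNAs and noise fragments placed in the gaps, antisense
lncRNAs inside coding genes on the opposite strand.  Counts follow a
negative-binomial model (variance mu + phi*mu^2) with planted CPE/SNE
fold-changes per chromatin class, sub-threshold means for noise
transcripts, and a shared latent factor inducing neighbor-gene expression
correlation.  ChIP/input track pairs carry Gaussian-shaped peaks flanking
the TSS of designated "high-mark" transcripts (the signal dips at the TSS
itself), with matching BED peak calls; motif intervals are planted inside
transcript spans at class-dependent containment rates.

All randomness flows from the single mandatory seed; two runs with the same
configuration produce byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from chefind.expression import CountMatrix
from chefind.genome import (
    BedInterval,
    GenomeAnnotation,
    TranscriptModel,
    write_bed,
    write_gtf,
)
from chefind.signaltrack import PeakSet, SignalTrack


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic fixture.

    Defaults: 160 coding genes, 100 intergenic and 40 antisense lncRNAs (300
    expressed transcripts) plus 700 sub-threshold noise fragments on four
    1-Mb chromosomes; planted |log2FC| = 2 between fractions, NB dispersion
    0.1, five replicates per fraction; half of the intergenic lncRNAs carry
    flanking H3K9me3-style peaks; one motif family is planted at elevated
    containment rate in cheRNA transcripts.
    """

    seed: int
    n_chroms: int = 4
    chrom_length: int = 1_000_000
    n_coding: int = 160
    n_intergenic: int = 100
    n_antisense: int = 40
    n_noise: int = 700
    planted_log2fc: float = 2.0
    nb_dispersion: float = 0.1
    n_replicates: int = 5
    cell_type: str = "simcell"
    # class mix among expressed transcripts
    lnc_class_probs: tuple[float, float, float] = (0.4, 0.4, 0.2)  # che, sne, ind
    coding_class_probs: tuple[float, float, float] = (0.15, 0.15, 0.70)
    # expression model
    base_mean: float = 200.0
    base_sigma: float = 0.8
    noise_mean: float = 0.05
    lib_sigma: float = 0.1
    # neighbor-correlation latent factor
    neighbor_effect: float = 0.8
    # chromatin signal
    high_mark_fraction: float = 0.5
    peak_amplitude: float = 4.0
    peak_offset: int = 400
    peak_sigma: int = 150
    mark: str = "H3K9me3"
    # motifs
    n_motif_families: int = 6
    motif_rate_background: float = 0.08
    motif_rate_target: float = 0.35
    target_family: str = "fam01"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.nb_dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        for n in (self.n_coding, self.n_intergenic, self.n_antisense, self.n_noise):
            if n < 0:
                raise ValueError("counts must be >= 0")


@dataclass
class GroundTruth:
    """Per-transcript truth table consistent with the emitted files."""

    table: pd.DataFrame  # indexed by transcript id

    def ids(self, **criteria) -> list[str]:
        mask = pd.Series(True, index=self.table.index)
        for col, val in criteria.items():
            mask &= self.table[col] == val
        return list(self.table.index[mask])


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    annotation: GenomeAnnotation
    truth: GroundTruth
    counts: Optional[CountMatrix] = None
    input_track: Optional[SignalTrack] = None
    chip_track: Optional[SignalTrack] = None
    peaks: Optional[PeakSet] = None
    motif_bed: Optional[list[BedInterval]] = None


class GeometryError(ValueError):
    pass


# ---------------------------------------------------------------------------
# annotation


def _make_exons(rng: np.random.Generator, start: int, end: int) -> list[tuple[int, int]]:
    n = int(rng.integers(1, 4))
    if n == 1 or end - start < 400 * n:
        return [(start, end)]
    cuts = np.sort(rng.choice(np.arange(start + 100, end - 100), size=2 * (n - 1),
                              replace=False))
    exons = []
    s = start
    for i in range(n - 1):
        exons.append((s, int(cuts[2 * i])))
        s = int(cuts[2 * i + 1])
    exons.append((s, end))
    return [e for e in exons if e[1] > e[0]]


def simulate_annotation(cfg: SimulationConfig) -> tuple[GenomeAnnotation, GroundTruth]:
    """Place coding genes, lncRNAs and noise fragments on toy chromosomes.

    Coding genes alternate with gaps; intergenic lncRNAs and noise fragments
    are placed inside gaps with a >= 1.5 kb margin from genes (so they never
    overlap coding loci); antisense lncRNAs sit strictly inside a coding
    gene's span on the opposite strand.  Raises :class:`GeometryError` when
    the requested transcripts do not fit.
    """
    rng = np.random.default_rng(cfg.seed)
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    chrom_sizes = {c: cfg.chrom_length for c in chroms}

    transcripts: list[TranscriptModel] = []
    truth_rows: list[dict] = []
    gaps: list[tuple[str, int, int]] = []  # usable intergenic regions

    margin = 1500
    per_chrom = int(np.ceil(cfg.n_coding / cfg.n_chroms))
    gi = 0
    for chrom in chroms:
        cursor = 0
        n_here = min(per_chrom, cfg.n_coding - gi)
        for _ in range(n_here):
            gap = int(rng.integers(8000, 16000))
            glen = int(rng.integers(2000, 8000))
            if cursor + gap + glen + 8000 > cfg.chrom_length:
                raise GeometryError(
                    f"coding genes do not fit on {chrom}; increase chrom_length"
                )
            if gap > 2 * margin + 1000:
                gaps.append((chrom, cursor + margin, cursor + gap - margin))
            gstart = cursor + gap
            gend = gstart + glen
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"gene{gi + 1:04d}"
            transcripts.append(
                TranscriptModel(
                    id=gid, chrom=chrom, start=gstart, end=gend, strand=strand,
                    exons=_make_exons(rng, gstart, gend),
                    biotype="protein_coding", annotated=True, gene_id=gid,
                )
            )
            truth_rows.append(dict(transcript_id=gid, kind="coding",
                                   positional="sense_overlap"))
            cursor = gend
            gi += 1
        tail_gap = cfg.chrom_length - cursor
        if tail_gap > 2 * margin + 1000:
            gaps.append((chrom, cursor + margin, cfg.chrom_length - margin))

    # place intergenic lncRNAs and noise fragments into gaps
    slots = [[c, s, e] for c, s, e in gaps]
    spacing = 300

    def place(length: int) -> tuple[str, int, int]:
        order = rng.permutation(len(slots))
        for k in order:
            c, s, e = slots[k]
            if e - s >= length + spacing:
                slots[k][1] = s + length + spacing
                return c, s, s + length
        raise GeometryError("no gap large enough; reduce transcript numbers")

    for i in range(cfg.n_intergenic):
        length = int(rng.integers(500, 3000))
        c, s, e = place(length)
        tid = f"ilnc{i + 1:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        transcripts.append(
            TranscriptModel(id=tid, chrom=c, start=s, end=e, strand=strand,
                            biotype="other", annotated=bool(rng.random() < 0.5),
                            gene_id=tid)
        )
        truth_rows.append(dict(transcript_id=tid, kind="intergenic",
                               positional="intergenic"))

    coding_list = [t for t in transcripts if t.biotype == "protein_coding"]
    host_idx = rng.choice(len(coding_list), size=cfg.n_antisense, replace=False)
    for i, hi in enumerate(host_idx):
        host = coding_list[int(hi)]
        max_len = min(3000, host.length - 200)
        length = int(rng.integers(400, max(max_len, 401)))
        offset = int(rng.integers(0, host.length - length))
        s = host.start + offset
        tid = f"aslnc{i + 1:04d}"
        strand = "-" if host.strand == "+" else "+"
        transcripts.append(
            TranscriptModel(id=tid, chrom=host.chrom, start=s, end=s + length,
                            strand=strand, biotype="other",
                            annotated=bool(rng.random() < 0.5), gene_id=tid)
        )
        truth_rows.append(dict(transcript_id=tid, kind="antisense",
                               positional="antisense"))

    for i in range(cfg.n_noise):
        length = int(rng.integers(200, 800))
        c, s, e = place(length)
        tid = f"noise{i + 1:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        transcripts.append(
            TranscriptModel(id=tid, chrom=c, start=s, end=e, strand=strand,
                            biotype="other", annotated=False, gene_id=tid)
        )
        truth_rows.append(dict(transcript_id=tid, kind="noise",
                               positional="intergenic"))

    annotation = GenomeAnnotation.from_transcripts(transcripts, chrom_sizes)
    truth = pd.DataFrame(truth_rows).set_index("transcript_id")
    truth["expressed"] = truth["kind"] != "noise"

    # chromatin class assignment
    classes = []
    for tid, row in truth.iterrows():
        if row["kind"] == "noise":
            classes.append("noise")
        elif row["kind"] == "coding":
            classes.append(
                str(rng.choice(["cheRNA", "sneRNA", "independent"],
                               p=cfg.coding_class_probs))
            )
        else:
            classes.append(
                str(rng.choice(["cheRNA", "sneRNA", "independent"],
                               p=cfg.lnc_class_probs))
            )
    truth["true_class"] = classes
    lfc = {"cheRNA": cfg.planted_log2fc, "sneRNA": -cfg.planted_log2fc}
    truth["true_log2fc"] = [lfc.get(c, 0.0) for c in truth["true_class"]]

    # neighbor designation for intergenic lncRNAs: nearest same-strand
    # flanking gene; each gene serves at most one lncRNA
    truth["neighbor_gene"] = ""
    truth["corr_sign"] = 0
    used_genes: set[str] = set()
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for g in coding_list:
        by_chrom.setdefault(g.chrom, []).append(g)
    for t in transcripts:
        if truth.loc[t.id, "kind"] != "intergenic":
            continue
        best, best_gap = None, None
        for g in by_chrom.get(t.chrom, []):
            if g.strand != t.strand or g.id in used_genes:
                continue
            if g.end <= t.start:
                gap = t.start - g.end
            elif g.start >= t.end:
                gap = g.start - t.end
            else:
                continue
            if best_gap is None or gap < best_gap:
                best, best_gap = g, gap
        if best is None:
            continue
        cls = truth.loc[t.id, "true_class"]
        sign = 1 if cls == "cheRNA" else (-1 if cls == "sneRNA" else 0)
        if sign != 0:
            used_genes.add(best.id)
            truth.loc[t.id, "neighbor_gene"] = best.id
            truth.loc[t.id, "corr_sign"] = sign

    # high/low mark designation over intergenic lncRNAs (resolved to the
    # final grouping once peaks are placed, see simulate_tracks)
    ilnc_ids = truth.index[truth["kind"] == "intergenic"].to_numpy()
    n_high = int(round(cfg.high_mark_fraction * len(ilnc_ids)))
    high_ids = set(rng.choice(ilnc_ids, size=n_high, replace=False))
    truth["mark_designated"] = [tid in high_ids for tid in truth.index]
    truth["mark_group"] = ""

    # motif families planted inside transcript spans
    families = [f"fam{i + 1:02d}" for i in range(cfg.n_motif_families)]
    fam_lists: dict[str, list[str]] = {tid: [] for tid in truth.index}
    noncoding = truth.index[truth["kind"].isin(["intergenic", "antisense"])]
    for fam in families:
        for tid in noncoding:
            rate = cfg.motif_rate_background
            if fam == cfg.target_family and truth.loc[tid, "true_class"] == "cheRNA":
                rate = cfg.motif_rate_target
            if rng.random() < rate:
                fam_lists[tid].append(fam)
    truth["motif_families"] = [";".join(fam_lists[tid]) for tid in truth.index]

    return annotation, GroundTruth(truth)


# ---------------------------------------------------------------------------
# counts


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB draws with variance mu + phi*mu^2 (gamma-Poisson mixture)."""
    mean = np.maximum(mean, 1e-12)
    shape = 1.0 / phi
    lam = rng.gamma(shape, mean / shape)
    return rng.poisson(lam)


def _sample_sheet(cfg: SimulationConfig) -> pd.DataFrame:
    rows = []
    for frac in ("CPE", "SNE"):
        for r in range(1, cfg.n_replicates + 1):
            rows.append((f"{frac}_{r}", frac, cfg.cell_type, r))
    return pd.DataFrame(
        rows, columns=["sample_id", "fraction", "cell_type", "replicate"]
    ).set_index("sample_id")


def simulate_counts(cfg: SimulationConfig, truth: GroundTruth) -> CountMatrix:
    """NB counts over CPE/SNE replicates with planted fold-changes.

    cheRNA-truth transcripts have a CPE:SNE mean ratio of 2^log2fc, sneRNA
    the inverse, independent transcripts none; noise transcripts get
    sub-threshold means.  Each designated intergenic lncRNA shares a latent
    log-normal factor with its neighbor gene (sign per the truth table),
    inducing the planted expression correlation.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    sheet = _sample_sheet(cfg)
    tab = truth.table
    n_samples = len(sheet)

    base = pd.Series(
        np.where(
            tab["true_class"].to_numpy() == "noise",
            cfg.noise_mean,
            rng.lognormal(np.log(cfg.base_mean), cfg.base_sigma, size=len(tab)),
        ),
        index=tab.index,
    )
    lib_factors = rng.lognormal(0.0, cfg.lib_sigma, size=n_samples)
    is_cpe = (sheet["fraction"] == "CPE").to_numpy()

    # latent factors shared between designated lncRNA/gene pairs
    latent = {}
    w = cfg.neighbor_effect
    for tid, row in tab.iterrows():
        if row.get("corr_sign", 0) != 0 and row.get("neighbor_gene"):
            z = rng.standard_normal(n_samples)
            latent[tid] = np.exp(w * z - 0.5 * w * w)
            latent[row["neighbor_gene"]] = np.exp(
                row["corr_sign"] * w * z - 0.5 * w * w
            )

    counts = np.zeros((len(tab), n_samples), dtype=int)
    half = 0.5 * cfg.planted_log2fc
    for i, (tid, row) in enumerate(tab.iterrows()):
        mult = np.ones(n_samples)
        if row["true_class"] == "cheRNA":
            mult = np.where(is_cpe, 2.0 ** half, 2.0 ** -half)
        elif row["true_class"] == "sneRNA":
            mult = np.where(is_cpe, 2.0 ** -half, 2.0 ** half)
        mean = base[tid] * mult * lib_factors
        if tid in latent:
            mean = mean * latent[tid]
        counts[i] = _nb_draw(rng, mean, cfg.nb_dispersion)

    df = pd.DataFrame(counts, index=tab.index, columns=sheet.index)
    return CountMatrix(df, sheet)


def simulate_class_counts(
    n_che: int = 200,
    n_sne: int = 200,
    n_null: int = 600,
    log2fc: float = 2.0,
    dispersion: float = 0.1,
    n_replicates: int = 5,
    seed: int = 1,
    base_mean: float = 200.0,
    base_sigma: float = 0.8,
) -> tuple[CountMatrix, pd.Series]:
    """Counts-only simulation with planted enrichment classes.

    Convenience wrapper for calibration studies: ``n_che`` transcripts at
    CPE:SNE ratio 2^log2fc, ``n_sne`` at the inverse, ``n_null`` with no
    difference; NB dispersion and replicate numbers as given.  Returns the
    count matrix and the per-transcript truth labels.
    """
    labels = (["cheRNA"] * n_che) + (["sneRNA"] * n_sne) + (["independent"] * n_null)
    ids = [f"t{i + 1:05d}" for i in range(len(labels))]
    tab = pd.DataFrame({"true_class": labels, "kind": "sim"}, index=ids)
    tab["expressed"] = True
    cfg = SimulationConfig(
        seed=seed,
        planted_log2fc=log2fc,
        nb_dispersion=dispersion,
        n_replicates=n_replicates,
        base_mean=base_mean,
        base_sigma=base_sigma,
    )
    m = simulate_counts(cfg, GroundTruth(tab))
    return m, tab["true_class"]


def simulate_pcc_mixture(
    n_pairs: int = 200,
    strong_fraction: float = 0.25,
    strong_rho: float = 0.95,
    n_samples: int = 30,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sampled pair correlations: a planted strong-positive mixture.

    A fraction of pairs is drawn from a bivariate normal with correlation
    ``strong_rho``; the rest are independent.  Returns the measured PCC
    values and the boolean planted-strong indicator.
    """
    rng = np.random.default_rng(seed)
    n_strong = int(round(strong_fraction * n_pairs))
    strong = np.zeros(n_pairs, dtype=bool)
    strong[:n_strong] = True
    pccs = np.empty(n_pairs)
    for i in range(n_pairs):
        rho = strong_rho if strong[i] else 0.0
        x = rng.standard_normal(n_samples)
        y = rho * x + np.sqrt(1 - rho ** 2) * rng.standard_normal(n_samples)
        pccs[i] = np.corrcoef(x, y)[0, 1]
    return pccs, strong


# ---------------------------------------------------------------------------
# tracks, peaks, motifs


def simulate_tracks(
    cfg: SimulationConfig, annotation: GenomeAnnotation, truth: GroundTruth
) -> tuple[SignalTrack, SignalTrack, PeakSet]:
    """Input/ChIP track pair plus peak calls for the configured mark.

    The input track is smoothed positive noise around 1.  The ChIP track
    adds two Gaussian-shaped peaks flanking the TSS of each designated
    high-mark transcript (at +/-``peak_offset`` bp, width ``peak_sigma``)
    while leaving the TSS itself at input level, so the signal-vs-input
    profile dips at the TSS.  Matching peak intervals (+/-2 sigma around
    each summit) are emitted, and the truth table's ``mark_group`` column is
    resolved against the placed peaks for every transcript.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    sizes = annotation.chrom_sizes
    tile = 200

    def noise_track() -> dict[str, np.ndarray]:
        data = {}
        for c, n in sizes.items():
            tiles = rng.gamma(20.0, 0.05, size=n // tile + 1)
            data[c] = np.repeat(tiles, tile)[:n]
        return data

    input_data = noise_track()
    chip_data = {c: v.copy() for c, v in input_data.items()}

    peak_ivs: list[BedInterval] = []
    tab = truth.table
    designated = [
        annotation[tid] for tid in tab.index
        if bool(tab.loc[tid, "mark_designated"])
    ]
    sig = cfg.peak_sigma
    for t in designated:
        for summit in (t.tss - cfg.peak_offset, t.tss + cfg.peak_offset):
            lo = max(summit - 3 * sig, 0)
            hi = min(summit + 3 * sig, sizes[t.chrom])
            x = np.arange(lo, hi)
            chip_data[t.chrom][lo:hi] += cfg.peak_amplitude * np.exp(
                -0.5 * ((x - summit) / sig) ** 2
            )
            peak_ivs.append(
                BedInterval(t.chrom, max(summit - 2 * sig, 0),
                            min(summit + 2 * sig, sizes[t.chrom]),
                            name=cfg.mark, score=cfg.peak_amplitude, strand=".")
            )

    peak_ivs.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    peaks = PeakSet(intervals=peak_ivs, mark=cfg.mark)

    # resolve the final mark grouping against the placed peaks
    proximity = 1000
    groups = []
    for tid in tab.index:
        t = annotation[tid]
        lo, hi = t.start - proximity, t.end + proximity
        hit = any(
            iv.chrom == t.chrom and iv.start < hi and iv.end > lo
            for iv in peak_ivs
        )
        groups.append("high" if hit else "low")
    tab["mark_group"] = groups

    input_track = SignalTrack(input_data, label="input")
    chip_track = SignalTrack(chip_data, label=cfg.mark)
    return input_track, chip_track, peaks


def motif_intervals(
    cfg: SimulationConfig, annotation: GenomeAnnotation, truth: GroundTruth
) -> list[BedInterval]:
    """Motif BED intervals realizing the truth table's family assignments.

    Each assigned family places one short motif fully inside the transcript
    span on the same strand.
    """
    rng = np.random.default_rng(cfg.seed + 3)
    out = []
    for tid, fams in truth.table["motif_families"].items():
        if not fams:
            continue
        t = annotation[tid]
        for fam in fams.split(";"):
            mlen = int(rng.integers(60, min(200, t.length)))
            off = int(rng.integers(0, t.length - mlen + 1))
            out.append(
                BedInterval(t.chrom, t.start + off, t.start + off + mlen,
                            name=fam, score=0.0, strand=t.strand)
            )
    out.sort(key=lambda iv: (iv.chrom, iv.start, iv.end, iv.name))
    return out


# ---------------------------------------------------------------------------
# one-call dataset + file emission


def simulate_dataset(cfg: SimulationConfig, with_tracks: bool = True) -> SimulatedDataset:
    """Generate the full fixture in memory."""
    annotation, truth = simulate_annotation(cfg)
    counts = simulate_counts(cfg, truth)
    ds = SimulatedDataset(config=cfg, annotation=annotation, truth=truth,
                          counts=counts)
    if with_tracks:
        ds.input_track, ds.chip_track, ds.peaks = simulate_tracks(
            cfg, annotation, truth
        )
    ds.motif_bed = motif_intervals(cfg, annotation, truth)
    return ds


def emit_dataset(ds: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the fixture to disk (GTF, TSVs, bedGraph, BED, chrom.sizes)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gtf": outdir / "annotation.gtf",
        "counts": outdir / "counts.tsv",
        "samples": outdir / "samples.tsv",
        "truth": outdir / "truth.tsv",
        "chrom_sizes": outdir / "chrom.sizes",
        "motifs": outdir / "motifs.bed",
    }
    write_gtf(ds.annotation, paths["gtf"])
    ds.counts.to_tsv(paths["counts"], paths["samples"])
    ds.truth.table.to_csv(paths["truth"], sep="\t", index_label="transcript_id")
    with open(paths["chrom_sizes"], "w") as fh:
        for c, n in ds.annotation.chrom_sizes.items():
            fh.write(f"{c}\t{n}\n")
    write_bed(ds.motif_bed or [], paths["motifs"])
    if ds.input_track is not None:
        paths["input_bedgraph"] = outdir / "input.bedgraph"
        paths["chip_bedgraph"] = outdir / f"{ds.config.mark}.bedgraph"
        paths["peaks"] = outdir / f"{ds.config.mark}_peaks.bed"
        ds.input_track.to_bedgraph(paths["input_bedgraph"])
        ds.chip_track.to_bedgraph(paths["chip_bedgraph"])
        write_bed(ds.peaks.intervals, paths["peaks"])
    return paths
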