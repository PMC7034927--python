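"""End-to-end orchestration of the cheRNA analysis stages.

Stages are pure file-to-file transforms: each reads its inputs from the run
directory, writes one or more TSV outputs with a provenance header, and
never mutates another stage's outputs, so any downstream stage can be
re-run alone from cached upstream files with identical results.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

import chefind
from chefind import correlation as corr
from chefind import enrichment as enr
from chefind import evaluation as ev
from chefind import expression as expr
from chefind import motifstats as ms
from chefind import signaltrack as sig
from chefind.genome import (
    GenomeAnnotation,
    PositionalClass,
    read_bed,
    read_chrom_sizes,
    read_gtf,
)
from chefind.simulate import SimulationConfig, simulate_dataset, emit_dataset


@dataclass
class RunConfig:
    """All pipeline parameters with their module-level defaults."""

    outdir: str = "chefind_run"
    seed: int = 1
    # expression filter
    cpm_threshold: float = 1.0
    min_fraction: float = 0.5
    # enrichment
    alpha_fdr: float = 0.05
    dispersion_shrink: float = 0.7
    # correlation
    pcc_cutoff: float = 0.8
    same_strand_flanks: bool = True
    log_prior: float = 1.0
    # signal
    half_window: int = 1000
    tss_bin: int = 50
    ratio_pseudocount: float = 1.0
    mark_proximity: int = 1000
    # motif stats
    or_threshold: float = 2.0
    fisher_alpha: float = 0.05

    def config_hash(self) -> str:
        params = {k: v for k, v in asdict(self).items() if k != "outdir"}
        payload = json.dumps(params, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _log(msg: str) -> None:
    print(f"[chefind] {msg}", file=sys.stderr)


def write_table(df: pd.DataFrame, path: Path, cfg: RunConfig, stage: str,
                index_label: str = "transcript_id", **params) -> None:
    """TSV with a provenance header (version, config hash, stage parameters)."""
    with open(path, "w") as fh:
        fh.write(f"# chefind {chefind.__version__}\n")
        fh.write(f"# config_hash={cfg.config_hash()} stage={stage}\n")
        if params:
            kv = " ".join(f"{k}={v}" for k, v in sorted(params.items()))
            fh.write(f"# {kv}\n")
        df.to_csv(fh, sep="\t", index_label=index_label)


def read_table(path: str | Path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: RunConfig) -> dict[str, Path]:
    sim_cfg = SimulationConfig(seed=cfg.seed)
    ds = simulate_dataset(sim_cfg)
    return emit_dataset(ds, Path(cfg.outdir) / "fixture")


def stage_filter(cfg: RunConfig) -> Path:
    fx = Path(cfg.outdir) / "fixture"
    m = expr.CountMatrix.from_tsv(fx / "counts.tsv", fx / "samples.tsv")
    cpm = expr.compute_cpm(m)
    kept = expr.filter_expressed(cpm, cfg.cpm_threshold, cfg.min_fraction)
    out = Path(cfg.outdir) / "expressed.tsv"
    write_table(
        pd.DataFrame(index=pd.Index(kept, name="transcript_id")),
        out, cfg, "filter",
        cpm_threshold=cfg.cpm_threshold, min_fraction=cfg.min_fraction,
    )
    return out


def stage_call(cfg: RunConfig) -> Path:
    fx = Path(cfg.outdir) / "fixture"
    m = expr.CountMatrix.from_tsv(fx / "counts.tsv", fx / "samples.tsv")
    kept = list(read_table(Path(cfg.outdir) / "expressed.tsv").index)
    sub = m.subset(kept)
    disp = enr.estimate_dispersion(sub, shrink=cfg.dispersion_shrink)
    calls = enr.test_fraction_enrichment(sub, disp, alpha_fdr=cfg.alpha_fdr)
    out = Path(cfg.outdir) / "calls.tsv"
    write_table(calls, out, cfg, "call", alpha_fdr=cfg.alpha_fdr)
    return out


def stage_classify(cfg: RunConfig) -> Path:
    from chefind.genome import classify_positions

    fx = Path(cfg.outdir) / "fixture"
    ann = read_gtf(fx / "annotation.gtf")
    kept = list(read_table(Path(cfg.outdir) / "expressed.tsv").index)
    classes = classify_positions(
        [ann[t] for t in kept], ann.coding_genes
    )
    out = Path(cfg.outdir) / "positional.tsv"
    write_table(
        pd.DataFrame(
            {"positional_class": [classes[t].value for t in kept]},
            index=pd.Index(kept, name="transcript_id"),
        ),
        out, cfg, "classify",
    )
    return out


def stage_combine(cfg: RunConfig) -> Path:
    outdir = Path(cfg.outdir)
    calls = read_table(outdir / "calls.tsv")
    pos = read_table(outdir / "positional.tsv")
    classes = {
        t: PositionalClass(v) for t, v in pos["positional_class"].items()
    }
    combined = enr.combine_labels(calls, classes)
    table = calls.join(pos).assign(combined_label=combined)
    out = outdir / "labels.tsv"
    write_table(table, out, cfg, "combine")
    return out


def _expression_vectors(cfg: RunConfig, ann: GenomeAnnotation) -> dict[str, np.ndarray]:
    fx = Path(cfg.outdir) / "fixture"
    m = expr.CountMatrix.from_tsv(fx / "counts.tsv", fx / "samples.tsv")
    lengths = pd.Series({t.id: t.length for t in ann.transcripts.values()})
    fpkm = expr.compute_fpkm(m, lengths.reindex(m.counts.index))
    logf = expr.log_expression(fpkm, prior=cfg.log_prior)
    return {tid: logf.loc[tid].to_numpy() for tid in logf.index}


def stage_correlate(cfg: RunConfig) -> dict[str, Path]:
    outdir = Path(cfg.outdir)
    fx = outdir / "fixture"
    ann = read_gtf(fx / "annotation.gtf")
    labels = read_table(outdir / "labels.tsv")
    vectors = _expression_vectors(cfg, ann)

    iche = [ann[t] for t in labels.index[labels["combined_label"] == "icheRNA"]]
    pairs = corr.pair_all_neighbors(
        iche, ann, vectors, same_strand=cfg.same_strand_flanks
    )
    coding_ids = [g.id for g in ann.coding_genes]
    control = corr.random_control_pairs(
        [p.rna_id for p in pairs], coding_ids, vectors, seed=cfg.seed
    )
    paths = {}
    paths["pairs"] = outdir / "neighbor_pairs.tsv"
    write_table(
        corr.pairs_to_frame(pairs).set_index("rna_id"),
        paths["pairs"], cfg, "correlate", index_label="rna_id",
        same_strand=cfg.same_strand_flanks,
    )
    if len(pairs) >= 20 and len(control) >= 20:
        curve = corr.relative_density(
            [p.pcc for p in pairs], [p.pcc for p in control]
        )
        paths["curve"] = outdir / "relative_density.tsv"
        write_table(curve.to_frame().set_index("grid"), paths["curve"], cfg,
                    "correlate", index_label="grid")
    pos_frac, neg_frac = corr.fraction_beyond_cutoff(pairs, cfg.pcc_cutoff) \
        if pairs else (float("nan"), float("nan"))
    paths["fractions"] = outdir / "correlation_fractions.tsv"
    write_table(
        pd.DataFrame(
            {"value": [pos_frac, neg_frac, len(pairs)]},
            index=pd.Index(["pos_fraction", "neg_fraction", "n_pairs"],
                           name="metric"),
        ),
        paths["fractions"], cfg, "correlate", index_label="metric",
        cutoff=cfg.pcc_cutoff,
    )
    return paths


def stage_metagene(cfg: RunConfig) -> dict[str, Path]:
    outdir = Path(cfg.outdir)
    fx = outdir / "fixture"
    ann = read_gtf(fx / "annotation.gtf")
    sizes = read_chrom_sizes(fx / "chrom.sizes")
    sim_cfg = SimulationConfig(seed=cfg.seed)
    chip = sig.SignalTrack.from_bedgraph(
        fx / f"{sim_cfg.mark}.bedgraph", sizes, label=sim_cfg.mark
    )
    inp = sig.SignalTrack.from_bedgraph(fx / "input.bedgraph", sizes, label="input")
    ratio = sig.signal_vs_input(chip, inp, pseudocount=cfg.ratio_pseudocount)
    peaks = sig.PeakSet(read_bed(fx / f"{sim_cfg.mark}_peaks.bed"), mark=sim_cfg.mark)

    labels = read_table(outdir / "labels.tsv")
    iche_ids = list(labels.index[labels["positional_class"] == "intergenic"])
    groups = sig.group_by_mark(
        [ann[t] for t in iche_ids], peaks, proximity=cfg.mark_proximity
    )
    paths = {}
    rows = []
    for name, members in groups.items():
        if not members:
            continue
        prof = sig.tss_profile(ratio, members, cfg.half_window, cfg.tss_bin)
        df = prof.to_frame().assign(group=name, n=prof.n_transcripts)
        rows.append(df)
    paths["profiles"] = outdir / "tss_profiles.tsv"
    write_table(pd.concat(rows).set_index("bin"), paths["profiles"], cfg,
                "metagene", index_label="bin",
                half_window=cfg.half_window, bin=cfg.tss_bin,
                proximity=cfg.mark_proximity)
    if len(groups["high"]) >= 5 and len(groups["low"]) >= 5:
        comp = sig.compare_groups_at_tss(
            ratio, groups["high"], groups["low"], cfg.half_window
        )
        paths["comparison"] = outdir / "mark_group_comparison.tsv"
        write_table(
            pd.DataFrame(
                {"value": [len(groups["high"]), len(groups["low"]),
                           comp.pvalue, comp.tier]},
                index=pd.Index(["n_high", "n_low", "pvalue", "tier"],
                               name="metric"),
            ),
            paths["comparison"], cfg, "metagene", index_label="metric",
        )
    return paths


def stage_rr(cfg: RunConfig) -> Path:
    outdir = Path(cfg.outdir)
    fx = outdir / "fixture"
    ann = read_gtf(fx / "annotation.gtf")
    labels = read_table(outdir / "labels.tsv")
    families = ms.read_motif_bed(fx / "motifs.bed")
    noncoding = [
        ann[t] for t in labels.index
        if ann[t].biotype != "protein_coding"
    ]
    target = [
        t for t in labels.index
        if labels.loc[t, "chromatin_class"] == "cheRNA"
        and ann[t].biotype != "protein_coding"
    ]
    report = ms.rr_report(target, families, noncoding)
    out = outdir / "rr_scores.tsv"
    write_table(report.set_index("family"), out, cfg, "rr",
                index_label="family", target="noncoding_cheRNA")
    return out


def stage_fisher(cfg: RunConfig) -> Path:
    outdir = Path(cfg.outdir)
    fx = outdir / "fixture"
    ann = read_gtf(fx / "annotation.gtf")
    labels = read_table(outdir / "labels.tsv")
    families = ms.read_motif_bed(fx / "motifs.bed")
    sim_cfg = SimulationConfig(seed=cfg.seed)
    universe = [t for t in labels.index if ann[t].biotype != "protein_coding"]
    che = {t for t in universe if labels.loc[t, "chromatin_class"] == "cheRNA"}
    fam = families.get(sim_cfg.target_family)
    with_motif = ms.annotated_ids([ann[t] for t in universe], fam) if fam else set()
    res = ms.fisher_co_enrichment(che, with_motif, universe,
                                  cfg.or_threshold, cfg.fisher_alpha)
    out = outdir / "fisher.tsv"
    write_table(
        pd.DataFrame(
            {"value": [res.odds_ratio, res.pvalue, res.enriched,
                       *[x for row in res.table for x in row]]},
            index=pd.Index(
                ["odds_ratio", "pvalue", "enriched",
                 "n_both", "n_a_only", "n_b_only", "n_neither"],
                name="metric"),
        ),
        out, cfg, "fisher", index_label="metric",
    )
    return out


def stage_evaluate(cfg: RunConfig) -> Path:
    outdir = Path(cfg.outdir)
    fx = outdir / "fixture"
    truth = read_table(fx / "truth.tsv")
    calls = read_table(outdir / "calls.tsv")
    rows = {}
    for direction in ("cheRNA", "sneRNA"):
        scores = ev.signed_score(calls, direction)
        positives = set(truth.index[truth["true_class"] == direction]) & set(
            calls.index
        )
        gs = ev.ProxyGoldStandard(positive_ids=positives,
                                  universe=set(calls.index))
        rows[f"auc_{direction}"] = ev.roc_auc(scores, gs).auc
    truth_classes = ev.CanonicalLocusSet(
        expected=dict(truth.loc[truth["expressed"].astype(bool), "true_class"])
    )
    rows["ppv_expressed"] = ev.ppv_canonical(
        dict(calls["chromatin_class"]), truth_classes
    )
    out = outdir / "evaluation.tsv"
    write_table(
        pd.DataFrame({"value": list(rows.values())},
                     index=pd.Index(rows.keys(), name="metric")),
        out, cfg, "evaluate", index_label="metric",
    )
    return out


STAGES = [
    ("simulate", stage_simulate),
    ("filter", stage_filter),
    ("call", stage_call),
    ("classify", stage_classify),
    ("combine", stage_combine),
    ("correlate", stage_correlate),
    ("metagene", stage_metagene),
    ("rr", stage_rr),
    ("fisher", stage_fisher),
    ("evaluate", stage_evaluate),
]


def run_pipeline(cfg: RunConfig) -> Path:
    """Run every stage in order; returns the run directory."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, fn in STAGES:
        t0 = time.time()
        fn(cfg)
        _log(f"stage {name} done in {time.time() - t0:.1f}s")
    return outdir
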