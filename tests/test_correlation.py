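import numpy as np
import pytest

from chefind.correlation import (
    NeighborPair,
    UndefinedCorrelationError,
    compute_pcc,
    fraction_beyond_cutoff,
    pair_neighbor_gene,
    random_control_pairs,
    relative_density,
)
from chefind.genome import TranscriptModel
from chefind.simulate import simulate_pcc_mixture


def tmodel(id, start=0, end=100, strand="+"):
    return TranscriptModel(id=id, chrom="chr1", start=start, end=end,
                           strand=strand)


# ---------------------------------------------------------------------------
# Pearson correlation


def test_pcc_perfect_linear():
    x = np.arange(10.0)
    assert compute_pcc(x, 2 * x + 1) == pytest.approx(1.0)
    assert compute_pcc(x, -x) == pytest.approx(-1.0)


def test_pcc_matches_covariance_formula(rng):
    for _ in range(20):
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        num = np.mean((x - x.mean()) * (y - y.mean()))
        expected = num / (x.std() * y.std())
        assert compute_pcc(x, y) == pytest.approx(expected, abs=1e-12)


def test_pcc_input_validation():
    with pytest.raises(UndefinedCorrelationError):
        compute_pcc([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        compute_pcc([1.0, 2.0], [1.0, 2.0])


# ---------------------------------------------------------------------------
# neighbor pairing


def test_pairing_prefers_highest_magnitude():
    x = np.arange(10.0)
    expr = {"rna": x, "up": 0.9 * x + np.array([0.1, -0.2, 0.3, 0, 0, 0.2, -0.1, 0, 0.1, 0]),
            "down": -x}
    up, down = tmodel("up"), tmodel("down", 200, 300)
    pair = pair_neighbor_gene(tmodel("rna", 120, 180), (up, down), expr)
    assert pair.gene_id == "down"  # |−1| beats |0.99…|
    assert pair.pcc == pytest.approx(-1.0)
    assert pair.side == "downstream"


def test_pairing_single_candidate_and_none():
    x = np.arange(10.0)
    expr = {"rna": x, "up": x + 1}
    pair = pair_neighbor_gene(tmodel("rna"), (tmodel("up", 200, 300), None), expr)
    assert pair.gene_id == "up" and pair.side == "upstream"
    assert pair_neighbor_gene(tmodel("rna"), (None, None), expr) is None


def test_pairing_flank_order_invariance(rng):
    x = rng.normal(size=10)
    expr = {"r": x, "a": rng.normal(size=10), "b": rng.normal(size=10)}
    a, b = tmodel("a"), tmodel("b", 200, 300)
    p1 = pair_neighbor_gene(tmodel("r", 120, 180), (a, b), expr)
    p2 = pair_neighbor_gene(tmodel("r", 120, 180), (b, a), expr)
    assert p1.gene_id == p2.gene_id
    assert p1.pcc == pytest.approx(p2.pcc)


def test_pairing_matches_brute_force_on_random_layouts(rng):
    """Max-|PCC| flank selection agrees with an exhaustive scan on 100
    random toy layouts."""
    for _ in range(100):
        x = rng.normal(size=10)
        expr = {"rna": x}
        flanks = []
        for name in ("up", "down"):
            if rng.random() < 0.8:
                expr[name] = rng.normal(size=10)
                flanks.append(tmodel(name, 200, 300))
            else:
                flanks.append(None)
        pair = pair_neighbor_gene(tmodel("rna"), tuple(flanks), expr)
        cands = {}
        for name in ("up", "down"):
            if name in expr:
                cands[name] = np.corrcoef(x, expr[name])[0, 1]
        if not cands:
            assert pair is None
            continue
        best = max(cands, key=lambda k: (abs(cands[k]), k == "down"))
        assert pair.gene_id == best
        assert pair.pcc == pytest.approx(cands[best], abs=1e-12)


# ---------------------------------------------------------------------------
# relative density


def test_relative_density_self_ratio_is_one(rng):
    sample = rng.normal(0, 0.3, size=100).clip(-1, 1)
    curve = relative_density(sample, sample)
    assert np.allclose(curve.ratio, 1.0)


def test_relative_density_shifted_group(rng):
    control = np.clip(rng.normal(0, 0.35, 500), -0.999, 0.999)
    group = np.clip(control + 0.75, -0.999, 0.999)  # shifted toward +1
    curve = relative_density(group, control)
    high = curve.grid > 0.5
    low = curve.grid < -0.5
    assert np.median(curve.ratio[high]) > 1
    assert np.median(curve.ratio[low]) < 1


def test_relative_density_requires_minimum_size(rng):
    small = rng.normal(size=10)
    with pytest.raises(ValueError):
        relative_density(small, rng.normal(size=100))


def test_relative_density_flags_floored_control(rng):
    group = rng.normal(0.9, 0.02, size=50)
    control = rng.normal(-0.9, 0.02, size=50)
    curve = relative_density(group, control)
    assert curve.floored.any()


def test_null_pairing_calibration():
    """Two independent random pairings of the same population give a
    relative density near 1 where the null has support (|PCC| <= 0.5)."""
    a, _ = simulate_pcc_mixture(n_pairs=1000, strong_fraction=0.0,
                                n_samples=10, seed=10)
    b, _ = simulate_pcc_mixture(n_pairs=1000, strong_fraction=0.0,
                                n_samples=10, seed=11)
    curve = relative_density(a, b)
    mask = np.abs(curve.grid) <= 0.5
    assert curve.ratio[mask].min() >= 0.8
    assert curve.ratio[mask].max() <= 1.25


# ---------------------------------------------------------------------------
# cutoff fractions


def test_fraction_cutoff_examples():
    pairs = [NeighborPair("r", "g", "upstream", 0.9)] * 4
    assert fraction_beyond_cutoff(pairs) == (1.0, 0.0)
    # exactly 0.8 counts as positive (inclusive)
    assert fraction_beyond_cutoff([0.8, -0.8]) == (0.5, 0.5)
    with pytest.raises(ValueError):
        fraction_beyond_cutoff([])


def test_planted_mixture_fraction():
    """A 25% planted strong-positive mixture yields a positive fraction
    within +/-0.05 of 0.25 at the +/-0.8 cutoff."""
    pccs, _ = simulate_pcc_mixture(seed=3)
    pos, neg = fraction_beyond_cutoff(list(pccs))
    assert abs(pos - 0.25) <= 0.05
    assert neg <= 0.02


def test_random_control_is_seeded(rng):
    expr = {f"g{i}": rng.normal(size=8) for i in range(30)}
    expr.update({f"r{i}": rng.normal(size=8) for i in range(10)})
    rnas = [f"r{i}" for i in range(10)]
    genes = [f"g{i}" for i in range(30)]
    p1 = random_control_pairs(rnas, genes, expr, seed=5)
    p2 = random_control_pairs(rnas, genes, expr, seed=5)
    assert [(p.rna_id, p.gene_id) for p in p1] == [(p.rna_id, p.gene_id) for p in p2]
    # without replacement: genes are distinct
    assert len({p.gene_id for p in p1}) == len(p1)
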