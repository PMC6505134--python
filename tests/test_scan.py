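"""Genome scan: map functions, HMM genotype probabilities, binary EM LOD,
permutation thresholds and interval calling."""

import math

import numpy as np
import pytest

from regrowqtl.genotypes import (AA, AB, BB, Dataset, GenotypeMatrix,
                                 MISSING, MarkerLocus, PhenotypeTable)
from regrowqtl.scan import (GenoProbTable, Interval, ScanConfig, ScanResult,
                            build_genetic_map, calc_genoprob, call_intervals,
                            genome_scan, haldane_d, haldane_r,
                            permutation_threshold, scan_binary_em)
from regrowqtl.simulate import (CausalModel, Chromosome, GenomeSpec,
                                simulate_f2_population)


def test_haldane_values():
    assert haldane_r(0.0) == 0.0
    assert haldane_r(10.0) == pytest.approx((1 - math.exp(-0.2)) / 2,
                                            abs=1e-12)
    with pytest.raises(ValueError):
        haldane_d(0.5)
    with pytest.raises(ValueError):
        haldane_r(-1.0)


def test_haldane_roundtrip():
    d = np.linspace(0.0, 200.0, 101)
    assert np.allclose(haldane_d(haldane_r(d)), d, atol=1e-9)


def test_physical_map_convention():
    markers = [MarkerLocus("1", 5_000_000, "a"), MarkerLocus("1", 7_500_000, "b"),
               MarkerLocus("2", 1_000_000, "c")]
    gmap = build_genetic_map(markers)
    assert gmap.cm["1"][0] == pytest.approx(5.0)
    assert gmap.cm["1"][1] == pytest.approx(7.5)
    assert gmap.cm["2"] == pytest.approx([1.0])


def test_single_marker_chromosome_map():
    gmap = build_genetic_map([MarkerLocus("3", 2_000_000, "x")])
    assert gmap.chromosomes == ["3"]
    assert len(gmap.cm["3"]) == 1


def test_em_estimated_map_recovers_r(small_genome, small_causal):
    """Adjacent-pair ML estimates track the simulated Haldane distances."""
    ds, _ = simulate_f2_population(600, small_genome, small_causal,
                                   noise=None, seed=31)
    gmap = build_genetic_map(ds.genotypes.markers, "em_estimated",
                             ds.genotypes)
    # markers are ~4.5 cM apart under the 1 cM/Mbp coupling
    for c in gmap.chromosomes:
        gaps = np.diff(gmap.cm[c])
        true_gaps = np.diff(gmap.bp[c]) * 1e-6
        r_true = haldane_r(true_gaps)
        se = 3 * np.sqrt(r_true * (1 - r_true) / 600)
        assert np.all(np.abs(haldane_r(gaps) - r_true) < se + 1e-3)


def _one_marker_dataset(calls, phen=None):
    plants = [f"p{i}" for i in range(len(calls))]
    g = GenotypeMatrix(plants, [MarkerLocus("1", 1_000_000, "m1")],
                       np.array(calls, dtype=np.int8).reshape(-1, 1))
    phen = phen or {p: "R" for p in plants}
    return Dataset(g, PhenotypeTable(phen))


def test_genoprob_single_site_bayes():
    """Isolated AA call: posterior matches the one-site Bayes computation."""
    eps = 1e-4
    d = _one_marker_dataset([AA])
    gp = calc_genoprob(d, build_genetic_map(d.genotypes.markers),
                       ScanConfig(error_prob=eps))
    prior = np.array([0.25, 0.5, 0.25])
    like = np.array([1 - eps, eps / 2, eps / 2])
    expect = prior * like / (prior * like).sum()
    assert gp.probs[0, 0] == pytest.approx(expect, abs=1e-12)
    assert gp.probs[0, 0, 0] == pytest.approx(0.99985, abs=1e-4)


def test_genoprob_missing_is_prior():
    d = _one_marker_dataset([MISSING])
    gp = calc_genoprob(d, build_genetic_map(d.genotypes.markers),
                       ScanConfig())
    assert gp.probs[0, 0] == pytest.approx([0.25, 0.5, 0.25])


def test_genoprob_triples_normalise_and_grid_spacing(small_f2):
    ds, _ = small_f2
    cfg = ScanConfig(step=1.0)
    gp = calc_genoprob(ds, build_genetic_map(ds.genotypes.markers), cfg)
    assert np.allclose(gp.probs.sum(axis=2), 1.0, atol=1e-9)
    for c in gp.positions["chromosome"].unique():
        cm = gp.positions.loc[gp.positions.chromosome == c, "cm"].to_numpy()
        assert (np.diff(cm) <= cfg.step + 1e-9).all()


def test_genoprob_zero_error_degenerate(small_f2):
    """With eps=0 and complete data, marker posteriors are point masses."""
    ds, _ = small_f2
    gp = calc_genoprob(ds, build_genetic_map(ds.genotypes.markers),
                       ScanConfig(error_prob=0.0))
    is_marker = gp.positions["is_marker"].to_numpy()
    ids = gp.positions["marker_id"].to_numpy()[is_marker]
    col = {mk.id: j for j, mk in enumerate(ds.genotypes.markers)}
    post = gp.probs[:, is_marker, :]
    for t, mid in enumerate(ids):
        calls = ds.genotypes.calls[:, col[mid]].astype(int)
        assert np.allclose(post[np.arange(len(calls)), t, calls], 1.0,
                           atol=1e-9)


def closed_form_lod(calls, y):
    """Binomial likelihood-ratio LOD at a fully informative marker."""
    calls, y = np.asarray(calls), np.asarray(y)
    l1 = 0.0
    for g in (AA, AB, BB):
        sel = calls == g
        if not sel.any():
            continue
        mu = y[sel].mean()
        if mu in (0.0, 1.0):
            continue
        l1 += (y[sel].sum() * math.log(mu)
               + (len(y[sel]) - y[sel].sum()) * math.log(1 - mu))
    mu = y.mean()
    l0 = 0.0 if mu in (0.0, 1.0) else \
        y.sum() * math.log(mu) + (len(y) - y.sum()) * math.log(1 - mu)
    return (l1 - l0) / math.log(10)


def test_scan_closed_form_dominance_lod(informative_sixteen):
    """4 AA / 8 AB / 4 BB with phenotype = dominance gives the closed-form
    LOD (-12 ln 0.75 - 4 ln 0.25)/ln 10."""
    cfg = ScanConfig(error_prob=0.0)
    gp = calc_genoprob(informative_sixteen,
                       build_genetic_map(informative_sixteen.genotypes.markers),
                       cfg)
    res = scan_binary_em(gp, informative_sixteen.phenotypes, cfg)
    expect = (-12 * math.log(0.75) - 4 * math.log(0.25)) / math.log(10)
    assert res.lod[0] == pytest.approx(expect, abs=1e-6)
    assert res.lod[0] == pytest.approx(3.9075, abs=5e-5)


def test_scan_matches_closed_form_on_random_phenotypes(informative_sixteen):
    cfg = ScanConfig(error_prob=0.0)
    gp = calc_genoprob(informative_sixteen,
                       build_genetic_map(informative_sixteen.genotypes.markers),
                       cfg)
    rng = np.random.default_rng(1)
    calls = informative_sixteen.genotypes.calls[:, 0]
    plants = informative_sixteen.plants
    for _ in range(20):
        y = rng.integers(0, 2, len(plants))
        phen = PhenotypeTable({p: ("R" if v else "NR")
                               for p, v in zip(plants, y)})
        res = scan_binary_em(gp, phen, cfg)
        assert res.lod[0] == pytest.approx(closed_form_lod(calls, y),
                                           abs=1e-6)


def test_scan_constant_phenotype_zero_lod(informative_sixteen):
    phen = PhenotypeTable({p: "R" for p in informative_sixteen.plants})
    cfg = ScanConfig()
    gp = calc_genoprob(informative_sixteen,
                       build_genetic_map(informative_sixteen.genotypes.markers),
                       cfg)
    res = scan_binary_em(gp, phen, cfg)
    assert np.all(res.lod == 0.0)


def test_em_loglik_monotone_in_iteration_budget(small_f2):
    ds, _ = small_f2
    gp = calc_genoprob(ds, build_genetic_map(ds.genotypes.markers),
                       ScanConfig())
    from regrowqtl.scan import _em_scan
    y = ds.phenotype_binary()
    prev = None
    for iters in (1, 2, 3, 5, 10, 50):
        ll, _, _ = _em_scan(gp.probs, y, ScanConfig(em_max_iter=iters,
                                                    em_tolerance=0.0))
        if prev is not None:
            assert (ll - prev >= -1e-9).all()
        prev = ll


def test_permutation_threshold_properties(small_f2):
    ds, _ = small_f2
    cfg = ScanConfig(n_permutations=60, alpha=0.05)
    gp = calc_genoprob(ds, build_genetic_map(ds.genotypes.markers), cfg)
    p5 = permutation_threshold(gp, ds.phenotypes, cfg,
                               np.random.default_rng(3))
    p5b = permutation_threshold(gp, ds.phenotypes, cfg,
                                np.random.default_rng(3))
    assert p5.threshold == p5b.threshold           # deterministic given seed
    cfg10 = ScanConfig(n_permutations=60, alpha=0.10)
    p10 = permutation_threshold(gp, ds.phenotypes, cfg10,
                                np.random.default_rng(3))
    assert p5.threshold >= p10.threshold           # quantile monotonicity
    # relabeling plants (same order of rows) leaves the threshold unchanged
    g2 = GenotypeMatrix([f"z{i}" for i in range(ds.genotypes.n_plants)],
                        ds.genotypes.markers, ds.genotypes.calls)
    phen2 = PhenotypeTable({f"z{i}": ds.phenotypes[p]
                            for i, p in enumerate(ds.plants)})
    gp2 = calc_genoprob(Dataset(g2, phen2),
                        build_genetic_map(g2.markers), cfg)
    pr = permutation_threshold(gp2, phen2, cfg, np.random.default_rng(3))
    assert pr.threshold == p5.threshold


def test_permutation_constant_phenotype_zero_threshold(informative_sixteen):
    phen = PhenotypeTable({p: "R" for p in informative_sixteen.plants})
    cfg = ScanConfig(n_permutations=25)
    gp = calc_genoprob(informative_sixteen,
                       build_genetic_map(informative_sixteen.genotypes.markers),
                       cfg)
    with pytest.warns(UserWarning):
        perm = permutation_threshold(gp, phen,
                                     ScanConfig(n_permutations=10), None)
    assert perm.threshold == 0.0
    assert (perm.maxima == 0.0).all()


def test_call_intervals_rule():
    import pandas as pd
    pos = pd.DataFrame({
        "chromosome": ["1"] * 5, "cm": [1.0, 2, 3, 4, 5],
        "position_bp": [1_000_000, 2_000_000, 3_000_000, 4_000_000,
                        5_000_000],
        "marker_id": [f"m{i}" for i in range(5)],
        "is_marker": [True] * 5})
    res = ScanResult(pos, np.array([1.0, 6.0, 7.0, 6.0, 2.0]),
                     np.zeros((5, 3)), 0.0)
    ivs = call_intervals(res, 5.23)
    assert len(ivs) == 1
    iv = ivs[0]
    assert (iv.start_bp, iv.end_bp, iv.peak_bp) \
        == (2_000_000, 4_000_000, 3_000_000)
    assert call_intervals(res, 10.0) == []


def test_call_intervals_exclude_pseudomarkers(small_f2):
    ds, _ = small_f2
    cfg = ScanConfig(n_permutations=20, seed=1)
    res = genome_scan(ds, cfg)
    bp = res.positions["position_bp"].to_numpy()
    marker_bp = set(bp[res.positions["is_marker"]])
    for iv in res.intervals:
        assert iv.start_bp in marker_bp and iv.end_bp in marker_bp
        assert iv.peak_bp in marker_bp


def test_two_peak_recovery_noise_free(small_f2, small_causal):
    """The planted chromosomes, and only they, carry significant intervals."""
    ds, _ = small_f2
    cfg = ScanConfig(n_permutations=100, seed=2)
    res = genome_scan(ds, cfg)
    chroms = {iv.chromosome for iv in res.intervals}
    assert chroms == {c for c, _ in small_causal.loci}
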