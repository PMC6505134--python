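"""SNP filtration cascade: coverage/MAF, missingness+imputation, the
model-constrained contingency chi-square, and haplotype-cluster collapsing."""

import numpy as np
import pytest

from regrowqtl.genotypes import (AA, AB, BB, Dataset, GenotypeMatrix,
                                 MISSING, MarkerLocus, PhenotypeTable)
from regrowqtl.filters import (FilterConfig, collapse_clusters,
                               missingness_filter_impute, model_fit_filter,
                               run_filter_cascade, site_filters)


def _matrix(cols, positions=None, chrom="1"):
    """Build a matrix from a list of per-marker call columns."""
    cols = [np.asarray(c, dtype=np.int8) for c in cols]
    n = len(cols[0])
    positions = positions or [100 * (j + 1) for j in range(len(cols))]
    markers = [MarkerLocus(chrom, p, f"m{j}")
               for j, p in enumerate(positions)]
    return GenotypeMatrix([f"p{i}" for i in range(n)], markers,
                          np.stack(cols, axis=1))


def test_site_filters_coverage_and_maf():
    cfg = FilterConfig()
    # 10 plants: 90% missing site; monomorphic site; healthy site
    g = _matrix([
        [MISSING] * 9 + [AA],
        [AA] * 10,
        [AA, AB, BB, AA, AB, BB, AA, AB, AA, AB],
    ])
    out = site_filters(g, cfg)
    assert out.marker_ids() == ["m2"]


def test_site_filters_maf_boundary():
    """1 het among 100 plants is MAF 0.005 (dropped); 2 hets is 0.01 (kept)."""
    col1 = [AB] + [AA] * 99
    col2 = [AB, AB] + [AA] * 98
    g = _matrix([col1, col2])
    out = site_filters(g, FilterConfig())
    assert out.marker_ids() == ["m1"]
    assert g.minor_allele_frequency()[0] == pytest.approx(0.005)
    assert g.minor_allele_frequency()[1] == pytest.approx(0.01)


def test_missingness_filter_and_imputation():
    g = _matrix([
        [MISSING] * 3 + [AA] * 7,          # 30% missing: dropped
        [MISSING] * 2 + [BB] * 8,          # 20% missing: kept, imputed
        [AA] * 10,                         # complete: unchanged
    ])
    out = missingness_filter_impute(g, FilterConfig())
    assert out.marker_ids() == ["m1", "m2"]
    assert not (out.calls == MISSING).any()
    assert (out.calls[:2, 0] == AB).all()
    assert (out.calls[2:, 0] == BB).all()
    again = missingness_filter_impute(out, FilterConfig())
    assert again == out


def _dataset_from_counts(r_counts, nr_counts):
    """One SNP with the given (AA, AB, BB) counts per phenotype class."""
    col, statuses = [], {}
    i = 0
    for cls, counts in (("R", r_counts), ("NR", nr_counts)):
        for call, k in zip((AA, AB, BB), counts):
            for _ in range(k):
                col.append(call)
                statuses[f"p{i}"] = cls
                i += 1
    g = _matrix([col])
    return Dataset(g, PhenotypeTable(statuses))


def test_model_filter_perfect_fit_kept():
    """Observed equal to expected under (1/3,2/3,0)/(1/7,2/7,4/7): chi2=0."""
    d = _dataset_from_counts((4, 8, 0), (2, 4, 8))
    fits = model_fit_filter(d)
    assert fits[0].chi2 == 0.0
    assert fits[0].keep
    assert fits[0].df == 4


def test_model_filter_bb_regrower_rejects():
    d = _dataset_from_counts((4, 7, 1), (2, 4, 8))
    fits = model_fit_filter(d)
    assert np.isinf(fits[0].chi2)
    assert not fits[0].keep


def test_model_filter_unlinked_snp_rejected():
    d = _dataset_from_counts((16, 31, 16), (12, 25, 12))
    fits = model_fit_filter(d)
    assert not fits[0].keep


def test_model_filter_requires_imputed_matrix():
    g = _matrix([[MISSING, AA, AB, BB]])
    p = PhenotypeTable({f"p{i}": ("R" if i < 2 else "NR") for i in range(4)})
    with pytest.raises(ValueError, match="imputed"):
        model_fit_filter(Dataset(g, p))


def test_model_filter_needs_both_classes():
    g = _matrix([[AA, AB, AB, BB]])
    p = PhenotypeTable({f"p{i}": "R" for i in range(4)})
    with pytest.raises(ValueError, match="class"):
        model_fit_filter(Dataset(g, p))


def test_model_filter_matches_brute_force_oracle():
    """chi2 agrees with an explicit 6-cell sum to 1e-9 on random SNPs."""
    rng = np.random.default_rng(17)
    n = 60
    y = np.array([1] * 33 + [0] * 27)
    exp_r = np.array([1 / 3, 2 / 3, 0.0]) * 33
    exp_nr = np.array([1 / 7, 2 / 7, 4 / 7]) * 27
    cols = rng.choice([AA, AB, BB], size=(n, 1000),
                      p=[0.25, 0.5, 0.25]).astype(np.int8)
    markers = [MarkerLocus("1", j + 1, f"m{j}") for j in range(1000)]
    g = GenotypeMatrix([f"p{i}" for i in range(n)], markers, cols)
    p = PhenotypeTable({f"p{i}": ("R" if y[i] else "NR") for i in range(n)})
    fits = model_fit_filter(Dataset(g, p))
    for j, fit in enumerate(fits):
        obs_r = [(cols[y == 1, j] == c).sum() for c in (AA, AB, BB)]
        obs_nr = [(cols[y == 0, j] == c).sum() for c in (AA, AB, BB)]
        if obs_r[2] > 0:
            assert np.isinf(fit.chi2)
            continue
        chi2 = sum((o - e) ** 2 / e
                   for o, e in zip(obs_r[:2], exp_r[:2])) \
            + sum((o - e) ** 2 / e for o, e in zip(obs_nr, exp_nr))
        assert fit.chi2 == pytest.approx(chi2, abs=1e-9)


def test_collapse_within_window_single_cluster():
    v = [AA, AB, BB, AA]
    g = _matrix([v, v, v], positions=[100, 180, 195])
    out, clusters = collapse_clusters(g, FilterConfig())
    assert len(clusters) == 1
    assert out.markers[0].position_bp == 100
    assert [m.position_bp for m in clusters[0].members] == [100, 180, 195]


def test_collapse_window_anchored_at_first_member():
    v = [AA, AB, BB, AA]
    g = _matrix([v, v, v], positions=[100, 150, 260])
    out, clusters = collapse_clusters(g, FilterConfig())
    assert [[m.position_bp for m in c.members] for c in clusters] \
        == [[100, 150], [260]]
    assert out.marker_ids() == ["m0", "m2"]


def test_collapse_differing_vectors_never_merge():
    g = _matrix([[AA, AB, BB], [AA, AB, AA]], positions=[100, 110])
    out, clusters = collapse_clusters(g, FilterConfig())
    assert len(clusters) == 2
    assert out.n_markers == 2


def test_collapse_does_not_merge_across_chromosomes():
    v = np.array([AA, AB, BB], dtype=np.int8)
    markers = [MarkerLocus("1", 100, "a"), MarkerLocus("2", 120, "b")]
    g = GenotypeMatrix(["p0", "p1", "p2"], markers,
                       np.stack([v, v], axis=1))
    _, clusters = collapse_clusters(g, FilterConfig())
    assert len(clusters) == 2


def test_collapse_no_adjacent_identical_within_window():
    rng = np.random.default_rng(3)
    cols = rng.choice([AA, AB, BB], size=(6, 40)).astype(np.int8)
    cols[:, 10] = cols[:, 9]          # force some duplicates
    cols[:, 25] = cols[:, 24]
    g = _matrix(list(cols.T), positions=[10 * (j + 1) for j in range(40)])
    out, _ = collapse_clusters(g, FilterConfig())
    for j in range(out.n_markers - 1):
        a, b = out.markers[j], out.markers[j + 1]
        if a.chromosome == b.chromosome \
                and b.position_bp - a.position_bp <= 100:
            assert not np.array_equal(out.calls[:, j], out.calls[:, j + 1])


def test_cascade_noise_free_keeps_everything_at_stage2(small_f2):
    ds, _ = small_f2
    res = run_filter_cascade(ds)
    assert res.after_impute.genotypes.n_markers \
        == res.after_site.genotypes.n_markers
    # stages only drop or merge columns; surviving calls are unchanged
    # (noise-free input has nothing to impute)
    orig = {mk.id: j for j, mk in enumerate(ds.genotypes.markers)}
    g4 = res.after_collapse.genotypes
    for j, mk in enumerate(g4.markers):
        assert np.array_equal(g4.calls[:, j], ds.genotypes.calls[:, orig[mk.id]])


def test_cascade_deterministic(small_f2):
    ds, _ = small_f2
    a = run_filter_cascade(ds)
    b = run_filter_cascade(ds)
    assert a.survivor_counts == b.survivor_counts
    assert a.after_collapse.genotypes == b.after_collapse.genotypes


def test_cascade_survivors_near_causal(small_f2, small_causal):
    """Model-filter survivors concentrate around the planted loci."""
    ds, truth = small_f2
    res = run_filter_cascade(ds)
    kept = {f.marker.id for f in res.model_fits if f.keep}
    assert kept, "model filter kept nothing"
    near = 0
    for mk_id in kept:
        mk = next(m for m in ds.genotypes.markers if m.id == mk_id)
        near += any(mk.chromosome == c and abs(mk.position_bp - bp) <= 10e6
                    for c, bp in truth.causal_loci)
    assert near / len(kept) > 0.5
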