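"""Window statistics against brute-force oracles and frozen hand values."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nemascape import (
    GenotypeMatrix,
    beta_score,
    fis_window,
    haplotype_homozygosity,
    ld_decay_profile,
    make_fixture_genotypes,
    omega_max,
    pairwise_dist_moments,
    pi_window,
    watterson_tajima,
    zns,
)
from nemascape.sumstats import (
    WindowSpec,
    compute_window_table,
    pairwise_distances,
    r_squared_matrix,
)

import oracles


def random_fixture(rng, n_sites=None, n_ind=None) -> GenotypeMatrix:
    n_sites = n_sites or int(rng.integers(1, 13))
    n_ind = n_ind or int(rng.integers(2, 11))
    while True:
        haps = rng.integers(0, 2, size=(n_sites, 2 * n_ind)).astype(np.int8)
        keep = [i for i in range(n_sites) if 0 < haps[i].sum() < 2 * n_ind]
        if keep:
            haps = haps[keep]
            break
    positions = np.sort(rng.choice(10_000, size=haps.shape[0], replace=False))
    return GenotypeMatrix.from_haplotypes(positions, haps, sequence_length=10_000)


# ---------------------------------------------------------------------------
# frozen worked examples
# ---------------------------------------------------------------------------


def test_pi_on_worked_fixture(four_hap_fixture):
    # derived counts (2, 1) on 4 haplotypes: 2/3 + 1/2
    assert pi_window(four_hap_fixture) == pytest.approx(7 / 6, abs=1e-12)
    assert pi_window(four_hap_fixture) == pytest.approx(
        oracles.pi_oracle(four_hap_fixture.haplotypes)
    )


def test_pi_monomorphic_is_zero():
    gm = GenotypeMatrix(
        positions=np.array([5]), dosages=np.zeros((1, 4), dtype=np.int8)
    )
    assert pi_window(gm) == 0.0


def test_watterson_tajima_on_worked_fixture(four_hap_fixture):
    theta, d = watterson_tajima(four_hap_fixture)
    assert theta == pytest.approx(2 / (1 + 1 / 2 + 1 / 3), abs=1e-9)  # 1.0909
    assert d == pytest.approx(0.59158, abs=1e-4)
    assert d == pytest.approx(
        oracles.tajima_d_oracle(four_hap_fixture.haplotypes), abs=1e-12
    )


def test_tajima_d_missing_when_no_segregating_sites():
    gm = GenotypeMatrix(
        positions=np.zeros(0, dtype=int), dosages=np.zeros((0, 4), dtype=np.int8)
    )
    theta, d = watterson_tajima(gm)
    assert theta == 0.0
    assert np.isnan(d)


def test_distance_moments_on_worked_fixture(four_hap_fixture):
    # pairwise distances (1,2,2,1,1,0): population variance 17/36
    var, skew, kurt = pairwise_dist_moments(four_hap_fixture)
    assert var == pytest.approx(17 / 36, abs=1e-12)
    ov, os_, ok = oracles.dist_moments_oracle(four_hap_fixture.haplotypes.T)
    assert (var, skew, kurt) == pytest.approx((ov, os_, ok))


def test_distance_moments_degenerate_all_equal():
    haps = np.array([[1, 0, 1, 0]], dtype=np.int8)  # all pairs differ by 0 or 2
    gm = GenotypeMatrix.from_haplotypes(np.array([1]), haps)
    var, skew, kurt = pairwise_dist_moments(gm)
    assert var > 0  # distances are 0/2 mixture, not degenerate
    gm2 = GenotypeMatrix(
        positions=np.zeros(0, dtype=int), dosages=np.zeros((0, 3), dtype=np.int8)
    )
    var, skew, kurt = pairwise_dist_moments(gm2)
    assert var == 0.0 and np.isnan(skew) and np.isnan(kurt)


def test_haplotype_homozygosity_frequencies():
    # haplotype frequencies (0.5, 0.25, 0.25)
    haps = np.array([[1, 1, 0, 0], [1, 0, 0, 0]], dtype=np.int8)
    gm = GenotypeMatrix.from_haplotypes(np.array([1, 2]), haps)
    n, h1, h12, h2h1 = haplotype_homozygosity(gm)
    assert (n, h1, h12) == (3, 0.375, 0.625)
    assert h2h1 == pytest.approx(1 / 3)


def test_haplotype_homozygosity_edges():
    gm = GenotypeMatrix(
        positions=np.zeros(0, dtype=int), dosages=np.zeros((0, 5), dtype=np.int8)
    )
    assert haplotype_homozygosity(gm) == (1, 1.0, 1.0, 0.0)
    # all haplotypes unique: H1 = 1/2n
    haps = np.eye(6, dtype=np.int8)
    gm = GenotypeMatrix.from_haplotypes(np.arange(1, 7), haps)
    n, h1, _, _ = haplotype_homozygosity(gm)
    assert n == 6 and h1 == pytest.approx(1 / 6)


def test_zns_worked_example():
    haps = np.array([[1, 1, 0, 0], [1, 0, 0, 0]], dtype=np.int8)
    gm = GenotypeMatrix.from_haplotypes(np.array([1, 2]), haps)
    assert zns(gm) == pytest.approx(1 / 3, abs=1e-12)


def test_zns_perfect_ld_and_missing():
    haps = np.array([[1, 1, 0, 0], [1, 1, 0, 0]], dtype=np.int8)
    gm = GenotypeMatrix.from_haplotypes(np.array([1, 2]), haps)
    assert zns(gm) == pytest.approx(1.0)
    one = GenotypeMatrix.from_haplotypes(np.array([1]), haps[:1])
    assert np.isnan(zns(one))


def test_omega_two_block_example():
    # two internally perfect 3-site blocks with cross-block r^2 = 0.25
    p1 = [1, 1, 1, 1, 0, 0, 0, 0]
    p2 = [1, 1, 1, 0, 1, 0, 0, 0]
    haps = np.array([p1, p1, p1, p2, p2, p2], dtype=np.int8)
    gm = GenotypeMatrix.from_haplotypes(np.arange(1, 7), haps)
    assert omega_max(gm) == pytest.approx(4.0, abs=1e-9)
    assert omega_max(gm) == pytest.approx(oracles.omega_oracle(haps))


def test_omega_uniform_r2_is_one():
    # every pair in perfect LD: omega = 1 at every split
    p = [1, 1, 0, 0]
    haps = np.array([p] * 5, dtype=np.int8)
    gm = GenotypeMatrix.from_haplotypes(np.arange(1, 6), haps)
    assert omega_max(gm) == pytest.approx(1.0)


def test_omega_needs_four_sites():
    haps = np.array([[1, 1, 0, 0]] * 3, dtype=np.int8)
    gm = GenotypeMatrix.from_haplotypes(np.arange(1, 4), haps)
    assert np.isnan(omega_max(gm))


def test_fis_trivial_cases():
    # no heterozygotes at p = 0.5
    d = np.array([[2] * 5 + [0] * 5], dtype=np.int8)
    gm = GenotypeMatrix(positions=np.array([1]), dosages=d)
    assert fis_window(gm) == pytest.approx(1.0)
    # all heterozygous
    d = np.full((1, 6), 1, dtype=np.int8)
    gm = GenotypeMatrix(positions=np.array([1]), dosages=d)
    assert fis_window(gm) == pytest.approx(-1.0)
    # Hardy-Weinberg counts 1:2:1
    d = np.array([[0, 1, 1, 2]], dtype=np.int8)
    gm = GenotypeMatrix(positions=np.array([1]), dosages=d)
    assert fis_window(gm) == pytest.approx(0.0, abs=1e-12)


def test_beta_zero_without_flank_and_cluster_sign():
    rng = np.random.default_rng(0)
    # a lone core has beta 0
    haps = np.array([[1, 1, 0, 0]], dtype=np.int8)
    gm = GenotypeMatrix.from_haplotypes(np.array([500]), haps)
    assert beta_score(gm, 0, flank_bp=100) == 0.0
    # cluster of intermediate-frequency variants scores above singletons
    n = 20
    core = np.zeros((1, n), dtype=np.int8)
    core[0, : n // 2] = 1
    mid = np.tile(core, (21, 1))
    for row in mid[1:]:
        rng.shuffle(row)  # same frequency, random phase
    sing = np.zeros((21, n), dtype=np.int8)
    sing[0] = core[0]
    for i in range(1, 21):
        sing[i, rng.integers(n)] = 1
    pos = np.arange(100, 100 + 21 * 10, 10)
    gm_mid = GenotypeMatrix.from_haplotypes(pos, mid)
    gm_sing = GenotypeMatrix.from_haplotypes(pos, sing)
    b_mid = beta_score(gm_mid, 0, flank_bp=1000)
    b_sing = beta_score(gm_sing, 0, flank_bp=1000)
    assert b_mid > 0 > b_sing


@pytest.mark.parametrize("folded", [True, False])
def test_beta_matches_literal_transcription(folded):
    rng = np.random.default_rng(42)
    for _ in range(100):
        gm = random_fixture(rng)
        n = gm.n_haplotypes
        counts = gm.dosages.astype(int).sum(axis=1)
        core = int(rng.integers(gm.n_sites))
        got = beta_score(gm, core, flank_bp=5000, folded=folded)
        want = oracles.beta_oracle(
            gm.positions, counts, n, core, 5000, 2.0, folded
        )
        assert got == pytest.approx(want, abs=1e-12)


# ---------------------------------------------------------------------------
# oracle equivalence on random fixtures
# ---------------------------------------------------------------------------


def test_all_statistics_match_oracles_on_random_fixtures():
    rng = np.random.default_rng(7)
    for _ in range(200):
        gm = random_fixture(rng)
        haps = gm.haplotypes
        assert pi_window(gm) == pytest.approx(oracles.pi_oracle(haps), abs=1e-10)
        theta, d = watterson_tajima(gm)
        assert theta == pytest.approx(
            oracles.watterson_oracle(gm.n_sites, gm.n_haplotypes)
        )
        if not np.isnan(d):
            assert d == pytest.approx(oracles.tajima_d_oracle(haps), abs=1e-10)
        if gm.n_haplotypes >= 3:
            got = pairwise_dist_moments(gm)
            want = oracles.dist_moments_oracle(haps.T.astype(float))
            for g, w in zip(got, want):
                if np.isnan(w):
                    assert np.isnan(g)
                else:
                    assert g == pytest.approx(w, abs=1e-9)
        assert haplotype_homozygosity(gm) == pytest.approx(
            oracles.h_stats_oracle(haps)
        )
        if gm.n_sites >= 2:
            assert zns(gm) == pytest.approx(oracles.zns_oracle(haps), abs=1e-10)
        if gm.n_sites >= 4:
            assert omega_max(gm) == pytest.approx(
                oracles.omega_oracle(haps), abs=1e-8
            )
        assert fis_window(gm, maf_min=0.05) == pytest.approx(
            oracles.fis_oracle(gm.dosages, 0.05), nan_ok=True
        )


# ---------------------------------------------------------------------------
# invariances
# ---------------------------------------------------------------------------


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_statistics_invariant_to_individual_order_and_allele_swap(seed):
    rng = np.random.default_rng(seed)
    gm = random_fixture(rng)
    perm = rng.permutation(gm.n_individuals)
    hap_perm = np.empty(gm.n_haplotypes, dtype=int)
    hap_perm[0::2] = 2 * perm
    hap_perm[1::2] = 2 * perm + 1
    shuffled = GenotypeMatrix.from_haplotypes(
        gm.positions, gm.haplotypes[:, hap_perm], gm.sequence_length
    )
    swapped = GenotypeMatrix.from_haplotypes(
        gm.positions, 1 - gm.haplotypes, gm.sequence_length
    )
    for alt in (shuffled, swapped):
        assert pi_window(alt) == pytest.approx(pi_window(gm), abs=1e-10)
        t0, d0 = watterson_tajima(gm)
        t1, d1 = watterson_tajima(alt)
        assert t1 == pytest.approx(t0)
        assert d1 == pytest.approx(d0, nan_ok=True, abs=1e-10)
        if gm.n_sites >= 2:
            assert zns(alt) == pytest.approx(zns(gm), abs=1e-10)
        assert fis_window(alt, maf_min=0.0) == pytest.approx(
            fis_window(gm, maf_min=0.0), nan_ok=True, abs=1e-10
        )
        b0 = beta_score(gm, 0, flank_bp=10_000, folded=True)
        b1 = beta_score(alt, 0, flank_bp=10_000, folded=True)
        assert b1 == pytest.approx(b0, abs=1e-10)


def test_pi_equals_mean_pairwise_distance_identity():
    rng = np.random.default_rng(11)
    for _ in range(20):
        gm = random_fixture(rng)
        d = pairwise_distances(gm)
        assert pi_window(gm) == pytest.approx(float(np.mean(d)), abs=1e-10)


# ---------------------------------------------------------------------------
# fixture generator and LD decay
# ---------------------------------------------------------------------------


def test_fixture_generator_hwe_and_extremes():
    gm = make_fixture_genotypes(200, 300, 0.5, fis=0.0, seed=5)
    het = float(np.mean(gm.dosages == 1))
    assert het == pytest.approx(0.5, abs=0.02)
    gm1 = make_fixture_genotypes(50, 50, 0.5, fis=1.0, seed=6)
    assert np.all(gm1.dosages != 1)
    gm2 = make_fixture_genotypes(50, 50, 0.5, fis=-1.0, seed=7)
    assert np.all(gm2.dosages == 1)
    with pytest.raises(ValueError):
        make_fixture_genotypes(10, 10, 0.05, fis=-0.9, seed=8)


def test_ld_decay_independent_sites_near_background():
    gm = make_fixture_genotypes(100, 200, 0.3, fis=0.0, seed=9, sequence_length=20_000)
    prof = ld_decay_profile(gm, max_dist=20_000, bins=4)
    med = prof["median_r2"].dropna()
    assert np.all(med < 0.05)  # background ~ 1/(2n) = 0.005


def test_ld_decay_duplicated_site_bin():
    haps = np.array([[1, 0, 1, 0], [1, 0, 1, 0], [0, 1, 1, 0]], dtype=np.int8)
    gm = GenotypeMatrix.from_haplotypes(np.array([0, 50, 900]), haps)
    prof = ld_decay_profile(gm, max_dist=1000, bins=np.array([0, 100, 1000]))
    assert prof.loc[0, "median_r2"] == pytest.approx(1.0)


def test_window_table_layout_and_coverage_defaults():
    gm = make_fixture_genotypes(20, 60, 0.3, seed=10, sequence_length=50_000)
    table = compute_window_table(gm, WindowSpec(size=10_000))
    assert len(table) == 5
    assert table["S"].sum() == gm.n_sites
    assert np.all(table["coverage_fraction"] == 1.0)
    assert np.all(table["pi"] >= 0)
    # H12 >= H1 invariant
    assert np.all(table["h12"] >= table["h1"] - 1e-12)


def test_window_table_normalization_single_window_warns():
    gm = make_fixture_genotypes(10, 20, 0.3, seed=11, sequence_length=5_000)
    with pytest.warns(UserWarning):
        raw = compute_window_table(gm, WindowSpec(size=5_000), normalize=True)
    assert raw.loc[0, "pi"] > 0  # raw values returned


def test_window_table_normalization_zscores():
    gm = make_fixture_genotypes(20, 200, 0.3, seed=12, sequence_length=100_000)
    norm = compute_window_table(gm, WindowSpec(size=10_000), normalize=True)
    assert abs(float(np.nanmean(norm["pi"]))) < 1e-9
    assert float(np.nanstd(norm["pi"])) == pytest.approx(1.0, abs=1e-9)


def test_r_squared_unphased_matches_dosage_correlation():
    gm = make_fixture_genotypes(40, 6, 0.4, seed=13)
    unphased = GenotypeMatrix(
        positions=gm.positions, dosages=gm.dosages, sequence_length=gm.sequence_length
    )
    r2 = r_squared_matrix(unphased)
    c = np.corrcoef(gm.dosages.astype(float))
    assert r2[0, 1] == pytest.approx(c[0, 1] ** 2, abs=1e-10)
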