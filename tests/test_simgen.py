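"""Scenario draws, the coalescent engine, read simulation, dataset builders."""

import numpy as np
import pytest

from coalcnn import simgen
from coalcnn.msio import HaplotypeAlignment

HARMONIC_49 = sum(1.0 / i for i in range(1, 50))


# --- scenario draws ----------------------------------------------------------


def test_recomb_scenario_draw_ranges():
    rng = np.random.default_rng(0)
    for _ in range(300):
        sc = simgen.draw_recomb_scenario(rng)
        assert sc.N in simgen.N_CHOICES_TRAIN
        assert 1e-8 <= sc.r <= 1e-6
        assert 2e-4 <= sc.rho_per_bp <= 2e-1


def test_theta_arithmetic_matches_lookup_values():
    # the composite-likelihood comparison used theta in {6,12,18,24,60}
    thetas = sorted(simgen.RecombScenario(N=N, r=1e-7).theta
                    for N in simgen.N_CHOICES_TRAIN)
    assert np.allclose(thetas, [6.0, 12.0, 18.0, 24.0, 60.0])
    assert simgen.RecombScenario(N=30_000, r=1e-7).theta == pytest.approx(36.0)


def test_interpolation_draw_uses_heldout_sizes():
    rng = np.random.default_rng(1)
    Ns = {simgen.draw_interpolation_scenario(rng).N for _ in range(200)}
    assert Ns == set(map(float, simgen.N_CHOICES_INTERPOLATION))


def test_demographic_draws_in_bounds_and_ordered():
    rng = np.random.default_rng(2)
    ranges = {"N0": (100, 1000), "N1": (100, 1000), "N2": (100, 1000),
              "T1": (10, 500), "T2": (10, 500)}
    models = [simgen.draw_demographic_model(rng, ranges) for _ in range(500)]
    for m in models:
        assert 100 <= m.N0 <= 1000 and 100 <= m.N1 <= 1000 and 100 <= m.N2 <= 1000
        assert m.T1 < m.T2
    # uniform-moment oracle: mean N0 near the midpoint
    draws = np.array([m.N0 for m in models])
    se = (1000 - 100) / np.sqrt(12) / np.sqrt(len(draws))
    assert abs(draws.mean() - 550) < 3 * se


def test_demographic_draw_rejects_bad_bounds():
    with pytest.raises(ValueError):
        simgen.draw_demographic_model(np.random.default_rng(0),
                                      {**simgen.DEMOGRAPHY_RANGES_DEFAULT,
                                       "N0": (10, 5)})


# --- engine -----------------------------------------------------------------


def test_same_seed_gives_identical_alignment():
    sc = simgen.RecombScenario(N=10_000, r=1e-7)
    a = simgen.simulate_alignment(sc, 10, seed=99)
    b = simgen.simulate_alignment(sc, 10, seed=99)
    assert (a.alleles == b.alleles).all()
    assert np.allclose(a.positions, b.positions)


def test_watterson_expected_segsites_small():
    """Constant-N theta=6, 50 chromosomes: mean S should match
    theta * sum(1/i) (~26.9) within 3 standard errors."""
    rng = np.random.default_rng(3)
    sc = simgen.ConstantThetaScenario(theta=6.0)
    S = np.array([simgen.simulate_alignment(sc, 50, seed=int(rng.integers(1, 2**31))).n_sites
                  for _ in range(1500)])
    expected = 6.0 * HARMONIC_49
    se = S.std(ddof=1) / np.sqrt(len(S))
    assert abs(S.mean() - expected) < 3 * se


def _ld_near_far_ratio(rho_bp, seed, reps=30):
    """Mean r^2 among closer-than-median pairs over farther pairs."""
    rng = np.random.default_rng(seed)
    near, far = [], []
    for _ in range(reps):
        sc = simgen.RecombScenario(N=10_000, r=rho_bp / 4e4, mu=2.5e-8)
        aln = simgen.simulate_alignment(sc, 50, seed=int(rng.integers(1, 2**31)))
        g = aln.alleles.astype(float)
        p = g.mean(axis=0)
        keep = (p > 0.1) & (p < 0.9)
        g, pos = g[:, keep], aln.positions[keep]
        if g.shape[1] < 6:
            continue
        r2 = np.corrcoef(g.T) ** 2
        iu = np.triu_indices(len(pos), 1)
        d = np.abs(pos[iu[0]] - pos[iu[1]])
        med = np.median(d)
        near += list(r2[iu][d < med])
        far += list(r2[iu][d >= med])
    return np.mean(near) / np.mean(far)


def test_ld_decay_absent_without_recombination():
    """With rho = 0, r^2 is independent of distance (near/far ratio ~1);
    with substantial rho, linkage decays with distance (ratio >> 1)."""
    assert _ld_near_far_ratio(0.0, seed=11) < 1.3
    assert _ld_near_far_ratio(5e-3, seed=12) > 1.8


def test_engine_failure_carries_scenario_context():
    with pytest.raises(RuntimeError, match="scenario"):
        simgen.simulate_alignment(object(), 10, seed=1)


def test_sweep_reduces_diversity_vs_neutral():
    """Hard-sweep windows carry less pairwise diversity than neutral
    windows simulated under the same size history."""
    rng = np.random.default_rng(4)

    def mean_pi(cls):
        vals = []
        for _ in range(12):
            sc = simgen.SweepScenario(sweep_class=cls, window_bp=40_000)
            aln = simgen.simulate_alignment(sc, 40, seed=int(rng.integers(1, 2**31)))
            p = aln.alleles.mean(axis=0)
            vals.append((2 * p * (1 - p)).sum())
        return np.mean(vals)

    assert mean_pi("hard") < 0.5 * mean_pi("neutral")


def test_sweep_position_classes():
    sc = simgen.SweepScenario(sweep_class="bogus")
    with pytest.raises(RuntimeError):
        simgen.simulate_alignment(sc, 8, seed=1)


# --- tetraploid reads ----------------------------------------------------------


def _uniform_dosage_alignment(n_sites, derived_per_site, n_chroms=48):
    alleles = np.zeros((n_chroms, n_sites), dtype=np.int8)
    alleles[:derived_per_site, :] = 1
    pos = np.linspace(0.01, 0.99, n_sites)
    return HaplotypeAlignment(alleles, pos)


def test_tetraploid_homozygous_fractions_exact():
    rng = np.random.default_rng(5)
    aln0 = _uniform_dosage_alignment(200, 0)
    assert (simgen.make_tetraploid_reads(aln0, rng=rng).fractions == 0).all()
    aln1 = _uniform_dosage_alignment(200, 48)
    assert (simgen.make_tetraploid_reads(aln1, rng=rng).fractions == 1).all()


@pytest.mark.parametrize("derived,x", [(12, 0.25), (24, 0.5), (36, 0.75)])
def test_tetraploid_heterozygous_fraction_means(derived, x):
    """Sites where a fraction x of all chromosomes carry the derived allele
    give read fractions with mean x (binomial reads over Poisson coverage,
    dosage hypergeometric across random groups)."""
    rng = np.random.default_rng(6)
    aln = _uniform_dosage_alignment(4000, derived)
    fr = simgen.make_tetraploid_reads(aln, rng=rng).fractions.ravel()
    se = fr.std(ddof=1) / np.sqrt(fr.size)
    assert abs(fr.mean() - x) < 3 * se


def test_tetraploid_shapes_and_partition():
    rng = np.random.default_rng(7)
    aln = _uniform_dosage_alignment(50, 24)
    rf = simgen.make_tetraploid_reads(aln, rng=rng)
    assert rf.fractions.shape == (50, 12)  # 48 chromosomes -> 12 individuals
    assert (np.bincount(rf.group_map) == 4).all()
    with pytest.raises(ValueError):
        simgen.make_tetraploid_reads(_uniform_dosage_alignment(5, 2, n_chroms=10),
                                     rng=rng)


# --- dataset builders -----------------------------------------------------------


def test_theta_toy_builder_labels_and_shapes():
    rng = np.random.default_rng(8)
    ds = simgen.build_theta_toy_dataset(rng, n_train=20, n_val=5, n_test=5)
    assert ds["train"].n == 20 and ds["test"].n == 5
    assert ((ds["train"].labels >= 10) & (ds["train"].labels <= 50)).all()
    W = ds["train"].images.shape[1]
    assert ds["train"].images.shape == (20, W, 40)
    assert ds["val"].images.shape[1] == W  # shared width across splits


def test_builders_are_reproducible_from_seed():
    a = simgen.build_theta_toy_dataset(np.random.default_rng(123), 8, 3, 3)
    b = simgen.build_theta_toy_dataset(np.random.default_rng(123), 8, 3, 3)
    assert (a["train"].images == b["train"].images).all()
    assert (a["test"].labels == b["test"].labels).all()


def test_introgression_builder_composition_and_balance():
    rng = np.random.default_rng(9)
    ds = simgen.build_introgression_dataset(
        rng, n_train=(43, 43, 3), n_val_per_class=4, n_test_per_class=5)
    # scaled train composition preserves the published 107.5 : 107.5 : 7.5 ratio
    assert ds["train"].class_counts().tolist() == [43, 43, 3]
    assert ds["val"].class_counts().tolist() == [4, 4, 4]
    assert ds["test"].class_counts().tolist() == [5, 5, 5]
    assert ds["train"].images.shape[2] == 34  # 20 + 14 chromosomes
    assert ds["train"].config["sort"] is False  # grouped by species, unsorted
    # labels partition the dataset
    assert ds["train"].class_counts().sum() == ds["train"].n


def test_sweep_builder_composition_and_filter():
    rng = np.random.default_rng(10)
    ds = simgen.build_sweep_dataset(rng, n_train_total=40, n_val_per_class=2,
                                    n_test_per_class=2, n_chroms=16,
                                    scenario=simgen.SweepScenario(window_bp=20_000),
                                    max_segsites=400)
    counts = ds["train"].class_counts()
    assert counts.sum() == 40
    # rebalanced toward linked classes: (.17,.17,.265,.265,.13) of 40
    assert counts.tolist() == [7, 7, 11, 11, 4]
    assert ds["val"].class_counts().tolist() == [2] * 5
    assert all(img.shape[0] <= 400 for img in ds["train"].images)


def test_sweep_counts_rounding():
    assert sum(simgen._sweep_counts(1000)) == 1000
    assert simgen._sweep_counts(1000)[:2] == [170, 170]


def test_demography_builder_shapes_and_distance_features():
    rng = np.random.default_rng(11)
    ranges = {"N0": (500, 2000), "N1": (500, 2000), "N2": (500, 2000),
              "T1": (50, 400), "T2": (50, 800)}
    ds = simgen.build_demography_dataset(rng, ranges=ranges, n_train=6, n_val=3,
                                         n_test=3, L_bp=100_000)
    assert ds["train"].labels.shape == (6, 5)
    assert (ds["train"].labels[:, 3] < ds["train"].labels[:, 4]).all()  # T1 < T2
    W = ds["train"].images.shape[1]
    assert ds["train"].positions.shape == (6, W - 1)
    # distance vectors are zero-padded gaps in [0, 1]
    assert (ds["train"].positions >= 0).all() and (ds["train"].positions <= 1).all()


def test_dataset_npz_roundtrip(tmp_path):
    rng = np.random.default_rng(12)
    ds = simgen.build_theta_toy_dataset(rng, 4, 2, 2)["train"]
    path = tmp_path / "train.npz"
    ds.save(path)
    back = simgen.LabeledDataset.load(path)
    assert (back.images == ds.images).all()
    assert (back.labels == ds.labels).all()
    assert back.split == "train" and back.config["task"] == "theta_toy"
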