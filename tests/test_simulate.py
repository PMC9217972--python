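import numpy as np
import pytest

from phylosignare.simulate import (
    TOPOLOGY_5,
    TOPOLOGY_7,
    SimulatedDataset,
    _largest_remainder_round,
    fig2_style_signature_sets,
    make_synthetic_catalog,
    random_signature_history,
    simulate_multinomial_style,
    simulate_physigs_style,
    write_dataset,
)
from phylosignare.phylogeny import Branch, CloneTree, read_newick
from phylosignare.spectra import MutationSpectrum, read_spectra_tsv


# ---------------------------------------------------------------------------
# synthetic catalog

def test_catalog_single_column():
    cat = make_synthetic_catalog(1, seed=0)
    assert cat.matrix.shape == (96, 1)
    assert cat.matrix.sum() == pytest.approx(1.0)


def test_catalog_deterministic_under_seed():
    c1 = make_synthetic_catalog(5, seed=42)
    c2 = make_synthetic_catalog(5, seed=42)
    np.testing.assert_array_equal(c1.matrix, c2.matrix)


def test_peaked_columns_are_well_separated():
    sims = []
    for seed in range(20):
        cat = make_synthetic_catalog(2, concentration=0.05, seed=seed)
        a, b = cat.matrix[:, 0], cat.matrix[:, 1]
        sims.append(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))
    assert np.mean(np.array(sims) < 0.3) >= 0.95


# ---------------------------------------------------------------------------
# signature histories

def test_history_recoverable_from_events(rng):
    cat = make_synthetic_catalog(10, seed=3)
    for _ in range(20):
        truth, events, region = random_signature_history(
            TOPOLOGY_7, cat.names, 3, 2, rng
        )
        tree = CloneTree(Branch(b, MutationSpectrum(), p)
                         for b, p in TOPOLOGY_7.items())
        replay = {bid: set(truth["A"]) for bid in TOPOLOGY_7}
        # trunk region never sees an event, so its set is the base set
        assert region["A"] == ()
        for kind, ebid, sig in events:
            for bid in tree.subtree(ebid):
                if kind == "gain":
                    replay[bid].add(sig)
                else:
                    replay[bid].discard(sig)
        assert replay == truth
        assert len(set(region.values())) <= 3


def test_history_rejects_too_many_events(rng):
    cat = make_synthetic_catalog(5, seed=1)
    with pytest.raises(ValueError):
        random_signature_history(TOPOLOGY_5, cat.names, 2, 3, rng)


# ---------------------------------------------------------------------------
# Gaussian-noise generator

def test_gaussian_generator_deterministic():
    cat = make_synthetic_catalog(10, seed=8)
    d1 = simulate_physigs_style(cat, seed=99)
    d2 = simulate_physigs_style(cat, seed=99)
    for bid in d1.tree.branches:
        np.testing.assert_array_equal(
            d1.tree.branch(bid).spectrum.counts, d2.tree.branch(bid).spectrum.counts
        )
    assert d1.truth_signatures == d2.truth_signatures


def test_gaussian_noiseless_limit_matches_expectation():
    cat = make_synthetic_catalog(6, seed=2)
    ds = simulate_physigs_style(cat, noise_sd=0.0, variants_per_branch=(5000, 5000),
                                seed=17)
    for bid, b in ds.tree.branches.items():
        acts = ds.truth_activities[bid]
        a = np.array([acts.get(n, 0.0) for n in cat.names])
        expected = cat.matrix @ a
        np.testing.assert_allclose(b.spectrum.proportions(), expected, atol=2e-4)


def test_gaussian_totals_conserved():
    cat = make_synthetic_catalog(8, seed=4)
    ds = simulate_physigs_style(cat, noise_sd=0.3, seed=55)
    for b in ds.tree.branches.values():
        assert b.total_n == int(b.total_n)
        assert 2 <= b.total_n <= 205
        assert (b.spectrum.counts == np.round(b.spectrum.counts)).all()


def test_region_exposures_shared():
    cat = make_synthetic_catalog(8, seed=4)
    ds = simulate_physigs_style(cat, seed=7)
    regions = ds.meta["region"]
    for b1 in ds.tree.branches:
        for b2 in ds.tree.branches:
            if regions[b1] == regions[b2]:
                assert ds.truth_activities[b1] == ds.truth_activities[b2]


def test_largest_remainder_conserves_total(rng):
    for _ in range(50):
        p = rng.dirichlet(np.ones(96))
        n = int(rng.integers(1, 300))
        rounded = _largest_remainder_round(p * n, n)
        assert rounded.sum() == n
        assert (rounded >= 0).all()


# ---------------------------------------------------------------------------
# multinomial generator

def test_multinomial_totals_and_bounds():
    cat = make_synthetic_catalog(5, seed=5)
    sets = fig2_style_signature_sets(("SYN1", "SYN2", "SYN3"))
    ds = simulate_multinomial_style(cat, sets, variants_per_branch=(20, 100), seed=1)
    for bid, b in ds.tree.branches.items():
        assert 20 <= b.total_n <= 100
        assert (b.spectrum.counts == np.round(b.spectrum.counts)).all()
        assert ds.truth_signatures[bid] == sets[bid]
        assert sum(ds.truth_activities[bid].values()) == pytest.approx(1.0)


def test_multinomial_law_of_large_numbers():
    cat = make_synthetic_catalog(3, seed=6)
    sets = {b: {"SYN1", "SYN2"} for b in TOPOLOGY_5}
    ds = simulate_multinomial_style(cat, sets, variants_per_branch=(10000, 10000),
                                    seed=2)
    for bid, b in ds.tree.branches.items():
        acts = ds.truth_activities[bid]
        a = np.array([acts.get(n, 0.0) for n in cat.names])
        p = cat.matrix @ a
        se = np.sqrt(p * (1 - p) / 10000)
        assert (np.abs(b.spectrum.proportions() - p) < 5 * se + 1e-4).all()


def test_multinomial_validation():
    cat = make_synthetic_catalog(3, seed=6)
    with pytest.raises(ValueError):
        simulate_multinomial_style(cat, {"A": {"SYN1"}}, TOPOLOGY_5, seed=0)
    sets = {b: {"SYN1"} for b in TOPOLOGY_5}
    with pytest.raises(ValueError):
        simulate_multinomial_style(cat, sets, variants_per_branch=(0, 10), seed=0)


def test_dirichlet_exposures_mean_uniform():
    cat = make_synthetic_catalog(4, seed=9)
    sets = {b: {"SYN1", "SYN2", "SYN3"} for b in TOPOLOGY_5}
    draws = []
    for seed in range(100):
        ds = simulate_multinomial_style(cat, sets, seed=seed)
        draws.extend(
            [ds.truth_activities[b][s] for s in ("SYN1", "SYN2", "SYN3")]
            for b in TOPOLOGY_5
        )
    mean = np.mean(draws, axis=0)
    np.testing.assert_allclose(mean, 1 / 3, atol=0.03)


# ---------------------------------------------------------------------------
# dataset I/O

def test_write_dataset_round_trips(tmp_path):
    cat = make_synthetic_catalog(4, seed=12)
    sets = fig2_style_signature_sets(("SYN1", "SYN2", "SYN4"))
    ds = simulate_multinomial_style(cat, sets, seed=3)
    write_dataset(ds, tmp_path)
    spectra = read_spectra_tsv(tmp_path / "counts.tsv")
    tree = read_newick(tmp_path / "tree.nwk", spectra)
    assert set(tree.branches) == set(TOPOLOGY_5)
    for bid in tree.branches:
        np.testing.assert_array_equal(
            tree.branch(bid).spectrum.counts, ds.tree.branch(bid).spectrum.counts
        )
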