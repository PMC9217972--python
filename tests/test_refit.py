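import numpy as np
import pytest

from phylosignare.refit import (
    RefitResult,
    SignatureCatalog,
    ZeroSpectrumError,
    bootstrap_support,
    drop_absent,
    read_catalog_tsv,
    reconstruct,
    refit,
    write_catalog_tsv,
)
from phylosignare.spectra import MutationSpectrum
from phylosignare.simulate import make_synthetic_catalog

from conftest import simplex_grid_argmin, spectrum_from_mixture


def test_exact_single_signature_fit(small_catalog):
    o = spectrum_from_mixture(small_catalog, {"SYN2": 1.0}, 100)
    result = refit(o, small_catalog, ["SYN2"])
    assert result.activities["SYN2"] == pytest.approx(1.0)
    assert result.residual_f == pytest.approx(0.0, abs=1e-9)


def test_noiseless_mixture_matches_grid_oracle(small_catalog):
    o = spectrum_from_mixture(small_catalog, {"SYN1": 0.7, "SYN2": 0.3}, 200)
    result = refit(o, small_catalog)
    oracle = simplex_grid_argmin(200 * small_catalog.matrix, o.counts)
    for name, a_star in zip(small_catalog.names, oracle):
        assert result.activities[name] == pytest.approx(a_star, abs=1e-3)
    assert result.activities["SYN3"] == pytest.approx(0.0, abs=1e-6)


def test_duplicate_columns_split_and_preserve_residual(rng):
    col = rng.dirichlet(np.full(96, 0.1))
    other = rng.dirichlet(np.full(96, 0.1))
    single = SignatureCatalog(np.stack([col, other], 1), ("a", "x"))
    dupl = SignatureCatalog(np.stack([col, col, other], 1), ("a1", "a2", "x"))
    o = MutationSpectrum(np.round(100 * (0.8 * col + 0.2 * other), 6))
    r1 = refit(o, single)
    r2 = refit(o, dupl)
    assert r2.residual_f == pytest.approx(r1.residual_f, abs=1e-6)
    assert r2.activities["a1"] + r2.activities["a2"] == pytest.approx(
        r1.activities["a"], abs=1e-6
    )


def test_refit_input_validation(small_catalog):
    with pytest.raises(ZeroSpectrumError):
        refit(MutationSpectrum(), small_catalog)
    with pytest.raises(KeyError):
        refit(spectrum_from_mixture(small_catalog, {"SYN1": 1.0}, 10),
              small_catalog, ["nope"])


def test_nested_optimality(small_catalog, rng):
    """Fitting over a superset can never worsen the residual."""
    for _ in range(20):
        o = MutationSpectrum(rng.multinomial(150, np.full(96, 1 / 96)).astype(float))
        full = refit(o, small_catalog)
        for drop in small_catalog.names:
            sub = [n for n in small_catalog.names if n != drop]
            assert full.residual_f <= refit(o, small_catalog, sub).residual_f + 1e-8


def test_scale_equivariance(small_catalog, rng):
    o = MutationSpectrum(rng.multinomial(120, np.full(96, 1 / 96)).astype(float))
    r1 = refit(o, small_catalog)
    r2 = refit(MutationSpectrum(3.5 * o.counts), small_catalog)
    for name in small_catalog.names:
        assert r2.activities[name] == pytest.approx(r1.activities[name], abs=1e-6)
    assert r2.residual_f == pytest.approx(3.5 * r1.residual_f, rel=1e-6)


def test_noisy_spectra_match_grid_oracle(rng):
    """Solver activities agree with an exhaustive simplex grid search."""
    for seed in range(5):
        cat = make_synthetic_catalog(3, seed=seed)
        true = rng.dirichlet(np.ones(3))
        p = cat.matrix @ true
        o = MutationSpectrum(rng.multinomial(150, p).astype(float))
        result = refit(o, cat)
        oracle = simplex_grid_argmin(150 * cat.matrix, o.counts)
        for name, a_star in zip(cat.names, oracle):
            assert result.activities[name] == pytest.approx(a_star, abs=2e-3)


# ---------------------------------------------------------------------------
# reconstruction and presence calls

def test_reconstruct_single_signature(small_catalog):
    m = reconstruct(small_catalog, {"SYN1": 1.0}, 50)
    np.testing.assert_allclose(m, 50 * small_catalog.column("SYN1"))


def test_reconstruct_conserves_total(small_catalog, rng):
    a = rng.dirichlet(np.ones(3))
    m = reconstruct(small_catalog, dict(zip(small_catalog.names, a)), 77)
    assert m.sum() == pytest.approx(77, abs=1e-6 * 77)


def test_drop_absent_threshold():
    r = RefitResult({"a": 0.9995, "b": 0.0005}, np.zeros(96), 0.0)
    assert drop_absent(r) == {"a"}
    r2 = RefitResult({"a": 0.5, "b": 0.5}, np.zeros(96), 0.0)
    assert drop_absent(r2) == {"a", "b"}


def test_drop_absent_never_empty_for_small_catalogs(rng):
    # on the simplex with K signatures, the max activity is >= 1/K >= floor
    a = rng.dirichlet(np.ones(20))
    r = RefitResult(dict(zip(map(str, range(20)), a)), np.zeros(96), 0.0)
    assert drop_absent(r, floor=0.001)


# ---------------------------------------------------------------------------
# bootstrap support

def test_bootstrap_overwhelming_signal(small_catalog):
    o = spectrum_from_mixture(small_catalog, {"SYN1": 1.0}, 500)
    support = bootstrap_support(o, small_catalog, ["SYN1", "SYN2"], n_reps=50, seed=3)
    assert support["SYN1"] == 1.0


def test_bootstrap_deterministic_under_seed(small_catalog):
    o = spectrum_from_mixture(small_catalog, {"SYN1": 0.6, "SYN2": 0.4}, 80)
    s1 = bootstrap_support(o, small_catalog, n_reps=40, seed=9)
    s2 = bootstrap_support(o, small_catalog, n_reps=40, seed=9)
    assert s1 == s2


def test_bootstrap_cutoff_filtering_monotone(small_catalog):
    o = spectrum_from_mixture(small_catalog, {"SYN1": 0.5, "SYN2": 0.45, "SYN3": 0.05}, 60)
    support = bootstrap_support(o, small_catalog, n_reps=60, seed=21)
    assert all(0.0 <= v <= 1.0 for v in support.values())
    sizes = [
        len([s for s, v in support.items() if v > cut])
        for cut in (0.60, 0.70, 0.80, 0.90, 0.95)
    ]
    assert sizes == sorted(sizes, reverse=True)


# ---------------------------------------------------------------------------
# catalog I/O and validation

def test_catalog_round_trip(tmp_path, small_catalog):
    path = tmp_path / "catalog.tsv"
    write_catalog_tsv(small_catalog, path)
    back = read_catalog_tsv(path)
    assert back.names == small_catalog.names
    np.testing.assert_allclose(back.matrix, small_catalog.matrix)


def test_cosmic_layout_accepted(tmp_path, small_catalog):
    import pandas as pd

    from phylosignare.spectra import CONTEXT_LABELS

    rows = []
    for i, label in enumerate(CONTEXT_LABELS):
        sub = label[2:5]
        tri = label[0] + label[3] + label[6]
        rows.append({
            "Substitution Type": sub,
            "Trinucleotide": tri,
            "Somatic Mutation Type": label,
            "Sig1": small_catalog.matrix[i, 0],
            "Sig2": small_catalog.matrix[i, 1],
        })
    path = tmp_path / "cosmic.tsv"
    pd.DataFrame(rows).sample(frac=1, random_state=0).to_csv(path, sep="\t", index=False)
    cat = read_catalog_tsv(path)
    assert cat.names == ("Sig1", "Sig2")
    np.testing.assert_allclose(cat.matrix, small_catalog.matrix[:, :2])


def test_catalog_validation():
    bad = np.full((96, 2), 1.0 / 96)
    bad[:, 1] *= 2  # column sums to 2
    with pytest.raises(ValueError):
        SignatureCatalog(bad, ("a", "b"))
    with pytest.raises(ValueError):
        SignatureCatalog(np.full((96, 2), 1.0 / 96), ("a", "a"))
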