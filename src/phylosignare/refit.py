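"""Signature refitting: simplex-constrained least squares on mutation counts.

Given an observed 96-context count vector *o* with total *N* and a catalog of
signature probability columns *P*, refitting estimates relative activities
*a* (non-negative, summing to one) minimising the Euclidean distance between
the reconstructed counts ``N * P @ a`` and *o*. This is the quadratic-
programming style refitter used throughout; alternative engines can be
plugged in via the :class:`Refitter` callable protocol.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .spectra import CONTEXT_LABELS, N_CONTEXTS, MutationSpectrum


class ZeroSpectrumError(ValueError):
    """Raised when refitting a spectrum with no variants."""


@dataclass
class SignatureCatalog:
    """A 96 x K column-stochastic matrix of signature probabilities."""

    matrix: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.names = tuple(str(n) for n in self.names)
        if self.matrix.shape != (N_CONTEXTS, len(self.names)):
            raise ValueError(
                f"catalog matrix must be {N_CONTEXTS} x {len(self.names)}"
            )
        if (self.matrix < 0).any():
            raise ValueError("catalog probabilities must be non-negative")
        colsums = self.matrix.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-6):
            bad = [self.names[i] for i in np.flatnonzero(np.abs(colsums - 1) > 1e-6)]
            raise ValueError(f"catalog columns must sum to 1; offending: {bad}")
        if len(set(self.names)) != len(self.names):
            raise ValueError("catalog signature names must be unique")

    @property
    def n_signatures(self) -> int:
        return len(self.names)

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]

    def subset(self, names: Sequence[str]) -> "SignatureCatalog":
        idx = []
        for n in names:
            if n not in self.names:
                raise KeyError(f"unknown signature {n!r}")
            idx.append(self.names.index(n))
        return SignatureCatalog(self.matrix[:, idx], tuple(names))


@dataclass
class RefitResult:
    """Estimated activities with the reconstructed counts and their residual."""

    activities: dict[str, float]
    reconstructed: np.ndarray
    residual_f: float

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.activities)


#: Plug-in protocol for refitting engines.
Refitter = Callable[[MutationSpectrum, SignatureCatalog, Sequence[str]], RefitResult]


def _simplex_lstsq(A: np.ndarray, o: np.ndarray) -> np.ndarray:
    """Minimise ||A a - o||_2 subject to a >= 0 and sum(a) = 1.

    Active-set scheme: a penalty-augmented NNLS proposes a support, then the
    equality-constrained problem on the support is solved exactly through its
    KKT system; variables leave the support while negative and enter while
    their reduced gradient undercuts the equality multiplier. Deterministic
    for a fixed column order; exactly collinear columns receive the
    minimum-norm (equal) split.
    """
    K = A.shape[1]
    if K == 1:
        return np.ones(1)
    w = 1e4 * max(np.linalg.norm(o), 1.0)
    a0, _ = nnls(np.vstack([A, w * np.ones((1, K))]), np.append(o, w))
    support = a0 > 1e-12
    if not support.any():
        support[:] = True
    G = A.T @ A
    c = A.T @ o

    def solve_on(idx: np.ndarray) -> tuple[np.ndarray, float]:
        k = len(idx)
        kkt = np.zeros((k + 1, k + 1))
        kkt[:k, :k] = 2 * G[np.ix_(idx, idx)]
        kkt[:k, k] = 1.0
        kkt[k, :k] = 1.0
        rhs = np.append(2 * c[idx], 1.0)
        sol = np.linalg.lstsq(kkt, rhs, rcond=None)[0]
        return sol[:k], sol[k]

    tol = 1e-9 * max(1.0, np.abs(c).max())
    for _ in range(4 * K + 8):
        idx = np.flatnonzero(support)
        a_s, mu = solve_on(idx)
        if (a_s < -1e-10).any():
            support[idx[int(np.argmin(a_s))]] = False
            if not support.any():
                support[idx[0]] = True
                break
            continue
        # KKT check for excluded columns: reduced gradient must not beat mu
        a_full = np.zeros(K)
        a_full[idx] = a_s
        grad = 2 * (G @ a_full - c)
        excluded = np.flatnonzero(~support)
        if excluded.size:
            viol = grad[excluded] - (-mu)
            j = excluded[int(np.argmin(viol))]
            if viol.min() < -tol:
                support[j] = True
                continue
        a_full = np.clip(a_full, 0.0, None)
        s = a_full.sum()
        return a_full / s if s > 0 else np.full(K, 1.0 / K)
    # fallback: penalty solution (reachable only on pathological cycling)
    s = a0.sum()
    return a0 / s if s > 0 else np.full(K, 1.0 / K)


def refit(
    spectrum: MutationSpectrum,
    catalog: SignatureCatalog,
    subset: Sequence[str] | None = None,
) -> RefitResult:
    """Estimate relative signature activities for one spectrum.

    Activities minimise the Euclidean distance between reconstructed and
    observed counts subject to non-negativity and unit sum. Deterministic
    for a fixed input and signature ordering.
    """
    if spectrum.total_n <= 0:
        raise ZeroSpectrumError("cannot refit a spectrum with zero variants")
    cat = catalog if subset is None else catalog.subset(subset)
    if cat.n_signatures == 0:
        raise ValueError("signature subset must be non-empty")
    N = spectrum.total_n
    a = _simplex_lstsq(N * cat.matrix, spectrum.counts)
    reconstructed = N * (cat.matrix @ a)
    residual = float(np.linalg.norm(reconstructed - spectrum.counts))
    return RefitResult(
        activities=dict(zip(cat.names, a.astype(float))),
        reconstructed=reconstructed,
        residual_f=residual,
    )


def reconstruct(
    catalog: SignatureCatalog,
    activities: Mapping[str, float],
    total_n: float,
) -> np.ndarray:
    """Expected context counts: total mutations times the catalog mixture."""
    a = np.array([activities.get(n, 0.0) for n in catalog.names])
    return total_n * (catalog.matrix @ a)


def drop_absent(result: RefitResult, floor: float = 0.001) -> set[str]:
    """Signatures considered present: relative activity at or above ``floor``."""
    return {name for name, a in result.activities.items() if a >= floor}


def bootstrap_support(
    spectrum: MutationSpectrum,
    catalog: SignatureCatalog,
    subset: Sequence[str] | None = None,
    n_reps: int = 1000,
    seed: int | np.random.Generator | None = None,
    floor: float = 0.001,
) -> dict[str, float]:
    """Fraction of multinomial bootstrap replicates detecting each signature.

    Each replicate redraws ``total_n`` mutations from the observed context
    proportions, refits, and applies the absence floor.
    """
    if spectrum.total_n <= 0:
        raise ZeroSpectrumError("cannot bootstrap a spectrum with zero variants")
    rng = np.random.default_rng(seed)
    p = spectrum.proportions()
    n = int(round(spectrum.total_n))
    names = tuple(subset) if subset is not None else catalog.names
    hits = {name: 0 for name in names}
    for _ in range(n_reps):
        counts = rng.multinomial(n, p).astype(float)
        detected = drop_absent(refit(MutationSpectrum(counts), catalog, names), floor)
        for name in detected:
            hits[name] += 1
    return {name: hits[name] / n_reps for name in names}


# ---------------------------------------------------------------------------
# Catalog I/O

_COSMIC_META_COLS = {"substitution type", "trinucleotide", "somatic mutation type"}


def read_catalog_tsv(path: str | Path) -> SignatureCatalog:
    """Read a signature catalog TSV.

    Accepts the COSMIC v2 layout (metadata columns "Substitution Type",
    "Trinucleotide", "Somatic Mutation Type" followed by one column per
    signature, rows keyed by context label) or a generic 96 x K table whose
    first column holds the canonical context labels.
    """
    df = pd.read_csv(path, sep="\t")
    lower = {c.lower().strip(): c for c in df.columns}
    if "somatic mutation type" in lower:
        df = df.set_index(lower["somatic mutation type"])
        drop = [lower[c] for c in _COSMIC_META_COLS if c in lower and lower[c] in df.columns]
        df = df.drop(columns=drop)
    else:
        df = df.set_index(df.columns[0])
    df = df.loc[:, [c for c in df.columns if not df[c].isna().all()]]
    try:
        df = df.loc[list(CONTEXT_LABELS)]
    except KeyError as exc:
        raise ValueError("catalog rows must be labelled with the 96 canonical "
                         "contexts, e.g. 'A[C>A]A'") from exc
    return SignatureCatalog(df.to_numpy(float), tuple(df.columns))


def write_catalog_tsv(catalog: SignatureCatalog, path: str | Path) -> None:
    df = pd.DataFrame(catalog.matrix, index=list(CONTEXT_LABELS), columns=catalog.names)
    df.index.name = "Somatic Mutation Type"
    df.to_csv(path, sep="\t")
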