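"""Leave-one-out importance scores for candidate signatures.

For a candidate set fitted to one branch spectrum, the importance score of a
signature S contrasts the reconstruction residual with and without S::

    iS = (f_S- - f) / f

where f is the Euclidean residual of the full fit and f_S- the residual when
S is excluded and the remaining candidates are refitted. A spurious
candidate barely changes the fit, so its iS sits near zero; the conventional
retention cutoff is iS > 0.02. No test statistic is involved - iS is a
descriptive heuristic chosen to stay informative at small variant counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .refit import Refitter, SignatureCatalog, refit as qp_refit
from .spectra import MutationSpectrum

#: Residuals below EPS_FACTOR * total_n count as a perfect fit.
EPS_FACTOR = 1e-9
#: Cap for iS when the full fit is (numerically) perfect.
SENTINEL = 1e6


@dataclass
class SignatureImportance:
    signature: str
    i_score: float
    residual_with: float  # f: all candidates included
    residual_without: float  # f_S-: this signature excluded
    activity: float


@dataclass
class ImportanceReport:
    per_signature: dict[str, SignatureImportance]
    residual_full: float

    def score(self, signature: str) -> float:
        return self.per_signature[signature].i_score

    def scores(self) -> dict[str, float]:
        return {s: rec.i_score for s, rec in self.per_signature.items()}


def importance_scores(
    spectrum: MutationSpectrum,
    catalog: SignatureCatalog,
    candidates: Sequence[str],
    refitter: Refitter = qp_refit,
) -> ImportanceReport:
    """Score each candidate by the residual increase its exclusion causes.

    Requires at least two candidates (excluding the sole candidate would
    leave nothing to refit). Scores are clamped below at zero: an optimal
    fit over a superset can never be worse, so negative raw values are
    solver jitter. When the full fit is numerically perfect the ratio is
    taken against a floor of ``EPS_FACTOR * total_n`` and capped at
    ``SENTINEL``.
    """
    candidates = list(candidates)
    if len(candidates) < 2:
        raise ValueError("importance scoring needs at least two candidates")
    full = refitter(spectrum, catalog, candidates)
    f = full.residual_f
    eps = EPS_FACTOR * max(spectrum.total_n, 1.0)
    report: dict[str, SignatureImportance] = {}
    for sig in candidates:
        reduced = [s for s in candidates if s != sig]
        f_minus = refitter(spectrum, catalog, reduced).residual_f
        denom = f if f > eps else eps
        raw = (f_minus - f) / denom
        score = min(max(raw, 0.0), SENTINEL)
        report[sig] = SignatureImportance(
            signature=sig,
            i_score=score,
            residual_with=f,
            residual_without=f_minus,
            activity=full.activities[sig],
        )
    return ImportanceReport(per_signature=report, residual_full=f)


def retain_important(report: ImportanceReport, cutoff: float = 0.02) -> set[str]:
    """Signatures whose importance score strictly exceeds ``cutoff``."""
    return {s for s, rec in report.per_signature.items() if rec.i_score > cutoff}
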