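"""Scoring signature detections against simulation truth.

A detection event is one (dataset, branch, signature) triple. Precision,
recall and F1 pool events over all branches and datasets; branches below a
minimum variant count are excluded from scoring because no refitting method
is informative there. Undefined ratios (0/0) are reported as ``None`` rather
than zero so that averages are not silently deflated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .phylogeny import CloneTree

#: Per-branch variant-count strata used to stratify benchmark scores.
DEFAULT_STRATA: tuple[tuple[float, float], ...] = ((0, 50), (50, 100), (100, np.inf))

Detections = Mapping[str, set[str]]  # branch id -> detected signature names


@dataclass
class DetectionScore:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float | None:
        d = self.tp + self.fp
        return self.tp / d if d else None

    @property
    def recall(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def f1(self) -> float | None:
        p, r = self.precision, self.recall
        if p is None or r is None or p + r == 0:
            return 0.0 if (p is not None and r is not None) else None
        return 2 * p * r / (p + r)


@dataclass
class PairComparison:
    """Set-equality comparisons between branch pairs of one phylogeny."""

    trunk_tip: list[tuple[str, str, bool]]  # (trunk, tip, same?)
    tip_tip: list[tuple[str, str, bool]]

    @property
    def n_trunk_tip_same(self) -> int:
        return sum(1 for *_, same in self.trunk_tip if same)

    @property
    def n_tip_tip_same(self) -> int:
        return sum(1 for *_, same in self.tip_tip if same)


def _iter_branches(
    detected: Sequence[Detections],
    truth: Sequence[Detections],
    sizes: Sequence[Mapping[str, float]] | None,
    min_branch_variants: float,
    stratum: tuple[float, float] | None,
):
    if len(detected) != len(truth):
        raise ValueError("detections and truths must align dataset-by-dataset")
    for d_idx, (det, tru) in enumerate(zip(detected, truth)):
        if set(det) != set(tru):
            raise ValueError(
                f"dataset {d_idx}: detected branches {sorted(det)} do not match "
                f"truth branches {sorted(tru)}"
            )
        for bid in det:
            if sizes is not None:
                n = sizes[d_idx][bid]
                if n < min_branch_variants:
                    continue
                if stratum is not None and not (stratum[0] <= n < stratum[1]):
                    continue
            yield det[bid], tru[bid]


def score_detections(
    detected: Sequence[Detections],
    truth: Sequence[Detections],
    sizes: Sequence[Mapping[str, float]] | None = None,
    min_branch_variants: float = 20,
    strata: Sequence[tuple[float, float]] | None = None,
) -> DetectionScore | tuple[DetectionScore, dict[tuple[float, float], DetectionScore]]:
    """Pool detection events over datasets and branches into P/R/F1 counts.

    With ``strata`` (half-open variant-count bins) the per-stratum scores
    are returned alongside the overall score. Branch sizes are only needed
    when filtering or stratifying.
    """

    def _score(stratum: tuple[float, float] | None) -> DetectionScore:
        tp = fp = fn = 0
        for det, tru in _iter_branches(
            detected, truth, sizes, min_branch_variants, stratum
        ):
            tp += len(det & tru)
            fp += len(det - tru)
            fn += len(tru - det)
        return DetectionScore(tp, fp, fn)

    overall = _score(None)
    if strata is None:
        return overall
    if sizes is None:
        raise ValueError("stratified scoring needs per-branch variant counts")
    return overall, {tuple(s): _score(tuple(s)) for s in strata}


def faint_recall(
    detected: Sequence[Detections],
    truth_activities: Sequence[Mapping[str, Mapping[str, float]]],
    sizes: Sequence[Mapping[str, float]] | None = None,
    min_branch_variants: float = 20,
    faint_cutoff: float = 0.10,
) -> float | None:
    """Recall restricted to true signatures below ``faint_cutoff`` activity.

    Returns ``None`` when no faint truth events exist.
    """
    tp = fn = 0
    for d_idx, (det, tru) in enumerate(zip(detected, truth_activities)):
        for bid, acts in tru.items():
            if sizes is not None and sizes[d_idx][bid] < min_branch_variants:
                continue
            for sig, act in acts.items():
                if act >= faint_cutoff:
                    continue
                if sig in det.get(bid, set()):
                    tp += 1
                else:
                    fn += 1
    total = tp + fn
    return tp / total if total else None


@dataclass
class ActivityErrorReport:
    differences: np.ndarray  # inferred - simulated, per true-positive event
    slope: float
    intercept: float
    r_squared: float

    @property
    def mean_difference(self) -> float:
        return float(self.differences.mean())

    @property
    def mean_absolute_error(self) -> float:
        return float(np.abs(self.differences).mean())


def activity_error(
    inferred: Sequence[Mapping[str, Mapping[str, float]]],
    truth: Sequence[Mapping[str, Mapping[str, float]]],
) -> ActivityErrorReport:
    """Compare inferred vs simulated activities over true-positive events.

    Fits an ordinary least-squares line of inferred on simulated activity
    and reports per-event differences.
    """
    sim, inf = [], []
    for det_acts, tru_acts in zip(inferred, truth):
        for bid, acts in tru_acts.items():
            got = det_acts.get(bid, {})
            for sig, true_a in acts.items():
                if sig in got:
                    sim.append(true_a)
                    inf.append(got[sig])
    if not sim:
        raise ValueError("no true-positive activity pairs to compare")
    sim_a = np.asarray(sim)
    inf_a = np.asarray(inf)
    if np.ptp(sim_a) == 0:  # degenerate regression
        slope, intercept, r2 = float("nan"), float("nan"), float("nan")
    else:
        fit = stats.linregress(sim_a, inf_a)
        slope, intercept, r2 = fit.slope, fit.intercept, fit.rvalue**2
    return ActivityErrorReport(inf_a - sim_a, float(slope), float(intercept), float(r2))


def activity_filter_baseline(
    activities: Mapping[str, Mapping[str, float]],
    cutoff: float = 0.05,
) -> dict[str, set[str]]:
    """Naive baseline: keep signatures with estimated activity >= cutoff."""
    return {
        bid: {sig for sig, a in acts.items() if a >= cutoff}
        for bid, acts in activities.items()
    }


@dataclass
class BenchmarkRun:
    """Detections and truth for one batch of simulated phylogenies.

    ``detections`` maps method name -> one Detections mapping per dataset.
    The raw-refit methods share the ``refit_activities`` estimates; the
    phylogeny-aware pipeline's activities are in ``ps_activities``.
    """

    detections: dict[str, list[Detections]]
    truth_sets: list[Detections]
    truth_activities: list[dict[str, dict[str, float]]]
    ps_activities: list[dict[str, dict[str, float]]]
    refit_activities: list[dict[str, dict[str, float]]]
    sizes: list[dict[str, float]]

    def score(self, method: str, min_branch_variants: float = 20) -> DetectionScore:
        return score_detections(
            self.detections[method], self.truth_sets, self.sizes, min_branch_variants
        )


def benchmark_simulated(
    catalog,
    n_datasets: int = 30,
    seed: int | np.random.Generator | None = 0,
    n_base_signatures: int = 2,
    n_events: int = 2,
    variants_per_branch: tuple[int, int] = (20, 100),
    filter_cutoffs: Sequence[float] = (0.01, 0.05, 0.10),
) -> BenchmarkRun:
    """Run the pipeline and refit baselines on multinomial simulations.

    Each dataset is a five-branch phylogeny whose signature sets change
    through at most two gain/loss events; exposures are symmetric-Dirichlet
    and counts multinomial. Compared methods: the phylogeny-aware pipeline
    (``ps``), a per-branch refit with the 0.001 absence floor (``refit``),
    and the refit with naive activity filters (``filter_5pct`` etc.).
    """
    from .pipeline import run_phylosignare
    from .refit import drop_absent, refit
    from .simulate import (
        TOPOLOGY_5,
        random_signature_history,
        simulate_multinomial_style,
    )

    rng = np.random.default_rng(seed)
    methods = ["ps", "refit"] + [
        f"filter_{round(100 * c)}pct" for c in filter_cutoffs
    ]
    run = BenchmarkRun({m: [] for m in methods}, [], [], [], [], [])
    for _ in range(n_datasets):
        truth, _, _ = random_signature_history(
            TOPOLOGY_5, catalog.names, n_base_signatures, n_events, rng
        )
        ds = simulate_multinomial_style(
            catalog, truth, TOPOLOGY_5,
            variants_per_branch=variants_per_branch, seed=rng,
        )
        result = run_phylosignare(ds.tree, catalog)
        run.detections["ps"].append(result.detections())
        run.ps_activities.append(
            {b: dict(r.activities) for b, r in result.branch_results.items()}
        )
        refit_acts = {
            bid: refit(b.spectrum, catalog).activities
            for bid, b in ds.tree.branches.items()
        }
        run.refit_activities.append(refit_acts)
        run.detections["refit"].append(
            {bid: {s for s, a in acts.items() if a >= 0.001}
             for bid, acts in refit_acts.items()}
        )
        for cut in filter_cutoffs:
            run.detections[f"filter_{round(100 * cut)}pct"].append(
                activity_filter_baseline(refit_acts, cut)
            )
        run.truth_sets.append(ds.truth_signatures)
        run.truth_activities.append(ds.truth_activities)
        run.sizes.append(ds.branch_sizes())
    return run


def compare_branch_pairs(detections: Detections, tree: CloneTree) -> PairComparison:
    """Trunk-tip and tip-tip signature-set comparisons on one phylogeny."""
    tips = sorted(tree.tips())
    trunk = tree.trunk_id
    trunk_tip = []
    for tip in tips:
        if tip == trunk:
            continue
        same = detections.get(trunk, set()) == detections.get(tip, set())
        trunk_tip.append((trunk, tip, same))
    tip_tip = []
    for i, t1 in enumerate(tips):
        for t2 in tips[i + 1 :]:
            same = detections.get(t1, set()) == detections.get(t2, set())
            tip_tip.append((t1, t2, same))
    return PairComparison(trunk_tip, tip_tip)
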