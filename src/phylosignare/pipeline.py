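"""The phylogeny-aware signature-detection pipeline.

Per branch the procedure is: (1) assemble candidate signatures by refitting
the branch's variants alone and pooled with each immediate relative
(sibling, direct ancestor, direct descendant, and all jointly), keeping any
signature whose estimated activity exceeds the inclusion floor in at least
one collection; (2) filter candidates on the branch's own spectrum with the
leave-one-out importance score; (3) a single neighbour-propagation pass adds
signatures retained only at immediate relatives, importance-tests the
additions on the branch itself, and refits the survivors for the final
activities. Branches below the minimum variant count are merged into their
ancestor first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .importance import ImportanceReport, importance_scores, retain_important
from .phylogeny import CloneTree, merge_small_branches
from .refit import Refitter, SignatureCatalog, drop_absent, refit as qp_refit
from .spectra import MutationSpectrum

logger = logging.getLogger(__name__)

#: COSMIC v2 signatures expected in lung adenocarcinoma.
LUNG_ADENO_SIGNATURES = ("S1", "S2", "S4", "S5", "S6", "S13", "S17")
#: COSMIC v2 signatures expected in lung squamous cell carcinoma.
LUNG_SQUAMOUS_SIGNATURES = ("S1", "S2", "S4", "S5", "S13")


@dataclass
class PipelineConfig:
    """Thresholds of the detection procedure (defaults are the standard ones).

    inclusion_floor:
        Minimum estimated activity, in any pooled collection, for a signature
        to enter a branch's candidate set.
    importance_cutoff:
        Candidates are retained when their importance score exceeds this.
    absence_floor:
        Relative activities below this are treated as absent.
    min_branch_variants:
        Branches with fewer variants are merged with a neighbouring branch
        before analysis.
    """

    inclusion_floor: float = 0.01
    importance_cutoff: float = 0.02
    absence_floor: float = 0.001
    min_branch_variants: float = 20


@dataclass
class BranchResult:
    branch_id: str
    detected: set[str]
    activities: dict[str, float]
    importance: ImportanceReport | None
    provenance: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class TreeResult:
    branch_results: dict[str, BranchResult]
    merged_tree: CloneTree
    merge_map: dict[str, str]

    @property
    def global_signatures(self) -> set[str]:
        out: set[str] = set()
        for r in self.branch_results.values():
            out |= r.detected
        return out

    def detections(self) -> dict[str, set[str]]:
        return {b: set(r.detected) for b, r in self.branch_results.items()}

    def activity_table(self) -> pd.DataFrame:
        rows = []
        for bid, r in self.branch_results.items():
            for sig in sorted(r.detected):
                rec = (
                    r.importance.per_signature.get(sig)
                    if r.importance is not None
                    else None
                )
                rows.append(
                    {
                        "branch": bid,
                        "signature": sig,
                        "activity": r.activities[sig],
                        "iS": rec.i_score if rec is not None else float("nan"),
                    }
                )
        return pd.DataFrame(rows, columns=["branch", "signature", "activity", "iS"])


def assemble_candidates(
    tree: CloneTree,
    branch_id: str,
    catalog: SignatureCatalog,
    refitter: Refitter = qp_refit,
    inclusion_floor: float = 0.01,
) -> tuple[set[str], dict[str, list[str]]]:
    """Candidate signatures for a branch, with per-signature provenance.

    Every pooled variant collection for the branch is refitted against the
    full catalog; a signature becomes a candidate when its estimated
    activity exceeds ``inclusion_floor`` in at least one collection.
    Provenance maps each candidate to the collection labels introducing it.
    """
    candidates: set[str] = set()
    provenance: dict[str, list[str]] = {}
    for label, pooled in tree.pooled_collections(branch_id):
        result = refitter(pooled, catalog, list(catalog.names))
        for sig, act in result.activities.items():
            if act > inclusion_floor:
                candidates.add(sig)
                provenance.setdefault(sig, []).append(label)
    return candidates, provenance


def filter_candidates(
    spectrum: MutationSpectrum,
    catalog: SignatureCatalog,
    candidates: Sequence[str],
    refitter: Refitter = qp_refit,
    cutoff: float = 0.02,
) -> tuple[set[str], ImportanceReport | None]:
    """Importance-test candidates on the branch's own spectrum.

    A single candidate is retained as-is (no exclusion is possible). When
    the test removes everything, the top-scoring candidate is kept so the
    branch still receives a detection.
    """
    candidates = sorted(candidates)
    if not candidates:
        return set(), None
    if len(candidates) == 1:
        return {candidates[0]}, None
    report = importance_scores(spectrum, catalog, candidates, refitter)
    retained = retain_important(report, cutoff)
    if not retained:
        best = max(report.scores(), key=lambda s: (report.score(s), s))
        logger.warning("importance filter emptied the candidate set; keeping %s", best)
        retained = {best}
    return retained, report


def propagate_neighbors(
    tree: CloneTree,
    retained: Mapping[str, set[str]],
    catalog: SignatureCatalog,
    refitter: Refitter = qp_refit,
    config: PipelineConfig | None = None,
) -> dict[str, BranchResult]:
    """One pass adding signatures detected only at immediate relatives.

    Neighbour-added signatures are importance-tested on the branch's own
    spectrum; a branch's own retained signatures are kept without re-testing.
    Survivors are refitted for final activities and the absence floor is
    applied (own signatures falling below it are dropped too).
    """
    cfg = config or PipelineConfig()
    results: dict[str, BranchResult] = {}
    for bid in tree.branches:
        own = set(retained.get(bid, set()))
        neighbour_only: set[str] = set()
        for nb in tree.neighbors(bid).all():
            neighbour_only |= set(retained.get(nb, set()))
        neighbour_only -= own
        spectrum = tree.branch(bid).spectrum
        test_set = sorted(own | neighbour_only)
        report: ImportanceReport | None = None
        if neighbour_only and len(test_set) >= 2:
            report = importance_scores(spectrum, catalog, test_set, refitter)
            accepted = {
                s for s in neighbour_only
                if report.score(s) > cfg.importance_cutoff
            }
        else:
            accepted = set()
        final_set = sorted(own | accepted)
        if not final_set:
            logger.warning("branch %s: empty signature set after propagation; "
                           "falling back to own retained set", bid)
            final_set = sorted(own)
        if not final_set:
            results[bid] = BranchResult(bid, set(), {}, report)
            continue
        fit = refitter(spectrum, catalog, final_set)
        detected = drop_absent(fit, cfg.absence_floor)
        if not detected:
            detected = {max(fit.activities, key=fit.activities.get)}
        acts = {s: fit.activities[s] for s in detected}
        total = sum(acts.values())
        acts = {s: a / total for s, a in acts.items()}
        if report is None and len(final_set) >= 2:
            report = importance_scores(spectrum, catalog, final_set, refitter)
        results[bid] = BranchResult(bid, detected, acts, report)
    return results


def run_phylosignare(
    tree: CloneTree,
    catalog: SignatureCatalog,
    refitter: Refitter = qp_refit,
    config: PipelineConfig | None = None,
) -> TreeResult:
    """Run the full branch-by-branch detection procedure on a clone tree."""
    cfg = config or PipelineConfig()
    merged, merge_map = merge_small_branches(tree, cfg.min_branch_variants)
    retained: dict[str, set[str]] = {}
    reports: dict[str, ImportanceReport | None] = {}
    provenance: dict[str, dict[str, list[str]]] = {}
    for bid in merged.branches:
        cands, prov = assemble_candidates(
            merged, bid, catalog, refitter, cfg.inclusion_floor
        )
        logger.info("branch %s: %d candidate signatures %s", bid, len(cands),
                    sorted(cands))
        kept, report = filter_candidates(
            merged.branch(bid).spectrum, catalog, sorted(cands), refitter,
            cfg.importance_cutoff,
        )
        logger.info("branch %s: retained %s after importance filtering",
                    bid, sorted(kept))
        retained[bid] = kept
        reports[bid] = report
        provenance[bid] = prov
    results = propagate_neighbors(merged, retained, catalog, refitter, cfg)
    for bid, res in results.items():
        res.provenance = {
            s: provenance[bid].get(s, ["neighbor-propagation"]) for s in res.detected
        }
    return TreeResult(results, merged, merge_map)


def refit_all(
    tree: CloneTree,
    catalog: SignatureCatalog,
    refitter: Refitter = qp_refit,
    floor: float = 0.001,
) -> set[str]:
    """Whole-tumour baseline: pool every branch's variants and refit once."""
    pooled = MutationSpectrum()
    for b in tree.branches.values():
        pooled = pooled + b.spectrum
    return drop_absent(refitter(pooled, catalog, list(catalog.names)), floor)


def global_signatures(result: TreeResult) -> set[str]:
    """Whole-tumour signature set: the union of per-branch detections."""
    return result.global_signatures


def write_results(result: TreeResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.activity_table().to_csv(out / "branch_signatures.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"signature": sorted(result.global_signatures)}
    ).to_csv(out / "global_signatures.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"original_branch": o, "analyzed_branch": n} for o, n in result.merge_map.items()]
    ).to_csv(out / "branch_merge_map.tsv", sep="\t", index=False)
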