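"""Synthetic clone-phylogeny signature datasets.

Two generators mirror the benchmark protocols the method is evaluated on:

* :func:`simulate_physigs_style` — five- or seven-branch phylogenies whose
  signature sets change through at most two gain/loss events, so the tree
  splits into at most three contiguous regions sharing one signature set and
  one symmetric-Dirichlet exposure vector; observed spectra are expected
  context proportions perturbed with Gaussian noise (sd 0.1, 0.2 or 0.3 on
  proportions), clamped, renormalised and scaled to the branch variant count.
* :func:`simulate_multinomial_style` — per-branch exposures drawn from a
  Dirichlet and integer counts drawn from a multinomial, the regime of the
  worked five-branch example (trunk A with one signature, B/C gaining a
  second, D/E a third, 20–100 variants per branch).

:func:`make_synthetic_catalog` builds sparse, well-separated probability
columns so the rest of the package is testable without any downloaded
catalog.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .phylogeny import Branch, CloneTree, to_newick
from .refit import SignatureCatalog
from .spectra import N_CONTEXTS, MutationSpectrum, write_spectra_tsv

#: Parent table of the five-branch example topology: trunk A, children B and
#: C, with C subtending the cherry (D, E).
TOPOLOGY_5 = {"A": None, "B": "A", "C": "A", "D": "C", "E": "C"}
#: Seven-branch extension: E subtends a further cherry (F, G).
TOPOLOGY_7 = {"A": None, "B": "A", "C": "A", "D": "C", "E": "C", "F": "E", "G": "E"}


@dataclass
class SimulatedDataset:
    tree: CloneTree
    truth_signatures: dict[str, set[str]]
    truth_activities: dict[str, dict[str, float]]
    meta: dict = field(default_factory=dict)

    def branch_sizes(self) -> dict[str, float]:
        return {bid: b.total_n for bid, b in self.tree.branches.items()}


def make_synthetic_catalog(
    n_signatures: int,
    concentration: float = 0.2,
    seed: int | np.random.Generator | None = None,
) -> SignatureCatalog:
    """Random column-stochastic catalog with controllable column separation.

    Each column is a draw from a symmetric Dirichlet over the 96 contexts;
    small ``concentration`` gives sparse, peaked, nearly orthogonal columns,
    large values give flat (hard-to-separate) ones. The default of 0.2
    yields spiky columns with mild pairwise overlap (median cosine
    similarity around 0.15), emulating the separation structure of the
    COSMIC v2 catalog.
    """
    if n_signatures < 1:
        raise ValueError("need at least one signature")
    rng = np.random.default_rng(seed)
    cols = rng.dirichlet(np.full(N_CONTEXTS, concentration), size=n_signatures).T
    names = tuple(f"SYN{i + 1}" for i in range(n_signatures))
    return SignatureCatalog(cols, names)


def _largest_remainder_round(values: np.ndarray, total: int) -> np.ndarray:
    """Round non-negative values to integers conserving their target total."""
    floors = np.floor(values).astype(int)
    shortfall = total - int(floors.sum())
    if shortfall > 0:
        order = np.argsort(-(values - floors), kind="stable")
        floors[order[:shortfall]] += 1
    return floors.astype(float)


def random_signature_history(
    topology: Mapping[str, str | None],
    catalog_names: Sequence[str],
    n_signatures: int,
    n_events: int,
    rng: np.random.Generator,
) -> tuple[dict[str, set[str]], list[tuple[str, str, str]], dict[str, int]]:
    """Assign signature sets along a tree via gain/loss events.

    A base set of ``n_signatures`` signatures (sampled uniformly without
    replacement) is active on the trunk; each of the ``n_events`` (at most
    two) gain or loss events hits a random non-trunk branch and applies to
    its whole clade, partitioning the tree into at most ``n_events + 1``
    contiguous regions. Returns per-branch truth sets, the event list
    (kind, branch, signature) and a per-branch region id (the tuple of
    event indices affecting the branch, so nested events yield distinct
    regions).
    """
    if n_events > 2:
        raise ValueError("at most two gain/loss events are supported")
    names = list(catalog_names)
    if n_signatures > len(names):
        raise ValueError("more signatures requested than the catalog holds")
    tree = CloneTree(Branch(bid, MutationSpectrum(), parent)
                     for bid, parent in topology.items())
    base = set(rng.choice(names, size=n_signatures, replace=False).tolist())
    truth = {bid: set(base) for bid in tree.branches}
    applied: dict[str, tuple[int, ...]] = {bid: () for bid in tree.branches}
    non_trunk = sorted(b for b in tree.branches if b != tree.trunk_id)
    events: list[tuple[str, str, str]] = []
    event_branches = rng.choice(non_trunk, size=min(n_events, len(non_trunk)),
                                replace=False)
    for k, ebid in enumerate(event_branches, start=1):
        clade = tree.subtree(str(ebid))
        current = truth[str(ebid)]
        gain_pool = sorted(set(names) - current)
        # a loss may not leave any branch in the clade without signatures
        loss_pool = sorted(
            s for s in current
            if all(len(truth[bid] - {s}) >= 1 for bid in clade)
        )
        kind = "gain"
        if loss_pool and (not gain_pool or rng.random() < 0.5):
            kind = "loss"
        if kind == "gain" and not gain_pool:
            continue
        if kind == "gain":
            sig = str(rng.choice(gain_pool))
            for bid in clade:
                truth[bid] = truth[bid] | {sig}
        else:
            sig = str(rng.choice(loss_pool))
            for bid in clade:
                truth[bid] = truth[bid] - {sig}
        for bid in clade:
            applied[bid] = applied[bid] + (k,)
        events.append((kind, str(ebid), sig))
    return truth, events, applied


def simulate_physigs_style(
    catalog: SignatureCatalog,
    topology: Mapping[str, str | None] | None = None,
    n_signatures: int = 3,
    n_events: int = 2,
    noise_sd: float = 0.1,
    variants_per_branch: tuple[int, int] = (2, 205),
    seed: int | np.random.Generator | None = None,
) -> SimulatedDataset:
    """Gaussian-noise benchmark generator (five/seven-branch phylogenies).

    Each region of the event partition shares one signature set and one
    symmetric-Dirichlet exposure vector. Observed spectra are the expected
    context proportions plus N(0, noise_sd) noise, clamped at zero,
    renormalised, scaled to the branch variant count and rounded with the
    largest-remainder rule (totals conserved exactly).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    topo = dict(topology or TOPOLOGY_5)
    truth, events, region = random_signature_history(
        topo, catalog.names, n_signatures, n_events, rng
    )
    region_acts: dict[tuple[int, ...], dict[str, float]] = {}
    for bid in sorted(topo):
        rid = region[bid]
        if rid not in region_acts:
            active = sorted(truth[bid])
            expo = rng.dirichlet(np.ones(len(active)))
            region_acts[rid] = dict(zip(active, expo.astype(float)))
    lo, hi = variants_per_branch
    branches = []
    activities: dict[str, dict[str, float]] = {}
    for bid, parent in topo.items():
        acts = region_acts[region[bid]]
        activities[bid] = dict(acts)
        a = np.array([acts.get(n, 0.0) for n in catalog.names])
        expected = catalog.matrix @ a
        noisy = np.clip(expected + rng.normal(0.0, noise_sd, N_CONTEXTS), 0.0, None)
        total = noisy.sum()
        noisy = noisy / total if total > 0 else expected
        n_b = int(rng.integers(lo, hi + 1))
        counts = _largest_remainder_round(noisy * n_b, n_b)
        branches.append(Branch(bid, MutationSpectrum(counts), parent))
    tree = CloneTree(branches)
    meta = {"generator": "gaussian", "noise_sd": noise_sd, "events": events,
            "region": region}
    return SimulatedDataset(tree, truth, activities, meta)


def simulate_multinomial_style(
    catalog: SignatureCatalog,
    branch_signatures: Mapping[str, set[str] | Sequence[str]],
    topology: Mapping[str, str | None] | None = None,
    dirichlet_alpha: float = 1.0,
    variants_per_branch: tuple[int, int] = (20, 100),
    seed: int | np.random.Generator | None = None,
) -> SimulatedDataset:
    """Multinomial benchmark generator with per-branch Dirichlet exposures."""
    rng = np.random.default_rng(seed)
    topo = dict(topology or TOPOLOGY_5)
    if set(topo) != set(branch_signatures):
        raise ValueError("branch_signatures must cover exactly the topology branches")
    lo, hi = variants_per_branch
    if lo < 1:
        raise ValueError("each branch needs at least one variant")
    branches = []
    truth: dict[str, set[str]] = {}
    activities: dict[str, dict[str, float]] = {}
    for bid, parent in topo.items():
        active = sorted(str(s) for s in branch_signatures[bid])
        if not active:
            raise ValueError(f"branch {bid!r} has an empty signature set")
        unknown = [s for s in active if s not in catalog.names]
        if unknown:
            raise KeyError(f"signatures not in catalog: {unknown}")
        expo = rng.dirichlet(np.full(len(active), dirichlet_alpha))
        a = np.array([dict(zip(active, expo)).get(n, 0.0) for n in catalog.names])
        n_b = int(rng.integers(lo, hi + 1))
        counts = rng.multinomial(n_b, catalog.matrix @ a).astype(float)
        branches.append(Branch(bid, MutationSpectrum(counts), parent))
        truth[bid] = set(active)
        activities[bid] = dict(zip(active, expo.astype(float)))
    tree = CloneTree(branches)
    meta = {"generator": "multinomial", "dirichlet_alpha": dirichlet_alpha}
    return SimulatedDataset(tree, truth, activities, meta)


def fig2_style_signature_sets(
    signatures: Sequence[str] = ("S17", "S13", "S1"),
) -> dict[str, set[str]]:
    """The worked example's gain history on the five-branch topology.

    The trunk carries the first signature; branches B and C gain the second;
    the cherry D/E gains the third.
    """
    s1, s2, s3 = signatures
    return {
        "A": {s1},
        "B": {s1, s2},
        "C": {s1, s2},
        "D": {s1, s2, s3},
        "E": {s1, s2, s3},
    }


def write_dataset(dataset: SimulatedDataset, out_dir: str | Path) -> None:
    """Write a dataset as Newick tree + counts TSV + truth TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "tree.nwk").write_text(to_newick(dataset.tree) + "\n")
    write_spectra_tsv(
        {bid: b.spectrum for bid, b in dataset.tree.branches.items()},
        out / "counts.tsv",
    )
    rows = []
    for bid in dataset.tree.branches:
        for sig, act in sorted(dataset.truth_activities[bid].items()):
            rows.append({"branch": bid, "signature": sig, "activity": act})
    pd.DataFrame(rows).to_csv(out / "truth.tsv", sep="\t", index=False)
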