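"""96-context single-base-substitution mutation spectra.

A mutation spectrum counts single-base substitutions in the 96 trinucleotide
contexts (six pyrimidine-centred substitution classes x 4 five-prime x 4
three-prime flanking bases). The context ordering follows the COSMIC v2
convention: substitution classes C>A, C>G, C>T, T>A, T>C, T>G, and within
each class the 16 flank combinations in alphabetical order, so the first
context is ``A[C>A]A`` and the last is ``T[T>G]T``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = "ACGT"
N_CONTEXTS = 96

#: Canonical context labels, e.g. "A[C>A]A", in COSMIC v2 row order.
CONTEXT_LABELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_CLASSES
    for five in BASES
    for three in BASES
)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_LABEL_INDEX = {label: i for i, label in enumerate(CONTEXT_LABELS)}


class InvalidVariantError(ValueError):
    """Raised for malformed substitution inputs (non-ACGT bases, ref == alt)."""


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def classify_context(ref_tri: str, alt: str) -> int:
    """Map a reference trinucleotide plus alternate base to its context index.

    Purine-centred substitutions are reverse-complemented onto the pyrimidine
    strand before indexing, so a variant and its reverse complement always
    share one of the 96 canonical contexts.

    Parameters
    ----------
    ref_tri:
        The reference trinucleotide; the middle base is the mutated base.
    alt:
        The alternate base observed at the middle position.

    Returns
    -------
    int
        Index into :data:`CONTEXT_LABELS` (0..95).
    """
    ref_tri = ref_tri.upper()
    alt = alt.upper()
    if len(ref_tri) != 3 or any(b not in _COMPLEMENT for b in ref_tri):
        raise InvalidVariantError(f"invalid trinucleotide {ref_tri!r}")
    if alt not in _COMPLEMENT:
        raise InvalidVariantError(f"invalid alternate base {alt!r}")
    if alt == ref_tri[1]:
        raise InvalidVariantError("alternate base equals the reference base")
    if ref_tri[1] in "AG":  # purine-centred: flip to the pyrimidine strand
        ref_tri = _revcomp(ref_tri)
        alt = _COMPLEMENT[alt]
    label = f"{ref_tri[0]}[{ref_tri[1]}>{alt}]{ref_tri[2]}"
    return _LABEL_INDEX[label]


@dataclass
class MutationSpectrum:
    """Counts of substitutions over the 96 canonical trinucleotide contexts."""

    counts: np.ndarray = field(default_factory=lambda: np.zeros(N_CONTEXTS))

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (N_CONTEXTS,):
            raise ValueError(f"spectrum must have {N_CONTEXTS} entries")
        if (self.counts < 0).any():
            raise ValueError("spectrum counts must be non-negative")

    @property
    def total_n(self) -> float:
        return float(self.counts.sum())

    def __add__(self, other: "MutationSpectrum") -> "MutationSpectrum":
        return MutationSpectrum(self.counts + other.counts)

    def proportions(self) -> np.ndarray:
        """Counts normalised to sum to one; zeros for an empty spectrum."""
        n = self.total_n
        return self.counts / n if n > 0 else np.zeros_like(self.counts)

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(CONTEXT_LABELS))

    @classmethod
    def from_mapping(cls, counts: Mapping[str, float]) -> "MutationSpectrum":
        arr = np.zeros(N_CONTEXTS)
        for label, value in counts.items():
            arr[_LABEL_INDEX[label]] = value
        return cls(arr)


@dataclass(frozen=True)
class VariantCall:
    """A single-base somatic substitution assigned to a clone-tree branch."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    branch_id: str

    def is_snv(self) -> bool:
        return (
            len(self.ref) == 1
            and len(self.alt) == 1
            and self.ref in _COMPLEMENT
            and self.alt in _COMPLEMENT
            and self.ref != self.alt
        )


def spectrum_from_variants(
    variants: Iterable[VariantCall],
    genome,
) -> dict[str, MutationSpectrum]:
    """Classify variants against a reference genome into per-branch spectra.

    ``genome`` is any mapping from chromosome name to an indexable sequence
    (a plain dict of strings, or a ``pyfaidx.Fasta``). Non-SNV records and
    records whose flanks fall outside the reference are skipped and counted
    in the log; the per-branch totals therefore equal the number of accepted
    SNVs on each branch.
    """
    per_branch: dict[str, np.ndarray] = {}
    skipped_non_snv = 0
    skipped_out_of_range = 0
    for v in variants:
        if not v.is_snv():
            skipped_non_snv += 1
            continue
        if v.pos < 2:  # no 5' flank
            tri = ""
        else:
            try:
                seq = genome[v.chrom]
                tri = str(seq[v.pos - 2 : v.pos + 1]).upper()
            except (KeyError, IndexError):
                tri = ""
        if len(tri) != 3:
            logger.warning("variant %s:%d outside reference; skipped", v.chrom, v.pos)
            skipped_out_of_range += 1
            continue
        if tri[1] != v.ref.upper():
            logger.warning(
                "reference mismatch at %s:%d (file %s, genome %s); skipped",
                v.chrom, v.pos, v.ref, tri[1],
            )
            skipped_out_of_range += 1
            continue
        idx = classify_context(tri, v.alt)
        per_branch.setdefault(v.branch_id, np.zeros(N_CONTEXTS))[idx] += 1
    if skipped_non_snv or skipped_out_of_range:
        logger.info(
            "skipped %d non-SNV and %d out-of-reference records",
            skipped_non_snv, skipped_out_of_range,
        )
    return {b: MutationSpectrum(c) for b, c in per_branch.items()}


# ---------------------------------------------------------------------------
# I/O

def read_variant_tsv(path: str | Path) -> list[VariantCall]:
    """Read a 5-column variant table: chrom, pos, ref, alt, branch_id.

    A header row is accepted and detected by a non-numeric second column.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 5:
        raise ValueError("variant TSV needs 5 columns: chrom pos ref alt branch_id")
    first = str(df.iloc[0, 1])
    if not first.isdigit():
        df = df.iloc[1:]
    return [
        VariantCall(str(r[0]), int(r[1]), str(r[2]), str(r[3]), str(r[4]))
        for r in df.itertuples(index=False)
    ]


def read_variants_vcf(path: str | Path, branch_info_key: str = "BRANCH") -> list[VariantCall]:
    """Read SNV records from a VCF; the branch id comes from an INFO field."""
    import pysam

    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            branch = rec.info.get(branch_info_key)
            if isinstance(branch, tuple):
                branch = branch[0]
            if branch is None:
                logger.warning("record %s:%d lacks INFO/%s; skipped",
                               rec.chrom, rec.pos, branch_info_key)
                continue
            for alt in rec.alts or ():
                calls.append(VariantCall(rec.chrom, rec.pos, rec.ref, alt, str(branch)))
    return calls


def read_spectra_tsv(path: str | Path) -> dict[str, MutationSpectrum]:
    """Read a branches x 96 spectrum table (rows = branches, canonical columns)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [c for c in CONTEXT_LABELS if c not in df.columns]
    if missing:
        raise ValueError(f"spectrum TSV missing context columns, e.g. {missing[0]!r}")
    df = df[list(CONTEXT_LABELS)]
    return {str(b): MutationSpectrum(row.to_numpy(float)) for b, row in df.iterrows()}


def write_spectra_tsv(spectra: Mapping[str, MutationSpectrum], path: str | Path) -> None:
    df = pd.DataFrame(
        {b: s.counts for b, s in spectra.items()}, index=list(CONTEXT_LABELS)
    ).T
    df.index.name = "branch"
    df.to_csv(path, sep="\t")
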