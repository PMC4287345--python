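"""Protein functional regions (PFRs) and mutation-to-region assignment.

A protein functional region is the unit of association testing: a Pfam
domain, a predicted domain, or an intrinsically disordered region (IDR)
within one protein isoform. Regions from different annotation sources are
kept independent — overlapping regions are never merged, and a mutation
falling inside several regions is assigned to each of them.

IDRs are predicted with the FoldIndex charge/hydropathy score

    FI = 2.785 * <H> - |<q>| - 1.151

computed in a sliding window, where ``<H>`` is the mean Kyte–Doolittle
hydropathy rescaled to [0, 1] and ``<q>`` the mean net charge (K, R = +1;
D, E = -1). Windows are truncated at the sequence termini. A residue with
FI below the disorder threshold (default -0.1) is called disordered, and
maximal disordered runs of at least ``min_length`` residues become IDRs.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ProteinIsoform",
    "Pfr",
    "MissenseMutation",
    "DisorderProfile",
    "PFR_SOURCES",
    "foldindex_profile",
    "predict_idrs",
    "select_largest_isoform",
    "assign_mutations_to_regions",
]

#: Kyte–Doolittle hydropathy index, one value per standard residue.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Net side-chain charge at physiological pH; residues not listed are 0.
RESIDUE_CHARGE: dict[str, float] = {"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0}

STANDARD_RESIDUES = frozenset(KYTE_DOOLITTLE)

PFR_SOURCES = frozenset({"pfam", "predicted_domain", "idr"})

# FoldIndex closed-form constants.
_FI_HYDRO_COEF = 2.785
_FI_OFFSET = 1.151

DEFAULT_FOLDINDEX_WINDOW = 51
DEFAULT_DISORDER_THRESHOLD = -0.1
DEFAULT_MIN_IDR_LENGTH = 10


@dataclass(frozen=True)
class ProteinIsoform:
    """One protein-coding isoform of a gene.

    The sequence uses the 20-letter amino-acid alphabet; 'X' is permitted
    for ambiguous residues. A gene may own several isoforms; downstream
    analyses conventionally keep only the largest one per gene
    (:func:`select_largest_isoform`).
    """

    gene_id: str
    isoform_id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"isoform {self.isoform_id!r}: empty sequence")
        bad = set(self.sequence) - STANDARD_RESIDUES - {"X"}
        if bad:
            raise ValueError(
                f"isoform {self.isoform_id!r}: non-standard residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Pfr:
    """A protein functional region: a 1-based inclusive residue interval.

    ``source`` records how the region was annotated (``pfam``,
    ``predicted_domain`` or ``idr``). Regions from different sources may
    overlap and are retained independently, never merged.
    """

    region_id: str
    gene_id: str
    isoform_id: str
    source: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.source not in PFR_SOURCES:
            raise ValueError(
                f"region {self.region_id!r}: unknown source {self.source!r} "
                f"(expected one of {sorted(PFR_SOURCES)})"
            )
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"region {self.region_id!r}: invalid interval "
                f"[{self.start}, {self.end}] (1-based inclusive)"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class MissenseMutation:
    """A single amino-acid substitution in one sample's protein isoform."""

    sample_id: str
    gene_id: str
    isoform_id: str
    position: int
    ref_aa: str
    alt_aa: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(
                f"mutation {self.sample_id}/{self.isoform_id}: "
                f"position {self.position} is not 1-based"
            )
        if self.ref_aa == self.alt_aa:
            raise ValueError(
                f"mutation {self.sample_id}/{self.isoform_id} at "
                f"{self.position}: ref and alt residues are identical "
                f"({self.ref_aa!r}) — not a missense change"
            )


@dataclass(frozen=True)
class DisorderProfile:
    """Per-residue FoldIndex scores for one isoform."""

    isoform_id: str
    scores: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "scores", np.asarray(self.scores, dtype=float))

    def __len__(self) -> int:
        return len(self.scores)


def foldindex_profile(
    sequence: str,
    window: int = DEFAULT_FOLDINDEX_WINDOW,
    isoform_id: str = "",
) -> DisorderProfile:
    """Compute the per-residue FoldIndex disorder profile of a sequence.

    For each residue the score ``2.785*<H> - |<q>| - 1.151`` is evaluated
    over the window centred on it, truncating the window at the termini.
    Hydropathy is Kyte–Doolittle rescaled to [0, 1] via ``(h + 4.5) / 9``;
    'X' contributes neutral hydropathy (0.5) and zero charge. Negative
    scores indicate a charged, hydrophilic — hence likely unfolded —
    segment.

    Parameters
    ----------
    sequence
        Amino-acid string over the 20-letter alphabet plus 'X'.
    window
        Odd positive window length in residues.
    isoform_id
        Carried through to the returned profile.
    """
    if not sequence:
        raise ValueError("foldindex_profile: empty sequence")
    if window < 1 or window % 2 == 0:
        raise ValueError(f"foldindex_profile: window must be odd and >= 1, got {window}")

    n = len(sequence)
    # Hydropathies have one decimal, so window sums are kept as exact
    # integers (tenths); this makes the profile invariant under sequence
    # reversal bit for bit, not just up to rounding.
    hydro10 = np.empty(n, dtype=np.int64)
    charge = np.empty(n, dtype=np.int64)
    for i, aa in enumerate(sequence):
        if aa == "X":
            hydro10[i] = 0  # neutral: scaled hydropathy 0.5
            charge[i] = 0
        elif aa in KYTE_DOOLITTLE:
            hydro10[i] = round(KYTE_DOOLITTLE[aa] * 10)
            charge[i] = int(RESIDUE_CHARGE.get(aa, 0.0))
        else:
            raise ValueError(f"foldindex_profile: non-standard residue {aa!r} at position {i + 1}")

    half = window // 2
    # Windowed sums with truncation at the termini, via cumulative sums.
    ch = np.concatenate(([0], np.cumsum(hydro10)))
    cq = np.concatenate(([0], np.cumsum(charge)))
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    width = hi - lo
    # <H> = mean of (h + 4.5)/9 over the window, as an exact ratio.
    mean_h = (ch[hi] - ch[lo] + 45 * width) / (90.0 * width)
    mean_q = (cq[hi] - cq[lo]) / width
    scores = _FI_HYDRO_COEF * mean_h - np.abs(mean_q) - _FI_OFFSET
    return DisorderProfile(isoform_id=isoform_id, scores=scores)


def predict_idrs(
    profile: DisorderProfile,
    threshold: float = DEFAULT_DISORDER_THRESHOLD,
    min_length: int = DEFAULT_MIN_IDR_LENGTH,
    gene_id: str = "",
) -> list[Pfr]:
    """Extract intrinsically disordered regions from a disorder profile.

    Returns the maximal runs of consecutive residues scoring strictly below
    ``threshold`` whose length is at least ``min_length``, as 1-based
    inclusive :class:`Pfr` intervals tagged ``source='idr'``. Runs are
    disjoint by construction and sorted by start coordinate.
    """
    if min_length < 1:
        raise ValueError(f"predict_idrs: min_length must be >= 1, got {min_length}")
    below = profile.scores < threshold
    regions: list[Pfr] = []
    start = None
    for i, flag in enumerate(np.append(below, False)):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= min_length:
                s, e = start + 1, i  # 1-based inclusive
                regions.append(
                    Pfr(
                        region_id=f"{profile.isoform_id}:idr:{s}-{e}",
                        gene_id=gene_id,
                        isoform_id=profile.isoform_id,
                        source="idr",
                        start=s,
                        end=e,
                        name="IDR",
                    )
                )
            start = None
    return regions


def select_largest_isoform(isoforms: Sequence[ProteinIsoform]) -> ProteinIsoform:
    """Pick the longest isoform of a gene; ties break to the smallest id."""
    if not isoforms:
        raise ValueError("select_largest_isoform: empty isoform list")
    genes = {iso.gene_id for iso in isoforms}
    if len(genes) > 1:
        raise ValueError(
            f"select_largest_isoform: isoforms from several genes {sorted(genes)}"
        )
    return min(isoforms, key=lambda iso: (-len(iso.sequence), iso.isoform_id))


def assign_mutations_to_regions(
    mutations: Iterable[MissenseMutation],
    regions: Iterable[Pfr],
    isoform_lengths: Mapping[str, int] | None = None,
) -> dict[str, set[tuple[str, int]]]:
    """Map each mutation onto every region of its isoform that covers it.

    Overlapping regions each receive the mutation; mutations covered by no
    region contribute nothing here but remain available for gene-level
    testing. When ``isoform_lengths`` is given, a mutation beyond its
    isoform's length is rejected with an error naming the record.

    Returns a mapping ``region_id -> {(sample_id, position), ...}`` with an
    entry for every input region (possibly empty).
    """
    by_isoform: dict[str, list[Pfr]] = defaultdict(list)
    assignments: dict[str, set[tuple[str, int]]] = {}
    for region in regions:
        by_isoform[region.isoform_id].append(region)
        assignments[region.region_id] = set()
    for mut in mutations:
        if isoform_lengths is not None:
            length = isoform_lengths.get(mut.isoform_id)
            if length is not None and mut.position > length:
                raise ValueError(
                    f"mutation {mut.sample_id}/{mut.gene_id}/{mut.isoform_id} "
                    f"at position {mut.position} exceeds isoform length {length}"
                )
        for region in by_isoform.get(mut.isoform_id, ()):
            if region.contains(mut.position):
                assignments[region.region_id].add((mut.sample_id, mut.position))
    return assignments
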