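"""Synthetic cohorts with known region-structured effects.

Generates proteomes (random sequences with non-overlapping functional
regions), cohorts of samples with randomly placed missense mutations, and
Gaussian activity-area values with *planted* per-region shifts. Because
the ground truth is known, every stage of the association screen can be
validated: type-I error on null cohorts, recovery of planted effects, and
the signature cancellation design in which two regions of one gene shift
drug activity in opposite directions so the whole-gene signal vanishes.

Defaults emulate an activity-area scale comparable to large cell-line
panels (baseline 3.0, noise sd 0.5 on a 0–8 range); all draws flow from a
single seeded generator, so a truth plus its seed reproduces the cohort
bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .association import AssociationResult, CohortDataset, DrugActivityTable
from .regions import MissenseMutation, Pfr, ProteinIsoform

__all__ = [
    "PlantedEffect",
    "SyntheticTruth",
    "RecoveryReport",
    "generate_proteome",
    "generate_cohort",
    "generate_opposing_effects_cohort",
    "recovery_report",
]

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

DEFAULT_BASELINE = 3.0
DEFAULT_NOISE_SD = 0.5
DEFAULT_MUTATION_RATE = 0.05


@dataclass(frozen=True)
class PlantedEffect:
    """A known shift in activity area for samples mutated in one region.

    Negative ``delta`` lowers the activity area of region-mutated samples
    (a resistance effect); positive raises it (sensitizing).
    """

    region_id: str
    drug_id: str
    delta: float


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a simulated cohort: planted effects plus noise model."""

    effects: tuple[PlantedEffect, ...] = ()
    baseline_mean: float = DEFAULT_BASELINE
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "effects", tuple(self.effects))
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd must be positive, got {self.noise_sd}")


def generate_proteome(
    n_genes: int,
    regions_per_gene: int | tuple[int, int] = 2,
    length_range: tuple[int, int] = (200, 800),
    seed: int = 0,
    region_length_range: tuple[int, int] = (30, 120),
    include_idr: bool = False,
) -> tuple[list[ProteinIsoform], list[Pfr]]:
    """Generate random protein isoforms with non-overlapping regions.

    Each gene gets one isoform of random length and ``regions_per_gene``
    disjoint regions (a fixed count, or a ``(lo, hi)`` inclusive range
    sampled per gene). With ``include_idr`` the last region of each gene
    is tagged as an IDR instead of a Pfam domain. Raises when the
    requested regions cannot fit into the shortest admissible sequence.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be positive")
    lo_k, hi_k = (
        (regions_per_gene, regions_per_gene)
        if isinstance(regions_per_gene, int)
        else regions_per_gene
    )
    if lo_k < 0 or hi_k < lo_k:
        raise ValueError(f"invalid regions_per_gene range ({lo_k}, {hi_k})")
    min_len, max_len = length_range
    r_lo, r_hi = region_length_range
    if hi_k > 0 and hi_k * r_lo > min_len:
        raise ValueError(
            f"cannot pack {hi_k} regions of at least {r_lo} residues into a "
            f"sequence of length {min_len}"
        )

    rng = np.random.default_rng(seed)
    isoforms: list[ProteinIsoform] = []
    regions: list[Pfr] = []
    for g in range(n_genes):
        gene = f"G{g:04d}"
        iso = f"{gene}.1"
        length = int(rng.integers(min_len, max_len + 1))
        seq = "".join(rng.choice(AMINO_ACIDS, size=length))
        isoforms.append(ProteinIsoform(gene_id=gene, isoform_id=iso, sequence=seq))

        k = int(rng.integers(lo_k, hi_k + 1))
        if k == 0:
            continue
        # One region per equal-width block keeps intervals disjoint.
        block = length // k
        for j in range(k):
            rlen = int(rng.integers(r_lo, min(r_hi, block) + 1))
            start0 = int(rng.integers(0, block - rlen + 1)) + j * block
            source = "idr" if include_idr and j == k - 1 else "pfam"
            regions.append(
                Pfr(
                    region_id=f"{iso}:R{j}",
                    gene_id=gene,
                    isoform_id=iso,
                    source=source,
                    start=start0 + 1,
                    end=start0 + rlen,
                    name=f"region_{j}",
                )
            )
    return isoforms, regions


def _random_missense(
    rng: np.random.Generator, sample: str, iso: ProteinIsoform, position: int
) -> MissenseMutation:
    ref = iso.sequence[position - 1]
    choices = AMINO_ACIDS[AMINO_ACIDS != ref]
    alt = str(rng.choice(choices))
    return MissenseMutation(
        sample_id=sample,
        gene_id=iso.gene_id,
        isoform_id=iso.isoform_id,
        position=position,
        ref_aa=ref,
        alt_aa=alt,
    )


def _activity_frame(
    rng: np.random.Generator,
    samples: list[str],
    drugs: Sequence[str],
    truth: SyntheticTruth,
    region_samples: dict[str, set[str]],
) -> DrugActivityTable:
    values = rng.normal(truth.baseline_mean, truth.noise_sd, size=(len(samples), len(drugs)))
    frame = pd.DataFrame(values, index=samples, columns=list(drugs))
    for eff in truth.effects:
        carriers = region_samples.get(eff.region_id, set())
        if carriers:
            frame.loc[sorted(carriers), eff.drug_id] += eff.delta
    # Activity areas are non-negative by definition.
    return DrugActivityTable(frame.clip(lower=0.0))


def generate_cohort(
    proteome: tuple[list[ProteinIsoform], list[Pfr]],
    n_samples: int,
    per_sample_mutation_rate: float,
    truth: SyntheticTruth,
    drugs: Sequence[str],
) -> CohortDataset:
    """Simulate a cohort over a generated proteome.

    Each sample independently acquires a mutation in each gene with
    probability ``per_sample_mutation_rate``; mutated positions are
    uniform over the gene's residues. Activity areas are drawn from
    ``Normal(baseline_mean, noise_sd)`` per (sample, drug), planted
    effects are added to region-mutated samples, and values are clipped
    at 0. Fully deterministic given ``truth.seed``.
    """
    if not 0.0 < per_sample_mutation_rate <= 1.0:
        raise ValueError(
            f"per_sample_mutation_rate must be in (0, 1], got {per_sample_mutation_rate}"
        )
    isoforms, regions = proteome
    rng = np.random.default_rng(truth.seed)
    samples = [f"S{i:04d}" for i in range(n_samples)]

    mutations: list[MissenseMutation] = []
    hits = rng.random((n_samples, len(isoforms))) < per_sample_mutation_rate
    for si, sample in enumerate(samples):
        for gi in np.flatnonzero(hits[si]):
            iso = isoforms[gi]
            position = int(rng.integers(1, len(iso) + 1))
            mutations.append(_random_missense(rng, sample, iso, position))

    region_samples: dict[str, set[str]] = {r.region_id: set() for r in regions}
    by_iso: dict[str, list[Pfr]] = {}
    for r in regions:
        by_iso.setdefault(r.isoform_id, []).append(r)
    for mut in mutations:
        for r in by_iso.get(mut.isoform_id, ()):
            if r.contains(mut.position):
                region_samples[r.region_id].add(mut.sample_id)

    activity = _activity_frame(rng, samples, drugs, truth, region_samples)
    return CohortDataset(
        isoforms=isoforms, regions=regions, mutations=mutations, activity=activity
    )


def generate_opposing_effects_cohort(
    n_genes: int = 5,
    n_mut_per_region: int = 15,
    delta: float = 1.0,
    noise_sd: float = DEFAULT_NOISE_SD,
    baseline_mean: float = DEFAULT_BASELINE,
    n_samples: int = 200,
    seed: int = 0,
) -> tuple[CohortDataset, SyntheticTruth]:
    """Build the two-region cancellation design with balanced mutation counts.

    Every gene carries two disjoint regions; exactly ``n_mut_per_region``
    samples are mutated in each (disjoint sample sets, chosen at random
    per gene), and the planted shifts are ``-delta`` on the first region
    and ``+delta`` on the second, applied to a drug private to that gene
    (one drug column per gene, so effects planted for different genes
    cannot contaminate each other's comparison groups). With balanced
    counts the two shifts cancel in the whole-gene mutated group, so the
    gene-level test stays null while both region-level contrasts carry
    full signal — the situation the region-centric screen exists to
    detect.
    """
    if 2 * n_mut_per_region > n_samples:
        raise ValueError("need n_samples >= 2 * n_mut_per_region")
    isoforms, regions = generate_proteome(
        n_genes, regions_per_gene=2, length_range=(300, 500), seed=seed
    )
    rng = np.random.default_rng(np.random.default_rng(seed).integers(2**31))
    samples = [f"S{i:04d}" for i in range(n_samples)]
    by_gene: dict[str, list[Pfr]] = {}
    for r in regions:
        by_gene.setdefault(r.gene_id, []).append(r)

    mutations: list[MissenseMutation] = []
    effects: list[PlantedEffect] = []
    iso_by_gene = {iso.gene_id: iso for iso in isoforms}
    drugs = {gene: f"DRUG_{gene}" for gene in sorted(by_gene)}
    for gene, (r_minus, r_plus) in sorted(by_gene.items()):
        chosen = rng.choice(n_samples, size=2 * n_mut_per_region, replace=False)
        iso = iso_by_gene[gene]
        for idx, region, sign in (
            (chosen[:n_mut_per_region], r_minus, -1.0),
            (chosen[n_mut_per_region:], r_plus, +1.0),
        ):
            for si in idx:
                position = int(rng.integers(region.start, region.end + 1))
                mutations.append(_random_missense(rng, samples[si], iso, position))
            effects.append(
                PlantedEffect(
                    region_id=region.region_id, drug_id=drugs[gene], delta=sign * delta
                )
            )

    truth = SyntheticTruth(
        effects=tuple(effects), baseline_mean=baseline_mean, noise_sd=noise_sd, seed=seed
    )
    region_samples: dict[str, set[str]] = {r.region_id: set() for r in regions}
    for mut in mutations:
        for r in by_gene[mut.gene_id]:
            if r.contains(mut.position):
                region_samples[r.region_id].add(mut.sample_id)
    activity = _activity_frame(
        rng, samples, [drugs[g] for g in sorted(by_gene)], truth, region_samples
    )
    dataset = CohortDataset(
        isoforms=isoforms, regions=regions, mutations=mutations, activity=activity
    )
    return dataset, truth


@dataclass(frozen=True)
class RecoveryReport:
    """How well a screen recovered the planted truth of a synthetic cohort."""

    n_planted: int
    n_tested: int
    true_positives: int
    false_positives: int
    missed: tuple[str, ...]
    sensitivity: float | None
    false_positive_fraction: float | None

    def as_dict(self) -> dict:
        d = {
            "n_planted": self.n_planted,
            "n_tested": self.n_tested,
            "true_positives": self.true_positives,
            "false_positives": self.false_positives,
            "missed": list(self.missed),
            "sensitivity": self.sensitivity,
            "false_positive_fraction": self.false_positive_fraction,
        }
        return d


def recovery_report(
    results: Sequence[AssociationResult], truth: SyntheticTruth
) -> RecoveryReport:
    """Score screen results against the planted truth.

    A planted pair counts as a true positive only when called significant
    *with the matching direction* (planted ``delta < 0`` must be called
    ``resistance``); a significant call on an unplanted pair, or with the
    wrong direction, is a false positive. The false-positive fraction is
    taken over tested (stage-I-reached) unplanted pairs — the empirical
    type-I error of the full staged procedure.
    """
    planted = {
        (e.region_id, e.drug_id): ("resistance" if e.delta < 0 else "sensitizing")
        for e in truth.effects
    }
    result_keys = {(r.region_id, r.drug_id) for r in results}
    unknown = set(planted) - result_keys
    if unknown:
        raise ValueError(
            f"planted pairs absent from results: {sorted(unknown)[:5]} "
            f"(results from a different dataset?)"
        )

    tp = fp = 0
    missed: list[str] = []
    n_tested = 0
    n_tested_unplanted = 0
    for r in results:
        key = (r.region_id, r.drug_id)
        tested = r.p_stage1 is not None
        n_tested += tested
        if key in planted:
            if r.status == "significant" and r.direction == planted[key]:
                tp += 1
            else:
                missed.append(f"{r.region_id}|{r.drug_id}")
                if r.status == "significant":  # wrong direction
                    fp += 1
        else:
            n_tested_unplanted += tested
            if r.status == "significant":
                fp += 1

    n_planted = len(planted)
    return RecoveryReport(
        n_planted=n_planted,
        n_tested=n_tested,
        true_positives=tp,
        false_positives=fp,
        missed=tuple(missed),
        sensitivity=(tp / n_planted) if n_planted else None,
        false_positive_fraction=(
            fp / n_tested_unplanted if n_tested_unplanted else None
        ),
    )
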