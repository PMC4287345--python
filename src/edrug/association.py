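"""The e-Drug association engine.

Tests, for every (protein functional region, drug) pair, whether samples
carrying a missense mutation in the region show shifted drug activity
(activity area — the area above the dose–response curve; higher values
mean a more effective drug). Three nested rank-sum comparisons filter the
candidate pairs:

* **stage I** — region-mutated samples vs a comparison group (by default
  samples with no missense anywhere in the gene); keep pairs with
  ``p < p_stage1`` (default 0.01);
* **gene level** — gene-mutated vs gene-unmutated samples; pairs whose
  gene already shows the association (``p < p_gene``, default 0.01) are
  discarded as carrying no region-specific signal;
* **stage II** — region-mutated vs mutated-elsewhere-in-the-gene; keep
  pairs with ``p < p_stage2`` (default 0.05, the looser level reflecting
  the smaller groups).

A pair passing all three is a significant region-specific association;
the sign of the median activity difference labels it *sensitizing*
(mutants respond better) or *resistance* (mutants respond worse). The
staged design recovers effects that cancel at the whole-gene level, e.g.
two regions of one gene shifting activity in opposite directions.
"""

from __future__ import annotations

import math
from functools import lru_cache
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .regions import MissenseMutation, Pfr, ProteinIsoform, assign_mutations_to_regions

__all__ = [
    "DrugActivityTable",
    "CohortDataset",
    "AssociationThresholds",
    "AssociationResult",
    "rank_sum_test",
    "stage1_test",
    "gene_level_test",
    "stage2_test",
    "run_edrug",
    "effect_direction",
    "results_to_frame",
]

ComparisonGroup = Literal["gene_unmutated", "region_unmutated"]

#: Largest *smaller-group* size at which the exact rank-sum null is used.
#: The staged screen routinely compares a handful of mutated samples with
#: hundreds of unmutated ones; in that regime the normal approximation is
#: badly conservative while the exact null stays cheap, so the switch is
#: keyed to the smaller group.
EXACT_MIN_GROUP = 8

STATUSES = (
    "significant",
    "insufficient_mutations",
    "fail_stage1",
    "gene_level",
    "fail_stage2",
)


class DrugActivityTable:
    """Samples × drugs matrix of activity-area values.

    Missing cells (``NaN``) mean the sample was not profiled for that
    drug; present values must be non-negative (the activity area is an
    area above a dose–response curve).
    """

    def __init__(self, frame: pd.DataFrame):
        if frame.index.has_duplicates:
            dup = frame.index[frame.index.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r} in activity table")
        if frame.columns.has_duplicates:
            dup = frame.columns[frame.columns.duplicated()][0]
            raise ValueError(f"duplicate drug id {dup!r} in activity table")
        values = frame.to_numpy(dtype=float, copy=False)
        if np.nanmin(values, initial=0.0) < 0:
            raise ValueError("activity area values must be >= 0")
        self.frame = frame.astype(float)

    @property
    def samples(self) -> list[str]:
        return list(self.frame.index)

    @property
    def drugs(self) -> list[str]:
        return list(self.frame.columns)

    def profiled(self, drug: str) -> pd.Series:
        """Non-missing activity values for one drug, indexed by sample."""
        if drug not in self.frame.columns:
            raise KeyError(f"drug {drug!r} not in activity table")
        return self.frame[drug].dropna()

    def __eq__(self, other: object) -> bool:
        return isinstance(other, DrugActivityTable) and self.frame.equals(other.frame)


@dataclass
class CohortDataset:
    """A cohort: isoforms, functional regions, mutations and drug response.

    Mutated samples absent from the activity table are tolerated (they are
    simply never profiled for any drug and drop out of every test).
    """

    isoforms: list[ProteinIsoform]
    regions: list[Pfr]
    mutations: list[MissenseMutation]
    activity: DrugActivityTable

    _region_samples: dict[str, frozenset[str]] = field(default=None, repr=False, compare=False)
    _gene_samples: dict[str, frozenset[str]] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        lengths = {iso.isoform_id: len(iso) for iso in self.isoforms}
        assigned = assign_mutations_to_regions(self.mutations, self.regions, lengths)
        self._region_samples = {
            rid: frozenset(s for s, _ in pairs) for rid, pairs in assigned.items()
        }
        gene_samples: dict[str, set[str]] = {}
        for mut in self.mutations:
            gene_samples.setdefault(mut.gene_id, set()).add(mut.sample_id)
        self._gene_samples = {g: frozenset(s) for g, s in gene_samples.items()}

    def region_mutated_samples(self, region_id: str) -> frozenset[str]:
        """Samples with >=1 missense mutation inside the region."""
        return self._region_samples.get(region_id, frozenset())

    def gene_mutated_samples(self, gene_id: str) -> frozenset[str]:
        """Samples with >=1 missense mutation anywhere in the gene."""
        return self._gene_samples.get(gene_id, frozenset())

    def unprofiled_samples(self) -> set[str]:
        """Mutated samples that never appear in the activity table."""
        profiled = set(self.activity.samples)
        return {m.sample_id for m in self.mutations} - profiled


@dataclass(frozen=True)
class AssociationThresholds:
    """Significance levels and the minimum-mutation filter for a run."""

    p_stage1: float = 0.01
    p_gene: float = 0.01
    p_stage2: float = 0.05
    min_mutated: int = 2

    def __post_init__(self) -> None:
        for name in ("p_stage1", "p_gene", "p_stage2"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.min_mutated < 1:
            raise ValueError(f"min_mutated must be >= 1, got {self.min_mutated}")


@dataclass(frozen=True)
class AssociationResult:
    """Outcome of the three-stage test for one (region, drug) pair."""

    region_id: str
    gene_id: str
    drug_id: str
    source: str
    n_region_mut: int
    n_other_mut: int
    n_unmut: int
    p_stage1: float | None
    p_gene: float | None
    p_stage2: float | None
    delta_median: float | None
    direction: str | None
    status: str
    q_stage1: float | None = None

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")


def rank_sum_test(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) p-value.

    Uses the exact null distribution of the U statistic — equivalent to
    enumerating every assignment of the pooled observations to the two
    groups — whenever the smaller group has at most
    :data:`EXACT_MIN_GROUP` members and there are no ties; otherwise the
    normal approximation with tie-corrected variance and a continuity
    correction. Ties receive average ranks.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("rank_sum_test: both groups must be non-empty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0

    has_ties = np.unique(pooled).size < pooled.size
    if min(n1, n2) <= EXACT_MIN_GROUP and not has_ties:
        return _exact_rank_sum_p(n1, n2, int(round(u1)))
    return _normal_rank_sum_p(pooled, ranks, n1, n2, u1)


@lru_cache(maxsize=8192)
def _mwu_null_cdf(m: int, n: int) -> tuple[np.ndarray, float]:
    """Exact null counts of the Mann–Whitney U statistic.

    Returns the cumulative counts ``cum[u] = #{m-subsets with U <= u}``
    for a group of size ``m`` against one of size ``n``, plus the total
    ``C(m+n, m)``. The count generating function is the Gaussian binomial
    coefficient ``[m+n, m]_q = prod_i (1-q^(n+i)) / (1-q^i)``, built by
    iterated polynomial multiplication/division. Counts are integers held
    in float64: exact up to 2**53, far beyond every regime where exact
    equality matters, and drifting only in the last ulp beyond it.
    """
    size = m * n + m + 1  # head-room for intermediate degrees
    poly = np.zeros(size)
    poly[0] = 1.0
    for i in range(1, m + 1):
        hi = n + i
        poly[hi:] -= poly[:-hi].copy()
        for r in range(i):  # divide by (1 - q^i): prefix sums at stride i
            poly[r::i] = np.cumsum(poly[r::i])
    counts = poly[: m * n + 1]
    cum = np.cumsum(counts)
    return cum, float(cum[-1])


def _exact_rank_sum_p(n1: int, n2: int, u1: int) -> float:
    """Exact two-sided p from the enumerated null distribution of U."""
    cum, total = _mwu_null_cdf(min(n1, n2), max(n1, n2))
    if n1 > n2:  # U of the larger group maps onto the smaller-group null
        u1 = n1 * n2 - u1
    le = cum[u1]
    ge = total - (cum[u1 - 1] if u1 > 0 else 0.0)
    return min(1.0, 2.0 * min(le, ge) / total)


def _normal_rank_sum_p(
    pooled: np.ndarray, ranks: np.ndarray, n1: int, n2: int, u1: float
) -> float:
    """Tie-corrected normal approximation with continuity correction."""
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (n * (n - 1.0))
    var = n1 * n2 / 12.0 * (n + 1.0 - tie_term)
    if var <= 0:
        return 1.0  # all observations identical
    diff = u1 - mu
    # Continuity correction shrinks the deviation by 1/2 toward the mean.
    cc = 0.5 * np.sign(diff)
    z = (diff - cc) / math.sqrt(var)
    return min(1.0, 2.0 * stats.norm.sf(abs(z)))


@dataclass(frozen=True)
class StageResult:
    p: float | None
    delta_median: float | None
    n_mut: int
    n_comp: int


def _group_values(act: pd.Series, samples: Iterable[str]) -> np.ndarray:
    idx = act.index.intersection(list(samples))
    return act.loc[idx].to_numpy()


def stage1_test(
    region: Pfr,
    drug: str,
    dataset: CohortDataset,
    comparison: ComparisonGroup = "gene_unmutated",
) -> StageResult:
    """Region-mutated vs comparison-group activity for one drug.

    The comparison group is either every profiled sample with no missense
    anywhere in the gene (``gene_unmutated``, the default) or every
    profiled sample with no missense in the region (``region_unmutated``,
    which additionally includes other-region mutants).
    """
    act = dataset.activity.profiled(drug)
    profiled = set(act.index)
    mutated = set(dataset.region_mutated_samples(region.region_id)) & profiled
    gene_mut = set(dataset.gene_mutated_samples(region.gene_id)) & profiled
    if comparison == "gene_unmutated":
        comp = profiled - gene_mut
    elif comparison == "region_unmutated":
        comp = profiled - mutated
    else:
        raise ValueError(f"unknown comparison group {comparison!r}")
    if not mutated or not comp:
        return StageResult(None, None, len(mutated), len(comp))
    a = _group_values(act, mutated)
    b = _group_values(act, comp)
    p = rank_sum_test(a, b)
    delta = float(np.median(a) - np.median(b))
    return StageResult(p, delta, len(mutated), len(comp))


def gene_level_test(gene: str, drug: str, dataset: CohortDataset) -> float:
    """Whole-gene mutated vs unmutated rank-sum p-value for one drug."""
    act = dataset.activity.profiled(drug)
    profiled = set(act.index)
    mutated = set(dataset.gene_mutated_samples(gene)) & profiled
    unmutated = profiled - mutated
    if not mutated or not unmutated:
        raise ValueError(
            f"gene_level_test: gene {gene!r} / drug {drug!r} has an empty group"
        )
    return rank_sum_test(_group_values(act, mutated), _group_values(act, unmutated))


def stage2_test(region: Pfr, drug: str, dataset: CohortDataset) -> float | None:
    """Region-mutated vs mutated-elsewhere-in-the-gene comparison.

    Samples mutated both inside and outside the region count as
    region-mutated only. Returns ``None`` when every gene mutation lies
    inside the region (no within-gene contrast exists); such a pair can
    never be called significant.
    """
    act = dataset.activity.profiled(drug)
    profiled = set(act.index)
    mutated = set(dataset.region_mutated_samples(region.region_id)) & profiled
    other = (set(dataset.gene_mutated_samples(region.gene_id)) & profiled) - mutated
    if not mutated:
        raise ValueError(
            f"stage2_test: region {region.region_id!r} has no mutated profiled samples"
        )
    if not other:
        return None
    return rank_sum_test(_group_values(act, mutated), _group_values(act, other))


def effect_direction(delta_median: float) -> str:
    """Label an activity shift: mutants with lower activity area resist the drug."""
    if not math.isfinite(delta_median):
        raise ValueError(f"effect_direction: non-finite delta {delta_median!r}")
    if delta_median < 0:
        return "resistance"
    if delta_median > 0:
        return "sensitizing"
    return "undetermined"


def run_edrug(
    dataset: CohortDataset,
    thresholds: AssociationThresholds = AssociationThresholds(),
    comparison: ComparisonGroup = "gene_unmutated",
) -> list[AssociationResult]:
    """Run the full three-stage screen over every (region, drug) pair.

    Every pair is reported with its status; intermediate p-values are
    retained for the stages each pair reached. Benjamini–Hochberg
    ``q_stage1`` values are attached across all stage-I-tested pairs as an
    informational column (the decision rule itself uses the raw staged
    thresholds). The output is deterministic, ordered by
    ``(drug_id, region_id)``.
    """
    results: list[AssociationResult] = []
    regions = sorted(dataset.regions, key=lambda r: r.region_id)
    gene_p_cache: dict[tuple[str, str], float] = {}

    for drug in sorted(dataset.activity.drugs):
        act = dataset.activity.profiled(drug)
        profiled = set(act.index)
        for region in regions:
            mutated = set(dataset.region_mutated_samples(region.region_id)) & profiled
            gene_mut = set(dataset.gene_mutated_samples(region.gene_id)) & profiled
            other = gene_mut - mutated
            unmut = profiled - gene_mut
            counts = dict(
                n_region_mut=len(mutated), n_other_mut=len(other), n_unmut=len(unmut)
            )
            common = dict(
                region_id=region.region_id,
                gene_id=region.gene_id,
                drug_id=drug,
                source=region.source,
                **counts,
            )

            if len(mutated) < thresholds.min_mutated:
                results.append(
                    AssociationResult(
                        **common,
                        p_stage1=None, p_gene=None, p_stage2=None,
                        delta_median=None, direction=None,
                        status="insufficient_mutations",
                    )
                )
                continue

            s1 = stage1_test(region, drug, dataset, comparison)
            if s1.p is None:  # comparison group empty
                results.append(
                    AssociationResult(
                        **common,
                        p_stage1=None, p_gene=None, p_stage2=None,
                        delta_median=None, direction=None,
                        status="insufficient_mutations",
                    )
                )
                continue
            direction = effect_direction(s1.delta_median)

            if s1.p >= thresholds.p_stage1:
                results.append(
                    AssociationResult(
                        **common,
                        p_stage1=s1.p, p_gene=None, p_stage2=None,
                        delta_median=s1.delta_median, direction=direction,
                        status="fail_stage1",
                    )
                )
                continue

            key = (region.gene_id, drug)
            if key not in gene_p_cache:
                gene_p_cache[key] = gene_level_test(region.gene_id, drug, dataset)
            pg = gene_p_cache[key]
            if pg < thresholds.p_gene:
                results.append(
                    AssociationResult(
                        **common,
                        p_stage1=s1.p, p_gene=pg, p_stage2=None,
                        delta_median=s1.delta_median, direction=direction,
                        status="gene_level",
                    )
                )
                continue

            p2 = stage2_test(region, drug, dataset)
            status = (
                "significant" if p2 is not None and p2 < thresholds.p_stage2
                else "fail_stage2"
            )
            results.append(
                AssociationResult(
                    **common,
                    p_stage1=s1.p, p_gene=pg, p_stage2=p2,
                    delta_median=s1.delta_median, direction=direction,
                    status=status,
                )
            )

    return _attach_q_stage1(results)


def _attach_q_stage1(results: list[AssociationResult]) -> list[AssociationResult]:
    tested = [i for i, r in enumerate(results) if r.p_stage1 is not None]
    if not tested:
        return results
    pvals = [results[i].p_stage1 for i in tested]
    qvals = multipletests(pvals, method="fdr_bh")[1]
    out = list(results)
    for i, q in zip(tested, qvals):
        r = out[i]
        out[i] = AssociationResult(
            region_id=r.region_id, gene_id=r.gene_id, drug_id=r.drug_id,
            source=r.source, n_region_mut=r.n_region_mut,
            n_other_mut=r.n_other_mut, n_unmut=r.n_unmut,
            p_stage1=r.p_stage1, p_gene=r.p_gene, p_stage2=r.p_stage2,
            delta_median=r.delta_median, direction=r.direction,
            status=r.status, q_stage1=float(q),
        )
    return out


RESULT_COLUMNS = [
    "region_id", "gene_id", "drug_id", "source",
    "n_region_mut", "n_other_mut", "n_unmut",
    "p_stage1", "p_gene", "p_stage2", "q_stage1",
    "delta_median", "direction", "status",
]


def results_to_frame(results: Iterable[AssociationResult]) -> pd.DataFrame:
    """Association results as a tidy DataFrame in the canonical column order."""
    rows = [{c: getattr(r, c) for c in RESULT_COLUMNS} for r in results]
    frame = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    return frame.sort_values(["drug_id", "region_id"], kind="mergesort").reset_index(drop=True)
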