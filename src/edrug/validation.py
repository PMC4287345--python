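"""Downstream validation of region–drug associations.

Operations mirroring the follow-up analyses a region-centric
pharmacogenomic screen feeds into:

* **survival** — stratify treated patients into three groups (mutated in
  a resistance-associated region, mutated elsewhere in the same genes,
  unmutated) and compare outcomes with Kaplan–Meier curves and the
  k-sample log-rank test;
* **proteomics** — rank-sum tests of protein expression between mutation
  groups, and Pearson correlation of expression with drug activity;
* **chemistry** — overlap of associated proteins with a drug's targets
  (STITCH-style 0–1000 interaction scores, Fisher exact test), optionally
  expanding the target set through chemicals with Tanimoto fingerprint
  similarity above a cutoff;
* **function** — GO term enrichment of associated genes against a
  background, with Benjamini–Hochberg q-values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .association import rank_sum_test
from .regions import MissenseMutation, Pfr

__all__ = [
    "ClinicalRecord",
    "SURVIVAL_GROUPS",
    "InteractionRecord",
    "Fingerprint",
    "SurvivalCurve",
    "LogrankResult",
    "classify_patients",
    "kaplan_meier",
    "logrank_test",
    "expression_group_test",
    "expression_activity_correlation",
    "fisher_exact",
    "target_overlap_test",
    "tanimoto",
    "expand_targets_by_similarity",
    "go_enrichment",
]

logger = logging.getLogger(__name__)

SURVIVAL_GROUPS = ("resistant_pfr_mutated", "other_region_mutated", "gene_unmutated")


@dataclass(frozen=True)
class ClinicalRecord:
    """One treated patient: survival outcome plus protein-level mutations.

    ``event=True`` marks an observed death/progression; ``False`` a
    censored follow-up. ``mutations=None`` means no mutation profiling is
    available (such patients are excluded from stratification), while an
    empty tuple means profiled and mutation-free.
    """

    patient_id: str
    drug_id: str
    time: float
    event: bool
    mutations: tuple[MissenseMutation, ...] | None = ()

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"patient {self.patient_id!r}: negative survival time")
        if self.mutations is not None:
            object.__setattr__(self, "mutations", tuple(self.mutations))


@dataclass(frozen=True)
class InteractionRecord:
    """A chemical–protein interaction with a 0–1000 confidence score."""

    chemical_id: str
    protein_id: str
    score: int

    def __post_init__(self) -> None:
        if not 0 <= self.score <= 1000:
            raise ValueError(
                f"interaction {self.chemical_id}–{self.protein_id}: "
                f"score {self.score} outside [0, 1000]"
            )


@dataclass(frozen=True)
class Fingerprint:
    """A chemical's 2D structural fingerprint as a fixed-length bit vector."""

    chemical_id: str
    bits: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "bits", np.asarray(self.bits, dtype=bool))


def classify_patients(
    records: Sequence[ClinicalRecord], resistance_regions: Iterable[Pfr]
) -> dict[str, str]:
    """Assign each profiled patient to one of the three survival strata.

    Only resistance-direction regions drive stratification. Precedence:
    a mutation inside any resistance region wins over mutations elsewhere
    in the same genes, which win over no mutation. Patients without
    mutation data are excluded (their count is logged).
    """
    regions = list(resistance_regions)
    genes = {r.gene_id for r in regions}
    labels: dict[str, str] = {}
    n_excluded = 0
    for rec in records:
        if rec.mutations is None:
            n_excluded += 1
            continue
        in_region = any(
            r.isoform_id == m.isoform_id and r.contains(m.position)
            for m in rec.mutations
            for r in regions
        )
        if in_region:
            labels[rec.patient_id] = "resistant_pfr_mutated"
        elif any(m.gene_id in genes for m in rec.mutations):
            labels[rec.patient_id] = "other_region_mutated"
        else:
            labels[rec.patient_id] = "gene_unmutated"
    if n_excluded:
        logger.info("classify_patients: excluded %d patients with no mutation data", n_excluded)
    return labels


@dataclass(frozen=True)
class SurvivalCurve:
    """A Kaplan–Meier product-limit estimate.

    ``times`` holds the distinct event times in increasing order and
    ``survival`` the estimate just after each; the curve is
    right-continuous with S(0) = 1 and drops only at event times.
    """

    times: np.ndarray
    survival: np.ndarray

    def at(self, t: float) -> float:
        """Survival probability at time ``t``."""
        i = np.searchsorted(self.times, t, side="right")
        return 1.0 if i == 0 else float(self.survival[i - 1])


def kaplan_meier(times: Sequence[float], events: Sequence[bool]) -> SurvivalCurve:
    """Product-limit survival estimate.

    At each distinct event time ``t`` with ``d`` events among ``n`` at
    risk the estimate is multiplied by ``1 - d/n``. Subjects censored at
    ``t`` are still at risk for the events at ``t`` (events processed
    first at ties).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValueError("kaplan_meier: empty input")
    if t.size != e.size:
        raise ValueError("kaplan_meier: times and events differ in length")
    if (t < 0).any():
        raise ValueError("kaplan_meier: negative survival time")

    event_times = np.unique(t[e])
    surv = []
    s = 1.0
    for et in event_times:
        n_at_risk = int((t >= et).sum())
        d = int(((t == et) & e).sum())
        s *= 1.0 - d / n_at_risk
        surv.append(s)
    return SurvivalCurve(times=event_times, survival=np.asarray(surv))


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    df: int
    p: float
    #: index of the group with more observed than expected events (worse
    #: outcome); only populated for two-group comparisons.
    worse_group: int | None
    observed: np.ndarray = field(repr=False)
    expected: np.ndarray = field(repr=False)


def logrank_test(
    groups: Sequence[tuple[Sequence[float], Sequence[bool]]]
) -> LogrankResult:
    """Unweighted k-sample log-rank test on ``(times, events)`` groups.

    Pools the groups, and at every distinct event time compares each
    group's observed event count with its expectation under the
    hypergeometric null given the risk sets; the quadratic form of the
    observed−expected vector in its estimated covariance is chi-squared
    with k−1 degrees of freedom.
    """
    k = len(groups)
    if k < 2:
        raise ValueError("logrank_test: need at least two groups")
    ts, es, labels = [], [], []
    for gi, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=bool)
        if t.size == 0:
            raise ValueError(f"logrank_test: group {gi} is empty")
        ts.append(t)
        es.append(e)
        labels.append(np.full(t.size, gi))
    t_all = np.concatenate(ts)
    e_all = np.concatenate(es)
    g_all = np.concatenate(labels)

    observed = np.zeros(k)
    expected = np.zeros(k)
    cov = np.zeros((k, k))
    for et in np.unique(t_all[e_all]):
        at_risk = t_all >= et
        n = int(at_risk.sum())
        n_j = np.array([(at_risk & (g_all == j)).sum() for j in range(k)], dtype=float)
        dying = (t_all == et) & e_all
        d = int(dying.sum())
        d_j = np.array([(dying & (g_all == j)).sum() for j in range(k)], dtype=float)
        observed += d_j
        p_j = n_j / n
        expected += d * p_j
        if n > 1:
            factor = d * (n - d) / (n - 1.0)
            cov += factor * (np.diag(p_j) - np.outer(p_j, p_j))

    v = (observed - expected)[: k - 1]
    vm = cov[: k - 1, : k - 1]
    statistic = float(v @ np.linalg.pinv(vm) @ v)
    p = float(stats.chi2.sf(statistic, df=k - 1))
    worse = None
    if k == 2:
        diff = observed - expected
        worse = int(np.argmax(diff)) if not np.allclose(diff, 0) else None
    return LogrankResult(
        statistic=statistic, df=k - 1, p=p, worse_group=worse,
        observed=observed, expected=expected,
    )


def expression_group_test(
    expression: Mapping[str, float],
    group_a_samples: Iterable[str],
    group_b_samples: Iterable[str],
) -> tuple[float, float]:
    """Rank-sum comparison of expression between two sample groups.

    Returns ``(p, delta_median)`` where ``delta_median`` is the median of
    group A minus the median of group B; samples without an expression
    value are ignored.
    """
    a = np.array([expression[s] for s in group_a_samples if s in expression])
    b = np.array([expression[s] for s in group_b_samples if s in expression])
    if a.size == 0 or b.size == 0:
        raise ValueError("expression_group_test: a group has no expression values")
    p = rank_sum_test(a, b)
    return p, float(np.median(a) - np.median(b))


def expression_activity_correlation(
    expression: Sequence[float], activity: Sequence[float]
) -> tuple[float, float]:
    """Pearson correlation of expression with drug activity.

    Pairs with a missing value on either side are dropped; at least three
    complete pairs and non-degenerate variance are required. The p-value
    is the two-sided t-transform with n−2 degrees of freedom.
    """
    x = np.asarray(expression, dtype=float)
    y = np.asarray(activity, dtype=float)
    if x.size != y.size:
        raise ValueError("expression_activity_correlation: length mismatch")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError(
            f"expression_activity_correlation: need >= 3 complete pairs, got {x.size}"
        )
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("expression_activity_correlation: zero variance in an input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def fisher_exact(
    table: Sequence[Sequence[int]], alternative: str = "greater"
) -> float:
    """Fisher exact test p-value on a 2×2 contingency table.

    Computed by exact integer enumeration of the hypergeometric
    distribution over all tables with the observed margins (so the result
    is the correctly rounded float of the rational tail probability).
    ``two-sided`` sums every table whose point probability does not
    exceed the observed one, the convention of R's ``fisher.test``. Any
    table with a zero margin has probability 1.
    """
    arr = np.asarray(table, dtype=int)
    if arr.shape != (2, 2):
        raise ValueError(f"fisher_exact: expected a 2x2 table, got shape {arr.shape}")
    if (arr < 0).any():
        raise ValueError("fisher_exact: negative counts")
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"fisher_exact: unknown alternative {alternative!r}")
    (a, b), (c, d) = arr.tolist()
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if 0 in (r1, r2, c1, c2):
        return 1.0
    n = r1 + r2
    k_lo, k_hi = max(0, c1 - r2), min(r1, c1)
    weight = {k: math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(k_lo, k_hi + 1)}
    total = math.comb(n, c1)
    if alternative == "greater":
        num = sum(w for k, w in weight.items() if k >= a)
    elif alternative == "less":
        num = sum(w for k, w in weight.items() if k <= a)
    else:
        num = sum(w for w in weight.values() if w <= weight[a])
    return min(1.0, num / total)


def target_overlap_test(
    associated_proteins: set[str],
    drug: str,
    interactions: Sequence[InteractionRecord],
    score_threshold: int,
    background: set[str],
) -> tuple[int, float]:
    """Enrichment of a drug's targets among its associated proteins.

    Target set = proteins interacting with the drug at or above
    ``score_threshold``, restricted to the tested background; the overlap
    with the associated set is scored by a one-sided Fisher exact test.
    A drug with no qualifying targets yields ``(0, 1.0)``.
    """
    if not associated_proteins <= background:
        extra = sorted(associated_proteins - background)[:5]
        raise ValueError(f"associated proteins outside background: {extra}")
    targets = {
        rec.protein_id
        for rec in interactions
        if rec.chemical_id == drug and rec.score >= score_threshold
    } & background
    if not targets:
        return 0, 1.0
    a = len(associated_proteins & targets)
    b = len(associated_proteins) - a
    c = len(targets) - a
    d = len(background) - len(associated_proteins) - c
    p = fisher_exact([[a, b], [c, d]], alternative="greater")
    return a, p


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto (Jaccard) similarity of two equal-length bit fingerprints.

    Defined as 1.0 when both fingerprints are all-zero.
    """
    if a.bits.size != b.bits.size:
        raise ValueError(
            f"tanimoto: fingerprint lengths differ ({a.bits.size} vs {b.bits.size})"
        )
    union = int(np.logical_or(a.bits, b.bits).sum())
    if union == 0:
        return 1.0
    inter = int(np.logical_and(a.bits, b.bits).sum())
    return inter / union


def expand_targets_by_similarity(
    drug: str,
    fingerprints: Sequence[Fingerprint],
    interactions: Sequence[InteractionRecord],
    tanimoto_cutoff: float = 0.70,
    score_threshold: int = 700,
) -> set[str]:
    """Union of target sets over the drug and its structural analogues.

    Chemicals with Tanimoto similarity to the drug strictly above
    ``tanimoto_cutoff`` contribute their targets (at ``score_threshold``)
    alongside the drug's own.
    """
    by_id = {fp.chemical_id: fp for fp in fingerprints}
    if drug not in by_id:
        raise ValueError(f"expand_targets_by_similarity: no fingerprint for {drug!r}")
    ref = by_id[drug]
    similar = {drug} | {
        fp.chemical_id
        for fp in fingerprints
        if fp.chemical_id != drug and tanimoto(ref, fp) > tanimoto_cutoff
    }
    return {
        rec.protein_id
        for rec in interactions
        if rec.chemical_id in similar and rec.score >= score_threshold
    }


def go_enrichment(
    gene_set: set[str],
    annotations: Mapping[str, set[str]],
    background: set[str],
) -> pd.DataFrame:
    """Per-term GO enrichment of a gene set against a background.

    One-sided Fisher exact test per term over the background universe,
    with Benjamini–Hochberg q-values across the tested terms. Terms with
    no annotated member in the background are skipped. Returns a frame
    with columns ``term, count_in_set, count_in_background, p, q`` sorted
    by ascending p.
    """
    if not background:
        raise ValueError("go_enrichment: empty background")
    if not gene_set <= background:
        extra = sorted(gene_set - background)[:5]
        raise ValueError(f"go_enrichment: genes outside background: {extra}")
    terms: dict[str, set[str]] = {}
    for gene in background:
        for term in annotations.get(gene, ()):
            terms.setdefault(term, set()).add(gene)

    rows = []
    n_bg = len(background)
    n_set = len(gene_set)
    for term in sorted(terms):
        members = terms[term]
        k = len(gene_set & members)
        big_k = len(members)
        table = [[k, n_set - k], [big_k - k, n_bg - n_set - (big_k - k)]]
        rows.append(
            {
                "term": term,
                "count_in_set": k,
                "count_in_background": big_k,
                "p": fisher_exact(table, alternative="greater"),
            }
        )
    frame = pd.DataFrame(rows, columns=["term", "count_in_set", "count_in_background", "p"])
    if len(frame):
        frame["q"] = multipletests(frame["p"].to_numpy(), method="fdr_bh")[1]
        frame = frame.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)
    else:
        frame["q"] = []
    return frame
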