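"""Site-level aggregation, unique-site accounting, overlaps, enrichment
with Benjamini-Hochberg FDR, and recovery scoring against planted truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _scipy_stats
from statsmodels.stats.multitest import multipletests

from .errors import GlycodiffError, InvalidParameterError
from .model import ISOFORMS, DifferentialCall, SiteCall, SyntheticTruth


# ---------------------------------------------------------------------------
# Site-level aggregation

def aggregate_site_quant(ratios) -> float:
    """Median ratio of the glycopeptides supporting one site (even counts
    use the mean of the two central values)."""
    values = list(ratios)
    if not values:
        raise GlycodiffError("empty support for site-level aggregation")
    return float(np.median(values))


# ---------------------------------------------------------------------------
# Unique-site accounting

@dataclass
class SiteCounts:
    """Unique-site counts split by multiplicity class and ambiguity."""

    unique: int = 0
    single: int = 0
    multiple: int = 0
    unambiguous: int = 0
    ambiguous: int = 0


def count_unique_sites(
    calls_by_isoform: dict[str, list[SiteCall]],
) -> dict[str, SiteCounts]:
    """Count unique site keys per isoform.

    A site supported by any single-glycan peptide is classed ``single``
    (best evidence wins); ambiguous site groups count once.  The single and
    multiple counts always partition the unique keys.
    """
    out: dict[str, SiteCounts] = {}
    for isoform, calls in calls_by_isoform.items():
        best_class: dict[str, str] = {}
        ambiguous: dict[str, bool] = {}
        for call in calls:
            key = call.key
            previous = best_class.get(key)
            if previous is None or (previous == "multiple" and call.multiplicity == "single"):
                best_class[key] = call.multiplicity
            ambiguous[key] = call.ambiguous
        counts = SiteCounts(unique=len(best_class))
        for key, cls in best_class.items():
            if cls == "single":
                counts.single += 1
            else:
                counts.multiple += 1
            if ambiguous[key]:
                counts.ambiguous += 1
            else:
                counts.unambiguous += 1
        out[isoform] = counts
    return out


# ---------------------------------------------------------------------------
# Venn overlaps

def overlap_sets(sets_by_isoform: dict[str, set[str]]) -> dict[str, int]:
    """Sizes of all seven Venn regions of up to three sets.

    Region labels join the member isoforms with ``&`` (e.g. ``"T1&T3"``
    means in T1 and T3 but not T2).  Regions always partition the union.
    """
    names = [iso for iso in ISOFORMS if iso in sets_by_isoform]
    if len(sets_by_isoform) > 3:
        raise InvalidParameterError("overlap_sets handles at most 3 sets")
    sets = {name: set(sets_by_isoform[name]) for name in names}
    union = set().union(*sets.values()) if sets else set()
    regions: dict[str, int] = {}
    for mask in range(1, 2 ** len(names)):
        members = [names[i] for i in range(len(names)) if mask >> i & 1]
        others = [n for n in names if n not in members]
        region = set(union)
        for name in members:
            region &= sets[name]
        for name in others:
            region -= sets[name]
        regions["&".join(members)] = len(region)
    regions["union"] = len(union)
    return regions


# ---------------------------------------------------------------------------
# Multiple testing and enrichment

def benjamini_hochberg(p_values) -> list[float]:
    """Step-up BH q-values: ``q_(i) = min_{j>=i} p_(j) * m / j``, clipped
    to 1 and order-preserving."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise InvalidParameterError("p values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


@dataclass
class EnrichmentResult:
    """Hypergeometric over-representation of one annotation term."""

    term: str
    k: int  # targets carrying the term
    K: int  # background carrying the term
    n: int  # target-set size
    N: int  # background size
    p: float
    q: float = math.nan


def enrichment_test(
    targets: set[str],
    background: set[str],
    term_map: dict[str, set[str]],
    mode: str = "hypergeometric",
) -> list[EnrichmentResult]:
    """One-sided over-representation per term with BH adjustment.

    ``term_map`` maps term -> annotated members.  ``p = P(X >= k)`` under
    the hypergeometric law with parameters (N, K, n); EASE mode substitutes
    ``k - 1`` (floor 0), the conservative variant popularized by DAVID.
    Results are sorted by q then p.
    """
    if not targets <= background:
        raise InvalidParameterError("target set must be a subset of background")
    if mode not in ("hypergeometric", "ease"):
        raise InvalidParameterError(f"unknown enrichment mode {mode!r}")
    N = len(background)
    n = len(targets)
    results: list[EnrichmentResult] = []
    for term in sorted(term_map):
        members = term_map[term] & background
        K = len(members)
        k = len(members & targets)
        k_eff = max(k - 1, 0) if mode == "ease" else k
        # survival function at k_eff - 1 gives P(X >= k_eff)
        p = float(_scipy_stats.hypergeom.sf(k_eff - 1, N, K, n))
        p = min(max(p, 0.0), 1.0)
        results.append(EnrichmentResult(term=term, k=k, K=K, n=n, N=N, p=p))
    qvalues = benjamini_hochberg([r.p for r in results])
    for result, q in zip(results, qvalues):
        result.q = float(q)
    results.sort(key=lambda r: (r.q, r.p, r.term))
    return results


# ---------------------------------------------------------------------------
# Recovery scoring

@dataclass
class IsoformRecovery:
    true_positives: int = 0
    false_positives: int = 0
    false_negatives: int = 0

    @property
    def precision(self) -> float | None:
        called = self.true_positives + self.false_positives
        return self.true_positives / called if called else None

    @property
    def recall(self) -> float | None:
        truth = self.true_positives + self.false_negatives
        return self.true_positives / truth if truth else None

    @property
    def f1(self) -> float | None:
        p, r = self.precision, self.recall
        if p is None or r is None or p + r == 0:
            return None
        return 2 * p * r / (p + r)


@dataclass
class RecoveryReport:
    """Precision/recall of site-level calls against planted truth."""

    per_isoform: dict[str, IsoformRecovery] = field(default_factory=dict)
    overall: IsoformRecovery = field(default_factory=IsoformRecovery)
    confusion: list[tuple[str, str, str]] = field(default_factory=list)


def evaluate_against_truth(
    calls: list[DifferentialCall], truth: SyntheticTruth
) -> RecoveryReport:
    """Score calls: a call is a true positive iff its site key and isoform
    match a planted truth entry."""
    truth_sets = truth.by_isoform()
    called_sets: dict[str, set[str]] = {iso: set() for iso in ISOFORMS}
    for call in calls:
        called_sets.setdefault(call.isoform, set()).add(call.target)
    report = RecoveryReport()
    for isoform in ISOFORMS:
        truth_keys = truth_sets.get(isoform, set())
        called = called_sets.get(isoform, set())
        rec = IsoformRecovery(
            true_positives=len(called & truth_keys),
            false_positives=len(called - truth_keys),
            false_negatives=len(truth_keys - called),
        )
        report.per_isoform[isoform] = rec
        report.overall.true_positives += rec.true_positives
        report.overall.false_positives += rec.false_positives
        report.overall.false_negatives += rec.false_negatives
        for key in sorted(called - truth_keys):
            report.confusion.append((isoform, key, "false_positive"))
        for key in sorted(truth_keys - called):
            report.confusion.append((isoform, key, "false_negative"))
    return report
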