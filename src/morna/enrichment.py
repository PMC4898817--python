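"""Differential-expression thresholding and binomial target enrichment.

Genes are classed DOWN / UP / UNCHANGED / NOT_DETECTED from a microarray
(or RNA-seq) table under strict fold-change and adjusted-p cutoffs
(defaults |FC| > 1.3 and adj. p < 0.002). For each candidate seed window,
its predicted targets are cross-tabulated against these classes and the
evidence that targets are down-regulated more often than chance is the
exact upper binomial tail

    P(X >= k_down),  X ~ Binomial(n_detected, p0),

with null rate ``p0`` defaulting to the array-wide fraction of detected
genes that are DOWN. Windows are ranked by this tail probability.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .seeds import SeedWindow, TargetSet


class DeClass(enum.Enum):
    DOWN = "DOWN"
    UP = "UP"
    UNCHANGED = "UNCHANGED"
    NOT_DETECTED = "NOT_DETECTED"


@dataclass(frozen=True)
class DeRecord:
    """One gene's differential-expression call.

    ``fold_change`` is magnitude-style and signed: |FC| >= 1 with a minus
    sign marking down-regulation (use :func:`coerce_fold_change` for
    ratio-style inputs where 0 < FC < 1 means down).
    """

    gene_id: str
    fold_change: Optional[float]
    adj_p: Optional[float]
    detected: bool = True

    def __post_init__(self) -> None:
        if self.adj_p is not None and not 0.0 <= self.adj_p <= 1.0:
            raise ValueError(f"{self.gene_id}: adj_p {self.adj_p} outside [0, 1]")
        if self.fold_change is not None and 0 < abs(self.fold_change) < 1:
            raise ValueError(
                f"{self.gene_id}: fold change {self.fold_change} has magnitude < 1; "
                "convert ratio-style values with coerce_fold_change()"
            )


def coerce_fold_change(value: float) -> float:
    """Convert a ratio-style fold change (0 < FC, 1 = no change) to the
    signed magnitude convention (down = negative, |FC| >= 1)."""
    if value <= 0:
        raise ValueError(f"ratio-style fold change must be positive, got {value}")
    return value if value >= 1 else -1.0 / value


@dataclass(frozen=True)
class DeThresholds:
    """Strict cutoffs defining significant regulation."""

    fc_cutoff: float = 1.3
    adjp_cutoff: float = 0.002

    def __post_init__(self) -> None:
        if self.fc_cutoff <= 1:
            raise ValueError("fc_cutoff must be > 1")
        if not 0 < self.adjp_cutoff < 1:
            raise ValueError("adjp_cutoff must be in (0, 1)")


def classify_de(record: DeRecord, thresholds: DeThresholds = DeThresholds()) -> DeClass:
    """DOWN/UP iff |FC| > fc_cutoff AND adj_p < adjp_cutoff (both strict),
    with the sign of the fold change; otherwise UNCHANGED. Undetected
    records are NOT_DETECTED."""
    if not record.detected:
        return DeClass.NOT_DETECTED
    if record.fold_change is None or record.adj_p is None:
        raise ValueError(f"{record.gene_id}: detected record lacks fold change or adj_p")
    if abs(record.fold_change) > thresholds.fc_cutoff and record.adj_p < thresholds.adjp_cutoff:
        return DeClass.DOWN if record.fold_change < 0 else DeClass.UP
    return DeClass.UNCHANGED


@dataclass(frozen=True)
class CrossTab:
    """DE-class composition of one window's predicted targets."""

    n_detected: int
    k_down: int
    k_up: int
    k_unchanged: int

    def __post_init__(self) -> None:
        if self.k_down + self.k_up + self.k_unchanged != self.n_detected:
            raise ValueError("k_down + k_up + k_unchanged must equal n_detected")


def cross_tab(
    targets: TargetSet | Iterable[str],
    de_table: Iterable[DeRecord] | Mapping[str, DeRecord],
    thresholds: DeThresholds = DeThresholds(),
) -> CrossTab:
    """Cross-tabulate predicted target genes against DE classes.

    Targets absent from the table count as NOT_DETECTED and are excluded
    from ``n_detected``.
    """
    genes = targets.genes if isinstance(targets, TargetSet) else set(targets)
    table = de_table if isinstance(de_table, Mapping) else {
        r.gene_id: r for r in de_table
    }
    k = {DeClass.DOWN: 0, DeClass.UP: 0, DeClass.UNCHANGED: 0}
    for gene in genes:
        record = table.get(gene)
        if record is None:
            continue
        cls = classify_de(record, thresholds)
        if cls is not DeClass.NOT_DETECTED:
            k[cls] += 1
    n = sum(k.values())
    return CrossTab(n, k[DeClass.DOWN], k[DeClass.UP], k[DeClass.UNCHANGED])


def estimate_null(
    de_table: Iterable[DeRecord],
    thresholds: DeThresholds = DeThresholds(),
) -> float:
    """Array-wide null down-regulation rate: detected-and-DOWN / detected."""
    n_detected = n_down = 0
    for record in de_table:
        cls = classify_de(record, thresholds)
        if cls is DeClass.NOT_DETECTED:
            continue
        n_detected += 1
        if cls is DeClass.DOWN:
            n_down += 1
    if n_detected == 0:
        raise ValueError("no detected records; cannot estimate the null rate")
    return n_down / n_detected


def binomial_tail(n: int, k: int, p0: float) -> float:
    """Exact one-sided upper binomial tail P(X >= k), X ~ Binomial(n, p0).

    Summed in log space (log-gamma binomial coefficients + log-sum-exp) so
    tails far below double precision of the largest term remain accurate.
    """
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError(f"p0 must be in [0, 1], got {p0}")
    if k == 0:
        return 1.0
    if p0 == 0.0:
        return 0.0
    if p0 == 1.0:
        return 1.0
    logp, logq = math.log(p0), math.log1p(-p0)
    lognf = math.lgamma(n + 1)
    terms = [
        lognf - math.lgamma(j + 1) - math.lgamma(n - j + 1) + j * logp + (n - j) * logq
        for j in range(k, n + 1)
    ]
    peak = max(terms)
    total = peak + math.log(math.fsum(math.exp(t - peak) for t in terms))
    return min(1.0, math.exp(total))


@dataclass(frozen=True)
class EnrichmentResult:
    """Cross-tabulation + binomial evidence for one seed window."""

    window: SeedWindow
    crosstab: CrossTab
    null_p0: float
    tail_prob: float


def enrich_window(
    window: SeedWindow,
    targets: TargetSet,
    de_table: Mapping[str, DeRecord] | Sequence[DeRecord],
    thresholds: DeThresholds = DeThresholds(),
    null_p0: Optional[float] = None,
) -> EnrichmentResult:
    """Cross-tabulate one window's targets and compute its binomial tail."""
    records = de_table.values() if isinstance(de_table, Mapping) else de_table
    if null_p0 is None:
        null_p0 = estimate_null(records, thresholds)
    ct = cross_tab(targets, de_table if isinstance(de_table, Mapping) else {
        r.gene_id: r for r in de_table
    }, thresholds)
    return EnrichmentResult(
        window=window, crosstab=ct, null_p0=null_p0,
        tail_prob=binomial_tail(ct.n_detected, ct.k_down, null_p0),
    )


def rank_windows(results: Iterable[EnrichmentResult]) -> list[EnrichmentResult]:
    """Sort ascending by tail probability; ties broken by larger k_down,
    then smaller window start."""
    return sorted(
        results,
        key=lambda r: (r.tail_prob, -r.crosstab.k_down, r.window.start),
    )


def bonferroni(results: Sequence[EnrichmentResult]) -> list[float]:
    """Supplementary Bonferroni-adjusted tails across the K tested windows."""
    k = len(results)
    return [min(1.0, r.tail_prob * k) for r in results]


@dataclass
class OverlapSets:
    """Multi-window membership of down-regulated predicted targets."""

    membership: dict[str, set[int]] = field(default_factory=dict)
    tiers: dict[int, set[str]] = field(default_factory=dict)

    @property
    def at_least_two(self) -> set[str]:
        """Genes predicted by >= 2 of the selected windows (the candidate-
        target criterion)."""
        return {g for g, wins in self.membership.items() if len(wins) >= 2}


def overlap_sets(target_down_sets: Mapping[int, Iterable[str]]) -> OverlapSets:
    """Per-gene window membership and exact-k tiers over >= 2 windows."""
    if len(target_down_sets) < 2:
        raise ValueError("overlap analysis needs at least two windows")
    membership: dict[str, set[int]] = {}
    for start, genes in target_down_sets.items():
        for gene in genes:
            membership.setdefault(gene, set()).add(start)
    tiers: dict[int, set[str]] = {k: set() for k in range(1, len(target_down_sets) + 1)}
    for gene, wins in membership.items():
        tiers[len(wins)].add(gene)
    return OverlapSets(membership=membership, tiers=tiers)


def enrich_all_windows(
    windows: Sequence[SeedWindow],
    target_sets: Mapping[int, TargetSet],
    de_table: Sequence[DeRecord],
    thresholds: DeThresholds = DeThresholds(),
    null_p0: Optional[float] = None,
) -> list[EnrichmentResult]:
    """Enrichment for every window (targets keyed by window start)."""
    table = {r.gene_id: r for r in de_table}
    if null_p0 is None:
        null_p0 = estimate_null(de_table, thresholds)
    return [
        enrich_window(w, target_sets[w.start], table, thresholds, null_p0)
        for w in windows
    ]
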