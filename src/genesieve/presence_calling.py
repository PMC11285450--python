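"""Three-state gene presence calls and the normalized-peptide-length U test.

A gene is judged from two evidence values computed upstream: the median best
identity over covered query positions and the position-loss percentage.
Clear evidence on both axes gives ``present``; identity below the lower
cutoff or loss above the upper cutoff gives ``likely_lost``; the bands in
between (identity 60-70, loss 20-30 by default) are deliberately gray and
give ``ambiguous``.

Degraded genes also betray themselves through translation: premature stop
codons shorten the stop-free peptide runs recoverable from reads. The
one-sided Mann-Whitney U test on normalized peptide lengths compares a
candidate gene set against an intact reference set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .hit_profiling import ProfileSummary
from .read_recovery import PeptideRecord

__all__ = [
    "CallThresholds",
    "PresenceCall",
    "UTestResult",
    "call_presence",
    "mann_whitney_u",
    "compare_gene_sets",
]

Alternative = Literal["less", "greater", "two_sided"]


@dataclass(frozen=True)
class CallThresholds:
    """Cutoffs delimiting present / ambiguous / likely_lost."""

    identity_present_min: float = 70.0
    identity_lost_max: float = 60.0
    loss_present_max: float = 20.0
    loss_lost_min: float = 30.0

    def __post_init__(self) -> None:
        if self.identity_lost_max > self.identity_present_min:
            raise ValueError("identity_lost_max must be <= identity_present_min")
        if self.loss_present_max > self.loss_lost_min:
            raise ValueError("loss_present_max must be <= loss_lost_min")


@dataclass(frozen=True)
class PresenceCall:
    species: str
    gene: str
    median_identity: float
    loss_percent: float
    call: Literal["present", "ambiguous", "likely_lost"]


@dataclass(frozen=True)
class UTestResult:
    u_statistic: float
    p_value: float
    alternative: Alternative
    method: Literal["exact", "normal_approx"]
    n_a: int
    n_b: int


def call_presence(
    summary: ProfileSummary,
    thresholds: CallThresholds | None = None,
    species: str = "",
    gene: str = "",
) -> PresenceCall:
    """Three-state call from median identity and loss percentage.

    ``likely_lost`` iff the median falls below the lower identity cutoff OR
    the loss exceeds the upper loss cutoff; ``present`` iff the median meets
    the upper identity cutoff AND the loss stays within the lower loss
    cutoff; anything in between is ``ambiguous``. An undefined median (zero
    coverage) is collapsed to ``likely_lost`` — loss is 100 there anyway.
    """
    t = thresholds or CallThresholds()
    median = summary.median_best_identity
    loss = summary.position_loss_percent
    if math.isnan(median) or median < t.identity_lost_max or loss > t.loss_lost_min:
        call = "likely_lost"
    elif median >= t.identity_present_min and loss <= t.loss_present_max:
        call = "present"
    else:
        call = "ambiguous"
    return PresenceCall(
        species=species,
        gene=gene or summary.query_id,
        median_identity=median,
        loss_percent=loss,
        call=call,
    )


def _has_ties(pooled: np.ndarray) -> bool:
    return len(np.unique(pooled)) < len(pooled)


def mann_whitney_u(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    alternative: Alternative = "two_sided",
) -> UTestResult:
    """Mann-Whitney U with exact small-sample p-values.

    The exact null distribution is used whenever both samples have at most
    20 observations and the pooled sample is tie-free; otherwise the normal
    approximation with continuity and tie corrections applies. U is the
    statistic of ``sample_a``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    exact = a.size <= 20 and b.size <= 20 and not _has_ties(np.concatenate([a, b]))
    scipy_alt = {"less": "less", "greater": "greater", "two_sided": "two-sided"}[
        alternative
    ]
    res = stats.mannwhitneyu(
        a, b, alternative=scipy_alt, method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return UTestResult(
        u_statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        alternative=alternative,
        method="exact" if exact else "normal_approx",
        n_a=int(a.size),
        n_b=int(b.size),
    )


def compare_gene_sets(
    peptide_records: Sequence[PeptideRecord],
    genes_a: Sequence[str],
    genes_b: Sequence[str],
    alternative: Alternative = "less",
) -> UTestResult:
    """U test on pooled normalized peptide lengths of two gene sets.

    ``alternative='less'`` (default) tests whether set A's normalized
    lengths are stochastically lower than set B's — the directional claim
    for a degraded gene set against intact genes.
    """
    set_a = set(genes_a)
    set_b = set(genes_b)
    values_a = [r.normalized_len for r in peptide_records if r.gene in set_a]
    values_b = [r.normalized_len for r in peptide_records if r.gene in set_b]
    if not values_a:
        raise ValueError(f"no peptide records for gene set {sorted(set_a)}")
    if not values_b:
        raise ValueError(f"no peptide records for gene set {sorted(set_b)}")
    return mann_whitney_u(values_a, values_b, alternative)
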