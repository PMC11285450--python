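"""Per-query-position best-hit profiles, medians and the position-loss statistic.

For every residue position of a query protein the profile records four values
from the reads that align across it: the best hit's percent identity, that
hit's mismatch and gap-open counts, and the lowest E-value over *all* covering
hits (tracked independently of the best-identity hit). Positions covered by
no hit are "lost"; the percentage of lost positions is the L statistic used
alongside the median best identity to judge gene presence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .sequence_io import SequenceRecord
from .translated_search import TranslatedHit

__all__ = [
    "PositionProfile",
    "ProfileSummary",
    "build_profile",
    "summarize_profile",
    "call_table",
    "write_profile_tsv",
]


@dataclass
class PositionProfile:
    """Best-hit statistics per query position (NaN where uncovered)."""

    query_id: str
    length: int
    best_identity: np.ndarray
    mismatches_best: np.ndarray
    gapopens_best: np.ndarray
    min_evalue: np.ndarray
    covered: np.ndarray
    n_hits: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": np.arange(1, self.length + 1),
                "best_identity": self.best_identity,
                "mismatches": self.mismatches_best,
                "gap_opens": self.gapopens_best,
                "min_evalue": self.min_evalue,
                "covered": self.covered,
            }
        )


@dataclass(frozen=True)
class ProfileSummary:
    """Median best identity over covered positions plus the loss percentage."""

    query_id: str
    median_best_identity: float  # NaN when no position is covered
    position_loss_percent: float
    n_hits: int


def _hit_rank_key(hit: TranslatedHit) -> tuple:
    """Orderable key: better hits sort smaller.

    Identity is primary (descending), then lower E-value, then longer
    alignment, then lexicographic read id — a total order, so profiles are
    independent of hit input order.
    """
    return (
        -hit.percent_identity,
        hit.evalue,
        -hit.alignment_length,
        hit.read_id,
    )


def _hit_positions(hit: TranslatedHit) -> range | list[int]:
    """0-based query positions where a hit provides residue evidence.

    When the hit carries its alignment strings, positions falling in gap
    columns (a deletion bridged by one read) contribute no coverage — a
    residue deleted from the genome must not count as recovered. Hits from
    external tabular output lack alignment detail, so their full span counts.
    """
    if hit.aligned_query is None or hit.aligned_target is None:
        return range(hit.query_start - 1, hit.query_end)
    positions = []
    qpos = hit.query_start - 1
    for cq, ct in zip(hit.aligned_query, hit.aligned_target):
        if cq == "-":
            continue
        if ct != "-":
            positions.append(qpos)
        qpos += 1
    return positions


def build_profile(query: SequenceRecord, hits: Sequence[TranslatedHit]) -> PositionProfile:
    """Aggregate hits into a per-position best-hit profile for one query.

    A position is covered iff some hit aligns a residue across it (see
    :func:`_hit_positions`); the best hit at a position is chosen by
    :func:`_hit_rank_key`. Raises ``ValueError`` for hits whose coordinates
    fall outside the query, naming the hit.
    """
    length = len(query)
    best_identity = np.full(length, np.nan)
    mismatches_best = np.full(length, np.nan)
    gapopens_best = np.full(length, np.nan)
    min_evalue = np.full(length, np.nan)
    covered = np.zeros(length, dtype=bool)
    best_keys: list[tuple | None] = [None] * length

    for hit in hits:
        if hit.query_id != query.id:
            raise ValueError(
                f"hit {hit.query_id}/{hit.read_id} does not reference query {query.id}"
            )
        if hit.query_start < 1 or hit.query_end > length:
            raise ValueError(
                f"hit {hit.query_id}/{hit.read_id} spans "
                f"{hit.query_start}-{hit.query_end}, outside query of length {length}"
            )
        key = _hit_rank_key(hit)
        for p in _hit_positions(hit):
            covered[p] = True
            if np.isnan(min_evalue[p]) or hit.evalue < min_evalue[p]:
                min_evalue[p] = hit.evalue
            if best_keys[p] is None or key < best_keys[p]:
                best_keys[p] = key
                best_identity[p] = hit.percent_identity
                mismatches_best[p] = hit.mismatches
                gapopens_best[p] = hit.gap_opens
    return PositionProfile(
        query_id=query.id,
        length=length,
        best_identity=best_identity,
        mismatches_best=mismatches_best,
        gapopens_best=gapopens_best,
        min_evalue=min_evalue,
        covered=covered,
        n_hits=len(hits),
    )


def summarize_profile(profile: PositionProfile, loss_as_zero: bool = False) -> ProfileSummary:
    """Median best identity and loss percentage for one profile.

    By default the median runs over covered positions only, with the loss
    percentage reported separately; ``loss_as_zero=True`` instead scores
    uncovered positions as identity 0 before taking the median (the
    alternative reading of a combined statistic).
    """
    n_cov = int(profile.covered.sum())
    loss = 100.0 * (profile.length - n_cov) / profile.length
    if n_cov == 0:
        median = float("nan")
    elif loss_as_zero:
        values = np.where(profile.covered, profile.best_identity, 0.0)
        median = float(np.median(values))
    else:
        median = float(np.median(profile.best_identity[profile.covered]))
    return ProfileSummary(
        query_id=profile.query_id,
        median_best_identity=median,
        position_loss_percent=loss,
        n_hits=profile.n_hits,
    )


def call_table(
    summaries: Mapping[tuple[str, str], ProfileSummary],
    thresholds=None,
    species: Sequence[str] | None = None,
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Long-format (species, gene) table of medians, losses and presence calls.

    ``summaries`` maps (species, gene) to a summary. When explicit species /
    gene lists are given, missing combinations appear as NA rows rather than
    being dropped silently. Duplicate keys cannot arise from a Mapping; a
    list of keyed pairs with duplicates raises.
    """
    from .presence_calling import CallThresholds, call_presence

    thresholds = thresholds or CallThresholds()
    if not isinstance(summaries, Mapping):
        pairs = list(summaries)
        keys = [k for k, _ in pairs]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate (species, gene) entries: {dupes}")
        summaries = dict(pairs)
    species = list(species) if species is not None else sorted({s for s, _ in summaries})
    genes = list(genes) if genes is not None else sorted({g for _, g in summaries})
    rows = []
    for sp in species:
        for gene in genes:
            summ = summaries.get((sp, gene))
            if summ is None:
                rows.append((sp, gene, np.nan, np.nan, 0, "NA"))
            else:
                call = call_presence(summ, thresholds)
                rows.append(
                    (
                        sp,
                        gene,
                        summ.median_best_identity,
                        summ.position_loss_percent,
                        summ.n_hits,
                        call.call,
                    )
                )
    return pd.DataFrame(
        rows,
        columns=["species", "gene", "median_identity", "loss_percent", "n_hits", "call"],
    )


def write_profile_tsv(profile: PositionProfile, path: str | Path) -> None:
    profile.to_frame().to_csv(path, sep="\t", index=False)
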