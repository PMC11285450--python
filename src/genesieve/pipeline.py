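"""End-to-end orchestration: search → profile → recover → reconstruct → call.

The library entry point is :func:`analyze_gene`, which runs the full
assembly-free pipeline for one query protein against one read set and
returns every intermediate product. The CLI wraps this (and the individual
stages) over files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .hit_profiling import PositionProfile, ProfileSummary, build_profile, summarize_profile
from .presence_calling import CallThresholds, PresenceCall, call_presence
from .protein_reconstruction import (
    ReconstructedProtein,
    ReconstructionReport,
    reconstruct,
    reconstruction_report,
)
from .read_recovery import PeptideRecord, TierThresholds, assign_tier, recover_peptides
from .sequence_io import ReadRecord, SequenceRecord
from .translated_search import ScoringParams, TranslatedHit, search_all

__all__ = ["PipelineResult", "analyze_gene"]


@dataclass
class PipelineResult:
    """All per-gene products of one pipeline run."""

    query: SequenceRecord
    hits: list[TranslatedHit]
    profile: PositionProfile
    summary: ProfileSummary
    peptides: list[PeptideRecord]
    reconstruction: ReconstructedProtein
    report: ReconstructionReport
    call: PresenceCall


def analyze_gene(
    query: SequenceRecord,
    reads: Sequence[ReadRecord],
    scoring: ScoringParams | None = None,
    tier_thresholds: TierThresholds | None = None,
    call_thresholds: CallThresholds | None = None,
    species: str = "",
    gene: str = "",
    threads: int = 1,
) -> PipelineResult:
    """Run search, profiling, recovery, reconstruction and calling for one gene."""
    tier_thresholds = tier_thresholds or TierThresholds()
    hits = search_all([query], list(reads), scoring, threads=threads)
    profile = build_profile(query, hits)
    summary = summarize_profile(profile)
    peptides = recover_peptides(list(reads), hits, tier_thresholds, gene=gene or query.id)
    tolerable = [h for h in hits if assign_tier(h, tier_thresholds) == "tolerable"]
    recon = reconstruct(query, tolerable)
    report = reconstruction_report(recon, query)
    call = call_presence(summary, call_thresholds, species=species, gene=gene or query.id)
    return PipelineResult(
        query=query,
        hits=hits,
        profile=profile,
        summary=summary,
        peptides=peptides,
        reconstruction=recon,
        report=report,
        call=call,
    )
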