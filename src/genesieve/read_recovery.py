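"""Tiered hit filtering, matched-region translation and normalized peptide lengths.

Hits are split into two evidence tiers before reconstruction:

* ``tolerable`` — E-value below 1e-4 **and** percent identity above 40;
* ``low``       — percent identity in (30, 40], with no E-value condition
  (the low tier is archived, not used for reconstruction by default).

Everything else is rejected. The boundaries are asymmetric on purpose: the
tolerable tier uses a strict ``> 40`` while the low tier is inclusive at 40
and strict at 30, and only the tolerable tier carries an E-value cap.

For each retained hit the matched read region is extracted, strand-corrected
and translated; the longest stop-free peptide run times the read's identity
fraction gives the *normalized translated peptide length* — the statistic
compared between gene sets to flag pseudogenes (premature stops shorten the
stop-free runs and drag the distribution down).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

from .sequence_io import FrameSpec, ReadRecord, reverse_complement, translate
from .translated_search import TranslatedHit

__all__ = [
    "TierThresholds",
    "PeptideRecord",
    "assign_tier",
    "extract_and_translate",
    "max_orf_len",
    "normalized_length",
    "recover_peptides",
    "peptides_to_frame",
]

Tier = Literal["tolerable", "low", "rejected"]


@dataclass(frozen=True)
class TierThresholds:
    """Similarity-tier cutoffs for read filtering."""

    evalue_max: float = 1e-4
    identity_min_tolerable: float = 40.0
    identity_min_low: float = 30.0

    def __post_init__(self) -> None:
        if not self.identity_min_low < self.identity_min_tolerable:
            raise ValueError("identity_min_low must be < identity_min_tolerable")


@dataclass(frozen=True)
class PeptideRecord:
    """A recovered, translated read region with its length statistic."""

    read_id: str
    query_id: str
    tier: str
    peptide: str
    max_orf_len: int
    identity_fraction: float
    normalized_len: float
    gene: str = ""


def assign_tier(hit: TranslatedHit, thresholds: TierThresholds | None = None) -> Tier:
    """Classify one hit as tolerable, low or rejected.

    Boundary behaviour: identity exactly at the tolerable cutoff (40) falls
    to the low tier (strict '>'); identity exactly at the low cutoff (30) is
    rejected (strict '<' from below); E-value exactly at the cap fails the
    tolerable tier (strict '<').
    """
    t = thresholds or TierThresholds()
    if hit.evalue < t.evalue_max and hit.percent_identity > t.identity_min_tolerable:
        return "tolerable"
    if t.identity_min_low < hit.percent_identity <= t.identity_min_tolerable:
        return "low"
    return "rejected"


def extract_and_translate(read: ReadRecord, hit: TranslatedHit) -> str:
    """Translate the matched region of a read, honouring strand and frame.

    The hit's nucleotide span is codon-aligned to the alignment's first
    residue, so the extracted region translates in frame 1 after optional
    reverse complementing; stops are kept as '*'.
    """
    if hit.read_id != read.id:
        raise ValueError(f"hit read id {hit.read_id!r} does not match read {read.id!r}")
    if hit.read_start < 1 or hit.read_end > len(read):
        raise ValueError(
            f"hit region {hit.read_start}-{hit.read_end} outside read "
            f"{read.id!r} of length {len(read)}"
        )
    region = read.bases[hit.read_start - 1 : hit.read_end]
    if hit.frame_spec.strand == "-":
        region = reverse_complement(region)
    return translate(region, FrameSpec("+", 1))


def max_orf_len(peptide: str) -> int:
    """Length of the longest stop-free run of residues."""
    return max((len(run) for run in peptide.split("*")), default=0)


def normalized_length(max_orf: int, identity_fraction: float) -> float:
    """Stop-free peptide length scaled by the read's identity fraction."""
    if not 0.0 <= identity_fraction <= 1.0:
        raise ValueError("identity_fraction must lie in [0, 1]")
    return max_orf * identity_fraction


def recover_peptides(
    reads: Sequence[ReadRecord],
    hits: Sequence[TranslatedHit],
    thresholds: TierThresholds | None = None,
    orf_scope: Literal["hit", "whole_read"] = "hit",
    gene: str = "",
) -> list[PeptideRecord]:
    """Filter hits into tiers and translate the retained read regions.

    ``orf_scope='hit'`` (default) computes the stop-free maximum on the
    matched region's translation; ``'whole_read'`` instead scans all six
    frame translations of the full read and takes the overall maximum.
    """
    thresholds = thresholds or TierThresholds()
    by_id = {r.id: r for r in reads}
    records: list[PeptideRecord] = []
    for hit in hits:
        tier = assign_tier(hit, thresholds)
        if tier == "rejected":
            continue
        read = by_id.get(hit.read_id)
        if read is None:
            raise ValueError(f"hit references unknown read {hit.read_id!r}")
        peptide = extract_and_translate(read, hit)
        if orf_scope == "hit":
            orf = max_orf_len(peptide)
        else:
            from .sequence_io import six_frame_translations

            orf = max(
                (max_orf_len(pep) for _, pep in six_frame_translations(read.bases)),
                default=0,
            )
        frac = hit.percent_identity / 100.0
        records.append(
            PeptideRecord(
                read_id=hit.read_id,
                query_id=hit.query_id,
                tier=tier,
                peptide=peptide,
                max_orf_len=orf,
                identity_fraction=frac,
                normalized_len=normalized_length(orf, frac),
                gene=gene or hit.query_id,
            )
        )
    return records


def peptides_to_frame(records: Iterable[PeptideRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.read_id, r.query_id, r.gene, r.tier, r.peptide, r.max_orf_len,
             r.identity_fraction, r.normalized_len)
            for r in records
        ],
        columns=[
            "read_id", "query_id", "gene", "tier", "peptide", "max_orf_len",
            "identity_fraction", "normalized_len",
        ],
    )


def write_peptides(
    records: Sequence[PeptideRecord], fasta_path: str | Path, tsv_path: str | Path
) -> None:
    """Recovered-peptides FASTA (statistics in the description) + TSV mirror."""
    with open(fasta_path, "w") as fh:
        for r in records:
            fh.write(
                f">{r.read_id} query={r.query_id} tier={r.tier} "
                f"max_orf={r.max_orf_len} identity={r.identity_fraction:.4f} "
                f"normalized_len={r.normalized_len:.4f}\n{r.peptide}\n"
            )
    peptides_to_frame(records).to_csv(tsv_path, sep="\t", index=False)
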