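"""Reference-guided protein reconstruction from overlapping best-hit reads.

The query protein provides the coordinate system; each tolerable-tier hit
contributes observed residues at the query positions its alignment covers.
At every position the consensus residue is taken from the best covering hit
(highest percent identity; ties resolved by lower E-value, then majority
vote across all covering hits, then alphabetically), producing a query-length
residue string in which '-' marks positions with no residue evidence. The
per-residue descriptors (best identity, mismatches, gap opens, lowest
E-value, depth) mirror the position profile and feed the same presence logic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .sequence_io import SequenceRecord
from .translated_search import TranslatedHit

__all__ = [
    "ReconstructedProtein",
    "ReconstructionReport",
    "project_hit_to_query",
    "reconstruct",
    "reconstruction_report",
]


@dataclass
class ReconstructedProtein:
    """Query-length consensus with per-residue evidence descriptors."""

    query_id: str
    residues: str  # '-' where no residue evidence exists
    best_identity: np.ndarray
    mismatches_best: np.ndarray
    gapopens_best: np.ndarray
    min_evalue: np.ndarray
    depth: np.ndarray  # covering hits contributing a residue (not a gap)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": np.arange(1, len(self.residues) + 1),
                "residue": list(self.residues),
                "depth": self.depth,
                "best_identity": self.best_identity,
                "mismatches": self.mismatches_best,
                "gap_opens": self.gapopens_best,
                "min_evalue": self.min_evalue,
            }
        )


@dataclass(frozen=True)
class ReconstructionReport:
    query_id: str
    identity_to_query: float  # over covered positions; NaN if none covered
    position_loss_percent: float
    mean_depth: float


def project_hit_to_query(hit: TranslatedHit) -> dict[int, str]:
    """Map 1-based query positions to the residues a hit observed there.

    Query-gap columns (insertions in the read) contribute nothing; read-gap
    columns (deletions) contribute '-' evidence at that query position.
    Raises ``ValueError`` when the aligned strings are missing or do not
    account for the hit's query span.
    """
    if hit.aligned_query is None or hit.aligned_target is None:
        raise ValueError(
            f"hit {hit.query_id}/{hit.read_id} carries no alignment strings"
        )
    if len(hit.aligned_query) != len(hit.aligned_target):
        raise ValueError("aligned strings differ in length")
    mapping: dict[int, str] = {}
    qpos = hit.query_start
    for cq, ct in zip(hit.aligned_query, hit.aligned_target):
        if cq == "-":
            continue  # insertion in read: consumes no query position
        mapping[qpos] = ct  # ct == '-' records deletion evidence
        qpos += 1
    if qpos - 1 != hit.query_end:
        raise ValueError(
            f"alignment of {hit.query_id}/{hit.read_id} consumes query positions "
            f"{hit.query_start}-{qpos - 1}, inconsistent with span "
            f"{hit.query_start}-{hit.query_end}"
        )
    return mapping


def reconstruct(
    query: SequenceRecord, tolerable_hits: Sequence[TranslatedHit]
) -> ReconstructedProtein:
    """Consensus reconstruction of the query-length protein from hit evidence.

    Deterministic and independent of hit input order: the best hit at each
    position is selected by (identity desc, E-value asc); residual ties among
    differing residues fall back to a majority vote over all residue evidence
    at the position, then to the alphabetically first residue.
    """
    length = len(query)
    best_identity = np.full(length, np.nan)
    mismatches_best = np.full(length, np.nan)
    gapopens_best = np.full(length, np.nan)
    min_evalue = np.full(length, np.nan)
    depth = np.zeros(length, dtype=int)
    # per position: list of (rank_key, residue, hit)
    evidence: list[list[tuple[tuple, str, TranslatedHit]]] = [[] for _ in range(length)]

    for hit in tolerable_hits:
        if hit.query_id != query.id:
            raise ValueError(
                f"hit {hit.query_id}/{hit.read_id} does not reference query {query.id}"
            )
        key = (-hit.percent_identity, hit.evalue, hit.read_id)
        for qpos, residue in project_hit_to_query(hit).items():
            p = qpos - 1
            evidence[p].append((key, residue, hit))
            if np.isnan(min_evalue[p]) or hit.evalue < min_evalue[p]:
                min_evalue[p] = hit.evalue
            if residue != "-":
                depth[p] += 1

    residues = []
    for p in range(length):
        residue_evidence = [(k, r, h) for k, r, h in evidence[p] if r != "-"]
        if not residue_evidence:
            residues.append("-")
            continue
        best_metric = min((k[0], k[1]) for k, _, _ in residue_evidence)
        tied = [(k, r, h) for k, r, h in residue_evidence if (k[0], k[1]) == best_metric]
        candidates = sorted({r for _, r, _ in tied})
        if len(candidates) == 1:
            chosen = candidates[0]
        else:
            votes = Counter(r for _, r, _ in residue_evidence)
            top = max(votes[c] for c in candidates)
            chosen = sorted(c for c in candidates if votes[c] == top)[0]
        residues.append(chosen)
        best_hit = min(tied, key=lambda t: t[0])[2]
        best_identity[p] = best_hit.percent_identity
        mismatches_best[p] = best_hit.mismatches
        gapopens_best[p] = best_hit.gap_opens
    return ReconstructedProtein(
        query_id=query.id,
        residues="".join(residues),
        best_identity=best_identity,
        mismatches_best=mismatches_best,
        gapopens_best=gapopens_best,
        min_evalue=min_evalue,
        depth=depth,
    )


def reconstruction_report(
    recon: ReconstructedProtein, query: SequenceRecord
) -> ReconstructionReport:
    """Overall identity to the query over covered positions, loss and depth."""
    length = len(recon.residues)
    covered = [i for i, r in enumerate(recon.residues) if r != "-"]
    loss = 100.0 * (length - len(covered)) / length
    if covered:
        matches = sum(1 for i in covered if recon.residues[i] == query.residues[i])
        identity = 100.0 * matches / len(covered)
    else:
        identity = float("nan")
    return ReconstructionReport(
        query_id=recon.query_id,
        identity_to_query=identity,
        position_loss_percent=loss,
        mean_depth=float(np.mean(recon.depth)),
    )


def write_reconstruction(
    recon: ReconstructedProtein, fasta_path: str | Path, tsv_path: str | Path
) -> None:
    with open(fasta_path, "w") as fh:
        fh.write(f">{recon.query_id}_reconstructed\n{recon.residues}\n")
    recon.to_frame().to_csv(tsv_path, sep="\t", index=False)
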