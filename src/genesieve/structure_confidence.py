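"""AlphaFold-output parsing and fold-reliability classification.

AlphaFold deposits its per-residue confidence (pLDDT, 0-100) in the B-factor
column of the PDB it writes, and its predicted aligned error (PAE, in Å) as a
JSON matrix. This module parses both and applies a simple reliability rule:
a secondary-structure region whose aggregate pLDDT falls below 70 cannot be
trusted to fold as modelled, and a protein with any unreliable designated
region gets an unreliable overall verdict. PAE is summarized as mean error
per region pair (both orientations pooled), so poorly packed domain pairs
stand out as high inter-region error.

Structure prediction itself is out of scope; only its outputs are consumed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from statistics import mean
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .region_phylo import RegionSpec

__all__ = [
    "ResidueConfidence",
    "PaeMatrix",
    "FoldVerdict",
    "parse_plddt",
    "parse_pae",
    "classify_fold",
    "summarize_pae",
]


@dataclass(frozen=True)
class ResidueConfidence:
    chain_id: str
    residue_index: int  # 1-based position within the chain
    plddt: float


@dataclass
class PaeMatrix:
    """Square predicted-aligned-error matrix; asymmetry is preserved."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("PAE matrix must be square")
        if (self.values < 0).any():
            raise ValueError("PAE values must be non-negative")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class FoldVerdict:
    region_status: dict[str, str]  # region name -> 'reliable' | 'unreliable'
    region_plddt: dict[str, float]
    reliable: bool


def parse_plddt(pdb_path: str | Path) -> list[ResidueConfidence]:
    """Per-residue pLDDT from a PDB file (CA atom's B-factor).

    A residue without a CA atom falls back to the mean B-factor of its atoms
    (with a warning). Raises ``ValueError`` when the file has no ATOM records.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        structure = PDBParser(QUIET=True).get_structure("model", str(pdb_path))
    confidences: list[ResidueConfidence] = []
    for model in structure:
        for chain in model:
            index = 0
            for residue in chain:
                if residue.id[0] != " ":  # skip heteroatoms/waters
                    continue
                index += 1
                if "CA" in residue:
                    value = float(residue["CA"].get_bfactor())
                else:
                    atoms = [float(a.get_bfactor()) for a in residue]
                    warnings.warn(
                        f"residue {chain.id}:{index} lacks a CA atom; "
                        "using mean atom B-factor"
                    )
                    value = mean(atoms)
                confidences.append(
                    ResidueConfidence(chain_id=chain.id, residue_index=index, plddt=value)
                )
        break  # first model only
    if not confidences:
        raise ValueError(f"no ATOM records found in {pdb_path}")
    return confidences


def parse_pae(json_path: str | Path) -> PaeMatrix:
    """Load a predicted-aligned-error matrix from AlphaFold JSON.

    Accepts the published layouts: a bare object or a one-element list with
    key ``predicted_aligned_error`` (or ``pae``) holding an n×n array.
    Ragged rows raise ``ValueError``.
    """
    with open(json_path) as fh:
        payload = json.load(fh)
    if isinstance(payload, list):
        if not payload:
            raise ValueError(f"empty JSON payload in {json_path}")
        payload = payload[0]
    matrix = payload.get("predicted_aligned_error", payload.get("pae"))
    if matrix is None:
        raise ValueError(
            f"{json_path} has neither 'predicted_aligned_error' nor 'pae'"
        )
    lengths = {len(row) for row in matrix}
    if len(lengths) != 1 or lengths.pop() != len(matrix):
        raise ValueError(f"ragged or non-square PAE rows in {json_path}")
    return PaeMatrix(values=np.asarray(matrix, dtype=float))


def classify_fold(
    residue_conf: Sequence[ResidueConfidence],
    region_specs: Sequence[RegionSpec],
    plddt_threshold: float = 70.0,
    aggregator: Literal["mean", "min"] = "mean",
) -> FoldVerdict:
    """Per-region reliability and a protein-level verdict.

    A region is unreliable iff its aggregate pLDDT (mean by default, minimum
    available) is strictly below the threshold; the boundary value itself
    counts as reliable. The protein verdict is unreliable iff any designated
    region is unreliable.
    """
    plddt = {rc.residue_index: rc.plddt for rc in residue_conf}
    status: dict[str, str] = {}
    region_value: dict[str, float] = {}
    for spec in region_specs:
        values = [plddt[i] for i in range(spec.start, spec.end + 1) if i in plddt]
        if not values:
            raise ValueError(f"region {spec.name!r} covers no residues")
        agg = mean(values) if aggregator == "mean" else min(values)
        region_value[spec.name] = agg
        status[spec.name] = "unreliable" if agg < plddt_threshold else "reliable"
    return FoldVerdict(
        region_status=status,
        region_plddt=region_value,
        reliable=all(s == "reliable" for s in status.values()),
    )


def summarize_pae(
    pae: PaeMatrix, region_specs: Sequence[RegionSpec]
) -> dict[tuple[str, str], float]:
    """Mean PAE per unordered region pair, pooling both orientations.

    The (A, A) entry is the intra-region mean; (A, B) pools pae[x in A, y in B]
    with pae[x in B, y in A].
    """
    idx = {
        spec.name: np.arange(spec.start - 1, spec.end) for spec in region_specs
    }
    for name, indices in idx.items():
        if indices.max() >= pae.n:
            raise ValueError(f"region {name!r} extends past the {pae.n}-residue matrix")
    out: dict[tuple[str, str], float] = {}
    names = [s.name for s in region_specs]
    for i, a in enumerate(names):
        for b in names[i:]:
            block_ab = pae.values[np.ix_(idx[a], idx[b])]
            if a == b:
                out[(a, b)] = float(block_ab.mean())
            else:
                block_ba = pae.values[np.ix_(idx[b], idx[a])]
                out[(a, b)] = float(
                    np.concatenate([block_ab.ravel(), block_ba.ravel()]).mean()
                )
    return out


def fold_report_frame(
    verdict: FoldVerdict, pae_summary: dict[tuple[str, str], float] | None = None
) -> pd.DataFrame:
    rows = [
        ("plddt", name, name, verdict.region_plddt[name], status)
        for name, status in verdict.region_status.items()
    ]
    if pae_summary:
        rows += [
            ("pae", a, b, value, "") for (a, b), value in pae_summary.items()
        ]
    return pd.DataFrame(
        rows, columns=["metric", "region_a", "region_b", "value", "status"]
    )
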