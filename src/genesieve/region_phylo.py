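"""Antigen-presenting-region extraction, identity matrices and NJ trees.

The α1/α2 helices and β-sheets form the antigen-presenting part of CD1-class
molecules; their sequences are extracted from column-aligned (equal-length)
reconstructions by reference coordinates, compared by percent identity with
gap-containing columns excluded, converted to p-style distances
(d = 100 − identity) and summarized as a neighbor-joining tree. The trees
are descriptive: a reconstructed protein accumulating many substitutions in
these regions shows up as a conspicuously long terminal branch.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RegionSpec",
    "DistanceMatrix",
    "extract_regions",
    "pairwise_identity",
    "identity_to_distance",
    "identity_matrix",
    "neighbor_joining",
    "read_region_specs",
]


@dataclass(frozen=True)
class RegionSpec:
    """A named residue window (1-based inclusive) on a reference query."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"region {self.name!r}: need 1 <= start <= end")

    def __len__(self) -> int:
        return self.end - self.start + 1


def validate_region_set(regions: Sequence[RegionSpec]) -> None:
    """Regions in one spec set must not overlap."""
    ordered = sorted(regions, key=lambda r: r.start)
    for left, right in zip(ordered, ordered[1:]):
        if right.start <= left.end:
            raise ValueError(f"regions {left.name!r} and {right.name!r} overlap")


@dataclass
class DistanceMatrix:
    """Symmetric, zero-diagonal distance matrix with labelled taxa."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if (self.values < -1e-12).any():
            raise ValueError("distances must be non-negative")


def extract_regions(residues: str, region_specs: Sequence[RegionSpec]) -> str:
    """Concatenate region windows, in spec order; '-' positions are kept."""
    out = []
    for spec in region_specs:
        if spec.end > len(residues):
            raise ValueError(
                f"region {spec.name!r} ({spec.start}-{spec.end}) extends past "
                f"sequence of length {len(residues)}"
            )
        out.append(residues[spec.start - 1 : spec.end])
    return "".join(out)


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity over columns where neither sequence has '-'.

    Sequences must already be column-aligned (equal length); region extracts
    on shared reference coordinates satisfy this by construction.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"length mismatch ({len(seq_a)} vs {len(seq_b)}): align or pad first"
        )
    comparable = matches = 0
    for ca, cb in zip(seq_a, seq_b):
        if ca == "-" or cb == "-":
            continue
        comparable += 1
        if ca == cb:
            matches += 1
    if comparable == 0:
        raise ValueError("no gap-free columns shared by the two sequences")
    return 100.0 * matches / comparable


def identity_to_distance(identity_percent: float) -> float:
    """p-style distance on the identity scale: d = 100 − identity."""
    if not 0.0 <= identity_percent <= 100.0:
        raise ValueError("identity must lie in [0, 100]")
    return 100.0 - identity_percent


def identity_matrix(sequences: dict[str, str]) -> DistanceMatrix:
    """Distance matrix (100 − pairwise identity) over labelled sequences."""
    labels = list(sequences)
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = identity_to_distance(
                pairwise_identity(sequences[labels[i]], sequences[labels[j]])
            )
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=labels, values=values)


def neighbor_joining(matrix: DistanceMatrix) -> str:
    """Saitou-Nei neighbor joining; returns an unrooted Newick string.

    Deterministic: among equally minimal Q pairs, the lexicographically
    smallest (label_i, label_j) pair joins first, an internal node carrying
    the smaller of its children's labels for subsequent tie-breaking.
    Negative branch lengths are clamped to zero with the deficit shifted to
    the sister branch, as is conventional for NJ on near-additive data.
    """
    n = len(matrix.labels)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    D = matrix.values.astype(float).copy()
    newick = list(matrix.labels)
    tie_label = list(matrix.labels)
    active = list(range(n))

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return li, max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                q = (m - 2) * sub[a, b] - r[a] - r[b]
                la, lb = tie_label[active[a]], tie_label[active[b]]
                pair_labels = (la, lb) if la <= lb else (lb, la)
                key = (q, pair_labels)
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        i, j = active[a], active[b]
        dij = sub[a, b]
        li = 0.5 * dij + (r[a] - r[b]) / (2 * (m - 2))
        lj = dij - li
        li, lj = clamp(li, lj)
        # distances from the new node to every remaining taxon
        new_row = np.zeros(D.shape[0] + 1)
        for c in range(m):
            k = active[c]
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (D[i, k] + D[j, k] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, : len(new_row) - 1] = new_row[:-1]
        D[: len(new_row) - 1, -1] = new_row[:-1]
        newick.append(f"({newick[i]}:{float(li)!r},{newick[j]}:{float(lj)!r})")
        tie_label.append(min(tie_label[i], tie_label[j]))
        active = [k for k in active if k not in (i, j)] + [D.shape[0] - 1]

    x, y, z = active
    lx = 0.5 * (D[x, y] + D[x, z] - D[y, z])
    ly = 0.5 * (D[x, y] + D[y, z] - D[x, z])
    lz = 0.5 * (D[x, z] + D[y, z] - D[x, y])
    lx, ly, lz = (max(v, 0.0) for v in (lx, ly, lz))
    return (
        f"({newick[x]}:{float(lx)!r},{newick[y]}:{float(ly)!r},"
        f"{newick[z]}:{float(lz)!r});"
    )


def read_region_specs(path: str | Path) -> list[RegionSpec]:
    """Region spec TSV with columns name, start, end."""
    frame = pd.read_csv(path, sep="\t")
    specs = [
        RegionSpec(str(row["name"]), int(row["start"]), int(row["end"]))
        for _, row in frame.iterrows()
    ]
    validate_region_set(specs)
    return specs
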