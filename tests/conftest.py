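from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from genesieve.sequence_io import SequenceRecord
from genesieve.synthetic_data import synthetic_query
from genesieve.translated_search import ScoringParams, TranslatedHit
from genesieve.sequence_io import FrameSpec


@pytest.fixture(scope="session")
def query() -> SequenceRecord:
    """The deterministic 120-residue synthetic query used across tests."""
    return synthetic_query()


@pytest.fixture
def scoring() -> ScoringParams:
    return ScoringParams(search_space_m=300, search_space_n=10_000)


def make_hit(
    query_id: str = "q",
    read_id: str = "r",
    qstart: int = 1,
    qend: int = 10,
    identity: float = 100.0,
    evalue: float = 1e-10,
    aln_len: int | None = None,
    mismatches: int = 0,
    gap_opens: int = 0,
    strand: str = "+",
    frame: int = 1,
    read_start: int = 1,
    read_end: int | None = None,
    aligned_query: str | None = None,
    aligned_target: str | None = None,
) -> TranslatedHit:
    """Hand-built span-based hit for profiling/reconstruction fixtures."""
    span = qend - qstart + 1
    return TranslatedHit(
        query_id=query_id,
        read_id=read_id,
        frame_spec=FrameSpec(strand, frame),
        query_start=qstart,
        query_end=qend,
        read_start=read_start,
        read_end=read_end if read_end is not None else read_start + 3 * span - 1,
        alignment_length=aln_len if aln_len is not None else span,
        percent_identity=identity,
        mismatches=mismatches,
        gap_opens=gap_opens,
        raw_score=50,
        evalue=evalue,
        aligned_query=aligned_query,
        aligned_target=aligned_target,
    )


def write_pdb(path: Path, plddts: list[float], drop_ca_for: set[int] = frozenset()) -> None:
    """Minimal synthetic single-chain PDB with pLDDT in the B-factor column."""
    lines = []
    serial = 1
    for i, value in enumerate(plddts, start=1):
        atoms = ["N", "CA", "C"] if i not in drop_ca_for else ["N", "C"]
        for atom in atoms:
            lines.append(
                f"ATOM  {serial:5d}  {atom:<3s}ALA A{i:4d}    "
                f"{1.0 * i:8.3f}{0.0:8.3f}{0.0:8.3f}{1.00:6.2f}{value:6.2f}"
                f"           {atom[0]}"
            )
            serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
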