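"""Per-motif sequence clues: intrinsic disorder and local conservation.

Disorder scores are consumed pre-computed (IUPred-style, one value in [0,1]
per residue).  Conservation is computed from an ortholog multiple sequence
alignment as per-column information content weighted by the column's
non-gap fraction; a residue is locally conserved when its score beats the
mean over a window of up to 31 residues on each side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO

from .io import STANDARD_AA
from .motifs import CandidateMotif

__all__ = [
    "DisorderTrack",
    "ConservationTrack",
    "motif_disorder",
    "column_conservation",
    "local_conservation",
    "motif_conserved",
    "read_disorder_tracks",
    "write_disorder_tracks",
    "conservation_from_msa",
    "write_conservation",
    "read_conservation",
]

MAX_IC = math.log2(20.0)
_GAPS = {"-", "."}


@dataclass
class DisorderTrack:
    protein_id: str
    scores: np.ndarray  # per residue, in [0, 1]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1 or self.scores.size == 0:
            raise ValueError(f"disorder track for {self.protein_id} must be 1-D, non-empty")
        if ((self.scores < 0) | (self.scores > 1)).any():
            raise ValueError(f"disorder scores for {self.protein_id} outside [0, 1]")


@dataclass
class ConservationTrack:
    protein_id: str
    scores: np.ndarray      # information content x non-gap fraction, bits
    local_flags: np.ndarray  # per-residue locally-conserved flag

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.local_flags = np.asarray(self.local_flags, dtype=bool)
        if self.scores.shape != self.local_flags.shape:
            raise ValueError("scores and flags must have equal length")
        if (self.scores < 0).any():
            raise ValueError("conservation scores must be non-negative")


def _check_bounds(motif: CandidateMotif, n: int) -> None:
    if motif.start < 1 or motif.end > n or motif.start > motif.end:
        raise ValueError(
            f"motif {motif.start}-{motif.end} outside track of length {n}"
        )


def motif_disorder(
    track: DisorderTrack, motif: CandidateMotif, cutoff: float = 0.5
) -> tuple[float, bool]:
    """Mean residue disorder over the motif; disordered iff mean > cutoff
    (strict; 0.5 is the predictor-recommended default)."""
    _check_bounds(motif, track.scores.size)
    mean = float(track.scores[motif.start - 1 : motif.end].mean())
    return mean, mean > cutoff


def column_conservation(
    rows: Mapping[str, str] | Sequence[tuple[str, str]], human_row_id: str
) -> np.ndarray:
    """Per-residue conservation scores for the reference (human) row of an MSA.

    For each column where the reference row is non-gap, the information
    content is the max-entropy baseline log2(20) minus the Shannon entropy of
    the amino-acid frequencies among non-gap entries, multiplied by the
    column's non-gap fraction.  Scores are indexed by reference-residue
    position.
    """
    rows = dict(rows)
    if human_row_id not in rows:
        raise ValueError(f"reference row {human_row_id!r} not found in alignment")
    lengths = {len(s) for s in rows.values()}
    if len(lengths) != 1:
        raise ValueError("alignment rows have unequal lengths")
    ref = rows[human_row_id].upper()
    others = [s.upper() for s in rows.values()]
    depth = len(others)

    scores = []
    for col in range(len(ref)):
        if ref[col] in _GAPS:
            continue
        letters = [s[col] for s in others if s[col] not in _GAPS]
        counts = np.array(
            [sum(1 for c in letters if c == aa) for aa in STANDARD_AA], dtype=float
        )
        total = counts.sum()
        if total > 0:
            p = counts[counts > 0] / total
            ic = MAX_IC + float((p * np.log2(p)).sum())
        else:
            ic = 0.0  # reference column of all-nonstandard residues
        scores.append(ic * len(letters) / depth)
    return np.array(scores)


def local_conservation(scores: np.ndarray, half_window: int = 31) -> np.ndarray:
    """Flag residues scoring strictly above the mean of their neighbourhood.

    The window spans up to ``half_window`` residues upstream and downstream,
    truncated at the ends and excluding the residue itself; a residue with no
    neighbours is never flagged.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty conservation track")
    csum = np.concatenate([[0.0], np.cumsum(scores)])
    n = scores.size
    flags = np.zeros(n, dtype=bool)
    for i in range(n):
        lo = max(0, i - half_window)
        hi = min(n - 1, i + half_window)
        count = hi - lo  # excludes center
        if count == 0:
            continue
        neighbour_sum = csum[hi + 1] - csum[lo] - scores[i]
        flags[i] = scores[i] > neighbour_sum / count
    return flags


def motif_conserved(flags: np.ndarray, motif: CandidateMotif) -> bool:
    """True iff every residue of the motif is locally conserved."""
    flags = np.asarray(flags, dtype=bool)
    _check_bounds(motif, flags.size)
    return bool(flags[motif.start - 1 : motif.end].all())


# ---------------------------------------------------------------------------
# file plumbing


def read_disorder_tracks(path: str | Path) -> dict[str, DisorderTrack]:
    """Disorder TSV (protein_id, position, score) -> per-protein tracks."""
    df = pd.read_csv(path, sep="\t", comment="#")
    tracks = {}
    for pid, grp in df.groupby("protein_id", sort=False):
        grp = grp.sort_values("position")
        positions = grp["position"].to_numpy()
        if not np.array_equal(positions, np.arange(1, len(positions) + 1)):
            raise ValueError(f"disorder positions for {pid} are not 1..L")
        tracks[str(pid)] = DisorderTrack(str(pid), grp["score"].to_numpy(float))
    return tracks


def write_disorder_tracks(path: str | Path, tracks: Mapping[str, DisorderTrack]) -> None:
    rows = [
        (pid, i + 1, float(s))
        for pid, tr in tracks.items()
        for i, s in enumerate(tr.scores)
    ]
    pd.DataFrame(rows, columns=["protein_id", "position", "score"]).to_csv(
        path, sep="\t", index=False
    )


def conservation_from_msa(
    path: str | Path, human_row_id: str, half_window: int = 31
) -> ConservationTrack:
    """Read a FASTA alignment and build the reference row's conservation track."""
    aln = AlignIO.read(str(path), "fasta")
    rows = {rec.id: str(rec.seq) for rec in aln}
    scores = column_conservation(rows, human_row_id)
    return ConservationTrack(human_row_id, scores, local_conservation(scores, half_window))


def write_conservation(path: str | Path, tracks: Mapping[str, ConservationTrack]) -> None:
    rows = [
        (pid, i + 1, float(s), bool(f))
        for pid, tr in tracks.items()
        for i, (s, f) in enumerate(zip(tr.scores, tr.local_flags))
    ]
    pd.DataFrame(
        rows, columns=["protein_id", "position", "score", "local_flag"]
    ).to_csv(path, sep="\t", index=False)


def read_conservation(path: str | Path) -> dict[str, ConservationTrack]:
    df = pd.read_csv(path, sep="\t", comment="#")
    tracks = {}
    for pid, grp in df.groupby("protein_id", sort=False):
        grp = grp.sort_values("position")
        tracks[str(pid)] = ConservationTrack(
            str(pid), grp["score"].to_numpy(float), grp["local_flag"].to_numpy(bool)
        )
    return tracks
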