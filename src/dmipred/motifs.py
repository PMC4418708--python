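"""Candidate-motif discovery.

Two routes, mirroring the two prediction paths:

* consensus matching — every occurrence of a motif class's regular
  expression in a protein, overlapping occurrences included (the scan
  attempts a match at every start position);
* template-peptide similarity — a sliding window of the template peptide's
  length scored against every window in the proteome with BLOSUM62, keeping
  windows ranked in the top fraction (default 0.05%) proteome-wide and
  binning the survivors by percentile rank.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .io import STANDARD_AA, ElmClassDef, ProteinRecord

__all__ = [
    "CandidateMotif",
    "match_consensus",
    "score_window",
    "scan_template_motif",
    "assign_sim_bin",
    "blosum62_matrix",
    "write_motifs",
    "read_motifs",
]

#: percentile-rank bin edges for window-scan similarity, as rank fractions.
#: B1: top 0.0001%, B2: 0.0001-0.001%, B3: 0.001-0.01%, B4: 0.01-0.05%.
SIM_BIN_EDGES = ((1e-6, "B1"), (1e-5, "B2"), (1e-4, "B3"), (5e-4, "B4"))

_ALPHABET = STANDARD_AA + "X"
_AA_INDEX = {aa: i for i, aa in enumerate(_ALPHABET)}


def blosum62_matrix() -> np.ndarray:
    """BLOSUM62 over (20 standard letters + X), X scoring 0 against anything.

    Loaded from biopython's copy of the published matrix; the X row/column is
    overridden to 0 so unknown residues are neutral rather than penalized.
    """
    b62 = substitution_matrices.load("BLOSUM62")
    m = np.zeros((21, 21), dtype=np.int64)
    for i, a in enumerate(STANDARD_AA):
        for j, b in enumerate(STANDARD_AA):
            m[i, j] = int(b62[a, b])
    return m


_B62 = blosum62_matrix()


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_AA_INDEX[c] for c in seq], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(f"non-amino-acid letter {exc.args[0]!r} in sequence") from exc


@dataclass(frozen=True)
class CandidateMotif:
    """One candidate motif occurrence (1-based inclusive coordinates).

    ``source`` is a motif class id for consensus matches or a template id for
    window-scan matches; ``sim_score``, ``rank_fraction`` and ``sim_bin`` are
    populated for window-scan motifs only.
    """

    protein_id: str
    start: int
    end: int
    sequence: str
    source: str
    sim_score: int | None = None
    rank_fraction: float | None = None
    sim_bin: str | None = None

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"motif bounds {self.start}-{self.end} disagree with "
                f"sequence length {len(self.sequence)}"
            )


def match_consensus(protein: ProteinRecord, elm_class: ElmClassDef) -> list[CandidateMotif]:
    """All occurrences of the class consensus pattern, overlaps included.

    A match is attempted at every start position, so overlapping occurrences
    that ``re.finditer`` would skip are reported; ``^``/``$`` anchors keep
    their usual semantics.
    """
    pattern = elm_class.regex
    seq = protein.sequence
    out = []
    for pos in range(len(seq)):
        m = pattern.match(seq, pos)
        if m is not None and m.end() > m.start():
            out.append(
                CandidateMotif(
                    protein_id=protein.protein_id,
                    start=m.start() + 1,
                    end=m.end(),
                    sequence=seq[m.start() : m.end()],
                    source=elm_class.class_id,
                )
            )
    return out


def score_window(window: str, template_motif: str) -> int:
    """Ungapped position-wise BLOSUM62 score of a window against the template."""
    if len(window) != len(template_motif):
        raise ValueError(
            f"window length {len(window)} != template length {len(template_motif)}"
        )
    return int(_B62[_encode(window), _encode(template_motif)].sum())


def assign_sim_bin(rank_fraction: float) -> str | None:
    """Similarity percentile bin, or None for ranks outside the top 0.05%."""
    if not 0 < rank_fraction <= 1:
        raise ValueError(f"rank_fraction {rank_fraction} outside (0, 1]")
    for edge, name in SIM_BIN_EDGES:
        if rank_fraction <= edge:
            return name
    return None


def scan_template_motif(
    proteome: Sequence[ProteinRecord],
    template_motif: str,
    template_id: str = "template",
    top_fraction: float = 5e-4,
) -> list[CandidateMotif]:
    """Score every x-residue window in the proteome against a template peptide.

    All windows fully inside each sequence are scored (sum over proteins of
    ``max(0, L - x + 1)`` windows).  The retention cutoff is the score of the
    ``ceil(top_fraction * total)``-th best window; windows tying the cutoff
    are all retained, which keeps the rule deterministic and order
    independent.  Each retained motif carries its raw score, its rank
    fraction (share of windows scoring at least as well) and a percentile
    bin.  Boundary ties can push a retained motif's rank fraction past the
    outermost bin edge; such motifs are assigned the outermost bin.
    """
    x = len(template_motif)
    if not 5 <= x <= 35:
        raise ValueError(f"template motif length {x} outside the modelable 5-35 range")
    tmpl = _encode(template_motif)

    per_protein: list[tuple[ProteinRecord, np.ndarray]] = []
    all_scores: list[np.ndarray] = []
    for protein in proteome:
        if protein.length < x:
            continue
        enc = _encode(protein.sequence)
        windows = np.lib.stride_tricks.sliding_window_view(enc, x)
        scores = _B62[windows, tmpl].sum(axis=1)
        per_protein.append((protein, scores))
        all_scores.append(scores)

    if not all_scores:
        raise ValueError(f"no windows: template length {x} exceeds every protein")

    pooled = np.concatenate(all_scores)
    total = pooled.size
    n_keep = max(1, math.ceil(top_fraction * total))
    cutoff = np.partition(pooled, total - n_keep)[total - n_keep]
    sorted_desc = np.sort(pooled)[::-1]

    out = []
    for protein, scores in per_protein:
        for idx in np.nonzero(scores >= cutoff)[0]:
            score = int(scores[idx])
            # windows scoring >= this one, via the descending sorted pool
            n_ge = int(np.searchsorted(-sorted_desc, -score, side="right"))
            rank = n_ge / total
            out.append(
                CandidateMotif(
                    protein_id=protein.protein_id,
                    start=int(idx) + 1,
                    end=int(idx) + x,
                    sequence=protein.sequence[idx : idx + x],
                    source=template_id,
                    sim_score=score,
                    rank_fraction=rank,
                    sim_bin=assign_sim_bin(rank) or SIM_BIN_EDGES[-1][1],
                )
            )
    return out


def write_motifs(path: str | Path, motifs: Iterable[CandidateMotif]) -> None:
    pd.DataFrame(
        [
            (m.protein_id, m.start, m.end, m.sequence, m.source,
             m.sim_score, m.rank_fraction, m.sim_bin)
            for m in motifs
        ],
        columns=["protein_id", "start", "end", "sequence", "source",
                 "sim_score", "rank_fraction", "sim_bin"],
    ).to_csv(path, sep="\t", index=False)


def read_motifs(path: str | Path) -> list[CandidateMotif]:
    df = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for r in df.itertuples():
        out.append(
            CandidateMotif(
                protein_id=str(r.protein_id),
                start=int(r.start),
                end=int(r.end),
                sequence=str(r.sequence),
                source=str(r.source),
                sim_score=None if pd.isna(r.sim_score) else int(r.sim_score),
                rank_fraction=None if pd.isna(r.rank_fraction) else float(r.rank_fraction),
                sim_bin=None if pd.isna(r.sim_bin) else str(r.sim_bin),
            )
        )
    return out
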