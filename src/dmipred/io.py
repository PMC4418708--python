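"""Core domain types and readers/writers for every file the pipeline touches.

All tabular formats are tab-delimited with a header row; lines starting with
``#`` are comments.  Protein coordinates are 1-based inclusive throughout,
matching Pfam/ELM conventions.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ProteinRecord",
    "DomainAnnotation",
    "ElmClassDef",
    "PairSet",
    "NsEvidenceTable",
    "canonical_pair",
    "read_fasta",
    "write_fasta",
    "read_domain_annotations",
    "write_domain_annotations",
    "read_elm_classes",
    "write_elm_classes",
    "read_pair_set",
    "write_pair_set",
    "read_ns_table",
    "write_ns_table",
]

#: the 20 standard amino-acid one-letter codes
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_NONSTANDARD = re.compile(rf"[^{STANDARD_AA}X]")


def normalize_sequence(seq: str) -> str:
    """Uppercase, strip '*' terminators, map non-standard letters to 'X'."""
    s = seq.upper().replace("*", "").replace("-", "")
    return _NONSTANDARD.sub("X", s)


@dataclass(frozen=True)
class ProteinRecord:
    """One proteome entry: 20 standard letters plus 'X' for anything else."""

    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"empty sequence for protein {self.protein_id!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DomainAnnotation:
    """A domain-family hit on a protein (e.g. pre-computed hmmscan output)."""

    protein_id: str
    family_id: str
    start: int  # 1-based inclusive
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(
                f"invalid domain bounds {self.start}-{self.end} on {self.protein_id}"
            )


@dataclass(frozen=True)
class ElmClassDef:
    """A motif class: a PRD domain family paired with a consensus regex."""

    class_id: str
    family_id: str
    pattern: str

    def __post_init__(self) -> None:
        try:
            re.compile(self.pattern)
        except re.error as exc:
            raise ValueError(
                f"class {self.class_id!r}: pattern {self.pattern!r} "
                f"is not a valid regular expression ({exc})"
            ) from exc

    @property
    def regex(self) -> re.Pattern:
        return re.compile(self.pattern)


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Unordered pair in canonical (sorted-id) order; idempotent."""
    return (a, b) if a <= b else (b, a)


@dataclass
class PairSet:
    """True-positive / true-negative protein pairs used to estimate clue LRs."""

    positives: list[tuple[str, str]]
    negatives: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.positives = sorted({canonical_pair(*p) for p in self.positives})
        self.negatives = sorted({canonical_pair(*p) for p in self.negatives})
        overlap = set(self.positives) & set(self.negatives)
        if overlap:
            raise ValueError(
                "pair(s) present in both the positive and negative set: "
                + ", ".join(f"{a}-{b}" for a, b in sorted(overlap)[:10])
            )

    @property
    def n_tp(self) -> int:
        return len(self.positives)

    @property
    def n_tn(self) -> int:
        return len(self.negatives)


class NsEvidenceTable:
    """Pair -> non-structural likelihood ratio (co-expression, GO, phylogeny).

    Pairs absent from the table look up as LR = 1, the multiplicative
    identity, so pairs without non-structural data are neither rewarded nor
    penalized.
    """

    def __init__(self, entries: Mapping[tuple[str, str], float] | None = None):
        self._lr: dict[tuple[str, str], float] = {}
        if entries:
            for (a, b), lr in entries.items():
                self.set(a, b, lr)

    def set(self, a: str, b: str, lr: float) -> None:
        if not lr > 0:
            raise ValueError(f"non-positive NS likelihood ratio {lr} for {a}-{b}")
        self._lr[canonical_pair(a, b)] = float(lr)

    def lookup(self, a: str, b: str) -> float:
        return self._lr.get(canonical_pair(a, b), 1.0)

    def __len__(self) -> int:
        return len(self._lr)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return canonical_pair(*pair) in self._lr

    def items(self):
        return self._lr.items()


# ---------------------------------------------------------------------------
# readers / writers


def _read_tsv(path: str | Path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate protein id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(ProteinRecord(rec.id, normalize_sequence(str(rec.seq))))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(path: str | Path, proteins: Iterable[ProteinRecord]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(p.sequence), id=p.protein_id, description="") for p in proteins),
        str(path),
        "fasta",
    )


def read_domain_annotations(path: str | Path) -> list[DomainAnnotation]:
    df = _read_tsv(path, ["protein_id", "family_id", "start", "end"])
    return [
        DomainAnnotation(r.protein_id, r.family_id, int(r.start), int(r.end))
        for r in df.itertuples()
    ]


def write_domain_annotations(path: str | Path, domains: Iterable[DomainAnnotation]) -> None:
    pd.DataFrame(
        [(d.protein_id, d.family_id, d.start, d.end) for d in domains],
        columns=["protein_id", "family_id", "start", "end"],
    ).to_csv(path, sep="\t", index=False)


def read_elm_classes(path: str | Path) -> list[ElmClassDef]:
    df = _read_tsv(path, ["class_id", "family_id", "pattern"])
    out = [ElmClassDef(r.class_id, r.family_id, r.pattern) for r in df.itertuples()]
    if not out:
        logging.getLogger(__name__).warning("no motif classes found in %s", path)
    return out


def write_elm_classes(path: str | Path, classes: Iterable[ElmClassDef]) -> None:
    pd.DataFrame(
        [(c.class_id, c.family_id, c.pattern) for c in classes],
        columns=["class_id", "family_id", "pattern"],
    ).to_csv(path, sep="\t", index=False)


def _read_pairs(path: str | Path) -> list[tuple[str, str]]:
    df = _read_tsv(path, ["protein_a", "protein_b"])
    return [canonical_pair(r.protein_a, r.protein_b) for r in df.itertuples()]


def read_pair_set(tp_path: str | Path, tn_path: str | Path) -> PairSet:
    return PairSet(_read_pairs(tp_path), _read_pairs(tn_path))


def write_pair_set(tp_path: str | Path, tn_path: str | Path, pairs: PairSet) -> None:
    for path, rows in ((tp_path, pairs.positives), (tn_path, pairs.negatives)):
        pd.DataFrame(rows, columns=["protein_a", "protein_b"]).to_csv(
            path, sep="\t", index=False
        )


def read_ns_table(path: str | Path) -> NsEvidenceTable:
    df = _read_tsv(path, ["protein_a", "protein_b", "lr"])
    table = NsEvidenceTable()
    for r in df.itertuples():
        table.set(r.protein_a, r.protein_b, float(r.lr))
    return table


def write_ns_table(path: str | Path, table: NsEvidenceTable) -> None:
    pd.DataFrame(
        [(a, b, lr) for (a, b), lr in sorted(table.items())],
        columns=["protein_a", "protein_b", "lr"],
    ).to_csv(path, sep="\t", index=False)
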