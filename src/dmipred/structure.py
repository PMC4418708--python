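"""Template-complex geometry: PDB ingestion, interface and surface residues.

A template is a PRD-peptide complex; candidate PRDs are filtered by (a)
structural distance to the template PRD (PSD, consumed from an external
structural aligner) and (b) how much of the template's binding interface
maps onto surface residues of the candidate model.

Residues are referenced as ``(chain_id, resnum, icode)`` triples; insertion
codes are normalized to ''.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "TemplateComplex",
    "StructAlignment",
    "parse_pdb",
    "interfacial_residues",
    "accessible_surface",
    "residue_asa",
    "interface_coverage",
    "assign_psd_bin",
    "filter_templates",
    "read_struct_alignments",
    "write_struct_alignments",
    "VDW_RADII",
    "DEFAULT_RADIUS",
]

#: van der Waals radii (Å) used for solvent accessibility
VDW_RADII = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8}
DEFAULT_RADIUS = 1.8

ResidueRef = tuple[str, int, str]


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    x: float
    y: float
    z: float

    @property
    def coord(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])

    @property
    def radius(self) -> float:
        r = VDW_RADII.get(self.element.upper())
        if r is None:
            warnings.warn(
                f"unknown element {self.element!r}; using default radius "
                f"{DEFAULT_RADIUS} Å",
                stacklevel=2,
            )
            return DEFAULT_RADIUS
        return r


@dataclass(frozen=True)
class Residue:
    chain_id: str
    resnum: int
    icode: str
    resname: str
    atoms: tuple[Atom, ...]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"residue {self.ref} has no atoms")

    @property
    def ref(self) -> ResidueRef:
        return (self.chain_id, self.resnum, self.icode)


@dataclass
class Structure:
    """Chains as ordered residue lists, keyed by chain id."""

    chains: dict[str, list[Residue]]

    def residues(self, chain_id: str | None = None) -> list[Residue]:
        if chain_id is not None:
            return self.chains[chain_id]
        return [r for residues in self.chains.values() for r in residues]

    def atom_coords(self, chain_id: str | None = None) -> np.ndarray:
        return np.array(
            [[a.x, a.y, a.z] for r in self.residues(chain_id) for a in r.atoms]
        )


@dataclass
class TemplateComplex:
    """A PRD-peptide complex used as an interaction template."""

    template_id: str
    structure: Structure
    prd_chain: str
    peptide_chain: str
    multimer_flag: bool = False

    @property
    def peptide_length(self) -> int:
        return len(self.structure.chains[self.peptide_chain])


@dataclass
class StructAlignment:
    """Candidate-domain-to-template correspondence with a PSD score.

    PSD (protein structural distance) comes from an external structural
    aligner; lower means more similar, and usable templates require
    PSD < 0.65.  ``correspondence`` maps template-PRD residue refs to
    candidate-model residue refs and must be injective.
    """

    template_id: str
    protein_id: str
    psd: float
    correspondence: dict[ResidueRef, ResidueRef] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.psd < 0:
            raise ValueError(f"negative PSD {self.psd}")
        values = list(self.correspondence.values())
        if len(set(values)) != len(values):
            raise ValueError(
                f"correspondence for {self.template_id}->{self.protein_id} "
                "is not injective"
            )


def parse_pdb(path) -> Structure:
    """Parse ATOM records of the first model; HETATM, waters and altloc B+
    are ignored; the highest-occupancy (or 'A') altloc is kept.

    Accepts a path or an open text handle of PDB-format text.
    """
    parser = PDBParser(QUIET=True)
    source = path if hasattr(path, "read") else str(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = next(parser.get_structure("s", source).get_models(), None)
    if model is None:
        raise ValueError(f"{path}: no ATOM records found")
    chains: dict[str, list[Residue]] = {}
    for chain in model:
        residues = []
        for res in chain:
            hetflag, resnum, icode = res.get_id()
            if hetflag.strip():  # HETATM / water
                continue
            atoms = tuple(
                Atom(a.get_name(), (a.element or "").strip() or a.get_name()[0],
                     *map(float, a.get_coord()))
                for a in res.get_atoms()
            )
            if atoms:
                residues.append(
                    Residue(chain.id, int(resnum), icode.strip(), res.get_resname(), atoms)
                )
        if residues:
            chains[chain.id] = residues
    if not chains:
        raise ValueError(f"{path}: no ATOM records found")
    return Structure(chains)


def interfacial_residues(
    template: TemplateComplex, cutoff: float = 4.5
) -> set[ResidueRef]:
    """PRD residues with any atom within ``cutoff`` Å (inclusive) of the peptide."""
    peptide = template.structure.chains.get(template.peptide_chain)
    if not peptide:
        raise ValueError(
            f"template {template.template_id}: peptide chain "
            f"{template.peptide_chain!r} is empty or missing"
        )
    pep_xyz = template.structure.atom_coords(template.peptide_chain)
    out: set[ResidueRef] = set()
    for res in template.structure.chains[template.prd_chain]:
        xyz = np.array([[a.x, a.y, a.z] for a in res.atoms])
        d2 = ((xyz[:, None, :] - pep_xyz[None, :, :]) ** 2).sum(axis=2)
        if d2.min() <= cutoff * cutoff:
            out.add(res.ref)
    return out


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral unit-sphere point set (Shrake-Rupley)."""
    i = np.arange(n)
    phi = math.pi * (3.0 - math.sqrt(5.0))  # golden angle
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    theta = phi * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def residue_asa(
    structure: Structure,
    probe: float = 1.4,
    n_points: int = 960,
    chain_id: str | None = None,
) -> dict[ResidueRef, float]:
    """Per-residue solvent accessible surface area (Å²), Shrake-Rupley scheme.

    Each atom's solvent sphere (vdW radius + probe) is sampled with a fixed
    golden-spiral point set; points falling inside any neighbouring atom's
    solvent sphere are occluded.  Deterministic by construction.
    """
    residues = structure.residues(chain_id)
    atoms = [a for r in residues for a in r.atoms]
    owner = np.repeat(np.arange(len(residues)), [len(r.atoms) for r in residues])
    xyz = np.array([[a.x, a.y, a.z] for a in atoms])
    radii = np.array([a.radius for a in atoms]) + probe
    unit = _sphere_points(n_points)

    asa = np.zeros(len(residues))
    for i in range(len(atoms)):
        pts = xyz[i] + radii[i] * unit
        d2 = ((xyz[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
        occluded = d2 < (radii[:, None] ** 2)
        occluded[i] = False
        accessible = ~occluded.any(axis=0)
        asa[owner[i]] += accessible.sum() / n_points * 4.0 * math.pi * radii[i] ** 2
    return {res.ref: float(a) for res, a in zip(residues, asa)}


def accessible_surface(
    structure: Structure,
    probe: float = 1.4,
    n_points: int = 960,
    threshold: float = 10.0,
    chain_id: str | None = None,
) -> set[ResidueRef]:
    """Residues whose ASA is at least ``threshold`` Å² (default 10 Å²)."""
    return {
        ref
        for ref, asa in residue_asa(structure, probe, n_points, chain_id).items()
        if asa >= threshold
    }


def interface_coverage(
    aln: StructAlignment,
    interfacial: set[ResidueRef],
    surface: set[ResidueRef],
    min_frac: float = 0.75,
) -> tuple[float, bool]:
    """Fraction of template interfacial residues aligned to candidate surface
    residues, and whether it reaches ``min_frac`` (inclusive)."""
    if not interfacial:
        raise ValueError(
            f"degenerate template {aln.template_id}: empty interfacial set"
        )
    mapped = sum(
        1
        for ref in interfacial
        if aln.correspondence.get(ref) in surface
    )
    frac = mapped / len(interfacial)
    return frac, frac >= min_frac


def assign_psd_bin(psd: float) -> str | None:
    """PSD bin: P1 for [0, 0.3], P2 for (0.3, 0.65); None at PSD >= 0.65."""
    if psd < 0:
        raise ValueError(f"negative PSD {psd}")
    if psd <= 0.3:
        return "P1"
    if psd < 0.65:
        return "P2"
    return None


def filter_templates(templates: Iterable[TemplateComplex]) -> list[TemplateComplex]:
    """Keep monomeric-PRD templates with peptide length in [5, 35]."""
    return [
        t
        for t in templates
        if not t.multimer_flag and 5 <= t.peptide_length <= 35
    ]


# ---------------------------------------------------------------------------
# structural-alignment TSV
#
# columns: template_id, protein_id, psd, t_chain, t_resnum, c_chain, c_resnum
# one row per corresponded residue; psd repeated on every row of an alignment.


def read_struct_alignments(path: str | Path) -> list[StructAlignment]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    out = []
    for (tid, pid), grp in df.groupby(["template_id", "protein_id"], sort=False):
        psd = float(grp["psd"].iloc[0])
        corr = {
            (r.t_chain, int(r.t_resnum), ""): (r.c_chain, int(r.c_resnum), "")
            for r in grp.itertuples()
            if not pd.isna(r.t_chain)
        }
        out.append(StructAlignment(str(tid), str(pid), psd, corr))
    return out


def write_struct_alignments(path: str | Path, alignments: Iterable[StructAlignment]) -> None:
    rows = []
    for aln in alignments:
        for (tc, tn, _), (cc, cn, _) in sorted(aln.correspondence.items()):
            rows.append((aln.template_id, aln.protein_id, aln.psd, tc, tn, cc, cn))
        if not aln.correspondence:
            rows.append((aln.template_id, aln.protein_id, aln.psd,
                         np.nan, np.nan, np.nan, np.nan))
    pd.DataFrame(
        rows,
        columns=["template_id", "protein_id", "psd",
                 "t_chain", "t_resnum", "c_chain", "c_resnum"],
    ).to_csv(path, sep="\t", index=False)
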