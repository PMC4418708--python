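"""Synthetic study-condition generator.

Builds every input the pipeline consumes — toy proteomes with planted
motifs, motif-class definitions, domain annotations, PRD-peptide template
complexes with idealized geometry, disorder tracks, ortholog alignments,
structural alignments, NS evidence tables and TP/TN pair sets with planted
clue frequencies — so the whole package builds and tests offline.

All randomness flows from one seed; every sub-generator draws from its own
spawned stream so adding a generator never perturbs the others.  The
default clue frequencies are the planted study conditions used throughout
the test-bench: a domain-motif match on 40% of interacting vs 2% of
non-interacting pairs (clue LR 20), with disorder/conservation/structure
clues enriched on true pairs, and log-normal NS evidence with a higher
median for true pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import (
    STANDARD_AA,
    DomainAnnotation,
    ElmClassDef,
    NsEvidenceTable,
    PairSet,
    ProteinRecord,
    canonical_pair,
    write_domain_annotations,
    write_elm_classes,
    write_fasta,
    write_ns_table,
    write_pair_set,
)
from .bayes import DmiMatch
from .features import DisorderTrack, write_disorder_tracks
from .structure import (
    StructAlignment,
    Structure,
    TemplateComplex,
    parse_pdb,
    write_struct_alignments,
)

__all__ = [
    "SynthConfig",
    "generate_proteome",
    "generate_training_sets",
    "generate_toy_complex",
    "generate_tracks_and_msa",
    "generate_bundle",
    "toy_psd",
]

#: consensus patterns available to the generator (ELM-style regex syntax)
_PATTERN_POOL = ["P..P", "RR.S", "L.G.E", "W..F", "D.E.D", "Y..N.P"]


@dataclass
class SynthConfig:
    """Study conditions for the synthetic bench.

    Pair-level clue frequencies are (TP, TN) probabilities; ``null()``
    returns the signal-off counterpart in which every TN frequency equals
    its TP value and the NS distributions coincide.
    """

    seed: int = 0
    # proteome
    n_proteins: int = 30
    length_range: tuple[int, int] = (60, 120)
    n_elm_classes: int = 3
    n_templates: int = 2
    planted_motifs: tuple[str, ...] = ()
    # pair sets
    n_tp: int = 2000
    n_tn: int = 2000
    # clue frequencies
    p_match_tp: float = 0.4
    p_match_tn: float = 0.02
    p_diso_tp: float = 0.8
    p_diso_tn: float = 0.3
    p_consv_tp: float = 0.7
    p_consv_tn: float = 0.2
    p_psd1_tp: float = 0.6
    p_psd1_tn: float = 0.3
    sim_probs_tp: tuple[float, ...] = (0.3, 0.3, 0.2, 0.2)
    sim_probs_tn: tuple[float, ...] = (0.05, 0.15, 0.3, 0.5)
    # NS evidence (log-normal)
    ns_median_tp: float = 20.0
    ns_median_tn: float = 0.8
    ns_sigma: float = 1.2
    # tracks
    disorder_background: float = 0.3
    disorder_motif: float = 0.7
    disorder_noise: float = 0.1
    msa_depth: int = 8
    msa_identity_background: float = 0.35
    msa_identity_motif: float = 0.95

    def __post_init__(self) -> None:
        probs = [
            self.p_match_tp, self.p_match_tn, self.p_diso_tp, self.p_diso_tn,
            self.p_consv_tp, self.p_consv_tn, self.p_psd1_tp, self.p_psd1_tn,
            *self.sim_probs_tp, *self.sim_probs_tn,
        ]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("clue frequencies must lie in [0, 1]")

    def null(self) -> "SynthConfig":
        """Signal-off twin: TN clue frequencies and NS distribution equal TP's."""
        return replace(
            self,
            p_match_tn=self.p_match_tp,
            p_diso_tn=self.p_diso_tp,
            p_consv_tn=self.p_consv_tp,
            p_psd1_tn=self.p_psd1_tp,
            sim_probs_tn=self.sim_probs_tp,
            ns_median_tn=self.ns_median_tp,
        )

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stream,))
        )


@dataclass(frozen=True)
class PlantedMotif:
    protein_id: str
    start: int
    end: int
    sequence: str
    source: str


def _random_sequence(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(STANDARD_AA), size=n))


def realize_pattern(pattern: str, rng: np.random.Generator) -> str:
    """A concrete peptide matching a simple consensus pattern ('.' and
    single-letter/character-class positions only)."""
    out = []
    i = 0
    while i < len(pattern):
        c = pattern[i]
        if c == ".":
            out.append(rng.choice(list(STANDARD_AA)))
            i += 1
        elif c == "[":
            j = pattern.index("]", i)
            out.append(rng.choice(list(pattern[i + 1 : j])))
            i = j + 1
        elif c in ("^", "$"):
            i += 1
        else:
            out.append(c)
            i += 1
    return "".join(out)


def generate_proteome(
    config: SynthConfig,
) -> tuple[list[ProteinRecord], list[PlantedMotif]]:
    """Uniform-random proteome with the configured motifs spliced in at
    recorded positions; the ledger is the ground truth for downstream
    feature generation."""
    if config.n_proteins < 1:
        raise ValueError("n_proteins must be at least 1")
    rng = config.rng(1)
    lo, hi = config.length_range
    proteins = []
    for i in range(config.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        proteins.append(ProteinRecord(f"P{i:04d}", _random_sequence(rng, length)))

    ledger: list[PlantedMotif] = []
    sequences = {p.protein_id: p.sequence for p in proteins}
    for j, motif in enumerate(config.planted_motifs):
        target = proteins[int(rng.integers(0, len(proteins)))]
        if len(motif) > target.length:
            raise ValueError(
                f"motif {motif!r} longer than protein {target.protein_id}"
            )
        start = int(rng.integers(0, target.length - len(motif) + 1))
        seq = sequences[target.protein_id]
        sequences[target.protein_id] = (
            seq[:start] + motif + seq[start + len(motif):]
        )
        ledger.append(
            PlantedMotif(target.protein_id, start + 1, start + len(motif),
                         motif, f"planted{j}")
        )
    proteins = [ProteinRecord(p.protein_id, sequences[p.protein_id]) for p in proteins]
    return proteins, ledger


def _draw_clues(
    rng: np.random.Generator, config: SynthConfig, is_tp: bool, method: str,
    class_ids: Sequence[str], template_ids: Sequence[str],
) -> tuple | None:
    """Clue tuple for one pair and route, or None when no match is drawn."""
    p_match = config.p_match_tp if is_tp else config.p_match_tn
    if rng.random() >= p_match:
        return None
    p_diso = config.p_diso_tp if is_tp else config.p_diso_tn
    p_consv = config.p_consv_tp if is_tp else config.p_consv_tn
    clues = [
        ("match", "present"),
        ("diso", bool(rng.random() < p_diso)),
        ("consv", bool(rng.random() < p_consv)),
    ]
    if method == "prd_motif":
        source = class_ids[int(rng.integers(0, len(class_ids)))]
        clues.append(("class", source))
    else:
        source = template_ids[int(rng.integers(0, len(template_ids)))]
        p_psd1 = config.p_psd1_tp if is_tp else config.p_psd1_tn
        clues.append(("psd", "P1" if rng.random() < p_psd1 else "P2"))
        probs = config.sim_probs_tp if is_tp else config.sim_probs_tn
        probs = np.asarray(probs, dtype=float)
        sim = ("B1", "B2", "B3", "B4")[int(rng.choice(4, p=probs / probs.sum()))]
        clues.append(("sim", sim))
    return source, tuple(clues)


def generate_training_sets(
    config: SynthConfig,
) -> tuple[PairSet, list[DmiMatch], NsEvidenceTable]:
    """TP/TN pair sets with clues planted at the configured frequencies.

    Each pair draws each evidence route independently: with probability
    p_match it carries a match whose dependent clues (class or PSD/SIM bins,
    disorder, conservation) are drawn from the route's conditional
    frequencies.  NS likelihood ratios are log-normal with a class-specific
    median.  Everything is seeded and reproducible.
    """
    if config.n_tp < 1 or config.n_tn < 1:
        raise ValueError("n_tp and n_tn must be at least 1")
    rng = config.rng(2)
    class_ids = [f"CLS{i:03d}" for i in range(max(1, config.n_elm_classes))]
    template_ids = [f"TPL{i:03d}" for i in range(max(1, config.n_templates))]

    positives = [(f"A{i:05d}", f"B{i:05d}") for i in range(config.n_tp)]
    negatives = [(f"C{i:05d}", f"D{i:05d}") for i in range(config.n_tn)]
    pair_set = PairSet(positives, negatives)

    matches: list[DmiMatch] = []
    ns = NsEvidenceTable()
    for pair_list, is_tp in ((pair_set.positives, True), (pair_set.negatives, False)):
        median = config.ns_median_tp if is_tp else config.ns_median_tn
        for pair in pair_list:
            for method in ("prd_motif", "struct"):
                drawn = _draw_clues(rng, config, is_tp, method, class_ids, template_ids)
                if drawn is not None:
                    source, clues = drawn
                    matches.append(DmiMatch(pair, method, source, clues))
            ns.set(*pair, float(np.exp(math.log(median)
                                       + config.ns_sigma * rng.standard_normal())))
    return pair_set, matches, ns


# ---------------------------------------------------------------------------
# toy structures


def _helix_coords(n: int) -> np.ndarray:
    """Idealized alpha-helix C-alpha trace (2.3 Å radius, 1.5 Å rise, 100°)."""
    i = np.arange(n)
    theta = np.deg2rad(100.0) * i
    return np.column_stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i])


def _strand_coords(n: int) -> np.ndarray:
    """Extended-strand C-alpha trace, 3.8 Å spacing along x."""
    return np.column_stack([3.8 * np.arange(n), np.zeros(n), np.zeros(n)])


_AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR", "X": "UNK",
}


def _pdb_atom_line(serial, name, resname, chain, resnum, xyz, element) -> str:
    return (
        f"ATOM  {serial:5d} {name:^4s}{resname:>4s} {chain}{resnum:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


def _chain_pdb_lines(
    seq: str, coords: np.ndarray, chain: str, serial0: int
) -> tuple[list[str], int]:
    lines = []
    serial = serial0
    for i, (aa, ca) in enumerate(zip(seq, coords)):
        lines.append(_pdb_atom_line(serial, "CA", _AA3[aa], chain, i + 1, ca, "C"))
        serial += 1
        if aa != "G":  # C-beta pseudo-atom, offset away from the local axis
            cb = ca + np.array([1.0, 1.0, 0.5]) / math.sqrt(2.25) * 1.53
            lines.append(_pdb_atom_line(serial, "CB", _AA3[aa], chain, i + 1, cb, "C"))
            serial += 1
    return lines, serial


def _min_dist(a: np.ndarray, b: np.ndarray) -> float:
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.min()))


def generate_toy_complex(
    prd_size: int = 20,
    peptide_len: int = 8,
    gap: float = 4.0,
    seed: int = 0,
    template_id: str = "TPL000",
) -> tuple[str, TemplateComplex, str]:
    """A PRD pseudo-helix (chain A) plus an extended peptide strand (chain B)
    placed so the minimum atom-atom distance equals ``gap`` (Å).

    Returns the PDB text, the parsed :class:`TemplateComplex` and the
    peptide sequence.  Geometry is deterministic for a given seed.
    """
    if not 5 <= peptide_len <= 35:
        raise ValueError(f"peptide length {peptide_len} outside the modelable 5-35 range")
    if prd_size < 1 or gap <= 0:
        raise ValueError("prd_size must be >= 1 and gap > 0")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(3,)))
    prd_seq = _random_sequence(rng, prd_size)
    pep_seq = _random_sequence(rng, peptide_len)

    def chain_atoms(seq: str, ca: np.ndarray) -> np.ndarray:
        pts = [ca]
        cb_mask = np.array([aa != "G" for aa in seq])
        if cb_mask.any():
            pts.append(ca[cb_mask] + np.array([1.0, 1.0, 0.5]) / math.sqrt(2.25) * 1.53)
        return np.vstack(pts)

    prd_ca = _helix_coords(prd_size)
    pep_base = _strand_coords(peptide_len)
    pep_base = pep_base - pep_base.mean(axis=0) + prd_ca.mean(axis=0)

    prd_atoms = chain_atoms(prd_seq, prd_ca)
    z0 = 60.0

    def min_dist_at(drop: float) -> float:
        ca = pep_base + np.array([0.0, 0.0, z0 - drop])
        return _min_dist(prd_atoms, chain_atoms(pep_seq, ca))

    lo, hi = 0.0, z0  # min distance decreases as the peptide drops
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if min_dist_at(mid) > gap:
            lo = mid
        else:
            hi = mid
    pep_ca = pep_base + np.array([0.0, 0.0, z0 - hi])

    lines, serial = _chain_pdb_lines(prd_seq, prd_ca, "A", 1)
    lines.append("TER")
    pep_lines, _ = _chain_pdb_lines(pep_seq, pep_ca, "B", serial)
    pdb_text = "\n".join(lines + pep_lines + ["TER", "END"]) + "\n"

    from io import StringIO

    structure = parse_pdb(StringIO(pdb_text))
    template = TemplateComplex(template_id, structure, "A", "B", multimer_flag=False)
    return pdb_text, template, pep_seq


def toy_psd(a: Structure, b: Structure, chain_a: str = "A", chain_b: str = "A") -> float:
    """SYNTHETIC stand-in pseudo-distance for fixture generation only.

    A squashed C-alpha RMSD over the common residue prefix, mapped to
    [0, 1) as rmsd/(rmsd+2).  This is NOT equivalent to a real structural
    aligner's protein structural distance; it exists so fixtures can carry
    internally consistent psd values.
    """
    ca_a = np.array([[at.x, at.y, at.z] for r in a.chains[chain_a] for at in r.atoms if at.name == "CA"])
    ca_b = np.array([[at.x, at.y, at.z] for r in b.chains[chain_b] for at in r.atoms if at.name == "CA"])
    n = min(len(ca_a), len(ca_b))
    rmsd = float(np.sqrt(((ca_a[:n] - ca_b[:n]) ** 2).sum(axis=1).mean()))
    return rmsd / (rmsd + 2.0)


# ---------------------------------------------------------------------------
# tracks, alignments, bundle


def generate_tracks_and_msa(
    proteome: Sequence[ProteinRecord],
    ledger: Sequence[PlantedMotif],
    config: SynthConfig,
) -> tuple[dict[str, DisorderTrack], dict[str, dict[str, str]]]:
    """Disorder tracks and ortholog MSAs consistent with the planted ledger.

    Planted-motif residues get disorder ~ N(0.7, noise) and near-identical
    alignment columns; background residues get ~ N(0.3, noise) and weakly
    conserved columns.
    """
    rng = config.rng(4)
    planted: dict[str, set[int]] = {}
    for pm in ledger:
        planted.setdefault(pm.protein_id, set()).update(range(pm.start, pm.end + 1))

    tracks: dict[str, DisorderTrack] = {}
    msas: dict[str, dict[str, str]] = {}
    aa = list(STANDARD_AA)
    for protein in proteome:
        hot = planted.get(protein.protein_id, set())
        mean = np.where(
            np.isin(np.arange(1, protein.length + 1), list(hot)),
            config.disorder_motif,
            config.disorder_background,
        )
        scores = np.clip(
            mean + config.disorder_noise * rng.standard_normal(protein.length), 0.0, 1.0
        )
        tracks[protein.protein_id] = DisorderTrack(protein.protein_id, scores)

        rows = {protein.protein_id: protein.sequence}
        for o in range(config.msa_depth - 1):
            chars = []
            for pos, c in enumerate(protein.sequence, start=1):
                p_same = (
                    config.msa_identity_motif
                    if pos in hot
                    else config.msa_identity_background
                )
                chars.append(c if rng.random() < p_same else str(rng.choice(aa)))
            rows[f"{protein.protein_id}_orth{o}"] = "".join(chars)
        msas[protein.protein_id] = rows
    return tracks, msas


def generate_bundle(config: SynthConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write the complete input bundle consumed by the pipeline CLI.

    Plants motif-class instances and template-peptide copies into a toy
    proteome so that a subset of the TP pairs has genuine domain-motif
    support, generates consistent disorder/conservation/structure inputs,
    and emits TP/TN pair lists plus an NS evidence table over the bundle's
    pairs.  Returns a manifest of written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "msa").mkdir(exist_ok=True)
    (out / "templates").mkdir(exist_ok=True)
    (out / "models").mkdir(exist_ok=True)
    rng = config.rng(5)

    # motif classes and their PRD families
    classes = [
        ElmClassDef(f"CLS{i:03d}", f"PF{i:05d}", _PATTERN_POOL[i % len(_PATTERN_POOL)])
        for i in range(config.n_elm_classes)
    ]

    # templates: toy complexes; peptides become plantable motifs
    templates: list[tuple[str, TemplateComplex, str]] = []
    for i in range(config.n_templates):
        pdb_text, template, pep_seq = generate_toy_complex(
            prd_size=20, peptide_len=8, gap=4.0,
            seed=config.seed + i, template_id=f"TPL{i:03d}",
        )
        (out / "templates" / f"TPL{i:03d}.pdb").write_text(pdb_text)
        templates.append((pdb_text, template, pep_seq))

    # pair universe over the toy proteome
    n = config.n_proteins
    n_tp = min(config.n_tp, max(5, n))
    n_tn = min(config.n_tn, max(10, n * 5))
    all_pairs = [
        (f"P{i:04d}", f"P{j:04d}") for i in range(n) for j in range(i + 1, n)
    ]
    if n_tp + n_tn > len(all_pairs):
        raise ValueError("proteome too small for the requested pair counts")
    chosen = rng.permutation(len(all_pairs))
    tp_pairs = [all_pairs[i] for i in chosen[:n_tp]]
    tn_pairs = [all_pairs[i] for i in chosen[n_tp : n_tp + n_tn]]

    # decide planted support and build the proteome
    plant: list[str] = []
    domain_rows: list[DomainAnnotation] = []
    planted_assignments: list[tuple[tuple[str, str], str, str, str]] = []
    for pairs, p_match in ((tp_pairs, config.p_match_tp), (tn_pairs, config.p_match_tn)):
        for pair in pairs:
            if rng.random() < p_match:
                cls = classes[int(rng.integers(0, len(classes)))]
                planted_assignments.append((pair, "prd_motif", cls.class_id, cls.pattern))
            if rng.random() < p_match and templates:
                ti = int(rng.integers(0, len(templates)))
                planted_assignments.append(
                    (pair, "struct", templates[ti][1].template_id, templates[ti][2])
                )

    proteins, _ = generate_proteome(replace(config, planted_motifs=()))
    sequences = {p.protein_id: p.sequence for p in proteins}
    ledger: list[PlantedMotif] = []
    psd_by_protein_template: dict[tuple[str, str], float] = {}
    for (a, b), method, source, pattern_or_pep in planted_assignments:
        domain_protein, motif_protein = (a, b) if rng.random() < 0.5 else (b, a)
        motif = (
            realize_pattern(pattern_or_pep, rng)
            if method == "prd_motif"
            else pattern_or_pep
        )
        seq = sequences[motif_protein]
        if len(motif) > len(seq):
            continue
        start = int(rng.integers(0, len(seq) - len(motif) + 1))
        sequences[motif_protein] = seq[:start] + motif + seq[start + len(motif):]
        ledger.append(
            PlantedMotif(motif_protein, start + 1, start + len(motif), motif, source)
        )
        if method == "prd_motif":
            cls = next(c for c in classes if c.class_id == source)
            dstart = int(rng.integers(1, max(2, len(sequences[domain_protein]) - 30)))
            domain_rows.append(
                DomainAnnotation(domain_protein, cls.family_id, dstart,
                                 min(dstart + 29, len(sequences[domain_protein])))
            )
        else:
            p_psd1 = config.p_psd1_tp if (canonical_pair(a, b) in
                                          {canonical_pair(*p) for p in tp_pairs}) else config.p_psd1_tn
            psd = (rng.uniform(0.05, 0.3) if rng.random() < p_psd1
                   else rng.uniform(0.31, 0.64))
            psd_by_protein_template.setdefault((domain_protein, source), psd)

    proteins = [ProteinRecord(p.protein_id, sequences[p.protein_id]) for p in proteins]

    # candidate models + structural alignments for the struct route
    alignments: list[StructAlignment] = []
    model_paths: dict[str, Path] = {}
    for (protein_id, template_id), psd in sorted(psd_by_protein_template.items()):
        if protein_id not in model_paths:
            pdb_text, _, _ = generate_toy_complex(
                prd_size=20, peptide_len=8, gap=25.0,
                seed=config.seed + 1000 + int(protein_id[1:]),
            )
            # model = the PRD chain only, same helix geometry as the template PRD
            model_text = "\n".join(
                ln for ln in pdb_text.splitlines()
                if not (ln.startswith("ATOM") and ln[21] == "B")
            ) + "\n"
            path = out / "models" / f"{protein_id}.pdb"
            path.write_text(model_text)
            model_paths[protein_id] = path
        corr = {("A", i, ""): ("A", i, "") for i in range(1, 21)}
        alignments.append(StructAlignment(template_id, protein_id, psd, corr))

    tracks, msas = generate_tracks_and_msa(proteins, ledger, config)

    # NS evidence over all bundle pairs
    ns = NsEvidenceTable()
    for pairs, median in ((tp_pairs, config.ns_median_tp), (tn_pairs, config.ns_median_tn)):
        for pair in pairs:
            ns.set(*pair, float(np.exp(math.log(median)
                                       + config.ns_sigma * rng.standard_normal())))

    # write everything
    manifest = {
        "proteome": out / "proteome.fasta",
        "elm_classes": out / "elm_classes.tsv",
        "domains": out / "domains.tsv",
        "disorder": out / "disorder.tsv",
        "tp_pairs": out / "tp_pairs.tsv",
        "tn_pairs": out / "tn_pairs.tsv",
        "ns_table": out / "ns_table.tsv",
        "struct_alignments": out / "struct_alignments.tsv",
        "template_meta": out / "templates.tsv",
        "msa_dir": out / "msa",
        "template_dir": out / "templates",
        "model_dir": out / "models",
    }
    write_fasta(manifest["proteome"], proteins)
    write_elm_classes(manifest["elm_classes"], classes)
    write_domain_annotations(manifest["domains"], domain_rows)
    write_disorder_tracks(manifest["disorder"], tracks)
    write_pair_set(manifest["tp_pairs"], manifest["tn_pairs"], PairSet(tp_pairs, tn_pairs))
    write_ns_table(manifest["ns_table"], ns)
    write_struct_alignments(manifest["struct_alignments"], alignments)
    with open(manifest["template_meta"], "w") as fh:
        fh.write("template_id\tpdb_path\tprd_chain\tpeptide_chain\tpeptide_seq\tmultimer_flag\n")
        for _, template, pep_seq in templates:
            fh.write(
                f"{template.template_id}\ttemplates/{template.template_id}.pdb"
                f"\tA\tB\t{pep_seq}\tFalse\n"
            )
    for protein in proteins:
        rows = msas[protein.protein_id]
        with open(out / "msa" / f"{protein.protein_id}.fasta", "w") as fh:
            for rid, seq in rows.items():
                fh.write(f">{rid}\n{seq}\n")
    return manifest
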