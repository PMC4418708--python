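"""End-to-end wiring of the two prediction routes.

``run_pipeline`` executes: motif scan (consensus + template windows) ->
sequence features -> structural filters -> clue LR training -> per-pair
combination with NS evidence -> strong-prediction flagging -> 5-fold
cross-validated evaluation.  Every numeric threshold lives on
:class:`RunConfig` in one auditable place, defaulting to the published
values.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, fields
from pathlib import Path

import pandas as pd

from . import bayes, evaluation, features, io, motifs, structure

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths to every input plus all tunable thresholds."""

    proteome: Path
    elm_classes: Path
    domains: Path
    disorder: Path
    msa_dir: Path
    template_meta: Path
    template_dir: Path
    model_dir: Path
    struct_alignments: Path
    tp_pairs: Path
    tn_pairs: Path
    ns_table: Path
    out_dir: Path
    # thresholds (published defaults)
    distance_cutoff: float = 4.5      # Å, interface contact
    asa_threshold: float = 10.0       # Å², surface residue
    coverage_min: float = 0.75        # interfacial residues on candidate surface
    top_fraction: float = 5e-4        # window-scan retention (top 0.05%)
    disorder_cutoff: float = 0.5      # mean motif disorder
    conservation_window: int = 31     # residues each side
    strong_threshold: float = 600.0   # final-LR strong flag (strict >)
    alpha: float = 0.0                # LR pseudocount
    lr_cap: float = 1e6
    seed: int = 0
    k: int = 5
    policy: str = "max"               # per-pair interface aggregation

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.type == "Path":
                setattr(self, f.name, Path(getattr(self, f.name)))
        if self.policy not in ("max", "product"):
            raise ValueError(f"aggregation policy must be 'max' or 'product', got {self.policy!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Flat key<TAB-or-=>value config file; keys match field names."""
        base = Path(path).parent
        kwargs: dict = {}
        numeric = {
            f.name: f.type for f in fields(cls) if f.type in ("float", "int", "str")
        }
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.replace("=", "\t", 1).partition("\t")
            key, value = key.strip(), value.strip()
            if key in numeric:
                kwargs[key] = (
                    int(value) if numeric[key] == "int"
                    else float(value) if numeric[key] == "float"
                    else value
                )
            else:
                kwargs[key] = base / value
        return cls(**kwargs)


def _motif_clues(
    motif: motifs.CandidateMotif,
    disorder_tracks: dict[str, features.DisorderTrack],
    conservation: dict[str, features.ConservationTrack],
    disorder_cutoff: float,
) -> tuple[bool, bool]:
    track = disorder_tracks.get(motif.protein_id)
    if track is None:
        raise FileNotFoundError(f"no disorder track for protein {motif.protein_id}")
    _, diso = features.motif_disorder(track, motif, cutoff=disorder_cutoff)
    cons_track = conservation.get(motif.protein_id)
    consv = (
        features.motif_conserved(cons_track.local_flags, motif)
        if cons_track is not None
        else False
    )
    return diso, consv


def collect_matches(config: RunConfig) -> tuple[list[bayes.DmiMatch], io.PairSet, io.NsEvidenceTable]:
    """Run both discovery routes and return clue-annotated candidate matches
    for every pair in the TP/TN benchmark universe."""
    proteome = io.read_fasta(config.proteome)
    by_id = {p.protein_id: p for p in proteome}
    classes = io.read_elm_classes(config.elm_classes)
    domains = io.read_domain_annotations(config.domains)
    pair_set = io.read_pair_set(config.tp_pairs, config.tn_pairs)
    ns_table = io.read_ns_table(config.ns_table)
    disorder_tracks = features.read_disorder_tracks(config.disorder)

    conservation: dict[str, features.ConservationTrack] = {}
    for protein in proteome:
        msa_path = Path(config.msa_dir) / f"{protein.protein_id}.fasta"
        if msa_path.exists():
            conservation[protein.protein_id] = features.conservation_from_msa(
                msa_path, protein.protein_id, half_window=config.conservation_window
            )

    universe = set(pair_set.positives) | set(pair_set.negatives)
    matches: set[bayes.DmiMatch] = set()

    # route 1: consensus matching (PRD family x motif class)
    carriers: dict[str, set[str]] = {}
    for d in domains:
        carriers.setdefault(d.family_id, set()).add(d.protein_id)
    for cls in classes:
        domain_proteins = carriers.get(cls.family_id, set())
        if not domain_proteins:
            continue
        for protein in proteome:
            for m in motifs.match_consensus(protein, cls):
                diso, consv = _motif_clues(
                    m, disorder_tracks, conservation, config.disorder_cutoff
                )
                for dp in domain_proteins:
                    if dp == m.protein_id:
                        continue
                    pair = io.canonical_pair(dp, m.protein_id)
                    if pair not in universe:
                        continue
                    matches.add(
                        bayes.DmiMatch(
                            pair, "prd_motif", cls.class_id,
                            (("match", "present"), ("class", cls.class_id),
                             ("diso", diso), ("consv", consv)),
                        )
                    )

    # route 2: template-based (structural filters x window scan)
    meta = pd.read_csv(config.template_meta, sep="\t", comment="#", dtype=str)
    templates: dict[str, structure.TemplateComplex] = {}
    peptide_seqs: dict[str, str] = {}
    for r in meta.itertuples():
        s = structure.parse_pdb(Path(config.template_meta).parent / r.pdb_path)
        templates[r.template_id] = structure.TemplateComplex(
            r.template_id, s, r.prd_chain, r.peptide_chain,
            multimer_flag=str(r.multimer_flag).lower() == "true",
        )
        peptide_seqs[r.template_id] = r.peptide_seq
    usable = {t.template_id: t for t in structure.filter_templates(templates.values())}

    surface_cache: dict[str, set] = {}
    candidate_prds: dict[str, list[tuple[str, str]]] = {}  # template -> [(protein, psd_bin)]
    for aln in structure.read_struct_alignments(config.struct_alignments):
        template = usable.get(aln.template_id)
        if template is None:
            continue
        psd_bin = structure.assign_psd_bin(aln.psd)
        if psd_bin is None:
            continue
        model_path = Path(config.model_dir) / f"{aln.protein_id}.pdb"
        if not model_path.exists():
            log.warning("no structural model for %s; skipping", aln.protein_id)
            continue
        if aln.protein_id not in surface_cache:
            surface_cache[aln.protein_id] = structure.accessible_surface(
                structure.parse_pdb(model_path), threshold=config.asa_threshold
            )
        interfacial = structure.interfacial_residues(template, cutoff=config.distance_cutoff)
        _, ok = structure.interface_coverage(
            aln, interfacial, surface_cache[aln.protein_id], min_frac=config.coverage_min
        )
        if ok:
            candidate_prds.setdefault(aln.template_id, []).append((aln.protein_id, psd_bin))

    for template_id, prds in candidate_prds.items():
        scan = motifs.scan_template_motif(
            proteome, peptide_seqs[template_id], template_id,
            top_fraction=config.top_fraction,
        )
        for m in scan:
            diso, consv = _motif_clues(
                m, disorder_tracks, conservation, config.disorder_cutoff
            )
            for prd_protein, psd_bin in prds:
                if prd_protein == m.protein_id:
                    continue
                pair = io.canonical_pair(prd_protein, m.protein_id)
                if pair not in universe:
                    continue
                matches.add(
                    bayes.DmiMatch(
                        pair, "struct", template_id,
                        (("match", "present"), ("psd", psd_bin), ("sim", m.sim_bin),
                         ("diso", diso), ("consv", consv)),
                    )
                )
    return sorted(matches, key=lambda m: (m.pair, m.method, m.source)), pair_set, ns_table


def run_pipeline(config: RunConfig) -> dict:
    """Execute scan -> features -> filters -> train -> combine -> evaluate.

    Writes predictions, clue LR tables, pooled ROC/PR curves and a summary
    JSON under ``config.out_dir``; returns the summary dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for f in fields(config):
        log.info("config %s = %s", f.name, getattr(config, f.name))

    matches, pair_set, ns_table = collect_matches(config)
    log.info("collected %d candidate matches over %d TP / %d TN pairs",
             len(matches), pair_set.n_tp, pair_set.n_tn)

    clf = bayes.DmiBayesClassifier(
        alpha=config.alpha, lr_cap=config.lr_cap, policy=config.policy,
        strong_threshold=config.strong_threshold,
    ).fit(matches, pair_set)
    for method, table in clf.lr_tables_.items():
        bayes.write_lr_table(out / f"lr_table_{method}.tsv", table)

    all_pairs = pair_set.positives + pair_set.negatives
    predictions = clf.predict_pairs(matches, all_pairs, ns_table=ns_table)
    bayes.write_predictions(out / "predictions.tsv", predictions)

    cv = evaluation.cross_validate(
        matches, pair_set, ns_table=ns_table, k=config.k, seed=config.seed,
        alpha=config.alpha, lr_cap=config.lr_cap, policy=config.policy,
    )
    pd.DataFrame(
        [(p.threshold, p.tpr, p.fpr, p.precision, p.recall) for p in cv.roc_points],
        columns=["threshold", "tpr", "fpr", "precision", "recall"],
    ).to_csv(out / "curves.tsv", sep="\t", index=False)

    summary = {
        "n_matches": len(matches),
        "n_tp": pair_set.n_tp,
        "n_tn": pair_set.n_tn,
        "n_strong": sum(p.strong for p in predictions),
        "auc": cv.auc,
        "auprc": cv.auprc,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    log.info("summary: %s", summary)
    return summary
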