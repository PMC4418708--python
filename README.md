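# dmipred

Bayesian prediction of peptide-mediated protein-protein interactions
(PPIs): interactions formed between a structured peptide-recognition
domain (PRD) — SH3, PDZ, SH2 and the like — on one protein and a short
linear motif (SLiM), typically 5–35 residues in a disordered region, on
another.  These interactions are systematically under-detected by
high-throughput experiments, so integrative computational prediction is a
practical way to map this part of the interactome.

## Method

Candidate domain-motif interfaces come from two routes:

* **consensus route** — a curated motif class pairs a PRD family with a
  consensus regular expression; a candidate interface exists whenever one
  protein carries the family's domain and the other a motif matching the
  pattern;
* **template route** — a PRD-peptide complex structure serves as a
  template; a candidate PRD must be structurally similar (protein
  structural distance PSD < 0.65, binned [0, 0.3] / (0.3, 0.65)) with at
  least 75% of the template's interfacial residues (atoms within 4.5 Å of
  the peptide) aligned onto surface residues of the candidate model
  (solvent-accessible area ≥ 10 Å²); candidate motifs are windows of the
  template-peptide length whose BLOSUM62 similarity to the template peptide
  ranks in the proteome-wide top 0.05%, binned by percentile.

Each candidate interface carries observable clues c_i: the motif-class or
template identity, the PSD bin, the similarity bin, whether the motif lies
in predicted disorder (mean residue score > 0.5), and whether all of its
residues are locally conserved (per-column information content of an
ortholog alignment, gap-weighted, compared against a ±31-residue window).
Clue likelihood ratios are estimated by counting over curated
true-positive / true-negative pair sets,

    LR(c_i) = P(c_i | TP) / P(c_i | TN),

and combined naive-Bayes style; motif-level clues presuppose the match
clue and are normalized by it:

    consensus:  LR(DMI) = LR(match) · LR(class)/LR(match) · LR(diso)/LR(match) · LR(consv)/LR(match)
    template:   LR(DMI) = LR(match) · LR(PSD)/LR(match) · LR(SIM)/LR(match) · LR(diso)/LR(match) · LR(consv)/LR(match)

Per pair, the best interface LR (max over candidates of both routes) is
multiplied by a pre-computed non-structural (NS) LR (co-expression, GO
similarity, phylogenetic profiles).  Pairs with final LR > 600 are
**strong predictions**: at prior odds of 1/600 that threshold corresponds
to posterior probability 0.5.  An existing domain-domain structural score
can be merged by taking the larger of the two structural LRs before NS
multiplication.

## Worked example

The synthetic bench plants a domain-motif match on 40% of interacting and
2% of non-interacting pairs (clue LR 20), with disorder, conservation and
structure clues enriched on true pairs and log-normal NS evidence:

```python
from dmipred import (SynthConfig, generate_training_sets,
                     DmiBayesClassifier, cross_validate, posterior)

config = SynthConfig(seed=1, n_tp=2000, n_tn=2000)
pairs, matches, ns = generate_training_sets(config)

clf = DmiBayesClassifier().fit(matches, pairs)
print("LR(match), consensus route:",
      round(clf.lr_tables_["prd_motif"].lr("match", "present"), 2))

cv = cross_validate(matches, pairs, ns_table=ns, k=5, seed=1)
print("pooled 5-fold ROC AUC:", round(cv.auc, 3))

universe = pairs.positives + pairs.negatives
preds = clf.predict_pairs(matches, universe, ns_table=ns)
print("strong predictions (LR > 600):", sum(p.strong for p in preds))
print("posterior at LR 600:", posterior(600, 1 / 600))
```

prints

```
LR(match), consensus route: 20.82
pooled 5-fold ROC AUC: 0.987
strong predictions (LR > 600): 972
posterior at LR 600: 0.5
```

The estimated LR(match) recovers the planted ratio 0.4/0.02 = 20;
cross-validated combined evidence separates the classes almost perfectly;
and combining interface with NS evidence yields far more strong
predictions than either source alone — the evidence-amplification effect
the Bayesian combination exists for.

The file-based pipeline is driven by the `dmi` CLI:

```
dmi simulate --seed 1 --out bundle/        # write a complete input bundle
dmi run --bundle bundle/ --out results/    # scan, filter, train, predict, evaluate
```

which writes `predictions.tsv` (per-pair interface LR, NS LR, final LR,
strong flag), per-route clue LR tables, pooled ROC/PR curves and a
`summary.json`.

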