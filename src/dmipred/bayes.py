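"""Naive-Bayes likelihood-ratio engine for domain-motif interaction evidence.

Each candidate domain-motif interface carries a set of observable clues.
For a clue value c, the likelihood ratio is

    LR(c) = P(c | interacting) / P(c | non-interacting)

estimated by counting pairs carrying c in curated true-positive and
true-negative pair sets.  The motif-level clues (class identity, PSD bin,
similarity bin, disorder, conservation) all presuppose that a domain-motif
match exists, so their LRs are normalized by LR(match) before
multiplication:

  consensus route:   LR(DMI) = LR(match) * (LR(class)/LR(match))
                               * (LR(diso)/LR(match)) * (LR(consv)/LR(match))
  template route:    LR(DMI) = LR(match) * (LR(PSD)/LR(match))
                               * (LR(SIM)/LR(match)) * (LR(diso)/LR(match))
                               * (LR(consv)/LR(match))

Per-pair evidence from multiple candidate interfaces (and from both routes)
is aggregated by taking the maximum interface LR; the result is multiplied
by the pair's non-structural LR.  Pairs with final LR above 600 are "strong
predictions": at prior odds of 1/600 that corresponds to posterior
probability 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from sklearn.base import BaseEstimator

from .io import NsEvidenceTable, PairSet, canonical_pair

__all__ = [
    "ClueValue",
    "LREntry",
    "LRTable",
    "DmiMatch",
    "PairPrediction",
    "DmiBayesClassifier",
    "estimate_clue_lr",
    "dmi_lr_prd_motif",
    "dmi_lr_struct",
    "aggregate_pair",
    "combine_with_ns",
    "merge_preppi",
    "posterior",
    "flag_strong",
    "write_lr_table",
    "read_lr_table",
    "write_predictions",
    "STRONG_LR_THRESHOLD",
    "PRIOR_ODDS",
]

STRONG_LR_THRESHOLD = 600.0
PRIOR_ODDS = 1.0 / 600.0

#: closed clue vocabularies; 'class' and 'template' are open (ids from data)
CLUE_VOCAB: dict[str, tuple] = {
    "match": ("present",),
    "psd": ("P1", "P2"),
    "sim": ("B1", "B2", "B3", "B4"),
    "diso": (True, False),
    "consv": (True, False),
}

ClueValue = tuple[str, object]  # (clue_id, categorical value)
Pair = tuple[str, str]


@dataclass(frozen=True)
class LREntry:
    n_tp: int
    n_tn: int
    lr: float
    capped: bool = False
    untrained: bool = False


@dataclass
class LRTable:
    """Clue-conditional likelihood ratios with their training counts.

    With pseudocount alpha and K values for a clue,
    ``LR = ((n_TP+a)/(N_TP+a*K)) / ((n_TN+a)/(N_TN+a*K))``, capped at
    ``lr_cap``.  With alpha = 0, an all-TP clue (n_TN = 0) is assigned the
    cap and flagged; a clue unseen in both sets is neutral (LR = 1).
    """

    entries: dict[ClueValue, LREntry]
    n_tp_total: int
    n_tn_total: int
    alpha: float = 0.0
    lr_cap: float = 1e6

    def lr(self, clue_id: str, value) -> float:
        entry = self.entries.get((clue_id, value))
        if entry is None:
            return 1.0  # never observed during training: neutral
        return entry.lr


@dataclass(frozen=True)
class DmiMatch:
    """One candidate domain-motif interface for a protein pair.

    ``method`` selects the evidence route; consensus matches carry clues
    {match, class, diso, consv}, template matches {match, psd, sim, diso,
    consv}.  ``source`` is the motif class id or template id.
    """

    pair: Pair
    method: str  # 'prd_motif' | 'struct'
    source: str
    clues: tuple[ClueValue, ...]
    lr_dmi: float | None = None

    def __post_init__(self) -> None:
        if self.method not in ("prd_motif", "struct"):
            raise ValueError(f"unknown method {self.method!r}")
        object.__setattr__(self, "pair", canonical_pair(*self.pair))
        object.__setattr__(self, "clues", tuple(self.clues))


@dataclass
class PairPrediction:
    pair: Pair
    lr_dmi: float
    lr_ns: float
    lr_final: float
    strong: bool
    lr_struct_orig: float | None = None


# ---------------------------------------------------------------------------
# LR estimation


def _clue_k(clue_id: str, observed_values: set) -> int:
    if clue_id in CLUE_VOCAB:
        return len(CLUE_VOCAB[clue_id])
    return max(1, len(observed_values))


def estimate_clue_lr(
    observations: Mapping[Pair, Iterable[ClueValue]],
    pairs: PairSet,
    alpha: float = 0.0,
    lr_cap: float = 1e6,
) -> LRTable:
    """Estimate clue LRs by exhaustive counting over the TP and TN pair lists.

    ``observations`` maps a canonical pair to the clue values observed for
    it; a pair contributes at most once to each (clue, value) count.
    """
    if pairs.n_tp == 0 or pairs.n_tn == 0:
        raise ValueError("both the positive and the negative set must be non-empty")

    tp = set(pairs.positives)
    tn = set(pairs.negatives)
    counts: dict[ClueValue, list[int]] = {}
    values_by_clue: dict[str, set] = {}
    for pair, clues in observations.items():
        pair = canonical_pair(*pair)
        is_tp = pair in tp
        if not is_tp and pair not in tn:
            continue
        for cv in set(clues):
            clue_id, value = cv
            values_by_clue.setdefault(clue_id, set()).add(value)
            c = counts.setdefault(cv, [0, 0])
            c[0 if is_tp else 1] += 1

    entries: dict[ClueValue, LREntry] = {}
    for cv, (n_tp, n_tn) in counts.items():
        k = _clue_k(cv[0], values_by_clue[cv[0]])
        p_tp = (n_tp + alpha) / (pairs.n_tp + alpha * k)
        p_tn = (n_tn + alpha) / (pairs.n_tn + alpha * k)
        if p_tn == 0:
            if p_tp == 0:
                entries[cv] = LREntry(n_tp, n_tn, 1.0, untrained=True)
            else:
                entries[cv] = LREntry(n_tp, n_tn, lr_cap, capped=True)
        else:
            entries[cv] = LREntry(n_tp, n_tn, min(p_tp / p_tn, lr_cap))
    return LRTable(entries, pairs.n_tp, pairs.n_tn, alpha, lr_cap)


# ---------------------------------------------------------------------------
# LR(DMI) formulas


def _required(clues: Mapping[str, object], needed: Sequence[str]) -> None:
    missing = [c for c in needed if c not in clues]
    if missing:
        raise ValueError(f"missing required clue(s): {missing}")


def _clue_dict(clues: Iterable[ClueValue] | Mapping[str, object]) -> dict[str, object]:
    if isinstance(clues, Mapping):
        return dict(clues)
    return {cid: val for cid, val in clues}


def dmi_lr_prd_motif(clues, table: LRTable) -> float:
    """Consensus-route interface LR: class, disorder and conservation clues
    normalized by the match clue."""
    c = _clue_dict(clues)
    _required(c, ["match", "class", "diso", "consv"])
    lr_match = table.lr("match", c["match"])
    if lr_match == 0:
        raise ValueError("untrained match clue (LR(match) = 0)")
    return (
        lr_match
        * (table.lr("class", c["class"]) / lr_match)
        * (table.lr("diso", c["diso"]) / lr_match)
        * (table.lr("consv", c["consv"]) / lr_match)
    )


def dmi_lr_struct(clues, table: LRTable) -> float:
    """Template-route interface LR: PSD, similarity, disorder and
    conservation clues normalized by the match clue."""
    c = _clue_dict(clues)
    _required(c, ["match", "psd", "sim", "diso", "consv"])
    lr_match = table.lr("match", c["match"])
    if lr_match == 0:
        raise ValueError("untrained match clue (LR(match) = 0)")
    return (
        lr_match
        * (table.lr("psd", c["psd"]) / lr_match)
        * (table.lr("sim", c["sim"]) / lr_match)
        * (table.lr("diso", c["diso"]) / lr_match)
        * (table.lr("consv", c["consv"]) / lr_match)
    )


def aggregate_pair(matches: Sequence[DmiMatch], policy: str = "max") -> float:
    """Aggregate interface LRs of one pair across matches of both routes.

    ``max`` (default) keeps the best-supported interface; ``product``
    multiplies, treating interfaces as independent evidence.  An empty match
    list means no interface evidence (neutral LR 1).
    """
    if policy not in ("max", "product"):
        raise ValueError(f"unknown aggregation policy {policy!r}")
    lrs = [m.lr_dmi for m in matches]
    if any(lr is None for lr in lrs):
        raise ValueError("matches must be scored (lr_dmi set) before aggregation")
    if not lrs:
        return 1.0
    if len({m.pair for m in matches}) != 1:
        raise ValueError("matches to aggregate must share one pair")
    if policy == "max":
        return float(max(lrs))
    return float(math.prod(lrs))


def combine_with_ns(lr_dmi: float, lr_ns: float) -> float:
    """Final pair LR: interface evidence times non-structural evidence."""
    if not lr_dmi > 0 or not lr_ns > 0:
        raise ValueError("likelihood ratios must be positive")
    return lr_dmi * lr_ns


def merge_preppi(lr_struct_orig: float, lr_dmi: float, lr_ns: float) -> float:
    """Merge with an existing domain-domain structural predictor: the larger
    of its LR and the domain-motif LR, multiplied by the non-structural LR."""
    if lr_struct_orig < 0 or lr_dmi < 0:
        raise ValueError("structural likelihood ratios must be non-negative")
    if not lr_ns > 0:
        raise ValueError("non-structural likelihood ratio must be positive")
    return max(lr_struct_orig, lr_dmi) * lr_ns


def posterior(lr: float, prior_odds: float = PRIOR_ODDS) -> float:
    """Posterior interaction probability from an LR and prior odds."""
    if lr < 0:
        raise ValueError("likelihood ratio must be non-negative")
    if not prior_odds > 0:
        raise ValueError("prior odds must be positive")
    odds = lr * prior_odds
    return odds / (1.0 + odds)


def flag_strong(lr_final: float, threshold: float = STRONG_LR_THRESHOLD) -> bool:
    """Strong prediction iff LR strictly exceeds the threshold (default 600)."""
    if lr_final < 0:
        raise ValueError("likelihood ratio must be non-negative")
    return lr_final > threshold


# ---------------------------------------------------------------------------
# estimator


class DmiBayesClassifier(BaseEstimator):
    """Naive-Bayes likelihood-ratio model over domain-motif interface clues.

    Parameters
    ----------
    alpha : float
        Additive pseudocount for clue probability estimation.
    lr_cap : float
        Cap applied to likelihood ratios when a clue never occurs in the
        negative set.
    policy : str
        Per-pair aggregation over candidate interfaces: 'max' or 'product'.
    strong_threshold : float
        Final-LR threshold for the strong-prediction flag (strict).

    Attributes
    ----------
    lr_tables_ : dict[str, LRTable]
        One trained table per evidence route ('prd_motif', 'struct').
    n_tp_, n_tn_ : int
        Training pair-set sizes.
    """

    def __init__(
        self,
        alpha: float = 0.0,
        lr_cap: float = 1e6,
        policy: str = "max",
        strong_threshold: float = STRONG_LR_THRESHOLD,
    ):
        self.alpha = alpha
        self.lr_cap = lr_cap
        self.policy = policy
        self.strong_threshold = strong_threshold

    # sklearn-style API -----------------------------------------------------

    def fit(self, X: Sequence[DmiMatch], y: PairSet) -> "DmiBayesClassifier":
        """Estimate per-route clue LR tables from matches and a TP/TN pair set."""
        self.lr_tables_ = {}
        for method in ("prd_motif", "struct"):
            obs: dict[Pair, set[ClueValue]] = {}
            for m in X:
                if m.method == method:
                    obs.setdefault(m.pair, set()).update(m.clues)
            if obs:
                self.lr_tables_[method] = estimate_clue_lr(
                    obs, y, alpha=self.alpha, lr_cap=self.lr_cap
                )
        self.n_tp_ = y.n_tp
        self.n_tn_ = y.n_tn
        return self

    def score_matches(self, X: Sequence[DmiMatch]) -> list[DmiMatch]:
        """Return matches with their interface LR (lr_dmi) filled in."""
        self._check_fitted()
        out = []
        for m in X:
            table = self.lr_tables_.get(m.method)
            if table is None:
                raise ValueError(f"no trained table for method {m.method!r}")
            fn = dmi_lr_prd_motif if m.method == "prd_motif" else dmi_lr_struct
            out.append(
                DmiMatch(m.pair, m.method, m.source, m.clues, fn(m.clues, table))
            )
        return out

    def predict_pairs(
        self,
        X: Sequence[DmiMatch],
        pairs: Sequence[Pair],
        ns_table: NsEvidenceTable | None = None,
        lr_struct_orig: Mapping[Pair, float] | None = None,
    ) -> list[PairPrediction]:
        """Aggregate match evidence per pair and combine with NS evidence.

        Pairs without any match get neutral interface LR 1.  When
        ``lr_struct_orig`` is given the max-merge rule is applied.
        """
        scored = self.score_matches(X)
        by_pair: dict[Pair, list[DmiMatch]] = {}
        for m in scored:
            by_pair.setdefault(m.pair, []).append(m)
        ns_table = ns_table or NsEvidenceTable()
        out = []
        for pair in pairs:
            pair = canonical_pair(*pair)
            matches = by_pair.get(pair, [])
            lr_dmi = aggregate_pair(matches, self.policy) if matches else 1.0
            lr_ns = ns_table.lookup(*pair)
            orig = None
            if lr_struct_orig is not None:
                orig = float(lr_struct_orig.get(pair, 0.0))
                lr_final = merge_preppi(orig, lr_dmi, lr_ns)
            elif lr_dmi > 0:
                lr_final = combine_with_ns(lr_dmi, lr_ns)
            else:
                # a clue unseen in the TP training set estimates LR 0;
                # the product with any NS evidence is then 0 as well
                lr_final = 0.0
            out.append(
                PairPrediction(
                    pair, lr_dmi, lr_ns, lr_final,
                    flag_strong(lr_final, self.strong_threshold), orig,
                )
            )
        return out

    def decision_function(self, X: Sequence[DmiMatch], pairs: Sequence[Pair]):
        """Aggregated interface LR per pair (no NS evidence), array-ordered
        like ``pairs``."""
        import numpy as np

        preds = self.predict_pairs(X, pairs)
        return np.array([p.lr_dmi for p in preds])

    def _check_fitted(self) -> None:
        if not hasattr(self, "lr_tables_"):
            raise ValueError("classifier is not fitted; call fit first")


# ---------------------------------------------------------------------------
# serialization (mirrors the supplementary clue-LR table layout)


def write_lr_table(path: str | Path, table: LRTable) -> None:
    rows = [
        (cid, value, e.n_tp, e.n_tn, e.lr, e.capped)
        for (cid, value), e in sorted(table.entries.items(), key=lambda kv: (kv[0][0], str(kv[0][1])))
    ]
    df = pd.DataFrame(rows, columns=["clue_id", "value", "n_TP", "n_TN", "LR", "capped"])
    with open(path, "w") as fh:
        fh.write(f"# N_TP={table.n_tp_total}\tN_TN={table.n_tn_total}"
                 f"\talpha={table.alpha}\tlr_cap={table.lr_cap}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_lr_table(path: str | Path) -> LRTable:
    meta = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            meta = dict(kv.split("=") for kv in first[1:].split())
    df = pd.read_csv(path, sep="\t", comment="#")
    entries = {}
    for r in df.itertuples():
        value: object = r.value
        if value in ("True", "False"):
            value = value == "True"
        entries[(r.clue_id, value)] = LREntry(int(r.n_TP), int(r.n_TN), float(r.LR), bool(r.capped))
    return LRTable(
        entries,
        int(meta.get("N_TP", 0)),
        int(meta.get("N_TN", 0)),
        float(meta.get("alpha", 0.0)),
        float(meta.get("lr_cap", 1e6)),
    )


def write_predictions(path: str | Path, predictions: Iterable[PairPrediction]) -> None:
    pd.DataFrame(
        [
            (p.pair[0], p.pair[1], p.lr_dmi, p.lr_ns, p.lr_final, p.strong)
            for p in predictions
        ],
        columns=["protein_a", "protein_b", "lr_dmi", "lr_ns", "lr_final", "strong"],
    ).to_csv(path, sep="\t", index=False)
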