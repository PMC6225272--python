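"""Rank-consistency scoring of docking orderings against experimental
toxicity by discounted cumulative gain.

DCG_p = rel_1 + sum_{i=2..p} rel_i / log2(i) (the Jarvelin-Kekalainen
discount); IDCG is the DCG of the relevance values sorted descending, and
NDCG = DCG/IDCG lies in (0, 1] with 1 for perfect concordance with the
experimental ordering.

The graded relevance of a compound can be taken as its raw pLD50, as the
rank complement n - rank + 1, or as the exponential gain 2^pLD50 - 1;
:func:`select_relevance_scheme` scores all three against reference NDCG
values and keeps the best-matching scheme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RELEVANCE_SCHEMES = ("pld50", "rank_complement", "exponential")
DEFAULT_SCHEME = "exponential"


def dcg(relevance_in_predicted_order) -> float:
    """Discounted cumulative gain of a relevance list already arranged in
    the predicted order."""
    rels = [float(r) for r in relevance_in_predicted_order]
    if not rels:
        raise ValueError("empty relevance list")
    return rels[0] + sum(r / math.log2(i) for i, r in enumerate(rels[1:], start=2))


def idcg(relevance) -> float:
    """DCG of the relevance values sorted descending (the ideal ordering)."""
    return dcg(sorted((float(r) for r in relevance), reverse=True))


@dataclass
class RankingTable:
    """Items with graded relevance and one or more named rank orderings.

    ``orderings`` maps a name (e.g. a receptor PDB id) to an integer rank
    per item, 1 = first position; every ordering must be a permutation of
    1..n over all items.
    """

    items: list[str]
    relevance: np.ndarray
    orderings: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.relevance = np.asarray(self.relevance, dtype=float)
        n = len(self.items)
        if self.relevance.shape != (n,):
            raise ValueError("one relevance value per item required")
        if not np.all(np.isfinite(self.relevance)) or np.any(self.relevance < 0):
            raise ValueError("relevance must be finite and non-negative")
        for name, ranks in self.orderings.items():
            ranks = np.asarray(ranks, dtype=int)
            if sorted(ranks) != list(range(1, n + 1)):
                raise ValueError(f"ordering {name!r} is not a permutation of 1..{n}")
            self.orderings[name] = ranks

    @property
    def n(self) -> int:
        return len(self.items)

    def relevance_in_order(self, ordering: str) -> np.ndarray:
        """Relevance values arranged by the named ordering's rank."""
        if ordering == "ideal":
            return np.sort(self.relevance)[::-1]
        if ordering not in self.orderings:
            raise KeyError(f"unknown ordering {ordering!r}")
        ranks = self.orderings[ordering]
        return self.relevance[np.argsort(ranks, kind="stable")]

    def with_relevance(self, relevance) -> "RankingTable":
        return RankingTable(list(self.items), relevance, dict(self.orderings))


@dataclass(frozen=True)
class NDCGResult:
    ordering: str
    dcg: float
    idcg: float
    ndcg: float


def ndcg(table: RankingTable, ordering: str) -> NDCGResult:
    """NDCG of one named ordering, reported to full precision (round to 4
    decimals when printing, matching the customary reporting precision)."""
    ideal = idcg(table.relevance)
    if ideal <= 0:
        raise ValueError("IDCG is zero (all-zero relevance)")
    d = dcg(table.relevance_in_order(ordering))
    return NDCGResult(ordering, d, ideal, d / ideal)


def apply_scheme(relevance: np.ndarray, exp_ranks: np.ndarray, scheme: str) -> np.ndarray:
    """Graded relevance under a named scheme; ``exp_ranks`` are the
    experimental ranks (1 = most toxic)."""
    relevance = np.asarray(relevance, dtype=float)
    n = len(relevance)
    if scheme == "pld50":
        return relevance
    if scheme == "rank_complement":
        return np.asarray(n - np.asarray(exp_ranks, dtype=float) + 1)
    if scheme == "exponential":
        return 2.0**relevance - 1.0
    raise ValueError(f"unknown relevance scheme {scheme!r}")


def select_relevance_scheme(table: RankingTable, exp_ranks: np.ndarray,
                            reference: dict[str, float],
                            decimals: int = 4) -> tuple[str, dict[str, dict[str, float]]]:
    """Score every candidate relevance scheme against reference NDCG values.

    Returns the winning scheme name and the per-scheme NDCG values. A
    scheme reproducing every reference value to ``decimals`` decimals wins
    outright; otherwise the scheme with the smallest total absolute error
    is kept (and the mismatch is the caller's to report).
    """
    results: dict[str, dict[str, float]] = {}
    best, best_err = None, np.inf
    for scheme in RELEVANCE_SCHEMES:
        graded = table.with_relevance(apply_scheme(table.relevance, exp_ranks, scheme))
        vals = {name: ndcg(graded, name).ndcg for name in reference}
        results[scheme] = vals
        if all(round(vals[k], decimals) == round(v, decimals) for k, v in reference.items()):
            return scheme, results
        err = sum(abs(vals[k] - v) for k, v in reference.items())
        if err < best_err:
            best, best_err = scheme, err
    return best, results


def read_ranking_csv(path, relevance_col: str = "relevance") -> RankingTable:
    """CSV with columns: id, <relevance_col>, one integer-rank column per
    ordering."""
    frame = pd.read_csv(path)
    items = [str(i) for i in frame["id"]]
    rel = frame[relevance_col].to_numpy(float)
    orderings = {c: frame[c].to_numpy(int) for c in frame.columns
                 if c not in ("id", relevance_col)}
    return RankingTable(items, rel, orderings)


def score_table(table: RankingTable, orderings=None) -> pd.DataFrame:
    names = list(orderings) if orderings else ["ideal", *table.orderings]
    rows = [ndcg(table, name) for name in names]
    return pd.DataFrame(
        [(r.ordering, r.dcg, r.idcg, r.ndcg) for r in rows],
        columns=["ordering", "dcg", "idcg", "ndcg"],
    ).set_index("ordering")
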