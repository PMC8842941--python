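"""Inter-rater reliability statistics for categorical slide annotations.

Ground truth for the detector rests on human annotations, so the pipeline
qualifies it with a concordance study: several raters independently
categorize the same items (image patches or objects) and agreement is
summarized by Fleiss' kappa and raw percent agreement.  Kappa corrects the
observed per-item agreement P̄ for the agreement P̄e expected by chance
from the pooled category marginals:

    κ = (P̄ − P̄e) / (1 − P̄e),   P̄e = Σ_j p_j².

κ = 1 means perfect agreement; κ ≈ 0 means agreement at chance level.
Pairwise kappas reuse the same pooled-marginal chance correction on each
two-rater subtable, so the two-rater Fleiss kappa and the pairwise kappa
coincide exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateMarginalsError, ValidationError


@dataclass
class RatingTable:
    """Items × raters table of categorical ratings.

    ``ratings`` may be any array-like of shape (n_items, n_raters); values
    are treated as opaque category labels.  Requires at least 2 items and
    2 raters and no missing cells.
    """

    ratings: np.ndarray

    def __init__(self, ratings) -> None:
        if isinstance(ratings, pd.DataFrame):
            ratings = ratings.to_numpy()
        arr = np.asarray(ratings, dtype=object)
        if arr.ndim != 2:
            raise ValidationError("rating table must be 2-dimensional")
        if arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValidationError("need at least 2 items and 2 raters")
        if any(v is None or (isinstance(v, float) and np.isnan(v)) for v in arr.ravel()):
            raise ValidationError("rating table has missing cells")
        self.ratings = arr

    @property
    def n_items(self) -> int:
        return self.ratings.shape[0]

    @property
    def n_raters(self) -> int:
        return self.ratings.shape[1]

    @property
    def categories(self) -> list:
        # only categories actually used; unused categories have zero
        # marginal mass and would not change P̄e anyway
        return sorted({str(v) for v in self.ratings.ravel()})

    def counts(self) -> np.ndarray:
        """Items × categories matrix of rating counts."""
        cats = self.categories
        idx = {c: j for j, c in enumerate(cats)}
        out = np.zeros((self.n_items, len(cats)), dtype=int)
        for i in range(self.n_items):
            for v in self.ratings[i]:
                out[i, idx[str(v)]] += 1
        return out

    def select_raters(self, raters) -> "RatingTable":
        return RatingTable(self.ratings[:, list(raters)])

    def to_csv(self, path) -> None:
        pd.DataFrame(self.ratings).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RatingTable":
        return cls(pd.read_csv(path, dtype=str))


def fleiss_kappa(table: RatingTable) -> float:
    """Multi-rater chance-corrected agreement on a complete rating table.

    Returns exactly 1.0 when all raters agree on every item.  Raises
    :class:`DegenerateMarginalsError` when a single category absorbs all
    ratings but agreement is imperfect (chance agreement 1 makes κ
    undefined) — unreachable with the used-categories convention, but kept
    as a guard against numerically degenerate marginals.
    """
    counts = table.counts()
    n = table.n_raters
    p_item = (np.sum(counts * (counts - 1), axis=1)) / (n * (n - 1))
    p_bar = float(np.mean(p_item))
    marginals = counts.sum(axis=0) / counts.sum()
    p_e = float(np.sum(marginals**2))
    if p_bar >= 1.0 - 1e-15:
        return 1.0
    if p_e >= 1.0 - 1e-15:
        raise DegenerateMarginalsError(
            "chance agreement is 1 with imperfect observed agreement"
        )
    return (p_bar - p_e) / (1.0 - p_e)


def pairwise_agreement(table: RatingTable) -> tuple[np.ndarray, np.ndarray]:
    """Percent agreement and kappa for every rater pair.

    Returns ``(agreement, kappa)``: symmetric ``n_raters × n_raters``
    matrices with unit diagonal.  Agreement is the raw fraction of items on
    which the pair gave identical categories (not chance-corrected); kappa
    is the two-rater Fleiss kappa on the pair's subtable.
    """
    m = table.n_raters
    agree = np.eye(m)
    kappa = np.eye(m)
    for a in range(m):
        for b in range(a + 1, m):
            sub = table.select_raters([a, b])
            frac = float(
                np.mean([str(x) == str(y) for x, y in sub.ratings])
            )
            agree[a, b] = agree[b, a] = frac
            kappa[a, b] = kappa[b, a] = fleiss_kappa(sub)
    return agree, kappa


def exclude_rank_items(table: RatingTable, rank: str, rule: str = "modal") -> RatingTable:
    """Remove items of the named category from a rating table.

    ``rule="modal"`` drops items whose most frequent rating equals ``rank``
    (ties keep the item); ``rule="any"`` drops items any rater placed in
    ``rank``.  Raises :class:`ValidationError` if fewer than 2 items remain,
    since agreement statistics are then undefined.
    """
    if rule not in ("modal", "any"):
        raise ValidationError(f"unknown exclusion rule {rule!r}")
    keep = []
    for i in range(table.n_items):
        row = [str(v) for v in table.ratings[i]]
        if rule == "any":
            drop = rank in row
        else:
            vals, cnts = np.unique(row, return_counts=True)
            top = vals[cnts == cnts.max()]
            drop = len(top) == 1 and top[0] == rank
        if not drop:
            keep.append(i)
    return RatingTable(table.ratings[keep])
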