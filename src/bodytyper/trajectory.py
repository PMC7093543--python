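"""Similarity links between body types and candidate aging trajectories.

The data are cross-sectional, so transitions between body types cannot
be observed directly.  Instead, pairs of highly similar participants
(small Euclidean distance in meta-measure space) from two different body
types are counted as "similarity links"; a high link count between two
types marks a soft boundary along which individuals plausibly drift as
they age.  Ordering each strongly linked pair by mean member age yields
a directed transition graph in an age-versus-BMI coordinate system.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .config import LinkRule

log = logging.getLogger(__name__)


@dataclass
class LinkMatrix:
    """Symmetric type x type counts of similarity links.

    The diagonal counts within-type links; transition reporting uses the
    off-diagonal cells only.  ``n_per_type`` allows normalization by the
    expected count under random mixing.
    """

    counts: pd.DataFrame
    n_per_type: pd.Series
    n_links: int
    rule: LinkRule = field(default_factory=LinkRule)
    age_bin: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if not c.index.equals(c.columns):
            raise ValueError("link matrix must be square with equal labels")
        if not np.allclose(c.to_numpy(), c.to_numpy().T):
            raise ValueError("link matrix must be symmetric")
        if (c.to_numpy() < 0).any():
            raise ValueError("link counts must be >= 0")

    def expected(self) -> pd.DataFrame:
        """Expected counts under random mixing (hypergeometric pair model)."""
        n = self.n_per_type.reindex(self.counts.index).to_numpy(dtype=float)
        tot = n.sum()
        pairs = np.outer(n, n).astype(float)       # off-diagonal: n_a * n_b
        np.fill_diagonal(pairs, n * (n - 1) / 2.0)
        all_pairs = tot * (tot - 1) / 2.0
        return pd.DataFrame(self.n_links * pairs / all_pairs,
                            index=self.counts.index, columns=self.counts.columns)

    def normalized(self) -> pd.DataFrame:
        """Observed / expected link frequencies."""
        exp = self.expected()
        return self.counts / exp.where(exp > 0)


# ----------------------------------------------------------------------
def _knn_pairs(X: np.ndarray, m: int) -> set[tuple[int, int]]:
    """Union of each point's m nearest neighbours as undirected pairs.

    Distance ties break deterministically by point order.
    """
    n = len(X)
    if n < m + 1:
        raise ValueError(f"need at least m+1={m + 1} participants, got {n}")
    nn = NearestNeighbors(n_neighbors=min(m + 2, n)).fit(X)
    dist, idx = nn.kneighbors(X)
    pairs: set[tuple[int, int]] = set()
    for i in range(n):
        order = sorted((float(round(dist[i][j], 12)), int(idx[i][j]))
                       for j in range(len(idx[i])) if idx[i][j] != i)
        for _, j in order[:m]:
            pairs.add((min(i, j), max(i, j)))
    return pairs


def _pairs_to_matrix(pairs: set[tuple[int, int]], labels: np.ndarray,
                     type_labels: list[str], n_per_type: pd.Series,
                     rule: LinkRule) -> LinkMatrix:
    pos = {t: i for i, t in enumerate(type_labels)}
    counts = np.zeros((len(type_labels), len(type_labels)), dtype=int)
    for i, j in pairs:
        a, b = pos[labels[i]], pos[labels[j]]
        counts[a, b] += 1
        if a != b:
            counts[b, a] += 1
    df = pd.DataFrame(counts, index=type_labels, columns=type_labels)
    return LinkMatrix(counts=df, n_per_type=n_per_type, n_links=len(pairs),
                      rule=rule)


def count_similarity_links(meta: pd.DataFrame, labels: pd.Series,
                           rule: LinkRule | None = None) -> LinkMatrix:
    """Tally "most similar" participant pairs by body-type pair.

    Default rule: each participant's m=3 nearest neighbours in Euclidean
    meta-measure distance; a pair is a link if either side selects the
    other.  Alternative (``method="quantile"``): all pairs below the
    given quantile of pairwise distances.
    """
    rule = LinkRule() if rule is None else rule
    rule.validate()
    labels = labels.reindex(meta.index)
    if labels.isna().any():
        raise ValueError("assignment does not cover all participants")
    X = meta.to_numpy()
    lab = labels.to_numpy()
    type_labels = sorted(labels.unique())
    n_per_type = labels.value_counts().reindex(type_labels)

    if rule.method == "knn":
        pairs = _knn_pairs(X, rule.m)
    else:
        from scipy.spatial.distance import pdist
        d = pdist(X)
        thr = np.quantile(d, rule.quantile)
        ii, jj = np.triu_indices(len(X), k=1)
        sel = d <= thr
        pairs = set(zip(ii[sel].tolist(), jj[sel].tolist()))
    return _pairs_to_matrix(pairs, lab, type_labels, n_per_type, rule)


def stratify_links_by_age(meta: pd.DataFrame, labels: pd.Series,
                          ages: pd.Series, rule: LinkRule | None = None,
                          bin_width: float = 10.0) -> list[LinkMatrix]:
    """Link matrices computed within each age bin (both members in bin)."""
    rule = LinkRule() if rule is None else rule
    lo = np.floor(ages.min() / bin_width) * bin_width
    out: list[LinkMatrix] = []
    edges = np.arange(lo, ages.max() + 1e-9, bin_width)
    type_labels = sorted(labels.unique())
    for lo_e in edges:
        hi_e = lo_e + bin_width
        ids = ages.index[(ages >= lo_e) & (ages < hi_e)]
        if len(ids) <= (rule.m if rule.method == "knn" else 1):
            log.warning("WARN age bin [%s, %s) too small (%d); empty matrix",
                        lo_e, hi_e, len(ids))
            empty = pd.DataFrame(0, index=type_labels, columns=type_labels)
            out.append(LinkMatrix(
                counts=empty,
                n_per_type=labels.loc[ids].value_counts().reindex(
                    type_labels, fill_value=0),
                n_links=0, rule=rule, age_bin=(float(lo_e), float(hi_e))))
            continue
        lm = count_similarity_links(meta.loc[ids], labels.loc[ids], rule)
        lm.counts = lm.counts.reindex(index=type_labels, columns=type_labels,
                                      fill_value=0)
        lm.n_per_type = lm.n_per_type.reindex(type_labels, fill_value=0)
        lm.age_bin = (float(lo_e), float(hi_e))
        out.append(lm)
    return out


def link_differential_profile(meta: pd.DataFrame, labels: pd.Series,
                              type_a: str, type_b: str,
                              rule: LinkRule | None = None) -> pd.Series:
    """Axis-wise meta-measure change along the A-B links.

    Mean profile of B's linked members minus that of A's linked members,
    restricted to participants involved in at least one A-B link.
    """
    if type_a == type_b:
        raise ValueError("types must differ")
    rule = LinkRule() if rule is None else rule
    rule.validate()
    labels = labels.reindex(meta.index)
    X = meta.to_numpy()
    lab = labels.to_numpy()
    if rule.method == "knn":
        pairs = _knn_pairs(X, rule.m)
    else:
        raise NotImplementedError("differential profiles use the knn rule")
    a_side: set[int] = set()
    b_side: set[int] = set()
    for i, j in pairs:
        li, lj = lab[i], lab[j]
        if {li, lj} == {type_a, type_b}:
            (a_side if li == type_a else b_side).add(i)
            (a_side if lj == type_a else b_side).add(j)
    if not a_side or not b_side:
        raise ValueError(f"no links between {type_a!r} and {type_b!r}")
    prof_a = meta.iloc[sorted(a_side)].mean()
    prof_b = meta.iloc[sorted(b_side)].mean()
    return prof_b - prof_a


def transition_graph(links: LinkMatrix, summary: pd.DataFrame,
                     count_quantile: float = 0.5) -> pd.DataFrame:
    """Directed edges between strongly linked types, young -> old.

    Edges are off-diagonal cells whose count reaches the given quantile
    of the nonzero off-diagonal counts (default: top half).  Direction
    runs from lower to higher mean age; exact age ties run toward the
    higher mean BMI.  Node coordinates (mean age, mean BMI) come from
    ``summary``.
    """
    c = links.counts.to_numpy().astype(float)
    off = ~np.eye(len(c), dtype=bool)
    nonzero = c[off][c[off] > 0]
    rows = []
    if len(nonzero):
        thr = np.quantile(nonzero, count_quantile)
        types = list(links.counts.index)
        for i in range(len(types)):
            for j in range(i + 1, len(types)):
                w = c[i, j]
                if w <= 0 or w < thr:
                    continue
                a, b = types[i], types[j]
                age_a, age_b = summary.loc[a, "mean_age"], summary.loc[b, "mean_age"]
                if age_a == age_b:
                    bmi_a = summary.loc[a, "mean_bmi"]
                    bmi_b = summary.loc[b, "mean_bmi"]
                    src, dst = (a, b) if bmi_a <= bmi_b else (b, a)
                else:
                    src, dst = (a, b) if age_a < age_b else (b, a)
                rows.append({"from": src, "to": dst, "weight": int(w)})
    if not rows:
        log.warning("WARN no edges above the link-count threshold")
        return pd.DataFrame(columns=["from", "to", "weight"])
    out = pd.DataFrame(rows).sort_values(["weight", "from", "to"],
                                         ascending=[False, True, True])
    return out.reset_index(drop=True)
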