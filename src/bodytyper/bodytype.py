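"""Body typing: clustering participants in meta-measure space.

Participants are clustered on their 13 meta-measure scores (k-means,
multiple restarts, default k=15).  Types are labeled by sex composition
-- F (almost exclusively women), M (almost exclusively men), B (mixed) --
and indexed by increasing mean member age (F1 is the youngest female
type).  Mixed types are additionally split into sex-specific views
(B1F/B1M/...) for all downstream statistics.  Each type's features are
compared against an age-matched, sex-specific reference group with
Wilcoxon's rank-sum test, and p values are rendered as the customary
+/- significance tiers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ranksums
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

log = logging.getLogger(__name__)


# ----------------------------------------------------------------------
@dataclass
class SignificanceMark:
    """Rank-sum comparison result rendered as +/- tiers.

    tier 3: p < 0.001, tier 2: 0.001 <= p < 0.01, tier 1: 0.01 <= p < 0.1,
    tier 0 (none) otherwise.  Direction is + if the group median exceeds
    the reference median, - otherwise.
    """
    p: float
    direction: str  # "+" | "-"
    tier: int

    @property
    def mark(self) -> str:
        sym = "+" if self.direction == "+" else "−"
        return sym * self.tier

    @staticmethod
    def tier_for(p: float) -> int:
        if p < 0.001:
            return 3
        if p < 0.01:
            return 2
        if p < 0.1:
            return 1
        return 0


def compare_to_reference(values: np.ndarray, reference: np.ndarray) -> SignificanceMark:
    """Two-sided Wilcoxon rank-sum test of a type against its reference.

    Degenerate all-tied data yields an empty mark with a logged warning.
    """
    values = np.asarray(values, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if len(values) == 0 or len(reference) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([values, reference])
    if np.all(pooled == pooled[0]):
        log.warning("WARN rank-sum comparison on all-tied data; no mark")
        return SignificanceMark(p=1.0, direction="+", tier=0)
    stat = ranksums(values, reference)
    direction = "+" if np.median(values) > np.median(reference) else "-"
    return SignificanceMark(p=float(stat.pvalue), direction=direction,
                            tier=SignificanceMark.tier_for(float(stat.pvalue)))


# ----------------------------------------------------------------------
@dataclass
class BodyTypeAssignment:
    """Participant -> body-type mapping plus per-type metadata.

    ``labels`` carries the final type labels (F1..F6, M1..M7, B1, B2);
    ``sex_view`` splits mixed types per sex (B1F, B1M, ...) and equals
    ``labels`` for single-sex types.  ``summary`` has one row per label:
    n, sex fractions, mean/median age and, when indices were provided,
    mean BMI and mean WTH.
    """

    labels: pd.Series
    sex_view: pd.Series
    summary: pd.DataFrame
    cluster_ids: pd.Series | None = None

    def members(self, label: str, view: bool = False) -> pd.Index:
        col = self.sex_view if view else self.labels
        return col.index[col == label]

    @property
    def type_labels(self) -> list[str]:
        return list(self.summary.index)

    def view_summary(self, participants: pd.DataFrame,
                     indices: pd.DataFrame | None = None) -> pd.DataFrame:
        """Per sex-view label summary (B types split per sex)."""
        return _summarize(self.sex_view, participants, indices)


def assign_body_types(meta: pd.DataFrame, k: int = 15, seed: int = 0,
                      n_init: int = 25) -> pd.Series:
    """Cluster participants in meta-measure space with k-means.

    Returns a Series of integer cluster ids aligned with ``meta``;
    deterministic under a fixed seed (best inertia over ``n_init``
    restarts).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(meta):
        raise ValueError(f"k={k} exceeds participant count {len(meta)}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    return pd.Series(km.fit_predict(meta.to_numpy()), index=meta.index,
                     name="cluster")


def auto_select_k_types(meta: pd.DataFrame, k_range=range(5, 26),
                        seed: int = 0, n_init: int = 10,
                        max_silhouette_n: int = 2000) -> int:
    """Participant-cluster count by maximal mean silhouette over k-means
    partitions; ties resolve to the smallest k.  Silhouette is evaluated
    on a fixed-seed subsample when the cohort is large."""
    ks = [k for k in k_range]
    if not ks:
        raise ValueError("empty k range")
    X = meta.to_numpy()
    rng = np.random.default_rng(seed)
    if len(X) > max_silhouette_n:
        sub = rng.choice(len(X), size=max_silhouette_n, replace=False)
    else:
        sub = np.arange(len(X))
    best_k, best_s = None, -np.inf
    for k in ks:
        if k < 2 or k >= len(X):
            continue
        labels = KMeans(n_clusters=k, n_init=n_init, random_state=seed
                        ).fit_predict(X)
        if len(np.unique(labels[sub])) < 2:
            continue
        s = silhouette_score(X[sub], labels[sub])
        if s > best_s + 1e-12:
            best_k, best_s = k, s
    if best_k is None:
        raise ValueError("no valid k in range")
    return best_k


def _summarize(labels: pd.Series, participants: pd.DataFrame,
               indices: pd.DataFrame | None) -> pd.DataFrame:
    rows = []
    for lab in sorted(labels.unique()):
        ids = labels.index[labels == lab]
        sub = participants.loc[ids]
        n = len(ids)
        row = {
            "label": lab, "n": n,
            "n_female": int((sub["sex"] == "F").sum()),
            "n_male": int((sub["sex"] == "M").sum()),
            "female_frac": float((sub["sex"] == "F").mean()),
            "mean_age": float(sub["age"].mean()),
            "median_age": float(sub["age"].median()),
        }
        if indices is not None:
            row["mean_bmi"] = float(indices.loc[ids, "bmi"].mean())
            row["mean_wth"] = float(indices.loc[ids, "wth"].mean())
        rows.append(row)
    return pd.DataFrame(rows).set_index("label")


def label_types(cluster_ids: pd.Series, participants: pd.DataFrame,
                indices: pd.DataFrame | None = None,
                purity_threshold: float = 0.9) -> BodyTypeAssignment:
    """Label clusters F/M/B by sex composition and order by mean age.

    A cluster is F if its female fraction is at least ``purity_threshold``
    (default 0.9, "almost exclusively women"), M symmetrically, B
    otherwise.  Within each family, indices are assigned by increasing
    mean member age.  Mixed types get per-sex view labels (e.g. B1F).
    """
    if cluster_ids.isna().any():
        raise ValueError("cluster ids contain missing values")
    fam: dict[int, str] = {}
    mean_age: dict[int, float] = {}
    for cid in cluster_ids.unique():
        ids = cluster_ids.index[cluster_ids == cid]
        if len(ids) == 0:
            raise ValueError(f"empty body type {cid}")
        sub = participants.loc[ids]
        ff = float((sub["sex"] == "F").mean())
        fam[cid] = "F" if ff >= purity_threshold else \
            "M" if (1.0 - ff) >= purity_threshold else "B"
        mean_age[cid] = float(sub["age"].mean())

    label_of: dict[int, str] = {}
    for family in ("F", "M", "B"):
        cids = sorted([c for c, f in fam.items() if f == family],
                      key=lambda c: (mean_age[c], c))
        for i, cid in enumerate(cids, start=1):
            label_of[cid] = f"{family}{i}"

    labels = cluster_ids.map(label_of).rename("body_type")
    sexes = participants.loc[labels.index, "sex"]
    sex_view = labels.where(~labels.str.startswith("B"), labels + sexes)
    sex_view = sex_view.rename("body_type_view")
    summary = _summarize(labels, participants, indices)
    return BodyTypeAssignment(labels=labels, sex_view=sex_view,
                              summary=summary, cluster_ids=cluster_ids)


# ----------------------------------------------------------------------
def build_reference_group(assignment: BodyTypeAssignment, label: str,
                          participants: pd.DataFrame,
                          window_years: float = 10.0,
                          view: bool = True) -> pd.Index:
    """Age-matched, sex-specific reference group for a body type.

    All same-sex participants whose age lies in the half-open window
    ``[median - w/2, median + w/2)`` centered on the type's median member
    age, independent of their own body type.  For mixed types use the
    sex-specific view label (e.g. ``B1F``).
    """
    members = assignment.members(label, view=view)
    if len(members) == 0:
        raise ValueError(f"body type {label!r} has no members")
    # reference sex = the type's majority sex (F/M types may contain a
    # small admixture below the purity threshold; B view labels are pure)
    counts = participants.loc[members, "sex"].value_counts()
    sex = counts.idxmax()
    center = float(participants.loc[members, "age"].median())
    lo, hi = center - window_years / 2.0, center + window_years / 2.0
    sel = participants[(participants["sex"] == sex)
                       & (participants["age"] >= lo)
                       & (participants["age"] < hi)]
    if len(sel) == 0:
        raise ValueError(f"empty reference group for type {label!r}")
    return sel.index


def compare_type_feature(assignment: BodyTypeAssignment, label: str,
                         feature: pd.Series, participants: pd.DataFrame,
                         window_years: float = 10.0,
                         view: bool = True) -> SignificanceMark:
    """Rank-sum mark of a type's feature values against its reference."""
    members = assignment.members(label, view=view)
    ref = build_reference_group(assignment, label, participants,
                                window_years, view=view)
    vals = feature.reindex(members).dropna()
    refvals = feature.reindex(ref).dropna()
    if len(vals) == 0 or len(refvals) == 0:
        raise ValueError(f"no feature data for type {label!r}")
    return compare_to_reference(vals.to_numpy(), refvals.to_numpy())
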