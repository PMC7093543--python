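"""Similarity links: counting rules, null behavior, transition graphs."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chisquare

from bodytyper.config import LinkRule
from bodytyper.trajectory import (count_similarity_links,
                                  link_differential_profile,
                                  stratify_links_by_age, transition_graph)
from conftest import make_planted_meta


def _brute_force_knn_pairs(X: np.ndarray, m: int) -> set[tuple[int, int]]:
    """Independent oracle: exhaustive pairwise distances, per-point m
    nearest, union over directions, ties by index order."""
    d = squareform(pdist(X))
    pairs = set()
    for i in range(len(X)):
        order = sorted((d[i, j], j) for j in range(len(X)) if j != i)
        for _, j in order[:m]:
            pairs.add((min(i, j), max(i, j)))
    return pairs


def test_separated_types_have_zero_cross_links():
    meta, labels = make_planted_meta(
        {"X": [0.0] * 5, "Y": [5.0] * 5}, n_per=60, sd=0.3, seed=1)
    lm = count_similarity_links(meta, labels, LinkRule(m=3))
    assert lm.counts.loc["X", "Y"] == 0
    assert lm.counts.loc["X", "X"] > 0 and lm.counts.loc["Y", "Y"] > 0


def test_link_matrix_is_symmetric(meta_default, assignment_default):
    lm = count_similarity_links(meta_default, assignment_default.labels)
    assert np.array_equal(lm.counts.to_numpy(), lm.counts.to_numpy().T)
    assert (lm.counts.to_numpy() >= 0).all()


def test_matches_brute_force_oracle_small_n():
    for seed in range(4):
        rng = np.random.default_rng(seed)
        n = 40
        X = rng.standard_normal((n, 4))
        meta = pd.DataFrame(X, index=[f"p{i}" for i in range(n)])
        labels = pd.Series(rng.choice(["a", "b", "c"], n), index=meta.index)
        lm = count_similarity_links(meta, labels, LinkRule(m=3))
        oracle = _brute_force_knn_pairs(X, 3)
        assert lm.n_links == len(oracle)
        counts = np.zeros((3, 3), int)
        types = sorted(labels.unique())
        pos = {t: i for i, t in enumerate(types)}
        for i, j in oracle:
            a, b = pos[labels.iloc[i]], pos[labels.iloc[j]]
            counts[a, b] += 1
            if a != b:
                counts[b, a] += 1
        assert np.array_equal(lm.counts.to_numpy(), counts)


def test_random_split_matches_random_mixing():
    """One homogeneous cloud split into two arbitrary 'types': the
    cross-type count sits within 3 sd of the random-mixing expectation."""
    rng = np.random.default_rng(7)
    meta = pd.DataFrame(rng.standard_normal((400, 6)),
                        index=[f"p{i}" for i in range(400)])
    labels = pd.Series(rng.choice(["u", "v"], 400), index=meta.index)
    lm = count_similarity_links(meta, labels, LinkRule(m=3))
    exp = lm.expected()
    obs = lm.counts.loc["u", "v"]
    sd = np.sqrt(exp.loc["u", "v"])
    assert abs(obs - exp.loc["u", "v"]) < 3 * sd


def test_null_chi_square_calibration():
    """Under random type splits, normalized link frequencies are flat:
    chi-square GOF p > 0.01 in at least 95 of 100 simulations."""
    ok = 0
    for i in range(100):
        rng = np.random.default_rng(9000 + i)
        meta = pd.DataFrame(rng.standard_normal((500, 13)))
        labels = pd.Series(rng.integers(0, 5, 500).astype(str),
                           index=meta.index)
        lm = count_similarity_links(meta, labels, LinkRule(m=3))
        iu = np.triu_indices(5)
        obs = lm.counts.to_numpy().astype(float)[iu]
        exp = lm.expected().to_numpy()[iu]
        exp = exp * obs.sum() / exp.sum()
        ok += chisquare(obs, exp).pvalue > 0.01
    assert ok >= 95


def test_permutation_invariance():
    rng = np.random.default_rng(3)
    meta = pd.DataFrame(rng.standard_normal((80, 5)),
                        index=[f"p{i}" for i in range(80)])
    labels = pd.Series(rng.choice(["a", "b"], 80), index=meta.index)
    lm1 = count_similarity_links(meta, labels)
    perm = rng.permutation(meta.index)
    lm2 = count_similarity_links(meta.loc[perm], labels.loc[perm])
    pd.testing.assert_frame_equal(lm1.counts, lm2.counts)


def test_too_few_participants_rejected():
    meta = pd.DataFrame(np.zeros((3, 2)), index=list("abc"))
    labels = pd.Series(["x", "x", "y"], index=meta.index)
    with pytest.raises(ValueError):
        count_similarity_links(meta, labels, LinkRule(m=3))


# ----------------------------------------------------------------------
def test_age_stratified_links_consistency():
    meta, labels = make_planted_meta({"X": [0.0] * 3, "Y": [1.5] * 3},
                                     n_per=100, sd=0.8, seed=4)
    rng = np.random.default_rng(4)
    ages = pd.Series(rng.uniform(40, 80, len(meta)), index=meta.index)
    whole = count_similarity_links(meta, labels)
    single = stratify_links_by_age(meta, labels, ages, bin_width=1000.0)
    assert len(single) == 1
    pd.testing.assert_frame_equal(single[0].counts, whole.counts)


def test_planted_young_only_overlap_concentrates_in_young_bins():
    rng = np.random.default_rng(5)
    n = 150
    young_x = np.column_stack([rng.normal(0, 0.4, n), rng.normal(0, 0.4, n)])
    young_y = np.column_stack([rng.normal(0.8, 0.4, n), rng.normal(0, 0.4, n)])
    old_x = young_x - 8.0   # far apart when old
    old_y = young_y + 8.0
    X = np.vstack([young_x, young_y, old_x, old_y])
    meta = pd.DataFrame(X, columns=["A", "B"],
                        index=[f"p{i}" for i in range(4 * n)])
    labels = pd.Series(["X"] * n + ["Y"] * n + ["X"] * n + ["Y"] * n,
                       index=meta.index)
    ages = pd.Series([45.0] * (2 * n) + [75.0] * (2 * n), index=meta.index)
    mats = stratify_links_by_age(meta, labels, ages, bin_width=20.0)
    young_bin = [m for m in mats if m.age_bin[0] == 40.0][0]
    old_bin = [m for m in mats if m.age_bin[0] == 60.0][0]
    assert young_bin.counts.loc["X", "Y"] > old_bin.counts.loc["X", "Y"]
    assert old_bin.counts.loc["X", "Y"] == 0


# ----------------------------------------------------------------------
def test_differential_profile_recovers_planted_axis():
    """A +0.5 Z offset on one axis appears on that axis only.

    Because the profile is restricted to linked (nearest-neighbour)
    members, the magnitude is attenuated toward the overlap region; the
    sign and the axis pattern are recovered exactly.
    """
    meta, labels = make_planted_meta(
        {"A": [0.0, 0.0, 0.0], "B": [0.0, 0.5, 0.0]},
        n_per=150, sd=0.8, seed=6)
    prof = link_differential_profile(meta, labels, "A", "B")
    assert 0.15 < prof.iloc[1] <= 0.6
    assert abs(prof.iloc[0]) < 0.15 and abs(prof.iloc[2]) < 0.15
    assert prof.abs().idxmax() == prof.index[1]
    # antisymmetry
    rev = link_differential_profile(meta, labels, "B", "A")
    pd.testing.assert_series_equal(prof, -rev)


def test_differential_profile_requires_links():
    meta, labels = make_planted_meta({"A": [0.0] * 4, "B": [9.0] * 4},
                                     n_per=50, sd=0.2, seed=7)
    with pytest.raises(ValueError, match="no links"):
        link_differential_profile(meta, labels, "A", "B")


# ----------------------------------------------------------------------
def _summary(rows):
    return pd.DataFrame(rows).set_index("label")


def test_transition_graph_recovers_planted_chain():
    """Three archetypes overlapping pairwise in sequence, with increasing
    ages, yield the path X -> Y -> Z."""
    meta, labels = make_planted_meta(
        {"X": [0.0, 0.0], "Y": [1.2, 0.0], "Z": [2.4, 0.0]},
        n_per=120, sd=0.45, seed=8)
    lm = count_similarity_links(meta, labels)
    summary = _summary([
        {"label": "X", "mean_age": 45.0, "mean_bmi": 23.0},
        {"label": "Y", "mean_age": 55.0, "mean_bmi": 26.0},
        {"label": "Z", "mean_age": 65.0, "mean_bmi": 29.0}])
    edges = transition_graph(lm, summary, count_quantile=0.0)
    got = {(r["from"], r["to"]) for _, r in edges.iterrows()}
    assert ("X", "Y") in got and ("Y", "Z") in got
    xy = edges.set_index(["from", "to"]).weight
    if ("X", "Z") in got:  # chain: direct X-Z links are the weakest
        assert xy[("X", "Z")] < xy[("X", "Y")]


def test_transition_graph_empty_for_isolated_types():
    meta, labels = make_planted_meta({"X": [0.0] * 4, "Y": [9.0] * 4},
                                     n_per=60, sd=0.2, seed=9)
    lm = count_similarity_links(meta, labels)
    summary = _summary([{"label": "X", "mean_age": 45.0, "mean_bmi": 22.0},
                        {"label": "Y", "mean_age": 60.0, "mean_bmi": 30.0}])
    edges = transition_graph(lm, summary)
    assert len(edges) == 0


def test_transition_tie_breaks_toward_higher_bmi():
    meta, labels = make_planted_meta({"X": [0.0, 0.0], "Y": [0.8, 0.0]},
                                     n_per=80, sd=0.4, seed=10)
    lm = count_similarity_links(meta, labels)
    summary = _summary([{"label": "X", "mean_age": 50.0, "mean_bmi": 30.0},
                        {"label": "Y", "mean_age": 50.0, "mean_bmi": 22.0}])
    edges = transition_graph(lm, summary, count_quantile=0.0)
    assert (edges["from"] == "Y").all()  # lower BMI is the source on ties
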