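"""Shared fixtures: small synthetic cohorts reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from bodytyper import GeneratorConfig, generate_cohort, simulate
from bodytyper.bodytype import label_types, assign_body_types
from bodytyper.metameasure import derive_metameasures, score_metameasures
from bodytyper.preprocess import cohort_body_indices, normalize_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Small full-featured cohort from the default archetype mixture."""
    cfg = GeneratorConfig(n_male=500, n_female=500, seed=11)
    return simulate(cfg)


@pytest.fixture(scope="session")
def z_default(default_cohort):
    return normalize_cohort(default_cohort)


@pytest.fixture(scope="session")
def meta_default(z_default):
    definition = derive_metameasures(z_default, k=13, seed=11)
    return score_metameasures(z_default, definition)


@pytest.fixture(scope="session")
def assignment_default(default_cohort, meta_default):
    clusters = assign_body_types(meta_default, k=15, seed=11)
    indices = cohort_body_indices(default_cohort)
    return label_types(clusters, default_cohort.participants, indices)


@pytest.fixture(scope="session")
def blocks_cohort():
    """Pure correlation-template cohort (no archetypes, no age drift)."""
    return generate_cohort(GeneratorConfig.blocks_only(n=1500, seed=7))


@pytest.fixture(scope="session")
def z_blocks(blocks_cohort):
    return normalize_cohort(blocks_cohort)


def make_planted_meta(centroids: dict[str, np.ndarray], n_per: int,
                      sd: float = 0.5, seed: int = 0,
                      axes: list[str] | None = None):
    """Isotropic Gaussian blobs in meta-measure space with known labels."""
    rng = np.random.default_rng(seed)
    axes = axes or list("ABCDEFGHIJKLM")
    frames, labels = [], []
    for name, c in centroids.items():
        c = np.asarray(c, dtype=float)
        pts = c + sd * rng.standard_normal((n_per, len(c)))
        frames.append(pd.DataFrame(pts, columns=axes[: len(c)]))
        labels += [name] * n_per
    meta = pd.concat(frames, ignore_index=True)
    meta.index = [f"P{i:05d}" for i in range(len(meta))]
    return meta, pd.Series(labels, index=meta.index, name="label")


@pytest.fixture
def planted_meta_factory():
    return make_planted_meta
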