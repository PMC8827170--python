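"""Shared fixtures: tiny hand-built studies and trees."""

import io as _io
import warnings

import numpy as np
import pandas as pd
import pytest
import skbio

import dyadome as dy


@pytest.fixture(autouse=True)
def _quiet_covariance_warnings():
    # the nearest-PD fallback of the generator is exercised deliberately
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=RuntimeWarning)
        warnings.filterwarnings("ignore", category=UserWarning)
        yield


@pytest.fixture
def four_tip_tree() -> skbio.TreeNode:
    return skbio.TreeNode.read(_io.StringIO("((A:1,B:1):1,(C:1,D:1):1):0;"))


@pytest.fixture
def star_tree() -> skbio.TreeNode:
    return skbio.TreeNode.read(_io.StringIO("(X:1,Y:1):0;"))


def make_metadata(assignment, seasons=None):
    """Metadata from {sample: (individual, group)}; one season by default."""
    sample_ids = list(assignment)
    seasons = seasons or {s: "season-1" for s in sample_ids}
    samples = pd.DataFrame(
        {
            "individual_id": [assignment[s][0] for s in sample_ids],
            "group_id": [assignment[s][1] for s in sample_ids],
            "season_id": [seasons[s] for s in sample_ids],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    individuals = (
        samples[["individual_id", "group_id"]]
        .drop_duplicates()
        .set_index("individual_id")
    )
    individuals["sex"] = "female"
    individuals["age_class"] = "adult"
    season_order = tuple(dict.fromkeys(seasons.values()))
    return dy.StudyMetadata(
        samples=samples, individuals=individuals, season_order=season_order
    )


@pytest.fixture
def two_group_toy():
    """4 singleton individuals, groups {a,b} and {c,d}; within 0.1, between 0.9."""
    ids = ["sa", "sb", "sc", "sd"]
    m = np.full((4, 4), 0.9)
    np.fill_diagonal(m, 0.0)
    m[0, 1] = m[1, 0] = 0.1
    m[2, 3] = m[3, 2] = 0.1
    d = skbio.DistanceMatrix(m, ids=ids)
    meta = make_metadata(
        {"sa": ("a", "g1"), "sb": ("b", "g1"), "sc": ("c", "g2"), "sd": ("d", "g2")}
    )
    return d, meta


@pytest.fixture
def small_study():
    """A small synthetic study with group structure, reused across tests."""
    cfg = dy.SimulationConfig(
        group_sizes=(4, 4, 3),
        n_seasons=2,
        n_asvs=60,
        samples_per_individual_season=2,
        sigma_group=1.2,
        kin_density=0.3,
        seed=42,
    )
    return dy.simulate_study(cfg)
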