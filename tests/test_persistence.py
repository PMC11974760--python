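"""Turnover/persistence arithmetic, depth curves, group characterization,
persistent-public sets and logo matrices."""

import numpy as np
import pandas as pd
import pytest

from repdrift import (
    LineageBias,
    SimulationConfig,
    ValidationError,
    characterize_persistent,
    clonotype_keys,
    logo_matrix,
    persistence_report,
    persistent_public,
    shared_clonotypes,
    sharing_vs_depth,
    simulate_study,
)
from conftest import make_records


def _records_for_species(names, **kw):
    """One record per species name; name doubles as the CDRH3."""
    return make_records([("IGHV1-2", "IGHJ4", name.upper() * 3, "IgM", 0,
                          "S1", kw.get("timepoint", "T1")) for name in names])


def test_worked_example_turnover():
    t1 = _records_for_species("abcdefgh")
    t2 = _records_for_species("defghijk", timepoint="T2")
    rep = persistence_report(t1, t2)
    assert (rep.n_appearing, rep.n_disappearing, rep.n_shared, rep.n_total) == (3, 3, 5, 11)
    assert rep.turnover_pct == pytest.approx(600 / 11)
    assert rep.persistence_pct == pytest.approx(100 - 600 / 11)  # ~45.45%
    assert rep.persistence_pct + rep.turnover_pct == 100.0


def test_identical_and_disjoint_timepoints():
    t1 = _records_for_species("abc")
    assert persistence_report(t1, t1).persistence_pct == 100.0
    t2 = _records_for_species("xyz", timepoint="T2")
    assert persistence_report(t1, t2).persistence_pct == 0.0
    with pytest.raises(ValidationError):
        persistence_report(t1.head(0), t2)


def test_persistence_identity_on_random_set_pairs(rng):
    for _ in range(200):
        n1, n2 = rng.integers(1, 40, 2)
        a = set(rng.integers(0, 50, n1).tolist())
        b = set(rng.integers(0, 50, n2).tolist())
        t1 = _records_for_species([f"{'ACDEFGHIKLMNPQRSTVWY'[i % 20]}{'ACDEFGHIKLMNPQRSTVWY'[i // 20]}" for i in a])
        t2 = _records_for_species([f"{'ACDEFGHIKLMNPQRSTVWY'[i % 20]}{'ACDEFGHIKLMNPQRSTVWY'[i // 20]}" for i in b],
                                  timepoint="T2")
        rep = persistence_report(t1, t2)
        assert rep.persistence_pct + rep.turnover_pct == 100.0
        assert rep.persistence_pct == pytest.approx(100 * len(a & b) / len(a | b), abs=1e-9)
        assert rep.n_appearing + rep.n_disappearing + rep.n_shared == rep.n_total


def test_sequence_level_never_exceeds_clonotype_level(default_records):
    for subject, sub in default_records.groupby("subject"):
        t1 = sub[sub["timepoint"] == "T1"]
        t2 = sub[sub["timepoint"] == "T2"]
        seq = persistence_report(t1, t2, level="sequence")
        clone = persistence_report(t1, t2, level="clonotype")
        assert seq.persistence_pct <= clone.persistence_pct + 1e-12


def test_report_consistent_with_shared_clonotypes(default_records):
    sub = default_records[default_records["subject"] == "S1"]
    t1 = sub[sub["timepoint"] == "T1"]
    t2 = sub[sub["timepoint"] == "T2"]
    rep = persistence_report(t1, t2)
    shared, only1, only2 = shared_clonotypes(set(clonotype_keys(t1)), set(clonotype_keys(t2)))
    assert rep.n_shared == len(shared)
    assert rep.n_disappearing == len(only1)
    assert rep.n_appearing == len(only2)


def test_sharing_vs_depth_monotone_and_deterministic(default_records):
    sub = default_records[default_records["subject"] == "S1"]
    t1 = sub[sub["timepoint"] == "T1"]
    t2 = sub[sub["timepoint"] == "T2"]
    cfg_depths = [10, 100, 1000]
    c1 = sharing_vs_depth(t1, t2, cfg_depths, n_boot=20, seed=7)
    c2 = sharing_vs_depth(t1, t2, cfg_depths, n_boot=20, seed=7)
    pd.testing.assert_frame_equal(c1, c2)
    means = c1["mean_shared_fraction"].to_numpy()
    assert means[-1] > means[0]  # sharing increases with sampling depth


def test_census_sharing_recovers_persistent_fraction():
    cfg = SimulationConfig(n_subjects=1, n_sequences_per_replicate=300,
                           persistent_fraction=0.5, public_pool_weight=0.0, seed=29)
    records, truth = simulate_study(cfg)
    t1 = records[records["timepoint"] == "T1"]
    t2 = records[records["timepoint"] == "T2"]
    shared, only1, _ = shared_clonotypes(set(clonotype_keys(t1)), set(clonotype_keys(t2)))
    observed = len(shared) / (len(shared) + len(only1))
    assert observed == pytest.approx(truth.persistent_fraction_observed("S1"), abs=1e-9)
    n = len(shared) + len(only1)
    assert abs(observed - 0.5) < 3 * np.sqrt(0.25 / n)


def test_characterize_directionality_with_memory_biased_persistence():
    cfg = SimulationConfig(
        n_subjects=1, n_sequences_per_replicate=800, persistent_fraction=0.3,
        public_pool_weight=0.0,
        persistent_bias=LineageBias(naive_fraction=0.1, shm_rate=12.0, igg_prob=0.8,
                                    cdrh3_length_shift=-3, size_multiplier=3.0),
        seed=31)
    records, _ = simulate_study(cfg)
    summary = characterize_persistent(records[records["timepoint"] == "T1"],
                                      records[records["timepoint"] == "T2"])
    tests = summary.tests.set_index("measure")
    assert tests.loc["igg_frequency", "mean_a"] > tests.loc["igg_frequency", "mean_b"]
    assert tests.loc["mean_v_mutations", "mean_a"] > tests.loc["mean_v_mutations", "mean_b"]
    assert tests.loc["multi_replicate", "mean_a"] > tests.loc["multi_replicate", "mean_b"]
    assert tests.loc["cdrh3_length", "mean_a"] < tests.loc["cdrh3_length", "mean_b"]
    assert "shared" in summary.logos and summary.logos["shared"].shape[0] == 20


def test_characterize_null_no_group_differences():
    cfg = SimulationConfig(n_subjects=1, n_sequences_per_replicate=600,
                           persistent_fraction=0.3, public_pool_weight=0.0, seed=37)
    records, _ = simulate_study(cfg)
    summary = characterize_persistent(records[records["timepoint"] == "T1"],
                                      records[records["timepoint"] == "T2"])
    assert (summary.tests["p_adjusted"] > 0.01).all()


def test_persistent_public_recovery():
    cfg = SimulationConfig(n_sequences_per_replicate=400, public_pool_size=50,
                           public_pool_weight=0.05, public_persistent_fraction=1.0,
                           persistent_fraction=0.02, seed=41)
    records, truth = simulate_study(cfg)
    by_subject = {s: {t: grp for t, grp in sub.groupby("timepoint")}
                  for s, sub in records.groupby("subject")}
    pp, summary = persistent_public(by_subject, mode="all")
    lin = truth.lineages
    pub = lin[lin["is_public"]]
    # public identities sampled at both timepoints by every subject
    persisted = pub[pub["is_persistent"]]
    counts = persisted.groupby("clonotype")["subject"].nunique()
    expected = set(counts[counts == cfg.n_subjects].index)
    assert expected <= pp
    # essentially nothing outside the configured pool is persistent-public
    assert len(pp - set(pub["clonotype"])) == 0


def test_persistent_public_modes_and_errors(default_records):
    by_subject = {s: {t: grp for t, grp in sub.groupby("timepoint")}
                  for s, sub in default_records.groupby("subject")}
    pp_all, _ = persistent_public(by_subject, mode="all")
    pp_any, _ = persistent_public(by_subject, mode="any")
    assert pp_all <= pp_any
    with pytest.raises(ValidationError):
        persistent_public({"S1": by_subject["S1"]})
    with pytest.raises(ValidationError):
        persistent_public(by_subject, mode="sometimes")


def test_public_short_cdrh3_bias_shifts_persistent_public_left():
    cfg = SimulationConfig(n_sequences_per_replicate=400, public_pool_size=60,
                           public_pool_weight=0.05, public_persistent_fraction=1.0,
                           public_bias=LineageBias(cdrh3_length_shift=-4),
                           persistent_fraction=0.02, seed=43)
    records, _ = simulate_study(cfg)
    by_subject = {s: {t: grp for t, grp in sub.groupby("timepoint")}
                  for s, sub in records.groupby("subject")}
    pp, _ = persistent_public(by_subject)
    assert len(pp) > 10
    pp_lengths = [len(key.split("|")[2]) for key in pp]
    all_lengths = records["cdrh3_length"]
    assert np.median(pp_lengths) < all_lengths.median()


def test_logo_matrix_basics():
    one = logo_matrix(["ARDYYYYYGMDVW"[:13]], 13)
    assert one.shape == (20, 13)
    assert np.allclose(one.sum(axis=0), 1.0)
    assert (one.max(axis=0) == 1.0).all()  # one-hot columns
    two = logo_matrix(["ARDYW", "ARDFW"], 5)
    assert two.loc["Y", "pos4"] == 0.5 and two.loc["F", "pos4"] == 0.5
    assert (two.drop(columns="pos4").max(axis=0) == 1.0).all()
    with pytest.raises(ValidationError):
        logo_matrix(["ARD"], 13)


def test_logo_matrix_uniform_monte_carlo(rng):
    """1e4 uniform random CDRH3s give near-uniform columns (within 4 SE)."""
    aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    seqs = ["".join(row) for row in aas[rng.integers(0, 20, size=(10_000, 9))]]
    mat = logo_matrix(seqs, 9)
    se = np.sqrt(0.05 * 0.95 / 10_000)
    assert np.abs(mat.to_numpy() - 0.05).max() <= 4 * se
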