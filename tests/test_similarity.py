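"""Morisita-Horn correctness against exact arithmetic, bootstrap behavior,
clustering against a brute-force oracle, and stratified comparisons."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from repdrift import (
    LineageBias,
    SimulationConfig,
    ValidationError,
    cluster_replicates,
    morisita_horn,
    pairwise_matrix,
    simulate_study,
    species_reduce,
    stratified_similarity,
    subsampled_similarity,
)
from repdrift.similarity import DEFAULT_STRATA
from conftest import make_records


def mh_exact(x: dict, y: dict) -> Fraction:
    """Independent oracle: the index evaluated in exact rational arithmetic."""
    species = set(x) | set(y)
    X = Fraction(sum(x.values()))
    Y = Fraction(sum(y.values()))
    num = 2 * sum(Fraction(x.get(s, 0)) * Fraction(y.get(s, 0)) for s in species)
    den = (sum(Fraction(x.get(s, 0)) ** 2 for s in species) / X ** 2
           + sum(Fraction(y.get(s, 0)) ** 2 for s in species) / Y ** 2) * X * Y
    return num / den


def test_worked_example_exact_rational():
    # x = {A:2, B:1}, y = {A:1, B:3} -> 10 / (170/12) = 12/17
    ch = morisita_horn({"A": 2, "B": 1}, {"A": 1, "B": 3})
    assert mh_exact({"A": 2, "B": 1}, {"A": 1, "B": 3}) == Fraction(12, 17)
    assert ch == pytest.approx(12 / 17, abs=1e-12)


def test_identity_and_disjoint_exact():
    x = {"a": 5, "b": 2, "c": 9}
    assert morisita_horn(x, x) == 1.0
    assert morisita_horn({"a": 3, "b": 1}, {"c": 2, "d": 7}) == 0.0


def test_zero_total_errors():
    with pytest.raises(ValidationError):
        morisita_horn({"a": 0}, {"a": 1})


def test_matches_exact_oracle_on_random_distributions():
    rng = np.random.default_rng(42)
    for _ in range(100):
        n_species = rng.integers(1, 11)
        labels = [f"sp{k}" for k in range(n_species)]
        x = {l: int(c) for l, c in zip(labels, rng.integers(0, 21, n_species))}
        y = {l: int(c) for l, c in zip(labels, rng.integers(0, 21, n_species))}
        x = {l: c for l, c in x.items() if c} or {labels[0]: 1}
        y = {l: c for l, c in y.items() if c} or {labels[0]: 1}
        assert morisita_horn(x, y) == pytest.approx(float(mh_exact(x, y)), abs=1e-12)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(counts=st.lists(st.tuples(st.integers(0, 30), st.integers(0, 30)),
                       min_size=1, max_size=8).filter(
                           lambda cs: sum(a for a, _ in cs) > 0 and sum(b for _, b in cs) > 0),
       scale=st.integers(1, 7))
def test_scaling_and_relabeling_invariance(counts, scale):
    x = {f"s{i}": a for i, (a, b) in enumerate(counts)}
    y = {f"s{i}": b for i, (a, b) in enumerate(counts)}
    x = {k: v for k, v in x.items() if v} or {"s0": 1}
    y = {k: v for k, v in y.items() if v} or {"s0": 1}
    ch = morisita_horn(x, y)
    assert 0.0 <= ch <= 1.0 + 1e-12
    scaled = {k: scale * v for k, v in x.items()}
    assert morisita_horn(scaled, y) == pytest.approx(ch, abs=1e-9)
    relabel = {k + "_renamed": v for k, v in x.items()}
    y_re = {k + "_renamed": v for k, v in y.items()}
    assert morisita_horn(relabel, y_re) == pytest.approx(ch, abs=1e-9)
    assert morisita_horn(y, x) == pytest.approx(ch, abs=1e-12)


def test_species_reduce_bookkeeping():
    recs = make_records([
        ("IGHV1-2", "IGHJ4", "A" * 13), ("IGHV1-2", "IGHJ4", "G" * 13),
        ("IGHV1-2", "IGHJ4", "Y" * 15), ("IGHV3-23", "IGHJ6", "S" * 13),
    ])
    counts = species_reduce(recs)
    assert counts.sum() == 4
    assert len(counts) == 3  # records differing only in AA content collapse by length
    assert counts[("IGHV1-2", "IGHJ4", 13)] == 2
    with pytest.raises(ValidationError):
        species_reduce(recs.head(0))


def test_bootstrap_similarity_deterministic_and_self_limit(default_records):
    sample = default_records[(default_records["subject"] == "S1")
                             & (default_records["timepoint"] == "T1")]
    depths = [10, 100, 1000, len(sample), 5 * len(sample)]
    c1 = subsampled_similarity(sample, sample, depths, n_boot=20, seed=3)
    c2 = subsampled_similarity(sample, sample, depths, n_boot=20, seed=3)
    pd.testing.assert_frame_equal(c1.table, c2.table)
    means = c1.table["mean_ch"].to_numpy()
    # self-similarity rises monotonically toward 1 with depth
    assert (np.diff(means) > 0).all()
    assert means[-1] > 0.95
    assert (c1.table["ci_low"] <= c1.table["mean_ch"]).all()
    assert (c1.table["mean_ch"] <= c1.table["ci_high"]).all()
    # depths past the census are permitted (bootstrap) but flagged
    assert bool(c1.table["exceeds_census"].iloc[-1]) is True
    assert bool(c1.table["exceeds_census"].iloc[-2]) is False


def test_bootstrap_mean_matches_exact_ch_at_census(default_records):
    a = default_records[(default_records["subject"] == "S1")
                        & (default_records["timepoint"] == "T1")]
    b = default_records[(default_records["subject"] == "S1")
                        & (default_records["timepoint"] == "T2")]
    exact = morisita_horn(species_reduce(a), species_reduce(b))
    curve = subsampled_similarity(a, b, [min(len(a), len(b))], n_boot=20, seed=5).table
    assert curve["ci_low"].iloc[0] - 0.02 <= exact <= curve["ci_high"].iloc[0] + 0.02


def test_disjoint_v_pools_give_zero_similarity():
    a = make_records([("IGHV1-2", "IGHJ4", "A" * 13)] * 30)
    b = make_records([("IGHV3-23", "IGHJ4", "A" * 13)] * 30)
    curve = subsampled_similarity(a, b, [10, 30], n_boot=5, seed=0).table
    assert (curve["mean_ch"] == 0.0).all()


def test_depth_grid_validation(default_records):
    s = default_records.head(50)
    with pytest.raises(ValidationError):
        subsampled_similarity(s, s, [], n_boot=5)
    with pytest.raises(ValidationError):
        subsampled_similarity(s, s, [5], n_boot=5)
    with pytest.raises(ValidationError):
        subsampled_similarity(s, s, [10], n_boot=1)


def test_pairwise_matrix_properties(default_records):
    samples = {f"{t}/{r}": grp for (t, r), grp in
               default_records[default_records["subject"] == "S1"]
               .groupby(["timepoint", "replicate"])}
    mat = pairwise_matrix(samples)
    assert mat.shape == (12, 12)
    assert np.allclose(mat, mat.T)
    assert np.allclose(np.diag(mat), 1.0)
    labels = list(mat.index)[:2]
    entry = morisita_horn(species_reduce(samples[labels[0]]),
                          species_reduce(samples[labels[1]]))
    assert mat.iloc[0, 1] == pytest.approx(entry, abs=1e-12)


def _brute_force_single_linkage(dist: np.ndarray):
    """Exhaustive-merge oracle: returns sorted merge heights."""
    clusters = [{i} for i in range(len(dist))]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = min(dist[a, b] for a in clusters[i] for b in clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        clusters[i] |= clusters[j]
        del clusters[j]
    return sorted(heights)


def test_single_linkage_matches_exhaustive_oracle():
    rng = np.random.default_rng(1)
    sim = rng.uniform(0.2, 1.0, size=(6, 6))
    sim = (sim + sim.T) / 2
    np.fill_diagonal(sim, 1.0)
    mat = pd.DataFrame(sim, index=list("abcdef"), columns=list("abcdef"))
    Z, leaves = cluster_replicates(mat, metric="euclidean")
    rows = mat.to_numpy()
    dist = np.sqrt(((rows[:, None, :] - rows[None, :, :]) ** 2).sum(-1))
    assert sorted(Z[:, 2]) == pytest.approx(_brute_force_single_linkage(dist), abs=1e-12)
    assert sorted(leaves) == list("abcdef")


def test_block_similarity_forms_two_clusters():
    labels = [f"g1_{i}" for i in range(4)] + [f"g2_{i}" for i in range(4)]
    sim = np.full((8, 8), 0.5)
    sim[:4, :4] = 0.99
    sim[4:, 4:] = 0.99
    np.fill_diagonal(sim, 1.0)
    mat = pd.DataFrame(sim, index=labels, columns=labels)
    Z, _ = cluster_replicates(mat)
    from scipy.cluster.hierarchy import fcluster
    assign = fcluster(Z, t=2, criterion="maxclust")
    assert len(set(assign[:4])) == 1 and len(set(assign[4:])) == 1
    assert assign[0] != assign[4]


def test_identical_rows_merge_at_zero():
    mat = pd.DataFrame(np.ones((3, 3)), index=list("abc"), columns=list("abc"))
    Z, _ = cluster_replicates(mat)
    assert np.allclose(Z[:, 2], 0.0)
    with pytest.raises(ValidationError):
        cluster_replicates(mat.iloc[:, :2])


def test_replicates_cluster_by_subject_and_timepoint():
    """With subject+timepoint usage shifts, replicates group by condition."""
    cfg = SimulationConfig(n_sequences_per_replicate=400,
                           subject_usage_concentration=30.0,
                           timepoint_usage_concentration=30.0,
                           persistent_fraction=0.02, seed=21)
    records, _ = simulate_study(cfg)
    samples = {f"{s}@{t}@{r}": grp for (s, t, r), grp in
               records.groupby(["subject", "timepoint", "replicate"])}
    mat = pairwise_matrix(samples)
    Z, _ = cluster_replicates(mat)
    from scipy.cluster.hierarchy import fcluster
    assign = fcluster(Z, t=4, criterion="maxclust")
    truth = [lab.rsplit("@", 1)[0] for lab in mat.index]
    purity = (pd.crosstab(pd.Series(truth), pd.Series(assign)).max(axis=0).sum()
              / len(truth))
    assert purity >= 0.9


def test_mutation_cut_stratum_assignment():
    recs = make_records([
        ("IGHV1-2", "IGHJ4", "ARDY", "IgM", 1),
        ("IGHV1-2", "IGHJ4", "ARDY", "IgM", 2),
        ("IGHV1-2", "IGHJ4", "ARDY", "IgG", 5),
    ])
    assert DEFAULT_STRATA["IgM_lt2mut"](recs).tolist() == [True, False, False]
    assert DEFAULT_STRATA["IgM_ge2mut"](recs).tolist() == [False, True, False]
    assert DEFAULT_STRATA["IgG"](recs).tolist() == [False, False, True]
    assert DEFAULT_STRATA["all"](recs).all()


def test_igg_repertoires_less_similar_across_timepoints():
    """When the stable (persistent) compartment is naive IgM and gene usage
    shifts between timepoints, IgG inter-timepoint similarity drops below IgM."""
    cfg = SimulationConfig(n_subjects=1, n_sequences_per_replicate=600,
                           persistent_fraction=0.5,
                           persistent_bias=LineageBias(naive_fraction=1.0),
                           timepoint_usage_concentration=25.0,
                           public_pool_weight=0.0, seed=23)
    records, _ = simulate_study(cfg)
    _, summary = stratified_similarity(records)
    inter = summary[summary["pair_type"] == "inter"].set_index("stratum")
    assert inter.loc["IgG", "median_ch"] < inter.loc["IgM_lt2mut", "median_ch"]


def test_no_timepoint_effect_gives_overlapping_intra_inter():
    """Null case: with no usage shift and clone dominance suppressed (sizes
    ~1, so timepoints are exchangeable draws from one species distribution),
    intra- and inter-timepoint similarity distributions overlap."""
    cfg = SimulationConfig(n_subjects=1, n_sequences_per_replicate=400,
                           lineage_size_exponent=5.0, public_pool_weight=0.0, seed=19)
    records, _ = simulate_study(cfg)
    _, summary = stratified_similarity(records, strata={"all": DEFAULT_STRATA["all"]})
    intra = summary[summary["pair_type"] == "intra"].iloc[0]
    inter = summary[summary["pair_type"] == "inter"].iloc[0]
    assert intra["q1_ch"] <= inter["q3_ch"] and inter["q1_ch"] <= intra["q3_ch"]


def test_empty_stratum_recorded_not_raised():
    recs = make_records([("IGHV1-2", "IGHJ4", "ARDY", "IgM", 0, "S1", "T1", "R1"),
                         ("IGHV1-2", "IGHJ4", "ARDY", "IgM", 0, "S1", "T1", "R2")])
    _, summary = stratified_similarity(recs)
    igg = summary[(summary["stratum"] == "IgG")]
    assert (igg["n_pairs"] == 0).all()
    assert igg["median_ch"].isna().all()
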