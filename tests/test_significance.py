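from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pytest

from bgcmodules.data import ValidationError
from bgcmodules.interactions import (
    ADJACENCY,
    COLOCALIZATION,
    PairProfile,
    collapse_dataset,
    count_adjacency,
    count_colocalization,
    enumerate_candidate_pairs,
)
from bgcmodules.significance import (
    adjacency_pvalue,
    colocalization_pvalue,
    conservative_pvalue,
    correct_fdr,
    profile_pvalue,
    test_all_pairs as score_all_pairs,
)

from conftest import make_cluster, make_dataset, random_dataset


# ---------------------------------------------------------------------------
# Independent oracles


def brute_force_pvalue(profile: PairProfile) -> Fraction:
    """Exact tail by enumerating every placement of the moving genes.

    Positions are labelled with their class weight (interactions contributed
    per gene); all C(N_tot, B_tot) subsets are enumerated directly.
    """
    weights = [k for k, n in enumerate(profile.capacities) for _ in range(n)]
    b_tot, i_orig = profile.b_tot, profile.i_orig
    if i_orig == 0:
        return Fraction(1)
    hits = sum(
        1 for subset in combinations(weights, b_tot) if sum(subset) >= i_orig
    )
    return Fraction(hits, comb(len(weights), b_tot))


def step_up_by(pvalues):
    """Reference Benjamini–Yekutieli adjustment, written from the formula."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    c_m = sum(1.0 / k for k in range(1, m + 1))
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running = min(running, p[idx] * m * c_m / rank_from_top)
        adjusted[idx] = min(running, 1.0)
    return adjusted


def random_profile(rng, kind):
    """Random small profile with C(N_tot, B_tot) <= 1e5."""
    while True:
        n_classes = 3 if kind == ADJACENCY else 2
        caps = tuple(int(rng.integers(0, 8)) for _ in range(n_classes))
        n_tot = sum(caps)
        if n_tot == 0:
            continue
        b_tot = int(rng.integers(1, min(n_tot, 8) + 1))
        if comb(n_tot, b_tot) > 1e5:
            continue
        # draw a feasible occupancy vector
        occ = list(rng.multivariate_hypergeometric(caps, b_tot))
        prof = PairProfile("A", "B", kind, caps, tuple(occ))
        if prof.i_orig == 0:
            continue
        return prof


# ---------------------------------------------------------------------------
# Worked examples


def test_adjacency_pvalue_enumerated_example():
    prof = PairProfile("A", "B", ADJACENCY, (2, 1, 0), (0, 1, 0))
    assert adjacency_pvalue(prof, exact=True) == Fraction(1, 3)


def test_adjacency_pvalue_zero_observation_is_one():
    prof = PairProfile("A", "B", ADJACENCY, (2, 1, 0), (1, 0, 0))
    assert adjacency_pvalue(prof, exact=True) == 1


def test_adjacency_pvalue_forced_support():
    # the single available position is flanked by two A genes: i is always 2
    prof = PairProfile("A", "B", ADJACENCY, (0, 0, 1), (0, 0, 1))
    assert adjacency_pvalue(prof, exact=True) == 1


def test_colocalization_pvalue_enumerated_example():
    prof = PairProfile("A", "B", COLOCALIZATION, (3, 2), (0, 1))
    assert colocalization_pvalue(prof, exact=True) == Fraction(2, 5)


def test_colocalization_pvalue_all_positions_coresident():
    prof = PairProfile("A", "B", COLOCALIZATION, (0, 4), (0, 3))
    assert colocalization_pvalue(prof, exact=True) == 1


def test_conservative_is_max():
    assert conservative_pvalue(0.01, 0.04) == 0.04
    assert conservative_pvalue(0.2, 0.2) == 0.2
    assert conservative_pvalue(1.0, 0.2) == 1.0
    with pytest.raises(ValidationError):
        conservative_pvalue(0.0, 0.5)


# ---------------------------------------------------------------------------
# Exactness against brute force


@pytest.mark.parametrize("kind", [ADJACENCY, COLOCALIZATION])
def test_pvalue_matches_brute_force(kind, rng):
    for _ in range(15):
        prof = random_profile(rng, kind)
        assert profile_pvalue(prof, exact=True) == brute_force_pvalue(prof)


def test_full_outcome_space_sums_to_one(rng):
    # the hypergeometric masses over the whole outcome space are a partition
    from bgcmodules.significance import _iter_adjacency_outcomes

    for _ in range(10):
        prof = random_profile(rng, ADJACENCY)
        total = sum(
            comb(prof.capacities[0], ba)
            * comb(prof.capacities[1], bb)
            * comb(prof.capacities[2], bc)
            for ba, bb, bc in _iter_adjacency_outcomes(prof.capacities, prof.b_tot)
        )
        assert total == comb(prof.n_tot, prof.b_tot)


def test_tail_monotone_in_observed_count():
    # fixed capacities and B_tot = 3; occupancy vectors realising i = 0..5
    caps = (5, 4, 2)
    occupancies = [
        (3, 0, 0),  # i = 0
        (2, 1, 0),  # i = 1
        (1, 2, 0),  # i = 2
        (0, 3, 0),  # i = 3
        (1, 0, 2),  # i = 4
        (0, 1, 2),  # i = 5
    ]
    previous = Fraction(2)
    for occ in occupancies:
        p = adjacency_pvalue(PairProfile("A", "B", ADJACENCY, caps, occ), exact=True)
        assert p <= previous
        previous = p


def test_log_path_agrees_with_exact(rng):
    for kind in (ADJACENCY, COLOCALIZATION):
        for _ in range(10):
            prof = random_profile(rng, kind)
            p_exact = float(profile_pvalue(prof, exact=True))
            p_log = profile_pvalue(prof, exact=False)
            assert p_log == pytest.approx(p_exact, rel=1e-10)


# ---------------------------------------------------------------------------
# BY correction


def test_by_matches_hand_computation():
    assert correct_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.055, 0.055, 0.055])


def test_by_single_value_identity():
    assert correct_fdr([1.0]) == pytest.approx([1.0])


def test_by_matches_reference_step_up(rng):
    for _ in range(25):
        p = rng.uniform(1e-6, 1.0, size=int(rng.integers(1, 40)))
        assert correct_fdr(p) == pytest.approx(step_up_by(p))


def test_by_rejects_out_of_range():
    with pytest.raises(ValidationError):
        correct_fdr([0.5, 0.0])
    with pytest.raises(ValidationError):
        correct_fdr([])


def test_by_is_monotone(rng):
    p = np.sort(rng.uniform(0, 1, size=20))
    q = correct_fdr(p)
    assert np.all(np.diff(q) >= -1e-15)


# ---------------------------------------------------------------------------
# Orchestration


def test_single_coresident_pair(toy_dataset):
    ds = make_dataset(
        make_cluster("c1", ["A", "B", "x"]),
        make_cluster("c2", ["A", "x", "x"]),
        make_cluster("c3", ["B", "x"]),
    )
    results = score_all_pairs(ds)
    kinds = {r.kind for r in results}
    assert {r.pair for r in results} == {("A", "B")}
    assert kinds == {ADJACENCY, COLOCALIZATION}


def test_adjusted_never_below_conservative(toy_dataset):
    results = score_all_pairs(toy_dataset)
    assert results, "toy dataset must yield tests"
    for r in results:
        assert r.p_adjusted >= r.p_conservative - 1e-15
        assert r.p_conservative == max(r.p_fixed_a, r.p_fixed_b)


def permutation_pvalue(profile: PairProfile, n_shuffles: int, rng) -> tuple[float, float]:
    """Monte-Carlo estimate of the directional p-value: redistribute the
    moving genes uniformly over the available positions (equivalently, draw
    the class occupancies from the multivariate hypergeometric)."""
    draws = rng.multivariate_hypergeometric(
        list(profile.capacities), profile.b_tot, size=n_shuffles
    )
    weights = np.arange(len(profile.capacities))
    i_sim = draws @ weights
    p_hat = float(np.mean(i_sim >= profile.i_orig))
    se = max(np.sqrt(p_hat * (1 - p_hat) / n_shuffles), 1.0 / n_shuffles)
    return p_hat, se


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_analytic_agrees_with_permutation(seed):
    rng = np.random.default_rng(seed)
    ds = random_dataset(rng, n_clusters=5, n_cogs=4)
    collapsed = collapse_dataset(ds)
    pairs = enumerate_candidate_pairs(ds)[:3]
    for a, b in pairs:
        for prof in (
            count_adjacency(ds, a, b),
            count_colocalization(collapsed, a, b),
        ):
            if prof.i_orig == 0 or prof.b_tot == 0:
                continue
            analytic = float(profile_pvalue(prof))
            p_hat, se = permutation_pvalue(prof, 5000, rng)
            assert abs(analytic - p_hat) <= 3 * se


def test_collapse_pvalue_is_conservative():
    """Collapsing duplicates of the FIXED orthogroup only inflates the
    co-resident position class, so the collapsed two-class p-value bounds the
    permutation estimate on the original geometry from above.

    Datasets are drawn so that only the fixed orthogroup is ever duplicated
    within a cluster (the case the transform exists for); the moving genes
    stay unique.
    """
    rng = np.random.default_rng(7)
    for seed in range(8):
        gen = np.random.default_rng(seed)
        clusters = []
        for ci in range(6):
            length = int(gen.integers(4, 8))
            seq = []
            for pos in range(length):
                u = gen.random()
                if u < 0.35:
                    seq.append("A")  # duplicated fixed cog
                elif u < 0.50 and "B" not in seq:
                    seq.append("B")
                else:
                    seq.append("x")
            clusters.append(make_cluster(f"c{ci}", seq))
        ds = make_dataset(*clusters)
        if "B" not in ds.smcogs or "A" not in ds.smcogs:
            continue
        prof_c = count_colocalization(collapse_dataset(ds), "A", "B")
        if prof_c.i_orig == 0:
            continue
        p_collapsed = float(colocalization_pvalue(prof_c))
        # permutation on the ORIGINAL geometry: B genes land uniformly on
        # non-A positions; i = number landing in A-containing clusters
        cap_a = cap_b = i_obs = b_tot = 0
        for cluster in ds.clusters:
            seq = cluster.smcog_sequence()
            k = sum(1 for s in seq if s == "A")
            nb = sum(1 for s in seq if s == "B")
            if k:
                cap_b += len(seq) - k
                i_obs += nb
            else:
                cap_a += len(seq)
            b_tot += nb
        draws = rng.multivariate_hypergeometric([cap_a, cap_b], b_tot, size=4000)
        p_hat = float(np.mean(draws[:, 1] >= i_obs))
        se = max(np.sqrt(p_hat * (1 - p_hat) / 4000), 1.0 / 4000)
        assert p_collapsed >= p_hat - 3 * se
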