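import numpy as np
import pytest

from mircircuit import (
    BinarizedDataset,
    ConstraintProfile,
    RelaxationPolicy,
    Strategy,
    brute_force_oracle,
    count_errors,
    find_optimal,
    format_classifier,
    parse_classifier,
    relax_and_solve,
    relaxation_schedule,
    validate_classifier,
)

from conftest import or_not_types, random_instance


def solution_key(sol):
    return (sol.status, sol.objective,
            tuple(format_classifier(c) for c in sol.classifiers))


def test_single_not_gate_optimum(reduced_profile):
    # positives are exactly the rows with g2 = 0: the one-input classifier
    # (!g2) is optimal; confirmed against the exhaustive oracle
    rng = np.random.default_rng(1)
    mat = rng.integers(0, 2, size=(8, 4))
    ann = 1 - mat[:, 1]
    ds = BinarizedDataset(range(8), ann, ["g1", "g2", "g3", "g4"], mat)
    p = ConstraintProfile(max_gates=3, max_inputs=3, gate_types=or_not_types(3, 3))
    sol = find_optimal(ds, p, "opt3", enumerate_all=True)
    assert sol.status == "OPTIMAL"
    assert sol.objective.as_tuple() == (1, 1)
    assert "(!g2)" in [format_classifier(c) for c in sol.classifiers]
    assert solution_key(sol) == solution_key(brute_force_oracle(ds, p, "opt3"))


def test_contradictory_profiles_are_infeasible_at_zero_bounds(reduced_profile):
    ds = BinarizedDataset([1, 2], [1, 0], ["g1", "g2"], [[1, 0], [1, 0]])
    sol = find_optimal(ds, reduced_profile, "opt3")
    assert sol.status == "INFEASIBLE"
    assert sol.classifiers == ()


def test_all_positive_dataset_solved_by_single_covering_gate(reduced_profile):
    ds = BinarizedDataset([1, 2, 3], [1, 1, 1], ["g1", "g2"],
                          [[1, 0], [1, 1], [1, 0]])
    sol = find_optimal(ds, reduced_profile, "opt1", enumerate_all=True)
    assert sol.status == "OPTIMAL"
    assert sol.objective.inputs == 1
    assert "(g1)" in [format_classifier(c) for c in sol.classifiers]


def test_solutions_satisfy_constraints_and_bounds(reduced_profile):
    # cross-module invariant: everything the engine returns passes
    # validate_classifier and the error bounds
    for seed in range(10):
        ds = random_instance(seed)
        p = reduced_profile.with_bounds(1, 1)
        sol = find_optimal(ds, p, "opt4", enumerate_all=True)
        for c in sol.classifiers:
            assert validate_classifier(c, p) == []
            e = count_errors(c, ds)
            assert e.fn <= 1 and e.fp <= 1


@pytest.mark.parametrize("strategy", list(Strategy))
def test_engine_matches_oracle_small_sample(strategy, reduced_profile):
    for seed in range(12):
        ds = random_instance(seed)
        p = reduced_profile.with_bounds(seed % 2, (seed // 2) % 2)
        a = find_optimal(ds, p, strategy, enumerate_all=True)
        b = brute_force_oracle(ds, p, strategy)
        assert solution_key(a) == solution_key(b), (seed, strategy)


def test_bilevel_matches_weighted_sum_realization(reduced_profile):
    # the sequential bi-level solve must agree with a one-shot weighted-sum
    # objective (inputs * (max_gates + 1) + gates) over the feasible set
    for seed in range(8):
        ds = random_instance(seed)
        sol = find_optimal(ds, reduced_profile, "opt3")
        feas = brute_force_oracle(ds, reduced_profile, "feasible")
        if feas.status == "INFEASIBLE":
            assert sol.status == "INFEASIBLE"
            continue
        w = reduced_profile.max_gates + 1
        best = min(c.n_inputs * w + c.n_gates for c in feas.classifiers)
        got = sol.objective.inputs * w + sol.objective.gates
        assert got == best


def test_optimality_certificate_by_tightening(reduced_profile):
    for seed in range(8):
        ds = random_instance(seed)
        sol = find_optimal(ds, reduced_profile, "opt1")
        if sol.status != "OPTIMAL" or sol.objective.inputs == 1:
            continue
        tightened = ConstraintProfile(
            max_gates=reduced_profile.max_gates,
            max_inputs=sol.objective.inputs - 1,
            gate_types=reduced_profile.gate_types,
        )
        assert find_optimal(ds, tightened, "opt1").status == "INFEASIBLE"


def test_enlarging_error_bounds_never_worsens_objective(reduced_profile):
    for seed in range(6):
        ds = random_instance(seed)
        base = find_optimal(ds, reduced_profile.with_bounds(0, 0), "opt3")
        relaxed = find_optimal(ds, reduced_profile.with_bounds(1, 1), "opt3")
        if base.status == "OPTIMAL":
            assert relaxed.status == "OPTIMAL"
            assert relaxed.objective.as_tuple() <= base.objective.as_tuple()


def test_determinism_identical_runs_identical_results(reduced_profile):
    ds = random_instance(3)
    runs = [find_optimal(ds, reduced_profile, "opt3", enumerate_all=True,
                         seed=0) for _ in range(2)]
    assert solution_key(runs[0]) == solution_key(runs[1])


def test_unique_input_constraint_respected():
    p = ConstraintProfile(max_gates=3, max_inputs=3,
                          gate_types=or_not_types(3, 3), unique_input=True)
    for seed in range(6):
        ds = random_instance(seed)
        sol = find_optimal(ds, p, "opt3", enumerate_all=True)
        for c in sol.classifiers:
            markers = [m for g in c.gates for m in g.markers()]
            assert len(markers) == len(set(markers))
        assert solution_key(sol) == solution_key(brute_force_oracle(ds, p, "opt3"))


def test_input_weights_steer_the_optimum(reduced_profile):
    # two equally short separations exist; penalizing one marker must
    # select the other
    mat = np.array([[1, 1, 0], [1, 1, 1], [0, 0, 1], [0, 0, 0]])
    ds = BinarizedDataset(range(4), [1, 1, 0, 0], ["g1", "g2", "g3"], mat)
    free = find_optimal(ds, reduced_profile, "opt1", enumerate_all=True)
    texts = [format_classifier(c) for c in free.classifiers]
    assert "(g1)" in texts and "(g2)" in texts
    steered = find_optimal(ds, reduced_profile, "opt1", enumerate_all=True,
                           input_weights={"g1": 10.0})
    texts = [format_classifier(c) for c in steered.classifiers]
    assert "(g1)" not in texts and "(g2)" in texts


def test_timeout_reports_timeout_status():
    rng = np.random.default_rng(0)
    mat = rng.integers(0, 2, size=(120, 120))
    ann = rng.integers(0, 2, size=120)
    ds = BinarizedDataset(range(120), ann, [f"g{i}" for i in range(120)], mat)
    from mircircuit import core_profile
    sol = find_optimal(ds, core_profile(), "opt3", time_limit=0.02)
    assert sol.status == "TIMEOUT"


def test_oracle_refuses_large_search_spaces(core):
    ds = random_instance(0, n_mirnas=6)
    with pytest.raises(ValueError, match="oracle refuses"):
        brute_force_oracle(ds, core, "opt1")  # max_inputs 8 beyond guard


# ---------------------------------------------------------------------------
# relaxation


def test_default_schedule_matches_stepwise_rule():
    assert relaxation_schedule(None, 2) == [
        (0, 0), (1, 0), (0, 1), (2, 0), (1, 1), (0, 2)]


def test_schedule_first_element_is_perfect_classifier():
    for policy in (None, RelaxationPolicy(forbid_fp=True),
                   RelaxationPolicy(forbid_fn=True)):
        assert relaxation_schedule(policy, 3)[0] == (0, 0)


def test_forbid_one_axis_schedules():
    assert relaxation_schedule(RelaxationPolicy(forbid_fp=True), 2) == \
        [(0, 0), (1, 0), (2, 0)]
    assert relaxation_schedule(RelaxationPolicy(forbid_fn=True), 2) == \
        [(0, 0), (0, 1), (0, 2)]


def test_both_forbid_flags_rejected():
    with pytest.raises(ValueError):
        relaxation_schedule(
            RelaxationPolicy(forbid_fp=True, forbid_fn=True), 2)


def test_explicit_schedule_validated():
    with pytest.raises(ValueError, match="start at"):
        RelaxationPolicy(schedule=((1, 0), (0, 0)))
    with pytest.raises(ValueError, match="non-decreasing"):
        RelaxationPolicy(schedule=((0, 0), (1, 1), (1, 0)))


def one_conflict_dataset(seed):
    """Separable dataset (labels planted by a profile-feasible classifier)
    plus one duplicated profile carrying the opposite label."""
    from mircircuit import annotate

    planted = parse_classifier("(g1 | g2) & !g3")
    rng = np.random.default_rng(seed)
    while True:
        mat = rng.integers(0, 2, size=(6, 4))
        if len({tuple(r) for r in mat.tolist()}) != 6:
            continue
        labels = annotate(mat, planted).annotations
        if 0 < labels.sum() < 6:
            break
    mat = np.vstack([mat, mat[0]])
    ann = np.append(labels, 1 - labels[0])
    return BinarizedDataset(range(7), ann, ["g1", "g2", "g3", "g4"], mat)


def test_consistent_dataset_relaxation_equals_direct_solve(reduced_profile):
    ds = random_instance(2)  # perfectly separable under the reduced profile
    direct = find_optimal(ds, reduced_profile, "opt3", enumerate_all=True)
    assert direct.status == "OPTIMAL"
    relaxed = relax_and_solve(ds, reduced_profile, "opt3", enumerate_all=True)
    assert solution_key(relaxed) == solution_key(direct)
    assert relaxed.bounds_used == (0, 0)


def test_single_conflict_first_succeeds_at_total_one(reduced_profile):
    ds = one_conflict_dataset(2)
    assert find_optimal(ds, reduced_profile, "opt3").status == "INFEASIBLE"
    sol = relax_and_solve(ds, reduced_profile, "opt3")
    assert sol.status == "OPTIMAL"
    assert sum(sol.bounds_used) == 1


def test_forbid_fp_relaxation_yields_fp_free_solution(reduced_profile):
    ds = one_conflict_dataset(2)
    sol = relax_and_solve(ds, reduced_profile, "opt3",
                          policy=RelaxationPolicy(forbid_fp=True))
    assert sol.status == "OPTIMAL"
    assert sol.bounds_used[1] == 0 and sol.bounds_used[0] >= 1
    e = count_errors(sol.classifiers[0], ds)
    assert e.fp == 0 and e.fn >= 1
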