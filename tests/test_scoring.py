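import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mircircuit import (
    BinarizedDataset,
    ContinuousDataset,
    HillOutputModel,
    ScoringConfig,
    boolean_rates,
    circuit_output,
    margins,
    parse_classifier,
    rank_solutions,
    s_auc,
    s_m,
    score_classifier,
)
from mircircuit.scoring import report_frame, round_half_up


class _LookupModel:
    """Output model stub returning a precomputed per-sample value (the
    'out' column); lets margin/AUC arithmetic be tested directly."""

    def __call__(self, c, profile):
        return float(profile["out"])


def outputs_dataset(pos_outputs, neg_outputs):
    vals = list(pos_outputs) + list(neg_outputs)
    ann = [1] * len(pos_outputs) + [0] * len(neg_outputs)
    return ContinuousDataset(range(len(vals)), ann, ["out"],
                             [[v] for v in vals])


LOOKUP_CFG = ScoringConfig(output_model=_LookupModel())
ANY = parse_classifier("(out)")


def pairwise_auc(pos, neg):
    """Independent oracle: concordant-pair count with half credit for ties."""
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# Boolean rates


def test_rates_match_published_arithmetic():
    # 4 FN among 167 positives -> 0.02; 3 FP among 11 negatives -> 0.27
    rng = np.random.default_rng(0)
    n_pos, n_neg, fn, fp = 167, 11, 4, 3
    g1 = np.concatenate([np.ones(n_pos - fn), np.zeros(fn),
                         np.zeros(n_neg - fp), np.ones(fp)]).astype(int)
    ann = np.concatenate([np.ones(n_pos), np.zeros(n_neg)]).astype(int)
    ds = BinarizedDataset(range(n_pos + n_neg), ann, ["g1"], g1[:, None])
    fn_rate, fp_rate = boolean_rates(parse_classifier("(g1)"), ds)
    assert round_half_up(fn_rate) == 0.02
    assert round_half_up(fp_rate) == 0.27


def test_perfect_classifier_rates_are_zero(fig3_dataset):
    assert boolean_rates(parse_classifier("(g1 | g3) & !g2"),
                         fig3_dataset) == (0.0, 0.0)


def test_rates_undefined_without_both_classes():
    ds = BinarizedDataset([1, 2], [1, 1], ["g1"], [[1], [0]])
    with pytest.raises(ValueError, match="class is absent"):
        boolean_rates(parse_classifier("(g1)"), ds)


def test_rates_consistent_with_error_counts():
    from mircircuit import count_errors
    rng = np.random.default_rng(1)
    for _ in range(50):
        n = int(rng.integers(4, 12))
        ann = np.zeros(n, int)
        ann[: int(rng.integers(1, n))] = 1
        rng.shuffle(ann)
        if ann.sum() in (0, n):
            continue
        ds = BinarizedDataset(range(n), ann, ["g1", "g2"],
                              rng.integers(0, 2, (n, 2)))
        c = parse_classifier("(g1 | g2)")
        e = count_errors(c, ds)
        fn_rate, fp_rate = boolean_rates(c, ds)
        assert fn_rate == e.fn / ds.n_positive
        assert fp_rate == e.fp / ds.n_negative


def test_half_up_rounding_convention():
    assert round_half_up(0.025) == 0.03
    assert round_half_up(3 / 11) == 0.27
    assert round_half_up(4 / 167) == 0.02


# ---------------------------------------------------------------------------
# circuit output model


def test_saturating_limits_reproduce_boolean_evaluation():
    steep = HillOutputModel(threshold=100.0, steepness=50.0)
    cfg = ScoringConfig(output_model=steep)
    act = parse_classifier("(g1)")
    rep = parse_classifier("(!g1)")
    high, low = {"g1": 1000.0}, {"g1": 10.0}
    assert circuit_output(act, high, cfg) == pytest.approx(1.0, abs=1e-3)
    assert circuit_output(act, low, cfg) == pytest.approx(0.0, abs=1e-3)
    assert circuit_output(rep, high, cfg) == pytest.approx(0.0, abs=1e-3)
    assert circuit_output(rep, low, cfg) == pytest.approx(1.0, abs=1e-3)


def test_output_strictly_positive():
    cfg = ScoringConfig(output_model=HillOutputModel(threshold=100))
    assert circuit_output(parse_classifier("(g1)"), {"g1": 0.0}, cfg) > 0


def test_two_gate_output_is_product_of_gate_activations():
    model = HillOutputModel(threshold=1.0, steepness=2.0, leak=0.0)
    cfg = ScoringConfig(output_model=model)
    c = parse_classifier("(g1 | g2) & (!g3)")
    x = {"g1": 2.0, "g2": 0.5, "g3": 1.5}
    h = lambda v: v**2 / (v**2 + 1.0)
    want = max(h(2.0), h(0.5)) * (1 - h(1.5))
    assert circuit_output(c, x, cfg) == pytest.approx(want)


def test_missing_marker_value_raises():
    cfg = ScoringConfig()
    with pytest.raises(KeyError, match="g2"):
        circuit_output(parse_classifier("(g2)"), {"g1": 1.0}, cfg)


# ---------------------------------------------------------------------------
# margins and S_m


def test_margins_direct_arithmetic():
    cds = outputs_dataset([4.0, 2.0], [1.0, 1.0])
    ma, mw = margins(ANY, cds, LOOKUP_CFG)
    assert ma == pytest.approx(3.0)   # mean 3 / mean 1
    assert mw == pytest.approx(2.0)   # min 2 / max 1


def test_equal_outputs_give_unit_margins_and_zero_log_margins():
    cds = outputs_dataset([5.0, 5.0], [5.0])
    ma, mw = margins(ANY, cds, LOOKUP_CFG)
    assert (ma, mw) == (1.0, 1.0)
    log_cfg = ScoringConfig(output_model=_LookupModel(),
                            margin_transform="log-ratio")
    ma, mw = margins(ANY, cds, log_cfg)
    assert ma == pytest.approx(0.0) and mw == pytest.approx(0.0)


@settings(max_examples=200, derandomize=True, deadline=None)
@given(seed=st.integers(0, 100_000))
def test_worst_margin_never_exceeds_average_margin(seed):
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0.01, 10.0, size=int(rng.integers(1, 6)))
    neg = rng.uniform(0.01, 10.0, size=int(rng.integers(1, 6)))
    ma, mw = margins(ANY, outputs_dataset(pos, neg), LOOKUP_CFG)
    assert mw <= ma + 1e-12


def test_s_m_is_exact_convex_combination():
    assert s_m(0.5, 0.1, 0.5) == pytest.approx(0.3)
    assert s_m(0.7, 0.2, 1.0) == 0.7
    assert s_m(0.7, 0.2, 0.0) == 0.2
    assert s_m(0.4, 0.4, 0.5) == pytest.approx(0.4)
    with pytest.raises(ValueError):
        s_m(1.0, 1.0, 1.5)


def test_s_m_monotone_in_both_margins():
    base = s_m(1.0, 0.5, 0.3)
    assert s_m(1.2, 0.5, 0.3) >= base
    assert s_m(1.0, 0.7, 0.3) >= base


# ---------------------------------------------------------------------------
# S_AUC


@pytest.mark.parametrize(
    "pos, neg, expected",
    [
        ([0.9, 0.8], [0.2, 0.1], 1.0),   # perfect separation
        ([0.5, 0.5], [0.5, 0.5], 0.5),   # constant outputs, midpoint ties
        ([0.9, 0.4], [0.5, 0.1], 0.75),  # 3 of 4 pairs concordant
    ],
)
def test_s_auc_reference_values(pos, neg, expected):
    cds = outputs_dataset(pos, neg)
    assert s_auc(ANY, cds, LOOKUP_CFG) == pytest.approx(expected)
    assert pairwise_auc(pos, neg) == pytest.approx(expected)


def test_s_auc_matches_pairwise_oracle_on_random_outputs():
    rng = np.random.default_rng(9)
    for _ in range(20):
        pos = rng.uniform(0, 1, size=int(rng.integers(1, 6))).round(1)
        neg = rng.uniform(0, 1, size=int(rng.integers(1, 6))).round(1)
        cds = outputs_dataset(pos, neg)
        assert s_auc(ANY, cds, LOOKUP_CFG) == pytest.approx(
            pairwise_auc(pos, neg))


def test_perfect_boolean_classifier_saturating_outputs_give_auc_one():
    # continuous profiles that binarize to a perfectly separated table
    cds = ContinuousDataset(
        [1, 2, 3, 4], [1, 1, 0, 0], ["g1"],
        [[900.0], [700.0], [20.0], [5.0]], threshold=250,
    )
    cfg = ScoringConfig(output_model=HillOutputModel(threshold=250,
                                                     steepness=20))
    assert s_auc(parse_classifier("(g1)"), cds, cfg) == 1.0


# ---------------------------------------------------------------------------
# ranking and reports


def test_ranking_prefers_higher_s_auc_then_higher_s_m():
    # emulate choosing between two optimal classifiers with equal AUC where
    # the higher S_m (0.25 over 0.24 style) wins, and a lower-AUC one sinks
    cds = ContinuousDataset(
        [1, 2, 3, 4], [1, 1, 0, 0], ["a", "b", "c"],
        [[9.0, 9.0, 1.0], [7.0, 8.0, 2.0], [1.0, 2.0, 8.0], [2.0, 1.0, 9.0]],
    )
    ds = BinarizedDataset([1, 2, 3, 4], [1, 1, 0, 0], ["a", "b", "c"],
                          [[1, 1, 0], [1, 1, 0], [0, 0, 1], [0, 0, 1]])
    cfg = ScoringConfig(output_model=HillOutputModel(threshold=5.0))
    sols = [parse_classifier("(c)"), parse_classifier("(a)"),
            parse_classifier("(b)")]
    ranked = rank_solutions(sols, cds, cfg, ds=ds)
    texts = [rep.classifier for _, rep in ranked]
    assert texts[-1] == "(c)"  # anti-correlated marker ranks last
    top_scores = [(rep.s_auc, rep.s_m) for _, rep in ranked]
    assert top_scores == sorted(top_scores, key=lambda t: (-t[0], -t[1]))


def test_ranking_tie_broken_by_canonical_text():
    cds = outputs_dataset([1.0, 1.0], [1.0])
    both = [parse_classifier("(out)"), parse_classifier("(out | out2)")]
    cds2 = ContinuousDataset(range(3), [1, 1, 0], ["out", "out2"],
                             [[1.0, 1.0]] * 3)
    ranked = rank_solutions(both, cds2, LOOKUP_CFG)
    assert [r.classifier for _, r in ranked] == ["(out | out2)", "(out)"]


def test_report_omits_continuous_scores_without_continuous_data(fig3_dataset):
    rep = score_classifier(parse_classifier("(g1 | g3) & !g2"), fig3_dataset)
    assert rep.s_auc is None and rep.s_m is None
    frame = report_frame([rep])
    assert frame.loc[0, "FN rate"] == 0.0
    assert frame.loc[0, "S_AUC"] is None or np.isnan(frame.loc[0, "S_AUC"])


def test_scoring_config_validates_lambda():
    with pytest.raises(ValueError, match="lambda"):
        ScoringConfig(lam=1.2)
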