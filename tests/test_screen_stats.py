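"""Plate normalization, UMVUE SSMD and two-tier gene calling."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from myoscreen import (
    HitThresholds,
    ScreenSimConfig,
    call_genes,
    compare_groups,
    control_qc,
    hits_to_amplicon_scores,
    load_reported_hits,
    normalize_plate,
    score_amplicons,
    simulate_screen,
    ssmd_umvue,
    summarize_calls,
)
from myoscreen.screen import ssmd_correction_factor


def wells_frame(rows):
    return pd.DataFrame(
        rows, columns=["plate_id", "well", "amplicon_id", "gene", "role", "index"]
    )


# --- normalization -------------------------------------------------------


def test_well_at_control_median_gets_zero():
    rows = [("P1", f"A{i:02d}", "lacZ_ctrl", "lacZ", "neg_ctrl", v)
            for i, v in enumerate([0.01, 0.02, 0.04], start=1)]
    rows.append(("P1", "B01", "x_1", "x", "sample", 0.02))
    out = normalize_plate(wells_frame(rows), min_neg_wells=3)
    assert out.loc[out.amplicon_id == "x_1", "d"].iloc[0] == pytest.approx(0.0)


def test_constant_plate_gives_all_zero_d():
    rows = [("P1", f"A{i:02d}", "lacZ_ctrl", "lacZ", "neg_ctrl", 0.05) for i in range(4)]
    rows += [("P1", f"B{i:02d}", f"g{i}_1", f"g{i}", "sample", 0.05) for i in range(6)]
    out = normalize_plate(wells_frame(rows))
    assert np.allclose(out["d"], 0.0)


def test_zero_index_epsilon_rule():
    rows = [("P1", f"A{i:02d}", "lacZ_ctrl", "lacZ", "neg_ctrl", 0.02) for i in range(4)]
    rows += [("P1", "B01", "z_1", "z", "sample", 0.0),
             ("P1", "B02", "y_1", "y", "sample", 0.004)]
    out = normalize_plate(wells_frame(rows))
    d_zero = out.loc[out.amplicon_id == "z_1", "d"].iloc[0]
    eps = 0.004 * 1e-3  # smallest positive index on the plate times 1e-3
    assert d_zero == pytest.approx(math.log(eps) - math.log(0.02))
    dropped = normalize_plate(wells_frame(rows), zero_policy="drop")
    assert "z_1" not in set(dropped.amplicon_id)


def test_plate_without_controls_rejected():
    good = [("P1", f"A{i:02d}", "lacZ_ctrl", "lacZ", "neg_ctrl", 0.02) for i in range(4)]
    good += [("P1", "B01", "x_1", "x", "sample", 0.03)]
    bad = [("P2", "B01", "x_1", "x", "sample", 0.03)]
    out = normalize_plate(wells_frame(good + bad))
    assert set(out.plate_id) == {"P1"}
    with pytest.raises(ValueError, match="negative-control"):
        normalize_plate(wells_frame(bad))


# --- SSMD ----------------------------------------------------------------


def test_ssmd_umvue_gamma_formula_example():
    """d=[1,2,3]: mean 2, sd 1, c(3)=1/sqrt(pi), score = 2/sqrt(pi)."""
    assert ssmd_umvue([1.0, 2.0, 3.0]) == pytest.approx(2 / math.sqrt(math.pi))
    assert ssmd_umvue([1.0, 2.0, 3.0]) == pytest.approx(1.1284, abs=1e-4)


def test_ssmd_zero_for_symmetric_differences():
    assert ssmd_umvue([-1.0, 0.0, 1.0]) == 0.0


def test_ssmd_error_paths():
    with pytest.raises(ValueError, match="insufficient"):
        ssmd_umvue([1.0, 2.0])
    with pytest.raises(ValueError, match="sign"):
        ssmd_umvue([-2.0, -2.0, -2.0])


def test_ssmd_umvue_is_unbiased(rng):
    """For d ~ N(beta*sigma, sigma^2) the estimator's mean is beta."""
    beta, sigma, n, reps = 1.0, 0.7, 4, 10_000
    d = rng.normal(beta * sigma, sigma, size=(reps, n))
    c = ssmd_correction_factor(n)
    est = c * d.mean(axis=1) / d.std(axis=1, ddof=1)
    se = est.std(ddof=1) / math.sqrt(reps)
    assert abs(est.mean() - beta) < 3 * se


def test_null_ssmd_follows_scaled_t(rng):
    """Under the null, score = c(n) * mean/sd ~ (c(n)/sqrt(n)) * t_{n-1};
    in particular the null law is independent of the noise scale."""
    n, reps = 3, 20_000
    for sigma in (0.02, 0.2):
        d = rng.normal(0.0, sigma, size=(reps, n))
        est = ssmd_correction_factor(n) * d.mean(axis=1) / d.std(axis=1, ddof=1)
        scale = ssmd_correction_factor(n) / math.sqrt(n)
        p = stats.kstest(est / scale, stats.t(df=n - 1).cdf).pvalue
        assert p > 1e-3


# --- amplicon scoring ----------------------------------------------------


def make_wells_with_d(entries):
    """entries: (amplicon, gene, role, plate, d)"""
    return pd.DataFrame(
        [
            {"plate_id": p, "well": f"W{i:02d}", "amplicon_id": a, "gene": g,
             "role": r, "index": 0.02, "d": d}
            for i, (a, g, r, p, d) in enumerate(entries)
        ]
    )


def test_score_amplicons_applies_umvue():
    wells = make_wells_with_d(
        [("a_1", "a", "sample", f"P{r}", float(r)) for r in (1, 2, 3)]
    )
    scores = score_amplicons(wells)
    assert scores.ssmd.iloc[0] == pytest.approx(2 / math.sqrt(math.pi))


def test_within_plate_duplicates_averaged_before_scoring():
    entries = [("a_1", "a", "sample", "P1", 0.0), ("a_1", "a", "sample", "P1", 2.0),
               ("a_1", "a", "sample", "P2", 2.0), ("a_1", "a", "sample", "P3", 3.0)]
    scores = score_amplicons(make_wells_with_d(entries))
    assert scores.n.iloc[0] == 3
    assert scores.ssmd.iloc[0] == pytest.approx(ssmd_umvue([1.0, 2.0, 3.0]))


def test_under_replicated_amplicon_excluded():
    entries = [("a_1", "a", "sample", "P1", 1.0), ("a_1", "a", "sample", "P2", 2.0)]
    scores = score_amplicons(make_wells_with_d(entries))
    assert len(scores) == 0


def test_noise_free_suppressor_scores_negative():
    cfg = ScreenSimConfig(
        gene_effect_map={"sup": 0.4, "null": 1.0}, wells_per_plate=96,
        n_neg_wells=8, n_pos_wells=4, sigma_plate=0.05, sigma_well=0.05, seed=3,
    )
    wells, _ = simulate_screen(cfg)
    scores = score_amplicons(normalize_plate(wells))
    sup = scores[scores.gene == "sup"]
    assert (sup.ssmd < 0).all()


def test_null_scores_balanced(rng):
    """theta = 1 amplicons score symmetrically around zero."""
    cfg = ScreenSimConfig(
        gene_effect_map={f"g{i:03d}": 1.0 for i in range(150)}, seed=17
    )
    wells, _ = simulate_screen(cfg)
    scores = score_amplicons(normalize_plate(wells))
    null = scores[scores.role == "sample"].ssmd.to_numpy()
    # sign balance within binomial noise
    pos_frac = (null > 0).mean()
    assert abs(pos_frac - 0.5) < 3 * math.sqrt(0.25 / null.size)


def test_strong_suppressor_control_scores_below_minus_one():
    """Atg18-like control (theta = 0.1) lands below -1 in >=95% of runs."""
    hits = 0
    n_runs = 40
    for seed in range(n_runs):
        cfg = ScreenSimConfig(
            gene_effect_map={f"g{i:02d}": 1.0 for i in range(30)},
            wells_per_plate=96, n_neg_wells=8, n_pos_wells=4,
            sigma_well=0.2, sigma_plate=0.1, pos_control_theta=0.1, seed=seed,
        )
        wells, _ = simulate_screen(cfg)
        scores = score_amplicons(normalize_plate(wells))
        ctrl = scores[scores.role == "pos_ctrl"].ssmd.iloc[0]
        hits += ctrl < -1.0
    assert hits / n_runs >= 0.95


# --- gene calling --------------------------------------------------------


def scores_frame(gene_scores):
    rows = []
    for gene, ss in gene_scores.items():
        for i, s in enumerate(ss):
            rows.append({"amplicon_id": f"{gene}_amp{i+1}", "gene": gene,
                         "role": "sample", "n": 3, "mean_d": s, "ssmd": s})
    return pd.DataFrame(rows)


@pytest.mark.parametrize(
    "scores, direction, tier",
    [
        ([-0.7, -0.6], "positive_regulator", "multi"),
        ([-1.2, 0.1], "positive_regulator", "single"),
        ([-1.2, 0.6], "none", "none"),
        ([0.55, 0.8, -0.2], "negative_regulator", "multi"),
        ([-0.5, -0.5], "positive_regulator", "multi"),  # ties count as passing
        ([1.0, 0.2], "negative_regulator", "single"),
        ([-0.4, 0.3], "none", "none"),
    ],
)
def test_two_tier_calling_rules(scores, direction, tier):
    calls = call_genes(scores_frame({"g": scores}))
    assert calls.direction.iloc[0] == direction
    assert calls.tier.iloc[0] == tier


def test_bidirectional_multi_flagged_ambiguous():
    calls = call_genes(scores_frame({"g": [-0.7, -0.6, 0.8, 0.9]}))
    assert calls.direction.iloc[0] == "none"
    assert bool(calls.ambiguous.iloc[0])


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    scores=st.lists(
        st.floats(min_value=-4, max_value=4, allow_nan=False), min_size=1, max_size=5
    ),
    seed=st.integers(0, 2**16),
)
def test_calling_is_permutation_invariant(scores, seed):
    base = call_genes(scores_frame({"g": scores}))
    shuffled = list(scores)
    np.random.default_rng(seed).shuffle(shuffled)
    perm = call_genes(scores_frame({"g": shuffled}))
    assert base.direction.iloc[0] == perm.direction.iloc[0]
    assert base.tier.iloc[0] == perm.tier.iloc[0]


@pytest.mark.parametrize(
    "scores, idx",
    [([-0.7, -0.6], 0), ([-1.2, 0.1], 0), ([0.55, 0.8, -0.2], 1)],
)
def test_extremizing_a_qualifying_score_keeps_the_hit(scores, idx):
    before = call_genes(scores_frame({"g": scores}))
    assert before.direction.iloc[0] != "none"
    extreme = list(scores)
    extreme[idx] = math.copysign(10.0, extreme[idx])
    after = call_genes(scores_frame({"g": extreme}))
    assert after.direction.iloc[0] == before.direction.iloc[0]


def test_summarize_empty_and_fixture():
    assert summarize_calls(pd.DataFrame()) == (0, 0, 0)
    hits = load_reported_hits()
    calls = call_genes(hits_to_amplicon_scores(hits))
    merged = calls.merge(hits, on="gene", suffixes=("_called", "_published"))
    # every packaged gene is reproduced at its published direction and tier
    expected = {"positive": "positive_regulator", "negative": "negative_regulator"}
    assert (merged.direction_called == merged.direction_published.map(expected)).all()
    assert (merged.tier_called == merged.tier_published).all()


def test_threshold_validation():
    with pytest.raises(ValueError):
        HitThresholds(multi_amplicon=1.0, single_amplicon=0.5).validate()


# --- group comparison ----------------------------------------------------


def test_t_test_identical_samples():
    assert compare_groups([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)


def test_t_test_separated_groups():
    a = [1.0, 2.0, 3.0]
    b = [101.0, 102.0, 103.0]
    assert compare_groups(a, b) < 1e-6


def test_t_test_matches_pooled_variance_formula():
    a, b = [1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0]
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
    t = (np.mean(a) - np.mean(b)) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * stats.t(df=na + nb - 2).sf(abs(t))
    assert compare_groups(a, b) == pytest.approx(p)


def test_t_test_error_paths():
    with pytest.raises(ValueError, match="two observations"):
        compare_groups([1.0], [1.0, 2.0])
    with pytest.raises(ValueError, match="pooled variance"):
        compare_groups([2.0, 2.0], [3.0, 3.0])


# --- QC ------------------------------------------------------------------


def test_control_qc_reports_both_roles():
    cfg = ScreenSimConfig(gene_effect_map={"a": 1.0}, wells_per_plate=96,
                          n_neg_wells=8, n_pos_wells=4, seed=5)
    wells, _ = simulate_screen(cfg)
    wells_d = normalize_plate(wells)
    scores = score_amplicons(wells_d)
    qc = control_qc(scores, wells_d)
    assert {"neg_ctrl", "pos_ctrl"} <= set(qc.role)
    amp = qc[(qc.level == "amplicon_score") & (qc.role == "pos_ctrl")]
    assert (amp["mean"] < -1).all()
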