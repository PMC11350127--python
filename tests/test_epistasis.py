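"""Staged backward elimination: OLS engine, marginality, sCSL analyses."""

import itertools

import numpy as np
import pytest

from cslmap import (
    CslGenotype,
    EffectModel,
    background_interaction,
    enumerate_panel,
    final_model,
    fit_linear,
    run_selection,
    scsl_main_effects,
    select_threeway,
    select_twoway,
    simulate_csl_trait,
)
from cslmap.epistasis import backward_eliminate, f_test_nested
from cslmap.panel import COL, LER, classify, design_matrix


def scsl_set(background, n=5):
    """The parent plus its n single-substitution lines."""
    base = 1 if background == COL else 0
    out = [CslGenotype.from_indicator([base] * n)]
    for k in range(n):
        bits = [base] * n
        bits[k] = 1 - base
        out.append(CslGenotype.from_indicator(bits))
    return out


# ---------------------------------------------------------------------------
# OLS engine
# ---------------------------------------------------------------------------

def test_fit_linear_exact_interpolation(panel5, rng):
    X = design_matrix(panel5, max_order=3)
    beta = rng.normal(size=X.shape[1])
    y = X.to_numpy() @ beta
    fit = fit_linear(np.repeat(y, 2), X.loc[X.index.repeat(2)])
    assert np.allclose(fit.params.to_numpy(), beta, atol=1e-9)
    assert fit.r2 == pytest.approx(1.0)


def test_fit_linear_intercept_only_is_mean(rng):
    y = rng.normal(size=40)
    import pandas as pd

    X = pd.DataFrame({"intercept": np.ones(40)})
    fit = fit_linear(y, X)
    assert fit.params["intercept"] == pytest.approx(y.mean(), abs=1e-12)


def test_fit_linear_matches_normal_equations_oracle(rng):
    """QR solution agrees with an independent normal-equation solve and
    with statsmodels OLS to high precision."""
    import pandas as pd
    import statsmodels.api as sm

    n, p = 60, 5
    A = rng.normal(size=(n, p))
    X = pd.DataFrame(A, columns=[f"x{i}" for i in range(p)])
    y = rng.normal(size=n)
    fit = fit_linear(y, X)
    beta_ne = np.linalg.solve(A.T @ A, A.T @ y)
    assert np.allclose(fit.params.to_numpy(), beta_ne, atol=1e-8)
    sm_fit = sm.OLS(y, A).fit()
    assert np.allclose(fit.params.to_numpy(), sm_fit.params, atol=1e-10)
    assert np.allclose(fit.se.to_numpy(), sm_fit.bse, atol=1e-10)
    assert np.allclose(fit.pvalues.to_numpy(), sm_fit.pvalues, atol=1e-10)


def test_fit_linear_rank_deficiency_names_columns(panel5):
    import pandas as pd

    X = design_matrix(panel5, max_order=1)
    X["Chr1_copy"] = X["Chr1"]
    with pytest.raises(np.linalg.LinAlgError, match="Chr1_copy"):
        fit_linear(np.zeros(len(X)), X)


def test_partial_f_matches_statsmodels(rng):
    import pandas as pd
    import statsmodels.api as sm

    n = 50
    A = rng.normal(size=(n, 3))
    y = rng.normal(size=n)
    Xs = pd.DataFrame(A[:, :2], columns=["a", "b"])
    Xf = pd.DataFrame(A, columns=["a", "b", "c"])
    F, p = f_test_nested(fit_linear(y, Xs), fit_linear(y, Xf))
    sm_fit = sm.OLS(y, A).fit()
    sm_small = sm.OLS(y, A[:, :2]).fit()
    F_sm, p_sm, _ = sm_fit.compare_f_test(sm_small)
    assert F == pytest.approx(F_sm, rel=1e-10)
    assert p == pytest.approx(p_sm, rel=1e-8)


# ---------------------------------------------------------------------------
# selection cascade
# ---------------------------------------------------------------------------

def test_noiseless_threeway_recovered_exactly(rng):
    model = EffectModel(mu=5.0, a=np.array([1, 0, 0, 0, 2.0]),
                        b={(1, 2): 1.0}, c={(1, 2, 5): 3.0}, sigma_e=0.0)
    y, geno = simulate_csl_trait(model, reps=4, rng=rng)
    S3, _ = select_threeway(y, geno)
    assert S3 == [(1, 2, 5)]


def test_marginality_forces_nested_twoway_terms(rng):
    """A selected three-way term protects its three two-way children even
    when the data contain no two-way signal."""
    model = EffectModel(mu=0.0, a=np.zeros(5), b={}, c={(1, 2, 5): 8.0},
                        sigma_e=2.0)
    y, geno = simulate_csl_trait(model, reps=12, rng=rng)
    S3, _ = select_threeway(y, geno)
    assert S3 == [(1, 2, 5)]
    S2, _ = select_twoway(y, geno, S3)
    assert {(1, 2), (1, 5), (2, 5)} <= set(S2)
    res = final_model(y, geno, S2, S3)
    assert res.satisfies_marginality()
    assert {1, 2, 5} <= set(res.mains)


def test_pure_noise_selects_intercept_only(rng):
    hits = 0
    for i in range(50):
        r = np.random.default_rng(3000 + i)
        y = r.normal(size=32 * 12)
        geno = [g for g in enumerate_panel(5) for _ in range(12)]
        res = run_selection(y, geno)
        hits += bool(res.mains or res.S2 or res.S3)
    assert hits <= 1  # <= 2% of null runs select anything


def test_noiseless_full_recovery_r2_one(rng):
    model = EffectModel(mu=10.0, a=np.array([1.0, -2.0, 0.0, 0.0, 0.5]),
                        b={(2, 5): 1.5}, c={}, sigma_e=0.0)
    y, geno = simulate_csl_trait(model, reps=4, rng=rng)
    res = run_selection(y, geno)
    assert set(res.mains) == {1, 2, 5}
    assert res.S2 == [(2, 5)]
    assert res.S3 == []
    assert res.r2_full == pytest.approx(1.0)


def test_r2_ordering_full_versus_main_only(rng):
    """The selected model never explains less than the main-effects model."""
    model = EffectModel.stem_length_default()
    y, geno = simulate_csl_trait(model, reps=12, rng=rng)
    res = run_selection(y, geno)
    assert res.r2_full >= res.r2_main_only


def test_class_means_match_observed_on_balanced_noiseless(rng):
    model = EffectModel(mu=0.0, a=np.zeros(5), c={(1, 2, 5): 10.0},
                        sigma_e=0.0)
    y, geno = simulate_csl_trait(model, reps=2, rng=rng)
    res = run_selection(y, geno)
    table = res.class_means["Chr1:Chr2:Chr5"]
    assert len(table) == 8
    top = table.loc[table["class"] == "Chr1^Col/Chr2^Col/Chr5^Col", "mean"]
    assert top.iloc[0] == pytest.approx(10.0, abs=1e-9)


def test_elimination_is_deterministic(rng):
    model = EffectModel(mu=0.0, a=np.zeros(5), sigma_e=1.0)
    y, geno = simulate_csl_trait(model, reps=6, rng=rng)
    res1 = run_selection(y.copy(), list(geno))
    res2 = run_selection(y.copy(), list(geno))
    assert res1.terms() == res2.terms()
    assert [s.dropped for s in res1.trace] == [s.dropped for s in res2.trace]


def test_adding_terms_never_decreases_r2(panel5, rng):
    y, geno = simulate_csl_trait(
        EffectModel(mu=0.0, a=rng.normal(size=5), sigma_e=1.0), reps=4,
        rng=rng,
    )
    X = design_matrix(geno, max_order=3)
    r2 = []
    for order in (1, 2, 3):
        Xo = design_matrix(geno, max_order=order)
        r2.append(fit_linear(y, Xo).r2)
    assert r2[0] <= r2[1] <= r2[2]


# ---------------------------------------------------------------------------
# sCSL analyses
# ---------------------------------------------------------------------------

def test_scsl_noiseless_additive_effects_exact(rng):
    geno_set = scsl_set(COL)
    model = EffectModel(mu=10.0, a=np.array([1.0, -2.0, 3.0, -4.0, 5.0]),
                        sigma_e=0.0)
    geno = [g for g in geno_set for _ in range(6)]
    y = np.array([model.value_from_indicator(g.indicator()) for g in geno])
    chroms, fit = scsl_main_effects(y, geno)
    assert chroms == [1, 2, 3, 4, 5]
    for k, a_k in enumerate(model.a, start=1):
        assert fit.params[f"Chr{k}"] == pytest.approx(a_k, abs=1e-9)


def test_scsl_rejects_mixed_backgrounds():
    mixed = scsl_set(COL)[1:3] + scsl_set(LER)[1:3]
    with pytest.raises(ValueError, match="mixed"):
        scsl_main_effects(np.zeros(len(mixed)), mixed)


def test_scsl_background_asymmetry_detectable(rng):
    """An effect present only in the Col background is selected there and
    absent from the reciprocal analysis."""

    def simulate(background, chrom_effect):
        geno = [g for g in scsl_set(background) for _ in range(12)]
        y = rng.normal(0.0, 1.0, size=len(geno))
        for i, g in enumerate(geno):
            cls = classify(g)
            if cls.label == "single_substitution":
                sub = int(np.flatnonzero(
                    g.indicator() != (1 if background == COL else 0)
                )[0]) + 1
                if sub == 4:
                    y[i] += chrom_effect * (1 if g.indicator()[3] else -1)
        return y, geno

    y_col, g_col = simulate(COL, 6.0)
    chroms_col, _ = scsl_main_effects(y_col, g_col)
    y_ler, g_ler = simulate(LER, 0.0)
    chroms_ler, _ = scsl_main_effects(y_ler, g_ler)
    assert 4 in chroms_col
    assert 4 not in chroms_ler


def test_background_interaction_null_is_unbiased(rng):
    """Under pure additivity the chromosome-by-background estimates cover 0."""
    geno_base = scsl_set(COL) + scsl_set(LER)
    model = EffectModel(mu=10.0, a=np.array([1.0, 2.0, -1.0, 0.5, 3.0]),
                        sigma_e=1.0)
    reps = 40
    geno = [g for g in geno_base for _ in range(reps)]
    y = np.array([model.value_from_indicator(g.indicator()) for g in geno])
    y = y + rng.normal(0.0, model.sigma_e, size=len(y))
    res = background_interaction(y, geno)
    for k in range(1, 6):
        name = f"Chr{k}:BG"
        if name in res.coef.index:
            lo = res.coef.loc[name, "ci_lo"]
            hi = res.coef.loc[name, "ci_hi"]
            assert lo < 0 < hi


def test_background_interaction_missing_reciprocal_named():
    geno = scsl_set(COL) + scsl_set(LER)
    # drop the Chr3-in-Ler-background sCSL
    geno = [
        g for g in geno
        if not (classify(g).background == LER and tuple(g.indicator()) ==
                (0, 0, 1, 0, 0))
    ]
    with pytest.raises(ValueError, match="Chr3.*Ler"):
        background_interaction(np.zeros(len(geno)), geno)


def test_background_interaction_detects_injected_term(rng):
    geno_base = scsl_set(COL) + scsl_set(LER)
    geno = [g for g in geno_base for _ in range(12)]
    sigma = 1.0
    y = rng.normal(0.0, sigma, size=len(geno))
    z = np.array([1.0 if classify(g).background == COL else 0.0 for g in geno])
    x5 = np.array([g.indicator()[4] for g in geno])
    y = y + 5.0 * sigma * x5 * z
    res = background_interaction(y, geno)
    assert 5 in res.selected_interactions


# ---------------------------------------------------------------------------
# stage-wise vs exhaustive selection
# ---------------------------------------------------------------------------

def brute_force_twoway_selection(y, geno, alpha):
    """Oracle: over all subsets of two-way terms (mains always included),
    the largest subset in which every member is significant; ties broken by
    residual sum of squares."""
    from cslmap.panel import interaction_term

    n = geno[0].n_chrom
    pairs = list(itertools.combinations(range(1, n + 1), 2))
    Xfull = design_matrix(geno, max_order=2)
    best = None
    for r in range(len(pairs), -1, -1):
        cands = []
        for sub in itertools.combinations(pairs, r):
            cols = ["intercept"] + [f"Chr{k}" for k in range(1, n + 1)] + [
                interaction_term(p) for p in sub
            ]
            fit = fit_linear(y, Xfull[cols])
            ok = all(
                fit.pvalues[interaction_term(p)] <= alpha for p in sub
            )
            if ok:
                cands.append((fit.rss, set(sub)))
        if cands:
            best = min(cands)[1]
            break
    return best


def test_backward_equals_exhaustive_on_small_panels():
    """Stage-wise backward elimination reaches the brute-force all-subsets
    selection on n=3 panels across 50 seeds."""
    alpha = 5e-5
    panel = enumerate_panel(3)
    agree = 0
    for seed in range(50):
        r = np.random.default_rng(seed)
        # truth: each two-way term either absent or strong
        b = {}
        for pair in itertools.combinations(range(1, 4), 2):
            if r.random() < 0.4:
                b[pair] = float(r.choice([-8.0, 8.0]))
        model = EffectModel(mu=0.0, a=r.normal(size=3), b=b, sigma_e=1.0)
        y, geno = simulate_csl_trait(model, reps=8, rng=r,
                                     genotypes=panel)
        S2, _ = select_twoway(y, geno, S3=[], alpha=alpha)
        oracle = brute_force_twoway_selection(y, geno, alpha)
        agree += set(S2) == oracle
    assert agree == 50
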