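"""Linkage mapping: predictors, Li-Ji thresholds, CIM, support intervals."""

import numpy as np
import pandas as pd
import pytest

from cslmap import (
    MarkerMap,
    RecombinantGenotype,
    cim_iterate,
    genetic_predictors,
    haldane_c,
    li_ji_meff,
    li_ji_threshold,
    nil_panel,
    nil_scan,
    ril_panel,
    ril_recomb,
    scan,
    simulate_ril_phenotypes,
    support_interval,
)
from cslmap.breeding import panel_to_frame
from cslmap.panel import COL, LER, CslGenotype


def two_marker_map(d, chrom=1):
    return MarkerMap(pd.DataFrame(
        {"marker": ["L", "R"], "chrom": [chrom, chrom], "cM": [0.0, d]}
    ))


def ril_conditional_oracle(gl, gr, dl, dr):
    """Enumerate the two-flank Markov chain: P(t=Col | left, right)."""
    rl = float(ril_recomb(haldane_c(dl)))
    rr = float(ril_recomb(haldane_c(dr)))
    num = 0.0
    den = 0.0
    for t in (0, 1):
        p = 0.5  # prior for the unobserved position; cancels in the ratio
        p *= (1 - rl) if t == gl else rl
        p *= (1 - rr) if t == gr else rr
        den += p
        if t == 1:
            num += p
    return num / den


def test_predictor_dosage_at_markers_is_observed(default_map, rng):
    rils = ril_panel(30, default_map, rng)
    pred = genetic_predictors(rils, default_map)
    frame = panel_to_frame(rils, default_map)
    marker_cols = pred.positions["is_marker"]
    assert marker_cols.all()  # default map already at 5 cM spacing
    obs = (frame.to_numpy() == COL).astype(float)
    # positions are sorted like the map for the default map
    assert np.array_equal(np.sort(pred.dosage, axis=0), np.sort(obs, axis=0))
    assert set(np.unique(pred.dosage)) <= {0.0, 1.0}


def test_predictor_midpoint_between_discordant_markers_is_half(rng):
    mm = two_marker_map(20.0)
    lines = [
        RecombinantGenotype("a", np.array([COL, LER])),
        RecombinantGenotype("b", np.array([LER, COL])),
    ]
    pred = genetic_predictors(lines, mm, step_cm=10.0)
    mid = pred.positions.index[~pred.positions["is_marker"]]
    assert len(mid) == 1
    assert np.allclose(pred.dosage[:, mid[0]], 0.5)


def test_predictor_matches_enumeration_oracle(rng):
    mm = two_marker_map(30.0)
    lines = [
        RecombinantGenotype("cc", np.array([COL, COL])),
        RecombinantGenotype("cl", np.array([COL, LER])),
        RecombinantGenotype("lc", np.array([LER, COL])),
        RecombinantGenotype("ll", np.array([LER, LER])),
    ]
    pred = genetic_predictors(lines, mm, step_cm=10.0)
    inner = np.flatnonzero(~pred.positions["is_marker"].to_numpy())
    for j in inner:
        cm = pred.positions["cM"].iloc[j]
        for i, (gl, gr) in enumerate([(1, 1), (1, 0), (0, 1), (0, 0)]):
            oracle = ril_conditional_oracle(gl, gr, cm, 30.0 - cm)
            assert pred.dosage[i, j] == pytest.approx(oracle / 1.0, abs=1e-10)


def test_predictor_monotone_between_discordant_flanks(rng):
    mm = two_marker_map(40.0)
    line = [RecombinantGenotype("x", np.array([COL, LER]))]
    pred = genetic_predictors(line, mm, step_cm=5.0)
    order = np.argsort(pred.positions["cM"].to_numpy())
    d = pred.dosage[0, order]
    assert d[0] == 1.0 and d[-1] == 0.0
    assert all(a >= b - 1e-12 for a, b in zip(d, d[1:]))


def test_li_ji_duplicate_markers_collapse_to_one(rng):
    x = rng.integers(0, 2, size=50).astype(float)
    dosage = np.column_stack([x, x])
    assert li_ji_meff(dosage, per_chrom=False) == pytest.approx(1.0, abs=1e-9)


def test_li_ji_independent_markers_count_fully(rng):
    """Orthogonal marker columns give M_eff = k exactly."""
    k = 6
    n = 2 ** k
    cols = [
        np.array([(i >> j) & 1 for i in range(n)], dtype=float)
        for j in range(k)
    ]
    dosage = np.column_stack(cols)
    assert li_ji_meff(dosage, per_chrom=False) == pytest.approx(k, abs=1e-9)


def test_li_ji_matches_independent_eigendecomposition(default_map, rng):
    from scipy import linalg

    rils = ril_panel(200, default_map, rng)
    pred = genetic_predictors(rils, default_map)
    chroms = pred.positions["chrom"].to_numpy()
    meff = li_ji_meff(pred.dosage, chrom=chroms)
    oracle = 0.0
    for c in np.unique(chroms):
        sub = pred.dosage[:, chroms == c]
        lam = linalg.eigh(np.corrcoef(sub, rowvar=False),
                          eigvals_only=True)
        lam = np.clip(lam, 0, None)
        oracle += np.sum((lam >= 1) + (lam - np.floor(lam)))
    assert meff == pytest.approx(oracle, abs=1e-8)


def test_li_ji_bounds_and_correlation_monotonicity(rng):
    """M_eff never exceeds the marker count and shrinks as maps densify."""
    meffs = []
    for step in (20.0, 10.0, 5.0):
        mm = MarkerMap.default(n_chrom=2, step_cm=step)
        rils = ril_panel(300, mm, np.random.default_rng(11))
        pred = genetic_predictors(rils, mm, step_cm=step)
        m = li_ji_meff(pred.dosage, pred.positions["chrom"].to_numpy())
        assert m <= pred.dosage.shape[1]
        meffs.append(m / pred.dosage.shape[1])
    assert meffs[0] >= meffs[1] >= meffs[2]


def test_li_ji_constant_column_dropped_with_warning(rng):
    x = rng.integers(0, 2, size=40).astype(float)
    dosage = np.column_stack([x, np.ones(40), rng.integers(0, 2, 40)])
    with pytest.warns(UserWarning, match="constant"):
        li_ji_meff(dosage, per_chrom=False)


def test_scan_noiseless_marker_phenotype_peaks_at_marker(default_map, rng):
    rils = ril_panel(80, default_map, rng)
    pred = genetic_predictors(rils, default_map)
    target = 30  # arbitrary predictor column
    pheno = pd.Series(pred.dosage[:, target],
                      index=[l.line_id for l in rils])
    profile = scan(pheno, pred)
    peak = profile["minus_log10_p"].idxmax()
    assert profile["chrom"].iloc[peak] == pred.positions["chrom"].iloc[target]
    assert profile["cM"].iloc[peak] == pred.positions["cM"].iloc[target]
    assert profile["minus_log10_p"].iloc[peak] > 50


def test_scan_profile_translation_and_scale_behaviour(default_map, rng):
    rils = ril_panel(60, default_map, rng)
    pred = genetic_predictors(rils, default_map)
    y = simulate_ril_phenotypes(rils, default_map, [(2, 40.0, 2.0)],
                                sigma_e=1.0, rng=rng)
    p0 = scan(y, pred)
    p_shift = scan(y + 50.0, pred)
    assert np.allclose(p0["minus_log10_p"], p_shift["minus_log10_p"],
                       atol=1e-9)
    p_scale = scan(y * 3.0, pred)
    assert np.allclose(p0["minus_log10_p"], p_scale["minus_log10_p"],
                       atol=1e-9)
    assert np.allclose(p_scale["beta"], 3.0 * p0["beta"], atol=1e-9)


def test_support_interval_triangular_geometry():
    cms = np.arange(0.0, 21.0)
    values = 10.0 - np.abs(cms - 10.0)  # slope 1 per cM, peak at 10
    lo, hi = support_interval(cms, values, peak_index=10, drop=2.0)
    assert (lo, hi) == (8.0, 12.0)


def test_support_interval_flat_profile_spans_chromosome():
    cms = np.linspace(0, 80, 17)
    values = np.full(17, 5.0)
    lo, hi = support_interval(cms, values, peak_index=8, drop=2.0)
    assert (lo, hi) == (0.0, 80.0)


def test_cim_single_qtl_stable_after_one_round(default_map, rng):
    rils = ril_panel(100, default_map, rng)
    pred = genetic_predictors(rils, default_map)
    y = simulate_ril_phenotypes(rils, default_map, [(3, 50.0, 2.0)],
                                sigma_e=1.0, rng=rng)
    res = cim_iterate(y, pred, marker_map=default_map)
    assert res.stable
    assert len(res.qtls) == 1
    assert res.qtls["chrom"].iloc[0] == 3
    assert abs(res.qtls["peak_cM"].iloc[0] - 50.0) <= 10.0
    assert res.qtls["sign"].iloc[0] == "+Col"
    lo, hi = res.qtls[["si_left_cM", "si_right_cM"]].iloc[0]
    assert lo <= 50.0 <= hi


def test_cim_two_unlinked_qtls_found_order_invariant(default_map, rng):
    rils = ril_panel(150, default_map, rng)
    pred = genetic_predictors(rils, default_map)
    qtls = [(1, 30.0, 2.0), (4, 60.0, 2.0)]
    y = simulate_ril_phenotypes(rils, default_map, qtls, sigma_e=1.0, rng=rng)
    res_a = cim_iterate(y, pred, marker_map=default_map)
    found = sorted(zip(res_a.qtls["chrom"], res_a.qtls["peak_cM"]))
    assert [c for c, _ in found] == [1, 4]
    for (chrom, cm), (tc, tcm, _) in zip(found, qtls):
        assert chrom == tc and abs(cm - tcm) <= 10.0
    # the scan is invariant to the order cofactors are supplied in
    p_ab = scan(y, pred, cofactors=found)
    p_ba = scan(y, pred, cofactors=found[::-1])
    assert np.allclose(p_ab["minus_log10_p"], p_ba["minus_log10_p"],
                       atol=1e-9)


def test_cim_null_data_returns_no_qtls(default_map, rng):
    rils = ril_panel(100, default_map, rng)
    pred = genetic_predictors(rils, default_map)
    y = pd.Series(rng.normal(size=100), index=[l.line_id for l in rils])
    res = cim_iterate(y, pred, marker_map=default_map)
    assert len(res.qtls) == 0


def test_cim_rejects_cofactor_off_grid(default_map, rng):
    rils = ril_panel(40, default_map, rng)
    pred = genetic_predictors(rils, default_map)
    y = pd.Series(rng.normal(size=40), index=[l.line_id for l in rils])
    with pytest.raises(ValueError, match="cofactor"):
        scan(y, pred, cofactors=[(1, 3.33)])


def test_nil_scan_sign_flips_between_reciprocal_backgrounds(default_map, rng):
    col_parent = CslGenotype((COL,) * 5)
    ler_parent = CslGenotype((LER,) * 5)
    scsl_col_bg = CslGenotype((COL, COL, COL, COL, LER))
    scsl_ler_bg = CslGenotype((LER, LER, LER, LER, COL))
    panels = {
        "Col": nil_panel(scsl_col_bg, col_parent, 60, default_map, rng),
        "Ler": nil_panel(scsl_ler_bg, ler_parent, 60, default_map, rng),
    }
    idx5 = default_map.marker_index(5)
    cms5 = default_map.frame["cM"].to_numpy()[idx5]
    j45 = idx5[int(np.argmin(np.abs(cms5 - 45.0)))]
    phenos = {}
    for bg, panel in panels.items():
        dos = np.array([l.dosage()[j45] for l in panel])
        effect = 4.0 if bg == "Col" else -4.0
        y = effect * dos + rng.normal(0, 1.0, size=len(panel))
        phenos[bg] = pd.Series(y, index=[l.line_id for l in panel])
    table = nil_scan(panels, phenos, default_map, target_chrom=5)
    at_peak = table[np.isclose(table["cM"], 45.0)]
    eff = at_peak.set_index("background")["effect"]
    assert eff["Col"] > 0 > eff["Ler"]
    # support interval covers the causal position in both backgrounds
    for bg in ("Col", "Ler"):
        row = table[table["background"] == bg].iloc[0]
        assert row["si_left_cM"] <= 45.0 <= row["si_right_cM"]


def test_nil_scan_flags_monomorphic_markers(default_map, rng):
    parent = CslGenotype((COL,) * 5)
    scsl = CslGenotype((COL, COL, COL, COL, LER))
    panel = nil_panel(scsl, parent, 40, default_map, rng)
    # chromosome 1 is monomorphic in this panel by construction
    pheno = pd.Series(rng.normal(size=40), index=[l.line_id for l in panel])
    table = nil_scan({"Col": panel}, {"Col": pheno}, default_map,
                     target_chrom=1)
    assert not table["tested"].any()


def test_csl_panel_beats_matched_ril_panel_in_power(default_map):
    """With matched plant numbers (32x12 vs 100x3-replicate means) and a
    moderate single-chromosome effect, the CSL main-effect test detects the
    chromosome more often than the genome-wide RIL scan."""
    from cslmap import EffectModel, enumerate_panel, simulate_csl_trait
    from cslmap.epistasis import fit_linear
    from cslmap.panel import design_matrix

    effect, sigma = 0.5, 1.0
    csl_hits = ril_hits = 0
    n_pairs = 200
    panel = enumerate_panel(5)
    Xcsl = design_matrix([g for g in panel for _ in range(12)], max_order=1)
    alpha_csl = 0.05 / 5
    for i in range(n_pairs):
        r = np.random.default_rng(7000 + i)
        model = EffectModel(mu=0.0, a=np.array([0, 0, effect, 0, 0.0]),
                            sigma_e=sigma)
        y, geno = simulate_csl_trait(model, reps=12, rng=r)
        fit = fit_linear(y, Xcsl)
        csl_hits += fit.pvalues["Chr3"] <= alpha_csl
        rils = ril_panel(100, default_map, r)
        pred = genetic_predictors(rils, default_map)
        yr = simulate_ril_phenotypes(
            rils, default_map, [(3, 50.0, effect)],
            sigma_e=sigma / np.sqrt(3), rng=r,
        )
        _, thr = li_ji_threshold(
            pred.dosage, pred.positions["chrom"].to_numpy()
        )
        profile = scan(yr, pred)
        ril_hits += profile["minus_log10_p"].max() >= thr
    assert csl_hits > ril_hits
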