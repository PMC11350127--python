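"""Full-factorial epistasis decomposition for complete CSL panels.

The complete panel of ``2**n`` chromosome substitution lines supports the
saturated-to-order-3 linear model

    y_ir = mu + sum_k a_k x_ik + sum_{k<l} b_kl x_ik x_il
              + sum_{k<l<m} c_klm x_ik x_il x_im + e_ir

fitted to plant-level (spatially corrected) trait values with 0/1 indicator
coding.  Model selection is a staged backward elimination: first the
three-way interactions are pruned against a stringent per-term threshold
(default alpha = 5e-5, correcting for the ten candidate terms), then the
two-way interactions not protected by a surviving three-way term (same
threshold), then unprotected main effects.  The marginality principle is
enforced throughout: any term nested under a selected higher-order
interaction is retained regardless of its own p-value.

For the single-substitution subsets the module provides the per-background
main-effect analysis (``scsl_main_effects``) and the chromosome-by-background
interaction model

    y_ir = mu + sum_k a_k x_ik + b z_i + sum_k c_k x_ik z_i + e_ir

(``background_interaction``), with z the recurrent-background indicator and
a default threshold alpha = 1e-3 over the five candidate interaction terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .panel import (
    COL,
    LER,
    PARENTAL,
    SINGLE_SUBSTITUTION,
    CslGenotype,
    classify,
    design_matrix,
    interaction_term,
    main_term,
    term_indices,
)

ALPHA_THREEWAY = 5e-5
ALPHA_TWOWAY = 5e-5
ALPHA_BACKGROUND = 1e-3


@dataclass
class FitResult:
    """Ordinary least squares fit of one model."""

    params: pd.Series
    se: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    cov_params: pd.DataFrame
    rss: float
    sigma2: float
    df_resid: int
    loglik: float
    r2: float
    nobs: int


def fit_linear(y: np.ndarray, X: pd.DataFrame) -> FitResult:
    """OLS fit with exact-arithmetic guarantees on full-rank designs.

    Uses the QR/lstsq orthogonal decomposition; raises on rank deficiency,
    naming the collinear columns so the caller can see which term is
    inestimable on its panel.
    """
    y = np.asarray(y, dtype=float)
    A = X.to_numpy(dtype=float)
    n, p = A.shape
    if len(y) != n:
        raise ValueError(f"y has {len(y)} rows, X has {n}")
    q, r = np.linalg.qr(A)
    diag = np.abs(np.diag(r))
    tol = max(n, p) * np.finfo(float).eps * (diag.max() if p else 1.0)
    if p and (diag < tol).any():
        bad = [X.columns[i] for i in np.flatnonzero(diag < tol)]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient; collinear columns: {bad}"
        )
    beta = np.linalg.solve(r, q.T @ y)
    fitted = A @ beta
    resid = y - fitted
    rss = float(resid @ resid)
    df_resid = n - p
    sigma2 = rss / df_resid if df_resid > 0 else np.nan
    rinv = np.linalg.inv(r)
    xtx_inv = rinv @ rinv.T
    cov = sigma2 * xtx_inv if df_resid > 0 else np.full((p, p), np.nan)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = (
        2.0 * stats.t.sf(np.abs(tvals), df_resid)
        if df_resid > 0
        else np.full(p, np.nan)
    )
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    # gaussian log-likelihood at the MLE variance rss/n
    loglik = (
        -0.5 * n * (np.log(2 * np.pi * rss / n) + 1.0) if rss > 0 else np.inf
    )
    idx = X.columns
    return FitResult(
        params=pd.Series(beta, index=idx),
        se=pd.Series(se, index=idx),
        tvalues=pd.Series(tvals, index=idx),
        pvalues=pd.Series(pvals, index=idx),
        cov_params=pd.DataFrame(cov, index=idx, columns=idx),
        rss=rss,
        sigma2=sigma2,
        df_resid=df_resid,
        loglik=float(loglik),
        r2=r2,
        nobs=n,
    )


def f_test_nested(fit_small: FitResult, fit_full: FitResult) -> tuple[float, float]:
    """Partial F-test of a nested model pair; returns (F, p)."""
    df_num = fit_small.df_resid - fit_full.df_resid
    if df_num <= 0:
        raise ValueError("models are not strictly nested")
    if fit_full.rss <= 0:
        return np.inf, 0.0
    F = ((fit_small.rss - fit_full.rss) / df_num) / (
        fit_full.rss / fit_full.df_resid
    )
    p = float(stats.f.sf(F, df_num, fit_full.df_resid))
    return float(F), p


@dataclass
class EliminationStep:
    dropped: str
    pvalue: float
    tvalue: float


def backward_eliminate(
    y: np.ndarray,
    X: pd.DataFrame,
    candidates: Sequence[str],
    alpha: float,
    protected: Sequence[str] = (),
) -> tuple[list[str], FitResult, list[EliminationStep]]:
    """Backward elimination of single-column terms by partial F (= t^2) test.

    Starting from the full design ``X``, repeatedly drop the least
    significant candidate term (largest p-value above ``alpha``), refit and
    repeat.  ``protected`` columns are never tested or dropped.  Ties on
    p-value are broken toward keeping the larger ``|t|``, then by reverse
    lexicographic name — the elimination path is fully deterministic.

    For a single-column term the drop-one partial F equals the squared
    t-statistic, so the t-test p-value is used directly.
    """
    X = X.copy()
    current = [c for c in candidates if c in X.columns]
    trace: list[EliminationStep] = []
    while True:
        fit = fit_linear(y, X)
        testable = [c for c in current if c not in protected]
        if not testable:
            break
        pv = fit.pvalues[testable]
        tv = fit.tvalues[testable].abs()
        order = sorted(
            testable, key=lambda c: (-pv[c], tv[c], tuple(-ord(ch) for ch in c))
        )
        worst = order[0]
        if pv[worst] <= alpha or not np.isfinite(pv[worst]):
            if np.isfinite(pv[worst]):
                break
            # non-finite p (saturated fit): treat as perfectly significant
            break
        trace.append(
            EliminationStep(worst, float(pv[worst]), float(fit.tvalues[worst]))
        )
        X = X.drop(columns=[worst])
        current.remove(worst)
    return current, fit, trace


def _nested_twoway(S3: Sequence[tuple[int, int, int]]) -> set[tuple[int, int]]:
    out: set[tuple[int, int]] = set()
    for (k, l, m) in S3:
        out.update({(k, l), (k, m), (l, m)})
    return out


def _nested_main(
    S2: Sequence[tuple[int, int]], S3: Sequence[tuple[int, int, int]]
) -> set[int]:
    out: set[int] = set()
    for t in list(S2) + list(S3):
        out.update(t)
    return out


def select_threeway(
    y: np.ndarray,
    genotypes: Sequence[CslGenotype],
    alpha: float = ALPHA_THREEWAY,
) -> tuple[list[tuple[int, int, int]], list[EliminationStep]]:
    """Stage 1: backward-eliminate three-way interactions.

    Starting from the saturated-to-order-3 model, three-way terms with
    partial-F p-value above ``alpha`` are dropped one at a time (refitting
    after each drop) until all survivors meet the threshold.  Returns the
    surviving index triples ``S_3`` (possibly empty).
    """
    X = design_matrix(genotypes, max_order=3)
    three = [c for c in X.columns if len(term_indices(c)) == 3]
    lower = [c for c in X.columns if len(term_indices(c)) < 3]
    surviving, _, trace = backward_eliminate(
        y, X, candidates=three, alpha=alpha, protected=lower
    )
    return sorted(term_indices(c) for c in surviving), trace


def select_twoway(
    y: np.ndarray,
    genotypes: Sequence[CslGenotype],
    S3: Sequence[tuple[int, int, int]],
    alpha: float = ALPHA_TWOWAY,
) -> tuple[list[tuple[int, int]], list[EliminationStep]]:
    """Stage 2: backward-eliminate unprotected two-way interactions.

    Two-way terms nested under a surviving three-way interaction are kept
    unconditionally (marginality); the rest are eliminated against
    ``alpha``.  Returns ``S_2`` including the protected terms.
    """
    X = design_matrix(genotypes, max_order=3)
    keep3 = {interaction_term(t) for t in S3}
    X = X.drop(columns=[c for c in X.columns
                        if len(term_indices(c)) == 3 and c not in keep3])
    protected_pairs = _nested_twoway(S3)
    two = [c for c in X.columns if len(term_indices(c)) == 2]
    protected = [c for c in X.columns if c not in two] + [
        c for c in two if term_indices(c) in protected_pairs
    ]
    candidates = [c for c in two if term_indices(c) not in protected_pairs]
    surviving, _, trace = backward_eliminate(
        y, X, candidates=candidates, alpha=alpha, protected=protected
    )
    S2 = sorted(
        set(term_indices(c) for c in surviving) | protected_pairs
    )
    return S2, trace


@dataclass
class SelectionResult:
    """Final selected model of the staged decomposition."""

    mains: list[int]
    S2: list[tuple[int, int]]
    S3: list[tuple[int, int, int]]
    coef: pd.DataFrame
    r2_full: float
    r2_main_only: float
    overall_F: float
    overall_p: float
    class_means: dict[str, pd.DataFrame] = field(default_factory=dict)
    trace: list[EliminationStep] = field(default_factory=list)
    fit: FitResult | None = None

    def terms(self) -> list[str]:
        return (
            [main_term(k) for k in self.mains]
            + [interaction_term(t) for t in self.S2]
            + [interaction_term(t) for t in self.S3]
        )

    def satisfies_marginality(self) -> bool:
        mains = set(self.mains)
        s2 = set(self.S2)
        for (k, l, m) in self.S3:
            if not {(k, l), (k, m), (l, m)} <= s2:
                return False
            if not {k, l, m} <= mains:
                return False
        for (k, l) in self.S2:
            if not {k, l} <= mains:
                return False
        return True


def _class_mean_table(
    fit: FitResult,
    X: pd.DataFrame,
    genotypes: Sequence[CslGenotype],
    idx: tuple[int, ...],
) -> pd.DataFrame:
    """Model-predicted means of the genotypic classes of an interaction.

    Each class (a corner of the involved chromosomes' 0/1 cube) is predicted
    at the average design row of the panel genotypes in that class, with a
    delta-method 95% confidence interval.
    """
    A = X.to_numpy(dtype=float)
    xs = np.stack([g.indicator() for g in genotypes])
    keys = [tuple(int(v) for v in row[[k - 1 for k in idx]]) for row in xs]
    rows = []
    for corner in sorted(set(keys)):
        mask = np.array([k == corner for k in keys])
        xrow = A[mask].mean(axis=0)
        pred = float(xrow @ fit.params.to_numpy())
        var = float(xrow @ fit.cov_params.to_numpy() @ xrow)
        halfw = stats.t.ppf(0.975, fit.df_resid) * np.sqrt(max(var, 0.0))
        label = "/".join(
            f"Chr{k}^{COL if v else LER}" for k, v in zip(idx, corner)
        )
        rows.append(
            {"class": label, "mean": pred, "ci_lo": pred - halfw,
             "ci_hi": pred + halfw, "n_genotypes": int(mask.sum())}
        )
    return pd.DataFrame(rows)


def final_model(
    y: np.ndarray,
    genotypes: Sequence[CslGenotype],
    S2: Sequence[tuple[int, int]],
    S3: Sequence[tuple[int, int, int]],
    alpha: float = ALPHA_TWOWAY,
) -> SelectionResult:
    """Stage 3: prune unprotected main effects and report the final model.

    Fits mean + mains + ``S2`` + ``S3``, drops main effects not nested under
    any selected interaction when their p-value exceeds ``alpha``, tests the
    final model against the intercept-only model with an overall F-test, and
    emits coefficients with 95% CIs plus predicted class means for every
    selected interaction (effect-plot data).
    """
    S2 = sorted(tuple(t) for t in S2)
    S3 = sorted(tuple(t) for t in S3)
    n_chrom = genotypes[0].n_chrom
    Xfull = design_matrix(genotypes, max_order=3)
    keep = (
        ["intercept"]
        + [main_term(k) for k in range(1, n_chrom + 1)]
        + [interaction_term(t) for t in S2]
        + [interaction_term(t) for t in S3]
    )
    X = Xfull[keep]
    protected_mains = _nested_main(S2, S3)
    main_cols = [main_term(k) for k in range(1, n_chrom + 1)]
    candidates = [
        main_term(k)
        for k in range(1, n_chrom + 1)
        if k not in protected_mains
    ]
    protected = [c for c in X.columns if c not in candidates]
    surviving_mains, fit, trace = backward_eliminate(
        y, X, candidates=candidates, alpha=alpha, protected=protected
    )
    mains = sorted(
        set(protected_mains)
        | {term_indices(c)[0] for c in surviving_mains}
    )
    final_cols = (
        ["intercept"]
        + [main_term(k) for k in mains]
        + [interaction_term(t) for t in S2]
        + [interaction_term(t) for t in S3]
    )
    Xf = Xfull[final_cols]
    fit = fit_linear(y, Xf)
    null_fit = fit_linear(y, Xfull[["intercept"]])
    if len(final_cols) > 1:
        overall_F, overall_p = f_test_nested(null_fit, fit)
    else:
        overall_F, overall_p = 0.0, 1.0
    main_fit = fit_linear(
        y, Xfull[["intercept"] + main_cols]
    )
    halfw = stats.t.ppf(0.975, fit.df_resid) * fit.se
    coef = pd.DataFrame(
        {
            "estimate": fit.params,
            "se": fit.se,
            "ci_lo": fit.params - halfw,
            "ci_hi": fit.params + halfw,
            "t": fit.tvalues,
            "p": fit.pvalues,
        }
    )
    class_means = {}
    for t in list(S2) + list(S3):
        name = interaction_term(t)
        class_means[name] = _class_mean_table(fit, Xf, genotypes, t)
    return SelectionResult(
        mains=mains,
        S2=list(S2),
        S3=list(S3),
        coef=coef,
        r2_full=fit.r2,
        r2_main_only=main_fit.r2,
        overall_F=overall_F,
        overall_p=overall_p,
        class_means=class_means,
        trace=trace,
        fit=fit,
    )


def run_selection(
    y: np.ndarray,
    genotypes: Sequence[CslGenotype],
    alpha3: float = ALPHA_THREEWAY,
    alpha2: float = ALPHA_TWOWAY,
) -> SelectionResult:
    """Run the full three-stage cascade on plant-level values."""
    S3, t3 = select_threeway(y, genotypes, alpha=alpha3)
    S2, t2 = select_twoway(y, genotypes, S3, alpha=alpha2)
    result = final_model(y, genotypes, S2, S3, alpha=alpha2)
    result.trace = t3 + t2 + result.trace
    return result


def scsl_main_effects(
    y: np.ndarray,
    genotypes: Sequence[CslGenotype],
    alpha: float = ALPHA_BACKGROUND,
) -> tuple[list[int], FitResult]:
    """Main-effects analysis of one background's sCSL set plus its parent.

    Input lines must all share one recurrent background (the parent plus its
    single-substitution lines).  Chromosome main effects are backward
    eliminated against ``alpha``; surviving chromosomes and their effect
    sizes are returned.
    """
    genotypes = list(genotypes)
    backgrounds = set()
    for g in genotypes:
        cls = classify(g)
        if cls.label not in (PARENTAL, SINGLE_SUBSTITUTION):
            raise ValueError(
                f"{g} is not a parent or single-substitution line"
            )
        if cls.label == SINGLE_SUBSTITUTION:
            backgrounds.add(cls.background)
    if len(backgrounds) > 1:
        raise ValueError(
            f"mixed recurrent backgrounds in input: {sorted(backgrounds)}"
        )
    X = design_matrix(genotypes, max_order=1)
    candidates = [c for c in X.columns if c != "intercept"]
    surviving, fit, _ = backward_eliminate(
        y, X, candidates=candidates, alpha=alpha, protected=["intercept"]
    )
    chroms = sorted(term_indices(c)[0] for c in surviving)
    return chroms, fit


@dataclass
class BackgroundResult:
    """Chromosome-by-background model on the full reciprocal sCSL set."""

    selected_interactions: list[int]
    coef: pd.DataFrame
    fit: FitResult
    background_effect: float


def background_interaction(
    y: np.ndarray,
    genotypes: Sequence[CslGenotype],
    alpha: float = ALPHA_BACKGROUND,
) -> BackgroundResult:
    """Test chromosome x recurrent-background interactions on all sCSLs.

    The input must contain both parents and all ``2 n`` reciprocal
    single-substitution lines (each chromosome substituted in each
    background).  Fits mean + chromosome mains + background + chromosome:background
    products and backward-eliminates the interaction terms at ``alpha``;
    main effects and the background term are retained per marginality.
    """
    genotypes = list(genotypes)
    n_chrom = genotypes[0].n_chrom
    seen: dict[tuple[str, int], bool] = {}
    for g in genotypes:
        cls = classify(g)
        if cls.label == SINGLE_SUBSTITUTION:
            sub = int(np.flatnonzero(
                g.indicator() != (0 if cls.background == LER else 1)
            )[0]) + 1
            seen[(cls.background, sub)] = True
        elif cls.label != PARENTAL:
            raise ValueError(f"{g} is not a parent or single-substitution line")
    missing = [
        (bg, k)
        for bg in (LER, COL)
        for k in range(1, n_chrom + 1)
        if (bg, k) not in seen
    ]
    if missing:
        raise ValueError(
            "missing reciprocal sCSLs: "
            + ", ".join(f"Chr{k} substituted in {bg} background"
                        for bg, k in missing)
        )
    z = np.array(
        [1.0 if classify(g).background == COL else 0.0 for g in genotypes]
    )
    X = design_matrix(genotypes, max_order=1)
    X["BG"] = z
    inter_cols = []
    for k in range(1, n_chrom + 1):
        name = f"{main_term(k)}:BG"
        X[name] = X[main_term(k)] * z
        inter_cols.append(name)
    protected = [c for c in X.columns if c not in inter_cols]
    surviving, fit, _ = backward_eliminate(
        y, X, candidates=inter_cols, alpha=alpha, protected=protected
    )
    halfw = stats.t.ppf(0.975, fit.df_resid) * fit.se
    coef = pd.DataFrame(
        {
            "estimate": fit.params,
            "se": fit.se,
            "ci_lo": fit.params - halfw,
            "ci_hi": fit.params + halfw,
            "t": fit.tvalues,
            "p": fit.pvalues,
        }
    )
    selected = sorted(int(c.split(":")[0][3:]) for c in surviving)
    return BackgroundResult(
        selected_interactions=selected,
        coef=coef,
        fit=fit,
        background_effect=float(fit.params["BG"]),
    )
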