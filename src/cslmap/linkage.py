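"""Linkage mapping for RIL and NIL comparison populations.

Implements Haley--Knott-style regression composite interval mapping (CIM)
on genotype-level trait values: genetic predictors (expected Col-allele
dosages) are evaluated on a grid no coarser than 5 cM, each position is
tested by regressing the phenotype on its dosage plus cofactor dosages
(cofactors within a 50 cM window of the tested position are excluded), and
QTLs above a Li--Ji genome-wide threshold are added as cofactors until the
QTL set stabilises, respecting a 30 cM minimum separation.  Support
intervals are the region within a 2-unit drop of the -log10(p) peak,
analogous to a 2-LOD interval.

NIL panels recombinant on a single chromosome are fine-mapped per marker
within each recurrent background, producing heatmap-ready effect/significance
tables and the same drop-2 support intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .breeding import (
    MarkerMap,
    RecombinantGenotype,
    haldane_c,
    panel_to_frame,
    ril_recomb,
)

STEP_CM = 5.0
COFACTOR_WINDOW_CM = 50.0
MIN_SEPARATION_CM = 30.0
SUPPORT_DROP = 2.0
ALPHA_GENOMEWIDE = 0.05


@dataclass
class GeneticPredictors:
    """Expected allele dosages on an evaluation grid.

    ``positions`` has columns ``chrom, cM, is_marker``; ``dosage`` is the
    matching lines x positions matrix of expected Col dosages in [0, 1]
    (exactly 0/1 at genotyped markers).
    """

    positions: pd.DataFrame
    dosage: np.ndarray
    line_ids: list[str]

    def chrom_columns(self, chrom: int) -> np.ndarray:
        return np.flatnonzero((self.positions["chrom"] == chrom).to_numpy())


def _transition(g: np.ndarray, r: float) -> np.ndarray:
    """P(next = Col) for current dosage-coded genotype g under flip prob r."""
    return g * (1.0 - r) + (1.0 - g) * r


def genetic_predictors(
    panel: Sequence[RecombinantGenotype],
    marker_map: MarkerMap,
    step_cm: float = STEP_CM,
) -> GeneticPredictors:
    """Interval-mapping dosages for a RIL panel on a <= ``step_cm`` grid.

    Between flanking markers the dosage is the conditional expectation of
    the Col allele given both markers under the Markov chain with
    adjacent-position recombination ``R = 2c/(1+2c)`` (Haldane ``c``);
    beyond the outermost markers it extrapolates from the nearest marker
    alone.  Grid points are the markers plus evenly spaced interior points
    so no gap exceeds ``step_cm``.
    """
    geno = panel_to_frame(panel, marker_map)
    D = (geno.to_numpy() == "Col").astype(float)
    line_ids = list(geno.index)
    pos_rows = []
    dos_cols = []
    for chrom in marker_map.chromosomes:
        idx = marker_map.marker_index(chrom)
        if len(idx) == 0:
            warnings.warn(f"chromosome {chrom} has no markers; skipped")
            continue
        cms = marker_map.frame["cM"].to_numpy(dtype=float)[idx]
        grid: list[tuple[float, bool, int | None]] = []
        for j in range(len(cms)):
            grid.append((cms[j], True, j))
            if j + 1 < len(cms):
                gap = cms[j + 1] - cms[j]
                n_extra = int(np.ceil(gap / step_cm)) - 1
                for t in range(1, n_extra + 1):
                    grid.append(
                        (cms[j] + gap * t / (n_extra + 1), False, j)
                    )
        for cm, is_marker, left_j in grid:
            if is_marker:
                d = D[:, idx[left_j]]
            else:
                gl = D[:, idx[left_j]]
                gr = D[:, idx[left_j + 1]]
                rl = float(ril_recomb(haldane_c(cm - cms[left_j])))
                rr = float(ril_recomb(haldane_c(cms[left_j + 1] - cm)))
                # two-step flip probability of the Markov chain L -> t -> R
                rlr = rl * (1 - rr) + rr * (1 - rl)
                # P(t=Col | L, R) via Bayes on the chain
                num = _transition(gl, rl) * np.where(gr == 1, 1 - rr, rr)
                den = np.where(gl == gr, 1 - rlr, rlr)
                d = num / den
            pos_rows.append({"chrom": chrom, "cM": float(cm),
                             "is_marker": bool(is_marker)})
            dos_cols.append(d)
    positions = pd.DataFrame(pos_rows)
    dosage = np.column_stack(dos_cols)
    order = np.lexsort((positions["cM"].to_numpy(),
                        positions["chrom"].to_numpy()))
    return GeneticPredictors(
        positions=positions.iloc[order].reset_index(drop=True),
        dosage=dosage[:, order],
        line_ids=line_ids,
    )


def li_ji_meff(
    dosage: np.ndarray,
    chrom: Sequence[int] | None = None,
    per_chrom: bool = True,
) -> float:
    """Effective number of independent tests from marker-correlation spectra.

    For each eigenvalue ``lam`` of the marker correlation matrix the
    contribution is ``I(lam >= 1) + (lam - floor(lam))``; contributions sum
    to ``M_eff``.  By default the matrix is formed per chromosome and the
    per-chromosome ``M_eff`` are summed (markers on different chromosomes
    are unlinked); ``per_chrom=False`` uses the whole-genome matrix.
    Constant marker columns are dropped with a warning.
    """
    dosage = np.asarray(dosage, dtype=float)
    if dosage.shape[1] < 2 or dosage.shape[0] < 3:
        raise ValueError("need >= 2 markers and >= 3 lines")
    if chrom is None or not per_chrom:
        groups = [np.arange(dosage.shape[1])]
    else:
        chrom = np.asarray(chrom)
        groups = [np.flatnonzero(chrom == c) for c in np.unique(chrom)]
    meff = 0.0
    for cols in groups:
        sub = dosage[:, cols]
        sd = sub.std(axis=0)
        const = sd < 1e-12
        if const.any():
            warnings.warn(
                f"{int(const.sum())} constant marker column(s) dropped "
                "before eigendecomposition"
            )
            sub = sub[:, ~const]
        if sub.shape[1] == 0:
            continue
        if sub.shape[1] == 1:
            meff += 1.0
            continue
        corr = np.corrcoef(sub, rowvar=False)
        lam = np.linalg.eigvalsh(corr)
        lam = np.clip(lam, 0.0, None)
        # guard the floor against floating-point eigenvalues (2 - eps)
        near = np.abs(lam - np.round(lam)) < 1e-8
        lam = np.where(near, np.round(lam), lam)
        meff += float(np.sum((lam >= 1.0) + (lam - np.floor(lam))))
    return meff


def li_ji_threshold(
    dosage: np.ndarray,
    chrom: Sequence[int] | None = None,
    alpha: float = ALPHA_GENOMEWIDE,
    per_chrom: bool = True,
) -> tuple[float, float]:
    """Genome-wide Li--Ji threshold: (per-test alpha, -log10 threshold).

    The per-test level is the Sidak correction
    ``alpha_p = 1 - (1 - alpha)**(1 / M_eff)``.
    """
    meff = li_ji_meff(dosage, chrom=chrom, per_chrom=per_chrom)
    alpha_p = 1.0 - (1.0 - alpha) ** (1.0 / meff)
    return alpha_p, float(-np.log10(alpha_p))


def scan(
    pheno: pd.Series,
    predictors: GeneticPredictors,
    cofactors: Sequence[tuple[int, float]] = (),
    window_cm: float = COFACTOR_WINDOW_CM,
) -> pd.DataFrame:
    """Single-pass genome scan: -log10(p) of the dosage term per position.

    At each grid position the phenotype is regressed on the local dosage
    plus the dosages of all cofactors except those on the same chromosome
    within ``window_cm`` of the tested position; the reported p-value is the
    partial F (= t^2) test of the local dosage term.
    """
    common = [l for l in predictors.line_ids if l in pheno.index]
    if not common:
        raise ValueError("no phenotyped lines match the predictor panel")
    sel = [predictors.line_ids.index(l) for l in common]
    D = predictors.dosage[sel]
    y = pheno.loc[common].to_numpy(dtype=float)
    n = len(y)
    pos = predictors.positions
    cof_idx = []
    for chrom, cm in cofactors:
        match = np.flatnonzero(
            (pos["chrom"] == chrom).to_numpy()
            & np.isclose(pos["cM"].to_numpy(), cm)
        )
        if len(match) == 0:
            raise ValueError(f"cofactor ({chrom}, {cm}) not on predictor grid")
        cof_idx.append(int(match[0]))

    out = []
    if not cof_idx:
        # vectorised simple regression at every position
        yc = y - y.mean()
        Dc = D - D.mean(axis=0, keepdims=True)
        sxx = (Dc ** 2).sum(axis=0)
        sxy = Dc.T @ yc
        syy = float(yc @ yc)
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), 0.0)
            r2 = np.where(sxx > 0, sxy ** 2 / (sxx * syy), 0.0) if syy > 0 else np.zeros_like(sxx)
        dfres = n - 2
        with np.errstate(divide="ignore", invalid="ignore"):
            F = np.where(r2 < 1.0, dfres * r2 / (1.0 - r2), np.inf)
        p = stats.f.sf(F, 1, dfres)
        p = np.clip(p, 1e-300, 1.0)
        mlp = -np.log10(p)
        for j in range(D.shape[1]):
            out.append(
                {"chrom": int(pos["chrom"].iloc[j]), "cM": float(pos["cM"].iloc[j]),
                 "minus_log10_p": float(mlp[j]), "beta": float(beta[j])}
            )
    else:
        for j in range(D.shape[1]):
            chrom_j = int(pos["chrom"].iloc[j])
            cm_j = float(pos["cM"].iloc[j])
            use = [
                ci for ci in cof_idx
                if not (
                    int(pos["chrom"].iloc[ci]) == chrom_j
                    and abs(float(pos["cM"].iloc[ci]) - cm_j) < window_cm
                )
            ]
            Xc = np.column_stack([np.ones(n)] + [D[:, ci] for ci in use])
            Xf = np.column_stack([Xc, D[:, j]])
            if np.linalg.matrix_rank(Xf) < Xf.shape[1]:
                out.append({"chrom": chrom_j, "cM": cm_j,
                            "minus_log10_p": 0.0, "beta": 0.0})
                continue
            bf, rssf = _ols_rss(Xf, y)
            _, rssc = _ols_rss(Xc, y)
            dfres = n - Xf.shape[1]
            if rssf <= 0:
                mlp, beta_j = 300.0, bf[-1]
            else:
                F = (rssc - rssf) / (rssf / dfres)
                pval = float(stats.f.sf(F, 1, dfres))
                mlp = float(-np.log10(max(pval, 1e-300)))
                beta_j = bf[-1]
            out.append({"chrom": chrom_j, "cM": cm_j,
                        "minus_log10_p": mlp, "beta": float(beta_j)})
    return pd.DataFrame(out)


def _ols_rss(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def pick_peaks(
    profile: pd.DataFrame,
    threshold: float,
    min_sep_cm: float = MIN_SEPARATION_CM,
) -> list[tuple[int, float]]:
    """Greedy peak selection above threshold with a minimum separation."""
    peaks: list[tuple[int, float]] = []
    for chrom, grp in profile.groupby("chrom"):
        grp = grp.sort_values("minus_log10_p", ascending=False)
        chosen: list[float] = []
        for _, row in grp.iterrows():
            if row["minus_log10_p"] < threshold:
                break
            if all(abs(row["cM"] - c) >= min_sep_cm for c in chosen):
                chosen.append(float(row["cM"]))
        peaks.extend((int(chrom), c) for c in sorted(chosen))
    return sorted(peaks)


def support_interval(
    cms: np.ndarray,
    values: np.ndarray,
    peak_index: int,
    drop: float = SUPPORT_DROP,
) -> tuple[float, float]:
    """Drop-``drop`` support interval around a profile peak on one chromosome.

    Returns the contiguous region containing the peak where the profile
    stays within ``drop`` units of the peak value, clipped at the
    chromosome ends.
    """
    cms = np.asarray(cms, dtype=float)
    values = np.asarray(values, dtype=float)
    cutoff = values[peak_index] - drop
    left = peak_index
    while left > 0 and values[left - 1] >= cutoff:
        left -= 1
    right = peak_index
    while right < len(values) - 1 and values[right + 1] >= cutoff:
        right += 1
    return float(cms[left]), float(cms[right])


def cm_to_bp(marker_map: MarkerMap, chrom: int, cm: float) -> float:
    """Piecewise-linear cM -> bp interpolation on the marker map."""
    sub = marker_map.chrom_slice(chrom)
    if "bp" not in sub.columns or sub["bp"].isna().all():
        return float("nan")
    cms = sub["cM"].to_numpy(dtype=float)
    bps = sub["bp"].to_numpy(dtype=float)
    if cm <= cms[0]:
        return float(bps[0])
    if cm >= cms[-1]:
        return float(bps[-1])
    return float(np.interp(cm, cms, bps))


@dataclass
class ScanResult:
    """CIM output: profile, threshold and the called QTLs."""

    profile: pd.DataFrame
    threshold: float
    alpha_per_test: float
    qtls: pd.DataFrame
    rounds: int = 1
    stable: bool = True


def _qtl_table(
    profile: pd.DataFrame,
    peaks: Sequence[tuple[int, float]],
    marker_map: MarkerMap | None,
    drop: float,
) -> pd.DataFrame:
    rows = []
    for chrom, cm in peaks:
        grp = profile[profile["chrom"] == chrom].reset_index(drop=True)
        j = int((grp["cM"] - cm).abs().idxmin())
        lo, hi = support_interval(
            grp["cM"].to_numpy(), grp["minus_log10_p"].to_numpy(), j, drop
        )
        beta = float(grp["beta"].iloc[j])
        rows.append(
            {
                "chrom": chrom,
                "peak_cM": float(grp["cM"].iloc[j]),
                "minus_log10_p": float(grp["minus_log10_p"].iloc[j]),
                "effect": beta,
                "sign": "+Col" if beta > 0 else "+Ler",
                "si_left_cM": lo,
                "si_right_cM": hi,
                "si_left_bp": cm_to_bp(marker_map, chrom, lo) if marker_map else np.nan,
                "si_right_bp": cm_to_bp(marker_map, chrom, hi) if marker_map else np.nan,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "peak_cM", "minus_log10_p", "effect", "sign",
            "si_left_cM", "si_right_cM", "si_left_bp", "si_right_bp",
        ],
    )


def _prune_joint(
    pheno: pd.Series,
    predictors: GeneticPredictors,
    qtls: list[tuple[int, float]],
    alpha_p: float,
) -> list[tuple[int, float]]:
    """Backward-eliminate the final QTL set in one joint multiple-QTL model.

    The per-position window exclusion lets shadow peaks linked to a true QTL
    reach the threshold; testing every called QTL with all others included
    (no exclusion) removes them.  Drops the least significant QTL with
    p > ``alpha_p`` and refits until all survive.
    """
    if not qtls:
        return qtls
    common = [l for l in predictors.line_ids if l in pheno.index]
    sel = [predictors.line_ids.index(l) for l in common]
    y = pheno.loc[common].to_numpy(dtype=float)
    pos = predictors.positions

    def col_of(q):
        chrom, cm = q
        j = np.flatnonzero(
            (pos["chrom"] == chrom).to_numpy()
            & np.isclose(pos["cM"].to_numpy(), cm)
        )
        return int(j[0])

    current = list(qtls)
    while current:
        X = np.column_stack(
            [np.ones(len(y))]
            + [predictors.dosage[sel, col_of(q)] for q in current]
        )
        _, rss_full = _ols_rss(X, y)
        dfres = len(y) - X.shape[1]
        worst, worst_p = None, -1.0
        for i, q in enumerate(current):
            Xr = np.delete(X, i + 1, axis=1)
            _, rss_r = _ols_rss(Xr, y)
            if rss_full <= 0:
                pval = 0.0
            else:
                F = (rss_r - rss_full) / (rss_full / dfres)
                pval = float(stats.f.sf(F, 1, dfres))
            if pval > worst_p:
                worst, worst_p = q, pval
        if worst_p <= alpha_p:
            break
        current.remove(worst)
    return current


def cim_iterate(
    pheno: pd.Series,
    predictors: GeneticPredictors,
    threshold: float | None = None,
    alpha: float = ALPHA_GENOMEWIDE,
    marker_map: MarkerMap | None = None,
    window_cm: float = COFACTOR_WINDOW_CM,
    min_sep_cm: float = MIN_SEPARATION_CM,
    drop: float = SUPPORT_DROP,
    max_rounds: int = 5,
) -> ScanResult:
    """Composite interval mapping: iterate scan -> cofactor update to a fixed point.

    Round one is a plain single-QTL scan; detected QTLs become cofactors for
    the next round.  Iteration stops when the QTL set repeats (stable) or
    after ``max_rounds`` (the last set is returned with ``stable=False`` and
    a warning).  The genome-wide threshold defaults to Li--Ji at ``alpha``
    computed from the marker dosages.
    """
    if threshold is None:
        marker_cols = np.flatnonzero(predictors.positions["is_marker"].to_numpy())
        alpha_p, threshold = li_ji_threshold(
            predictors.dosage[:, marker_cols],
            chrom=predictors.positions["chrom"].to_numpy()[marker_cols],
            alpha=alpha,
        )
    else:
        alpha_p = 10.0 ** (-threshold)
    qtls: list[tuple[int, float]] = []
    seen = [tuple(qtls)]
    profile = scan(pheno, predictors, cofactors=(), window_cm=window_cm)
    stable = True
    rounds = 0
    for rounds in range(1, max_rounds + 1):
        profile = scan(pheno, predictors, cofactors=qtls, window_cm=window_cm)
        new = pick_peaks(profile, threshold, min_sep_cm)
        if tuple(new) == tuple(qtls):
            stable = True
            break
        if tuple(new) in seen:  # oscillation: keep the last set
            warnings.warn("CIM cofactor set oscillates; returning last set")
            qtls = new
            stable = False
            break
        seen.append(tuple(new))
        qtls = new
        stable = False
    qtls = _prune_joint(pheno, predictors, qtls, alpha_p)
    table = _qtl_table(profile, qtls, marker_map, drop)
    return ScanResult(
        profile=profile,
        threshold=float(threshold),
        alpha_per_test=float(alpha_p),
        qtls=table,
        rounds=rounds,
        stable=stable,
    )


def nil_scan(
    panels: Mapping[str, Sequence[RecombinantGenotype]],
    phenos: Mapping[str, pd.Series],
    marker_map: MarkerMap,
    target_chrom: int,
    alpha: float = ALPHA_GENOMEWIDE,
    drop: float = SUPPORT_DROP,
) -> pd.DataFrame:
    """Per-marker fine-mapping of a single-chromosome NIL set per background.

    For every marker on the target chromosome and every background panel the
    phenotype is regressed on the local introgression dosage; monomorphic
    markers are flagged (``tested = False``) rather than tested.
    Significance uses a per-chromosome Li--Ji correction; support intervals
    apply the drop-2 rule to the -log10(p) profile of each background.
    The output is heatmap-ready: one row per (background, marker).
    """
    out_rows = []
    idx = marker_map.marker_index(target_chrom)
    cms = marker_map.frame["cM"].to_numpy(dtype=float)[idx]
    names = marker_map.frame["marker"].to_numpy()[idx]
    for bg, panel in panels.items():
        pheno = phenos[bg]
        frame = panel_to_frame(panel, marker_map)
        common = [l for l in frame.index if l in pheno.index]
        D = (frame.loc[common].to_numpy() == "Col").astype(float)[:, idx]
        y = pheno.loc[common].to_numpy(dtype=float)
        poly = D.std(axis=0) > 1e-12
        if poly.sum() >= 2:
            _, thr = li_ji_threshold(
                D[:, poly], chrom=np.full(int(poly.sum()), target_chrom),
                alpha=alpha,
            )
        else:
            thr = -np.log10(alpha)
        mlps = np.zeros(len(idx))
        effects = np.full(len(idx), np.nan)
        for j in range(len(idx)):
            if not poly[j]:
                continue
            x = D[:, j]
            xc = x - x.mean()
            yc = y - y.mean()
            sxx = float(xc @ xc)
            beta = float(xc @ yc) / sxx
            resid = yc - beta * xc
            dfres = len(y) - 2
            s2 = float(resid @ resid) / dfres
            se = np.sqrt(s2 / sxx) if s2 > 0 else 0.0
            if se == 0:
                pval = 0.0 if beta != 0 else 1.0
            else:
                pval = 2 * stats.t.sf(abs(beta / se), dfres)
            mlps[j] = -np.log10(max(pval, 1e-300))
            effects[j] = beta
        peak = int(np.argmax(mlps))
        si = (
            support_interval(cms, mlps, peak, drop)
            if mlps[peak] >= thr
            else (np.nan, np.nan)
        )
        for j in range(len(idx)):
            out_rows.append(
                {
                    "background": bg,
                    "marker": names[j],
                    "chrom": target_chrom,
                    "cM": float(cms[j]),
                    "effect": effects[j],
                    "minus_log10_p": float(mlps[j]),
                    "tested": bool(poly[j]),
                    "significant": bool(poly[j] and mlps[j] >= thr),
                    "threshold": float(thr),
                    "si_left_cM": si[0],
                    "si_right_cM": si[1],
                }
            )
    return pd.DataFrame(out_rows)
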