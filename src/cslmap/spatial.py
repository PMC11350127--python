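"""Spatial adjustment of field-trial data with a linear mixed model.

Field trials show smooth fertility/microclimate trends and row/column
artefacts that inflate the residual if ignored.  This stage removes them
with a standard mixed model

    y = mean + population + block + f(row, col)            (fixed)
        + row + col + genotype-within-population + e       (random)

where ``f`` is a low-degree tensor-polynomial surface and the genotype
variance is heterogeneous across populations (one variance component per
population, e.g. CSLs vs RILs).  Variance components are estimated by
REML; genotype BLUPs provide shrunken line means.

Outputs follow the routing the downstream statistics expect: plant-level
*corrected* values (raw minus the fitted environmental part, genotype
signal retained) feed the full-factorial epistasis decomposition, while
genotype-level shrunken means (BLUPs) feed the linkage scans.

The REML objective is profiled through the Woodbury identity so each
evaluation costs O(q^3) in the number of random levels (~200 for the
default layout) rather than O(n^3) in plants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize


@dataclass
class AdjustedData:
    """Result of the spatial fit.

    Attributes
    ----------
    plants
        Copy of the input records with a ``corrected`` column (raw minus
        fitted environmental part) and a ``fitted_env`` column.
    genotype_means
        One row per line: ``population``, ``adjusted_mean`` (mean of the
        corrected values), ``shrunken_mean`` (population mean + BLUP) and
        ``n_plants``.
    varcomp
        Variance components: ``sigma2_e``, ``sigma2_row``, ``sigma2_col``
        and ``sigma2_geno:<population>``.
    population_means
        Fitted fixed-effect mean per population.
    reml_trace
        Best-so-far REML log-likelihood across optimiser evaluations.
    """

    plants: pd.DataFrame
    genotype_means: pd.DataFrame
    varcomp: dict[str, float]
    population_means: dict[str, float]
    reml_trace: list[float] = field(default_factory=list)
    loglik: float = float("nan")


def _indicator(codes: np.ndarray, n_levels: int) -> np.ndarray:
    Z = np.zeros((len(codes), n_levels))
    Z[np.arange(len(codes)), codes] = 1.0
    return Z


def _surface_basis(row: np.ndarray, col: np.ndarray, degree: int) -> np.ndarray:
    """Centred tensor-polynomial basis in scaled row/col coordinates."""
    r = (row - row.mean()) / max(row.std(), 1e-12)
    c = (col - col.mean()) / max(col.std(), 1e-12)
    cols = []
    for i in range(degree + 1):
        for j in range(degree + 1 - i):
            if i + j == 0:
                continue
            cols.append((r ** i) * (c ** j))
    B = np.column_stack(cols) if cols else np.empty((len(r), 0))
    return B - B.mean(axis=0, keepdims=True)


class _RemlProblem:
    """Profiled REML for y = Xb + Z u + e with diagonal blocked G."""

    def __init__(self, y: np.ndarray, X: np.ndarray, Z: np.ndarray,
                 group_sizes: Sequence[int]):
        self.y = y
        self.X = X
        self.Z = Z
        self.group_sizes = list(group_sizes)
        self.n, self.p = X.shape
        self.q = Z.shape[1]
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.ZtZ = Z.T @ Z
        self.ZtX = Z.T @ X
        self.Zty = Z.T @ y
        # expand per-group variances to per-level
        self._expand = np.concatenate(
            [np.full(sz, gi) for gi, sz in enumerate(self.group_sizes)]
        ).astype(int) if self.q else np.empty(0, dtype=int)

    def _core(self, sigma2_e: float, group_vars: np.ndarray):
        d = group_vars[self._expand] if self.q else np.empty(0)
        s = np.sqrt(d)
        A = np.eye(self.q) + (s[:, None] * self.ZtZ * s[None, :]) / sigma2_e
        cA = np.linalg.cholesky(A)
        logdetA = 2.0 * np.log(np.diag(cA)).sum()

        def vinv_quad(ZtM, NtM, ZtN):
            # N' V^{-1} M given cross-products; all small matrices
            u = np.linalg.solve(cA, s[:, None] * ZtM)
            w = np.linalg.solve(cA, s[:, None] * ZtN)
            return (NtM - (w.T @ u) / sigma2_e) / sigma2_e

        XtVX = vinv_quad(self.ZtX, self.XtX, self.ZtX)
        XtVy = vinv_quad(self.Zty[:, None], self.Xty[:, None], self.ZtX)[:, 0]
        ytVy = vinv_quad(self.Zty[:, None], np.array([[self.yty]]),
                         self.Zty[:, None])[0, 0]
        return logdetA, XtVX, XtVy, ytVy, cA, s

    def neg_reml(self, theta: np.ndarray) -> float:
        sigma2_e = np.exp(theta[0])
        gv = np.exp(theta[1:])
        try:
            logdetA, XtVX, XtVy, ytVy, _, _ = self._core(sigma2_e, gv)
            cX = np.linalg.cholesky(XtVX)
        except np.linalg.LinAlgError:
            return 1e10
        logdet_XtVX = 2.0 * np.log(np.diag(cX)).sum()
        beta = np.linalg.solve(XtVX, XtVy)
        ypy = ytVy - float(XtVy @ beta)
        logdetV = self.n * np.log(sigma2_e) + logdetA
        ll = -0.5 * (logdetV + logdet_XtVX + ypy)
        if not np.isfinite(ll):
            return 1e10
        return -ll

    def solve(self, sigma2_e: float, group_vars: np.ndarray):
        """Return (beta, u, fitted pieces) at given variances."""
        logdetA, XtVX, XtVy, ytVy, cA, s = self._core(sigma2_e, group_vars)
        beta = np.linalg.solve(XtVX, XtVy)
        resid = self.y - self.X @ beta
        Ztr = self.Z.T @ resid if self.q else np.empty(0)
        if self.q:
            tmp = np.linalg.solve(cA, s * Ztr)
            tmp = np.linalg.solve(cA.T, tmp)
            ZtVr = (Ztr - self.ZtZ @ (s * tmp) / sigma2_e) / sigma2_e
            d = group_vars[self._expand]
            u = d * ZtVr
        else:
            u = np.empty(0)
        return beta, u


def fit_spatial(
    records: pd.DataFrame,
    populations: Mapping[str, str],
    trait: str | None = None,
    surface_degree: int = 3,
    fixed_zero: Sequence[str] = (),
    n_restarts: int = 2,
    seed: int = 0,
) -> AdjustedData:
    """Fit the spatial mixed model and return adjusted data.

    Parameters
    ----------
    records
        Plant records with columns ``line_id, block, row, col, value`` (and
        optionally ``trait``; pass ``trait=`` to select one when several are
        present).
    populations
        Mapping line_id -> population label (e.g. ``"CSL"`` / ``"RIL"``);
        genotype variance is estimated separately per population.
    surface_degree
        Total degree of the tensor-polynomial trend surface.
    fixed_zero
        Variance components forced to zero, by name: ``"row"``, ``"col"``
        or ``"geno:<population>"``.  Forcing a genotype variance to zero
        collapses that population's shrunken means onto the population
        mean.
    """
    df = records.copy()
    if "trait" in df.columns:
        traits = df["trait"].unique()
        if trait is None:
            if len(traits) > 1:
                raise ValueError(
                    f"records contain several traits {list(traits)}; pass trait="
                )
        else:
            df = df[df["trait"] == trait]
            if df.empty:
                raise ValueError(f"no records for trait {trait!r}")
    for col in ("line_id", "block", "row", "col", "value"):
        if col not in df.columns:
            raise ValueError(f"records missing column {col!r}")
    df = df[df["value"].notna()].reset_index(drop=True)
    if df.empty:
        raise ValueError("no non-missing records")
    if df[["row", "col"]].drop_duplicates().shape[0] == 1 and len(df) > 1:
        raise ValueError("degenerate design: all plants share one grid cell")
    counts = df["line_id"].value_counts()
    if (counts < 2).all():
        raise ValueError("no replication: every line has a single plant")

    y = df["value"].to_numpy(dtype=float)
    n = len(y)
    row = df["row"].to_numpy(dtype=float)
    col = df["col"].to_numpy(dtype=float)

    pop = np.array([populations.get(l, "pop") for l in df["line_id"]])
    pop_levels = sorted(set(pop))
    lines = df["line_id"].to_numpy()

    # ---- fixed part: intercept + population + centred block + centred surface
    X_parts = [np.ones((n, 1))]
    for p in pop_levels[1:]:
        X_parts.append((pop == p).astype(float)[:, None])
    n_pop_cols = len(pop_levels) - 1
    blocks = sorted(df["block"].unique())
    env_cols = []
    for b in blocks[1:]:
        v = (df["block"] == b).astype(float).to_numpy()
        env_cols.append(v - v.mean())
    B = _surface_basis(row, col, surface_degree)
    if B.shape[1]:
        env_cols.extend(B.T)
    X_env = np.column_stack(env_cols) if env_cols else np.empty((n, 0))
    X = np.column_stack(X_parts + [X_env]) if X_env.shape[1] else np.column_stack(X_parts)
    # guard against exactly collinear surface columns on tiny grids
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        q_, r_ = np.linalg.qr(X)
        keep = np.abs(np.diag(r_)) > 1e-9 * np.abs(np.diag(r_)).max()
        X = X[:, keep]

    # ---- random part
    group_names: list[str] = []
    Z_blocks: list[np.ndarray] = []
    group_sizes: list[int] = []
    level_labels: list[tuple[str, object]] = []

    row_levels = np.unique(row)
    col_levels = np.unique(col)
    for name, vals, levels in (("row", row, row_levels), ("col", col, col_levels)):
        if name in fixed_zero:
            continue
        codes = np.searchsorted(levels, vals)
        group_names.append(name)
        Z_blocks.append(_indicator(codes, len(levels)))
        group_sizes.append(len(levels))
        level_labels.extend((name, lv) for lv in levels)
    geno_groups: dict[str, list[str]] = {}
    for p in pop_levels:
        gname = f"geno:{p}"
        if gname in fixed_zero:
            continue
        lns = sorted(set(lines[pop == p]))
        codes_full = np.full(n, -1)
        lookup = {l: i for i, l in enumerate(lns)}
        mask = pop == p
        Zg = np.zeros((n, len(lns)))
        for i in np.flatnonzero(mask):
            Zg[i, lookup[lines[i]]] = 1.0
        group_names.append(gname)
        Z_blocks.append(Zg)
        group_sizes.append(len(lns))
        level_labels.extend((gname, l) for l in lns)
        geno_groups[p] = lns
    Z = np.hstack(Z_blocks) if Z_blocks else np.empty((n, 0))

    prob = _RemlProblem(y, X, Z, group_sizes)
    var_y = max(y.var(), 1e-12)
    rng = np.random.default_rng(seed)
    n_groups = len(group_sizes)

    trace: list[float] = []

    def objective(theta):
        val = prob.neg_reml(theta)
        ll = -val
        if not trace or ll > trace[-1]:
            trace.append(ll)
        else:
            trace.append(trace[-1])
        return val

    best = None
    starts = [np.log(np.r_[0.5 * var_y, np.full(n_groups, 0.1 * var_y)])]
    for _ in range(max(0, n_restarts - 1)):
        starts.append(
            np.log(var_y * np.exp(rng.uniform(-3, 1, size=n_groups + 1)))
        )
    # the residual variance is floored well above machine noise: letting it
    # collapse makes the Woodbury solves catastrophically ill-conditioned
    lo_e = np.log(var_y) - 10.0
    lo_g = np.log(var_y) - 25.0
    hi = np.log(var_y) + 6.0
    bounds = [(lo_e, hi)] + [(lo_g, hi)] * n_groups
    lows = np.array([b[0] for b in bounds])
    for x0 in starts:
        res = optimize.minimize(
            objective, np.clip(x0, lows, hi), method="L-BFGS-B",
            bounds=bounds, options={"ftol": 1e-13, "gtol": 1e-10,
                                    "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    # parsimony polish: a component whose removal does not worsen the REML
    # objective is snapped to zero — with noise-free data the profile is
    # flat there and the minimal-variance solution is preferred
    x = best.x.copy()
    fbest = best.fun
    zeroed = np.zeros(n_groups, dtype=bool)
    for j in range(1, n_groups + 1):
        if np.exp(x[j]) < 1e-2 * np.exp(x).max():
            trial = x.copy()
            trial[j] = lo_g
            ftrial = prob.neg_reml(trial)
            if ftrial <= fbest + 1e-6:
                x, fbest = trial, min(fbest, ftrial)
                zeroed[j - 1] = True
    best_fun = fbest
    sigma2_e = float(np.exp(x[0]))
    group_vars = np.exp(x[1:])
    group_vars[zeroed] = 0.0
    group_vars = np.where(group_vars < 1e-9 * var_y, 0.0, group_vars)

    # noise-free degeneracy: when the residual variance sits on its floor the
    # fit is an interpolation; solve the BLUP system at a much smaller
    # residual variance so corrected values honour the exact fit
    sigma2_e_solve = sigma2_e
    if sigma2_e <= 1.5 * var_y * np.exp(-10.0):
        sigma2_e_solve = var_y * np.exp(-25.0)
    beta, u = prob.solve(sigma2_e_solve, group_vars)

    # ---- decompose fitted values
    n_fixed_env = X.shape[1] - 1 - n_pop_cols
    env_fixed = X[:, 1 + n_pop_cols:] @ beta[1 + n_pop_cols:] if n_fixed_env else np.zeros(n)
    env_random = np.zeros(n)
    geno_blup = np.zeros(n)
    offset = 0
    u_by_level: dict[tuple[str, object], float] = {}
    for gname, Zb, sz in zip(group_names, Z_blocks, group_sizes):
        ug = u[offset:offset + sz]
        contrib = Zb @ ug
        if gname.startswith("geno:"):
            geno_blup += contrib
        else:
            env_random += contrib
        for j in range(sz):
            u_by_level[level_labels[offset + j]] = float(ug[j])
        offset += sz
    env = env_fixed + env_random

    pop_mean = {pop_levels[0]: float(beta[0])}
    for i, p in enumerate(pop_levels[1:]):
        pop_mean[p] = float(beta[0] + beta[1 + i])

    plants = df.copy()
    plants["fitted_env"] = env
    plants["corrected"] = y - env

    # ---- genotype-level table
    recs = []
    for line in sorted(set(lines)):
        p = populations.get(line, "pop")
        mask = lines == line
        blup = u_by_level.get((f"geno:{p}", line), 0.0)
        recs.append(
            {
                "line_id": line,
                "population": p,
                "n_plants": int(mask.sum()),
                "adjusted_mean": float(plants.loc[mask, "corrected"].mean()),
                "shrunken_mean": pop_mean[p] + blup,
            }
        )
    genotype_means = pd.DataFrame(recs).set_index("line_id")

    varcomp = {"sigma2_e": sigma2_e}
    for gname, v in zip(group_names, group_vars):
        varcomp[f"sigma2_{gname}"] = float(v)
    for gname in fixed_zero:
        varcomp[f"sigma2_{gname}"] = 0.0

    return AdjustedData(
        plants=plants,
        genotype_means=genotype_means,
        varcomp=varcomp,
        population_means=pop_mean,
        reml_trace=trace,
        loglik=float(-best_fun),
    )


def corrected_table(adjusted: AdjustedData, level: str = "plant") -> pd.DataFrame:
    """Extract the corrected data at plant or genotype level.

    ``level="plant"`` returns one row per non-missing input plant with the
    ``corrected`` column (this feeds the epistasis decomposition);
    ``level="genotype"`` returns one row per line with the shrunken
    (BLUP-analogue) mean (this feeds the linkage scans).
    """
    if level == "plant":
        return adjusted.plants.copy()
    if level == "genotype":
        return adjusted.genotype_means.reset_index()
    raise ValueError(f"level must be 'plant' or 'genotype', got {level!r}")
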