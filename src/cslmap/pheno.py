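"""Synthetic phenotyping experiments for CSL / RIL panels.

Generates per-plant trait values from a full-factorial chromosome effect
model

    y_ir = mu + sum_k a_k x_ik + sum_{k<l} b_kl x_ik x_il
              + sum_{k<l<m} c_klm x_ik x_il x_im + e_ir

with 0/1 indicator coding (Ler -> 0, Col -> 1), on top of a randomised
complete block field layout, additive block effects, a smooth spatial
surface, and Gaussian residual noise.  The default layout mirrors the study
design the statistics are built for: 32 CSLs x 12 replicates grown alongside
100 RILs x 3 replicates on a 12 x 60 grid split into three complete blocks
of 12 x 20.

The simulator is first-class, tested code: the generative model is exactly
the model the epistasis decomposition fits, so calibration simulations have
a known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .breeding import MarkerMap, RecombinantGenotype, haldane_c, ril_recomb
from .panel import CslGenotype, enumerate_panel


@dataclass
class EffectModel:
    """Coefficients of the full-factorial chromosome effect model.

    Parameters
    ----------
    mu
        Overall mean, in trait units (the expected value of the all-Ler
        genotype, for which every indicator is zero).
    a
        Additive (main) effect of the Col allele of each chromosome,
        length ``n_chrom``.
    b
        Sparse two-way interaction effects, keyed ``(k, l)`` with
        ``1 <= k < l <= n_chrom``.
    c
        Sparse three-way interaction effects, keyed ``(k, l, m)`` with
        ``k < l < m``.
    sigma_e
        Residual standard deviation (per plant), >= 0.
    """

    mu: float
    a: np.ndarray
    b: dict[tuple[int, int], float] = field(default_factory=dict)
    c: dict[tuple[int, int, int], float] = field(default_factory=dict)
    sigma_e: float = 1.0

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        n = len(self.a)
        for key in self.b:
            k, l = key
            if not (1 <= k < l <= n):
                raise ValueError(f"two-way key {key} invalid for n_chrom={n}")
        for key in self.c:
            k, l, m = key
            if not (1 <= k < l < m <= n):
                raise ValueError(f"three-way key {key} invalid for n_chrom={n}")
        if self.sigma_e < 0:
            raise ValueError("sigma_e must be >= 0")

    @property
    def n_chrom(self) -> int:
        return len(self.a)

    def value_from_indicator(self, x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        v = self.mu + float(self.a @ x)
        for (k, l), coef in self.b.items():
            v += coef * x[k - 1] * x[l - 1]
        for (k, l, m), coef in self.c.items():
            v += coef * x[k - 1] * x[l - 1] * x[m - 1]
        return v

    @classmethod
    def flowering_time_default(cls) -> "EffectModel":
        """Default flowering-time truth (days): chromosome 5 dominant,
        two-way epistasis among chromosomes 1, 3 and 5."""
        return cls(
            mu=75.0,
            a=np.array([1.5, 4.0, 2.5, 1.0, -6.0]),
            b={(1, 3): 2.0, (1, 5): -2.5, (3, 5): 2.0},
            c={},
            sigma_e=2.0,
        )

    @classmethod
    def stem_length_default(cls) -> "EffectModel":
        """Default main-stem-length truth (mm): a strong chromosome-2 main
        effect plus a large three-way interaction among chromosomes 1, 2, 5."""
        return cls(
            mu=150.0,
            a=np.array([10.0, 60.0, 15.0, 0.0, 12.0]),
            b={(1, 2): 15.0, (1, 5): -12.0, (2, 5): 18.0, (3, 5): -20.0},
            c={(1, 2, 5): 40.0},
            sigma_e=15.0,
        )


def genotype_value(g: CslGenotype, model: EffectModel) -> float:
    """Expected trait value of a genotype under an effect model."""
    if g.n_chrom != model.n_chrom:
        raise ValueError(
            f"genotype has {g.n_chrom} chromosomes, model {model.n_chrom}"
        )
    return model.value_from_indicator(g.indicator())


@dataclass
class FieldLayout:
    """A randomised complete block layout on a rectangular grid.

    ``frame`` has one row per grid position with columns
    ``row, col, block, line_id, replicate``; unassigned positions carry
    ``line_id = None``.  Blocks partition the grid and each line appears
    ``reps / n_blocks`` times in every block.
    """

    frame: pd.DataFrame
    n_rows: int
    n_cols: int
    n_blocks: int

    def filled(self) -> pd.DataFrame:
        return self.frame[self.frame["line_id"].notna()]


def make_layout(
    line_reps: Mapping[str, int],
    grid: tuple[int, int] = (12, 60),
    n_blocks: int = 3,
    rng: np.random.Generator | None = None,
) -> FieldLayout:
    """Randomise a complete block design for the given replication plan.

    ``line_reps`` maps line_id -> total replicates; every count must be
    divisible by ``n_blocks`` (complete blocks) and the total must fit the
    grid.  Blocks are contiguous column bands (e.g. three 12 x 20 blocks on
    a 12 x 60 grid); placement within a block is uniformly random.
    """
    if rng is None:
        rng = np.random.default_rng()
    n_rows, n_cols = grid
    if n_cols % n_blocks != 0:
        raise ValueError(
            f"grid columns {n_cols} not divisible into {n_blocks} blocks"
        )
    total = sum(line_reps.values())
    capacity = n_rows * n_cols
    if total > capacity:
        raise ValueError(
            f"layout needs {total} positions but the grid holds {capacity}"
        )
    bad = {k: v for k, v in line_reps.items() if v % n_blocks != 0}
    if bad:
        raise ValueError(
            f"replicate counts must be divisible by n_blocks={n_blocks}: {bad}"
        )
    band = n_cols // n_blocks
    rows = []
    rep_counter = {line: 0 for line in line_reps}
    for b in range(n_blocks):
        cols = range(b * band, (b + 1) * band)
        positions = [(r, c) for r in range(n_rows) for c in cols]
        entries: list[str | None] = []
        for line, reps in line_reps.items():
            entries.extend([line] * (reps // n_blocks))
        entries.extend([None] * (len(positions) - len(entries)))
        order = rng.permutation(len(positions))
        for pos_i, ent_i in zip(range(len(positions)), order):
            r, c = positions[pos_i]
            line = entries[ent_i]
            if line is None:
                rows.append(
                    {"row": r, "col": c, "block": b + 1, "line_id": None,
                     "replicate": 0}
                )
            else:
                rep_counter[line] += 1
                rows.append(
                    {"row": r, "col": c, "block": b + 1, "line_id": line,
                     "replicate": rep_counter[line]}
                )
    frame = pd.DataFrame(rows)
    return FieldLayout(frame=frame, n_rows=n_rows, n_cols=n_cols, n_blocks=n_blocks)


def default_csl_ril_spec(
    csl_lines: Sequence[str] | None = None,
    ril_lines: Sequence[str] | None = None,
    csl_reps: int = 12,
    ril_reps: int = 3,
) -> dict[str, int]:
    """The study-design replication plan: 32 CSLs x 12 plus 100 RILs x 3.

    Fills 684 of the 720 positions of the default 12 x 60 grid (the rest
    stay empty).
    """
    if csl_lines is None:
        csl_lines = [g.label() for g in enumerate_panel(5)]
    if ril_lines is None:
        ril_lines = [f"RIL{i + 1:03d}" for i in range(100)]
    spec = {line: csl_reps for line in csl_lines}
    spec.update({line: ril_reps for line in ril_lines})
    return spec


def spatial_surface(
    layout: FieldLayout,
    amplitude: float,
    n_components: int = 3,
    max_cycles: float = 1.0,
    row_sd: float = 0.0,
    col_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Draw a smooth zero-mean environmental surface over the grid.

    The smooth part is a sum of ``n_components`` low-frequency 2-D cosine
    waves with random orientations and phases (frequencies uniform up to
    ``max_cycles`` cycles across each grid dimension), rescaled so its
    standard deviation over the grid equals ``amplitude``.  Independent
    N(0, row_sd^2) row offsets and N(0, col_sd^2) column offsets are added,
    and the total is centred to zero grid mean.

    Returns a Series aligned to ``layout.frame`` (one offset per position).
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if rng is None:
        rng = np.random.default_rng()
    r = layout.frame["row"].to_numpy(dtype=float)
    c = layout.frame["col"].to_numpy(dtype=float)
    surf = np.zeros(len(r))
    if amplitude > 0 and n_components > 0:
        raw = np.zeros(len(r))
        for _ in range(n_components):
            fr = rng.uniform(0.15, max_cycles)
            fc = rng.uniform(0.15, max_cycles)
            phase = rng.uniform(0, 2 * np.pi)
            amp = rng.uniform(0.5, 1.0)
            raw += amp * np.cos(
                2 * np.pi * (fr * r / layout.n_rows + fc * c / layout.n_cols)
                + phase
            )
        sd = raw.std()
        if sd > 0:
            surf = raw * (amplitude / sd)
    if row_sd > 0:
        offsets = rng.normal(0.0, row_sd, size=layout.n_rows)
        surf = surf + offsets[layout.frame["row"].to_numpy(dtype=int)]
    if col_sd > 0:
        offsets = rng.normal(0.0, col_sd, size=layout.n_cols)
        surf = surf + offsets[layout.frame["col"].to_numpy(dtype=int)]
    surf = surf - surf.mean()
    return pd.Series(surf, index=layout.frame.index, name="surface")


def simulate_experiment(
    layout: FieldLayout,
    genotypes: Mapping[str, CslGenotype],
    model: EffectModel,
    trait: str = "trait",
    block_sd: float = 0.0,
    surface: pd.Series | None = None,
    missing_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate per-plant trait values for every assigned grid position.

    ``y = genotype value + block effect + spatial offset + N(0, sigma_e^2)``.
    Lines absent from ``genotypes`` (e.g. RIL ids in a CSL-only model) are
    skipped.  Returns the plant records (``line_id, block, row, col, trait,
    value``) and a truth dictionary carrying the genotype values, block
    effects and surface used, so any record can be reproduced exactly.
    """
    if rng is None:
        rng = np.random.default_rng()
    filled = layout.filled()
    block_ids = sorted(filled["block"].unique())
    block_eff = {
        b: (rng.normal(0.0, block_sd) if block_sd > 0 else 0.0)
        for b in block_ids
    }
    if surface is None:
        surface = pd.Series(0.0, index=layout.frame.index)
    truth_values = {
        line: genotype_value(g, model) for line, g in genotypes.items()
    }
    rows = []
    for idx, rec in filled.iterrows():
        line = rec["line_id"]
        if line not in truth_values:
            continue
        if missing_rate > 0 and rng.random() < missing_rate:
            continue
        noise = rng.normal(0.0, model.sigma_e) if model.sigma_e > 0 else 0.0
        y = truth_values[line] + block_eff[rec["block"]] + surface.loc[idx] + noise
        rows.append(
            {
                "line_id": line,
                "block": int(rec["block"]),
                "row": int(rec["row"]),
                "col": int(rec["col"]),
                "trait": trait,
                "value": float(y),
            }
        )
    records = pd.DataFrame(rows)
    truth = {
        "trait": trait,
        "genotype_values": truth_values,
        "block_effects": block_eff,
        "surface": surface,
        "sigma_e": model.sigma_e,
    }
    return records, truth


def simulate_csl_trait(
    model: EffectModel,
    reps: int,
    rng: np.random.Generator,
    genotypes: Sequence[CslGenotype] | None = None,
) -> tuple[np.ndarray, list[CslGenotype]]:
    """Fast path for calibration studies: balanced replicated panel values.

    Returns ``y`` (length ``len(genotypes) * reps``) and the matching
    genotype list, without any field structure — pure effect model plus
    residual noise.  This is the generative side of the epistasis
    decomposition's null/power simulations.
    """
    if genotypes is None:
        genotypes = enumerate_panel(model.n_chrom)
    genotypes = list(genotypes)
    means = np.array([genotype_value(g, model) for g in genotypes])
    y = np.repeat(means, reps)
    if model.sigma_e > 0:
        y = y + rng.normal(0.0, model.sigma_e, size=len(y))
    geno_rep = [g for g in genotypes for _ in range(reps)]
    return y, geno_rep


def simulate_ril_phenotypes(
    panel: Sequence[RecombinantGenotype],
    marker_map: MarkerMap,
    qtls: Sequence[tuple[int, float, float]],
    mu: float = 0.0,
    sigma_e: float = 1.0,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Genotype-level RIL trait values from a sparse QTL model.

    Each QTL is ``(chrom, cM, effect)``; its genetic predictor is the Col
    dosage at the nearest mapped marker.  Returns a Series indexed by
    line_id, suitable as input to the linkage scan.
    """
    if rng is None:
        rng = np.random.default_rng()
    y = np.full(len(panel), float(mu))
    for chrom, pos, effect in qtls:
        idx = marker_map.marker_index(chrom)
        if len(idx) == 0:
            raise ValueError(f"no markers on chromosome {chrom}")
        cms = marker_map.frame["cM"].to_numpy(dtype=float)[idx]
        j = idx[int(np.argmin(np.abs(cms - pos)))]
        dos = np.array([ln.dosage()[j] for ln in panel])
        y = y + effect * dos
    if sigma_e > 0:
        y = y + rng.normal(0.0, sigma_e, size=len(y))
    return pd.Series(y, index=[ln.line_id for ln in panel], name="value")
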