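"""Monte-Carlo simulation of reverse-breeding genetics.

Reverse breeding suppresses meiotic crossovers in a hybrid so that gametes
carry intact parental chromosomes.  Crossing such achiasmatic gametes to a
haploid inducer and doubling the resulting haploids yields chromosome
substitution lines (CSLs) in three generations: each line is a random draw
from the ``2**n`` factorial of whole-chromosome combinations, each genotype
appearing with probability ``1/2**n``.

This module simulates that process (``achiasmatic_gamete`` / ``dh_panel``)
and its logistics (``panel_completeness``), plus ordinary recombinant meiosis
for the fine-mapping populations: near-isogenic lines (NILs) recombinant on a
single chromosome (``nil_panel``) and recombinant inbred lines (RILs) mosaic
genome-wide (``ril_panel``).  Crossovers follow a Haldane model: counts are
Poisson in map length, positions uniform on the genetic map, no interference.
RIL genotypes use the selfing expansion ``R = 2c / (1 + 2c)`` of the gamete
recombination fraction ``c``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .panel import ALLELES, COL, LER, CslGenotype, enumerate_panel


def haldane_c(d_cm: float | np.ndarray) -> float | np.ndarray:
    """Haldane map function: recombination fraction for a distance in cM."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def ril_recomb(c: float | np.ndarray) -> float | np.ndarray:
    """Expected RIL (repeated-selfing) recombination fraction R = 2c/(1+2c)."""
    c = np.asarray(c, dtype=float)
    return 2.0 * c / (1.0 + 2.0 * c)


@dataclass(frozen=True)
class MarkerMap:
    """Genetic (and optionally physical) positions of a marker set.

    ``frame`` has columns ``marker, chrom, cM`` and optionally ``bp``;
    markers must be sorted by (chrom, cM) with non-decreasing positions
    within each chromosome and chromosome indices in ``1..n_chrom``.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"marker", "chrom", "cM"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"MarkerMap missing columns {sorted(missing)}")
        if self.frame["marker"].duplicated().any():
            dups = self.frame["marker"][self.frame["marker"].duplicated()]
            raise ValueError(f"duplicated marker names: {list(dups)}")
        for chrom, grp in self.frame.groupby("chrom"):
            if not grp["cM"].is_monotonic_increasing:
                raise ValueError(
                    f"marker positions not sorted on chromosome {chrom}"
                )
        object.__setattr__(self, "frame", self.frame.reset_index(drop=True))

    @property
    def n_markers(self) -> int:
        return len(self.frame)

    @property
    def chromosomes(self) -> list[int]:
        return sorted(int(c) for c in self.frame["chrom"].unique())

    def chrom_slice(self, chrom: int) -> pd.DataFrame:
        return self.frame[self.frame["chrom"] == chrom]

    def positions(self, chrom: int) -> np.ndarray:
        return self.chrom_slice(chrom)["cM"].to_numpy(dtype=float)

    def marker_index(self, chrom: int) -> np.ndarray:
        """Row indices (into ``frame``) of the markers on ``chrom``."""
        return np.flatnonzero((self.frame["chrom"] == chrom).to_numpy())

    @classmethod
    def default(
        cls,
        n_chrom: int = 5,
        lengths_cm: Sequence[float] = (120.0, 85.0, 95.0, 90.0, 110.0),
        step_cm: float = 5.0,
        bp_per_cm: float = 250_000.0,
    ) -> "MarkerMap":
        """Arabidopsis-like default map: markers every ``step_cm`` cM.

        Chromosome lengths default to 85-120 cM and the physical scale to
        ~250 kb/cM, matching the ~5 cM (~2.5 Mbp) marker resolution of a
        typical Arabidopsis SNP set.
        """
        if n_chrom > len(lengths_cm):
            lengths_cm = tuple(lengths_cm) * (n_chrom // len(lengths_cm) + 1)
        rows = []
        for chrom in range(1, n_chrom + 1):
            length = float(lengths_cm[chrom - 1])
            pos = np.arange(0.0, length + 1e-9, step_cm)
            if pos[-1] < length:
                pos = np.append(pos, length)
            for i, p in enumerate(pos):
                rows.append(
                    {
                        "marker": f"m{chrom}_{i + 1}",
                        "chrom": chrom,
                        "cM": float(p),
                        "bp": int(round(p * bp_per_cm)),
                    }
                )
        return cls(pd.DataFrame(rows))


@dataclass
class RecombinantGenotype:
    """Per-marker allele calls of one recombinant (RIL or NIL) line.

    ``alleles`` is aligned to a :class:`MarkerMap`; ``breakpoints`` optionally
    records the crossover positions (cM, per chromosome) that the simulator
    injected, so that detected introgression boundaries can be checked
    against the truth.
    """

    line_id: str
    alleles: np.ndarray  # dtype str, values in {"Col", "Ler"}
    panel: str = "RIL"
    breakpoints: dict[int, tuple[float, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype="<U3")
        bad = set(np.unique(self.alleles)) - set(ALLELES)
        if bad:
            raise ValueError(f"unknown allele labels {sorted(bad)}")

    def dosage(self) -> np.ndarray:
        """0/1 Col-allele dosage vector."""
        return (self.alleles == COL).astype(float)


def panel_to_frame(lines: Sequence[RecombinantGenotype], marker_map: MarkerMap) -> pd.DataFrame:
    """Stack a recombinant panel into a lines x markers allele table."""
    for ln in lines:
        if len(ln.alleles) != marker_map.n_markers:
            raise ValueError(
                f"line {ln.line_id} has {len(ln.alleles)} alleles for "
                f"{marker_map.n_markers} markers"
            )
    return pd.DataFrame(
        np.stack([ln.alleles for ln in lines]),
        index=pd.Index([ln.line_id for ln in lines], name="line_id"),
        columns=marker_map.frame["marker"].tolist(),
    )


# ---------------------------------------------------------------------------
# achiasmatic (whole-chromosome) meiosis and DH panels
# ---------------------------------------------------------------------------

def achiasmatic_gamete(n_chrom: int, rng: np.random.Generator) -> CslGenotype:
    """Draw one gamete of an achiasmatic hybrid.

    Without crossovers each chromosome segregates intact, independently and
    with equal probability from either parent, so any specific genotype has
    probability ``1 / 2**n_chrom``.
    """
    bits = rng.integers(0, 2, size=int(n_chrom))
    return CslGenotype.from_indicator(bits)


def dh_panel(
    n_lines: int, n_chrom: int, rng: np.random.Generator
) -> list[CslGenotype]:
    """Simulate ``n_lines`` doubled haploids from achiasmatic gametes.

    Each DH is fully homozygous, so its genotype is exactly the gamete's.
    """
    if n_lines < 1:
        raise ValueError(f"n_lines must be >= 1, got {n_lines}")
    bits = rng.integers(0, 2, size=(int(n_lines), int(n_chrom)))
    return [CslGenotype.from_indicator(row) for row in bits]


def panel_completeness(
    lines: Sequence[CslGenotype], n_chrom: int | None = None
) -> list[CslGenotype]:
    """Report which panel genotypes are missing from a set of lines.

    Returns the missing genotypes in panel enumeration order; an empty list
    means the panel is complete.
    """
    lines = list(lines)
    if n_chrom is None:
        if not lines:
            raise ValueError("n_chrom required when no lines are given")
        n_chrom = lines[0].n_chrom
    observed = set(lines)
    return [g for g in enumerate_panel(n_chrom) if g not in observed]


# ---------------------------------------------------------------------------
# recombinant meiosis
# ---------------------------------------------------------------------------

def recombinant_gamete(
    parent_a: np.ndarray,
    parent_b: np.ndarray,
    marker_map: MarkerMap,
    rng: np.random.Generator,
    return_breakpoints: bool = False,
):
    """Simulate one gamete of an F1 between two marker-genotyped parents.

    Per chromosome the crossover count is Poisson in the map length (Morgans),
    positions are uniform on the genetic map and there is no interference
    (Haldane model); the starting parental phase is Bernoulli(1/2) and flips
    at every crossover.  Markers co-located with a crossover stay with the
    phase to their left.
    """
    parent_a = np.asarray(parent_a, dtype="<U3")
    parent_b = np.asarray(parent_b, dtype="<U3")
    if parent_a.shape != parent_b.shape or len(parent_a) != marker_map.n_markers:
        raise ValueError(
            "parents must both be genotyped on the supplied marker map"
        )
    gamete = np.empty(marker_map.n_markers, dtype="<U3")
    breakpoints: dict[int, tuple[float, ...]] = {}
    for chrom in marker_map.chromosomes:
        idx = marker_map.marker_index(chrom)
        pos = marker_map.frame["cM"].to_numpy(dtype=float)[idx]
        length_m = (pos[-1] - pos[0]) / 100.0 if len(pos) > 1 else 0.0
        n_xo = int(rng.poisson(length_m))
        xo = np.sort(rng.uniform(pos[0], pos[-1], size=n_xo)) if n_xo else np.empty(0)
        phase0 = int(rng.integers(0, 2))
        # parity of crossovers strictly left of each marker flips the phase
        parity = np.searchsorted(xo, pos, side="left") % 2
        phase = (phase0 + parity) % 2
        chrom_alleles = np.where(phase == 0, parent_a[idx], parent_b[idx])
        gamete[idx] = chrom_alleles
        breakpoints[chrom] = tuple(float(x) for x in xo)
    if return_breakpoints:
        return gamete, breakpoints
    return gamete


def _csl_marker_alleles(g: CslGenotype, marker_map: MarkerMap) -> np.ndarray:
    """Expand a whole-chromosome genotype to per-marker allele calls."""
    chroms = marker_map.frame["chrom"].to_numpy(dtype=int)
    if g.n_chrom < chroms.max():
        raise ValueError(
            f"genotype has {g.n_chrom} chromosomes but map uses chromosome "
            f"{chroms.max()}"
        )
    return np.array([g.origins[c - 1] for c in chroms], dtype="<U3")


def nil_panel(
    scsl: CslGenotype,
    recurrent: CslGenotype,
    n_lines: int,
    marker_map: MarkerMap,
    rng: np.random.Generator,
) -> list[RecombinantGenotype]:
    """Simulate a NIL panel from a backcross of an sCSL to its recurrent parent.

    The F1 of ``scsl x recurrent`` is heterozygous only on the single
    substituted chromosome, so DHs of its gametes are monomorphic (and equal
    to the recurrent background) everywhere else while the target chromosome
    carries ordinary crossover mosaics.  All DHs are kept; crossover
    positions on the target chromosome are recorded per line as injected
    introgression breakpoints.
    """
    if scsl.n_chrom != recurrent.n_chrom:
        raise ValueError("scsl and recurrent parent differ in chromosome number")
    diffs = [
        k + 1
        for k in range(scsl.n_chrom)
        if scsl.origins[k] != recurrent.origins[k]
    ]
    if len(diffs) != 1:
        raise ValueError(
            f"scsl must differ from the recurrent parent on exactly one "
            f"chromosome, differs on {diffs}"
        )
    target = diffs[0]
    if n_lines < 1:
        raise ValueError(f"n_lines must be >= 1, got {n_lines}")
    pa = _csl_marker_alleles(scsl, marker_map)
    pb = _csl_marker_alleles(recurrent, marker_map)
    lines = []
    for i in range(int(n_lines)):
        gamete, bp = recombinant_gamete(pa, pb, marker_map, rng, return_breakpoints=True)
        lines.append(
            RecombinantGenotype(
                line_id=f"NIL{target}_{i + 1:03d}",
                alleles=gamete,
                panel="NIL",
                breakpoints={target: bp[target]},
            )
        )
    return lines


def _meiosis_batch(
    h1: np.ndarray,
    h2: np.ndarray,
    flip_probs: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete per row from diploids (h1, h2) on one chromosome.

    Under the Haldane model the crossover process has independent
    increments, so the parental phase at ordered marker loci is an exact
    Markov chain: start phase Bernoulli(1/2), phase flips between adjacent
    markers Bernoulli(c_j).  Vectorised across lines.
    """
    n_lines, m = h1.shape
    phase = np.empty((n_lines, m), dtype=int)
    phase[:, 0] = rng.integers(0, 2, size=n_lines)
    for j, cj in enumerate(flip_probs):
        flip = rng.random(n_lines) < cj
        phase[:, j + 1] = np.where(flip, 1 - phase[:, j], phase[:, j])
    return np.where(phase == 0, h1, h2)


def ril_panel(
    n_lines: int,
    marker_map: MarkerMap,
    rng: np.random.Generator,
    n_generations: int = 10,
) -> list[RecombinantGenotype]:
    """Simulate RIL genotypes by explicit repeated-selfing meiosis.

    Every line starts as the fully heterozygous F1 and is selfed for
    ``n_generations`` rounds of exact Haldane meiosis (crossover counts
    Poisson in map length, positions uniform, no interference), which
    reproduces both the pairwise selfing expansion ``R = 2c/(1+2c)`` and
    the genuinely non-Markov multi-locus correlation of real RILs.
    Residual heterozygosity after 10 generations (~0.1% per locus) is
    resolved by reporting one haplotype.  Chromosomes are independent.
    """
    if n_lines < 1:
        raise ValueError(f"n_lines must be >= 1, got {n_lines}")
    n_lines = int(n_lines)
    geno = np.empty((n_lines, marker_map.n_markers), dtype=int)
    for chrom in marker_map.chromosomes:
        idx = marker_map.marker_index(chrom)
        pos = marker_map.frame["cM"].to_numpy(dtype=float)[idx]
        cj = np.asarray(haldane_c(np.diff(pos)), dtype=float)
        h1 = np.zeros((n_lines, len(idx)), dtype=int)
        h2 = np.ones((n_lines, len(idx)), dtype=int)
        for _ in range(int(n_generations)):
            g1 = _meiosis_batch(h1, h2, cj, rng)
            g2 = _meiosis_batch(h1, h2, cj, rng)
            h1, h2 = g1, g2
        geno[:, idx] = h1
    alleles = np.where(geno == 1, COL, LER)
    return [
        RecombinantGenotype(line_id=f"RIL{i + 1:03d}", alleles=alleles[i], panel="RIL")
        for i in range(n_lines)
    ]


def detect_introgression_boundaries(
    line: RecombinantGenotype, marker_map: MarkerMap, chrom: int
) -> list[tuple[float, float]]:
    """Locate allele switches on one chromosome of a recombinant line.

    Each switch between adjacent markers is reported as the flanking-marker
    interval ``(left cM, right cM)``; the midpoint convention is the interval
    mean.  With fully informative markers every recorded crossover that
    changes the local genotype falls inside exactly one reported interval.
    """
    idx = marker_map.marker_index(chrom)
    pos = marker_map.frame["cM"].to_numpy(dtype=float)[idx]
    alle = line.alleles[idx]
    switches = np.flatnonzero(alle[:-1] != alle[1:])
    return [(float(pos[s]), float(pos[s + 1])) for s in switches]
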