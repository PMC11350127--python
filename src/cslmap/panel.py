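"""Genotype algebra for chromosome-substitution panels.

A chromosome substitution line (CSL) is a fully homozygous line whose genome
is a mosaic of whole, non-recombinant chromosomes drawn from two inbred
parents (here the Arabidopsis accessions Col-0 and Ler).  With ``n`` haploid
chromosomes the complete panel holds all ``2**n`` chromosome combinations,
giving a perfectly balanced full-factorial design: every chromosome, every
chromosome pair and every chromosome triple occurs in equal class sizes.

This module provides the encoding (:class:`CslGenotype`), enumeration of the
complete panel, classification into parental / single-substitution /
multi-substitution groups, and construction of the 0/1-coded design matrix
with main-effect and interaction columns used by both the phenotype simulator
and the epistasis decomposition.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Parental allele labels.  ``Ler`` codes 0 and ``Col`` codes 1 in the
#: indicator parameterisation used throughout the package.
LER = "Ler"
COL = "Col"
ALLELES = (LER, COL)

#: Largest haploid chromosome number accepted by :func:`enumerate_panel`;
#: guards against accidental combinatorial explosion (2**20 ~ 1e6 lines).
MAX_N_CHROM = 20

PARENTAL = "parental"
SINGLE_SUBSTITUTION = "single_substitution"
MULTI_SUBSTITUTION = "multi_substitution"


@dataclass(frozen=True)
class CslGenotype:
    """One CSL genotype: an ordered vector of whole-chromosome origins.

    Parameters
    ----------
    origins
        Tuple of length ``n_chrom`` with elements in ``{"Ler", "Col"}``;
        position ``k`` (0-based) is chromosome ``k + 1``.
    """

    origins: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.origins) == 0:
            raise ValueError("CslGenotype needs at least one chromosome")
        bad = [o for o in self.origins if o not in ALLELES]
        if bad:
            raise ValueError(
                f"chromosome origins must be one of {ALLELES}, got {bad!r}"
            )
        # normalise to a tuple so instances hash and compare by value
        object.__setattr__(self, "origins", tuple(self.origins))

    @property
    def n_chrom(self) -> int:
        return len(self.origins)

    def indicator(self) -> np.ndarray:
        """Return the 0/1 indicator vector ``x`` (Ler -> 0, Col -> 1)."""
        return np.fromiter(
            (1.0 if o == COL else 0.0 for o in self.origins),
            dtype=float,
            count=len(self.origins),
        )

    @classmethod
    def from_indicator(cls, x: Sequence[int]) -> "CslGenotype":
        return cls(tuple(COL if int(v) else LER for v in x))

    def label(self) -> str:
        """Compact line label, e.g. ``CCLLC`` for Col,Col,Ler,Ler,Col."""
        return "".join(o[0] for o in self.origins)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return "/".join(
            f"Chr{k + 1}^{o}" for k, o in enumerate(self.origins)
        )


@dataclass(frozen=True)
class PanelClass:
    """Classification of a CSL within the complete panel.

    ``background`` is the recurrent parent when 0 or 1 chromosomes are
    substituted and ``"none"`` otherwise; it maps to the background indicator
    ``z`` (Ler -> 0, Col -> 1) of the chromosome-by-background model.
    """

    label: str
    background: str
    n_substituted: int


def enumerate_panel(n_chrom: int) -> list[CslGenotype]:
    """Enumerate the complete CSL panel of ``2**n_chrom`` genotypes.

    Ordering is deterministic and lexicographic with chromosome 1 the most
    significant position and ``Ler`` sorting before ``Col`` (so the all-Ler
    parent is first and the all-Col parent last).

    Raises
    ------
    ValueError
        If ``n_chrom`` is outside ``1..20``.
    """
    if not isinstance(n_chrom, (int, np.integer)):
        raise ValueError(f"n_chrom must be an integer, got {n_chrom!r}")
    if not 1 <= n_chrom <= MAX_N_CHROM:
        raise ValueError(
            f"n_chrom must be in 1..{MAX_N_CHROM}, got {n_chrom}"
        )
    return [
        CslGenotype(combo)
        for combo in itertools.product(ALLELES, repeat=int(n_chrom))
    ]


def classify(genotype: CslGenotype) -> PanelClass:
    """Classify a genotype as parental / single- / multi-substitution.

    A single substitution carries exactly one chromosome differing from the
    majority origin, and its background is that majority origin.  For the
    complete n=5 panel the classes partition as 2 parental, 10 single
    (2 x 5, reciprocally) and 20 multi (2 x 10, reciprocally).
    """
    n = genotype.n_chrom
    n_col = int(genotype.indicator().sum())
    if n_col == 0:
        return PanelClass(PARENTAL, LER, 0)
    if n_col == n:
        return PanelClass(PARENTAL, COL, 0)
    if n_col == 1:
        return PanelClass(SINGLE_SUBSTITUTION, LER, 1)
    if n_col == n - 1:
        return PanelClass(SINGLE_SUBSTITUTION, COL, 1)
    return PanelClass(MULTI_SUBSTITUTION, "none", min(n_col, n - n_col))


def main_term(k: int) -> str:
    """Column name for the chromosome-``k`` main effect (1-based)."""
    return f"Chr{k}"


def interaction_term(indices: Iterable[int]) -> str:
    """Column name for an interaction, e.g. ``Chr1:Chr3`` or ``Chr1:Chr2:Chr5``."""
    idx = tuple(indices)
    if list(idx) != sorted(set(idx)):
        raise ValueError(f"interaction indices must be strictly increasing, got {idx}")
    return ":".join(main_term(k) for k in idx)


def term_indices(term: str) -> tuple[int, ...]:
    """Parse a term name back to its 1-based chromosome indices.

    ``"intercept"`` parses to the empty tuple.
    """
    if term == "intercept":
        return ()
    parts = term.split(":")
    idx = []
    for p in parts:
        if not p.startswith("Chr"):
            raise ValueError(f"unparseable term {term!r}")
        idx.append(int(p[3:]))
    return tuple(idx)


def design_matrix(
    genotypes: Sequence[CslGenotype], max_order: int = 3
) -> pd.DataFrame:
    """Build the 0/1-coded predictor table for a list of genotypes.

    Columns are ``intercept``, main effects ``Chr1..Chrn``, all two-way
    products ``Chrk:Chrl`` (k<l) when ``max_order >= 2`` and all three-way
    products when ``max_order == 3``.  Interaction columns are exact
    elementwise products of their parent main-effect columns, so the
    marginality structure of the model is built into the matrix.

    On the complete balanced panel with ``max_order=3`` the matrix has full
    column rank: every main, two-way and three-way effect is estimable.
    """
    genotypes = list(genotypes)
    if not genotypes:
        raise ValueError("design_matrix requires at least one genotype")
    if max_order not in (1, 2, 3):
        raise ValueError(f"max_order must be 1, 2 or 3, got {max_order}")
    n = genotypes[0].n_chrom
    if any(g.n_chrom != n for g in genotypes):
        raise ValueError("all genotypes must have the same chromosome number")

    X = np.stack([g.indicator() for g in genotypes])  # (n_geno, n)
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(genotypes))}
    for k in range(1, n + 1):
        cols[main_term(k)] = X[:, k - 1]
    for order in (2, 3):
        if max_order < order:
            break
        for idx in itertools.combinations(range(1, n + 1), order):
            prod = np.ones(len(genotypes))
            for k in idx:
                prod = prod * X[:, k - 1]
            cols[interaction_term(idx)] = prod
    return pd.DataFrame(cols, index=[g.label() for g in genotypes])


def panel_frame(genotypes: Sequence[CslGenotype]) -> pd.DataFrame:
    """Tabulate genotypes as a line-by-chromosome allele table.

    The layout matches the genotype TSV interface: one row per line
    (index = line label) and one ``Chr{k}`` column per chromosome, values in
    ``{"Col", "Ler"}``.
    """
    genotypes = list(genotypes)
    if not genotypes:
        raise ValueError("panel_frame requires at least one genotype")
    n = genotypes[0].n_chrom
    data = {
        main_term(k): [g.origins[k - 1] for g in genotypes]
        for k in range(1, n + 1)
    }
    return pd.DataFrame(data, index=pd.Index([g.label() for g in genotypes], name="line_id"))


def frame_to_genotypes(frame: pd.DataFrame) -> dict[str, CslGenotype]:
    """Invert :func:`panel_frame`: map line_id -> :class:`CslGenotype`."""
    chrom_cols = [c for c in frame.columns if c.startswith("Chr")]
    chrom_cols.sort(key=lambda c: int(c[3:]))
    out: dict[str, CslGenotype] = {}
    for line_id, row in frame[chrom_cols].iterrows():
        out[str(line_id)] = CslGenotype(tuple(row.tolist()))
    return out
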