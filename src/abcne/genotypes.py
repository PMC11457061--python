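"""Diploid biallelic genotype container shared by I/O, statistics and simulation.

A :class:`GenotypeMatrix` holds one population sample of S individuals typed at
L SNP loci.  Alleles are coded ``1`` and ``2``; ``0`` marks a missing allele.
Missingness is per-genotype: either both alleles of a call are missing or
neither is.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Allele code marking a missing call.
MISSING = 0

_VALID_CODES = frozenset({0, 1, 2})


@dataclass
class GenotypeMatrix:
    """One population sample of unordered diploid biallelic genotypes.

    Parameters
    ----------
    calls
        Integer array of shape ``(S, L, 2)``; entries in ``{0, 1, 2}`` where
        0 means missing.  Both alleles of a genotype must be missing together.
    individual_ids, locus_ids
        Row and column labels; locus labels must be unique.
    population_label
        Free-text label, round-tripped through the GENEPOP title line.
    """

    calls: np.ndarray
    individual_ids: Sequence[str] = field(default=None)  # type: ignore[assignment]
    locus_ids: Sequence[str] = field(default=None)  # type: ignore[assignment]
    population_label: str = "pop"

    def __post_init__(self) -> None:
        calls = np.ascontiguousarray(np.asarray(self.calls), dtype=np.int8)
        if calls.ndim != 3 or calls.shape[2] != 2:
            raise ValueError("calls must have shape (S, L, 2)")
        n_ind, n_loc, _ = calls.shape
        if n_ind < 1 or n_loc < 1:
            raise ValueError("need at least one individual and one locus")
        if self.individual_ids is None:
            self.individual_ids = [f"ind_{k + 1}" for k in range(n_ind)]
        if self.locus_ids is None:
            self.locus_ids = [f"locus_{k + 1}" for k in range(n_loc)]
        self.individual_ids = list(self.individual_ids)
        self.locus_ids = list(self.locus_ids)
        if len(self.individual_ids) != n_ind:
            raise ValueError("individual_ids length does not match calls")
        if len(self.locus_ids) != n_loc:
            raise ValueError("locus_ids length does not match calls")
        if len(set(self.locus_ids)) != n_loc:
            raise ValueError("locus_ids must be unique")
        if not np.isin(calls, (0, 1, 2)).all():
            raise ValueError("allele codes must be 0 (missing), 1 or 2")
        half = (calls == MISSING).sum(axis=2) == 1
        if half.any():
            raise ValueError("half-missing genotype: both alleles must be missing together")
        self.calls = calls

    # -- basic geometry -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    @property
    def called(self) -> np.ndarray:
        """Boolean ``(S, L)`` mask of non-missing genotypes."""
        return self.calls[:, :, 0] != MISSING

    # -- derived views --------------------------------------------------

    def dosage(self) -> np.ndarray:
        """Copies of allele 1 per genotype, ``(S, L)`` in {0, 1, 2}.

        Missing cells read 0; consult :attr:`called` to tell them apart
        from homozygous-2 genotypes.
        """
        return (self.calls == 1).sum(axis=2).astype(np.int8)

    def allele1_frequency(self) -> np.ndarray:
        """Per-locus frequency of allele 1 over called alleles (NaN if none)."""
        called = self.called
        n_alleles = 2.0 * called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, self.dosage().sum(axis=0) / n_alleles, np.nan)

    def minor_allele_frequency(self) -> np.ndarray:
        p = self.allele1_frequency()
        return np.minimum(p, 1.0 - p)

    def missing_fraction_by_locus(self) -> np.ndarray:
        return 1.0 - self.called.mean(axis=0)

    def missing_fraction_by_individual(self) -> np.ndarray:
        return 1.0 - self.called.mean(axis=1)

    # -- subsetting ------------------------------------------------------

    def take_individuals(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.calls[index],
            [self.individual_ids[k] for k in index],
            self.locus_ids,
            self.population_label,
        )

    def take_loci(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.calls[:, index],
            self.individual_ids,
            [self.locus_ids[k] for k in index],
            self.population_label,
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            isinstance(other, GenotypeMatrix)
            and self.individual_ids == other.individual_ids
            and self.locus_ids == other.locus_ids
            and self.population_label == other.population_label
            and np.array_equal(self.calls, other.calls)
        )
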