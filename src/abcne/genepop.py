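"""GENEPOP reading/writing and sample-level filtering for SNP data.

Supports the 2-digit (``0101``) and 3-digit (``001001``) GENEPOP dialects with
``00``/``000`` as the missing-allele code.  Only biallelic SNP codes (1, 2)
are accepted; microsatellite-style codes are rejected.  Filtering follows a
fixed order: high-missingness loci, then high-missingness individuals, then
minor-allele-frequency — dropping bad loci first avoids discarding
individuals over loci that would be removed anyway.
"""

from __future__ import annotations

import io
import logging
import os
import warnings
from dataclasses import dataclass
from typing import TextIO, Union

import numpy as np

from .genotypes import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


class GenepopError(ValueError):
    """Malformed or unsupported GENEPOP content."""


class GenepopParseError(GenepopError):
    """Parse failure at a specific line of a GENEPOP file."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


class FilterError(ValueError):
    """A filter left too little data for the estimator to be meaningful."""


@dataclass
class FilterConfig:
    """Missing-data and minor-allele-frequency cutoffs.

    ``min_maf`` is a lower bound that passes (loci with MAF exactly at the
    cutoff are retained); the missing-rate thresholds are strict upper
    bounds (a locus/individual is removed only when its missing fraction
    strictly exceeds the threshold).
    """

    min_maf: float = 0.05
    max_missing_individual: float = 0.20
    max_missing_locus: float = 0.20

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must lie in [0, 0.5]")
        for name in ("max_missing_individual", "max_missing_locus"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


# ---------------------------------------------------------------------------
# reading


def _decode_token(token: str, width: int, lineno: int) -> tuple[int, int]:
    a, b = int(token[:width]), int(token[width:])
    for code in (a, b):
        if code not in (0, 1, 2):
            raise GenepopError(
                f"line {lineno}: allele code {code} is not a SNP code "
                "(only 1/2 plus 0 for missing are supported)"
            )
    return a, b


def parse_genepop(text: str) -> GenotypeMatrix:
    """Parse GENEPOP text into a :class:`GenotypeMatrix`.

    Multiple ``Pop`` blocks are concatenated with a warning: the estimator
    is a single-population method.
    """
    lines = text.splitlines()
    if not lines or not any(ln.strip() for ln in lines):
        raise GenepopParseError(1, "empty GENEPOP file")
    title = lines[0].strip()

    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        chunk = lines[i].strip()
        if chunk:
            loci.extend(name.strip() for name in chunk.split(",") if name.strip())
        i += 1
    if i >= len(lines):
        raise GenepopParseError(len(lines), "no 'Pop' separator found")
    if not loci:
        raise GenepopParseError(2, "no locus names before the first 'Pop'")

    n_loci = len(loci)
    width: int | None = None
    ids: list[str] = []
    rows: list[np.ndarray] = []
    n_pops = 0
    block_size = -1  # individuals in the current Pop block

    for lineno in range(i, len(lines)):
        raw = lines[lineno].strip()
        if not raw:
            continue
        if raw.lower() == "pop":
            if block_size == 0:
                raise GenepopParseError(lineno + 1, "empty 'Pop' block")
            n_pops += 1
            block_size = 0
            continue
        if "," not in raw:
            raise GenepopParseError(
                lineno + 1, "individual line lacks the ',' after the identifier"
            )
        ident, _, geno_part = raw.partition(",")
        tokens = geno_part.split()
        if len(tokens) != n_loci:
            raise GenepopParseError(
                lineno + 1,
                f"expected {n_loci} genotypes, found {len(tokens)}",
            )
        if width is None:
            if len(tokens[0]) == 4:
                width = 2
            elif len(tokens[0]) == 6:
                width = 3
            else:
                raise GenepopParseError(
                    lineno + 1,
                    f"genotype token '{tokens[0]}' is neither 4 nor 6 characters",
                )
        row = np.empty((n_loci, 2), dtype=np.int8)
        for k, tok in enumerate(tokens):
            if len(tok) != 2 * width:
                raise GenepopParseError(
                    lineno + 1,
                    f"genotype token '{tok}' does not match the detected "
                    f"{width}-digit allele width",
                )
            a, b = _decode_token(tok, width, lineno + 1)
            if (a == 0) != (b == 0):
                warnings.warn(
                    f"line {lineno + 1}: half-missing genotype '{tok}' treated as missing",
                    stacklevel=2,
                )
                a = b = MISSING
            row[k] = (a, b)
        ids.append(ident.strip())
        rows.append(row)
        block_size += 1

    if block_size == 0:
        raise GenepopParseError(len(lines), "empty 'Pop' block")
    if not rows:
        raise GenepopParseError(len(lines), "no individuals found")
    if n_pops > 1:
        warnings.warn(
            f"{n_pops} 'Pop' blocks merged into one sample "
            "(single-population estimator)",
            stacklevel=2,
        )
    return GenotypeMatrix(np.stack(rows), ids, loci, population_label=title or "pop")


def read_genepop(source: Union[str, os.PathLike, TextIO]) -> GenotypeMatrix:
    """Read a GENEPOP file from a path or an open text stream."""
    if isinstance(source, (str, os.PathLike)):
        with open(source, "r", encoding="utf-8") as handle:
            return parse_genepop(handle.read())
    return parse_genepop(source.read())


# ---------------------------------------------------------------------------
# writing


def write_genepop(matrix: GenotypeMatrix, allele_width: int = 2) -> str:
    """Serialize a matrix so that :func:`parse_genepop` round-trips it."""
    if allele_width not in (2, 3):
        raise ValueError("allele_width must be 2 or 3")
    if matrix.n_individuals < 1:
        raise ValueError("refusing to write a matrix with no individuals")
    out = io.StringIO()
    out.write(f"{matrix.population_label}\n")
    for name in matrix.locus_ids:
        out.write(f"{name}\n")
    out.write("Pop\n")
    for ident, row in zip(matrix.individual_ids, matrix.calls):
        tokens = "".join(f" {a:0{allele_width}d}{b:0{allele_width}d}" for a, b in row)
        out.write(f"{ident} ,{tokens}\n")
    return out.getvalue()


def save_genepop(matrix: GenotypeMatrix, path: Union[str, os.PathLike], allele_width: int = 2) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(write_genepop(matrix, allele_width))


# ---------------------------------------------------------------------------
# filters


def filter_missing(matrix: GenotypeMatrix, cfg: FilterConfig) -> GenotypeMatrix:
    """Drop loci, then individuals, whose missing fraction exceeds the cutoffs.

    Raises :class:`FilterError` when fewer than 2 individuals or 1 locus
    survive: the summary statistics are undefined below that.
    """
    keep_loci = np.flatnonzero(
        matrix.missing_fraction_by_locus() <= cfg.max_missing_locus
    )
    n_loci_removed = matrix.n_loci - keep_loci.size
    if keep_loci.size == 0:
        raise FilterError(
            "all loci exceed the missing-data threshold "
            f"({cfg.max_missing_locus:.0%}); relax the locus cutoff"
        )
    trimmed = matrix.take_loci(keep_loci) if n_loci_removed else matrix

    keep_ind = np.flatnonzero(
        trimmed.missing_fraction_by_individual() <= cfg.max_missing_individual
    )
    n_ind_removed = trimmed.n_individuals - keep_ind.size
    if keep_ind.size < 2:
        raise FilterError(
            "fewer than 2 individuals survive the missing-data filter; "
            "relax the individual cutoff or check genotyping quality"
        )
    result = trimmed.take_individuals(keep_ind) if n_ind_removed else trimmed
    if n_loci_removed or n_ind_removed:
        logger.info(
            "missing-data filter removed %d loci and %d individuals",
            n_loci_removed,
            n_ind_removed,
        )
    return result


def filter_maf(matrix: GenotypeMatrix, min_maf: float) -> GenotypeMatrix:
    """Drop loci whose minor-allele frequency is strictly below ``min_maf``.

    Monomorphic loci (MAF 0) are always removed when ``min_maf > 0``.
    """
    if not 0.0 <= min_maf <= 0.5:
        raise ValueError("min_maf must lie in [0, 0.5]")
    if min_maf == 0.0:
        return matrix
    maf = matrix.minor_allele_frequency()
    keep = np.flatnonzero(~(np.nan_to_num(maf, nan=0.0) < min_maf))
    if keep.size == 0:
        raise FilterError(
            f"no locus has minor-allele frequency >= {min_maf}; "
            "lower the MAF cutoff or check the data"
        )
    removed = matrix.n_loci - keep.size
    if removed:
        logger.info("MAF filter removed %d loci", removed)
        return matrix.take_loci(keep)
    return matrix


def apply_filters(matrix: GenotypeMatrix, cfg: FilterConfig) -> GenotypeMatrix:
    """Missing-locus → missing-individual → MAF, in that fixed order."""
    return filter_maf(filter_missing(matrix, cfg), cfg.min_maf)
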