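"""The five summary statistics that drive the ABC matching.

For a sample of S diploid individuals at L biallelic loci the statistics are

* ``he`` — mean expected heterozygosity, (1/L) sum_i 2 p_i (1 - p_i);
* ``fis`` — fixation index, 1 - (1/L) sum_i Ho_i / He_i (mean of per-locus
  ratios);
* ``h_mean``, ``h_var`` — mean and sample variance (S - 1 denominator) of
  the per-individual count of homozygous called loci;
* ``r2`` — mean over usable locus pairs of the squared Burrows composite
  disequilibrium correlation, a phase-free LD measure.

Burrows' composite estimator for a pair of loci, over the n individuals
called at both, with dosages x, y in {0, 1, 2} counting allele 1:

    delta = sum(x * y) / (2 n) - 2 p q
    r     = delta / sqrt((p (1 - p) + D_x)(q (1 - q) + D_y))

where p, q are allele-1 frequencies and D_x = P(homozygous 1) - p^2 is the
Hardy–Weinberg departure at each locus.  ``r`` is clamped to [-1, 1].  A pair
is unusable (excluded from the mean, not an error) when either locus is
monomorphic within the jointly called individuals, when fewer than two
individuals are called at both loci, or when the denominator vanishes.

Single-locus statistics use per-locus deletion of missing genotypes; the LD
statistic uses pairwise deletion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .genotypes import GenotypeMatrix

_EPS = 1e-12


class StatsError(ValueError):
    """A summary statistic is undefined on the given matrix."""


@dataclass(frozen=True)
class SummaryStatVector:
    """The five summary statistics for one dataset."""

    he: float
    fis: float
    h_mean: float
    h_var: float
    r2: float

    names = ("he", "fis", "h_mean", "h_var", "r2")

    def as_array(self) -> np.ndarray:
        return np.array([self.he, self.fis, self.h_mean, self.h_var, self.r2])

    @classmethod
    def from_array(cls, values: np.ndarray) -> "SummaryStatVector":
        return cls(*(float(v) for v in values))


@dataclass(frozen=True)
class BurrowsPairLD:
    """Composite-disequilibrium summary for one unordered locus pair."""

    locus_i: int
    locus_j: int
    delta: float
    r_hat: float
    n_used: int
    usable: bool = True


# ---------------------------------------------------------------------------
# single-locus statistics


def _per_locus_freq(matrix: GenotypeMatrix) -> np.ndarray:
    p = matrix.allele1_frequency()
    if np.isnan(p).any():
        bad = int(np.flatnonzero(np.isnan(p))[0])
        raise StatsError(
            f"locus {matrix.locus_ids[bad]!r} has no called genotypes; "
            "apply the missing-data filter first"
        )
    return p


def expected_heterozygosity(matrix: GenotypeMatrix) -> float:
    """Mean over loci of 2 p (1 - p); monomorphic loci contribute 0."""
    p = _per_locus_freq(matrix)
    return float(np.mean(2.0 * p * (1.0 - p)))


def fixation_index(matrix: GenotypeMatrix, *, skip_monomorphic: bool = False) -> float:
    """1 minus the mean over loci of observed/expected heterozygosity.

    With ``skip_monomorphic`` loci whose expected heterozygosity is zero are
    left out of the average instead of raising; the pipeline applies this
    symmetrically to the input sample and every simulated sample.
    """
    p = _per_locus_freq(matrix)
    he = 2.0 * p * (1.0 - p)
    called = matrix.called
    ho = (matrix.dosage() == 1).sum(axis=0) / called.sum(axis=0)
    poly = he > _EPS
    if not poly.all():
        if not skip_monomorphic:
            bad = int(np.flatnonzero(~poly)[0])
            raise StatsError(
                f"locus {matrix.locus_ids[bad]!r} is monomorphic; "
                "apply the MAF filter before computing the fixation index"
            )
        if not poly.any():
            raise StatsError("every locus is monomorphic; fixation index undefined")
    return float(1.0 - np.mean(ho[poly] / he[poly]))


def multilocus_homozygosity(matrix: GenotypeMatrix) -> tuple[float, float]:
    """Mean and sample variance of per-individual homozygous-locus counts."""
    if matrix.n_individuals < 2:
        raise StatsError("multilocus homozygosity variance needs at least 2 individuals")
    homo = matrix.called & (matrix.dosage() != 1)
    h = homo.sum(axis=1)
    return float(h.mean()), float(h.var(ddof=1))


# ---------------------------------------------------------------------------
# Burrows composite LD


def burrows_pair(matrix: GenotypeMatrix, i: int, j: int) -> BurrowsPairLD:
    """Burrows composite disequilibrium between allele 1 at loci ``i`` and ``j``."""
    if i == j:
        raise ValueError("need two distinct loci")
    if i > j:
        i, j = j, i
    called = matrix.called
    both = called[:, i] & called[:, j]
    n = int(both.sum())
    if n < 2:
        return BurrowsPairLD(i, j, np.nan, np.nan, n, usable=False)
    d = matrix.dosage()
    x = d[both, i].astype(np.float64)
    y = d[both, j].astype(np.float64)
    p, q = x.mean() / 2.0, y.mean() / 2.0
    delta = float(x @ y) / (2.0 * n) - 2.0 * p * q
    dx = float((x == 2).mean()) - p * p
    dy = float((y == 2).mean()) - q * q
    vx = p * (1.0 - p) + dx
    vy = q * (1.0 - q) + dy
    if min(p, 1.0 - p) < _EPS or min(q, 1.0 - q) < _EPS or vx < _EPS or vy < _EPS:
        return BurrowsPairLD(i, j, delta, np.nan, n, usable=False)
    r = float(np.clip(delta / np.sqrt(vx * vy), -1.0, 1.0))
    return BurrowsPairLD(i, j, delta, r, n)


def _pairwise_r(matrix: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Clamped Burrows r for every unordered pair, with a usability mask.

    Returns ``(r, usable)`` as condensed upper-triangle vectors.  Uses a few
    L x L matrix products so that pairwise deletion stays vectorized.
    """
    w = matrix.called.astype(np.float64)
    g = matrix.dosage().astype(np.float64)  # missing cells are 0, masked by w
    hom1 = ((g == 2) & matrix.called).astype(np.float64)

    n = w.T @ w
    sx = g.T @ w  # sum of dosage at row-locus over jointly called individuals
    sxy = g.T @ g
    hx = hom1.T @ w

    with np.errstate(invalid="ignore", divide="ignore"):
        p = sx / (2.0 * n)  # p[i, j]: allele-1 freq at locus i within pair (i, j)
        p2 = hx / n
        dhw = p2 - p * p
        v = p * (1.0 - p) + dhw
        delta = sxy / (2.0 * n) - 2.0 * p * p.T
        denom = np.sqrt(v * v.T)
        r = np.clip(delta / denom, -1.0, 1.0)

    iu, ju = np.triu_indices(matrix.n_loci, k=1)
    poly = np.minimum(p, 1.0 - p) > _EPS
    usable = (n >= 2) & poly & poly.T & (v > _EPS) & (v.T > _EPS)
    return r[iu, ju], usable[iu, ju]


def mean_r2(
    matrix: GenotypeMatrix,
    *,
    square_first: bool = True,
    max_pairs: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Mean squared Burrows correlation over usable locus pairs.

    ``square_first=False`` instead averages r over pairs and squares the
    average (an alternative reading of the statistic; the default mean of
    squares is the form LD-based Ne theory uses).  ``max_pairs`` caps the
    all-pairs scan by seeded random subsampling, for very large panels where
    LD dominates runtime.
    """
    if matrix.n_loci < 2:
        raise StatsError("LD statistic needs at least 2 loci")
    r, usable = _pairwise_r(matrix)
    if max_pairs is not None and r.size > max_pairs:
        if rng is None:
            rng = np.random.default_rng(0)
        pick = rng.choice(r.size, size=max_pairs, replace=False)
        r, usable = r[pick], usable[pick]
    if not usable.any():
        raise StatsError(
            "no usable locus pair for the LD statistic "
            "(all pairs monomorphic or insufficiently called)"
        )
    r_ok = r[usable]
    if square_first:
        return float(np.mean(r_ok**2))
    return float(np.mean(r_ok) ** 2)


# ---------------------------------------------------------------------------
# bundling


def stats_vector(
    matrix: GenotypeMatrix,
    *,
    skip_monomorphic: bool = False,
    square_first: bool = True,
    max_pairs: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> SummaryStatVector:
    """All five summary statistics for one dataset; deterministic given the matrix."""
    he = expected_heterozygosity(matrix)
    fis = fixation_index(matrix, skip_monomorphic=skip_monomorphic)
    h_mean, h_var = multilocus_homozygosity(matrix)
    r2 = mean_r2(matrix, square_first=square_first, max_pairs=max_pairs, rng=rng)
    return SummaryStatVector(he, fis, h_mean, h_var, r2)


def _stats_from_dosage(dosage: np.ndarray) -> np.ndarray:
    """Fast path for complete (no-missing) dosage matrices.

    Returns ``[he, fis, h_mean, h_var, r2]``; ``fis``/``r2`` are NaN when
    undefined (fully monomorphic sample, no usable pair) so the reference
    table builder can redraw the trial.  Must agree with
    :func:`stats_vector` on complete data — a unit test enforces this.
    """
    s, n_loci = dosage.shape
    g = dosage.astype(np.float64)
    p = g.mean(axis=0) / 2.0
    he_i = 2.0 * p * (1.0 - p)
    he = float(he_i.mean())

    poly = he_i > _EPS
    if poly.any():
        ho = (dosage == 1).mean(axis=0)
        fis = float(1.0 - np.mean(ho[poly] / he_i[poly]))
    else:
        fis = np.nan

    h = (dosage != 1).sum(axis=1)
    h_mean = float(h.mean())
    h_var = float(h.var(ddof=1)) if s >= 2 else np.nan

    p2 = (dosage == 2).mean(axis=0)
    v = p * (1.0 - p) + (p2 - p * p)
    usable_loc = poly & (v > _EPS)
    idx = np.flatnonzero(usable_loc)
    if idx.size >= 2:
        gu = g[:, idx]
        pu, vu = p[idx], v[idx]
        delta = (gu.T @ gu) / (2.0 * s) - 2.0 * np.outer(pu, pu)
        r = np.clip(delta / np.sqrt(np.outer(vu, vu)), -1.0, 1.0)
        iu, ju = np.triu_indices(idx.size, k=1)
        r2 = float(np.mean(r[iu, ju] ** 2))
    else:
        r2 = np.nan
    return np.array([he, fis, h_mean, h_var, r2])
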