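"""End-to-end Ne estimation as a scikit-learn-style estimator.

:class:`NeEstimator` consumes one genotype sample (a
:class:`~abcne.genotypes.GenotypeMatrix` or a raw ``(S, L, 2)`` allele-code
array), applies the missing-data and MAF filters, computes the five summary
statistics, builds (or reuses) a Wright–Fisher reference table matched to
the filtered sample's dimensions, and runs rejection + local-linear ABC.
Fitted attributes carry the posterior and its diagnostics; ``estimate_ne``
is the functional wrapper over the same pipeline.
"""

from __future__ import annotations

from contextlib import contextmanager
from typing import Optional, Union

import numpy as np
from sklearn.base import BaseEstimator

from . import abc as abc_mod
from .abc import AbcConfig, NeEstimate, summarize_posterior
from .genepop import FilterConfig, apply_filters
from .genotypes import GenotypeMatrix
from .simulate import PriorConfig, ReferenceTable, build_reference_table
from .stats import SummaryStatVector, stats_vector


class PipelineError(RuntimeError):
    """Failure in a named stage of the estimation pipeline."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


@contextmanager
def _stage(name: str):
    try:
        yield
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-tag with the stage name
        raise PipelineError(name, str(exc)) from exc


class NeEstimator(BaseEstimator):
    """Single-sample effective-population-size estimator (ABC + regression).

    Parameters mirror the method's configuration: uniform prior bounds on Ne
    and on the number of generations ``t``, log-uniform bounds on the
    population mutation rate theta, the per-allele mutation rate ``mu``, the
    simulation budget ``n_trials``, the sample filters, and the
    acceptance/adjustment settings.  ``maf_floor`` conditions the simulated
    loci's initial minor frequency and defaults to ``min_maf`` so the
    reference panel mirrors a MAF-filtered input.

    After :meth:`fit` the posterior is available as ``posterior_samples_``
    / ``weights_`` with summaries ``median_``, ``ci_low_``, ``ci_high_``,
    plus ``n_accepted_``, ``delta_``, ``reference_table_``,
    ``target_stats_`` and the full :class:`~abcne.abc.NeEstimate` in
    ``estimate_``.
    """

    def __init__(
        self,
        *,
        ne_low: int = 50,
        ne_high: int = 150,
        t_low: int = 2,
        t_high: int = 8,
        theta_low: float = 4.8e-5,
        theta_high: float = 4.8e-3,
        theta_prior: str = "log-uniform",
        mu: float = 1.2e-8,
        n_trials: int = 20_000,
        min_maf: float = 0.05,
        max_missing_individual: float = 0.20,
        max_missing_locus: float = 0.20,
        maf_floor: Optional[float] = None,
        acceptance_fraction: float = 0.02,
        boxcox_lambda: float = -0.2,
        standardization: str = "mad",
        adjust: bool = True,
        max_pairs: Optional[int] = None,
        random_state: Optional[int] = None,
        n_jobs: int = 1,
    ):
        self.ne_low = ne_low
        self.ne_high = ne_high
        self.t_low = t_low
        self.t_high = t_high
        self.theta_low = theta_low
        self.theta_high = theta_high
        self.theta_prior = theta_prior
        self.mu = mu
        self.n_trials = n_trials
        self.min_maf = min_maf
        self.max_missing_individual = max_missing_individual
        self.max_missing_locus = max_missing_locus
        self.maf_floor = maf_floor
        self.acceptance_fraction = acceptance_fraction
        self.boxcox_lambda = boxcox_lambda
        self.standardization = standardization
        self.adjust = adjust
        self.max_pairs = max_pairs
        self.random_state = random_state
        self.n_jobs = n_jobs

    # -- configuration views --------------------------------------------

    def _prior_config(self) -> PriorConfig:
        return PriorConfig(
            ne_low=self.ne_low,
            ne_high=self.ne_high,
            t_low=self.t_low,
            t_high=self.t_high,
            theta_low=self.theta_low,
            theta_high=self.theta_high,
            mu=self.mu,
            trials_j=self.n_trials,
            theta_prior=self.theta_prior,
        )

    def _filter_config(self) -> FilterConfig:
        return FilterConfig(
            min_maf=self.min_maf,
            max_missing_individual=self.max_missing_individual,
            max_missing_locus=self.max_missing_locus,
        )

    def _abc_config(self) -> AbcConfig:
        return AbcConfig(
            acceptance_fraction=self.acceptance_fraction,
            boxcox_lambda=self.boxcox_lambda,
            standardization=self.standardization,
            adjust=self.adjust,
        )

    # -- fitting ---------------------------------------------------------

    def fit(
        self,
        X: Union[GenotypeMatrix, np.ndarray],
        y=None,
        *,
        reference_table: Optional[ReferenceTable] = None,
    ) -> "NeEstimator":
        """Estimate Ne from one genotype sample.

        ``reference_table`` reuses a precomputed table (its (S, L) must
        match the filtered sample), which is how replicate analyses at the
        same design share the expensive simulation step.
        """
        with _stage("configuration"):
            priors = self._prior_config()
            filters = self._filter_config()
            abc_cfg = self._abc_config()
            maf_floor = self.min_maf if self.maf_floor is None else self.maf_floor
            root = np.random.SeedSequence(self.random_state)
            table_seed, pair_seed = root.spawn(2)

        with _stage("input"):
            if not isinstance(X, GenotypeMatrix):
                X = GenotypeMatrix(np.asarray(X))

        with _stage("filter"):
            matrix = apply_filters(X, filters)

        with _stage("summary-statistics"):
            target = stats_vector(
                matrix,
                skip_monomorphic=True,
                max_pairs=self.max_pairs,
                rng=np.random.default_rng(pair_seed),
            )

        with _stage("reference-table"):
            if reference_table is None:
                table = build_reference_table(
                    priors,
                    matrix.n_individuals,
                    matrix.n_loci,
                    maf_floor=maf_floor,
                    seed=table_seed,
                    workers=self.n_jobs,
                )
            else:
                table = reference_table
                if (
                    table.n_individuals != matrix.n_individuals
                    or table.n_loci != matrix.n_loci
                ):
                    raise ValueError(
                        f"reference table is {table.n_individuals}x{table.n_loci} "
                        f"but the filtered sample is "
                        f"{matrix.n_individuals}x{matrix.n_loci}"
                    )

        with _stage("standardize"):
            z_table, z_target, kept = abc_mod.standardize_stats(
                table.stats,
                target.as_array(),
                method=abc_cfg.standardization,
                names=SummaryStatVector.names,
            )

        with _stage("select"):
            accepted, dist, delta = abc_mod.select_accepted(
                z_table, z_target, abc_cfg.acceptance_fraction
            )

        with _stage("regression-adjust"):
            samples, weights, diagnostics = abc_mod.local_linear_adjust(
                table.ne[accepted],
                z_table[accepted],
                z_target,
                dist,
                delta,
                abc_cfg,
                (float(self.ne_low), float(self.ne_high)),
            )
            diagnostics["kept_statistics"] = [
                SummaryStatVector.names[k] for k in np.flatnonzero(kept)
            ]
            diagnostics["n_filtered_individuals"] = matrix.n_individuals
            diagnostics["n_filtered_loci"] = matrix.n_loci

        with _stage("summarize"):
            estimate = summarize_posterior(
                samples,
                weights,
                n_accepted=accepted.size,
                delta_used=delta,
                mode=diagnostics.get("mode", "regression"),
                diagnostics=diagnostics,
                seed=self.random_state,
                config=self.get_params(),
            )

        self.filtered_matrix_ = matrix
        self.target_stats_ = target
        self.reference_table_ = table
        self.posterior_samples_ = estimate.posterior_samples
        self.weights_ = estimate.weights
        self.median_ = estimate.median
        self.ci_low_ = estimate.ci_low
        self.ci_high_ = estimate.ci_high
        self.n_accepted_ = estimate.n_accepted
        self.delta_ = estimate.delta_used
        self.mode_ = estimate.mode
        self.n_individuals_ = matrix.n_individuals
        self.n_loci_ = matrix.n_loci
        self.estimate_ = estimate
        return self

    def summary(self) -> str:
        """Human-readable one-paragraph report of the fitted estimate."""
        if not hasattr(self, "estimate_"):
            raise RuntimeError("call fit() first")
        e = self.estimate_
        return (
            f"Ne median {e.median:.1f} "
            f"(95% interval {e.ci_low:.1f}-{e.ci_high:.1f}); "
            f"{e.n_accepted} accepted simulations at delta={e.delta_used:.4g} "
            f"({e.mode} mode) from {len(self.reference_table_)} trials on a "
            f"{self.n_individuals_}x{self.n_loci_} filtered sample"
        )


def estimate_ne(
    matrix: Union[GenotypeMatrix, np.ndarray],
    priors: Optional[PriorConfig] = None,
    filters: Optional[FilterConfig] = None,
    abc: Optional[AbcConfig] = None,
    seed: Optional[int] = None,
    workers: int = 1,
    *,
    maf_floor: Optional[float] = None,
    max_pairs: Optional[int] = None,
    reference_table: Optional[ReferenceTable] = None,
) -> NeEstimate:
    """Functional façade over :class:`NeEstimator` using config dataclasses."""
    priors = priors or PriorConfig()
    filters = filters or FilterConfig()
    abc = abc or AbcConfig()
    est = NeEstimator(
        ne_low=priors.ne_low,
        ne_high=priors.ne_high,
        t_low=priors.t_low,
        t_high=priors.t_high,
        theta_low=priors.theta_low,
        theta_high=priors.theta_high,
        theta_prior=priors.theta_prior,
        mu=priors.mu,
        n_trials=priors.trials_j,
        min_maf=filters.min_maf,
        max_missing_individual=filters.max_missing_individual,
        max_missing_locus=filters.max_missing_locus,
        maf_floor=maf_floor,
        acceptance_fraction=abc.acceptance_fraction,
        boxcox_lambda=abc.boxcox_lambda,
        standardization=abc.standardization,
        adjust=abc.adjust,
        max_pairs=max_pairs,
        random_state=seed,
        n_jobs=workers,
    )
    est.fit(matrix, reference_table=reference_table)
    return est.estimate_
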