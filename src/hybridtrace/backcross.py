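"""Multinomial likelihoods for backcross-generation models.

A BCgF1 individual results from an interspecific F1 backcrossed to the
recurrent parent (species A) for g successive generations.  At sites
fixed for opposite alleles in the two species, its expected genotype
class frequencies are

    q_Aa = (1 - p_error) * 2^(-g)
    q_AA = (1 - p_error) * (1 - 2^(-g))
    q_aa = p_error

where ``p_error`` absorbs genotyping error and mis-ascribed fixed
differences: the aa class (homozygous for the donor allele) is
impossible under a pure backcross pedigree, so all its observed mass is
attributed to error.  g=1 gives ((1-p)/2, (1-p)/2, p) and g=2 gives
(3(1-p)/4, (1-p)/4, p); g=0 (a plain F1) makes q_AA = 0, so any observed
AA genotype drives the F1 model's likelihood to -inf.

The log-likelihood of observed class counts (N_AA, N_Aa, N_aa) is the
multinomial log-pmf, with the multinomial coefficient evaluated by
log-gamma.  The coefficient is identical across models for fixed counts,
so model ranking does not depend on it, but reported values include it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2

from hybridtrace.errors import ArgumentError

NEG_INF = float("-inf")


@dataclass(frozen=True)
class BackcrossModel:
    """A backcross-generation hypothesis with its class probabilities."""

    generation: int
    p_error: float
    q_AA: float
    q_Aa: float
    q_aa: float

    @property
    def name(self) -> str:
        return "F1" if self.generation == 0 else f"BC{self.generation}F1"

    @property
    def q(self) -> tuple[float, float, float]:
        return (self.q_AA, self.q_Aa, self.q_aa)


@dataclass(frozen=True)
class ModelComparisonResult:
    """Ranked model fits on one set of genotype-class counts."""

    models: tuple[BackcrossModel, ...]
    lnL: tuple[float, ...]
    best: BackcrossModel
    runner_up: BackcrossModel
    delta_lnL: float
    lrt_statistic: float
    p_value_heuristic: float  #: chi-square(df=1) tail of 2*delta_lnL; heuristic —
    #: the compared models are non-nested point hypotheses
    p_value_bootstrap: float | None = None

    def as_dict(self) -> dict:
        return {
            "models": [
                {"name": m.name, "generation": m.generation, "p_error": m.p_error,
                 "q": list(m.q), "lnL": l}
                for m, l in zip(self.models, self.lnL)
            ],
            "best": self.best.name,
            "runner_up": self.runner_up.name,
            "delta_lnL": self.delta_lnL,
            "lrt_statistic": self.lrt_statistic,
            "p_value_heuristic": self.p_value_heuristic,
            "p_value_bootstrap": self.p_value_bootstrap,
        }


def expected_frequencies(g: int, p_error: float) -> tuple[float, float, float]:
    """Expected (q_AA, q_Aa, q_aa) for a BCgF1 individual at diagnostic sites."""
    if g < 0:
        raise ArgumentError("generation must be >= 0")
    if not 0 <= p_error < 1:
        raise ArgumentError("p_error must be in [0, 1)")
    het = 2.0 ** (-g)
    return ((1 - p_error) * (1 - het), (1 - p_error) * het, p_error)


def make_model(g: int, p_error: float) -> BackcrossModel:
    q_AA, q_Aa, q_aa = expected_frequencies(g, p_error)
    return BackcrossModel(generation=g, p_error=p_error, q_AA=q_AA, q_Aa=q_Aa, q_aa=q_aa)


def _check_counts(counts: Sequence[int]) -> np.ndarray:
    counts = np.asarray(counts, dtype=np.int64)
    if counts.shape != (3,):
        raise ArgumentError("counts must be (N_AA, N_Aa, N_aa)")
    if np.any(counts < 0):
        raise ArgumentError("counts must be non-negative")
    return counts


def log_likelihood(counts: Sequence[int], model: BackcrossModel) -> float:
    """Multinomial log-likelihood of class counts under a backcross model.

    Includes the log-gamma multinomial coefficient.  A class with zero
    probability but positive count yields ``-inf`` (not an exception).
    """
    counts = _check_counts(counts)
    total = counts.sum()
    if total == 0:
        raise ArgumentError("total count must be positive")
    q = np.asarray(model.q, dtype=float)
    if np.any((q == 0) & (counts > 0)):
        return NEG_INF
    coeff = gammaln(total + 1) - gammaln(counts + 1).sum()
    nz = counts > 0
    return float(coeff + np.sum(counts[nz] * np.log(q[nz])))


def estimate_error_rate(counts: Sequence[int]) -> float:
    """Observed aa-class fraction N_aa / total, the plug-in error rate.

    The aa class is impossible under a pure backcross pedigree, so its
    observed frequency estimates the combined genotyping/ascertainment
    error.  Returned unrounded; callers may override with a fixed value.
    """
    counts = _check_counts(counts)
    total = counts.sum()
    if total == 0:
        raise ArgumentError("total count must be positive")
    p = float(counts[2] / total)
    if p >= 0.5:
        warnings.warn(
            "estimated error rate >= 0.5: the aa class dominates; the "
            "backcross-direction assumption is probably violated",
            stacklevel=2,
        )
    return p


def compare_models(
    counts: Sequence[int],
    generations: Sequence[int],
    p_error: float | None = None,
    bootstrap_reps: int = 0,
    seed: int | None = None,
) -> ModelComparisonResult:
    """Fit and rank backcross-generation models on genotype-class counts.

    Parameters
    ----------
    counts:
        (N_AA, N_Aa, N_aa).
    generations:
        Generations g to compare (>= 2 of them).
    p_error:
        Error rate shared by all models; default is the plug-in estimate
        :func:`estimate_error_rate`.
    bootstrap_reps:
        If > 0, also compute a parametric-bootstrap p-value of the best
        model against the runner-up (see :func:`bootstrap_pvalue`).

    Notes
    -----
    The heuristic p-value is the chi-square(df=1) tail probability of
    ``2 * delta_lnL``.  The compared models are simple (non-nested point)
    hypotheses, so this is a rough reference only; the bootstrap p-value
    is the recommended inferential statement.
    """
    generations = list(generations)
    if len(generations) < 2:
        raise ArgumentError("at least 2 generations must be compared")
    counts = _check_counts(counts)
    if p_error is None:
        p_error = estimate_error_rate(counts)
    models = tuple(make_model(g, p_error) for g in generations)
    lnL = tuple(log_likelihood(counts, m) for m in models)
    order = sorted(range(len(models)), key=lambda i: lnL[i], reverse=True)
    best, runner = models[order[0]], models[order[1]]
    if math.isinf(lnL[order[0]]):
        raise ArgumentError("all models have -inf likelihood on these counts")
    delta = lnL[order[0]] - lnL[order[1]]  # inf if runner-up is impossible
    lrt = 2 * delta
    p_heur = float(chi2.sf(lrt, df=1)) if math.isfinite(lrt) else 0.0
    p_boot = None
    if bootstrap_reps:
        p_boot = bootstrap_pvalue(
            counts, null_model=runner, alt_model=best, n_reps=bootstrap_reps, seed=seed
        )
    return ModelComparisonResult(
        models=models,
        lnL=lnL,
        best=best,
        runner_up=runner,
        delta_lnL=float(delta),
        lrt_statistic=float(lrt),
        p_value_heuristic=p_heur,
        p_value_bootstrap=p_boot,
    )


def bootstrap_pvalue(
    counts: Sequence[int],
    null_model: BackcrossModel,
    alt_model: BackcrossModel,
    n_reps: int = 1000,
    seed: int | None = None,
) -> float:
    """Parametric-bootstrap p-value for alt vs. null backcross models.

    Simulates ``n_reps`` multinomial count vectors of the observed total
    under the null model and returns the fraction whose likelihood-ratio
    statistic ``2 (lnL_alt - lnL_null)`` is at least the observed one.
    Reproducible under a fixed ``seed``; resolution is 1/n_reps.
    """
    if n_reps < 100:
        raise ArgumentError("n_reps must be >= 100")
    counts = _check_counts(counts)
    total = int(counts.sum())
    rng = np.random.default_rng(seed)

    def stat(c: np.ndarray) -> float:
        ln_null = log_likelihood(c, null_model)
        ln_alt = log_likelihood(c, alt_model)
        if ln_alt == NEG_INF and ln_null == NEG_INF:
            return 0.0
        return 2 * (ln_alt - ln_null)

    observed = stat(counts)
    sims = rng.multinomial(total, np.asarray(null_model.q, dtype=float), size=n_reps)
    exceed = sum(1 for c in sims if stat(c) >= observed)
    return exceed / n_reps
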