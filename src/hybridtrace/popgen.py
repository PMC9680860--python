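"""Nucleotide diversity and genome-averaged Wright's F_ST.

The diversity estimator is the average pairwise difference among the
``n = 2 x (diploid panel size)`` sampled chromosomes, with a small-sample
factor ``n/(n-1)`` and normalization by the average number of mapped
(callable) sites ``L_bar``:

    theta_pi = (1 / L_bar) * (n / (n - 1)) * sum_{i<j} k_ij / (n(n-1)/2)

where ``k_ij`` is the number of nucleotide differences between haplotype
sequences i and j.  Because all sites are biallelic and genotypes
unphased, the pairwise sum is computed per site from allele counts: a
site with minor-allele count ``c`` among ``n`` chromosomes contributes
``c * (n - c)`` to ``sum k_ij``, which equals the explicit all-pairs sum
regardless of phase.

``L_bar`` is the mean over panel samples of the number of reference
positions with a confident call.  It depends on upstream coverage data
the pipeline does not see, so it is always an explicit input.

F_ST at a site is ``(H_T - H_S) / H_T`` with ``H_S`` the unweighted mean
of the two within-panel expected heterozygosities ``2p(1-p)`` and ``H_T``
the expected heterozygosity at the pooled (equal-weight) allele
frequency.  Genome-wide F_ST is by default the arithmetic mean of
per-site values over sites with ``H_T > 0``; a ratio-of-means variant is
available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from hybridtrace.errors import ArgumentError, UndefinedResultError
from hybridtrace.variants_io import MISSING, GenotypeMatrix, SamplePanel


@dataclass(frozen=True)
class DiversityResult:
    """Per-site nucleotide diversity of one panel."""

    theta_pi: float
    n_chromosomes: int
    L_bar: float
    n_snps_used: int


@dataclass(frozen=True)
class FstResult:
    """Genome-averaged Wright's F_ST between two panels."""

    fst_mean: float
    n_sites: int


def _alt_counts(matrix: GenotypeMatrix, idx: np.ndarray) -> tuple[np.ndarray, int]:
    """Per-site count of alt alleles among the 2*len(idx) panel chromosomes."""
    gt = matrix.gt[:, idx, :]
    if np.any(gt == MISSING):
        raise ArgumentError(
            "matrix contains missing genotypes in the panel; "
            "apply filter_biallelic_complete first"
        )
    if np.any(gt > 1):
        raise ArgumentError("matrix contains non-biallelic genotypes; filter first")
    n = 2 * len(idx)
    return gt.sum(axis=(1, 2)), n


def nucleotide_diversity(
    matrix: GenotypeMatrix, panel: SamplePanel | str, L_bar: float
) -> DiversityResult:
    """Panel nucleotide diversity theta_pi.

    Parameters
    ----------
    matrix:
        Pre-filtered to biallelic SNPs with no missing genotype within
        the panel.  Sites monomorphic in the panel contribute zero and
        may be present.
    panel:
        Panel (or panel name registered on the matrix) of >= 2 diploids.
    L_bar:
        Average number of mapped/callable sites per panel sample; the
        per-site denominator of the estimator.
    """
    if L_bar <= 0:
        raise ArgumentError("L_bar must be positive")
    idx = matrix.panel_indices(panel)
    if len(idx) < 2:
        raise ArgumentError("panel must contain at least 2 samples")
    c_alt, n = _alt_counts(matrix, idx)
    # per-site contribution to sum_{i<j} k_ij for a biallelic site
    k_sum = float(np.sum(c_alt.astype(np.float64) * (n - c_alt)))
    n_pairs = n * (n - 1) / 2
    theta = (1.0 / L_bar) * (n / (n - 1)) * (k_sum / n_pairs)
    return DiversityResult(
        theta_pi=theta,
        n_chromosomes=n,
        L_bar=float(L_bar),
        n_snps_used=int(np.count_nonzero((c_alt > 0) & (c_alt < n))),
    )


def pairwise_fst(
    matrix: GenotypeMatrix,
    panelA: SamplePanel | str,
    panelB: SamplePanel | str,
    ratio_of_means: bool = False,
) -> FstResult:
    """Genome-averaged Wright's F_ST between two panels.

    Sites must be biallelic with no missing genotype in either panel.
    Sites with zero total heterozygosity (monomorphic in the pooled
    sample) are skipped.  With ``ratio_of_means=True`` the estimate is
    ``sum(H_T - H_S) / sum(H_T)`` instead of the mean of per-site ratios.
    """
    iA = matrix.panel_indices(panelA)
    iB = matrix.panel_indices(panelB)
    if len(iA) < 2 or len(iB) < 2:
        raise ArgumentError("both panels must contain at least 2 samples")
    cA, nA = _alt_counts(matrix, iA)
    cB, nB = _alt_counts(matrix, iB)
    pA = cA / nA
    pB = cB / nB
    hA = 2 * pA * (1 - pA)
    hB = 2 * pB * (1 - pB)
    hS = (hA + hB) / 2
    pbar = (pA + pB) / 2
    hT = 2 * pbar * (1 - pbar)
    informative = hT > 0
    if not np.any(informative):
        raise UndefinedResultError("no sites with H_T > 0; F_ST undefined")
    if ratio_of_means:
        fst = float((hT[informative] - hS[informative]).sum() / hT[informative].sum())
    else:
        fst = float(np.mean(1.0 - hS[informative] / hT[informative]))
    return FstResult(fst_mean=fst, n_sites=int(np.count_nonzero(informative)))


def per_site_fst(pA: np.ndarray, pB: np.ndarray) -> np.ndarray:
    """Per-site Wright's F_ST from the two panels' allele frequencies.

    NaN where the pooled sample is monomorphic.
    """
    pA = np.asarray(pA, dtype=float)
    pB = np.asarray(pB, dtype=float)
    hS = (2 * pA * (1 - pA) + 2 * pB * (1 - pB)) / 2
    pbar = (pA + pB) / 2
    hT = 2 * pbar * (1 - pbar)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(hT > 0, 1.0 - hS / hT, np.nan)
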