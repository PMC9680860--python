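"""Species-diagnostic SNP extraction and focal-genotype classification.

A diagnostic (discriminatory) site is a biallelic SNP at which every
sample of one parental panel is homozygous for one allele and every
sample of the other panel is homozygous for the other allele — "fixed in
the opposite direction".  At such sites the focal individual's genotype
reveals its ancestry dosage: homozygous for the panel-A allele (class
``AA``), heterozygous (``Aa``) or homozygous for the panel-B allele
(``aa``).

Fixation is judged on genotype calls (all samples homozygous), matching
small panels of a few individuals per species; an allele-frequency
threshold mode (``min_freq``) is available for larger panels but is off
by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hybridtrace.errors import ArgumentError, ConfigurationError, DataError
from hybridtrace.variants_io import MISSING, GenotypeMatrix, SamplePanel

#: genotype class codes used throughout the pipeline
CLASS_AA, CLASS_HET, CLASS_aa, CLASS_OTHER = 0, 1, 2, 3
CLASS_LABELS = ("AA", "Aa", "aa", "other")


@dataclass(frozen=True)
class DiagnosticSiteSet:
    """Sites fixed for opposite alleles between two parental panels.

    ``table`` has columns ``chrom, pos, allele_A, allele_a`` sorted in
    matrix order; ``site_index`` holds each row's index into the source
    matrix.  ``allele_A`` is the panel-A-specific base.
    """

    table: pd.DataFrame
    site_index: np.ndarray
    panelA_name: str = "parentA"
    panelB_name: str = "parentB"

    def __len__(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class GenotypeClassTable:
    """Counts and fractions of focal genotype classes per scope.

    One row per chromosome (plus ``unanchored`` if contigs were grouped)
    and a genome-wide ``All`` row equal to the column-wise sum of the
    others.  ``other`` counts focal genotypes carrying an allele that is
    neither parental-panel allele; they are excluded from the three-class
    fractions.
    """

    table: pd.DataFrame

    @property
    def counts(self) -> tuple[int, int, int]:
        """Genome-wide (N_AA, N_Aa, N_aa)."""
        row = self.table.loc["All"]
        return int(row["N_AA"]), int(row["N_Aa"]), int(row["N_aa"])


def find_discriminatory_sites(
    matrix: GenotypeMatrix,
    panelA: SamplePanel | str,
    panelB: SamplePanel | str,
    min_freq: float = 1.0,
) -> DiagnosticSiteSet:
    """Find sites fixed for opposite alleles in the two parental panels.

    The matrix must already be restricted to biallelic SNPs with no
    missing genotype across both panels (and the focal sample, if the
    result will be used for classification).

    Parameters
    ----------
    min_freq:
        Minimum within-panel frequency of the panel-specific allele.
        The default 1.0 requires strict fixation (every sample
        homozygous); lower values admit near-fixed sites in larger
        panels.
    """
    if isinstance(panelA, str):
        panelA = matrix.panels[panelA]
    if isinstance(panelB, str):
        panelB = matrix.panels[panelB]
    shared = set(panelA.sample_ids) & set(panelB.sample_ids)
    if shared:
        raise ConfigurationError(f"panels share sample ids: {sorted(shared)}")
    iA = matrix.panel_indices(panelA)
    iB = matrix.panel_indices(panelB)
    gA = matrix.gt[:, iA, :]
    gB = matrix.gt[:, iB, :]
    if np.any(gA == MISSING) or np.any(gB == MISSING):
        raise DataError("missing genotypes in parental panels; filter first")

    if min_freq >= 1.0:
        fixedA = (gA == gA[:, :1, :1]).all(axis=(1, 2))
        fixedB = (gB == gB[:, :1, :1]).all(axis=(1, 2))
        aA = gA[:, 0, 0].astype(np.int64)
        aB = gB[:, 0, 0].astype(np.int64)
        mask = fixedA & fixedB & (aA != aB)
    else:
        # frequency-threshold mode: major allele of each panel at >= min_freq
        if not (0.5 < min_freq < 1.0):
            raise ArgumentError("min_freq must be in (0.5, 1.0] ")
        altA = gA.sum(axis=(1, 2)) / (2 * len(iA))
        altB = gB.sum(axis=(1, 2)) / (2 * len(iB))
        aA = (altA >= 0.5).astype(np.int64)
        aB = (altB >= 0.5).astype(np.int64)
        freqA = np.where(aA == 1, altA, 1 - altA)
        freqB = np.where(aB == 1, altB, 1 - altB)
        mask = (freqA >= min_freq) & (freqB >= min_freq) & (aA != aB)

    idx = np.flatnonzero(mask)
    allele_A = [matrix.alleles(i)[aA[i]] for i in idx]
    allele_a = [matrix.alleles(i)[aB[i]] for i in idx]
    table = pd.DataFrame(
        {
            "chrom": np.asarray(matrix.chrom, dtype=object)[idx],
            "pos": matrix.pos[idx],
            "allele_A": allele_A,
            "allele_a": allele_a,
            "idx_A": aA[idx],
            "idx_a": aB[idx],
        }
    ).reset_index(drop=True)
    return DiagnosticSiteSet(
        table=table, site_index=idx, panelA_name=panelA.name, panelB_name=panelB.name
    )


def classify_focal_genotypes(
    siteset: DiagnosticSiteSet,
    matrix: GenotypeMatrix,
    focal: str,
    anchored: "list[str] | None" = None,
) -> tuple[pd.DataFrame, GenotypeClassTable]:
    """Classify the focal individual's genotype at each diagnostic site.

    Returns ``(classes, table)`` where ``classes`` is a per-site frame
    with columns ``chrom, pos, class`` (labels ``AA``/``Aa``/``aa``/
    ``other``) in chromosome order, and ``table`` aggregates counts and
    fractions per chromosome plus a genome-wide ``All`` row.

    Parameters
    ----------
    anchored:
        If given, chromosomes not in this list are pooled into a single
        ``unanchored`` scope (the genome-wide row still includes them).
    """
    j = matrix.sample_index(focal)
    idx = siteset.site_index
    g = matrix.gt[idx, j, :].astype(np.int64)
    if np.any(g == MISSING):
        bad = int(np.flatnonzero(np.any(g == MISSING, axis=1))[0])
        raise DataError(
            f"missing focal genotype at diagnostic site "
            f"{siteset.table['chrom'][bad]}:{siteset.table['pos'][bad]}"
        )
    iA = siteset.table["idx_A"].to_numpy()
    ia = siteset.table["idx_a"].to_numpy()
    a, b = g[:, 0], g[:, 1]
    cls = np.full(len(idx), CLASS_OTHER, dtype=np.int8)
    cls[(a == iA) & (b == iA)] = CLASS_AA
    cls[(a == ia) & (b == ia)] = CLASS_aa
    cls[(np.minimum(iA, ia) == a) & (np.maximum(iA, ia) == b)] = CLASS_HET

    classes = pd.DataFrame(
        {
            "chrom": siteset.table["chrom"],
            "pos": siteset.table["pos"],
            "class": [CLASS_LABELS[c] for c in cls],
        }
    )
    return classes, tabulate_classes(classes, anchored=anchored)


def tabulate_classes(
    classes: pd.DataFrame, anchored: "list[str] | None" = None
) -> GenotypeClassTable:
    """Aggregate per-site classes into per-scope counts and fractions."""
    scope = classes["chrom"].astype(object)
    if anchored is not None:
        scope = scope.where(scope.isin(anchored), "unanchored")
    rows = []
    scopes = list(dict.fromkeys(scope))
    for s in scopes + ["All"]:
        sub = classes if s == "All" else classes[(scope == s).to_numpy()]
        counts = {lab: int((sub["class"] == lab).sum()) for lab in CLASS_LABELS}
        n3 = counts["AA"] + counts["Aa"] + counts["aa"]
        rows.append(
            {
                "scope": s,
                "N_AA": counts["AA"],
                "N_Aa": counts["Aa"],
                "N_aa": counts["aa"],
                "N_other": counts["other"],
                "frac_AA": counts["AA"] / n3 if n3 else np.nan,
                "frac_Aa": counts["Aa"] / n3 if n3 else np.nan,
                "frac_aa": counts["aa"] / n3 if n3 else np.nan,
            }
        )
    return GenotypeClassTable(table=pd.DataFrame(rows).set_index("scope"))


def per_chromosome_summary(classes: pd.DataFrame) -> pd.DataFrame:
    """Per-chromosome heterozygosity rate N_Aa / (N_AA + N_Aa + N_aa).

    ``other``-class sites are excluded from the denominator.  A
    chromosome whose sites are all ``other`` gets rate NaN (undefined),
    never 0.
    """
    rows = []
    for chrom, sub in classes.groupby("chrom", sort=False):
        n_aa = int((sub["class"] == "AA").sum())
        n_het = int((sub["class"] == "Aa").sum())
        n_bb = int((sub["class"] == "aa").sum())
        total = n_aa + n_het + n_bb
        rows.append(
            {
                "chrom": chrom,
                "n_sites": total,
                "het_rate": n_het / total if total else np.nan,
            }
        )
    return pd.DataFrame(rows)
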