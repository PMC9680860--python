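"""Synthetic hybrid-pedigree genomes with ground truth.

The generator emulates the data regime the pipeline is designed for: two
diverged diploid species panels genotyped at many SNPs, of which a
configurable fraction are fixed for opposite alleles between the species
(the true diagnostic sites), a fraction are polymorphic within one
species, and the rest are monomorphic.  A focal individual is built from
a cross/backcross pedigree (F1, BC1F1, BC2F1, or deeper) using
Haldane-model meiosis: crossover counts per chromosome are Poisson with
mean equal to the genetic map length in Morgans, breakpoints uniform on
the site-index range, no interference.  Organelles are inherited
maternally and recorded as a lineage label.  Genotype error is applied
to the focal sample only.

Site roles are assigned in exact (rounded) proportions and shuffled, so
a configuration requesting e.g. 2,000 diagnostic sites per chromosome
yields exactly that many.  Within-species polymorphic sites are
resampled until the drawn panel is actually polymorphic; without this,
a noticeable fraction of such sites would by chance be fixed in a small
panel and contaminate the diagnostic set, and the generator's truth
record could not list the diagnostic sites exactly.

All randomness flows from one seeded generator; the seed and full
configuration are recorded in the output VCF header, and equal seeds
give byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from hybridtrace.errors import ArgumentError
from hybridtrace.variants_io import GenotypeMatrix, SamplePanel, write_vcf

_BASES = np.array(list("ACGT"))

#: site roles
ROLE_FIXED_DIFF, ROLE_POLY_A, ROLE_POLY_B, ROLE_MONO = 0, 1, 2, 3


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulated dataset.

    Defaults mirror the study design the pipeline targets at desk scale:
    three diploid individuals per parental species, ten chromosomes, one
    Morgan of genetic map per chromosome, a 2% focal genotype error
    rate, and 2,000 diagnostic sites per chromosome (half of 4,000
    simulated SNPs; a quarter polymorphic within a species, the rest
    monomorphic).
    """

    n_chromosomes: int = 10
    sites_per_chromosome: int = 4000
    map_length: float = 1.0  #: Morgans per chromosome
    fixed_diff_fraction: float = 0.5
    within_pop_het_fraction: float = 0.25  #: split evenly between the species
    n_panelA: int = 3
    n_panelB: int = 3
    error_rate: float = 0.02
    seed: int = 1
    site_spacing: int = 100  #: bp between adjacent simulated sites
    chrom_prefix: str = "chr"

    def __post_init__(self) -> None:
        if self.fixed_diff_fraction + self.within_pop_het_fraction > 1 + 1e-12:
            raise ArgumentError("fixed_diff_fraction + within_pop_het_fraction must be <= 1")
        if self.map_length < 0:
            raise ArgumentError("map_length must be >= 0")
        if not 0 <= self.error_rate < 1:
            raise ArgumentError("error_rate must be in [0, 1)")
        if min(self.n_chromosomes, self.sites_per_chromosome) < 1:
            raise ArgumentError("need at least one chromosome and one site")

    @property
    def chrom_names(self) -> list[str]:
        return [f"{self.chrom_prefix}{i + 1}" for i in range(self.n_chromosomes)]


@dataclass
class SiteModel:
    """Per-chromosome site parameterization drawn once per simulation."""

    role: list  # per-chrom int8 arrays
    species_allele_A: list  # allele index carried by species A (per site)
    species_allele_B: list
    freq_alt: list  # alt-allele frequency in the polymorphic species (NaN elsewhere)
    ref: list  # base chars
    alt: list


@dataclass
class SimulatedIndividual:
    """A diploid with per-chromosome haplotypes and ancestry labels.

    ``haplotypes[c]`` is a ``(2, n_sites)`` array of allele indices;
    ``ancestry[c]`` the matching array of species-of-origin labels
    (0 = species A, 1 = species B).  The organelle label records the
    maternal lineage.
    """

    haplotypes: list
    ancestry: list
    sex: str = "U"
    organelle: str = "A"


def _draw_site_model(config: SimConfig, rng: np.random.Generator) -> SiteModel:
    S = config.sites_per_chromosome
    n_fd = round(config.fixed_diff_fraction * S)
    n_wp = round(config.within_pop_het_fraction * S)
    n_pa = n_wp // 2
    n_pb = n_wp - n_pa
    n_mono = S - n_fd - n_pa - n_pb
    base_roles = np.concatenate(
        [
            np.full(n_fd, ROLE_FIXED_DIFF, dtype=np.int8),
            np.full(n_pa, ROLE_POLY_A, dtype=np.int8),
            np.full(n_pb, ROLE_POLY_B, dtype=np.int8),
            np.full(n_mono, ROLE_MONO, dtype=np.int8),
        ]
    )
    roles, sA, sB, freqs, refs, alts = [], [], [], [], [], []
    for _ in range(config.n_chromosomes):
        role = rng.permutation(base_roles)
        # which of ref(0)/alt(1) species A carries at fixed-difference sites
        a_of_A = rng.integers(0, 2, size=S).astype(np.int8)
        allele_A = np.zeros(S, dtype=np.int8)
        allele_B = np.zeros(S, dtype=np.int8)
        fd = role == ROLE_FIXED_DIFF
        allele_A[fd] = a_of_A[fd]
        allele_B[fd] = 1 - a_of_A[fd]
        freq = np.full(S, np.nan)
        poly = (role == ROLE_POLY_A) | (role == ROLE_POLY_B)
        freq[poly] = rng.uniform(0.1, 0.9, size=int(poly.sum()))
        ref_idx = rng.integers(0, 4, size=S)
        alt_idx = (ref_idx + rng.integers(1, 4, size=S)) % 4
        roles.append(role)
        sA.append(allele_A)
        sB.append(allele_B)
        freqs.append(freq)
        refs.append(_BASES[ref_idx])
        alts.append(_BASES[alt_idx])
    return SiteModel(role=roles, species_allele_A=sA, species_allele_B=sB,
                     freq_alt=freqs, ref=refs, alt=alts)


def _draw_haplotype(
    sites: SiteModel, chrom: int, species: int, rng: np.random.Generator
) -> np.ndarray:
    base = (sites.species_allele_A if species == 0 else sites.species_allele_B)[chrom]
    hap = base.copy()
    poly_role = ROLE_POLY_A if species == 0 else ROLE_POLY_B
    poly = sites.role[chrom] == poly_role
    n = int(poly.sum())
    if n:
        hap[poly] = (rng.random(n) < sites.freq_alt[chrom][poly]).astype(np.int8)
    return hap


def draw_individual(
    sites: SiteModel, species: int, rng: np.random.Generator, sex: str = "U"
) -> SimulatedIndividual:
    """Draw one individual of the given species (0 = A, 1 = B)."""
    n_chrom = len(sites.role)
    haps = [np.stack([_draw_haplotype(sites, c, species, rng) for _ in range(2)])
            for c in range(n_chrom)]
    anc = [np.full((2, len(sites.role[c])), species, dtype=np.int8) for c in range(n_chrom)]
    return SimulatedIndividual(
        haplotypes=haps, ancestry=anc, sex=sex, organelle="AB"[species]
    )


def simulate_parental_panels(
    config: SimConfig, rng: np.random.Generator
) -> tuple[list, list, SiteModel]:
    """Draw the two parental panels and the site parameterization.

    Within-species polymorphic sites are redrawn until the panel sample
    segregates at them, so the true diagnostic sites are exactly the
    fixed-difference sites (role 0) — nothing else can appear fixed-
    opposite in the panels.
    """
    sites = _draw_site_model(config, rng)
    panels: list[list] = []
    for species, n_ind in ((0, config.n_panelA), (1, config.n_panelB)):
        inds = [draw_individual(sites, species, rng) for _ in range(n_ind)]
        poly_role = ROLE_POLY_A if species == 0 else ROLE_POLY_B
        for c in range(config.n_chromosomes):
            poly_idx = np.flatnonzero(sites.role[c] == poly_role)
            if len(poly_idx) == 0 or n_ind == 0:
                continue
            haps = np.stack([ind.haplotypes[c][h] for ind in inds for h in range(2)])
            freq = sites.freq_alt[c][poly_idx]
            fixed_in_sample = np.all(
                haps[:, poly_idx] == haps[:1, poly_idx], axis=0
            )
            bad = poly_idx[fixed_in_sample]
            while len(bad):
                redraw = (rng.random((haps.shape[0], len(bad)))
                          < sites.freq_alt[c][bad]).astype(np.int8)
                haps[:, bad] = redraw
                still = np.all(redraw == redraw[:1], axis=0)
                bad = bad[still]
            for i, ind in enumerate(inds):
                ind.haplotypes[c][0] = haps[2 * i]
                ind.haplotypes[c][1] = haps[2 * i + 1]
        panels.append(inds)
    return panels[0], panels[1], sites


def meiosis(
    parent: SimulatedIndividual, chrom: int, map_length: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One gamete haplotype for ``chrom`` under the Haldane model.

    Crossover count ~ Poisson(map_length); breakpoints uniform on the
    site-index range; the gamete alternates between the parent's two
    haplotypes starting from one chosen with probability 1/2.  Returns
    ``(alleles, ancestry)`` arrays.
    """
    S = parent.haplotypes[chrom].shape[1]
    n_cx = rng.poisson(map_length)
    breaks = np.sort(rng.uniform(0, S, size=n_cx))
    start = int(rng.integers(0, 2))
    # phase at site i = start + number of breakpoints left of the site's midpoint
    phase = (start + np.searchsorted(breaks, np.arange(S) + 0.5)) % 2
    alleles = np.where(phase == 0, parent.haplotypes[chrom][0], parent.haplotypes[chrom][1])
    ancestry = np.where(phase == 0, parent.ancestry[chrom][0], parent.ancestry[chrom][1])
    return alleles.astype(np.int8), ancestry.astype(np.int8)


def _mate(
    mother: SimulatedIndividual,
    father: SimulatedIndividual,
    map_length: float,
    rng: np.random.Generator,
    sex: str = "F",
) -> SimulatedIndividual:
    n_chrom = len(mother.haplotypes)
    haps, anc = [], []
    for c in range(n_chrom):
        am, gm = meiosis(mother, c, map_length, rng)
        af, gf = meiosis(father, c, map_length, rng)
        haps.append(np.stack([am, af]))
        anc.append(np.stack([gm, gf]))
    return SimulatedIndividual(haplotypes=haps, ancestry=anc, sex=sex,
                               organelle=mother.organelle)


_PEDIGREES = {"F1": 0, "BC1F1": 1, "BC2F1": 2}


def pedigree_generation(pedigree: "str | int") -> int:
    """Number of backcross generations implied by a pedigree label."""
    if isinstance(pedigree, int):
        if pedigree < 0:
            raise ArgumentError("backcross depth must be >= 0")
        return pedigree
    if pedigree in _PEDIGREES:
        return _PEDIGREES[pedigree]
    if pedigree.startswith("BC") and pedigree.endswith("F1"):
        try:
            return int(pedigree[2:-2])
        except ValueError:
            pass
    raise ArgumentError(f"unknown pedigree {pedigree!r}")


def make_hybrid(
    pedigree: "str | int",
    config: SimConfig,
    rng: np.random.Generator,
    sites: SiteModel,
    mother_species: str = "B",
) -> tuple[SimulatedIndividual, dict]:
    """Build the focal individual by iterated meiosis and record the truth.

    The initial cross takes the F1's mother from ``mother_species`` (the
    default matches a female species-B x male species-A cross); each
    backcross mates the current (female) hybrid with a freshly drawn
    species-A male.  The truth record stores the generation, the per-site
    species-A ancestry dosage, the true diagnostic sites and the
    organelle (maternal) lineage.
    """
    g = pedigree_generation(pedigree)
    mother_sp = {"A": 0, "B": 1}[mother_species]
    mother = draw_individual(sites, mother_sp, rng, sex="F")
    father = draw_individual(sites, 1 - mother_sp, rng, sex="M")
    child = _mate(mother, father, config.map_length, rng)
    for _ in range(g):
        recurrent = draw_individual(sites, 0, rng, sex="M")  # species A recurrent parent
        child = _mate(child, recurrent, config.map_length, rng)
    truth: dict = {
        "pedigree": pedigree if isinstance(pedigree, str) else f"BC{g}F1",
        "generation": g,
        "organelle": child.organelle,
        "chroms": {},
    }
    for c, name in enumerate(config.chrom_names):
        dosage_A = (child.ancestry[c] == 0).sum(axis=0)  # 0..2 species-A alleles
        diag = sites.role[c] == ROLE_FIXED_DIFF
        true_class = np.array(["aa", "Aa", "AA"], dtype=object)[dosage_A[diag]]
        n_blocks = 1 + int(np.count_nonzero(np.diff(dosage_A[diag]) != 0)) if diag.any() else 0
        truth["chroms"][name] = {
            "dosage_A": dosage_A.astype(int).tolist(),
            "diagnostic_index": np.flatnonzero(diag).tolist(),
            "true_class": true_class.tolist(),
            "n_blocks_diagnostic": n_blocks,
        }
    return child, truth


def apply_genotype_error(
    gt_pair: np.ndarray,
    error_rate: float,
    rng: np.random.Generator,
    mode: str = "uniform",
    aa_allele: "np.ndarray | None" = None,
) -> np.ndarray:
    """Apply per-site genotype error to one sample's ``(n_sites, 2)`` calls.

    ``uniform`` mode replaces the genotype, with probability
    ``error_rate``, by one drawn uniformly from the three biallelic
    genotype classes at that site (it may redraw the original).  For a
    BC1F1 focal this maps the simulator rate eps to the likelihood
    model's ``p_error`` as eps/3 exactly.  ``aa_flip`` mode instead
    replaces the genotype by the homozygote for ``aa_allele`` (the
    species-B-specific allele), making ``p_error`` equal to eps at true
    diagnostic sites.
    """
    if not 0 <= error_rate < 1:
        raise ArgumentError("error_rate must be in [0, 1)")
    out = gt_pair.copy()
    n = len(out)
    hit = rng.random(n) < error_rate
    if not hit.any():
        return out
    if mode == "uniform":
        choice = rng.integers(0, 3, size=int(hit.sum()))  # 0 -> 0/0, 1 -> 0/1, 2 -> 1/1
        pairs = np.array([[0, 0], [0, 1], [1, 1]], dtype=out.dtype)
        out[hit] = pairs[choice]
    elif mode == "aa_flip":
        if aa_allele is None:
            raise ArgumentError("aa_flip mode requires aa_allele")
        idx = np.flatnonzero(hit)
        out[idx, 0] = aa_allele[idx]
        out[idx, 1] = aa_allele[idx]
    else:
        raise ArgumentError(f"unknown error mode {mode!r}")
    return out


@dataclass
class SimulatedDataset:
    """A simulated dataset: genotype matrix, truth record and raw individuals."""

    matrix: GenotypeMatrix
    truth: dict
    panelA: list
    panelB: list
    focal: SimulatedIndividual
    sites: SiteModel
    config: SimConfig


def simulate_dataset(
    config: SimConfig,
    pedigree: "str | int" = "BC1F1",
    error_mode: str = "uniform",
    mother_species: str = "B",
    rng: "np.random.Generator | None" = None,
) -> SimulatedDataset:
    """Run the full generator: panels, pedigree, error, genotype matrix.

    Sample names are ``A1..An`` (species-A panel), ``B1..Bm`` (species-B
    panel) and ``hybrid`` (the focal individual); panels are registered
    on the matrix as ``parentA``/``parentB``/``focal``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    panelA, panelB, sites = simulate_parental_panels(config, rng)
    focal, truth = make_hybrid(pedigree, config, rng, sites, mother_species=mother_species)
    truth["error_rate"] = config.error_rate
    truth["error_mode"] = error_mode
    truth["seed"] = config.seed

    individuals = panelA + panelB + [focal]
    names = (
        [f"A{i + 1}" for i in range(len(panelA))]
        + [f"B{i + 1}" for i in range(len(panelB))]
        + ["hybrid"]
    )
    S = config.sites_per_chromosome
    chrom_col, pos_col, ref_col, alt_col, gt_blocks = [], [], [], [], []
    for c, cname in enumerate(config.chrom_names):
        pos = (np.arange(S, dtype=np.int64) + 1) * config.site_spacing
        gt = np.empty((S, len(individuals), 2), dtype=np.int16)
        for j, ind in enumerate(individuals):
            pair = np.sort(ind.haplotypes[c].T.astype(np.int16), axis=1)
            gt[:, j, :] = pair
        if config.error_rate > 0:
            gt[:, -1, :] = np.sort(
                apply_genotype_error(
                    gt[:, -1, :],
                    config.error_rate,
                    rng,
                    mode=error_mode,
                    aa_allele=sites.species_allele_B[c].astype(np.int16),
                ),
                axis=1,
            )
        chrom_col.append(np.full(S, cname, dtype=object))
        pos_col.append(pos)
        ref_col.append(sites.ref[c].astype(object))
        alt_col.append(np.array([(a,) for a in sites.alt[c]], dtype=object))
        gt_blocks.append(gt)

    matrix = GenotypeMatrix(
        chrom=np.concatenate(chrom_col),
        pos=np.concatenate(pos_col),
        ref=np.concatenate(ref_col),
        alt=np.concatenate(alt_col),
        gt=np.concatenate(gt_blocks),
        samples=names,
        panels={
            "parentA": SamplePanel("parentA", tuple(names[: len(panelA)])),
            "parentB": SamplePanel(
                "parentB", tuple(names[len(panelA) : len(panelA) + len(panelB)])
            ),
            "focal": SamplePanel("focal", ("hybrid",)),
        },
    )
    return SimulatedDataset(
        matrix=matrix, truth=truth, panelA=panelA, panelB=panelB,
        focal=focal, sites=sites, config=config,
    )


def write_simulated_vcf(
    dataset: SimulatedDataset, out_dir: "str | Path", prefix: str = "sim"
) -> dict:
    """Write the dataset as VCF + panel TSV + truth JSON sidecar.

    The VCF header records the seed and the full configuration, so equal
    seeds produce byte-identical files.  Returns the paths written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vcf_path = out_dir / f"{prefix}.vcf"
    cfg = dataclasses.asdict(dataset.config)
    write_vcf(
        dataset.matrix,
        vcf_path,
        extra_header_lines=[
            f"##hybridtrace_sim_seed={dataset.config.seed}",
            f"##hybridtrace_sim_config={json.dumps(cfg, sort_keys=True)}",
            f"##hybridtrace_sim_pedigree={dataset.truth['pedigree']}",
        ],
    )
    panel_path = out_dir / f"{prefix}.panels.tsv"
    with open(panel_path, "w") as fh:
        for pname, panel in dataset.matrix.panels.items():
            for sid in panel.sample_ids:
                fh.write(f"{sid}\t{pname}\n")
    truth_path = out_dir / f"{prefix}.truth.json"
    with open(truth_path, "w") as fh:
        json.dump(dataset.truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return {"vcf": vcf_path, "panels": panel_path, "truth": truth_path}
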