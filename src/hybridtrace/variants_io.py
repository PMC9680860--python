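"""Genotype matrix container, VCF input/output and SNP-alignment export.

Every downstream stage (diversity, diagnostic-site extraction, likelihood
fitting, painting) consumes the :class:`GenotypeMatrix` produced here.
Genotypes are treated as unphased, unordered diploid pairs of allele
indices; phase separators in the input are ignored.  Coordinates are VCF
1-based inclusive throughout; interval exports (BED) are 0-based
half-open.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from hybridtrace.errors import (
    ArgumentError,
    ConfigurationError,
    UnsupportedSiteError,
    VcfParseError,
)

MISSING = -1

#: two-base IUPAC ambiguity codes, keyed by the unordered base pair
IUPAC_2BASE = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}


@dataclass(frozen=True)
class SamplePanel:
    """A named group of samples (parental species panel, focal, outgroup).

    Parameters
    ----------
    name:
        Panel label, e.g. ``"parentA"``, ``"parentB"``, ``"focal"``.
    sample_ids:
        Sample identifiers as they appear in the VCF header.
    ploidy:
        Ploidy of the panel's samples.  All diversity and diagnostic
        stages require diploids.
    """

    name: str
    sample_ids: tuple[str, ...]
    ploidy: int = 2

    def __post_init__(self) -> None:
        if not self.sample_ids:
            raise ConfigurationError(f"panel {self.name!r} has no samples")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ConfigurationError(f"panel {self.name!r} has duplicate sample ids")


@dataclass
class GenotypeMatrix:
    """Sites x samples unphased diploid genotype calls with panel assignments.

    Attributes
    ----------
    chrom, pos, ref, alt:
        Per-site arrays: chromosome name, 1-based position, reference
        allele, tuple of alternate alleles.  Sites are ordered by
        chromosome (order of first appearance) with strictly increasing
        positions within each chromosome.
    gt:
        ``(n_sites, n_samples, 2)`` int16 array of allele indices
        (0 = ref, k = k-th alt); ``-1`` marks a missing call.  Each pair
        is stored sorted, so genotypes are unordered.
    samples:
        Column order of ``gt``.
    panels:
        Mapping of panel name to :class:`SamplePanel`.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    gt: np.ndarray
    samples: list[str]
    panels: dict[str, SamplePanel] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.gt = np.asarray(self.gt, dtype=np.int16)
        if self.gt.ndim != 3 or self.gt.shape[2] != 2:
            raise ArgumentError("gt must have shape (n_sites, n_samples, 2)")
        if self.gt.shape[0] != len(self.pos) or self.gt.shape[1] != len(self.samples):
            raise ArgumentError("gt shape inconsistent with sites/samples")
        seen: set[str] = set()
        sample_set = set(self.samples)
        for panel in self.panels.values():
            for sid in panel.sample_ids:
                if sid not in sample_set:
                    raise ConfigurationError(f"panel sample {sid!r} not in matrix samples")
                if sid in seen:
                    raise ConfigurationError(f"sample {sid!r} assigned to multiple panels")
                seen.add(sid)
        self._validate_order()

    def _validate_order(self) -> None:
        chrom = np.asarray(self.chrom, dtype=object)
        if len(chrom) < 2:
            return
        same = chrom[1:] == chrom[:-1]
        if np.any(same & (np.diff(self.pos) <= 0)):
            raise ArgumentError("site positions must be strictly increasing within chromosomes")
        # a chromosome must not re-appear after another chromosome intervened
        first_seen: dict[str, int] = {}
        last: str | None = None
        for i, c in enumerate(chrom):
            if c != last:
                if c in first_seen:
                    raise ArgumentError(f"sites for chromosome {c!r} are not contiguous")
                first_seen[c] = i
                last = c

    # -- basic introspection ------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.samples.index(sample_id)
        except ValueError:
            raise ConfigurationError(f"unknown sample id {sample_id!r}") from None

    def panel_indices(self, panel: "SamplePanel | str") -> np.ndarray:
        if isinstance(panel, str):
            if panel not in self.panels:
                raise ConfigurationError(f"unknown panel {panel!r}")
            panel = self.panels[panel]
        return np.array([self.sample_index(s) for s in panel.sample_ids], dtype=np.intp)

    def alleles(self, site: int) -> tuple[str, ...]:
        """All alleles at ``site``: ``(ref, alt1, ...)``."""
        return (self.ref[site],) + tuple(self.alt[site])

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        """Matrix restricted to the sites selected by ``index`` (mask or indices)."""
        index = np.asarray(index)
        return replace(
            self,
            chrom=np.asarray(self.chrom, dtype=object)[index],
            pos=self.pos[index],
            ref=np.asarray(self.ref, dtype=object)[index],
            alt=np.asarray(self.alt, dtype=object)[index],
            gt=self.gt[index],
        )


# -- panel configuration ----------------------------------------------------


def read_panel_config(path: str | Path) -> dict[str, list[str]]:
    """Read a panel assignment file.

    TSV files have two columns ``sample_id<TAB>panel`` (no header); YAML
    files (``.yaml``/``.yml``) map panel names to lists of sample ids.
    """
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: YAML panel config must map panel -> samples")
        return {str(k): [str(s) for s in v] for k, v in raw.items()}
    panels: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ConfigurationError(
                    f"{path}:{lineno}: expected 'sample_id<TAB>panel', got {line!r}"
                )
            sample, panel = parts
            panels.setdefault(panel, []).append(sample)
    if not panels:
        raise ConfigurationError(f"{path}: empty panel config")
    return panels


def _build_panels(
    panel_config: Mapping[str, Sequence[str]], samples: Sequence[str]
) -> dict[str, SamplePanel]:
    sample_set = set(samples)
    panels = {}
    for name, ids in panel_config.items():
        for sid in ids:
            if sid not in sample_set:
                raise ConfigurationError(
                    f"panel {name!r} names sample {sid!r} absent from the VCF header"
                )
        panels[name] = SamplePanel(name=name, sample_ids=tuple(ids))
    return panels


# -- VCF input / output -----------------------------------------------------


def read_vcf(
    path: str | Path,
    panel_config: Mapping[str, Sequence[str]] | str | Path | None = None,
) -> GenotypeMatrix:
    """Read a VCF v4.x file (plain or bgzipped) into a :class:`GenotypeMatrix`.

    Parameters
    ----------
    path:
        VCF file path.
    panel_config:
        Either a mapping of panel name to sample ids, or a path to a
        panel config file (see :func:`read_panel_config`).  Every panel
        sample must appear in the VCF header.

    Notes
    -----
    All records are retained, including multiallelic sites and indels;
    filtering is a separate, explicit step
    (:func:`filter_biallelic_complete`).  Missing calls (``./.``) are
    preserved as missing.  Phase separators are ignored.
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path, gts012=False)
    except Exception as exc:  # htslib raises bare OSError/Exception
        raise VcfParseError(f"{path}: cannot open as VCF: {exc}") from exc

    samples = list(vcf.samples)
    if isinstance(panel_config, (str, Path)):
        panel_config = read_panel_config(panel_config)
    panels = _build_panels(panel_config or {}, samples)

    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[tuple[str, ...]] = []
    gts: list[np.ndarray] = []
    try:
        for rec_i, rec in enumerate(vcf, 1):
            chroms.append(rec.CHROM)
            poss.append(rec.POS)
            refs.append(rec.REF)
            alts.append(tuple(rec.ALT))
            g = np.array([row[:2] for row in rec.genotypes], dtype=np.int16)
            # a half-missing call is treated as fully missing
            g[np.any(g < 0, axis=1)] = MISSING
            g.sort(axis=1)
            gts.append(g)
    except Exception as exc:
        raise VcfParseError(f"{path}: malformed VCF near record {len(poss) + 1}: {exc}") from exc
    finally:
        vcf.close()

    if gts:
        gt = np.stack(gts)
    else:
        gt = np.empty((0, len(samples), 2), dtype=np.int16)
    return GenotypeMatrix(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        gt=gt,
        samples=samples,
        panels=panels,
    )


def write_vcf(
    matrix: GenotypeMatrix,
    path: str | Path,
    extra_header_lines: Iterable[str] = (),
) -> None:
    """Write the matrix as an uncompressed VCF v4.2 file.

    Round-trips through :func:`read_vcf`: chrom/pos/alleles/genotypes are
    preserved exactly (genotypes as unphased ``a/b`` with ``a <= b``).
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for line in extra_header_lines:
            fh.write(line.rstrip("\n") + "\n")
        chrom_arr = np.asarray(matrix.chrom, dtype=object)
        for c in dict.fromkeys(chrom_arr):  # preserves first-appearance order
            mask = chrom_arr == c
            length = int(matrix.pos[mask].max()) if mask.any() else 1
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        for i in range(matrix.n_sites):
            alt = ",".join(matrix.alt[i]) if matrix.alt[i] else "."
            calls = []
            for a, b in matrix.gt[i]:
                calls.append("./." if a == MISSING else f"{a}/{b}")
            fh.write(
                f"{matrix.chrom[i]}\t{matrix.pos[i]}\t.\t{matrix.ref[i]}\t{alt}"
                f"\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n"
            )


# -- filtering --------------------------------------------------------------


def is_snp(matrix: GenotypeMatrix) -> np.ndarray:
    """Per-site mask: all alleles are single nucleotides (no indels/symbolic)."""
    out = np.empty(matrix.n_sites, dtype=bool)
    for i in range(matrix.n_sites):
        out[i] = len(matrix.ref[i]) == 1 and all(
            len(a) == 1 and a in "ACGT" for a in matrix.alt[i]
        )
    return out


def filter_biallelic_complete(
    matrix: GenotypeMatrix, sample_subset: Sequence[str]
) -> GenotypeMatrix:
    """Restrict to biallelic SNPs with no missing genotype in ``sample_subset``.

    Multiallelic records are excluded outright (never split); alleles
    must be single nucleotides.  Site order is preserved, so the filter
    is idempotent.
    """
    if len(sample_subset) == 0:
        raise ArgumentError("sample_subset must not be empty")
    idx = np.array([matrix.sample_index(s) for s in sample_subset], dtype=np.intp)
    n_alt = np.array([len(a) for a in matrix.alt])
    complete = np.all(matrix.gt[:, idx, :] != MISSING, axis=(1, 2))
    mask = (n_alt == 1) & is_snp(matrix) & complete
    return matrix.take_sites(mask)


# -- alignment export -------------------------------------------------------


def genotype_to_iupac(base_a: str, base_b: str) -> str:
    """One-letter code for an unordered diploid genotype of two bases."""
    if len(base_a) != 1 or len(base_b) != 1:
        raise UnsupportedSiteError(f"not a SNP genotype: {base_a}/{base_b}")
    if base_a == base_b:
        return base_a
    return IUPAC_2BASE[frozenset((base_a, base_b))]


def export_iupac_fasta(
    matrix: GenotypeMatrix,
    samples: Sequence[str] | None = None,
    chroms: Sequence[str] | None = None,
    line_width: int = 70,
) -> str:
    """Concatenate SNP genotypes into a FASTA alignment.

    Each sample becomes one record whose k-th character is its genotype
    at the k-th site: homozygotes as the base itself, heterozygotes as
    the two-base IUPAC ambiguity code.  Requires biallelic SNPs with no
    missing genotype in the exported samples.

    Parameters
    ----------
    samples:
        Samples to export (default: all).
    chroms:
        Restrict to these chromosomes (default: all sites, including any
        unanchored contigs).
    """
    if samples is None:
        samples = matrix.samples
    m = matrix
    if chroms is not None:
        chrom_arr = np.asarray(m.chrom, dtype=object)
        m = m.take_sites(np.isin(chrom_arr, list(chroms)))
    idx = [matrix.sample_index(s) for s in samples]
    for i in range(m.n_sites):
        alleles = m.alleles(i)
        if len(alleles) != 2 or any(len(a) != 1 for a in alleles):
            raise UnsupportedSiteError(
                f"site {m.chrom[i]}:{m.pos[i]} is not a biallelic SNP"
            )
    out = io.StringIO()
    for sample, j in zip(samples, idx):
        seq_chars = []
        for i in range(m.n_sites):
            a, b = m.gt[i, j]
            if a == MISSING:
                raise UnsupportedSiteError(
                    f"missing genotype for {sample} at {m.chrom[i]}:{m.pos[i]}"
                )
            alleles = m.alleles(i)
            seq_chars.append(genotype_to_iupac(alleles[a], alleles[b]))
        out.write(f">{sample}\n")
        seq = "".join(seq_chars)
        for k in range(0, len(seq), line_width):
            out.write(seq[k : k + line_width] + "\n")
    return out.getvalue()


def export_nexus(matrix: GenotypeMatrix, samples: Sequence[str] | None = None) -> str:
    """NEXUS export of the IUPAC SNP alignment, for external network software."""
    if samples is None:
        samples = matrix.samples
    fasta = export_iupac_fasta(matrix, samples=samples, line_width=10**9)
    seqs = {}
    name = None
    for line in fasta.splitlines():
        if line.startswith(">"):
            name = line[1:]
            seqs[name] = ""
        elif name is not None:
            seqs[name] += line
    nchar = len(next(iter(seqs.values()))) if seqs else 0
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"  DIMENSIONS NTAX={len(seqs)} NCHAR={nchar};",
        "  FORMAT DATATYPE=DNA MISSING=? GAP=-;",
        "  MATRIX",
    ]
    for s, seq in seqs.items():
        lines.append(f"    {s} {seq}")
    lines += ["  ;", "END;", ""]
    return "\n".join(lines)
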