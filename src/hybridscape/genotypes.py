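"""Diploid SNP genotype matrices: reading, validation, filtering, allele frequencies.

Genotypes are stored as an ``(n_individuals, n_loci)`` int8 array holding the
number of alternate-allele copies (0, 1, 2) or :data:`MISSING` (-1).  Two text
dialects are supported: VCF v4.x and the header-free two-row-per-individual
STRUCTURE format (columns: id, population code, one allele code per locus;
missing allele = -9).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING: int = -1
_STRUCTURE_MISSING = -9

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "FilterReport",
    "GenotypeParseError",
    "GenotypeValidationError",
    "read_genotypes",
    "write_genotypes",
    "filter_loci",
    "allele_freqs",
]


class GenotypeParseError(ValueError):
    """A genotype file could not be parsed in the named dialect."""


class GenotypeValidationError(ValueError):
    """Parsed genotypes violate a GenotypeMatrix invariant."""


@dataclass
class GenotypeMatrix:
    """Diploid biallelic calls with species/locality labels.

    Parameters
    ----------
    genotypes : ndarray of int8, shape (n_individuals, n_loci)
        Alternate-allele copy counts; ``MISSING`` (-1) marks no-calls.
    individual_ids, species, locality : sequences of str, length n_individuals
    locus_ids : sequence of str, unique, length n_loci
    tag_ids : sequence of str or None
        RAD-tag identifier per locus; required by the one-SNP-per-tag filter.
    """

    genotypes: np.ndarray
    individual_ids: list[str]
    species: list[str]
    locus_ids: list[str]
    locality: list[str] | None = None
    tag_ids: list[str] | None = None
    ref_alleles: list[str] | None = field(default=None, repr=False)
    alt_alleles: list[str] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise GenotypeValidationError("genotypes must be 2-D (individuals x loci)")
        n_ind, n_loc = self.genotypes.shape
        if len(self.individual_ids) != n_ind or len(self.species) != n_ind:
            raise GenotypeValidationError("individual_ids/species length mismatch")
        if len(self.locus_ids) != n_loc:
            raise GenotypeValidationError("locus_ids length mismatch")
        if len(set(self.locus_ids)) != n_loc:
            raise GenotypeValidationError("locus_ids must be unique")
        if self.locality is None:
            self.locality = [""] * n_ind
        if self.tag_ids is not None and len(self.tag_ids) != n_loc:
            raise GenotypeValidationError("tag_ids length mismatch")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise GenotypeValidationError(
                f"genotype values outside {{0,1,2,MISSING}} at {int(bad.sum())} cells"
            )

    # -- basic accessors ---------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    @property
    def species_labels(self) -> list[str]:
        return sorted(set(self.species))

    def individuals_of(self, species: str) -> np.ndarray:
        """Row indices of the individuals belonging to *species*."""
        mask = np.asarray([s == species for s in self.species])
        return np.flatnonzero(mask)

    def select_loci(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            genotypes=self.genotypes[:, idx],
            locus_ids=[self.locus_ids[i] for i in idx],
            tag_ids=None if self.tag_ids is None else [self.tag_ids[i] for i in idx],
            ref_alleles=None if self.ref_alleles is None else [self.ref_alleles[i] for i in idx],
            alt_alleles=None if self.alt_alleles is None else [self.alt_alleles[i] for i in idx],
        )

    def select_individuals(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            genotypes=self.genotypes[idx, :],
            individual_ids=[self.individual_ids[i] for i in idx],
            species=[self.species[i] for i in idx],
            locality=[self.locality[i] for i in idx],
        )


# ---------------------------------------------------------------------------
# Reading


def read_genotypes(
    path,
    format: str = "vcf",
    popmap: dict[str, str] | None = None,
    locality_map: dict[str, str] | None = None,
    tag_map: dict[str, str] | None = None,
    on_multiallelic: str = "error",
) -> GenotypeMatrix:
    """Read a genotype matrix from *path*.

    Parameters
    ----------
    format : {"vcf", "structure2row"}
    popmap : mapping individual id -> species label.  Required for VCF (the
        format carries no population information); optional for STRUCTURE,
        where it overrides the integer population codes.
    tag_map : mapping locus id -> RAD-tag id.  For VCF the CHROM field is used
        as the tag by default.
    on_multiallelic : {"error", "drop"}
        Sites with more than two observed alleles are rejected (listing the
        offending loci) or silently dropped.
    """
    if format == "vcf":
        gm = _read_vcf(path, popmap, locality_map, on_multiallelic)
    elif format == "structure2row":
        gm = _read_structure(path, popmap, locality_map, on_multiallelic)
    else:
        raise ValueError(f"unknown format {format!r}")
    if tag_map is not None:
        gm.tag_ids = [tag_map.get(l) for l in gm.locus_ids]
        if any(t is None for t in gm.tag_ids):
            missing = [l for l, t in zip(gm.locus_ids, gm.tag_ids) if t is None]
            raise GenotypeValidationError(f"tag_map missing loci: {missing[:5]}")
    return gm


def _read_vcf(path, popmap, locality_map, on_multiallelic):
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("cyvcf2 is required for VCF input") from exc
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, locus_ids, tag_ids, refs, alts = [], [], [], [], []
    bad_loci = []
    for var in vcf:
        lid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        if len(var.ALT) != 1:
            bad_loci.append(lid)
            continue
        # gt_types: 0=hom-ref, 1=het, 2=hom-alt (with gts012=False default it's 3)
        g = np.array([_vcf_gt(v) for v in var.genotypes], dtype=np.int8)
        rows.append(g)
        locus_ids.append(lid)
        tag_ids.append(var.CHROM)
        refs.append(var.REF)
        alts.append(var.ALT[0])
    if bad_loci and on_multiallelic == "error":
        raise GenotypeValidationError(f"non-biallelic loci: {bad_loci}")
    if not rows:
        raise GenotypeParseError(f"no usable biallelic records in {path}")
    geno = np.stack(rows, axis=1)
    if popmap is None:
        raise ValueError("a popmap (individual -> species) is required for VCF input")
    species = [popmap[s] for s in samples]
    locality = [locality_map.get(s, "") for s in samples] if locality_map else None
    return GenotypeMatrix(geno, samples, species, locus_ids, locality, tag_ids, refs, alts)


def _vcf_gt(gt) -> int:
    a, b = gt[0], gt[1]
    if a < 0 or b < 0:
        return MISSING
    return int(a > 0) + int(b > 0)


def _read_structure(path, popmap, locality_map, on_multiallelic):
    if hasattr(path, "read"):
        lines = path.read().splitlines()
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()
    lines = [ln for ln in lines if ln.strip()]
    if len(lines) % 2:
        raise GenotypeParseError("odd number of rows: two rows per individual expected")
    table = []
    for i, ln in enumerate(lines, start=1):
        parts = ln.split()
        if len(parts) < 3:
            raise GenotypeParseError(f"line {i}: expected id, pop code and allele columns")
        table.append(parts)
    n_loci = len(table[0]) - 2
    for i, parts in enumerate(table, start=1):
        if len(parts) - 2 != n_loci:
            raise GenotypeParseError(
                f"line {i}: {len(parts) - 2} allele columns, expected {n_loci}"
            )
    ids, pops, allele_rows = [], [], []
    for r1, r2 in zip(table[::2], table[1::2]):
        if r1[0] != r2[0]:
            raise GenotypeParseError(f"row pair mismatch: {r1[0]!r} vs {r2[0]!r}")
        ids.append(r1[0])
        pops.append(r1[1])
        allele_rows.append(
            (np.array(r1[2:], dtype=int), np.array(r2[2:], dtype=int))
        )
    # per locus: map observed allele codes to ref (smaller code) / alt (larger)
    geno = np.empty((len(ids), n_loci), dtype=np.int8)
    bad_loci = []
    locus_ids = [f"L{j}" for j in range(n_loci)]
    for j in range(n_loci):
        col = np.array([[a[j], b[j]] for a, b in allele_rows])
        obs = np.unique(col[col != _STRUCTURE_MISSING])
        if len(obs) > 2:
            bad_loci.append(locus_ids[j])
            geno[:, j] = MISSING
            continue
        alt = obs.max() if len(obs) == 2 else None
        for i in range(len(ids)):
            a, b = col[i]
            if a == _STRUCTURE_MISSING or b == _STRUCTURE_MISSING:
                geno[i, j] = MISSING
            elif alt is None:
                geno[i, j] = 0
            else:
                geno[i, j] = int(a == alt) + int(b == alt)
    if bad_loci and on_multiallelic == "error":
        raise GenotypeValidationError(f"non-biallelic loci: {bad_loci}")
    keep = [j for j in range(n_loci) if locus_ids[j] not in bad_loci]
    species = [popmap[i] if popmap else f"pop{p}" for i, p in zip(ids, pops)]
    locality = [locality_map.get(i, "") for i in ids] if locality_map else None
    gm = GenotypeMatrix(geno, ids, species, locus_ids, locality)
    return gm.select_loci(np.array(keep)) if bad_loci else gm


# ---------------------------------------------------------------------------
# Writing


def write_genotypes(gm: GenotypeMatrix, path, format: str = "vcf") -> None:
    """Write *gm* as plain-text VCF or two-row STRUCTURE."""
    own = not hasattr(path, "write")
    fh = open(path, "w") if own else path
    try:
        if format == "vcf":
            _write_vcf(gm, fh)
        elif format == "structure2row":
            _write_structure(gm, fh)
        else:
            raise ValueError(f"unknown format {format!r}")
    finally:
        if own:
            fh.close()


def _write_vcf(gm: GenotypeMatrix, fh) -> None:
    fh.write("##fileformat=VCFv4.2\n")
    fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    chroms = gm.tag_ids if gm.tag_ids is not None else ["chr1"] * gm.n_loci
    for c in dict.fromkeys(chroms):
        fh.write(f"##contig=<ID={c}>\n")
    fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
    fh.write("\t".join(gm.individual_ids) + "\n")
    codes = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    refs = gm.ref_alleles or ["A"] * gm.n_loci
    alts = gm.alt_alleles or ["T"] * gm.n_loci
    pos = {}
    for j, lid in enumerate(gm.locus_ids):
        c = chroms[j]
        pos[c] = pos.get(c, 0) + 1
        cells = "\t".join(codes[int(g)] for g in gm.genotypes[:, j])
        fh.write(f"{c}\t{pos[c]}\t{lid}\t{refs[j]}\t{alts[j]}\t.\tPASS\t.\tGT\t{cells}\n")


def _write_structure(gm: GenotypeMatrix, fh) -> None:
    pop_codes = {s: i + 1 for i, s in enumerate(gm.species_labels)}
    for i, ind in enumerate(gm.individual_ids):
        for copy in (0, 1):
            alleles = []
            for g in gm.genotypes[i]:
                if g == MISSING:
                    alleles.append(_STRUCTURE_MISSING)
                else:  # allele codes 1=ref, 2=alt
                    alleles.append(2 if g > copy else 1)
            row = [ind, str(pop_codes[gm.species[i]])] + [str(a) for a in alleles]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Filtering


@dataclass
class FilterReport:
    """Loci dropped by each rule, applied in order."""

    loci_in: int
    dropped_tag_presence: int = 0
    dropped_sample_fraction: int = 0
    dropped_maf: int = 0
    dropped_one_per_tag: int = 0
    loci_out: int = 0

    @property
    def total_dropped(self) -> int:
        return (
            self.dropped_tag_presence
            + self.dropped_sample_fraction
            + self.dropped_maf
            + self.dropped_one_per_tag
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rule": ["tag_presence", "sample_fraction", "maf", "one_per_tag"],
                "dropped": [
                    self.dropped_tag_presence,
                    self.dropped_sample_fraction,
                    self.dropped_maf,
                    self.dropped_one_per_tag,
                ],
            }
        )


def filter_loci(
    gm: GenotypeMatrix,
    maf_min: float = 0.01,
    min_species_with_tag: int = 3,
    min_sample_fraction: float = 0.40,
    one_snp_per_tag: bool = True,
    return_report: bool = False,
):
    """Apply the downstream SNP filters, in order.

    1. keep loci on RAD-tags genotyped in at least ``min_species_with_tag``
       species;
    2. keep loci genotyped in at least ``min_sample_fraction`` of all
       individuals;
    3. keep loci with minor-allele frequency >= ``maf_min`` over all genotyped
       individuals (boundary inclusive);
    4. keep one SNP per tag (fewest missing calls, then first within-tag
       position, then lexicographic locus id).
    """
    if one_snp_per_tag and gm.tag_ids is None:
        raise ValueError("one_snp_per_tag=True requires tag_ids on the matrix")
    report = FilterReport(loci_in=gm.n_loci)
    geno = gm.genotypes
    called = geno != MISSING
    keep = np.ones(gm.n_loci, dtype=bool)

    if min_species_with_tag > 1:
        if gm.tag_ids is None:
            raise ValueError("min_species_with_tag > 1 requires tag_ids")
        species_rows = {s: gm.individuals_of(s) for s in gm.species_labels}
        tag_species: dict[str, set] = {}
        for j, tag in enumerate(gm.tag_ids):
            present = tag_species.setdefault(tag, set())
            for s, rows in species_rows.items():
                if s not in present and called[rows, j].any():
                    present.add(s)
        ok = np.array(
            [len(tag_species[t]) >= min_species_with_tag for t in gm.tag_ids]
        )
        report.dropped_tag_presence = int((keep & ~ok).sum())
        keep &= ok

    frac = called.mean(axis=0)
    ok = frac >= min_sample_fraction
    report.dropped_sample_fraction = int((keep & ~ok).sum())
    keep &= ok

    with np.errstate(invalid="ignore"):
        n_called = called.sum(axis=0)
        alt = np.where(called, geno, 0).sum(axis=0)
        p = np.divide(alt, 2.0 * n_called, out=np.zeros(gm.n_loci), where=n_called > 0)
    maf = np.minimum(p, 1.0 - p)
    ok = (maf >= maf_min) & (n_called > 0)
    report.dropped_maf = int((keep & ~ok).sum())
    keep &= ok

    if one_snp_per_tag:
        n_missing = gm.n_individuals - called.sum(axis=0)
        best: dict[str, int] = {}
        order: dict[str, int] = {}
        for j in np.flatnonzero(keep):
            tag = gm.tag_ids[j]
            pos = order.setdefault(tag, 0)
            order[tag] += 1
            cand = (n_missing[j], pos, gm.locus_ids[j], j)
            if tag not in best or cand[:3] < best[tag][:3]:
                best[tag] = cand
        winners = {c[3] for c in best.values()}
        ok = np.array([j in winners for j in range(gm.n_loci)])
        report.dropped_one_per_tag = int((keep & ~ok).sum())
        keep &= ok

    out = gm.select_loci(np.flatnonzero(keep))
    report.loci_out = out.n_loci
    return (out, report) if return_report else out


# ---------------------------------------------------------------------------
# Allele frequencies


def allele_freqs(gm: GenotypeMatrix, group) -> pd.DataFrame:
    """Per-locus alternate-allele frequencies in a group of individuals.

    *group* is a species label, a locality prefixed ``"locality:"``, or an
    explicit sequence of individual ids.  Frequencies are computed over
    non-missing calls only; loci with zero genotyped individuals get
    ``freq = NaN`` and ``flagged = True``.
    """
    if isinstance(group, str):
        if group.startswith("locality:"):
            loc = group.split(":", 1)[1]
            rows = np.flatnonzero(np.asarray([l == loc for l in gm.locality]))
            label = loc
        else:
            rows = gm.individuals_of(group)
            label = group
    else:
        wanted = set(group)
        rows = np.flatnonzero(np.asarray([i in wanted for i in gm.individual_ids]))
        label = ",".join(sorted(wanted))
    if rows.size == 0:
        raise ValueError(f"empty group {group!r}")
    geno = gm.genotypes[rows]
    called = geno != MISSING
    n = called.sum(axis=0)
    alt = np.where(called, geno, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n > 0, alt / (2.0 * n), np.nan)
    if (n == 0).any():
        warnings.warn(f"{int((n == 0).sum())} loci with no genotyped individuals in {label}")
    return pd.DataFrame(
        {
            "locus_id": gm.locus_ids,
            "freq": freq,
            "n_genotyped": n,
            "group": label,
            "flagged": n == 0,
        }
    )
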