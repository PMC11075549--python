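"""Genotype data model and standard-format I/O (VCF, BED, sample maps).

The genotype container is a plain dosage matrix (accessions x sites) with
codes 0 = hom-ref, 1 = het, 2 = hom-alt, -1 = missing.  Every downstream
statistic consumes this container; none of them impute, each states its own
missing-data policy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1
_VALID_CODES = frozenset({-1, 0, 1, 2})


class VcfParseError(ValueError):
    """Raised on a malformed VCF header or record; carries the line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


@dataclass
class GenotypeMatrix:
    """Biallelic diploid genotypes for a panel of accessions.

    Attributes
    ----------
    dosages : (n_accessions, n_sites) int8 array with codes {0, 1, 2, -1}.
    chrom : (n_sites,) array of chromosome labels.
    pos : (n_sites,) int array of 1-based positions, strictly increasing
        within each chromosome.
    qual : (n_sites,) float array of site quality scores (NaN if absent).
    sample_ids : (n_accessions,) array of unique accession identifiers.
    ref, alt : per-site allele strings (kept for round-trip fidelity).
    """

    dosages: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    qual: np.ndarray
    sample_ids: np.ndarray
    ref: np.ndarray | None = None
    alt: np.ndarray | None = None

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.qual = np.asarray(self.qual, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.ref is None:
            self.ref = np.full(self.n_sites, "A", dtype=object)
        if self.alt is None:
            self.alt = np.full(self.n_sites, "T", dtype=object)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self._validate()

    def _validate(self):
        n_acc, n_sites = self.dosages.shape
        if len(self.sample_ids) != n_acc:
            raise ValueError("sample_ids length does not match dosage rows")
        if len(set(self.sample_ids)) != n_acc:
            raise ValueError("sample_ids must be unique")
        for arr, name in ((self.chrom, "chrom"), (self.pos, "pos"),
                          (self.qual, "qual"), (self.ref, "ref"), (self.alt, "alt")):
            if len(arr) != n_sites:
                raise ValueError(f"{name} length does not match dosage columns")
        bad = ~np.isin(self.dosages, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError(f"invalid dosage codes present: {np.unique(self.dosages[bad])}")
        # strictly increasing positions within each chromosome
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not np.all(np.diff(p) > 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_accessions(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[1]

    def take_sites(self, index) -> "GenotypeMatrix":
        """Subset to the given site indices (order preserved)."""
        index = np.asarray(index)
        return GenotypeMatrix(
            dosages=self.dosages[:, index],
            chrom=self.chrom[index],
            pos=self.pos[index],
            qual=self.qual[index],
            sample_ids=self.sample_ids,
            ref=self.ref[index],
            alt=self.alt[index],
        )

    def take_samples(self, index) -> "GenotypeMatrix":
        """Subset to the given accession indices (order preserved)."""
        index = np.asarray(index)
        return GenotypeMatrix(
            dosages=self.dosages[index, :],
            chrom=self.chrom,
            pos=self.pos,
            qual=self.qual,
            sample_ids=self.sample_ids[index],
            ref=self.ref,
            alt=self.alt,
        )

    def sample_index(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"accession {e.args[0]!r} not in genotype matrix") from None

    def allele_frequencies(self) -> np.ndarray:
        """Alt-allele frequency per site from non-missing calls (NaN if none)."""
        d = self.dosages
        obs = d >= 0
        n_called = obs.sum(axis=0)
        alt = np.where(obs, d, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_called > 0, alt / (2.0 * n_called), np.nan)

    def __eq__(self, other):
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        qual_eq = np.array_equal(self.qual, other.qual, equal_nan=True)
        return (
            np.array_equal(self.dosages, other.dosages)
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and qual_eq
            and np.array_equal(self.sample_ids, other.sample_ids)
        )


@dataclass
class PopulationMap:
    """Accession -> (clade, lineage) assignment."""

    clade: dict[str, str]
    lineage: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.lineage:
            self.lineage = dict(self.clade)

    @property
    def samples(self) -> list[str]:
        return list(self.clade)

    def clades(self) -> list[str]:
        return sorted(set(self.clade.values()))

    def lineages(self) -> list[str]:
        return sorted(set(self.lineage.values()))

    def group_indices(self, gm: GenotypeMatrix, level: str = "clade") -> dict[str, np.ndarray]:
        """Map each population label to row indices in ``gm``.

        Every mapped accession must be present in the genotype matrix.
        """
        assign = self.clade if level == "clade" else self.lineage
        lookup = {s: i for i, s in enumerate(gm.sample_ids)}
        missing = [s for s in assign if s not in lookup]
        if missing:
            raise KeyError(f"accessions in population map absent from genotypes: {missing[:5]}")
        groups: dict[str, list[int]] = {}
        for s, g in assign.items():
            groups.setdefault(g, []).append(lookup[s])
        if len(groups) < 2:
            raise ValueError("need at least 2 populations for differentiation statistics")
        return {g: np.array(sorted(ix), dtype=int) for g, ix in sorted(groups.items())}

    @classmethod
    def read(cls, path) -> "PopulationMap":
        """Read a tab-separated sample map (sample_id, clade[, lineage])."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        cols = [c.lower() for c in df.columns]
        df.columns = cols
        if "sample_id" not in cols or "clade" not in cols:
            raise ValueError("sample map needs 'sample_id' and 'clade' columns")
        clade = dict(zip(df["sample_id"], df["clade"]))
        lineage = dict(zip(df["sample_id"], df["lineage"])) if "lineage" in cols else {}
        return cls(clade=clade, lineage=lineage)

    def write(self, path):
        rows = [(s, self.clade[s], self.lineage.get(s, self.clade[s])) for s in self.clade]
        pd.DataFrame(rows, columns=["sample_id", "clade", "lineage"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class GeneRegions:
    """Named genomic intervals in BED convention (0-based, half-open)."""

    regions: list[tuple[str, int, int, str]]

    def __post_init__(self):
        names = [r[3] for r in self.regions]
        if len(set(names)) != len(names):
            raise ValueError("region names must be unique")
        for chrom, start, end, name in self.regions:
            if not start < end:
                raise ValueError(f"region {name}: start {start} must be < end {end}")

    def __len__(self):
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    @classmethod
    def read_bed(cls, path) -> "GeneRegions":
        regions = []
        with open(path) as fh:
            for i, line in enumerate(fh):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(f"{path}: line {i + 1}: BED needs >= 3 columns")
                name = fields[3] if len(fields) > 3 else f"region_{len(regions) + 1}"
                regions.append((fields[0], int(fields[1]), int(fields[2]), name))
        return cls(regions)

    def write_bed(self, path):
        with open(path, "w") as fh:
            for chrom, start, end, name in self.regions:
                fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

_GT_CODE = {
    "0/0": 0, "0|0": 0,
    "0/1": 1, "1/0": 1, "0|1": 1, "1|0": 1,
    "1/1": 2, "1|1": 2,
    "./.": MISSING, ".|.": MISSING, ".": MISSING,
}


def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF with a GT FORMAT field into a :class:`GenotypeMatrix`.

    Multi-allelic records are dropped (the filtering chain keeps biallelic
    sites only).  Phased separators are treated as unphased.  Site order is
    preserved.
    """
    sample_ids: list[str] | None = None
    chroms, poss, quals, refs, alts = [], [], [], [], []
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                header = line.split("\t")
                if header[:9] != ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL",
                                  "FILTER", "INFO", "FORMAT"]:
                    raise VcfParseError("malformed #CHROM header line", lineno)
                sample_ids = header[9:]
                continue
            if sample_ids is None:
                raise VcfParseError("data record before #CHROM header", lineno)
            fields = line.split("\t")
            if len(fields) != 9 + len(sample_ids):
                raise VcfParseError(
                    f"expected {9 + len(sample_ids)} columns, got {len(fields)}", lineno
                )
            alt = fields[4]
            if "," in alt:
                continue  # multi-allelic: split-rejected
            fmt = fields[8].split(":")
            try:
                gt_idx = fmt.index("GT")
            except ValueError:
                raise VcfParseError("FORMAT lacks GT field", lineno) from None
            row = np.empty(len(sample_ids), dtype=np.int8)
            for j, cell in enumerate(fields[9:]):
                gt = cell.split(":")[gt_idx]
                try:
                    row[j] = _GT_CODE[gt]
                except KeyError:
                    raise VcfParseError(f"unsupported GT value {gt!r}", lineno) from None
            chroms.append(fields[0])
            poss.append(int(fields[1]))
            refs.append(fields[3])
            alts.append(alt)
            quals.append(float("nan") if fields[5] == "." else float(fields[5]))
            rows.append(row)
    if sample_ids is None:
        raise VcfParseError("no #CHROM header found in file")
    n_sites = len(rows)
    dosages = (
        np.array(rows, dtype=np.int8).T
        if n_sites
        else np.empty((len(sample_ids), 0), dtype=np.int8)
    )
    return GenotypeMatrix(
        dosages=dosages,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        qual=np.array(quals, dtype=float),
        sample_ids=np.array(sample_ids, dtype=object),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
    )


_DOSAGE_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a VCFv4.2 file with a single GT FORMAT field.

    Heterozygotes are always written as the canonical "0/1"; missing calls
    as "./.".  ``read_vcf(write_vcf(gm)) == gm``.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in gm.sample_ids)
            + "\n"
        )
        for k in range(gm.n_sites):
            q = gm.qual[k]
            qual_str = "." if np.isnan(q) else f"{q:g}"
            gts = "\t".join(_DOSAGE_GT[int(d)] for d in gm.dosages[:, k])
            fh.write(
                f"{gm.chrom[k]}\t{gm.pos[k]}\t.\t{gm.ref[k]}\t{gm.alt[k]}\t"
                f"{qual_str}\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_variants(
    gm: GenotypeMatrix,
    max_alleles: int = 2,
    max_missing_count: int | None = None,
    min_qual: float | None = None,
    drop_het_sites: bool = False,
    max_het_count: int = 0,
) -> GenotypeMatrix:
    """Site-level filter chain: biallelic / missing-count / quality / het.

    All criteria are per-site and independent, so the filter is idempotent
    and order-insensitive.  Sites with unknown (NaN) quality pass the
    quality criterion.  Heterozygous-call screening removes whole sites
    carrying more than ``max_het_count`` het calls — residual hets in a
    near-complete selfer flag duplicated sequence, not true heterozygosity.
    """
    keep = np.ones(gm.n_sites, dtype=bool)
    # biallelic: multi-allelic records are already dropped at read time; the
    # dosage coding itself cannot express >2 alleles, so this is a no-op
    # guard kept for contract clarity.
    if max_alleles < 2:
        raise ValueError("max_alleles must be >= 2 for diploid biallelic coding")
    if max_missing_count is not None:
        n_missing = (gm.dosages == MISSING).sum(axis=0)
        keep &= n_missing <= max_missing_count
    if min_qual is not None:
        with np.errstate(invalid="ignore"):
            keep &= ~(gm.qual < min_qual)  # NaN qual passes
    if drop_het_sites:
        n_het = (gm.dosages == 1).sum(axis=0)
        keep &= n_het <= max_het_count
    return gm.take_sites(np.flatnonzero(keep))


def thin(gm: GenotypeMatrix, min_spacing_bp: int) -> GenotypeMatrix:
    """Greedy left-to-right thinning: keep a site iff it is >= min_spacing_bp
    from the last kept site on the same chromosome.  First site per
    chromosome is always kept."""
    keep = []
    last_kept: dict = {}
    for k in range(gm.n_sites):
        c, p = gm.chrom[k], gm.pos[k]
        if c not in last_kept or p - last_kept[c] >= min_spacing_bp:
            keep.append(k)
            last_kept[c] = p
    return gm.take_sites(np.array(keep, dtype=int))


def maf_filter(gm: GenotypeMatrix, min_maf: float) -> GenotypeMatrix:
    """Keep sites with minor allele frequency >= min_maf (boundary inclusive).

    Frequencies come from non-missing calls only; sites with every call
    missing are removed and logged.
    """
    if not 0 <= min_maf <= 0.5:
        raise ValueError("min_maf must be in [0, 0.5]")
    f = gm.allele_frequencies()
    all_missing = np.isnan(f)
    if all_missing.any():
        logger.info("maf_filter: removing %d sites with no called genotypes",
                    int(all_missing.sum()))
    with np.errstate(invalid="ignore"):
        maf = np.minimum(f, 1.0 - f)
        keep = ~all_missing & (maf >= min_maf)
    return gm.take_sites(np.flatnonzero(keep))


def extract_regions(
    gm: GenotypeMatrix, regions: GeneRegions
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Subset to sites inside named regions; returns (subset, region names).

    BED intervals are 0-based half-open; VCF positions 1-based.  A site at
    position p lies in region (start, end) iff start < p <= end.  A site in
    several regions is assigned to the first by sort order, with a warning.
    """
    sorted_regions = sorted(regions, key=lambda r: (r[0], r[1], r[2]))
    assignment = np.full(gm.n_sites, None, dtype=object)
    overlap_warned = False
    for chrom, start, end, name in sorted_regions:
        inside = (gm.chrom == chrom) & (gm.pos > start) & (gm.pos <= end)
        for k in np.flatnonzero(inside):
            if assignment[k] is None:
                assignment[k] = name
            elif not overlap_warned:
                warnings.warn(
                    "overlapping regions: sites assigned to first region by sort order",
                    stacklevel=2,
                )
                overlap_warned = True
    keep = np.flatnonzero(assignment != None)  # noqa: E711 — element-wise
    return gm.take_sites(keep), assignment[keep].astype(object)


def heterozygosity_fraction(
    gm: GenotypeMatrix, regions: GeneRegions | None = None
) -> float:
    """Fraction of heterozygous calls among non-missing calls in scope."""
    scope = gm if regions is None else extract_regions(gm, regions)[0]
    d = scope.dosages
    n_called = int((d >= 0).sum())
    if n_called == 0:
        raise ValueError("no non-missing calls in scope")
    return int((d == 1).sum()) / n_called
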