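"""Genotype matrix container, VCF I/O, the site-filtering cascade, and
duplicate-pair genotype concordance.

Genotype calls are stored as alternate-allele counts (0/1/2) with -1 for
missing, in an individuals x sites int8 array, optionally accompanied by a
per-genotype read depth array.  Filtering applies, in a pinned order:

    genotype-depth masking -> site missingness -> repeat-mask exclusion
    -> biallelic-SNP restriction -> MAF -> MAC

and every removed site is attributed to the first rule it fails.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

__all__ = [
    "GenotypeMatrix",
    "FilterConfig",
    "FilterReport",
    "read_vcf",
    "write_vcf",
    "read_bed",
    "apply_genotype_depth_filter",
    "filter_sites",
    "duplicate_concordance",
]

MISSING = -1

SITE_COLUMNS = ["scaffold", "pos", "ref", "alt", "biallelic"]


@dataclass
class GenotypeMatrix:
    """Biallelic SNP calls for a cohort.

    ``sites`` is a DataFrame with columns scaffold, pos (1-based), ref, alt
    and a ``biallelic`` flag (multi-allelic or non-SNP records are kept on
    read but flagged for the biallelic filter).  ``calls[i, j]`` counts
    alternate alleles for individual i at site j, -1 when missing.
    """

    individuals: list[str]
    sites: pd.DataFrame
    calls: np.ndarray
    depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.individuals), len(self.sites)):
            raise ValueError("calls shape inconsistent with individuals/sites")
        if not np.isin(self.calls, [MISSING, 0, 1, 2]).all():
            raise ValueError("calls must be in {-1, 0, 1, 2}")
        if self.depth is not None:
            self.depth = np.asarray(self.depth)
            if self.depth.shape != self.calls.shape:
                raise ValueError("depth shape inconsistent with calls")
        self._check_sorted()

    def _check_sorted(self) -> None:
        pos = self.sites["pos"].to_numpy()
        scaf = self.sites["scaffold"].to_numpy()
        same = scaf[1:] == scaf[:-1] if len(pos) > 1 else np.array([], dtype=bool)
        if np.any(same & (pos[1:] <= pos[:-1])):
            raise ValueError("sites must be strictly increasing in position per scaffold")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask, dtype=bool)
        return GenotypeMatrix(
            individuals=list(self.individuals),
            sites=self.sites.loc[mask].reset_index(drop=True),
            calls=self.calls[:, mask].copy(),
            depth=None if self.depth is None else self.depth[:, mask].copy(),
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            individuals=list(self.individuals),
            sites=self.sites.copy().reset_index(drop=True),
            calls=self.calls.copy(),
            depth=None if self.depth is None else self.depth.copy(),
        )

    def index_of(self, individual: str) -> int:
        try:
            return self.individuals.index(individual)
        except ValueError:
            raise KeyError(f"unknown individual: {individual}") from None


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the site-filtering cascade.

    ``max_site_missingness`` 0.2 keeps sites present in >= 80% of
    individuals; sites are retained when MAF strictly exceeds ``maf_min``
    and the minor allele count is at least ``mac_min``.
    ``min_genotype_depth`` of 0/None disables depth masking.
    """

    max_site_missingness: float = 0.2
    maf_min: float = 0.01
    mac_min: int = 3
    min_genotype_depth: int | None = None
    repeat_mask: pd.DataFrame | None = None  # BED: scaffold, start, end (0-based half-open)

    def __post_init__(self) -> None:
        if not 0 <= self.max_site_missingness <= 1:
            raise ValueError("max_site_missingness must be in [0, 1]")
        if not 0 <= self.maf_min < 0.5:
            raise ValueError("maf_min must be in [0, 0.5)")
        if self.mac_min < 0:
            raise ValueError("mac_min must be >= 0")


@dataclass
class FilterReport:
    n_input: int = 0
    genotypes_depth_masked: int = 0
    removed_missingness: int = 0
    removed_repeat_mask: int = 0
    removed_not_biallelic: int = 0
    removed_maf: int = 0
    removed_mac: int = 0
    n_retained: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_vcf(path) -> GenotypeMatrix:
    """Read GT (and DP when present) from a VCF into a GenotypeMatrix.

    Records with more than one ALT allele or non-SNP alleles are retained
    but flagged non-biallelic; their calls are stored as missing.
    """
    vcf = VCF(str(path), gts012=True)
    individuals = list(vcf.samples)
    rows = []
    call_cols = []
    depth_cols = []
    any_depth = False
    for i, var in enumerate(vcf):
        alts = var.ALT
        biallelic = (
            len(alts) == 1 and len(var.REF) == 1 and len(alts[0]) == 1
            and alts[0] in "ACGT" and var.REF in "ACGT" and alts[0] != var.REF
        )
        if var.POS < 1:
            raise ValueError(f"malformed record at line-index {i}: position {var.POS}")
        rows.append(
            (var.CHROM, var.POS, var.REF, ",".join(alts) if alts else ".", biallelic)
        )
        if biallelic:
            # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
            gt = var.gt_types.astype(np.int8)
            gt[gt == 3] = MISSING
        else:
            gt = np.full(len(individuals), MISSING, dtype=np.int8)
        call_cols.append(gt)
        try:
            dp = var.format("DP")
        except KeyError:  # DP not declared in the header
            dp = None
        if dp is not None:
            dp = dp.reshape(-1).astype(np.int64)
            dp[dp < 0] = 0  # cyvcf2 encodes missing DP as a large negative sentinel
            any_depth = True
            depth_cols.append(dp)
        else:
            depth_cols.append(np.zeros(len(individuals), dtype=np.int64))
    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    calls = (
        np.stack(call_cols, axis=1) if call_cols
        else np.empty((len(individuals), 0), dtype=np.int8)
    )
    depth = np.stack(depth_cols, axis=1) if (depth_cols and any_depth) else None
    return GenotypeMatrix(individuals=individuals, sites=sites, calls=calls, depth=depth)


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path, contig_lengths: dict[str, int] | None = None) -> None:
    """Write a GenotypeMatrix as an uncompressed VCF v4.2 with GT and DP."""
    path = Path(path)
    with_dp = matrix.depth is not None
    lines = ["##fileformat=VCFv4.2"]
    for scaf in dict.fromkeys(matrix.sites["scaffold"]):
        if contig_lengths and scaf in contig_lengths:
            lines.append(f"##contig=<ID={scaf},length={contig_lengths[scaf]}>")
        else:
            lines.append(f"##contig=<ID={scaf}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    if with_dp:
        lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">')
    header = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT"
    lines.append(header + "\t" + "\t".join(matrix.individuals))
    fmt = "GT:DP" if with_dp else "GT"
    for j in range(matrix.n_sites):
        site = matrix.sites.iloc[j]
        fields = [
            str(site.scaffold), str(int(site.pos)), ".", str(site.ref),
            str(site.alt), ".", ".", ".", fmt,
        ]
        for i in range(matrix.n_individuals):
            g = _GT_STR[int(matrix.calls[i, j])]
            if with_dp:
                g = f"{g}:{int(matrix.depth[i, j])}"
            fields.append(g)
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n")


def read_bed(path) -> pd.DataFrame:
    """Read a 3+-column BED (0-based, half-open) repeat mask."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2], names=["scaffold", "start", "end"],
    )
    if (df["end"] < df["start"]).any():
        raise ValueError("BED interval with end < start")
    return df


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def apply_genotype_depth_filter(matrix: GenotypeMatrix, min_depth: int) -> GenotypeMatrix:
    """Set genotypes with read depth below ``min_depth`` to missing."""
    if min_depth <= 0:
        return matrix.copy()
    if matrix.depth is None:
        raise ValueError("depth filtering requested but matrix carries no depth")
    out = matrix.copy()
    out.calls[out.depth < min_depth] = MISSING
    return out


def _in_repeat_mask(sites: pd.DataFrame, bed: pd.DataFrame) -> np.ndarray:
    """True where a site's 1-based position falls in any BED interval."""
    hit = np.zeros(len(sites), dtype=bool)
    for scaf, sub in bed.groupby("scaffold"):
        sel = sites["scaffold"] == scaf
        if not sel.any():
            continue
        pos0 = sites.loc[sel, "pos"].to_numpy() - 1  # to 0-based
        inside = np.zeros(len(pos0), dtype=bool)
        for start, end in sub[["start", "end"]].itertuples(index=False):
            inside |= (pos0 >= start) & (pos0 < end)
        hit[sel.to_numpy()] = inside
    return hit


def site_allele_stats(matrix: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (non-missing count, alt allele count, minor allele count)."""
    typed = matrix.calls != MISSING
    n_typed = typed.sum(axis=0)
    alt = np.where(typed, matrix.calls, 0).sum(axis=0)
    total = 2 * n_typed
    mac = np.minimum(alt, total - alt)
    return n_typed, alt, mac


def filter_sites(matrix: GenotypeMatrix, config: FilterConfig) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the pinned filtering cascade; attribute removals to first-failing rule."""
    report = FilterReport(n_input=matrix.n_sites)

    if config.min_genotype_depth:
        before = matrix.calls != MISSING
        matrix = apply_genotype_depth_filter(matrix, config.min_genotype_depth)
        report.genotypes_depth_masked = int((before & (matrix.calls == MISSING)).sum())
    else:
        matrix = matrix.copy()

    n_ind = matrix.n_individuals
    missing_frac = (matrix.calls == MISSING).sum(axis=0) / n_ind
    fail_miss = missing_frac > config.max_site_missingness

    if config.repeat_mask is not None and len(config.repeat_mask):
        in_mask = _in_repeat_mask(matrix.sites, config.repeat_mask)
    else:
        in_mask = np.zeros(matrix.n_sites, dtype=bool)

    not_biallelic = ~matrix.sites["biallelic"].to_numpy()

    n_typed, alt, mac = site_allele_stats(matrix)
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(n_typed > 0, alt / np.maximum(2 * n_typed, 1), 0.0)
    maf = np.minimum(af, 1 - af)
    fail_maf = maf <= config.maf_min
    fail_mac = mac < config.mac_min

    removed = np.zeros(matrix.n_sites, dtype=bool)
    for fail, attr in [
        (fail_miss, "removed_missingness"),
        (in_mask, "removed_repeat_mask"),
        (not_biallelic, "removed_not_biallelic"),
        (fail_maf, "removed_maf"),
        (fail_mac, "removed_mac"),
    ]:
        newly = fail & ~removed
        setattr(report, attr, int(newly.sum()))
        removed |= fail

    out = matrix.subset_sites(~removed)
    report.n_retained = out.n_sites
    return out, report


# ---------------------------------------------------------------------------
# Duplicate concordance
# ---------------------------------------------------------------------------

def duplicate_concordance(
    matrix: GenotypeMatrix, pairs: Sequence[tuple[str, str]]
) -> pd.DataFrame:
    """Genotype concordance between duplicate samples.

    ``assessed`` counts sites where both members are non-missing;
    ``discordant`` counts unequal calls among those.
    """
    rows = []
    for a, b in pairs:
        ia, ib = matrix.index_of(a), matrix.index_of(b)
        ca, cb = matrix.calls[ia], matrix.calls[ib]
        both = (ca != MISSING) & (cb != MISSING)
        assessed = int(both.sum())
        discordant = int((ca[both] != cb[both]).sum())
        rows.append(
            {
                "id_a": a,
                "id_b": b,
                "assessed": assessed,
                "discordant": discordant,
                "fraction": discordant / assessed if assessed else np.nan,
            }
        )
    return pd.DataFrame(rows)
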