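"""Data containers and on-disk formats for haplotype-level ancestry analysis.

The toolkit works on phased biallelic haplotypes and per-haplotype,
per-site local ancestry calls (the output format of RFMix v1: site-major
whitespace-delimited integer codes).  This module defines the in-memory
containers shared by every other module and the readers/writers for the
plain-text interchange formats:

* phased VCF (GT only) -> :class:`HaplotypePanel`
* RFMix-style Viterbi text -> :class:`LocalAncestryCalls`
* RFMix-style posterior text -> :class:`PosteriorArray`
* pedigree TSV -> :class:`PedigreeTable`
* site-map TSV -> :class:`SiteMap`

Conventions
-----------
Internal arrays are 0-based; file coordinates are 1-based base pairs per
VCF convention.  Haplotype rows follow VCF sample order, copy 1 before
copy 2; a haploid male X sample contributes a single row (copy 1).
``MISSING`` (= -1) is the single sentinel for an absent allele or an
absent ancestry call; ancestry codes are 1..K as in RFMix output.  Sex is
taken from metadata, never inferred from heterozygosity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger("lanctk")

#: Sentinel for a missing allele or missing ancestry call.  Distinct from
#: the allele alphabet {0, 1} and from ancestry codes {1..K}.
MISSING: int = -1

DEFAULT_ANCESTRY_LABELS = ("African", "Amerindian", "European")

SEXES = ("male", "female", "unknown")


class FormatError(ValueError):
    """A file violates the contract of its format (dimensions, codes, phasing)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SiteMap:
    """Marker coordinates: chromosome, 1-based bp position, id, optional cM.

    Positions must be strictly increasing within each chromosome.
    """

    table: pd.DataFrame  # columns: chrom, pos_bp, site_id[, pos_cm]

    def __post_init__(self) -> None:
        required = {"chrom", "pos_bp", "site_id"}
        if not required.issubset(self.table.columns):
            raise FormatError(f"site map needs columns {sorted(required)}")
        for _, grp in self.table.groupby("chrom", sort=False):
            pos = grp["pos_bp"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise FormatError("positions not strictly increasing within chromosome")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def chrom(self) -> np.ndarray:
        return self.table["chrom"].to_numpy()

    @property
    def pos_bp(self) -> np.ndarray:
        return self.table["pos_bp"].to_numpy()

    @property
    def pos_cm(self) -> np.ndarray | None:
        if "pos_cm" in self.table.columns:
            return self.table["pos_cm"].to_numpy(dtype=float)
        return None

    def subset(self, idx: np.ndarray) -> "SiteMap":
        return SiteMap(self.table.iloc[np.asarray(idx)].reset_index(drop=True))


def make_hap_meta(
    sample_ids: Sequence[str],
    copies: Sequence[int],
    sexes: Sequence[str] | None = None,
    groups: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Build the per-haplotype metadata frame (sample_id, copy, sex, group)."""
    n = len(sample_ids)
    return pd.DataFrame(
        {
            "sample_id": list(sample_ids),
            "copy": list(copies),
            "sex": list(sexes) if sexes is not None else ["unknown"] * n,
            "group": list(groups) if groups is not None else [""] * n,
        }
    )


def _check_hap_meta(hap_meta: pd.DataFrame, n_rows: int) -> None:
    if len(hap_meta) != n_rows:
        raise FormatError(
            f"hap_meta has {len(hap_meta)} rows, matrix has {n_rows} haplotypes"
        )
    # Each sample's rows must be consecutive, copies 1..ploidy in order.
    ids = hap_meta["sample_id"].to_numpy()
    copies = hap_meta["copy"].to_numpy()
    seen: set[str] = set()
    i = 0
    while i < len(ids):
        sid = ids[i]
        if sid in seen:
            raise FormatError(f"haplotype rows of sample {sid!r} are not consecutive")
        seen.add(sid)
        j = i
        while j < len(ids) and ids[j] == sid:
            j += 1
        ploidy = j - i
        if ploidy not in (1, 2) or list(copies[i:j]) != list(range(1, ploidy + 1)):
            raise FormatError(f"sample {sid!r} has invalid copy sequence {copies[i:j]}")
        i = j


@dataclass
class HaplotypePanel:
    """H x M matrix of alleles in {0, 1, MISSING} with per-haplotype metadata.

    Each diploid sample contributes two consecutive rows (copy 1 then 2);
    a haploid male X sample contributes one row.
    """

    alleles: np.ndarray
    hap_meta: pd.DataFrame
    sites: SiteMap

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise FormatError("alleles must be a 2-D matrix")
        bad = ~np.isin(self.alleles, (0, 1, MISSING))
        if bad.any():
            raise FormatError("alleles outside {0, 1, MISSING}")
        if self.alleles.shape[1] != len(self.sites):
            raise FormatError("site map length does not match allele matrix")
        _check_hap_meta(self.hap_meta, self.alleles.shape[0])

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(dict.fromkeys(self.hap_meta["sample_id"]))

    def rows_of(self, sample_id: str) -> np.ndarray:
        """Row indices of a sample's haplotypes, in copy order."""
        return np.flatnonzero((self.hap_meta["sample_id"] == sample_id).to_numpy())

    def subset_sites(self, idx: np.ndarray) -> "HaplotypePanel":
        idx = np.asarray(idx)
        return HaplotypePanel(self.alleles[:, idx], self.hap_meta.copy(), self.sites.subset(idx))

    def subset_haplotypes(self, rows: np.ndarray) -> "HaplotypePanel":
        rows = np.asarray(rows)
        return HaplotypePanel(
            self.alleles[rows], self.hap_meta.iloc[rows].reset_index(drop=True), self.sites
        )


@dataclass
class LocalAncestryCalls:
    """H x M integer ancestry codes in {1..K} or MISSING, with K labels."""

    calls: np.ndarray
    ancestry_labels: tuple[str, ...] = DEFAULT_ANCESTRY_LABELS
    hap_meta: pd.DataFrame | None = None
    sites: SiteMap | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int16)
        self.ancestry_labels = tuple(self.ancestry_labels)
        if self.n_ancestries < 2:
            raise FormatError("need at least 2 ancestry labels")
        if len(set(self.ancestry_labels)) != self.n_ancestries:
            raise FormatError("ancestry labels must be unique")
        ok = ((self.calls >= 1) & (self.calls <= self.n_ancestries)) | (self.calls == MISSING)
        if not ok.all():
            raise FormatError("ancestry codes outside 1..K / MISSING")
        if self.sites is not None and self.calls.shape[1] != len(self.sites):
            raise FormatError("site map length does not match call matrix")
        if self.hap_meta is not None:
            _check_hap_meta(self.hap_meta, self.calls.shape[0])

    @property
    def n_ancestries(self) -> int:
        return len(self.ancestry_labels)

    @property
    def n_haplotypes(self) -> int:
        return self.calls.shape[0]

    @property
    def n_sites(self) -> int:
        return self.calls.shape[1]

    def code_of(self, label: str) -> int:
        """1-based ancestry code of a label."""
        try:
            return self.ancestry_labels.index(label) + 1
        except ValueError:
            raise KeyError(f"unknown ancestry label {label!r}; have {self.ancestry_labels}")

    def rows_of(self, sample_id: str) -> np.ndarray:
        if self.hap_meta is None:
            raise ValueError("calls carry no haplotype metadata")
        return np.flatnonzero((self.hap_meta["sample_id"] == sample_id).to_numpy())


@dataclass
class PosteriorArray:
    """H x M x K posterior ancestry probabilities; each (h, m) slice sums to 1."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 3:
            raise FormatError("posterior array must be H x M x K")
        if (self.probs < 0).any():
            raise FormatError("negative posterior probability")
        sums = self.probs.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise FormatError("posterior slices do not sum to 1 (tol 1e-6)")


@dataclass
class PedigreeTable:
    """Family records classified into trios (both parents) and pairs (one parent).

    ``records`` columns: child, mother, father, sex, kind; missing parents are
    empty strings.  Children with neither parent are dropped at read time.
    """

    records: pd.DataFrame
    n_dropped: int = 0

    def __post_init__(self) -> None:
        for _, r in self.records.iterrows():
            if r["child"] in (r["mother"], r["father"]):
                raise FormatError(f"individual {r['child']!r} listed as its own parent")

    @property
    def trios(self) -> pd.DataFrame:
        return self.records[self.records["kind"] == "trio"].reset_index(drop=True)

    @property
    def pairs(self) -> pd.DataFrame:
        return self.records[self.records["kind"] == "pair"].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Phased VCF
# ---------------------------------------------------------------------------

_MISSING_PARENT = {"", "0", "NA", "na", ".", "nan"}


def read_phased_vcf(
    path: str | Path,
    region: str | None = None,
    sex_map: dict[str, str] | None = None,
) -> HaplotypePanel:
    """Read phased GT fields from a VCF into a haplotype panel.

    Diploid samples contribute two rows per site (copy 1 before copy 2, in
    header sample order); a single-allele (haploid) GT contributes one row,
    as on male X.  ``.`` alleles become :data:`MISSING`.  Multiallelic
    records are skipped with a logged count.  Any unphased two-allele
    genotype (``/`` separator, not fully missing) is a hard error naming
    the site and sample.

    Parameters
    ----------
    path
        VCF file (plain text or bgzipped).
    region
        Optional chromosome label; only records on that chromosome are kept.
    sex_map
        Optional sample -> {'male','female','unknown'} labels attached to
        the metadata; never inferred from the genotypes.
    """
    sex_map = sex_map or {}
    path = Path(path)
    try:
        vcf = pysam.VariantFile(str(path))
    except Exception as exc:  # pragma: no cover - pysam error text varies
        raise FormatError(f"cannot read VCF {path}: {exc}") from exc
    samples = list(vcf.header.samples)
    if not samples:
        raise FormatError(f"VCF {path} has no samples")

    columns: list[list[int]] = []
    chroms: list[str] = []
    pos: list[int] = []
    ids: list[str] = []
    ploidy: dict[str, int] = {}
    n_multi = 0
    for rec in vcf:
        if region is not None and rec.chrom != region:
            continue
        if rec.alts is None or len(rec.alts) != 1:
            n_multi += 1
            continue
        site_alleles: list[int] = []
        for s in samples:
            call = rec.samples[s]
            gt = call["GT"]
            if gt is None or len(gt) == 0:
                gt = (None,)
            fully_missing = all(a is None for a in gt)
            if len(gt) == 2 and not call.phased and not fully_missing:
                raise FormatError(
                    f"unphased genotype for sample {s} at {rec.chrom}:{rec.pos}"
                )
            p = ploidy.setdefault(s, len(gt))
            if len(gt) != p:
                if fully_missing:  # '.' in a diploid sample: both copies missing
                    gt = (None,) * p
                else:
                    raise FormatError(
                        f"ploidy of sample {s} changes at {rec.chrom}:{rec.pos}"
                    )
            site_alleles.extend(MISSING if a is None else int(a) for a in gt)
        columns.append(site_alleles)
        chroms.append(rec.chrom)
        pos.append(rec.pos)
        ids.append(rec.id or f"{rec.chrom}:{rec.pos}")
    vcf.close()
    if not columns:
        raise FormatError(f"VCF {path} contains no usable biallelic records")
    if n_multi:
        logger.info("read_phased_vcf: skipped %d multiallelic record(s)", n_multi)

    alleles = np.asarray(columns, dtype=np.int8).T  # site-major -> hap-major
    sample_col: list[str] = []
    copy_col: list[int] = []
    for s in samples:
        for c in range(1, ploidy[s] + 1):
            sample_col.append(s)
            copy_col.append(c)
    meta = make_hap_meta(
        sample_col, copy_col, [sex_map.get(s, "unknown") for s in sample_col]
    )
    sites = SiteMap(pd.DataFrame({"chrom": chroms, "pos_bp": pos, "site_id": ids}))
    return HaplotypePanel(alleles, meta, sites)


def write_phased_vcf(panel: HaplotypePanel, path: str | Path) -> None:
    """Write a panel as a minimal GT-only phased VCF (haploid rows -> single allele)."""
    path = Path(path)
    ids = panel.hap_meta["sample_id"].to_numpy()
    samples = panel.sample_ids
    rows_per_sample = {s: np.flatnonzero(ids == s) for s in samples}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(panel.sites.chrom):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        site_ids = panel.sites.table["site_id"].to_numpy()
        for m in range(panel.n_sites):
            fields = [
                str(panel.sites.chrom[m]),
                str(int(panel.sites.pos_bp[m])),
                str(site_ids[m]),
                "A",
                "G",
                ".",
                "PASS",
                ".",
                "GT",
            ]
            for s in samples:
                alleles = panel.alleles[rows_per_sample[s], m]
                gt = "|".join("." if a == MISSING else str(int(a)) for a in alleles)
                fields.append(gt)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# RFMix-style call text (site-major)
# ---------------------------------------------------------------------------


def read_rfmix_viterbi(
    path: str | Path,
    labels: Sequence[str],
    sites: SiteMap,
    hap_meta: pd.DataFrame | None = None,
) -> LocalAncestryCalls:
    """Read site-major whitespace-delimited integer ancestry codes.

    One row per site, one column per haplotype, codes 1..K; column order is
    the haplotype order of the companion panel.
    """
    path = Path(path)
    labels = tuple(labels)
    k = len(labels)
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            vals = np.array(line.split(), dtype=np.int16)
            if ((vals < 1) | (vals > k)).any():
                raise FormatError(f"{path}:{lineno}: ancestry code outside 1..{k}")
            rows.append(vals)
    if len(rows) != len(sites):
        raise FormatError(
            f"{path}: {len(rows)} call rows but site map has {len(sites)} sites"
        )
    calls = np.vstack(rows).T  # site-major on disk -> haplotype-major in memory
    return LocalAncestryCalls(calls, labels, hap_meta, sites)


def write_rfmix_viterbi(calls: LocalAncestryCalls, path: str | Path) -> None:
    """Write calls in the site-major space-delimited format read by read_rfmix_viterbi."""
    np.savetxt(path, calls.calls.T, fmt="%d", delimiter=" ")


def read_rfmix_posterior(path: str | Path, n_ancestries: int) -> PosteriorArray:
    """Read site-major posterior text: K columns per haplotype, one row per site."""
    mat = np.loadtxt(path, dtype=float, ndmin=2)
    n_sites, ncol = mat.shape
    if ncol % n_ancestries:
        raise FormatError(
            f"{path}: {ncol} columns not divisible by K={n_ancestries}"
        )
    h = ncol // n_ancestries
    probs = mat.reshape(n_sites, h, n_ancestries).transpose(1, 0, 2)
    return PosteriorArray(probs)


def write_rfmix_posterior(post: PosteriorArray, path: str | Path) -> None:
    h, m, k = post.probs.shape
    np.savetxt(path, post.probs.transpose(1, 0, 2).reshape(m, h * k), fmt="%.6g")


# ---------------------------------------------------------------------------
# Pedigree and site-map TSV
# ---------------------------------------------------------------------------


def read_pedigree(path: str | Path) -> PedigreeTable:
    """Read a pedigree TSV (child, mother, father, sex).

    Missing parents are coded 0/NA/blank.  Records with both parents become
    trios, with exactly one a pair; children with neither parent are dropped
    (count logged and kept on the returned table).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"child", "mother", "father", "sex"}
    if not required.issubset(df.columns):
        raise FormatError(f"pedigree needs columns {sorted(required)}")

    def norm(v: str) -> str:
        return "" if v.strip() in _MISSING_PARENT else v.strip()

    records = []
    n_dropped = 0
    for _, r in df.iterrows():
        mother, father = norm(r["mother"]), norm(r["father"])
        if not mother and not father:
            n_dropped += 1
            continue
        kind = "trio" if mother and father else "pair"
        records.append(
            {
                "child": r["child"].strip(),
                "mother": mother,
                "father": father,
                "sex": r["sex"].strip().lower(),
                "kind": kind,
            }
        )
    if n_dropped:
        logger.info("read_pedigree: dropped %d record(s) with no parents", n_dropped)
    cols = ["child", "mother", "father", "sex", "kind"]
    out = pd.DataFrame(records, columns=cols)
    return PedigreeTable(out, n_dropped=n_dropped)


def write_pedigree(ped: PedigreeTable, path: str | Path) -> None:
    ped.records[["child", "mother", "father", "sex"]].to_csv(path, sep="\t", index=False)


def read_sitemap(path: str | Path) -> SiteMap:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "site_id": str})
    return SiteMap(df)


def write_sitemap(sites: SiteMap, path: str | Path) -> None:
    sites.table.to_csv(path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path: str | Path, float_decimals: int = 4) -> None:
    """Write a result table as TSV with a header row, floats to fixed decimals."""
    df.to_csv(path, sep="\t", index=False, float_format=f"%.{float_decimals}f")
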