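"""Masking, global-ancestry summaries, filters, thinning and concordance.

These are the bookkeeping steps between raw local-ancestry calls and the
downstream analyses: masking alleles outside a target ancestry, turning
per-site calls into per-sample global proportions, the >=50%-ancestry
inclusion filter, deterministic marker thinning, reference-panel
filtering from an externally supplied Q-matrix, call-set concordance
with unordered (max-agreement) diploid matching, and averages of
highest posterior probabilities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .haplotype_io import (
    MISSING,
    HaplotypePanel,
    LocalAncestryCalls,
    PosteriorArray,
    SiteMap,
)

logger = logging.getLogger("lanctk")


# ---------------------------------------------------------------------------
# Masking
# ---------------------------------------------------------------------------


def mask_by_ancestry(
    panel: HaplotypePanel, calls: LocalAncestryCalls, target: str
) -> HaplotypePanel:
    """Set to MISSING every allele on haplotype segments not called ``target``.

    The mask applies per haplotype (not per genotype): allele (h, m) is
    kept only where call (h, m) equals the target ancestry; alleles that
    were already missing stay missing.
    """
    if panel.alleles.shape != calls.calls.shape:
        raise ValueError("panel and calls are not dimension-aligned")
    code = calls.code_of(target)
    out = np.where(calls.calls == code, panel.alleles, np.int8(MISSING))
    return HaplotypePanel(out.astype(np.int8), panel.hap_meta.copy(), panel.sites)


# ---------------------------------------------------------------------------
# Global ancestry proportions and threshold filter
# ---------------------------------------------------------------------------


@dataclass
class AncestryProportions:
    """Per-sample global ancestry fractions averaged over haplotypes and sites.

    ``table`` has one row per sample with one column per ancestry label;
    samples whose calls are entirely missing get NaN rows and are listed
    in ``undefined``.
    """

    table: pd.DataFrame  # index: sample_id; columns: ancestry labels
    undefined: list[str]

    def __getitem__(self, sample_id: str) -> np.ndarray:
        return self.table.loc[sample_id].to_numpy()


def global_proportions(calls: LocalAncestryCalls) -> AncestryProportions:
    """Fraction of each sample's non-missing (haplotype, site) cells called k."""
    if calls.hap_meta is None:
        raise ValueError("calls need haplotype metadata to group by sample")
    if calls.calls.size == 0:
        raise ValueError("empty call matrix")
    k = calls.n_ancestries
    rows = []
    undefined: list[str] = []
    sample_order = list(dict.fromkeys(calls.hap_meta["sample_id"]))
    ids = calls.hap_meta["sample_id"].to_numpy()
    for sid in sample_order:
        cells = calls.calls[ids == sid].ravel()
        cells = cells[cells != MISSING]
        if cells.size == 0:
            undefined.append(sid)
            rows.append(np.full(k, np.nan))
        else:
            counts = np.bincount(cells, minlength=k + 1)[1 : k + 1]
            rows.append(counts / cells.size)
    table = pd.DataFrame(rows, index=pd.Index(sample_order, name="sample_id"),
                         columns=list(calls.ancestry_labels))
    if undefined:
        logger.warning("global_proportions: %d sample(s) all-missing", len(undefined))
    return AncestryProportions(table, undefined)


def filter_by_ancestry_threshold(
    props: AncestryProportions, target: str, threshold: float = 0.5
) -> list[str]:
    """Samples with proportion of ``target`` ancestry >= threshold (inclusive)."""
    col = props.table[target]
    return list(props.table.index[col.to_numpy() >= threshold])


# ---------------------------------------------------------------------------
# Marker thinning
# ---------------------------------------------------------------------------


def _largest_remainder(counts: np.ndarray, total: int) -> np.ndarray:
    """Apportion ``total`` across groups proportionally to ``counts``."""
    quota = counts / counts.sum() * total
    alloc = np.floor(quota).astype(int)
    short = total - alloc.sum()
    if short > 0:
        order = np.argsort(-(quota - alloc), kind="stable")
        alloc[order[:short]] += 1
    return alloc


def thin_markers(panel: HaplotypePanel, n_target: int = 10_000) -> HaplotypePanel:
    """Deterministically thin to ``n_target`` sites, evenly spaced by index.

    Sites are allocated to chromosomes proportionally to their site counts
    (largest-remainder rounding) and chosen evenly spaced within each
    chromosome.  Default 10,000 markers keeps interhaplotype distance
    computation cheap and damps local linkage disequilibrium.
    """
    return panel.subset_sites(thin_indices(panel.sites, n_target))


def thin_indices(sites: SiteMap, n_target: int) -> np.ndarray:
    """Site indices thin_markers would retain, for applying the same thinning elsewhere."""
    if n_target <= 0:
        raise ValueError("n_target must be positive")
    if n_target > len(sites):
        raise ValueError("n_target exceeds available sites")
    chroms = sites.chrom
    uniq = list(dict.fromkeys(chroms))
    counts = np.array([(chroms == c).sum() for c in uniq])
    alloc = _largest_remainder(counts, n_target)
    keep = []
    for c, n_c in zip(uniq, alloc):
        idx = np.flatnonzero(chroms == c)
        if n_c == 0:
            continue
        picks = np.unique(np.round(np.linspace(0, len(idx) - 1, n_c)).astype(int))
        keep.append(idx[picks])
    return np.sort(np.concatenate(keep))


# ---------------------------------------------------------------------------
# Reference-panel filtering and site intersection
# ---------------------------------------------------------------------------


def filter_reference_panel(
    q: pd.DataFrame,
    min_fraction: float = 0.9,
    exclude: set[str] | None = None,
) -> pd.DataFrame:
    """Retain reference individuals nearly unadmixed in a non-excluded cluster.

    ``q`` is an externally estimated ancestry-fraction matrix (rows:
    individuals, columns: clusters, rows summing to 1), e.g. from an
    unsupervised ADMIXTURE run.  An individual is retained iff its largest
    fraction over non-excluded clusters is >= ``min_fraction`` (inclusive);
    the returned frame maps individual -> assigned cluster.  Excluding a
    cluster (e.g. an out-of-model continental group) drops individuals
    whose dominant ancestry is that cluster.
    """
    exclude = set(exclude or ())
    unknown = exclude - set(q.columns)
    if unknown:
        raise ValueError(f"excluded clusters not in Q-matrix: {sorted(unknown)}")
    keep_cols = [c for c in q.columns if c not in exclude]
    if not keep_cols:
        raise ValueError("exclusion covers all clusters")
    sums = q.sum(axis=1).to_numpy()
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError("Q-matrix rows must sum to 1")
    sub = q[keep_cols]
    best = sub.max(axis=1)
    assigned = sub.idxmax(axis=1)
    mask = best.to_numpy() >= min_fraction
    return pd.DataFrame(
        {"individual": q.index[mask], "cluster": assigned[mask].to_numpy()}
    ).reset_index(drop=True)


def intersect_sites(a: SiteMap, b: SiteMap) -> tuple[np.ndarray, np.ndarray]:
    """Index vectors into ``a`` and ``b`` of the sites shared on (chrom, pos)."""
    for name, m in (("first", a), ("second", b)):
        key = m.table[["chrom", "pos_bp"]]
        if key.duplicated().any():
            raise ValueError(f"duplicate positions in {name} site map")
    ka = a.table.assign(_ia=np.arange(len(a)))
    kb = b.table.assign(_ib=np.arange(len(b)))
    merged = ka.merge(kb, on=["chrom", "pos_bp"], how="inner", sort=False)
    return merged["_ia"].to_numpy(), merged["_ib"].to_numpy()


# ---------------------------------------------------------------------------
# Call-set concordance (unordered diploid matching)
# ---------------------------------------------------------------------------


def match_diploid_calls(
    call_a: tuple[int, int], call_b: tuple[int, int]
) -> tuple[int, tuple[tuple[int, int], tuple[int, int]]]:
    """Align two unordered diploid ancestry calls to maximize agreement.

    Local-ancestry phase is not comparable across call sets, so the two
    haplotypes of one call are matched to the two of the other in
    whichever of the two possible alignments agrees on more haplotypes
    (ties broken toward the identity alignment).  Returns the agreement
    count (0-2) and the matched (label_a, label_b) pairs.
    """
    a1, a2 = call_a
    b1, b2 = call_b
    agree_id = (a1 == b1) + (a2 == b2)
    agree_sw = (a1 == b2) + (a2 == b1)
    if agree_sw > agree_id:
        return agree_sw, ((a1, b2), (a2, b1))
    return agree_id, ((a1, b1), (a2, b2))


@dataclass
class ConcordanceTable:
    """K x K proportions of matched haplotype calls between two call sets."""

    table: pd.DataFrame  # rows: labels of set a; columns: labels of set b
    overall_agreement: float
    n_cells: int  # matched haplotype pairs counted

    def __post_init__(self) -> None:
        total = float(self.table.to_numpy().sum())
        if self.n_cells and abs(total - 1.0) > 1e-9:
            raise ValueError("concordance proportions must sum to 1")


def concordance_table(
    calls_a: LocalAncestryCalls, calls_b: LocalAncestryCalls
) -> ConcordanceTable:
    """Cross-tabulate two call sets with per-(sample, site) max-agreement matching.

    For every sample and site the two unordered diploid calls are aligned
    by :func:`match_diploid_calls`; matched (label_a, label_b) haplotype
    pairs are pooled over all samples and sites into a K x K proportion
    table.  Overall agreement is the diagonal sum.  Sites where any of the
    four calls is missing are excluded.
    """
    if calls_a.calls.shape != calls_b.calls.shape:
        raise ValueError("call sets are not dimension-aligned")
    if calls_a.ancestry_labels != calls_b.ancestry_labels:
        raise ValueError("call sets use different ancestry alphabets")
    if calls_a.hap_meta is None:
        raise ValueError("calls need haplotype metadata to pair haplotypes by sample")
    k = calls_a.n_ancestries
    counts = np.zeros((k, k), dtype=np.int64)
    ids = calls_a.hap_meta["sample_id"].to_numpy()
    for sid in dict.fromkeys(ids):
        rows = np.flatnonzero(ids == sid)
        if len(rows) != 2:
            continue  # concordance is defined on diploid calls
        a1, a2 = calls_a.calls[rows[0]], calls_a.calls[rows[1]]
        b1, b2 = calls_b.calls[rows[0]], calls_b.calls[rows[1]]
        ok = (a1 != MISSING) & (a2 != MISSING) & (b1 != MISSING) & (b2 != MISSING)
        a1, a2, b1, b2 = a1[ok], a2[ok], b1[ok], b2[ok]
        agree_id = (a1 == b1).astype(np.int8) + (a2 == b2)
        agree_sw = (a1 == b2).astype(np.int8) + (a2 == b1)
        swap = agree_sw > agree_id
        pb1 = np.where(swap, b2, b1)
        pb2 = np.where(swap, b1, b2)
        for xa, xb in ((a1, pb1), (a2, pb2)):
            flat = (xa.astype(np.int64) - 1) * k + (xb.astype(np.int64) - 1)
            counts += np.bincount(flat, minlength=k * k).reshape(k, k)
    n_cells = int(counts.sum())
    if n_cells == 0:
        raise ValueError("no non-missing diploid cells to compare")
    props = counts / n_cells
    labels = list(calls_a.ancestry_labels)
    table = pd.DataFrame(props, index=labels, columns=labels)
    return ConcordanceTable(table, float(np.trace(props)), n_cells)


# ---------------------------------------------------------------------------
# Posterior summaries
# ---------------------------------------------------------------------------


def avg_max_posterior(
    post: PosteriorArray, labels: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """Average highest posterior probability, by winning ancestry and overall.

    For each haplotype and position the highest of the K posterior
    probabilities is recorded together with its ancestry; the table
    reports the mean of those maxima grouped by winning ancestry plus the
    ungrouped overall mean.  Ties go to the lowest ancestry index
    (logged).  Values near 1 indicate a confident caller; note that
    confidence is not the same thing as accuracy.
    """
    if post.probs.size == 0:
        raise ValueError("empty posterior array")
    k = post.probs.shape[2]
    if labels is None:
        labels = tuple(f"ancestry_{i + 1}" for i in range(k))
    if len(labels) != k:
        raise ValueError("label count does not match K")
    maxima = post.probs.max(axis=2)
    winner = post.probs.argmax(axis=2)  # numpy argmax takes lowest index on ties
    n_ties = int((np.isclose(post.probs, maxima[..., None]).sum(axis=2) > 1).sum())
    if n_ties:
        logger.info("avg_max_posterior: %d tie(s) broken toward lowest index", n_ties)
    rows = []
    for j, lab in enumerate(labels):
        sel = winner == j
        rows.append(
            {
                "ancestry": lab,
                "mean_max_posterior": float(maxima[sel].mean()) if sel.any() else np.nan,
                "n_cells": int(sel.sum()),
            }
        )
    rows.append(
        {
            "ancestry": "Overall",
            "mean_max_posterior": float(maxima.mean()),
            "n_cells": int(maxima.size),
        }
    )
    return pd.DataFrame(rows)
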