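"""Ancestry-specific PCA via multidimensional scaling of masked haplotypes.

Masking sets to missing every allele outside the target ancestry, so the
missingness pattern lives on haplotypes, not genotypes, and principal
components are computed per haplotype.  Classical (Torgerson) MDS of
Euclidean interhaplotype distances is exactly PCA when there is no
missing data, and degrades gracefully under masking: distances use only
positions where both haplotypes are non-missing, scaled up
proportionally for the skipped positions, and a pair sharing no
positions at all gets the mean distance over all defined pairs.  This
avoids the artifactual reference/admixed cluster separation that
subspace-reconstruction approaches to masked PCA can produce.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ancestry_ops import (
    filter_by_ancestry_threshold,
    global_proportions,
    mask_by_ancestry,
    thin_indices,
)
from .haplotype_io import MISSING, HaplotypePanel, LocalAncestryCalls

logger = logging.getLogger("lanctk")


@dataclass
class DistanceMatrix:
    """Symmetric haplotype distances with bookkeeping for masked overlaps.

    ``imputed[i, j]`` marks pairs that shared no non-missing site and were
    assigned the mean over defined off-diagonal distances; ``n_shared``
    counts the non-missing positions each distance is based on.
    """

    d: np.ndarray
    imputed: np.ndarray
    n_shared: np.ndarray

    def __post_init__(self) -> None:
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if (self.d < 0).any():
            raise ValueError("distances must be nonnegative")


@dataclass
class PCResult:
    """MDS/PCA embedding: H x k coordinates plus the eigenvalues behind them.

    Column j of ``coords`` is eigenvector j scaled by sqrt(eigenvalue j);
    ``n_positive`` reports how many of the requested components were
    backed by positive eigenvalues (the rest are zero columns).
    """

    coords: np.ndarray
    eigenvalues: np.ndarray
    n_positive: int
    hap_meta: pd.DataFrame | None = None


def pairwise_distance(panel: HaplotypePanel, scaled: bool = True) -> DistanceMatrix:
    """Euclidean distances between haplotype rows under pairwise deletion.

    Alleles are treated as 0/1 coordinates.  For haplotypes i, j with
    ``s`` shared non-missing sites out of M, the scaled convention is

        d(i, j) = sqrt( (M / s) * sum over shared sites (x - y)^2 ),

    i.e. the mean squared difference over observed positions scaled back
    up to the full site count — the missing-value convention of R's
    ``dist()``.  With ``scaled=False`` the raw sqrt of the sum is
    returned instead (sensitivity analysis).  Pairs with s = 0 are set,
    after all defined pairs are computed, to the mean of the defined
    off-diagonal distances, in a single pass.
    """
    x = panel.alleles
    h, m = x.shape
    if m < 1:
        raise ValueError("panel has no sites")
    valid = (x != MISSING)
    ones = ((x == 1) & valid).astype(np.float64)
    zeros = ((x == 0) & valid).astype(np.float64)
    # 0/1 alleles: squared difference over shared sites = mismatch count.
    mism = ones @ zeros.T
    mism += mism.T
    n_shared = (valid.astype(np.float64) @ valid.T.astype(np.float64)).astype(np.int64)
    defined = n_shared > 0
    np.fill_diagonal(defined, True)
    d = np.zeros((h, h))
    with np.errstate(divide="ignore", invalid="ignore"):
        if scaled:
            d = np.sqrt(np.where(defined, m / np.maximum(n_shared, 1) * mism, 0.0))
        else:
            d = np.sqrt(np.where(defined, mism, 0.0))
    np.fill_diagonal(d, 0.0)
    off = ~np.eye(h, dtype=bool)
    if not (defined & off).any():
        raise ValueError("panel too sparse: no haplotype pair shares a non-missing site")
    imputed = (~defined) & off
    if imputed.any():
        mean_d = d[defined & off].mean()
        d[imputed] = mean_d
        logger.info(
            "pairwise_distance: %d pair(s) with no shared sites set to mean %.4f",
            int(imputed.sum()) // 2,
            mean_d,
        )
    return DistanceMatrix(d, imputed, n_shared)


def classical_mds(dist: DistanceMatrix | np.ndarray, k: int) -> PCResult:
    """Torgerson scaling: double-center squared distances and eigendecompose.

    B = -1/2 J D.D J with J = I - 11'/H; coordinates are the top-k
    eigenvectors scaled by sqrt(eigenvalue).  Only positive eigenvalues
    yield coordinates; if fewer than k exist the remaining columns are
    zero and ``n_positive`` reports the shortfall.  Each column's sign is
    fixed so its largest-magnitude entry is positive, for determinism
    across linear-algebra backends.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    d = dist.d if isinstance(dist, DistanceMatrix) else np.asarray(dist, dtype=float)
    h = d.shape[0]
    if h < k + 1:
        raise ValueError(f"need at least {k + 1} haplotypes for k={k} components")
    d2 = d * d
    # Double-centering without forming J explicitly.
    row_mean = d2.mean(axis=1, keepdims=True)
    b = -0.5 * (d2 - row_mean - row_mean.T + d2.mean())
    b = (b + b.T) / 2.0
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    eps = 1e-9 * max(1.0, abs(evals[0])) if h else 0.0
    n_positive = min(k, int((evals > eps).sum()))
    coords = np.zeros((h, k))
    for j in range(n_positive):
        v = evecs[:, j] * np.sqrt(evals[j])
        i_max = np.argmax(np.abs(v))
        if v[i_max] < 0:
            v = -v
        coords[:, j] = v
    return PCResult(coords, evals[:k].copy(), n_positive)


def ancestry_specific_pca(
    panel: HaplotypePanel,
    calls: LocalAncestryCalls,
    target: str,
    threshold: float = 0.5,
    n_sites: int = 10_000,
    exclude: list[str] | None = None,
    k: int = 4,
    reference: HaplotypePanel | None = None,
    scaled: bool = True,
) -> PCResult:
    """End-to-end ancestry-specific PCA of the target component.

    Pipeline: drop excluded samples (e.g. close relatives, supplied as a
    list) -> keep samples with >= ``threshold`` global target ancestry ->
    thin to ``n_sites`` markers -> mask alleles not called ``target`` ->
    pairwise distances under masking -> classical MDS with ``k``
    components.  Both haplotypes of each retained sample enter as
    separate rows.  ``reference`` haplotypes, when supplied (site-aligned
    with ``panel``), pass through unmasked alongside the masked admixed
    haplotypes, so admixed target-ancestry segments can be placed
    relative to reference populations.

    Returns a :class:`PCResult` whose ``hap_meta`` identifies each row
    (sample, copy, and a ``role`` column: admixed vs reference).
    """
    if panel.alleles.shape != calls.calls.shape:
        raise ValueError("panel and calls are not dimension-aligned")
    exclude_set = set(exclude or ())
    ids = panel.hap_meta["sample_id"].to_numpy()
    keep_rows = np.flatnonzero(~np.isin(ids, list(exclude_set)))
    work_panel = panel.subset_haplotypes(keep_rows)
    work_calls = LocalAncestryCalls(
        calls.calls[keep_rows],
        calls.ancestry_labels,
        panel.hap_meta.iloc[keep_rows].reset_index(drop=True),
        calls.sites,
    )
    props = global_proportions(work_calls)
    retained = set(filter_by_ancestry_threshold(props, target, threshold))
    rows = np.flatnonzero(
        np.isin(work_panel.hap_meta["sample_id"].to_numpy(), list(retained))
    )
    if len(rows) == 0:
        raise ValueError(f"no samples with >= {threshold:.0%} {target} ancestry")
    work_panel = work_panel.subset_haplotypes(rows)
    work_calls = LocalAncestryCalls(
        work_calls.calls[rows],
        work_calls.ancestry_labels,
        work_panel.hap_meta,
        work_calls.sites,
    )
    n_sites = min(n_sites, work_panel.n_sites)
    sel = thin_indices(work_panel.sites, n_sites)
    work_panel = work_panel.subset_sites(sel)
    work_calls = LocalAncestryCalls(
        work_calls.calls[:, sel],
        work_calls.ancestry_labels,
        work_panel.hap_meta,
        work_panel.sites,
    )
    masked = mask_by_ancestry(work_panel, work_calls, target)
    logger.info(
        "ancestry_specific_pca: %d admixed haplotypes, %d sites after thinning",
        masked.n_haplotypes,
        masked.n_sites,
    )
    meta = masked.hap_meta.copy()
    meta["role"] = "admixed"
    alleles = masked.alleles
    if reference is not None:
        if reference.n_sites != panel.n_sites:
            raise ValueError("reference panel is not site-aligned with the admixed panel")
        ref_sub = reference.subset_sites(sel)
        ref_meta = ref_sub.hap_meta.copy()
        ref_meta["role"] = "reference"
        alleles = np.vstack([alleles, ref_sub.alleles])
        meta = pd.concat([meta, ref_meta], ignore_index=True)
    if alleles.shape[0] < k + 1:
        raise ValueError(
            f"only {alleles.shape[0]} haplotypes retained; need at least {k + 1}"
        )
    stacked = HaplotypePanel(alleles, meta, masked.sites)
    dist = pairwise_distance(stacked, scaled=scaled)
    result = classical_mds(dist, k)
    result.hap_meta = meta
    return result
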