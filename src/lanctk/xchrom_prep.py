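"""X-chromosome coding schemes for diploid-only local-ancestry callers.

Males are haploid for the non-pseudoautosomal X, but RFMix-style callers
expect diploid input.  Coding a reference male as homozygous diploid
doubles the apparent frequency of his haplotype in the reference panel,
so instead reference males are artificially paired into phased
pseudodiploids within each continental reference group (discarding the
final male of any odd-sized group); the caller never rephases the
reference, so no phase information is lost.  For the admixed cohort
three schemes are supported:

* Option 1 — separate analyses for admixed males (haploid, known phase)
  and admixed females (diploid, statistically phased), both against the
  pseudodiploid reference;
* Option 2 — one analysis of all admixed individuals with admixed males
  coded homozygous, reference males pseudodiploid;
* Option 3 — one analysis with every male (admixed and reference) coded
  homozygous, no pseudodiploid pairing.

Options 2 and 3 encode the admixed individuals identically; they differ
only in the reference-male encoding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .haplotype_io import HaplotypePanel, make_hap_meta

logger = logging.getLogger("lanctk")


@dataclass
class XEncodedSet:
    """One analysis-ready X input: encoded panel, phase flag and manifest."""

    panel: HaplotypePanel
    phase: str  # 'known' or 'statistical'
    manifest: pd.DataFrame  # sample, role, coding


def _require_role(panel: HaplotypePanel) -> None:
    if "role" not in panel.hap_meta.columns:
        raise ValueError("hap_meta needs a 'role' column (admixed/reference)")


def pair_reference_males(
    males: HaplotypePanel,
    rng: np.random.Generator | None = None,
) -> tuple[HaplotypePanel, list[str]]:
    """Pair haploid reference males into phased pseudodiploids within groups.

    Males are paired in input order (first with second, and so on) within
    each group label; pass ``rng`` to shuffle within groups first.  The
    trailing male of an odd-sized group is dropped and returned in the
    dropped list; a group with fewer than two males contributes no
    pseudodiploids (warning logged).  Allele content of the non-dropped
    haplotypes is unchanged — only the sample grouping metadata changes.
    """
    meta = males.hap_meta
    if (meta["sex"] != "male").any():
        raise ValueError("pair_reference_males expects only male haplotypes")
    counts = meta.groupby("sample_id", sort=False).size()
    if (counts != 1).any():
        raise ValueError("reference males must be haploid (one row per sample)")
    rows_out: list[np.ndarray] = []
    meta_rows: list[dict] = []
    dropped: list[str] = []
    for group in dict.fromkeys(meta["group"]):
        idx = np.flatnonzero((meta["group"] == group).to_numpy())
        if rng is not None:
            idx = rng.permutation(idx)
        if len(idx) < 2:
            logger.warning(
                "group %r has %d male(s); no pseudodiploid formed", group, len(idx)
            )
            dropped.extend(meta["sample_id"].iloc[idx])
            continue
        if len(idx) % 2:
            dropped.append(meta["sample_id"].iloc[idx[-1]])
            idx = idx[:-1]
        for a, b in zip(idx[0::2], idx[1::2]):
            sid_a = meta["sample_id"].iloc[a]
            sid_b = meta["sample_id"].iloc[b]
            pseudo_id = f"{sid_a}+{sid_b}"
            rows_out.append(males.alleles[a])
            rows_out.append(males.alleles[b])
            for copy, origin in ((1, sid_a), (2, sid_b)):
                meta_rows.append(
                    {"sample_id": pseudo_id, "copy": copy, "sex": "unknown",
                     "group": group, "origin": origin}
                )
    if not rows_out:
        raise ValueError("no group contained two or more males to pair")
    out_meta = pd.DataFrame(meta_rows)
    if "role" in meta.columns:
        out_meta["role"] = "reference"
    panel = HaplotypePanel(np.vstack(rows_out), out_meta, males.sites)
    return panel, dropped


def code_males_homozygous(panel: HaplotypePanel, which: str = "both") -> HaplotypePanel:
    """Duplicate each haploid male row into a homozygous diploid pair.

    ``which`` restricts the coding to 'admixed' or 'reference' samples
    (requires a ``role`` metadata column) or applies to 'both'.  A male
    already carrying two rows is an error (the coding is not idempotent);
    females pass through unchanged.
    """
    if which not in ("admixed", "reference", "both"):
        raise ValueError("which must be 'admixed', 'reference' or 'both'")
    meta = panel.hap_meta
    if which != "both":
        _require_role(panel)
    rows_out: list[np.ndarray] = []
    meta_rows: list[pd.Series] = []
    ids = meta["sample_id"].to_numpy()
    for sid in dict.fromkeys(ids):
        rows = np.flatnonzero(ids == sid)
        sub = meta.iloc[rows]
        sex = sub["sex"].iloc[0]
        in_scope = which == "both" or sub.get("role", pd.Series(["?"])).iloc[0] == which
        if sex == "male" and in_scope:
            if len(rows) != 1:
                raise ValueError(f"male {sid} is already diploid; refusing to re-code")
            rows_out.append(panel.alleles[rows[0]])
            rows_out.append(panel.alleles[rows[0]])
            first = sub.iloc[0].copy()
            second = sub.iloc[0].copy()
            first["copy"], second["copy"] = 1, 2
            meta_rows.extend([first, second])
        else:
            if sex != "male":
                logger.debug("code_males_homozygous: %s (%s) unchanged", sid, sex)
            for r in rows:
                rows_out.append(panel.alleles[r])
                meta_rows.append(meta.iloc[r])
    out_meta = pd.DataFrame(meta_rows).reset_index(drop=True)
    return HaplotypePanel(np.vstack(rows_out), out_meta, panel.sites)


def _concat_panels(a: HaplotypePanel, b: HaplotypePanel) -> HaplotypePanel:
    meta = pd.concat([a.hap_meta, b.hap_meta], ignore_index=True)
    return HaplotypePanel(np.vstack([a.alleles, b.alleles]), meta, a.sites)


def _manifest(panel: HaplotypePanel, coding_by_sample: dict[str, str]) -> pd.DataFrame:
    rows = []
    for sid in panel.sample_ids:
        sub = panel.hap_meta[panel.hap_meta["sample_id"] == sid]
        rows.append(
            {
                "sample": sid,
                "role": sub["role"].iloc[0] if "role" in sub.columns else "",
                "sex": sub["sex"].iloc[0],
                "coding": coding_by_sample.get(sid, "diploid"),
            }
        )
    return pd.DataFrame(rows)


def build_x_option_inputs(
    panel: HaplotypePanel,
    option: int,
    rng: np.random.Generator | None = None,
) -> dict[str, XEncodedSet]:
    """Encode an X panel under one of the three male-coding schemes.

    ``panel`` holds all individuals with ``role`` metadata (admixed or
    reference); males are haploid rows.  Returns one or two named
    analysis-ready sets (Option 1 gives 'males' and 'females'; Options 2
    and 3 give 'all').
    """
    _require_role(panel)
    if option not in (1, 2, 3):
        raise ValueError("option must be 1, 2 or 3")
    meta = panel.hap_meta
    unknown = sorted(set(meta.loc[meta["sex"] == "unknown", "sample_id"]))
    if unknown:
        raise ValueError(f"samples with unknown sex: {unknown}")

    def rows_where(**conds) -> np.ndarray:
        m = np.ones(len(meta), dtype=bool)
        for col, val in conds.items():
            m &= (meta[col] == val).to_numpy()
        return np.flatnonzero(m)

    adm_male = panel.subset_haplotypes(rows_where(role="admixed", sex="male"))
    adm_female = panel.subset_haplotypes(rows_where(role="admixed", sex="female"))
    ref_male = panel.subset_haplotypes(rows_where(role="reference", sex="male"))
    ref_female = panel.subset_haplotypes(rows_where(role="reference", sex="female"))

    out: dict[str, XEncodedSet] = {}
    if option in (1, 2):
        ref_pd, dropped = pair_reference_males(ref_male, rng=rng)
        if dropped:
            logger.info("build_x_option_inputs: dropped odd males %s", dropped)
        reference = (
            _concat_panels(ref_pd, ref_female) if ref_female.n_haplotypes else ref_pd
        )
        coding = {sid: "pseudodiploid" for sid in ref_pd.sample_ids}
        if option == 1:
            male_set = _concat_panels(adm_male, reference)
            female_set = _concat_panels(adm_female, reference)
            c1 = dict(coding, **{s: "haploid" for s in adm_male.sample_ids})
            out["males"] = XEncodedSet(male_set, "known", _manifest(male_set, c1))
            out["females"] = XEncodedSet(
                female_set, "statistical", _manifest(female_set, coding)
            )
        else:
            adm_male_hom = (
                code_males_homozygous(adm_male, "admixed")
                if adm_male.n_haplotypes
                else adm_male
            )
            all_set = _concat_panels(
                _concat_panels(adm_male_hom, adm_female), reference
            )
            c2 = dict(coding, **{s: "homozygous" for s in adm_male_hom.sample_ids})
            out["all"] = XEncodedSet(all_set, "statistical", _manifest(all_set, c2))
    else:  # option 3: everyone homozygous, no pairing
        parts = []
        coding3: dict[str, str] = {}
        for part in (adm_male, ref_male):
            if part.n_haplotypes:
                hom = code_males_homozygous(part, "both")
                parts.append(hom)
                coding3.update({s: "homozygous" for s in hom.sample_ids})
        for part in (adm_female, ref_female):
            if part.n_haplotypes:
                parts.append(part)
        all_set = parts[0]
        for p in parts[1:]:
            all_set = _concat_panels(all_set, p)
        out["all"] = XEncodedSet(all_set, "statistical", _manifest(all_set, coding3))
    return out
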