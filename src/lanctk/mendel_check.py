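"""Mendelian consistency of local-ancestry calls in parent-offspring families.

A child inherits exactly one chromosome from each parent, so at any locus
the child's unordered pair of ancestry calls must be explainable by
transmitting one call from the mother's pair and one from the father's.
A family whose calls cannot arise that way is Mendelian inconsistent at
the locus; since true Mendelian inconsistency in ancestry is essentially
impossible at these scales, the inconsistency rate is a proxy for
local-ancestry call error.  Pairs (one parent unobserved) are a
relaxation of trios: the missing parent is unconstrained, so pair rates
underestimate the error detectable with both parents.

All predicates treat calls as unordered multisets — statistically
inferred phase is not reliable enough across individuals to support a
phased check — and any family member missing at a site removes that
(family, site) cell from both numerator and denominator.

On the X chromosome males are haploid (single call), giving three family
configurations: mother-daughter (same rule as an autosomal pair),
mother-son (the son's single X is maternal), and mother-father-daughter
(the daughter carries the father's X unchanged plus one maternal X).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .haplotype_io import MISSING, LocalAncestryCalls, PedigreeTable

logger = logging.getLogger("lanctk")

X_CONFIGS = ("mother_daughter", "mother_son", "mother_father_daughter")


# ---------------------------------------------------------------------------
# Predicates on single-locus calls
# ---------------------------------------------------------------------------


def consistent_pair(parent: tuple[int, int], child: tuple[int, int]) -> bool:
    """One observed parent: the child must carry at least one allele from it.

    True iff some element of the child's multiset appears in the parent's;
    the unobserved parent can always account for the other chromosome.
    """
    p1, p2 = parent
    c1, c2 = child
    return c1 in (p1, p2) or c2 in (p1, p2)


def consistent_trio(
    mother: tuple[int, int], father: tuple[int, int], child: tuple[int, int]
) -> bool:
    """Both parents observed: some ordering (c1, c2) of the child's calls
    has c1 from the mother and c2 from the father (multiset-aware)."""
    c1, c2 = child
    return (c1 in mother and c2 in father) or (c2 in mother and c1 in father)


def consistent_x(config: str, **calls) -> bool:
    """X-chromosome consistency for one of the three family configurations.

    mother_son: the son's single X call must be in the mother's pair.
    mother_daughter: same rule as an autosomal pair.
    mother_father_daughter: the father's single call must be in the
    daughter's pair, and the remaining daughter call (after removing one
    instance of the father's) must be in the mother's pair.

    Keyword arguments per configuration: ``mother`` (pair), and ``son``
    (single int), ``daughter`` (pair) or ``father`` (single int) +
    ``daughter`` as appropriate.
    """
    mother = calls["mother"]
    if len(mother) != 2:
        raise ValueError("mother must carry a size-2 call")
    if config == "mother_son":
        son = calls["son"]
        if isinstance(son, (tuple, list)):
            raise ValueError("son must carry a single (haploid) call")
        return son in mother
    if config == "mother_daughter":
        daughter = calls["daughter"]
        if len(daughter) != 2:
            raise ValueError("daughter must carry a size-2 call")
        return consistent_pair(mother, daughter)
    if config == "mother_father_daughter":
        father = calls["father"]
        daughter = calls["daughter"]
        if isinstance(father, (tuple, list)):
            raise ValueError("father must carry a single (haploid) call on X")
        if len(daughter) != 2:
            raise ValueError("daughter must carry a size-2 call")
        d1, d2 = daughter
        if father == d1:
            return d2 in mother
        if father == d2:
            return d1 in mother
        return False
    raise ValueError(f"unknown X configuration {config!r}; expected one of {X_CONFIGS}")


# ---------------------------------------------------------------------------
# Vectorized per-site evaluation
# ---------------------------------------------------------------------------


def _pair_consistent_vec(p1, p2, c1, c2) -> np.ndarray:
    return (c1 == p1) | (c1 == p2) | (c2 == p1) | (c2 == p2)


def _trio_consistent_vec(m1, m2, f1, f2, c1, c2) -> np.ndarray:
    c1_m = (c1 == m1) | (c1 == m2)
    c2_m = (c2 == m1) | (c2 == m2)
    c1_f = (c1 == f1) | (c1 == f2)
    c2_f = (c2 == f1) | (c2 == f2)
    return (c1_m & c2_f) | (c2_m & c1_f)


def _mfd_consistent_vec(m1, m2, f, d1, d2) -> np.ndarray:
    # father's X must match one daughter call; the other must be maternal
    via_d1 = (f == d1) & ((d2 == m1) | (d2 == m2))
    via_d2 = (f == d2) & ((d1 == m1) | (d1 == m2))
    return via_d1 | via_d2


# ---------------------------------------------------------------------------
# Genome-wide rates
# ---------------------------------------------------------------------------


@dataclass
class InconsistencyReport:
    """Pooled Mendelian-inconsistency rates per family configuration.

    ``summary`` has one row per configuration with the number of
    evaluated (family, site) cells, inconsistent cells, and their ratio;
    ``per_family`` breaks the same counts down by child id.  Rates pool
    all cells equally across families and sites.
    """

    summary: pd.DataFrame
    per_family: pd.DataFrame
    skipped_families: list[str]

    def rate(self, configuration: str) -> float:
        row = self.summary[self.summary["configuration"] == configuration]
        if row.empty:
            raise KeyError(f"no configuration {configuration!r} in report")
        return float(row["rate"].iloc[0])


def _diploid_rows(calls: LocalAncestryCalls, sample: str) -> np.ndarray | None:
    try:
        rows = calls.rows_of(sample)
    except ValueError:
        raise
    return rows if len(rows) else None


def inconsistency_rates(
    calls: LocalAncestryCalls, ped: PedigreeTable, chrom_mode: str = "autosome"
) -> InconsistencyReport:
    """Evaluate Mendelian consistency at every site for every family.

    ``chrom_mode='autosome'`` evaluates trios and pairs on diploid calls;
    ``chrom_mode='X'`` evaluates the three X configurations using haploid
    calls for males.  Families with a member absent from the call set are
    skipped with a log entry.  Cells with any missing call are excluded
    from numerator and denominator; rates are reported to 4 decimals by
    the CLI but kept at full precision here.
    """
    if chrom_mode not in ("autosome", "X"):
        raise ValueError("chrom_mode must be 'autosome' or 'X'")
    if calls.hap_meta is None:
        raise ValueError("calls need haplotype metadata")
    present = set(calls.hap_meta["sample_id"])
    per_family: list[dict] = []
    skipped: list[str] = []

    for _, fam in ped.records.iterrows():
        child, mother, father = fam["child"], fam["mother"], fam["father"]
        members = [m for m in (child, mother, father) if m]
        if any(m not in present for m in members):
            skipped.append(child)
            logger.warning("family of %s skipped: member absent from calls", child)
            continue
        crows = calls.rows_of(child)
        if chrom_mode == "autosome":
            if len(crows) != 2:
                skipped.append(child)
                continue
            c1, c2 = calls.calls[crows[0]], calls.calls[crows[1]]
            if fam["kind"] == "trio":
                mrows, frows = calls.rows_of(mother), calls.rows_of(father)
                m1, m2 = calls.calls[mrows[0]], calls.calls[mrows[1]]
                f1, f2 = calls.calls[frows[0]], calls.calls[frows[1]]
                ok = _all_observed(m1, m2, f1, f2, c1, c2)
                cons = _trio_consistent_vec(m1, m2, f1, f2, c1, c2)
                config = "trio"
            else:
                parent = mother or father
                prows = calls.rows_of(parent)
                p1, p2 = calls.calls[prows[0]], calls.calls[prows[1]]
                ok = _all_observed(p1, p2, c1, c2)
                cons = _pair_consistent_vec(p1, p2, c1, c2)
                config = "pair"
        else:
            sex = fam["sex"][:1].lower() if fam["sex"] else "?"
            if not mother:  # father-only families have no X configuration
                skipped.append(child)
                continue
            mrows = calls.rows_of(mother)
            if len(mrows) != 2:
                skipped.append(child)
                continue
            m1, m2 = calls.calls[mrows[0]], calls.calls[mrows[1]]
            if sex == "m":
                if len(crows) != 1:
                    raise ValueError(f"son {child} should carry one X haplotype")
                s = calls.calls[crows[0]]
                ok = _all_observed(m1, m2, s)
                cons = (s == m1) | (s == m2)
                config = "mother_son"
            elif sex == "f":
                if len(crows) != 2:
                    raise ValueError(f"daughter {child} should carry two X haplotypes")
                d1, d2 = calls.calls[crows[0]], calls.calls[crows[1]]
                if fam["kind"] == "trio":
                    frows = calls.rows_of(father)
                    if len(frows) != 1:
                        raise ValueError(f"father {father} should carry one X haplotype")
                    f = calls.calls[frows[0]]
                    ok = _all_observed(m1, m2, f, d1, d2)
                    cons = _mfd_consistent_vec(m1, m2, f, d1, d2)
                    config = "mother_father_daughter"
                else:
                    ok = _all_observed(m1, m2, d1, d2)
                    cons = _pair_consistent_vec(m1, m2, d1, d2)
                    config = "mother_daughter"
            else:
                raise ValueError(f"sex of {child} unknown; required for X analysis")
        n_eval = int(ok.sum())
        n_bad = int((~cons & ok).sum())
        per_family.append(
            {
                "child": child,
                "configuration": config,
                "n_evaluated": n_eval,
                "n_inconsistent": n_bad,
                "rate": n_bad / n_eval if n_eval else np.nan,
            }
        )

    per_family_df = pd.DataFrame(
        per_family,
        columns=["child", "configuration", "n_evaluated", "n_inconsistent", "rate"],
    )
    configs = (
        ["pair", "trio"] if chrom_mode == "autosome" else list(X_CONFIGS)
    )
    rows = []
    for config in configs:
        sub = per_family_df[per_family_df["configuration"] == config]
        n_eval = int(sub["n_evaluated"].sum())
        n_bad = int(sub["n_inconsistent"].sum())
        rows.append(
            {
                "configuration": config,
                "n_families": len(sub),
                "n_evaluated": n_eval,
                "n_inconsistent": n_bad,
                "rate": n_bad / n_eval if n_eval else np.nan,
            }
        )
    return InconsistencyReport(pd.DataFrame(rows), per_family_df, skipped)


def _all_observed(*arrays: np.ndarray) -> np.ndarray:
    ok = arrays[0] != MISSING
    for a in arrays[1:]:
        ok = ok & (a != MISSING)
    return ok
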