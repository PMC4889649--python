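"""Synthetic admixed genomes with known local-ancestry truth.

The generator emulates the data shapes the rest of the toolkit consumes,
without requiring any controlled-access cohort: K continental
ancestries, each optionally split into nested subpopulations, drift
modelled by the Balding-Nichols construction (population allele
frequencies Beta-distributed around an ancestral frequency with an
FST-like parameter F); admixed haplotypes built as mosaics of ancestry
tracts whose switch points follow a Poisson process of intensity g (the
number of generations since admixture) per Morgan, with tract ancestries
drawn i.i.d. from the admixture proportions pi; trios produced by
explicit meiosis (crossovers at 1 per Morgan) that transmits alleles and
ancestry labels together, so truth calls are Mendelian-consistent by
construction; and haploid-male X chromosomes with the correct
transmission (a son receives one maternal recombinant X, a daughter the
paternal X unchanged plus one maternal recombinant).

Sites are independent given the population frequencies — there is no
background linkage disequilibrium, no mutation and no selection.  All
randomness flows through a single `numpy.random.Generator`, so a fixed
seed gives identical output on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .haplotype_io import (
    DEFAULT_ANCESTRY_LABELS,
    HaplotypePanel,
    LocalAncestryCalls,
    MISSING,
    PedigreeTable,
    SiteMap,
    make_hap_meta,
)


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic admixed cohort.

    Defaults describe a three-way admixed population resembling a
    Hispanic/Latino cohort: African/Amerindian/European ancestry with
    mean proportions (0.14, 0.31, 0.55), admixture g = 8 generations
    ago, continental differentiation F = 0.15 and within-continent
    subpopulation differentiation F = 0.05.
    """

    labels: tuple[str, ...] = DEFAULT_ANCESTRY_LABELS
    f_cont: float = 0.15
    #: per-continent (number of subpopulations, F_sub); length K
    subpops: tuple[tuple[int, float], ...] = ((1, 0.05), (1, 0.05), (1, 0.05))
    pi: tuple[float, ...] = (0.14, 0.31, 0.55)
    g: float = 8.0
    n_sites: int = 2000
    map_length_morgans: float = 1.0
    chrom: str = "1"
    n_ref: int = 30  #: diploid reference individuals per subpopulation
    n_admixed: int = 100
    n_trios: int = 20
    seed: int = 0
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        if abs(sum(self.pi) - 1.0) > 1e-9:
            raise ValueError("pi must sum to 1")
        if len(self.pi) != self.k or len(self.subpops) != self.k:
            raise ValueError("pi and subpops must have length K")
        if not 0 < self.f_cont < 1:
            raise ValueError("F_cont must be in (0, 1)")
        for _, f in self.subpops:
            if not 0 < f < 1:
                raise ValueError("F_sub must be in (0, 1)")
        if self.g <= 0:
            raise ValueError("g must be positive")
        if not 0 <= self.error_rate <= 1:
            raise ValueError("error_rate must be in [0, 1]")

    @property
    def k(self) -> int:
        return len(self.labels)

    def site_map(self) -> SiteMap:
        m = self.n_sites
        return SiteMap(
            pd.DataFrame(
                {
                    "chrom": [self.chrom] * m,
                    "pos_bp": (np.arange(m) + 1) * 1000,
                    "site_id": [f"{self.chrom}:{(i + 1) * 1000}" for i in range(m)],
                    "pos_cm": np.linspace(0.0, self.map_length_morgans * 100.0, m),
                }
            )
        )

    def positions_morgans(self) -> np.ndarray:
        return np.linspace(0.0, self.map_length_morgans, self.n_sites)


@dataclass
class AlleleFrequencies:
    """Ancestral, continental and subpopulation allele frequencies per site."""

    ancestral: np.ndarray  # (M,)
    continent: np.ndarray  # (K, M)
    subpop: list[np.ndarray] = field(default_factory=list)  # per continent, (S_k, M)


def _balding_nichols(p: np.ndarray, f: float, rng: np.random.Generator) -> np.ndarray:
    """Draw descendant frequencies Beta(p(1-F)/F, (1-p)(1-F)/F) around p."""
    c = (1.0 - f) / f
    return rng.beta(np.clip(p, 1e-6, 1 - 1e-6) * c, (1.0 - np.clip(p, 1e-6, 1 - 1e-6)) * c)


def draw_allele_frequencies(
    config: SimulationConfig, rng: np.random.Generator
) -> AlleleFrequencies:
    """Balding-Nichols frequencies: ancestral -> continents -> subpopulations."""
    m = config.n_sites
    ancestral = rng.uniform(0.05, 0.95, size=m)
    continent = np.vstack(
        [_balding_nichols(ancestral, config.f_cont, rng) for _ in range(config.k)]
    )
    subpop = []
    for k, (n_sub, f_sub) in enumerate(config.subpops):
        subpop.append(
            np.vstack(
                [_balding_nichols(continent[k], f_sub, rng) for _ in range(n_sub)]
            )
        )
    return AlleleFrequencies(ancestral, continent, subpop)


# ---------------------------------------------------------------------------
# Haplotype construction
# ---------------------------------------------------------------------------


def _tract_ancestry(
    config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Per-site ancestry codes (1..K) from the Poisson tract-switch process."""
    pos = config.positions_morgans()
    length = config.map_length_morgans
    n_switch = rng.poisson(config.g * length)
    switches = np.sort(rng.uniform(0.0, length, size=n_switch))
    tract_idx = np.searchsorted(switches, pos, side="right")
    tract_anc = rng.choice(config.k, size=n_switch + 1, p=np.asarray(config.pi)) + 1
    return tract_anc[tract_idx].astype(np.int16)


def simulate_admixed_haplotype(
    config: SimulationConfig,
    freqs: AlleleFrequencies,
    rng: np.random.Generator,
    subpop_of: tuple[int, ...] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One admixed haplotype: (alleles, true per-site ancestry codes).

    ``subpop_of`` gives, per continent, the subpopulation index the
    individual's ancestors of that continent came from (default 0);
    alleles on a tract of continent k are Bernoulli draws from that
    subpopulation's frequencies.
    """
    if subpop_of is None:
        subpop_of = (0,) * config.k
    anc = _tract_ancestry(config, rng)
    p = np.empty(config.n_sites)
    for k in range(config.k):
        sel = anc == k + 1
        if sel.any():
            p[sel] = freqs.subpop[k][subpop_of[k]][sel]
    alleles = (rng.random(config.n_sites) < p).astype(np.int8)
    return alleles, anc


def _meiosis(
    alleles: np.ndarray,  # (2, M) parental haplotypes
    ancestry: np.ndarray,  # (2, M) parental truth
    pos_morgans: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One gamete: crossovers Poisson(1/Morgan), copying alleles and ancestry."""
    length = pos_morgans[-1] - pos_morgans[0] if len(pos_morgans) > 1 else 0.0
    n_cross = rng.poisson(length)
    cross = np.sort(rng.uniform(pos_morgans[0], pos_morgans[0] + length, size=n_cross))
    seg = np.searchsorted(cross, pos_morgans, side="right")
    start = rng.integers(0, 2)
    active = (start + seg) % 2
    idx = np.arange(len(pos_morgans))
    return alleles[active, idx].copy(), ancestry[active, idx].copy()


# ---------------------------------------------------------------------------
# Cohort-level generators
# ---------------------------------------------------------------------------


def simulate_reference_panel(
    config: SimulationConfig,
    freqs: AlleleFrequencies,
    rng: np.random.Generator,
    n_per_subpop: int | None = None,
) -> tuple[HaplotypePanel, LocalAncestryCalls]:
    """Unadmixed diploid reference individuals, grouped by (continent, subpop).

    Each individual's two haplotypes are single-tract draws from one
    subpopulation's frequencies; the companion truth calls are constant
    per haplotype.  Group labels are '<ancestry>/<subpop index>'.
    """
    n = config.n_ref if n_per_subpop is None else n_per_subpop
    rows, anc_rows, meta = [], [], {"sample_id": [], "copy": [], "sex": [], "group": []}
    for k in range(config.k):
        n_sub = config.subpops[k][0]
        for s in range(n_sub):
            p = freqs.subpop[k][s]
            for i in range(n):
                sid = f"ref_{config.labels[k]}_{s}_{i:03d}"
                for copy in (1, 2):
                    rows.append((rng.random(config.n_sites) < p).astype(np.int8))
                    anc_rows.append(np.full(config.n_sites, k + 1, dtype=np.int16))
                    meta["sample_id"].append(sid)
                    meta["copy"].append(copy)
                    meta["sex"].append("unknown")
                    meta["group"].append(f"{config.labels[k]}/{s}")
    hap_meta = pd.DataFrame(meta)
    sites = config.site_map()
    panel = HaplotypePanel(np.vstack(rows), hap_meta, sites)
    calls = LocalAncestryCalls(np.vstack(anc_rows), config.labels, hap_meta.copy(), sites)
    return panel, calls


def simulate_admixed_cohort(
    config: SimulationConfig,
    freqs: AlleleFrequencies,
    rng: np.random.Generator,
    n: int | None = None,
    prefix: str = "adm",
) -> tuple[HaplotypePanel, LocalAncestryCalls, pd.DataFrame]:
    """Admixed diploids with true tract-level ancestry.

    Each individual draws, per continent, a subpopulation of origin
    (uniform over that continent's subpopulations; shared by both
    haplotypes), so within-continent structure is recoverable from the
    target-ancestry segments.  Returns (panel, truth calls, per-sample
    subpopulation assignment frame).
    """
    n = config.n_admixed if n is None else n
    rows, anc_rows = [], []
    meta = {"sample_id": [], "copy": [], "sex": [], "group": []}
    assign_rows = []
    for i in range(n):
        sid = f"{prefix}_{i:04d}"
        subpop_of = tuple(
            int(rng.integers(0, config.subpops[k][0])) for k in range(config.k)
        )
        assign_rows.append(
            {"sample_id": sid, **{
                f"subpop_{lab}": subpop_of[k] for k, lab in enumerate(config.labels)
            }}
        )
        sex = "female" if rng.integers(0, 2) else "male"
        for copy in (1, 2):
            a, t = simulate_admixed_haplotype(config, freqs, rng, subpop_of)
            rows.append(a)
            anc_rows.append(t)
            meta["sample_id"].append(sid)
            meta["copy"].append(copy)
            meta["sex"].append(sex)
            meta["group"].append("admixed")
    hap_meta = pd.DataFrame(meta)
    sites = config.site_map()
    panel = HaplotypePanel(np.vstack(rows), hap_meta, sites)
    calls = LocalAncestryCalls(np.vstack(anc_rows), config.labels, hap_meta.copy(), sites)
    return panel, calls, pd.DataFrame(assign_rows)


def simulate_trios(
    config: SimulationConfig,
    freqs: AlleleFrequencies,
    rng: np.random.Generator,
    n_trios: int | None = None,
) -> tuple[HaplotypePanel, LocalAncestryCalls, PedigreeTable]:
    """Mother-father-child trios with truth transmitted through meiosis.

    Children's haplotypes copy alleles and ancestry labels jointly from
    the active parental haplotype between crossovers, so the truth calls
    of every trio are Mendelian-consistent at every site by construction.
    """
    n_trios = config.n_trios if n_trios is None else n_trios
    pos = config.positions_morgans()
    rows, anc_rows = [], []
    meta = {"sample_id": [], "copy": [], "sex": [], "group": []}
    ped_rows = []

    def add_sample(sid, haps, ancs, sex):
        for copy, (a, t) in enumerate(zip(haps, ancs), start=1):
            rows.append(a)
            anc_rows.append(t)
            meta["sample_id"].append(sid)
            meta["copy"].append(copy)
            meta["sex"].append(sex)
            meta["group"].append("trio")

    for i in range(n_trios):
        parents = {}
        for role, sex in (("mo", "female"), ("fa", "male")):
            h, t = zip(*(simulate_admixed_haplotype(config, freqs, rng) for _ in range(2)))
            parents[role] = (np.vstack(h), np.vstack(t))
            add_sample(f"{role}_{i:03d}", h, t, sex)
        child_sex = "female" if rng.integers(0, 2) else "male"
        gm = _meiosis(*parents["mo"], pos, rng)
        gf = _meiosis(*parents["fa"], pos, rng)
        add_sample(f"ch_{i:03d}", (gm[0], gf[0]), (gm[1], gf[1]), child_sex)
        ped_rows.append(
            {
                "child": f"ch_{i:03d}",
                "mother": f"mo_{i:03d}",
                "father": f"fa_{i:03d}",
                "sex": child_sex,
                "kind": "trio",
            }
        )
    hap_meta = pd.DataFrame(meta)
    sites = config.site_map()
    panel = HaplotypePanel(np.vstack(rows), hap_meta, sites)
    calls = LocalAncestryCalls(np.vstack(anc_rows), config.labels, hap_meta.copy(), sites)
    ped = PedigreeTable(pd.DataFrame(ped_rows))
    return panel, calls, ped


def simulate_x_families(
    config: SimulationConfig,
    freqs: AlleleFrequencies,
    rng: np.random.Generator,
    n_families: int | None = None,
) -> tuple[HaplotypePanel, LocalAncestryCalls, PedigreeTable]:
    """X-chromosome families: diploid mothers, haploid fathers, one child each.

    A son receives a single maternal recombinant X; a daughter receives
    the paternal X unchanged plus a maternal recombinant.  The pedigree
    alternates sons and daughters so all three X configurations
    (mother-daughter, mother-son, mother-father-daughter) are exercised.
    """
    n_families = config.n_trios if n_families is None else n_families
    pos = config.positions_morgans()
    rows, anc_rows = [], []
    meta = {"sample_id": [], "copy": [], "sex": [], "group": []}
    ped_rows = []

    def add(sid, haps, ancs, sex):
        for copy, (a, t) in enumerate(zip(haps, ancs), start=1):
            rows.append(a)
            anc_rows.append(t)
            meta["sample_id"].append(sid)
            meta["copy"].append(copy)
            meta["sex"].append(sex)
            meta["group"].append("xfam")

    for i in range(n_families):
        mh, mt = zip(*(simulate_admixed_haplotype(config, freqs, rng) for _ in range(2)))
        mother = (np.vstack(mh), np.vstack(mt))
        add(f"xmo_{i:03d}", mh, mt, "female")
        fh, ft = simulate_admixed_haplotype(config, freqs, rng)
        add(f"xfa_{i:03d}", (fh,), (ft,), "male")
        gm = _meiosis(*mother, pos, rng)
        # cycle the three configurations: full trio daughter, son (pair),
        # daughter with the father left out of the pedigree (pair)
        kind_cycle = i % 3
        child_sex = "male" if kind_cycle == 1 else "female"
        if child_sex == "female":
            add(f"xch_{i:03d}", (gm[0], fh), (gm[1], ft), "female")
        else:
            add(f"xch_{i:03d}", (gm[0],), (gm[1],), "male")
        with_father = kind_cycle == 0
        ped_rows.append(
            {
                "child": f"xch_{i:03d}",
                "mother": f"xmo_{i:03d}",
                "father": f"xfa_{i:03d}" if with_father else "",
                "sex": child_sex,
                "kind": "trio" if with_father else "pair",
            }
        )
    hap_meta = pd.DataFrame(meta)
    sites = config.site_map()
    panel = HaplotypePanel(np.vstack(rows), hap_meta, sites)
    calls = LocalAncestryCalls(np.vstack(anc_rows), config.labels, hap_meta.copy(), sites)
    return panel, calls, PedigreeTable(pd.DataFrame(ped_rows))


def corrupt_calls(
    calls: LocalAncestryCalls, epsilon: float, rng: np.random.Generator
) -> LocalAncestryCalls:
    """Flip each non-missing call to a uniformly random *different* ancestry
    with probability epsilon, emulating caller error."""
    if not 0 <= epsilon <= 1:
        raise ValueError("epsilon must be in [0, 1]")
    k = calls.n_ancestries
    out = calls.calls.copy()
    flip = (rng.random(out.shape) < epsilon) & (out != MISSING)
    # offset 1..K-1 from the current code, wrapping inside 1..K
    offsets = rng.integers(1, k, size=int(flip.sum()))
    out[flip] = ((out[flip] - 1 + offsets) % k + 1).astype(np.int16)
    return LocalAncestryCalls(
        out,
        calls.ancestry_labels,
        None if calls.hap_meta is None else calls.hap_meta.copy(),
        calls.sites,
    )
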