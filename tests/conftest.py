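import itertools

import numpy as np
import pandas as pd
import pytest

from lanctk import HaplotypePanel, LocalAncestryCalls, SiteMap, make_hap_meta

K = 3  # African, Amerindian, European


def make_sites(m, chrom="1", start=1000, step=1000):
    pos = start + step * np.arange(m)
    return SiteMap(
        pd.DataFrame(
            {
                "chrom": [chrom] * m,
                "pos_bp": pos,
                "site_id": [f"{chrom}:{p}" for p in pos],
            }
        )
    )


def make_multi_chrom_sites(counts):
    frames = []
    for i, n in enumerate(counts, start=1):
        pos = 1000 * (1 + np.arange(n))
        frames.append(
            pd.DataFrame(
                {"chrom": [str(i)] * n, "pos_bp": pos,
                 "site_id": [f"{i}:{p}" for p in pos]}
            )
        )
    return SiteMap(pd.concat(frames, ignore_index=True))


def make_panel(alleles, sample_ids=None, copies=None, sexes=None, sites=None):
    alleles = np.asarray(alleles, dtype=np.int8)
    h, m = alleles.shape
    if sample_ids is None:
        sample_ids = [f"S{i // 2}" for i in range(h)]
        copies = [i % 2 + 1 for i in range(h)]
    meta = make_hap_meta(sample_ids, copies, sexes)
    return HaplotypePanel(alleles, meta, sites or make_sites(m))


def make_calls(calls, sample_ids=None, copies=None, sites=None):
    calls = np.asarray(calls, dtype=np.int16)
    h, m = calls.shape
    if sample_ids is None:
        sample_ids = [f"S{i // 2}" for i in range(h)]
        copies = [i % 2 + 1 for i in range(h)]
    meta = make_hap_meta(sample_ids, copies)
    return LocalAncestryCalls(calls, hap_meta=meta, sites=sites or make_sites(m))


def unordered_pairs(k=K):
    """All unordered diploid ancestry calls over codes 1..k."""
    return list(itertools.combinations_with_replacement(range(1, k + 1), 2))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
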