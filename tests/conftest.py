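"""Shared fixtures: a small synthetic cohort exercised by most suites.

Everything is generated at test time from fixed seeds; nothing is read
from disk except files the tests themselves write.
"""

from __future__ import annotations

import pandas as pd
import pytest

from mutbench.curation import curate, score_evidence
from mutbench.simulate import (
    CohortConfig,
    curation_caller_profiles,
    simulate_counts,
    simulate_submission,
    simulate_truth,
)
from mutbench.variants import normalize_callset


SMALL_CONFIG = CohortConfig(
    contig_lengths={"1": 400_000, "2": 300_000},
    contig_copy_number={"1": 4, "2": 2},
)


@pytest.fixture(scope="session")
def small_cohort():
    """~0.7-Mb cohort: genome, truth, deep submissions, scored evidence."""
    sg, truth = simulate_truth(SMALL_CONFIG, seed=11)
    profiles = curation_caller_profiles(6, seed=11)
    subs = [simulate_submission(sg, truth, p) for p in profiles]
    extra = pd.concat(
        [s.to_dataframe()[["chrom", "pos", "ref", "alt"]] for s in subs],
        ignore_index=True,
    ).drop_duplicates()
    evidence = simulate_counts(sg, truth, extra_sites=extra, seed=12)
    evidence = score_evidence(evidence)
    normalized = [normalize_callset(s, sg.genome) for s in subs]
    for raw, norm in zip(subs, normalized):
        norm.ledger = raw.ledger  # keep generator bookkeeping
    return {
        "config": SMALL_CONFIG,
        "sg": sg,
        "truth": truth,
        "profiles": profiles,
        "subs": normalized,
        "evidence": evidence,
    }


@pytest.fixture(scope="session")
def small_gold(small_cohort):
    """Gold sets curated from the small cohort with default thresholds."""
    return curate(small_cohort["subs"], small_cohort["evidence"])
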