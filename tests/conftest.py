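"""Shared fixtures: small deterministic datasets with planted structure."""

from __future__ import annotations

import pandas as pd
import pytest

from congenerics import SimulationConfig

STRAINS = ["Dsv", "Dcm", "Dnl", "Dnm", "Dbt", "Dta"]
CONDITIONS = [f"cond_{i:02d}" for i in range(1, 9)]
REPLICATES = [1, 2, 3]


def _regression_design() -> dict[str, list[tuple[str, bool, list[str], int]]]:
    """Per strain: (protein_id, core_encoded, detected conditions, count).

    Planted 2x2 category design per strain: 10 core+constitutive proteins
    at count 20, 5 core+nonconstitutive at count 10 (first 4 conditions),
    15 noncore+constitutive at count 5, 20 noncore+nonconstitutive at
    count 2 (last 4 conditions).
    """
    design = {}
    for strain in STRAINS:
        rows = []
        for i in range(10):
            rows.append((f"{strain}_cc{i:02d}", True, CONDITIONS, 20))
        for i in range(5):
            rows.append((f"{strain}_cn{i:02d}", True, CONDITIONS[:4], 10))
        for i in range(15):
            rows.append((f"{strain}_nc{i:02d}", False, CONDITIONS, 5))
        for i in range(20):
            rows.append((f"{strain}_nn{i:02d}", False, CONDITIONS[4:], 2))
        design[strain] = rows
    return design


@pytest.fixture(scope="session")
def regression_design():
    return _regression_design()


@pytest.fixture(scope="session")
def regression_counts(regression_design) -> pd.DataFrame:
    """6-strain x 8-condition x 3-replicate peptide-count table.

    Every detected protein appears in all 3 replicates with its design
    count in the soluble fraction and half that (min 1) in the membrane
    fraction, so fraction merging keeps the soluble count.  One extra
    'ghost' protein per strain appears in a single replicate only and must
    be removed by the replicate filter.
    """
    rows = []
    for strain, prots in regression_design.items():
        for pid, _core, conds, count in prots:
            for cond in conds:
                for rep in REPLICATES:
                    rows.append((strain, cond, rep, "soluble", pid, count))
                    rows.append((strain, cond, rep, "membrane", pid,
                                 max(1, count // 2)))
        rows.append((strain, CONDITIONS[0], 1, "soluble",
                     f"{strain}_ghost", 7))
    return pd.DataFrame(rows, columns=["strain", "condition", "replicate",
                                       "fraction", "protein_id",
                                       "peptide_count"])


@pytest.fixture(scope="session")
def regression_core(regression_design) -> dict[str, set[str]]:
    return {strain: {pid for pid, core, _, _ in prots if core}
            for strain, prots in regression_design.items()}


@pytest.fixture
def default_cfg() -> SimulationConfig:
    return SimulationConfig(seed=7)
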