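"""Shared fixtures: simulated crosses at two scales.

Session-scoped so the study-scale family (170 offspring x 42 LGs) is
simulated once and reused by every summary/recovery test.
"""

import numpy as np
import pandas as pd
import pytest

from charrcross import crossovers as cxo
from charrcross.io import GeneticMap, PhasedGenotypes
from charrcross.simulate import (LGSpec, QTLEffect, SimConfig,
                                 default_config, simulate_cross)


def small_config(seed: int = 5, **overrides) -> SimConfig:
    """Six-LG miniature family for fast unit tests."""
    lgs = [LGSpec("SM01", "fused_metacentric", 88.0, 47.6, tetraploid=True)]
    lgs += [LGSpec(f"SM{i:02d}", "acrocentric", 42.0, 22.7)
            for i in range(2, 6)]
    lgs.append(LGSpec("SM06", "acrocentric", 42.0, 42.0, sex_linked=True))
    cfg = SimConfig(
        n_offspring=80, lg_spec=lgs, n_markers_per_lg=40,
        traits=["trait_a"], residual_sd={"trait_a": 1.0},
        qtl_effects=[QTLEffect(marker="SM02_m020", effect=0.5,
                               trait="trait_a")],
        seed=seed,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


@pytest.fixture(scope="session")
def study_sim():
    """Full study-condition synthetic family."""
    return simulate_cross(default_config(seed=11))


@pytest.fixture(scope="session")
def study_events(study_sim):
    gmap, geno, _, _ = study_sim
    raw = cxo.detect_crossovers(geno, gmap, informative_both_only=True)
    corrected = cxo.apply_correction(raw)
    return raw, corrected


@pytest.fixture(scope="session")
def small_sim():
    return simulate_cross(small_config())


@pytest.fixture(scope="session")
def clean_sim():
    """Small family with no genotyping errors or missing data."""
    cfg = small_config(seed=6, error_rate=0.0, missing_rate=0.0,
                       tetraploid_depletion=0.0)
    return simulate_cross(cfg)


def labels_to_genotypes(label_matrix: np.ndarray) -> tuple[PhasedGenotypes,
                                                           GeneticMap]:
    """Build a dam-informative genotype set from raw 0/1/-1 label rows.

    Markers are nnxnp at 1 cM spacing, so the dam label sequence of each
    'offspring' row is exactly the input row — handy for driving the
    detector with constructed label sequences.
    """
    n, m = label_matrix.shape
    markers = [f"T_m{j:03d}" for j in range(m)]
    table = pd.DataFrame({
        "marker": markers, "lg": "T", "pos_cM": np.arange(m, dtype=float),
        "seg_type": "nnxnp", "lg_class": "acrocentric",
        "tetraploid": False, "sex_linked": False, "centromere_end": "start",
    })
    gmap = GeneticMap.from_table(table)
    code = np.array(["nn", "np"], dtype=object)
    vals = np.where(label_matrix < 0, "-", code[np.clip(label_matrix, 0, 1)])
    codes = pd.DataFrame(vals, columns=markers,
                         index=[f"row{i}" for i in range(n)])
    return PhasedGenotypes.from_codes(codes, gmap), gmap


def oracle_min_switches(labels) -> int:
    """Dynamic-programming minimal phase-switch count (independent oracle).

    Assign each position a haplotype state consistent with its label
    (unknowns free) and minimize the number of state changes.
    """
    inf = 10 ** 9
    dp0 = dp1 = 0
    for x in labels:
        if x == 0:
            dp0, dp1 = min(dp0, dp1 + 1), inf
        elif x == 1:
            dp0, dp1 = inf, min(dp1, dp0 + 1)
        else:
            dp0, dp1 = min(dp0, dp1 + 1), min(dp1, dp0 + 1)
    return min(dp0, dp1)


def make_events(midpoints, offspring="o1", parent="dam", lg="L1",
                lg_len=200.0) -> pd.DataFrame:
    """Minimal raw event table from a list of midpoints."""
    rows = []
    for m in midpoints:
        rows.append({
            "offspring": offspring, "parent": parent, "lg": lg,
            "left_marker": "x", "left_pos": m - 1.0, "right_marker": "y",
            "right_pos": m + 1.0, "midpoint": float(m),
            "percent_pos": 100.0 * m / lg_len, "cluster": -1,
            "status": "retained",
        })
    return pd.DataFrame(rows, columns=cxo.EVENT_COLUMNS)
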