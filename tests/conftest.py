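import numpy as np
import pandas as pd
import pytest

import ctscreen as cs


@pytest.fixture(scope="session")
def default_dataset():
    """Default planted-truth scenario, fixed seed."""
    cfg = cs.SimulationConfig(seed=42)
    return cs.generate_dataset(cfg)


@pytest.fixture(scope="session")
def default_screen(default_dataset):
    """Full screen on the default scenario, thresholds pinned to the
    generator's stated tier boundaries."""
    ds = default_dataset
    return cs.run_screen(
        ds.matrix, ds.samples, ds.probesets,
        thresholds=ds.config.intended_thresholds(),
    )


@pytest.fixture(scope="session")
def default_recovery(default_dataset, default_screen):
    return cs.evaluate_recovery(
        default_dataset.truth, default_screen.tissue_records, default_screen.calls
    )


def tiny_annotation(n_target=1, n_normal=3, n_cancer=1, samples_per_group=2, rng=None):
    """Small random-but-valid sample annotation."""
    rng = rng or np.random.default_rng(0)
    groups, rows = [], []
    normals = [f"n{i}" for i in range(n_normal)]
    for g in normals:
        groups.append((g, "NORMAL", "", ""))
    for i in range(n_target):
        groups.append((f"t{i}", "TARGET", "", ""))
    for i in range(n_cancer):
        groups.append((f"c{i}", "CANCER", normals[int(rng.integers(n_normal))], ""))
    gdf = pd.DataFrame(groups, columns=["group_id", "category", "matched_normal", "label"])
    for g in gdf["group_id"]:
        for j in range(samples_per_group):
            rows.append((f"{g}_s{j}", g))
    sdf = pd.DataFrame(rows, columns=["sample_id", "group_id"]).set_index("sample_id")
    return cs.SampleAnnotation(samples=sdf, groups=gdf.set_index("group_id"))


def dummy_contrast(q: pd.Series) -> cs.ContrastResult:
    """ContrastResult carrying only q-values, for classifier unit tests."""
    table = pd.DataFrame({"q": q})
    table.index.name = "probeset_id"
    return cs.ContrastResult(
        table=table, prior=cs.PriorEstimate(d0=1.0, s0_sq=1.0),
        df_residual=1.0, df_total=2.0,
    )
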