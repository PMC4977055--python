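import numpy as np
import pandas as pd
import pytest

from refewas.containers import BetaMatrix
from refewas.simulate import SimConfig, null_config, simulate_beta_matrix

NO_MISSING = {"placenta_as": 0.0, "toenail_as": 0.0, "urine_as": 0.0}
NO_BATCH = dict(batch_shift_loc=(0.0, 0.0, 0.0, 0.0), batch_shift_scale=(1.0, 1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort with all effect types present."""
    cfg = SimConfig(
        n_samples=100,
        n_loci=800,
        n_marker_loci=100,
        n_direct_loci=20,
        seed=42,
        missing_frac=NO_MISSING,
    )
    bm, truth = simulate_beta_matrix(cfg)
    return cfg, bm, truth


@pytest.fixture()
def tiny_beta_matrix():
    """A hand-built 6-probe matrix exercising each filtering rule."""
    probes = pd.Index(
        ["p_xy", "p_xr", "p_snp", "p_det", "p_ok1", "p_ok2"], name="probe_id"
    )
    samples = pd.Index(["s1", "s2", "s3"], name="sample_id")
    rng = np.random.default_rng(0)
    beta = pd.DataFrame(rng.uniform(0.2, 0.8, (6, 3)), index=probes, columns=samples)
    annotation = pd.DataFrame(
        {
            "chrom": ["X", "3", "5", "7", "11", "13"],
            "pos": np.arange(1000, 7000, 1000),
            "gene": [f"G{i}" for i in range(6)],
            "gene_region": ["TSS200", "Body", "Body", "3'UTR", "TSS1500", "Body"],
            "island_relation": ["Island", "Shore", "Shelf", "OpenSea", "Island", "Shore"],
            "snp_flag": [False, False, True, False, False, False],
            "crossreactive_flag": [False, True, False, False, False, False],
        },
        index=probes,
    )
    detection = pd.DataFrame(0.001, index=probes, columns=samples)
    detection.loc["p_det", "s2"] = 0.02
    sheet = pd.DataFrame({"plate": ["a", "a", "b"]}, index=samples)
    return BetaMatrix(beta, annotation, sheet, detection)
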