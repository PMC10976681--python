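import numpy as np
import pandas as pd
import pytest

from pbmckit import simulate as sim


@pytest.fixture(scope="session")
def small_cohort():
    """3 balanced cell types, 6+6 samples, planted DE — shared across tests."""
    cfg = sim.SimConfig(
        n_case=6, n_control=6, cell_types=["A", "B", "C"],
        abundance=[1 / 3] * 3, cells_per_sample=150, genes=900,
        n_feature_genes_per_type=30,
        de_spec=sim.default_de_spec(["A", "B", "C"], 30, 20, 1.0),
        seed=42,
    )
    return sim.generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """No planted DE, no composition shift: case/control exchangeable."""
    cfg = sim.SimConfig(
        n_case=5, n_control=5, cell_types=["A", "B"], abundance=[0.5, 0.5],
        cells_per_sample=120, genes=600, n_feature_genes_per_type=20, seed=7,
    )
    return sim.generate_cohort(cfg)


@pytest.fixture(scope="session")
def sub_cohort():
    """3 compartments x 2 subtypes, balanced — for hierarchy annotation."""
    types = ["T_a", "T_b", "B_a", "B_b", "M_a", "M_b"]
    comp = {"T_a": "T", "T_b": "T", "B_a": "B", "B_b": "B",
            "M_a": "M", "M_b": "M"}
    cfg = sim.SimConfig(
        n_case=4, n_control=4, cell_types=types, compartment_of=comp,
        abundance=sim.balanced_abundance(types, comp),
        cells_per_sample=250, genes=900, n_feature_genes_per_type=40, seed=3,
    )
    return sim.generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_pseudobulk_frame(counts, n_case, n_control, cell_type="t"):
    """Wrap a raw samples x genes array as a Pseudobulk for direct DE tests."""
    from pbmckit.de import Pseudobulk

    counts = np.asarray(counts)
    n = counts.shape[0]
    assert n == n_case + n_control
    idx = pd.Index([f"S{i}" for i in range(n)], name="sample")
    cond = pd.Series([1] * n_case + [0] * n_control, index=idx)
    return Pseudobulk(
        cell_type=cell_type,
        counts=pd.DataFrame(
            counts, index=idx,
            columns=[f"g{j}" for j in range(counts.shape[1])],
        ),
        cell_counts=pd.Series(10, index=idx),
        condition=cond,
    )
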