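import numpy as np
import pandas as pd
import pytest

from woodnet.containers import CountExperiment, SectionSeries
from woodnet.simulate import default_config, default_count_config, generate_count_experiment, generate_section_series


@pytest.fixture(scope="session")
def section_series():
    """Default planted section series (seed 1) with ground truth."""
    return generate_section_series(default_config(seed=1))


@pytest.fixture(scope="session")
def count_experiment():
    """Default planted count experiment (seed 1) with ground truth."""
    return generate_count_experiment(default_count_config(seed=1))


@pytest.fixture()
def tiny_series():
    """Hand-built 4-gene × 2-tree series for filter/scaling toys."""
    sections = [f"T{t}.{p}" for t in (1, 2) for p in (1, 2, 3)]
    meta = pd.DataFrame(
        {
            "tree": ["T1"] * 3 + ["T2"] * 3,
            "zone": ["P/C", "Ex", "SCW"] * 2,
            "position": [1, 2, 3] * 2,
        },
        index=pd.Index(sections, name="section"),
    )
    values = pd.DataFrame(
        [
            [5.0, 4.0, 3.5, 5.0, 4.5, 0.0],  # expressed in both trees
            [9.0, 9.0, 9.0, 0.0, 0.0, 0.0],  # one tree only
            [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],  # silent
            [1.0, 2.0, 3.0, 1.0, 2.0, 3.0],  # weakly expressed
        ],
        index=pd.Index(["A", "B", "C", "D"], name="gene"),
        columns=sections,
    )
    return SectionSeries(values, meta)


def make_count_experiment(counts: np.ndarray, n_reps: int = 1) -> CountExperiment:
    """Wrap a gene × library array in a minimal factorial design."""
    genotypes = ("WT", "etr1_LMX5", "etr1_35S")
    treatments = ("mock", "ACC")
    libs = [
        f"{g}.{t}.r{r}"
        for g in genotypes
        for t in treatments
        for r in range(1, n_reps + 1)
    ]
    assert counts.shape[1] == len(libs)
    meta = pd.DataFrame(
        {
            "genotype": [l.split(".")[0] for l in libs],
            "treatment": [l.split(".")[1] for l in libs],
            "replicate": [int(l.split(".r")[1]) for l in libs],
        },
        index=pd.Index(libs, name="library"),
    )
    genes = pd.Index([f"g{i + 1}" for i in range(counts.shape[0])], name="gene")
    return CountExperiment(pd.DataFrame(counts.astype(np.int64), index=genes, columns=libs), meta)
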