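import numpy as np
import pandas as pd
import pytest

from methlineage import synthetic
from methlineage.matrix import MethylationMatrix
from methlineage.synthetic import CohortDesign, GroupSpec


@pytest.fixture(scope="session")
def small_manifest() -> pd.DataFrame:
    return synthetic.generate_manifest(400, seed=42)


@pytest.fixture(scope="session")
def two_group_cohort(small_manifest):
    """Small two-group cohort with planted lineage signal."""
    design = CohortDesign(
        groups=[GroupSpec("A", "epithelial", "none", 5), GroupSpec("B", "neural", "none", 5)],
        n_probes=400,
        n_lineage_cpgs=40,
        n_program_cpgs=0,
        effect_delta_beta=0.35,
        seed=7,
    )
    return synthetic.generate_cohort(design, small_manifest)


@pytest.fixture()
def tiny_beta_matrix() -> MethylationMatrix:
    rng = np.random.default_rng(0)
    vals = pd.DataFrame(
        rng.uniform(0.05, 0.95, size=(30, 6)),
        index=[f"cg{i:03d}" for i in range(30)],
        columns=[f"s{j}" for j in range(6)],
    )
    return MethylationMatrix(vals, "beta", {f"s{j}": ("G1" if j < 3 else "G2") for j in range(6)})
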