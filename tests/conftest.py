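import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cecofec.core_tables import OtuTable, SampleMetadata, build_paired_design
from cecofec.synthetic import SyntheticParams, generate_dataset

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """A small synthetic paired dataset shared across tests (8 animals, 40 OTUs)."""
    params = SyntheticParams(n_animals=8, n_otus=40, frac_differential=0.25,
                             origin_effect_size=0.8, seed=5)
    table, meta, taxonomy, tree, truth = generate_dataset(params)
    return {
        "params": params, "table": table, "meta": meta,
        "taxonomy": taxonomy, "tree": tree, "truth": truth,
        "design": build_paired_design(meta, table),
    }


@pytest.fixture()
def tiny_table():
    """3 OTUs x 2 samples with hand-checkable counts."""
    return OtuTable(np.array([[1, 0, 4], [2, 5, 0]]), ("s1", "s2"), ("o1", "o2", "o3"))


def make_design(n, regime="restricted"):
    """A complete paired design over n animals with uniform regime."""
    pairs = tuple((f"A{i}", f"A{i}_C", f"A{i}_F") for i in range(n))
    from cecofec.core_tables import PairedDesign

    return PairedDesign(pairs, {f"A{i}": regime for i in range(n)})


def paired_values(cecum, feces):
    """Map sample ids of make_design(n) onto paired value vectors."""
    vals = {}
    for i, (c, f) in enumerate(zip(cecum, feces)):
        vals[f"A{i}_C"] = float(c)
        vals[f"A{i}_F"] = float(f)
    return vals
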