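import numpy as np
import pandas as pd
import pytest

from editnet import (
    ExpressionSimSpec,
    VariantTable,
    default_region,
    enumerate_variants,
    gen_expression_study,
)


@pytest.fixture(scope="session")
def region():
    return default_region()


@pytest.fixture(scope="session")
def variant_labels(region):
    return enumerate_variants(region)


def make_variant_table(freqs_by_sample: dict[str, dict[str, float]], labels, total=1000):
    """Build a VariantTable from per-sample frequency dicts."""
    rows = {}
    for sample, freqs in freqs_by_sample.items():
        rows[sample] = {lab: total * freqs.get(lab, 0.0) for lab in labels}
    return VariantTable(pd.DataFrame.from_dict(rows, orient="index")[list(labels)])


@pytest.fixture
def random_variant_table(variant_labels):
    rng = np.random.default_rng(42)
    counts = rng.integers(0, 500, size=(8, len(variant_labels)))
    counts[:, 0] += 1  # no empty samples
    return VariantTable(
        pd.DataFrame(counts, index=[f"s{i}" for i in range(8)], columns=variant_labels)
    )


@pytest.fixture(scope="session")
def null_study():
    """No planted effects, no blocks: pure NB noise."""
    spec = ExpressionSimSpec(n_genes=400, n_samples_per_group=8, seed=7)
    return gen_expression_study(spec).normalize()
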