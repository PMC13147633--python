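import numpy as np
import pandas as pd
import pytest

from netstrat import CohortConfig, generate_cohort

#: scaled-down cohort for unit tests that refit the whole pipeline; the
#: full-size defaults are exercised by the recovery and acceptance tests
SMALL = dict(
    n_patients_gep=28,
    n_patients_common=24,
    n_responders_common=12,
    n_responders_gep=14,
    n_genes=72,
    n_planted_hubs=8,
)


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(CohortConfig(seed=5, **SMALL))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def gmt_file(tmp_path, default_cohort):
    """GMT collection over the synthetic gene panel: one set matching a
    planted hub star, plus unrelated random sets."""
    genes = list(default_cohort.expression.index)
    hub = default_cohort.truth.planted_hub_genes[0]
    star = [hub] + [
        b for a, b in default_cohort.truth.planted_differential_pairs if a == hub
    ]
    r = np.random.default_rng(0)
    lines = ["star_set\tplanted star\t" + "\t".join(star)]
    for i in range(5):
        members = r.choice(genes, size=20, replace=False)
        lines.append(f"random_set_{i}\trandom\t" + "\t".join(members))
    path = tmp_path / "sets.gmt"
    path.write_text("\n".join(lines) + "\n")
    return path
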