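import numpy as np
import pandas as pd
import pytest

from laborbasin.expression import Cohort, minmax_normalize
from laborbasin.synthetic_data import default_config, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(default_config(seed=11))


@pytest.fixture(scope="session")
def normalized_cohort(default_cohort):
    return minmax_normalize(default_cohort)


@pytest.fixture(scope="session")
def toy_cohort():
    """A hand-built 8-sample single-platform cohort (4 IL, 4 NIL).

    Small enough that the 36-partition sweep can be cross-checked against
    the scalar classifier constructors.
    """
    rng = np.random.default_rng(7)
    rows = []
    for j in range(4):
        rows.append((f"T_IL_{j+1}", "rnaseq", "IL"))
    for j in range(4):
        rows.append((f"T_NIL_{j+1}", "rnaseq", "NIL"))
    df = pd.DataFrame(rows, columns=["sample_id", "platform", "group"])
    means = {"FOXO1A": (0.3, 0.7), "FKBP5": (0.35, 0.75),
             "IL1B": (0.8, 0.2), "IL6": (0.7, 0.25), "IL8": (0.75, 0.3)}
    for gene, (mu_il, mu_nil) in means.items():
        mu = np.where(df["group"] == "IL", mu_il, mu_nil)
        df[gene] = mu + rng.normal(0, 0.08, size=len(df))
    return minmax_normalize(Cohort(data=df, normalized=False))
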