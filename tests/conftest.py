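import numpy as np
import pandas as pd
import pytest

import pharmacoscape as ps


def make_matrix(values, sample_ids=None, cfe_ids=None, cohort="cell_line",
                cancer_types=None, msi=None):
    """Build an AlterationMatrix from a plain array."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    sample_ids = sample_ids or [f"S{i + 1}" for i in range(n)]
    cfe_ids = cfe_ids or [f"F{j + 1}" for j in range(m)]
    ann = pd.DataFrame(
        {
            "cohort": cohort,
            "cancer_type": cancer_types if cancer_types is not None else "CT01",
            "msi": msi if msi is not None else "MSS",
        },
        index=sample_ids,
    )
    return ps.AlterationMatrix(
        pd.DataFrame(values, index=sample_ids, columns=cfe_ids), ann
    )


@pytest.fixture(scope="session")
def cohort():
    """Default desk-scale paired cohort with planted effects (seed 11)."""
    cfg = ps.default_config(seed=11)
    tumors, lines, catalog, truth = ps.simulate_cohort(cfg)
    return cfg, tumors, lines, catalog, truth


@pytest.fixture(scope="session")
def responses(cohort):
    cfg, _, lines, _, _ = cohort
    table, truth = ps.simulate_drug_response(lines, cfg)
    return table, truth
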