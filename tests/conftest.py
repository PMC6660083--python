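import numpy as np
import pandas as pd
import pytest

import metsig as ms


def make_cohort(values: np.ndarray, labels: list[str],
                metabolites: list[str] | None = None) -> ms.CohortMatrix:
    """Small helper: wrap a raw array as a CohortMatrix."""
    values = np.asarray(values, dtype=float)
    metabolites = metabolites or [f"m{j}" for j in range(values.shape[1])]
    samples = [f"s{i}" for i in range(values.shape[0])]
    return ms.CohortMatrix(
        data=pd.DataFrame(values, index=samples, columns=metabolites),
        labels=pd.Series(labels, index=samples),
    )


def zscores_from_z(z_values: np.ndarray, labels: list[str],
                   metabolites: list[str] | None = None) -> ms.ZScoreMatrix:
    """Wrap an already-Z-scaled array directly (bypassing log/scaling)."""
    z_values = np.asarray(z_values, dtype=float)
    metabolites = metabolites or [f"m{j}" for j in range(z_values.shape[1])]
    samples = [f"s{i}" for i in range(z_values.shape[0])]
    return ms.ZScoreMatrix(
        z=pd.DataFrame(z_values, index=samples, columns=metabolites),
        labels=pd.Series(labels, index=samples),
        control_means=pd.Series(0.0, index=metabolites),
        control_sds=pd.Series(1.0, index=metabolites),
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (20/20, 358 metabolites) plus truth."""
    config = ms.CohortConfig(seed=20260930)
    cohort, truth = ms.generate_cohort(config)
    return cohort, config, truth


@pytest.fixture(scope="session")
def default_zscores(default_cohort):
    cohort, config, truth = default_cohort
    z = ms.zscore_against_controls(ms.log_transform(cohort))
    return z, config, truth


@pytest.fixture(scope="session")
def default_screen(default_zscores):
    z, config, truth = default_zscores
    model = ms.fit_plsda(z)
    return ms.screen_metabolites(z, model), z, config, truth


@pytest.fixture(scope="session")
def small_informative_zscores():
    """40 samples x 8 metabolites; the first three metabolites shifted +1.2
    in cases, the rest pure noise."""
    rng = np.random.default_rng(7)
    n = 20
    z = rng.standard_normal((2 * n, 8))
    z[:n, :3] += 1.2
    return zscores_from_z(z, ["case"] * n + ["control"] * n)
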