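import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from clonaltracer import GenotypeMatrix

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_matrix(
    calls,
    cells=None,
    sites=None,
    tissues=None,
    refs=None,
    alts=None,
    variant_class=None,
    vaf=None,
):
    """Assemble a GenotypeMatrix from a call array with minimal metadata."""
    calls = np.asarray(calls, dtype=float)
    n, m = calls.shape
    cells = cells or [f"c{i}" for i in range(n)]
    sites = sites or [f"S{j}" for j in range(m)]
    tissues = tissues or ["tumor"] * n
    refs = refs or ["A"] * m
    alts = alts or ["T"] * m
    variant_class = variant_class or ["SNV"] * m
    site_meta = pd.DataFrame(
        {
            "chrom": ["1"] * m,
            "pos": np.arange(1, m + 1) * 100,
            "ref": refs,
            "alt": alts,
            "gene": [f"G{j}" for j in range(m)],
            "variant_class": variant_class,
            "vaf": vaf if vaf is not None else [np.nan] * m,
        },
        index=sites,
    )
    cell_meta = pd.DataFrame({"tissue": tissues}, index=cells)
    return GenotypeMatrix(
        cells=cells, sites=sites, calls=calls, site_meta=site_meta,
        cell_meta=cell_meta,
    )


@pytest.fixture
def matrix_factory():
    return make_matrix
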