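import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from kidneygps.pipeline import run_pipeline
from kidneygps.sumstats import SumStats

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_stats(rows, trait="eGFRcrea"):
    """Build a SumStats table from (cpaid, ea, oa, eaf, beta, se, p, n[, info]) tuples."""
    recs = []
    for r in rows:
        cpaid, ea, oa, eaf, beta, se, p, n = r[:8]
        info = r[8] if len(r) > 8 else np.nan
        chrom, pos, _ = cpaid.split(":", 2)
        recs.append(dict(cpaid=cpaid, chrom=chrom, pos=int(pos), ea=ea, oa=oa,
                         eaf=eaf, beta=beta, se=se, p=p, n=n, info=info))
    return SumStats(pd.DataFrame(recs), trait=trait)


@pytest.fixture(scope="session")
def pipeline_result():
    """Standard seeded end-to-end scenario, shared across tests."""
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline()
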