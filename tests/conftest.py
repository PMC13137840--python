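import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from methylink.io import GeneCatalog, GeneModel

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_catalog():
    """Three hand-built genes: plus, minus, and a second chromosome."""
    return GeneCatalog(
        [
            GeneModel(
                gene_id="plusA",
                chrom="chr1",
                strand="+",
                tx_start=10_000,
                tx_end=20_000,
                exons=((10_000, 12_000), (15_000, 20_000)),
            ),
            GeneModel(
                gene_id="minusB",
                chrom="chr1",
                strand="-",
                tx_start=60_000,
                tx_end=70_000,
                exons=((60_000, 62_000), (68_000, 70_000)),
            ),
            GeneModel(
                gene_id="otherC",
                chrom="chr2",
                strand="+",
                tx_start=5_000,
                tx_end=9_000,
                exons=((5_000, 9_000),),
            ),
        ]
    )


def cov_frame(rows):
    """Build a coverage DataFrame from (chrom, pos, meth, unmeth) tuples."""
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "count_meth", "count_unmeth"]
    ).astype({"pos": np.int64, "count_meth": np.int64, "count_unmeth": np.int64})
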