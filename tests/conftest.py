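import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from tnprof import GeneAnnotation, InsertionTable

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_annotation() -> GeneAnnotation:
    """Three scorable genes, one excluded tRNA, one essential gene (0-based half-open)."""
    genes = pd.DataFrame(
        [
            ("geneA", "chr", 9, 40, "+", "gene", False, False),
            ("geneB", "chr", 49, 90, "-", "gene", False, False),
            ("geneC", "chr", 110, 150, "+", "gene", False, False),
            ("trna1", "chr", 160, 175, "+", "tRNA", False, True),
            ("geneE", "chr", 200, 260, "-", "gene", True, False),
        ],
        columns=[
            "gene_id", "contig", "start", "end", "strand",
            "feature_type", "essential", "excluded",
        ],
    )
    return GeneAnnotation(genes=genes, contig_lengths={"chr": 300})


def make_table(entries, sample_id="s", contig="chr") -> InsertionTable:
    """Build an insertion table from {position: reads}."""
    return InsertionTable(
        sample_id=sample_id,
        sites=pd.DataFrame(
            {
                "contig": contig,
                "position": list(entries),
                "reads": list(entries.values()),
            }
        ),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
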