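import pandas as pd
import pytest

from clonetrace import (
    DEFAULT_CONSTRUCT,
    ConstructSpec,
    SimulationConfig,
    SizeDist,
    simulate_clones,
)

# short anchors keep hand-built reads readable; 12 is the minimum length
UP = "ACGTACGTACGT"
DOWN = "TGCATGCATGCA"


@pytest.fixture
def spec():
    return ConstructSpec(upstream_anchor=UP, downstream_anchor=DOWN)


@pytest.fixture
def small_truth():
    """A small but non-trivial clone population (table-only, no reads)."""
    config = SimulationConfig(
        seed=7,
        n_clones=40,
        clone_size=SizeDist(name="poisson", lam=4.0),
        downstream_per_hspc=5.0,
        unbarcoded_fraction=0.4,
    )
    return simulate_clones(config)


@pytest.fixture
def toy_cells():
    """Hand-built per-cell table: 10 HSPC + 100 downstream over 2 lineages,
    clone X in 2 HSPC and 40 downstream (30 in A, 10 in B)."""
    rows = []
    for i in range(10):
        rows.append(
            {
                "cell_id": f"h{i}",
                "clone_id": "X" if i < 2 else None,
                "lineage": "HSPC",
                "is_hspc": True,
                "qc_pass": True,
            }
        )
    for i in range(100):
        lineage = "A" if i < 50 else "B"
        clone = "X" if (i < 30 or 50 <= i < 60) else None
        rows.append(
            {
                "cell_id": f"d{i}",
                "clone_id": clone,
                "lineage": lineage,
                "is_hspc": False,
                "qc_pass": True,
            }
        )
    return pd.DataFrame(rows)
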