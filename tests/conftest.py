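import numpy as np
import pandas as pd
import pytest

import poolscreen as ps


@pytest.fixture(scope="session")
def small_screen():
    """A 20-gene, 2-line screen with two common and two mutant-specific
    planted lethals -- small enough for every stage to run in milliseconds."""
    design = ps.cohort_design(
        n_wildtype=1, n_mutant=1, n_genes=20, seed=7, coverage=1000.0
    )
    library = ps.simulate_library(design)
    effects = ps.random_effects(
        library, n_common=2, n_genotype=2, fc_range=(0.1, 0.3),
        off_target_rate=0.0, seed=8,
    )
    table, truth = ps.simulate_screen(library, design, effects)
    return design, library, effects, table, truth


@pytest.fixture()
def hairpin_results():
    """A handcrafted per-hairpin results frame covering hit/non-hit cases."""
    rows = [
        # gene, fc, p, retained
        ("hp1", "GA", 0.20, 0.01, True),
        ("hp2", "GA", 0.25, 0.02, True),
        ("hp3", "GA", 0.60, 0.30, True),
        ("hp4", "GB", 0.28, 0.05, True),
        ("hp5", "GB", 0.95, 0.90, True),
        ("hp6", "GB", 1.05, 0.80, True),
        ("hp7", "GC", 0.90, 0.60, True),
        ("hp8", "GC", 1.10, 0.70, True),
        ("hp9", "GD", 0.15, 0.001, True),   # single retained hairpin
        ("hp10", "GD", 0.50, 0.20, False),
    ]
    df = pd.DataFrame(
        rows, columns=["hairpin_id", "gene", "fc", "p_value", "retained"]
    ).set_index("hairpin_id")
    df["log2fc"] = np.log2(df["fc"])
    return df
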