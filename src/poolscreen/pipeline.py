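"""End-to-end convenience: count table -> per-line hit calls -> hit matrix.

Thin glue over :mod:`depletion`, :mod:`hits` and :mod:`cohort` for the
common case of screening a whole cell-line panel.
"""

from __future__ import annotations

import pandas as pd

from .cohort import HitMatrix, build_hit_matrix
from .depletion import hairpin_depletion_table
from .hits import HitCriteria, score_line
from .screen_io import CountTable, HairpinLibrary


def score_cohort(
    table: CountTable,
    library: HairpinLibrary,
    genotypes: pd.Series,
    criteria: HitCriteria | None = None,
    *,
    abundance_floor: float = 30.0,
    pseudocount: float = 0.5,
) -> tuple[dict[str, pd.DataFrame], HitMatrix]:
    """Run depletion testing and hit calling for every line in the table.

    Returns the per-line gene summary frames (all genes, with criterion
    flags) and the assembled hit matrix.
    """
    if criteria is None:
        criteria = HitCriteria()
    summaries: dict[str, pd.DataFrame] = {}
    for line in table.cell_lines:
        results = hairpin_depletion_table(
            table, line, library,
            abundance_floor=abundance_floor, pseudocount=pseudocount,
        )
        summaries[line] = score_line(results, criteria)
    hm = build_hit_matrix(summaries, genotypes)
    return summaries, hm
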