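"""qPCR quantification: relative expression (delta-delta-Ct) and
ChIP percent-of-input.

Both statistics assume exponential amplification with a fixed efficiency
(default 2.0, i.e. perfect doubling per cycle).  Replicate Ct values are
averaged on the cycle scale, the standard convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ParameterError


@dataclass(frozen=True)
class QpcrMeasurement:
    """Replicate Ct values for a target gene and a reference gene in one
    sample (e.g. a GAPDH-normalized expression assay)."""

    sample: str
    target_gene: str
    reference_gene: str
    ct_target: tuple[float, ...]
    ct_reference: tuple[float, ...]

    def __post_init__(self) -> None:
        for name, cts in (("target", self.ct_target),
                          ("reference", self.ct_reference)):
            arr = np.asarray(cts, dtype=float)
            if arr.size == 0:
                raise ParameterError(f"{name} Ct values: need >= 1 replicate")
            if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
                raise ParameterError(f"{name} Ct values must be finite and > 0")

    @property
    def delta_ct(self) -> float:
        """Mean target Ct minus mean reference Ct."""
        return float(np.mean(self.ct_target) - np.mean(self.ct_reference))


def relative_expression(
    treated: QpcrMeasurement,
    control: QpcrMeasurement,
    efficiency: float = 2.0,
) -> float:
    """Fold change of the target in ``treated`` relative to ``control``,
    normalized to the reference gene: efficiency^-(ddCt) with
    ddCt = dCt_treated - dCt_control."""
    if treated.target_gene != control.target_gene:
        raise ParameterError("target genes differ between samples")
    if treated.reference_gene != control.reference_gene:
        raise ParameterError("reference genes differ between samples")
    if efficiency <= 1:
        raise ParameterError("amplification efficiency must be > 1")
    ddct = treated.delta_ct - control.delta_ct
    return float(efficiency ** (-ddct))


@dataclass(frozen=True)
class ChipQpcr:
    """Ct values of an immunoprecipitation and its chromatin input, with
    the fraction of chromatin the input represents."""

    ct_ip: float
    ct_input: float
    input_fraction: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.input_fraction <= 1:
            raise ParameterError("input_fraction must be in (0, 1]")
        for name, ct in (("ct_ip", self.ct_ip), ("ct_input", self.ct_input)):
            if not np.isfinite(ct) or ct <= 0:
                raise ParameterError(f"{name} must be finite and > 0")


def percent_input(m: ChipQpcr) -> float:
    """ChIP enrichment as a percentage of chromatin input.

    The input Ct is first adjusted for the dilution of the input aliquot
    (subtracting log2(1/input_fraction) cycles), then

        100 * 2^(Ct_input_adjusted - Ct_IP)
    """
    ct_input_adj = m.ct_input - np.log2(1.0 / m.input_fraction)
    return float(100.0 * 2.0 ** (ct_input_adj - m.ct_ip))
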