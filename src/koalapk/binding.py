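"""Plasma-protein binding from ultrafiltration assay concentrations.

Percent bound is 100 - (free/total)*100 per measurement.  Plasma replicates
are summarised as mean +/- SD (n-1 denominator) per nominal concentration;
buffer-matrix measurements quantify non-specific binding to the filtration
membrane and are summarised separately (no correction is applied to the
plasma results, mirroring how such assays are conventionally reported).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["BindingMeasurement", "percent_bound", "summarize_binding"]

MATRICES = ("plasma", "buffer")
NSB_THRESHOLD = 5.0  # percent; below this non-specific binding is negligible


@dataclass(frozen=True)
class BindingMeasurement:
    """One ultrafiltration measurement (total and free drug, ug/mL)."""

    nominal_conc: float
    drug_total: float
    drug_free: float
    matrix: str = "plasma"

    def __post_init__(self) -> None:
        if self.matrix not in MATRICES:
            raise ValidationError(f"matrix must be one of {MATRICES}")
        if self.drug_total <= 0:
            raise ValidationError("drug_total must be positive")
        if self.drug_free < 0:
            raise ValidationError("drug_free must be >= 0")


def percent_bound(m: BindingMeasurement) -> float:
    """100 - (free/total)*100, in [0, 100]."""
    if m.drug_free > m.drug_total:
        raise ValidationError(
            f"free ({m.drug_free}) exceeds total ({m.drug_total}): invalid measurement"
        )
    return 100.0 - (m.drug_free / m.drug_total) * 100.0


def summarize_binding(measurements: Iterable[BindingMeasurement]) -> pd.DataFrame:
    """Mean +/- SD percent bound per (matrix, nominal concentration).

    SD uses the n-1 denominator and is NaN for single replicates.  Buffer
    rows represent non-specific binding; ``nsb_negligible`` flags whether the
    group mean is below 5%.
    """
    ms = list(measurements)
    if not ms:
        raise ValidationError("no measurements supplied")
    rows = [
        {
            "matrix": m.matrix,
            "nominal_conc": m.nominal_conc,
            "percent_bound": percent_bound(m),
        }
        for m in ms
    ]
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["matrix", "nominal_conc"], sort=True)["percent_bound"]
        .agg(n="count", mean="mean", sd=lambda s: s.std(ddof=1))
        .reset_index()
    )
    out["nsb_negligible"] = np.where(
        out["matrix"] == "buffer", out["mean"] < NSB_THRESHOLD, pd.NA
    )
    return out
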