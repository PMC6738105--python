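"""qPCR quantification formulas.

Relative expression by the comparative-Ct (delta-delta-Ct) method normalised
to a reference gene, and ChIP-qPCR enrichment as percent of chromatin input
with the input Ct adjusted for the fraction of chromatin it represents.
Both assume 100% amplification efficiency (a doubling per cycle).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["ddct", "percent_input", "relative_expression_table"]


def ddct(ct_target: float, ct_ref: float, ct_target_ctrl: float,
         ct_ref_ctrl: float) -> float:
    """Relative quantity 2**(-ddCt) of a target vs a reference gene,
    normalised to a control condition.

    ``ddCt = (Ct_target - Ct_ref) - (Ct_target_ctrl - Ct_ref_ctrl)``.
    """
    cts = (ct_target, ct_ref, ct_target_ctrl, ct_ref_ctrl)
    if not all(math.isfinite(c) for c in cts):
        raise ValidationError("Ct values must be finite")
    delta_delta = (ct_target - ct_ref) - (ct_target_ctrl - ct_ref_ctrl)
    return 2.0 ** (-delta_delta)


def percent_input(ct_ip: float, ct_input: float, input_fraction: float) -> float:
    """ChIP enrichment as percent of chromatin input.

    The input Ct is first adjusted by ``log2(1/input_fraction)`` to the
    100%-input scale; the result is ``100 * 2**(adjusted_input - ct_ip)``.
    """
    if not (math.isfinite(ct_ip) and math.isfinite(ct_input)):
        raise ValidationError("Ct values must be finite")
    if not 0 < input_fraction <= 1:
        raise ValidationError("input_fraction must lie in (0, 1]")
    adjusted = ct_input - math.log2(1.0 / input_fraction)
    return 100.0 * 2.0 ** (adjusted - ct_ip)


def relative_expression_table(df: pd.DataFrame, control_condition: str) -> pd.DataFrame:
    """Relative quantities from a tidy Ct table.

    Expects columns ``sample``, ``condition``, ``target_ct``, ``reference_ct``.
    Technical replicates (duplicate sample rows) are averaged on the Ct scale
    before transformation; the control condition's mean dCt is the calibrator.
    """
    required = {"sample", "condition", "target_ct", "reference_ct"}
    if not required <= set(df.columns):
        raise ValidationError(f"Ct table must carry columns {sorted(required)}")
    agg = df.groupby(["condition", "sample"], sort=False)[
        ["target_ct", "reference_ct"]].mean().reset_index()
    if control_condition not in set(agg["condition"]):
        raise ValidationError(f"control condition {control_condition!r} not present")
    agg["dct"] = agg["target_ct"] - agg["reference_ct"]
    calibrator = agg.loc[agg["condition"] == control_condition, "dct"].mean()
    agg["rq"] = 2.0 ** (-(agg["dct"] - calibrator))
    return agg[["condition", "sample", "dct", "rq"]]
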