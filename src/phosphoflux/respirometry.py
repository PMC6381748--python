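"""Quantification of glucose-induced oxygen-consumption responses.

The response statistic is the signed trapezoidal area under (OCR - basal)
from the stimulus time to the trace end, where basal is the mean OCR over
the pre-stimulus cycles.  Treatment responses are normalized to mock wells
and compared with a two-sided unpaired (Welch) t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import OCRTrace

__all__ = ["RespResponse", "basal_rate", "response_auc", "quantify_trace",
           "compare_to_control"]

#: relative shift in basal rate beyond which a compound is flagged as
#: perturbing resting respiration (its glucose response is confounded)
BASAL_SHIFT_FLAG = 0.15


@dataclass(frozen=True)
class RespResponse:
    well: str
    treatment: str | None
    basal_rate: float            # pmol O2/min
    auc_over_basal: float        # pmol O2


def basal_rate(trace: OCRTrace, window: tuple[float, float] | None = None) -> float:
    """Mean OCR over the pre-stimulus cycles.

    Default window is everything before the trace's injection annotation.
    """
    if window is None:
        if trace.injection_time is None:
            raise ValueError(f"well {trace.well}: no injection time annotated "
                             "and no window given")
        window = (trace.times[0], float(trace.injection_time))
    lo, hi = window
    if lo < trace.times[0] - 1e-9 or hi > trace.times[-1] + 1e-9:
        raise ValueError(f"well {trace.well}: basal window {window} outside trace")
    mask = (trace.times >= lo) & (trace.times < hi)
    if mask.sum() < 2:
        raise ValueError(f"well {trace.well}: fewer than 2 cycles in basal window")
    return float(trace.ocr[mask].mean())


def response_auc(trace: OCRTrace, stimulus_time: float, basal: float) -> float:
    """Signed trapezoidal integral of (OCR - basal) from the stimulus to the
    trace end, on the actual timestamps.  Below-basal excursions count
    negatively (no clipping)."""
    if not (trace.times[0] <= stimulus_time <= trace.times[-1]):
        raise ValueError(f"stimulus time {stimulus_time} outside trace span")
    mask = trace.times >= stimulus_time
    if mask.sum() < 2:
        raise ValueError("fewer than 2 post-stimulus points")
    t = trace.times[mask]
    y = trace.ocr[mask] - basal
    return float(np.trapezoid(y, t))


def quantify_trace(trace: OCRTrace, stimulus_time: float | None = None
                   ) -> RespResponse:
    stim = stimulus_time if stimulus_time is not None else trace.injection_time
    if stim is None:
        raise ValueError(f"well {trace.well}: no stimulus time")
    b = basal_rate(trace, (trace.times[0], float(stim)))
    return RespResponse(trace.well, trace.treatment, b,
                        response_auc(trace, float(stim), b))


def compare_to_control(responses: list[RespResponse], control_label: str = "mock"
                       ) -> pd.DataFrame:
    """Per-treatment fold change vs the mean mock AUC with a two-sided
    Welch t-test across replicate wells.

    A treatment whose mean basal rate differs from the mock basal by more
    than 15% is flagged ``basal_perturbed``: its glucose response cannot be
    read independently of the resting-respiration effect.
    """
    by_treat: dict[str, list[RespResponse]] = {}
    for r in responses:
        by_treat.setdefault(r.treatment or "unannotated", []).append(r)
    if control_label not in by_treat:
        raise ValueError(f"missing control group {control_label!r}")
    ctrl = by_treat[control_label]
    ctrl_auc = np.array([r.auc_over_basal for r in ctrl])
    ctrl_basal = float(np.mean([r.basal_rate for r in ctrl]))
    rows = []
    for treat, group in sorted(by_treat.items()):
        auc = np.array([r.auc_over_basal for r in group])
        if treat == control_label:
            fold, p = 1.0, 1.0
        else:
            fold = float(auc.mean() / ctrl_auc.mean())
            if len(auc) < 2 or len(ctrl_auc) < 2:
                raise ValueError(f"group {treat!r}: need >=2 replicate wells")
            if np.allclose(auc, ctrl_auc.mean()) and np.allclose(ctrl_auc,
                                                                 ctrl_auc.mean()):
                p = 1.0   # identical groups: no difference to test
            else:
                p = float(stats.ttest_ind(auc, ctrl_auc, equal_var=False).pvalue)
        basal = float(np.mean([r.basal_rate for r in group]))
        rows.append({
            "treatment": treat,
            "n_wells": len(group),
            "mean_basal": basal,
            "mean_auc_over_basal": float(auc.mean()),
            "fold_vs_control": fold,
            "p_value": p,
            "basal_perturbed": bool(abs(basal - ctrl_basal)
                                    > BASAL_SHIFT_FLAG * abs(ctrl_basal)),
        })
    return pd.DataFrame(rows).set_index("treatment")
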