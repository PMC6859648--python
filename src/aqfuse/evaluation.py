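"""Model performance metrics and the dispersion-vs-fusion comparison.

For modeled values C^M_i and observed C^O_i at n sites:

    MB   = (1/n) sum (C^M_i - C^O_i)            mean bias
    ME   = (1/n) sum |C^M_i - C^O_i|            mean (absolute) error
    RMSE = sqrt((1/n) sum (C^M_i - C^O_i)^2)    root-mean-squared error
    NMB  = sum (C^M_i - C^O_i) / sum C^O_i      normalized mean bias

MB, ME and RMSE are in concentration units; NMB is reported in percent.
By Jensen / Cauchy-Schwarz, ME >= |MB| and RMSE >= ME always hold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["MetricReport", "compute_metrics", "compare_methods"]


@dataclass(frozen=True)
class MetricReport:
    """MB/ME/RMSE in concentration units, NMB in percent, for one method."""

    method: str
    mb: float
    me: float
    rmse: float
    nmb_pct: float
    n: int

    def as_series(self) -> pd.Series:
        return pd.Series(
            {"MB": self.mb, "ME": self.me, "RMSE": self.rmse, "NMB": self.nmb_pct},
            name=self.method,
        )


def compute_metrics(modeled, observed, method: str = "model") -> MetricReport:
    """MB, ME, RMSE and NMB (in percent) of modeled vs observed values."""
    cm = np.asarray(modeled, dtype=float)
    co = np.asarray(observed, dtype=float)
    if cm.shape != co.shape:
        raise ValueError(f"length mismatch: {cm.shape} vs {co.shape}")
    if cm.size < 1:
        raise ValueError("need at least one site")
    obs_sum = co.sum()
    if obs_sum <= 0:
        raise ValueError("NMB undefined: observed values sum to 0")
    diff = cm - co
    return MetricReport(
        method=method,
        mb=float(diff.mean()),
        me=float(np.abs(diff).mean()),
        rmse=float(np.sqrt((diff ** 2).mean())),
        nmb_pct=float(diff.sum() / obs_sum * 100.0),
        n=cm.size,
    )


def compare_methods(observed, model_values, fused_values) -> pd.DataFrame:
    """Two-column metric table: dispersion model alone vs data fusion.

    Rows MB, ME, RMSE (concentration units) and NMB (%), columns
    ``dispersion`` and ``fusion``, both scored against the same observed
    values at the same sites.
    """
    obs = np.asarray(observed, dtype=float)
    disp = compute_metrics(model_values, obs, method="dispersion")
    fus = compute_metrics(fused_values, obs, method="fusion")
    return pd.concat([disp.as_series(), fus.as_series()], axis=1)
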