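"""Evaluation metrics for blood-pressure estimates.

The field's standard trio — SD, RMSE, MAE — plus threshold proportions: the
fraction of subjects whose absolute error falls strictly below a tolerance
(10 mmHg is the bar used by the BHS/AAMI device standards, which require
>= 85% of readings within it).

Conventions (documented because the literature is loose):
- errors are ``e = predicted - truth``;
- SD is the *population* standard deviation of the error distribution (so
  ``RMSE^2 = SD^2 + mean(e)^2`` holds exactly);
- the threshold comparison is strict (``|e| < threshold``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class MetricsReport:
    """SD / RMSE / MAE (mmHg) for one target, with optional extras."""

    target: str
    n: int
    sd: float
    rmse: float
    mae: float
    pct_within: dict = field(default_factory=dict)  # threshold mmHg -> proportion
    per_group: pd.DataFrame | None = None


def _check(predicted, truth) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(predicted, dtype=float).ravel()
    t = np.asarray(truth, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("empty prediction vector")
    if p.size != t.size:
        raise ValueError(f"length mismatch: {p.size} predictions vs {t.size} truths")
    return p, t


def compute_metrics(
    predicted,
    truth,
    target: str = "sbp",
    thresholds: tuple[float, ...] = (5.0, 10.0, 15.0),
    groups=None,
) -> MetricsReport:
    """SD, RMSE and MAE of the errors, plus threshold proportions.

    ``groups`` (optional, same length) adds a per-group breakdown — useful to
    see which BP interval the model serves best.
    """
    p, t = _check(predicted, truth)
    e = p - t
    mae = float(np.abs(e).mean())
    rmse = float(np.sqrt((e * e).mean()))
    sd = float(e.std())  # population form
    pct = {thr: proportion_within(p, t, thr) for thr in thresholds}
    per_group = None
    if groups is not None:
        g = np.asarray(groups).ravel()
        if g.size != p.size:
            raise ValueError("groups length mismatch")
        rows = []
        for gv in np.unique(g):
            sel = g == gv
            eg = e[sel]
            rows.append(
                {
                    "group": gv,
                    "n": int(sel.sum()),
                    "sd": float(eg.std()),
                    "rmse": float(np.sqrt((eg * eg).mean())),
                    "mae": float(np.abs(eg).mean()),
                }
            )
        per_group = pd.DataFrame(rows)
    return MetricsReport(target=target, n=p.size, sd=sd, rmse=rmse, mae=mae, pct_within=pct, per_group=per_group)


def proportion_within(predicted, truth, threshold: float) -> float:
    """Fraction of absolute errors strictly below ``threshold`` mmHg."""
    p, t = _check(predicted, truth)
    return float((np.abs(p - t) < threshold).mean())


def render_report(reports: list[MetricsReport]) -> str:
    """Aligned text table, one row per target, columns SD / RMSE / MAE."""
    if not reports:
        raise ValueError("need at least one report")
    df = report_frame(reports)
    return df.to_string(index=False, float_format=lambda v: f"{v:8.2f}")


def report_frame(reports: list[MetricsReport]) -> pd.DataFrame:
    """The same table as a DataFrame (CSV-ready); column order SD, RMSE, MAE."""
    rows = []
    for r in reports:
        row = {"target": r.target.upper(), "n": r.n, "sd": r.sd, "rmse": r.rmse, "mae": r.mae}
        for thr, frac in sorted(r.pct_within.items()):
            row[f"pct_within_{thr:g}"] = frac
        rows.append(row)
    return pd.DataFrame(rows)
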