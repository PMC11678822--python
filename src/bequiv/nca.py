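"""Non-compartmental analysis of single-dose concentration profiles.

Per subject x period this derives Cmax, tmax, AUC truncated at 72 h
(linear-up/log-down trapezoid), and the apparent terminal elimination rate
constant lambda_z with its half-life ln2/lambda_z, from an ln-linear fit to
the terminal phase.

BLQ handling: observations below the limit of quantification are zero before
the subject's first quantifiable concentration (no drug yet) and are treated
as missing afterwards — excluded from the lambda_z fit, with AUC intervals
bridging across them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import DataError, StudyDataset, completers

logger = logging.getLogger("bequiv")

AUC_CUTOFF_H = 72.0


class NCAFailure(DataError):
    """Profile cannot support the requested metric (e.g. all BLQ)."""


@dataclass(frozen=True)
class NCAResult:
    subject_id: str
    period: int
    formulation: str
    cmax_ng_ml: float
    tmax_h: float
    auc0_72_ng_h_ml: float
    lambda_z_per_h: float | None
    t_half_h: float | None
    lambda_z_points: int
    lambda_z_r2adj: float | None
    auc_evaluable: bool = True


def _usable(t, c):
    """Apply the BLQ rules: returns (t, c) with leading BLQ as 0, later BLQ dropped.

    ``c`` may contain NaN for BLQ/missing values.
    """
    t = np.asarray(t, dtype=float)
    c = np.asarray(c, dtype=float)
    order = np.argsort(t, kind="stable")
    t, c = t[order], c[order]
    quant = np.isfinite(c) & (c > 0)
    if not quant.any():
        raise NCAFailure("no quantifiable concentration in profile")
    first = np.argmax(quant)
    lead = np.arange(t.size) < first
    c = np.where(lead, 0.0, c)
    keep = lead | np.isfinite(c)
    return t[keep], c[keep]


def cmax_tmax(t, c) -> tuple[float, float]:
    """Maximum observed concentration and the earliest time attaining it."""
    t, c = _usable(t, c)
    i = int(np.argmax(c))  # argmax returns the first maximum: earliest-tie rule
    if c[i] <= 0:
        raise NCAFailure("no positive concentration in profile")
    return float(c[i]), float(t[i])


def auc_0_72(t, c, cutoff_h: float = AUC_CUTOFF_H, method: str = "lin-up/log-down"):
    """Trapezoidal AUC from dosing to ``cutoff_h`` (ng*h/mL).

    Descending segments with two positive endpoints use the log trapezoid
    (C1-C2)*dt/ln(C1/C2); all other segments (rising, flat, or touching
    zero) use the linear rule.  ``method='linear'`` forces the linear rule
    everywhere.  Returns ``(auc, evaluable)`` where ``evaluable`` is False
    when the profile ends before ``cutoff_h`` and the area had to be
    truncated at the last quantifiable time.
    """
    try:
        t, c = _usable(t, c)
    except NCAFailure:
        # a fully unquantifiable profile has zero area by convention
        t = np.sort(np.asarray(t, dtype=float))
        if t.size < 2:
            raise
        return 0.0, bool(np.isclose(t[t <= cutoff_h + 1e-12][-1], cutoff_h))
    within = t <= cutoff_h + 1e-12
    t, c = t[within], c[within]
    if t.size < 2:
        raise NCAFailure("fewer than 2 usable points for AUC")
    evaluable = bool(np.isclose(t[-1], cutoff_h))
    if not evaluable:
        logger.warning("profile ends at %.2f h < %.2f h; AUC truncated early", t[-1], cutoff_h)
    c1, c2 = c[:-1], c[1:]
    dt = np.diff(t)
    lin = 0.5 * (c1 + c2) * dt
    if method == "linear":
        seg = lin
    elif method == "lin-up/log-down":
        down = (c2 < c1) & (c2 > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            logseg = (c1 - c2) * dt / np.log(c1 / c2)
        seg = np.where(down, logseg, lin)
    else:
        raise ValueError(f"unknown AUC method {method!r}")
    return float(seg.sum()), evaluable


def lambda_z(t, c):
    """Terminal elimination rate by best-fit ln-linear regression.

    Candidate point sets are the trailing k quantifiable points strictly
    after tmax, k >= 3; the set maximizing adjusted R^2 wins (ties toward
    more points).  When fewer than three points follow the peak — e.g. a
    profile already in decline at its first sample — the peak itself is
    admitted to the candidate pool.  Returns ``(lambda_z, t_half, n_points, r2adj)`` or
    ``(None, None, 0, None)`` when no candidate yields a positive rate.
    """
    t, c = _usable(t, c)
    _, tm = cmax_tmax(t, c)
    mask = (t > tm) & (c > 0)
    if mask.sum() < 3:
        # monotone-declining profiles peak at their first quantifiable point;
        # admit it so a pure terminal phase is still fittable
        mask = (t >= tm) & (c > 0)
    tt, cc = t[mask], np.log(c[mask])
    m = tt.size
    if m < 3:
        return None, None, 0, None

    best = None
    for k in range(m, 2, -1):
        x, y = tt[m - k:], cc[m - k:]
        xm, ym = x.mean(), y.mean()
        sxx = ((x - xm) ** 2).sum()
        sxy = ((x - xm) * (y - ym)).sum()
        syy = ((y - ym) ** 2).sum()
        if sxx == 0 or syy == 0:
            continue
        slope = sxy / sxx
        if slope >= 0:
            continue
        r2 = sxy * sxy / (sxx * syy)
        r2adj = 1.0 - (1.0 - r2) * (k - 1) / (k - 2)
        if best is None or r2adj > best[0] + 1e-12:
            best = (r2adj, slope, k)
    if best is None:
        return None, None, 0, None
    r2adj, slope, k = best
    lz = -slope
    return float(lz), float(np.log(2.0) / lz), int(k), float(r2adj)


def nca_profile(subject: str, period: int, formulation: str, t, c,
                fit_lambda_z: bool = True) -> NCAResult:
    cmax, tmax = cmax_tmax(t, c)
    auc, evaluable = auc_0_72(t, c)
    if fit_lambda_z:
        lz, th, npts, r2 = lambda_z(t, c)
    else:
        lz = th = r2 = None
        npts = 0
    return NCAResult(subject, int(period), formulation, cmax, tmax, auc, lz, th, npts, r2,
                     auc_evaluable=evaluable)


def run_nca(dataset: StudyDataset, fit_lambda_z: bool = True,
            completers_only: bool = True) -> pd.DataFrame:
    """NCA metrics for every subject x period; one row per profile.

    With ``completers_only`` (the default) subjects lacking evaluable data in
    either period are dropped, matching the analysis population used for the
    comparative statistics.
    """
    keep = completers(dataset) if completers_only else set(dataset.subjects())
    rows = []
    for (subject, period), grp in dataset.records.groupby(["subject", "period"], sort=True):
        if subject not in keep:
            continue
        form = grp["formulation"].iloc[0]
        try:
            res = nca_profile(subject, period, form, grp["time_h"].to_numpy(),
                              grp["conc_ng_ml"].to_numpy(), fit_lambda_z=fit_lambda_z)
        except NCAFailure as exc:
            logger.warning("NCA failed for subject %s period %s: %s", subject, period, exc)
            continue
        rows.append({**res.__dict__, "sequence": grp["sequence"].iloc[0]})
    if not rows:
        raise DataError("NCA produced no evaluable profiles")
    return pd.DataFrame(rows)
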