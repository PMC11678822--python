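"""Average bioequivalence on ln-transformed PK metrics.

The classical 2x2x2 crossover ANOVA is fit by least squares with Sequence,
Subject nested within Sequence, Period and Formulation all as fixed effects
(sum-to-zero coding).  Because the subject term absorbs all between-subject
variation, the residual mean square is the within-subject (intra-subject)
variance on the ln scale; the intra-subject coefficient of variation is

    ISCV% = 100 * sqrt(exp(s^2) - 1),

with s^2 the residual mean square.  The Formulation contrast gives the
Test/Reference geometric least-square-means ratio (GMR) with its 90%
two-sided CI (equivalent to two one-sided tests at alpha = 0.05), judged
against the fixed [80.00, 125.00]% acceptance interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import DataError

BE_LIMITS_PCT = (80.00, 125.00)

_METRIC_COLUMNS = {"cmax": "cmax_ng_ml", "auc0_72": "auc0_72_ng_h_ml"}


@dataclass(frozen=True)
class ABEResult:
    metric_name: str
    n_subjects: int
    lsm_test: float
    lsm_ref: float
    gmr_pct: float
    ci90_pct: tuple[float, float]
    mse: float
    df_resid: int
    iscv_pct: float
    anova_table: pd.DataFrame = field(repr=False, default=None)


@dataclass(frozen=True)
class BEDecision:
    bioequivalent: bool
    interval_pct: tuple[float, float] = BE_LIMITS_PCT


def iscv_from_mse(mse: float) -> float:
    """Intra-subject CV (%) from the ln-scale residual mean square."""
    if mse < 0:
        raise ValueError(f"mse must be non-negative, got {mse}")
    return 100.0 * np.sqrt(np.expm1(mse))


def mse_from_iscv(iscv_pct: float) -> float:
    """Inverse map: ln-scale variance implied by an ISCV percentage."""
    return float(np.log1p((iscv_pct / 100.0) ** 2))


def be_decision(result: ABEResult) -> BEDecision:
    """Bioequivalent iff both unrounded CI bounds lie inside the closed interval."""
    lo, hi = result.ci90_pct
    return BEDecision(bioequivalent=(BE_LIMITS_PCT[0] <= lo and hi <= BE_LIMITS_PCT[1]))


def _design_matrix(sequence, subject, period, formulation):
    """Full-rank sum-to-zero design for the four fixed effects.

    Column order: intercept | sequence | subject-within-sequence contrasts |
    period | formulation.  Effect columns are +/-1/2 so the formulation
    coefficient is directly ln(GMR) and the intercept the grand marginal
    mean; subject contrasts sum to zero within each sequence, making the
    intercept +/- half-effect the least-square means.
    """
    sequence = np.asarray(sequence)
    subject = np.asarray(subject)
    period = np.asarray(period, dtype=int)
    formulation = np.asarray(formulation)

    n_obs = sequence.size
    cols = [np.ones(n_obs), np.where(sequence == "TR", 0.5, -0.5)]
    subj_start = 2
    for seq in ("TR", "RT"):
        subs = sorted(set(subject[sequence == seq]))
        if not subs:
            raise DataError(f"sequence {seq} has no subjects (singular design)")
        last = subs[-1]
        for s in subs[:-1]:
            cols.append(np.where(subject == s, 1.0, 0.0) - np.where(subject == last, 1.0, 0.0))
    n_subj_cols = len(cols) - subj_start
    cols.append(np.where(period == 1, 0.5, -0.5))
    cols.append(np.where(formulation == "Test", 0.5, -0.5))
    X = np.column_stack(cols)
    groups = {
        "Sequence": [1],
        "Subject(Sequence)": list(range(subj_start, subj_start + n_subj_cols)),
        "Period": [X.shape[1] - 2],
        "Formulation": [X.shape[1] - 1],
    }
    return X, groups


def fit_crossover(values, sequence, subject, period, formulation, alpha: float = 0.05,
                  with_anova: bool = True):
    """Least-squares fit of ln(value) on the crossover design.

    Returns a dict with the ln-scale formulation estimate, its standard
    error, residual MSE/df, the grand marginal mean, and the Type-III ANOVA
    table.  ``alpha`` is the one-sided level; the reported CI is the
    (1 - 2*alpha) two-sided interval.
    """
    values = np.asarray(values, dtype=float)
    if (values <= 0).any() or not np.isfinite(values).all():
        raise DataError("metric values must be strictly positive and finite")
    y = np.log(values)
    X, groups = _design_matrix(sequence, subject, period, formulation)

    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ssr = float(resid @ resid)
    df_resid = X.shape[0] - rank
    if df_resid < 1:
        raise DataError("no residual degrees of freedom (need >= 3 completers per sequence)")
    mse = ssr / df_resid

    xtx_inv = np.linalg.pinv(X.T @ X)
    i_form = groups["Formulation"][0]
    est = float(beta[i_form])
    se = float(np.sqrt(mse * xtx_inv[i_form, i_form]))
    tcrit = stats.t.ppf(1 - alpha, df_resid)

    # Type-III sums of squares: RSS increase from dropping each term group
    rows = []
    ms_subj = None
    for term, idx in groups.items() if with_anova else ():
        keep = [j for j in range(X.shape[1]) if j not in idx]
        beta_r = np.linalg.lstsq(X[:, keep], y, rcond=None)[0]
        resid_r = y - X[:, keep] @ beta_r
        ss = float(resid_r @ resid_r) - ssr
        df_t = len(idx)
        rows.append({"term": term, "ss": ss, "df": df_t, "ms": ss / df_t})
        if term == "Subject(Sequence)":
            ms_subj = ss / df_t
    for row in rows:
        # Sequence is a between-subject effect: tested against the
        # subject-within-sequence mean square; the rest against the residual.
        if row["term"] == "Sequence" and ms_subj:
            denom, ddf = ms_subj, len(groups["Subject(Sequence)"])
        else:
            denom, ddf = mse, df_resid
        if denom > 0:
            row["F"] = row["ms"] / denom
            row["p"] = float(stats.f.sf(row["F"], row["df"], ddf))
        else:
            row["F"] = np.nan
            row["p"] = np.nan
    rows.append({"term": "Residual", "ss": ssr, "df": df_resid, "ms": mse,
                 "F": np.nan, "p": np.nan})
    anova = pd.DataFrame(rows).set_index("term")

    return {
        "estimate_ln": est,
        "se_ln": se,
        "ci_ln": (est - tcrit * se, est + tcrit * se),
        "mu_ln": float(beta[0]),
        "mse": mse,
        "df_resid": int(df_resid),
        "anova": anova,
    }


def run_abe(nca_table: pd.DataFrame, metric: str = "cmax", alpha: float = 0.05) -> ABEResult:
    """Average-bioequivalence analysis of one NCA metric.

    ``nca_table`` is the output of :func:`bequiv.nca.run_nca` (one row per
    subject x period).  Only subjects contributing a positive, evaluable
    value in both periods enter the model.
    """
    if metric not in _METRIC_COLUMNS:
        raise ValueError(f"metric must be one of {sorted(_METRIC_COLUMNS)}")
    col = _METRIC_COLUMNS[metric]
    df = nca_table.copy()
    if metric == "auc0_72" and "auc_evaluable" in df.columns:
        bad = set(df.loc[~df["auc_evaluable"], "subject_id"])
        df = df[~df["subject_id"].isin(bad)]
    df = df[np.isfinite(df[col]) & (df[col] > 0)]
    both = df.groupby("subject_id")["period"].nunique()
    keep = set(both[both == 2].index)
    df = df[df["subject_id"].isin(keep)]
    if df.empty:
        raise DataError("no completers with usable metric values")

    if "sequence" in df.columns:
        sequence = df["sequence"].to_numpy()
    else:  # reconstruct from the period-1 formulation
        p1 = df[df["period"] == 1].set_index("subject_id")["formulation"]
        seq_map = p1.map({"Test": "TR", "Reference": "RT"})
        sequence = df["subject_id"].map(seq_map).to_numpy()

    fit = fit_crossover(df[col], sequence, df["subject_id"], df["period"], df["formulation"],
                        alpha=alpha)
    est, (lo, hi) = fit["estimate_ln"], fit["ci_ln"]
    return ABEResult(
        metric_name=metric,
        n_subjects=len(keep),
        lsm_test=float(np.exp(fit["mu_ln"] + est / 2)),
        lsm_ref=float(np.exp(fit["mu_ln"] - est / 2)),
        gmr_pct=float(100 * np.exp(est)),
        ci90_pct=(float(100 * np.exp(lo)), float(100 * np.exp(hi))),
        mse=fit["mse"],
        df_resid=fit["df_resid"],
        iscv_pct=float(iscv_from_mse(fit["mse"])),
        anova_table=fit["anova"],
    )


def gmr_from_lsms(lsm_test: float, lsm_ref: float) -> float:
    """Geometric-LSM ratio as a percentage (e.g. for checking published tables)."""
    if lsm_test <= 0 or lsm_ref <= 0:
        raise ValueError("least-square means must be positive")
    return 100.0 * lsm_test / lsm_ref
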