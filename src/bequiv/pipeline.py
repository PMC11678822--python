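"""End-to-end study analysis: NCA -> average BE -> f2 -> decision report.

``run_pipeline`` is a pure function of (dataset, mode): it derives the NCA
metrics, runs the average-bioequivalence ANOVA on ln-Cmax and ln-AUC0-72,
computes the Cmax f2 factor (pilot mode only — pivotal studies are decided
on the CI alone), and assembles a report mirroring the usual BE study
tables: arithmetic mean (CV%) per metric and formulation, median (range)
for tmax, GMR with 90% CI and ISCV, the [80.00-125.00]% decision, and a
recommendation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .abe import ABEResult, BEDecision, be_decision, run_abe
from .f2 import Band, F2Result, f2_analysis
from .io import DataError, StudyDataset
from .nca import run_nca

_SUMMARY_METRICS = [
    ("cmax_ng_ml", "Cmax (ng/mL)"),
    ("tmax_h", "tmax (h)"),
    ("auc0_72_ng_h_ml", "AUC0-72 (ng*h/mL)"),
    ("lambda_z_per_h", "lambda_z (1/h)"),
    ("t_half_h", "t1/2 (h)"),
]


@dataclass
class StudyReport:
    label: str
    mode: str
    n_completers: int
    nca_summary: pd.DataFrame
    abe: dict[str, ABEResult]
    decision: BEDecision
    f2: F2Result | None
    recommendation: str
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def _abe(a: ABEResult) -> dict:
            return {
                "metric": a.metric_name,
                "n": a.n_subjects,
                "lsm_test": round(a.lsm_test, 2),
                "lsm_ref": round(a.lsm_ref, 2),
                "gmr_pct": round(a.gmr_pct, 2),
                "ci90_pct": [round(a.ci90_pct[0], 2), round(a.ci90_pct[1], 2)],
                "iscv_pct": round(a.iscv_pct, 1),
                "mse": a.mse,
                "df_resid": a.df_resid,
                "anova": a.anova_table.reset_index().to_dict(orient="records"),
            }

        out = {
            "label": self.label,
            "mode": self.mode,
            "n_completers": self.n_completers,
            "nca_summary": self.nca_summary.reset_index().to_dict(orient="records"),
            "abe": {k: _abe(v) for k, v in self.abe.items()},
            "bioequivalent": self.decision.bioequivalent,
            "acceptance_interval_pct": list(self.decision.interval_pct),
            "recommendation": self.recommendation,
            "provenance": self.provenance,
        }
        if self.f2 is None:
            out["f2"] = "NC"  # not calculated (pivotal mode)
        else:
            out["f2"] = {
                "f2": round(self.f2.f2, 2),
                "cmax_ref": round(self.f2.pair.cmax_ref, 2),
                "tmax_ref_h": self.f2.pair.tmax_ref_h,
                "n_points": self.f2.pair.n_points,
                "band": self.f2.band.value if self.f2.band else None,
                "outside_tabulated": self.f2.outside_tabulated,
            }
        return out

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def to_text(self) -> str:
        a = self.abe["cmax"]
        lines = [
            f"Study: {self.label}  [{self.mode} mode, n={self.n_completers} completers]",
            "",
            self.nca_summary.to_string(),
            "",
            f"ln-Cmax ANOVA: GMR {a.gmr_pct:.2f}% "
            f"[{a.ci90_pct[0]:.2f}-{a.ci90_pct[1]:.2f}]%, ISCV {a.iscv_pct:.1f}%",
            f"Bioequivalent (Cmax, [80.00-125.00]%): {'yes' if self.decision.bioequivalent else 'no'}",
        ]
        if self.f2 is not None:
            lines.append(
                f"Cmax f2 factor: {self.f2.f2:.2f} (CmaxR {self.f2.pair.cmax_ref:.2f} ng/mL, "
                f"truncated at {self.f2.pair.tmax_ref_h:g} h, n={self.f2.pair.n_points})"
            )
        else:
            lines.append("Cmax f2 factor: NC (not calculated in pivotal mode)")
        lines.append(f"Recommendation: {self.recommendation}")
        return "\n".join(lines)


def summarize_nca(nca_table: pd.DataFrame) -> pd.DataFrame:
    """Per-formulation summaries: arithmetic mean (CV%), median (range) for tmax."""
    rows = {}
    for form, grp in nca_table.groupby("formulation"):
        col = {}
        for name, label in _SUMMARY_METRICS:
            v = grp[name].dropna().to_numpy(dtype=float)
            if v.size == 0:
                col[label] = "NC"
            elif name == "tmax_h":
                col[label] = f"{np.median(v):.2f} ({v.min():.2f}-{v.max():.2f})"
            else:
                cv = 100.0 * v.std(ddof=1) / v.mean() if v.size > 1 else np.nan
                col[label] = f"{v.mean():,.2f} ({cv:.1f}%)" if np.isfinite(cv) else f"{v.mean():,.2f}"
        rows[form] = col
    return pd.DataFrame(rows).reindex(columns=["Test", "Reference"])


def run_pipeline(dataset: StudyDataset, mode: str = "pilot") -> StudyReport:
    """Full analysis of one crossover study.

    Pilot mode adds the f2 similarity analysis on the mean profiles; pivotal
    mode reports it as not calculated.  Deterministic given the input.
    """
    if mode not in ("pilot", "pivotal"):
        raise ValueError("mode must be 'pilot' or 'pivotal'")
    try:
        nca_table = run_nca(dataset)
    except DataError as exc:
        raise DataError(f"[nca] {exc}") from exc

    abe_results: dict[str, ABEResult] = {}
    for metric in ("cmax", "auc0_72"):
        try:
            abe_results[metric] = run_abe(nca_table, metric=metric)
        except DataError as exc:
            raise DataError(f"[average-be:{metric}] {exc}") from exc

    cmax_abe = abe_results["cmax"]
    decision = be_decision(cmax_abe)

    f2_result = None
    if mode == "pilot":
        try:
            f2_result = f2_analysis(dataset, iscv_pct=cmax_abe.iscv_pct)
        except DataError as exc:
            raise DataError(f"[f2] {exc}") from exc

    recommendation = _recommend(mode, decision, f2_result)

    digest = hashlib.sha256(
        pd.util.hash_pandas_object(dataset.records, index=False).to_numpy().tobytes()
    ).hexdigest()[:16]
    report = StudyReport(
        label=dataset.config.label,
        mode=mode,
        n_completers=cmax_abe.n_subjects,
        nca_summary=summarize_nca(nca_table),
        abe=abe_results,
        decision=decision,
        f2=f2_result,
        recommendation=recommendation,
        provenance={
            "software": f"bequiv {__version__}",
            "data_sha256_16": digest,
            "lloq_ng_ml": dataset.config.lloq_ng_ml,
            "dose_mg": dataset.config.dose_mg,
        },
    )
    return report


def _recommend(mode: str, decision: BEDecision, f2_result: F2Result | None) -> str:
    if decision.bioequivalent:
        return "Bioequivalence shown for Cmax: 90% CI within [80.00-125.00]%."
    if mode == "pivotal" or f2_result is None:
        return "Bioequivalence not shown for Cmax: 90% CI outside [80.00-125.00]%."
    if f2_result.band is None or f2_result.band == Band.below_cutoff:
        return ("90% CI outside the acceptance interval and f2 below 35: "
                "similarity not shown; pivotal study not supported.")
    return (f"90% CI outside the acceptance interval, but Cmax f2 = {f2_result.f2:.2f}: "
            + _BAND_SENTENCE[f2_result.band])


_BAND_SENTENCE = {
    Band.conf_gt60: "confidence in proceeding to a pivotal study is >60%.",
    Band.conf_gt80: "confidence in proceeding to a pivotal study is >80%.",
    Band.conf_gt90: "confidence in proceeding to a pivotal study is high (>90%).",
}
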