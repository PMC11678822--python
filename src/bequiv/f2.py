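"""Cmax f2 similarity factor for pilot bioequivalence studies.

The f2 statistic, borrowed from dissolution-profile comparison, is applied
to in-vivo absorption: the arithmetic-mean Test and Reference
concentration-time profiles are normalized to the maximum of the *mean
Reference* profile (CmaxR) and truncated at the time that maximum occurs
(tmaxR),

    CtN = 100 * Cbar_t / CmaxR,   0 <= t <= tmaxR,

and the similarity of the two normalized absorption-phase curves is

    f2 = 50 * log10( 100 * (1 + (1/n) * sum_t (RtN - TtN)^2 )^(-1/2) ),

summed over the n post-dose grid points with 0 < t <= tmaxR.  Identical
curves give f2 = 100; an average point difference of 10 normalized units
gives f2 just under 50.

An f2 of at least 35 indicates similarity in the rate of absorption; for a
highly variable drug the magnitude of f2, together with the ANOVA ISCV,
maps to a confidence level for proceeding from a failed-CI pilot to a
full-size pivotal study.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .io import DataError, StudyDataset, completers

F2_CUTOFF = 35.0


class Band(str, enum.Enum):
    below_cutoff = "below_cutoff"
    conf_gt60 = "conf_gt60"
    conf_gt80 = "conf_gt80"
    conf_gt90 = "conf_gt90"


_BAND_TEXT = {
    Band.below_cutoff: "f2 below the similarity cut-off of 35: similarity in the rate of "
                       "absorption not shown; proceeding to a pivotal study is not supported.",
    Band.conf_gt60: ">60% confidence in proceeding to a pivotal study.",
    Band.conf_gt80: ">80% confidence in proceeding to a pivotal study.",
    Band.conf_gt90: ">90% confidence in proceeding to a pivotal study (regardless of ISCV).",
}


@dataclass(frozen=True)
class MeanProfile:
    times_h: np.ndarray
    mean_conc: np.ndarray
    n_subjects: int
    formulation: str


@dataclass(frozen=True)
class NormalizedPair:
    times_h: np.ndarray
    ref_norm: np.ndarray
    test_norm: np.ndarray
    cmax_ref: float
    tmax_ref_h: float

    @property
    def n_points(self) -> int:
        """Post-dose points entering the f2 sum (0 < t <= tmaxR)."""
        return int(np.sum(self.times_h > 0))


@dataclass(frozen=True)
class F2Result:
    f2: float
    pair: NormalizedPair
    cutoff: float = F2_CUTOFF
    band: Band | None = None
    outside_tabulated: bool = False


def mean_profile(dataset: StudyDataset, formulation: str) -> MeanProfile:
    """Arithmetic mean concentration at each nominal time, over completers.

    A BLQ sample before a subject's first quantifiable concentration counts
    as 0 (drug not yet absorbed); BLQ/missing samples later in the profile
    are excluded from that time's mean.
    """
    keep = completers(dataset)
    if not keep:
        raise DataError("no completers to average")
    rec = dataset.records
    rec = rec[(rec["formulation"] == formulation) & rec["subject"].isin(keep)]
    times = np.asarray(dataset.nominal_times_h)

    # wide matrix: one row per subject-period profile of this formulation;
    # grid times nobody quantified come back as NaN columns via reindex
    wide = rec.pivot_table(index=["subject", "period"], columns="time_h",
                           values="conc_ng_ml")
    wide = wide.reindex(columns=times)
    vals = wide.to_numpy()
    vals = vals[np.isfinite(vals).any(axis=1)]  # profiles with no quantifiable point
    quant = np.isfinite(vals) & (vals > 0)
    first = np.where(quant.any(axis=1), np.argmax(quant, axis=1), vals.shape[1])
    lead = np.arange(vals.shape[1])[None, :] < first[:, None]
    vals = np.where(lead, 0.0, vals)
    with np.errstate(invalid="ignore"):
        means = np.nanmean(vals, axis=0)
    return MeanProfile(times_h=times, mean_conc=means,
                       n_subjects=len(keep), formulation=formulation)


def normalize_pair(ref: MeanProfile, test: MeanProfile) -> NormalizedPair:
    """Normalize both mean curves to the Reference mean Cmax and truncate at its tmax.

    The single constant CmaxR (maximum of the mean Reference curve, earliest
    time on ties) scales both formulations; the window is 0 <= t <= tmaxR.
    """
    if ref.times_h.shape != test.times_h.shape or not np.allclose(ref.times_h, test.times_h):
        raise DataError("Reference and Test mean profiles must share a time grid")
    finite = np.isfinite(ref.mean_conc)
    if not finite.any() or np.nanmax(ref.mean_conc) <= 0:
        raise DataError("Reference mean profile has no positive concentration to normalize by")
    i_max = int(np.nanargmax(ref.mean_conc))  # first maximum: earliest-tie rule
    cmax_ref = float(ref.mean_conc[i_max])
    tmax_ref = float(ref.times_h[i_max])
    window = ref.times_h <= tmax_ref
    return NormalizedPair(
        times_h=ref.times_h[window],
        ref_norm=100.0 * ref.mean_conc[window] / cmax_ref,
        test_norm=100.0 * test.mean_conc[window] / cmax_ref,
        cmax_ref=cmax_ref,
        tmax_ref_h=tmax_ref,
    )


def f2_factor(pair: NormalizedPair) -> F2Result:
    """The f2 similarity value over the post-dose points of the normalized window."""
    post = pair.times_h > 0
    n = int(post.sum())
    if n < 1:
        raise DataError("no post-dose points in the normalized window")
    diff = pair.ref_norm[post] - pair.test_norm[post]
    if not np.isfinite(diff).all():
        raise DataError("normalized curves contain missing values inside the window")
    msd = float(np.mean(diff ** 2))
    f2 = 50.0 * np.log10(100.0 / np.sqrt(1.0 + msd))
    return F2Result(f2=float(f2), pair=pair)


def confidence_band(f2: float, iscv_pct: float) -> tuple[Band, str, bool]:
    """Map (f2, ISCV) to the strongest applicable confidence band.

    Bands, strongest first: f2 >= 50 -> >90% confidence regardless of ISCV;
    f2 >= 41 with ISCV >= 50% -> >80%; f2 >= 35 with ISCV > 40% -> >60%;
    f2 < 35 -> similarity not shown.  A combination covered by none of the
    tabulated rules (e.g. f2 in [35, 50) at low ISCV) conservatively reports
    the weakest band, flagged as outside the tabulated scenarios.
    """
    if not (np.isfinite(f2) and np.isfinite(iscv_pct)):
        raise ValueError("f2 and ISCV must be finite")
    if f2 < F2_CUTOFF:
        return Band.below_cutoff, _BAND_TEXT[Band.below_cutoff], False
    if f2 >= 50.0:
        band, outside = Band.conf_gt90, False
    elif f2 >= 41.0 and iscv_pct >= 50.0:
        band, outside = Band.conf_gt80, False
    elif iscv_pct > 40.0:
        band, outside = Band.conf_gt60, False
    else:
        band, outside = Band.conf_gt60, True
    text = _BAND_TEXT[band]
    if outside:
        text += " (outside tabulated scenarios: ISCV below the tabulated range for this f2)"
    return band, text, outside


def f2_analysis(dataset: StudyDataset, iscv_pct: float | None = None) -> F2Result:
    """End-to-end f2: mean profiles -> normalization -> f2 -> optional band."""
    ref = mean_profile(dataset, "Reference")
    test = mean_profile(dataset, "Test")
    result = f2_factor(normalize_pair(ref, test))
    if iscv_pct is not None:
        band, _, outside = confidence_band(result.f2, iscv_pct)
        result = F2Result(f2=result.f2, pair=result.pair, band=band,
                          outside_tabulated=outside)
    return result
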