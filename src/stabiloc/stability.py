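"""Transcriptome-wide mRNA half-life estimation and stability classification.

The analysis consumes per-condition expression matrices from a
transcription-shutoff (actinomycin-D chase) time course. Each transcript's
trajectory is converted to a remaining-fraction curve R(t) after normalizing
out the global RNA decline with the geometric mean of stable reference
transcripts; a small family of first-order decay models is fitted per
transcript; the best model yields a half-life; and a fixed filter cascade
(expression floor, goodness of fit, rapid decay, censoring) precedes the
two-condition fold-change classification into stabilized / destabilized /
unchanged transcripts.

Kinetic model shapes (t in hours, k in 1/h):

* ``EXP``          M(t) = exp(-k t)
* ``DELAY_EXP``    M(t) = 1 for t <= t0, exp(-k (t - t0)) afterwards
* ``PLATEAU_EXP``  M(t) = (1 - c) exp(-k t) + c, plateau c in [0, 1)

Each candidate is fitted as A * M(t) with a free nuisance amplitude A and
weights proportional to the observed remaining fraction (multiplicative
measurement noise). The amplitude matters: the t = 0 measurement is as noisy
as any other, and forcing the curve through R(0) = 1 propagates that noise
into the rate. A never enters the half-life, which is defined on the
normalized shape — the time at which M crosses 0.5: ln2/k for EXP; ln2/k of
the decay phase for DELAY_EXP (intrinsic stability, onset excluded); for
PLATEAU_EXP the crossing exists only when c < 0.5 and equals
-ln((0.5 - c)/(1 - c))/k, otherwise the transcript is censored (t1/2 = +inf).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

logger = logging.getLogger(__name__)

DEFAULT_TIMEPOINTS_H = (0.0, 3.0, 6.0, 9.0, 12.0, 24.0, 30.0)
DEFAULT_REFERENCES = ("RPLP0", "PGK1", "TRAP1")

MODELS = ("EXP", "DELAY_EXP", "PLATEAU_EXP")

#: decay rates below this (1/h) are treated as "no decay" -> censored
CENSOR_RATE = 1e-6

# classification labels
STABILIZED = "STABILIZED"
DESTABILIZED = "DESTABILIZED"
UNCHANGED = "UNCHANGED"
EXCLUDED_BASELINE = "EXCLUDED_BASELINE"
EXCLUDED_FIT = "EXCLUDED_FIT"
EXCLUDED_RAPID = "EXCLUDED_RAPID"
EXCLUDED_CENSORED = "EXCLUDED_CENSORED"

CLASSES = (
    STABILIZED,
    DESTABILIZED,
    UNCHANGED,
    EXCLUDED_BASELINE,
    EXCLUDED_FIT,
    EXCLUDED_RAPID,
    EXCLUDED_CENSORED,
)


class NormalizationError(ValueError):
    """A reference transcript is missing or has a non-positive value."""


class FitError(ValueError):
    """A decay series cannot be fitted (too few or non-finite points)."""


@dataclass
class TimeCourseMatrix:
    """Transcript-by-timepoint expression values for one condition.

    ``values`` is indexed by transcript id with one float column per time
    point (hours). Values are FPKM-like: non-negative, finite. At least four
    time points including t = 0 are required.
    """

    condition: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        tp = self.timepoints
        if len(tp) < 4:
            raise ValueError("time course needs at least 4 time points")
        if tp[0] != 0:
            raise ValueError("time course must include t = 0 as first column")
        if not np.all(np.diff(tp) > 0):
            raise ValueError("time points must be strictly increasing")
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise ValueError("expression values must be finite and non-negative")
        if self.values.index.duplicated().any():
            raise ValueError("transcript ids must be unique")

    @property
    def timepoints(self) -> np.ndarray:
        return np.asarray([float(c) for c in self.values.columns], dtype=float)

    @property
    def transcripts(self) -> pd.Index:
        return self.values.index

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.columns = [f"t{c:g}h" for c in self.timepoints]
        out.index.name = "transcript_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, condition: str = "") -> "TimeCourseMatrix":
        df = pd.read_csv(path, sep="\t", index_col="transcript_id")
        hours = []
        for c in df.columns:
            name = str(c)
            if not (name.startswith("t") and name.endswith("h")):
                raise ValueError(f"unrecognized time-point column {name!r}")
            hours.append(float(name[1:-1]))
        df.columns = hours
        return cls(condition=condition or Path(path).stem, values=df.astype(float))


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the filter cascade and classification.

    r2_min: minimum coefficient of determination of the selected model,
        required in both conditions.
    t_half_min_h: rapid-decay floor; transcripts below it in either condition
        are excluded because early time points cannot resolve their decay.
    fold_change: half-life ratio (control/knockdown) at or beyond which a
        transcript is called stabilized (or destabilized at the reciprocal).
    min_baseline_expression: expression floor at t = 0; avoids remaining
        fractions computed from near-zero baselines.
    """

    r2_min: float = 0.9
    t_half_min_h: float = 3.0
    fold_change: float = 2.0
    min_baseline_expression: float = 1.0

    def __post_init__(self) -> None:
        if min(self.r2_min, self.t_half_min_h, self.min_baseline_expression) <= 0:
            raise ValueError("all filter thresholds must be positive")
        if self.fold_change <= 1:
            raise ValueError("fold_change must exceed 1")


@dataclass(frozen=True)
class DecayModelFit:
    """Selected kinetic model for one transcript's remaining-fraction curve."""

    transcript_id: str
    model: str  # EXP | DELAY_EXP | PLATEAU_EXP
    k: float | None  # decay rate 1/h; None when censored
    aux: float | None  # onset t0 (DELAY_EXP) or plateau c (PLATEAU_EXP)
    r2: float
    t_half: float  # hours; +inf when censored

    @property
    def censored(self) -> bool:
        return math.isinf(self.t_half)


def geometric_mean(x: np.ndarray, axis: int = 0) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("geometric mean requires strictly positive values")
    return np.exp(np.mean(np.log(x), axis=axis))


def normalize_timecourse(
    matrix: TimeCourseMatrix,
    refs: Sequence[str] = DEFAULT_REFERENCES,
    params: FilterParams = FilterParams(),
) -> tuple[pd.DataFrame, list[str]]:
    """Convert expression values to remaining fractions R(t).

    The per-time-point scale factor s(t) = geomean(refs at t)/geomean(refs at 0)
    removes global drift (transcription shutoff depresses total RNA, so raw
    FPKM of even perfectly stable transcripts drifts); then
    R(t) = (value(t)/s(t)) / value(0). R(0) = 1 exactly.

    Returns (remaining-fraction DataFrame without the reference transcripts,
    list of transcript ids excluded for baseline expression below
    ``params.min_baseline_expression``).
    """
    refs = list(refs)
    if not refs:
        raise NormalizationError("reference set is empty")
    missing = [r for r in refs if r not in matrix.values.index]
    if missing:
        raise NormalizationError(f"reference transcripts missing from matrix: {missing}")
    ref_vals = matrix.values.loc[refs].to_numpy(dtype=float)
    if np.any(ref_vals <= 0):
        bad = [
            refs[i]
            for i in range(len(refs))
            if np.any(ref_vals[i] <= 0)
        ]
        raise NormalizationError(
            f"reference transcript(s) with non-positive value: {bad}"
        )
    scale = geometric_mean(ref_vals, axis=0)
    scale = scale / scale[0]

    others = matrix.values.drop(index=refs)
    baseline = others.iloc[:, 0].to_numpy(dtype=float)
    keep = baseline >= params.min_baseline_expression
    excluded = list(others.index[~keep])
    kept = others.loc[keep]
    rel = kept.to_numpy(dtype=float) / scale[np.newaxis, :]
    rel = rel / rel[:, [0]]
    out = pd.DataFrame(rel, index=kept.index, columns=matrix.values.columns)
    return out, excluded


# ---------------------------------------------------------------------------
# model fitting


def _model_exp(t: np.ndarray, k: float, a: float) -> np.ndarray:
    return a * np.exp(-k * t)


def _model_delay(t: np.ndarray, k: float, t0: float, a: float) -> np.ndarray:
    return a * np.where(t <= t0, 1.0, np.exp(-k * np.maximum(t - t0, 0.0)))


def _model_plateau(t: np.ndarray, k: float, c: float, a: float) -> np.ndarray:
    return a * ((1.0 - c) * np.exp(-k * t) + c)


#: bounds of the nuisance amplitude; wide enough to absorb t=0 measurement
#: noise, tight enough to keep the plateau parameter identifiable
_AMP_BOUNDS = (0.2, 5.0)

#: weight floor so near-zero late points do not dominate the weighted fit
_WEIGHT_FLOOR = 0.05


def _initial_rate(t: np.ndarray, r: np.ndarray) -> float:
    """Log-linear slope estimate on the positive part of the curve."""
    pos = r > 1e-9
    if pos.sum() >= 2:
        slope = np.polyfit(t[pos], np.log(r[pos]), 1)[0]
        if slope < 0:
            return float(min(-slope, 50.0))
        return 0.0  # non-decaying: start at the k >= 0 bound
    return 0.1


def _rss(resid: np.ndarray) -> float:
    return float(np.dot(resid, resid))


def _fit_candidate(model: str, t: np.ndarray, r: np.ndarray):
    """Weighted least-squares fit of one candidate.

    Returns (params, weighted_rss, unweighted_rss) or None on non-convergence.
    Weights are 1/max(observed, floor): residuals are treated as relative,
    matching multiplicative measurement noise.
    """
    k0 = _initial_rate(t, r)
    t_max = float(t[-1])
    sigma = np.maximum(r, _WEIGHT_FLOOR)
    a_lo, a_hi = _AMP_BOUNDS
    try:
        if model == "EXP":
            p, _ = optimize.curve_fit(
                _model_exp,
                t,
                r,
                p0=[k0, 1.0],
                sigma=sigma,
                bounds=([0.0, a_lo], [np.inf, a_hi]),
                maxfev=5000,
            )
            resid = _model_exp(t, *p) - r
        elif model == "DELAY_EXP":
            p, _ = optimize.curve_fit(
                _model_delay,
                t,
                r,
                p0=[k0, 0.0, 1.0],
                sigma=sigma,
                bounds=([0.0, 0.0, a_lo], [np.inf, 0.9 * t_max, a_hi]),
                maxfev=8000,
            )
            resid = _model_delay(t, *p) - r
        elif model == "PLATEAU_EXP":
            c0 = float(np.clip(r[-1], 0.0, 0.95))
            p, _ = optimize.curve_fit(
                _model_plateau,
                t,
                r,
                p0=[max(k0, 1e-3), c0, 1.0],
                sigma=sigma,
                bounds=([0.0, 0.0, a_lo], [np.inf, 1.0 - 1e-9, a_hi]),
                maxfev=8000,
            )
            resid = _model_plateau(t, *p) - r
        else:  # pragma: no cover - guarded by caller
            raise ValueError(f"unknown model {model!r}")
    except RuntimeError:  # optimizer did not converge: drop this candidate
        logger.debug("candidate %s did not converge", model)
        return None
    return np.asarray(p, dtype=float), _rss(resid / sigma), _rss(resid)


def _n_params(model: str) -> int:
    return 2 if model == "EXP" else 3

#: RSS floor keeping AICc finite; below it fits count as numerically perfect
#: ties and the parameter penalty decides (so a nested model cannot win on
#: optimizer round-off of an already-perfect simpler fit)
_RSS_FLOOR = 1e-8


def _aicc(rss: float, n: int, p: int) -> float:
    rss = max(rss, _RSS_FLOOR)
    aic = n * math.log(rss / n) + 2 * p
    denom = n - p - 1
    if denom <= 0:
        return math.inf
    return aic + 2 * p * (p + 1) / denom


def _r_squared(r: np.ndarray, rss: float) -> float:
    tss = float(np.sum((r - r.mean()) ** 2))
    if tss <= 1e-30:
        # constant series: a numerically perfect flat fit counts as explained
        return 1.0 if rss <= 1e-12 else 0.0
    return 1.0 - rss / tss


def _half_life(model: str, k: float, aux: float | None) -> float:
    if k < CENSOR_RATE:
        return math.inf
    if model in ("EXP", "DELAY_EXP"):
        return math.log(2.0) / k
    # PLATEAU_EXP: (1-c) exp(-k t) + c = 0.5 has a solution only for c < 0.5
    c = aux if aux is not None else 0.0
    if c >= 0.5:
        return math.inf
    return -math.log((0.5 - c) / (1.0 - c)) / k


def fit_decay(
    times_h: Sequence[float],
    remaining: Sequence[float],
    transcript_id: str = "",
    model_set: Sequence[str] = MODELS,
    selection: str = "AICC",
) -> DecayModelFit:
    """Fit candidate decay models to one remaining-fraction series and select.

    All candidates are fitted by nonlinear least squares on the untransformed
    remaining fraction (log-linear regression would discard near-zero late
    points). Selection is by small-sample-corrected AIC (``"AICC"``, default)
    or by best coefficient of determination (``"BEST_R2"``); ties go to the
    model with fewer parameters. A winning rate below 1e-6/h means the series
    does not decay on the observed window: the fit is censored with
    t1/2 = +inf.
    """
    t = np.asarray(times_h, dtype=float)
    r = np.asarray(remaining, dtype=float)
    if t.shape != r.shape or t.size < 4:
        raise FitError("need at least 4 matched (time, fraction) points")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(r))):
        raise FitError("non-finite values in decay series")
    if selection not in ("AICC", "BEST_R2"):
        raise ValueError(f"unknown selection rule {selection!r}")
    unknown = set(model_set) - set(MODELS)
    if unknown:
        raise ValueError(f"unknown models {sorted(unknown)}")

    candidates = []
    for model in MODELS:
        if model not in model_set:
            continue
        fit = _fit_candidate(model, t, r)
        if fit is None:
            continue
        params, wrss, rss = fit
        score = (
            _aicc(wrss, t.size, _n_params(model))
            if selection == "AICC"
            else -_r_squared(r, rss)
        )
        candidates.append((score, _n_params(model), model, params, rss))
    if not candidates:
        raise FitError(f"no candidate model converged for {transcript_id!r}")

    candidates.sort(key=lambda c: (c[0], c[1]))
    _, _, model, params, rss = candidates[0]
    k = float(params[0])
    aux = float(params[1]) if model != "EXP" else None
    r2 = _r_squared(r, rss)
    t_half = _half_life(model, k, aux)
    return DecayModelFit(
        transcript_id=transcript_id,
        model=model,
        k=None if k < CENSOR_RATE else k,
        aux=aux,
        r2=r2,
        t_half=t_half,
    )


def fit_all(
    rel: pd.DataFrame,
    model_set: Sequence[str] = MODELS,
    selection: str = "AICC",
) -> dict[str, DecayModelFit]:
    """Fit every row of a remaining-fraction DataFrame (columns = hours)."""
    t = np.asarray([float(c) for c in rel.columns])
    out: dict[str, DecayModelFit] = {}
    for tid, row in zip(rel.index, rel.to_numpy(dtype=float)):
        out[str(tid)] = fit_decay(t, row, str(tid), model_set, selection)
    return out


# ---------------------------------------------------------------------------
# filter cascade and classification

_TABLE_COLUMNS = [
    "transcript_id",
    "model_control",
    "k_control",
    "r2_control",
    "t_half_control",
    "model_knockdown",
    "k_knockdown",
    "r2_knockdown",
    "t_half_knockdown",
    "ratio",
    "class",
]


def _fit_fields(fit: DecayModelFit | None, suffix: str) -> dict:
    if fit is None:
        return {
            f"model_{suffix}": None,
            f"k_{suffix}": np.nan,
            f"r2_{suffix}": np.nan,
            f"t_half_{suffix}": np.nan,
        }
    return {
        f"model_{suffix}": fit.model,
        f"k_{suffix}": np.nan if fit.k is None else fit.k,
        f"r2_{suffix}": fit.r2,
        f"t_half_{suffix}": fit.t_half,
    }


def filter_fits(
    fits_control: dict[str, DecayModelFit],
    fits_knockdown: dict[str, DecayModelFit],
    params: FilterParams = FilterParams(),
    excluded_baseline: Iterable[str] = (),
) -> pd.DataFrame:
    """Apply the filter cascade, producing a call-table skeleton.

    Fixed order: missing fit or r2 below threshold in either condition ->
    EXCLUDED_FIT; then half-life below the rapid floor in either ->
    EXCLUDED_RAPID; then censored in either -> EXCLUDED_CENSORED; survivors
    carry an empty class for :func:`classify_stability`.
    """
    rows = []
    for tid in sorted(set(excluded_baseline)):
        rows.append(
            {
                "transcript_id": tid,
                **_fit_fields(None, "control"),
                **_fit_fields(None, "knockdown"),
                "ratio": np.nan,
                "class": EXCLUDED_BASELINE,
            }
        )
    seen_baseline = set(excluded_baseline)
    all_ids = sorted((set(fits_control) | set(fits_knockdown)) - seen_baseline)
    for tid in all_ids:
        fc = fits_control.get(tid)
        fk = fits_knockdown.get(tid)
        row = {
            "transcript_id": tid,
            **_fit_fields(fc, "control"),
            **_fit_fields(fk, "knockdown"),
            "ratio": np.nan,
            "class": "",
        }
        if fc is None or fk is None:
            logger.debug("%s present in only one condition -> EXCLUDED_FIT", tid)
            row["class"] = EXCLUDED_FIT
        elif fc.r2 < params.r2_min or fk.r2 < params.r2_min:
            row["class"] = EXCLUDED_FIT
        elif fc.t_half < params.t_half_min_h or fk.t_half < params.t_half_min_h:
            row["class"] = EXCLUDED_RAPID
        elif math.isinf(fc.t_half) or math.isinf(fk.t_half):
            row["class"] = EXCLUDED_CENSORED
        rows.append(row)
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


def classify_stability(
    table: pd.DataFrame, params: FilterParams = FilterParams()
) -> pd.DataFrame:
    """Call survivors stabilized / destabilized / unchanged by half-life ratio.

    ratio = t1/2(control) / t1/2(knockdown); the fold-change boundary is
    inclusive on both sides. The comparison carries a 1e-6 relative tolerance
    so a ratio mathematically equal to the boundary is not pushed off it by
    optimizer round-off.
    """
    table = table.copy()
    surv = table["class"] == ""
    ratio = table.loc[surv, "t_half_control"] / table.loc[surv, "t_half_knockdown"]
    table.loc[surv, "ratio"] = ratio
    eps = 1e-6
    table.loc[surv, "class"] = np.select(
        [
            ratio >= params.fold_change * (1.0 - eps),
            ratio <= (1.0 + eps) / params.fold_change,
        ],
        [STABILIZED, DESTABILIZED],
        default=UNCHANGED,
    )
    return table


def funnel_counts(table: pd.DataFrame) -> dict[str, int]:
    """Cascade bookkeeping in figure order (each stage nested in the last)."""
    n = len(table)
    counts = table["class"].value_counts().to_dict()

    def c(label: str) -> int:
        return int(counts.get(label, 0))

    total_fitted = n - c(EXCLUDED_BASELINE)
    r2_pass = total_fitted - c(EXCLUDED_FIT)
    rapid_pass = r2_pass - c(EXCLUDED_RAPID)
    analyzable = rapid_pass - c(EXCLUDED_CENSORED)
    changed = c(STABILIZED) + c(DESTABILIZED)
    return {
        "input": n,
        "total_fitted": total_fitted,
        "r2_pass": r2_pass,
        "rapid_pass": rapid_pass,
        "analyzable": analyzable,
        "changed": changed,
        "stabilized": c(STABILIZED),
        "destabilized": c(DESTABILIZED),
        "unchanged": c(UNCHANGED),
        "excluded_baseline": c(EXCLUDED_BASELINE),
        "excluded_fit": c(EXCLUDED_FIT),
        "excluded_rapid": c(EXCLUDED_RAPID),
        "excluded_censored": c(EXCLUDED_CENSORED),
    }


def stability_pipeline(
    control: TimeCourseMatrix,
    knockdown: TimeCourseMatrix,
    refs: Sequence[str] = DEFAULT_REFERENCES,
    params: FilterParams = FilterParams(),
    model_set: Sequence[str] = MODELS,
    selection: str = "AICC",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Run normalization, fitting, filtering and classification end to end.

    Returns the full stability call table (one row per non-reference
    transcript in either input) and the funnel counts.
    """
    shared = control.transcripts.intersection(knockdown.transcripts)
    if len(shared.difference(refs)) == 0:
        raise ValueError("no shared transcripts between conditions")
    rel_c, excl_c = normalize_timecourse(control, refs, params)
    rel_k, excl_k = normalize_timecourse(knockdown, refs, params)
    excluded_baseline = set(excl_c) | set(excl_k)
    fits_c = fit_all(rel_c.drop(index=excluded_baseline, errors="ignore"), model_set, selection)
    fits_k = fit_all(rel_k.drop(index=excluded_baseline, errors="ignore"), model_set, selection)
    skeleton = filter_fits(fits_c, fits_k, params, excluded_baseline)
    table = classify_stability(skeleton, params)
    return table, funnel_counts(table)
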