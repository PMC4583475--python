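"""Psychometric analysis of 4-AFC threshold series and gLMS intensity ratings.

Detection series come from a four-alternative forced-choice staircase of
twelve concentrations in geometric progression (common ratio 1.5): the
probability of a correct choice rises from the 0.25 guessing rate to 1 with
concentration.  Recognition series are the paired yes/no bitterness
judgements (guess rate 0).  Both are fitted per subject, compound and
repetition by maximum likelihood with a logistic link on log10
concentration; the reported threshold is the midpoint of the non-guessing
component (P = 0.625 for detection, P = 0.5 for recognition), the
ISO-13301-consistent default.

Suprathreshold intensity ratings on the general Labeled Magnitude Scale
(gLMS, percent of scale length) are fitted with a saturating logistic and
inverted at the fixed label positions weak 6, moderate 17, strong 34.7 and
very strong 52.5 percent of the scale.

Outliers across subjects are removed with Peirce's criterion (Gould's
iterative formulation).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize
from scipy.special import erfc, expit, logit

MEASURES = ("detection", "recognition", "weak", "moderate", "strong", "very_strong")
GLMS_PERCENT = {"weak": 6.0, "moderate": 17.0, "strong": 34.7, "very_strong": 52.5}


def geometric_series(start: float, ratio: float, n_steps: int) -> np.ndarray:
    """Concentration series c_k = start * ratio**(k-1), k = 1..n_steps."""
    if start <= 0 or ratio <= 0 or n_steps < 1:
        raise ValueError("start and ratio must be positive and n_steps >= 1")
    return start * ratio ** np.arange(n_steps)


def fold_range(values) -> float:
    """max/min of a set of positive concentrations."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("fold_range of empty input")
    if np.any(values <= 0):
        raise ValueError("fold_range requires positive values")
    return float(values.max() / values.min())


def fold_range_rounded(values) -> int:
    return round(fold_range(values))


@dataclass
class PsychometricFit:
    mu: float  # log10 M, threshold location
    slope: float  # 1 / log10-units
    guess_rate: float
    converged: bool
    censor: str | None  # None, 'low', or 'high'
    n_trials: int
    loglik: float

    @property
    def threshold(self) -> float:
        """Threshold concentration in M (10**mu)."""
        return 10.0**self.mu


def _nll(params, x, y, gamma):
    mu, log_slope = params
    p = gamma + (1 - gamma) * expit((x - mu) * math.exp(log_slope))
    p = np.clip(p, 1e-9, 1 - 1e-9)
    return -np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))


def fit_psychometric(
    conc: np.ndarray, response: np.ndarray, kind: str = "detection"
) -> PsychometricFit:
    """Maximum-likelihood logistic fit of one response series.

    ``kind`` fixes the guess rate: 0.25 for 4-AFC detection, 0 for yes/no
    recognition.  Degenerate series (all correct, or at chance throughout)
    are returned as censored fits rather than raising.
    """
    if kind not in ("detection", "recognition"):
        raise ValueError("kind must be 'detection' or 'recognition'")
    gamma = 0.25 if kind == "detection" else 0.0
    conc = np.asarray(conc, dtype=float)
    response = np.asarray(response, dtype=float)
    ok = np.isfinite(response)
    conc, response = conc[ok], response[ok]
    if len(np.unique(conc)) < 4:
        raise ValueError("need responses at >= 4 concentration steps")
    x = np.log10(conc)
    xmin, xmax = x.min(), x.max()
    bounds = [(xmin - 5.0, xmax + 5.0), (np.log(0.2), np.log(100.0))]
    starts = [
        (xmin + frac * (xmax - xmin), np.log(s0))
        for frac, s0 in ((0.25, 4.0), (0.5, 4.0), (0.75, 4.0), (0.5, 1.0), (0.5, 15.0))
    ]
    best = None
    for p0 in starts:
        res = minimize(
            _nll, p0, args=(x, response, gamma), method="L-BFGS-B", bounds=bounds
        )
        key = (res.fun, math.exp(res.x[1]))  # ties by likelihood, then smallest slope
        if best is None or key < best[0]:
            best = (key, res)
    res = best[1]
    mu, slope = float(res.x[0]), float(math.exp(res.x[1]))
    censor = None
    if mu < xmin:
        censor = "low"
    elif mu > xmax:
        censor = "high"
    return PsychometricFit(
        mu=mu,
        slope=slope,
        guess_rate=gamma,
        converged=bool(res.success),
        censor=censor,
        n_trials=len(response),
        loglik=-float(res.fun),
    )


@dataclass
class IntensityCurve:
    """Saturating logistic gLMS curve: I(log10 c) = imax * expit((x - mu) / s)."""

    imax: float
    mu: float
    s: float
    x_range: tuple[float, float]
    converged: bool

    def value(self, conc: float) -> float:
        return self.imax * float(expit((math.log10(conc) - self.mu) / self.s))


def fit_intensity(conc: np.ndarray, intensity: np.ndarray) -> IntensityCurve:
    """Least-squares logistic fit of gLMS ratings (percent of scale) against
    log10 concentration; the floor is fixed at 0."""
    conc = np.asarray(conc, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    ok = np.isfinite(intensity)
    conc, intensity = conc[ok], intensity[ok]
    if len(np.unique(conc)) < 4:
        raise ValueError("need ratings at >= 4 concentration steps")
    x = np.log10(conc)
    span = max(x.max() - x.min(), 0.5)

    def resid(p):
        imax, mu, log_s = p
        return imax * expit((x - mu) / math.exp(log_s)) - intensity

    p0 = [max(intensity.max(), 5.0), float(np.median(x)), math.log(span / 4)]
    res = least_squares(
        resid,
        p0,
        bounds=([1.0, x.min() - 5, math.log(0.02)], [110.0, x.max() + 5, math.log(5.0)]),
    )
    imax, mu, log_s = res.x
    return IntensityCurve(
        imax=float(imax),
        mu=float(mu),
        s=float(math.exp(log_s)),
        x_range=(float(x.min()), float(x.max())),
        converged=bool(res.success),
    )


def invert_intensity(curve: IntensityCurve, pct: float) -> tuple[float | None, str | None]:
    """Concentration (M) at which the fitted curve reaches ``pct`` percent of
    the scale; (None, reason) when the inversion is undefined, and a censor
    tag when the solution extrapolates beyond the tested range."""
    if pct <= 0:
        raise ValueError("pct must be positive")
    if not curve.converged or curve.imax <= pct:
        return None, "undefined"
    x = curve.mu + curve.s * float(logit(pct / curve.imax))
    censor = None
    if x < curve.x_range[0]:
        censor = "low"
    elif x > curve.x_range[1]:
        censor = "high"
    return float(10.0**x), censor


def peirce_threshold(n: int, n_doubtful: int, n_unknowns: int = 1) -> float:
    """Squared deviation-ratio threshold x² of Peirce's criterion, by Gould's
    iterative procedure, for ``n`` observations with ``n_doubtful`` suspected
    outliers and ``n_unknowns`` fitted quantities (1 for a plain mean)."""
    if n <= n_doubtful + n_unknowns:
        return 0.0
    q = (n_doubtful ** (n_doubtful / n) * (n - n_doubtful) ** ((n - n_doubtful) / n)) / n
    r_old, r_new = 0.0, 1.0
    x2 = 0.0
    for _ in range(200):
        if abs(r_new - r_old) < 2e-16 * n:
            break
        lam = (q**n / r_new**n_doubtful) ** (1.0 / (n - n_doubtful))
        x2 = 1.0 + (n - n_unknowns - n_doubtful) / n_doubtful * (1.0 - lam**2)
        if x2 < 0:
            x2 = 0.0
            break
        r_old = r_new
        r_new = math.exp((x2 - 1) / 2.0) * erfc(math.sqrt(x2 / 2.0))
    return x2


def peirce_outliers(values) -> np.ndarray:
    """Keep-mask (True = keep) after applying Peirce's criterion.

    Follows the classical procedure: deviations are measured from the mean
    and standard deviation of the full sample, the number of doubtful
    observations is raised while at least that many observations exceed the
    criterion ratio, and the final rejection set is read off at the largest
    supported count.  Fewer than three finite values is a no-op.
    """
    values = np.asarray(values, dtype=float)
    mask = np.ones(len(values), dtype=bool)
    finite = np.isfinite(values)
    if finite.sum() < 3:
        return mask
    x = values[finite]
    n = len(x)
    mean = x.mean()
    std = x.std(ddof=1)
    if std == 0:
        return mask
    dev = np.abs(x - mean)
    rejected = np.zeros(n, dtype=bool)
    for k in range(1, n - 1):
        thr = math.sqrt(peirce_threshold(n, k)) * std
        exceed = dev > thr
        if exceed.sum() >= k:
            rejected = exceed
        else:
            break
    keep_finite = ~rejected
    mask[np.where(finite)[0]] = keep_finite
    return mask


def build_phenotype_table(
    trials: pd.DataFrame,
    pooled_repetitions: bool = False,
    apply_peirce: bool = True,
) -> pd.DataFrame:
    """Fit every subject x compound x repetition series and assemble the
    phenotype table.

    ``trials`` columns: subject, compound, repetition, step, conc,
    correct_4afc, recognized, intensity.  Output: one row per subject x
    compound x repetition with concentration columns for detection,
    recognition, weak, moderate, strong and very_strong, censor tags, and a
    Peirce outlier flag per measure (computed across subject x repetition
    cells within each compound on the log10 scale).
    """
    rows = []
    group_keys = ["subject", "compound"] if pooled_repetitions else [
        "subject",
        "compound",
        "repetition",
    ]
    for keys, sub in trials.groupby(group_keys, sort=True):
        if pooled_repetitions:
            subject, compound = keys
            repetition = 0
        else:
            subject, compound, repetition = keys
        row: dict = {"subject": subject, "compound": compound, "repetition": repetition}
        det = fit_psychometric(sub["conc"], sub["correct_4afc"], "detection")
        rec_resp = sub["recognized"].astype(float)
        rec = fit_psychometric(sub["conc"], rec_resp, "recognition")
        row["detection"] = det.threshold
        row["detection_censor"] = det.censor
        row["recognition"] = rec.threshold
        row["recognition_censor"] = rec.censor
        curve = fit_intensity(sub["conc"], sub["intensity"])
        for measure, pct in GLMS_PERCENT.items():
            conc, censor = invert_intensity(curve, pct)
            row[measure] = conc if conc is not None else np.nan
            row[f"{measure}_censor"] = censor
        rows.append(row)
    pheno = pd.DataFrame(rows)
    if apply_peirce:
        for measure in MEASURES:
            flag = np.zeros(len(pheno), dtype=bool)
            for compound, idx in pheno.groupby("compound").groups.items():
                vals = np.log10(pheno.loc[idx, measure].to_numpy(dtype=float))
                keep = peirce_outliers(vals)
                flag[pheno.index.get_indexer(idx)] = ~keep
            pheno[f"{measure}_outlier"] = flag
    return pheno
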