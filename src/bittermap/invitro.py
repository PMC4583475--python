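"""Calcium-imaging plate analysis for heterologously expressed receptors.

Raw plate data carry one row per well: peak fluorescence F and baseline F0
(RFU) for a receptor-allele construct, an empty-vector negative control, or
a per-day positive control.  Analysis proceeds in the fixed order

1. well-to-well correction: each well's response is its own baseline ratio
   ΔF/F = (F - F0) / F0;
2. negative-control correction: the mean empty-vector ΔF/F matched on
   (day, compound, concentration) is subtracted, removing
   receptor-independent artefacts and drift;
3. positive-control correction: responses are rescaled by
   grand positive-control mean / that day's positive-control mean, putting
   experimental days on a common scale.

The activation threshold of a receptor-compound pair is the lowest
concentration whose corrected responses differ significantly from the
matched empty-vector wells (one-way ANOVA gate, then per-concentration
comparisons with Bonferroni correction over the tested concentrations).
Dose-response curves are fitted to the Hill equation
f(c) = A c^n / (EC50^n + c^n) by bounded nonlinear least squares.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

EMPTY_VECTOR = "empty_vector"
POSITIVE_CONTROL = "positive_control"


def delta_f_over_f(F, F0):
    """Baseline-normalised fluorescence change (F - F0) / F0."""
    F = np.asarray(F, dtype=float)
    F0 = np.asarray(F0, dtype=float)
    if np.any(F0 <= 0):
        raise ValueError("baseline fluorescence F0 must be positive")
    return (F - F0) / F0


def hill(conc, ec50: float, amplitude: float, n: float):
    conc = np.asarray(conc, dtype=float)
    cn = conc**n
    return amplitude * cn / (ec50**n + cn)


def correct_fluorescence(plates: pd.DataFrame) -> pd.DataFrame:
    """Apply the three-step correction; returns non-control wells with a
    ``response`` column of corrected ΔF/F (empty-vector wells are retained,
    centred at zero within each matched group, for use as the reference in
    threshold calls).

    Wells without a matched (day, compound, conc) empty-vector group are
    dropped; days whose positive-control mean is not positive are dropped.
    """
    df = plates.copy()
    df["dff"] = delta_f_over_f(df["F"], df["F0"])

    pc = df[df["construct"] == POSITIVE_CONTROL]
    if pc.empty:
        raise ValueError("no positive-control wells present")
    day_means = pc.groupby("day")["dff"].mean()
    good_days = day_means[day_means > 0]
    grand = pc[pc["day"].isin(good_days.index)]["dff"].mean()
    scale = grand / good_days  # per-day rescaling factor

    exp = df[df["construct"] != POSITIVE_CONTROL].copy()
    exp = exp[exp["day"].isin(good_days.index)]
    neg = exp[exp["construct"] == EMPTY_VECTOR]
    neg_mean = neg.groupby(["day", "compound", "conc"])["dff"].mean()
    key = pd.MultiIndex.from_frame(exp[["day", "compound", "conc"]])
    matched = key.isin(neg_mean.index)
    exp = exp[matched].copy()
    baseline = neg_mean.reindex(
        pd.MultiIndex.from_frame(exp[["day", "compound", "conc"]])
    ).to_numpy()
    exp["response"] = (exp["dff"].to_numpy() - baseline) * scale.reindex(
        exp["day"]
    ).to_numpy()
    return exp.drop(columns=["dff"])


def call_threshold(
    corrected: pd.DataFrame,
    construct: str,
    compound: str,
    alpha: float = 0.05,
    ceiling: float | None = None,
) -> float | None:
    """Activation threshold: lowest concentration with corrected responses
    significantly above the matched empty-vector wells.

    Gate: one-way ANOVA across concentration groups plus control; then
    per-concentration two-sample comparisons against empty vector with
    Bonferroni correction (m = number of tested concentrations up to the
    compound's artefact-free ceiling).  Returns None when nothing reaches
    significance (receptor not activated).
    """
    sel = corrected[
        (corrected["construct"] == construct) & (corrected["compound"] == compound)
    ]
    ctrl = corrected[
        (corrected["construct"] == EMPTY_VECTOR) & (corrected["compound"] == compound)
    ]
    concs = sorted(sel["conc"].unique())
    if ceiling is not None:
        concs = [c for c in concs if c <= ceiling * (1 + 1e-9)]
    if len(concs) < 2:
        raise ValueError("need >= 2 tested concentrations")
    groups = [sel[sel["conc"] == c]["response"].to_numpy() for c in concs]
    if any(len(g) < 3 for g in groups):
        raise ValueError("need >= 3 replicates per concentration")
    ctrl_resp = ctrl[ctrl["conc"].isin(concs)]["response"].to_numpy()
    if np.allclose(np.concatenate(groups + [ctrl_resp]), groups[0][0]):
        return None
    _, p_gate = stats.f_oneway(*groups, ctrl_resp)
    if not np.isfinite(p_gate) or p_gate > alpha:
        return None
    m = len(concs)
    for c, g in zip(concs, groups):
        ref = ctrl[ctrl["conc"] == c]["response"].to_numpy()
        if len(ref) < 2:
            ref = ctrl_resp
        _, p = stats.ttest_ind(g, ref, equal_var=False)
        if p <= alpha / m and g.mean() > ref.mean():
            return float(c)
    return None


@dataclass
class DoseResponseFit:
    allele: str
    compound: str
    ec50: float
    amplitude: float
    hill_n: float
    threshold_conc: float | None
    activated: bool
    rss: float
    converged: bool
    boundary_pinned: bool = False


def fit_hill(
    conc,
    response,
    allele: str = "",
    compound: str = "",
    threshold_conc: float | None = None,
) -> DoseResponseFit:
    """Bounded least-squares Hill fit of mean corrected responses.

    EC50 is constrained to [c_min/10, c_max*10], the Hill coefficient to
    [0.5, 4] and the amplitude to be non-negative; fits pinned at a bound or
    failing to converge are flagged not-activated.
    """
    conc = np.asarray(conc, dtype=float)
    response = np.asarray(response, dtype=float)
    if len(conc) < 4:
        raise ValueError("need >= 4 concentrations for a Hill fit")
    if not np.all(np.isfinite(response)):
        raise ValueError("non-finite responses")
    lc = np.log10(conc)
    lo, hi = lc.min() - 1.0, lc.max() + 1.0
    amax = max(2.0 * response.max(), 1e-6)

    def resid(p):
        lec50, amp, n = p
        return hill(conc, 10.0**lec50, amp, n) - response

    best = None
    for lec0 in np.linspace(lc.min(), lc.max(), 5):
        res = least_squares(
            resid,
            [lec0, max(response.max(), 1e-3), 1.0],
            bounds=([lo, 0.0, 0.5], [hi, amax, 4.0]),
        )
        if best is None or res.cost < best.cost - 1e-15:
            best = res
    lec50, amp, n = best.x
    rss = float(2 * best.cost)
    pinned = bool(
        lec50 <= lo + 1e-6
        or lec50 >= hi - 1e-6
        or amp <= 1e-9
        or n <= 0.5 + 1e-9
        or n >= 4.0 - 1e-9
    )
    activated = bool(best.success and not pinned and (threshold_conc is not None))
    return DoseResponseFit(
        allele=allele,
        compound=compound,
        ec50=float(10.0**lec50),
        amplitude=float(amp),
        hill_n=float(n),
        threshold_conc=threshold_conc,
        activated=activated,
        rss=rss,
        converged=bool(best.success),
        boundary_pinned=pinned,
    )


def analyze_plates(
    plates: pd.DataFrame,
    alpha: float = 0.05,
    ceilings: dict[str, float] | None = None,
) -> list[DoseResponseFit]:
    """Full plate pipeline: correct, call thresholds, fit Hill curves for
    every receptor construct x compound present."""
    corrected = correct_fluorescence(plates)
    fits = []
    constructs = [
        c for c in corrected["construct"].unique() if c not in (EMPTY_VECTOR,)
    ]
    for construct in sorted(constructs):
        for compound in sorted(
            corrected[corrected["construct"] == construct]["compound"].unique()
        ):
            ceiling = (ceilings or {}).get(compound)
            thr = call_threshold(corrected, construct, compound, alpha, ceiling)
            sel = corrected[
                (corrected["construct"] == construct)
                & (corrected["compound"] == compound)
            ]
            if ceiling is not None:
                sel = sel[sel["conc"] <= ceiling * (1 + 1e-9)]
            means = sel.groupby("conc")["response"].mean()
            fit = fit_hill(
                means.index.to_numpy(),
                means.to_numpy(),
                allele=construct,
                compound=compound,
                threshold_conc=thr,
            )
            fits.append(fit)
    return fits


def curves_to_json(
    fits: list[DoseResponseFit], concentrations, path: str
) -> None:
    """Export fitted dose-response curve points (one record per allele x
    compound) for plotting elsewhere."""
    import json

    concs = [float(c) for c in concentrations]
    records = []
    for f in fits:
        curve = (
            hill(np.array(concs), f.ec50, f.amplitude, f.hill_n).tolist()
            if f.activated
            else [0.0] * len(concs)
        )
        records.append(
            {
                "allele": f.allele,
                "compound": f.compound,
                "ec50": f.ec50 if f.activated else None,
                "amplitude": f.amplitude,
                "hill_n": f.hill_n,
                "threshold_conc": f.threshold_conc,
                "activated": f.activated,
                "conc": concs,
                "response": curve,
            }
        )
    with open(path, "w") as fh:
        json.dump(records, fh, indent=2)


def fits_to_frame(fits: list[DoseResponseFit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "allele": f.allele,
                "compound": f.compound,
                "ec50": f.ec50,
                "amplitude": f.amplitude,
                "hill_n": f.hill_n,
                "threshold_conc": f.threshold_conc,
                "activated": f.activated,
                "rss": f.rss,
                "converged": f.converged,
            }
            for f in fits
        ]
    )
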