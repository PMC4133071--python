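"""Single-reaction amplification-efficiency estimation from raw fluorescence.

Four estimator families, each consuming one raw (baseline-uncorrected)
amplification curve and returning the per-cycle amplification factor E
(1 = no amplification, 2 = perfect doubling; efficiency% = 100*(E-1)):

* :func:`estimate_linreg` — window-of-linearity regression: subtract a
  background line fitted to the pre-lift-off cycles, then take the best
  4-6-cycle window of log(signal) vs cycle; E = exp(slope).
* :func:`estimate_dart` — baseline from a saturation-function fit to early
  cycles, then log-linear regression over the cycles spanning a 10-fold
  signal range around the exponential-phase midpoint (geometric mean of the
  lift-off threshold and the maximal baseline-subtracted signal).
* :func:`estimate_miner` — four-parameter logistic fit to locate the
  exponential phase, then a three-parameter exponential fit on that phase.
* :func:`estimate_lre` — fixed early-cycle baseline, per-cycle efficiency
  ratios E_c = S_c/S_{c-1} regressed linearly against signal; E is the
  intercept, the efficiency extrapolated to zero product.

Estimates with E > 2 are flagged (a chemistry cannot more than double its
product per cycle), and estimates are aggregated per gene with
:func:`aggregate_gene_efficiency`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .simdata import AmpCurve

__all__ = [
    "EfficiencyEstimate",
    "estimate_linreg",
    "estimate_dart",
    "estimate_miner",
    "estimate_lre",
    "EFFICIENCY_METHODS",
    "run_estimator",
    "estimate_curves",
    "aggregate_gene_efficiency",
]


@dataclass
class EfficiencyEstimate:
    """One reaction's amplification-factor estimate with fit diagnostics."""

    method: str
    e: float
    valid: bool = True
    window: tuple | None = None
    r2: float | None = None
    sample: str = ""
    gene: str = ""
    reason: str = ""
    warnings: list = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.valid:
            if not np.isfinite(self.e) or self.e <= 1.0:
                self.valid = False
                self.reason = self.reason or f"estimated E = {self.e:.4g} <= 1"
            elif self.e > 2.0 and "above_doubling" not in self.warnings:
                self.warnings.append("above_doubling")

    @property
    def efficiency_percent(self) -> float:
        return 100.0 * (self.e - 1.0)


def _invalid(method: str, curve: AmpCurve, reason: str) -> EfficiencyEstimate:
    return EfficiencyEstimate(method, np.nan, valid=False, reason=reason,
                              sample=curve.sample, gene=curve.gene)


def _has_exponential_phase(f: np.ndarray, k: float = 10.0) -> bool:
    """Signal must rise well clear of the early-cycle spread."""
    early = f[:8]
    spread = max(float(np.std(early)), 1e-12 * max(abs(float(np.median(early))), 1.0), 1e-300)
    return float(f.max() - np.median(early)) > k * spread


def _window_fit(logs: np.ndarray, cycles: np.ndarray, wmin: int = 4, wmax: int = 6):
    """Best linear fit of log-signal vs cycle over any wmin..wmax-cycle window.

    Returns (slope, r2, (c_start, c_end)) or None if no valid window.
    """
    best = None
    n = len(logs)
    from numpy.lib.stride_tricks import sliding_window_view

    for w in range(wmin, wmax + 1):
        if n < w:
            continue
        yw = sliding_window_view(logs, w)           # (n-w+1, w)
        xw = sliding_window_view(cycles, w)
        ok = np.all(np.isfinite(yw), axis=1)
        if not ok.any():
            continue
        xm = xw.mean(axis=1, keepdims=True)
        ym = yw.mean(axis=1, keepdims=True)
        sxx = np.sum((xw - xm) ** 2, axis=1)
        with np.errstate(invalid="ignore"):
            sxy = np.sum((xw - xm) * (yw - ym), axis=1)
            syy = np.sum((yw - ym) ** 2, axis=1)
            slope = sxy / sxx
            r2 = np.where(syy == 0, 1.0, sxy ** 2 / np.where(syy * sxx == 0, np.inf, syy * sxx))
        r2 = np.where(ok, r2, -np.inf)
        i = int(np.argmax(r2))
        if np.isfinite(r2[i]) and (best is None or r2[i] > best[1]):
            best = (float(slope[i]), float(r2[i]), (int(xw[i, 0]), int(xw[i, -1])))
    return best


def estimate_linreg(curve: AmpCurve) -> EfficiencyEstimate:
    """Window-of-linearity estimate with a pre-lift-off background fit.

    The background (level plus any linear drift) is estimated by a
    straight-line fit to the cycles before the signal rises 10 early-cycle
    SDs above the early median.  On the background-subtracted signal the
    best 4-6-cycle window of log(S) vs cycle is taken inside the band
    (0.02, 0.2) x Smax -- clear of the noise floor, before plateau
    curvature depresses the slope.  E = exp(slope).
    """
    f, cycles = curve.fluorescence, curve.cycles
    if not _has_exponential_phase(f):
        return _invalid("linreg", curve, "no exponential phase")
    early = f[:8]
    thresh = float(np.median(early) + 10.0 * np.std(early))
    above = np.nonzero(f > thresh)[0]
    liftoff = int(above[0]) if len(above) else len(f)
    npre = max(liftoff - 1, 5)
    coef = np.polyfit(cycles[:npre], f[:npre], 1)
    s_all = f - np.polyval(coef, cycles)
    smax = float(s_all.max())
    if smax <= 0:
        return _invalid("linreg", curve, "no positive baseline-subtracted window")

    def fit_band(lower, upper):
        usable = (s_all > lower * smax) & (s_all < upper * smax)
        with np.errstate(invalid="ignore", divide="ignore"):
            logs = np.log(np.where((s_all > 0) & usable, s_all, np.nan))
        fit = _window_fit(logs, cycles)
        # a true amplification window at least quarter-doubles per cycle;
        # flatter "windows" are residual background, not signal
        return fit if fit is not None and fit[0] > np.log(1.25) else None

    warnings = []
    fit = fit_band(0.02, 0.2)
    if fit is None:
        # a 10-fold band can lack a 4-cycle window when E is near 2 and
        # noise bites; widen rather than fail, at a small depletion cost
        fit = fit_band(0.01, 1.0 / 3.0)
        warnings.append("relaxed_window")
    if fit is None:
        return _invalid("linreg", curve, "no positive baseline-subtracted window")
    slope, r2, window = fit
    baseline = float(np.polyval(coef, cycles[:npre]).mean())
    return EfficiencyEstimate("linreg", float(np.exp(slope)), window=window, r2=r2,
                              sample=curve.sample, gene=curve.gene, warnings=warnings,
                              extras={"baseline": baseline,
                                      "baseline_slope": float(coef[0])})


def _saturation(c, a, b, d):
    return a * c / (b + c) + d


def estimate_dart(curve: AmpCurve) -> EfficiencyEstimate:
    """Baseline from a saturation fit to cycles 2-10, regression over a
    10-fold signal range around the exponential-phase midpoint.

    The midpoint combines the maximal baseline-subtracted fluorescence with
    the early-cycle residual SD: lift-off = 10 x early SD, midpoint signal =
    geometric mean of lift-off and maximum.  E = exp(slope) of log(signal)
    vs cycle over cycles whose signal lies within sqrt(10)-fold of the
    midpoint.
    """
    f, cycles = curve.fluorescence, curve.cycles
    early_sel = (cycles >= 2) & (cycles <= 10)
    warnings = []
    try:
        p0 = (float(f[early_sel][-1] - f[early_sel][0]), 5.0, float(f[early_sel][0]))
        popt, _ = optimize.curve_fit(_saturation, cycles[early_sel], f[early_sel],
                                     p0=p0, maxfev=5000)
        baseline = _saturation(cycles, *popt)
    except (RuntimeError, TypeError):
        baseline = np.full_like(f, float(f[early_sel].mean()))
        warnings.append("saturation_fit_failed_mean_fallback")
    s = f - baseline
    early_sd = float(np.std(s[early_sel], ddof=1))
    smax = float(s.max())
    lift = 10.0 * max(early_sd, smax * 1e-6, 1e-300)
    if smax <= lift or not _has_exponential_phase(f):
        return _invalid("dart", curve, "no exponential phase")
    smid = float(np.sqrt(lift * smax))
    lo, hi = smid / np.sqrt(10.0), smid * np.sqrt(10.0)
    sel = (s >= lo) & (s <= hi)
    if sel.sum() < 3:  # widen to nearest usable cycles on the log scale
        pos = s > 0
        order = np.argsort(np.abs(np.log(np.where(pos, s, np.nan) / smid)))
        sel = np.zeros_like(sel)
        sel[order[:4]] = True
        sel &= pos
    if sel.sum() < 3:
        return _invalid("dart", curve, "fewer than 3 usable window cycles")
    x, y = cycles[sel], np.log(s[sel])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid ** 2)) / ss_tot
    if slope <= 0:
        return _invalid("dart", curve, "non-positive slope in window")
    return EfficiencyEstimate("dart", float(np.exp(slope)),
                              window=(int(x[0]), int(x[-1])), r2=r2,
                              sample=curve.sample, gene=curve.gene,
                              warnings=warnings)


def _logistic(c, fb, fmax, c_half, k):
    z = np.clip(-(c - c_half) / k, -700.0, 700.0)  # avoid exp overflow
    return fb + fmax / (1.0 + np.exp(z))


def _exp_model(c, fb, f0, e):
    return fb + f0 * np.power(e, c)


def estimate_miner(curve: AmpCurve) -> EfficiencyEstimate:
    """Four-parameter logistic fit, then exponential fit on the located phase.

    The logistic fit (three deterministic multi-starts) locates the
    exponential phase: signal between 1% and 10% of the fitted plateau
    (extended downward to at least 4 cycles).  A three-parameter exponential
    ``Fb + F0*E^c`` is then fitted to the raw fluorescence of that phase.
    """
    f, cycles = curve.fluorescence, curve.cycles
    if not _has_exponential_phase(f):
        return _invalid("miner", curve, "no exponential phase")
    fb0 = float(np.median(f[:5]))
    amp0 = float(f.max() - f.min())
    c_half0 = float(cycles[np.argmax(np.diff(f, prepend=f[0]))])
    best = None
    for k0 in (1.0, 2.0, 4.0):
        try:
            popt, _ = optimize.curve_fit(
                _logistic, cycles, f, p0=(fb0, amp0, c_half0, k0),
                bounds=([-np.inf, 1e-12, -np.inf, 1e-3],
                        [np.inf, np.inf, np.inf, 50.0]),
                maxfev=10000)
            resid = float(np.sum((f - _logistic(cycles, *popt)) ** 2))
            if best is None or resid < best[1]:
                best = (popt, resid)
        except RuntimeError:
            continue
    if best is None:
        return _invalid("miner", curve, "logistic fit did not converge")
    fb, fmax, c_half, k = best[0]

    s = f - fb
    smax_obs = float(s.max())
    # exponential phase on signal fractions (so fast growth still yields
    # >= 4 cycles): lift-off at 1% of the plateau, ending at 10% — safely
    # before the curvature that the logistic's second-derivative maximum
    # (~21% of plateau) marks
    plateau = fmax if fmax < 3.0 * (smax_obs + 1e-300) else smax_obs
    phase = (s >= 0.01 * plateau) & (s <= 0.10 * plateau)
    if phase.sum() < 4:  # extend downward over the largest below-range signals
        below = np.flatnonzero((s > 0) & (s < 0.01 * plateau))
        for i in reversed(below):
            phase[i] = True
            if phase.sum() >= 4:
                break
    if phase.sum() < 4:
        idx = int(np.argmin(np.abs(s - 0.10 * plateau)))
        phase = np.zeros_like(phase)
        phase[max(idx - 4, 0):idx + 1] = True
    x, y = cycles[phase], f[phase]

    pos = y - fb > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(x[pos], np.log(y[pos] - fb), 1)
        e0_guess = float(np.exp(slope))
        f0_guess = float(np.exp(intercept))
    else:
        e0_guess, f0_guess = 1.9, max(smax_obs * 1e-6, 1e-12)
    try:
        popt, _ = optimize.curve_fit(
            _exp_model, x, y, p0=(fb, f0_guess, min(max(e0_guess, 1.05), 3.0)),
            bounds=([-np.inf, 1e-300, 1.0 + 1e-9], [np.inf, np.inf, 4.0]),
            maxfev=10000, xtol=1e-12, ftol=1e-12)
        e = float(popt[2])
    except (RuntimeError, ValueError):
        if not np.isfinite(e0_guess) or e0_guess <= 1.0:
            return _invalid("miner", curve, "exponential fit failed")
        e = e0_guess
    resid = y - _exp_model(x, *popt) if "popt" in locals() else np.zeros_like(y)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(np.asarray(resid) ** 2)) / ss_tot
    return EfficiencyEstimate("miner", e, window=(int(x[0]), int(x[-1])), r2=r2,
                              sample=curve.sample, gene=curve.gene,
                              extras={"c_half": float(c_half), "k": float(k)})


def estimate_lre(curve: AmpCurve, max_window: int = 8,
                 r2_min: float = 0.99) -> EfficiencyEstimate:
    """Linear regression of per-cycle efficiency on signal; E = intercept.

    Baseline is the mean fluorescence of cycles 6-12.  Per-cycle efficiency
    ratios ``E_c = S_c / S_{c-1}`` decline as product accumulates; over the
    window where this decline is linear in signal, the regression intercept
    extrapolates the efficiency to zero product (the maximal efficiency of
    the sigmoid-derivative formulation).
    """
    f, cycles = curve.fluorescence, curve.cycles
    if not _has_exponential_phase(f):
        return _invalid("lre", curve, "no exponential phase")
    base_sel = (cycles >= 6) & (cycles <= 12)
    b = float(f[base_sel].mean())
    s = f - b
    early_sd = float(np.std(f[base_sel], ddof=1))
    floor = max(3.0 * early_sd, 1e-12 * max(abs(b), 1.0))
    valid = np.zeros(len(s), dtype=bool)
    valid[1:] = (s[1:] > 0) & (s[:-1] > floor)
    if valid.sum() < 4:
        return _invalid("lre", curve, "fewer than 4 usable window cycles")
    ec = np.full(len(s), np.nan)
    ec[valid] = s[valid] / s[np.flatnonzero(valid) - 1]
    # the per-cycle ratio E_c is produced by the product present *before*
    # cycle c, so the regression abscissa is the previous cycle's signal
    xsig = np.full(len(s), np.nan)
    xsig[valid] = s[np.flatnonzero(valid) - 1]

    ds = np.diff(s, prepend=s[0])
    ds[~valid] = -np.inf
    seed = int(np.argmax(ds))
    idx = [seed]
    lo = hi = seed

    def fit(ii):
        x, y = xsig[ii], ec[ii]
        if np.ptp(y) < 1e-6 * max(abs(float(np.mean(y))), 1.0):
            return 0.0, float(np.mean(y)), 1.0
        res = stats.linregress(x, y)
        return float(res.slope), float(res.intercept), float(res.rvalue ** 2)

    while len(idx) < max_window:
        grown = False
        for cand in (lo - 1, hi + 1):
            if 0 <= cand < len(s) and valid[cand] and cand not in idx:
                trial = sorted(idx + [cand])
                if len(trial) < 3 or fit(trial)[2] >= r2_min:
                    idx = trial
                    lo, hi = idx[0], idx[-1]
                    grown = True
        if not grown:
            break
    if len(idx) < 4:
        return _invalid("lre", curve, "fewer than 4 usable window cycles")
    slope, intercept, r2 = fit(idx)
    warnings = [] if slope <= 0 else ["efficiency_not_declining"]
    return EfficiencyEstimate("lre", intercept, window=(int(cycles[idx[0]]), int(cycles[idx[-1]])),
                              r2=r2, sample=curve.sample, gene=curve.gene,
                              warnings=warnings, extras={"slope": slope, "baseline": b})


EFFICIENCY_METHODS = {
    "linreg": estimate_linreg,
    "dart": estimate_dart,
    "miner": estimate_miner,
    "lre": estimate_lre,
}


def run_estimator(name: str, curve: AmpCurve) -> EfficiencyEstimate:
    try:
        fn = EFFICIENCY_METHODS[name]
    except KeyError:
        raise ValueError(f"unknown efficiency method {name!r}; "
                         f"choose from {sorted(EFFICIENCY_METHODS)}") from None
    return fn(curve)


def estimate_curves(curves, methods=None) -> pd.DataFrame:
    """Run estimators over many curves; one row per (curve, method)."""
    methods = list(methods or EFFICIENCY_METHODS)
    rows = []
    for c in curves:
        for m in methods:
            est = run_estimator(m, c)
            rows.append({"sample": c.sample, "gene": c.gene, "method": m,
                         "e": est.e, "valid": est.valid, "r2": est.r2,
                         "reason": est.reason,
                         "flag_above_doubling": "above_doubling" in est.warnings,
                         "true_e0": c.true_e0})
    return pd.DataFrame(rows)


def aggregate_gene_efficiency(estimates: pd.DataFrame):
    """Per-gene mean amplification factor per method + cross-method Pearson r.

    Invalid estimates are excluded (counts reported); genes with no valid
    estimate for a method are dropped from that method's means with a
    warning entry.  Returns ``(gene_means, corr_r, corr_p, excluded)`` where
    ``gene_means`` is genes x methods.
    """
    df = pd.DataFrame(estimates)
    if df["gene"].nunique() < 2 or df["method"].nunique() < 2:
        raise ValueError("need >= 2 genes and >= 2 methods to aggregate")
    excluded = (~df["valid"]).groupby([df["gene"], df["method"]]).sum().rename("n_invalid")
    ok = df[df["valid"]]
    gene_means = ok.pivot_table(index="gene", columns="method", values="e",
                                aggfunc="mean")
    methods = list(gene_means.columns)
    r = pd.DataFrame(np.eye(len(methods)), index=methods, columns=methods)
    p = pd.DataFrame(np.zeros((len(methods), len(methods))), index=methods,
                     columns=methods)
    for a, b in itertools.combinations(methods, 2):
        sub = gene_means[[a, b]].dropna()
        if len(sub) >= 3 and sub[a].std() > 0 and sub[b].std() > 0:
            res = stats.pearsonr(sub[a], sub[b])
            r.loc[a, b] = r.loc[b, a] = res.statistic
            p.loc[a, b] = p.loc[b, a] = res.pvalue
        else:
            r.loc[a, b] = r.loc[b, a] = np.nan
            p.loc[a, b] = p.loc[b, a] = np.nan
    return gene_means, r, p, excluded.reset_index()
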