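"""Deployment summaries and the statistical comparisons used with them.

Covers per-individual foraging-dive summaries (mean +/- SE of depth,
submerged time, transit rates/speeds, breaths and lunges per dive, breathing
rate), hourly day/night event-rate tables, time-at-depth distributions by
diel class, a Wilcoxon rank-sum test with midranks and exact small-sample
enumeration, and (generalized) linear model fits for the three model
families used for power, energy expenditure and breathing rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .tag_io import ParameterError
from .dive_phases import DiveRecord, hourly_rates

__all__ = [
    "dive_summary",
    "time_at_depth",
    "rank_sum_test",
    "FitError",
    "fit_model",
]


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def _mean_se(x: np.ndarray) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        return np.nan, np.nan
    mean = float(np.mean(x))
    se = float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else np.nan
    return mean, se


def dive_summary(
    dives: list[DiveRecord],
    breath_times: np.ndarray | None = None,
    energetics: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Mean +/- SE of foraging-dive characteristics.

    Foraging dives are those with at least one lunge.  Breaths per dive and
    breathing rate use the post-dive surface interval (dive end to next dive
    start, or record end); breathing rate is breaths per minute of that
    interval.  With a single dive the SE is undefined and reported NaN.
    """
    foraging = [d for d in dives if d.n_lunges >= 1]
    if not foraging:
        return pd.DataFrame([{"field": "n_foraging_dives", "mean": 0.0,
                              "se": np.nan}])
    breath_times = (np.asarray(breath_times, dtype=float)
                    if breath_times is not None else np.array([]))
    rows = [("n_foraging_dives", float(len(foraging)), np.nan)]
    fields = {
        "dive_depth_m": [d.max_depth for d in foraging],
        "submerged_time_s": [d.submerged_time for d in foraging],
        "descent_rate_m_s": [d.descent_rate for d in foraging],
        "descent_speed_m_s": [d.descent_speed for d in foraging],
        "ascent_rate_m_s": [d.ascent_rate for d in foraging],
        "ascent_speed_m_s": [d.ascent_speed for d in foraging],
        "lunges_per_dive": [float(d.n_lunges) for d in foraging],
    }
    # post-dive surfacing: breaths and breathing rate
    all_sorted = sorted(dives, key=lambda d: d.t_start)
    nb, rate_min = [], []
    for d in foraging:
        later = [x.t_start for x in all_sorted if x.t_start > d.t_end]
        t_next = min(later) if later else (
            d.t_end + 60.0 if breath_times.size == 0
            else max(breath_times.max() + 1.0, d.t_end + 1.0))
        k = int(((breath_times > d.t_end) & (breath_times <= t_next)).sum())
        d.n_breaths_after = k
        nb.append(float(k))
        dur_min = (t_next - d.t_end) / 60.0
        rate_min.append(k / dur_min if dur_min > 0 else np.nan)
    fields["breaths_per_dive"] = nb
    fields["breathing_rate_per_min"] = rate_min
    if energetics is not None and len(energetics):
        per_dive = energetics.groupby("dive_id")["work"].sum()
        fields["dive_work_j"] = [per_dive.get(d.dive_id, np.nan)
                                 for d in foraging]
    for name, vals in fields.items():
        mean, se = _mean_se(np.asarray(vals, dtype=float))
        rows.append((name, mean, se))
    return pd.DataFrame(rows, columns=["field", "mean", "se"])


def time_at_depth(
    depth: np.ndarray,
    diel: np.ndarray,
    bins: np.ndarray | list[float],
) -> pd.DataFrame:
    """Fraction of time per depth bin and diel class, plus cumulative curve.

    Sample counts proxy time (uniform rate).  The cumulative column is the
    fraction of time at the bin's upper edge or shallower; per class the bin
    fractions sum to 1 and the cumulative curve is non-decreasing, ending
    at 1.  An empty diel class is simply absent from the table.
    """
    depth = np.asarray(depth, dtype=float)
    diel = np.asarray(diel)
    edges = np.asarray(bins, dtype=float)
    if edges.size < 2:
        raise ParameterError("need at least two bin edges")
    rows = []
    for lab in pd.unique(diel):
        z = depth[diel == lab]
        if z.size == 0:
            continue
        z = np.clip(z, edges[0], np.nextafter(edges[-1], -np.inf))
        counts, _ = np.histogram(z, bins=edges)
        frac = counts / counts.sum()
        cum = np.cumsum(frac)
        for k in range(edges.size - 1):
            rows.append({"diel": lab, "bin_lo": edges[k], "bin_hi": edges[k + 1],
                         "fraction": frac[k], "cumulative": cum[k]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Rank-sum test
# ---------------------------------------------------------------------------

def _midranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="stable")
    ranks = np.empty(values.size, dtype=float)
    sorted_vals = values[order]
    i = 0
    while i < values.size:
        j = i
        while j < values.size and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0     # 1-based midrank
        i = j
    return ranks


def rank_sum_test(x, y, exact_max_n: int = 12) -> dict:
    """Wilcoxon rank-sum test of two samples, two-sided.

    ``W`` is the rank sum of the first sample with midranks for ties.  When
    the combined sample size is at most ``exact_max_n`` the p-value comes
    from full enumeration of all C(n, n_x) rank assignments (probability of
    |W - E[W]| at least as large as observed); otherwise from the normal
    approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx == 0 or ny == 0:
        raise ParameterError("both groups must be non-empty")
    ranks = _midranks(np.concatenate([x, y]))
    w = float(ranks[:nx].sum())
    n = nx + ny
    mean_w = nx * (n + 1) / 2.0
    if n <= exact_max_n:
        obs = abs(w - mean_w)
        hits = 0
        for idx in combinations(range(n), nx):
            if abs(ranks[list(idx)].sum() - mean_w) >= obs - 1e-12:
                hits += 1
        p = hits / comb(n, nx)
        method = "exact"
    else:
        # variance with tie correction over the pooled midranks
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = float(np.sum(counts ** 3 - counts)) / (n * (n - 1))
        var_w = nx * ny / 12.0 * ((n + 1) - tie_term)
        if var_w <= 0:
            p = 1.0
        else:
            z = (w - mean_w) / np.sqrt(var_w)
            from scipy.stats import norm
            p = float(2.0 * norm.sf(abs(z)))
        method = "normal"
    return {"W": w, "p": min(p, 1.0), "method": method, "n_x": nx, "n_y": ny}


# ---------------------------------------------------------------------------
# Model fits
# ---------------------------------------------------------------------------

class FitError(RuntimeError):
    """The iteratively reweighted least-squares fit did not converge."""


_FAMILIES = ("gaussian-log-response", "gamma-log-link", "quasipoisson-log-link")


def fit_model(
    response: np.ndarray,
    covariates: np.ndarray | pd.DataFrame,
    family: str,
    add_intercept: bool = True,
    max_iter: int = 100,
) -> dict:
    """Fit one of the three model families used for activity energetics.

    * ``gaussian-log-response`` — ordinary least squares of ``ln(y)`` on the
      covariates (log-transformed power model);
    * ``gamma-log-link`` — Gamma GLM with log link (energy expenditure);
    * ``quasipoisson-log-link`` — Poisson GLM with log link and dispersion
      estimated from the Pearson chi-square (breath counts).

    Returns coefficients, standard errors, dispersion and the design-column
    names.  Deterministic given its inputs.
    """
    if family not in _FAMILIES:
        raise ParameterError(f"family must be one of {_FAMILIES}")
    y = np.asarray(response, dtype=float)
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        x = covariates.to_numpy(dtype=float)
    else:
        x = np.asarray(covariates, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        names = [f"x{i}" for i in range(x.shape[1])]
    if add_intercept:
        x = np.column_stack([np.ones(y.size), x])
        names = ["intercept"] + names
    if y.size <= x.shape[1]:
        raise ParameterError("need more observations than coefficients")
    if family in ("gaussian-log-response", "gamma-log-link") and np.any(y <= 0):
        raise ParameterError(f"{family} requires strictly positive responses")

    if family == "gaussian-log-response":
        res = sm.OLS(np.log(y), x).fit()
        dispersion = float(res.scale)
    else:
        if family == "gamma-log-link":
            fam = sm.families.Gamma(link=sm.families.links.Log())
        else:
            fam = sm.families.Poisson(link=sm.families.links.Log())
        model = sm.GLM(y, x, family=fam)
        try:
            res = model.fit(maxiter=max_iter)
        except Exception as exc:               # singular / failed IRLS
            raise FitError(f"IRLS failed: {exc}") from exc
        if not getattr(res, "converged", True):
            # on noiseless data the deviance criterion can chatter at machine
            # precision while the coefficients are pinned; accept stable params
            hist = getattr(res, "fit_history", {}).get("params", [])
            stable = (len(hist) >= 2
                      and np.all(np.isfinite(hist[-1]))
                      and np.allclose(hist[-1], hist[-2], rtol=0, atol=1e-10))
            if not stable:
                dev = getattr(res, "fit_history", {}).get("deviance", [])[-3:]
                raise FitError(
                    f"IRLS did not converge in {max_iter} iterations "
                    f"(last deviances: {dev})")
        dispersion = float(res.scale)
    bse = np.asarray(res.bse, dtype=float)
    if family == "quasipoisson-log-link":
        # quasi-likelihood: Poisson point estimates, Pearson-X2 dispersion
        # inflating the standard errors
        df = max(int(res.df_resid), 1)
        dispersion = float(res.pearson_chi2) / df
        bse = bse * np.sqrt(max(dispersion, 0.0))
    return {
        "coefficients": dict(zip(names, np.asarray(res.params, dtype=float))),
        "standard_errors": dict(zip(names, bse)),
        "dispersion": dispersion,
        "family": family,
        "n": int(y.size),
    }
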