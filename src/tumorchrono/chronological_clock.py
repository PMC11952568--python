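"""Chronological timing from clock-like CpG>TpG mutations.

The clock model assumes CpG>TpG mutations in an NpCpG context accumulate at
a constant rate mu per year per diploid genome before the MRCA of the tumor
and at a * mu afterwards.  Burdens are adjusted for copy number (scaling to
a diploid genome via the length-weighted mean autosomal copy number) and for
intratumor heterogeneity (subclonal mutations weighted by their CCF), so the
adjusted pre-/post-MRCA counts are directly proportional to elapsed years.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .clonal_architecture import TimedMutation, mean_autosomal_cn
from .core_io import AUTOSOMES, CNSegment, SampleProfile

CLONAL_CLASSES = ("early_clonal", "late_clonal", "clonal_unspecified")


@dataclass
class ClockEstimate:
    """Adjusted clock burdens and the chronology they imply for one tumor."""

    sample_id: str
    b_clonal: float        # adjusted pre-MRCA clock count
    b_subclonal: float     # adjusted post-MRCA clock count
    mu: Optional[float]    # cohort-calibrated rate, if available
    accel: float
    mrca_age: float
    latency: float
    ci_low: float
    ci_high: float
    clamped: bool = False


def clock_burden(
    timed: Sequence[TimedMutation],
    segments: Sequence[CNSegment],
) -> tuple[float, float]:
    """Copy-number and ITH-adjusted clock burdens (pre-MRCA, post-MRCA).

    Clonal clock mutations contribute their multiplicity (a mutation on m
    copies marks m copies' worth of mutation time), subclonal ones their CCF;
    both are scaled by 2 / psi_bar with psi_bar the length-weighted mean
    autosomal total copy number.  Sex-chromosome mutations are excluded.
    """
    psi_bar = mean_autosomal_cn(segments)
    if psi_bar <= 0:
        raise ValueError("mean autosomal copy number must be positive")
    scale = 2.0 / psi_bar
    b_clonal = 0.0
    b_sub = 0.0
    for tm in timed:
        if not tm.mutation.is_clock or tm.mutation.chrom not in AUTOSOMES:
            continue
        if tm.clonality in CLONAL_CLASSES:
            b_clonal += tm.multiplicity * scale
        elif tm.clonality == "subclonal":
            b_sub += tm.ccf * scale
    return b_clonal, b_sub


# ---------------------------------------------------------------------------
# Cohort rate calibration


@dataclass
class RateCalibration:
    mu_global: float
    se_global: float
    sigma2: float              # residual variance
    tau2: float                # between-group slope variance
    groups: pd.DataFrame       # per-group raw and shrunken slopes


def calibrate_rate(
    burdens: Sequence[float],
    ages: Sequence[float],
    groups: Sequence[str],
    min_group: int = 10,
    max_iter: int = 200,
) -> RateCalibration:
    """Per-group clock rates mu_g with partial pooling toward a global mu.

    A random-slope model through the origin: burden_i = mu_g * age_i + eps,
    mu_g ~ N(mu, tau^2), fitted by empirical Bayes.  Group slopes are
    estimated by through-origin least squares and shrunk toward the global
    mean according to their sampling variance; groups smaller than
    ``min_group`` contribute to the global fit only.  A non-positive fitted
    slope falls back to the pooled global slope with a warning.
    """
    b = np.asarray(burdens, float)
    x = np.asarray(ages, float)
    g = np.asarray(groups)
    if np.any(x <= 0):
        raise ValueError("ages must be positive for a through-origin fit")
    sxx_all = float(np.sum(x * x))
    mu_pooled = float(np.sum(x * b) / sxx_all)

    names = [name for name in pd.unique(g) if np.sum(g == name) >= min_group]
    if not names:
        resid = b - mu_pooled * x
        sigma2 = float(np.sum(resid**2) / max(len(b) - 1, 1))
        se = float(np.sqrt(sigma2 / sxx_all))
        empty = pd.DataFrame(
            columns=["group", "n", "slope", "se", "slope_shrunk", "se_shrunk"])
        return RateCalibration(mu_pooled, se, sigma2, 0.0, empty)

    slopes, sxx, ns, rss, dfs = [], [], [], 0.0, 0
    for name in names:
        mask = g == name
        sxx_g = float(np.sum(x[mask] ** 2))
        s = float(np.sum(x[mask] * b[mask]) / sxx_g)
        slopes.append(s)
        sxx.append(sxx_g)
        ns.append(int(mask.sum()))
        rss += float(np.sum((b[mask] - s * x[mask]) ** 2))
        dfs += int(mask.sum()) - 1
    slopes = np.array(slopes)
    sxx = np.array(sxx)
    sigma2 = rss / max(dfs, 1)
    v = sigma2 / sxx                      # sampling variance of each slope

    if sigma2 == 0.0:                     # exact interpolation, no shrinkage
        mu = float(np.mean(slopes))
        post, post_se, tau2 = slopes.copy(), np.zeros_like(slopes), 0.0
    else:
        tau2 = max(float(np.var(slopes)) - float(np.mean(v)), 0.0)
        mu = float(np.mean(slopes))
        for _ in range(max_iter):
            w = 1.0 / (v + tau2)
            mu_new = float(np.sum(w * slopes) / np.sum(w))
            tau2_new = max(
                float(np.sum(w**2 * ((slopes - mu_new) ** 2 - v)) / np.sum(w**2)),
                0.0,
            )
            if abs(mu_new - mu) < 1e-12 and abs(tau2_new - tau2) < 1e-12:
                mu, tau2 = mu_new, tau2_new
                break
            mu, tau2 = mu_new, tau2_new
        if tau2 == 0.0:
            post = np.full_like(slopes, mu)
            post_se = np.sqrt(v * 0.0)
        else:
            prec = 1.0 / v + 1.0 / tau2
            post = (slopes / v + mu / tau2) / prec
            post_se = np.sqrt(1.0 / prec)

    if mu <= 0:
        warnings.warn("non-positive fitted rate; falling back to pooled slope")
        mu = mu_pooled
    w = 1.0 / (v + tau2) if sigma2 > 0 else np.full(len(slopes), np.inf)
    se_global = float(np.sqrt(1.0 / np.sum(w))) if sigma2 > 0 else 0.0
    table = pd.DataFrame({
        "group": names, "n": ns, "slope": slopes,
        "se": np.sqrt(v), "slope_shrunk": post, "se_shrunk": post_se,
    })
    return RateCalibration(mu, se_global, float(sigma2), float(tau2), table)


# ---------------------------------------------------------------------------
# MRCA and latency


def mrca_and_latency(
    sample_id: str,
    age: float,
    b_clonal: float,
    b_subclonal: float,
    accel: float = 1.0,
    mu: Optional[float] = None,
    n_boot: int = 200,
    seed: int = 0,
) -> ClockEstimate:
    """MRCA age and tumor latency from adjusted clock burdens.

    Under a rate mu before the MRCA and a * mu afterwards, the burdens obey
    N_pre / N_post = t / (a * (A - t)), giving

        t_MRCA = A * a * N_pre / (N_post + a * N_pre)

    and latency = A - t_MRCA (zero when no subclonal clock mutations exist:
    the MRCA is at diagnosis).  The CI propagates Poisson uncertainty in both
    burdens by resampling.
    """
    if accel <= 0:
        raise ValueError("accel must be > 0")
    if b_clonal < 0 or b_subclonal < 0:
        raise ValueError("burdens must be >= 0")
    if b_clonal + b_subclonal == 0:
        raise ValueError("need at least one clock mutation")

    def solve(pre: float, post: float) -> float:
        if pre + post == 0:
            return age
        t = age * accel * pre / (post + accel * pre)
        return float(np.clip(t, 0.0, age))

    t = solve(b_clonal, b_subclonal)
    clamped = not (0.0 < t < age) and b_subclonal > 0
    rng = np.random.default_rng(seed)
    pre_star = rng.poisson(b_clonal, size=n_boot)
    post_star = rng.poisson(b_subclonal, size=n_boot)
    lat_star = np.array([age - solve(p, q) for p, q in zip(pre_star, post_star)])
    lo, hi = np.percentile(lat_star, [2.5, 97.5])
    return ClockEstimate(
        sample_id=sample_id, b_clonal=b_clonal, b_subclonal=b_subclonal,
        mu=mu, accel=accel, mrca_age=t, latency=age - t,
        ci_low=float(lo), ci_high=float(hi), clamped=clamped,
    )


def cohort_latency(
    profiles: Sequence[SampleProfile],
    burdens: Sequence[tuple[float, float]],
    accel: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    rows = []
    for i, (p, (b_c, b_s)) in enumerate(zip(profiles, burdens)):
        est = mrca_and_latency(
            p.sample_id, p.age_dx, b_c, b_s, accel=accel, seed=seed + i)
        rows.append({
            "sample_id": est.sample_id, "age_dx": p.age_dx,
            "b_clonal": est.b_clonal, "b_subclonal": est.b_subclonal,
            "mrca_age": est.mrca_age, "latency": est.latency,
            "ci_low": est.ci_low, "ci_high": est.ci_high, "accel": accel,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Latency-covariate association


@dataclass
class AssociationResult:
    ranksum: pd.DataFrame     # per binary feature: two-group test + FDR
    ols: pd.DataFrame         # multivariable linear model coefficients


def associate_latency(
    latencies: Sequence[float], covariates: pd.DataFrame
) -> AssociationResult:
    """Associate tumor latency with covariates.

    Binary features get a two-sided rank-sum test with BH correction across
    features; all features enter one multivariable ordinary linear model with
    95% coefficient CIs.  Constant covariates are dropped with a warning.
    """
    y = np.asarray(latencies, float)
    cov = covariates.copy()
    for col in list(cov.columns):
        if cov[col].nunique() <= 1:
            warnings.warn(f"covariate {col} is constant; dropped")
            cov = cov.drop(columns=col)
    rows = []
    for col in cov.columns:
        vals = cov[col]
        if vals.nunique() == 2:
            lo, hi = sorted(vals.unique())
            y0, y1 = y[vals == lo], y[vals == hi]
            if len(np.unique(y)) == 1:
                stat, p = np.nan, 1.0
            else:
                stat, p = mannwhitneyu(y1, y0, alternative="two-sided")
            rows.append({
                "feature": col, "n_high": len(y1), "n_low": len(y0),
                "median_diff": float(np.median(y1) - np.median(y0)),
                "statistic": stat, "p": p,
            })
    ranksum = pd.DataFrame(rows)
    if len(ranksum):
        ranksum["fdr"] = multipletests(ranksum["p"], method="fdr_bh")[1]

    X = sm.add_constant(cov.astype(float), has_constant="add")
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int()
    ols = pd.DataFrame({
        "feature": X.columns, "coef": fit.params.to_numpy(),
        "se": fit.bse.to_numpy(), "p": fit.pvalues.to_numpy(),
        "ci_low": ci[0].to_numpy(), "ci_high": ci[1].to_numpy(),
    })
    return AssociationResult(ranksum, ols)
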