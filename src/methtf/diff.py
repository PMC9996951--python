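"""Differential methylation: beta -> M transformation, empirical-Bayes
moderated t-testing per CpG, FDR adjustment and hypo/hyper classification.

The testing model
-----------------
Beta values (methylated fraction, in [0, 1]) are logit-transformed to
M-values, M = log2(beta / (1 - beta)), which are approximately
homoscedastic and suit linear modelling.  Each probe is tested for a
condition effect with a moderated t-statistic: the per-probe residual
variance ``s_g^2`` (df ``d_g``) is shrunk toward a pooled prior
``s_0^2`` with prior degrees of freedom ``d_0``,

    s_tilde_g^2 = (d_0 s_0^2 + d_g s_g^2) / (d_0 + d_g),
    t_g = effect_g / (s_tilde_g * c),    t_g ~ t(d_0 + d_g) under the null,

with (d_0, s_0^2) estimated by method of moments on the log residual
variances (the scaled-F / log-chi-square moment equations, solved with a
Newton trigamma inverse).  With three donor pairs per condition this
borrowing of strength across probes is what makes per-CpG testing viable.

The paired (donor-blocked) design is the default: each donor contributes
one reference and one treatment sample, and the test is on the per-donor
M-value differences.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .formats import SampleSheet

logger = logging.getLogger(__name__)

#: cap representing an effectively infinite prior df
PRIOR_DF_CAP = 1e6

_P_FLOOR = 1e-300


def beta_to_m(beta, clip_epsilon: float = 1e-3):
    """M = log2(beta' / (1 - beta')) with beta' clipped to [eps, 1-eps].

    Clipping keeps array-typical beta values of exactly 0 or 1 finite.
    Accepts scalars or arrays; beta outside [0, 1] is a hard error.
    """
    if not 0.0 < clip_epsilon < 0.5:
        raise ValueError(f"clip_epsilon must be in (0, 0.5), got {clip_epsilon}")
    b = np.asarray(beta, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any((b < 0) | (b > 1)):
            raise ValueError("beta values must lie in [0, 1]")
    bc = np.clip(b, clip_epsilon, 1.0 - clip_epsilon)
    m = np.log2(bc / (1.0 - bc))
    m = np.where(np.isnan(b), np.nan, m)
    return float(m) if np.isscalar(beta) else m


def m_to_beta(m):
    """Inverse of :func:`beta_to_m` (ignoring the clip): 2^M / (1 + 2^M)."""
    m = np.asarray(m, dtype=float)
    b = np.exp2(m) / (1.0 + np.exp2(m))
    return float(b) if b.ndim == 0 else b


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return PRIOR_DF_CAP
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Method-of-moments fit of (prior df d0, prior variance s0^2).

    Moment equations on z = log(s^2): under the scaled-F model,
    E[z] = log(s0^2) + digamma(d0/2) - log(d0/2) + digamma(d/2) - log(d/2)
    and Var[z] = trigamma(d0/2) + trigamma(d/2); the excess variance of
    the observed z over the chi-square part identifies d0.
    Zero or non-finite variances are excluded from the fit.
    """
    ok = np.isfinite(s2) & (s2 > 0) & (df >= 1)
    if ok.sum() < 2:
        # too little information to estimate a prior: no shrinkage
        return 0.0, float(np.nanmean(s2[ok])) if ok.any() else 1.0
    s2 = s2[ok]
    df = df[ok].astype(float)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    n = len(e)
    evar = ((e - emean) ** 2).sum() / (n - 1)
    evar -= np.mean(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        d0 = min(d0, PRIOR_DF_CAP)
        s0_2 = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = PRIOR_DF_CAP
        s0_2 = np.exp(emean)
    return float(d0), float(s0_2)


def _t_and_p(effect: np.ndarray, se: np.ndarray, df: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """t = effect / se with the zero-variance convention: when se == 0,
    t is 0 for a zero effect (p = 1) and +/-inf otherwise (p -> floor)."""
    t = np.zeros_like(effect)
    with np.errstate(divide="ignore", invalid="ignore"):
        nz = se > 0
        t[nz] = effect[nz] / se[nz]
        t[~nz & (effect != 0)] = np.sign(effect[~nz & (effect != 0)]) * np.inf
    p = np.ones_like(t)
    finite = np.isfinite(t) & (df >= 1)
    p[finite] = 2.0 * stats.t.sf(np.abs(t[finite]), df[finite])
    p[np.isinf(t)] = _P_FLOOR
    return t, np.clip(p, _P_FLOOR, 1.0)


def moderated_diff_test(
    m: pd.DataFrame,
    sheet: SampleSheet,
    paired: bool = True,
    shrink: bool = True,
) -> pd.DataFrame:
    """Per-probe moderated t-test of treatment vs reference M-values.

    Parameters
    ----------
    m : probes x samples M-value matrix (columns = sample ids).
    sheet : sample-to-condition (and donor) assignment.
    paired : donor-blocked design (test on per-donor differences) when
        True; two-sample pooled-variance design otherwise.
    shrink : apply empirical-Bayes variance shrinkage.  With
        ``shrink=False`` the statistic reduces exactly to the ordinary
        (paired or two-sample) t-test.

    Returns a DataFrame indexed like ``m`` with columns ``delta_m``, ``t``,
    ``p``, ``df_residual``, ``low_n`` (True where fewer than 2 usable
    values per condition forced p = 1).
    """
    ref_cols = sheet.samples("reference")
    trt_cols = sheet.samples("treatment")
    if len(ref_cols) < 2 or len(trt_cols) < 2:
        raise ValueError("need at least 2 samples per condition")
    missing = (set(ref_cols) | set(trt_cols)) - set(m.columns)
    if missing:
        raise ValueError(f"samples absent from matrix: {sorted(missing)}")

    if paired:
        pairs = sheet.donor_pairs()
        R = m[[r for _, r, _ in pairs]].to_numpy(dtype=float)
        T = m[[t for _, _, t in pairs]].to_numpy(dtype=float)
        D = T - R
        n = np.sum(np.isfinite(D), axis=1)
        with np.errstate(invalid="ignore"):
            effect = np.where(n > 0, np.nansum(D, axis=1) / np.maximum(n, 1), np.nan)
            dev = np.where(np.isfinite(D), D - effect[:, None], 0.0)
            s2 = np.where(n > 1, (dev**2).sum(axis=1) / np.maximum(n - 1, 1), np.nan)
        df = (n - 1).astype(float)
        c2 = np.where(n > 0, 1.0 / np.maximum(n, 1), np.nan)
        low_n = n < 2
    else:
        R = m[ref_cols].to_numpy(dtype=float)
        T = m[trt_cols].to_numpy(dtype=float)
        n1 = np.sum(np.isfinite(R), axis=1)
        n2 = np.sum(np.isfinite(T), axis=1)
        with np.errstate(invalid="ignore"):
            m1 = np.where(n1 > 0, np.nansum(R, axis=1) / np.maximum(n1, 1), np.nan)
            m2 = np.where(n2 > 0, np.nansum(T, axis=1) / np.maximum(n2, 1), np.nan)
            v1 = np.nansum(np.where(np.isfinite(R), (R - m1[:, None]) ** 2, 0.0), axis=1)
            v2 = np.nansum(np.where(np.isfinite(T), (T - m2[:, None]) ** 2, 0.0), axis=1)
        effect = m2 - m1
        df = (n1 + n2 - 2).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            s2 = np.where(df > 0, (v1 + v2) / np.maximum(df, 1), np.nan)
            c2 = 1.0 / np.maximum(n1, 1) + 1.0 / np.maximum(n2, 1)
        low_n = (n1 < 2) | (n2 < 2)

    usable = ~low_n
    flagged_partial = usable & (
        np.sum(~np.isfinite(np.c_[R, T]), axis=1) > 0
    )

    if shrink:
        d0, s0_2 = fit_variance_prior(s2[usable], df[usable])
        logger.info(
            "moderated_diff_test: prior df=%.4g, prior var=%.4g", d0, s0_2
        )
        with np.errstate(invalid="ignore"):
            s2_post = np.where(
                usable, (d0 * s0_2 + df * np.nan_to_num(s2)) / (d0 + df), np.nan
            )
            df_total = np.where(usable, df + min(d0, PRIOR_DF_CAP), np.nan)
    else:
        s2_post = s2
        df_total = df

    se = np.sqrt(np.maximum(s2_post, 0.0) * c2)
    t = np.zeros(len(m))
    p = np.ones(len(m))
    eff_u = np.nan_to_num(effect)
    tu, pu = _t_and_p(eff_u[usable], se[usable], df_total[usable])
    t[usable] = tu
    p[usable] = pu
    # probes with < 2 usable values per condition: untestable, p = 1
    t[low_n] = 0.0
    p[low_n] = 1.0

    out = pd.DataFrame(
        {
            "delta_m": effect,
            "t": t,
            "p": p,
            "df_residual": df,
            "low_n": low_n,
            "partial_data": flagged_partial,
        },
        index=m.index,
    )
    return out


def bh_adjust(p: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order kept)."""
    p = np.asarray(list(p), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_cpgs(
    table: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.Index, pd.Index]:
    """Split significant probes into hypo- and hyper-methylated sets.

    Adds/overwrites a ``class`` column in ``table`` (values ``hypo``,
    ``hyper``, ``ns``): significant means adj_p <= alpha; the sign of
    ``delta_m`` (treatment - reference) gives the direction.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if "adj_p" not in table.columns:
        raise ValueError("table lacks 'adj_p'; run bh_adjust first")
    sig = table["adj_p"] <= alpha
    hypo = sig & (table["delta_m"] < 0)
    hyper = sig & (table["delta_m"] > 0)
    cls = np.where(hypo, "hypo", np.where(hyper, "hyper", "ns"))
    table["class"] = cls
    hypo_ids = table.index[hypo]
    hyper_ids = table.index[hyper]
    logger.info(
        "classify_cpgs: %d significant (%d hypo, %d hyper) of %d at alpha=%g",
        int(sig.sum()), len(hypo_ids), len(hyper_ids), len(table), alpha,
    )
    return hypo_ids, hyper_ids


def differential_methylation(
    beta: pd.DataFrame,
    sheet: SampleSheet,
    paired: bool = True,
    alpha: float = 0.05,
    clip_epsilon: float = 1e-3,
    shrink: bool = True,
    adjust: str = "fdr_bh",
) -> pd.DataFrame:
    """Full differential-methylation call: beta -> M, moderated test,
    multiple-testing adjustment, hypo/hyper classification.

    Returns a table with columns probe_id (index), delta_beta, delta_m,
    t, p, adj_p, class.
    """
    with np.errstate(invalid="ignore"):
        if np.any((beta.to_numpy(dtype=float) < 0) | (beta.to_numpy(dtype=float) > 1)):
            raise ValueError("beta matrix contains values outside [0, 1]")
    m = pd.DataFrame(
        beta_to_m(beta.to_numpy(dtype=float), clip_epsilon),
        index=beta.index,
        columns=beta.columns,
    )
    table = moderated_diff_test(m, sheet, paired=paired, shrink=shrink)
    ref_mean = beta[sheet.samples("reference")].mean(axis=1)
    trt_mean = beta[sheet.samples("treatment")].mean(axis=1)
    table.insert(0, "delta_beta", trt_mean - ref_mean)
    if adjust == "fdr_bh":
        table["adj_p"] = bh_adjust(table["p"])
    else:
        table["adj_p"] = multipletests(table["p"].to_numpy(), method=adjust)[1]
    classify_cpgs(table, alpha=alpha)
    return table
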