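"""Differential expression for the 3-genotype × 2-treatment ACC design.

The pipeline mirrors the standard count-based workflow: a low-count filter,
trimmed-mean-of-M-values (TMM) normalization factors, log2 counts per
million, a genewise cell-means linear model over the six genotype ×
treatment cells, empirical-Bayes shrinkage of the residual variances
toward a scaled inverse-chi-square prior, moderated t-statistics, and
Benjamini–Hochberg q-values per genotype contrast.

An "ethylene-responsive" gene is one whose wild-type ACC response is at
least two-fold (|log2FC| >= 1) at q < 0.01 AND differs by at least
two-fold from the response of BOTH ethylene-insensitive genotypes — the
insensitive lines act as the specificity control for genuine ethylene
signaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import rankdata, t as t_dist
from statsmodels.stats.multitest import multipletests

from .containers import GENOTYPES, TREATMENTS, CountExperiment

_D0_CAP = 1e9  # "infinite" prior df when the s^2 spread is pure chi-square noise


def filter_low_counts(
    exp: CountExperiment, min_count: int = 10, mode: str = "all_libraries"
) -> CountExperiment:
    """Drop weakly covered genes.

    ``mode="all_libraries"`` (default) removes a gene if *any* library has
    fewer than ``min_count`` reads; ``mode="any_library_passes"`` keeps a
    gene if at least one library reaches ``min_count``.
    """
    if mode == "all_libraries":
        keep = (exp.counts >= min_count).all(axis=1)
    elif mode == "any_library_passes":
        keep = (exp.counts >= min_count).any(axis=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return CountExperiment(exp.counts.loc[keep], exp.library_meta)


def _upper_quartile(counts: np.ndarray, libsize: np.ndarray) -> np.ndarray:
    return np.quantile(counts / libsize, 0.75, axis=0)


def normalization_factors(
    exp: CountExperiment,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
    weighted: bool = True,
) -> pd.Series:
    """TMM normalization factors, geometric mean 1.

    The reference library is the one whose upper-quartile count fraction is
    closest to the mean across libraries.  For each library, gene-wise
    log2-ratios (M) and average log2-abundances (A) against the reference
    are doubly trimmed (30% on M, 5% on A) and the factor is
    ``2**weighted-mean(M)`` with precision (inverse asymptotic variance)
    weights.
    """
    counts = exp.counts.to_numpy(dtype=float)
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 libraries")
    libsize = counts.sum(axis=0)
    if (libsize == 0).any():
        raise ValueError("library with all-zero counts")

    f75 = _upper_quartile(counts, libsize)
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    ref_counts, ref_size = counts[:, ref], libsize[ref]

    factors = np.ones(counts.shape[1])
    for k in range(counts.shape[1]):
        obs, n_obs = counts[:, k], libsize[k]
        ok = (obs > 0) & (ref_counts > 0)
        if not ok.any():
            continue
        o, r = obs[ok], ref_counts[ok]
        logR = np.log2((o / n_obs) / (r / ref_size))
        absE = 0.5 * np.log2((o / n_obs) * (r / ref_size))
        v = (n_obs - o) / (n_obs * o) + (ref_size - r) / (ref_size * r)
        if np.max(np.abs(logR)) < 1e-6:
            continue
        n = len(logR)
        loL, hiL = np.floor(n * logratio_trim) + 1, n - np.floor(n * logratio_trim)
        loS, hiS = np.floor(n * sum_trim) + 1, n - np.floor(n * sum_trim)
        rR = rankdata(logR)
        rS = rankdata(absE)
        keep = (rR >= loL) & (rR <= hiL) & (rS >= loS) & (rS <= hiS)
        if not keep.any():
            continue
        w = 1.0 / v[keep] if weighted else np.ones(keep.sum())
        factors[k] = 2.0 ** (np.sum(w * logR[keep]) / np.sum(w))

    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=exp.counts.columns, name="norm_factor")


def log_cpm(
    exp: CountExperiment, factors: pd.Series | None = None, prior: float = 0.5
) -> pd.DataFrame:
    """log2 counts-per-million with a small prior count.

    ``log2((count + prior) / (libsize * factor + 2 * prior) * 1e6)`` —
    the offset keeps zero counts finite and the doubled prior in the
    denominator keeps the transform scale-invariant.
    """
    counts = exp.counts.to_numpy(dtype=float)
    libsize = counts.sum(axis=0)
    f = (
        factors.reindex(exp.counts.columns).to_numpy(dtype=float)
        if factors is not None
        else np.ones(counts.shape[1])
    )
    if (f <= 0).any():
        raise ValueError("normalization factors must be positive")
    eff = libsize * f
    out = np.log2((counts + prior) / (eff + 2 * prior)[None, :] * 1e6)
    return pd.DataFrame(out, index=exp.counts.index, columns=exp.counts.columns)


@dataclass
class GenewiseFit:
    """Cell-means OLS fit of log-CPM over genotype × treatment cells."""

    coefficients: pd.DataFrame  # genes × 6 cells ("genotype:treatment")
    log2fc: pd.DataFrame  # genes × genotypes, ACC - mock contrast
    s2: pd.Series  # residual variance per gene
    df: int  # residual degrees of freedom
    se_unit: pd.Series  # per genotype: sqrt(1/n_ACC + 1/n_mock)


def fit_genewise_model(logcpm: pd.DataFrame, library_meta: pd.DataFrame) -> GenewiseFit:
    """Fit the six cell means per gene by OLS and form ACC - mock
    contrasts per genotype (log2 units)."""
    cells = [f"{g}:{t}" for g in GENOTYPES for t in TREATMENTS]
    lib_cell = (
        library_meta["genotype"].astype(str) + ":" + library_meta["treatment"].astype(str)
    )
    counts_per_cell = lib_cell.value_counts()
    missing = [c for c in cells if counts_per_cell.get(c, 0) == 0]
    if missing:
        raise ValueError(f"empty design cell(s): {missing}")

    X = np.zeros((len(lib_cell), len(cells)))
    for j, c in enumerate(cells):
        X[:, j] = (lib_cell == c).to_numpy(dtype=float)
    Y = logcpm.to_numpy(dtype=float).T  # libraries × genes

    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    df = X.shape[0] - len(cells)
    if df < 1:
        raise ValueError("no residual degrees of freedom (need replicates)")
    s2 = (resid**2).sum(axis=0) / df

    coef = pd.DataFrame(beta.T, index=logcpm.index, columns=cells)
    lfc = pd.DataFrame(
        {g: coef[f"{g}:ACC"] - coef[f"{g}:mock"] for g in GENOTYPES},
        index=logcpm.index,
    )
    se_unit = pd.Series(
        {
            g: float(
                np.sqrt(1.0 / counts_per_cell[f"{g}:ACC"] + 1.0 / counts_per_cell[f"{g}:mock"])
            )
            for g in GENOTYPES
        }
    )
    return GenewiseFit(coef, lfc, pd.Series(s2, index=logcpm.index), df, se_unit)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        return _D0_CAP
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


@dataclass
class Moderation:
    """Scaled inverse-chi-square prior fitted to genewise variances."""

    d0: float  # prior degrees of freedom (capped when effectively infinite)
    s02: float  # prior variance
    s2_post: pd.Series  # posterior (shrunken) variances


def moderate_variances(s2: pd.Series, df: int, prior_df: float | None = None) -> Moderation:
    """Fit the variance prior by method of moments on log s² and shrink.

    The sample variances are modeled as ``s² | σ² ~ σ² χ²_d / d`` with
    ``σ² ~ s0² d0 / χ²_{d0}``; matching the mean and variance of
    ``log s²`` (corrected by di/trigamma terms) yields ``d0`` and ``s0²``.
    The posterior variance is ``(d0 s0² + d s²) / (d0 + d)``.

    ``prior_df`` overrides the fitted ``d0`` (0 recovers ordinary t).
    """
    vals = s2.to_numpy(dtype=float)
    if len(vals) < 2:
        raise ValueError("need at least 2 genes")
    if (vals <= 0).all():
        raise ValueError("all residual variances are zero")

    pos = vals[vals > 0]
    z = np.log(pos)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    evar = np.var(e, ddof=1) - polygamma(1, df / 2.0)

    if prior_df is not None:
        d0 = float(prior_df)
        if d0 == 0:
            return Moderation(0.0, float("nan"), s2.copy())
    elif evar > 0:
        d0 = 2.0 * _trigamma_inverse(float(evar))
    else:
        d0 = _D0_CAP
    d0 = min(d0, _D0_CAP)
    if d0 >= _D0_CAP:
        # no excess spread beyond chi-square sampling noise: the prior is
        # the common variance itself (geometric mean, no digamma offset)
        s02 = float(np.exp(np.mean(z)))
    else:
        s02 = float(np.exp(np.mean(e) + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    post = (d0 * s02 + df * vals) / (d0 + df)
    return Moderation(d0, s02, pd.Series(post, index=s2.index))


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr
    if ((arr < 0) | (arr > 1)).any() or not np.isfinite(arr).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def response_table(
    exp: CountExperiment,
    min_count: int = 10,
    filter_mode: str = "all_libraries",
    prior: float = 0.5,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Run the full DE pipeline and return the per-gene response table.

    Columns: ``log2fc_<genotype>``, ``t_<genotype>``, ``p_<genotype>``,
    ``q_<genotype>`` for each genotype's ACC - mock contrast, plus the
    ``responsive`` flag from :func:`call_ethylene_responsive`.
    """
    filtered = filter_low_counts(exp, min_count=min_count, mode=filter_mode)
    if len(filtered.genes) == 0:
        raise ValueError("no genes left after the low-count filter")
    factors = normalization_factors(filtered)
    lc = log_cpm(filtered, factors, prior=prior)
    fit = fit_genewise_model(lc, filtered.library_meta)
    mod = moderate_variances(fit.s2, fit.df, prior_df=prior_df)
    total_df = (mod.d0 if mod.d0 > 0 else 0.0) + fit.df
    total_df = min(total_df, _D0_CAP)

    table = pd.DataFrame(index=lc.index)
    s_post = np.sqrt(mod.s2_post.to_numpy(dtype=float))
    for g in GENOTYPES:
        lfc = fit.log2fc[g].to_numpy(dtype=float)
        tstat = lfc / (s_post * fit.se_unit[g])
        pval = 2.0 * t_dist.sf(np.abs(tstat), total_df)
        table[f"log2fc_{g}"] = lfc
        table[f"t_{g}"] = tstat
        table[f"p_{g}"] = pval
        table[f"q_{g}"] = bh_adjust(pval)
    table["responsive"] = call_ethylene_responsive(table)
    return table


def call_ethylene_responsive(
    table: pd.DataFrame,
    fc_threshold: float = 1.0,
    q_threshold: float = 0.01,
    delta_threshold: float = 1.0,
) -> pd.Series:
    """Flag ethylene-responsive genes.

    Responsive iff ``|log2fc_WT| >= fc_threshold`` AND
    ``q_WT < q_threshold`` AND ``|log2fc_WT - log2fc_g| >= delta_threshold``
    for BOTH ethylene-insensitive genotypes g.
    """
    needed = ["log2fc_WT", "q_WT"] + [f"log2fc_{g}" for g in GENOTYPES[1:]]
    for col in needed:
        if col not in table.columns:
            raise ValueError(f"response table lacks column {col!r}")
    wt = table["log2fc_WT"]
    ok = (wt.abs() >= fc_threshold) & (table["q_WT"] < q_threshold)
    for g in GENOTYPES[1:]:
        ok &= (wt - table[f"log2fc_{g}"]).abs() >= delta_threshold
    return ok.rename("responsive")


def relative_expression(ct_target: float, ct_reference: float) -> float:
    """Relative qPCR expression, ``2**-(Ct_target - Ct_reference)``."""
    dct = float(ct_target) - float(ct_reference)
    if not np.isfinite(dct):
        raise ValueError("Ct values must be finite")
    return float(2.0**-dct)
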