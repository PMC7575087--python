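"""Count-based differential expression with a negative-binomial model.

Two contrasts mirror the smoltification study design: an exact test for
the freshwater-vs-seawater challenge and an ANOVA-like likelihood-ratio
test across developmental stages T1-T6, both run on TMM-normalized
effective library sizes with Benjamini-Hochberg FDR control (threshold
0.01 by default).

A single common NB dispersion is estimated by maximizing the
sum-constrained (conditional) likelihood over all genes — tagwise
shrinkage is deliberately not attempted, since the target gene sets are
small. Unequal library sizes are handled by scaling counts to the
geometric-mean effective library before conditioning; the exact test
conditions analytically on the group totals instead of constructing
quantile-adjusted pseudo-counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .simdata import ExpressionBundle

__all__ = [
    "DispersionEstimate",
    "DEResult",
    "estimate_common_dispersion",
    "nb_exact_test",
    "timecourse_test",
    "bh_fdr",
    "sw_contrast_table",
    "timecourse_table",
]


@dataclass
class DispersionEstimate:
    dispersion: float
    method: str = "conditional-ML (common)"


@dataclass
class DEResult:
    gene: str
    contrast: str
    log2fc: float
    statistic: float
    p: float
    fdr: float = float("nan")


def bh_fdr(p) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p-values (capped at 1, monotone)."""

    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

def _equalized_counts(counts: np.ndarray, eff_libsizes: np.ndarray) -> np.ndarray:
    """Scale every sample to the geometric-mean effective library size."""

    target = np.exp(np.mean(np.log(eff_libsizes)))
    return counts * (target / eff_libsizes)[None, :]


def _conditional_loglik(counts: np.ndarray, group_ids: np.ndarray, dispersion: float) -> float:
    """Conditional NB log-likelihood given per-group sums, all genes.

    For iid NB observations with common mean and dispersion phi (size
    r = 1/phi), the likelihood of the counts conditional on their group
    sum depends only on phi: sum_i lgamma(y_i + r) - n*lgamma(r)
    + lgamma(n r) - lgamma(z + n r), up to phi-free terms. Works on
    continuous (library-equalized) pseudo-counts.
    """

    if dispersion <= 0:
        raise ValueError("use the Poisson limit explicitly")
    r = 1.0 / dispersion
    total = 0.0
    for g in np.unique(group_ids):
        y = counts[:, group_ids == g]
        n = y.shape[1]
        z = y.sum(axis=1)
        total += float(
            np.sum(special.gammaln(y + r))
            - y.shape[0] * n * special.gammaln(r)
            + y.shape[0] * special.gammaln(n * r)
            - np.sum(special.gammaln(z + n * r))
        )
    return total


def estimate_common_dispersion(
    counts: pd.DataFrame | np.ndarray,
    groups,
    norm_factors=None,
    grid: tuple[float, float, int] = (1e-4, 4.0, 25),
) -> DispersionEstimate:
    """Common NB dispersion by conditional maximum likelihood.

    Counts are scaled to a common effective library size, then the
    sum-constrained likelihood is maximized over a log-spaced dispersion
    grid refined by bounded scalar optimization; 0 (the Poisson limit)
    is returned when the boundary wins.
    """

    counts = counts.to_numpy(dtype=float) if isinstance(counts, pd.DataFrame) else np.asarray(counts, float)
    if counts.sum() == 0:
        raise ValueError("all-zero count matrix")
    groups = np.asarray(groups)
    uniq, group_ids = np.unique(groups, return_inverse=True)
    for g in range(len(uniq)):
        if (group_ids == g).sum() < 2:
            raise ValueError("every group needs >=2 replicates")
    libsizes = counts.sum(axis=0)
    factors = np.ones_like(libsizes) if norm_factors is None else np.asarray(norm_factors, float)
    eq = _equalized_counts(counts, libsizes * factors)
    keep = eq.sum(axis=1) > 0
    eq = eq[keep]

    lo, hi, n_grid = grid
    phis = np.geomspace(lo, hi, n_grid)
    lls = np.array([_conditional_loglik(eq, group_ids, ph) for ph in phis])
    best = int(np.argmax(lls))
    if best == 0:
        return DispersionEstimate(dispersion=0.0)
    bracket_lo = phis[max(best - 1, 0)]
    bracket_hi = phis[min(best + 1, n_grid - 1)]
    res = optimize.minimize_scalar(
        lambda lg: -_conditional_loglik(eq, group_ids, float(np.exp(lg))),
        bounds=(np.log(bracket_lo), np.log(bracket_hi)),
        method="bounded",
        options={"xatol": 1e-4},
    )
    return DispersionEstimate(dispersion=float(np.exp(res.x)))


# ---------------------------------------------------------------------------
# exact test (FW vs SW)
# ---------------------------------------------------------------------------

def _group_sum_pmf(k: np.ndarray, mean: float, n: int, dispersion: float) -> np.ndarray:
    """pmf of a sum of n iid NB(mean/n each) counts; Poisson when phi=0."""

    if dispersion <= 0:
        return stats.poisson.pmf(k, mean)
    size = n / dispersion
    return stats.nbinom.pmf(k, size, size / (size + mean))


def nb_exact_test(
    counts1,
    counts2,
    dispersion: float,
    eff_libsizes1=None,
    eff_libsizes2=None,
    contrast: str = "SW_vs_FW",
    gene: str = "",
) -> DEResult:
    """Two-sided exact NB test for one gene between two groups.

    Counts are equalized to a common library size, group sums formed,
    and the conditional distribution of group-1's sum given the total
    computed from NB group-sum pmfs (binomial split in the Poisson
    limit). The two-sided p sums all outcomes no more probable than the
    observed one. log2fc is from mean cpm with a +0.5 offset,
    group2 over group1.
    """

    y1 = np.asarray(counts1, dtype=float)
    y2 = np.asarray(counts2, dtype=float)
    n1, n2 = len(y1), len(y2)
    L1 = np.ones(n1) if eff_libsizes1 is None else np.asarray(eff_libsizes1, float)
    L2 = np.ones(n2) if eff_libsizes2 is None else np.asarray(eff_libsizes2, float)
    target = np.exp(np.mean(np.log(np.concatenate([L1, L2]))))
    s1 = float(np.round((y1 * target / L1).sum()))
    s2 = float(np.round((y2 * target / L2).sum()))
    total = int(s1 + s2)

    cpm1 = float(np.mean(y1 / L1)) * 1e6
    cpm2 = float(np.mean(y2 / L2)) * 1e6
    log2fc = float(np.log2((cpm2 + 0.5) / (cpm1 + 0.5)))

    if total == 0:
        return DEResult(gene=gene, contrast=contrast, log2fc=log2fc, statistic=0.0, p=1.0)

    mu = total / (n1 + n2)
    k = np.arange(total + 1)
    pmf = _group_sum_pmf(k, n1 * mu, n1, dispersion) * _group_sum_pmf(
        total - k, n2 * mu, n2, dispersion
    )
    norm = pmf.sum()
    if norm <= 0:
        return DEResult(gene=gene, contrast=contrast, log2fc=log2fc, statistic=0.0, p=1.0)
    pmf = pmf / norm
    p_obs = pmf[int(s1)]
    p = float(pmf[pmf <= p_obs * (1 + 1e-12)].sum())
    return DEResult(
        gene=gene, contrast=contrast, log2fc=log2fc, statistic=float(s1), p=min(p, 1.0)
    )


# ---------------------------------------------------------------------------
# ANOVA-like time-course test
# ---------------------------------------------------------------------------

def _nb_deviance(y, mu, dispersion) -> float:
    y = np.asarray(y, float)
    mu = np.clip(np.asarray(mu, float), 1e-10, None)
    ys = np.clip(y, 1e-10, None)
    if dispersion <= 0:
        return float(2.0 * np.sum(y * np.log(ys / mu) - (y - mu)))
    r = 1.0 / dispersion
    return float(
        2.0 * np.sum(y * np.log(ys / mu) - (y + r) * np.log((y + r) / (mu + r)))
    )


def _fit_nb_glm(y, X, offset, dispersion):
    """NB GLM (log link, fixed dispersion) via statsmodels IRLS."""

    import statsmodels.api as sm

    fam = sm.families.Poisson() if dispersion <= 0 else sm.families.NegativeBinomial(alpha=dispersion)
    model = sm.GLM(y, X, family=fam, offset=offset)
    res = model.fit(maxiter=200, tol=1e-10)
    return res.mu


def timecourse_test(
    counts,
    stages,
    dispersion: float,
    eff_libsizes=None,
    contrast: str = "timecourse_T1_T6",
    gene: str = "",
) -> DEResult:
    """ANOVA-like NB likelihood-ratio test across developmental stages.

    Fits an NB log-linear model with a stage factor against the
    intercept-only model at the given common dispersion; the deviance
    difference is referred to chi-square with (n_stages - 1) df.
    """

    y = np.asarray(counts, dtype=float)
    stages = np.asarray(stages)
    uniq, stage_ids = np.unique(stages, return_inverse=True)
    if len(uniq) < 3:
        raise ValueError("time-course test needs >=3 stages")
    for g in range(len(uniq)):
        if (stage_ids == g).sum() < 2:
            raise ValueError("every stage needs >=2 replicates")
    L = np.ones(len(y)) if eff_libsizes is None else np.asarray(eff_libsizes, float)
    offset = np.log(L)
    X_full = np.zeros((len(y), len(uniq)))
    X_full[np.arange(len(y)), stage_ids] = 1.0
    X_null = np.ones((len(y), 1))
    if y.sum() == 0:
        return DEResult(gene=gene, contrast=contrast, log2fc=float("nan"), statistic=0.0, p=1.0)
    mu_full = _fit_nb_glm(y, X_full, offset, dispersion)
    mu_null = _fit_nb_glm(y, X_null, offset, dispersion)
    lr = _nb_deviance(y, mu_null, dispersion) - _nb_deviance(y, mu_full, dispersion)
    lr = max(lr, 0.0)
    df = len(uniq) - 1
    p = float(stats.chi2.sf(lr, df))
    return DEResult(gene=gene, contrast=contrast, log2fc=float("nan"), statistic=float(lr), p=p)


# ---------------------------------------------------------------------------
# table-level drivers
# ---------------------------------------------------------------------------

def _effective_libsizes(bundle: ExpressionBundle) -> np.ndarray:
    return (bundle.library_sizes * bundle.norm_factors).to_numpy()


def sw_contrast_table(
    bundle: ExpressionBundle, dispersion: float | None = None, fdr_threshold: float = 0.01
) -> pd.DataFrame:
    """Exact-test table for the FW-vs-SW challenge, BH-adjusted."""

    meta = bundle.meta
    fw = meta.index[meta["condition"] == "FW"]
    sw = meta.index[meta["condition"] == "SW"]
    if len(fw) == 0 or len(sw) == 0:
        raise ValueError("seawater contrast needs both FW and SW samples")
    eff = pd.Series(_effective_libsizes(bundle), index=meta.index)
    if dispersion is None:
        dispersion = estimate_common_dispersion(
            bundle.counts, meta["condition"].to_numpy(), bundle.norm_factors.to_numpy()
        ).dispersion
    rows = []
    for gene in bundle.counts.index:
        res = nb_exact_test(
            bundle.counts.loc[gene, fw],
            bundle.counts.loc[gene, sw],
            dispersion,
            eff[fw].to_numpy(),
            eff[sw].to_numpy(),
            gene=gene,
        )
        rows.append({"gene": gene, "contrast": res.contrast, "log2fc": res.log2fc,
                     "statistic": res.statistic, "p": res.p})
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = out["fdr"] < fdr_threshold
    out.attrs["dispersion"] = dispersion
    return out


def timecourse_table(
    bundle: ExpressionBundle, dispersion: float | None = None, fdr_threshold: float = 0.01
) -> pd.DataFrame:
    """ANOVA-like test table over the T1-T6 stages, BH-adjusted."""

    meta = bundle.meta
    stages = meta["time"].to_numpy()
    eff = _effective_libsizes(bundle)
    if dispersion is None:
        dispersion = estimate_common_dispersion(
            bundle.counts, stages, bundle.norm_factors.to_numpy()
        ).dispersion
    rows = []
    for gene in bundle.counts.index:
        res = timecourse_test(bundle.counts.loc[gene].to_numpy(), stages, dispersion, eff, gene=gene)
        rows.append({"gene": gene, "contrast": res.contrast, "log2fc": res.log2fc,
                     "statistic": res.statistic, "p": res.p})
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = out["fdr"] < fdr_threshold
    out.attrs["dispersion"] = dispersion
    return out
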