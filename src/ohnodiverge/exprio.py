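"""Count-matrix IO, TMM normalization, cpm and expression filtering.

The normalization pipeline follows the standard count-based workflow:
genes kept at >=1 count per million (cpm) in >=5 libraries, library
composition corrected by trimmed-mean-of-M-values (TMM) scaling, and cpm
computed on the effective library size (library size x TMM factor).

TMM is implemented here with the published defaults — 30 % two-sided
trim on M (log ratio), 5 % on A (log abundance), inverse-asymptotic-
variance weighting, factors rescaled to geometric mean 1 — since no
installed Python package provides it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simdata import ExpressionBundle

__all__ = [
    "ExpressionBundle",
    "NormalizedMatrix",
    "read_counts",
    "read_metadata",
    "write_counts",
    "cpm",
    "tmm_factors",
    "filter_low_expression",
    "condition_mesor",
]


@dataclass
class NormalizedMatrix:
    """cpm values (genes x samples) plus what was done to obtain them."""

    values: pd.DataFrame
    filter_applied: bool = False
    tmm_applied: bool = False
    log2: bool = False
    prior_count: float = 0.0


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index.name = "gene"
    return df


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, comment="#", keep_default_na=False)


def write_counts(df: pd.DataFrame, path, header_lines: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t")


def cpm(
    bundle: ExpressionBundle,
    use_norm_factors: bool = True,
    log2: bool = False,
    prior_count: float = 0.5,
) -> NormalizedMatrix:
    """Counts per million on effective library sizes.

    ``cpm[g, s] = counts[g, s] / (libsize_s * factor_s) * 1e6``. With
    ``log2=True`` a +``prior_count`` offset is added to the counts before
    division (recorded in provenance) so zeros stay finite.
    """

    libsizes = bundle.library_sizes
    zero = libsizes[libsizes <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {', '.join(zero.index)}")
    factors = bundle.norm_factors if use_norm_factors else pd.Series(1.0, index=libsizes.index)
    eff = libsizes * factors
    counts = bundle.counts.astype(float)
    if log2:
        vals = np.log2((counts + prior_count).div(eff, axis=1) * 1e6)
    else:
        vals = counts.div(eff, axis=1) * 1e6
    return NormalizedMatrix(
        values=vals,
        tmm_applied=use_norm_factors and not np.allclose(factors, 1.0),
        log2=log2,
        prior_count=prior_count if log2 else 0.0,
    )


def _choose_reference(counts: np.ndarray, libsizes: np.ndarray) -> int:
    # sample whose upper-quartile relative abundance is closest to the mean
    f75 = np.array(
        [np.percentile(counts[:, j] / libsizes[j], 75) for j in range(counts.shape[1])]
    )
    return int(np.argmin(np.abs(f75 - f75.mean())))


def _tmm_one(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
    weighted: bool,
) -> float:
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        return 1.0
    o, r = obs[keep], ref[keep]
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    if np.abs(m).max() < 1e-6:  # pure depth difference: factor is exactly 1
        return 1.0
    n = len(m)
    lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
    from scipy.stats import rankdata

    rm, ra = rankdata(m), rankdata(a)
    keep2 = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep2.any():
        return 1.0
    if weighted:
        f = np.sum(m[keep2] / w[keep2]) / np.sum(1.0 / w[keep2])
    else:
        f = np.mean(m[keep2])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_factors(
    bundle: ExpressionBundle,
    reference_sample: str | None = None,
    trim_M: float = 0.30,
    trim_A: float = 0.05,
    weighted: bool = True,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    For each sample, gene-wise log2 ratios (M) against the reference are
    trimmed by ``trim_M`` on each side and by ``trim_A`` on log
    abundance, then averaged with precision weights; the factor is 2 to
    that mean. A sample sharing no expressed genes with the reference
    gets factor 1 with a warning.
    """

    import warnings

    if bundle.counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    counts = bundle.counts.to_numpy(dtype=float)
    libsizes = bundle.library_sizes.to_numpy()
    samples = list(bundle.counts.columns)
    if reference_sample is None:
        ref_j = _choose_reference(counts, libsizes)
    else:
        ref_j = samples.index(reference_sample)
    ref, n_ref = counts[:, ref_j], libsizes[ref_j]
    factors = np.ones(len(samples))
    for j in range(len(samples)):
        if j == ref_j:
            factors[j] = 1.0
            continue
        if not ((counts[:, j] > 0) & (ref > 0)).any():
            warnings.warn(f"sample {samples[j]} shares no expressed genes with reference")
            factors[j] = 1.0
            continue
        factors[j] = _tmm_one(counts[:, j], ref, libsizes[j], n_ref, trim_M, trim_A, weighted)
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=samples, name="tmm_factor")


def filter_low_expression(
    matrix: NormalizedMatrix | pd.DataFrame, min_cpm: float = 1.0, min_samples: int = 5
) -> tuple[list[str], pd.DataFrame]:
    """Keep genes with cpm >= ``min_cpm`` in >= ``min_samples`` libraries."""

    vals = matrix.values if isinstance(matrix, NormalizedMatrix) else matrix
    keep = (vals >= min_cpm).sum(axis=1) >= min_samples
    kept = list(vals.index[keep])
    return kept, vals.loc[keep]


def condition_mesor(
    matrix: NormalizedMatrix | pd.DataFrame,
    meta: pd.DataFrame,
    gene: str,
    tissue: str,
    condition: str | None = None,
) -> float:
    """Mean normalized expression of ``gene`` over a tissue (x condition) group.

    Returns NaN for an empty group (flagged rather than raised so table
    builders can carry the gap forward).
    """

    vals = matrix.values if isinstance(matrix, NormalizedMatrix) else matrix
    sel = meta["tissue"] == tissue
    if condition is not None:
        sel &= meta["condition"] == condition
    samples = meta.index[sel]
    if len(samples) == 0 or gene not in vals.index:
        return float("nan")
    return float(vals.loc[gene, samples].mean())
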