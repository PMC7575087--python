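"""Nonparametric diel/circadian rhythm detection.

The detector correlates each expression series, by Kendall rank
correlation (tau-b), against cosine reference waveforms of fixed 24-h
period laid out on a grid of candidate peak phases; the test statistic
is the maximum tau over the phase grid. Significance comes from a
permutation null in which timepoint labels are shuffled with replicate
blocks kept intact — the null distribution is of the *maximal* tau, so
the phase search incurs no multiplicity leak. Benjamini-Hochberg
adjustment is applied within each tissue x condition stratum.

Cosine convention: ``signal = amplitude * cos(2*pi*(t - phase)/24)``
with t in hours, so ``phase`` is the peak time. The diel analysis
window runs ZT5 through the following ZT5 (hour 29); constant-condition
(LL/DD) windows run CT9-CT29.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exprio import NormalizedMatrix
from .destats import bh_fdr

__all__ = [
    "RhythmResult",
    "reference_waveforms",
    "kendall_tau",
    "rhythm_test",
    "screen_rhythms",
    "DEFAULT_WINDOWS",
]

DEFAULT_WINDOWS = {"diel": (5.0, 29.0), "LL": (9.0, 29.0), "DD": (9.0, 29.0)}


@dataclass
class RhythmResult:
    gene: str
    tissue: str
    condition: str
    window: tuple[float, float]
    tau: float
    period_h: float
    phase_h: float
    amplitude: float
    mesor: float
    p: float
    adj_p: float = float("nan")


def reference_waveforms(
    times: np.ndarray, period_h: float = 24.0, phase_step_h: float = 4.0
) -> tuple[np.ndarray, np.ndarray]:
    """Cosine rank templates at every candidate peak phase.

    ``times`` lists the sampling time (hours) of every observation,
    replicates included. Returns ``(phases, rank_templates)`` where row
    k holds the ranks of ``cos(2*pi*(t - phases[k])/period)`` over the
    observations.
    """

    if period_h <= 0:
        raise ValueError("period must be positive")
    if phase_step_h <= 0 or abs(period_h / phase_step_h - round(period_h / phase_step_h)) > 1e-9:
        raise ValueError("phase_step_h must divide the period")
    times = np.asarray(times, dtype=float)
    phases = np.arange(0.0, period_h, phase_step_h)
    templates = np.cos(2 * np.pi * (times[None, :] - phases[:, None]) / period_h)
    ranks = np.vstack([stats.rankdata(row) for row in templates])
    for row in ranks:
        if len(np.unique(row)) < 3:
            raise ValueError("degenerate design: fewer than 3 distinct template ranks")
    return phases, ranks


def kendall_tau(x, y) -> float:
    """Tie-corrected Kendall tau-b; NaN when either input is constant."""

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("inputs must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.kendalltau(x, y).statistic)


# ---------------------------------------------------------------------------
# vectorized tau machinery (shared by the single test and the screen)
# ---------------------------------------------------------------------------

def _pair_signs(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Signs of all n-choose-2 pairwise differences, rows x pairs.

    Returns the sign matrix and, per row, the tie-corrected denominator
    term ``n0 - t`` (number of pairs not tied within the row).
    """

    n = mat.shape[1]
    iu, ju = np.triu_indices(n, k=1)
    signs = np.sign(mat[:, iu] - mat[:, ju])
    untied = np.abs(signs).sum(axis=1)
    return signs, untied


def _tau_matrix(x_signs, x_untied, t_signs, t_untied) -> np.ndarray:
    """tau-b between every x row and every template row (x rows x t rows)."""

    concordant = x_signs @ t_signs.T
    denom = np.sqrt(np.outer(x_untied, t_untied))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, concordant / denom, np.nan)


def _permuted_templates(
    times: np.ndarray,
    phases: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    period_h: float = 24.0,
    scheme: str = "observations",
) -> np.ndarray:
    """Rank templates under permutations of the timepoint labels.

    ``scheme='observations'`` (default) shuffles all observation labels
    freely — the exchangeability the iid-noise null grants, and the
    scheme with useful power on short designs. ``scheme='blocks'``
    moves replicate blocks as units, robust to shared within-timepoint
    effects but markedly conservative with few timepoints. Returns an
    array of shape (n_perm + 1, n_phases, n_obs); permutation 0 is the
    identity (the observed assignment).
    """

    uniq, inv = np.unique(times, return_inverse=True)
    base = np.cos(2 * np.pi * (uniq[None, :] - phases[:, None]) / period_h)
    obs_vals = base[:, inv]
    obs_ranks = np.vstack([stats.rankdata(row) for row in obs_vals])
    out = np.empty((n_perm + 1, len(phases), len(times)))
    out[0] = obs_ranks
    if scheme == "observations":
        for b in range(1, n_perm + 1):
            out[b] = obs_ranks[:, rng.permutation(len(times))]
    elif scheme == "blocks":
        for b in range(1, n_perm + 1):
            perm = rng.permutation(len(uniq))
            vals = base[:, perm][:, inv]
            out[b] = np.vstack([stats.rankdata(row) for row in vals])
    else:
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    return out


def _max_tau_and_null(
    X: np.ndarray, times: np.ndarray, phases: np.ndarray, n_perm: int, rng,
    period_h: float = 24.0, scheme: str = "observations",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Observed max-tau, argmax phase index and permutation p per row of X."""

    templates = _permuted_templates(times, phases, n_perm, rng, period_h, scheme)
    x_signs, x_untied = _pair_signs(X)
    n_obs = X.shape[1]
    iu_len = n_obs * (n_obs - 1) // 2
    flat = templates.reshape(-1, n_obs)
    t_signs, t_untied = _pair_signs(flat)
    taus = _tau_matrix(x_signs, x_untied, t_signs, t_untied)
    taus = taus.reshape(X.shape[0], templates.shape[0], len(phases))
    constant = x_untied == 0
    taus[constant] = 0.0  # placeholder; these rows are flagged below
    stat = np.nanmax(taus, axis=2)  # genes x (1 + n_perm)
    obs = stat[:, 0]
    argmax = np.nanargmax(np.where(np.isnan(taus[:, 0, :]), -np.inf, taus[:, 0, :]), axis=1)
    null = stat[:, 1:]
    p = np.ones(X.shape[0])
    ok = ~constant
    if ok.any():
        exceed = (null[ok] >= obs[ok][:, None] - 1e-12).sum(axis=1)
        p[ok] = (1.0 + exceed) / (n_perm + 1.0)
    obs = np.where(constant, np.nan, obs)
    return obs, argmax, p


def _cosinor(x: np.ndarray, times: np.ndarray, phase: float, period_h: float = 24.0):
    """Least-squares mesor/amplitude at a fixed peak phase."""

    c = np.cos(2 * np.pi * (times - phase) / period_h)
    design = np.column_stack([np.ones_like(c), c])
    coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    mesor, amp = float(coef[0]), float(coef[1])
    if amp < 0:  # peak is antiphase to the template; fold into [0, 24)
        amp, phase = -amp, (phase + period_h / 2) % period_h
    return mesor, amp, phase % period_h


def rhythm_test(
    values,
    times,
    window: tuple[float, float] | None = None,
    phase_step_h: float = 4.0,
    period_h: float = 24.0,
    n_perm: int = 5000,
    seed: int = 0,
    scheme: str = "observations",
) -> RhythmResult:
    """Max-over-phases Kendall test for one series.

    ``values``/``times`` are parallel observation vectors (replicates as
    repeated times). The permutation null shuffles time labels (see
    :func:`_permuted_templates` for the two schemes) and is a null of
    the maximal tau, so the phase search incurs no multiplicity leak.
    """

    if n_perm < 100:
        raise ValueError("n_perm < 100 gives unstable p-values; refuse")
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    if window is not None:
        keep = (times >= window[0]) & (times <= window[1])
        values, times = values[keep], times[keep]
    phases, _ = reference_waveforms(times, period_h, phase_step_h)
    rng = np.random.default_rng(seed)
    obs, argmax, p = _max_tau_and_null(
        values[None, :], times, phases, n_perm, rng, period_h, scheme
    )
    if np.isnan(obs[0]):
        return RhythmResult(
            gene="", tissue="", condition="", window=window or (times.min(), times.max()),
            tau=float("nan"), period_h=period_h, phase_h=float("nan"),
            amplitude=0.0, mesor=float(values.mean()), p=1.0,
        )
    phase = float(phases[argmax[0]])
    mesor, amp, phase = _cosinor(values, times, phase, period_h)
    return RhythmResult(
        gene="", tissue="", condition="", window=window or (times.min(), times.max()),
        tau=float(obs[0]), period_h=period_h, phase_h=phase,
        amplitude=amp, mesor=mesor, p=float(p[0]),
    )


def screen_rhythms(
    matrix: NormalizedMatrix | pd.DataFrame,
    meta: pd.DataFrame,
    conditions: tuple[str, ...] = ("diel", "LL", "DD"),
    windows: dict[str, tuple[float, float]] | None = None,
    alpha: float = 0.05,
    phase_step_h: float = 4.0,
    period_h: float = 24.0,
    n_perm: int = 5000,
    seed: int = 0,
    scheme: str = "observations",
) -> pd.DataFrame:
    """Rhythm screen across genes, tissues and conditions.

    ``matrix`` holds normalized expression; the rank statistic itself is
    invariant to monotone transforms, while the cosinor amplitude/mesor
    are computed on log2 of the given values when they are not already
    logged. BH adjustment is per tissue x condition stratum; a row is
    significant when ``adj_p < alpha``.
    """

    vals = matrix.values if isinstance(matrix, NormalizedMatrix) else matrix
    already_log = isinstance(matrix, NormalizedMatrix) and matrix.log2
    windows = {**DEFAULT_WINDOWS, **(windows or {})}
    rows: list[dict] = []
    for tissue in sorted(meta["tissue"].unique()):
        for cond in conditions:
            sel = (meta["tissue"] == tissue) & (meta["condition"] == cond)
            if not sel.any():
                continue
            sub = meta.loc[sel]
            times = sub["time"].to_numpy(dtype=float)
            lo, hi = windows[cond]
            keep = (times >= lo) & (times <= hi)
            samples = sub.index[keep]
            times = times[keep]
            X = vals.loc[:, samples].to_numpy(dtype=float)
            Xst = X if already_log else np.log2(X + 0.5)
            phases, _ = reference_waveforms(times, period_h, phase_step_h)
            stratum_tag = zlib.crc32(f"{tissue}|{cond}".encode()) % (2**31)
            rng = np.random.default_rng([seed, stratum_tag])
            obs, argmax, p = _max_tau_and_null(Xst, times, phases, n_perm, rng, period_h, scheme)
            adj = bh_fdr(p)
            for i, gene in enumerate(vals.index):
                if np.isnan(obs[i]):
                    rows.append(
                        dict(gene=gene, tissue=tissue, condition=cond, window_start=lo,
                             window_end=hi, tau=np.nan, period_h=period_h, phase_h=np.nan,
                             amplitude=0.0, mesor=float(Xst[i].mean()), p=1.0, adj_p=adj[i])
                    )
                    continue
                mesor, amp, phase = _cosinor(Xst[i], times, float(phases[argmax[i]]), period_h)
                rows.append(
                    dict(gene=gene, tissue=tissue, condition=cond, window_start=lo,
                         window_end=hi, tau=float(obs[i]), period_h=period_h, phase_h=phase,
                         amplitude=amp, mesor=mesor, p=float(p[i]), adj_p=float(adj[i]))
                )
    out = pd.DataFrame(rows)
    if len(out):
        out["significant"] = out["adj_p"] < alpha
    return out
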