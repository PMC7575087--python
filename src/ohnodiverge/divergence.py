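"""Within-pair regulatory divergence: EDI, profile tests, clustering.

Four complementary views of how the two members of an Ss4R ohnologue
pair have diverged in regulation:

* the expression divergence index, EDI = \\|log2(gene1/gene2)\\|, per
  tissue, summarized by the median across tissues;
* an extra-sum-of-squares F test comparing a shared sixth-order
  centered-polynomial fit of two mean-normalized time courses against
  separate fits;
* a two-way ANOVA (gene copy x FW/SW condition) on log2 cpm, whose
  interaction term asks whether the copies respond differently to
  seawater exposure;
* hierarchical clustering (1 - Pearson r distance, average linkage) of
  standardized developmental profiles into k archetypes (default 5).

The pair report combines these into a divergence mode per pair: none,
one-copy-regulated, different-dynamics, or both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

__all__ = [
    "compute_edi",
    "edi_table",
    "ProfileDivergenceResult",
    "profile_divergence_test",
    "InteractionResult",
    "interaction_test",
    "cluster_profiles",
    "pair_divergence_report",
]


def compute_edi(expr1, expr2, offset: float = 0.5):
    """Expression divergence index: \\|log2(expr1/expr2)\\|.

    A +``offset`` is added to *both* values only when either is zero, so
    the index stays finite while remaining symmetric and exactly zero
    for identical inputs. Scalar or array inputs.
    """

    e1 = np.asarray(expr1, dtype=float)
    e2 = np.asarray(expr2, dtype=float)
    if (e1 < 0).any() or (e2 < 0).any():
        raise ValueError("expression values must be non-negative")
    engage = (e1 == 0) | (e2 == 0)
    a = np.where(engage, e1 + offset, e1)
    b = np.where(engage, e2 + offset, e2)
    out = np.abs(np.log2(a / b))
    return float(out) if out.ndim == 0 else out


def edi_table(
    pairs: pd.DataFrame, expression: pd.DataFrame, meta: pd.DataFrame, offset: float = 0.5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-tissue EDI for every pair plus the per-pair median summary.

    ``pairs`` needs gene1/gene2 (and optionally orthogroup + class)
    columns; ``expression`` is a normalized genes x samples matrix and
    tissue means are taken over ``meta``. Pairs with a gene missing from
    the matrix are flagged and excluded from the summary.
    """

    tissues = sorted(meta["tissue"].unique())
    tissue_means = {
        t: expression.loc[:, meta.index[meta["tissue"] == t]].mean(axis=1) for t in tissues
    }
    class_col = next((c for c in ("rediploid_class", "class") if c in pairs.columns), None)
    records, summaries = [], []
    for _, row in pairs.iterrows():
        pid = row["orthogroup"] if "orthogroup" in pairs.columns else f"{row.gene1}__{row.gene2}"
        missing = row["gene1"] not in expression.index or row["gene2"] not in expression.index
        if missing:
            summaries.append(
                {"pair": pid, "gene1": row["gene1"], "gene2": row["gene2"],
                 "median_edi": np.nan, "flagged_missing": True}
            )
            continue
        edis = []
        for t in tissues:
            e = compute_edi(tissue_means[t][row["gene1"]], tissue_means[t][row["gene2"]], offset)
            rec = {"pair": pid, "tissue": t, "expr1": float(tissue_means[t][row["gene1"]]),
                   "expr2": float(tissue_means[t][row["gene2"]]), "edi": float(e)}
            if class_col is not None:
                rec["rediploid_class"] = row[class_col]
            records.append(rec)
            edis.append(e)
        summaries.append(
            {"pair": pid, "gene1": row["gene1"], "gene2": row["gene2"],
             "median_edi": float(np.median(edis)), "flagged_missing": False}
        )
    return pd.DataFrame(records), pd.DataFrame(summaries)


# ---------------------------------------------------------------------------
# profile divergence (extra-sum-of-squares F on nested polynomial fits)
# ---------------------------------------------------------------------------

@dataclass
class ProfileDivergenceResult:
    rss_shared: float
    rss_separate: float
    df_num: int
    df_den: int
    F: float
    p: float


def _poly_design(t: np.ndarray, order: int, center: float) -> np.ndarray:
    tc = t - center
    return np.vander(tc, N=order + 1, increasing=True)


def profile_divergence_test(
    series1, series2, times, order: int = 6, normalize: bool = True
) -> ProfileDivergenceResult:
    """Extra-sum-of-squares F test for two time-course profiles.

    Each series (sampled at the same ``times``) is divided by its own
    mean, then fit by a centered polynomial of the given order either
    jointly (one coefficient set) or separately; the F statistic
    compares the residual sums of squares of the nested fits. The
    polynomial is linear in its coefficients, so ordinary least squares
    is exact.
    """

    y1 = np.asarray(series1, dtype=float)
    y2 = np.asarray(series2, dtype=float)
    t = np.asarray(times, dtype=float)
    if len(y1) != len(t) or len(y2) != len(t):
        raise ValueError("series and times must align")
    k = order + 1
    if len(np.unique(t)) < k:
        raise ValueError(f"need >= {k} distinct timepoints for an order-{order} polynomial")
    if len(y1) + len(y2) <= 2 * k:
        raise ValueError(f"need more than {2 * k} total observations")
    if normalize:
        if y1.mean() == 0 or y2.mean() == 0:
            raise ValueError("cannot mean-normalize an all-zero series")
        y1 = y1 / y1.mean()
        y2 = y2 / y2.mean()
    center = t.mean()
    X = _poly_design(t, order, center)

    def rss(X_, y_):
        coef, *_ = np.linalg.lstsq(X_, y_, rcond=None)
        r = y_ - X_ @ coef
        return float(r @ r)

    rss_sep = rss(X, y1) + rss(X, y2)
    X_shared = np.vstack([X, X])
    rss_shared = rss(X_shared, np.concatenate([y1, y2]))
    df_sep = len(y1) + len(y2) - 2 * k
    df_num = k
    if df_sep <= 0:
        raise ValueError("no residual degrees of freedom in the separate fit")
    F = ((rss_shared - rss_sep) / df_num) / (rss_sep / df_sep)
    F = max(F, 0.0)
    p = float(stats.f.sf(F, df_num, df_sep))
    return ProfileDivergenceResult(
        rss_shared=rss_shared, rss_separate=rss_sep, df_num=df_num, df_den=df_sep, F=float(F), p=p
    )


# ---------------------------------------------------------------------------
# seawater interaction (two-way ANOVA on log2 cpm)
# ---------------------------------------------------------------------------

@dataclass
class InteractionResult:
    log2fc_gene1: float
    log2fc_gene2: float
    F: float
    interaction_p: float
    divergent: bool


def interaction_test(
    cpm_gene1_fw, cpm_gene1_sw, cpm_gene2_fw, cpm_gene2_sw, alpha: float = 0.05,
    prior: float = 0.5,
) -> InteractionResult:
    """Two-way ANOVA (gene copy x condition) interaction on log2 cpm.

    The interaction term is the extra-sum-of-squares comparison between
    the additive model (copy + condition) and the full model with the
    copy:condition product, so the result is unambiguous also for
    unbalanced designs. Inputs are cpm vectors per cell; each cell
    needs >=2 replicates.
    """

    cells = [np.asarray(c, dtype=float) for c in
             (cpm_gene1_fw, cpm_gene1_sw, cpm_gene2_fw, cpm_gene2_sw)]
    if any(len(c) < 2 for c in cells):
        raise ValueError("every (gene, condition) cell needs >=2 replicates")
    y = np.concatenate([np.log2(c + prior) for c in cells])
    copy = np.concatenate([np.zeros(len(cells[0]) + len(cells[1])),
                           np.ones(len(cells[2]) + len(cells[3]))])
    cond = np.concatenate([np.zeros(len(cells[0])), np.ones(len(cells[1])),
                           np.zeros(len(cells[2])), np.ones(len(cells[3]))])

    def rss(X_):
        coef, *_ = np.linalg.lstsq(X_, y, rcond=None)
        r = y - X_ @ coef
        return float(r @ r)

    ones = np.ones_like(y)
    X_add = np.column_stack([ones, copy, cond])
    X_full = np.column_stack([ones, copy, cond, copy * cond])
    rss_add, rss_full = rss(X_add), rss(X_full)
    df_den = len(y) - 4
    F = max((rss_add - rss_full) / 1.0 / (rss_full / df_den), 0.0)
    p = float(stats.f.sf(F, 1, df_den))
    fc1 = float(np.mean(np.log2(cells[1] + prior)) - np.mean(np.log2(cells[0] + prior)))
    fc2 = float(np.mean(np.log2(cells[3] + prior)) - np.mean(np.log2(cells[2] + prior)))
    return InteractionResult(
        log2fc_gene1=fc1, log2fc_gene2=fc2, F=float(F), interaction_p=p, divergent=p < alpha
    )


# ---------------------------------------------------------------------------
# profile clustering
# ---------------------------------------------------------------------------

def cluster_profiles(profiles: pd.DataFrame, k: int = 5) -> tuple[pd.Series, pd.DataFrame]:
    """Hierarchical clustering of expression profiles into k archetypes.

    Distance is 1 - Pearson correlation between profiles (rows),
    linkage is average; the tree is cut at ``k`` clusters. Rows are
    sorted by gene id first so the result is deterministic, and
    zero-variance profiles are excluded with a warning. Returns
    (assignments indexed by gene, cluster mean profiles of the
    standardized data).
    """

    import warnings

    profiles = profiles.sort_index()
    var = profiles.var(axis=1, ddof=0)
    dropped = profiles.index[var == 0]
    if len(dropped):
        warnings.warn(f"excluded {len(dropped)} zero-variance profile(s)")
    prof = profiles.loc[var > 0]
    if len(prof) < k:
        raise ValueError(f"need at least k={k} variable profiles")
    X = prof.to_numpy(dtype=float)
    X = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
    d = pdist(X, metric="correlation")  # 1 - Pearson r
    Z = linkage(d, method="average")
    labels = fcluster(Z, t=k, criterion="maxclust")
    assign = pd.Series(labels, index=prof.index, name="cluster")
    means = pd.DataFrame(
        {c: X[labels == c].mean(axis=0) for c in sorted(set(labels))},
        index=prof.columns,
    ).T
    return assign, means


# ---------------------------------------------------------------------------
# pair report
# ---------------------------------------------------------------------------

def _mode_from_flags(sig1: bool, sig2: bool, different_dynamics: bool) -> str:
    if sig1 != sig2:
        return "one-copy-regulated"
    if sig1 and sig2 and different_dynamics:
        return "different-dynamics"
    return "none"


def pair_divergence_report(
    pairs: pd.DataFrame,
    edi_summary: pd.DataFrame | None = None,
    gene_significance: dict[str, pd.Series] | None = None,
    clusters: pd.Series | None = None,
    profile_p: pd.Series | None = None,
    interaction_p: pd.Series | None = None,
    p_profile: float = 0.01,
    alpha_interaction: float = 0.05,
) -> pd.DataFrame:
    """Combine all divergence evidence into one row per pair.

    ``gene_significance`` maps an assay name (e.g. 'timecourse', 'sw',
    'rhythm') to a boolean Series per gene; ``clusters`` assigns genes
    to archetype clusters; ``profile_p``/``interaction_p`` are indexed
    by pair id. Per assay a mode is derived (one-copy-regulated when
    exactly one copy is significant; different-dynamics when both are
    but sit in different clusters, or when the profile/interaction test
    rejects); the overall mode is 'both' when different assays show the
    two distinct modes.
    """

    gene_significance = gene_significance or {}
    rows = []
    for row in pairs.itertuples():
        pid = getattr(row, "orthogroup", f"{row.gene1}__{row.gene2}")
        rec: dict = {"pair": pid, "gene1": row.gene1, "gene2": row.gene2}
        if edi_summary is not None and pid in set(edi_summary["pair"]):
            rec["median_edi"] = float(
                edi_summary.loc[edi_summary["pair"] == pid, "median_edi"].iloc[0]
            )
        modes = set()
        for assay, sig in gene_significance.items():
            s1 = bool(sig.get(row.gene1, False))
            s2 = bool(sig.get(row.gene2, False))
            rec[f"{assay}_sig_gene1"], rec[f"{assay}_sig_gene2"] = s1, s2
            diff_dyn = False
            if clusters is not None and s1 and s2:
                c1, c2 = clusters.get(row.gene1), clusters.get(row.gene2)
                rec["cluster_gene1"], rec["cluster_gene2"] = c1, c2
                diff_dyn = c1 is not None and c2 is not None and c1 != c2
            mode = _mode_from_flags(s1, s2, diff_dyn)
            rec[f"{assay}_mode"] = mode
            if mode != "none":
                modes.add(mode)
        if profile_p is not None and pid in profile_p.index:
            rec["profile_p"] = float(profile_p[pid])
            if profile_p[pid] < p_profile:
                modes.add("different-dynamics")
        if interaction_p is not None and pid in interaction_p.index:
            rec["interaction_p"] = float(interaction_p[pid])
            if interaction_p[pid] < alpha_interaction:
                modes.add("different-dynamics")
        if not modes:
            rec["mode"] = "none"
        elif modes == {"one-copy-regulated"}:
            rec["mode"] = "one-copy-regulated"
        elif modes == {"different-dynamics"}:
            rec["mode"] = "different-dynamics"
        else:
            rec["mode"] = "both"
        rows.append(rec)
    return pd.DataFrame(rows)
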