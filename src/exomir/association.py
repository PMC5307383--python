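"""Phenotype group comparisons and miR-phenotype Spearman association maps.

Group comparisons follow a Shapiro-Wilk-gated scheme: if every group in a
comparison looks normal the parametric test is used (independent-samples t
for either postmenopausal group vs the premenopausal one, paired t for the
within-twin-pair HRT comparison), otherwise the rank-based analogue
(Mann-Whitney U, Wilcoxon signed-rank).  Associations between miR read
counts and phenotypes use Spearman's rank correlation with midrank ties,
BH-FDR over the full miR x phenotype grid, and a complete-linkage clustered
heatmap with two-tier significance marks (* nominal p<0.05, ** FDR q<0.05).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import dendrogram, linkage
from scipy.spatial.distance import pdist
from scipy.stats import mannwhitneyu, shapiro, spearmanr, ttest_ind, ttest_rel, wilcoxon

from .datatypes import (
    GROUP_HRT,
    GROUP_NOHRT,
    GROUP_PRE,
    CountMatrix,
    SampleTable,
)
from .twin_model import fdr_adjust

#: comparison label -> (first group, second group, paired?)
COMPARISON_SPEC = {
    "NOHRT_vs_PRE": (GROUP_NOHRT, GROUP_PRE, False),
    "HRT_vs_PRE": (GROUP_HRT, GROUP_PRE, False),
    "HRT_vs_NOHRT": (GROUP_HRT, GROUP_NOHRT, True),
}


@dataclass
class GroupTestResult:
    variable: str
    comparison: str
    test_used: str
    statistic: float
    p: float


def _values(series: pd.Series, samples: SampleTable, group: str) -> np.ndarray:
    ids = samples.group_samples(group)
    return series.reindex(ids).dropna().to_numpy(float)


def compare_groups(
    values: pd.Series,
    samples: SampleTable,
    alpha_normality: float = 0.05,
    variable: str = "",
) -> list[GroupTestResult]:
    """Three pairwise group comparisons of one phenotype.

    ``values`` is indexed by sample_id.  Each group entering a comparison is
    Shapiro-Wilk tested at ``alpha_normality``; the parametric branch is
    taken only when every involved group passes.  The twin comparison is
    paired via pair_id and requires complete pairs.
    """
    series = values if isinstance(values, pd.Series) else pd.Series(values, index=samples.sample_ids)
    normal = {}
    for g in (GROUP_PRE, GROUP_NOHRT, GROUP_HRT):
        v = _values(series, samples, g)
        if len(v) < 3:
            raise ValueError(f"group {g} needs >= 3 observations for the normality gate")
        normal[g] = shapiro(v).pvalue >= alpha_normality

    results = []
    for comp, (g1, g2, paired) in COMPARISON_SPEC.items():
        if paired:
            pairs = samples.pairs()
            a = series.reindex(pairs[g1]).to_numpy(float)
            b = series.reindex(pairs[g2]).to_numpy(float)
            keep = np.isfinite(a) & np.isfinite(b)
            if keep.sum() < len(pairs):
                raise ValueError(f"comparison {comp} has incomplete pairs")
            a, b = a[keep], b[keep]
            d = a - b
            if np.allclose(d, 0.0) or d.std(ddof=1) == 0.0:
                results.append(GroupTestResult(variable, comp, "t_paired", np.nan, np.nan))
                continue
            if normal[g1] and normal[g2]:
                st = ttest_rel(a, b)
                results.append(GroupTestResult(variable, comp, "t_paired", st.statistic, st.pvalue))
            else:
                st = wilcoxon(a, b)
                results.append(
                    GroupTestResult(variable, comp, "wilcoxon_paired", st.statistic, st.pvalue)
                )
        else:
            a = _values(series, samples, g1)
            b = _values(series, samples, g2)
            if normal[g1] and normal[g2]:
                st = ttest_ind(a, b)
                results.append(
                    GroupTestResult(variable, comp, "t_independent", st.statistic, st.pvalue)
                )
            else:
                st = mannwhitneyu(a, b, alternative="two-sided")
                results.append(
                    GroupTestResult(variable, comp, "mann_whitney", st.statistic, st.pvalue)
                )
    return results


def compare_groups_table(
    samples: SampleTable, variables: list[str] | None = None, alpha_normality: float = 0.05
) -> pd.DataFrame:
    """compare_groups over every phenotype column, as one tidy table."""
    variables = variables if variables is not None else samples.phenotype_names
    rows = []
    df = samples.table.set_index("sample_id")
    for var in variables:
        for r in compare_groups(df[var], samples, alpha_normality, variable=var):
            rows.append(vars(r))
    return pd.DataFrame(rows)


@dataclass
class AssociationMatrix:
    """Spearman rho/p/q matrices (miRs x phenotypes) plus clustering orders."""

    rho: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    row_order: list[str] | None = None
    col_order: list[str] | None = None
    row_linkage: np.ndarray | None = None
    col_linkage: np.ndarray | None = None

    def long(self) -> pd.DataFrame:
        out = (
            self.rho.stack().rename("rho").to_frame()
            .join(self.p.stack().rename("p"))
            .join(self.q.stack().rename("q"))
            .reset_index()
        )
        out.columns = ["mir_id", "phenotype", "rho", "p", "q"]
        return out


def spearman_association(
    counts: CountMatrix,
    phenotypes: SampleTable,
    sample_ids: list[str] | None = None,
    min_n: int = 4,
) -> AssociationMatrix:
    """Spearman correlation of each miR's counts with each phenotype.

    Missing phenotype values are dropped pairwise; cells with fewer than
    ``min_n`` complete observations or a constant vector are reported
    missing.  Nominal p-values use the t-approximation; q-values are BH over
    the full grid.
    """
    ids = sample_ids if sample_ids is not None else phenotypes.sample_ids
    cdf = counts.counts[ids]
    pdf_ = phenotypes.table.set_index("sample_id").loc[ids, phenotypes.phenotype_names]
    mirs = list(cdf.index)
    phenos = list(pdf_.columns)
    rho = np.full((len(mirs), len(phenos)), np.nan)
    pv = np.full_like(rho, np.nan)
    for j, ph in enumerate(phenos):
        y = pdf_[ph].to_numpy(float)
        ok = np.isfinite(y)
        if ok.sum() < min_n:
            continue
        for i, m in enumerate(mirs):
            x = cdf.loc[m].to_numpy(float)[ok]
            yy = y[ok]
            if np.all(x == x[0]) or np.all(yy == yy[0]):
                continue  # rho undefined for a constant vector
            r = spearmanr(x, yy)
            rho[i, j] = r.statistic
            pv[i, j] = r.pvalue
    qv = fdr_adjust(pv.ravel()).reshape(pv.shape)
    idx = pd.Index(mirs, name="mir_id")
    cols = pd.Index(phenos, name="phenotype")
    return AssociationMatrix(
        rho=pd.DataFrame(rho, index=idx, columns=cols),
        p=pd.DataFrame(pv, index=idx, columns=cols),
        q=pd.DataFrame(qv, index=idx, columns=cols),
    )


def _ordered_linkage(mat: np.ndarray, ids: list[str], method: str, metric: str):
    # pre-sort by id so equal-distance merges resolve deterministically
    order0 = np.argsort(ids, kind="mergesort")
    Z = linkage(pdist(mat[order0], metric=metric), method=method)
    leaves = dendrogram(Z, no_plot=True)["leaves"]
    return Z, [ids[order0[i]] for i in leaves], order0


def cluster_heatmap(
    assoc: AssociationMatrix,
    method: str = "complete",
    metric: str = "euclidean",
    fig_path=None,
) -> AssociationMatrix:
    """Hierarchically cluster the rho matrix rows and columns.

    Returns a new AssociationMatrix with leaf orders and linkages attached;
    rho/p/q values are untouched.  If ``fig_path`` is given, draws the
    clustered heatmap with significance marks (* nominal, ** FDR).
    """
    rho = assoc.rho
    if rho.shape[0] < 2 or rho.shape[1] < 2:
        raise ValueError("clustering needs at least 2 rows and 2 columns")
    if rho.isna().all(axis=1).any() or rho.isna().all(axis=0).any():
        raise ValueError("all-missing rows/columns cannot be clustered")
    filled = rho.fillna(0.0).to_numpy()
    row_Z, row_order, _ = _ordered_linkage(filled, list(rho.index), method, metric)
    col_Z, col_order, _ = _ordered_linkage(filled.T, list(rho.columns), method, metric)
    out = AssociationMatrix(
        rho=assoc.rho,
        p=assoc.p,
        q=assoc.q,
        row_order=row_order,
        col_order=col_order,
        row_linkage=row_Z,
        col_linkage=col_Z,
    )
    if fig_path is not None:
        _draw_heatmap(out, fig_path)
    return out


def _draw_heatmap(assoc: AssociationMatrix, fig_path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    rho = assoc.rho.loc[assoc.row_order, assoc.col_order]
    p = assoc.p.loc[assoc.row_order, assoc.col_order]
    q = assoc.q.loc[assoc.row_order, assoc.col_order]
    marks = np.where(q < 0.05, "**", np.where(p < 0.05, "*", ""))
    fig, ax = plt.subplots(
        figsize=(1.2 + 0.5 * rho.shape[1], 1.2 + 0.35 * rho.shape[0])
    )
    sns.heatmap(
        rho,
        cmap="RdBu_r",
        vmin=-1,
        vmax=1,
        center=0,
        annot=marks,
        fmt="",
        cbar_kws={"label": "Spearman rho"},
        ax=ax,
    )
    ax.set_xlabel("")
    ax.set_ylabel("")
    fig.tight_layout()
    fig.savefig(fig_path, dpi=150)
    plt.close(fig)
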