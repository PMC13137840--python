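"""Differential CpG methylation calling between two groups.

The model follows the standard replicated bisulfite workflow: per-CpG
binomial logistic regression of methylated/unmethylated counts on a group
indicator, a likelihood-ratio test against the intercept-only model,
Benjamini-Hochberg correction, and a joint call on q-value and pooled
percent methylation difference.  With a single binary covariate the
binomial logistic MLE has a closed form (the group-pooled proportions), so
the LRT is computed exactly and vectorised over sites; there is no
iterative fit and hence no convergence failure path.  A pooled two-sided
Fisher exact test is the alternative back-end, selected automatically when
either group has a single sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from scipy.special import xlogy
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .io import GeneCatalog
from .simulate import _promoter_interval

__all__ = [
    "MethylationMatrix",
    "merge_samples",
    "filter_coverage",
    "test_sites",
    "adjust_bh",
    "meth_diff",
    "call_dm",
    "annotate_sites",
    "classify_gene_meth_status",
    "DifferentialMethylation",
]


@dataclass
class MethylationMatrix:
    """Per-CpG counts across samples with a two-group design.

    ``sites`` holds (chrom, pos); ``count_meth`` and ``count_total`` are
    (n_sites, n_samples) arrays aligned with ``samples``.
    """

    sites: pd.DataFrame
    count_meth: np.ndarray
    count_total: np.ndarray
    samples: list
    design: dict
    n_dropped_sites: int = 0

    def __post_init__(self):
        if (self.count_meth > self.count_total).any():
            raise ValueError("count_meth exceeds count_total")
        if (self.count_meth < 0).any():
            raise ValueError("negative counts")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def group_masks(self) -> tuple[np.ndarray, np.ndarray, str, str]:
        """Masks for (test, reference) samples.

        Group names are ordered so that ``test`` is the lexicographically
        later label unless the design uses the conventional names
        ``test``/``ref``, which are honoured directly.
        """
        groups = sorted({self.design[s] for s in self.samples})
        if len(groups) != 2:
            raise ValueError(f"need exactly 2 groups, got {groups}")
        if set(groups) == {"test", "ref"}:
            g_test, g_ref = "test", "ref"
        else:
            g_ref, g_test = groups  # alphabetical: first = reference
        lab = np.array([self.design[s] for s in self.samples])
        return lab == g_test, lab == g_ref, g_test, g_ref


def merge_samples(samples: dict, design: dict) -> MethylationMatrix:
    """Intersect site keys across samples into one count matrix.

    ``samples`` maps sample name to a coverage DataFrame (``chrom, pos,
    count_meth, count_unmeth``); ``design`` maps sample name to group.
    Sites missing from any sample are dropped and counted.
    """
    names = list(samples)
    if not names:
        raise ValueError("no samples")
    groups = {}
    for s in names:
        if s not in design:
            raise ValueError(f"sample {s!r} not in design")
        groups.setdefault(design[s], []).append(s)
    for g, members in groups.items():
        if not members:
            raise ValueError(f"group {g!r} has no samples")

    key = ["chrom", "pos"]
    indexed = {s: df.set_index(key) for s, df in samples.items()}
    common = indexed[names[0]].index
    union = indexed[names[0]].index
    for s in names[1:]:
        common = common.intersection(indexed[s].index)
        union = union.union(indexed[s].index)
    common = common.sortlevel()[0]
    n_dropped = len(union) - len(common)

    meth = np.empty((len(common), len(names)), dtype=np.int64)
    total = np.empty_like(meth)
    for j, s in enumerate(names):
        sub = indexed[s].loc[common]
        meth[:, j] = sub["count_meth"].to_numpy()
        total[:, j] = (sub["count_meth"] + sub["count_unmeth"]).to_numpy()
    sites = pd.DataFrame(list(common), columns=key)
    return MethylationMatrix(
        sites=sites,
        count_meth=meth,
        count_total=total,
        samples=names,
        design=dict(design),
        n_dropped_sites=n_dropped,
    )


def filter_coverage(
    matrix: MethylationMatrix,
    min_total_across: int = 10,
    min_per_sample: int = 1,
) -> MethylationMatrix:
    """Keep sites with summed coverage strictly above ``min_total_across``
    and every sample at or above ``min_per_sample`` reads."""
    keep = (matrix.count_total.sum(axis=1) > min_total_across) & (
        matrix.count_total >= min_per_sample
    ).all(axis=1)
    return MethylationMatrix(
        sites=matrix.sites.loc[keep].reset_index(drop=True),
        count_meth=matrix.count_meth[keep],
        count_total=matrix.count_total[keep],
        samples=matrix.samples,
        design=matrix.design,
        n_dropped_sites=matrix.n_dropped_sites,
    )


def _binom_ll(m, t, p):
    """Binomial log-likelihood kernel (constants dropped), 0*log(0) = 0."""
    return xlogy(m, p) + xlogy(t - m, 1.0 - p)


def _logistic_lrt_p(matrix: MethylationMatrix) -> np.ndarray:
    """Vectorised LRT p for the binomial logistic group model.

    With one binary covariate the fitted probabilities are the group-pooled
    proportions, so the LRT reduces to the pooled group vs overall
    log-likelihood difference; the statistic is referred to chi-square(1).
    """
    test, ref, _, _ = matrix.group_masks()
    M_t = matrix.count_meth[:, test].sum(axis=1)
    T_t = matrix.count_total[:, test].sum(axis=1)
    M_r = matrix.count_meth[:, ref].sum(axis=1)
    T_r = matrix.count_total[:, ref].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_t = np.where(T_t > 0, M_t / np.maximum(T_t, 1), 0.0)
        p_r = np.where(T_r > 0, M_r / np.maximum(T_r, 1), 0.0)
        p_0 = (M_t + M_r) / np.maximum(T_t + T_r, 1)
    ll_alt = _binom_ll(M_t, T_t, p_t) + _binom_ll(M_r, T_r, p_r)
    ll_null = _binom_ll(M_t + M_r, T_t + T_r, p_0)
    lrt = np.maximum(2.0 * (ll_alt - ll_null), 0.0)
    return stats.chi2.sf(lrt, df=1)


def _fisher_pooled_p(matrix: MethylationMatrix) -> np.ndarray:
    """Two-sided Fisher exact test on group-pooled 2x2 tables."""
    test, ref, _, _ = matrix.group_masks()
    M_t = matrix.count_meth[:, test].sum(axis=1)
    U_t = matrix.count_total[:, test].sum(axis=1) - M_t
    M_r = matrix.count_meth[:, ref].sum(axis=1)
    U_r = matrix.count_total[:, ref].sum(axis=1) - M_r
    p = np.empty(matrix.n_sites)
    for i in range(matrix.n_sites):
        p[i] = stats.fisher_exact(
            [[M_t[i], U_t[i]], [M_r[i], U_r[i]]], alternative="two-sided"
        )[1]
    return p


def test_sites(matrix: MethylationMatrix, method: str = "logistic") -> np.ndarray:
    """Per-site p-values for group differential methylation.

    ``method`` is ``logistic`` (binomial logistic LRT) or ``fisher_pooled``
    (two-sided exact test on pooled counts).  The Fisher back-end is
    selected automatically when either group has exactly one sample.
    """
    test, ref, _, _ = matrix.group_masks()
    if method == "logistic" and (test.sum() == 1 or ref.sum() == 1):
        method = "fisher_pooled"
    if method == "logistic":
        return _logistic_lrt_p(matrix)
    if method == "fisher_pooled":
        return _fisher_pooled_p(matrix)
    raise ValueError(f"unknown method {method!r}")


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def meth_diff(matrix: MethylationMatrix) -> np.ndarray:
    """Group-pooled percent methylation difference (test - reference)."""
    test, ref, _, _ = matrix.group_masks()
    M_t = matrix.count_meth[:, test].sum(axis=1)
    T_t = matrix.count_total[:, test].sum(axis=1)
    M_r = matrix.count_meth[:, ref].sum(axis=1)
    T_r = matrix.count_total[:, ref].sum(axis=1)
    if (T_t == 0).any() or (T_r == 0).any():
        raise ValueError("zero group total; apply the coverage filter first")
    return 100.0 * (M_t / T_t - M_r / T_r)


def site_stats(matrix: MethylationMatrix, method: str = "logistic") -> pd.DataFrame:
    """All per-site statistics: meth_diff, p, q."""
    out = matrix.sites.copy()
    out["meth_diff"] = meth_diff(matrix)
    out["p"] = test_sites(matrix, method=method)
    out["q"] = adjust_bh(out["p"].to_numpy())
    return out


def call_dm(
    matrix: MethylationMatrix,
    q_threshold: float = 0.05,
    diff_threshold: float = 10.0,
    method: str = "logistic",
) -> pd.DataFrame:
    """Call DM sites at q < ``q_threshold`` and |diff| > ``diff_threshold``.

    Both inequalities are strict.  Returns a DataFrame with ``chrom, pos,
    meth_diff, p, q, direction``.
    """
    table = site_stats(matrix, method=method)
    keep = (table["q"] < q_threshold) & (table["meth_diff"].abs() > diff_threshold)
    out = table.loc[keep].reset_index(drop=True)
    out["direction"] = np.where(out["meth_diff"] > 0, "hyper", "hypo")
    return out


# --------------------------------------------------------------------------
# feature annotation


def annotate_sites(
    dm_sites: pd.DataFrame,
    catalog: GeneCatalog,
    promoter_window: tuple = (1000, 1000),
    max_tss_distance: int = 100_000,
) -> pd.DataFrame:
    """Annotate sites with genomic feature, gene and signed TSS distance.

    Feature precedence is promoter > exon > intron > intergenic; the
    promoter window is strand-oriented around the TSS.  Intergenic sites
    are assigned the nearest-TSS gene within ``max_tss_distance`` (empty
    gene_id beyond it).  The signed distance is ``pos - tss`` on the plus
    strand and ``tss - pos`` on the minus strand (downstream positive).
    """
    up, down = promoter_window
    prom_trees: dict[str, IntervalTree] = {}
    span_trees: dict[str, IntervalTree] = {}
    tss_by_chrom: dict[str, list] = {}
    for g in catalog:
        p0, p1 = _promoter_interval(g, up, down)
        prom_trees.setdefault(g.chrom, IntervalTree())[max(p0, 0):p1] = g
        span_trees.setdefault(g.chrom, IntervalTree())[g.tx_start:g.tx_end] = g
        tss_by_chrom.setdefault(g.chrom, []).append((g.tss, g))
    tss_sorted = {
        c: sorted(v, key=lambda t: (t[0], t[1].gene_id))
        for c, v in tss_by_chrom.items()
    }
    tss_arrays = {c: np.array([t[0] for t in v]) for c, v in tss_sorted.items()}

    def signed_dist(pos, g):
        return pos - g.tss if g.strand == "+" else g.tss - pos

    features, gene_ids, distances = [], [], []
    warned_chroms = set()
    for row in dm_sites.itertuples(index=False):
        chrom, pos = row.chrom, row.pos
        if chrom not in tss_arrays:
            if chrom not in warned_chroms:
                warnings.warn(
                    f"chromosome {chrom!r} absent from the gene catalog; "
                    f"sites there are intergenic",
                    stacklevel=2,
                )
                warned_chroms.add(chrom)
            features.append("intergenic")
            gene_ids.append("")
            distances.append(np.nan)
            continue
        prom_hits = [iv.data for iv in prom_trees[chrom][pos]]
        if prom_hits:
            g = min(prom_hits, key=lambda g: (abs(pos - g.tss), g.gene_id))
            features.append("promoter")
            gene_ids.append(g.gene_id)
            distances.append(signed_dist(pos, g))
            continue
        span_hits = [iv.data for iv in span_trees.get(chrom, IntervalTree())[pos]]
        if span_hits:
            g = min(span_hits, key=lambda g: (abs(pos - g.tss), g.gene_id))
            in_exon = any(s <= pos < e for s, e in g.exons)
            features.append("exon" if in_exon else "intron")
            gene_ids.append(g.gene_id)
            distances.append(signed_dist(pos, g))
            continue
        # intergenic: nearest TSS within the window
        arr = tss_arrays[chrom]
        i = np.searchsorted(arr, pos)
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(arr):
                g = tss_sorted[chrom][j][1]
                d = abs(pos - g.tss)
                if best is None or d < best[0]:
                    best = (d, g)
        if best is not None and best[0] <= max_tss_distance:
            features.append("intergenic")
            gene_ids.append(best[1].gene_id)
            distances.append(signed_dist(pos, best[1]))
        else:
            features.append("intergenic")
            gene_ids.append("")
            distances.append(np.nan)

    out = dm_sites.reset_index(drop=True).copy()
    out["feature"] = features
    out["gene_id"] = gene_ids
    out["signed_tss_distance"] = distances
    return out


def classify_gene_meth_status(
    annotated_sites: pd.DataFrame, scope: str = "promoter"
) -> pd.DataFrame:
    """Classify genes as hypo_only / hyper_only / mixed over their DM sites.

    ``scope='promoter'`` considers promoter sites only; ``scope='whole_gene'``
    considers promoter, exon and intron sites.  Genes with no DM sites in
    scope are absent from the output.
    """
    if scope == "promoter":
        mask = annotated_sites["feature"] == "promoter"
    elif scope == "whole_gene":
        mask = annotated_sites["feature"].isin(["promoter", "exon", "intron"])
    else:
        raise ValueError(f"unknown scope {scope!r}")
    sub = annotated_sites.loc[mask & (annotated_sites["gene_id"] != "")]
    rows = []
    for gid, grp in sub.groupby("gene_id", sort=True):
        n_hypo = int((grp["direction"] == "hypo").sum())
        n_hyper = int((grp["direction"] == "hyper").sum())
        if n_hypo and n_hyper:
            status = "mixed"
        elif n_hypo:
            status = "hypo_only"
        else:
            status = "hyper_only"
        rows.append((gid, status, n_hypo, n_hyper, n_hypo + n_hyper))
    return pd.DataFrame(
        rows, columns=["gene_id", "status", "n_hypo", "n_hyper", "n_sites"]
    )


class DifferentialMethylation(BaseEstimator):
    """Two-group differential-methylation caller.

    Parameters
    ----------
    min_total_coverage : int
        Sites must have summed coverage strictly above this across samples.
    min_per_sample : int
        Minimum coverage required in every sample.
    method : {'logistic', 'fisher_pooled'}
        Per-site test; 'fisher_pooled' is auto-selected for 1-vs-n designs.
    q_threshold, diff_threshold : float
        Strict DM cutoffs on the BH q-value and the absolute pooled percent
        methylation difference.

    Attributes
    ----------
    matrix_ : MethylationMatrix
        Merged, coverage-filtered count matrix.
    results_ : DataFrame
        Per-site statistics for every retained site.
    dm_sites_ : DataFrame
        Sites passing both DM cutoffs, with direction.
    n_dropped_sites_, n_filtered_sites_ : int
        Sites lost at merging and at coverage filtering.
    """

    def __init__(
        self,
        min_total_coverage: int = 10,
        min_per_sample: int = 1,
        method: str = "logistic",
        q_threshold: float = 0.05,
        diff_threshold: float = 10.0,
    ):
        self.min_total_coverage = min_total_coverage
        self.min_per_sample = min_per_sample
        self.method = method
        self.q_threshold = q_threshold
        self.diff_threshold = diff_threshold

    def fit(self, samples: dict, design: dict):
        merged = merge_samples(samples, design)
        self.n_dropped_sites_ = merged.n_dropped_sites
        self.matrix_ = filter_coverage(
            merged,
            min_total_across=self.min_total_coverage,
            min_per_sample=self.min_per_sample,
        )
        self.n_filtered_sites_ = merged.n_sites - self.matrix_.n_sites
        self.results_ = site_stats(self.matrix_, method=self.method)
        keep = (self.results_["q"] < self.q_threshold) & (
            self.results_["meth_diff"].abs() > self.diff_threshold
        )
        dm = self.results_.loc[keep].reset_index(drop=True)
        dm["direction"] = np.where(dm["meth_diff"] > 0, "hyper", "hypo")
        self.dm_sites_ = dm
        return self
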