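"""Sample-exclusion diagnostics on promoter methylation matrices.

The screen mirrors the standard multivariate QC sequence for small
group-structured designs: pool percent methylation per gene promoter, run a
PCA with group centroid overlays, measure each sample's distance to its own
group centroid, test homogeneity of multivariate dispersion by label
permutation, and flag samples that either sit extremely far from their
centroid or closer to another group's centroid.  Flags are reported, never
auto-applied — exclusion remains a user decision.

The extreme-distance rule is calibrated against a Gaussian within-group
null: squared centroid distances, corrected for the own-sample term and
scaled by the pooled within-group variance, are referred to an F
distribution with a Bonferroni familywise level (default 0.001).  A robust
MAD-based z-score is unusable here: with 3-4 samples per group the MAD has
no breakdown resistance and centroid distances are Rayleigh-skewed, so a
z>3 rule flags a large fraction of perfectly clean cohorts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .io import GeneCatalog
from .simulate import _promoter_interval

__all__ = [
    "promoter_matrix",
    "pca_scores",
    "centroid_distances",
    "dispersion_test",
    "flag_outliers",
    "QCReport",
    "PromoterOutlierQC",
]


def promoter_matrix(
    samples: dict,
    catalog: GeneCatalog,
    promoter_window: tuple = (1000, 1000),
) -> pd.DataFrame:
    """Samples x promoters pooled percent-methylation matrix.

    Per sample and gene, percent methylation is pooled over the CpGs covered
    inside the strand-oriented promoter window.  Promoters covered in every
    sample are retained; columns are ordered by (chrom, tss).
    """
    up, down = promoter_window
    genes = sorted(catalog, key=lambda g: (g.chrom, g.tss, g.gene_id))
    cols = {}
    for name, cov in samples.items():
        by_chrom = {}
        for chrom, grp in cov.groupby("chrom", sort=False):
            order = np.argsort(grp["pos"].to_numpy(), kind="mergesort")
            pos = grp["pos"].to_numpy()[order]
            meth = grp["count_meth"].to_numpy()[order]
            total = meth + grp["count_unmeth"].to_numpy()[order]
            cm = np.concatenate([[0], np.cumsum(meth)])
            ct = np.concatenate([[0], np.cumsum(total)])
            by_chrom[chrom] = (pos, cm, ct)
        vals = {}
        for g in genes:
            if g.chrom not in by_chrom:
                continue
            pos, cm, ct = by_chrom[g.chrom]
            p0, p1 = _promoter_interval(g, up, down)
            lo = np.searchsorted(pos, p0, side="left")
            hi = np.searchsorted(pos, p1, side="left")
            m = cm[hi] - cm[lo]
            t = ct[hi] - ct[lo]
            if t > 0:
                vals[g.gene_id] = 100.0 * m / t
        cols[name] = vals
    frame = pd.DataFrame(cols).T  # samples x promoters
    frame = frame.dropna(axis=1)  # promoters covered in all samples
    ordered = [g.gene_id for g in genes if g.gene_id in frame.columns]
    return frame[ordered]


def pca_scores(matrix: pd.DataFrame, n_pcs: int = 2):
    """Column-centred SVD scores and explained-variance fractions.

    Sign convention: within each component, the loading of largest
    magnitude is made positive.
    """
    X = matrix.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n_pcs, len(s))
    for j in range(k):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] = -Vt[j]
            U[:, j] = -U[:, j]
    scores = U[:, :k] * s[:k]
    var = s**2
    evr = var[:k] / var.sum() if var.sum() > 0 else np.zeros(k)
    return (
        pd.DataFrame(
            scores, index=matrix.index, columns=[f"PC{j + 1}" for j in range(k)]
        ),
        evr,
    )


def centroid_distances(scores: pd.DataFrame, groups: dict) -> pd.DataFrame:
    """Distance of each sample to its own-group centroid, plus the nearest
    centroid over all groups (the sample is included in its own centroid)."""
    lab = np.array([groups[s] for s in scores.index])
    X = scores.to_numpy(dtype=float)
    names = sorted(set(lab))
    cents = {g: X[lab == g].mean(axis=0) for g in names}
    dist = np.array([np.linalg.norm(X[i] - cents[lab[i]]) for i in range(len(X))])
    nearest = []
    for i in range(len(X)):
        d_all = {g: np.linalg.norm(X[i] - cents[g]) for g in names}
        nearest.append(min(sorted(d_all), key=lambda g: d_all[g]))
    return pd.DataFrame(
        {"group": lab, "distance": dist, "nearest_centroid": nearest},
        index=scores.index,
    )


def _dispersion_f(X: np.ndarray, lab: np.ndarray) -> float:
    """One-way F statistic on distances to own-group centroids."""
    names = sorted(set(lab))
    d = np.empty(len(X))
    for g in names:
        m = lab == g
        c = X[m].mean(axis=0)
        d[m] = np.linalg.norm(X[m] - c, axis=1)
    grand = d.mean()
    ssb = sum((lab == g).sum() * (d[lab == g].mean() - grand) ** 2 for g in names)
    ssw = sum(((d[lab == g] - d[lab == g].mean()) ** 2).sum() for g in names)
    df_b = len(names) - 1
    df_w = len(X) - len(names)
    if ssw == 0 or df_w <= 0:
        return np.nan
    return (ssb / df_b) / (ssw / df_w)


def dispersion_test(
    scores: pd.DataFrame,
    groups: dict,
    n_permutations: int = 9999,
    random_state=None,
) -> dict:
    """Permutation test for homogeneity of multivariate dispersions.

    For every group pair (and the overall comparison when more than two
    groups are present) the observed F statistic on distances-to-own-
    centroid is compared with label permutations; p = (1 + #{F_perm >=
    F_obs}) / (n + 1).  Degenerate zero within-group spread yields p = 1
    with a warning.
    """
    rng = np.random.default_rng(random_state)
    X = scores.to_numpy(dtype=float)
    lab = np.array([groups[s] for s in scores.index])
    names = sorted(set(lab))
    comparisons = [tuple(names)] if len(names) > 2 else []
    comparisons += [
        (a, b) for i, a in enumerate(names) for b in names[i + 1:]
    ]
    out = {}
    for comp in comparisons:
        m = np.isin(lab, comp)
        Xc, lc = X[m], lab[m]
        f_obs = _dispersion_f(Xc, lc)
        key = " vs ".join(comp) if len(comp) == 2 else "overall"
        if not np.isfinite(f_obs):
            warnings.warn(
                f"{key}: degenerate dispersion statistic (zero within-group "
                f"spread); p = 1",
                stacklevel=2,
            )
            out[key] = 1.0
            continue
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(lc)
            f = _dispersion_f(Xc, perm)
            if np.isfinite(f) and f >= f_obs:
                count += 1
        out[key] = (1 + count) / (n_permutations + 1)
    return out


def flag_outliers(
    distances: pd.DataFrame,
    n_dims: int,
    alpha: float = 0.001,
) -> pd.DataFrame:
    """Flag extreme-distance and wrong-centroid samples.

    The squared distance to the own-group centroid, deflation-corrected for
    the sample's own contribution to the centroid (factor 1 - 1/n_g) and
    scaled by the leave-one-out pooled within-group variance (so an extreme
    sample cannot mask itself), is referred to F(n_dims, n_dims * (N - 1 -
    G)) at a Bonferroni-adjusted familywise level ``alpha``.  Samples whose
    nearest centroid is another group's are flagged ``wrong_centroid``.
    Zero pooled variance disables distance flags (degenerate rule).
    """
    lab = distances["group"].to_numpy()
    d = distances["distance"].to_numpy(dtype=float)
    names = sorted(set(lab))
    N, G = len(d), len(names)
    df_w = n_dims * (N - 1 - G)
    flags, reasons = [], []
    d2 = d**2
    if df_w > 0 and d2.sum() > 0:
        sigma2_loo = (d2.sum() - d2) / df_w  # excludes the tested sample
        fac = np.array([1.0 - 1.0 / (lab == g).sum() for g in lab])
        with np.errstate(divide="ignore", invalid="ignore"):
            t = d2 / (fac * n_dims * sigma2_loo)
        # zero leave-one-out spread: flag only a genuinely nonzero distance
        t[~np.isfinite(t)] = np.inf
        t[d2 == 0] = 0.0
        crit = stats.f.isf(alpha / N, n_dims, df_w)
    else:
        t = np.zeros(N)
        crit = np.inf
    wrong = distances["nearest_centroid"].to_numpy() != lab
    for i in range(N):
        reason = []
        if wrong[i]:
            reason.append("wrong_centroid")
        if t[i] > crit:
            reason.append("extreme_distance")
        flags.append(bool(reason))
        reasons.append(",".join(reason))
    out = distances.copy()
    out["distance_stat"] = t
    out["flag"] = flags
    out["reason"] = reasons
    return out


@dataclass
class QCReport:
    """Per-sample QC diagnostics: PC scores, centroid distances, flags,
    and dispersion-test p-values."""

    scores: pd.DataFrame
    explained_variance: np.ndarray
    flags: pd.DataFrame
    dispersion_p: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "samples": {
                s: {
                    "scores": [float(v) for v in self.scores.loc[s]],
                    "group": str(self.flags.loc[s, "group"]),
                    "distance": float(self.flags.loc[s, "distance"]),
                    "nearest_centroid": str(self.flags.loc[s, "nearest_centroid"]),
                    "flag": bool(self.flags.loc[s, "flag"]),
                    "reason": str(self.flags.loc[s, "reason"]),
                }
                for s in self.scores.index
            },
            "explained_variance": [float(v) for v in self.explained_variance],
            "dispersion_p": {k: float(v) for k, v in self.dispersion_p.items()},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)


class PromoterOutlierQC(BaseEstimator):
    """PCA centroid-distance outlier screen for promoter methylation.

    Parameters
    ----------
    n_pcs : int
        Principal components retained for distances (default 2).
    alpha : float
        Familywise level of the calibrated extreme-distance rule.
    n_permutations : int
        Label permutations for the dispersion test (0 disables it).
    space : {'pca', 'raw'}
        Whether distances are measured in PC space or raw feature space.
    random_state : int or None
        Seed for the dispersion permutations.

    Attributes
    ----------
    report_ : QCReport
    matrix_ : DataFrame — the promoter percent-methylation matrix used.
    """

    def __init__(
        self,
        n_pcs: int = 2,
        alpha: float = 0.001,
        n_permutations: int = 9999,
        space: str = "pca",
        random_state=None,
    ):
        self.n_pcs = n_pcs
        self.alpha = alpha
        self.n_permutations = n_permutations
        self.space = space
        self.random_state = random_state

    def fit(self, samples, design: dict, catalog: GeneCatalog | None = None,
            promoter_window: tuple = (1000, 1000)):
        """Run the screen.

        ``samples`` is either a dict of per-sample coverage DataFrames
        (requires ``catalog``) or a precomputed samples x features matrix.
        """
        if isinstance(samples, pd.DataFrame):
            matrix = samples
        else:
            if catalog is None:
                raise ValueError("catalog required to build the promoter matrix")
            matrix = promoter_matrix(samples, catalog, promoter_window)
        # deterministic sample order regardless of input order
        matrix = matrix.sort_index()
        self.matrix_ = matrix
        scores, evr = pca_scores(matrix, n_pcs=self.n_pcs)
        space = scores if self.space == "pca" else matrix
        ndim = space.shape[1]
        dist = centroid_distances(space, design)
        flags = flag_outliers(dist, n_dims=ndim, alpha=self.alpha)
        disp = (
            dispersion_test(
                space,
                design,
                n_permutations=self.n_permutations,
                random_state=self.random_state,
            )
            if self.n_permutations
            else {}
        )
        self.report_ = QCReport(
            scores=scores,
            explained_variance=evr,
            flags=flags,
            dispersion_p=disp,
        )
        return self
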