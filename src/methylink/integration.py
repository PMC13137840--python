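"""Methylome-transcriptome integration by regulatory-potential scoring.

Each gene g receives a regulatory potential

    s_g = sum_i exp(-(0.5 + 4 * d_i / W))

over the differentially methylated CpG sites within W = 100 kb of its TSS,
where d_i is the unsigned site-TSS distance (so the boundary term is
e^{-4.5} and a site at the TSS contributes e^{-0.5}).  Genes are ranked by
potential and, within the up- and down-regulated DE partitions, by DE
significance; the product of normalised ranks is the joint evidence score.
Up-regulated genes with a rank product below the cutoff are "activated"
targets, down-regulated ones "repressed", everything else a non-target.
Significance of the coupling is assessed with one-tailed KS tests of the
DE sets' potential ranks against background, and per-gene empirical
p-values come from re-placing the observed sites uniformly across the
catalog's TSS neighbourhoods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .io import GeneCatalog

__all__ = [
    "scaled_distance",
    "regulatory_potential",
    "partition_de",
    "rank_product",
    "ks_function_test",
    "permutation_test",
    "call_targets",
    "compare_targets",
    "FunctionTestResult",
    "RegulatoryPotentialIntegrator",
]

DEFAULT_WINDOW = 100_000


def scaled_distance(site_pos: int, tss: int, window: int = DEFAULT_WINDOW):
    """Distance from TSS scaled to [0, 1] by the inclusion window.

    Returns ``None`` when the site lies strictly beyond the window.
    """
    d = abs(site_pos - tss)
    if d > window:
        return None
    return d / window


def _site_term(delta):
    return np.exp(-(0.5 + 4.0 * np.asarray(delta, dtype=float)))


def regulatory_potential(
    catalog: GeneCatalog,
    dm_sites: pd.DataFrame,
    window: int = DEFAULT_WINDOW,
    direction_filter: str = "none",
    max_sites: int | None = None,
) -> pd.DataFrame:
    """Per-gene regulatory potential over DM sites within the TSS window.

    ``dm_sites`` needs columns ``chrom, pos`` and, for the direction
    breakdown, ``direction``; ``direction_filter`` restricts scoring to
    hypo- or hypermethylated sites.  ``max_sites`` keeps only the top-N
    sites by ascending q (requires a ``q`` column).

    Returns a DataFrame indexed 0..n_genes-1 with columns ``gene_id, s_g,
    k, n_hypo, n_hyper, mean_abs_tss_distance``.
    """
    sites = dm_sites
    if direction_filter != "none":
        if direction_filter not in ("hypo", "hyper"):
            raise ValueError(f"unknown direction_filter {direction_filter!r}")
        sites = sites.loc[sites["direction"] == direction_filter]
    if max_sites is not None and len(sites) > max_sites:
        if "q" not in sites.columns:
            raise ValueError("max_sites requires a q column on the DM sites")
        sites = sites.nsmallest(max_sites, "q", keep="first")

    pos_by_chrom: dict[str, np.ndarray] = {}
    dir_by_chrom: dict[str, np.ndarray] = {}
    has_dir = "direction" in sites.columns
    for chrom, grp in sites.groupby("chrom", sort=True):
        order = np.argsort(grp["pos"].to_numpy(), kind="mergesort")
        pos_by_chrom[chrom] = grp["pos"].to_numpy()[order]
        if has_dir:
            dir_by_chrom[chrom] = grp["direction"].to_numpy()[order]

    rows = []
    for g in catalog:
        pos = pos_by_chrom.get(g.chrom)
        if pos is None or len(pos) == 0:
            rows.append((g.gene_id, 0.0, 0, 0, 0, np.nan))
            continue
        lo = np.searchsorted(pos, g.tss - window, side="left")
        hi = np.searchsorted(pos, g.tss + window, side="right")
        d = np.abs(pos[lo:hi] - g.tss)
        keep = d <= window
        d = d[keep]
        k = int(len(d))
        if k == 0:
            rows.append((g.gene_id, 0.0, 0, 0, 0, np.nan))
            continue
        s_g = float(_site_term(d / window).sum())
        if has_dir:
            dirs = dir_by_chrom[g.chrom][lo:hi][keep]
            n_hypo = int((dirs == "hypo").sum())
            n_hyper = int((dirs == "hyper").sum())
        else:
            n_hypo = n_hyper = 0
        rows.append((g.gene_id, s_g, k, n_hypo, n_hyper, float(d.mean())))
    return pd.DataFrame(
        rows,
        columns=["gene_id", "s_g", "k", "n_hypo", "n_hyper", "mean_abs_tss_distance"],
    )


def partition_de(de_table: pd.DataFrame, df: float = 0.05) -> pd.DataFrame:
    """Partition DE genes into up / down / background with DE ranks.

    up: padj < df and log2fc > 0; down: padj < df and log2fc < 0; all other
    genes are background (a significant gene with log2fc exactly 0 is moved
    to background with a warning).  ``rank_de`` is assigned within the up
    and down sets by ascending padj, ties by descending |log2fc| then
    gene_id; background genes have no DE rank.
    """
    out = de_table.copy().reset_index(drop=True)
    sig = out["padj"] < df
    zero_sig = sig & (out["log2fc"] == 0.0)
    if zero_sig.any():
        warnings.warn(
            f"{int(zero_sig.sum())} significant gene(s) with log2fc == 0 "
            f"assigned to background",
            stacklevel=2,
        )
    out["de_class"] = "background"
    out.loc[sig & (out["log2fc"] > 0), "de_class"] = "up"
    out.loc[sig & (out["log2fc"] < 0), "de_class"] = "down"
    out["rank_de"] = np.nan
    for cls in ("up", "down"):
        mask = out["de_class"] == cls
        sub = out.loc[mask].sort_values(
            by=["padj", "log2fc", "gene"],
            key=lambda s: -s.abs() if s.name == "log2fc" else s,
            kind="mergesort",
        )
        out.loc[sub.index, "rank_de"] = np.arange(1, len(sub) + 1)
    return out


def rank_potential(scores: pd.DataFrame) -> pd.DataFrame:
    """Rank genes by descending regulatory potential.

    Genes with positive potential get ordinal ranks 1..n (ties broken by
    gene_id); genes with zero potential all share the maximal rank N.
    """
    out = scores.copy().reset_index(drop=True)
    N = len(out)
    pos = out["s_g"] > 0
    sub = out.loc[pos].sort_values(
        by=["s_g", "gene_id"], ascending=[False, True], kind="mergesort"
    )
    out["rank_rp"] = N
    out.loc[sub.index, "rank_rp"] = np.arange(1, len(sub) + 1)
    out["rank_rp"] = out["rank_rp"].astype(int)
    return out


def rank_product(rank_rp, rank_de, n_rp: int, n_de: int) -> float:
    """Product of normalised ranks; lower = stronger joint evidence."""
    return (rank_rp / n_rp) * (rank_de / n_de)


@dataclass
class FunctionTestResult:
    """One-tailed KS comparison of DE-set potential ranks vs background."""

    p_activate: float
    p_repress: float
    n_up: int
    n_down: int
    n_background: int

    def to_dict(self) -> dict:
        return {
            "p_activate": self.p_activate,
            "p_repress": self.p_repress,
            "n_up": self.n_up,
            "n_down": self.n_down,
            "n_background": self.n_background,
        }


def ks_function_test(ranked: pd.DataFrame) -> FunctionTestResult:
    """Test whether up/down genes have systematically better potential ranks.

    ``ranked`` must carry ``rank_rp`` and ``de_class``.  The alternative is
    that the DE set's ranks are stochastically smaller than background's
    (i.e. higher regulatory potential).
    """
    ranks = {
        cls: ranked.loc[ranked["de_class"] == cls, "rank_rp"].to_numpy(dtype=float)
        for cls in ("up", "down", "background")
    }
    bg = ranks["background"]
    ps = {}
    for cls in ("up", "down"):
        x = ranks[cls]
        if len(x) == 0 or len(bg) == 0:
            warnings.warn(f"empty partition for {cls} vs background; p = 1")
            ps[cls] = 1.0
        else:
            # 'greater': CDF of the first sample is above the second's,
            # i.e. the DE set's ranks are stochastically smaller
            ps[cls] = float(stats.ks_2samp(x, bg, alternative="greater").pvalue)
    return FunctionTestResult(
        p_activate=ps["up"],
        p_repress=ps["down"],
        n_up=len(ranks["up"]),
        n_down=len(ranks["down"]),
        n_background=len(bg),
    )


def _merged_neighbourhoods(catalog: GeneCatalog, window: int):
    """Merged union of [tss - w, tss + w] per chromosome."""
    by_chrom: dict[str, list] = {}
    for g in catalog:
        by_chrom.setdefault(g.chrom, []).append((g.tss - window, g.tss + window + 1))
    merged = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        out = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = np.asarray(out)
    return merged


def permutation_test(
    scores: pd.DataFrame,
    dm_sites: pd.DataFrame,
    catalog: GeneCatalog,
    n_permutations: int = 100_000,
    window: int = DEFAULT_WINDOW,
    random_state=None,
) -> pd.DataFrame:
    """Per-gene empirical significance of the regulatory potential.

    The null re-places the observed number of DM sites uniformly across the
    merged union of all ±window TSS neighbourhoods and recomputes every
    gene's potential; ``perm_p = (1 + #{null s >= observed}) / (n + 1)``.
    Genes with zero observed potential get p = 1 by construction.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    rng = np.random.default_rng(random_state)
    n_sites = len(dm_sites)
    neigh = _merged_neighbourhoods(catalog, window)
    chroms = sorted(neigh)
    seg_chrom, seg_start, seg_len = [], [], []
    for c in chroms:
        for s, e in neigh[c]:
            seg_chrom.append(c)
            seg_start.append(s)
            seg_len.append(e - s)
    seg_start = np.asarray(seg_start)
    seg_len = np.asarray(seg_len, dtype=float)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]

    gene_ids = scores["gene_id"].to_numpy()
    obs = scores.set_index("gene_id")["s_g"]
    tss_by_chrom: dict[str, np.ndarray] = {}
    gidx_by_chrom: dict[str, np.ndarray] = {}
    for i, g in enumerate(catalog):
        tss_by_chrom.setdefault(g.chrom, []).append(g.tss)
        gidx_by_chrom.setdefault(g.chrom, []).append(i)
    for c in list(tss_by_chrom):
        order = np.argsort(tss_by_chrom[c])
        tss_by_chrom[c] = np.asarray(tss_by_chrom[c])[order]
        gidx_by_chrom[c] = np.asarray(gidx_by_chrom[c])[order]

    s_obs = np.array([obs.get(g, 0.0) for g in gene_ids])
    ge_count = np.zeros(len(gene_ids), dtype=np.int64)
    # map score-row order onto catalog order
    cat_ids = [g.gene_id for g in catalog]
    cat_to_row = {gid: r for r, gid in enumerate(gene_ids)}
    row_of_cat = np.array([cat_to_row.get(gid, -1) for gid in cat_ids])

    for _ in range(n_permutations):
        u = rng.random(n_sites) * total
        seg = np.searchsorted(cum, u, side="right") - 1
        pos = (seg_start[seg] + (u - cum[seg])).astype(np.int64)
        s_null_cat = _null_scores(
            pos, seg, seg_chrom, tss_by_chrom, gidx_by_chrom, len(cat_ids), window
        )
        s_null = np.zeros(len(gene_ids))
        ok = row_of_cat >= 0
        s_null[row_of_cat[ok]] = s_null_cat[ok]
        ge_count += s_null >= s_obs
    out = scores[["gene_id"]].copy()
    out["perm_p"] = (1.0 + ge_count) / (n_permutations + 1.0)
    return out


def _null_scores(pos, seg, seg_chrom, tss_by_chrom, gidx_by_chrom, n_genes, window):
    s = np.zeros(n_genes)
    chrom_of_site = np.asarray(seg_chrom, dtype=object)[seg]
    for c, tss in tss_by_chrom.items():
        mask = chrom_of_site == c
        if not mask.any():
            continue
        p = np.sort(pos[mask])
        lo = np.searchsorted(p, tss - window, side="left")
        hi = np.searchsorted(p, tss + window, side="right")
        lens = hi - lo
        if lens.sum() == 0:
            continue
        gene_rep = np.repeat(np.arange(len(tss)), lens)
        site_idx = _concat_ranges(lo, hi)
        d = np.abs(p[site_idx] - tss[gene_rep])
        contrib = _site_term(d / window)
        contrib[d > window] = 0.0
        np.add.at(s, gidx_by_chrom[c][gene_rep], contrib)
    return s


def _concat_ranges(starts, stops):
    """Concatenate integer ranges [starts[i], stops[i]) into one index array."""
    lens = stops - starts
    total = int(lens.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    rep_starts = np.repeat(starts, lens)
    offsets = np.arange(total) - np.repeat(np.cumsum(lens) - lens, lens)
    return rep_starts + offsets


def call_targets(
    scores: pd.DataFrame, partitioned_de: pd.DataFrame, c: float = 0.05
) -> pd.DataFrame:
    """Join potential ranks with DE ranks and classify target genes.

    activated: up-regulated with rank product < c; repressed: down-regulated
    with rank product < c; everything else (including all background genes)
    non_target.  Output is sorted by (class, rank_product_score, gene_id).
    """
    ranked = rank_potential(scores)
    merged = partitioned_de.merge(
        ranked, left_on="gene", right_on="gene_id", how="inner"
    )
    n_rp = len(ranked)
    n_up = int((merged["de_class"] == "up").sum())
    n_down = int((merged["de_class"] == "down").sum())
    score = np.full(len(merged), np.nan)
    for cls, n_de in (("up", n_up), ("down", n_down)):
        m = (merged["de_class"] == cls).to_numpy()
        if n_de:
            score[m] = (
                merged.loc[m, "rank_rp"].to_numpy() / n_rp
            ) * (merged.loc[m, "rank_de"].to_numpy() / n_de)
    merged["rank_product_score"] = score
    cls = np.full(len(merged), "non_target", dtype=object)
    is_target = score < c  # strict; NaN never passes
    cls[(merged["de_class"] == "up") & is_target] = "activated"
    cls[(merged["de_class"] == "down") & is_target] = "repressed"
    merged["target_class"] = cls
    order = pd.Categorical(
        merged["target_class"], categories=["activated", "repressed", "non_target"]
    )
    merged["_ord"] = order.codes
    merged = (
        merged.sort_values(
            by=["_ord", "rank_product_score", "gene_id"],
            kind="mergesort",
            na_position="last",
        )
        .drop(columns=["_ord", "gene"])
        .reset_index(drop=True)
    )
    return merged


def compare_targets(targets_a: pd.DataFrame, targets_b: pd.DataFrame) -> dict:
    """Set overlap of two runs' target genes (activated + repressed)."""
    a = set(
        targets_a.loc[targets_a["target_class"] != "non_target", "gene_id"]
    )
    b = set(
        targets_b.loc[targets_b["target_class"] != "non_target", "gene_id"]
    )
    inter = a & b
    denom = min(len(a), len(b))
    return {
        "n_a": len(a),
        "n_b": len(b),
        "n_common": len(inter),
        "common": sorted(inter),
        "overlap_fraction": len(inter) / denom if denom else 0.0,
        "jaccard": len(inter) / len(a | b) if (a | b) else 0.0,
    }


class RegulatoryPotentialIntegrator(BaseEstimator):
    """Integrate DM sites with DE results into target-gene calls.

    Parameters
    ----------
    window : int
        TSS inclusion window in bp; sites strictly beyond it are excluded
        and the scaled distance is d / window.
    df : float
        FDR cutoff partitioning the DE table into up / down / background.
    c : float
        Rank-product cutoff below which an up/down gene becomes a target.
    direction_filter : {'none', 'hypo', 'hyper'}
        Optionally restrict scoring to one methylation direction.
    max_sites : int or None
        Optional cap: keep only the top-N DM sites by ascending q.
    n_permutations : int
        Number of site re-placements for per-gene empirical p-values;
        0 disables the permutation test.
    random_state : int or None
        Seed for the permutation null.

    Attributes
    ----------
    scores_ : DataFrame — per-gene potential with rank_rp.
    targets_ : DataFrame — per-gene classification and rank products.
    function_test_ : FunctionTestResult — KS coupling test.
    perm_p_ : DataFrame — per-gene permutation p (when enabled).
    """

    def __init__(
        self,
        window: int = DEFAULT_WINDOW,
        df: float = 0.05,
        c: float = 0.05,
        direction_filter: str = "none",
        max_sites: int | None = None,
        n_permutations: int = 0,
        random_state=None,
    ):
        self.window = window
        self.df = df
        self.c = c
        self.direction_filter = direction_filter
        self.max_sites = max_sites
        self.n_permutations = n_permutations
        self.random_state = random_state

    def fit(self, dm_sites: pd.DataFrame, de_table: pd.DataFrame, catalog: GeneCatalog):
        scores = regulatory_potential(
            catalog,
            dm_sites,
            window=self.window,
            direction_filter=self.direction_filter,
            max_sites=self.max_sites,
        )
        part = partition_de(de_table, df=self.df)
        self.targets_ = call_targets(scores, part, c=self.c)
        self.scores_ = rank_potential(scores)
        self.function_test_ = ks_function_test(self.targets_)
        if self.n_permutations:
            self.perm_p_ = permutation_test(
                scores,
                dm_sites
                if self.direction_filter == "none"
                else dm_sites.loc[dm_sites["direction"] == self.direction_filter],
                catalog,
                n_permutations=self.n_permutations,
                window=self.window,
                random_state=self.random_state,
            )
        return self
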