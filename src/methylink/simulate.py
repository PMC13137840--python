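"""Synthetic-data generators with known ground truth.

Every pipeline input — per-sample CpG coverage files, a gene annotation,
a differential-expression summary table, cell-type signature and bulk
matrices — can be generated here with planted truth (differentially
methylated sites, methylation-regulated genes, mixture proportions,
injected outlier samples), in the same file formats the real data use.

The defaults emulate a two-group myonuclear RRBS contrast at desk scale:
3 samples per group, ~40x negative-binomial coverage per CpG, Beta(2, 2)
baseline methylation, planted 25-point methylation shifts, and planted
target genes whose promoter hypomethylation (hypermethylation) is coupled
to transcriptional up- (down-) regulation.

Each generator draws from its own RNG stream, seeded as ``seed + offset``,
so adding one generator never perturbs another's output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GeneCatalog, GeneModel

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_genome",
    "simulate_methylation",
    "simulate_de",
    "make_signature",
    "simulate_mixtures",
    "inject_outlier",
    "simulate_qc_cohort",
]

# fixed per-generator RNG stream offsets
_STREAM = {
    "genome": 0,
    "methylation": 1,
    "de": 2,
    "signature": 3,
    "mixtures": 4,
    "outlier": 5,
    "qc": 6,
}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic two-group design."""

    n_genes: int = 2000
    chrom: str = "chr1"
    chrom_length: int = 60_000_000
    n_samples_per_group: int = 3
    mean_coverage: float = 40.0
    coverage_dispersion: float = 5.0  # negative-binomial size parameter
    baseline_meth_a: float = 2.0  # Beta prior on per-site baseline methylation
    baseline_meth_b: float = 2.0
    effect_size: float = 25.0  # planted shift, percentage points
    frac_dm_sites: float = 0.06
    frac_target_genes: float = 0.1  # split evenly activated / repressed
    de_lfc_effect: float = 3.0
    de_null_sd: float = 0.5
    dirichlet_alpha: tuple = (2.0, 2.0, 2.0, 2.0, 2.0)
    expr_noise_sd: float = 0.05  # relative to the mean bulk signal
    n_mixture_samples: int = 100
    n_signature_genes: int = 300
    promoter_upstream: int = 1000
    promoter_downstream: int = 1000
    cpgs_per_promoter: float = 5.0  # Poisson means
    cpgs_per_gene_body: float = 3.0
    intergenic_sites_per_gene: float = 2.0
    seed: int = 0

    def __post_init__(self):
        for name in ("frac_dm_sites", "frac_target_genes"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.effect_size <= 100.0:
            raise ValueError("effect_size must be in [0, 100] percentage points")
        if self.mean_coverage <= 0 or self.coverage_dispersion <= 0:
            raise ValueError("coverage parameters must be positive")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(self.seed + _STREAM[stream])


@dataclass
class SyntheticTruth:
    """Planted ground truth: the recovery oracle for every stage."""

    dm_sites: pd.DataFrame = field(default_factory=pd.DataFrame)
    #: gene_id -> "activated" | "repressed"
    target_genes: dict = field(default_factory=dict)
    #: cell_type x sample proportions
    mixture_proportions: pd.DataFrame = field(default_factory=pd.DataFrame)
    outlier_samples: list = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "dm_sites": self.dm_sites.to_dict(orient="list"),
            "target_genes": self.target_genes,
            "mixture_proportions": (
                self.mixture_proportions.to_dict(orient="list")
                if len(self.mixture_proportions)
                else {}
            ),
            "outlier_samples": self.outlier_samples,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def simulate_genome(config: SimulationConfig) -> GeneCatalog:
    """Place non-overlapping genes with random strand and 2-8 exons each."""
    rng = config.rng("genome")
    n = config.n_genes
    if n == 0:
        return GeneCatalog([])
    slot = config.chrom_length // n
    max_len = 10_000
    if slot < max_len + 2_000:
        raise ValueError(
            f"cannot pack {n} genes into {config.chrom_length} bp "
            f"(need at least {(max_len + 2000) * n})"
        )
    genes = []
    for i in range(n):
        length = int(rng.integers(2_000, max_len + 1))
        jitter = int(rng.integers(0, slot - length - 1_000))
        start = i * slot + 500 + jitter
        end = start + length
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(2, 9))
        # split the span into exons separated by introns
        cuts = np.sort(rng.choice(np.arange(1, length), 2 * n_exons - 1, replace=False))
        bounds = np.concatenate([[0], cuts, [length]])
        exons = tuple(
            (start + int(bounds[2 * j]), start + int(bounds[2 * j + 1]))
            for j in range(n_exons)
        )
        genes.append(
            GeneModel(
                gene_id=f"gene{i:05d}",
                chrom=config.chrom,
                strand=strand,
                tx_start=start,
                tx_end=end,
                exons=exons,
            )
        )
    return GeneCatalog(genes)


def _promoter_interval(gene: GeneModel, up: int, down: int) -> tuple[int, int]:
    """0-based half-open promoter window, strand-oriented around the TSS."""
    if gene.strand == "+":
        return gene.tss - up, gene.tss + down
    return gene.tss - down + 1, gene.tss + up + 1


def _place_sites(catalog: GeneCatalog, config: SimulationConfig, rng):
    """Lay out CpG sites in promoters, gene bodies, and intergenic space."""
    pos, feature, gene_id = [], [], []
    for g in catalog:
        p0, p1 = _promoter_interval(
            g, config.promoter_upstream, config.promoter_downstream
        )
        p0 = max(p0, 0)
        k = max(1, rng.poisson(config.cpgs_per_promoter))
        for p in sorted(rng.integers(p0, p1, size=k)):
            pos.append(int(p))
            feature.append("promoter")
            gene_id.append(g.gene_id)
        k = rng.poisson(config.cpgs_per_gene_body)
        for p in sorted(rng.integers(g.tx_start, g.tx_end, size=k)):
            pos.append(int(p))
            feature.append("body")
            gene_id.append(g.gene_id)
    n_inter = int(round(config.intergenic_sites_per_gene * len(catalog)))
    for p in rng.integers(0, config.chrom_length, size=n_inter):
        pos.append(int(p))
        feature.append("intergenic")
        gene_id.append("")
    sites = pd.DataFrame(
        {"chrom": config.chrom, "pos": pos, "feature": feature, "gene_id": gene_id}
    )
    sites = sites.drop_duplicates(subset=["chrom", "pos"])
    return sites.sort_values("pos", kind="mergesort").reset_index(drop=True)


def _nb_coverage(rng, shape, config: SimulationConfig):
    size = config.coverage_dispersion
    p = size / (size + config.mean_coverage)
    cov = rng.negative_binomial(size, p, size=shape)
    return np.maximum(cov, 1)


def simulate_methylation(catalog: GeneCatalog, config: SimulationConfig):
    """Generate per-sample CpG counts for a two-group design.

    Returns ``(samples, design, sites, truth)`` where ``samples`` maps
    sample name to a coverage DataFrame (``chrom, pos, count_meth,
    count_unmeth``), ``design`` maps sample name to group (``ref`` /
    ``test``), ``sites`` describes every simulated CpG, and ``truth``
    records the planted DM sites and target genes.

    Planted effects: promoters of "activated" target genes are shifted by
    ``-effect_size`` points in the test group (hypomethylation), promoters
    of "repressed" genes by ``+effect_size``; additional scattered sites are
    shifted with random sign until ``frac_dm_sites`` of all sites carry an
    effect.  Shifted proportions are clipped to [0.01, 0.99].
    """
    rng = config.rng("methylation")
    sites = _place_sites(catalog, config, rng)
    n_sites = len(sites)
    baseline = rng.beta(config.baseline_meth_a, config.baseline_meth_b, size=n_sites)

    gene_ids = catalog.gene_ids
    n_targets = int(round(config.frac_target_genes * len(gene_ids)))
    if config.effect_size == 0:
        n_targets = 0  # no effect, no planted methylation-expression coupling
    chosen = rng.choice(len(gene_ids), size=n_targets, replace=False)
    half = n_targets // 2
    target_genes = {gene_ids[i]: "activated" for i in chosen[:half]}
    target_genes.update({gene_ids[i]: "repressed" for i in chosen[half:]})

    shift = np.zeros(n_sites)
    eff = config.effect_size / 100.0
    if eff > 0:
        is_prom = sites["feature"].to_numpy() == "promoter"
        cls = sites["gene_id"].map(target_genes).to_numpy(dtype=object)
        shift[is_prom & (cls == "activated")] = -eff
        shift[is_prom & (cls == "repressed")] = +eff
        n_planted_goal = int(round(config.frac_dm_sites * n_sites))
        extra_needed = n_planted_goal - int((shift != 0).sum())
        if extra_needed > 0:
            free = np.flatnonzero(shift == 0)
            extra = rng.choice(free, size=min(extra_needed, len(free)), replace=False)
            shift[extra] = np.where(rng.random(len(extra)) < 0.5, -eff, +eff)

    pi_ref = baseline
    pi_test = np.clip(baseline + shift, 0.01, 0.99)

    samples: dict[str, pd.DataFrame] = {}
    design: dict[str, str] = {}
    for group, pi in (("ref", pi_ref), ("test", pi_test)):
        for j in range(config.n_samples_per_group):
            name = f"{group}_{j + 1}"
            total = _nb_coverage(rng, n_sites, config)
            meth = rng.binomial(total, pi)
            samples[name] = pd.DataFrame(
                {
                    "chrom": sites["chrom"],
                    "pos": sites["pos"],
                    "count_meth": meth.astype(np.int64),
                    "count_unmeth": (total - meth).astype(np.int64),
                }
            )
            design[name] = group

    planted = shift != 0
    truth = SyntheticTruth(
        dm_sites=pd.DataFrame(
            {
                "chrom": sites.loc[planted, "chrom"].to_numpy(),
                "pos": sites.loc[planted, "pos"].to_numpy(),
                "direction": np.where(shift[planted] < 0, "hypo", "hyper"),
            }
        ),
        target_genes=target_genes,
    )
    return samples, design, sites, truth


def simulate_de(
    catalog: GeneCatalog, truth: SyntheticTruth, config: SimulationConfig
) -> pd.DataFrame:
    """Simulate a DE summary table coupled to the planted target genes.

    Activated genes: log2fc ~ N(+de_lfc_effect, 0.25), padj ~ U(1e-8, 1e-3);
    repressed genes the negative; null genes log2fc ~ N(0, de_null_sd),
    padj ~ U(0, 1).
    """
    rng = config.rng("de")
    rows = []
    for gid in catalog.gene_ids:
        cls = truth.target_genes.get(gid)
        if cls == "activated":
            lfc = rng.normal(config.de_lfc_effect, 0.25)
            padj = rng.uniform(1e-8, 1e-3)
        elif cls == "repressed":
            lfc = rng.normal(-config.de_lfc_effect, 0.25)
            padj = rng.uniform(1e-8, 1e-3)
        else:
            lfc = rng.normal(0.0, config.de_null_sd)
            padj = rng.uniform(0.0, 1.0)
        rows.append((gid, lfc, padj))
    return pd.DataFrame(rows, columns=["gene", "log2fc", "padj"])


def make_signature(config: SimulationConfig) -> pd.DataFrame:
    """Build a synthetic cell-type signature matrix with marker structure.

    Each cell type receives an exclusive block of high-expression marker
    genes on top of a shared low-level background, mimicking a reference
    built from clustered single-cell profiles.
    """
    rng = config.rng("signature")
    n_types = len(config.dirichlet_alpha)
    n_genes = config.n_signature_genes
    genes = [f"sig{i:04d}" for i in range(n_genes)]
    types = [f"celltype{k + 1}" for k in range(n_types)]
    S = rng.lognormal(mean=0.0, sigma=0.5, size=(n_genes, n_types))
    block = n_genes // n_types
    for k in range(n_types):
        rows = slice(k * block, (k + 1) * block)
        S[rows, k] += rng.lognormal(mean=3.0, sigma=0.5, size=block)
    return pd.DataFrame(S, index=genes, columns=types)


def simulate_mixtures(signature: pd.DataFrame, config: SimulationConfig):
    """Mix the signature under Dirichlet proportions plus truncated noise.

    Returns ``(bulk, proportions)``: bulk is genes x samples, proportions is
    cell_types x samples.  Noise is N(0, expr_noise_sd * mean(S @ w)) per
    entry, truncated at zero.
    """
    rng = config.rng("mixtures")
    alpha = np.asarray(config.dirichlet_alpha, dtype=float)
    n = config.n_mixture_samples
    W = rng.dirichlet(alpha, size=n)  # samples x types
    S = signature.to_numpy()
    B = S @ W.T  # genes x samples
    if config.expr_noise_sd > 0:
        scale = config.expr_noise_sd * B.mean(axis=0, keepdims=True)
        B = np.maximum(B + rng.normal(0.0, 1.0, size=B.shape) * scale, 0.0)
    cols = [f"sample{j + 1}" for j in range(n)]
    bulk = pd.DataFrame(B, index=signature.index, columns=cols)
    props = pd.DataFrame(W.T, index=signature.columns, columns=cols)
    return bulk, props


def inject_outlier(
    samples: dict,
    design: dict,
    catalog: GeneCatalog,
    sample_id: str,
    magnitude: float,
    config: SimulationConfig,
    toward: str | None = None,
):
    """Shift one sample's promoter methylation toward the other group's mean.

    For every CpG inside a promoter window, the sample's methylation
    proportion becomes ``(1 - magnitude) * own + magnitude * other`` where
    ``other`` is the mean proportion of the samples in the target group
    (``toward``; by default every sample outside the sample's own group —
    the natural reading for a two-group design).  Methylated counts are
    re-rounded at fixed coverage.  ``magnitude = 0`` leaves the files
    unchanged; ``magnitude = 1`` is a full swap.

    Returns ``(samples, truth_ids)`` with a modified copy of the sample
    table and the list of injected sample ids.
    """
    if sample_id not in samples:
        raise KeyError(f"unknown sample {sample_id!r}")
    if not 0.0 <= magnitude <= 1.0:
        raise ValueError("magnitude must be in [0, 1]")
    own_group = design[sample_id]
    if toward is not None:
        if toward == own_group:
            raise ValueError("toward must name a different group")
        others = [s for s, g in design.items() if g == toward]
    else:
        others = [s for s, g in design.items() if g != own_group]
    if not others:
        raise ValueError("need at least one sample outside the target group")

    prom_mask = _promoter_site_mask(samples[sample_id], catalog, config)
    target = samples[sample_id]
    key = ["chrom", "pos"]
    merged = target[key].copy()
    num = np.zeros(len(target))
    den = np.zeros(len(target))
    for s in others:
        other = samples[s].set_index(key)
        aligned = other.reindex(pd.MultiIndex.from_frame(merged))
        tot = (aligned["count_meth"] + aligned["count_unmeth"]).to_numpy()
        with np.errstate(invalid="ignore"):
            p = aligned["count_meth"].to_numpy() / tot
        ok = np.isfinite(p)
        num[ok] += p[ok]
        den[ok] += 1

    total = (target["count_meth"] + target["count_unmeth"]).to_numpy()
    own_p = target["count_meth"].to_numpy() / total
    other_p = np.where(den > 0, num / np.maximum(den, 1), own_p)
    new_p = np.where(
        prom_mask, (1.0 - magnitude) * own_p + magnitude * other_p, own_p
    )
    new_meth = np.rint(new_p * total).astype(np.int64)

    out = dict(samples)
    modified = target.copy()
    modified["count_meth"] = new_meth
    modified["count_unmeth"] = (total - new_meth).astype(np.int64)
    out[sample_id] = modified
    return out, [sample_id]


def _promoter_site_mask(cov: pd.DataFrame, catalog: GeneCatalog, config):
    """Boolean mask of rows falling in any promoter window."""
    mask = np.zeros(len(cov), dtype=bool)
    pos = cov["pos"].to_numpy()
    chrom = cov["chrom"].to_numpy()
    for g in catalog:
        p0, p1 = _promoter_interval(
            g, config.promoter_upstream, config.promoter_downstream
        )
        mask |= (chrom == g.chrom) & (pos >= p0) & (pos < p1)
    return mask


def simulate_qc_cohort(
    catalog: GeneCatalog,
    config: SimulationConfig,
    group_sizes: tuple = (3, 4, 3, 3),
    group_effect: float = 30.0,
    frac_group_promoters: float = 0.08,
):
    """Generate a four-group 2x2 factorial cohort for the QC diagnostics.

    The design mirrors a two-factor study (e.g., age x intervention): each
    factor owns a disjoint random subset (``frac_group_promoters``) of gene
    promoters whose methylation it shifts by ±``group_effect`` points in
    the groups where the factor is "on".  Groups are ``group1`` (neither
    factor), ``group2`` (factor A), ``group3`` (factor B) and ``group4``
    (both), so the four centroids span a two-dimensional plane that the
    default two-component PCA captures in full.

    Returns ``(samples, design, sites)``.
    """
    if len(group_sizes) != 4:
        raise ValueError("the factorial cohort needs exactly 4 groups")
    rng = config.rng("qc")
    sites = _place_sites(catalog, config, rng)
    n_sites = len(sites)
    baseline = rng.beta(config.baseline_meth_a, config.baseline_meth_b, size=n_sites)
    is_prom = sites["feature"].to_numpy() == "promoter"
    site_gene = sites["gene_id"].to_numpy(dtype=object)

    gene_ids = np.asarray(catalog.gene_ids, dtype=object)
    n_pick = max(1, int(round(frac_group_promoters * len(gene_ids))))
    picked = rng.choice(gene_ids, size=min(2 * n_pick, len(gene_ids)), replace=False)
    factor_sets = (picked[:n_pick], picked[n_pick:])
    factor_shift = []
    for genes_f in factor_sets:
        signs = {g: (-1.0 if rng.random() < 0.5 else 1.0) for g in genes_f}
        shift = np.zeros(n_sites)
        for i in np.flatnonzero(is_prom & np.isin(site_gene, genes_f)):
            shift[i] = signs[site_gene[i]] * group_effect / 100.0
        factor_shift.append(shift)
    # group -> (factor A on, factor B on)
    layout = {"group1": (0, 0), "group2": (1, 0), "group3": (0, 1), "group4": (1, 1)}

    samples: dict[str, pd.DataFrame] = {}
    design: dict[str, str] = {}
    for k, n_samp in enumerate(group_sizes):
        group = f"group{k + 1}"
        a_on, b_on = layout[group]
        pi = np.clip(
            baseline + a_on * factor_shift[0] + b_on * factor_shift[1], 0.01, 0.99
        )
        for j in range(n_samp):
            name = f"{group}_s{j + 1}"
            total = _nb_coverage(rng, n_sites, config)
            meth = rng.binomial(total, pi)
            samples[name] = pd.DataFrame(
                {
                    "chrom": sites["chrom"],
                    "pos": sites["pos"],
                    "count_meth": meth.astype(np.int64),
                    "count_unmeth": (total - meth).astype(np.int64),
                }
            )
            design[name] = group
    return samples, design, sites


def config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["dirichlet_alpha"] = list(d["dirichlet_alpha"])
    return d
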