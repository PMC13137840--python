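"""Readers and writers for the file dialects the pipeline touches.

All in-memory coordinates are 0-based half-open.  The two external dialects
that use 1-based inclusive coordinates (Bismark ``.cov`` and GTF) are
converted exactly once, at read/write time.  Chromosome names are matched by
exact string equality; no ``chr`` prefix normalisation is performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MethylationRecord",
    "GeneModel",
    "GeneCatalog",
    "read_bismark_cov",
    "write_bismark_cov",
    "read_gene_annotation",
    "read_de_table",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "write_bed_peaks",
]

#: columns of the DataFrame returned by :func:`read_bismark_cov`
COV_COLUMNS = ["chrom", "pos", "count_meth", "count_unmeth"]


@dataclass(frozen=True)
class MethylationRecord:
    """A single CpG observation: 0-based position and read counts."""

    chrom: str
    pos: int
    count_meth: int
    count_unmeth: int
    strand: str = "unknown"

    def __post_init__(self):
        if self.pos < 0:
            raise ValueError(f"negative position {self.pos}")
        if self.count_meth < 0 or self.count_unmeth < 0:
            raise ValueError("negative read count")
        if self.count_meth + self.count_unmeth < 1:
            raise ValueError("record with zero total coverage")


@dataclass(frozen=True)
class GeneModel:
    """A gene model with 0-based half-open transcript and exon intervals.

    The TSS is the strand-aware 5' end: ``tx_start`` on the plus strand,
    ``tx_end - 1`` on the minus strand.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if not self.tx_start < self.tx_end:
            raise ValueError(f"{self.gene_id}: tx_start must be < tx_end")
        prev_end = self.tx_start
        for s, e in self.exons:
            if s < prev_end or e > self.tx_end or s >= e:
                raise ValueError(
                    f"{self.gene_id}: exons must be sorted, non-overlapping "
                    f"and within the transcript"
                )
            prev_end = e

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end - 1


class GeneCatalog:
    """An ordered collection of :class:`GeneModel` keyed by ``gene_id``."""

    def __init__(self, genes: Iterable[GeneModel]):
        self._genes: dict[str, GeneModel] = {}
        for g in genes:
            if g.gene_id in self._genes:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            self._genes[g.gene_id] = g

    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self):
        return iter(self._genes.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._genes[gene_id]

    @property
    def gene_ids(self) -> list[str]:
        return list(self._genes)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (g.gene_id, g.chrom, g.strand, g.tx_start, g.tx_end, g.tss)
            for g in self
        ]
        return pd.DataFrame(
            rows, columns=["gene_id", "chrom", "strand", "tx_start", "tx_end", "tss"]
        )

    def to_bed12(self, path) -> None:
        with open(path, "w") as fh:
            for g in self:
                exons = g.exons or ((g.tx_start, g.tx_end),)
                sizes = ",".join(str(e - s) for s, e in exons) + ","
                starts = ",".join(str(s - g.tx_start) for s, e in exons) + ","
                fh.write(
                    "\t".join(
                        [
                            g.chrom,
                            str(g.tx_start),
                            str(g.tx_end),
                            g.gene_id,
                            "0",
                            g.strand,
                            str(g.tx_start),
                            str(g.tx_end),
                            "0",
                            str(len(exons)),
                            sizes,
                            starts,
                        ]
                    )
                    + "\n"
                )


def _fmt_percent(count_meth: int, total: int) -> str:
    # 6 significant digits; integral values print without a decimal point
    return format(100.0 * count_meth / total, ".6g")


def read_bismark_cov(path) -> pd.DataFrame:
    """Read a Bismark coverage file into a DataFrame.

    The ``.cov`` dialect is 6 tab-separated columns: chrom, 1-based start,
    1-based end, percent methylation, methylated count, unmethylated count.
    Positions are converted to 0-based; the percent column is ignored in
    favour of the counts (a >0.5-point disagreement triggers a warning).

    Returns a DataFrame with columns ``chrom, pos, count_meth, count_unmeth``
    sorted by (chrom, pos).
    """
    chroms, poss, meths, unmeths = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ValueError(
                    f"{path}: line {lineno}: expected 6 tab-separated "
                    f"columns, found {len(fields)}"
                )
            chrom, start_s, _end_s, pct_s, m_s, u_s = fields
            try:
                start = int(start_s)
                m = int(m_s)
                u = int(u_s)
                pct = float(pct_s)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
            if m < 0 or u < 0:
                raise ValueError(f"{path}: line {lineno}: negative count")
            if m + u < 1:
                raise ValueError(f"{path}: line {lineno}: zero total coverage")
            if abs(pct - 100.0 * m / (m + u)) > 0.5:
                warnings.warn(
                    f"{path}: line {lineno}: percent column ({pct}) "
                    f"inconsistent with counts; counts win",
                    stacklevel=2,
                )
            chroms.append(chrom)
            poss.append(start - 1)  # 1-based inclusive -> 0-based
            meths.append(m)
            unmeths.append(u)
    df = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": np.asarray(poss, dtype=np.int64),
            "count_meth": np.asarray(meths, dtype=np.int64),
            "count_unmeth": np.asarray(unmeths, dtype=np.int64),
        }
    )
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def write_bismark_cov(records, path) -> None:
    """Write methylation records to a Bismark ``.cov`` file.

    ``records`` is a DataFrame with :data:`COV_COLUMNS` or an iterable of
    :class:`MethylationRecord`.  Coordinates are written 1-based inclusive;
    the percent column is recomputed from the counts to 6 significant digits.
    """
    if isinstance(records, pd.DataFrame):
        rows = records[COV_COLUMNS].itertuples(index=False)
    else:
        rows = ((r.chrom, r.pos, r.count_meth, r.count_unmeth) for r in records)
    with open(path, "w") as fh:
        for chrom, pos, m, u in rows:
            total = m + u
            fh.write(
                f"{chrom}\t{pos + 1}\t{pos + 1}\t{_fmt_percent(m, total)}\t{m}\t{u}\n"
            )


def _read_bed12(path) -> GeneCatalog:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(
                    f"{path}: line {lineno}: BED needs at least 6 columns"
                )
            chrom, start, end, name, _score, strand = f[:6]
            start, end = int(start), int(end)
            if len(f) >= 12:
                n_blocks = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
                if len(sizes) != n_blocks or len(offsets) != n_blocks:
                    raise ValueError(
                        f"{path}: line {lineno}: block count mismatch"
                    )
                exons = tuple(
                    (start + o, start + o + s) for o, s in zip(offsets, sizes)
                )
            else:
                exons = ((start, end),)
            genes.append(
                GeneModel(
                    gene_id=name,
                    chrom=chrom,
                    strand=strand,
                    tx_start=start,
                    tx_end=end,
                    exons=exons,
                )
            )
    return GeneCatalog(genes)


def _gtf_gene_id(attributes: str, path, lineno: int) -> str:
    for part in attributes.split(";"):
        part = part.strip()
        if part.startswith("gene_id"):
            return part[len("gene_id"):].strip().strip('"')
    raise ValueError(f"{path}: line {lineno}: missing gene_id attribute")


def _read_gtf(path) -> GeneCatalog:
    spans: dict[str, tuple[str, str, int, int]] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}  # chrom, strand seen on any feature
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise ValueError(f"{path}: line {lineno}: expected 9 columns")
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attrs = f
            if feature not in ("gene", "exon"):
                continue
            gid = _gtf_gene_id(attrs, path, lineno)
            # GTF is 1-based inclusive -> 0-based half-open
            start, end = int(start_s) - 1, int(end_s)
            if gid not in exons:
                order.append(gid)
                exons[gid] = []
                meta[gid] = (chrom, strand)
            if feature == "gene":
                if gid in spans:
                    raise ValueError(f"{path}: line {lineno}: duplicate gene_id {gid!r}")
                spans[gid] = (chrom, strand, start, end)
            else:
                exons[gid].append((start, end))
    genes = []
    for gid in order:
        ex = sorted(exons[gid])
        if gid in spans:
            chrom, strand, start, end = spans[gid]
        else:
            # no gene feature: derive the span from the exons
            chrom, strand = meta[gid]
            start, end = ex[0][0], max(e for _s, e in ex)
        if not ex:
            warnings.warn(
                f"gene {gid!r} has no exons; using transcript bounds as a "
                f"single exon",
                stacklevel=2,
            )
            ex = [(start, end)]
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=chrom,
                strand=strand,
                tx_start=start,
                tx_end=end,
                exons=tuple(ex),
            )
        )
    return GeneCatalog(genes)


def read_gene_annotation(path, format: str = "bed12") -> GeneCatalog:
    """Read a gene annotation in BED12 or GTF format into a GeneCatalog."""
    if format == "bed12":
        return _read_bed12(path)
    if format == "gtf":
        return _read_gtf(path)
    raise ValueError(f"unknown annotation format {format!r}")


def read_de_table(path) -> pd.DataFrame:
    """Read a differential-expression summary table.

    Expects a TSV with a header containing columns ``gene``, ``log2FC`` and
    ``padj``.  Rows with missing ``padj`` are dropped; the number dropped is
    attached as ``df.attrs['n_dropped']``.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("gene", "log2FC", "padj"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    df = df.rename(columns={"log2FC": "log2fc"})
    n0 = len(df)
    df = df.dropna(subset=["padj"]).reset_index(drop=True)
    n_dropped = n0 - len(df)
    df["log2fc"] = df["log2fc"].astype(float)
    df["padj"] = df["padj"].astype(float)
    if ((df["padj"] < 0) | (df["padj"] > 1)).any():
        raise ValueError(f"{path}: padj outside [0, 1]")
    if df["gene"].duplicated().any():
        dup = df.loc[df["gene"].duplicated(), "gene"].iloc[0]
        raise ValueError(f"{path}: duplicate gene_id {dup!r}")
    out = df[["gene", "log2fc", "padj"]]
    out.attrs["n_dropped"] = n_dropped
    return out


def read_matrix_tsv(path) -> pd.DataFrame:
    """Read a labelled numeric matrix (rows x columns) from TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(float)


def write_matrix_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def write_bed_peaks(dm_sites: pd.DataFrame, path) -> None:
    """Write DM sites as a BED6 "peak" file.

    One single-base 0-based half-open interval per site; the name column is
    the direction (``hypo``/``hyper``) and the score the absolute percent
    methylation difference.
    """
    with open(path, "w") as fh:
        for row in dm_sites.itertuples(index=False):
            direction = getattr(row, "direction", None)
            if direction is None:
                direction = "hyper" if row.meth_diff > 0 else "hypo"
            score = format(abs(row.meth_diff), ".6g")
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.pos + 1}\t{direction}\t{score}\t.\n"
            )
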