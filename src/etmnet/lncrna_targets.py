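"""Cis and trans lncRNA target-gene prediction.

*Cis*: a gene is a candidate target of an lncRNA when the two lie on the
same chromosome within a fixed genomic window (default 100 kb) of each
other, measured as the nearest-edge gap between the two intervals; an
overlapping or contained gene counts as distance 0.  Strand is ignored and
upstream/downstream are reported in genome orientation.

*Trans*: a gene is a candidate target when the absolute sample-level
Pearson correlation between the lncRNA and gene expression rows strictly
exceeds a threshold (default 0.95).  Correlation is computed across all
replicate sample columns rather than tissue means — with only 4 tissues an
|r| > 0.95 cutoff on tissue means would be nearly unconstrained — but
tissue means can be requested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .expression_specificity import aggregate_tissues
from .io_formats import ExpressionMatrix, GenomicFeature

logger = logging.getLogger(__name__)

__all__ = ["CisTarget", "TransTarget", "predict_cis", "predict_trans"]


@dataclass(frozen=True)
class CisTarget:
    lncrna_id: str
    gene_id: str
    distance_bp: int
    side: str  # upstream | downstream | overlap

    def __post_init__(self) -> None:
        if self.distance_bp < 0:
            raise ValueError("distance_bp must be >= 0")
        if (self.side == "overlap") != (self.distance_bp == 0):
            raise ValueError("side=overlap iff distance_bp == 0")


@dataclass(frozen=True)
class TransTarget:
    lncrna_id: str
    gene_id: str
    r: float
    n_samples: int

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise ValueError(f"|r| = {abs(self.r)} exceeds 1")
        if self.n_samples < 3:
            raise ValueError("n_samples must be >= 3")


def predict_cis(
    lncrnas: list[GenomicFeature],
    genes: list[GenomicFeature],
    window_bp: int = 100_000,
) -> list[CisTarget]:
    """All (lncRNA, gene) pairs within ``window_bp`` on the same chromosome.

    The window is inclusive (gap <= window_bp reported).  Self-pairs by id
    are excluded.  Output sorted by (lncrna_id, distance_bp, gene_id).
    Genes are bucketed per chromosome and sorted by start so each lncRNA
    only examines candidates overlapping its extended window.
    """
    by_chrom: dict[str, list[GenomicFeature]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for lst in by_chrom.values():
        lst.sort(key=lambda f: (f.start, f.end, f.id))

    out: list[CisTarget] = []
    for lnc in lncrnas:
        for gene in by_chrom.get(lnc.chrom, []):
            if gene.start > lnc.end + window_bp:
                break
            if gene.id == lnc.id:
                continue
            gap = max(lnc.start, gene.start) - min(lnc.end, gene.end)
            if gap > window_bp:
                continue
            if gap <= 0:
                out.append(CisTarget(lnc.id, gene.id, 0, "overlap"))
            elif gene.end <= lnc.start:
                out.append(CisTarget(lnc.id, gene.id, gap, "upstream"))
            else:
                out.append(CisTarget(lnc.id, gene.id, gap, "downstream"))
    out.sort(key=lambda c: (c.lncrna_id, c.distance_bp, c.gene_id))
    return out


def predict_trans(
    lnc_expr: ExpressionMatrix,
    gene_expr: ExpressionMatrix,
    r_threshold: float = 0.95,
    use_tissue_means: bool = False,
) -> list[TransTarget]:
    """All (lncRNA, gene) pairs with defined |Pearson r| strictly > threshold.

    Both matrices must share identical sample columns.  Zero-variance rows
    cannot yield a defined correlation and are skipped (count logged).
    Output sorted by (lncrna_id, gene_id).
    """
    if lnc_expr.sample_labels != gene_expr.sample_labels:
        raise ValueError("lncRNA and gene matrices have different sample columns")

    if use_tissue_means:
        def to_array(m: ExpressionMatrix) -> tuple[np.ndarray, list[str]]:
            profiles = aggregate_tissues(m)
            arr = np.array(
                [[v for _, v in p.tissue_values] for p in profiles], dtype=float
            )
            return arr, [p.feature_id for p in profiles]

        lnc_arr, lnc_ids = to_array(lnc_expr)
        gene_arr, gene_ids = to_array(gene_expr)
    else:
        lnc_arr = lnc_expr.values.to_numpy(dtype=float)
        gene_arr = gene_expr.values.to_numpy(dtype=float)
        lnc_ids = lnc_expr.feature_ids
        gene_ids = gene_expr.feature_ids

    n = lnc_arr.shape[1]
    if n < 3:
        raise ValueError("need at least 3 columns for correlation")

    def standardize(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        centered = arr - arr.mean(axis=1, keepdims=True)
        sd = centered.std(axis=1)
        ok = sd > 0
        z = np.zeros_like(centered)
        z[ok] = centered[ok] / sd[ok][:, None]
        return z, ok

    z_lnc, ok_lnc = standardize(lnc_arr)
    z_gene, ok_gene = standardize(gene_arr)
    n_skipped = int((~ok_lnc).sum() + (~ok_gene).sum())
    if n_skipped:
        logger.info("skipped %d zero-variance rows in trans prediction", n_skipped)

    r = (z_lnc @ z_gene.T) / n
    out: list[TransTarget] = []
    for i, j in zip(*np.nonzero(np.abs(r) > r_threshold)):
        if not (ok_lnc[i] and ok_gene[j]):
            continue
        if lnc_ids[i] == gene_ids[j]:
            continue
        rij = float(np.clip(r[i, j], -1.0, 1.0))
        out.append(TransTarget(lnc_ids[i], gene_ids[j], rij, n))
    out.sort(key=lambda t: (t.lncrna_id, t.gene_id))
    return out
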