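"""Tissue specificity (tau), top-fraction selection, DE filtering, qPCR utilities.

The tau index summarizes how concentrated a feature's expression is in one
tissue:

    tau = sum_i (1 - x_i / max_j x_j) / (n - 1)

over the ``n`` tissue-level values ``x_i`` (TPM for miRNAs, FPKM for
lncRNAs and genes).  tau = 1 means expression confined to a single tissue,
tau = 0 means perfectly uniform expression; it is undefined for an
all-zero profile.  Replicates are collapsed to tissue values by the
arithmetic mean, on the raw linear scale of the formula.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import DERecord, ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "TissueProfile",
    "TauResult",
    "aggregate_tissues",
    "compute_tau",
    "select_top_fraction",
    "filter_de",
    "delta_delta_ct",
    "pearson_r",
]


@dataclass(frozen=True)
class TissueProfile:
    """Per-tissue mean expression for one feature."""

    feature_id: str
    tissue_values: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if len(self.tissue_values) < 2:
            raise ValueError(f"{self.feature_id!r}: need >= 2 tissues for tau")
        for tissue, v in self.tissue_values:
            if not math.isfinite(v) or v < 0:
                raise ValueError(
                    f"{self.feature_id!r}: invalid value {v!r} for tissue {tissue!r}"
                )

    @property
    def n(self) -> int:
        return len(self.tissue_values)


@dataclass(frozen=True)
class TauResult:
    feature_id: str
    tau: float | None
    peak_tissue: str | None
    peak_value: float
    defined: bool


def aggregate_tissues(
    matrix: ExpressionMatrix, tissue_order: list[str] | None = None
) -> list[TissueProfile]:
    """Collapse replicate sample columns to per-tissue arithmetic means.

    Tissue order follows ``tissue_order`` if given, else first appearance
    across the sample columns.  A requested tissue with no samples is an
    error.
    """
    tissues = tissue_order if tissue_order is not None else matrix.tissues
    cols_by_tissue: dict[str, list[str]] = {t: [] for t in tissues}
    for s in matrix.sample_labels:
        t = matrix.tissue_of_sample[s]
        if t in cols_by_tissue:
            cols_by_tissue[t].append(s)
    for t, cols in cols_by_tissue.items():
        if not cols:
            raise ValueError(f"tissue {t!r} has no sample columns")
    means = {t: matrix.values[cols].mean(axis=1) for t, cols in cols_by_tissue.items()}
    return [
        TissueProfile(
            fid, tuple((t, float(means[t].loc[fid])) for t in tissues)
        )
        for fid in matrix.feature_ids
    ]


def compute_tau(profile: TissueProfile) -> TauResult:
    """tau = sum(1 - x_i/max(x)) / (n - 1); undefined when max(x) = 0."""
    values = np.array([v for _, v in profile.tissue_values], dtype=float)
    peak = float(values.max())
    if peak == 0.0:
        return TauResult(profile.feature_id, None, None, 0.0, False)
    xhat = values / peak
    tau = float((1.0 - xhat).sum() / (len(values) - 1))
    peak_tissue = profile.tissue_values[int(values.argmax())][0]
    return TauResult(profile.feature_id, tau, peak_tissue, peak, True)


def select_top_fraction(
    results: list[TauResult], fraction: float = 0.05
) -> list[str]:
    """Ids of the top ``floor(fraction * N_defined)`` features by tau.

    Undefined tau (all-zero profiles) are excluded before ranking; their
    count is logged.  Ties are broken by higher peak tissue value, then by
    lexicographic feature id, making the selection a deterministic,
    permutation-invariant function of its input.
    """
    if not results:
        raise ValueError("no tau results to rank")
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction {fraction} outside (0, 1]")
    defined = [r for r in results if r.defined]
    n_dropped = len(results) - len(defined)
    if n_dropped:
        logger.info("excluded %d features with undefined tau", n_dropped)
    k = math.floor(fraction * len(defined))
    ranked = sorted(
        defined, key=lambda r: (-r.tau, -r.peak_value, r.feature_id)  # type: ignore[operator]
    )
    return [r.feature_id for r in ranked[:k]]


def filter_de(
    records: list[DERecord], padj_lt: float = 0.05, abs_lfc_gt: float = 1.0
) -> list[str]:
    """Feature ids with padj strictly below and |log2FC| strictly above cutoff.

    Boundary rows (padj exactly at the cutoff, |log2FC| exactly at the
    cutoff) are dropped.  A duplicated (feature, contrast) key is an error.
    Output is the sorted set of qualifying feature ids.
    """
    seen: set[tuple[str, str]] = set()
    kept: set[str] = set()
    for r in records:
        key = (r.feature_id, r.contrast)
        if key in seen:
            raise ValueError(f"duplicate DE record for {key!r}")
        seen.add(key)
        if r.padj < padj_lt and abs(r.log2fc) > abs_lfc_gt:
            kept.add(r.feature_id)
    return sorted(kept)


def delta_delta_ct(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """Relative expression by the 2^-ddCt method.

    ddCt = (Ct_target - Ct_ref)_sample - (Ct_target - Ct_ref)_calibrator;
    the result 2^-ddCt is strictly positive for finite inputs.
    """
    cts = (ct_target_sample, ct_ref_sample, ct_target_calibrator, ct_ref_calibrator)
    if not all(math.isfinite(c) for c in cts):
        raise ValueError(f"non-finite Ct value in {cts}")
    ddct = (ct_target_sample - ct_ref_sample) - (
        ct_target_calibrator - ct_ref_calibrator
    )
    return 2.0 ** (-ddct)


def pearson_r(x, y) -> float | None:
    """Sample Pearson correlation; ``None`` when either vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(stats.pearsonr(x, y).statistic)
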