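"""Synthetic pipeline inputs with known planted structure.

Every downstream stage of the pipeline is validated against data generated
here: lncRNA transcripts carrying eTM sites constructed to satisfy (or to
violate exactly one of) the three pairing rules, a 4-tissue x 3-replicate
expression design with planted tissue-specific features and planted
correlated lncRNA-gene pairs, genome annotations with exact inter-feature
distances, and DE tables with rows straddling the significance thresholds.
A manifest records the ground truth for each planted item.

Modelling choices (none of which the real study states, all configurable):
background sequence composition is uniform over {A,C,G,U}; background
expression baselines are log-normal with multiplicative log-normal
replicate noise of coefficient of variation ``noise_cv``; planted
correlated pairs are built from a shared latent signal plus independent
noise and rejection-sampled until the realized sample correlation is
within +/-0.02 of the requested value (exact control is not possible
analytically at 12 samples).

All outputs are deterministic functions of ``SynthConfig.seed``:
re-running with the same config yields byte-identical files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .etm_finder import EtmParams, complement_rna
from .io_formats import (
    Alphabet,
    DERecord,
    ExpressionMatrix,
    FeatureClass,
    GenomicFeature,
    SequenceRecord,
    write_de_table,
    write_expression,
    write_fasta,
    write_features,
)

import pandas as pd

__all__ = [
    "PlantedEtm",
    "PlantedTau",
    "CisSpec",
    "TransSpec",
    "SynthConfig",
    "SynthManifest",
    "build_etm_site",
    "gen_sequences",
    "gen_expression",
    "gen_annotation",
    "gen_de_table",
    "default_config",
    "simulate_all",
]

_RNA = "ACGU"
_TISSUES = ("leaf", "petal", "stamen", "pistil")


@dataclass(frozen=True)
class PlantedEtm:
    """One site to splice into a lncRNA.

    ``violate_rule`` of 1, 2 or 3 plants a negative breaking exactly that
    rule; ``None`` plants a rule-satisfying positive.
    """

    mirna_index: int
    lncrna_index: int
    offset: int
    bulge_length: int = 0
    n_mismatches: int = 0
    n_wobbles: int = 0
    violate_rule: int | None = None


@dataclass(frozen=True)
class PlantedTau:
    feature_id: str
    target_tissue: str
    fold_over_background: float


@dataclass(frozen=True)
class CisSpec:
    lncrna_id: str
    gene_id: str
    signed_distance_bp: int  # >0 gene downstream of lncRNA, <0 upstream, 0 overlap


@dataclass(frozen=True)
class TransSpec:
    lncrna_id: str
    gene_id: str
    target_r: float


@dataclass
class SynthConfig:
    seed: int = 0
    n_tissues: int = 4
    n_replicates: int = 3
    tissue_names: tuple[str, ...] = _TISSUES
    n_mirnas: int = 12
    n_lncrnas: int = 40
    n_genes: int = 120
    mirna_length_range: tuple[int, int] = (20, 24)
    lncrna_length_range: tuple[int, int] = (300, 600)
    noise_cv: float = 0.1
    planted_etm_spec: list[PlantedEtm] = field(default_factory=list)
    planted_tau_spec: list[PlantedTau] = field(default_factory=list)
    cis_distance_spec: list[CisSpec] = field(default_factory=list)
    trans_r_spec: list[TransSpec] = field(default_factory=list)
    n_de_planted: int = 20
    n_de_background: int = 80
    etm_params: EtmParams = field(default_factory=EtmParams)

    def __post_init__(self) -> None:
        if self.n_tissues != len(self.tissue_names):
            raise ValueError("n_tissues must match tissue_names")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        for p in self.planted_etm_spec:
            if not (0 <= p.mirna_index < self.n_mirnas):
                raise ValueError(f"mirna_index {p.mirna_index} out of range")
            if not (0 <= p.lncrna_index < self.n_lncrnas):
                raise ValueError(f"lncrna_index {p.lncrna_index} out of range")
            if p.n_mismatches + p.n_wobbles > self.etm_params.max_mismatch_wobble:
                raise ValueError(
                    "planted mismatches + wobbles exceed the rule-3 budget"
                )
            if not (0 <= p.bulge_length <= self.etm_params.max_bulge):
                raise ValueError("bulge_length outside [0, max_bulge]")
        for t in self.trans_r_spec:
            if not (-1.0 < t.target_r < 1.0):
                raise ValueError(f"target_r {t.target_r} outside (-1, 1)")


@dataclass
class SynthManifest:
    """Ground truth for every planted item, one entry per item."""

    etm_sites: list[dict] = field(default_factory=list)
    tau_targets: list[dict] = field(default_factory=list)
    cis_pairs: list[dict] = field(default_factory=list)
    trans_pairs: list[dict] = field(default_factory=list)
    de_features: list[dict] = field(default_factory=list)
    tissue_of_sample: dict[str, str] = field(default_factory=dict)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthManifest":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _rng(config: SynthConfig, stream: int) -> np.random.Generator:
    # independent substream per generator stage so stages stay composable
    return np.random.default_rng([config.seed % (2**31), stream])


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_RNA), size=length))


def _mismatch_char(rng: np.random.Generator, mirna_char: str) -> str:
    wc = complement_rna(mirna_char)
    banned = {wc}
    if mirna_char == "G":
        banned.add("U")
    if mirna_char == "U":
        banned.add("G")
    return str(rng.choice(sorted(set(_RNA) - banned)))


def _wobble_char(mirna_char: str) -> str:
    if mirna_char == "G":
        return "U"
    if mirna_char == "U":
        return "G"
    raise ValueError(f"no wobble partner for {mirna_char!r}")


def build_etm_site(
    mirna_seq: str,
    spec: PlantedEtm,
    rng: np.random.Generator,
    params: EtmParams | None = None,
) -> tuple[str, dict]:
    """Construct a site sequence (5'->3') for splicing into an lncRNA.

    Positives start from the exact reverse complement and then receive the
    requested mismatches and wobbles at positions outside the seed window
    (2-8) and, if requested, a target-side bulge anchored inside 9-12.
    Negatives break exactly one rule: a seed mismatch (rule 1), an
    over-long bulge at a legal anchor (rule 2), or three mismatches
    outside the seed (rule 3).
    """
    params = params or EtmParams()
    L = len(mirna_seq)
    # pairing-orientation site: index i pairs miRNA position i+1
    revsite = [complement_rna(c) for c in mirna_seq]

    seed_positions = set(range(params.seed_start, params.seed_end + 1))
    outside_seed = [p for p in range(1, L + 1) if p not in seed_positions]

    n_mm, n_wb = spec.n_mismatches, spec.n_wobbles
    bulge_len = spec.bulge_length
    bulge_anchor: int | None = None
    mm_positions: list[int] = []
    wb_positions: list[int] = []

    if spec.violate_rule == 1:
        p = int(rng.choice(sorted(seed_positions)))
        revsite[p - 1] = _mismatch_char(rng, mirna_seq[p - 1])
        mm_positions = [p]
        n_mm, n_wb, bulge_len = 0, 0, 0
    elif spec.violate_rule == 2:
        # an over-long bulge at a legal anchor violates rule 2 and nothing
        # else; no shorter in-window bulge placement can re-pair the
        # shifted 3' half, so the site cannot be rescued by re-alignment
        bulge_len = params.max_bulge + 1
        bulge_anchor = int(
            rng.integers(params.bulge_anchor_start, params.bulge_anchor_end + 1)
        )
        n_mm, n_wb = 0, 0
    elif spec.violate_rule == 3:
        chosen = rng.choice(outside_seed, size=3, replace=False)
        for p in sorted(int(q) for q in chosen):
            revsite[p - 1] = _mismatch_char(rng, mirna_seq[p - 1])
            mm_positions.append(p)
        n_mm, n_wb, bulge_len = 3, 0, 0
    elif spec.violate_rule is not None:
        raise ValueError(f"unknown rule {spec.violate_rule}")

    if spec.violate_rule is None:
        wobble_eligible = [p for p in outside_seed if mirna_seq[p - 1] in "GU"]
        if n_wb > len(wobble_eligible):
            raise ValueError(
                f"cannot place {n_wb} wobbles: only {len(wobble_eligible)} "
                f"miRNA positions outside the seed carry G or U"
            )
        wb_positions = sorted(
            int(q) for q in rng.choice(wobble_eligible, size=n_wb, replace=False)
        )
        mm_eligible = [p for p in outside_seed if p not in wb_positions]
        if n_mm > len(mm_eligible):
            raise ValueError(f"cannot place {n_mm} mismatches")
        mm_positions = sorted(
            int(q) for q in rng.choice(mm_eligible, size=n_mm, replace=False)
        )
        for p in wb_positions:
            revsite[p - 1] = _wobble_char(mirna_seq[p - 1])
        for p in mm_positions:
            revsite[p - 1] = _mismatch_char(rng, mirna_seq[p - 1])
        if bulge_len > 0:
            bulge_anchor = int(
                rng.integers(params.bulge_anchor_start, params.bulge_anchor_end + 1)
            )

    if bulge_len > 0:
        assert bulge_anchor is not None
        insert = [str(rng.choice(list(_RNA))) for _ in range(bulge_len)]
        revsite = revsite[:bulge_anchor] + insert + revsite[bulge_anchor:]

    site = "".join(reversed(revsite))
    meta = {
        "site_length": len(site),
        "n_mismatches": len(mm_positions),
        "n_wobbles": len(wb_positions),
        "mismatch_positions": mm_positions,
        "wobble_positions": wb_positions,
        "bulge_length": bulge_len,
        "bulge_anchor": bulge_anchor,
        "violated_rule": spec.violate_rule,
    }
    return site, meta


def gen_sequences(
    config: SynthConfig,
) -> tuple[list[SequenceRecord], list[SequenceRecord], SynthManifest]:
    """Random miRNAs and lncRNAs with the configured sites spliced in."""
    rng = _rng(config, 1)
    lo, hi = config.mirna_length_range
    mirnas = [
        SequenceRecord(
            f"miR{i:03d}", Alphabet.RNA, _random_rna(rng, int(rng.integers(lo, hi + 1)))
        )
        for i in range(config.n_mirnas)
    ]
    llo, lhi = config.lncrna_length_range
    lnc_seqs = [
        list(_random_rna(rng, int(rng.integers(llo, lhi + 1))))
        for _ in range(config.n_lncrnas)
    ]

    manifest = SynthManifest()
    for spec in config.planted_etm_spec:
        mirna = mirnas[spec.mirna_index]
        site, meta = build_etm_site(
            mirna.residues, spec, rng, config.etm_params
        )
        lnc = lnc_seqs[spec.lncrna_index]
        if spec.offset < 0 or spec.offset + len(site) > len(lnc):
            raise ValueError(
                f"site of length {len(site)} at offset {spec.offset} does not "
                f"fit in lncRNA of length {len(lnc)}"
            )
        lnc[spec.offset : spec.offset + len(site)] = list(site)
        manifest.etm_sites.append(
            {
                "mirna_id": mirna.id,
                "lncrna_id": f"lnc{spec.lncrna_index:03d}",
                "site_start": spec.offset,
                "site_end": spec.offset + len(site),
                "is_positive": spec.violate_rule is None,
                **meta,
            }
        )

    lncrnas = [
        SequenceRecord(f"lnc{i:03d}", Alphabet.RNA, "".join(seq))
        for i, seq in enumerate(lnc_seqs)
    ]
    return mirnas, lncrnas, manifest


def _noisy_profile(
    rng: np.random.Generator,
    tissue_means: np.ndarray,
    n_replicates: int,
    noise_cv: float,
) -> np.ndarray:
    """Replicate values: tissue mean x mean-1 log-normal noise (CV = noise_cv)."""
    base = np.repeat(tissue_means, n_replicates)
    if noise_cv == 0:
        return base
    sigma = math.sqrt(math.log(1.0 + noise_cv**2))
    noise = np.exp(rng.normal(-sigma**2 / 2.0, sigma, size=base.size))
    return base * noise


def gen_expression(
    config: SynthConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, SynthManifest]:
    """lncRNA/gene (FPKM-like) and miRNA (TPM-like) matrices.

    Background features share one baseline mean across tissues; planted
    tissue-specific features are raised ``fold_over_background``-fold in
    their target tissue; planted correlated pairs are rejection-sampled to
    the requested sample-level Pearson r.
    """
    rng = _rng(config, 2)
    manifest = SynthManifest()
    samples = [
        f"{t}_r{r + 1}" for t in config.tissue_names for r in range(config.n_replicates)
    ]
    tissue_of_sample = {s: s.rsplit("_r", 1)[0] for s in samples}
    manifest.tissue_of_sample = tissue_of_sample
    n_t, n_r = config.n_tissues, config.n_replicates

    lnc_ids = [f"lnc{i:03d}" for i in range(config.n_lncrnas)]
    gene_ids = [f"gene{i:03d}" for i in range(config.n_genes)]
    mir_ids = [f"miR{i:03d}" for i in range(config.n_mirnas)]

    tau_by_feature = {p.feature_id: p for p in config.planted_tau_spec}
    known_ids = set(lnc_ids) | set(gene_ids) | set(mir_ids)
    for p in config.planted_tau_spec:
        if p.feature_id not in known_ids:
            raise ValueError(f"planted tau feature {p.feature_id!r} unknown")
        if p.target_tissue not in config.tissue_names:
            raise ValueError(f"unknown tissue {p.target_tissue!r}")

    def baseline() -> float:
        return float(np.exp(rng.normal(np.log(20.0), 1.0)))

    def feature_row(fid: str) -> np.ndarray:
        mu = baseline()
        means = np.full(n_t, mu)
        planted = tau_by_feature.get(fid)
        if planted is not None:
            idx = config.tissue_names.index(planted.target_tissue)
            means[idx] = mu * planted.fold_over_background
            manifest.tau_targets.append(
                {
                    "feature_id": fid,
                    "target_tissue": planted.target_tissue,
                    "fold_over_background": planted.fold_over_background,
                }
            )
        return _noisy_profile(rng, means, n_r, config.noise_cv)

    rows: dict[str, np.ndarray] = {}
    for fid in lnc_ids + gene_ids:
        rows[fid] = feature_row(fid)

    # planted correlated lncRNA-gene pairs (overwrites the gene row)
    for spec in config.trans_r_spec:
        if spec.lncrna_id not in rows or spec.gene_id not in rows:
            raise ValueError(
                f"trans spec references unknown ids "
                f"({spec.lncrna_id!r}, {spec.gene_id!r})"
            )
        x = rows[spec.lncrna_id]
        if x.std() == 0:
            raise ValueError(
                f"lncRNA row {spec.lncrna_id!r} is constant; cannot plant a "
                f"correlated pair (needs noise_cv > 0)"
            )
        zx = (x - x.mean()) / x.std()
        mu_g = baseline()
        achieved = None
        for _ in range(10_000):
            eps = rng.normal(size=x.size)
            eps = (eps - eps.mean()) / eps.std()
            y_std = spec.target_r * zx + math.sqrt(1 - spec.target_r**2) * eps
            y = mu_g * (1.0 + 0.2 * y_std)
            if y.min() <= 0:
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            if abs(abs(r) - abs(spec.target_r)) <= 0.02 and (r >= 0) == (
                spec.target_r >= 0
            ):
                rows[spec.gene_id] = y
                achieved = r
                break
        if achieved is None:
            raise RuntimeError(
                f"could not realize r={spec.target_r} for "
                f"({spec.lncrna_id}, {spec.gene_id})"
            )
        manifest.trans_pairs.append(
            {
                "lncrna_id": spec.lncrna_id,
                "gene_id": spec.gene_id,
                "target_r": spec.target_r,
                "achieved_r": round(achieved, 6),
            }
        )

    lnc_gene_df = pd.DataFrame.from_dict(
        {fid: rows[fid] for fid in lnc_ids + gene_ids}, orient="index", columns=samples
    )
    mir_df = pd.DataFrame.from_dict(
        {fid: feature_row(fid) for fid in mir_ids}, orient="index", columns=samples
    )
    return (
        ExpressionMatrix(lnc_gene_df, tissue_of_sample),
        ExpressionMatrix(mir_df, tissue_of_sample),
        manifest,
    )


def gen_annotation(
    config: SynthConfig, window_bp: int = 100_000
) -> tuple[list[GenomicFeature], SynthManifest]:
    """Features realizing each requested signed nearest-edge distance.

    Each specified (lncRNA, gene) pair gets its own chromosome so requested
    distances can never contradict each other; distractor genes are placed
    more than ``window_bp`` beyond each lncRNA and on a separate chromosome.
    """
    manifest = SynthManifest()
    feats: list[GenomicFeature] = []
    seen_pair: set[tuple[str, str]] = set()
    lnc_positions: dict[str, GenomicFeature] = {}
    lnc_len, gene_len = 1_000, 2_000
    chrom_of_lnc: dict[str, str] = {}

    for i, spec in enumerate(config.cis_distance_spec):
        key = (spec.lncrna_id, spec.gene_id)
        if key in seen_pair:
            raise ValueError(f"duplicate cis spec pair {key}")
        seen_pair.add(key)
        if spec.lncrna_id not in lnc_positions:
            chrom = f"chr{len(chrom_of_lnc) + 1}"
            chrom_of_lnc[spec.lncrna_id] = chrom
            lnc = GenomicFeature(
                spec.lncrna_id, chrom, 10_000_000, 10_000_000 + lnc_len,
                "+", FeatureClass.lncRNA,
            )
            lnc_positions[spec.lncrna_id] = lnc
            feats.append(lnc)
        lnc = lnc_positions[spec.lncrna_id]
        d = spec.signed_distance_bp
        if d > 0:
            start = lnc.end + d
        elif d < 0:
            start = lnc.start + d - gene_len
        else:
            start = lnc.start + 100  # overlapping gene
        gene = GenomicFeature(
            spec.gene_id, lnc.chrom, start, start + gene_len, "+", FeatureClass.gene
        )
        gap = max(lnc.start, gene.start) - min(lnc.end, gene.end)
        realized = max(0, gap)
        if realized != abs(d):
            raise ValueError(
                f"placement for {key} realized distance {realized}, wanted {abs(d)}"
            )
        feats.append(gene)
        manifest.cis_pairs.append(
            {
                "lncrna_id": spec.lncrna_id,
                "gene_id": spec.gene_id,
                "signed_distance_bp": d,
                "within_window": abs(d) <= window_bp,
            }
        )

    n_used = len({s.gene_id for s in config.cis_distance_spec})
    for j in range(max(0, config.n_genes - n_used)):
        start = 1_000_000 + j * (window_bp * 3)
        feats.append(
            GenomicFeature(
                f"distractor_gene{j:03d}", "chr0", start, start + gene_len,
                "+", FeatureClass.gene,
            )
        )
    return feats, manifest


def gen_de_table(config: SynthConfig) -> tuple[list[DERecord], SynthManifest]:
    """DE rows with planted positives and boundary-straddling background.

    Planted features clear both thresholds (padj < 0.05, |log2FC| > 1);
    background rows fail one or both, including rows sitting exactly on
    each boundary to exercise strict-inequality filtering.
    """
    rng = _rng(config, 4)
    manifest = SynthManifest()
    records: list[DERecord] = []
    contrast = "petal_vs_leaf"
    for i in range(config.n_de_planted):
        fid = f"de_pos{i:03d}"
        padj = float(rng.uniform(1e-6, 0.049))
        lfc = float(rng.uniform(1.1, 6.0)) * (1 if rng.random() < 0.5 else -1)
        records.append(DERecord(fid, contrast, lfc, padj))
        manifest.de_features.append({"feature_id": fid, "contrast": contrast})
    boundary = [
        (0.05, 3.0),  # padj exactly at the cutoff
        (0.01, 1.0),  # |log2FC| exactly at the cutoff
        (0.05, 1.0),  # both exactly at the cutoff
    ]
    for i in range(config.n_de_background):
        fid = f"de_bg{i:03d}"
        if i < len(boundary):
            padj, lfc = boundary[i]
        else:
            kind = i % 3
            if kind == 0:
                padj = float(rng.uniform(0.05, 1.0))
                lfc = float(rng.uniform(1.1, 6.0))
            elif kind == 1:
                padj = float(rng.uniform(1e-6, 0.049))
                lfc = float(rng.uniform(-1.0, 1.0))
            else:
                padj = float(rng.uniform(0.05, 1.0))
                lfc = float(rng.uniform(-1.0, 1.0))
        records.append(DERecord(fid, contrast, lfc, padj))
    return records, manifest


def default_config(seed: int = 0) -> SynthConfig:
    """The stock study-shaped configuration used by ``simulate``/``run-all``.

    Twelve samples (4 tissues x 3 replicates), planted eTM positives
    covering the gapless, mismatch, wobble and bulged cases, one negative
    per rule, tissue-specific features at 1000-fold enrichment, cis pairs
    inside and outside the 100-kb window (including the exact boundary),
    and correlated pairs at |r| = 0.99 of both signs.
    """
    return SynthConfig(
        seed=seed,
        planted_etm_spec=[
            PlantedEtm(0, 0, 50),
            PlantedEtm(1, 1, 120, n_mismatches=1),
            PlantedEtm(2, 2, 200, n_wobbles=1),
            PlantedEtm(3, 3, 80, bulge_length=1),
            PlantedEtm(4, 4, 150, bulge_length=2, n_mismatches=1, n_wobbles=1),
            PlantedEtm(5, 5, 60, n_mismatches=2),
            PlantedEtm(6, 6, 90, violate_rule=1),
            PlantedEtm(7, 7, 110, violate_rule=2),
            PlantedEtm(8, 8, 130, violate_rule=3),
        ],
        planted_tau_spec=[
            PlantedTau("lnc010", "stamen", 1000.0),
            PlantedTau("lnc011", "pistil", 1000.0),
            PlantedTau("gene010", "leaf", 1000.0),
            PlantedTau("miR009", "petal", 1000.0),
        ],
        cis_distance_spec=[
            CisSpec("lnc020", "gene020", 50_000),
            CisSpec("lnc021", "gene021", -30_000),
            CisSpec("lnc022", "gene022", 0),
            CisSpec("lnc023", "gene023", 100_000),  # inclusive boundary
            CisSpec("lnc024", "gene024", 150_000),  # outside the window
            CisSpec("lnc025", "gene025", 250_000),  # far outside
        ],
        trans_r_spec=[
            TransSpec("lnc030", "gene030", 0.99),
            TransSpec("lnc031", "gene031", 0.99),
            TransSpec("lnc032", "gene032", -0.99),
        ],
    )


def simulate_all(config: SynthConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate every input file plus the merged manifest; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mirnas, lncrnas, m_seq = gen_sequences(config)
    lnc_gene_expr, mir_expr, m_expr = gen_expression(config)
    features, m_annot = gen_annotation(config)
    de_records, m_de = gen_de_table(config)

    manifest = SynthManifest(
        etm_sites=m_seq.etm_sites,
        tau_targets=m_expr.tau_targets,
        cis_pairs=m_annot.cis_pairs,
        trans_pairs=m_expr.trans_pairs,
        de_features=m_de.de_features,
        tissue_of_sample=m_expr.tissue_of_sample,
    )
    paths = {
        "mirnas_fasta": outdir / "mirnas.fasta",
        "lncrnas_fasta": outdir / "lncrnas.fasta",
        "lnc_gene_expression": outdir / "expression_lnc_gene.tsv",
        "mirna_expression": outdir / "expression_mirna.tsv",
        "annotation_gff3": outdir / "annotation.gff3",
        "de_table": outdir / "de_table.tsv",
        "manifest": outdir / "manifest.yaml",
    }
    write_fasta(mirnas, paths["mirnas_fasta"])
    write_fasta(lncrnas, paths["lncrnas_fasta"])
    write_expression(lnc_gene_expr, paths["lnc_gene_expression"])
    write_expression(mir_expr, paths["mirna_expression"])
    write_features(features, paths["annotation_gff3"], "GFF3")
    write_de_table(de_records, paths["de_table"])
    manifest.to_yaml(paths["manifest"])
    return paths
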