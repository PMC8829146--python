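"""Readers and writers for the external formats the pipeline touches.

Conventions fixed here once, so downstream stages never argue about them:

* genomic intervals are 0-based half-open internally; GFF3 (1-based,
  inclusive) is converted at this boundary only;
* sequences are uppercase; RNA is the canonical alphabet for pairing work,
  and ``T`` in RNA input is transcribed to ``U`` with a logged warning;
* tables are plain TSV, UTF-8, no quoting; ``.`` or an empty field means
  missing where a column allows it;
* duplicate identifiers are hard errors, never last-wins, because network
  node identity depends on them.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "Alphabet",
    "FeatureClass",
    "Interaction",
    "SequenceRecord",
    "GenomicFeature",
    "ExpressionMatrix",
    "DERecord",
    "TargetPair",
    "read_fasta",
    "write_fasta",
    "read_features",
    "write_features",
    "read_expression",
    "write_expression",
    "read_de_table",
    "write_de_table",
    "read_pair_table",
    "write_pair_table",
]


class Alphabet(str, enum.Enum):
    RNA = "RNA"
    DNA = "DNA"


_VALID_CHARS = {Alphabet.RNA: frozenset("ACGU"), Alphabet.DNA: frozenset("ACGT")}


class FeatureClass(str, enum.Enum):
    gene = "gene"
    lncRNA = "lncRNA"
    TF_gene = "TF_gene"
    other = "other"


class Interaction(str, enum.Enum):
    mirna_cleaves_mrna = "mirna_cleaves_mrna"
    mirna_cleaves_lncrna = "mirna_cleaves_lncrna"


@dataclass(frozen=True)
class SequenceRecord:
    """A single named RNA or DNA sequence (a mature miRNA or an lncRNA)."""

    id: str
    alphabet: Alphabet
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r}: residues must be non-empty")
        valid = _VALID_CHARS[Alphabet(self.alphabet)]
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in valid:
                raise ValueError(
                    f"sequence {self.id!r}: invalid {self.alphabet.value} "
                    f"character {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GenomicFeature:
    """A located feature; coordinates 0-based half-open on ``chrom``."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    feature_class: FeatureClass = FeatureClass.other

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError(f"feature {self.id!r}: chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature {self.id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"feature {self.id!r}: invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class ExpressionMatrix:
    """Feature x sample abundance matrix (FPKM or TPM) with a tissue map.

    ``values`` is a pandas DataFrame indexed by feature id with one column
    per sample; every sample must appear in ``tissue_of_sample``.
    """

    values: pd.DataFrame
    tissue_of_sample: dict[str, str]

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate feature id {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample label {dup!r}")
        missing = [s for s in self.values.columns if s not in self.tissue_of_sample]
        if missing:
            raise ValueError(f"samples not in tissue map: {missing}")
        arr = self.values.to_numpy(dtype=float)
        if pd.isna(arr).any():
            i, j = map(int, next(iter(zip(*pd.isna(arr).nonzero()))))
            raise ValueError(
                f"missing expression value at feature "
                f"{self.values.index[i]!r}, sample {self.values.columns[j]!r}"
            )
        bad = ~np.isfinite(arr) | (arr < 0)
        if bad.any():
            i, j = map(int, next(iter(zip(*bad.nonzero()))))
            raise ValueError(
                f"invalid expression value {arr[i, j]!r} at feature "
                f"{self.values.index[i]!r}, sample {self.values.columns[j]!r}"
            )
        if not set(self.tissue_of_sample.values()):
            raise ValueError("at least one tissue required")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_labels(self) -> list[str]:
        return list(self.values.columns)

    @property
    def tissues(self) -> list[str]:
        """Tissue names in order of first appearance across sample columns."""
        seen: list[str] = []
        for s in self.values.columns:
            t = self.tissue_of_sample[s]
            if t not in seen:
                seen.append(t)
        return seen


@dataclass(frozen=True)
class DERecord:
    """One row of a differential-expression result table."""

    feature_id: str
    contrast: str
    log2fc: float
    padj: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.log2fc):
            raise ValueError(f"{self.feature_id!r}: log2fc must be finite")
        if not (0.0 <= self.padj <= 1.0):
            raise ValueError(f"{self.feature_id!r}: padj {self.padj} outside [0, 1]")


@dataclass(frozen=True)
class TargetPair:
    """A regulator->target cleavage relation, as emitted by degradome analysis."""

    regulator_id: str
    target_id: str
    interaction: Interaction
    cleavage_position: int | None = None

    def __post_init__(self) -> None:
        if self.regulator_id == self.target_id:
            raise ValueError(f"self-pair {self.regulator_id!r}")
        if self.cleavage_position is not None and self.cleavage_position < 1:
            raise ValueError(
                f"{self.regulator_id}->{self.target_id}: "
                f"cleavage_position must be >= 1 (1-based)"
            )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, alphabet: Alphabet | str) -> list[SequenceRecord]:
    """Read a FASTA file into validated :class:`SequenceRecord` objects.

    Residues are uppercased.  For ``alphabet=RNA`` any ``T`` is transcribed
    to ``U`` (logged); ambiguity codes and other characters are rejected
    with the record id and position.
    """
    alphabet = Alphabet(alphabet)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        if alphabet is Alphabet.RNA and "T" in residues:
            logger.warning(
                "sequence %r: DNA-style T converted to U for RNA alphabet", rec.id
            )
            residues = residues.replace("T", "U")
        records.append(SequenceRecord(rec.id, alphabet, residues))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(bio, fh, "fasta-2line")


# ---------------------------------------------------------------------------
# GFF3 / BED

_DEFAULT_CLASS_MAP = {
    "gene": FeatureClass.gene,
    "mRNA": FeatureClass.gene,
    "lncRNA": FeatureClass.lncRNA,
    "lnc_RNA": FeatureClass.lncRNA,
    "TF_gene": FeatureClass.TF_gene,
}


def _parse_gff3_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in attr.strip().split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        out[key.strip()] = value.strip()
    return out


def read_features(
    path: str | Path,
    dialect: str = "GFF3",
    class_map: Mapping[str, FeatureClass] | None = None,
) -> list[GenomicFeature]:
    """Read GFF3 (1-based inclusive) or BED4+ (0-based half-open) features.

    Coordinates are normalized to 0-based half-open.  ``feature_class`` is
    inferred from the GFF3 type column through ``class_map`` (BED features
    default to ``other`` unless the name encodes nothing better).
    """
    if dialect not in {"GFF3", "BED"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    cmap = dict(_DEFAULT_CLASS_MAP)
    if class_map:
        cmap.update(class_map)
    feats: list[GenomicFeature] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if dialect == "GFF3":
                if len(cols) < 9:
                    raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
                chrom, _source, ftype, start1, end1, _score, strand, _frame, attr = cols[:9]
                start = int(start1) - 1
                end = int(end1)
                attrs = _parse_gff3_attributes(attr)
                fid = attrs.get("ID") or attrs.get("Name")
                if not fid:
                    raise ValueError(f"{path}:{lineno}: feature without ID attribute")
                fclass = cmap.get(ftype, FeatureClass.other)
            else:
                if len(cols) < 4:
                    raise ValueError(f"{path}:{lineno}: expected >= 4 BED columns")
                chrom, start_s, end_s, fid = cols[:4]
                start, end = int(start_s), int(end_s)
                strand = cols[5] if len(cols) >= 6 else "."
                fclass = FeatureClass.other
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: empty/inverted interval after conversion "
                    f"({start}, {end})"
                )
            if fid in seen:
                raise ValueError(f"{path}:{lineno}: duplicate feature id {fid!r}")
            seen.add(fid)
            strand = strand if strand in {"+", "-"} else "."
            feats.append(GenomicFeature(fid, chrom, start, end, strand, fclass))
    return feats


_CLASS_TO_GFF_TYPE = {
    FeatureClass.gene: "gene",
    FeatureClass.lncRNA: "lnc_RNA",
    FeatureClass.TF_gene: "TF_gene",
    FeatureClass.other: "region",
}


def write_features(
    features: Iterable[GenomicFeature], path: str | Path, dialect: str = "GFF3"
) -> None:
    """Write features, converting back to 1-based inclusive for GFF3."""
    if dialect not in {"GFF3", "BED"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        if dialect == "GFF3":
            fh.write("##gff-version 3\n")
            for f in features:
                fh.write(
                    "\t".join(
                        [
                            f.chrom,
                            "etmnet",
                            _CLASS_TO_GFF_TYPE[f.feature_class],
                            str(f.start + 1),
                            str(f.end),
                            ".",
                            f.strand if f.strand in {"+", "-"} else ".",
                            ".",
                            f"ID={f.id}",
                        ]
                    )
                    + "\n"
                )
        else:
            for f in features:
                fh.write(
                    f"{f.chrom}\t{f.start}\t{f.end}\t{f.id}\t0\t"
                    f"{f.strand if f.strand in {'+', '-'} else '.'}\n"
                )


# ---------------------------------------------------------------------------
# Expression matrices


def read_expression(
    path: str | Path, tissue_map: Mapping[str, str]
) -> ExpressionMatrix:
    """Read a TSV (first column feature ids, header row sample labels)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["", "."])
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df.astype(float), dict(tissue_map))


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", float_format="%.6f", index_label="feature_id")


# ---------------------------------------------------------------------------
# DE tables


def read_de_table(path: str | Path) -> list[DERecord]:
    df = pd.read_csv(path, sep="\t", dtype={"feature_id": str, "contrast": str})
    required = {"feature_id", "contrast", "log2fc", "padj"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    return [
        DERecord(r.feature_id, r.contrast, float(r.log2fc), float(r.padj))
        for r in df.itertuples(index=False)
    ]


def write_de_table(records: Iterable[DERecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("feature_id\tcontrast\tlog2fc\tpadj\n")
        for r in records:
            fh.write(f"{r.feature_id}\t{r.contrast}\t{r.log2fc:.6g}\t{r.padj:.6g}\n")


# ---------------------------------------------------------------------------
# Target-pair tables (degradome-style)

_PAIR_COLUMNS = ["regulator_id", "target_id", "interaction", "cleavage_position"]


def read_pair_table(path: str | Path) -> list[TargetPair]:
    pairs: list[TargetPair] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(_PAIR_COLUMNS)] != _PAIR_COLUMNS:
            raise ValueError(f"{path}: unexpected header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 columns")
            reg, tgt, inter = cols[0], cols[1], cols[2]
            try:
                interaction = Interaction(inter)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: unknown interaction token {inter!r}"
                ) from None
            pos_s = cols[3] if len(cols) > 3 else ""
            pos = None if pos_s in {"", "."} else int(pos_s)
            pairs.append(TargetPair(reg, tgt, interaction, pos))
    return pairs


def write_pair_table(pairs: Iterable[TargetPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_PAIR_COLUMNS) + "\n")
        for p in pairs:
            pos = "" if p.cleavage_position is None else str(p.cleavage_position)
            fh.write(f"{p.regulator_id}\t{p.target_id}\t{p.interaction.value}\t{pos}\n")
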