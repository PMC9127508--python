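"""Readers and writers for every external tabular format the pipeline touches.

All inputs are plain TSV. Matrices are genes (or miRNAs) in rows, samples in
columns, with the row-name column called ``gene`` (``mirna``). Interaction
networks are STRING-dialect edge lists with per-channel scores. Writers emit
byte-stable output: fixed column order, floats at six significant digits.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .config import MISSING, MUTATION_TYPES, RunConfig, _Missing

logger = logging.getLogger(__name__)

TUMOR = "TUMOR"
NORMAL = "NORMAL"

_REQUIRED_MUTATION_COLS = ("sample", "gene", "chrom", "pos", "ref", "alt", "type")


@dataclass
class MutationRecord:
    """One annotated somatic mutation.

    Coordinates are 1-based and fully closed (MAF convention); allele
    strings are uppercased on parse so matching is case-insensitive.
    """

    sample_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    mutation_type: str
    tool_scores: dict[str, float | _Missing] = field(default_factory=dict)
    tool_preds: dict[str, str | _Missing] = field(default_factory=dict)
    domains: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.mutation_type not in MUTATION_TYPES:
            raise ValueError(f"unknown mutation_type {self.mutation_type!r}")


@dataclass
class CountsMatrix:
    """Raw read counts (genes x samples) with a tumor/normal condition map."""

    counts: pd.DataFrame  # genes x samples, non-negative integers
    condition: dict[str, str]  # sample -> TUMOR | NORMAL

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dupes = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene symbols in counts: {dupes}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts are not allowed")
        for s in self.counts.columns:
            if s not in self.condition:
                raise ValueError(f"sample {s!r} missing from condition map")
            if self.condition[s] not in (TUMOR, NORMAL):
                raise ValueError(f"condition for {s!r} must be TUMOR or NORMAL")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def tumor_samples(self) -> list[str]:
        return [s for s in self.counts.columns if self.condition[s] == TUMOR]

    @property
    def normal_samples(self) -> list[str]:
        return [s for s in self.counts.columns if self.condition[s] == NORMAL]


@dataclass
class CNVMatrix:
    """GISTIC-style integer copy-number scores (genes x samples); 0 = no change."""

    scores: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.scores.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("CNV scores must be integer-valued")
            self.scores = self.scores.astype(int)

    def altered_pairs(self) -> set[tuple[str, str]]:
        """(sample, gene) pairs with a nonzero copy-number score."""
        rows, cols = np.nonzero(self.scores.to_numpy())
        return {
            (self.scores.columns[c], self.scores.index[r]) for r, c in zip(rows, cols)
        }


@dataclass
class MiRNAMatrix:
    """miRNA expression (miRNAs x samples) with a declared onco-miRNA subset."""

    expression: pd.DataFrame
    onco_mirnas: tuple[str, ...]

    def __post_init__(self) -> None:
        unknown = [m for m in self.onco_mirnas if m not in self.expression.index]
        if unknown:
            logger.warning("onco-miRNAs absent from matrix (treated as 0): %s", unknown)


@dataclass
class EdgeList:
    """Filtered, deduplicated, undirected interaction edges."""

    edges: pd.DataFrame  # gene_a, gene_b, experimental_score, database_score

    def pairs(self) -> list[tuple[str, str]]:
        return list(zip(self.edges["gene_a"], self.edges["gene_b"]))

    def nodes(self) -> set[str]:
        return set(self.edges["gene_a"]) | set(self.edges["gene_b"])

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class DriverResources:
    """Curated mutation-level and gene-level driver lists plus neutral genes."""

    mutation_drivers: pd.DataFrame  # gene, pos, ref, alt, label, evidence_score
    gene_drivers: pd.DataFrame  # gene, tag, cancer_type
    neutral_genes: set[str]

    def __post_init__(self) -> None:
        driver_symbols = set(self.gene_drivers["gene"])
        overlap = self.neutral_genes & driver_symbols
        if overlap:
            logger.warning(
                "genes in both neutral and driver lists dropped from neutral: %s",
                sorted(overlap),
            )
            self.neutral_genes = self.neutral_genes - overlap


def _parse_cell(value: object) -> float | _Missing:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return MISSING
    s = str(value).strip()
    if s in ("", "."):
        return MISSING
    return float(s)


def _parse_pred(value: object) -> str | _Missing:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return MISSING
    s = str(value).strip()
    if s in ("", "."):
        return MISSING
    return s


def read_mutations(path: str | Path, config: RunConfig) -> list[MutationRecord]:
    """Parse an annotated mutation table into :class:`MutationRecord` rows.

    Blank or ``"."`` score/prediction cells become MISSING; the domain cell
    is split on ``config.domain_delimiter`` into Pfam accessions; unknown
    mutation types are mapped to ``"other"`` with a logged warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in _REQUIRED_MUTATION_COLS:
        if col not in df.columns:
            raise ValueError(f"mutation table is missing required column {col!r}")
    records: list[MutationRecord] = []
    for row in df.itertuples(index=False):
        row = row._asdict()
        mtype = row["type"].strip()
        if mtype not in MUTATION_TYPES:
            logger.warning("unknown mutation type %r mapped to 'other'", mtype)
            mtype = "other"
        scores: dict[str, float | _Missing] = {}
        preds: dict[str, str | _Missing] = {}
        for tool in config.tools:
            scores[tool] = _parse_cell(row.get(f"{tool}_score", "."))
            preds[tool] = _parse_pred(row.get(f"{tool}_pred", "."))
        domain_cell = str(row.get("domains", "")).strip()
        domains = frozenset(
            d.strip()
            for d in domain_cell.split(config.domain_delimiter)
            if d.strip() and d.strip() != "."
        )
        records.append(
            MutationRecord(
                sample_id=row["sample"],
                gene=row["gene"].strip(),
                chrom=row["chrom"],
                pos=int(row["pos"]),
                ref=row["ref"].strip().upper(),
                alt=row["alt"].strip().upper(),
                mutation_type=mtype,
                tool_scores=scores,
                tool_preds=preds,
                domains=domains,
            )
        )
    return records


_EDGE_COL_ALIASES = {
    "gene_a": ("gene_a", "protein1", "node1"),
    "gene_b": ("gene_b", "protein2", "node2"),
    "experimental_score": ("experimental_score", "experimental", "experiments"),
    "database_score": ("database_score", "database"),
}


def read_network(path: str | Path, config: RunConfig) -> EdgeList:
    """Read a STRING-dialect edge list and apply the score filter.

    An edge is retained iff max(experimental, database) score is strictly
    greater than ``config.string_score_cutoff``. Self-loops are dropped and
    symmetric duplicates collapsed (undirected semantics).
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    colmap: dict[str, str] = {}
    for canonical, aliases in _EDGE_COL_ALIASES.items():
        for alias in aliases:
            if alias in df.columns:
                colmap[canonical] = alias
                break
        else:
            raise ValueError(f"edge list is missing a column for {canonical!r}")
    for canonical in ("experimental_score", "database_score"):
        col = df[colmap[canonical]]
        for i, v in enumerate(col):
            try:
                int(v)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-integer {canonical} {v!r} at row {i + 1}"
                ) from None
    exp = df[colmap["experimental_score"]].astype(int).to_numpy()
    dbs = df[colmap["database_score"]].astype(int).to_numpy()
    a = df[colmap["gene_a"]].str.strip().to_numpy()
    b = df[colmap["gene_b"]].str.strip().to_numpy()

    keep = np.maximum(exp, dbs) > config.string_score_cutoff
    keep &= a != b
    seen: set[tuple[str, str]] = set()
    rows = []
    for ga, gb, e, d, k in zip(a, b, exp, dbs, keep):
        if not k:
            continue
        key = (ga, gb) if ga <= gb else (gb, ga)
        if key in seen:
            continue
        seen.add(key)
        rows.append((key[0], key[1], int(e), int(d)))
    out = pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "experimental_score", "database_score"]
    )
    return EdgeList(out)


def _read_matrix(path: str | Path, index_name: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if index_name not in df.columns:
        raise ValueError(f"matrix file is missing the {index_name!r} column")
    df = df.set_index(index_name)
    df.index = df.index.astype(str)
    return df


def read_counts(counts_path: str | Path, condition_path: str | Path) -> CountsMatrix:
    """Read a gene-level count matrix plus its two-column condition map."""
    counts = _read_matrix(counts_path, "gene")
    arr = counts.to_numpy()
    if (arr < 0).any():
        raise ValueError("counts file contains negative values")
    counts = counts.astype(int)
    cond_df = pd.read_csv(condition_path, sep="\t", dtype=str)
    for col in ("sample", "condition"):
        if col not in cond_df.columns:
            raise ValueError(f"condition map is missing column {col!r}")
    condition = {
        r.sample: r.condition.strip().upper() for r in cond_df.itertuples(index=False)
    }
    return CountsMatrix(counts, condition)


def read_cnv(path: str | Path) -> CNVMatrix:
    return CNVMatrix(_read_matrix(path, "gene"))


def read_mirna(path: str | Path, onco_path: str | Path) -> MiRNAMatrix:
    expr = _read_matrix(path, "mirna")
    onco = pd.read_csv(onco_path, sep="\t", dtype=str)
    if "mirna" not in onco.columns:
        raise ValueError("onco-miRNA list is missing the 'mirna' column")
    return MiRNAMatrix(expr, tuple(onco["mirna"]))


def read_driver_resources(
    mutation_path: str | Path, gene_path: str | Path, neutral_path: str | Path
) -> DriverResources:
    """Read mutation-level drivers, gene-level TSG/OG lists, and neutral genes."""
    mut = pd.read_csv(mutation_path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("gene", "pos", "ref", "alt", "label", "evidence_score"):
        if col not in mut.columns:
            raise ValueError(f"mutation driver list is missing column {col!r}")
    mut = mut.assign(
        pos=mut["pos"].astype(int),
        ref=mut["ref"].str.upper(),
        alt=mut["alt"].str.upper(),
        evidence_score=[_parse_cell(v) for v in mut["evidence_score"]],
    )
    gene = pd.read_csv(gene_path, sep="\t", dtype=str)
    for col in ("gene", "tag", "cancer_type"):
        if col not in gene.columns:
            raise ValueError(f"gene driver list is missing column {col!r}")
    neutral = pd.read_csv(neutral_path, sep="\t", dtype=str)
    if "gene" not in neutral.columns:
        raise ValueError("neutral gene list is missing the 'gene' column")
    return DriverResources(mut, gene, set(neutral["gene"]))


# ---------------------------------------------------------------------------
# Writers


def _format_float(x: object) -> str:
    if isinstance(x, (float, np.floating)):
        return f"{x:.6g}"
    return str(x)


_KEY_COLS = ("sample", "gene", "label", "alteration_kind", "strategy")


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table with stable column order and 6-sig-digit floats.

    Key columns (sample, gene, and label-like columns if present) come
    first; feature columns follow in sorted order. Two writes of equal
    tables are byte-identical.
    """
    keys = [c for c in _KEY_COLS if c in table.columns]
    features = sorted(c for c in table.columns if c not in keys)
    out = table[keys + features]
    with open(path, "w") as fh:
        fh.write("\t".join(out.columns) + "\n")
        for row in out.itertuples(index=False):
            fh.write("\t".join(_format_float(v) for v in row) + "\n")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_predictions(preds: pd.DataFrame, path: str | Path) -> None:
    """Write per-pair predicted classes and class probabilities as TSV."""
    lead = [c for c in ("sample", "gene", "predicted") if c in preds.columns]
    rest = sorted(c for c in preds.columns if c not in lead)
    out = preds[lead + rest]
    with open(path, "w") as fh:
        fh.write("\t".join(out.columns) + "\n")
        for row in out.itertuples(index=False):
            fh.write("\t".join(_format_float(v) for v in row) + "\n")


def write_matrix(df: pd.DataFrame, path: str | Path, index_name: str) -> None:
    df = df.copy()
    df.index.name = index_name
    df.to_csv(path, sep="\t")
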