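"""Readers for the tab-separated inputs of the pipeline.

Three files drive an analysis: a genes x samples expression matrix, a
clinical table with overall-survival time and event status, and a
protein-protein interaction (PPI) edge list (two gene-ID columns with an
optional confidence score, STRING-style).  Gene identifiers are treated as
opaque strings throughout; no ID translation is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "PPIEdgeList",
    "ParseError",
    "read_expression",
    "read_clinical",
    "read_ppi",
    "collapse_probes",
]


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class ExpressionMatrix:
    """Dense expression matrix, genes in rows, samples in columns."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_genes, n_samples)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample IDs")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            gene_ids=[str(g) for g in df.index],
            sample_ids=[str(s) for s in df.columns],
            values=df.to_numpy(dtype=float),
        )

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return ExpressionMatrix(list(self.gene_ids), list(sample_ids), self.values[:, idx])


@dataclass
class ClinicalTable:
    """Per-sample overall-survival outcome: days to death/censoring and event flag."""

    sample_ids: list[str]
    days: np.ndarray  # float, >= 0
    dead: np.ndarray  # bool
    extra: pd.DataFrame | None = None  # optional age/stage/grade, unused by the core

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.dead = np.asarray(self.dead, dtype=bool)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample IDs in clinical table")
        if not (len(self.sample_ids) == len(self.days) == len(self.dead)):
            raise ValueError("clinical table columns have unequal lengths")
        if np.any(self.days < 0):
            raise ValueError("negative survival time")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"days_to_death": self.days, "death_status": self.dead.astype(int)},
            index=self.sample_ids,
        )


@dataclass
class PPIEdgeList:
    """Unordered protein-protein interaction pairs, optionally scored."""

    pairs: list[tuple[str, str]] = field(default_factory=list)
    scores: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        canon = []
        seen = set()
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"self-pair {a!r}")
            key = (a, b) if a <= b else (b, a)
            if key in seen:
                raise ValueError(f"duplicate pair {key}")
            seen.add(key)
            canon.append(key)
        self.pairs = canon

    def __len__(self) -> int:
        return len(self.pairs)

    def genes(self) -> set[str]:
        return {g for pair in self.pairs for g in pair}

    def restricted_to(self, genes) -> "PPIEdgeList":
        keep = set(genes)
        pairs = [p for p in self.pairs if p[0] in keep and p[1] in keep]
        return PPIEdgeList(pairs, {p: self.scores[p] for p in pairs if p in self.scores})


def read_expression(path) -> ExpressionMatrix:
    """Read a genes x samples TSV: first column = gene/probe ID, header = sample IDs.

    Rows with non-numeric entries and ragged rows raise :class:`ParseError`
    naming the offending line.
    """
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise ParseError(f"{path}: empty file, no header")
        sample_ids = header.rstrip("\n").split("\t")[1:]
        if not sample_ids:
            raise ParseError(f"{path}: header has no sample columns")
        if len(set(sample_ids)) != len(sample_ids):
            raise ParseError(f"{path}: duplicate sample IDs in header")
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(sample_ids) + 1:
                raise ParseError(
                    f"{path}:{lineno}: expected {len(sample_ids) + 1} fields, "
                    f"got {len(fields)}"
                )
            try:
                rows.append([float(v) for v in fields[1:]])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric entry ({exc})") from None
            gene_ids.append(fields[0])
    if not rows:
        raise ParseError(f"{path}: no data rows")
    return ExpressionMatrix(gene_ids, sample_ids, np.array(rows, dtype=float))


def read_clinical(path) -> ClinicalTable:
    """Read a clinical TSV with columns sample_id, days_to_death, death_status."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    required = {"sample_id", "days_to_death", "death_status"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    extra_cols = [c for c in df.columns if c not in required]
    return ClinicalTable(
        sample_ids=[str(s) for s in df["sample_id"]],
        days=df["days_to_death"].to_numpy(dtype=float),
        dead=df["death_status"].to_numpy().astype(bool),
        extra=df[extra_cols].set_axis(df["sample_id"]) if extra_cols else None,
    )


def read_ppi(path, min_score: float | None = None) -> PPIEdgeList:
    """Read a PPI edge list (gene_a, gene_b[, score]) and apply a score cutoff.

    Pairs with score >= ``min_score`` are retained (the STRING convention of
    keeping pairs "with score of no less than" the cutoff); with
    ``min_score=None`` every pair is kept.  Self-pairs are dropped and the two
    orientations of a pair are collapsed to one unordered pair.
    """
    pairs: list[tuple[str, str]] = []
    scores: dict[tuple[str, str], float] = {}
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected at least 2 columns")
            a, b = fields[0], fields[1]
            score = None
            if len(fields) >= 3 and fields[2] != "":
                try:
                    score = float(fields[2])
                except ValueError:
                    raise ParseError(f"{path}:{lineno}: non-numeric score") from None
            if min_score is not None:
                if score is None:
                    raise ParseError(
                        f"{path}:{lineno}: min_score given but row has no score column"
                    )
                if score < min_score:
                    continue
            if a == b:
                continue
            key = (a, b) if a <= b else (b, a)
            if key in seen:
                continue
            seen.add(key)
            pairs.append(key)
            if score is not None:
                scores[key] = score
    return PPIEdgeList(pairs, scores)


def collapse_probes(m: ExpressionMatrix, probe_to_gene: dict[str, str]) -> ExpressionMatrix:
    """Average the rows of all probes mapping to the same gene.

    Probes absent from ``probe_to_gene`` are dropped.  Output genes are ordered
    by first appearance of any of their probes.
    """
    if not probe_to_gene:
        raise ValueError("empty probe-to-gene mapping")
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for i, probe in enumerate(m.gene_ids):
        gene = probe_to_gene.get(probe)
        if gene is None:
            continue
        if gene not in groups:
            groups[gene] = []
            order.append(gene)
        groups[gene].append(i)
    if not order:
        raise ValueError("no probe mapped to any gene")
    values = np.vstack([m.values[groups[g]].mean(axis=0) for g in order])
    return ExpressionMatrix(order, list(m.sample_ids), values)
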