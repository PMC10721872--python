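"""Readers and writers for expression matrices, gene signatures, survival
tables and score tables.

Formats
-------
* Dense TSV: first column holds gene identifiers, header row holds sample
  identifiers.
* MatrixMarket coordinate triplet (``.mtx``, 1-based indices) with companion
  ``genes.tsv`` / ``samples.tsv`` one-identifier-per-line files.
* GMT per the MSigDB convention (name, description, genes...). Line pairs
  following the ``<name>_UP`` / ``<name>_DN`` suffix convention are merged
  into a single signed signature.
* Survival TSV with columns ``sample``, ``time`` (days), ``event``
  (0 = censored, 1 = death).

Gene and sample identifiers are opaque, case-sensitive strings; no symbol or
Ensembl mapping is attempted. Missing values are not permitted anywhere.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import ParseError, SchemaError, ValidationError

MODALITIES = ("bulk", "scrna")
SCALES = ("raw_count", "tpm", "log2_tpm10p1", "normalized")

#: TSV float format giving 12 significant digits, enough for value-faithful
#: round-trips of doubles at the precision the package guarantees.
FLOAT_FORMAT = "%.12g"


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """A gene x sample (or gene x cell) numeric expression matrix.

    Parameters
    ----------
    genes, samples
        Ordered unique identifiers for the rows / columns.
    values
        Dense float array of shape ``(len(genes), len(samples))``.
    modality
        ``"bulk"`` or ``"scrna"``.
    scale
        Declared value scale; one of :data:`SCALES`. ``log2_tpm10p1`` means
        values are stored as ``log2(TPM/10 + 1)``.
    """

    genes: list[str]
    samples: list[str]
    values: np.ndarray
    modality: str = "bulk"
    scale: str = "normalized"

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        self.samples = list(self.samples)
        self.values = np.asarray(self.values, dtype=float)
        if self.modality not in MODALITIES:
            raise ValidationError(f"unknown modality {self.modality!r}")
        if self.scale not in SCALES:
            raise ValidationError(f"unknown scale {self.scale!r}")
        _check_unique(self.genes, "gene")
        _check_unique(self.samples, "sample")
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if not np.isfinite(self.values).all():
            raise ValidationError("matrix contains non-finite values")
        if self.scale in ("raw_count", "tpm") and (self.values < 0).any():
            raise ValidationError(f"negative values not allowed under scale {self.scale!r}")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        """Row indices of ``genes``; raises if any are absent."""
        lookup = {g: i for i, g in enumerate(self.genes)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise ValidationError(f"genes absent from matrix: {missing}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_index(genes)
        return ExpressionMatrix(
            list(genes), self.samples, self.values[idx], self.modality, self.scale
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)


@dataclass
class GeneSignature:
    """A named signature with an up-regulated and optional down-regulated arm."""

    name: str
    up: list[str]
    down: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.up = list(self.up)
        self.down = list(self.down)
        _check_unique(self.up, "up-gene")
        _check_unique(self.down, "down-gene")
        overlap = set(self.up) & set(self.down)
        if overlap:
            raise ValidationError(
                f"signature {self.name!r}: up and down lists overlap: {sorted(overlap)}"
            )
        if not self.up and not self.down:
            raise ValidationError(f"signature {self.name!r} is empty")

    @property
    def genes(self) -> list[str]:
        return self.up + self.down


@dataclass
class SurvivalTable:
    """Right-censored survival outcomes, one row per sample.

    ``time`` is a nonnegative duration in days; ``event`` is 1 for death and
    0 for censoring.
    """

    samples: list[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        _check_unique(self.samples, "sample")
        if self.time.shape != (len(self.samples),) or self.event.shape != (len(self.samples),):
            raise ValidationError("survival columns must have one entry per sample")
        if not np.isfinite(self.time).all() or (self.time < 0).any():
            raise ValidationError("survival times must be finite and >= 0")
        if not np.isin(self.event, [0, 1]).all():
            raise ValidationError("event indicator must be 0 (censored) or 1 (death)")
        self.event = self.event.astype(int)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample": self.samples, "time": self.time, "event": self.event})

    def subset(self, samples: Sequence[str]) -> "SurvivalTable":
        lookup = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in samples if s not in lookup]
        if missing:
            raise ValidationError(f"samples absent from survival table: {missing[:5]}")
        idx = np.array([lookup[s] for s in samples], dtype=int)
        return SurvivalTable(list(samples), self.time[idx], self.event[idx])


# ---------------------------------------------------------------------------
# expression matrices


def read_expression_matrix(
    path: str,
    format: str = "tsv",
    modality: str = "bulk",
    scale: str = "normalized",
    genes_path: str | None = None,
    samples_path: str | None = None,
) -> ExpressionMatrix:
    """Load an expression matrix from a dense TSV or an MTX triplet.

    For ``format="mtx_triplet"``, ``path`` names the ``.mtx`` file; the
    companion identifier lists default to ``genes.tsv`` and ``samples.tsv``
    next to it.
    """
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:  # pragma: no cover - pandas message wrapped
            raise ParseError(f"could not parse {path}: {exc}") from exc
        if df.isna().any().any():
            bad = int(np.argmax(df.isna().any(axis=1).to_numpy())) + 2
            raise ParseError(f"{path}: missing value at data line {bad}")
        return ExpressionMatrix(
            [str(g) for g in df.index],
            [str(s) for s in df.columns],
            df.to_numpy(dtype=float),
            modality,
            scale,
        )
    if format == "mtx_triplet":
        base = os.path.dirname(path)
        genes_path = genes_path or os.path.join(base, "genes.tsv")
        samples_path = samples_path or os.path.join(base, "samples.tsv")
        for p in (path, genes_path, samples_path):
            if not os.path.exists(p):
                raise ParseError(f"missing companion or matrix file: {p}")
        genes = _read_id_list(genes_path)
        samples = _read_id_list(samples_path)
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:
            raise ParseError(f"could not parse {path}: {exc}") from exc
        dense = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float
        )
        return ExpressionMatrix(genes, samples, dense, modality, scale)
    raise ValidationError(f"unknown matrix format {format!r}")


def write_expression_matrix(
    path: str,
    matrix: ExpressionMatrix,
    format: str = "tsv",
) -> None:
    """Write a matrix as dense TSV or as an MTX triplet (plus companions)."""
    if format == "tsv":
        matrix.to_frame().to_csv(path, sep="\t", float_format=FLOAT_FORMAT)
    elif format == "mtx_triplet":
        base = os.path.dirname(path)
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(matrix.values))
        _write_id_list(os.path.join(base, "genes.tsv"), matrix.genes)
        _write_id_list(os.path.join(base, "samples.tsv"), matrix.samples)
    else:
        raise ValidationError(f"unknown matrix format {format!r}")


def _read_id_list(path: str) -> list[str]:
    with open(path) as fh:
        ids = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    if not ids:
        raise ParseError(f"{path}: empty identifier list")
    return ids


def _write_id_list(path: str, ids: Sequence[str]) -> None:
    with open(path, "w") as fh:
        for x in ids:
            fh.write(f"{x}\n")


# ---------------------------------------------------------------------------
# signatures


def read_gmt(path: str, merge_up_down: bool = True) -> list[GeneSignature]:
    """Parse a GMT file into signatures.

    When ``merge_up_down`` is set, consecutive records named ``<name>_UP``
    and ``<name>_DN`` are merged into one signed signature called ``<name>``.
    """
    raw: list[tuple[str, list[str]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields")
            name, _desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            if not genes:
                raise ValidationError(f"{path}:{lineno}: signature {name!r} has no genes")
            raw.append((name, genes))

    if not merge_up_down:
        return [GeneSignature(name, genes) for name, genes in raw]

    by_stem: dict[str, dict[str, list[str]]] = {}
    order: list[str] = []
    for name, genes in raw:
        stem, arm = name, "up"
        if name.endswith("_UP"):
            stem, arm = name[:-3], "up"
        elif name.endswith("_DN"):
            stem, arm = name[:-3], "down"
        if stem not in by_stem:
            by_stem[stem] = {}
            order.append(stem)
        if arm in by_stem[stem]:
            raise ValidationError(f"{path}: duplicate record for {name!r}")
        by_stem[stem][arm] = genes

    out = []
    for stem in order:
        arms = by_stem[stem]
        out.append(GeneSignature(stem, arms.get("up", []), arms.get("down", [])))
    return out


def write_gmt(path: str, signatures: Sequence[GeneSignature]) -> None:
    """Write signatures as GMT; signed signatures become an _UP/_DN pair."""
    with open(path, "w") as fh:
        for sig in signatures:
            if sig.down:
                fh.write("\t".join([f"{sig.name}_UP", "."] + sig.up) + "\n")
                fh.write("\t".join([f"{sig.name}_DN", "."] + sig.down) + "\n")
            else:
                fh.write("\t".join([sig.name, "."] + sig.up) + "\n")


# ---------------------------------------------------------------------------
# survival and score tables


def read_survival_table(path: str) -> SurvivalTable:
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing survival columns {sorted(missing)}")
    return SurvivalTable(
        [str(s) for s in df["sample"]], df["time"].to_numpy(), df["event"].to_numpy()
    )


def write_survival_table(path: str, table: SurvivalTable) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def write_scores(path: str, table: pd.DataFrame) -> None:
    """Write any per-sample score table as TSV at 12 significant digits."""
    table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_scores(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
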