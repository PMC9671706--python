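"""Readers and writers for the tabular formats the pipeline touches.

Everything on disk is plain text: TSV for the expression matrix, sample
metadata, RNA-interaction and protein-interaction tables; GMT for pathway
gene sets; SIF plus a node-attribute TSV for the exported ceRNA network;
JSON for ground truth and run reports.  Readers validate strictly and
errors always name the offending row or column, so a malformed input fails
loudly before any statistics are computed.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ConsistencyError",
    "ExpressionMatrix",
    "InteractionEdge",
    "PPIEdge",
    "GeneSet",
    "GeneSetCollection",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_lncrna_list",
    "read_interaction_table",
    "write_interaction_table",
    "read_ppi_table",
    "write_ppi_table",
    "read_gmt",
    "write_gmt",
    "write_network",
]

LNC_MIR = "lncrna-mirna"
MIR_MRNA = "mirna-mrna"

GROUP_CASE = "schizophrenic"
GROUP_CONTROL = "control"

#: Table-1 style metadata header, in the order the paper prints it.
METADATA_COLUMNS = [
    "Sample",
    "Source name",
    "Age",
    "Gender",
    "Ph",
    "Post-mortem delay (h)",
]

#: The sole missing-value token accepted in metadata files.
NA_TOKEN = "NA"


class FormatError(ValueError):
    """A file does not conform to its documented format."""


class ConsistencyError(ValueError):
    """Two inputs that must agree (e.g. symbols across files) do not."""


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------


class ExpressionMatrix:
    """A genes x samples numeric matrix with an explicit scale flag.

    Parameters
    ----------
    data:
        DataFrame with gene symbols as the index and sample identifiers as
        columns.  Values must be finite; on the linear scale they must be
        strictly positive (otherwise log2 is undefined downstream).
    scale:
        Either ``"linear"`` or ``"log2"``.
    """

    SCALES = ("linear", "log2")

    def __init__(self, data: pd.DataFrame, scale: str):
        if scale not in self.SCALES:
            raise ValueError(f"scale must be one of {self.SCALES}, got {scale!r}")
        if data.index.has_duplicates:
            dup = data.index[data.index.duplicated()][0]
            raise FormatError(f"duplicate gene identifier {dup!r}")
        if data.columns.has_duplicates:
            dup = data.columns[data.columns.duplicated()][0]
            raise FormatError(f"duplicate sample identifier {dup!r}")
        values = data.to_numpy(dtype=float, copy=False)
        if not np.all(np.isfinite(values)):
            g, s = np.argwhere(~np.isfinite(values))[0]
            raise FormatError(
                f"non-finite value at gene {data.index[g]!r}, sample {data.columns[s]!r}"
            )
        if scale == "linear" and values.size and values.min() <= 0:
            g, s = np.argwhere(values <= 0)[0]
            raise FormatError(
                f"non-positive linear value at gene {data.index[g]!r}, "
                f"sample {data.columns[s]!r} (log2 undefined)"
            )
        self.data = data.astype(float)
        self.scale = scale

    # -- convenience accessors ------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.copy(), self.scale)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(genes)], self.scale)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        g, s = self.shape
        return f"ExpressionMatrix({g} genes x {s} samples, scale={self.scale})"


def read_expression_matrix(path: str | Path, scale: str) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column = gene symbols).

    Duplicate symbols are an error, not silently collapsed: probe-to-gene
    collapsing is a deliberate preprocessing decision and must happen before
    the matrix is written.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise FormatError(f"{path.name}: duplicate gene symbol {dup!r}")
    data = pd.DataFrame(index=raw.index.str.strip())
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            gene = raw.index[bad][0]
            raise FormatError(
                f"{path.name}: non-numeric cell at gene {gene!r}, sample {col!r}"
            )
        if converted.isna().any():
            gene = raw.index[converted.isna()][0]
            raise FormatError(f"{path.name}: empty cell at gene {gene!r}, sample {col!r}")
        data[col] = converted.to_numpy(dtype=float)
    try:
        return ExpressionMatrix(data, scale)
    except FormatError as err:
        raise FormatError(f"{path.name}: {err}") from None


def write_expression_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    m.data.to_csv(path, sep="\t", index_label="symbol", float_format="%.6f")


# ---------------------------------------------------------------------------
# Sample metadata (Table-1 shaped)
# ---------------------------------------------------------------------------


def _group_from_source(source_name: str, sample_id: str) -> str:
    low = source_name.lower()
    if GROUP_CASE in low:
        return GROUP_CASE
    if GROUP_CONTROL in low:
        return GROUP_CONTROL
    raise FormatError(
        f"sample {sample_id!r}: source name {source_name!r} matches neither "
        f"'schizophrenic' nor 'control'"
    )


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Parse a Table-1 style metadata TSV.

    The diagnosis is encoded only in the free-text source name (GEO style),
    so the group label is derived from a case-insensitive substring match.
    The literal string ``NA`` is the only missing-value token.

    Returns a DataFrame with columns ``sample_id, source_name, group, age,
    gender, ph, pmd_hours``; gender is ``male``/``female`` or ``NaN``.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    colmap: dict[str, str] = {}
    for col in raw.columns:
        low = col.strip().lower()
        if low == "sample":
            colmap[col] = "sample_id"
        elif low.startswith("source"):
            colmap[col] = "source_name"
        elif low == "age":
            colmap[col] = "age"
        elif low == "gender":
            colmap[col] = "gender"
        elif low == "ph":
            colmap[col] = "ph"
        elif low.startswith("post-mortem"):
            colmap[col] = "pmd_hours"
    missing = {"sample_id", "source_name", "age", "gender"} - set(colmap.values())
    if missing:
        raise FormatError(f"{path.name}: missing metadata column(s) {sorted(missing)}")
    df = raw.rename(columns=colmap)

    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise FormatError(f"{path.name}: duplicate sample identifier {dup!r}")

    out = pd.DataFrame()
    out["sample_id"] = df["sample_id"].str.strip()
    out["source_name"] = df["source_name"].str.strip()
    out["group"] = [
        _group_from_source(s, i) for s, i in zip(out["source_name"], out["sample_id"])
    ]

    def _numeric(col: str) -> pd.Series:
        if col not in df:
            return pd.Series([np.nan] * len(df))
        vals = df[col].str.strip().replace(NA_TOKEN, np.nan)
        try:
            return pd.to_numeric(vals)
        except ValueError as err:
            raise FormatError(f"{path.name}: column {col!r}: {err}") from None

    out["age"] = _numeric("age")
    if (out["age"] <= 0).any():
        bad = out.loc[out["age"] <= 0, "sample_id"].iloc[0]
        raise FormatError(f"{path.name}: non-positive age for sample {bad!r}")
    gender = df["gender"].str.strip().str.lower().replace(NA_TOKEN.lower(), np.nan)
    bad_gender = gender.dropna()[~gender.dropna().isin(["male", "female"])]
    if len(bad_gender):
        raise FormatError(f"{path.name}: unrecognised gender value {bad_gender.iloc[0]!r}")
    out["gender"] = gender
    out["ph"] = _numeric("ph")
    out["pmd_hours"] = _numeric("pmd_hours")
    return out


def write_sample_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    """Write metadata back out with the Table-1 column names."""
    df = pd.DataFrame(
        {
            "Sample": meta["sample_id"],
            "Source name": meta["source_name"],
            "Age": meta["age"],
            "Gender": meta["gender"].map(
                lambda g: NA_TOKEN if pd.isna(g) else str(g).capitalize()
            ),
            "Ph": meta["ph"],
            "Post-mortem delay (h)": meta["pmd_hours"],
        }
    )
    for col in ("Age", "Ph", "Post-mortem delay (h)"):
        df[col] = df[col].map(lambda v: NA_TOKEN if pd.isna(v) else f"{v:g}")
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# lncRNA symbol list
# ---------------------------------------------------------------------------


def read_lncrna_list(path: str | Path) -> set[str]:
    """Read an HGNC-style approved-symbol list into a set.

    Accepts either a TSV with a header naming a column that contains
    ``symbol`` (case-insensitive) or a plain one-symbol-per-line file.
    Whitespace is trimmed, case preserved, duplicates collapsed.
    """
    path = Path(path)
    lines = [l for l in path.read_text().splitlines() if l.strip()]
    if not lines:
        raise FormatError(f"{path.name}: empty lncRNA list")
    first = lines[0].split("\t")
    symbol_col = next(
        (i for i, name in enumerate(first) if "symbol" in name.lower()), None
    )
    if symbol_col is not None:
        body = lines[1:]
        if not body:
            raise FormatError(f"{path.name}: header but no symbols")
        symbols = {row.split("\t")[symbol_col].strip() for row in body}
    else:
        symbols = {row.split("\t")[0].strip() for row in lines}
    symbols.discard("")
    if not symbols:
        raise FormatError(f"{path.name}: no symbols found")
    return symbols


# ---------------------------------------------------------------------------
# RNA interaction tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class InteractionEdge:
    """One database interaction: lncRNA->miRNA or miRNA->mRNA.

    ``qualifier`` holds the kind-appropriate confidence label: the
    lncRNA-miRNA confidence level (``high``/``low``) or the miRNA-mRNA
    evidence class (``strong``/``weak``).
    """

    source: str
    target: str
    kind: str
    species: str
    qualifier: str

    def __post_init__(self):
        if self.kind not in (LNC_MIR, MIR_MRNA):
            raise FormatError(f"unknown interaction kind {self.kind!r}")
        if self.source == self.target:
            raise FormatError(f"self-edge {self.source!r}")
        allowed = ("high", "low") if self.kind == LNC_MIR else ("strong", "weak")
        if self.qualifier not in allowed:
            raise FormatError(
                f"edge {self.source}->{self.target}: qualifier {self.qualifier!r} "
                f"not in {allowed} for kind {self.kind}"
            )


_INTERACTION_HEADERS = {
    LNC_MIR: ["lncrna", "mirna", "species", "confidence"],
    MIR_MRNA: ["mirna", "mrna", "species", "evidence"],
}


def read_interaction_table(path: str | Path, kind: str) -> list[InteractionEdge]:
    """Read a DIANA-LncBase / miRTarBase style export."""
    if kind not in _INTERACTION_HEADERS:
        raise FormatError(f"unknown interaction kind {kind!r}")
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = [c.strip().lower() for c in df.columns]
    expected = _INTERACTION_HEADERS[kind]
    if cols[: len(expected)] != expected:
        raise FormatError(
            f"{path.name}: expected columns {expected}, found {cols[:len(expected)]}"
        )
    df.columns = cols + list(df.columns[len(cols) :])
    edges = []
    for row_idx, row in df.iterrows():
        try:
            edges.append(
                InteractionEdge(
                    source=row[expected[0]].strip(),
                    target=row[expected[1]].strip(),
                    kind=kind,
                    species=row["species"].strip(),
                    qualifier=row[expected[3]].strip().lower(),
                )
            )
        except FormatError as err:
            raise FormatError(f"{path.name}: row {row_idx + 2}: {err}") from None
    return edges


def write_interaction_table(
    edges: Iterable[InteractionEdge], kind: str, path: str | Path
) -> None:
    header = _INTERACTION_HEADERS[kind]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for e in edges:
            if e.kind != kind:
                raise ConsistencyError(f"edge {e} has kind {e.kind}, expected {kind}")
            fh.write(f"{e.source}\t{e.target}\t{e.species}\t{e.qualifier}\n")


# ---------------------------------------------------------------------------
# PPI table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PPIEdge:
    """Undirected protein-protein interaction with a combined confidence score.

    Scores live on [0, 1] in memory.  STRING exports print integers on
    0-999; pass ``string_scale=True`` to the reader to divide by 1000 —
    the unit conversion is never silent.
    """

    protein_a: str
    protein_b: str
    combined_score: float

    def __post_init__(self):
        if self.protein_a == self.protein_b:
            raise FormatError(f"PPI self-edge {self.protein_a!r}")
        if not (0.0 <= self.combined_score <= 1.0):
            raise FormatError(
                f"PPI edge {self.protein_a}-{self.protein_b}: combined score "
                f"{self.combined_score} outside [0, 1]"
            )

    @property
    def key(self) -> tuple[str, str]:
        """Order-independent identity of the undirected edge."""
        return (min(self.protein_a, self.protein_b), max(self.protein_a, self.protein_b))

    def __eq__(self, other):
        if not isinstance(other, PPIEdge):
            return NotImplemented
        return self.key == other.key and self.combined_score == other.combined_score

    def __hash__(self):
        return hash((self.key, self.combined_score))


def read_ppi_table(path: str | Path, string_scale: bool = False) -> list[PPIEdge]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = [c.strip().lower() for c in df.columns]
    expected = ["protein_a", "protein_b", "combined_score"]
    if cols[:3] != expected:
        raise FormatError(f"{path.name}: expected columns {expected}, found {cols[:3]}")
    df.columns = cols + list(df.columns[3:])
    edges = []
    for row_idx, row in df.iterrows():
        try:
            score = float(row["combined_score"])
        except ValueError:
            raise FormatError(
                f"{path.name}: row {row_idx + 2}: non-numeric combined score "
                f"{row['combined_score']!r}"
            ) from None
        if string_scale:
            score /= 1000.0
        try:
            edges.append(
                PPIEdge(row["protein_a"].strip(), row["protein_b"].strip(), score)
            )
        except FormatError as err:
            raise FormatError(f"{path.name}: row {row_idx + 2}: {err}") from None
    return edges


def write_ppi_table(edges: Iterable[PPIEdge], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_a\tprotein_b\tcombined_score\n")
        for e in edges:
            fh.write(f"{e.protein_a}\t{e.protein_b}\t{e.combined_score:.3f}\n")


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: tuple[str, ...]


@dataclass
class GeneSetCollection:
    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self):
        names = [s.name for s in self.sets]
        if len(names) != len(set(names)):
            dup = next(n for n in names if names.count(n) > 1)
            raise FormatError(f"duplicate gene-set name {dup!r}")
        for s in self.sets:
            if not s.genes:
                raise FormatError(f"gene set {s.name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a standard GMT file: name, description, then member symbols."""
    path = Path(path)
    sets = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(
                f"{path.name}: line {lineno}: GMT line needs >= 3 tab-separated "
                f"fields, found {len(fields)}"
            )
        genes = tuple(g.strip() for g in fields[2:] if g.strip())
        if not genes:
            raise FormatError(f"{path.name}: line {lineno}: gene set with no members")
        sets.append(GeneSet(fields[0].strip(), fields[1].strip(), genes))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


# ---------------------------------------------------------------------------
# Network export (SIF + node attributes)
# ---------------------------------------------------------------------------


def write_network(
    axes: Sequence,
    ppi: Sequence[PPIEdge],
    out_prefix: str | Path,
    de_table: pd.DataFrame | None = None,
) -> tuple[Path, Path]:
    """Export a ceRNA network as SIF plus a node-attribute TSV.

    SIF relations: ``sponges`` (lncRNA -> miRNA), ``targets`` (miRNA ->
    mRNA), ``ppi`` (mRNA -- mRNA).  The node table lists each node exactly
    once with its molecular type, DE direction and log2FC (miRNAs, which
    the array does not measure, get NA for both).

    ``axes`` is a sequence of objects with ``lncrna``/``mirna``/``mrna``
    and optionally ``direction`` attributes (see ``axis_builder.CeRNAAxis``).
    """
    out_prefix = Path(out_prefix)
    sif_path = out_prefix.with_suffix(".sif")
    node_path = Path(str(out_prefix) + "_nodes.tsv")

    sif_lines: list[str] = []
    seen_edges: set[tuple[str, str, str]] = set()

    def _edge(src: str, rel: str, dst: str) -> None:
        key = (src, rel, dst)
        if key not in seen_edges:
            seen_edges.add(key)
            sif_lines.append(f"{src}\t{rel}\t{dst}")

    nodes: dict[str, str] = {}  # symbol -> type, insertion ordered
    for ax in axes:
        nodes.setdefault(ax.lncrna, "lncRNA")
        nodes.setdefault(ax.mirna, "miRNA")
        nodes.setdefault(ax.mrna, "mRNA")
        _edge(ax.lncrna, "sponges", ax.mirna)
        _edge(ax.mirna, "targets", ax.mrna)
    for e in ppi:
        a, b = e.key
        nodes.setdefault(a, "mRNA")
        nodes.setdefault(b, "mRNA")
        _edge(a, "ppi", b)

    sif_path.write_text("\n".join(sif_lines) + ("\n" if sif_lines else ""))

    directions: dict[str, str] = {}
    lfcs: dict[str, float] = {}
    if de_table is not None:
        sub = de_table.loc[de_table.index.isin(nodes)]
        directions.update(sub["status"].to_dict() if "status" in sub else {})
        lfcs.update(sub["log2fc"].to_dict() if "log2fc" in sub else {})
    for ax in axes:
        direction = getattr(ax, "direction", None)
        if direction is not None:
            directions.setdefault(ax.lncrna, direction)
            directions.setdefault(ax.mrna, direction)

    with open(node_path, "w") as fh:
        fh.write("node\ttype\tdirection\tlog2fc\n")
        for sym, ntype in nodes.items():
            d = directions.get(sym, NA_TOKEN)
            lfc = lfcs.get(sym, math.nan)
            lfc_s = NA_TOKEN if (isinstance(lfc, float) and math.isnan(lfc)) else f"{lfc:.4f}"
            fh.write(f"{sym}\t{ntype}\t{d}\t{lfc_s}\n")
    return sif_path, node_path
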