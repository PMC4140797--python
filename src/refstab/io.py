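"""Domain types and file readers/writers.

Two measurement platforms feed the pipeline:

* qRT-PCR threshold-cycle (CT) tables — genes × samples, where one CT cycle
  corresponds to a two-fold difference in template abundance and *lower*
  CT means *higher* expression.  On disk these follow the common
  spreadsheet layout (samples in rows, genes in columns); in memory the
  canonical orientation is genes × samples.
* Normalized microarray expression matrices — probes × conditions, in
  arbitrary fluorescence units, with a probe→gene annotation.  Both a
  plain TSV dialect and the GEO Series Matrix dialect (table fenced by
  ``!series_matrix_table_begin`` / ``!series_matrix_table_end``) are read.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import FormatError, InputError

logger = logging.getLogger(__name__)

#: Cell tokens (case-insensitive, after stripping) treated as missing CT.
MISSING_TOKENS = frozenset({"", "na", "nan", "n/a"})

_SERIES_MATRIX_BEGIN = "!series_matrix_table_begin"
_SERIES_MATRIX_END = "!series_matrix_table_end"


def _check_unique(labels: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for lab in labels:
        if lab in seen:
            dups.append(lab)
        seen.add(lab)
    if dups:
        raise FormatError(f"duplicate {what} label(s): {sorted(set(dups))}")


# ---------------------------------------------------------------------------
# CT tables
# ---------------------------------------------------------------------------

@dataclass
class CtTable:
    """Threshold-cycle matrix (genes × samples) with optional sample metadata.

    Parameters
    ----------
    ct
        DataFrame indexed by gene id with sample ids as columns.  Missing
        CT values are stored as NaN; finite values must be positive.
    sample_meta
        Optional per-sample metadata indexed by sample id with columns
        ``time_point`` (days since injury, 0 = uninjured control),
        ``model`` (e.g. ``crush``, ``cut_repair``, ``control``) and
        ``replicate``.
    """

    ct: pd.DataFrame
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.ct = self.ct.astype(float)
        _check_unique(self.ct.index, "gene")
        _check_unique(self.ct.columns, "sample")
        finite = self.ct.to_numpy()
        bad = np.isfinite(finite) & (finite <= 0)
        if bad.any():
            g, s = np.argwhere(bad)[0]
            raise InputError(
                f"CT values must be > 0; offending cell "
                f"({self.ct.index[g]}, {self.ct.columns[s]}) = {finite[g, s]}"
            )
        if self.sample_meta is not None:
            missing = self.ct.columns.difference(self.sample_meta.index)
            if len(missing):
                raise InputError(f"sample_meta lacks samples: {list(missing)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.ct.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.ct.columns)

    @property
    def n_missing(self) -> int:
        return int(self.ct.isna().to_numpy().sum())

    def drop_incomplete(self, axis: str = "genes") -> "CtTable":
        """Return a copy without genes (or samples) that contain missing CTs."""
        if axis == "genes":
            keep = self.ct.notna().all(axis=1)
            ct = self.ct.loc[keep]
            meta = self.sample_meta
        elif axis == "samples":
            keep = self.ct.notna().all(axis=0)
            ct = self.ct.loc[:, keep]
            meta = None if self.sample_meta is None else self.sample_meta.loc[ct.columns]
        else:
            raise InputError("axis must be 'genes' or 'samples'")
        return CtTable(ct.copy(), meta)


def _parse_cell(token: str, row_label: str, col_label: str) -> float:
    tok = token.strip()
    if tok.lower() in MISSING_TOKENS:
        return float("nan")
    try:
        return float(tok)
    except ValueError:
        raise FormatError(
            f"non-numeric CT cell at (sample={row_label!r}, gene={col_label!r}): {token!r}"
        ) from None


def read_ct_table(path: str | Path, dialect: str = "wide_tsv") -> CtTable:
    """Read a CT table from a wide TSV (samples in rows, genes in columns).

    The first row holds gene names, the first column sample names; the
    table is transposed into the canonical genes × samples orientation.
    Cells equal to ``NA`` (case-insensitive) or empty are recorded as
    missing, never dropped.
    """
    if dialect != "wide_tsv":
        raise InputError(f"unknown CT dialect: {dialect!r}")
    path = Path(path)
    lines = [ln.rstrip("\n").rstrip("\r") for ln in path.read_text().splitlines()]
    lines = [ln for ln in lines if ln.strip() != ""]
    if len(lines) < 2:
        raise FormatError(f"{path}: need a header row and at least one sample row")
    header = lines[0].split("\t")
    genes = [g.strip() for g in header[1:]]
    _check_unique(genes, "gene")
    samples: list[str] = []
    rows: list[list[float]] = []
    for ln in lines[1:]:
        fields = ln.split("\t")
        sample = fields[0].strip()
        cells = fields[1:]
        if len(cells) != len(genes):
            raise FormatError(
                f"{path}: sample {sample!r} has {len(cells)} cells, expected {len(genes)}"
            )
        samples.append(sample)
        rows.append([_parse_cell(c, sample, g) for c, g in zip(cells, genes)])
    _check_unique(samples, "sample")
    wide = pd.DataFrame(rows, index=samples, columns=genes)
    return CtTable(wide.T)


def write_ct_table(table: CtTable, path: str | Path) -> None:
    """Write a CT table in the wide spreadsheet layout (samples in rows).

    Finite values round-trip bit-exactly through :func:`read_ct_table`;
    missing values are written as ``NA``.
    """
    wide = table.ct.T
    with open(path, "w") as fh:
        fh.write("sample\t" + "\t".join(map(str, wide.columns)) + "\n")
        for sample, row in wide.iterrows():
            cells = ["NA" if not np.isfinite(v) else repr(float(v)) for v in row]
            fh.write(str(sample) + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Normalized microarray fluorescence, probes × conditions.

    ``probe2gene`` maps every retained probe to exactly one gene symbol.
    ``condition_meta`` (indexed by condition id) carries ``time_point``
    (days) and ``replicate``; a condition is one time point × replicate.
    """

    fluorescence: pd.DataFrame
    probe2gene: pd.Series
    condition_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.fluorescence = self.fluorescence.astype(float)
        _check_unique(self.fluorescence.index, "probe")
        _check_unique(self.fluorescence.columns, "condition")
        if (self.fluorescence.to_numpy() < 0).any():
            raise InputError("fluorescence values must be >= 0")
        missing = self.fluorescence.index.difference(self.probe2gene.index)
        if len(missing):
            raise InputError(f"probe2gene lacks probes: {list(missing)[:5]} ...")
        self.probe2gene = self.probe2gene.loc[self.fluorescence.index]
        if self.condition_meta is not None:
            lacked = self.fluorescence.columns.difference(self.condition_meta.index)
            if len(lacked):
                raise InputError(f"condition_meta lacks conditions: {list(lacked)}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.fluorescence.index)

    @property
    def condition_ids(self) -> list[str]:
        return list(self.fluorescence.columns)

    @property
    def genes(self) -> list[str]:
        return sorted(set(self.probe2gene))


_COND_RE = re.compile(r"^(?:d|day)?(\d+)[._\-]?(?:r|rep)(\d+)$", re.IGNORECASE)


def infer_condition_meta(condition_ids: Iterable[str]) -> pd.DataFrame | None:
    """Infer time point and replicate from condition ids like ``d7_r2``.

    Returns ``None`` when any id does not match the convention.
    """
    rows = []
    for cid in condition_ids:
        m = _COND_RE.match(str(cid).strip())
        if m is None:
            return None
        rows.append((cid, int(m.group(1)), int(m.group(2))))
    return pd.DataFrame(rows, columns=["condition_id", "time_point", "replicate"]).set_index(
        "condition_id"
    )


def _read_matrix_block(path: Path, dialect: str) -> pd.DataFrame:
    text = path.read_text().splitlines()
    if dialect == "geo_series_matrix":
        try:
            begin = next(i for i, ln in enumerate(text) if ln.strip().lower().startswith(_SERIES_MATRIX_BEGIN))
            end = next(i for i, ln in enumerate(text) if ln.strip().lower().startswith(_SERIES_MATRIX_END))
        except StopIteration:
            raise FormatError(f"{path}: series matrix table fences not found") from None
        body = text[begin + 1 : end]
    elif dialect == "plain_tsv":
        body = [ln for ln in text if ln.strip() != ""]
    else:
        raise InputError(f"unknown matrix dialect: {dialect!r}")
    if len(body) < 2:
        raise FormatError(f"{path}: matrix block is empty")

    def split(ln: str) -> list[str]:
        return [c.strip().strip('"') for c in ln.rstrip("\n").split("\t")]

    header = split(body[0])
    cols = header[1:]
    probes: list[str] = []
    rows: list[list[float]] = []
    for ln in body[1:]:
        fields = split(ln)
        if not fields or fields == [""]:
            continue
        probes.append(fields[0])
        try:
            rows.append([float(v) if v != "" else float("nan") for v in fields[1:]])
        except ValueError:
            raise FormatError(f"{path}: unreadable matrix row for probe {fields[0]!r}") from None
        if len(rows[-1]) != len(cols):
            raise FormatError(f"{path}: ragged row for probe {fields[0]!r}")
    return pd.DataFrame(rows, index=probes, columns=cols)


def read_probe_annotation(path: str | Path) -> pd.Series:
    """Read a probe→gene TSV with columns ``probe_id`` and ``gene_symbol``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"probe_id", "gene_symbol"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: annotation needs columns {sorted(required)}")
    _check_unique(df["probe_id"], "probe")
    return df.set_index("probe_id")["gene_symbol"]


def read_expression_matrix(
    path: str | Path,
    annotation_path: str | Path,
    dialect: str = "plain_tsv",
    condition_meta: pd.DataFrame | str | Path | None = None,
) -> ExpressionMatrix:
    """Read a probes × conditions matrix plus its probe→gene annotation.

    Probes without a gene mapping are dropped (the count is logged).
    When ``condition_meta`` is omitted, time point and replicate are
    inferred from condition ids of the form ``d<days>_r<rep>`` if possible.
    """
    path = Path(path)
    values = _read_matrix_block(path, dialect)
    mapping = read_probe_annotation(annotation_path)
    keep = values.index.intersection(mapping.index)
    if len(keep) == 0:
        raise InputError(f"{path}: no probe in the matrix is covered by the annotation")
    n_dropped = len(values.index) - len(keep)
    if n_dropped:
        logger.warning("%s: dropped %d probe(s) without a gene mapping", path, n_dropped)
    values = values.loc[keep]
    if condition_meta is None:
        meta = infer_condition_meta(values.columns)
    elif isinstance(condition_meta, (str, Path)):
        meta = pd.read_csv(condition_meta, sep="\t").set_index("condition_id")
    else:
        meta = condition_meta
    return ExpressionMatrix(values, mapping.loc[keep], meta)


# ---------------------------------------------------------------------------
# Gene annotation (pseudogene / intron flags)
# ---------------------------------------------------------------------------

@dataclass
class GeneAnnotation:
    """Per-gene flags: accession, pseudogene presence, intron-spanning design.

    A pseudogene is a processed copy of the gene elsewhere in the genome;
    primers landing on it would amplify genomic DNA, so candidates with
    pseudogenes are excluded from the final reference-gene list.
    """

    table: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["accession", "has_pseudogene", "intron_spanning"]))

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "gene symbol")

    def has_pseudogene(self, gene: str) -> bool | None:
        """True/False flag, or ``None`` when the gene is not annotated."""
        if gene not in self.table.index:
            return None
        return bool(self.table.loc[gene, "has_pseudogene"])

    def __contains__(self, gene: str) -> bool:
        return gene in self.table.index


_BOOL_TOKENS = {"true": True, "1": True, "yes": True, "y": True,
                "false": False, "0": False, "no": False, "n": False}


def read_gene_annotation(path: str | Path) -> GeneAnnotation:
    """Read a gene annotation TSV: symbol, accession, has_pseudogene, intron_spanning."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"symbol", "accession", "has_pseudogene", "intron_spanning"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: gene annotation needs columns {sorted(required)}")

    def to_bool(tok: str, col: str) -> bool:
        try:
            return _BOOL_TOKENS[str(tok).strip().lower()]
        except KeyError:
            raise FormatError(f"{path}: unparseable boolean {tok!r} in column {col}") from None

    out = df.set_index("symbol")[["accession"]].copy()
    out["has_pseudogene"] = [to_bool(v, "has_pseudogene") for v in df["has_pseudogene"]]
    out["intron_spanning"] = [to_bool(v, "intron_spanning") for v in df["intron_spanning"]]
    return GeneAnnotation(out)


# ---------------------------------------------------------------------------
# CT summaries (box-plot five-number summaries)
# ---------------------------------------------------------------------------

def ct_summary(table: CtTable) -> pd.DataFrame:
    """Per-gene five-number summary of CT values (box-plot statistics).

    Quartiles use linear interpolation between order statistics (the
    ubiquitous "type 7" definition shared by numpy and most plotting
    libraries).  Missing CTs are ignored per gene; a gene with no
    observed CT at all is an error.
    """
    rows = {}
    for gene, row in table.ct.iterrows():
        vals = row.to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise InputError(f"gene {gene!r} has no non-missing CT value")
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows[gene] = {"min": vals.min(), "q1": q1, "median": med,
                      "q3": q3, "max": vals.max()}
    return pd.DataFrame.from_dict(rows, orient="index").loc[table.gene_ids]
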