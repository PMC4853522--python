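"""Tabular I/O and locus-identifier parsing for the trait-SAM pipeline.

Everything the pipeline reads or writes is tab-separated UTF-8 text with a
"." decimal point: the probe x sample expression matrix, the sample sheet
(sample_id / genotype / condition / replicate), the genotype x trait table,
GO annotations (2-4 column TSV or GAF 2.x), a RAP->MSU identifier mapping
and a protein-interaction edge list.  All readers validate strictly and
never return partially-parsed objects.

RAP-DB locus identifiers (``Os06g0699400``) encode the chromosome in their
first two digits; :func:`parse_rap_locus` extracts it.  MSU (TIGR)
identifiers look like ``LOC_Os06g48590``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import GoAnnotation

logger = logging.getLogger("traitsam")

CONDITIONS = ("control", "stressed")
SCALES = ("linear", "log2")

_RAP_RE = re.compile(r"^Os(\d{2})g(\d{7})$")
_MSU_RE = re.compile(r"^LOC_Os(\d{2})g(\d{5})(\.\d+)?$")


class FormatError(ValueError):
    """Raised when an input file violates its documented format."""


class LocusParseError(FormatError):
    """Raised for identifiers that are not canonical RAP locus ids."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Probe x sample intensity matrix plus per-sample metadata.

    ``values`` holds intensities on either the linear or the log2 scale, as
    recorded by ``scale``; ``samples`` is indexed by sample id with columns
    ``genotype``, ``condition`` and ``replicate``.
    """

    values: np.ndarray
    probe_ids: list[str]
    samples: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.probe_ids = list(self.probe_ids)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        if self.values.ndim != 2:
            raise FormatError("expression values must be a 2-D matrix")
        n_probes, n_samples = self.values.shape
        if n_probes != len(self.probe_ids):
            raise FormatError("row count does not match number of probe ids")
        if n_samples != len(self.samples):
            raise FormatError("column count does not match sample sheet")
        seen: set[str] = set()
        for p in self.probe_ids:
            if p in seen:
                raise FormatError(f"duplicate probe id {p!r}")
            seen.add(p)
        if self.samples.index.has_duplicates:
            dup = self.samples.index[self.samples.index.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        for col in ("genotype", "condition", "replicate"):
            if col not in self.samples.columns:
                raise FormatError(f"sample sheet lacks required column {col!r}")
        bad = set(self.samples["condition"]) - set(CONDITIONS)
        if bad:
            raise FormatError(f"unknown condition label(s): {sorted(bad)}")
        reps = self.samples["replicate"]
        if (reps.astype(int) != reps).any() or (reps.astype(int) < 1).any():
            raise FormatError("replicate indices must be integers >= 1")
        if not np.isfinite(self.values).all():
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise FormatError(
                f"non-finite value at probe {self.probe_ids[i]!r}, "
                f"sample {self.samples.index[j]!r}"
            )
        if self.scale not in SCALES:
            raise FormatError(f"unknown scale flag {self.scale!r}")

    # -- conveniences -------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples.index)

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.probe_ids, name="probe_id"),
                            columns=self.samples.index)

    def select_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        """Column subset (and/or reorder) by sample id."""
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(
            self.values[:, idx], list(self.probe_ids),
            self.samples.loc[sample_ids].copy(), self.scale,
        )

    def with_values(self, values: np.ndarray, scale: str | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(values, list(self.probe_ids), self.samples.copy(),
                                self.scale if scale is None else scale)


@dataclass
class TraitTable:
    """Genotype x trait table of raw morpho-physiological measurements.

    ``data`` is indexed by genotype with one column per trait; missing
    measurements are NaN and are never imputed.  ``condition`` records which
    growth condition the measurements pair with.
    """

    data: pd.DataFrame
    condition: str | None = None

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise FormatError(f"duplicate genotype row {dup!r}")
        for trait in self.data.columns:
            if self.data[trait].notna().sum() == 0:
                raise FormatError(f"trait {trait!r} has no non-missing values")

    @property
    def genotypes(self) -> list[str]:
        return list(self.data.index)

    @property
    def traits(self) -> list[str]:
        return list(self.data.columns)


@dataclass(frozen=True)
class LocusInfo:
    """Parsed RAP locus id: chromosome (1-12) and the 7-digit locus number."""

    locus_id: str
    chromosome: int
    locus_number: int

    def canonical(self) -> str:
        return f"Os{self.chromosome:02d}g{self.locus_number:07d}"


@dataclass
class IdMapping:
    """RAP-DB -> MSU (TIGR) identifier mapping."""

    rap_to_msu: dict[str, str]

    def __post_init__(self) -> None:
        for rap, msu in self.rap_to_msu.items():
            if not _MSU_RE.match(msu):
                raise FormatError(f"mapping value {msu!r} (for {rap!r}) is not an MSU id")

    def reverse(self) -> dict[str, list[str]]:
        rev: dict[str, list[str]] = {}
        for rap, msu in self.rap_to_msu.items():
            rev.setdefault(msu, []).append(rap)
        return rev


@dataclass
class InteractionEdges:
    """Undirected protein-interaction edge list.

    Edges are stored as lexicographically ordered pairs, deduplicated and
    free of self-loops; ``confidence`` is carried but never thresholded here.
    ``namespace`` tags the identifier system of the nodes (``RAP``/``MSU``).
    """

    edges: list[tuple[str, str]]
    confidence: dict[tuple[str, str], float] = field(default_factory=dict)
    namespace: str | None = None

    def __post_init__(self) -> None:
        canon: list[tuple[str, str]] = []
        seen: set[tuple[str, str]] = set()
        for a, b in self.edges:
            if a == b:
                raise FormatError(f"self-edge ({a!r}, {b!r}) in InteractionEdges")
            e = (a, b) if a <= b else (b, a)
            if e in seen:
                raise FormatError(f"duplicate edge {e!r} in InteractionEdges")
            seen.add(e)
            canon.append(e)
        self.edges = canon

    @property
    def nodes(self) -> set[str]:
        return {n for e in self.edges for n in e}

    def __len__(self) -> int:
        return len(self.edges)


# ---------------------------------------------------------------------------
# locus-id parsing
# ---------------------------------------------------------------------------

def parse_rap_locus(locus_id: str) -> LocusInfo:
    """Parse a RAP locus id (``Os09g0286400``) into chromosome and number.

    The two digits after ``Os`` are the chromosome (01-12); parsing is
    case-sensitive and malformed ids raise :class:`LocusParseError` rather
    than being skipped.
    """
    m = _RAP_RE.match(locus_id)
    if not m:
        raise LocusParseError(f"not a RAP locus id: {locus_id!r}")
    chrom = int(m.group(1))
    if not 1 <= chrom <= 12:
        raise LocusParseError(f"chromosome {chrom:02d} out of range 1-12 in {locus_id!r}")
    return LocusInfo(locus_id, chrom, int(m.group(2)))


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def read_sample_sheet(path) -> tuple[pd.DataFrame, str]:
    """Read a sample sheet; returns (metadata indexed by sample id, scale flag).

    Required columns: ``sample_id``, ``genotype``, ``condition``,
    ``replicate``.  An optional ``scale`` column (uniform value ``linear`` or
    ``log2``) records the scale of the paired expression matrix; the default
    is linear intensities.
    """
    sheet = _read_tsv(path)
    for col in ("sample_id", "genotype", "condition", "replicate"):
        if col not in sheet.columns:
            raise FormatError(f"sample sheet {path}: missing column {col!r}")
    if sheet["sample_id"].duplicated().any():
        dup = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"sample sheet {path}: duplicate sample id {dup!r}")
    try:
        sheet["replicate"] = sheet["replicate"].astype(int)
    except ValueError as exc:
        raise FormatError(f"sample sheet {path}: non-integer replicate") from exc
    scale = "linear"
    if "scale" in sheet.columns:
        uniq = set(sheet["scale"])
        if len(uniq) != 1:
            raise FormatError(f"sample sheet {path}: non-uniform scale column")
        scale = uniq.pop()
        if scale not in SCALES:
            raise FormatError(f"sample sheet {path}: unknown scale {scale!r}")
    meta = sheet.set_index("sample_id")[["genotype", "condition", "replicate"]]
    return meta, scale


def read_expression_matrix(path, sample_sheet) -> ExpressionMatrix:
    """Read an expression TSV (first column probe ids, header sample ids).

    Every matrix column must be registered in the sample sheet; genotype and
    condition are never inferred from column names.  Non-numeric cells are
    reported with their probe and sample.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate probe id {dup!r}")
    meta, scale = read_sample_sheet(sample_sheet)
    for sid in raw.columns:
        if sid not in meta.index:
            raise FormatError(f"{path}: unregistered sample {sid}")
    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        cells = raw[col].str.strip()
        try:
            # numpy's parser round-trips repr-precision decimals exactly
            values[:, j] = cells.to_numpy(dtype=str).astype(np.float64)
        except ValueError:
            for probe, cell in zip(raw.index, cells):
                try:
                    float(cell)
                except ValueError:
                    raise FormatError(
                        f"{path}: non-numeric cell at probe {probe!r}, "
                        f"sample {col!r}"
                    ) from None
    return ExpressionMatrix(values, list(raw.index), meta.loc[list(raw.columns)].copy(),
                            scale)


def read_trait_table(path, condition: str | None = None) -> TraitTable:
    """Read a genotype x trait TSV; empty cells mark missing measurements."""
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate genotype row {dup!r}")
    data = pd.DataFrame(index=raw.index.copy())
    for trait in raw.columns:
        col = raw[trait].str.strip().replace({"": None, "NA": None})
        numeric = pd.to_numeric(col, errors="coerce")
        garbled = numeric.isna() & col.notna()
        if garbled.any():
            g = raw.index[garbled.to_numpy().nonzero()[0][0]]
            raise FormatError(f"{path}: non-numeric trait value at ({g!r}, {trait!r})")
        data[trait] = numeric
    return TraitTable(data, condition=condition)


def _read_go_tsv(path) -> GoAnnotation:
    gene_to_terms: dict[str, set[str]] = {}
    namespaces: dict[str, str] = {}
    labels: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("!") or line.startswith("#"):
                continue
            parts = line.split("\t")
            if not 2 <= len(parts) <= 4:
                raise FormatError(
                    f"{path}:{lineno}: GO table rows need 2-4 columns, got {len(parts)}"
                )
            gene, term = parts[0], parts[1]
            gene_to_terms.setdefault(gene, set()).add(term)
            if len(parts) >= 3 and parts[2]:
                namespaces[term] = parts[2]
            if len(parts) == 4 and parts[3]:
                labels[term] = parts[3]
    return GoAnnotation({g: frozenset(t) for g, t in gene_to_terms.items()},
                        namespaces, labels)


_GAF_ASPECT = {"P": "biological_process", "F": "molecular_function",
               "C": "cellular_component"}


def _read_gaf(path) -> GoAnnotation:
    gene_to_terms: dict[str, set[str]] = {}
    namespaces: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            parts = line.split("\t")
            if len(parts) not in (15, 16, 17):
                raise FormatError(
                    f"{path}:{lineno}: GAF rows need 15-17 columns, got {len(parts)}"
                )
            gene, term, aspect = parts[1], parts[4], parts[8]
            gene_to_terms.setdefault(gene, set()).add(term)
            if aspect in _GAF_ASPECT:
                namespaces[term] = _GAF_ASPECT[aspect]
    return GoAnnotation({g: frozenset(t) for g, t in gene_to_terms.items()}, namespaces)


def read_go_annotation(path) -> GoAnnotation:
    """Read GO annotation from a 2-4 column TSV or a GAF 2.x file."""
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    if first.startswith("!gaf-version"):
        return _read_gaf(path)
    # sniff: GAF data rows have >= 15 columns
    for line in open(path, encoding="utf-8"):
        if line.strip() and not line.startswith(("!", "#")):
            if len(line.rstrip("\n").split("\t")) >= 15:
                return _read_gaf(path)
            break
    return _read_go_tsv(path)


def read_id_mapping(path) -> IdMapping:
    """Read a two-column RAP -> MSU mapping TSV (no header)."""
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: mapping rows need 2 columns")
            rap, msu = parts[0].strip(), parts[1].strip()
            if rap in mapping and mapping[rap] != msu:
                raise FormatError(
                    f"{path}:{lineno}: conflicting mapping for {rap!r}: "
                    f"{mapping[rap]!r} vs {msu!r}"
                )
            mapping[rap] = msu
    return IdMapping(mapping)


def read_edge_list(path, namespace: str | None = None) -> InteractionEdges:
    """Read a 2-3 column edge TSV; self-edges dropped (logged), duplicates collapsed.

    For duplicate unordered pairs the maximum confidence is retained.
    """
    pairs: dict[tuple[str, str], float] = {}
    n_self = 0
    n_dup = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (2, 3):
                raise FormatError(f"{path}:{lineno}: edge rows need 2-3 columns")
            a, b = parts[0].strip(), parts[1].strip()
            if a == b:
                n_self += 1
                continue
            try:
                conf = float(parts[2]) if len(parts) == 3 and parts[2].strip() else np.nan
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric confidence") from exc
            e = (a, b) if a <= b else (b, a)
            if e in pairs:
                n_dup += 1
                if not np.isnan(conf):
                    pairs[e] = conf if np.isnan(pairs[e]) else max(pairs[e], conf)
            else:
                pairs[e] = conf
    if n_self:
        logger.info("read_edge_list: dropped %d self-edge(s) from %s", n_self, path)
    if n_dup:
        logger.info("read_edge_list: collapsed %d duplicate edge(s) from %s", n_dup, path)
    edges = sorted(pairs)
    conf = {e: c for e, c in pairs.items() if not np.isnan(c)}
    return InteractionEdges(edges, conf, namespace)


def read_annotation_tables(
    go_path=None, mapping_path=None, edges_path=None
) -> tuple[GoAnnotation | None, IdMapping | None, InteractionEdges | None]:
    """Read the optional GO / id-mapping / interaction tables in one call."""
    go = read_go_annotation(go_path) if go_path is not None else None
    mapping = read_id_mapping(mapping_path) if mapping_path is not None else None
    edges = read_edge_list(edges_path) if edges_path is not None else None
    return go, mapping, edges


_HEADER_TOKENS = {"probe_name", "probe_id", "gene", "gene_id", "locus_id"}


def read_gene_list(path) -> list[str]:
    """Read one gene id per line (or the first TSV column), order-preserving.

    A leading header row whose first field is a common column name
    (``probe_name``, ``gene_id``, ...) is skipped.
    """
    genes: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            token = line.split("\t")[0]
            if lineno == 0 and token in _HEADER_TOKENS:
                continue
            genes.append(token)
    return genes


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_expression_matrix(matrix: ExpressionMatrix, path, sheet_path=None) -> None:
    """Write a matrix (and optionally its sample sheet) back to TSV.

    Floats are written with full ``repr`` precision so a read -> write ->
    read round trip is value-identical.
    """
    matrix.to_frame().to_csv(path, sep="\t", float_format="%.17g")
    if sheet_path is not None:
        sheet = matrix.samples.reset_index()
        sheet.columns = ["sample_id", "genotype", "condition", "replicate"]
        sheet["scale"] = matrix.scale
        sheet.to_csv(sheet_path, sep="\t", index=False)


def write_trait_table(traits: TraitTable, path) -> None:
    traits.data.to_csv(path, sep="\t", index_label="genotype")


SIGNIFICANT_COLUMNS = ["probe_name", "annotation", "fold_score_d",
                       "q_value_percent", "direction", "trait", "condition"]


def write_significant_table(result, path, annotations: dict[str, str] | None = None) -> None:
    """Write a significant-gene set as a TSV in the selection-table layout.

    Columns: probe_name, annotation, fold_score_d (2 dp), q_value_percent
    (2 dp), direction, trait, condition; rows ordered by \\|d\\| descending
    with lexicographic probe-id tie-break.
    """
    annotations = annotations or {}
    table = result.table.copy()
    table["_abs_d"] = table["d"].abs()
    table = table.sort_values(["_abs_d", "probe_id"], ascending=[False, True],
                              kind="stable")
    out = pd.DataFrame({
        "probe_name": table["probe_id"].to_numpy(),
        "annotation": [annotations.get(p, "") for p in table["probe_id"]],
        "fold_score_d": [f"{v:.2f}" for v in table["d"]],
        "q_value_percent": [f"{v:.2f}" for v in table["q_percent"]],
        "direction": table["direction"].to_numpy(),
        "trait": result.trait or "",
        "condition": result.condition or "",
    }, columns=SIGNIFICANT_COLUMNS)
    out.to_csv(path, sep="\t", index=False)
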