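"""User gene lists: reading, cutoffs, grouping, ordering and the input dump.

A *dataset* is a named list of gene records (symbol plus optional
significance value, timepoint and direction of change) together with
presentation metadata (integration group, color, order) and an optional
experimental background universe.  Background universes arrive in
companion ``*_bgGenes`` files: a single headerless column of symbols,
matched to data files by name.

The *input dump* mirrors the import dialect so a finished session
(datasets, backgrounds, parameter settings) can be re-imported losslessly
and reproduce identical enrichment results.
"""

from __future__ import annotations

import json
import logging

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import pandas as pd

from pathnet.errors import ColumnNotFoundError, ParameterError, ParseError
from pathnet.ontology import normalize_symbol

logger = logging.getLogger(__name__)

DIRECTIONS = ("up", "down", "unspecified")

#: fields of the import column map
DATASET_FIELDS = (
    "symbol",
    "dataset_name",
    "integration_group",
    "color",
    "value",
    "timepoint",
    "direction",
    "order_index",
)

#: 20-color palette cycled over integration-group keys in lexicographic order
PALETTE = (
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
    "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf",
    "#aec7e8", "#ffbb78", "#98df8a", "#ff9896", "#c5b0d5",
    "#c49c94", "#f7b6d2", "#c7c7c7", "#dbdb8d", "#9edae5",
)

BG_SUFFIX = "_bgGenes"


@dataclass
class GeneRecord:
    """One gene entry of a dataset."""

    symbol: str
    value: Optional[float] = None
    timepoint: Optional[str] = None
    direction: str = "unspecified"

    def __post_init__(self):
        if not self.symbol:
            raise ParameterError("gene symbol must be non-empty")
        if self.direction not in DIRECTIONS:
            raise ParameterError(
                f"direction must be one of {DIRECTIONS}, got {self.direction!r}"
            )


@dataclass
class Dataset:
    """A named gene list with presentation metadata and optional background."""

    name: str
    integration_group: str = ""
    color: str = ""
    order_index: int = 0
    records: list[GeneRecord] = field(default_factory=list)
    background: Optional[set[str]] = None
    source_file: Optional[str] = None  # file stem the dataset was read from

    @property
    def genes(self) -> set[str]:
        return {r.symbol for r in self.records}

    @property
    def timepoint(self) -> Optional[str]:
        """The single timepoint shared by all records, if any."""
        tps = {r.timepoint for r in self.records}
        if len(tps) == 1:
            return next(iter(tps))
        return None

    @property
    def direction(self) -> Optional[str]:
        dirs = {r.direction for r in self.records}
        if len(dirs) == 1:
            return next(iter(dirs))
        return None

    def copy(self) -> "Dataset":
        return replace(
            self,
            records=[replace(r) for r in self.records],
            background=set(self.background) if self.background is not None else None,
        )


@dataclass
class CutoffSpec:
    """Significance cutoffs selecting which genes enter enrichment analysis.

    ``keep_top_n`` keeps the n records with the smallest value (significance
    semantics; boundary ties included); set ``top_largest`` to rank by
    largest value instead.
    """

    max_value: Optional[float] = None
    min_value: Optional[float] = None
    keep_top_n: Optional[int] = None
    top_largest: bool = False

    def __post_init__(self):
        if self.keep_top_n is not None and self.keep_top_n < 1:
            raise ParameterError(
                f"keep_top_n must be a positive integer, got {self.keep_top_n}"
            )

    @property
    def is_empty(self) -> bool:
        return (
            self.max_value is None
            and self.min_value is None
            and self.keep_top_n is None
        )


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _normalize_direction(raw: str) -> str:
    s = str(raw).strip().lower()
    if s in ("up", "+", "increased"):
        return "up"
    if s in ("down", "-", "decreased"):
        return "down"
    return "unspecified"


def _is_background_file(path: Path) -> bool:
    return path.stem.endswith(BG_SUFFIX)


def _read_one_file(
    path: Path, column_map: dict[str, str], delimiter: str
) -> list[Dataset]:
    try:
        df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        logger.warning("skipping empty file %s", path)
        return []
    if df.empty:
        logger.warning("skipping file with no data rows: %s", path)
        return []
    for fld, col in column_map.items():
        if col not in df.columns:
            raise ColumnNotFoundError(f"{col} not found in {path}")

    def cell(row, fld):
        col = column_map.get(fld)
        return row[col] if col is not None else None

    groups: dict[str, Dataset] = {}
    for _, row in df.iterrows():
        name = cell(row, "dataset_name") or path.stem
        if name not in groups:
            order_raw = cell(row, "order_index")
            groups[name] = Dataset(
                name=name,
                integration_group=cell(row, "integration_group") or "",
                color=cell(row, "color") or "",
                order_index=int(order_raw) if order_raw else 0,
                source_file=path.stem,
            )
        value_raw = cell(row, "value")
        value = None
        if value_raw not in (None, ""):
            try:
                value = float(value_raw)
            except ValueError:
                raise ParseError(
                    f"{path}: value {value_raw!r} for gene "
                    f"{cell(row, 'symbol')!r} is not a number"
                )
        tp = cell(row, "timepoint")
        groups[name].records.append(
            GeneRecord(
                symbol=normalize_symbol(cell(row, "symbol")),
                value=value,
                timepoint=tp if tp else None,
                direction=_normalize_direction(cell(row, "direction") or ""),
            )
        )
    return list(groups.values())


def read_datasets(
    path: str | Path,
    column_map: dict[str, str],
    delimiter: str = "\t",
) -> list[Dataset]:
    """Read gene-list datasets from one delimited file or a directory of them.

    ``column_map`` maps a subset of the fields ``symbol``, ``dataset_name``,
    ``integration_group``, ``color``, ``value``, ``timepoint``, ``direction``
    and ``order_index`` to column names in the files; unmapped fields are
    ignored.  A mapped column absent from a file raises an error naming the
    file and column.  When no ``dataset_name`` column is mapped each file
    yields one dataset named after the file.  ``*_bgGenes`` companions and
    ``parameters.txt`` are skipped here (see :func:`attach_backgrounds`).
    """
    if "symbol" not in column_map:
        raise ParameterError("column_map must map the 'symbol' field")
    unknown = set(column_map) - set(DATASET_FIELDS)
    if unknown:
        raise ParameterError(f"unknown fields in column_map: {sorted(unknown)}")

    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir()
            if p.is_file()
            and not _is_background_file(p)
            and p.name != "parameters.txt"
        )
    else:
        if not path.exists():
            raise OSError(f"cannot read dataset file: {path}")
        files = [path]

    datasets: list[Dataset] = []
    seen: set[str] = set()
    for f in files:
        for ds in _read_one_file(f, column_map, delimiter):
            if ds.name in seen:
                raise ParameterError(
                    f"dataset name {ds.name!r} defined by more than one file"
                )
            seen.add(ds.name)
            if "order_index" not in column_map:
                ds.order_index = len(datasets)
            datasets.append(ds)
    return datasets


def read_background_file(path: str | Path) -> set[str]:
    """Read a headerless single-column gene list."""
    genes: set[str] = set()
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if s:
                genes.add(normalize_symbol(s))
    return genes


def attach_backgrounds(datasets: list[Dataset], path: str | Path) -> list[Dataset]:
    """Attach ``<stem>_bgGenes`` background universes to matching datasets.

    Every dataset read from ``X.txt`` receives the gene set from
    ``X_bgGenes.txt`` when that file exists in ``path``; others keep their
    background absent.  Empty background files are warned about and treated
    as absent.  Returns copies; inputs are unmodified.
    """
    path = Path(path)
    bg_by_stem: dict[str, set[str]] = {}
    for f in sorted(path.iterdir()) if path.is_dir() else []:
        if f.is_file() and _is_background_file(f):
            stem = f.stem[: -len(BG_SUFFIX)]
            genes = read_background_file(f)
            if not genes:
                logger.warning("background file %s is empty; ignored", f)
                continue
            bg_by_stem[stem] = genes
    out = []
    for ds in datasets:
        ds = ds.copy()
        if ds.source_file in bg_by_stem:
            ds.background = set(bg_by_stem[ds.source_file])
        out.append(ds)
    return out


# ---------------------------------------------------------------------------
# cutoffs
# ---------------------------------------------------------------------------

def apply_cutoffs(dataset: Dataset, spec: CutoffSpec) -> Dataset:
    """Filter a dataset's records by significance-value criteria.

    min/max bounds are inclusive; ``keep_top_n`` retains the n records with
    the smallest (or largest, per ``spec.top_largest``) value, boundary ties
    included.  Returns a new dataset; the input is unmodified.
    """
    if spec.is_empty:
        raise ParameterError("cutoff spec sets no criterion")
    out = dataset.copy()
    records = out.records
    if any(r.value is None for r in records):
        raise ParameterError(
            f"dataset {dataset.name!r} has records without values; "
            "value-based cutoffs cannot be applied"
        )
    if spec.min_value is not None:
        records = [r for r in records if r.value >= spec.min_value]
    if spec.max_value is not None:
        records = [r for r in records if r.value <= spec.max_value]
    if spec.keep_top_n is not None and records:
        ranked = sorted((r.value for r in records), reverse=spec.top_largest)
        if spec.keep_top_n < len(ranked):
            threshold = ranked[spec.keep_top_n - 1]
            if spec.top_largest:
                records = [r for r in records if r.value >= threshold]
            else:
                records = [r for r in records if r.value <= threshold]
    out.records = records
    return out


# ---------------------------------------------------------------------------
# grouping and ordering
# ---------------------------------------------------------------------------

@dataclass
class GroupingRule:
    """How to derive integration-group keys from dataset metadata.

    ``kind`` is one of ``by_timepoint``, ``by_direction`` or
    ``by_name_substring``.  For substring grouping the dataset name is split
    on ``delimiter`` and the parts selected by ``index_spec`` — a
    comma-separated list of 1-based indices counted from the left (positive)
    or from the right (negative) — are joined with '|' to form the key.
    """

    kind: str
    delimiter: Optional[str] = None
    index_spec: Optional[str] = None

    def __post_init__(self):
        if self.kind not in ("by_timepoint", "by_direction", "by_name_substring"):
            raise ParameterError(f"unknown grouping rule kind {self.kind!r}")
        if self.kind == "by_name_substring":
            if not self.delimiter or not self.index_spec:
                raise ParameterError(
                    "by_name_substring requires delimiter and index_spec"
                )

    def key_for(self, dataset: Dataset) -> str:
        if self.kind == "by_timepoint":
            tp = dataset.timepoint
            if tp is None:
                raise ParameterError(
                    f"dataset {dataset.name!r} has no single shared timepoint"
                )
            return tp
        if self.kind == "by_direction":
            d = dataset.direction
            if d is None:
                raise ParameterError(
                    f"dataset {dataset.name!r} has no single shared direction"
                )
            return d
        parts = dataset.name.split(self.delimiter)
        selected = []
        for raw in self.index_spec.split(","):
            idx = int(raw.strip())
            if idx == 0:
                raise ParameterError("substring indices are 1-based; 0 is invalid")
            pos = idx - 1 if idx > 0 else len(parts) + idx
            if not (0 <= pos < len(parts)):
                raise ParameterError(
                    f"substring index {idx} out of range for dataset "
                    f"{dataset.name!r} ({len(parts)} parts)"
                )
            selected.append(parts[pos])
        return "|".join(selected)


def assign_groups(
    datasets: list[Dataset],
    rule: GroupingRule,
    assign_colors: bool = False,
) -> list[Dataset]:
    """Assign integration groups (and optionally colors) by a shared key.

    Datasets sharing the rule's key receive the same integration group.
    Colors, when requested, come from a fixed 20-color palette cycled over
    the distinct keys in lexicographic order, so the assignment depends only
    on the keys, never on input order.  Returns copies.
    """
    keyed = [(rule.key_for(ds), ds.copy()) for ds in datasets]
    palette_of = {}
    if assign_colors:
        for i, key in enumerate(sorted({k for k, _ in keyed})):
            palette_of[key] = PALETTE[i % len(PALETTE)]
    out = []
    for key, ds in keyed:
        ds.integration_group = key
        if assign_colors:
            ds.color = palette_of[key]
        out.append(ds)
    return out


def set_order(datasets: list[Dataset], ordering: list[str]) -> list[Dataset]:
    """Set display order within an integration group.

    Datasets named in ``ordering`` get order_index 0, 1, ...; unlisted
    datasets follow, keeping their prior relative order.  Returns copies.
    """
    by_name = {ds.name: ds for ds in datasets}
    for name in ordering:
        if name not in by_name:
            raise ParameterError(f"unknown dataset name in ordering: {name!r}")
    out = [ds.copy() for ds in datasets]
    if not ordering:
        return out
    listed = set(ordering)
    rank = {name: i for i, name in enumerate(ordering)}
    unlisted = sorted(
        (ds for ds in out if ds.name not in listed),
        key=lambda d: d.order_index,
    )
    for i, ds in enumerate(unlisted):
        rank[ds.name] = len(ordering) + i
    for ds in out:
        ds.order_index = rank[ds.name]
    return out


# ---------------------------------------------------------------------------
# input dump (reproducibility)
# ---------------------------------------------------------------------------

DUMP_COLUMN_MAP = {
    "symbol": "gene_symbol",
    "dataset_name": "dataset",
    "integration_group": "integration_group",
    "color": "color",
    "value": "value",
    "timepoint": "timepoint",
    "direction": "direction",
    "order_index": "order_index",
}
PARAMETERS_FILE = "parameters.txt"
_RESERVED_PREFIX = "__"


def _dump_stem(index: int) -> str:
    return f"dataset_{index:03d}"


def write_input_dump(
    datasets: list[Dataset], parameters: dict, out_dir: str | Path
) -> list[Path]:
    """Write datasets, backgrounds and parameters for lossless re-import.

    Emits one TSV per dataset (the import dialect with the default column
    names), a ``*_bgGenes`` file per present background, and a
    ``parameters.txt`` with JSON-encoded values.  Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    bg_files: list[str] = []
    for i, ds in enumerate(datasets):
        stem = _dump_stem(i)
        rows = []
        for r in ds.records:
            rows.append({
                "gene_symbol": r.symbol,
                "dataset": ds.name,
                "integration_group": ds.integration_group,
                "color": ds.color,
                "order_index": ds.order_index,
                "value": "" if r.value is None else repr(r.value),
                "timepoint": r.timepoint or "",
                "direction": r.direction,
            })
        df = pd.DataFrame(rows, columns=list(DUMP_COLUMN_MAP.values()))
        fpath = out_dir / f"{stem}.txt"
        df.to_csv(fpath, sep="\t", index=False)
        written.append(fpath)
        if ds.background is not None:
            bpath = out_dir / f"{stem}{BG_SUFFIX}.txt"
            bpath.write_text("\n".join(sorted(ds.background)) + "\n")
            written.append(bpath)
            bg_files.append(bpath.name)
    payload = {f"{_RESERVED_PREFIX}background_files": bg_files}
    for k, v in parameters.items():
        if k.startswith(_RESERVED_PREFIX):
            raise ParameterError(f"parameter names may not start with '__': {k!r}")
        payload[k] = v
    ppath = out_dir / PARAMETERS_FILE
    with open(ppath, "w") as fh:
        for k, v in payload.items():
            fh.write(f"{k}={json.dumps(v)}\n")
    written.append(ppath)
    return written


def read_input_dump(dump_dir: str | Path) -> tuple[list[Dataset], dict]:
    """Re-import a previously written input dump.

    Round trip with :func:`write_input_dump` is the identity on dataset
    names, groups, colors, order, records and backgrounds, and on all
    parameter values.
    """
    dump_dir = Path(dump_dir)
    ppath = dump_dir / PARAMETERS_FILE
    if not ppath.exists():
        raise OSError(f"missing parameter file on reimport: {ppath}")
    payload: dict = {}
    with open(ppath) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if "=" not in line:
                raise ParseError(f"{ppath}:{lineno}: expected key=value")
            k, v = line.split("=", 1)
            payload[k] = json.loads(v)
    for bg_name in payload.get(f"{_RESERVED_PREFIX}background_files", []):
        if not (dump_dir / bg_name).exists():
            raise OSError(f"missing background file on reimport: {dump_dir / bg_name}")

    datasets = read_datasets(dump_dir, DUMP_COLUMN_MAP)
    datasets = attach_backgrounds(datasets, dump_dir)
    # file naming dataset_<i> preserves the original list order
    for ds in datasets:
        ds.source_file = None
    parameters = {
        k: v for k, v in payload.items() if not k.startswith(_RESERVED_PREFIX)
    }
    return datasets, parameters
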