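"""Reading, normalizing, grouping and snapshotting user gene lists.

Datasets are tab-delimited text files with a header row; a configurable
:class:`ColumnMapping` maps file columns onto dataset fields (gene symbol,
significance value, integration group, ...).  Files whose names end in
``_bgGenes`` are single-column, headerless background gene lists attached to
all datasets read from the like-named data file.  Gene symbols are uppercased
everywhere.  A written ``Input_data`` snapshot reloads byte-identically,
giving reproducible sessions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

BG_SUFFIX = "_bgGenes"

#: fixed 20-color palette for deterministic automatic color assignment
COLOR_PALETTE = (
    "#1F77B4", "#FF7F0E", "#2CA02C", "#D62728", "#9467BD",
    "#8C564B", "#E377C2", "#7F7F7F", "#BCBD22", "#17BECF",
    "#AEC7E8", "#FFBB78", "#98DF8A", "#FF9896", "#C5B0D5",
    "#C49C94", "#F7B6D2", "#C7C7C7", "#DBDB8D", "#9EDAE5",
)


class DatasetError(ValueError):
    """Raised for malformed dataset files or mappings."""


@dataclass(frozen=True)
class ColumnMapping:
    """Names of file columns carrying each dataset field; the gene column is mandatory."""

    gene: str = "gene"
    value: str | None = None
    dataset_name: str | None = None
    integration_group: str | None = None
    color: str | None = None
    timepoint: str | None = None
    direction: str | None = None
    order: str | None = None

    def set_fields(self) -> dict[str, str]:
        return {
            f: getattr(self, f)
            for f in (
                "gene", "value", "dataset_name", "integration_group",
                "color", "timepoint", "direction", "order",
            )
            if getattr(self, f)
        }


#: mapping used when writing/reloading Input_data snapshots
SNAPSHOT_MAPPING = ColumnMapping(
    gene="gene",
    value="value",
    dataset_name="dataset",
    integration_group="group",
    color="color",
    timepoint="timepoint",
    direction="direction",
    order="order",
)


class GeneCutoff:
    """Significance cutoff selecting which genes enter enrichment analysis."""

    def __init__(self, value_threshold: float, comparison: Literal["le", "ge"] = "le"):
        if comparison not in ("le", "ge"):
            raise ValueError(f"comparison must be 'le' or 'ge', got {comparison!r}")
        self.value_threshold = float(value_threshold)
        self.comparison = comparison

    def passes(self, value: float) -> bool:
        if self.comparison == "le":
            return value <= self.value_threshold
        return value >= self.value_threshold

    def __repr__(self) -> str:  # pragma: no cover
        return f"GeneCutoff({self.value_threshold}, {self.comparison!r})"


@dataclass
class Dataset:
    """A named gene list with optional per-gene values and background."""

    name: str
    genes: list[str] = field(default_factory=list)  # ordered, unique, uppercase
    values: dict[str, float] | None = None
    background: set[str] | None = None
    integration_group: str = "default"
    color: str = COLOR_PALETTE[0]
    order_index: int = 0
    timepoint: str | None = None
    direction: str | None = None

    @property
    def gene_set(self) -> set[str]:
        return set(self.genes)

    @property
    def analyzable(self) -> bool:
        return len(self.genes) > 0

    def copy(self) -> "Dataset":
        return replace(
            self,
            genes=list(self.genes),
            values=dict(self.values) if self.values is not None else None,
            background=set(self.background) if self.background is not None else None,
        )


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------


def _is_bg_file(path: Path) -> bool:
    return path.stem.endswith(BG_SUFFIX)


def _read_background(path: Path) -> set[str]:
    genes: set[str] = set()
    for line in path.read_text(encoding="utf-8").splitlines():
        g = line.strip()
        if g:
            genes.add(g.upper())
    return genes


def _add_gene(dataset: Dataset, gene: str, value: float | None) -> None:
    gene = gene.strip().upper()
    if not gene:
        return
    if gene not in dataset.gene_set:
        dataset.genes.append(gene)
        if value is not None:
            dataset.values = dataset.values or {}
            dataset.values[gene] = value
    elif value is not None and dataset.values is not None:
        # duplicate rows keep the most significant (smallest) value
        dataset.values[gene] = min(dataset.values.get(gene, math.inf), value)


def _read_data_file(path: Path, mapping: ColumnMapping) -> list[Dataset]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        logger.warning("file %s is empty; skipped", path)
        return []
    missing = [c for c in mapping.set_fields().values() if c not in df.columns]
    if missing:
        raise DatasetError(
            f"column(s) {', '.join(repr(c) for c in missing)} not found in {path}"
        )
    datasets: dict[str, Dataset] = {}
    for _, row in df.iterrows():
        gene = row[mapping.gene]
        if pd.isna(gene):
            continue
        name = (
            str(row[mapping.dataset_name])
            if mapping.dataset_name and pd.notna(row[mapping.dataset_name])
            else path.stem
        )
        d = datasets.get(name)
        if d is None:
            d = datasets[name] = Dataset(name=name)
        value = None
        if mapping.value and pd.notna(row[mapping.value]):
            value = float(row[mapping.value])
        _add_gene(d, str(gene), value)
        if mapping.integration_group and pd.notna(row[mapping.integration_group]):
            d.integration_group = str(row[mapping.integration_group])
        if mapping.color and pd.notna(row[mapping.color]):
            d.color = str(row[mapping.color])
        if mapping.timepoint and pd.notna(row[mapping.timepoint]):
            d.timepoint = str(row[mapping.timepoint])
        if mapping.direction and pd.notna(row[mapping.direction]):
            d.direction = str(row[mapping.direction]).lower()
        if mapping.order and pd.notna(row[mapping.order]):
            d.order_index = int(float(row[mapping.order]))
    return list(datasets.values())


def read_datasets(
    source: str | Path,
    mapping: ColumnMapping | None = None,
    exclude: set[str] | None = None,
) -> list[Dataset]:
    """Read one file or every data file in a directory into datasets.

    One dataset is produced per distinct dataset-name value (or per file when
    no name column is mapped).  ``*_bgGenes`` files are parsed as headerless
    single-column background lists and attached to all datasets from the
    like-named data file.  Genes listed but absent from their background are
    dropped with a warning, keeping the contingency table consistent.
    ``exclude`` names files (relative to the directory) that are not data,
    e.g. ontology inputs living in the same directory.
    """
    mapping = mapping or ColumnMapping()
    exclude = exclude or set()
    source = Path(source)
    if source.is_dir():
        files = sorted(
            p for p in source.iterdir()
            if p.is_file() and p.suffix.lower() in (".txt", ".tsv", ".tab")
            and p.name not in exclude
        )
    else:
        files = [source]
        sibling = source.with_name(source.stem + BG_SUFFIX + source.suffix)
        if sibling.exists():
            files.append(sibling)

    data_files = [p for p in files if not _is_bg_file(p)
                  and not p.stem.startswith("parameter_settings")]
    bg_files = {p.stem[: -len(BG_SUFFIX)]: p for p in files if _is_bg_file(p)}

    datasets: list[Dataset] = []
    for path in data_files:
        ds = _read_data_file(path, mapping)
        bg_path = bg_files.get(path.stem)
        if bg_path is not None:
            bg = _read_background(bg_path)
            for d in ds:
                d.background = set(bg)
        datasets.extend(ds)

    for i, d in enumerate(datasets):
        if d.order_index == 0:
            d.order_index = i + 1
        if d.background is not None:
            lost = [g for g in d.genes if g not in d.background]
            if lost:
                logger.warning(
                    "dataset %s: %d genes not in its background were dropped: %s",
                    d.name, len(lost), ", ".join(lost[:10]),
                )
                d.genes = [g for g in d.genes if g in d.background]
                if d.values is not None:
                    d.values = {g: v for g, v in d.values.items() if g in d.background}
    return datasets


def apply_gene_cutoffs(d: Dataset, c: GeneCutoff) -> Dataset:
    """Keep only genes whose value satisfies the cutoff.

    Datasets without values are returned unchanged with a warning; a dataset
    whose genes all fail becomes empty and is flagged unanalyzable.
    """
    if d.values is None:
        logger.warning("dataset %s has no values; cutoff not applied", d.name)
        return d.copy()
    out = d.copy()
    out.genes = [g for g in d.genes if g in d.values and c.passes(d.values[g])]
    out.values = {g: d.values[g] for g in out.genes}
    if not out.genes:
        logger.warning("dataset %s: no genes pass the cutoff; unanalyzable", d.name)
    return out


# ---------------------------------------------------------------------------
# grouping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupingRule:
    """How integration-group keys are derived from dataset metadata.

    ``by_timepoint`` and ``by_direction`` group on those fields;
    ``by_substring`` splits each dataset name on ``delimiter`` and combines
    the 1-based substrings selected by ``left_indices`` (counted from the
    left) and ``right_indices`` (counted from the right).
    """

    kind: Literal["by_timepoint", "by_direction", "by_substring"]
    delimiter: str = " - "
    left_indices: tuple[int, ...] = ()
    right_indices: tuple[int, ...] = ()


def _substring_key(name: str, rule: GroupingRule) -> str:
    parts = name.split(rule.delimiter)
    picked: list[str] = []
    for i in rule.left_indices:
        if not 1 <= i <= len(parts):
            raise DatasetError(
                f"left index {i} out of range for dataset name {name!r}"
            )
        picked.append(parts[i - 1])
    for i in rule.right_indices:
        if not 1 <= i <= len(parts):
            raise DatasetError(
                f"right index {i} out of range for dataset name {name!r}"
            )
        picked.append(parts[len(parts) - i])
    return " | ".join(picked)


def group_key(d: Dataset, rule: GroupingRule) -> str:
    if rule.kind == "by_timepoint":
        return d.timepoint or "no timepoint"
    if rule.kind == "by_direction":
        return d.direction or "no direction"
    if rule.kind == "by_substring":
        if not rule.left_indices and not rule.right_indices:
            raise DatasetError("by_substring grouping needs at least one index")
        return _substring_key(d.name, rule)
    raise DatasetError(f"unknown grouping rule {rule.kind!r}")


def assign_groups(datasets: Sequence[Dataset], rule: GroupingRule) -> list[Dataset]:
    """Assign integration groups, palette colors and order indices.

    Datasets sharing the derived key receive the same integration group;
    within a group, each dataset gets a color from the fixed 20-color palette
    and an order index, deterministically by position.
    """
    out = [d.copy() for d in datasets]
    for d in out:
        d.integration_group = group_key(d, rule)
    counters: dict[str, int] = {}
    for d in out:
        i = counters.get(d.integration_group, 0)
        d.color = COLOR_PALETTE[i % len(COLOR_PALETTE)]
        d.order_index = i + 1
        counters[d.integration_group] = i + 1
    return out


# ---------------------------------------------------------------------------
# snapshotting
# ---------------------------------------------------------------------------


def _safe_filename(name: str) -> str:
    return "".join(c if c.isalnum() or c in "-_." else "_" for c in name)


def write_input_snapshot(
    datasets: Iterable[Dataset],
    params: "object | None",
    results_dir: str | Path,
) -> Path:
    """Write the analyzed gene lists, backgrounds and parameters to ``Input_data``.

    The snapshot is written so that ``read_datasets(snapshot_dir,
    SNAPSHOT_MAPPING)`` reproduces the session: gene order, values,
    backgrounds, groups, colors and order indices all round-trip.
    """
    snap = Path(results_dir) / "Input_data"
    snap.mkdir(parents=True, exist_ok=True)
    for d in datasets:
        stem = _safe_filename(d.name)
        rows = []
        for g in d.genes:
            rows.append({
                "gene": g,
                "value": "" if d.values is None or g not in d.values
                          else repr(d.values[g]),
                "dataset": d.name,
                "group": d.integration_group,
                "color": d.color,
                "timepoint": d.timepoint or "",
                "direction": d.direction or "",
                "order": d.order_index,
            })
        pd.DataFrame(rows, columns=list(rows[0]) if rows else [
            "gene", "value", "dataset", "group", "color",
            "timepoint", "direction", "order",
        ]).to_csv(snap / f"{stem}.txt", sep="\t", index=False, lineterminator="\n")
        if d.background is not None:
            (snap / f"{stem}{BG_SUFFIX}.txt").write_text(
                "\n".join(sorted(d.background)) + "\n", encoding="utf-8"
            )
    if params is not None:
        from . import cli_config

        cli_config.save_parameters(params, snap / cli_config.PARAMS_FILENAME)
    return snap
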