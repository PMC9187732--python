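"""Input/output for the tabular formats the pipeline touches.

All tabular inputs are tab-separated; gene symbols are matched verbatim and
case-sensitively throughout the package (no alias resolution). Gene sets use
the GMT dialect (one set per line: name, description, then gene symbols).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

VALID_GROUPS = ("case", "control")


class FormatError(ValueError):
    """A file does not conform to the expected tabular dialect."""


class ConsistencyError(ValueError):
    """Parsed content violates a cross-field invariant (e.g. donor in both groups)."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Gene (or transcript) x sample matrix of non-negative FPKM-scale values.

    ``data`` is a pandas DataFrame with unique row ids (genes/transcripts) and
    unique column ids (samples). ``gene_of_transcript`` optionally maps
    transcript row ids to gene symbols for representative-transcript selection.
    """

    data: pd.DataFrame
    gene_of_transcript: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate row ids: {dups[:5]}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate column ids: {dups[:5]}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("expression values must be numeric")
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise FormatError(
                f"non-finite value at row {self.data.index[bad[0]]!r}, "
                f"column {self.data.columns[bad[1]]!r}"
            )

    @property
    def row_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class SampleSheet:
    """Per-sample design: donor, replicate index and case/control group."""

    table: pd.DataFrame  # columns: sample_id, donor_id, replicate_index, group

    REQUIRED = ("sample_id", "donor_id", "replicate_index", "group")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise FormatError(f"sample sheet missing required columns: {missing}")
        t = self.table
        if t["sample_id"].duplicated().any():
            dups = t.loc[t["sample_id"].duplicated(), "sample_id"].tolist()
            raise ConsistencyError(f"duplicate sample ids: {dups}")
        groups = t["group"].astype(str).str.lower()
        unknown = sorted(set(groups) - set(VALID_GROUPS))
        if unknown:
            raise FormatError(f"unknown group labels: {unknown}")
        self.table = t.assign(group=groups)
        per_donor = self.table.groupby("donor_id")["group"].nunique()
        mixed = per_donor[per_donor > 1].index.tolist()
        if mixed:
            raise ConsistencyError(f"donors assigned to both groups: {mixed}")
        if (self.table["replicate_index"].astype(int) < 1).any():
            raise FormatError("replicate_index must be a positive integer")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.table.loc[self.table["group"] == group, "sample_id"])

    @property
    def case_samples(self) -> list[str]:
        return self.samples_in_group("case")

    @property
    def control_samples(self) -> list[str]:
        return self.samples_in_group("control")

    def donor_of(self) -> pd.Series:
        return self.table.set_index("sample_id")["donor_id"]

    def group_indicator(self, sample_order: Sequence[str]) -> np.ndarray:
        """0/1 case indicator aligned to ``sample_order``."""
        lookup = self.table.set_index("sample_id")["group"]
        missing = [s for s in sample_order if s not in lookup.index]
        if missing:
            raise ConsistencyError(f"samples absent from sheet: {missing[:5]}")
        return (lookup.loc[list(sample_order)] == "case").to_numpy(dtype=float)


@dataclass
class GeneSetCollection:
    """Ordered named gene sets (cell-type clusters, atlas cell types, panels)."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def genes(self, name: str) -> list[str]:
        return self.sets[name][1]

    def __len__(self) -> int:
        return len(self.sets)

    def items(self) -> Iterable[tuple[str, list[str]]]:
        for name, (_, genes) in self.sets.items():
            yield name, genes


@dataclass
class AnalysisConfig:
    """Run configuration; defaults follow the published analysis settings."""

    fpkm_threshold: float = 2.0
    intra_sd_z: float = 2.0
    inter_sd_z: float = 1.5
    n_permutations: int = 100_000
    seed: int = 0
    fwer_levels: tuple[float, ...] = (0.05, 0.1)
    overlap_merge_threshold: float = 50.0

    def __post_init__(self) -> None:
        if self.fpkm_threshold <= 0 or self.intra_sd_z <= 0 or self.inter_sd_z <= 0:
            raise ValueError("thresholds must be positive")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "fwer_levels" in raw:
            raw["fwer_levels"] = tuple(raw["fwer_levels"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["fwer_levels"] = list(self.fwer_levels)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_expression_matrix(
    path: str | Path,
    id_map_path: str | Path | None = None,
    allow_negative: bool = False,
) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column row ids, header sample ids).

    ``id_map_path`` optionally points to a two-column TSV mapping transcript id
    to gene symbol; when given it populates ``gene_of_transcript``. Raw FPKM
    matrices must be non-negative; set ``allow_negative`` to read back a
    normalized (inverse-normal) matrix.
    """
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
    samples = first.split("\t")[1:]  # read raw: pandas would mangle duplicates
    seen: set[str] = set()
    for s in samples:
        if s in seen:
            raise FormatError(f"duplicate sample id in header: {s!r}")
        seen.add(s)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = [str(c) for c in samples]
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate row ids: {dups[:5]}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~df.isna()
    if bad.to_numpy().any() or numeric.isna().to_numpy().any():
        mask = numeric.isna().to_numpy()
        r, c = np.argwhere(mask)[0]
        raise FormatError(
            f"non-numeric or missing value at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    if not allow_negative and (numeric.to_numpy() < 0).any():
        r, c = np.argwhere(numeric.to_numpy() < 0)[0]
        raise FormatError(
            f"negative value at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    gene_map = None
    if id_map_path is not None:
        mapping = pd.read_csv(
            id_map_path, sep="\t", header=None, names=["transcript", "gene"]
        )
        gene_map = dict(zip(mapping["transcript"].astype(str), mapping["gene"].astype(str)))
    return ExpressionMatrix(numeric.astype(float), gene_of_transcript=gene_map)


def write_expression_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    m.data.to_csv(path, sep="\t", float_format="%.17g", index_label="id")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "donor_id": str})
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, sep="\t", index=False)


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file; duplicate genes within a set are collapsed (warned)."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"line {lineno}: expected >=3 tab-separated fields")
            name, description, genes = fields[0], fields[1], fields[2:]
            genes = [g for g in genes if g != ""]
            if not genes:
                raise FormatError(f"line {lineno}: gene set {name!r} is empty")
            if name in sets:
                raise FormatError(f"line {lineno}: duplicate set name {name!r}")
            deduped = list(dict.fromkeys(genes))
            if len(deduped) < len(genes):
                logger.warning(
                    "set %r: collapsed %d duplicated gene entries",
                    name,
                    len(genes) - len(deduped),
                )
            sets[name] = (description, deduped)
    return GeneSetCollection(sets)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, (description, genes) in collection.sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def format_empirical_p(p: float, at_floor: bool) -> str:
    """Render an empirical p-value; at the permutation floor emit a bound."""
    if at_floor:
        return f"<{p:.0e}"
    return format(p, ".6g")


def write_results_table(
    rows: Sequence[Mapping[str, object]],
    path: str | Path,
    columns: Sequence[str] | None = None,
) -> None:
    """Write homogeneous records as a TSV with header.

    Floats are rendered with six significant digits. A record may carry an
    ``at_floor`` boolean; when true its ``p_empirical`` field is rendered as an
    upper bound ("<1e-06" style) rather than a number.
    """
    rows = list(rows)
    if rows:
        keys = list(rows[0].keys())
        for r in rows:
            if list(r.keys()) != keys:
                raise ValueError("records are not homogeneous")
    else:
        keys = list(columns) if columns is not None else []
    with open(path, "w") as fh:
        fh.write("\t".join(keys) + "\n")
        for r in rows:
            rendered = []
            for k in keys:
                v = r[k]
                if k == "p_empirical" and bool(r.get("at_floor", False)):
                    rendered.append(format_empirical_p(float(v), True))
                elif isinstance(v, float):
                    rendered.append("NA" if math.isnan(v) else format(v, ".6g"))
                else:
                    rendered.append(str(v))
            fh.write("\t".join(rendered) + "\n")
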