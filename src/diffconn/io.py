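"""Readers and writers for the tabular formats the pipeline touches.

Expression matrices are plain TSV (features x samples, header row of sample
ids, first column feature ids), accompanied by a sample sheet TSV
(``sample_id``, ``condition``, optional ``batch``).  Gene sets use GMT
semantics; interaction networks come in as SIF or 2/3-column edge TSV.  No
statistics live here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import __version__

logger = logging.getLogger(__name__)

CODING = "coding"
NON_CODING = "non_coding"
FEATURE_TYPES = (CODING, NON_CODING)


def _header_comment(what: str, **params: object) -> str:
    kv = " ".join(f"{k}={v}" for k, v in params.items())
    return f"# diffconn v{__version__} {what} {kv}".rstrip() + "\n"


@dataclass
class ExpressionMatrix:
    """Log2-scale expression values for features x samples with metadata.

    Parameters
    ----------
    values
        DataFrame of finite log2 intensities, index = feature ids,
        columns = sample ids, both unique.
    condition_of
        Series mapping every sample id to one of exactly two condition
        labels.
    feature_type_of
        Series mapping every feature id to ``"coding"`` or ``"non_coding"``.
    """

    values: pd.DataFrame
    condition_of: pd.Series
    feature_type_of: pd.Series

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()][0]
            raise ValueError(f"duplicate feature id: {dup!r}")
        if v.columns.duplicated().any():
            dup = v.columns[v.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if not np.isfinite(arr).all():
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite value for feature {v.index[i]!r}, sample {v.columns[j]!r}"
            )
        missing = [s for s in v.columns if s not in self.condition_of.index]
        if missing:
            raise ValueError(f"sample {missing[0]!r} has no condition assignment")
        self.condition_of = self.condition_of.loc[v.columns]
        conds = pd.unique(self.condition_of)
        if len(conds) != 2:
            raise ValueError(
                f"expected exactly 2 conditions, found {len(conds)}: {sorted(map(str, conds))}"
            )
        counts = self.condition_of.value_counts()
        if (counts < 2).any():
            small = counts.index[counts < 2][0]
            raise ValueError(f"condition {small!r} has fewer than 2 samples")
        missing_ft = [f for f in v.index if f not in self.feature_type_of.index]
        if missing_ft:
            raise ValueError(f"feature {missing_ft[0]!r} has no coding/non-coding flag")
        self.feature_type_of = self.feature_type_of.loc[v.index]
        bad = set(self.feature_type_of) - set(FEATURE_TYPES)
        if bad:
            raise ValueError(f"unknown feature type {bad.pop()!r}")

    # -- convenience ----------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def conditions(self) -> list[str]:
        return list(pd.unique(self.condition_of))

    def samples_of(self, condition: str) -> list[str]:
        if condition not in set(self.condition_of):
            raise ValueError(f"unknown condition label {condition!r}")
        return list(self.condition_of.index[self.condition_of == condition])

    def subset_features(self, feature_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(feature_ids)
        unknown = [f for f in ids if f not in self.values.index]
        if unknown:
            raise ValueError(f"unknown feature id {unknown[0]!r}")
        return ExpressionMatrix(
            self.values.loc[ids],
            self.condition_of.copy(),
            self.feature_type_of.loc[ids],
        )


def read_expression_matrix(
    path: str | Path,
    sample_sheet_path: str | Path,
    feature_annotation_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read an expression TSV plus its sample sheet into an ExpressionMatrix.

    The matrix must be complete: an ``NA`` or non-numeric cell is an error,
    never an imputation trigger.  Sample order follows the file.  The
    optional feature annotation TSV (columns ``feature_id``,
    ``feature_type``) marks coding vs non-coding; without it every feature
    is treated as coding.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            row = df.index[bad][0]
            raise ValueError(
                f"non-numeric or missing cell at feature {row!r}, sample {col!r}"
            )
        df[col] = coerced.astype(float)

    sheet = read_sample_sheet(sample_sheet_path)
    condition_of = sheet.condition_of()
    absent = [s for s in df.columns if s not in condition_of.index]
    if absent:
        raise ValueError(f"sample {absent[0]!r} missing from the sample sheet")

    if feature_annotation_path is not None:
        ann = pd.read_csv(feature_annotation_path, sep="\t", comment="#", dtype=str)
        if not {"feature_id", "feature_type"} <= set(ann.columns):
            raise ValueError(
                "feature annotation needs columns feature_id, feature_type"
            )
        feature_type_of = ann.set_index("feature_id")["feature_type"]
        missing = [f for f in df.index if f not in feature_type_of.index]
        if missing:
            raise ValueError(f"feature {missing[0]!r} missing from the annotation")
        feature_type_of = feature_type_of.loc[df.index]
    else:
        feature_type_of = pd.Series(CODING, index=df.index)

    return ExpressionMatrix(df, condition_of.loc[df.columns], feature_type_of)


def write_expression_matrix(
    em: ExpressionMatrix, path: str | Path, sample_sheet_path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment("expression-matrix", shape=em.values.shape))
        em.values.rename_axis("feature_id").to_csv(fh, sep="\t")
    sheet = pd.DataFrame(
        {"sample_id": em.sample_ids, "condition": em.condition_of.to_numpy()}
    )
    with open(sample_sheet_path, "w") as fh:
        fh.write(_header_comment("sample-sheet"))
        sheet.to_csv(fh, sep="\t", index=False)


@dataclass
class SampleSheet:
    """Rows of (sample_id, condition, optional batch)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if not {"sample_id", "condition"} <= set(self.table.columns):
            raise ValueError("sample sheet needs columns sample_id, condition")
        dup = self.table["sample_id"].duplicated()
        if dup.any():
            raise ValueError(
                f"duplicate sample id in sheet: {self.table['sample_id'][dup].iloc[0]!r}"
            )

    def condition_of(self) -> pd.Series:
        return self.table.set_index("sample_id")["condition"]


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return SampleSheet(df)


@dataclass
class GeneSetCollection:
    """Named, non-empty sets of feature ids with optional descriptions."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (name, description, members, tab-separated).

    Duplicate members within a set are deduplicated; a line with fewer than
    three fields is rejected with its line number.
    """
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: fewer than 3 fields")
            name, desc, *members = fields
            if name in sets:
                raise ValueError(f"GMT line {lineno}: duplicate set name {name!r}")
            members = [m for m in members if m]
            if not members:
                raise ValueError(f"GMT line {lineno}: set {name!r} has no members")
            sets[name] = set(members)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


Edge = tuple[str, str, float | None]


def read_edge_list(path: str | Path) -> list[Edge]:
    """Read an undirected edge list from SIF or 2/3-column TSV.

    SIF rows are ``source relation target [target ...]``; TSV rows are
    ``a<TAB>b[<TAB>weight]``.  Self-loops are dropped (count logged),
    duplicate edges collapsed keeping the first weight seen.
    """
    path = Path(path)
    is_sif = path.suffix.lower() == ".sif"
    edges: dict[tuple[str, str], float | None] = {}
    self_loops = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            tokens = line.split("\t") if "\t" in line else line.split()
            tokens = [t for t in tokens if t]
            pairs: list[tuple[str, str, float | None]] = []
            if is_sif:
                if len(tokens) == 1:
                    continue  # isolated node line, legal SIF
                if len(tokens) < 3:
                    raise ValueError(f"edge list line {lineno}: malformed SIF row")
                src, _rel, *targets = tokens
                pairs = [(src, t, None) for t in targets]
            elif len(tokens) == 2:
                pairs = [(tokens[0], tokens[1], None)]
            elif len(tokens) == 3:
                try:
                    w = float(tokens[2])
                except ValueError:
                    # three non-numeric columns: treat as SIF-style a rel b
                    pairs = [(tokens[0], tokens[2], None)]
                else:
                    pairs = [(tokens[0], tokens[1], w)]
            else:
                raise ValueError(
                    f"edge list line {lineno}: expected 2 or 3 columns, got {len(tokens)}"
                )
            for a, b, w in pairs:
                if a == b:
                    self_loops += 1
                    continue
                key = (a, b) if a <= b else (b, a)
                edges.setdefault(key, w)
    if self_loops:
        logger.info("dropped %d self-loop(s) reading %s", self_loops, path)
    return [(a, b, w) for (a, b), w in edges.items()]


def write_edge_list(edges: Iterable[Edge], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment("edge-list"))
        for a, b, w in edges:
            if w is None:
                fh.write(f"{a}\t{b}\n")
            else:
                fh.write(f"{a}\t{b}\t{w}\n")


def read_id_list(path: str | Path) -> set[str]:
    """Plain-text id list, one id per line; blank lines and '#' comments skipped."""
    out: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return out


def write_table(df: pd.DataFrame, path: str | Path, what: str, **params: object) -> None:
    """Write a result table as TSV with a provenance comment header."""
    with open(path, "w") as fh:
        fh.write(_header_comment(what, **params))
        df.to_csv(fh, sep="\t", index=False)
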