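"""Data model and I/O for multi-omics matrices, sample metadata, cross-omic
feature mappings and gene-set collections.

Conventions
-----------
* Omics matrices place features on rows and samples in columns.
* Metadata tables place samples on rows and variables in columns.
* All on-disk formats are UTF-8 tab-delimited text (TSV, GMT); writers emit
  deterministic column order so that ``read -> write -> read`` is an identity.
* Identifier matching is exact, case-sensitive string equality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DataValidationError",
    "OmicsDataset",
    "TimeToEvent",
    "SampleMetadata",
    "FeatureMapping",
    "GeneSet",
    "GeneSetCollection",
    "read_omics_matrix",
    "write_omics_matrix",
    "read_sample_metadata",
    "write_sample_metadata",
    "align_common_samples",
    "center_and_frobenius_scale",
    "combine_mappings",
    "read_feature_mapping",
    "write_feature_mapping",
    "read_gmt",
    "write_gmt",
]


class DataValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


def _first_duplicate(ids: Sequence[str]) -> str | None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


# ---------------------------------------------------------------------------
# Omics matrix
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OmicsDataset:
    """One omic block: a features x samples numeric matrix with identifiers.

    Parameters
    ----------
    name
        Label for the block (e.g. ``"mrna"``).
    feature_ids, sample_ids
        Ordered, unique identifiers for rows and columns respectively.
    values
        Matrix of shape ``(len(feature_ids), len(sample_ids))``; all entries
        must be finite.
    """

    name: str
    feature_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "feature_ids", tuple(str(f) for f in self.feature_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        if values.ndim != 2:
            raise DataValidationError(f"{self.name}: values must be 2-D, got ndim={values.ndim}")
        if values.shape[0] == 0 or values.shape[1] == 0:
            raise DataValidationError(f"{self.name}: empty matrix")
        if values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise DataValidationError(
                f"{self.name}: shape {values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        for kind, ids in (("feature", self.feature_ids), ("sample", self.sample_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise DataValidationError(f"{self.name}: duplicate {kind} id {dup!r}")
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise DataValidationError(
                f"{self.name}: non-finite value at feature {self.feature_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.feature_ids), columns=list(self.sample_ids))

    def subset_samples(self, sample_ids: Sequence[str]) -> "OmicsDataset":
        """Restrict (and reorder) to the given samples."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise DataValidationError(f"{self.name}: unknown sample id {missing[0]!r}")
        idx = [pos[s] for s in sample_ids]
        return OmicsDataset(self.name, self.feature_ids, tuple(sample_ids), self.values[:, idx])


def read_omics_matrix(path: str | Path, name: str | None = None, drop_missing: bool = False) -> OmicsDataset:
    """Read a features x samples TSV matrix.

    The first column holds feature identifiers; the header row holds sample
    identifiers.  Missing values are rejected unless ``drop_missing`` is set,
    in which case features with any missing entry are dropped (with a log
    message stating how many).
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, header=0, dtype=str)
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise DataValidationError(f"{path}: empty matrix")
    dup = _first_duplicate([str(x) for x in raw.index])
    if dup is not None:
        raise DataValidationError(f"{path}: duplicate feature id {dup!r}")
    dup = _first_duplicate([str(x) for x in raw.columns])
    if dup is not None:
        raise DataValidationError(f"{path}: duplicate sample id {dup!r}")

    coerced = raw.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna() & raw.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise DataValidationError(
            f"{path}: non-numeric value {raw.iat[i, j]!r} at feature "
            f"{raw.index[i]!r}, sample {raw.columns[j]!r}"
        )
    # re-read numerically with round-trip float parsing (the default parser
    # loses the last ulp, breaking write(read(x)) == x)
    numeric = pd.read_csv(path, sep="\t", index_col=0, header=0,
                          float_precision="round_trip")
    numeric.index = numeric.index.astype(str)
    numeric.columns = numeric.columns.astype(str)
    if numeric.isna().to_numpy().any():
        if not drop_missing:
            i, j = np.argwhere(numeric.isna().to_numpy())[0]
            raise DataValidationError(
                f"{path}: missing value at feature {raw.index[i]!r}, sample "
                f"{raw.columns[j]!r} (pass drop_missing=True to drop such features)"
            )
        keep = ~numeric.isna().any(axis=1)
        logger.info("%s: dropping %d/%d features with missing values", path, (~keep).sum(), len(keep))
        numeric = numeric.loc[keep]
        if numeric.shape[0] == 0:
            raise DataValidationError(f"{path}: all features had missing values")
    return OmicsDataset(
        name=name if name is not None else path.stem,
        feature_ids=tuple(str(x) for x in numeric.index),
        sample_ids=tuple(str(x) for x in numeric.columns),
        values=numeric.to_numpy(dtype=float),
    )


def write_omics_matrix(dataset: OmicsDataset, path: str | Path) -> None:
    dataset.to_frame().to_csv(path, sep="\t", index_label="feature_id")


def align_common_samples(a: OmicsDataset, b: OmicsDataset) -> tuple[OmicsDataset, OmicsDataset]:
    """Restrict both blocks to their shared samples, in block ``a``'s order.

    Only samples common to the two blocks can enter a joint analysis; fewer
    than two shared samples is a hard error.
    """
    in_b = set(b.sample_ids)
    common = [s for s in a.sample_ids if s in in_b]
    if len(common) < 2:
        raise DataValidationError(
            f"blocks {a.name!r} and {b.name!r} share only {len(common)} sample(s); need >= 2"
        )
    if common == list(a.sample_ids) == list(b.sample_ids):
        return a, b
    return a.subset_samples(common), b.subset_samples(common)


def center_and_frobenius_scale(d: OmicsDataset, per_feature: bool = False) -> OmicsDataset:
    """Mean-center every feature, then normalize to unit sum of squares.

    By default the *whole block* is scaled to unit Frobenius norm after
    row-centering, which equalizes block influence in a joint decomposition.
    With ``per_feature=True`` each feature row is scaled to unit sum of
    squares instead (zero-variance rows stay all-zero).
    """
    if d.n_samples < 2:
        raise DataValidationError(f"{d.name}: need >= 2 samples to center")
    x = d.values - d.values.mean(axis=1, keepdims=True)
    if per_feature:
        ss = (x**2).sum(axis=1, keepdims=True)
        nonzero = ss[:, 0] > 0
        if not nonzero.any():
            raise DataValidationError(f"{d.name}: matrix is all-zero after centering")
        x = np.where(nonzero[:, None], x / np.sqrt(np.where(nonzero[:, None], ss, 1.0)), 0.0)
    else:
        norm = np.sqrt((x**2).sum())
        if norm == 0:
            raise DataValidationError(f"{d.name}: matrix is all-zero after centering")
        x = x / norm
    return OmicsDataset(d.name, d.feature_ids, d.sample_ids, x)


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TimeToEvent:
    """Right-censored survival outcome: positive times plus 0/1 event flags."""

    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        event = np.asarray(self.event, dtype=int)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", event)
        if time.shape != event.shape or time.ndim != 1:
            raise DataValidationError("time and event must be 1-D arrays of equal length")
        if not np.all(time > 0):
            raise DataValidationError("time-to-event requires strictly positive times")
        if not np.isin(event, (0, 1)).all():
            raise DataValidationError("event indicator must be 0 or 1")

    def take(self, idx) -> "TimeToEvent":
        return TimeToEvent(self.time[idx], self.event[idx])

    def __len__(self) -> int:
        return len(self.time)


class SampleMetadata:
    """Per-sample variables, each typed categorical / numeric / time-to-event.

    A time-to-event variable ``v`` is stored as the column pair
    ``{v}_time`` / ``{v}_event`` in the underlying table.
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        categorical: Sequence[str] = (),
        numeric: Sequence[str] = (),
        time_to_event: Mapping[str, tuple[str, str]] | None = None,
    ) -> None:
        if frame.index.has_duplicates:
            dup = frame.index[frame.index.duplicated()][0]
            raise DataValidationError(f"duplicate sample id {dup!r} in metadata")
        self.frame = frame.copy()
        self.frame.index = self.frame.index.astype(str)
        self.categorical = tuple(categorical)
        self.numeric = tuple(numeric)
        self.time_to_event = dict(time_to_event or {})
        for v in self.categorical + self.numeric:
            if v not in self.frame.columns:
                raise DataValidationError(f"metadata variable {v!r} not in table")
        for v, (tcol, ecol) in self.time_to_event.items():
            for c in (tcol, ecol):
                if c not in self.frame.columns:
                    raise DataValidationError(f"time-to-event column {c!r} for {v!r} not in table")
            TimeToEvent(self.frame[tcol].to_numpy(float), self.frame[ecol].to_numpy())
        overlap = set(self.categorical) & set(self.numeric)
        if overlap:
            raise DataValidationError(f"variable(s) typed twice: {sorted(overlap)}")

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.frame.index)

    @property
    def variables(self) -> list[tuple[str, str]]:
        out = [(v, "categorical") for v in self.categorical]
        out += [(v, "numeric") for v in self.numeric]
        out += [(v, "time_to_event") for v in self.time_to_event]
        return out

    def kind_of(self, name: str) -> str:
        for v, kind in self.variables:
            if v == name:
                return kind
        raise KeyError(name)

    def get(self, name: str):
        """Return the variable as an array (categorical/numeric) or TimeToEvent."""
        if name in self.categorical:
            return self.frame[name].to_numpy(object)
        if name in self.numeric:
            return self.frame[name].to_numpy(float)
        if name in self.time_to_event:
            tcol, ecol = self.time_to_event[name]
            return TimeToEvent(self.frame[tcol].to_numpy(float), self.frame[ecol].to_numpy())
        raise KeyError(name)

    def subset(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        missing = [s for s in sample_ids if s not in self.frame.index]
        if missing:
            raise DataValidationError(f"unknown sample id {missing[0]!r} in metadata subset")
        return SampleMetadata(
            self.frame.loc[list(sample_ids)], self.categorical, self.numeric, self.time_to_event
        )


def read_sample_metadata(
    path: str | Path,
    categorical: Sequence[str] | None = None,
    numeric: Sequence[str] | None = None,
    time_to_event: Mapping[str, tuple[str, str]] | None = None,
) -> SampleMetadata:
    """Read a samples x variables TSV (sample ids in the first column).

    Variable types may be given explicitly; otherwise column pairs named
    ``{v}_time`` / ``{v}_event`` become time-to-event variables, numeric
    columns become numeric, and everything else is categorical.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0, header=0)
    if time_to_event is None:
        time_to_event = {}
        for col in frame.columns:
            if col.endswith("_time") and col[: -len("_time")] + "_event" in frame.columns:
                v = col[: -len("_time")]
                time_to_event[v] = (col, v + "_event")
    tte_cols = {c for pair in time_to_event.values() for c in pair}
    rest = [c for c in frame.columns if c not in tte_cols]
    if numeric is None:
        numeric = [c for c in rest if (categorical is None or c not in categorical)
                   and pd.api.types.is_numeric_dtype(frame[c])]
    if categorical is None:
        categorical = [c for c in rest if c not in set(numeric)]
    return SampleMetadata(frame, categorical, numeric, time_to_event)


def write_sample_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.frame.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Cross-omic feature mapping
# ---------------------------------------------------------------------------


MappingTuple = tuple[str, str | None, str | None]


@dataclass(frozen=True)
class FeatureMapping:
    """Gene-referenced tuples linking features of two omic blocks.

    Each tuple is ``(reference_gene, feature_a, feature_b)`` where one of the
    two features may be absent (``None``) only when ``retain_all`` is set.
    """

    tuples: tuple[MappingTuple, ...]
    retain_all: bool = True

    def __post_init__(self) -> None:
        tuples = tuple((str(g), a if a is None else str(a), b if b is None else str(b))
                       for g, a, b in self.tuples)
        object.__setattr__(self, "tuples", tuples)
        if len(tuples) == 0:
            raise DataValidationError("feature mapping has zero tuples")
        seen = set()
        for g, a, b in tuples:
            if a is None and b is None:
                raise DataValidationError(f"mapping tuple for gene {g!r} has no features")
            if not self.retain_all and (a is None or b is None):
                raise DataValidationError(
                    f"incomplete tuple ({g!r}, {a!r}, {b!r}) with retain_all=False"
                )
            key = (g, a, b)
            if key in seen:
                raise DataValidationError(f"duplicate mapping tuple {key!r}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.tuples)

    @property
    def features_a(self) -> set[str]:
        return {a for _, a, _ in self.tuples if a is not None}

    @property
    def features_b(self) -> set[str]:
        return {b for _, _, b in self.tuples if b is not None}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(g, a or "", b or "") for g, a, b in self.tuples],
            columns=["gene", "feature_a", "feature_b"],
        )


def _as_pairs(table) -> list[tuple[str, str]]:
    """Normalize a feature->gene mapping input to (feature, gene) pairs."""
    if isinstance(table, pd.DataFrame):
        if table.shape[1] < 2:
            raise DataValidationError("mapping table needs >= 2 columns (feature, gene)")
        return [(str(f), str(g)) for f, g in table.iloc[:, :2].itertuples(index=False)]
    if isinstance(table, Mapping):
        return [(str(f), str(g)) for f, g in table.items()]
    return [(str(f), str(g)) for f, g in table]


def combine_mappings(map_a, map_b, retain_all: bool = True) -> FeatureMapping:
    """Join two feature->gene tables on the shared gene namespace.

    For every gene mapped in both tables the cross product of its features is
    emitted (one tuple per combination).  With ``retain_all`` genes mapped in
    only one table produce tuples with the other feature absent.
    """
    pairs_a, pairs_b = _as_pairs(map_a), _as_pairs(map_b)
    if not pairs_a or not pairs_b:
        raise DataValidationError("mapping tables must be nonempty")
    by_gene_a: dict[str, list[str]] = {}
    by_gene_b: dict[str, list[str]] = {}
    for f, g in pairs_a:
        by_gene_a.setdefault(g, []).append(f)
    for f, g in pairs_b:
        by_gene_b.setdefault(g, []).append(f)

    tuples: list[MappingTuple] = []
    for g in sorted(set(by_gene_a) | set(by_gene_b)):
        fa = by_gene_a.get(g, [])
        fb = by_gene_b.get(g, [])
        if fa and fb:
            tuples.extend((g, a, b) for a in sorted(set(fa)) for b in sorted(set(fb)))
        elif retain_all:
            tuples.extend((g, a, None) for a in sorted(set(fa)))
            tuples.extend((g, None, b) for b in sorted(set(fb)))
    # dedupe, preserving sorted order
    tuples = list(dict.fromkeys(tuples))
    if not tuples:
        raise DataValidationError(
            "combining mappings produced zero tuples (no shared genes; "
            "consider retain_all=True)"
        )
    return FeatureMapping(tuple(tuples), retain_all=retain_all)


def read_feature_mapping(path: str | Path) -> FeatureMapping:
    """Read a mapping TSV with columns gene / feature_a / feature_b.

    A ``#retain_all=<true|false>`` comment on the first line, as emitted by
    :func:`write_feature_mapping`, restores the flag; it defaults to whether
    any incomplete tuple is present.
    """
    path = Path(path)
    retain_all = None
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("#retain_all="):
            retain_all = first.strip().split("=", 1)[1].lower() == "true"
            frame = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
        else:
            fh.seek(0)
            frame = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    tuples = tuple(
        (g, a or None, b or None)
        for g, a, b in frame[["gene", "feature_a", "feature_b"]].itertuples(index=False)
    )
    if retain_all is None:
        retain_all = any(a is None or b is None for _, a, b in tuples)
    return FeatureMapping(tuples, retain_all=retain_all)


def write_feature_mapping(mapping: FeatureMapping, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#retain_all={'true' if mapping.retain_all else 'false'}\n")
        mapping.to_frame().to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    genes: frozenset[str]
    description: str = ""
    p_value: float | None = None
    source_analysis: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(str(g) for g in self.genes))
        if len(self.genes) < 1:
            raise DataValidationError(f"gene set {self.set_id!r} is empty")
        if self.p_value is not None and not (0.0 <= self.p_value <= 1.0):
            raise DataValidationError(f"gene set {self.set_id!r}: p_value {self.p_value} outside [0,1]")

    def with_p_value(self, p: float, source: str | None = None) -> "GeneSet":
        return GeneSet(self.set_id, self.genes, self.description, p,
                       self.source_analysis if source is None else source)


class GeneSetCollection:
    """Ordered collection of uniquely-identified gene sets."""

    def __init__(self, sets: Iterable[GeneSet]) -> None:
        self.sets = list(sets)
        dup = _first_duplicate([s.set_id for s in self.sets])
        if dup is not None:
            raise DataValidationError(f"duplicate gene-set id {dup!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, set_id: str) -> GeneSet:
        for s in self.sets:
            if s.set_id == set_id:
                return s
        raise KeyError(set_id)

    @property
    def set_ids(self) -> list[str]:
        return [s.set_id for s in self.sets]

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for s in self.sets:
            out |= s.genes
        return out


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: set id, description, then tab-separated genes.

    Duplicate genes within a line are deduplicated; a line with fewer than
    three fields is a hard error naming the line.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataValidationError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3")
            genes = [g for g in fields[2:] if g]
            sets.append(GeneSet(fields[0], frozenset(genes), description=fields[1]))
    if not sets:
        raise DataValidationError(f"{path}: empty GMT file")
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in collection:
            fh.write("\t".join([s.set_id, s.description] + sorted(s.genes)) + "\n")
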