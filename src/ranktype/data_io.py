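"""Expression-matrix I/O, z-score normalisation and model (de)serialisation.

Input convention follows the GEO series-matrix layout: genes in rows with the
gene identifier in the first column, samples in columns with sample identifiers
in the header row.  Values may be log-scale microarray intensities or TPM; the
downstream method only consumes intrasample ranks, so the scale is free.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("ranktype")

#: Schema tag written into every serialised model; bumped on breaking changes.
MODEL_SCHEMA_VERSION = 1

#: The four WHO consensus medulloblastoma subgroups, in fixed order.  The
#: order is recorded in the model and used for deterministic tie-breaking.
DEFAULT_SUBTYPES = ("SHH", "WNT", "Group3", "Group4")


class DataError(ValueError):
    """Invalid or inconsistent input data (exit code 2 at the CLI)."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for x in ids:
        if x in seen and x not in dups:
            dups.append(x)
        seen.add(x)
    if dups:
        raise DataError(f"duplicate {what}: {', '.join(map(str, dups[:10]))}")


@dataclass
class SubtypeSet:
    """Ordered, fixed set of subtype names used throughout a model."""

    names: tuple[str, ...] = DEFAULT_SUBTYPES

    def __post_init__(self) -> None:
        self.names = tuple(self.names)
        if len(self.names) < 2:
            raise DataError("need at least 2 subtype names")
        _check_unique(self.names, "subtype names")

    def __iter__(self):
        return iter(self.names)

    def __len__(self) -> int:
        return len(self.names)

    def others(self, subtype: str) -> tuple[str, ...]:
        if subtype not in self.names:
            raise DataError(f"unknown subtype {subtype!r}")
        return tuple(s for s in self.names if s != subtype)


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric matrix with identifiers and optional metadata.

    ``labels`` maps sample_id -> subtype name and ``batches`` maps
    sample_id -> batch name; both are optional and only labelled/annotated
    samples need appear in them.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    labels: dict[str, str] | None = None
    batches: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.gene_ids, "gene IDs")
        _check_unique(self.sample_ids, "sample IDs")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.isfinite(self.values).all():
            r, c = np.argwhere(~np.isfinite(self.values))[0]
            raise DataError(
                f"non-finite expression value at gene {self.gene_ids[r]!r}, "
                f"sample {self.sample_ids[c]!r}"
            )
        for name, mapping in (("label", self.labels), ("batch", self.batches)):
            if mapping is not None:
                unknown = sorted(set(mapping) - set(self.sample_ids))
                if unknown:
                    raise DataError(
                        f"{name} table references unknown sample(s): "
                        f"{', '.join(unknown[:10])}"
                    )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def select_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in idx]
        if missing:
            raise DataError(f"unknown gene(s): {', '.join(missing[:10])}")
        rows = [idx[g] for g in genes]
        return ExpressionMatrix(
            list(genes), list(self.sample_ids), self.values[rows, :],
            labels=self.labels, batches=self.batches,
        )

    def select_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in idx]
        if missing:
            raise DataError(f"unknown sample(s): {', '.join(missing[:10])}")
        cols = [idx[s] for s in samples]
        sub = set(samples)
        return ExpressionMatrix(
            list(self.gene_ids), list(samples), self.values[:, cols],
            labels={s: v for s, v in (self.labels or {}).items() if s in sub} or None,
            batches={s: v for s, v in (self.batches or {}).items() if s in sub} or None,
        )


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column (sample_id, subtype) table; header optional."""
    df = pd.read_csv(path, sep=None, engine="python", header=None, dtype=str)
    if df.shape[1] < 2:
        raise DataError(f"label file {path} must have two columns")
    # Tolerate a header row like "sample_id<TAB>subtype".
    if str(df.iloc[0, 0]).lower() in {"sample_id", "sample", "id"}:
        df = df.iloc[1:]
    pairs = list(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
    _check_unique([s for s, _ in pairs], "sample IDs in label file")
    return dict(pairs)


def read_expression(
    path: str | Path,
    format: str | None = None,
    label_path: str | Path | None = None,
    batch_path: str | Path | None = None,
    drop_missing_genes: bool = False,
) -> ExpressionMatrix:
    """Read a genes x samples TSV/CSV into an :class:`ExpressionMatrix`.

    First column = gene IDs, header row = sample IDs; row order is preserved.
    Non-numeric cells are a hard error with coordinates.  Missing values are
    rejected unless ``drop_missing_genes`` is set, in which case any gene row
    containing a missing entry is dropped (with a logged count).
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "tsv"
    if format not in {"tsv", "csv"}:
        raise DataError(f"unknown format {format!r} (expected 'tsv' or 'csv')")
    sep = "\t" if format == "tsv" else ","
    # round_trip parsing keeps written float64 values bit-exact on re-read
    raw = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    raw.index = raw.index.astype(str)
    _check_unique(list(raw.index), "gene IDs")
    _check_unique(list(raw.columns), "sample IDs")

    num = raw.copy()
    for c in raw.columns:
        if raw[c].dtype == object:  # at least one non-float cell in this column
            converted = np.empty(len(raw), dtype=float)
            for i, v in enumerate(raw[c]):
                if v is None or (isinstance(v, float) and np.isnan(v)):
                    converted[i] = np.nan
                    continue
                try:
                    converted[i] = float(v)
                except (TypeError, ValueError):
                    raise DataError(
                        f"non-numeric value {v!r} at gene {raw.index[i]!r}, "
                        f"sample {c!r}"
                    ) from None
            num[c] = converted
    num = num.astype(float)
    missing = num.isna().any(axis=1)
    if missing.any():
        if not drop_missing_genes:
            r = int(np.argmax(missing.to_numpy()))
            raise DataError(
                f"missing value(s) in {int(missing.sum())} gene row(s), first at "
                f"gene {num.index[r]!r}; pass drop_missing_genes=True to drop them"
            )
        logger.warning("dropping %d gene(s) with missing values", int(missing.sum()))
        num = num.loc[~missing]

    labels = read_labels(label_path) if label_path is not None else None
    batches = read_labels(batch_path) if batch_path is not None else None
    return ExpressionMatrix(
        list(num.index), list(num.columns), num.to_numpy(dtype=float),
        labels=labels, batches=batches,
    )


def write_expression(X: ExpressionMatrix, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "tsv"
    sep = "\t" if format == "tsv" else ","
    df = X.to_frame()
    df.index.name = "gene_id"
    # repr() round-trips float64 bit-exactly through text.
    df.to_csv(path, sep=sep, float_format=lambda v: repr(float(v)))


def zscore_normalize(X: ExpressionMatrix, axis: str = "per_sample") -> ExpressionMatrix:
    """Standardise each sample (column) or gene (row) to mean 0, sd 1.

    Uses the sample standard deviation (divisor n-1).  Zero-variance vectors
    are replaced with all-zeros and a warning is logged, so constant probes do
    not abort a run.  Per-sample standardisation is a strictly increasing
    affine map of each column and therefore leaves all intrasample ranks
    unchanged.
    """
    if axis not in {"per_sample", "per_gene"}:
        raise DataError(f"axis must be 'per_sample' or 'per_gene', got {axis!r}")
    ax = 0 if axis == "per_sample" else 1
    v = X.values
    mean = v.mean(axis=ax, keepdims=True)
    with np.errstate(invalid="ignore"):
        sd = v.std(axis=ax, ddof=1, keepdims=True)
    degenerate = ~(sd > 0)
    if degenerate.any():
        logger.warning(
            "zscore_normalize: %d zero-variance %s vector(s) set to all-zeros",
            int(degenerate.sum()), "sample" if axis == "per_sample" else "gene",
        )
    sd = np.where(degenerate, 1.0, sd)
    out = (v - mean) / sd
    out = np.where(np.broadcast_to(degenerate, out.shape), 0.0, out)
    return ExpressionMatrix(
        list(X.gene_ids), list(X.sample_ids), out, labels=X.labels, batches=X.batches
    )


# -- model serialisation ------------------------------------------------------
#
# A model is a single JSON document with a schema-version tag.  Gene pairs are
# stored by gene ID, not matrix index, so a saved model applies to matrices
# with different gene orderings.


def save_model(model, path: str | Path) -> None:
    """Serialise a fitted :class:`~ranktype.refine.GERModel` to JSON."""
    doc = {"schema_version": MODEL_SCHEMA_VERSION, "model": model.to_dict()}
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model(path: str | Path):
    """Load a model saved by :func:`save_model`; version mismatch is an error."""
    from .refine import GERModel  # local import to avoid a module cycle

    try:
        doc = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise DataError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(doc, dict) or "schema_version" not in doc:
        raise DataError(f"model file {path} has no schema_version tag")
    if doc["schema_version"] != MODEL_SCHEMA_VERSION:
        raise DataError(
            f"model schema version {doc['schema_version']} != "
            f"supported {MODEL_SCHEMA_VERSION}"
        )
    model = GERModel.from_dict(doc["model"])
    empty = [s for s, feats in model.features.items() if not feats]
    if empty:
        logger.warning("loaded model has no features for subtype(s): %s", ", ".join(empty))
    return model
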