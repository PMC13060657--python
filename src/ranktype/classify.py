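"""Score samples against a fitted pair model and assign subtypes.

Prediction is a three-stage procedure: (a) restrict the input to the model's
gene universe and recompute intrasample ranks within it, (b) evaluate every
retained pair indicator and average them per subtype, (c) assign each sample
the subtype with the highest mean indicator score (ties broken by the model's
fixed subtype order, with a flag).

Because stage (a) ranks within the model's own gene universe, prediction only
needs those genes to be measured — inputs from platforms with different gene
sets remain comparable, and any strictly increasing per-sample distortion of
expression leaves scores and predictions unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import DataError, ExpressionMatrix
from .ranking import rank_transform
from .refine import GERModel

logger = logging.getLogger("ranktype")


@dataclass
class SubtypeScoreMatrix:
    """Samples x subtypes mean-indicator scores with argmax predictions."""

    sample_ids: list[str]
    subtypes: list[str]
    scores: np.ndarray
    predictions: list[str]
    tie_flags: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.scores, index=pd.Index(self.sample_ids, name="sample_id"),
                          columns=[f"score_{s}" for s in self.subtypes])
        df.insert(0, "predicted", self.predictions)
        df["tie_flag"] = self.tie_flags
        return df

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SubtypeScoreMatrix":
        subtypes = [c[len("score_"):] for c in df.columns if c.startswith("score_")]
        if not subtypes or "predicted" not in df.columns:
            raise DataError("prediction table lacks 'predicted'/'score_*' columns")
        tie = df["tie_flag"].astype(bool).to_numpy() if "tie_flag" in df.columns \
            else np.zeros(len(df), dtype=bool)
        return cls(
            sample_ids=[str(s) for s in df.index],
            subtypes=subtypes,
            scores=df[[f"score_{s}" for s in subtypes]].to_numpy(dtype=float),
            predictions=[str(p) for p in df["predicted"]],
            tie_flags=tie,
        )

    @classmethod
    def read_tsv(cls, path) -> "SubtypeScoreMatrix":
        return cls.from_frame(pd.read_csv(path, sep="\t", index_col=0))


def _usable_features(model: GERModel, present: set[str], max_missing_frac: float):
    """Per-subtype features evaluable with the available genes.

    Pairs touching a missing gene are skipped when they are at most
    ``max_missing_frac`` of a subtype's features; beyond that the input is
    considered incompatible with the model and a hard error names the genes.
    """
    usable = {}
    for s, feats in model.features.items():
        ok = [f for f in feats if f.gene_hi in present and f.gene_lo in present]
        if feats and len(ok) < len(feats):
            frac = 1 - len(ok) / len(feats)
            missing = sorted({g for f in feats for g in (f.gene_hi, f.gene_lo)} - present)
            if frac > max_missing_frac:
                raise DataError(
                    f"{frac:.1%} of subtype {s}'s features reference missing gene(s): "
                    f"{', '.join(missing[:20])}"
                )
            logger.warning(
                "predict: skipping %d/%d features of %s over missing genes",
                len(feats) - len(ok), len(feats), s,
            )
        usable[s] = ok
    return usable


def _score_ranks(rank_values: np.ndarray, gene_index: dict[str, int],
                 usable: dict[str, list]) -> tuple[np.ndarray, list[str]]:
    subtypes = list(usable.keys())
    n_samples = rank_values.shape[1]
    scores = np.zeros((n_samples, len(subtypes)))
    for k, s in enumerate(subtypes):
        feats = usable[s]
        if not feats:
            continue
        hi = np.array([gene_index[f.gene_hi] for f in feats], dtype=int)
        lo = np.array([gene_index[f.gene_lo] for f in feats], dtype=int)
        scores[:, k] = (rank_values[hi, :] > rank_values[lo, :]).mean(axis=0)
    return scores, subtypes


def _argmax_with_ties(scores: np.ndarray, subtypes: list[str],
                      eligible: np.ndarray) -> tuple[list[str], np.ndarray]:
    masked = np.where(eligible[None, :], scores, -np.inf)
    best = masked.max(axis=1)
    is_max = masked == best[:, None]
    tie_flags = is_max.sum(axis=1) >= 2
    picks = is_max.argmax(axis=1)  # first True in fixed subtype order
    return [subtypes[i] for i in picks], tie_flags


def predict(
    X: ExpressionMatrix,
    model: GERModel,
    rank_mode: str = "model_genes",
    max_missing_frac: float = 0.05,
) -> SubtypeScoreMatrix:
    """Score every sample of ``X`` against ``model`` and assign subtypes.

    ``rank_mode='model_genes'`` (default) recomputes ranks within the model's
    gene universe; ``'full'`` ranks within all genes of ``X`` (sensitivity
    analysis — scores are then relative to the input platform's gene set).
    """
    if rank_mode not in {"model_genes", "full"}:
        raise DataError(f"rank_mode must be 'model_genes' or 'full', got {rank_mode!r}")
    if model.n_features == 0:
        raise DataError("model has no features; cannot predict")
    present_all = set(X.gene_ids)
    usable = _usable_features(model, present_all, max_missing_frac)
    empty = [s for s, f in usable.items() if not f]
    if empty:
        logger.warning("predict: subtype(s) with no usable features never predicted: %s",
                       ", ".join(empty))

    if rank_mode == "model_genes":
        genes = [g for g in model.gene_universe if g in present_all]
        Xr = X.select_genes(genes)
    else:
        Xr = X
    R = rank_transform(Xr)
    gene_index = {g: i for i, g in enumerate(R.gene_ids)}
    scores, subtypes = _score_ranks(R.ranks, gene_index, usable)
    eligible = np.array([bool(usable[s]) for s in subtypes])
    predictions, tie_flags = _argmax_with_ties(scores, subtypes, eligible)
    if tie_flags.any():
        logger.warning("predict: %d sample(s) with tied top scores; broken by subtype order",
                       int(tie_flags.sum()))
    return SubtypeScoreMatrix(
        sample_ids=list(X.sample_ids), subtypes=subtypes, scores=scores,
        predictions=predictions, tie_flags=tie_flags,
    )


def score_sample(ranks, model: GERModel, max_missing_frac: float = 0.05) -> dict[str, float]:
    """Per-subtype mean indicator scores for one sample's rank vector.

    ``ranks`` maps gene ID -> intrasample rank (any consistent rank scale).
    """
    usable = _usable_features(model, set(ranks), max_missing_frac)
    out = {}
    for s, feats in usable.items():
        if not feats:
            out[s] = 0.0
            continue
        out[s] = float(np.mean([1.0 if ranks[f.gene_hi] > ranks[f.gene_lo] else 0.0
                                for f in feats]))
    return out
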