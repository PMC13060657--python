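"""Synthetic multi-batch expression cohorts with planted rank-reversal markers.

The generator emulates the structure of a multi-cohort tumor-subtyping study:
a four-class cohort with realistic class imbalance, subtype marker genes whose
intrasample rank is displaced up or down by a controlled amount, and per-batch
distortions of two kinds — a sample-level strictly increasing warp (which
changes absolute values but cannot change ranks) and gene-level additive batch
shifts (which genuinely perturb ranks).  The second kind is deliberate: purely
monotone distortions are provably invisible to a rank-pair classifier, so only
rank-perturbing batch noise makes held-out evaluation non-trivial.

The truth record (labels, batches, planted markers) suffices to compute recall
and precision of every pipeline stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_io import DataError, ExpressionMatrix, DEFAULT_SUBTYPES, write_expression

logger = logging.getLogger("ranktype")

#: Default class proportions: a large training-cohort composition where the
#: numerically designated groups dominate and WNT is rare (223:70:144:326).
DEFAULT_PROPORTIONS = (223, 70, 144, 326)


@dataclass
class BatchSpec:
    """One batch: sample count, monotone warp family, gene-level shift sd.

    ``warp`` is applied to the positive expression scale per sample and is
    strictly increasing (rank-preserving): ``identity``; ``affine`` (gain,
    offset with gain > 0); ``power`` (x**g, g > 0); ``log`` (log1p).
    ``shift_sd`` is the sd of per-(gene, batch) additive shifts on the log
    scale — the rank-perturbing component of the batch effect.
    """

    name: str
    n_samples: int
    warp: str = "identity"
    warp_params: tuple = ()
    shift_sd: float = 0.4

    def __post_init__(self) -> None:
        if self.warp not in {"identity", "affine", "power", "log"}:
            raise DataError(f"unknown warp family {self.warp!r}")
        if self.n_samples < 1:
            raise DataError(f"batch {self.name}: n_samples must be >= 1")
        if self.shift_sd < 0:
            raise DataError(f"batch {self.name}: shift_sd must be >= 0")
        if self.warp == "affine":
            gain = self.warp_params[0] if self.warp_params else None
            if gain is None or gain <= 0:
                raise DataError(f"batch {self.name}: affine warp needs gain > 0")
        if self.warp == "power":
            if not self.warp_params or self.warp_params[0] <= 0:
                raise DataError(f"batch {self.name}: power warp needs exponent > 0")

    def apply_warp(self, x: np.ndarray) -> np.ndarray:
        if self.warp == "identity":
            return x
        if self.warp == "affine":
            gain, offset = self.warp_params[0], (self.warp_params[1] if len(self.warp_params) > 1 else 0.0)
            return gain * x + offset
        if self.warp == "power":
            return x ** self.warp_params[0]
        return np.log1p(x)


def default_batches(n_samples: int, shift_sd: float = 0.4) -> list[BatchSpec]:
    """Three equal batches with distinct warp families (identity/affine/power)."""
    base = n_samples // 3
    sizes = [base, base, n_samples - 2 * base]
    warps = [("identity", ()), ("affine", (1.6, 3.0)), ("power", (0.7,))]
    return [
        BatchSpec(name=f"batch{i + 1}", n_samples=sz, warp=w, warp_params=p, shift_sd=shift_sd)
        for i, (sz, (w, p)) in enumerate(zip(sizes, warps))
    ]


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic cohort."""

    n_genes: int = 2000
    n_samples: int = 240
    proportions: tuple = DEFAULT_PROPORTIONS
    subtypes: tuple = DEFAULT_SUBTYPES
    markers_per_subtype: int = 40
    marker_shift: float = 0.2
    batches: list[BatchSpec] | None = None
    baseline_sd: float = 2.0
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.marker_shift < 0.5:
            raise DataError(f"marker_shift must be in (0, 0.5), got {self.marker_shift}")
        if len(self.proportions) != len(self.subtypes):
            raise DataError("proportions and subtypes must have equal length")
        if self.markers_per_subtype * len(self.subtypes) > self.n_genes:
            raise DataError(
                f"{self.markers_per_subtype} markers x {len(self.subtypes)} subtypes "
                f"exceed {self.n_genes} genes"
            )
        if self.batches is None:
            self.batches = default_batches(self.n_samples)
        total = sum(b.n_samples for b in self.batches)
        if total != self.n_samples:
            raise DataError(f"batch sizes sum to {total}, expected {self.n_samples}")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort."""

    labels: dict[str, str]
    batches: dict[str, str]
    markers: dict[str, dict[str, list[str]]]  # subtype -> {"up": [...], "down": [...]}

    def marker_genes(self, subtype: str) -> set[str]:
        m = self.markers[subtype]
        return set(m["up"]) | set(m["down"])

    def to_dict(self) -> dict:
        return {"labels": self.labels, "batches": self.batches, "markers": self.markers}


def _allocate_counts(n: int, proportions: np.ndarray) -> np.ndarray:
    """Largest-remainder allocation of n samples to classes; every class >= 1."""
    frac = proportions / proportions.sum()
    base = np.floor(frac * n).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(frac * n - base))
    base[order[:rem]] += 1
    # Guarantee presence of every class in every batch.
    while (base == 0).any():
        give = int(np.argmin(base))
        take = int(np.argmax(base))
        base[give] += 1
        base[take] -= 1
    return base


def generate(spec: SyntheticSpec) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Generate a cohort: lognormal baseline + planted marker shifts + batch effects.

    Marker shifts are calibrated on the rank scale: an up-marker's baseline
    log-mean is raised to the value at ``marker_shift * n_genes`` positions
    higher in the sorted baseline (down-markers symmetrically), so the target
    mean rank displacement is ``marker_shift`` as a fraction of the gene count
    at any ``n_genes``.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_genes, spec.n_samples
    subtypes = list(spec.subtypes)
    gene_ids = [f"G{i:05d}" for i in range(n)]

    mu = rng.normal(0.0, spec.baseline_sd, size=n)
    order = np.argsort(mu)
    position = np.empty(n, dtype=int)
    position[order] = np.arange(n)
    mu_sorted = mu[order]

    shift_steps = int(round(spec.marker_shift * n))
    band = (position >= shift_steps) & (position < n - shift_steps)
    eligible = np.nonzero(band)[0]
    need = spec.markers_per_subtype * len(subtypes)
    if len(eligible) < need:
        raise DataError(
            f"only {len(eligible)} genes have rank headroom for marker_shift="
            f"{spec.marker_shift}; need {need}"
        )
    chosen = rng.choice(eligible, size=need, replace=False)

    half = spec.markers_per_subtype // 2
    markers: dict[str, dict[str, list[str]]] = {}
    delta = np.zeros((n, len(subtypes)))
    for k, s in enumerate(subtypes):
        block = chosen[k * spec.markers_per_subtype:(k + 1) * spec.markers_per_subtype]
        up, down = block[:spec.markers_per_subtype - half], block[spec.markers_per_subtype - half:]
        for g in up:
            delta[g, k] = mu_sorted[min(position[g] + shift_steps, n - 1)] - mu[g]
        for g in down:
            delta[g, k] = mu_sorted[max(position[g] - shift_steps, 0)] - mu[g]
        markers[s] = {"up": [gene_ids[g] for g in up], "down": [gene_ids[g] for g in down]}

    sample_ids: list[str] = []
    labels: dict[str, str] = {}
    batch_of: dict[str, str] = {}
    label_idx: list[int] = []
    batch_cols: dict[str, list[int]] = {}
    props = np.asarray(spec.proportions, dtype=float)
    col = 0
    for b in spec.batches:
        counts = _allocate_counts(b.n_samples, props)
        batch_cols[b.name] = []
        for k, s in enumerate(subtypes):
            for _ in range(counts[k]):
                sid = f"{b.name}_S{col:04d}"
                sample_ids.append(sid)
                labels[sid] = s
                batch_of[sid] = b.name
                label_idx.append(k)
                batch_cols[b.name].append(col)
                col += 1
    label_idx_arr = np.array(label_idx)

    Z = mu[:, None] + delta[:, label_idx_arr]
    for b in spec.batches:
        cols = batch_cols[b.name]
        if b.shift_sd > 0:
            Z[:, cols] += rng.normal(0.0, b.shift_sd, size=n)[:, None]
    Z += rng.normal(0.0, spec.noise_sd, size=(n, m))
    X = np.exp(Z)
    for b in spec.batches:
        cols = batch_cols[b.name]
        X[:, cols] = b.apply_warp(X[:, cols])

    em = ExpressionMatrix(gene_ids, sample_ids, X, labels=labels, batches=batch_of)
    return em, SyntheticTruth(labels=labels, batches=batch_of, markers=markers)


def make_train_test(
    spec: SyntheticSpec, test_batches
) -> tuple[ExpressionMatrix, ExpressionMatrix, SyntheticTruth]:
    """Generate one cohort and split it into train/test by whole batches."""
    test_batches = set(test_batches)
    names = {b.name for b in spec.batches}
    unknown = sorted(test_batches - names)
    if unknown:
        raise DataError(f"unknown test batch(es): {', '.join(unknown)}")
    if not test_batches or test_batches == names:
        raise DataError("test_batches must be a proper non-empty subset of batches")
    X, truth = generate(spec)
    test_ids = [s for s in X.sample_ids if truth.batches[s] in test_batches]
    train_ids = [s for s in X.sample_ids if truth.batches[s] not in test_batches]
    return X.select_samples(train_ids), X.select_samples(test_ids), truth


def write_cohort(X: ExpressionMatrix, truth: SyntheticTruth, out_dir) -> dict[str, Path]:
    """Write expression TSV + label TSV + batch TSV + truth JSON for CLI use."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "labels": out / "labels.tsv",
        "batches": out / "batches.tsv",
        "truth": out / "truth.json",
    }
    write_expression(X, paths["expression"])
    with open(paths["labels"], "w") as fh:
        fh.write("sample_id\tsubtype\n")
        for s in X.sample_ids:
            fh.write(f"{s}\t{truth.labels[s]}\n")
    with open(paths["batches"], "w") as fh:
        fh.write("sample_id\tbatch\n")
        for s in X.sample_ids:
            fh.write(f"{s}\t{truth.batches[s]}\n")
    paths["truth"].write_text(json.dumps(truth.to_dict(), indent=1))
    return paths
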