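"""Elastic-net refinement of screened gene-pair features and model assembly.

The screened reversal pairs are pruned with penalized logistic regression:
minimize  mean binomial deviance/2  +  lambda * (alpha*||b||_1 + (1-alpha)/2*||b||_2^2)
over a descending lambda path, choosing lambda by the 1-SE rule from k-fold
cross-validated deviance (the sparsest model within one standard error of the
CV optimum).  One run per (subtype, other-subtype) comparison — 12 runs for a
four-subgroup model — and each subtype keeps the intersection of its three
selected sets.

Binary {0,1} indicator features share a common scale already, so no
standardization is applied before penalization.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
from numba import njit
from sklearn.model_selection import StratifiedKFold

from .data_io import DataError, SubtypeSet
from .ranking import RankMatrix, rank_transform, diff_rank_genes, subtype_signature_genes
from .reversal import GERFeature, ReversalThresholds, screen_gers

logger = logging.getLogger("ranktype")

_COEF_ZERO_TOL = 0.0  # saga's L1 prox produces exact zeros


@dataclass
class ElasticNetConfig:
    """Settings for one penalized-logistic selection run.

    ``alpha`` is the L1/L2 mixing parameter (0.1: mostly ridge with a sparse
    touch, keeping groups of correlated pairs together while still zeroing
    irrelevant ones).  The lambda path has ``n_lambda`` log-spaced values from
    the all-null lambda_max down ``lambda_decades`` decades.
    """

    alpha: float = 0.1
    n_folds: int = 10
    lambda_rule: str = "lambda_1se"  # or "lambda_min"
    seed: int = 0
    n_lambda: int = 100
    lambda_decades: float = 4.0
    cv_loss: str = "deviance"  # or "misclassification"
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise DataError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.n_folds < 2:
            raise DataError(f"n_folds must be >= 2, got {self.n_folds}")
        if self.lambda_rule not in {"lambda_1se", "lambda_min"}:
            raise DataError(f"unknown lambda_rule {self.lambda_rule!r}")
        if self.cv_loss not in {"deviance", "misclassification"}:
            raise DataError(f"unknown cv_loss {self.cv_loss!r}")


def _derive_seed(seed: int, *parts: str) -> int:
    """Stable per-run seed below 2**31, derived from a base seed and tags."""
    tag = ":".join(map(str, parts))
    return (int(seed) * 2654435761 + zlib.crc32(tag.encode())) % (2**31 - 1)


def lambda_path(X: np.ndarray, y: np.ndarray, cfg: ElasticNetConfig) -> np.ndarray:
    """Descending lambda grid starting at the smallest all-zero-coefficient lambda."""
    n = len(y)
    ybar = y.mean()
    # Smallest lambda at which the L1 subgradient condition zeroes every
    # coefficient of the (intercept-only) null model.
    grad = X.T @ (y - ybar) / n
    alpha = max(cfg.alpha, 1e-3)  # guard the ridge limit
    lam_max = np.abs(grad).max() / alpha
    if lam_max <= 0:
        lam_max = 1e-3
    return np.geomspace(lam_max, lam_max * 10.0 ** (-cfg.lambda_decades), cfg.n_lambda)


@njit(cache=True)
def _cd_path_kernel(X, y, lambdas, alpha, tol):  # pragma: no cover - jitted
    """Warm-started IRLS + cyclic coordinate descent over a descending
    lambda path.

    Minimizes (1/n)*binomial negative log-likelihood + lam*(alpha*||b||_1 +
    (1-alpha)/2*||b||_2^2) with an unpenalized intercept.  Each IRLS step
    solves its penalized weighted least-squares subproblem by coordinate
    descent with soft-thresholding, which yields exact zeros.
    """
    n, p = X.shape
    L = lambdas.shape[0]
    coefs = np.zeros((L, p))
    intercepts = np.zeros(L)
    beta = np.zeros(p)
    ybar = y.mean()
    if ybar < 1e-12:
        ybar = 1e-12
    if ybar > 1.0 - 1e-12:
        ybar = 1.0 - 1e-12
    b0 = np.log(ybar / (1.0 - ybar))
    eta = np.full(n, b0)
    for k in range(L):
        lam = lambdas[k]
        thr = lam * alpha
        for _irls in range(50):
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = mu * (1.0 - mu)
            for i in range(n):
                if w[i] < 1e-5:
                    w[i] = 1e-5
            z = eta + (y - mu) / w
            wx2 = np.zeros(p)
            for j in range(p):
                s = 0.0
                for i in range(n):
                    s += w[i] * X[i, j] * X[i, j]
                wx2[j] = s / n
            wsum = w.sum() / n
            r = z - eta
            outer_delta = 0.0
            for _sweep in range(1000):
                delta_max = 0.0
                num0 = 0.0
                for i in range(n):
                    num0 += w[i] * r[i]
                shift = num0 / n / wsum
                b0 += shift
                for i in range(n):
                    r[i] -= shift
                if abs(shift) > delta_max:
                    delta_max = abs(shift)
                for j in range(p):
                    bj = beta[j]
                    num = 0.0
                    for i in range(n):
                        num += w[i] * X[i, j] * r[i]
                    num = num / n + wx2[j] * bj
                    if num > thr:
                        bj_new = (num - thr) / (wx2[j] + lam * (1.0 - alpha))
                    elif num < -thr:
                        bj_new = (num + thr) / (wx2[j] + lam * (1.0 - alpha))
                    else:
                        bj_new = 0.0
                    if bj_new != bj:
                        d = bj - bj_new
                        for i in range(n):
                            r[i] += X[i, j] * d
                        beta[j] = bj_new
                        if abs(d) > delta_max:
                            delta_max = abs(d)
                if outer_delta < delta_max:
                    outer_delta = delta_max
                if delta_max < tol:
                    break
            eta = z - r
            if outer_delta < 10.0 * tol:
                break
        coefs[k] = beta
        intercepts[k] = b0
    return coefs, intercepts


def _fit_path(
    X: np.ndarray, y: np.ndarray, lambdas: np.ndarray, cfg: ElasticNetConfig, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Coefficients (len(lambdas) x n_features) and intercepts along a
    descending, warm-started lambda path.  Fully deterministic; ``seed`` is
    accepted for interface stability but unused."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    lambdas = np.asarray(lambdas, dtype=np.float64)
    return _cd_path_kernel(X, y, lambdas, float(cfg.alpha), float(cfg.tol))


def _deviance(p: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


@dataclass
class SelectionResult:
    """Outcome of one elastic-net selection run."""

    selected: np.ndarray          # indices with nonzero coefficient at chosen lambda
    coefficients: np.ndarray      # coefficients of the selected features
    lambdas: np.ndarray
    cv_mean: np.ndarray
    cv_se: np.ndarray
    lambda_index: int

    @property
    def chosen_lambda(self) -> float:
        return float(self.lambdas[self.lambda_index])


def elastic_net_select(
    X: np.ndarray, y: np.ndarray, cfg: ElasticNetConfig
) -> SelectionResult:
    """Select informative feature columns by the cross-validated 1-SE rule.

    ``X`` is a samples x features (binary indicator) matrix and ``y`` a binary
    label vector.  Fold assignment is stratified and derived deterministically
    from ``cfg.seed``; when a class has fewer members than ``n_folds`` the fold
    count degrades to the minority class size (with a warning).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != len(y):
        raise DataError(f"X shape {X.shape} incompatible with y length {len(y)}")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise DataError("y has a single class; logistic selection undefined")
    if counts.min() < 2:
        raise DataError(f"each class needs >= 2 samples, got counts {dict(zip(classes, counts))}")

    # Constant columns carry no information; with an unpenalized intercept
    # their optimal penalized coefficient is exactly zero, so exclude them
    # outright (exactness regardless of solver tolerance).
    variable = X.min(axis=0) != X.max(axis=0)
    Xv = X[:, variable]
    var_idx = np.nonzero(variable)[0]
    if Xv.shape[1] == 0:
        logger.warning("elastic_net_select: all features constant; nothing selectable")
        return SelectionResult(
            np.array([], dtype=int), np.array([]), np.array([1.0]),
            np.array([np.nan]), np.array([np.nan]), 0,
        )

    n_folds = cfg.n_folds
    if counts.min() < n_folds:
        n_folds = max(2, int(counts.min()))
        logger.warning(
            "elastic_net_select: fold count reduced to %d (minority class size)", n_folds
        )

    lambdas = lambda_path(Xv, y, cfg)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=cfg.seed % (2**31 - 1))
    fold_loss = np.empty((n_folds, len(lambdas)))
    for f, (tr, va) in enumerate(skf.split(Xv, y)):
        coefs, intercepts = _fit_path(Xv[tr], y[tr], lambdas, cfg, _derive_seed(cfg.seed, "fold", f))
        logits = Xv[va] @ coefs.T + intercepts
        p = 1.0 / (1.0 + np.exp(-logits))
        if cfg.cv_loss == "deviance":
            pc = np.clip(p, 1e-12, 1 - 1e-12)
            yv = y[va][:, None]
            fold_loss[f] = (-2.0 * (yv * np.log(pc) + (1 - yv) * np.log(1 - pc))).mean(axis=0)
        else:
            fold_loss[f] = ((p >= 0.5).astype(float) != y[va][:, None]).mean(axis=0)
    cv_mean = fold_loss.mean(axis=0)
    cv_se = fold_loss.std(axis=0, ddof=1) / np.sqrt(n_folds)

    k_min = int(np.argmin(cv_mean))
    if cfg.lambda_rule == "lambda_min":
        k_sel = k_min
    else:
        bound = cv_mean[k_min] + cv_se[k_min]
        # lambdas descend, so the first index within the bound is the largest lambda.
        k_sel = int(np.nonzero(cv_mean <= bound)[0][0])

    full_coefs, _ = _fit_path(Xv, y, lambdas[: k_sel + 1], cfg, _derive_seed(cfg.seed, "full"))
    beta = full_coefs[k_sel]
    nz = np.abs(beta) > _COEF_ZERO_TOL
    return SelectionResult(
        selected=var_idx[nz],
        coefficients=beta[nz],
        lambdas=lambdas,
        cv_mean=cv_mean,
        cv_se=cv_se,
        lambda_index=k_sel,
    )


@dataclass
class GERModel:
    """Fitted classifier: per-subtype oriented pair features plus configuration."""

    subtypes: SubtypeSet
    features: dict[str, list[GERFeature]]
    gene_universe: list[str]
    configs: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        universe = set(self.gene_universe)
        for s, feats in self.features.items():
            for f in feats:
                if f.gene_hi not in universe or f.gene_lo not in universe:
                    raise DataError(
                        f"feature ({f.gene_hi}, {f.gene_lo}) outside gene universe"
                    )

    @property
    def n_features(self) -> int:
        return sum(len(v) for v in self.features.values())

    def to_dict(self) -> dict:
        return {
            "subtypes": list(self.subtypes.names),
            "features": {s: [f.to_dict() for f in feats] for s, feats in self.features.items()},
            "gene_universe": list(self.gene_universe),
            "configs": self.configs,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GERModel":
        return cls(
            subtypes=SubtypeSet(tuple(d["subtypes"])),
            features={s: [GERFeature.from_dict(f) for f in feats]
                      for s, feats in d["features"].items()},
            gene_universe=list(d["gene_universe"]),
            configs=dict(d.get("configs", {})),
            provenance=dict(d.get("provenance", {})),
        )


def _indicator_matrix(R: RankMatrix, features: Sequence[GERFeature]) -> np.ndarray:
    """Samples x features binary indicator matrix for a list of pairs."""
    gene_index = {g: i for i, g in enumerate(R.gene_ids)}
    hi = np.array([gene_index[f.gene_hi] for f in features], dtype=int)
    lo = np.array([gene_index[f.gene_lo] for f in features], dtype=int)
    return (R.ranks[hi, :] > R.ranks[lo, :]).T.astype(float)


def build_model(
    R: RankMatrix,
    labels,
    screened: Mapping[str, Sequence[GERFeature]],
    cfg: ElasticNetConfig,
    subtypes: SubtypeSet | None = None,
    configs: Mapping | None = None,
    provenance: Mapping | None = None,
) -> GERModel:
    """Refine screened pairs per subtype and assemble the final model.

    For each subtype S and each other subtype O, the run restricts samples to
    S u O with y = [sample in S] and features = S's screened pair indicators;
    S's final features are the pairs selected in all of its comparisons.  The
    stored coefficient is the mean of a feature's (nonzero) coefficients
    across the runs that selected it; scoring does not use coefficients, they
    are reported for inspection only.
    """
    if subtypes is None:
        present = tuple(sorted({v for v in labels.values()}))
        subtypes = SubtypeSet() if set(present) == {"SHH", "WNT", "Group3", "Group4"} \
            else SubtypeSet(present)
    cols: dict[str, np.ndarray] = {}
    for s in subtypes:
        cols[s] = np.array([i for i, sid in enumerate(R.sample_ids) if labels.get(sid) == s], dtype=int)
        if len(cols[s]) < 2:
            raise DataError(f"subtype {s!r} has {len(cols[s])} labelled sample(s); need >= 2")

    final: dict[str, list[GERFeature]] = {}
    for s in subtypes:
        feats = list(screened.get(s, []))
        if not feats:
            logger.warning("build_model: no screened pairs for %s; empty feature list", s)
            final[s] = []
            continue
        ind = _indicator_matrix(R, feats)  # all samples x pairs
        keep: np.ndarray | None = None
        coef_sum = np.zeros(len(feats))
        coef_cnt = np.zeros(len(feats))
        for o in subtypes.others(s):
            rows = np.concatenate([cols[s], cols[o]])
            y = np.concatenate([np.ones(len(cols[s])), np.zeros(len(cols[o]))])
            run_cfg = ElasticNetConfig(**{**asdict(cfg), "seed": _derive_seed(cfg.seed, s, o)})
            res = elastic_net_select(ind[rows], y, run_cfg)
            sel = np.zeros(len(feats), dtype=bool)
            sel[res.selected] = True
            coef_sum[res.selected] += res.coefficients
            coef_cnt[res.selected] += 1
            keep = sel if keep is None else (keep & sel)
            logger.info("build_model: %s vs %s selected %d / %d pairs (lambda=%.4g)",
                        s, o, len(res.selected), len(feats), res.chosen_lambda)
        kept_idx = np.nonzero(keep)[0]
        final[s] = []
        for k in kept_idx:
            f = feats[k]
            final[s].append(GERFeature(
                gene_hi=f.gene_hi, gene_lo=f.gene_lo, subtype=f.subtype,
                ratios=dict(f.ratios), pvalues=dict(f.pvalues),
                coefficient=float(coef_sum[k] / coef_cnt[k]),
            ))
        if not final[s]:
            logger.warning("build_model: empty selection intersection for %s", s)

    universe = sorted({g for feats in final.values() for f in feats for g in (f.gene_hi, f.gene_lo)})
    prov = dict(provenance or {})
    prov.setdefault("n_genes", R.n_genes)
    prov.setdefault("n_samples", len(R.sample_ids))
    prov.setdefault("label_counts", {s: int(len(cols[s])) for s in subtypes})
    return GERModel(
        subtypes=subtypes,
        features=final,
        gene_universe=universe,
        configs=dict(configs or {}),
        provenance=prov,
    )


@dataclass
class FitResult:
    """Full training run: the model, per-stage accounting, signature genes."""

    model: GERModel
    stage_counts: dict
    signatures: dict[str, set] = field(default_factory=dict)


def fit_pipeline(
    X,
    labels,
    subtypes: SubtypeSet | None = None,
    rank_frac: float = 0.11,
    diff_alpha: float = 0.05,
    thresholds: ReversalThresholds | None = None,
    screen_alpha: float = 0.05,
    enet: ElasticNetConfig | None = None,
) -> FitResult:
    """Run the full training workflow: ranks -> signatures -> screening -> refinement.

    ``X`` is an :class:`~ranktype.data_io.ExpressionMatrix` whose ``labels``
    (or the ``labels`` argument) assign each training sample a subtype.
    """
    labels = dict(labels if labels is not None else (X.labels or {}))
    if not labels:
        raise DataError("no training labels provided")
    if subtypes is None:
        present = tuple(sorted(set(labels.values())))
        subtypes = SubtypeSet() if set(present) == {"SHH", "WNT", "Group3", "Group4"} \
            else SubtypeSet(present)
    unknown = sorted(set(labels.values()) - set(subtypes.names))
    if unknown:
        raise DataError(f"label(s) outside the subtype set: {', '.join(unknown)}")
    missing_subtypes = [s for s in subtypes if s not in set(labels.values())]
    if missing_subtypes:
        raise DataError(f"no samples labelled for subtype(s): {', '.join(missing_subtypes)}")
    if thresholds is None:
        thresholds = ReversalThresholds.default(subtypes) \
            if set(subtypes.names) == {"SHH", "WNT", "Group3", "Group4"} \
            else ReversalThresholds.uniform(subtypes, 0.9)
    enet = enet or ElasticNetConfig()

    R = rank_transform(X)
    stage: dict = {"n_genes": X.n_genes, "n_samples": X.n_samples}

    diff: dict[str, list] = {s: [] for s in subtypes}
    diff_counts = {}
    for s in subtypes:
        for o in subtypes.others(s):
            r = diff_rank_genes(R, labels, s, o, rank_frac=rank_frac, alpha=diff_alpha)
            diff[s].append(r)
            diff_counts[f"{s} vs {o}"] = {"up": len(r.up_genes), "down": len(r.down_genes)}
    stage["diff_rank"] = diff_counts

    signatures = {s: subtype_signature_genes(diff[s], s) for s in subtypes}
    stage["signature_genes"] = {s: len(g) for s, g in signatures.items()}

    screened = {
        s: screen_gers(R, labels, s, signatures[s], thresholds,
                       subtypes=subtypes, alpha=screen_alpha)
        for s in subtypes
    }
    stage["screened_pairs"] = {s: len(v) for s, v in screened.items()}

    configs = {
        "rank_frac": rank_frac, "diff_alpha": diff_alpha,
        "screen_alpha": screen_alpha, "thresholds": thresholds.to_dict(),
        "elastic_net": asdict(enet),
    }
    model = build_model(R, labels, screened, enet, subtypes=subtypes, configs=configs)
    stage["final_pairs"] = {s: len(v) for s, v in model.features.items()}
    stage["final_pairs_total"] = model.n_features
    stage["unique_genes"] = len(model.gene_universe)
    logger.info("fit_pipeline: stage counts %s", stage)
    return FitResult(model=model, stage_counts=stage, signatures=signatures)
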