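"""Gene-pair reversal features: indicator encoding, reversal ratio, Fisher
screening.

For an ordered gene pair (i, j) and a sample with ranks Ti, Tj the indicator
is 1 if Ti > Tj and 0 otherwise (ties fall in the 0 branch).  A pair is a
subtype-specific "reversal" feature when the indicator is predominantly 1 in
the selected subtype and predominantly 0 in a comparison subtype — quantified
by the reversal ratio (f11 + f22) / t of the 2x2 sample-count table — and the
association is significant by a two-sided Fisher exact test.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .data_io import DataError, SubtypeSet
from .ranking import RankMatrix

logger = logging.getLogger("ranktype")

#: Relative tolerance used when comparing hypergeometric point probabilities
#: for the two-sided Fisher rule; absorbs floating-point noise in exact ties.
_FISHER_RELATIVE_GATE = 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 sample-count table: rows (selected, rest) x columns (Ti>Tj, Ti<=Tj)."""

    f11: int
    f12: int
    f21: int
    f22: int

    def __post_init__(self) -> None:
        cells = (self.f11, self.f12, self.f21, self.f22)
        if any(c < 0 or c != int(c) for c in cells):
            raise DataError(f"contingency cells must be non-negative integers: {cells}")
        if sum(cells) <= 0:
            raise DataError("contingency table is empty (t = 0)")

    @property
    def t(self) -> int:
        return self.f11 + self.f12 + self.f21 + self.f22


def ger_indicator(ti: float, tj: float) -> int:
    """Indicator for the oriented pair: 1 iff ti strictly outranks tj."""
    return 1 if ti > tj else 0


def reversal_ratio(ct: ContingencyTable) -> float:
    """Fraction of samples agreeing with the subtype-characteristic orientation."""
    return (ct.f11 + ct.f22) / ct.t


def enumerate_pairs(genes: Iterable[str]) -> list[tuple[str, str]]:
    """All n(n-1)/2 unordered gene pairs, in lexicographic order."""
    ordered = sorted(set(genes))
    if len(ordered) < 2:
        raise DataError(f"need at least 2 genes to form pairs, got {len(ordered)}")
    return list(itertools.combinations(ordered, 2))


def fisher_p_many(
    f11: np.ndarray, f12: np.ndarray, f21: np.ndarray, f22: np.ndarray
) -> np.ndarray:
    """Vectorised two-sided Fisher exact p for arrays of 2x2 tables.

    Two-sided by the point-probability rule: with all margins fixed, sum the
    hypergeometric probabilities of every table whose point probability does
    not exceed that of the observed table (up to a tiny relative tolerance for
    floating-point ties).  Screening evaluates ~1e5-1e6 tables that share row
    margins, so tables are grouped by their margin triple and each group's
    hypergeometric support is enumerated once.
    """
    f11 = np.asarray(f11, dtype=int).ravel()
    f12 = np.asarray(f12, dtype=int).ravel()
    f21 = np.asarray(f21, dtype=int).ravel()
    f22 = np.asarray(f22, dtype=int).ravel()
    if np.any((f11 < 0) | (f12 < 0) | (f21 < 0) | (f22 < 0)):
        raise DataError("contingency cells must be non-negative")
    t = f11 + f12 + f21 + f22
    if np.any(t <= 0):
        raise DataError("contingency table is empty (t = 0)")
    n1 = f11 + f12          # selected-subtype samples
    K = f11 + f21           # column margin for indicator 1
    out = np.empty(len(f11), dtype=float)

    keys = np.stack([t, n1, K], axis=1)
    uniq, inverse = np.unique(keys, axis=0, return_inverse=True)
    for g, (tg, n1g, Kg) in enumerate(uniq):
        members = np.nonzero(inverse == g)[0]
        lo = max(0, Kg - (tg - n1g))
        hi = min(Kg, n1g)
        support = np.arange(lo, hi + 1)
        pmf = stats.hypergeom.pmf(support, tg, Kg, n1g)
        order = np.argsort(pmf, kind="stable")
        csum = np.cumsum(pmf[order])
        p_obs = pmf[f11[members] - lo]
        pos = np.searchsorted(pmf[order], p_obs * (1.0 + _FISHER_RELATIVE_GATE), side="right")
        out[members] = np.minimum(csum[pos - 1], 1.0)
    return out


def fisher_p(ct: ContingencyTable) -> float:
    """Two-sided Fisher exact p-value for one 2x2 table."""
    return float(fisher_p_many(
        np.array([ct.f11]), np.array([ct.f12]), np.array([ct.f21]), np.array([ct.f22])
    )[0])


@dataclass
class ReversalThresholds:
    """Minimum reversal ratio per ordered (selected, rest) subtype comparison.

    The defaults encode the asymmetric stringency of the four-subgroup design:
    0.95 for the six comparisons selecting SHH or WNT (cleanly separable
    subgroups), 0.90 for Group3/Group4 vs SHH, 0.85 for Group3/Group4 vs WNT
    and Group4 vs Group3, and 0.80 for Group3 vs Group4 (the hardest,
    molecularly closest comparison).
    """

    thresholds: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        for pair, v in self.thresholds.items():
            if not 0.5 < v <= 1.0:
                raise DataError(f"threshold for {pair} must be in (0.5, 1], got {v}")

    def get(self, selected: str, rest: str) -> float:
        try:
            return self.thresholds[(selected, rest)]
        except KeyError:
            raise DataError(f"no reversal threshold for comparison ({selected}, {rest})")

    @classmethod
    def default(cls, subtypes: SubtypeSet | Sequence[str] = ("SHH", "WNT", "Group3", "Group4")) -> "ReversalThresholds":
        names = tuple(subtypes.names if isinstance(subtypes, SubtypeSet) else subtypes)
        if set(names) != {"SHH", "WNT", "Group3", "Group4"}:
            raise DataError(
                "default thresholds are defined for the SHH/WNT/Group3/Group4 "
                "subgroups; use ReversalThresholds.uniform() for other sets"
            )
        thr: dict[tuple[str, str], float] = {}
        for sel in names:
            for rest in names:
                if sel == rest:
                    continue
                if sel in ("SHH", "WNT"):
                    thr[(sel, rest)] = 0.95
                elif rest == "SHH":
                    thr[(sel, rest)] = 0.90
                elif rest == "WNT":
                    thr[(sel, rest)] = 0.85
                elif (sel, rest) == ("Group4", "Group3"):
                    thr[(sel, rest)] = 0.85
                else:  # (Group3, Group4)
                    thr[(sel, rest)] = 0.80
        return cls(thr)

    @classmethod
    def uniform(cls, subtypes: SubtypeSet | Sequence[str], value: float) -> "ReversalThresholds":
        names = tuple(subtypes.names if isinstance(subtypes, SubtypeSet) else subtypes)
        return cls({(a, b): value for a in names for b in names if a != b})

    def to_dict(self) -> dict[str, float]:
        return {f"{a}|{b}": v for (a, b), v in self.thresholds.items()}

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "ReversalThresholds":
        return cls({tuple(k.split("|", 1)): float(v) for k, v in d.items()})


@dataclass
class GERFeature:
    """One oriented gene pair characteristic of a subtype.

    Orientation convention: rank(gene_hi) > rank(gene_lo) is the pattern that
    votes FOR the subtype (indicator 1).  ``ratios`` and ``pvalues`` map each
    comparison subtype to the screening reversal ratio / Fisher p in this
    orientation; ``coefficient`` is filled in by elastic-net refinement.
    """

    gene_hi: str
    gene_lo: str
    subtype: str
    ratios: dict[str, float] = field(default_factory=dict)
    pvalues: dict[str, float] = field(default_factory=dict)
    coefficient: float | None = None

    def __post_init__(self) -> None:
        if self.gene_hi == self.gene_lo:
            raise DataError(f"degenerate pair ({self.gene_hi}, {self.gene_lo})")

    def to_dict(self) -> dict:
        return {
            "gene_hi": self.gene_hi, "gene_lo": self.gene_lo, "subtype": self.subtype,
            "ratios": self.ratios, "pvalues": self.pvalues, "coefficient": self.coefficient,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GERFeature":
        return cls(
            gene_hi=d["gene_hi"], gene_lo=d["gene_lo"], subtype=d["subtype"],
            ratios=dict(d.get("ratios", {})), pvalues=dict(d.get("pvalues", {})),
            coefficient=d.get("coefficient"),
        )


def screen_gers(
    R: RankMatrix,
    labels,
    subtype: str,
    signature_genes: Iterable[str],
    thresholds: ReversalThresholds,
    subtypes: SubtypeSet | None = None,
    alpha: float = 0.05,
    strict: bool = False,
    chunk_size: int = 100_000,
) -> list[GERFeature]:
    """Screen subtype-specific reversal pairs among the signature genes.

    Every unordered pair of signature genes is tested against each other
    subtype.  A pair passes a comparison, in a given orientation, when its
    reversal ratio meets that comparison's threshold (>= by default) and the
    Fisher exact p is below ``alpha``.  A pair is retained only if one
    orientation passes all comparisons; pairs whose passing orientation
    conflicts across comparisons are discarded.  Pair iteration is chunked
    (``chunk_size`` pairs at a time) with output identical to full enumeration.
    """
    if subtypes is None:
        present = sorted({v for v in labels.values()})
        if subtype not in present:
            raise DataError(f"subtype {subtype!r} has no labelled samples")
        subtypes = SubtypeSet(tuple(present)) if set(present) != {"SHH", "WNT", "Group3", "Group4"} \
            else SubtypeSet()
    others = subtypes.others(subtype)

    sig = sorted(set(signature_genes))
    if len(sig) < 2:
        logger.warning(
            "screen_gers: %d signature gene(s) for %s; no pairs to screen",
            len(sig), subtype,
        )
        return []
    gene_index = {g: i for i, g in enumerate(R.gene_ids)}
    missing = [g for g in sig if g not in gene_index]
    if missing:
        raise DataError(f"signature gene(s) not in rank matrix: {', '.join(missing[:10])}")
    sub = R.ranks[[gene_index[g] for g in sig], :]

    groups: dict[str, np.ndarray] = {}
    for s in (subtype, *others):
        cols = np.array([i for i, sid in enumerate(R.sample_ids) if labels.get(sid) == s], dtype=int)
        if len(cols) < 1:
            raise DataError(f"subtype {s!r} has no samples in the rank matrix")
        groups[s] = cols
    n_sel = len(groups[subtype])

    pairs = enumerate_pairs(sig)
    pos = {g: i for i, g in enumerate(sig)}
    idx_i = np.array([pos[a] for a, _ in pairs], dtype=int)
    idx_j = np.array([pos[b] for _, b in pairs], dtype=int)

    features: list[GERFeature] = []
    for start in range(0, len(pairs), chunk_size):
        sl = slice(start, min(start + chunk_size, len(pairs)))
        ci, cj = idx_i[sl], idx_j[sl]
        m = len(ci)
        # Per-orientation pass masks and per-comparison stats.
        pass_fwd = np.ones(m, dtype=bool)   # orientation: rank(i) > rank(j) in subtype
        pass_rev = np.ones(m, dtype=bool)
        stats_fwd: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        stats_rev: dict[str, tuple[np.ndarray, np.ndarray]] = {}

        gt = {}
        lt = {}
        for s, cols in groups.items():
            a = sub[ci][:, cols]
            b = sub[cj][:, cols]
            gt[s] = (a > b).sum(axis=1)   # indicator 1 counts, forward orientation
            lt[s] = (b > a).sum(axis=1)   # indicator 1 counts, reverse orientation
        for other in others:
            n_oth = len(groups[other])
            t = n_sel + n_oth
            thr = thresholds.get(subtype, other)
            for orient, counts, (passes, stash) in (
                ("fwd", gt, (pass_fwd, stats_fwd)),
                ("rev", lt, (pass_rev, stats_rev)),
            ):
                f11 = counts[subtype]
                f21 = counts[other]
                ratio = (f11 + (n_oth - f21)) / t
                ok = ratio > thr if strict else ratio >= thr
                p = np.ones(m, dtype=float)
                if ok.any():
                    p[ok] = fisher_p_many(
                        f11[ok], n_sel - f11[ok], f21[ok], n_oth - f21[ok]
                    )
                ok &= p < alpha
                passes &= ok
                stash[other] = (ratio, p)

        conflict = pass_fwd & pass_rev
        if conflict.any():  # unreachable for thresholds > 0.5 without ties
            logger.warning("screen_gers: %d pair(s) passed in both orientations; kept forward", int(conflict.sum()))
            pass_rev &= ~conflict
        for k in np.nonzero(pass_fwd)[0]:
            features.append(GERFeature(
                gene_hi=sig[ci[k]], gene_lo=sig[cj[k]], subtype=subtype,
                ratios={o: float(stats_fwd[o][0][k]) for o in others},
                pvalues={o: float(stats_fwd[o][1][k]) for o in others},
            ))
        for k in np.nonzero(pass_rev)[0]:
            features.append(GERFeature(
                gene_hi=sig[cj[k]], gene_lo=sig[ci[k]], subtype=subtype,
                ratios={o: float(stats_rev[o][0][k]) for o in others},
                pvalues={o: float(stats_rev[o][1][k]) for o in others},
            ))
    logger.info("screen_gers: %s retained %d / %d candidate pairs", subtype, len(features), len(pairs))
    return features


def features_to_frame(features: Sequence[GERFeature]):
    """Tabulate screened/refined features for TSV export."""
    import pandas as pd

    rows = []
    for f in features:
        row = {"subtype": f.subtype, "gene_hi": f.gene_hi, "gene_lo": f.gene_lo,
               "coefficient": f.coefficient}
        for o, r in sorted(f.ratios.items()):
            row[f"ratio_vs_{o}"] = r
        for o, p in sorted(f.pvalues.items()):
            row[f"p_vs_{o}"] = p
        rows.append(row)
    return pd.DataFrame(rows)
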