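"""Inter-method agreement statistics for paired immunohistochemistry scores.

Implements the statistical framework used to compare visual, digital and
hyperspectral scoring of the same cores: Cohen's kappa on dichotomised
scores (with the Landis-Koch interpretation bands), Spearman rank
correlation on the raw scores, the exact two-sided Wilcoxon signed-rank test
for paired differences, and a Shapiro-Wilk normality gate (reported only;
the non-parametric suite always runs regardless).

Dichotomisation rules: Allred totals split at 6/7 (LOW = 0-6, HIGH = 7-8);
H-scores split at the pooled mean over all methods and cases (HIGH strictly
above the mean).

The exact Wilcoxon null distribution is obtained by convolving the
sign-assignment distribution of the (tie-averaged) ranks — numerically
identical to enumerating all 2^n sign patterns, but usable at n well beyond
enumeration range. Zero differences are dropped (classical convention).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Dichotomy",
    "PairedScores",
    "ConcordanceReport",
    "cohen_kappa",
    "kappa_band",
    "agreement_table",
    "dichotomise_allred",
    "dichotomise_hscore",
    "spearman_rho",
    "wilcoxon_signed_rank",
    "shapiro_wilk",
    "build_report",
]


class Dichotomy(IntEnum):
    """Binary score category; integer codes follow the 1 = low, 2 = high convention."""

    LOW = 1
    HIGH = 2


#: Landis-Koch interpretation bands, upper-inclusive on kappa.
_KAPPA_BANDS = (
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (np.inf, "near-perfect"),
)


def kappa_band(kappa: float) -> str:
    if kappa < 0:
        return "poor"
    for upper, name in _KAPPA_BANDS:
        if kappa <= upper:
            return name
    raise AssertionError("unreachable")


def cohen_kappa(table: np.ndarray) -> tuple[float, str]:
    """Chance-corrected agreement kappa = (Po - Pe) / (1 - Pe) from a contingency table.

    Rows are rater A's categories, columns rater B's. Degenerate rule: when
    the expected agreement Pe equals 1, kappa is 1 if the observed agreement
    is also 1, else 0.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] != table.shape[1]:
        raise ValueError("agreement table must be square")
    if (table < 0).any():
        raise ValueError("agreement table counts must be non-negative")
    total = table.sum()
    if total <= 0:
        raise ValueError("agreement table must contain at least one observation")
    po = np.trace(table) / total
    pe = float(np.sum(table.sum(axis=1) * table.sum(axis=0)) / total**2)
    if pe >= 1.0 - 1e-12:
        kappa = 1.0 if po >= 1.0 - 1e-12 else 0.0
    else:
        kappa = (po - pe) / (1.0 - pe)
    return float(kappa), kappa_band(float(kappa))


def agreement_table(a, b, categories=None) -> np.ndarray:
    """Contingency counts between two categorical vectors."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("category vectors must have equal length")
    if categories is None:
        categories = np.unique(np.concatenate([a, b]))
    k = len(categories)
    index = {c: i for i, c in enumerate(categories)}
    table = np.zeros((k, k), dtype=int)
    for ai, bi in zip(a, b):
        table[index[ai], index[bi]] += 1
    return table


def dichotomise_allred(score: int) -> Dichotomy:
    """Allred totals 0-6 are LOW, 7-8 HIGH."""
    if not float(score).is_integer() or not 0 <= score <= 8:
        raise ValueError("Allred total must be an integer in 0..8")
    return Dichotomy.LOW if score <= 6 else Dichotomy.HIGH


def dichotomise_hscore(
    values: dict[str, np.ndarray], pooling: str = "pooled_all"
) -> dict[str, np.ndarray]:
    """Split H-scores at the mean; HIGH strictly above the threshold.

    ``pooling="pooled_all"`` (default) thresholds at the mean over all
    methods and cases jointly; ``"per_method"`` uses each method's own mean.
    """
    if pooling not in ("pooled_all", "per_method"):
        raise ValueError(f"unknown pooling '{pooling}'")
    if not values or any(len(np.atleast_1d(v)) == 0 for v in values.values()):
        raise ValueError("no H-score values to dichotomise")
    arrays = {m: np.asarray(v, dtype=float) for m, v in values.items()}
    if pooling == "pooled_all":
        threshold = np.concatenate(list(arrays.values())).mean()
        thresholds = {m: threshold for m in arrays}
    else:
        thresholds = {m: v.mean() for m, v in arrays.items()}
    return {
        m: np.where(v > thresholds[m], int(Dichotomy.HIGH), int(Dichotomy.LOW))
        for m, v in arrays.items()
    }


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) and its p-value.

    Returns (nan, nan) when either vector has zero rank variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("spearman_rho needs two equal-length vectors, n >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def _signed_rank_setup(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    d = x - y
    d = d[d != 0]  # classical zero-difference drop
    return d


def wilcoxon_signed_rank(x, y, mode: str = "exact") -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Returns (statistic, p) where the statistic is min(W+, W-), the smaller
    of the positive- and negative-difference rank sums. Zero differences are
    dropped; if all differences are zero the degenerate convention
    (statistic 0, p = 1) applies. ``mode="exact"`` computes the p-value from
    the exact sign-assignment distribution of the observed (tie-averaged)
    ranks; ``mode="normal_approx"`` uses the large-sample normal
    approximation with tie correction.
    """
    if mode not in ("exact", "normal_approx"):
        raise ValueError(f"unknown mode '{mode}'")
    d = _signed_rank_setup(x, y)
    n = d.size
    if n == 0:
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    statistic = min(w_pos, w_neg)

    if mode == "exact":
        if n > 500:
            raise ValueError("exact mode supported for n <= 500")
        p = _exact_signed_rank_p(ranks, w_pos)
    else:
        mu = n * (n + 1) / 4.0
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = float(np.sum(counts**3 - counts)) / 48.0
        sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        if sigma2 <= 0:
            return statistic, 1.0
        z = (w_pos - mu) / np.sqrt(sigma2)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return statistic, min(p, 1.0)


def _exact_signed_rank_p(ranks: np.ndarray, w_pos: float) -> float:
    """Exact two-sided p from the distribution of W+ over all sign patterns.

    Ranks are doubled so tie-averaged half-ranks become integers; the
    distribution of the rank sum over all 2^n sign assignments is built by
    convolution, which is identical to explicit enumeration.
    """
    doubled = np.rint(2.0 * ranks).astype(int)
    total = int(doubled.sum())
    dist = np.zeros(total + 1, dtype=float)
    dist[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    w = int(np.rint(2.0 * w_pos))
    cdf = float(dist[: w + 1].sum())
    sf = float(dist[w:].sum())  # P(W+ >= w), inclusive
    return min(1.0, 2.0 * min(cdf, sf))


def wilcoxon_exact_enumeration(x, y) -> tuple[float, float]:
    """Literal 2^n enumeration of sign patterns; oracle-grade, n <= ~16."""
    d = _signed_rank_setup(x, y)
    n = d.size
    if n == 0:
        return 0.0, 1.0
    if n > 16:
        raise ValueError("enumeration oracle limited to n <= 16")
    ranks = stats.rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    sums = np.array(
        [sum(r for r, s in zip(ranks, signs) if s) for signs in
         itertools.product((False, True), repeat=n)]
    )
    cdf = np.mean(sums <= w_obs + 1e-12)
    sf = np.mean(sums >= w_obs - 1e-12)
    statistic = min(w_obs, float(ranks.sum()) - w_obs)
    return statistic, min(1.0, 2.0 * min(cdf, sf))


def shapiro_wilk(x) -> tuple[float, float]:
    """Shapiro-Wilk W and p; reported as a gate only, never used to switch methods."""
    x = np.asarray(x, dtype=float)
    if x.size < 3 or x.size > 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        return float("nan"), float("nan")
    w, p = stats.shapiro(x)
    return float(w), float(p)


@dataclass
class PairedScores:
    """One score type (H or Allred) for the same cases under several methods."""

    case_ids: list
    values: dict[str, np.ndarray]  # method name -> per-case scores
    score_type: str = "H"

    def __post_init__(self) -> None:
        n = len(self.case_ids)
        self.values = {m: np.asarray(v, dtype=float) for m, v in self.values.items()}
        for method, v in self.values.items():
            if v.shape != (n,):
                raise ValueError(f"method '{method}' has {v.size} values for {n} cases")
            if np.isnan(v).any():
                raise ValueError(f"method '{method}' has missing values")

    @property
    def methods(self) -> list[str]:
        return list(self.values)


@dataclass
class ConcordanceReport:
    """Per-pair agreement statistics mirroring a three-method comparison study."""

    methods: list[str]
    kappa: dict[tuple[str, str, str], tuple[float, str]] = field(default_factory=dict)
    spearman: dict[tuple[str, str, str], tuple[float, float]] = field(default_factory=dict)
    wilcoxon: dict[tuple[str, str, str], tuple[float, float]] = field(default_factory=dict)
    shapiro: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    means: dict[tuple[str, str], float] = field(default_factory=dict)
    categories: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (score, a, b), (kappa, band) in self.kappa.items():
            rho, rho_p = self.spearman[(score, a, b)]
            w, w_p = self.wilcoxon[(score, a, b)]
            rows.append(
                {
                    "score_type": score,
                    "method_a": a,
                    "method_b": b,
                    "kappa": kappa,
                    "kappa_band": band,
                    "spearman_rho": rho,
                    "spearman_p": rho_p,
                    "wilcoxon_statistic": w,
                    "wilcoxon_p": w_p,
                }
            )
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        frame = self.to_frame()
        payload = {
            "methods": self.methods,
            "pairs": frame.to_dict(orient="records"),
            "means": {f"{s}:{m}": v for (s, m), v in self.means.items()},
            "categories": {
                f"{s}:{m}": np.asarray(v).astype(int).tolist()
                for (s, m), v in self.categories.items()
            },
        }
        return json.dumps(payload, indent=2)


def build_report(
    h_scores: PairedScores,
    allred_scores: PairedScores,
    pooling: str = "pooled_all",
    wilcoxon_mode: str = "exact",
) -> ConcordanceReport:
    """Full pairwise concordance report for H and Allred scores.

    Kappa is computed on dichotomised categories (Allred at the 6/7 split,
    H-scores at the pooled mean), Spearman and Wilcoxon on the raw scores,
    and per-method means and Shapiro-Wilk gates are reported.
    """
    if len(h_scores.case_ids) < 2:
        raise ValueError("need at least 2 cases")
    report = ConcordanceReport(methods=h_scores.methods)

    h_cat = dichotomise_hscore(h_scores.values, pooling=pooling)
    allred_cat = {
        m: np.array([int(dichotomise_allred(s)) for s in v])
        for m, v in allred_scores.values.items()
    }
    for score_type, scores, cats in (
        ("H", h_scores, h_cat),
        ("Allred", allred_scores, allred_cat),
    ):
        for m in scores.methods:
            report.means[(score_type, m)] = float(scores.values[m].mean())
            report.categories[(score_type, m)] = cats[m]
            if len(scores.values[m]) >= 3:
                report.shapiro[(score_type, m)] = shapiro_wilk(scores.values[m])
        for a, b in itertools.combinations(scores.methods, 2):
            table = agreement_table(
                cats[a], cats[b], categories=[int(Dichotomy.LOW), int(Dichotomy.HIGH)]
            )
            report.kappa[(score_type, a, b)] = cohen_kappa(table)
            report.spearman[(score_type, a, b)] = spearman_rho(
                scores.values[a], scores.values[b]
            )
            report.wilcoxon[(score_type, a, b)] = wilcoxon_signed_rank(
                scores.values[a], scores.values[b], mode=wilcoxon_mode
            )
    return report
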