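"""Correlation, model-fit, grouping and comparison statistics.

Conventions shared by the whole pipeline:

* expression enters every correlation as log10(FPKM + 1);
* correlations are Spearman (mid-ranks for ties);
* the saturating expression law is y = a * log10(x + c) + b with c
  defaulting to 0.03;
* significance stars: * p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001,
  "ns" otherwise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

STAR_LADDER = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))

EXACT_PERMUTATION_MAX_N = 10


def stars(p: float) -> str:
    """Significance stars for a p-value."""
    for cut, label in STAR_LADDER:
        if p < cut:
            return label
    return "ns"


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    method: str = "spearman"
    undefined: bool = False  # constant input: rho has no meaning

    @property
    def stars(self) -> str:
        return "ns" if self.undefined else stars(self.p_value)


@dataclass
class LogFitResult:
    """Least-squares fit of y = a * log10(x + c) + b."""

    a: float
    b: float
    c: float
    r_squared: float
    n: int

    def predict(self, x):
        return self.a * np.log10(np.asarray(x, dtype=float) + self.c) + self.b


@dataclass
class CorrGroupLabel:
    gene_id: str
    cor_tc: float
    cor_tw: float
    label: str
    kmeans_cluster: int | None = None


def _drop_missing(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with mid-ranks for ties.

    The p-value uses the t approximation for n > 10 and exact permutation
    enumeration for n <= 10.  Pairs with missing values are dropped
    listwise; a constant vector yields an undefined (flagged) result rather
    than rho = 0.
    """
    x, y = _drop_missing(x, y)
    n = len(x)
    if n < 3:
        raise ValueError("spearman needs at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(rho=math.nan, p_value=math.nan, n=n, undefined=True)
    rx = stats.rankdata(x)  # mid-ranks
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= EXACT_PERMUTATION_MAX_N:
        p = _exact_permutation_p(rx, ry, rho)
    else:
        t = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho * rho))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(rho=rho, p_value=min(1.0, p), n=n)


_PERMUTATION_CACHE: dict[int, np.ndarray] = {}


def _all_permutations(n: int) -> np.ndarray:
    """All n! index permutations, cached (n <= 10 -> at most ~36 MB int8)."""
    if n not in _PERMUTATION_CACHE:
        _PERMUTATION_CACHE[n] = np.array(
            list(itertools.permutations(range(n))), dtype=np.int8
        )
    return _PERMUTATION_CACHE[n]


def _exact_permutation_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact p by enumerating all permutations of the y ranks."""
    n = len(rx)
    perms = _all_permutations(n)
    ry_perm = ry[perms]  # (n!, n)
    rxc = rx - rx.mean()
    ryc = ry_perm - ry.mean()
    denom = math.sqrt(float(np.sum(rxc**2)) * float(np.sum(ryc[0] ** 2)))
    rhos = (ryc @ rxc) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def fit_log_model(
    x,
    y,
    offset: float = 0.03,
    estimate_offset: bool = False,
    offset_bounds: tuple[float, float] = (1e-4, 1.0),
) -> LogFitResult:
    """Fit y = a * log10(x + c) + b by least squares.

    With ``estimate_offset`` the offset c is chosen by a 1-D bounded search
    maximising the profile R-squared over ``offset_bounds`` (searched on
    log10 c, since c acts multiplicatively).
    """
    x, y = _drop_missing(x, y)
    if len(x) < 3:
        raise ValueError("fit_log_model needs at least 3 complete pairs")
    if np.any(x < 0):
        raise ValueError("x must be >= 0")
    if np.ptp(y) == 0:
        raise ValueError("y has zero variance; nothing to fit")

    def _fit(c: float):
        z = np.log10(x + c)
        a, b = np.polyfit(z, y, 1)
        resid = y - (a * z + b)
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        return a, b, 1.0 - ss_res / ss_tot

    c = offset
    if estimate_offset:
        lo, hi = offset_bounds
        res = optimize.minimize_scalar(
            lambda logc: -_fit(10.0**logc)[2],
            bounds=(math.log10(lo), math.log10(hi)),
            method="bounded",
            options={"xatol": 1e-6},
        )
        c = float(10.0**res.x)
    a, b, r2 = _fit(c)
    return LogFitResult(a=float(a), b=float(b), c=c, r_squared=r2, n=len(x))


def binned_scatter(x, y, n_bins: int = 100, by: str = "y") -> list[tuple[float, float]]:
    """Equal-size rank bins on the grouping variable; per-bin means of both.

    ``by`` selects the grouping variable ("y" mirrors ranking genes by
    expression and averaging the paired feature per group).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if n_bins > len(x):
        raise ValueError(f"n_bins={n_bins} exceeds n={len(x)}")
    order = np.argsort(y if by == "y" else x, kind="stable")
    out = []
    for idx in np.array_split(order, n_bins):
        out.append((float(x[idx].mean()), float(y[idx].mean())))
    return out


def label_corr_groups(
    correlations: dict[str, tuple[float, float]],
    threshold: float = 0.5,
    run_kmeans: bool = False,
    k: int = 3,
    seed: int = 0,
) -> list[CorrGroupLabel]:
    """Label genes by |cor| > threshold on (cor_TC, cor_TW).

    Labels: TC&TW if both exceed, TC / TW if only one does, nTC&TW
    otherwise (strict inequality, on absolute values).  Optionally a
    seeded k-means on the correlation pairs is recorded alongside as a
    diagnostic; the deterministic threshold rule is the primary grouping.
    Genes with a missing correlation are excluded.
    """
    rows: list[CorrGroupLabel] = []
    pts = []
    for gene_id in sorted(correlations):
        cor_tc, cor_tw = correlations[gene_id]
        if not (math.isfinite(cor_tc) and math.isfinite(cor_tw)):
            continue
        tc_hit = abs(cor_tc) > threshold
        tw_hit = abs(cor_tw) > threshold
        label = {
            (True, True): "TC&TW",
            (True, False): "TC",
            (False, True): "TW",
            (False, False): "nTC&TW",
        }[(tc_hit, tw_hit)]
        rows.append(CorrGroupLabel(gene_id=gene_id, cor_tc=cor_tc, cor_tw=cor_tw, label=label))
        pts.append((cor_tc, cor_tw))
    if run_kmeans and rows:
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=min(k, len(rows)), random_state=seed, n_init=10)
        assignments = km.fit_predict(np.asarray(pts))
        for row, a in zip(rows, assignments):
            row.kmeans_cluster = int(a)
    return rows


def welch_ttest(a, b) -> tuple[float, float, str]:
    """Two-sided Welch (unequal variance) t-test with significance stars."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("welch_ttest needs >= 2 values per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return 0.0, 1.0, "ns"
        return math.inf, 0.0, "****"
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p), stars(float(p))


def top_cw_and_control(
    tfcrs, n: int = 200, seed: int = 0
) -> tuple[list, list]:
    """Top-n TFCRs by unit-base complexity plus a seeded random control.

    Ties break by TC then id (deterministic); the control is a uniform
    sample of n from the remaining TFCRs, disjoint from the top set.
    """
    if len(tfcrs) < 2 * n:
        raise ValueError(f"need >= {2 * n} TFCRs for top-{n} plus control")
    ranked = sorted(tfcrs, key=lambda t: (-t.cw, -t.tc, t.tfcr_id))
    top = ranked[:n]
    rest = ranked[n:]
    rng = np.random.default_rng(seed)
    control = [rest[i] for i in sorted(rng.choice(len(rest), size=n, replace=False))]
    return top, control


def gene_set_stats(
    genes_by_group: dict[str, set], reference_set: set
) -> dict[str, tuple[int, float]]:
    """Per group: overlap count with the reference set and its fraction."""
    if not reference_set:
        raise ValueError("empty reference gene set")
    out = {}
    for group, genes in genes_by_group.items():
        count = len(set(genes) & reference_set)
        out[group] = (count, count / len(reference_set))
    return out
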