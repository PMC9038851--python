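"""Reader-study statistics for ordinal image-quality ratings.

Ratings live in a long-form table — one row per
(exam, side, level, fov, reader) with an integer Likert score 1–5
(1 = non-diagnostic … 5 = excellent).  The analysis chain mirrors a
standard multi-reader image-quality study: exclude non-diagnostic
segments, quantify inter-rater reliability with ICC(2,k) (two-way random
effects, absolute agreement, mean of k raters), pool readers, then
compare the paired FOV groups per vessel level with the Wilcoxon
signed-rank test and a paired Student t-test, and the two body sides
with the Wilcoxon rank-sum test.  No multiple-testing correction is
applied (alpha = 0.05 throughout); summary outputs say so.

The Wilcoxon tests use exact null distributions for small samples, with
tied ranks averaged (the exact distribution is computed on the realised
rank vector, so ties are handled exactly); larger samples use the normal
approximation with tie correction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import distributions

__all__ = [
    "REQUIRED_COLUMNS",
    "ICCResult",
    "TestResult",
    "validate_ratings",
    "load_ratings",
    "exclude_non_diagnostic",
    "pool_readers",
    "count_segments",
    "rating_matrix",
    "icc2k",
    "icc_category",
    "wilcoxon_signed_rank",
    "wilcoxon_rank_sum",
    "delta_means",
    "summarize_segments",
    "compare_sides",
]

REQUIRED_COLUMNS = ("exam", "side", "level", "fov", "reader", "score")

_LEVELS = ("femoral", "popliteal", "crural", "pedal")
_KEY = ["exam", "side", "level", "fov"]


class DegenerateDataError(ValueError):
    """No information left to test (e.g. all-zero paired differences)."""


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: int


@dataclass(frozen=True)
class ICCResult:
    """Inter-rater reliability of the mean of k raters.

    Two-way random-effects model with absolute agreement — ICC(2,k):
    (MSR − MSE) / (MSR + (MSC − MSE)/n) from the two-way ANOVA mean
    squares (rows = targets, columns = raters).
    """

    value: float
    ci95: tuple[float, float]
    n_targets: int
    n_raters: int
    category: str
    model: str = "two-way random, absolute agreement, mean of k raters (ICC2k)"


def validate_ratings(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-form rating table and normalise its dtypes.

    Enforces the column schema, integer scores in [1, 5], and uniqueness
    of the (exam, side, level, fov, reader) key; derives the
    ``non_diagnostic`` flag (score == 1).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"rating table missing columns {missing}")
    if len(df) == 0:
        raise ValueError("rating table is empty")
    out = df.copy()
    scores = out["score"].to_numpy()
    if not np.array_equal(scores, scores.astype(int)):
        raise ValueError("scores must be integers")
    out["score"] = scores.astype(int)
    if out["score"].min() < 1 or out["score"].max() > 5:
        raise ValueError("scores must lie in [1, 5]")
    key = [*_KEY, "reader"]
    if out.duplicated(subset=key).any():
        dup = out[out.duplicated(subset=key, keep=False)].head(4)
        raise ValueError(f"duplicate rating keys, e.g.\n{dup}")
    out["non_diagnostic"] = out["score"] == 1
    return out


def load_ratings(path) -> pd.DataFrame:
    """Read a ratings CSV (header: exam,side,level,fov,reader,score)."""
    return validate_ratings(pd.read_csv(path))


def exclude_non_diagnostic(
    df: pd.DataFrame, policy: str = "per-segment-pair"
) -> pd.DataFrame:
    """Drop non-diagnostic (score 1) ratings.

    ``per-rating`` removes only the offending rows; ``per-segment-pair``
    (default, appropriate before paired FOV tests) removes both FOV
    members of any (exam, side, level, reader) whose either member is
    non-diagnostic, preserving the pairing.
    """
    if policy == "per-rating":
        return df[df["score"] > 1].reset_index(drop=True)
    if policy == "per-segment-pair":
        bad = df.loc[df["score"] == 1, ["exam", "side", "level", "reader"]]
        bad_keys = set(map(tuple, bad.to_numpy()))
        keys = list(map(tuple, df[["exam", "side", "level", "reader"]].to_numpy()))
        keep = [k not in bad_keys for k in keys]
        return df[keep].reset_index(drop=True)
    raise ValueError(f"unknown policy {policy!r}")


def pool_readers(df: pd.DataFrame) -> pd.DataFrame:
    """Average scores over readers per (exam, side, level, fov)."""
    pooled = (
        df.groupby(_KEY, as_index=False)
        .agg(score=("score", "mean"), n_readers=("reader", "nunique"))
    )
    return pooled


def count_segments(df: pd.DataFrame) -> int:
    """Number of distinct evaluated segment records (exam, side, level, fov)."""
    return int(df.drop_duplicates(subset=_KEY).shape[0])


def rating_matrix(df: pd.DataFrame, on_incomplete: str = "raise") -> np.ndarray:
    """Targets x raters score matrix for the ICC.

    Each target is one (exam, side, level, fov) rating unit; columns are
    readers.  Incomplete units (not rated by every reader, e.g. after a
    per-rating exclusion) raise by default or are dropped with
    ``on_incomplete='drop'``; scores are never imputed.
    """
    wide = df.pivot_table(index=_KEY, columns="reader", values="score")
    if wide.isna().any().any():
        if on_incomplete == "drop":
            wide = wide.dropna()
        else:
            raise ValueError("incomplete rating matrix: every target needs all readers")
    return wide.to_numpy(dtype=float)


def icc_category(icc: float) -> str:
    """Reliability band: <0.5 poor, 0.5–0.75 moderate, 0.75–0.9 good, >0.9 excellent."""
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc <= 0.9:
        return "good"
    return "excellent"


def icc2k(matrix: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """ICC(2,k) from the two-way ANOVA decomposition.

    ``matrix`` is complete, targets (rows) x raters (columns).  The 95%
    confidence interval follows the F-based construction of McGraw & Wong
    (Satterthwaite degrees of freedom on the single-rater bound, then the
    Spearman–Brown step up to the mean of k raters).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need at least 2 targets and 2 raters")
    if np.isnan(m).any():
        raise ValueError("incomplete matrix: missing scores are not imputed")
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((m - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (msc - mse) / n
    icc_k = (msr - mse) / denom if denom != 0 else 1.0

    # single-rater ICC(2,1) CI via Satterthwaite df, then Spearman-Brown
    denom1 = msr + (k - 1) * mse + k * (msc - mse) / n
    icc1 = (msr - mse) / denom1 if denom1 != 0 else 1.0
    if mse == 0:
        lb, ub = icc_k, icc_k
    else:
        fj = msc / mse
        vn = (k - 1) * (n - 1) * (
            (k * icc1 * fj + n * (1 + (k - 1) * icc1) - k * icc1) ** 2
        )
        vd = (n - 1) * k**2 * icc1**2 * fj**2 + (
            n * (1 + (k - 1) * icc1) - k * icc1
        ) ** 2
        v = vn / vd
        with np.errstate(invalid="ignore", divide="ignore"):
            f2u = distributions.f.ppf(1 - alpha / 2, n - 1, v)
            f2l = distributions.f.ppf(1 - alpha / 2, v, n - 1)
            lb1 = n * (msr - f2u * mse) / (
                f2u * (k * msc + (k * n - k - n) * mse) + n * msr
            )
            ub1 = n * (f2l * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f2l * msr
            )
        lb = lb1 * k / (1 + lb1 * (k - 1))
        ub = ub1 * k / (1 + ub1 * (k - 1))
    return ICCResult(
        value=float(icc_k),
        ci95=(float(lb), float(ub)),
        n_targets=n,
        n_raters=k,
        category=icc_category(float(icc_k)),
    )


def _signed_rank_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p for the signed-rank statistic on given ranks.

    Enumerates the null distribution of W+ over all sign assignments via
    dynamic programming on doubled (integer) ranks, so averaged tied
    ranks are handled exactly.
    """
    r2 = np.round(ranks * 2).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    w2 = int(round(w_plus * 2))
    lower = dist[: w2 + 1].sum()
    upper = dist[w2:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def wilcoxon_signed_rank(differences, exact_max_n: int = 25) -> TestResult:
    """Wilcoxon signed-rank test on paired differences (two-sided).

    Zero differences are dropped; ties in |d| get averaged ranks.  The
    statistic is W+ (sum of ranks of the positive differences).  Exact
    null distribution up to ``exact_max_n`` non-zero differences, normal
    approximation with tie correction beyond.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise DegenerateDataError("all paired differences are zero")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        p = _signed_rank_exact_p(ranks, w_plus)
        method = "exact"
    else:
        mu = n * (n + 1) / 4.0
        # tie correction: subtract sum(t^3 - t)/48 from the null variance
        _, counts = np.unique(ranks, return_counts=True)
        tie = np.sum(counts**3 - counts) / 48.0
        sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie
        z = (w_plus - mu) / math.sqrt(sigma2)
        p = float(2.0 * distributions.norm.sf(abs(z)))
        method = "normal-approx"
    return TestResult(statistic=w_plus, p_value=p, method=method, n=n)


def _rank_sum_exact_p(ranks: np.ndarray, na: int, w_obs: float) -> float:
    """Exact two-sided p for the rank-sum statistic by enumeration of all
    assignments of ``na`` of the pooled (tie-averaged) ranks to group A."""
    r2 = np.round(ranks * 2).astype(int)
    w2 = int(round(w_obs * 2))
    total = 0
    lower = 0
    upper = 0
    for combo in itertools.combinations(range(len(r2)), na):
        s = sum(r2[i] for i in combo)
        total += 1
        if s <= w2:
            lower += 1
        if s >= w2:
            upper += 1
    return float(min(1.0, 2.0 * min(lower, upper) / total))


def wilcoxon_rank_sum(
    group_a, group_b, exact_max_combinations: int = 200_000
) -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney) test, two-sided.

    The statistic is the rank sum of group A in the pooled tie-averaged
    ranking.  Exact enumeration when the number of group assignments is
    manageable, normal approximation with tie correction otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    na, nb = a.size, b.size
    w = float(ranks[:na].sum())
    if math.comb(na + nb, na) <= exact_max_combinations:
        p = _rank_sum_exact_p(ranks, na, w)
        method = "exact"
    else:
        n = na + nb
        mu = na * (n + 1) / 2.0
        _, counts = np.unique(ranks, return_counts=True)
        tie = np.sum(counts**3 - counts) / (n * (n - 1))
        sigma2 = na * nb / 12.0 * ((n + 1) - tie)
        z = (w - mu) / math.sqrt(sigma2)
        p = float(2.0 * distributions.norm.sf(abs(z)))
        method = "normal-approx"
    return TestResult(statistic=w, p_value=p, method=method, n=na + nb)


def delta_means(means: dict[tuple[str, str], float]) -> dict[str, float]:
    """Per-level mean-score difference, small FOV minus large FOV."""
    levels = sorted({lvl for lvl, _ in means}, key=lambda l: _LEVELS.index(l)
                    if l in _LEVELS else 99)
    return {lvl: means[(lvl, "small")] - means[(lvl, "large")] for lvl in levels}


def summarize_segments(pooled: pd.DataFrame) -> pd.DataFrame:
    """Per-(level, fov) summary with paired FOV tests per level.

    Returns one row per vessel level: mean ± sd (sample, n−1), median and
    IQR per FOV, Δmean (small − large), and two-sided p-values of the
    Wilcoxon signed-rank test and the paired Student t-test on the
    pooled (exam, side) scores.
    """
    if pooled.empty:
        raise ValueError("pooled table is empty")
    rows = []
    for level, g in pooled.groupby("level", sort=False):
        entry: dict = {"level": level}
        for fov in ("large", "small"):
            s = g.loc[g["fov"] == fov, "score"].to_numpy(dtype=float)
            if s.size == 0:
                raise ValueError(f"no {fov}-FOV scores at level {level!r}")
            q25, q75 = np.percentile(s, [25, 75])
            entry[f"{fov}_n"] = s.size
            entry[f"{fov}_mean"] = s.mean()
            entry[f"{fov}_sd"] = s.std(ddof=1) if s.size > 1 else np.nan
            entry[f"{fov}_median"] = float(np.median(s))
            entry[f"{fov}_iqr"] = (float(q25), float(q75))
        entry["delta_mean"] = entry["small_mean"] - entry["large_mean"]

        wide = g.pivot_table(index=["exam", "side"], columns="fov", values="score")
        wide = wide.dropna()
        diffs = (wide["small"] - wide["large"]).to_numpy()
        try:
            entry["p_wilcoxon"] = wilcoxon_signed_rank(diffs).p_value
        except DegenerateDataError:
            entry["p_wilcoxon"] = np.nan
        if diffs.size < 2 or np.allclose(diffs, diffs[0]):
            entry["p_ttest"] = np.nan
        else:
            entry["p_ttest"] = float(
                stats.ttest_rel(wide["small"], wide["large"]).pvalue
            )
        rows.append(entry)
    order = {lvl: i for i, lvl in enumerate(_LEVELS)}
    rows.sort(key=lambda r: order.get(r["level"], 99))
    return pd.DataFrame(rows)


def compare_sides(pooled: pd.DataFrame) -> pd.DataFrame:
    """Right-vs-left rank-sum comparison per (level, fov)."""
    rows = []
    for (level, fov), g in pooled.groupby(["level", "fov"], sort=False):
        right = g.loc[g["side"] == "right", "score"].to_numpy()
        left = g.loc[g["side"] == "left", "score"].to_numpy()
        res = wilcoxon_rank_sum(right, left)
        rows.append(
            {"level": level, "fov": fov, "statistic": res.statistic,
             "p_value": res.p_value, "method": res.method}
        )
    return pd.DataFrame(rows)
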