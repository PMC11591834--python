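"""Paired comfort-vs-fatigue inference with normality gating and FDR control.

Test selection follows the gate: Shapiro-Wilk on the paired differences; if
normality is not rejected (p >= alpha) a paired t-test is used, otherwise a
Wilcoxon signed-rank test (Pratt zero handling, normal approximation at
typical sample sizes, exact below n = 10 when no zero differences occur).
Statistics are computed on comfort minus fatigue, so a higher fatigue value
yields a negative statistic. Edge-wise maps use a plain paired t-test with
Benjamini-Hochberg adjustment across the electrode pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .connectivity import PLVMatrix
from .montage import Montage

__all__ = [
    "PairedSample",
    "ComparisonResult",
    "EdgeComparisonMap",
    "NodeDifferenceMap",
    "paired_compare",
    "fdr_adjust",
    "compare_edges",
    "compare_global_across_thresholds",
    "node_difference_map",
    "significance_stars",
]

STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass(frozen=True)
class PairedSample:
    comfort: np.ndarray
    fatigue: np.ndarray
    unit: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.comfort, dtype=float)
        f = np.asarray(self.fatigue, dtype=float)
        object.__setattr__(self, "comfort", c)
        object.__setattr__(self, "fatigue", f)
        if c.shape != f.shape or c.ndim != 1:
            raise ValueError("comfort and fatigue must be aligned 1-D arrays")
        if c.size < 3:
            raise ValueError("paired comparison needs n >= 3")
        if not (np.isfinite(c).all() and np.isfinite(f).all()):
            raise ValueError("paired sample contains NaN/inf")


def _descriptives(x: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return {
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
    }


@dataclass(frozen=True)
class ComparisonResult:
    test_used: str  # paired_t | wilcoxon | degenerate
    normality_p: float
    statistic: float
    p_value: float
    tail: str
    n: int
    comfort: dict = field(default_factory=dict)
    fatigue: dict = field(default_factory=dict)

    def describe(self, condition: str) -> str:
        """Table-style cell: 'mean (sd)' if the t-test was chosen, else
        'median (q1~q3)'."""
        d = self.comfort if condition == "comfort" else self.fatigue
        if self.test_used == "wilcoxon":
            return f"{d['median']:.2f} ({d['q1']:.2f}~{d['q3']:.2f})"
        return f"{d['mean']:.2f} ({d['sd']:.2f})"

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


def significance_stars(p: float) -> str:
    for level, mark in STAR_LEVELS:
        if p < level:
            return mark
    return ""


def _wilcoxon_pratt_z(d: np.ndarray) -> float:
    """Signed-rank z with Pratt zero handling and tie correction."""
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    nz = d != 0
    w_plus = ranks[(d > 0)].sum()
    n0 = int(np.count_nonzero(~nz))
    mu = n * (n + 1) / 4.0 - n0 * (n0 + 1) / 4.0
    var = (n * (n + 1) * (2 * n + 1) - n0 * (n0 + 1) * (2 * n0 + 1)) / 24.0
    _, counts = np.unique(ranks, return_counts=True)
    var -= (counts**3 - counts).sum() / 48.0
    if var <= 0:
        return 0.0
    return float((w_plus - mu) / np.sqrt(var))


def paired_compare(
    comfort: np.ndarray,
    fatigue: np.ndarray,
    alpha_normality: float = 0.05,
    tail: str = "two",
    force_test: str | None = None,
    on_degenerate: str = "value",
) -> ComparisonResult:
    """Gated paired comparison of two condition vectors.

    ``tail="one"`` tests the directed hypothesis fatigue > comfort. When
    every difference is zero no test is defined; by default a degenerate
    result (statistic 0, p = 1) is returned, or pass
    ``on_degenerate="raise"``.
    """
    sample = PairedSample(comfort, fatigue)
    if tail not in ("two", "one"):
        raise ValueError("tail must be 'two' or 'one'")
    c, f = sample.comfort, sample.fatigue
    d = c - f
    desc = {"comfort": _descriptives(c), "fatigue": _descriptives(f)}
    if np.all(d == 0):
        if on_degenerate == "raise":
            raise ValueError("all paired differences are zero; test degenerate")
        return ComparisonResult(
            test_used="degenerate",
            normality_p=float("nan"),
            statistic=0.0,
            p_value=1.0,
            tail=tail,
            n=d.size,
            **desc,
        )
    if np.ptp(d) == 0:  # constant non-zero differences: Shapiro undefined
        norm_p = 0.0
    else:
        norm_p = float(sps.shapiro(d).pvalue)
    test = force_test or ("paired_t" if norm_p >= alpha_normality else "wilcoxon")

    alternative = "two-sided" if tail == "two" else "less"  # comfort < fatigue
    if test == "paired_t":
        res = sps.ttest_rel(c, f, alternative=alternative)
        stat, p = float(res.statistic), float(res.pvalue)
    elif test == "wilcoxon":
        n0 = int(np.count_nonzero(d == 0))
        if d.size < 10 and n0 == 0:
            res = sps.wilcoxon(c, f, alternative=alternative, method="exact")
            stat, p = float(res.statistic), float(res.pvalue)
        else:
            z = _wilcoxon_pratt_z(d)
            p = 2 * sps.norm.sf(abs(z)) if tail == "two" else sps.norm.cdf(z)
            stat = z
    else:
        raise ValueError(f"unknown test {test!r}")
    return ComparisonResult(
        test_used=test,
        normality_p=norm_p,
        statistic=stat,
        p_value=float(p),
        tail=tail,
        n=d.size,
        **desc,
    )


def fdr_adjust(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and rejection flags.

    Returns (adjusted, reject) in the input order; ``reject`` is True where
    the adjusted p-value is below ``q``.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj, adj < q


@dataclass(frozen=True)
class EdgeComparisonMap:
    """Per electrode-pair paired-test results with FDR adjustment."""

    table: pd.DataFrame  # chan_a, chan_b, means, statistic, p, p_adj, significant
    summary: dict
    band: str = ""


def compare_edges(
    plvs_comfort: list[PLVMatrix],
    plvs_fatigue: list[PLVMatrix],
    q: float = 0.05,
    method: str = "paired_t",
    tail: str = "two",
) -> EdgeComparisonMap:
    """Edge-wise comfort/fatigue comparison over all unique electrode pairs.

    ``method="paired_t"`` applies the t-test to every pair (the edge-map
    convention); ``method="gated"`` uses the Shapiro-Wilk gate per pair.
    """
    if len(plvs_comfort) != len(plvs_fatigue) or not plvs_comfort:
        raise ValueError("need equal, non-empty per-condition matrix lists")
    for mc, mf in zip(plvs_comfort, plvs_fatigue):
        if mc.participant != mf.participant:
            raise ValueError(
                f"participant mismatch: {mc.participant!r} vs {mf.participant!r}"
            )
        if mc.channel_labels != plvs_comfort[0].channel_labels:
            raise ValueError("channel labels differ across participants")
    labels = plvs_comfort[0].channel_labels
    comfort = np.stack([m.pair_values() for m in plvs_comfort])  # (n, pairs)
    fatigue = np.stack([m.pair_values() for m in plvs_fatigue])
    n, n_pairs = comfort.shape

    if method == "paired_t":
        res = sps.ttest_rel(
            comfort, fatigue, axis=0,
            alternative="two-sided" if tail == "two" else "less",
        )
        stats_arr = np.asarray(res.statistic, dtype=float)
        pvals = np.asarray(res.pvalue, dtype=float)
        # zero-variance pairs (identical data) are not evidence: p = 1
        degen = ~np.isfinite(stats_arr)
        stats_arr[degen] = 0.0
        pvals[degen] = 1.0
        tests = np.where(degen, "degenerate", "paired_t")
    elif method == "gated":
        stats_arr = np.empty(n_pairs)
        pvals = np.empty(n_pairs)
        tests = np.empty(n_pairs, dtype=object)
        for k in range(n_pairs):
            r = paired_compare(comfort[:, k], fatigue[:, k], tail=tail)
            stats_arr[k], pvals[k], tests[k] = r.statistic, r.p_value, r.test_used
    else:
        raise ValueError(f"unknown method {method!r}")

    p_adj, reject = fdr_adjust(pvals, q=q)
    iu = np.triu_indices(len(labels), k=1)
    table = pd.DataFrame(
        {
            "chan_a": [labels[i] for i in iu[0]],
            "chan_b": [labels[j] for j in iu[1]],
            "comfort_mean": comfort.mean(axis=0),
            "comfort_sd": comfort.std(axis=0, ddof=1),
            "fatigue_mean": fatigue.mean(axis=0),
            "fatigue_sd": fatigue.std(axis=0, ddof=1),
            "test_used": tests,
            "statistic": stats_arr,
            "p_value": pvals,
            "p_adj": p_adj,
            "significant": reject,
        }
    )
    sig = table[table["significant"]]
    summary = {
        "n_participants": n,
        "n_pairs": n_pairs,
        "plv_comfort_mean": float(comfort.mean()),
        "plv_comfort_sd": float(comfort.std(ddof=1)),
        "plv_fatigue_mean": float(fatigue.mean()),
        "plv_fatigue_sd": float(fatigue.std(ddof=1)),
        "n_significant": int(sig.shape[0]),
        "p_adj_significant_mean": float(sig["p_adj"].mean()) if len(sig) else float("nan"),
        "p_adj_significant_sd": float(sig["p_adj"].std(ddof=1)) if len(sig) > 1 else float("nan"),
        "plv_comfort_sig_mean": float(
            comfort[:, sig.index].mean()) if len(sig) else float("nan"),
        "plv_fatigue_sig_mean": float(
            fatigue[:, sig.index].mean()) if len(sig) else float("nan"),
    }
    band = plvs_comfort[0].band
    return EdgeComparisonMap(table=table, summary=summary, band=band)


GRAPH_METRICS = ("bc", "ne", "cc", "cpl")


def _graph_level(df: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Per participant/condition scalar for one metric (node mean or GLOBAL)."""
    if metric == "cpl":
        sub = df[(df["metric"] == "cpl") & (df["node"] == "GLOBAL")]
        return sub.groupby(["participant", "condition"])["value"].mean().reset_index()
    sub = df[(df["metric"] == metric) & (df["node"] != "GLOBAL")]
    return sub.groupby(["participant", "condition"])["value"].mean().reset_index()


def compare_global_across_thresholds(
    metrics_df: pd.DataFrame,
    grid=None,
    q: float = 0.05,
    tail: str = "two",
) -> pd.DataFrame:
    """Graph-level paired comparisons for each band x metric x threshold.

    ``metrics_df`` is the long table emitted by ``MetricTable.to_frame``
    (concatenated over participants, conditions, bands and thresholds).
    Node metrics are averaged over nodes per participant first. Participants
    with an undefined (NaN) value in either condition are dropped pairwise.
    """
    if grid is None:
        grid = sorted(metrics_df["threshold"].unique())
    rows = []
    for band in sorted(metrics_df["band"].unique()):
        band_df = metrics_df[metrics_df["band"] == band]
        for metric in GRAPH_METRICS:
            for thr in grid:
                sub = band_df[np.isclose(band_df["threshold"], thr)]
                if sub.empty:
                    raise ValueError(f"no metric rows for threshold {thr} in {band}")
                g = _graph_level(sub, metric)
                pivot = g.pivot(index="participant", columns="condition", values="value")
                missing = {"comfort", "fatigue"} - set(pivot.columns)
                if missing:
                    raise ValueError(f"missing condition(s) {sorted(missing)}")
                pivot = pivot.dropna()
                row = {"band": band, "metric": metric, "threshold": thr,
                       "n": len(pivot)}
                if len(pivot) < 3:
                    # e.g. CPL undefined for (almost) every participant at an
                    # extreme threshold: report the cell, but no test
                    row.update(
                        comfort="", fatigue="",
                        comfort_mean=float("nan"), fatigue_mean=float("nan"),
                        test_used="insufficient", statistic=float("nan"),
                        p_value=float("nan"), significant=False, stars="",
                    )
                else:
                    r = paired_compare(
                        pivot["comfort"].to_numpy(),
                        pivot["fatigue"].to_numpy(),
                        tail=tail,
                    )
                    row.update(
                        comfort=r.describe("comfort"),
                        fatigue=r.describe("fatigue"),
                        comfort_mean=r.comfort["mean"],
                        fatigue_mean=r.fatigue["mean"],
                        test_used=r.test_used,
                        statistic=r.statistic,
                        p_value=r.p_value,
                        significant=bool(r.p_value < q),
                        stars=r.stars,
                    )
                rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class NodeDifferenceMap:
    """Per-channel fatigue-minus-comfort differences with paired tests."""

    table: pd.DataFrame  # channel, region, mean_diff, statistic, p, significant
    region_summary: pd.DataFrame  # region, n_channels, n_significant
    metric: str
    band: str
    threshold: float


def node_difference_map(
    metrics_df: pd.DataFrame,
    metric: str,
    band: str,
    threshold: float,
    montage: Montage,
    alpha: float = 0.05,
    tail: str = "two",
) -> NodeDifferenceMap:
    """Channel-wise condition differences for one node metric at one threshold."""
    if metric not in ("bc", "ne", "cc"):
        raise ValueError("metric must be one of bc, ne, cc")
    sub = metrics_df[
        (metrics_df["band"] == band)
        & np.isclose(metrics_df["threshold"], threshold)
        & (metrics_df["metric"] == metric)
        & (metrics_df["node"] != "GLOBAL")
    ]
    if sub.empty:
        raise ValueError(f"no rows for {metric}/{band} at threshold {threshold}")
    rows = []
    for channel in sub["node"].unique():
        if channel not in montage.region_of:
            raise KeyError(f"channel {channel!r} missing from montage")
        ch = sub[sub["node"] == channel].pivot(
            index="participant", columns="condition", values="value"
        )
        r = paired_compare(
            ch["comfort"].to_numpy(), ch["fatigue"].to_numpy(), tail=tail
        )
        rows.append(
            {
                "channel": channel,
                "region": montage.region_of[channel],
                "mean_diff": r.fatigue["mean"] - r.comfort["mean"],
                "test_used": r.test_used,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "significant": r.p_value < alpha,
                "stars": r.stars,
            }
        )
    table = pd.DataFrame(rows)
    region_summary = (
        table.groupby("region")
        .agg(n_channels=("channel", "size"), n_significant=("significant", "sum"))
        .reset_index()
    )
    return NodeDifferenceMap(
        table=table,
        region_summary=region_summary,
        metric=metric,
        band=band,
        threshold=threshold,
    )
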