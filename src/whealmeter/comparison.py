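"""Method-agreement statistics for paired area measurements.

Implements the comparison machinery used to argue that the pixel-proportion
area outperforms diameter-based protocols: Bland-Altman bias and limits of
agreement, paired Wilcoxon signed-rank tests (exact for small n), Pearson
correlation, ECDF superposition after bias shift, cumulative-mean
convergence across shuffles, and the regular/irregular percentage-deviation
study.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from whealmeter.geometry import (
    Calibration,
    calibrate,
    cluster_area_cm2,
    cluster_pixels,
    computational_diameters,
    ma1_area,
    ma2_area,
)

#: zero differences are dropped (Wilcoxon's original convention); the exact
#: null distribution is used up to this n, the tie-corrected normal
#: approximation beyond it.
EXACT_WILCOXON_MAX_N = 25


class DegenerateTestError(ValueError):
    """All paired differences are zero; the signed-rank test is undefined."""


@dataclass(frozen=True)
class AgreementReport:
    bias: float  # mean of a - b
    sd_diff: float
    loa_low: float  # bias - 1.96 sd
    loa_high: float  # bias + 1.96 sd
    proportional_bias_slope: float
    proportional_bias_r: float
    proportional_bias_degenerate: bool
    pearson_rho: float
    wilcoxon_statistic: float | None
    wilcoxon_p: float | None
    n: int


@dataclass(frozen=True)
class DeviationSummary:
    group: str
    reference: str
    method: str
    mean_pct: float
    sd_pct: float
    min_pct: float
    max_pct: float
    n: int


def _paired(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"paired inputs must be equal-length 1-D, got {a.shape}, {b.shape}")
    return a, b


def bland_altman(a, b) -> AgreementReport:
    """Bland-Altman agreement of two paired measurement series.

    Differences are ``a - b``; limits of agreement are ``bias +- 1.96 sd``.
    Proportional bias is the correlation/slope of the differences against the
    pair means; it is flagged degenerate (and reported as 0) when the
    differences are constant.
    """
    a, b = _paired(a, b)
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    d = a - b
    mean_ab = (a + b) / 2.0
    bias = float(d.mean())
    sd = float(d.std(ddof=1))

    degenerate = bool(np.isclose(sd, 0.0)) or bool(np.isclose(np.std(mean_ab), 0.0))
    if degenerate:
        slope, r = 0.0, 0.0
    else:
        slope = float(np.polyfit(mean_ab, d, 1)[0])
        r = float(stats.pearsonr(mean_ab, d).statistic)

    if np.isclose(np.std(a), 0.0) or np.isclose(np.std(b), 0.0):
        rho = 1.0 if np.allclose(a, b) else 0.0
    else:
        rho = float(stats.pearsonr(a, b).statistic)

    try:
        w_stat, w_p = paired_wilcoxon(a, b)
    except DegenerateTestError:
        w_stat, w_p = None, None

    return AgreementReport(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        proportional_bias_slope=slope,
        proportional_bias_r=r,
        proportional_bias_degenerate=degenerate,
        pearson_rho=rho,
        wilcoxon_statistic=w_stat,
        wilcoxon_p=w_p,
        n=int(a.size),
    )


def _signed_ranks(d: np.ndarray) -> np.ndarray:
    return stats.rankdata(np.abs(d))


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p via the generating polynomial of the rank sum.

    Average ranks are half-integers, so doubling makes every rank an integer
    and the null distribution of 2*W+ is the coefficient sequence of
    ``prod_i (1 + x^{2 r_i})``.  Handles ties exactly.
    """
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        counts[r:] += counts[: total + 1 - r].copy()
    counts /= counts.sum()
    w2 = int(round(2 * w_plus))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def _approx_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Tie-corrected normal approximation with continuity correction."""
    n = ranks.size
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    # tie correction: subtract sum(t^3 - t)/48 over tied groups
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= np.sum(tie_counts**3 - tie_counts) / 48.0
    if var <= 0:
        raise DegenerateTestError("zero variance in signed-rank statistic")
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / np.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def paired_wilcoxon(a, b) -> tuple[float, float]:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped.  Returns ``(W+, p)`` with the exact null
    distribution for n <= 25 and the tie-corrected normal approximation
    otherwise.
    """
    a, b = _paired(a, b)
    d = a - b
    d = d[d != 0.0]
    if d.size == 0:
        raise DegenerateTestError("all paired differences are zero")
    ranks = _signed_ranks(d)
    w_plus = float(ranks[d > 0].sum())
    if d.size <= EXACT_WILCOXON_MAX_N:
        p = _exact_signed_rank_p(ranks, w_plus)
    else:
        p = _approx_signed_rank_p(ranks, w_plus)
    return w_plus, p


# ---------------------------------------------------------------------------
# distribution comparisons
# ---------------------------------------------------------------------------


def ecdf(values) -> tuple[np.ndarray, np.ndarray]:
    """Sorted sample points and ECDF heights."""
    x = np.sort(np.asarray(values, dtype=float))
    return x, np.arange(1, x.size + 1) / x.size


def _max_ecdf_distance(x1: np.ndarray, x2: np.ndarray) -> float:
    """Kolmogorov-style sup distance between the ECDFs of two samples."""
    grid = np.concatenate([x1, x2])
    f1 = np.searchsorted(np.sort(x1), grid, side="right") / x1.size
    f2 = np.searchsorted(np.sort(x2), grid, side="right") / x2.size
    return float(np.abs(f1 - f2).max())


def ecdf_bias_shift(table: pd.DataFrame, reference: str) -> dict:
    """ECDFs per method, re-evaluated after adding the bias vs. the reference.

    For each non-reference method, the Bland-Altman bias (reference - method)
    is added to the method's values; the maximal vertical ECDF distance to
    the reference is reported before and after the shift.
    """
    if reference not in table.columns:
        raise ValueError(f"reference method {reference!r} not in table")
    methods = [c for c in table.columns if c != reference]
    if not methods:
        raise ValueError("need at least one non-reference method")
    out: dict = {"reference": reference, "methods": {}}
    for m in methods:
        sub = table[[reference, m]].dropna()
        ref_v = sub[reference].to_numpy(dtype=float)
        met_v = sub[m].to_numpy(dtype=float)
        bias = float(np.mean(ref_v - met_v))
        shifted = met_v + bias
        out["methods"][m] = {
            "bias": bias,
            "n": int(sub.shape[0]),
            "ecdf": ecdf(met_v),
            "ecdf_shifted": ecdf(shifted),
            "max_distance_before": _max_ecdf_distance(ref_v, met_v),
            "max_distance_after": _max_ecdf_distance(ref_v, shifted),
        }
    return out


def cumulative_mean_convergence(
    values, n_shuffles: int = 15, seed: int | None = None
) -> dict:
    """Cumulative-mean behavior across random shuffles of the sample.

    Returns the per-shuffle cumulative means, their average curve, and the
    standard-error decay ``sd / sqrt(k)``.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    rng = np.random.default_rng(seed)
    k = np.arange(1, x.size + 1)
    curves = np.empty((n_shuffles, x.size))
    for i in range(n_shuffles):
        perm = rng.permutation(x)
        curves[i] = np.cumsum(perm) / k
    sd = float(x.std(ddof=1))
    return {
        "k": k,
        "curves": curves,
        "mean_curve": curves.mean(axis=0),
        "se_curve": sd / np.sqrt(k),
        "sample_mean": float(x.mean()),
    }


# ---------------------------------------------------------------------------
# regular/irregular deviation study
# ---------------------------------------------------------------------------


def build_area_table(
    group_files: list, angle_step_deg: float = 1.0, min_size: int = 10
) -> pd.DataFrame:
    """Per-shape area estimates for a :func:`make_shape_group` output.

    Columns: ``file``, ``shape``, ``AIS`` (pixel-proportion), ``MA1``, ``MA2``
    (from computational diameters), and ``Expected`` (analytic; NaN for
    pseudopods).  Calibration comes from each file's rendered tag.
    """
    rows = []
    for file_idx, (mask, rendered) in enumerate(group_files):
        cal = calibrate(mask)
        clusters = cluster_pixels(mask, min_size=min_size)
        matched = _match_clusters_to_shapes(clusters, rendered)
        for shape_idx, (cluster, rshape) in enumerate(matched):
            ld, pd_ = computational_diameters(cluster, cal, angle_step_deg)
            rows.append(
                {
                    "file": file_idx,
                    "shape": shape_idx,
                    "AIS": cluster_area_cm2(cluster, cal),
                    "MA1": ma1_area(ld, pd_),
                    "MA2": ma2_area(ld, pd_),
                    "Expected": (
                        np.nan
                        if rshape.spec.analytic_area_cm2 is None
                        else rshape.spec.analytic_area_cm2
                    ),
                }
            )
    return pd.DataFrame(rows)


def _match_clusters_to_shapes(clusters, rendered):
    """Pair detected clusters with ground-truth shapes by pixel overlap."""
    pairs = []
    for rshape in rendered:
        best, best_ov = None, 0
        for cl in clusters:
            ov = int(rshape.pixel_mask[cl.pixels[:, 0], cl.pixels[:, 1]].sum())
            if ov > best_ov:
                best, best_ov = cl, ov
        if best is None:
            raise ValueError("a ground-truth shape has no detected cluster")
        pairs.append((best, rshape))
    return pairs


def deviation_summary(
    table: pd.DataFrame,
    reference: str,
    methods: list[str],
    group: str = "",
) -> list[DeviationSummary]:
    """Absolute percentage deviation of each method from the reference."""
    if reference not in table.columns:
        raise ValueError(f"missing reference column {reference!r}")
    out = []
    for m in methods:
        sub = table[[reference, m]].dropna()
        ref_v = sub[reference].to_numpy(dtype=float)
        met_v = sub[m].to_numpy(dtype=float)
        dev = 100.0 * np.abs(met_v - ref_v) / ref_v
        out.append(
            DeviationSummary(
                group=group,
                reference=reference,
                method=m,
                mean_pct=float(dev.mean()),
                sd_pct=float(dev.std(ddof=1)) if dev.size > 1 else 0.0,
                min_pct=float(dev.min()),
                max_pct=float(dev.max()),
                n=int(dev.size),
            )
        )
    return out


def deviation_study(
    group_files: list,
    group: str,
    methods: list[str] = ("AIS", "MA1", "MA2"),  # type: ignore[assignment]
    reference: str | None = None,
    angle_step_deg: float = 1.0,
) -> tuple[pd.DataFrame, list[DeviationSummary]]:
    """Percentage-deviation study for one shape group.

    The regular group is referenced against the analytic (``Expected``) area;
    the irregular group, which has no analytic area, against the
    pixel-proportion (``AIS``) estimate.
    """
    table = build_area_table(group_files, angle_step_deg=angle_step_deg)
    if reference is None:
        reference = "Expected" if group == "regular" else "AIS"
    if reference == "Expected" and table["Expected"].isna().all():
        raise ValueError("group has no analytic reference areas")
    methods = [m for m in methods if m != reference]
    return table, deviation_summary(table, reference, methods, group=group)
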