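"""Distribution statistics for inter-CDS length samples.

Lengths are analysed on the log10 scale, where neutral, length-proportional
indel dynamics predict a normal (hence raw-scale log-normal) distribution.
Promoter-containing strata are left-truncated by the minimal regulatory
space; the left edge is estimated by a low empirical quantile. Bimodality of
divergent strata (shared vs. independent promoters) is probed by fitting one
and two scaled Gaussian curves to the binned log10 histogram and comparing
the fits with a nested F-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .regions import AGE_OLD, AGE_YOUNG, ORIENTATIONS, InterCDSRegion

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LowerLimitEstimate:
    """Estimated left edge of a length distribution (bp)."""

    value: int
    method: str  # "min" or "quantile"
    quantile: float
    n: int


@dataclass(frozen=True)
class GaussianComponent:
    mean: float  # log10 bp
    sd: float  # log10 bp
    weight: float  # fraction of total area
    amplitude: float  # peak height in counts

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("component sd must be positive")


@dataclass(frozen=True)
class MixtureFit:
    components: tuple[GaussianComponent, ...]
    rss: float
    n_params: int
    bin_width: float
    bin_edges: tuple[float, ...]
    bin_counts: tuple[int, ...]

    @property
    def k(self) -> int:
        return len(self.components)


@dataclass(frozen=True)
class FitComparison:
    f_statistic: float
    p_value: float
    df_num: int
    df_den: int


def estimate_lower_limit(
    lengths: Sequence[int] | np.ndarray,
    method: str = "quantile",
    q: float = 0.01,
) -> LowerLimitEstimate:
    """Estimate the location of the lower limit of a length sample.

    ``method="min"`` returns the sample minimum. ``method="quantile"``
    (default) returns the empirical q-quantile with linear interpolation,
    which is robust to a stray mis-annotation; it falls back to the minimum
    (with a warning) for samples smaller than 20.
    """
    arr = np.asarray(lengths, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot estimate a lower limit from an empty sample")
    if method not in ("min", "quantile"):
        raise ValueError(f"unknown method {method!r}")
    if not 0.0 <= q <= 0.05:
        raise ValueError("q must lie in [0, 0.05]")
    if method == "quantile" and arr.size < 20:
        logger.warning(
            "lower-limit sample has n=%d < 20; falling back to the minimum", arr.size
        )
        method = "min"
    if method == "min":
        value = float(arr.min())
    else:
        value = float(np.quantile(arr, q, method="linear"))
    return LowerLimitEstimate(int(round(value)), method, q, int(arr.size))


# ---------------------------------------------------------------------------
# Gaussian fits on binned log10 histograms


def _histogram_log10(lengths: np.ndarray, bin_width: float):
    logs = np.log10(lengths)
    lo = np.floor(logs.min() / bin_width) * bin_width
    hi = np.ceil(logs.max() / bin_width) * bin_width
    n_bins = max(int(round((hi - lo) / bin_width)), 1)
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(logs, bins=edges)
    return edges, counts


def _gauss_sum(x: np.ndarray, params: np.ndarray) -> np.ndarray:
    """Sum of scaled Gaussians; params = [amp1, mu1, sd1, amp2, mu2, sd2, ...]."""
    y = np.zeros_like(x)
    for amp, mu, sd in params.reshape(-1, 3):
        y = y + amp * np.exp(-0.5 * ((x - mu) / sd) ** 2)
    return y


def _ls_fit(centers, counts, p0, bounds):
    # bin counts are Poisson; scaling residuals by sqrt(count) makes them
    # approximately unit-variance, which the nested F-test assumes
    sigma = np.sqrt(np.maximum(counts, 1.0))
    # x_scale='jac' equalises the wildly different parameter scales
    # (amplitudes in counts vs sds in log10 units)
    res = optimize.least_squares(
        lambda p: (_gauss_sum(centers, p) - counts) / sigma,
        p0, bounds=bounds, method="trf", x_scale="jac", max_nfev=5000,
    )
    # status 0 = evaluation budget exhausted; anything positive is a
    # convergence criterion being met
    return res.x, float(np.sum(res.fun**2)), res.status > 0


def fit_gaussians(
    lengths: Sequence[int] | np.ndarray,
    k: int,
    bin_width_log10: float = 0.1,
    seed: int | None = 0,
) -> MixtureFit:
    """Least-squares fit of k scaled Gaussian curves to the log10 histogram.

    Each component carries an amplitude, mean and sd (3 free parameters per
    component). For k=2 the optimiser is multi-started: means at the 25%/75%
    sample quantiles, four seeded random perturbations, and a degenerate
    split of the k=1 solution (which guarantees RSS(k=2) <= RSS(k=1));
    the best RSS wins. Components are reported in order of increasing mean.
    """
    if k not in (1, 2):
        raise ValueError("k must be 1 or 2")
    arr = np.asarray(lengths, dtype=float)
    if arr.size < 50:
        raise ValueError(f"need n >= 50 lengths to fit a histogram, got {arr.size}")
    if (arr < 1).any():
        raise ValueError("lengths must be >= 1 bp")
    edges, counts = _histogram_log10(arr, bin_width_log10)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts_f = counts.astype(float)

    logs = np.log10(arr)
    mu0, sd0 = float(logs.mean()), float(max(logs.std(ddof=1), bin_width_log10))
    amp0 = float(max(counts.max(), 1.0))
    # identifiability constraints: a component narrower than one bin cannot
    # be located within it, and a component centred outside the observed
    # range can mimic an arbitrary spike with a runaway amplitude — so sd is
    # floored at the bin width and means stay inside the histogram
    lo_b = [0.0, edges[0], bin_width_log10]
    hi_b = [np.inf, edges[-1], 10.0 * max(sd0, 1.0)]

    p1, rss1, ok1 = _ls_fit(
        centers, counts_f, np.array([amp0, mu0, sd0]), (lo_b, hi_b)
    )
    if k == 1:
        if not ok1:
            raise RuntimeError("single-Gaussian fit did not converge")
        return _make_fit(p1, edges, counts, bin_width_log10)

    rng = np.random.default_rng(seed)
    sd_floor = bin_width_log10
    q25, q75 = np.quantile(logs, [0.25, 0.75])
    s0 = max(sd0 / 2, sd_floor)
    starts = [np.array([amp0 / 2, q25, s0, amp0 / 2, q75, s0])]
    for _ in range(4):
        mus = rng.uniform(logs.min(), logs.max(), size=2)
        sds = np.maximum(rng.uniform(0.3, 1.5, size=2) * sd0, sd_floor)
        amps = rng.uniform(0.2, 1.0, size=2) * amp0
        starts.append(np.array([amps[0], mus[0], sds[0], amps[1], mus[1], sds[1]]))
    # degenerate split of the k=1 optimum: reproduces its curve exactly,
    # so the k=2 optimum can never be worse (nested models)
    starts.append(np.array([p1[0] / 2, p1[1], p1[2], p1[0] / 2, p1[1], p1[2]]))

    best = None
    failures = []
    for s in starts:
        try:
            p, rss, ok = _ls_fit(centers, counts_f, s, (lo_b * 2, hi_b * 2))
        except Exception as exc:  # pragma: no cover - optimizer edge cases
            failures.append((s, str(exc)))
            continue
        if not ok:
            failures.append((s, "no convergence"))
            continue
        if best is None or rss < best[1]:
            best = (p, rss)
    if best is None:
        raise RuntimeError(f"two-Gaussian fit failed from all starts: {failures}")
    return _make_fit(best[0], edges, counts, bin_width_log10)


def _make_fit(params, edges, counts, bin_width) -> MixtureFit:
    comps = sorted(params.reshape(-1, 3), key=lambda c: c[1])
    areas = np.array([amp * sd for amp, _, sd in comps])
    total = areas.sum()
    weights = areas / total if total > 0 else np.full(len(comps), 1 / len(comps))
    centers = 0.5 * (edges[:-1] + edges[1:])
    sigma = np.sqrt(np.maximum(counts, 1.0))
    rss = float(
        np.sum(((_gauss_sum(centers, np.concatenate(comps)) - counts) / sigma) ** 2)
    )
    return MixtureFit(
        components=tuple(
            GaussianComponent(mean=float(mu), sd=float(sd), weight=float(w),
                              amplitude=float(amp))
            for (amp, mu, sd), w in zip(comps, weights)
        ),
        rss=rss,
        n_params=3 * len(comps),
        bin_width=float(bin_width),
        bin_edges=tuple(float(e) for e in edges),
        bin_counts=tuple(int(c) for c in counts),
    )


def compare_fits(fit1: MixtureFit, fit2: MixtureFit) -> FitComparison:
    """Nested-model F-test on binned residuals (1 vs 2 Gaussian components)."""
    if fit1.k != 1 or fit2.k != 2:
        raise ValueError("compare_fits expects a k=1 fit and a k=2 fit")
    if fit1.bin_edges != fit2.bin_edges:
        raise ValueError("fits must share identical histogram bins")
    n_bins = len(fit1.bin_counts)
    df_num = fit2.n_params - fit1.n_params
    df_den = n_bins - fit2.n_params
    if df_den <= 0:
        raise ValueError(f"too few bins ({n_bins}) for the F-test")
    if fit2.rss > fit1.rss * (1 + 1e-9) + 1e-12:
        raise RuntimeError(
            "RSS(k=2) exceeds RSS(k=1); the two-component optimiser failed — refit"
        )
    rss2 = fit2.rss
    if rss2 == 0.0:
        return FitComparison(np.inf, 0.0, df_num, df_den)
    f_stat = max((fit1.rss - rss2) / df_num, 0.0) / (rss2 / df_den)
    p = float(sps.f.sf(f_stat, df_num, df_den))
    return FitComparison(float(f_stat), p, df_num, df_den)


# ---------------------------------------------------------------------------
# stratified summaries and cross-species statistics


def summarize_lengths(
    regions: Iterable[InterCDSRegion],
    lower_limit_method: str = "quantile",
    lower_limit_q: float = 0.01,
) -> pd.DataFrame:
    """Per-(species, age, orientation) stratum means and lower limits.

    Replicates the layout of a per-species summary table: arithmetic mean of
    raw lengths (bp, rounded) and the estimated location of the lower limit.
    Tandem- or repeat-flagged regions and unassigned ages are excluded. Empty
    strata yield rows with missing markers so that no stratum silently
    disappears.
    """
    rows = []
    kept = [r for r in regions if r.retained and r.age_label in (AGE_OLD, AGE_YOUNG)]
    by_stratum: dict[tuple[str, str, str], list[int]] = {}
    for r in kept:
        by_stratum.setdefault((r.species, r.age_label, r.orientation), []).append(r.length)
    species = sorted({r.species for r in kept})
    for sp in species:
        for age in (AGE_OLD, AGE_YOUNG):
            for orientation in ORIENTATIONS:
                lengths = by_stratum.get((sp, age, orientation), [])
                if lengths:
                    ll = estimate_lower_limit(lengths, lower_limit_method, lower_limit_q)
                    rows.append(
                        {"species": sp, "age": age, "orientation": orientation,
                         "n": len(lengths),
                         "mean_bp": int(round(float(np.mean(lengths)))),
                         "lower_limit_bp": ll.value}
                    )
                else:
                    rows.append(
                        {"species": sp, "age": age, "orientation": orientation,
                         "n": 0, "mean_bp": pd.NA, "lower_limit_bp": pd.NA}
                    )
    return pd.DataFrame(
        rows, columns=["species", "age", "orientation", "n", "mean_bp", "lower_limit_bp"]
    )


def cv_across_species(values: Sequence[float]) -> float:
    """Coefficient of variation (sample sd / mean) of one value per species."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("mean is zero; CV undefined")
    return float(arr.std(ddof=1) / mean)


@dataclass(frozen=True)
class CompositionTest:
    chi2: float
    p_value: float
    observed: tuple[int, int, int]  # divergent, unidirectional, convergent
    expected: tuple[float, float, float]


def orientation_composition_test(
    regions: Iterable[InterCDSRegion],
    length_window: tuple[float, float],
) -> CompositionTest:
    """Chi-square test of orientation counts in a length window vs 25/50/25.

    Under random, orientation-independent gene placement one expects 25%
    divergent, 50% co-oriented and 25% convergent pairs in any length window;
    departures flag orientation-specific length constraints.
    """
    lo, hi = length_window
    if hi < lo:
        raise ValueError("empty length window")
    counts = {o: 0 for o in ORIENTATIONS}
    for r in regions:
        if r.retained and lo <= r.length <= hi:
            counts[r.orientation] += 1
    observed = (counts["divergent"], counts["unidirectional"], counts["convergent"])
    total = sum(observed)
    if total < 1:
        raise ValueError("no regions in the length window")
    expected = (0.25 * total, 0.50 * total, 0.25 * total)
    chi2, p = sps.chisquare(observed, expected)
    return CompositionTest(float(chi2), float(p), observed, expected)


def correlate(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation with two-sided t-test p-value (df = n - 2)."""
    xa, ya = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if xa.size != ya.size or xa.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if not (np.isfinite(xa).all() and np.isfinite(ya).all()):
        raise ValueError("non-finite values")
    if xa.std() == 0 or ya.std() == 0:
        raise ValueError("zero variance in x or y")
    r, p = sps.pearsonr(xa, ya)
    return float(r), float(p)


def optimized_space(canonical_promoter_bp: float, median_utr5_bp: float) -> float:
    """Optimized regulatory space of a divergent pair: promoter + 2 x 5'UTR."""
    if canonical_promoter_bp < 0 or median_utr5_bp < 0:
        raise ValueError("inputs must be non-negative")
    return canonical_promoter_bp + 2.0 * median_utr5_bp
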