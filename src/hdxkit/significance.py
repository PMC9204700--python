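"""Hybrid statistical significance testing of differential HDX data.

A difference between two states is called significant only when it
clears *both* hurdles: the absolute difference exceeds a dataset-wide
global threshold derived from replicate variability, and a Welch t test
(Satterthwaite degrees of freedom) gives p < alpha.  The global
threshold removes the flood of tiny-but-"significant" differences that
a t test alone produces on low-replicate HDX data.

Because fitted quantities (uptake area, k_obs, Pf) have no direct
per-replicate value, replicate-level distributions are built by
re-fitting combinations of replicates in three ways: one fit per
replicate index, random replicate-per-time-point combinations, or
bootstrap resampling over all time->replicate assignments.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .cluster_io import Species, UptakeCurve, iter_species
from .kinetics import fit_stretched_exponential, integrate_area

DISTRIBUTION_METHODS = ("per_replicate", "random", "bootstrap")
THRESHOLD_METHODS = ("sd_ci", "pairwise_ci", "bootstrap_ci")
OUTLIER_METHODS = ("none", "mean", "median", "quartiles", "grubbs", "gesd")

#: Normal-consistency scaled-MAD constant, -1/(sqrt(2)*erfcinv(3/2)).
_MAD_SCALE = float(-1.0 / (math.sqrt(2.0) * special.erfcinv(1.5)))


class SignificanceError(ValueError):
    pass


@dataclass
class DistributionSet:
    """Replicate-level samples of one metric for one species/state."""

    species: Species
    state: str
    metric: str                      # uptake | uptake_area | k_obs | pf
    samples: np.ndarray
    method: str                      # per_replicate | random | bootstrap
    combo_values: np.ndarray | None = None   # the s combination fits (bootstrap)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise SignificanceError("empty distribution")
        if self.method not in DISTRIBUTION_METHODS:
            raise SignificanceError(f"unknown distribution method {self.method!r}")

    @property
    def mean(self) -> float:
        return float(self.samples.mean())

    @property
    def sd(self) -> float:
        return float(self.samples.std(ddof=1)) if len(self.samples) > 1 else 0.0


@dataclass(frozen=True)
class GlobalThreshold:
    """Dataset-wide minimum |difference| required for significance."""

    metric: str
    method: str
    confidence: float
    value: float
    outlier_method: str = "none"
    pool_size: int = 0
    n_a: int | None = None
    n_b: int | None = None


@dataclass
class ComparisonResult:
    """Per-species (or per-residue) difference between two states."""

    species: Species | int | None
    state_a: str
    state_b: str
    metric: str
    difference: float                # mean_a - mean_b
    p_value: float
    threshold: float = math.nan
    significant: bool | None = None


# ---------------------------------------------------------------------------
# Replicate-combination distributions


def _metric_fn(metric: str, species: Species, window, fit_settings: dict,
               time: float | None, k_int: float | None) -> Callable:
    settings = dict(nexp=1, fix_n=False, n_starts=2)
    settings.update(fit_settings or {})
    nexp = settings.pop("nexp")
    n_max = settings.pop("n_max", float(species.max_uptake) or math.inf)

    def fit_curve(sub: UptakeCurve):
        return fit_stretched_exponential(sub, nexp=nexp, n_max=n_max, **settings)

    if metric == "uptake_area":
        def fn(sub: UptakeCurve) -> float:
            fit = fit_curve(sub)
            return integrate_area(fit, window).hdx_area
        return fn
    if metric == "k_obs":
        return lambda sub: fit_curve(sub).k_obs
    if metric == "pf":
        if k_int is None:
            raise SignificanceError("metric 'pf' requires k_int")
        return lambda sub: k_int / fit_curve(sub).k_obs
    raise SignificanceError(f"unknown fitted metric {metric!r}")


def enumerate_assignments(curve: UptakeCurve, cap: int = 100_000) -> list[dict]:
    """All time -> replicate assignments (the bootstrap candidate pool)."""
    times = curve.unique_times()
    options = [curve.replicates_at(t) for t in times]
    total = int(np.prod([len(o) for o in options]))
    if total > cap:
        raise SignificanceError(
            f"{total} assignments exceed enumeration cap {cap}")
    return [dict(zip(times, combo)) for combo in itertools.product(*options)]


def _random_assignment(curve: UptakeCurve, rng: np.random.Generator) -> dict:
    return {t: rng.choice(curve.replicates_at(t)) for t in curve.unique_times()}


def build_distribution(curve: UptakeCurve, method: str,
                       metric: str = "uptake_area", *,
                       window: tuple[float, float] | None = None,
                       time: float | None = None,
                       k_int: float | None = None,
                       n_samples_s: int = 100,
                       bootstrap_b: int = 10_000,
                       seed: int | np.random.Generator | None = None,
                       fit_settings: dict | None = None) -> DistributionSet:
    """Build the replicate-level distribution of a metric for one curve.

    Methods:

    * ``per_replicate`` — one fit per replicate index; times where that
      replicate is missing are simply skipped for it.
    * ``random`` — n fits (n = number of replicates), each drawing one
      random replicate per time point.
    * ``bootstrap`` — ``n_samples_s`` assignments drawn uniformly with
      replacement from all time->replicate assignments are fitted, then
      ``bootstrap_b`` bootstrap resamples of those fitted values are
      drawn and each resample's mean recorded.

    The ``uptake`` metric comes straight from the experimental points at
    ``time`` (no fitting) and supports ``per_replicate`` only.
    Deterministic under a fixed ``seed``.
    """
    if method not in DISTRIBUTION_METHODS:
        raise SignificanceError(f"unknown distribution method {method!r}")
    if curve.n_replicates < 2:
        raise SignificanceError(
            f"{curve.species.label}: a single replicate admits no distribution")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if metric == "uptake":
        if time is None:
            raise SignificanceError("metric 'uptake' requires a time point")
        if method != "per_replicate":
            raise SignificanceError(
                "the uptake metric is read from the experimental points; "
                "use the per_replicate method")
        mask = curve.times == time
        if not mask.any():
            raise SignificanceError(f"no measurements at t={time}s")
        order = np.argsort(curve.replicates[mask])
        samples = curve.uptakes[mask][order]
        return DistributionSet(curve.species, curve.state, metric, samples, method)

    if window is None:
        tpos = curve.times[curve.times > 0]
        window = (float(tpos.min()), float(tpos.max()))
    fn = _metric_fn(metric, curve.species, window, fit_settings, time, k_int)

    if method == "per_replicate":
        samples = [fn(curve.subset_replicate(r)) for r in curve.replicate_ids()]
        return DistributionSet(curve.species, curve.state, metric,
                               np.array(samples), method)

    if method == "random":
        n = curve.n_replicates
        samples = [fn(curve.subset_assignment(_random_assignment(curve, rng)))
                   for _ in range(n)]
        return DistributionSet(curve.species, curve.state, metric,
                               np.array(samples), method)

    # bootstrap: sample assignments uniformly with replacement, fit each,
    # then bootstrap the mean of the fitted values.
    combo_values = np.array([
        fn(curve.subset_assignment(_random_assignment(curve, rng)))
        for _ in range(n_samples_s)
    ])
    idx = rng.integers(0, n_samples_s, size=(bootstrap_b, n_samples_s))
    # resample centered deviations: identical combination values then
    # yield exactly identical means (no summation-order jitter)
    center = combo_values.mean()
    means = center + (combo_values - center)[idx].mean(axis=1)
    return DistributionSet(curve.species, curve.state, metric, means,
                           method, combo_values=combo_values)


# ---------------------------------------------------------------------------
# Outlier removal (isoutlier-compatible methods)


def remove_outliers(values, method: str = "median", alpha: float = 0.05,
                    ) -> np.ndarray:
    """Remove outliers with one of the five supported detectors.

    mean: outside mean ± 3 sd; median: outside median ± 3 scaled MAD;
    quartiles: outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR]; grubbs: iterative
    two-sided Grubbs test; gesd: generalized extreme studentized deviate
    with at most ceil(10%) outliers.  Fewer than 3 values are returned
    unchanged with a warning.
    """
    if method == "none":
        return np.asarray(values, dtype=float)
    if method not in OUTLIER_METHODS:
        raise SignificanceError(f"unknown outlier method {method!r}")
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        import logging
        logging.getLogger(__name__).warning(
            "outlier removal skipped: need >= 3 values, got %d", len(x))
        return x

    if method == "mean":
        mu, sd = x.mean(), x.std(ddof=1)
        return x[np.abs(x - mu) <= 3 * sd]
    if method == "median":
        med = np.median(x)
        smad = _MAD_SCALE * np.median(np.abs(x - med))
        return x[np.abs(x - med) <= 3 * smad]
    if method == "quartiles":
        q1, q3 = np.percentile(x, [25, 75])
        iqr = q3 - q1
        return x[(x >= q1 - 1.5 * iqr) & (x <= q3 + 1.5 * iqr)]
    if method == "grubbs":
        keep = x.copy()
        while len(keep) >= 3:
            mu, sd = keep.mean(), keep.std(ddof=1)
            if sd == 0:
                break
            n = len(keep)
            dev = np.abs(keep - mu)
            i = int(dev.argmax())
            g = dev[i] / sd
            t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
            crit = (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))
            if g > crit:
                keep = np.delete(keep, i)
            else:
                break
        return keep
    # gesd
    n = len(x)
    r_max = math.ceil(0.10 * n)
    keep = x.copy()
    removed_idx: list[int] = []
    stats_r, crits = [], []
    work = keep.copy()
    for i in range(1, r_max + 1):
        sd = work.std(ddof=1)
        if sd == 0 or len(work) < 3:
            break
        dev = np.abs(work - work.mean())
        j = int(dev.argmax())
        stats_r.append(dev[j] / sd)
        nn = len(work)
        p = 1 - alpha / (2 * nn)
        t = stats.t.ppf(p, nn - 2)
        crits.append((nn - 1) * t / math.sqrt((nn - 2 + t * t) * nn))
        work = np.delete(work, j)
    n_out = 0
    for i in range(len(stats_r)):
        if stats_r[i] > crits[i]:
            n_out = i + 1
    if n_out == 0:
        return keep
    work = keep.copy()
    for _ in range(n_out):
        dev = np.abs(work - work.mean())
        work = np.delete(work, int(dev.argmax()))
    return work


# ---------------------------------------------------------------------------
# Global significance thresholds


def _z(confidence: float) -> float:
    if not 0.5 < confidence < 1.0:
        raise SignificanceError(f"confidence {confidence} outside (0.5, 1)")
    return float(stats.norm.ppf(1 - (1 - confidence) / 2))


def global_threshold_sd(dists: Sequence[DistributionSet], confidence: float,
                        n_a: int, n_b: int,
                        outlier_method: str = "none") -> GlobalThreshold:
    """Confidence-interval threshold from pooled replicate SDs.

    The per-species variances (across all species and both states) are
    pooled by averaging; the threshold on a difference of state means is
    ``z * sqrt(s2/n_a + s2/n_b)``.
    """
    if len(dists) < 2:
        raise SignificanceError("need sd estimates from >= 2 species")
    sds = np.array([d.sd for d in dists])
    sds = remove_outliers(sds, outlier_method)
    s2 = float(np.mean(sds ** 2))
    value = _z(confidence) * math.sqrt(s2 / n_a + s2 / n_b)
    return GlobalThreshold(dists[0].metric, "sd_ci", confidence, value,
                           outlier_method, len(sds), n_a, n_b)


def global_threshold_pairwise(dists: Sequence[DistributionSet],
                              confidence: float,
                              outlier_method: str = "none") -> GlobalThreshold:
    """Threshold from within-state pairwise replicate differences.

    All pairwise differences between replicate-level values within each
    state are pooled across species (pairwise rather than vs-the-mean so
    a single outlier cannot drag the center away from zero), optionally
    cleaned of outliers, and fitted with a zero-mean normal; the upper
    two-sided CI limit z*sd is the threshold.  Only defined for the
    per_replicate and random distribution methods.
    """
    diffs = []
    for d in dists:
        if d.method == "bootstrap":
            raise SignificanceError(
                "pairwise threshold applies to per_replicate/random "
                "distributions, not bootstrap")
        for a, b in itertools.combinations(d.samples, 2):
            diffs.append(a - b)
    if not diffs:
        raise SignificanceError("no pairwise differences available")
    diffs = remove_outliers(np.array(diffs), outlier_method)
    sd = math.sqrt(float(np.mean(np.square(diffs))))  # zero-mean normal fit
    return GlobalThreshold(dists[0].metric, "pairwise_ci", confidence,
                           _z(confidence) * sd, outlier_method, len(diffs))


def global_threshold_bootstrap(dists: Sequence[DistributionSet],
                               confidence: float) -> GlobalThreshold:
    """Percentile threshold from pooled bootstrap means.

    Every species' bootstrap means are centered on the species' own
    overall mean and pooled; the threshold is the upper bound of the
    two-sided confidence interval of the pooled distribution (percentile
    method).  Centering makes the pool a null distribution so that
    noise-free data yield a threshold of exactly zero.
    """
    if not 0.5 < confidence < 1.0:
        raise SignificanceError(f"confidence {confidence} outside (0.5, 1)")
    pool = []
    for d in dists:
        if d.method != "bootstrap":
            raise SignificanceError("bootstrap threshold needs bootstrap distributions")
        if np.ptp(d.samples) == 0.0:
            # degenerate (noise-free) distribution: centering must be
            # exact, not subject to summation rounding of the mean
            pool.append(np.zeros_like(d.samples))
        else:
            pool.append(d.samples - d.samples.mean())
    pool = np.concatenate(pool)
    value = float(np.quantile(pool, 1 - (1 - confidence) / 2))
    return GlobalThreshold(dists[0].metric, "bootstrap_ci", confidence,
                           max(value, 0.0), "none", len(pool))


# ---------------------------------------------------------------------------
# Welch's t test and the hybrid criterion


def welch_test(samples_a, samples_b) -> tuple[float, float, float]:
    """Two-sided Welch t test with Satterthwaite degrees of freedom.

    Returns (t, df, p).  Degenerate zero-variance groups fall back to
    the convention p = 1 for equal means and p = 0 otherwise.
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise SignificanceError("Welch test needs >= 2 samples per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    if va == 0 and vb == 0:
        import logging
        logging.getLogger(__name__).info(
            "Welch test on two zero-variance groups; p set by convention")
        equal = a.mean() == b.mean()
        return (0.0 if equal else math.inf * np.sign(a.mean() - b.mean()),
                float(na + nb - 2), 1.0 if equal else 0.0)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), float(df), p


def hybrid_test(comparisons: Sequence[ComparisonResult],
                threshold: GlobalThreshold,
                alpha: float = 0.05) -> list[ComparisonResult]:
    """Apply the hybrid criterion: |Δ| > threshold AND p < alpha."""
    out = []
    for comp in comparisons:
        if comp.metric != threshold.metric:
            raise SignificanceError(
                f"metric mismatch: comparison {comp.metric!r} vs "
                f"threshold {threshold.metric!r}")
        sig = (abs(comp.difference) > threshold.value) and (comp.p_value < alpha)
        out.append(replace(comp, threshold=threshold.value, significant=sig))
    return out


# ---------------------------------------------------------------------------
# End-to-end differential analysis


def differential_analysis(table: pd.DataFrame, state_a: str, state_b: str, *,
                          metric: str = "uptake_area",
                          dist_method: str = "per_replicate",
                          threshold_method: str = "sd_ci",
                          confidence: float = 0.95,
                          alpha: float = 0.05,
                          outlier_method: str = "none",
                          window: tuple[float, float] | None = None,
                          time: float | None = None,
                          n_samples_s: int = 100,
                          bootstrap_b: int = 10_000,
                          seed: int | None = None,
                          fit_settings: dict | None = None,
                          ) -> tuple[pd.DataFrame, GlobalThreshold,
                                     list[ComparisonResult]]:
    """Compare two states of an uptake table species by species.

    Builds the replicate-level metric distributions for both states,
    derives the requested global threshold from the pooled dataset,
    Welch-tests each species (on the replicate-level samples; for the
    bootstrap threshold the t test still uses per-replicate fits), and
    applies the hybrid criterion.  Returns a tidy comparison frame, the
    threshold, and the raw comparison objects.
    """
    if threshold_method not in THRESHOLD_METHODS:
        raise SignificanceError(f"unknown threshold method {threshold_method!r}")
    if threshold_method == "bootstrap_ci" and dist_method != "bootstrap":
        raise SignificanceError("bootstrap_ci requires the bootstrap distributions")
    if threshold_method == "pairwise_ci" and dist_method == "bootstrap":
        raise SignificanceError("pairwise_ci is undefined for bootstrap distributions")

    rng = np.random.default_rng(seed)
    dists: list[DistributionSet] = []
    welch_dists: dict[tuple, dict[str, DistributionSet]] = {}
    species_list: list[Species] = []
    for species, _sub in iter_species(table):
        try:
            curves = {s: UptakeCurve.from_table(table, species, s)
                      for s in (state_a, state_b)}
        except ValueError:
            continue  # species absent from one state
        species_list.append(species)
        for state, curve in curves.items():
            dist = build_distribution(
                curve, dist_method, metric, window=window, time=time,
                n_samples_s=n_samples_s, bootstrap_b=bootstrap_b, seed=rng,
                fit_settings=fit_settings)
            dists.append(dist)
            if dist_method == "bootstrap":
                # Welch needs replicate-level samples, not bootstrap means.
                wdist = build_distribution(
                    curve, "per_replicate", metric, window=window, time=time,
                    seed=rng, fit_settings=fit_settings)
            else:
                wdist = dist
            welch_dists.setdefault(species.key, {})[state] = wdist
    if not species_list:
        raise SignificanceError(
            f"no species observed in both {state_a!r} and {state_b!r}")

    n_a = len(welch_dists[species_list[0].key][state_a].samples)
    n_b = len(welch_dists[species_list[0].key][state_b].samples)
    if threshold_method == "sd_ci":
        threshold = global_threshold_sd(dists, confidence, n_a, n_b, outlier_method)
    elif threshold_method == "pairwise_ci":
        threshold = global_threshold_pairwise(dists, confidence, outlier_method)
    else:
        threshold = global_threshold_bootstrap(dists, confidence)

    comparisons = []
    for species in species_list:
        da = welch_dists[species.key][state_a]
        db = welch_dists[species.key][state_b]
        _t, _df, p = welch_test(da.samples, db.samples)
        comparisons.append(ComparisonResult(
            species, state_a, state_b, metric, da.mean - db.mean, p))
    comparisons = hybrid_test(comparisons, threshold, alpha)

    frame = pd.DataFrame([{
        "protein": c.species.protein, "start": c.species.start,
        "end": c.species.end, "sequence": c.species.sequence,
        "modification": c.species.modification, "fragment": c.species.fragment,
        "state_a": c.state_a, "state_b": c.state_b, "metric": c.metric,
        "difference": c.difference, "p_value": c.p_value,
        "threshold": c.threshold, "significant": c.significant,
    } for c in comparisons])
    return frame, threshold, comparisons
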