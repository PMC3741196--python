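"""The three per-probe-set tissue-specificity detectors.

``roku_spm``
    Entropy-gated classification: a robustly centred Shannon entropy decides
    specific-vs-ubiquitous, an AIC-based one-sided outlier search locates up
    to two candidate tissues, and the SPM specificity measure (squared cosine
    between the expression vector and a tissue indicator) confirms them.

``decision``
    Gap-based classification on the sorted profile: the gap g between
    consecutive order statistics, the specificity fraction sp = g / range and
    the decision value d = g / sd(low group) must all clear thresholds.

``bayes``
    An encompassing-prior Bayes factor on replicated data: the ratio of the
    posterior and prior probabilities that the top-ranked tissue mean exceeds
    the rest by a margin of c between-tissue standard deviations
    (specificity), or that the top two do (2-selectivity).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .datatypes import Call, Category, ValidationError

__all__ = [
    "RokuSpmParams",
    "DecisionParams",
    "BayesParams",
    "BfSimConfig",
    "tukey_biweight",
    "roku_entropy",
    "spm",
    "ueda_outliers",
    "roku_spm_classify",
    "decision_function_classify",
    "bayes_factor",
    "bayes_factor_details",
    "bayes_classify",
    "calibrate_bf_thresholds",
    "RokuSpmDetector",
    "DecisionDetector",
    "BayesDetector",
    "make_detector",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RokuSpmParams:
    """Entropy threshold (bits) plus the two SPM confirmation thresholds."""

    h_max: float = 2.5
    spm1: float = 0.8
    spm2: float = 0.7

    def __post_init__(self) -> None:
        if self.h_max < 0:
            raise ValidationError("h_max must be >= 0")
        for name in ("spm1", "spm2"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValidationError(f"{name} must lie in (0, 1], got {v}")


@dataclass(frozen=True)
class DecisionParams:
    """Minimum gap (log2 units), specificity fraction and decision value."""

    g_min: float = 2.0
    sp_min: float = 0.3
    d_min: float = 3.0

    def __post_init__(self) -> None:
        if not (0 < self.sp_min <= 1):
            raise ValidationError(f"sp_min must lie in (0, 1], got {self.sp_min}")


@dataclass(frozen=True)
class BayesParams:
    """Margin constant c, Bayes-factor thresholds and Monte-Carlo settings."""

    c: float = 1.0
    bf1: float = 10.0
    bf2: float = 10.0
    n_draws: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c < 0:
            raise ValidationError("c must be >= 0")
        if self.bf1 <= 0 or self.bf2 <= 0:
            raise ValidationError("Bayes-factor thresholds must be > 0")
        if self.n_draws < 10_000:
            raise ValidationError("n_draws must be >= 10^4 for a stable estimate")


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

_BIWEIGHT_C = 5.0
_BIWEIGHT_EPS = 1e-4


def tukey_biweight(values: Sequence[float]) -> float:
    """One-step Tukey biweight location estimate (tuning constant 5).

    The MAD in the denominator is guarded by a small epsilon so that
    profiles with a zero MAD still downweight gross outliers.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValidationError("tukey_biweight requires at least one value")
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    u = (x - med) / (_BIWEIGHT_C * mad + _BIWEIGHT_EPS)
    w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
    if w.sum() == 0:
        return med
    return float(np.sum(w * x) / np.sum(w))


def roku_entropy(profile: Sequence[float]) -> float:
    """Shannon entropy (bits) of the robustly centred expression profile.

    The profile is processed as x'_t = |x_t - Tbi(x)| and normalised to a
    probability vector.  A flat profile (all x' zero) returns the maximal
    entropy log2(n) by convention.
    """
    x = np.asarray(profile, dtype=float)
    if x.size < 3:
        raise ValidationError("entropy needs a profile over >= 3 tissues")
    processed = np.abs(x - tukey_biweight(x))
    total = processed.sum()
    if total <= 0:
        return float(np.log2(x.size))
    p = processed / total
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def spm(profile: Sequence[float], tissue_subset: Sequence[int]) -> float:
    """Specificity measure: squared cosine to the subset indicator vector.

    For one tissue i this is x_i^2 / sum_j x_j^2; for a pair it is the
    squared cosine to the equal-weight two-tissue indicator.  Intensities
    must be non-negative (linear scale).
    """
    x = np.asarray(profile, dtype=float)
    idx = list(tissue_subset)
    if len(idx) not in (1, 2):
        raise ValidationError("SPM is defined for subsets of 1 or 2 tissues")
    if np.any(x < 0):
        raise ValidationError("SPM requires non-negative intensities")
    denom = float(np.sum(x**2))
    if denom == 0:
        raise ValidationError("SPM undefined for an all-zero profile")
    dot = float(x[idx].sum())
    return dot**2 / (len(idx) * denom)


_RSS_FLOOR = 1e-12


def _rank_desc(x: np.ndarray) -> list[int]:
    """Indices sorted by value descending; ties broken by panel position."""
    return sorted(range(x.size), key=lambda i: (-x[i], i))


def ueda_outliers(profile: Sequence[float], max_outliers: int = 2) -> list[int]:
    """AIC-selected set of high-side outlier tissues (at most ``max_outliers``).

    Candidate outlier sets are the prefixes of the descending value ranking
    (including the empty set).  The AIC of a candidate U is
    m*ln(RSS/m) + 2*(|U|+1) with m non-outlier values; the minimising U is
    returned (ordered by rank), preferring fewer outliers on ties.
    """
    if max_outliers not in (1, 2):
        raise ValidationError("max_outliers must be 1 or 2")
    x = np.asarray(profile, dtype=float)
    order = _rank_desc(x)
    best_u: list[int] = []
    best_aic = math.inf
    for k in range(0, max_outliers + 1):
        rest = np.delete(x, order[:k])
        m = rest.size
        if m == 0:
            break
        rss = float(np.sum((rest - rest.mean()) ** 2))
        aic = m * math.log(max(rss, _RSS_FLOOR) / m) + 2.0 * (k + 1)
        if aic < best_aic:
            best_aic = aic
            best_u = order[:k]
    return list(best_u)


# ---------------------------------------------------------------------------
# ROKU-SPM classifier
# ---------------------------------------------------------------------------

def _linear(profile: np.ndarray, spm_scale: str) -> np.ndarray:
    if spm_scale == "linear":
        return np.exp2(profile)
    if spm_scale == "log2":
        return profile
    raise ValidationError(f"spm_scale must be 'linear' or 'log2', got {spm_scale!r}")


def roku_spm_classify(
    profile: Sequence[float],
    params: RokuSpmParams,
    panel: Sequence[str] | None = None,
    spm_scale: str = "linear",
) -> Call:
    """Classify one profile with the entropy gate -> outliers -> SPM ladder.

    Failed SPM checks degrade to the next weaker call: two outliers failing
    spm2 fall back to a specific call if the top outlier passes spm1; all
    failures yield ubiquitous.
    """
    x = np.asarray(profile, dtype=float)
    names = list(panel) if panel is not None else [f"t{i+1}" for i in range(x.size)]
    if roku_entropy(x) > params.h_max:
        return Call.ubiquitous(source="roku")
    outliers = ueda_outliers(x, max_outliers=2)
    if not outliers:
        return Call.ubiquitous(source="roku")
    lin = _linear(x, spm_scale)
    if len(outliers) == 2 and spm(lin, outliers) >= params.spm2:
        return Call.two_selective(names[outliers[0]], names[outliers[1]], source="roku")
    top = outliers[0]
    if spm(lin, [top]) >= params.spm1:
        return Call.specific(names[top], source="roku")
    return Call.ubiquitous(source="roku")


# ---------------------------------------------------------------------------
# decision function classifier
# ---------------------------------------------------------------------------

def _decision_stats(x: np.ndarray) -> dict:
    order = _rank_desc(x)
    xs = x[order]
    n = xs.size
    rng = xs[0] - xs[-1]
    stats: dict = {"order": order, "constant": rng == 0}
    for k in (1, 2):
        gap = xs[k - 1] - xs[k]
        sp = gap / rng if rng > 0 else 0.0
        low = xs[k:]
        sd = float(np.std(low, ddof=1))
        if sd == 0:
            d = math.inf if gap > 0 else 0.0
        else:
            d = gap / sd
        stats[k] = (float(gap), float(sp), float(d))
    return stats


def decision_function_classify(
    profile: Sequence[float],
    params: DecisionParams,
    panel: Sequence[str] | None = None,
) -> Call:
    """Gap / specificity-fraction / decision-value classification.

    The profile is sorted descending; k=1 tests the top tissue against the
    rest, k=2 tests the top pair.  Needs >= 4 tissues so the low group has a
    spread.
    """
    x = np.asarray(profile, dtype=float)
    if x.size < 4:
        raise ValidationError("decision function needs >= 4 tissues")
    names = list(panel) if panel is not None else [f"t{i+1}" for i in range(x.size)]
    stats = _decision_stats(x)
    return _decision_from_stats(stats, params, names)


def _decision_from_stats(stats: dict, params: DecisionParams, names: Sequence[str]) -> Call:
    if stats["constant"]:
        return Call.ubiquitous(source="decision")
    order = stats["order"]
    g1, sp1, d1 = stats[1]
    if g1 >= params.g_min and sp1 >= params.sp_min and d1 >= params.d_min:
        return Call.specific(names[order[0]], source="decision")
    g2, sp2, d2 = stats[2]
    if g2 >= params.g_min and sp2 >= params.sp_min and d2 >= params.d_min:
        return Call.two_selective(names[order[0]], names[order[1]], source="decision")
    return Call.ubiquitous(source="decision")


# ---------------------------------------------------------------------------
# Bayes factor classifier
# ---------------------------------------------------------------------------

# shared diffuse normal-inverse-gamma prior: mu ~ N(m0, sigma^2/k0),
# sigma^2 ~ InvGamma(a0, b0).  a0 = b0 = 1/2 keeps the prior heavy-tailed
# without the numerical under/overflow of near-improper shapes, so prior
# draws stay finite and exchangeable across tissues.
_PRIOR_M0 = 0.0
_PRIOR_K0 = 1e-4
_PRIOR_A0 = 0.5
_PRIOR_B0 = 0.5


@dataclass(frozen=True)
class BayesFactorResult:
    bf: float
    posterior_fraction: float
    prior_fraction: float
    hypothesis: str


def _check_replicates(replicate_data: Mapping[str, np.ndarray]) -> None:
    for tissue, vals in replicate_data.items():
        if np.asarray(vals).size < 2:
            raise ValidationError(
                "method requires multiple samples per tissue "
                f"(tissue {tissue!r} has {np.asarray(vals).size})"
            )


def _posterior_draws(
    vals: np.ndarray, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Draws of the tissue mean under the conjugate NIG posterior."""
    n = vals.size
    ybar = vals.mean()
    kn = _PRIOR_K0 + n
    mn = (_PRIOR_K0 * _PRIOR_M0 + n * ybar) / kn
    an = _PRIOR_A0 + n / 2.0
    bn = (
        _PRIOR_B0
        + 0.5 * float(np.sum((vals - ybar) ** 2))
        + _PRIOR_K0 * n * (ybar - _PRIOR_M0) ** 2 / (2.0 * kn)
    )
    sigma2 = bn / rng.gamma(an, 1.0, size=n_draws)
    return rng.normal(mn, np.sqrt(sigma2 / kn))


def _prior_draws(n_draws: int, rng: np.random.Generator) -> np.ndarray:
    sigma2 = _PRIOR_B0 / rng.gamma(_PRIOR_A0, 1.0, size=n_draws)
    return rng.normal(_PRIOR_M0, np.sqrt(sigma2 / _PRIOR_K0))


def _constraint_fraction(
    mu: np.ndarray, top: Sequence[int], rest: Sequence[int], margin: float
) -> float:
    """Fraction of draws where every top tissue exceeds max(rest) + margin."""
    threshold = mu[list(rest), :].max(axis=0) + margin
    ok = np.all(mu[list(top), :] > threshold, axis=0)
    return float(ok.mean())


def bayes_factor_details(
    replicate_data: Mapping[str, Sequence[float]],
    hypothesis: str,
    c: float,
    n_draws: int = 10_000,
    seed: int = 0,
) -> BayesFactorResult:
    """Encompassing-prior Bayes factor for H01 (specific) or H02 (2-selective).

    Tissues are ranked by sample mean (descending, panel order on ties).
    H01: mu(1) > c*s(2..J) + max_{j>=2} mu(j), with s(2..J) the sd of the
    sample means of tissues ranked 2..J.  H02: mu(1) and mu(2) both exceed
    c*s(3..J) + max_{j>=3} mu(j).  The BF is the ratio of the posterior and
    prior fractions of draws satisfying the constraint.
    """
    data = {t: np.asarray(v, dtype=float) for t, v in replicate_data.items()}
    _check_replicates(data)
    tissues = list(data)
    means = np.array([data[t].mean() for t in tissues])
    order = _rank_desc(means)
    J = len(tissues)
    if hypothesis == "H01":
        if J < 3:
            raise ValidationError("H01 needs >= 3 tissues for the between-tissue sd")
        top, rest = order[:1], order[1:]
    elif hypothesis == "H02":
        if J < 4:
            raise ValidationError("H02 needs >= 4 tissues for the between-tissue sd")
        top, rest = order[:2], order[2:]
    else:
        raise ValidationError(f"hypothesis must be 'H01' or 'H02', got {hypothesis!r}")
    margin = c * float(np.std(means[rest], ddof=1))

    rng = np.random.default_rng(seed)
    post = np.empty((J, n_draws))
    for i, t in enumerate(tissues):
        post[i] = _posterior_draws(data[t], n_draws, rng)
    prior = np.empty((J, n_draws))
    for i in range(J):
        prior[i] = _prior_draws(n_draws, rng)

    post_frac = _constraint_fraction(post, top, rest, margin)
    prior_frac = _constraint_fraction(prior, top, rest, margin)
    # guard: an empty prior cell would make the ratio undefined; floor the
    # count at half a draw so enormous but finite evidence is reported
    prior_frac_eff = max(prior_frac, 0.5 / n_draws)
    return BayesFactorResult(post_frac / prior_frac_eff, post_frac, prior_frac, hypothesis)


def bayes_factor(
    replicate_data: Mapping[str, Sequence[float]],
    hypothesis: str,
    c: float,
    n_draws: int = 10_000,
    seed: int = 0,
) -> float:
    return bayes_factor_details(replicate_data, hypothesis, c, n_draws, seed).bf


def bayes_classify(
    replicate_data: Mapping[str, Sequence[float]],
    params: BayesParams,
    seed: int | None = None,
) -> Call:
    """SPECIFIC if BF(H01) >= bf1, else TWO_SELECTIVE if BF(H02) >= bf2."""
    data = {t: np.asarray(v, dtype=float) for t, v in replicate_data.items()}
    _check_replicates(data)
    tissues = list(data)
    means = np.array([data[t].mean() for t in tissues])
    order = _rank_desc(means)
    use_seed = params.seed if seed is None else seed
    bf1 = bayes_factor(data, "H01", params.c, params.n_draws, use_seed)
    if bf1 >= params.bf1:
        return Call.specific(tissues[order[0]], source="bayes")
    if len(tissues) >= 4:
        bf2 = bayes_factor(data, "H02", params.c, params.n_draws, use_seed + 1)
        if bf2 >= params.bf2:
            return Call.two_selective(
                tissues[order[0]], tissues[order[1]], source="bayes"
            )
    return Call.ubiquitous(source="bayes")


# ---------------------------------------------------------------------------
# Bayes threshold calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BfSimConfig:
    """Simulation design for calibrating the Bayes-factor thresholds."""

    n_tissues: int = 10
    n_replicates: int = 3
    effect_size: float = 3.0
    within_sd: float = 1.0
    target_fpr: float = 0.05
    n_sims: int = 100
    c: float = 1.0
    n_draws: int = 10_000

    def __post_init__(self) -> None:
        if self.n_tissues < 4:
            raise ValidationError("calibration needs >= 4 tissues")
        if self.n_sims < 10:
            raise ValidationError("calibration needs >= 10 simulated datasets")


def _null_dataset(cfg: BfSimConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    return {
        f"t{j+1}": rng.normal(0.0, cfg.within_sd, size=cfg.n_replicates)
        for j in range(cfg.n_tissues)
    }


def _smallest_threshold(null_bfs: np.ndarray, target_fpr: float) -> float:
    """Smallest threshold t with P(BF >= t) <= target on the null sample."""
    b = np.sort(null_bfs)[::-1]
    m = b.size
    k = int(math.floor(target_fpr * m))
    if k >= m:
        return float(b[-1])  # everything may be called
    t = float(np.nextafter(b[k], np.inf))
    return t


def calibrate_bf_thresholds(
    sim_config: BfSimConfig, seed: int = 0
) -> BayesParams:
    """Pick the smallest (bf1, bf2) meeting the target null call rate.

    Null datasets are exchangeable (all tissue means equal); the thresholds
    are the smallest values whose exceedance rate on the simulated nulls is
    at most ``target_fpr``.  Deterministic under ``seed``.
    """
    if not (0.0 <= sim_config.target_fpr <= 1.0):
        raise ValidationError(
            f"target FPR {sim_config.target_fpr} unattainable; achievable range is [0, 1]"
        )
    rng = np.random.default_rng(seed)
    bf1s = np.empty(sim_config.n_sims)
    bf2s = np.empty(sim_config.n_sims)
    for i in range(sim_config.n_sims):
        data = _null_dataset(sim_config, rng)
        sub = int(rng.integers(0, 2**31 - 1))
        bf1s[i] = bayes_factor(data, "H01", sim_config.c, sim_config.n_draws, sub)
        bf2s[i] = bayes_factor(data, "H02", sim_config.c, sim_config.n_draws, sub + 1)
    bf1 = _smallest_threshold(bf1s, sim_config.target_fpr)
    bf2 = _smallest_threshold(bf2s, sim_config.target_fpr)
    return BayesParams(
        c=sim_config.c,
        bf1=bf1,
        bf2=bf2,
        n_draws=sim_config.n_draws,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# detector objects (cached statistics for fast grid search)
# ---------------------------------------------------------------------------

class RokuSpmDetector:
    """ROKU-SPM detector with per-probe statistics cached once.

    Entropy, the outlier set and the candidate SPM values do not depend on
    the thresholds, so a parameter sweep only re-applies cheap comparisons.
    """

    name = "roku"
    requires_replicates = False
    params_cls = RokuSpmParams

    def __init__(self, spm_scale: str = "linear") -> None:
        self.spm_scale = spm_scale

    def prepare(self, dataset) -> dict[str, dict]:
        stats: dict[str, dict] = {}
        panel = dataset.tissue_panel
        for probe in dataset.probe_sets:
            x = dataset.tissue_means(probe)
            entropy = roku_entropy(x)
            outliers = ueda_outliers(x, max_outliers=2)
            lin = _linear(x, self.spm_scale)
            spm_top = spm(lin, outliers[:1]) if outliers else float("nan")
            spm_pair = spm(lin, outliers) if len(outliers) == 2 else float("nan")
            stats[probe] = {
                "entropy": entropy,
                "outliers": outliers,
                "spm_top": spm_top,
                "spm_pair": spm_pair,
                "panel": panel,
            }
        return stats

    def classify(self, stats: dict, params: RokuSpmParams) -> Call:
        if stats["entropy"] > params.h_max:
            return Call.ubiquitous(source=self.name)
        outliers = stats["outliers"]
        if not outliers:
            return Call.ubiquitous(source=self.name)
        panel = stats["panel"]
        if len(outliers) == 2 and stats["spm_pair"] >= params.spm2:
            return Call.two_selective(panel[outliers[0]], panel[outliers[1]], source=self.name)
        if stats["spm_top"] >= params.spm1:
            return Call.specific(panel[outliers[0]], source=self.name)
        return Call.ubiquitous(source=self.name)

    def default_grid(self, n_tissues: int) -> list[RokuSpmParams]:
        h_values = np.round(np.arange(1.0, np.log2(n_tissues) + 1e-9, 0.25), 2)
        spm_values = np.round(np.arange(0.95, 0.5 - 1e-9, -0.05), 2)  # strict first
        return [
            RokuSpmParams(h_max=float(h), spm1=float(s1), spm2=float(s2))
            for s1 in spm_values
            for s2 in spm_values
            for h in h_values
        ]


class DecisionDetector:
    name = "decision"
    requires_replicates = False
    params_cls = DecisionParams

    def prepare(self, dataset) -> dict[str, dict]:
        stats: dict[str, dict] = {}
        panel = dataset.tissue_panel
        if len(panel) < 4:
            raise ValidationError("decision function needs >= 4 tissues")
        for probe in dataset.probe_sets:
            s = _decision_stats(dataset.tissue_means(probe))
            s["panel"] = panel
            stats[probe] = s
        return stats

    def classify(self, stats: dict, params: DecisionParams) -> Call:
        return _decision_from_stats(stats, params, stats["panel"])

    def default_grid(self, n_tissues: int) -> list[DecisionParams]:
        g_values = np.round(np.arange(4.0, 0.5 - 1e-9, -0.5), 2)  # strict first
        sp_values = np.round(np.arange(0.9, 0.1 - 1e-9, -0.1), 2)
        d_values = np.round(np.arange(5.0, 1.0 - 1e-9, -0.5), 2)
        return [
            DecisionParams(g_min=float(g), sp_min=float(sp), d_min=float(d))
            for g in g_values
            for sp in sp_values
            for d in d_values
        ]


class BayesDetector:
    """Bayes-factor detector; BF values are cached per margin constant c."""

    name = "bayes"
    requires_replicates = True
    params_cls = BayesParams

    def __init__(self, n_draws: int = 10_000, seed: int = 0) -> None:
        self.n_draws = n_draws
        self.seed = seed

    def prepare(self, dataset, c_values: Iterable[float] = (1.0,)) -> dict[str, dict]:
        if not dataset.has_replicates:
            raise ValidationError(
                f"dataset {dataset.dataset_id!r}: the Bayes factor method requires "
                "multiple samples per tissue"
            )
        stats: dict[str, dict] = {}
        tissues = dataset.tissue_panel
        for k, probe in enumerate(dataset.probe_sets):
            data = dataset.replicate_values(probe)
            means = np.array([data[t].mean() for t in tissues])
            order = _rank_desc(means)
            per_c: dict[float, tuple[float, float]] = {}
            for c in c_values:
                sub = (self.seed + 7919 * k) % (2**31 - 1)
                bf1 = bayes_factor(data, "H01", c, self.n_draws, sub)
                bf2 = (
                    bayes_factor(data, "H02", c, self.n_draws, sub + 1)
                    if len(tissues) >= 4
                    else 0.0
                )
                per_c[float(c)] = (bf1, bf2)
            stats[probe] = {"order": order, "panel": tissues, "bf": per_c}
        return stats

    def classify(self, stats: dict, params: BayesParams) -> Call:
        key = float(params.c)
        if key not in stats["bf"]:
            raise ValidationError(
                f"Bayes statistics were not prepared for c={params.c}"
            )
        bf1, bf2 = stats["bf"][key]
        panel, order = stats["panel"], stats["order"]
        if bf1 >= params.bf1:
            return Call.specific(panel[order[0]], source=self.name)
        if bf2 >= params.bf2:
            return Call.two_selective(panel[order[0]], panel[order[1]], source=self.name)
        return Call.ubiquitous(source=self.name)

    C_GRID = (0.0, 0.5, 1.0, 2.0)

    def default_grid(
        self,
        n_tissues: int,
        n_replicates: int = 3,
        target_fpr: float = 0.05,
        n_sims: int = 60,
        seed: int = 0,
    ) -> list[BayesParams]:
        """Calibrated (c, bf1, bf2) combinations over the default c grid."""
        grid: list[BayesParams] = []
        for c in self.C_GRID:
            cfg = BfSimConfig(
                n_tissues=min(n_tissues, 10),
                n_replicates=n_replicates,
                target_fpr=target_fpr,
                n_sims=n_sims,
                c=c,
                n_draws=self.n_draws,
            )
            grid.append(calibrate_bf_thresholds(cfg, seed=seed))
        return grid


def make_detector(name: str, spm_scale: str = "linear", n_draws: int = 10_000, seed: int = 0):
    if name == "roku":
        return RokuSpmDetector(spm_scale=spm_scale)
    if name == "decision":
        return DecisionDetector()
    if name == "bayes":
        return BayesDetector(n_draws=n_draws, seed=seed)
    raise ValidationError(f"unknown detector {name!r}")
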