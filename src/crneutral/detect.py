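"""Statistical machinery for detecting (non-)neutrality in simulated data.

The primary instrument is a discrete Cramér-von Mises goodness-of-fit test of
a community snapshot against the log-series SAD with its parameter estimated
from the sample mean; because the parameter is estimated, null distributions
come from a parametric bootstrap with re-estimation rather than asymptotic
tables.  A logistic regression of fit successes against a non-neutrality
index turns ensembles of such tests into a threshold estimate.  Further
diagnostics: extinction-time binning against the neutral closed form,
empirical across-history variance of relative abundance fluctuations, and
the mean pairwise cosine between empirically observed consumer preference
vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .neutral import LogSeriesModel, fit_logseries_p, neutral_extinction_time

__all__ = [
    "GofResult",
    "ThresholdEstimate",
    "cvm_discrete_statistic",
    "cvm_discrete_test",
    "logistic_threshold",
    "extinction_statistics",
    "empirical_var_D",
    "observed_preference_cosines",
]


@dataclass(frozen=True)
class GofResult:
    """Outcome of one discrete CvM goodness-of-fit test."""

    statistic: float
    p_value: float
    p_hat: float
    n_boot: int
    cutoff: float = 0.05

    @property
    def success(self) -> bool:
        return self.p_value > self.cutoff


def _cell_probs(p: float, k_max: int) -> np.ndarray:
    """Log-series cell probabilities for 1..k_max plus the aggregated tail."""
    k = np.arange(1, k_max + 1)
    alpha = -1.0 / np.log1p(-p)
    probs = alpha * np.power(p, k) / k
    tail = max(1.0 - probs.sum(), 0.0)
    return np.append(probs, tail)


def cvm_discrete_statistic(sample: np.ndarray, p: float) -> float:
    """Choulakian-style discrete CvM statistic ``W^2`` against log-series(p).

    Support cells are abundances ``1..max(sample)`` with one aggregated tail
    cell; ``W^2 = n sum_j (S_j - T_j)^2 p_j`` over cells, with ``S_j``/``T_j``
    the empirical/fitted cumulative distributions.  Zero iff the cumulative
    distributions agree on every cell.
    """
    sample = np.asarray(sample)
    n = sample.size
    k_max = int(sample.max())
    probs = _cell_probs(p, k_max)
    counts = np.bincount(sample, minlength=k_max + 1)[1:]
    counts = np.append(counts, 0)  # tail cell: nothing observed beyond k_max
    S = np.cumsum(counts) / n
    T = np.cumsum(probs)
    return float(n * np.sum((S - T) ** 2 * probs))


def cvm_discrete_test(
    sample,
    n_boot: int = 999,
    seed: int | np.random.SeedSequence | None = None,
    cutoff: float = 0.05,
) -> GofResult:
    """Fit a log-series to an abundance sample and bootstrap-test the fit.

    The parameter ``p`` is estimated from the sample mean, the discrete CvM
    statistic computed, and its null distribution obtained by parametric
    bootstrap: each replicate resamples ``n`` abundances from the fitted
    log-series, re-estimates ``p`` from the replicate mean, and recomputes the
    statistic.  ``p_value = (1 + #{W2_boot >= W2_obs}) / (n_boot + 1)``; the
    fit is deemed successful when the p-value exceeds ``cutoff``.
    """
    sample = np.asarray(sample, dtype=np.int64)
    if sample.size < 2:
        raise ValueError("need at least two abundances")
    if np.any(sample < 1):
        raise ValueError("abundances must be >= 1")
    if sample.mean() <= 1.0:
        raise ValueError("sample mean <= 1: log-series parameter not estimable")
    rng = np.random.default_rng(seed)
    p_hat = fit_logseries_p(sample.mean())
    w2 = cvm_discrete_statistic(sample, p_hat)
    model = LogSeriesModel(p_hat)
    exceed = 0
    for _ in range(n_boot):
        boot = model.rvs(sample.size, rng)
        m = boot.mean()
        if m <= 1.0:  # degenerate all-ones replicate: as extreme as anything
            exceed += 1
            continue
        pb = fit_logseries_p(m)
        if cvm_discrete_statistic(boot, pb) >= w2:
            exceed += 1
    p_value = (1 + exceed) / (n_boot + 1)
    return GofResult(statistic=w2, p_value=p_value, p_hat=p_hat, n_boot=n_boot, cutoff=cutoff)


@dataclass(frozen=True)
class ThresholdEstimate:
    """Index value where the fitted success probability crosses the cutoff."""

    threshold: float
    se: float
    beta0: float
    beta1: float
    prob_cutoff: float = 0.5
    separation: bool = False


def logistic_threshold(
    index_values,
    successes,
    prob_cutoff: float = 0.5,
) -> ThresholdEstimate:
    """Logistic regression of fit success on a non-neutrality index.

    The threshold is the index at which the fitted success probability equals
    ``prob_cutoff`` — for the default 0.5 this is ``-beta0/beta1`` — with a
    delta-method standard error.  Complete separation (all successes below all
    failures) is detected and reported: the threshold is then bracketed at the
    midpoint of the gap and the standard error flagged unreliable.
    """
    x = np.asarray(index_values, float)
    y = np.asarray(successes, int)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("index_values and successes must be matching 1-d arrays")
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")

    max_succ = x[y == 1].max()
    min_fail = x[y == 0].min()
    if max_succ < min_fail:  # complete separation
        return ThresholdEstimate(
            threshold=float(0.5 * (max_succ + min_fail)),
            se=float("nan"),
            beta0=float("nan"),
            beta1=float("nan"),
            prob_cutoff=prob_cutoff,
            separation=True,
        )

    import statsmodels.api as sm

    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    b0, b1 = fit.params
    logit_c = np.log(prob_cutoff / (1.0 - prob_cutoff))
    threshold = (logit_c - b0) / b1
    grad = np.array([-1.0 / b1, -(logit_c - b0) / b1**2])
    se = float(np.sqrt(grad @ fit.cov_params() @ grad))
    return ThresholdEstimate(
        threshold=float(threshold),
        se=se,
        beta0=float(b0),
        beta1=float(b1),
        prob_cutoff=prob_cutoff,
    )


def extinction_statistics(
    linked: pd.DataFrame,
    p: float | None = None,
    bin_base: float = 2.0,
) -> pd.DataFrame:
    """Bin linked (abundance, wait) extinction records logarithmically.

    ``linked`` must carry columns ``observed_abundance`` and
    ``wait_generations`` (see :func:`crneutral.simulate.link_extinctions`).
    Bins are powers of ``bin_base``; each row reports the per-bin mean wait,
    its standard error (NaN when a bin holds a single record), the count, the
    geometric-mean abundance, and — when a log-series parameter ``p`` is
    given — the neutral expected extinction time at that abundance.
    """
    if linked.empty:
        raise ValueError("extinction log is empty")
    ab = linked["observed_abundance"].to_numpy()
    wait = linked["wait_generations"].to_numpy(float)
    bins = np.floor(np.log(ab) / np.log(bin_base)).astype(int)
    rows = []
    for b in np.unique(bins):
        sel = bins == b
        w = wait[sel]
        a = ab[sel]
        gmean = float(np.exp(np.mean(np.log(a))))
        se = float(w.std(ddof=1) / np.sqrt(w.size)) if w.size > 1 else float("nan")
        row = {
            "bin": int(b),
            "bin_low": bin_base**b,
            "bin_high": bin_base ** (b + 1),
            "gmean_abundance": gmean,
            "mean_wait": float(w.mean()),
            "se_wait": se,
            "count": int(w.size),
        }
        if p is not None:
            row["predicted_wait"] = float(
                neutral_extinction_time(max(1, int(round(gmean))), p)
            )
        rows.append(row)
    out = pd.DataFrame(rows)
    if out["count"].min() == 1:
        warnings.warn("some abundance bins hold a single record; SE undefined there")
    return out


def empirical_var_D(
    histories: np.ndarray,
    n0: np.ndarray,
    n0_min: int = 20,
) -> pd.DataFrame:
    """Across-history variance of ``D(t) = (n(t) - n0)/n0``, averaged over species.

    ``histories`` has shape ``(n_hist, n_times, S)`` — replicate abundance
    trajectories started from one common snapshot with initial abundances
    ``n0`` (extinct species must already be zeroed by the caller).  For every
    species with ``n0 >= n0_min`` the variance of ``D`` across histories is
    computed per time point; the table reports the mean across qualifying
    species and its standard error.
    """
    histories = np.asarray(histories, float)
    if histories.ndim != 3 or histories.shape[0] < 2:
        raise ValueError("need an (n_hist >= 2, n_times, S) array")
    n0 = np.asarray(n0, float)
    keep = n0 >= n0_min
    if not np.any(keep):
        raise ValueError(f"no species with initial abundance >= {n0_min}")
    D = (histories[:, :, keep] - n0[keep]) / n0[keep]
    var = D.var(axis=0, ddof=1)  # (n_times, S_keep)
    n_sp = var.shape[1]
    return pd.DataFrame(
        {
            "t_index": np.arange(var.shape[0]),
            "var_D": var.mean(axis=1),
            "se": var.std(axis=1, ddof=1) / np.sqrt(n_sp) if n_sp > 1 else np.nan,
            "n_species": n_sp,
        }
    )


def observed_preference_cosines(
    event_counts: np.ndarray, ci_level: float = 0.95
) -> dict:
    """Mean pairwise cosine between consumers' empirical preference vectors.

    Each consumer's preference vector is its column of per-resource
    consumption-event counts.  Returns the mean cosine over all unordered
    consumer pairs with a normal-approximation confidence interval for the
    mean (pairs treated as approximately independent).  Consumers with zero
    recorded events are excluded with a warning.
    """
    counts = np.asarray(event_counts, float)
    tot = counts.sum(axis=0)
    if np.any(tot == 0):
        warnings.warn(f"{int((tot == 0).sum())} consumer(s) with no events excluded")
        counts = counts[:, tot > 0]
    S = counts.shape[1]
    if S < 2:
        raise ValueError("need at least two consumers with recorded events")
    unit = counts / np.linalg.norm(counts, axis=0)
    gram = unit.T @ unit
    iu = np.triu_indices(S, k=1)
    cosines = gram[iu]
    mean = float(cosines.mean())
    se = float(cosines.std(ddof=1) / np.sqrt(cosines.size))
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    return {
        "mean_cosine": mean,
        "ci_low": mean - z * se,
        "ci_high": mean + z * se,
        "se": se,
        "n_pairs": int(cosines.size),
        "ci_method": "normal over pairs",
    }
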