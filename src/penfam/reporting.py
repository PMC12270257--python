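"""Posterior summarization and convergence diagnostics.

Each retained draw is mapped through the quantile-to-Weibull transform and
evaluated on the annual age grid, giving a matrix of penetrance curves per
sex; summaries are pointwise means, medians and equal-tailed credible
bands.  Diagnostics are the standard toolkit: autocorrelation functions
(biased estimator), effective sample size with initial-positive-sequence
truncation, and split-chain potential scale reduction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mcmc import BLOCK, McmcConfig, PosteriorSamples
from .model import DEFAULT_MAX_AGE, FEMALE, MALE

_LN2 = math.log(2.0)
_LN43 = math.log(4.0 / 3.0)


class ReportingError(ValueError):
    pass


def _curves_from_block(draws: np.ndarray, max_age: int) -> np.ndarray:
    """(n_draws, max_age) penetrance curves from (n, 4) quantile-space draws."""
    q1 = draws[:, 0:1]
    med = draws[:, 1:2]
    gamma = draws[:, 2:3]
    delta = draws[:, 3:4]
    beta = np.log(_LN43 / _LN2) / np.log((q1 - delta) / (med - delta))
    alpha = (med - delta) / _LN2 ** (1.0 / beta)
    ages = np.arange(1, max_age + 1, dtype=float)[None, :]
    shifted = np.clip(ages - delta, 0.0, None)
    with np.errstate(over="ignore"):
        return gamma * -np.expm1(-((shifted / alpha) ** beta))


def weibull_block(draws: np.ndarray) -> np.ndarray:
    """(n, 4) quantile-space draws -> (n, 4) columns (alpha, beta, gamma, delta)."""
    q1, med, gamma, delta = draws.T
    beta = np.log(_LN43 / _LN2) / np.log((q1 - delta) / (med - delta))
    alpha = (med - delta) / _LN2 ** (1.0 / beta)
    return np.column_stack([alpha, beta, gamma, delta])


@dataclass
class PenetranceSummary:
    curves: dict[str, pd.DataFrame]  # per sex: age x (mean, median, bands)
    params: pd.DataFrame  # posterior parameter summaries, both spaces
    levels: tuple[float, ...]

    def curve_table(self, sex: str) -> pd.DataFrame:
        return self.curves[sex]


def _param_summary_rows(name_prefix: str, cols: dict[str, np.ndarray]) -> list[dict]:
    rows = []
    for pname, v in cols.items():
        rows.append(
            {
                "parameter": f"{name_prefix}{pname}",
                "mean": float(np.mean(v)),
                "sd": float(np.std(v, ddof=1)) if v.size > 1 else 0.0,
                "median": float(np.median(v)),
                "q2.5": float(np.percentile(v, 2.5)),
                "q97.5": float(np.percentile(v, 97.5)),
            }
        )
    return rows


def summarize(
    samples: PosteriorSamples,
    max_age: int | None = None,
    levels: tuple[float, ...] = (0.95, 0.5),
) -> PenetranceSummary:
    """Posterior penetrance curves and parameter summaries from retained draws."""
    pooled = samples.pooled()
    if pooled.shape[0] == 0:
        raise ReportingError("no retained draws to summarize")
    cfg = samples.config
    max_age = max_age or cfg.max_age
    levels = tuple(sorted(levels, reverse=True))

    blocks = {}
    if cfg.sex_specific:
        blocks[FEMALE] = pooled[:, :4]
        blocks[MALE] = pooled[:, 4:]
    else:
        blocks[FEMALE] = pooled
        blocks[MALE] = pooled

    curves = {}
    rows: list[dict] = []
    seen = set()
    for sex, blk in blocks.items():
        mat = _curves_from_block(blk, max_age)
        data = {
            "age": np.arange(1, max_age + 1),
            "mean": mat.mean(axis=0),
            "median": np.median(mat, axis=0),
        }
        for lv in levels:
            a = 100.0 * (1.0 - lv) / 2.0
            data[f"lo{int(round(lv * 100))}"] = np.percentile(mat, a, axis=0)
            data[f"hi{int(round(lv * 100))}"] = np.percentile(mat, 100.0 - a, axis=0)
        curves[sex] = pd.DataFrame(data)

        key = blk.tobytes()
        if key in seen:
            continue
        seen.add(key)
        prefix = f"{sex}." if cfg.sex_specific else ""
        wb = weibull_block(blk)
        rows += _param_summary_rows(prefix, dict(zip(BLOCK, blk.T)))
        rows += _param_summary_rows(prefix, dict(zip(["alpha", "beta"], wb.T[:2])))
    return PenetranceSummary(curves=curves, params=pd.DataFrame(rows), levels=levels)


# ---------------------------------------------------------------------------
# convergence diagnostics


def autocorrelation(x: np.ndarray, max_lag: int | None = None) -> np.ndarray:
    """Biased-normalization ACF of a 1-d chain, lags 0..max_lag."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if max_lag is None:
        max_lag = min(n - 1, 1000)
    xc = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[: max_lag + 1] / n
    if acov[0] <= 0:
        out = np.zeros(max_lag + 1)
        out[0] = 1.0
        return out
    return acov / acov[0]


def effective_sample_size(x: np.ndarray) -> float:
    """ESS via Geyer's initial-positive-sequence truncation."""
    n = x.size
    rho = autocorrelation(x, max_lag=min(n - 1, 2000))
    s = 0.0
    t = 1
    while t + 1 < rho.size:
        pair = rho[t] + rho[t + 1]
        if pair <= 0.0:
            break
        s += pair
        t += 2
    ess = n / (1.0 + 2.0 * s)
    return float(min(ess, n))


def split_rhat(chains: list[np.ndarray]) -> float:
    """Split-chain potential scale reduction factor for one parameter."""
    halves = []
    for c in chains:
        h = c.size // 2
        if h < 2:
            return float("nan")
        halves += [c[:h], c[h : 2 * h]]
    m = len(halves)
    n = halves[0].size
    means = np.array([h.mean() for h in halves])
    vars_ = np.array([h.var(ddof=1) for h in halves])
    w = vars_.mean()
    b = n * means.var(ddof=1)
    if w <= 0:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(math.sqrt(var_plus / w))


@dataclass
class Diagnostics:
    table: pd.DataFrame  # parameter x (ess, rhat)
    acf: dict[str, np.ndarray] = field(default_factory=dict)
    accept_rates: list[float] = field(default_factory=list)


def diagnostics(samples: PosteriorSamples, acf_lags: int = 50) -> Diagnostics:
    """ESS, split-Rhat and ACF per parameter; PSRF omitted for single chains."""
    names = samples.param_names
    rows = []
    acfs: dict[str, np.ndarray] = {}
    for j, name in enumerate(names):
        per_chain = [c.draws[:, j] for c in samples.chains if c.draws.shape[0] > 0]
        ess = float(sum(effective_sample_size(x) for x in per_chain))
        rhat = split_rhat(per_chain) if len(per_chain) >= 2 else float("nan")
        pooled = np.concatenate(per_chain)
        acfs[name] = autocorrelation(pooled, max_lag=min(acf_lags, pooled.size - 1))
        rows.append({"parameter": name, "ess": ess, "rhat": rhat})
    return Diagnostics(
        table=pd.DataFrame(rows),
        acf=acfs,
        accept_rates=[c.accept_rate for c in samples.chains],
    )


def plot_penetrance(summary: PenetranceSummary, sex: str, ax=None):
    """Optional matplotlib rendering of a summarized curve (headless-safe)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = summary.curves[sex]
    ax.plot(t["age"], t["mean"], label=f"{sex} mean")
    lv = int(round(summary.levels[0] * 100))
    ax.fill_between(t["age"], t[f"lo{lv}"], t[f"hi{lv}"], alpha=0.3)
    ax.set_xlabel("age")
    ax.set_ylabel("cumulative penetrance")
    ax.legend()
    return ax
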