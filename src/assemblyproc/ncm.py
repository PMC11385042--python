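"""Sloan neutral community model (NCM) fitting.

The NCM predicts how often a taxon should occur across local
communities from nothing but its mean relative abundance p in the
metacommunity.  Under neutral immigration-drift dynamics at stationarity,
a taxon's local relative abundance follows Beta(N*m*p, N*m*(1-p)),
where N is the local community size (reads per sample here) and m the
immigration probability.  Its predicted occurrence frequency is the
probability that this Beta exceeds the detection limit d:

    freq(p) = 1 - I_d(N*m*p, N*m*(1-p))

with I the regularized incomplete beta function.  Fitting m by least
squares on (p, observed frequency) pairs gives the familiar Nm and R^2
summary: large Nm means dispersal is strong enough that occurrence
tracks regional abundance; high R^2 means neutral processes explain
most of the occupancy-abundance relationship.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import beta as beta_dist
from statsmodels.stats.proportion import proportion_confint

from .io_core import CountTable

__all__ = ["NCMFit", "occurrence_frequency", "ncm_predict", "ncm_predict_reads", "fit_ncm"]


@dataclass
class NCMFit:
    m: float                 # immigration probability
    N: float                 # community size (mean reads per sample)
    Nm: float                # N * m, the dispersal summary reported with the fit
    d: float                 # detection limit (relative abundance of one read)
    r_squared: float
    ci_level: float
    n_samples: int
    taxa: pd.DataFrame = field(repr=False)  # p, freq_obs, freq_pred, lo, hi, partition

    def partition_counts(self) -> dict[str, int]:
        return self.taxa["partition"].value_counts().to_dict()


def occurrence_frequency(table: CountTable) -> pd.DataFrame:
    """Mean relative abundance and occurrence frequency per taxon.

    Taxa absent from every sample are excluded with a warning (their
    frequency carries no information for the fit).
    """
    if len(table.sample_ids) < 2:
        raise ValueError("occurrence frequency needs at least 2 samples")
    counts = table.counts.astype(float)
    totals = counts.sum(axis=0)
    if np.any(totals == 0):
        raise ValueError("samples with zero total reads are not allowed")
    rel = counts / totals
    p = rel.mean(axis=1)
    freq = (counts > 0).mean(axis=1)
    df = pd.DataFrame({"p": p, "freq": freq}, index=table.taxon_ids)
    absent = df["p"] == 0
    if absent.any():
        warnings.warn(f"excluding {int(absent.sum())} taxa absent from all samples", stacklevel=2)
        df = df.loc[~absent]
    return df


def ncm_predict(p, m: float, N: float, d: float):
    """Predicted occurrence frequency 1 - I_d(N*m*p, N*m*(1-p))."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("p must lie strictly inside (0, 1)")
    if not 0 < m <= 1:
        raise ValueError(f"m must be in (0, 1], got {m}")
    if N <= 0:
        raise ValueError(f"N must be positive, got {N}")
    if not 0 < d < 1:
        raise ValueError(f"detection limit must be in (0, 1), got {d}")
    nm = N * m
    pred = beta_dist.sf(d, nm * p, nm * (1.0 - p))
    return float(pred) if np.isscalar(p) or p.ndim == 0 else pred


def ncm_predict_reads(p, m: float, N: float, n_reads: float | None = None):
    """Predicted occurrence frequency under read-level detection.

    A taxon is observed when at least one of the sample's reads hits it.
    Integrating the binomial miss probability over the Sloan stationary
    Beta gives the closed form

        freq(p) = 1 - B(a, b + R) / B(a, b),  a = N*m*p, b = N*m*(1-p)

    with R the reads per sample (defaults to N).  This replaces the
    sharp detection threshold of :func:`ncm_predict` with the exact
    probability of missing every read, which is what a count table
    actually records.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("p must lie strictly inside (0, 1)")
    if not 0 < m <= 1:
        raise ValueError(f"m must be in (0, 1], got {m}")
    if N <= 0:
        raise ValueError(f"N must be positive, got {N}")
    r = N if n_reads is None else float(n_reads)
    a = N * m * p
    b = N * m * (1.0 - p)
    from scipy.special import betaln

    pred = 1.0 - np.exp(betaln(a, b + r) - betaln(a, b))
    return float(pred) if np.isscalar(p) or p.ndim == 0 else pred


def fit_ncm(
    table: CountTable | None = None,
    ci_level: float = 0.95,
    detection: str = "reads",
    detection_limit: float | None = None,
    m_bounds: tuple[float, float] = (1e-6, 1.0),
    *,
    stats: pd.DataFrame | None = None,
    N: float | None = None,
    n_samples: int | None = None,
) -> NCMFit:
    """Fit the immigration parameter m by bounded least squares.

    N is the mean sample total.  ``detection="reads"`` (default) uses
    the exact read-level detection curve of :func:`ncm_predict_reads`,
    which is unbiased for count tables; ``detection="threshold"`` uses
    the classical sharp detection limit (default 1/N, one read) of
    :func:`ncm_predict`.  R^2 is computed on untransformed frequencies.
    The envelope around the fitted curve is a Wilson score interval
    with n = number of samples; taxa are partitioned into above /
    within / below the envelope.
    """
    if detection not in ("reads", "threshold"):
        raise ValueError(f"detection must be 'reads' or 'threshold', got {detection!r}")
    if stats is None:
        if table is None:
            raise ValueError("give a count table or a precomputed (p, freq) stats frame")
        stats = occurrence_frequency(table)
        n_samples = len(table.sample_ids)
        N = float(np.mean(table.sample_totals()))
    else:
        # advanced seam: fit directly from per-taxon (p, freq) pairs
        if N is None or n_samples is None:
            raise ValueError("stats-based fitting requires N and n_samples")
        stats = stats[["p", "freq"]].copy()
    d = 1.0 / N if detection_limit is None else detection_limit
    usable = (stats["p"] > 0) & (stats["p"] < 1)
    interior = stats.loc[usable & (stats["freq"] > 0) & (stats["freq"] < 1)]
    if len(interior) == 0:
        raise RuntimeError("NCM fit impossible: no taxon with interior occurrence frequency")
    if len(interior) < 10:
        warnings.warn(
            f"only {len(interior)} taxa with interior frequency; fit may be unstable", stacklevel=2
        )
    fit_data = stats.loc[usable]
    p = fit_data["p"].to_numpy()
    freq_obs = fit_data["freq"].to_numpy()

    if detection == "reads":
        predict = lambda pp, m: ncm_predict_reads(pp, m, N)  # noqa: E731
    else:
        predict = lambda pp, m: ncm_predict(pp, m, N, d)  # noqa: E731

    def sse(m: float) -> float:
        return float(np.sum((freq_obs - predict(p, m)) ** 2))

    res = optimize.minimize_scalar(sse, bounds=m_bounds, method="bounded",
                                   options={"xatol": 1e-12})
    if not res.success:
        raise RuntimeError(f"NCM optimizer failed: {res.message}")
    m_hat = float(res.x)
    pred = predict(p, m_hat)
    ss_res = float(np.sum((freq_obs - pred) ** 2))
    ss_tot = float(np.sum((freq_obs - freq_obs.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    lo, hi = proportion_confint(pred * n_samples, n_samples, alpha=1 - ci_level, method="wilson")
    partition = np.where(freq_obs > hi, "above", np.where(freq_obs < lo, "below", "within"))
    taxa = pd.DataFrame(
        {
            "p": p,
            "freq_obs": freq_obs,
            "freq_pred": pred,
            "lower": lo,
            "upper": hi,
            "partition": partition,
        },
        index=fit_data.index,
    )
    return NCMFit(m_hat, N, N * m_hat, d, r2, ci_level, n_samples, taxa)
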