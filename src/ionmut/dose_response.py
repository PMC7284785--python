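"""Single-hit multi-target (SHMT) dose-response modelling.

The SHMT survival model describes the fraction of cells (or here,
seedlings / seed set relative to control) surviving a radiation dose D:

    S(D) = (1 - (1 - exp(-D / D0))**N) * 100        [percent]

with mean lethal dose D0 (Gy) and extrapolation number N (dimensionless).
N > 1 produces the characteristic low-dose "shoulder" whose width is the
quasi-threshold dose Dq = D0 * ln(N). High-LET radiation typically shows
a small shoulder (N near 1), low-LET a broad one.

Fitting is nonlinear least squares on the percent scale, multi-started
over N to cope with the strongly correlated (D0, N) likelihood ridge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares


@dataclass
class DoseResponseSeries:
    """Observed (dose, % response) points for one genotype/ion/endpoint.

    ``points`` columns: ``dose_gy``, ``response_pct`` and optionally
    ``replicate``. Responses are percentages relative to the unirradiated
    control and may exceed 100 through sampling noise.
    """

    points: pd.DataFrame
    genotype: str = ""
    ion: str = ""
    endpoint: str = "seedling_survival"

    def __post_init__(self) -> None:
        req = {"dose_gy", "response_pct"}
        if not req.issubset(self.points.columns):
            raise ValueError(f"points must have columns {req}")
        if (self.points["dose_gy"] < 0).any():
            raise ValueError("doses must be >= 0")


@dataclass
class ShmtFit:
    """Fitted SHMT parameters with the derived shoulder width."""

    D0: float
    N: float
    rss: float
    converged: bool
    n_points: int = 0
    Dq: float = field(init=False)

    def __post_init__(self) -> None:
        self.Dq = self.D0 * math.log(self.N)


def shmt_response(D, D0: float, N: float):
    """Evaluate S(D) = (1 - (1 - e^(-D/D0))^N) * 100.

    Accepts scalar or array dose; returns percent response in (0, 100].
    """
    if D0 <= 0:
        raise ValueError("D0 must be > 0")
    if N < 1:
        raise ValueError("N must be >= 1")
    D = np.asarray(D, dtype=float)
    if (D < 0).any():
        raise ValueError("dose must be >= 0")
    S = (1.0 - (1.0 - np.exp(-D / D0)) ** N) * 100.0
    return float(S) if S.ndim == 0 else S


def fit_shmt(series: DoseResponseSeries | pd.DataFrame) -> ShmtFit:
    """Least-squares fit of (D0, N) to a dose-response series.

    Replicates are fitted as individual points; responses above 100% are
    retained (clipping them biases D0 upward). The optimizer is started
    from N in {1, 2, 4, 8} with bounds D0 in (0, 10*max dose], N in
    [1, 50]; the best run by residual sum of squares wins.

    A series with fewer than 3 distinct doses raises ``ValueError``. A
    series carrying no mortality signal (no response below 80%) returns
    ``converged=False`` rather than a spurious estimate.
    """
    pts = series.points if isinstance(series, DoseResponseSeries) else series
    d = pts["dose_gy"].to_numpy(dtype=float)
    y = pts["response_pct"].to_numpy(dtype=float)
    if len(np.unique(d)) < 3:
        raise ValueError("need >= 3 distinct doses to fit the SHMT model")

    dmax = float(d.max())
    ub_d0 = 10.0 * dmax if dmax > 0 else 1e4

    def resid(theta):
        D0, N = theta
        return (1.0 - (1.0 - np.exp(-d / D0)) ** N) * 100.0 - y

    best = None
    for n0 in (1.0, 2.0, 4.0, 8.0):
        d0_start = max(dmax / 3.0, 1e-3)
        try:
            sol = least_squares(
                resid,
                x0=[d0_start, n0],
                bounds=([1e-9, 1.0], [ub_d0, 50.0]),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
        except Exception:
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol

    if best is None:
        return ShmtFit(D0=float("nan"), N=1.0, rss=float("nan"), converged=False, n_points=len(d))

    D0_hat, N_hat = map(float, best.x)
    rss = float(2.0 * best.cost)
    informative = bool((y < 80.0).any())
    at_bound = D0_hat > 0.95 * ub_d0
    return ShmtFit(
        D0=D0_hat,
        N=N_hat,
        rss=rss,
        converged=informative and not at_bound,
        n_points=len(d),
    )


def quasi_threshold(fit: ShmtFit) -> float:
    """Shoulder width Dq = D0 * ln(N); zero iff N = 1 (pure exponential)."""
    return fit.D0 * math.log(fit.N)


def dose_at_response(fit: ShmtFit, level: float) -> float:
    """Iso-effect dose: the D solving S(D) = level, by the closed-form inverse.

    D = -D0 * ln(1 - (1 - level/100)^(1/N)), for level in (0, 100).
    The 50% level underlies practical dose recommendations.
    """
    if not 0.0 < level < 100.0:
        raise ValueError("level must be in (0, 100) percent")
    inner = 1.0 - (1.0 - level / 100.0) ** (1.0 / fit.N)
    return -fit.D0 * math.log(inner)
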