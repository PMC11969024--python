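"""Log-logistic dose-response fitting, potency transforms, chemokine pool
design and many-to-one (Dunnett) comparisons.

The response model is the standard log-logistic

    f(x) = c + (d - c) / (1 + exp(b * (ln x - ln e)))

with slope ``b``, lower asymptote ``c``, upper asymptote ``d`` and midpoint
``e`` (molar). Agonist (EC) fits fix d = 100 on a percent scale; inhibitor
(IC) fits fix c = 0, so three parameters are free in either mode. Before an
agonist fit, doses above the peak whose mean response falls below the peak
are excluded (receptor desensitization). Potencies are reported as
pX = -log10(X in mol/L).

Many-to-one comparisons use Dunnett's procedure: the familywise-adjusted
p-value of each group-vs-control t statistic is computed from the
equicoordinate probability of the many-to-one multivariate t distribution
(product correlation structure), evaluated by Gauss-Hermite x chi
quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats


@dataclass
class DoseResponseData:
    """Long-form dose-response observations (one row per replicate)."""

    doses: np.ndarray  # molar, > 0
    responses: np.ndarray
    response_scale: str = "percent"  # or "counts"

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.doses.shape != self.responses.shape:
            raise ValueError("doses and responses must align")
        if (self.doses <= 0).any():
            raise ValueError("doses must be positive molar concentrations")
        if self.response_scale not in ("percent", "counts"):
            raise ValueError("response_scale must be percent or counts")

    @property
    def n_distinct_doses(self) -> int:
        return len(np.unique(self.doses))

    def mean_by_dose(self) -> pd.Series:
        return (
            pd.DataFrame({"dose": self.doses, "response": self.responses})
            .groupby("dose")["response"]
            .mean()
        )

    def to_percent(self) -> "DoseResponseData":
        """Rescale so the maximal per-dose mean response is 100%."""
        if self.response_scale == "percent":
            return self
        peak = self.mean_by_dose().max()
        if peak <= 0:
            raise ValueError("cannot normalise: peak mean response is not positive")
        return DoseResponseData(self.doses, self.responses * 100.0 / peak, "percent")


def exclude_desensitized(data: DoseResponseData) -> DoseResponseData:
    """Drop supra-peak doses whose mean response falls below the peak.

    The peak dose itself and every lower dose are always retained; monotone
    data come back unchanged.
    """
    means = data.mean_by_dose()
    peak_dose = means.idxmax()
    peak_resp = means.max()
    bad_doses = means.index[(means.index > peak_dose) & (means < peak_resp)]
    if len(bad_doses) == 0:
        return data
    keep = ~np.isin(data.doses, bad_doses)
    return DoseResponseData(data.doses[keep], data.responses[keep], data.response_scale)


def ll3(x: np.ndarray, b: float, c: float, d: float, e: float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore"):
        return c + (d - c) / (1.0 + np.exp(b * (np.log(x) - np.log(e))))


@dataclass
class LogLogisticFit:
    b: float
    c: float
    d: float
    e: float  # molar midpoint
    fixed_mask: dict[str, bool]
    converged: bool
    rss: float
    n_obs: int
    mode: str  # "EC" or "IC"

    def __post_init__(self) -> None:
        if self.e <= 0:
            raise ValueError("midpoint e must be positive")

    def predict(self, x: np.ndarray) -> np.ndarray:
        return ll3(x, self.b, self.c, self.d, self.e)


def fit_ll3(data: DoseResponseData, mode: str = "EC") -> LogLogisticFit:
    """Least-squares 3-parameter log-logistic fit.

    EC mode fixes the upper asymptote d = 100 (percent scale; free b, c, e);
    IC mode fixes the lower asymptote c = 0 (free b, d, e). A multi-start
    over slope sign and a log-spaced midpoint grid guards against local
    minima; non-convergence is flagged, never silently replaced.
    """
    if mode not in ("EC", "IC"):
        raise ValueError("mode must be EC or IC")
    if data.n_distinct_doses < 3:
        raise ValueError("need >= 3 distinct doses to fit")
    if mode == "EC":
        data = exclude_desensitized(data.to_percent())
    x, y = data.doses, data.responses
    log_e_grid = np.linspace(np.log(x.min()), np.log(x.max()), 5)

    def residuals(theta: np.ndarray) -> np.ndarray:
        if mode == "EC":
            b, c, log_e = theta
            return ll3(x, b, c, 100.0, np.exp(log_e)) - y
        b, d, log_e = theta
        return ll3(x, b, 0.0, d, np.exp(log_e)) - y

    best = None
    for b0 in (-2.0, -1.0, -0.5, 0.5, 1.0, 2.0):
        for log_e0 in log_e_grid:
            other0 = 0.0 if mode == "EC" else max(y.max(), 1e-6)
            try:
                res = optimize.least_squares(
                    residuals,
                    x0=np.array([b0, other0, log_e0]),
                    xtol=1e-14, ftol=1e-14, gtol=1e-14,
                    max_nfev=2000,
                )
            except Exception:
                continue
            if best is None or res.cost < best.cost - 1e-30:
                best = res
    if best is None:
        raise RuntimeError("all optimizer starts failed")
    converged = bool(best.success and np.isfinite(best.cost))
    if mode == "EC":
        b, c, log_e = best.x
        d = 100.0
        fixed = {"b": False, "c": False, "d": True, "e": False}
    else:
        b, other, log_e = best.x
        c, d = 0.0, other
        fixed = {"b": False, "c": True, "d": False, "e": False}
    if c > d:
        b, c, d = -b, d, c  # canonical orientation: c <= d
    return LogLogisticFit(
        b=float(b), c=float(c), d=float(d), e=float(np.exp(log_e)),
        fixed_mask=fixed, converged=converged,
        rss=float(2 * best.cost), n_obs=len(y), mode=mode,
    )


def derive_ecf(fit: LogLogisticFit, f: float) -> float:
    """Dose at which the fitted response reaches f% of the span (c, d).

    Closed form: x = e * ((100 - f) / f) ** (1 / b); f = 50 returns the
    midpoint e exactly.
    """
    if not 0 < f < 100:
        raise ValueError("f must lie in (0, 100)")
    if not fit.converged:
        raise ValueError("cannot derive effective dose from a non-converged fit")
    if fit.b == 0:
        raise ValueError("degenerate fit: zero slope")
    return float(fit.e * ((100.0 - f) / f) ** (1.0 / fit.b))


def to_potency(value_molar: float) -> float:
    """pX = -log10 of a molar EC50/EC80/IC50; e.g. 9.5e-6 M -> 5.02."""
    if value_molar <= 0:
        raise ValueError("potency transform requires a positive molar value")
    return float(-np.log10(value_molar))


@dataclass(frozen=True)
class PotencySummary:
    ec50: float | None = None
    ec80: float | None = None
    ic50: float | None = None

    @property
    def pec50(self) -> float | None:
        return None if self.ec50 is None else to_potency(self.ec50)

    @property
    def pec80(self) -> float | None:
        return None if self.ec80 is None else to_potency(self.ec80)

    @property
    def pic50(self) -> float | None:
        return None if self.ic50 is None else to_potency(self.ic50)


def summarize_potency(fit: LogLogisticFit) -> PotencySummary:
    if fit.mode == "IC":
        return PotencySummary(ic50=fit.e)
    return PotencySummary(ec50=fit.e, ec80=derive_ecf(fit, 80.0))


def design_pool(tpm: dict[str, float] | pd.Series) -> pd.Series:
    """Molar fractions proportional to mean expression (TPM) per chemokine."""
    s = pd.Series(tpm, dtype=float)
    if (s < 0).any():
        raise ValueError("TPM values must be non-negative")
    total = s.sum()
    if total == 0:
        raise ValueError("all-zero TPM table: pool ratios undefined")
    return s / total


# ---------------------------------------------------------------------------
# Dunnett many-to-one comparisons


from functools import lru_cache


@lru_cache(maxsize=64)
def _dunnett_nodes(df: int, n_z: int, n_s: int):
    xh, wh = np.polynomial.hermite.hermgauss(n_z)
    z = np.sqrt(2.0) * xh
    wz = wh / np.sqrt(np.pi)
    q = (np.arange(n_s) + 0.5) / n_s
    s = np.sqrt(stats.chi2.ppf(q, df) / df)
    return z, wz, s


def dunnett_sf(t: np.ndarray, lambdas: np.ndarray, df: int,
               n_z: int = 48, n_s: int = 64) -> np.ndarray:
    """Two-sided survival function P(max_i |T_i| >= t) for many-to-one t.

    T has the product correlation structure rho_ij = lambda_i * lambda_j with
    lambda_i = sqrt(n_i / (n_i + n_0)) and df error degrees of freedom.
    Evaluated by Gauss-Hermite quadrature over the shared control variate and
    a midpoint rule over the chi-distributed scale. With a single comparison
    this reduces exactly to the two-sided Student t tail.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    lambdas = np.asarray(lambdas, dtype=float)
    k = len(lambdas)
    if k == 1:
        return 2.0 * stats.t.sf(np.abs(t), df)
    if len(t) > 512:  # bound the quadrature tensor's memory footprint
        return np.concatenate(
            [dunnett_sf(chunk, lambdas, df, n_z, n_s)
             for chunk in np.array_split(t, int(np.ceil(len(t) / 512)))]
        )
    # z nodes: N(0,1) via Hermite; s nodes: chi_df/sqrt(df) via quantile midpoints
    z, wz, s = _dunnett_nodes(df, n_z, n_s)
    ws = np.full(n_s, 1.0 / n_s)
    denom = np.sqrt(1.0 - lambdas**2)  # (k,)
    out = np.empty(t.shape)
    ts = np.abs(t)[:, None, None] * s[None, None, :]  # (T, 1, S)
    lz = (lambdas[:, None] * z[None, :])[None, :, :, None]  # (1, k, Z, 1)
    upper = (ts[:, None, :, :] + lz) / denom[None, :, None, None]
    lower = (-ts[:, None, :, :] + lz) / denom[None, :, None, None]
    from scipy.special import ndtr

    probs = ndtr(upper) - ndtr(lower)  # (T, k, Z, S)
    inner = probs.prod(axis=1)  # (T, Z, S)
    cdf = np.einsum("tzs,z,s->t", inner, wz, ws)
    out = 1.0 - cdf
    return np.clip(out, 0.0, 1.0)


def significance_stars(p: float) -> str:
    """Star bins used in the report figures."""
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 5e-2)):
        if p <= cut:
            return stars
    return ""


def dunnett_familywise_error(
    n_test_groups: int = 5,
    n_per_group: int = 3,
    n_reps: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Simulated familywise type-I error of the Dunnett procedure under a
    Gaussian null (all group means equal).

    The minimum adjusted p over comparisons is a monotone function of the
    maximum |t|, so each replicate rejects iff the adjusted p of its largest
    statistic falls below alpha; statistics are computed exactly as in
    :func:`dunnett_compare` (pooled one-way error variance), vectorised over
    replicates.
    """
    rng = np.random.default_rng(seed)
    k, n = n_test_groups, n_per_group
    data = rng.normal(size=(n_reps, k + 1, n))  # last group is the control
    means = data.mean(axis=2)
    df = (k + 1) * (n - 1)
    s2 = ((data - means[:, :, None]) ** 2).sum(axis=(1, 2)) / df
    diffs = means[:, :k] - means[:, k:]
    tstat = diffs / np.sqrt(s2[:, None] * (2.0 / n))
    max_t = np.abs(tstat).max(axis=1)
    lambdas = np.full(k, np.sqrt(n / (2.0 * n)))
    p_min = dunnett_sf(max_t, lambdas, df)
    return float((p_min <= alpha).mean())


@dataclass
class DunnettResult:
    table: pd.DataFrame  # group, mean_diff, t, p_adj, stars
    control: str
    df: int


def dunnett_compare(
    groups: dict[str, np.ndarray], control: str
) -> DunnettResult:
    """Two-sided Dunnett comparisons of every group against the control.

    Uses the pooled one-way-ANOVA error variance; adjusted p-values come
    from the many-to-one multivariate-t equicoordinate probability.
    """
    if control not in groups:
        raise ValueError(f"control group {control!r} not supplied")
    names = [g for g in groups if g != control]
    if not names:
        raise ValueError("need at least one non-control group")
    arrs = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    if any(len(v) < 2 for v in arrs.values()):
        raise ValueError("every group needs >= 2 replicates")
    n_total = sum(len(v) for v in arrs.values())
    k_all = len(arrs)
    df = n_total - k_all
    sse = sum(((v - v.mean()) ** 2).sum() for v in arrs.values())
    if sse == 0:
        raise ValueError("zero within-group variance in every group")
    s2 = sse / df
    n0 = len(arrs[control])
    m0 = arrs[control].mean()
    ns = np.array([len(arrs[g]) for g in names], dtype=float)
    diffs = np.array([arrs[g].mean() - m0 for g in names])
    se = np.sqrt(s2 * (1.0 / ns + 1.0 / n0))
    tstat = diffs / se
    lambdas = np.sqrt(ns / (ns + n0))
    p_adj = dunnett_sf(np.abs(tstat), lambdas, df)
    table = pd.DataFrame(
        {
            "group": names,
            "mean_diff": diffs,
            "t": tstat,
            "p_adj": p_adj,
            "stars": [significance_stars(p) for p in p_adj],
        }
    )
    return DunnettResult(table=table, control=control, df=df)
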