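"""Saturation of mutation detection with coverage, and its suppression by
normal-cell contamination.

The number of mutations detected at mean coverage c follows a
Michaelis-Menten curve, n(c) = n_max * c / (k_half + c): detection
saturates once coverage comfortably exceeds the depth needed to sample
the minor allele at every site.  Mixing a fraction f of normal reads into
the tumour acts like a mixed-type enzyme inhibitor — it both shifts the
half-saturation coverage and lowers the attainable plateau:

    n(c, f) = n_max * c / (k_half * alpha + c * alpha')
    alpha  = 1 + f / ki_competitive
    alpha' = 1 + f / ki_uncompetitive

so f = 0 reduces exactly to the plain curve, and any f > 0 caps the
asymptote at n_max / alpha' < n_max.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .simulate import thin_and_mix


@dataclass
class CallerRule:
    """Threshold caller applied to thinned counts (stand-in for a full
    somatic pipeline): minimum tumour alt reads, maximum normal alt reads
    and minimum observed AF."""

    min_t_alt: int = 4
    max_n_alt: int = 1
    min_af: float = 0.02

    def count_calls(self, evidence: pd.DataFrame) -> int:
        t_alt = evidence["t_alt"].to_numpy()
        depth = np.maximum((evidence["t_alt"] + evidence["t_ref"]).to_numpy(), 1)
        ok = (
            (t_alt >= self.min_t_alt)
            & (evidence["n_alt"].to_numpy() <= self.max_n_alt)
            & (t_alt / depth >= self.min_af)
        )
        return int(ok.sum())


def saturation_series(
    evidence: pd.DataFrame,
    coverages: list[float],
    contaminations: list[float] = (0.0,),
    caller: CallerRule | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Detected-mutation counts over a coverage x contamination grid.

    Each cell thins the full-depth evidence to the requested mean coverage
    (and mixes in normal reads at the requested proportion) and counts
    sites passing the caller rule.  Deterministic given seed.
    """
    caller = caller or CallerRule()
    full = float((evidence["t_alt"] + evidence["t_ref"]).mean())
    rows = []
    for i, f in enumerate(sorted(contaminations)):
        for j, cov in enumerate(sorted(coverages)):
            if cov > full:
                raise ValueError(
                    f"requested coverage {cov} exceeds available depth {full:.0f}"
                )
            thinned = thin_and_mix(
                evidence, fraction=cov / full, contamination=f,
                seed=seed + 1000 * i + j,
            )
            rows.append({
                "coverage": cov,
                "contamination": f,
                "count": caller.count_calls(thinned),
            })
    return pd.DataFrame(rows)


@dataclass
class SaturationFit:
    """Fitted saturation parameters; ``ki_*`` are None for the plain fit."""

    n_max: float
    k_half: float
    ki_competitive: float | None = None
    ki_uncompetitive: float | None = None
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))

    def predict(self, coverage, contamination=0.0) -> np.ndarray:
        c = np.asarray(coverage, dtype=float)
        f = np.asarray(contamination, dtype=float)
        alpha = 1.0 + (f / self.ki_competitive if self.ki_competitive else 0.0 * f)
        alpha_p = 1.0 + (f / self.ki_uncompetitive if self.ki_uncompetitive else 0.0 * f)
        return self.n_max * c / (self.k_half * alpha + c * alpha_p)

    def fraction_of_max(self, coverage) -> np.ndarray:
        """c / (k_half + c): fraction of the asymptote detected at c."""
        c = np.asarray(coverage, dtype=float)
        return c / (self.k_half + c)


def fit_mm(points: pd.DataFrame) -> SaturationFit:
    """Least-squares Michaelis-Menten fit to contamination-free points.

    Multi-start initialisation: n_max from the largest observed count,
    k_half from the half-maximum crossing (plus coarse alternatives);
    non-convergence raises with diagnostics.
    """
    pts = points[points.get("contamination", 0.0) == 0.0] if "contamination" in points else points
    c = pts["coverage"].to_numpy(dtype=float)
    y = pts["count"].to_numpy(dtype=float)
    if len(np.unique(c)) < 3:
        raise ValueError("need at least three distinct coverages")

    def resid(theta):
        n_max, k_half = theta
        return n_max * c / (k_half + c) - y

    y_max = max(y.max(), 1.0)
    half_cross = c[np.argmin(np.abs(y - y_max / 2))]
    starts = [
        (y_max, max(half_cross, 1.0)),
        (1.2 * y_max, np.median(c)),
        (2.0 * y_max, c.max()),
    ]
    best = None
    for x0 in starts:
        sol = least_squares(resid, x0=x0, bounds=([1e-9, 1e-9], [np.inf, np.inf]))
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        raise RuntimeError(f"Michaelis-Menten fit did not converge: {best}")
    n_max, k_half = best.x
    return SaturationFit(n_max=float(n_max), k_half=float(k_half),
                         residuals=best.fun)


def fit_mixed_inhibition(points: pd.DataFrame) -> SaturationFit:
    """Fit the mixed-inhibition surface over coverage and contamination.

    Requires at least two contamination levels including 0.  Inhibition is
    parameterised internally by inverse constants (>= 0) so the fit can
    reach the no-inhibition limit (ki -> infinity) smoothly.
    """
    c = points["coverage"].to_numpy(dtype=float)
    f = points["contamination"].to_numpy(dtype=float)
    y = points["count"].to_numpy(dtype=float)
    levels = np.unique(f)
    if len(levels) < 2 or 0.0 not in levels:
        raise ValueError("need >=2 contamination levels including 0")

    def model(theta):
        n_max, k_half, inv_kc, inv_ku = theta
        return n_max * c / (k_half * (1 + f * inv_kc) + c * (1 + f * inv_ku))

    def resid(theta):
        return model(theta) - y

    base = fit_mm(points[points["contamination"] == 0.0])
    best = None
    for inv0 in ((1.0, 1.0), (5.0, 0.5), (0.1, 5.0)):
        sol = least_squares(
            resid, x0=(base.n_max, base.k_half, *inv0),
            bounds=([1e-9, 1e-9, 0.0, 0.0], np.inf),
        )
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        raise RuntimeError(f"mixed-inhibition fit did not converge: {best}")
    n_max, k_half, inv_kc, inv_ku = best.x
    return SaturationFit(
        n_max=float(n_max),
        k_half=float(k_half),
        ki_competitive=float(1.0 / inv_kc) if inv_kc > 0 else np.inf,
        ki_uncompetitive=float(1.0 / inv_ku) if inv_ku > 0 else np.inf,
        residuals=best.fun,
    )


def simulate_curves(
    fit: SaturationFit, coverages, contaminations
) -> pd.DataFrame:
    """Model curves for requested contamination fractions (the dashed
    companion lines of an observed saturation plot)."""
    rows = []
    for f in contaminations:
        for c in coverages:
            rows.append({
                "coverage": c,
                "contamination": f,
                "count": float(fit.predict(c, f)),
            })
    return pd.DataFrame(rows)
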