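"""Four-parameter logistic (4PL) concentration-response modelling.

The response of a one-site inhibition assay as a function of inhibitor
concentration c is modelled as

    y(c) = bottom + (top - bottom) / (1 + (IC50/c)^hill)

which runs from ``bottom`` at c -> 0 to ``top`` at c -> inf and passes
through the midpoint at c = IC50.  On a normalised %-inhibition scale the
asymptotes are fixed at 0 and 100 by default; a flag frees them.

Fitting is nonlinear least squares with the IC50 parametrised as
log10(IC50), which makes the fit equivariant under rescaling of the
concentration axis and keeps the optimiser away from the c <= 0 boundary.
A fitted IC50 above the top tested concentration is reported as a censored
"> c_max" bound instead of an extrapolated value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = ["DoseResponseCurve", "FitResult", "four_pl", "fit_4pl", "fit_curve_table"]


def four_pl(conc, ic50: float, hill: float = 1.0, top: float = 100.0, bottom: float = 0.0):
    """4PL response at concentration(s) *conc* (µM); vectorised over conc."""
    conc = np.asarray(conc, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be > 0")
    if ic50 <= 0:
        raise ValueError(f"ic50 must be > 0, got {ic50}")
    if hill <= 0:
        raise ValueError(f"hill must be > 0, got {hill}")
    resp = bottom + (top - bottom) / (1.0 + (ic50 / conc) ** hill)
    return float(resp) if resp.ndim == 0 else resp


@dataclass
class DoseResponseCurve:
    """Replicated (concentration, response) observations for one assay."""

    compound_id: str
    kinase_id: str
    conc: np.ndarray
    response: np.ndarray

    def __post_init__(self) -> None:
        self.conc = np.asarray(self.conc, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.conc.shape != self.response.shape:
            raise ValueError("conc and response must have equal length")
        if np.any(self.conc <= 0):
            raise ValueError("concentrations must be positive")
        if not np.all(np.isfinite(self.response)):
            raise ValueError("responses must be finite")

    @property
    def n_distinct_conc(self) -> int:
        return len(np.unique(self.conc))


@dataclass
class FitResult:
    """4PL fit outcome.  ``converged=False`` flags failure; never an exception."""

    compound_id: str
    kinase_id: str
    ic50: float
    hill: float
    top: float
    bottom: float
    rss: float
    converged: bool
    censored: bool = False
    ic50_stderr: Optional[float] = None


_XTOL = 1e-12
_MAX_ITER = 500


def fit_4pl(curve: DoseResponseCurve, free_asymptotes: bool = False,
            top: float = 100.0, bottom: float = 0.0) -> FitResult:
    """Least-squares 4PL fit of a dose-response curve.

    By default the asymptotes are constrained to (bottom=0, top=100) on the
    %-inhibition scale and only log10(IC50) and the Hill slope are free;
    ``free_asymptotes=True`` fits all four parameters.  Initialisation:
    bottom/top from the data extremes, IC50 at the concentration whose mean
    response is nearest the half-height, hill = 1.

    Returns a :class:`FitResult`; degenerate data (flat responses, optimiser
    failure) yields ``converged=False`` rather than raising.  A fitted IC50
    beyond the top tested concentration is flagged ``censored`` with the
    bound set to that concentration.
    """
    if curve.n_distinct_conc < 4:
        raise ValueError(
            f"{curve.compound_id}/{curve.kinase_id}: need >= 4 distinct "
            f"concentrations, got {curve.n_distinct_conc}"
        )
    c, y = curve.conc, curve.response
    c_max = float(c.max())

    # flat data carries no information about the midpoint
    if np.ptp(y) < 1e-9:
        return FitResult(curve.compound_id, curve.kinase_id, c_max, 1.0,
                         top, bottom, float(np.sum((y - y.mean()) ** 2)),
                         converged=False, censored=True)

    b0 = float(y.min()) if free_asymptotes else bottom
    t0 = float(y.max()) if free_asymptotes else top
    half = 0.5 * (t0 + b0)
    # initial IC50: tested concentration whose response is nearest half-height
    mid_idx = int(np.argmin(np.abs(y - half)))
    x0_log_ic50 = np.log10(c[mid_idx])

    if free_asymptotes:
        x0 = np.array([x0_log_ic50, 1.0, t0, b0])
        lo = [-12.0, 1e-3, -np.inf, -np.inf]
        hi = [12.0, 20.0, np.inf, np.inf]

        def resid(x):
            return four_pl(c, 10.0 ** x[0], x[1], x[2], x[3]) - y
    else:
        x0 = np.array([x0_log_ic50, 1.0])
        lo = [-12.0, 1e-3]
        hi = [12.0, 20.0]

        def resid(x):
            return four_pl(c, 10.0 ** x[0], x[1], top, bottom) - y

    try:
        sol = least_squares(resid, x0, bounds=(lo, hi), xtol=_XTOL, ftol=_XTOL,
                            gtol=_XTOL, max_nfev=_MAX_ITER * len(x0))
    except Exception:
        return FitResult(curve.compound_id, curve.kinase_id, np.nan, np.nan,
                         top, bottom, np.nan, converged=False)

    ic50 = float(10.0 ** sol.x[0])
    hill = float(sol.x[1])
    t_fit, b_fit = (float(sol.x[2]), float(sol.x[3])) if free_asymptotes else (top, bottom)
    rss = float(np.sum(sol.fun ** 2))
    converged = bool(sol.success) and np.isfinite(rss) and b_fit <= t_fit

    stderr = None
    if converged and sol.jac is not None:
        # delta-method stderr on IC50 from the log10(IC50) covariance
        dof = max(len(y) - len(sol.x), 1)
        try:
            jtj_inv = np.linalg.pinv(sol.jac.T @ sol.jac)
            var_log = jtj_inv[0, 0] * rss / dof
            stderr = float(ic50 * np.log(10.0) * np.sqrt(max(var_log, 0.0)))
        except np.linalg.LinAlgError:
            stderr = None

    censored = converged and ic50 > c_max
    if censored:
        ic50 = c_max
    return FitResult(curve.compound_id, curve.kinase_id, ic50, hill, t_fit,
                     b_fit, rss, converged, censored, stderr)


def fit_curve_table(df: pd.DataFrame, free_asymptotes: bool = False) -> pd.DataFrame:
    """Fit every (compound, kinase) group of a long-format curve table.

    Input columns ``compound_id,kinase_id,conc_uM,response_pct``; output one
    row per pair with columns
    ``compound_id,kinase_id,ic50_uM,hill,top,bottom,rss,converged,censored``,
    sorted by compound then kinase id.
    """
    need = {"compound_id", "kinase_id", "conc_uM", "response_pct"}
    if not need <= set(df.columns):
        raise ValueError(f"curve table missing columns: {sorted(need - set(df.columns))}")
    rows = []
    keys = sorted(set(zip(df["compound_id"].astype(str), df["kinase_id"].astype(str))))
    grouped = df.assign(
        compound_id=df["compound_id"].astype(str), kinase_id=df["kinase_id"].astype(str)
    ).groupby(["compound_id", "kinase_id"])
    for cid, kid in keys:
        g = grouped.get_group((cid, kid))
        curve = DoseResponseCurve(cid, kid, g["conc_uM"].to_numpy(), g["response_pct"].to_numpy())
        r = fit_4pl(curve, free_asymptotes=free_asymptotes)
        rows.append({
            "compound_id": r.compound_id, "kinase_id": r.kinase_id,
            "ic50_uM": r.ic50, "hill": r.hill, "top": r.top, "bottom": r.bottom,
            "rss": r.rss, "converged": r.converged, "censored": r.censored,
        })
    return pd.DataFrame(rows, columns=["compound_id", "kinase_id", "ic50_uM", "hill",
                                       "top", "bottom", "rss", "converged", "censored"])
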