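"""Two-state ion-induced folding fits of E_FRET titrations.

The fraction of folded molecules at Mg2+ concentration c follows a
Hill-type two-state isotherm,

    E_FRET(c) = E0 + dE * K_A * c**n / (1 + K_A * c**n),

with E0 the efficiency with no added ions, dE the change at saturation
(negative dE represents curves that decrease with added ions), K_A an
apparent association constant (uM**-n) and n a phenomenological Hill
coefficient.  The half-transition concentration is
[Mg2+]_1/2 = (1/K_A)**(1/n).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import DomainError, InsufficientPoints

#: minimum points for a meaningful four-parameter fit
MIN_POINTS = 5
#: default detectability threshold on dE for calling folding
DETECT_DE = 0.05


@dataclass(frozen=True)
class TitrationCurve:
    """(Mg2+ concentration in uM, E_FRET) series for one construct."""

    conc: np.ndarray
    efret: np.ndarray
    construct_id: str = ""
    replicate_id: str | None = None

    def __post_init__(self) -> None:
        conc = np.asarray(self.conc, dtype=float)
        efret = np.asarray(self.efret, dtype=float)
        if conc.shape != efret.shape or conc.ndim != 1:
            raise ValueError("conc and efret must be equal-length 1-D arrays")
        if np.any(conc < 0):
            raise DomainError("negative Mg2+ concentration")
        if np.any(np.diff(conc) < 0):
            raise ValueError("concentrations must be non-decreasing")
        if np.count_nonzero(conc == 0) > 1:
            raise ValueError("at most one zero-concentration point per replicate")
        object.__setattr__(self, "conc", conc)
        object.__setattr__(self, "efret", efret)


def efret_two_state(conc, e0: float, de: float, k_a: float, n: float):
    """Evaluate the two-state isotherm; scalar or array ``conc`` in uM."""
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise DomainError("negative Mg2+ concentration")
    if k_a <= 0 or n <= 0:
        raise DomainError("K_A and n must be positive")
    with np.errstate(over="ignore"):
        term = k_a * np.power(conc, n)
        out = e0 + de * term / (1.0 + term)
    # saturation limit where K_A * c**n overflows
    out = np.where(np.isfinite(term), out, e0 + de)
    return float(out) if out.ndim == 0 else out


def half_transition(k_a: float, n: float) -> float:
    """[Mg2+]_1/2 = (1/K_A)**(1/n), in uM."""
    if k_a <= 0 or n <= 0:
        raise DomainError("K_A and n must be positive")
    return float((1.0 / k_a) ** (1.0 / n))


@dataclass(frozen=True)
class TwoStateFit:
    """Fitted two-state parameters for one titration."""

    e0: float
    de: float
    k_a: float
    n: float
    mg_half: float
    covariance: np.ndarray | None
    rms_residual: float
    converged: bool
    folding_detected: bool
    de_stderr: float = float("nan")
    construct_id: str = ""

    def predict(self, conc):
        return efret_two_state(conc, self.e0, self.de, self.k_a, self.n)


def fit_two_state(
    curve: TitrationCurve,
    fix_n: float | None = None,
    n_bounds: tuple[float, float] = (0.5, 4.0),
    detect_de: float = DETECT_DE,
) -> TwoStateFit:
    """Nonlinear least-squares fit of the two-state isotherm.

    Initialization: E0 = first point, dE = last - first, K_A =
    1/median(conc>0), n = 1.  Bounds: E0 in [-0.1, 1.1], |dE| <= 1,
    K_A > 0, n in ``n_bounds`` (or fixed at ``fix_n``).  A fit is reported
    with ``converged=False`` rather than raised when the optimizer fails;
    ``folding_detected`` requires convergence, dE >= ``detect_de`` and
    dE > 2 standard errors.
    """
    conc, efret = curve.conc, curve.efret
    if conc.size < MIN_POINTS:
        raise InsufficientPoints(
            f"{conc.size} points < {MIN_POINTS} required for the two-state fit"
        )
    positive = conc[conc > 0]
    e0_init = float(efret[0])
    de_init = float(np.clip(efret[-1] - efret[0], -1.0, 1.0))
    ka_init = 1.0 / float(np.median(positive)) if positive.size else 1.0

    if fix_n is not None:
        def model(c, e0, de, log_ka):
            return efret_two_state(c, e0, de, np.exp(log_ka), fix_n)
        p0 = [e0_init, de_init, np.log(ka_init)]
        lower = [-0.1, -1.0, -60.0]
        upper = [1.1, 1.0, 60.0]
    else:
        def model(c, e0, de, log_ka, n):
            return efret_two_state(c, e0, de, np.exp(log_ka), n)
        p0 = [e0_init, de_init, np.log(ka_init), 1.0]
        lower = [-0.1, -1.0, -60.0, n_bounds[0]]
        upper = [1.1, 1.0, 60.0, n_bounds[1]]
    p0 = np.clip(p0, lower, upper)

    converged = True
    cov = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(
                model, conc, efret, p0=p0, bounds=(lower, upper),
                method="trf", maxfev=20000, xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        cov = pcov
    except (RuntimeError, ValueError):
        converged = False
        popt = np.asarray(p0, dtype=float)

    e0, de, log_ka = popt[0], popt[1], popt[2]
    n = float(fix_n) if fix_n is not None else float(popt[3])
    k_a = float(np.exp(log_ka))
    resid = efret - model(conc, *popt)
    rms = float(np.sqrt(np.mean(resid**2)))

    de_stderr = float("nan")
    if cov is not None and np.isfinite(cov[1, 1]):
        de_stderr = float(np.sqrt(cov[1, 1]))

    # an unresolved (infinite/undefined) stderr never counts as detected
    detected = (
        converged
        and de >= detect_de
        and np.isfinite(de_stderr)
        and de > 2.0 * de_stderr
    )

    return TwoStateFit(
        e0=float(e0),
        de=float(de),
        k_a=k_a,
        n=n,
        mg_half=half_transition(k_a, n),
        covariance=cov,
        rms_residual=rms,
        converged=converged,
        folding_detected=bool(detected),
        de_stderr=de_stderr,
        construct_id=curve.construct_id,
    )


def average_replicates(curves: list[TitrationCurve]) -> TitrationCurve:
    """Point-wise mean of replicate titrations sharing one grid.

    Averaging replicates before fitting is the standard way to beat
    per-point noise; the half-transition precision of a single curve is
    bounded by its information content.
    """
    if not curves:
        raise InsufficientPoints("no replicates to average")
    grid = curves[0].conc
    for curve in curves[1:]:
        if curve.conc.shape != grid.shape or not np.allclose(curve.conc, grid):
            raise ValueError("replicates must share one concentration grid")
    return TitrationCurve(
        grid,
        np.mean([c.efret for c in curves], axis=0),
        construct_id=curves[0].construct_id,
    )


@dataclass(frozen=True)
class FinalStateSummary:
    """Initial and saturating E_FRET plus a folding call for one construct."""

    construct_id: str
    initial_efret: float
    final_efret: float
    folding_call: str  # folds | impaired | none


def summarize_final_state(
    fit_or_curve: TwoStateFit | TitrationCurve,
    folded_min: float = 0.35,
    unfolded_max: float = 0.32,
    plateau_points: int = 3,
) -> FinalStateSummary:
    """Final-state summary from a fit, or from plateau points as fallback.

    With a detected folding transition the final efficiency is E0 + dE;
    a curve input uses the mean of the top-concentration points instead.
    Calls: >= ``folded_min`` folds, <= ``unfolded_max`` none, otherwise
    impaired (the indeterminate band).
    """
    if isinstance(fit_or_curve, TwoStateFit):
        fit = fit_or_curve
        initial = fit.e0
        if not fit.folding_detected:
            return FinalStateSummary(fit.construct_id, initial, initial, "none")
        final = fit.e0 + fit.de
        construct_id = fit.construct_id
    else:
        curve = fit_or_curve
        if curve.conc.size < plateau_points:
            raise InsufficientPoints("need >= 3 plateau points")
        initial = float(curve.efret[0])
        final = float(np.mean(curve.efret[-plateau_points:]))
        construct_id = curve.construct_id
    if final >= folded_min:
        call = "folds"
    elif final <= unfolded_max:
        call = "none"
    else:
        call = "impaired"
    return FinalStateSummary(construct_id, float(initial), float(final), call)


# ---------------------------------------------------------------------------
# tabular interfaces

def read_titrations_csv(path) -> list[TitrationCurve]:
    """Titration CSV: construct_id, conc_uM, efret[, replicate]."""
    import pandas as pd

    frame = pd.read_csv(path)
    if "replicate" not in frame.columns:
        frame["replicate"] = ""
    curves = []
    for (cid, rep), grp in frame.groupby(["construct_id", "replicate"], sort=False):
        grp = grp.sort_values("conc_uM")
        curves.append(
            TitrationCurve(
                grp["conc_uM"].to_numpy(float),
                grp["efret"].to_numpy(float),
                construct_id=str(cid),
                replicate_id=str(rep) or None,
            )
        )
    return curves


def fits_table(fits: list[TwoStateFit]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "construct_id": f.construct_id,
                "E0": f.e0,
                "dE": f.de,
                "K_A": f.k_a,
                "n": f.n,
                "mg_half_uM": f.mg_half,
                "rmsd": f.rms_residual,
                "converged": f.converged,
                "folding_detected": f.folding_detected,
            }
            for f in fits
        ]
    )
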