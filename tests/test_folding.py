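"""Two-state isotherm evaluation and titration fitting."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import kturnfold as kf
from kturnfold.errors import DomainError, InsufficientPoints
from kturnfold.folding import TitrationCurve


def test_isotherm_anchor_points():
    e0, de, k_a, n = 0.3, 0.25, 0.01, 1.3
    assert kf.efret_two_state(0.0, e0, de, k_a, n) == pytest.approx(e0)
    half = kf.half_transition(k_a, n)
    assert kf.efret_two_state(half, e0, de, k_a, n) == pytest.approx(e0 + de / 2)
    assert kf.efret_two_state(1e6 * half, e0, de, k_a, 1.0) == pytest.approx(
        e0 + de, abs=1e-5
    )


def test_isotherm_domain_errors():
    with pytest.raises(DomainError):
        kf.efret_two_state(-1.0, 0.3, 0.2, 0.01, 1.0)
    with pytest.raises(DomainError):
        kf.half_transition(-1.0, 1.0)


@pytest.mark.parametrize(
    "k_a, n, expected",
    [(1.0, 1.0, 1.0), (9.09e-3, 1.0, 110.01), (4.0, 2.0, 0.5)],
)
def test_half_transition_closed_form(k_a, n, expected):
    assert kf.half_transition(k_a, n) == pytest.approx(expected, rel=1e-4)


@given(
    de=st.floats(min_value=-1.0, max_value=1.0),
    n=st.floats(min_value=0.5, max_value=4.0),
)
def test_isotherm_monotone_in_concentration(de, n):
    """Non-decreasing for dE > 0, non-increasing for dE < 0."""
    conc = np.logspace(-1, 4, 40)
    values = kf.efret_two_state(conc, 0.3, de, 0.01, n)
    diffs = np.diff(values)
    if de > 0:
        assert np.all(diffs >= -1e-12)
    elif de < 0:
        assert np.all(diffs <= 1e-12)


def test_noiseless_fit_recovers_parameters():
    """Round trip at the stated generating parameters to 1e-6 relative."""
    true = dict(e0=0.30, de=0.25, k_a=0.01, n=1.0)
    conc = np.logspace(-0.5, 4, 16)
    curve = TitrationCurve(conc, kf.efret_two_state(conc, **true))
    fit = kf.fit_two_state(curve)
    assert fit.converged
    assert fit.e0 == pytest.approx(true["e0"], rel=1e-6, abs=1e-9)
    assert fit.de == pytest.approx(true["de"], rel=1e-6)
    assert fit.k_a == pytest.approx(true["k_a"], rel=1e-6)
    assert fit.n == pytest.approx(true["n"], rel=1e-6)
    assert fit.mg_half == pytest.approx(kf.half_transition(0.01, 1.0), rel=1e-6)


def test_flat_curve_no_folding_detected():
    curve = TitrationCurve(np.logspace(0, 3, 8), np.full(8, 0.42))
    fit = kf.fit_two_state(curve)
    assert not fit.folding_detected


def test_decreasing_titration_fitted_with_negative_de():
    """Curves that fall with added ions fit with dE < 0 and never count
    as folding."""
    conc = np.logspace(0, 4, 12)
    curve = TitrationCurve(conc, kf.efret_two_state(conc, 0.40, -0.12, 0.005, 1.0))
    fit = kf.fit_two_state(curve)
    assert fit.converged
    assert fit.de == pytest.approx(-0.12, rel=1e-4)
    assert not fit.folding_detected


def test_insufficient_points():
    with pytest.raises(InsufficientPoints):
        kf.fit_two_state(TitrationCurve(np.array([0.0, 1.0, 10.0, 100.0]),
                                        np.array([0.3, 0.32, 0.4, 0.5])))


def test_unit_covariance_mm_vs_um():
    """Fitting in mM with K_A rescaled gives the same mg_half after
    conversion (relative difference < 1e-6)."""
    conc_um = np.logspace(0, 4, 16)
    efret = kf.efret_two_state(conc_um, 0.30, 0.33, 1 / 110.0, 1.0)
    fit_um = kf.fit_two_state(TitrationCurve(conc_um, efret))
    fit_mm = kf.fit_two_state(TitrationCurve(conc_um / 1000.0, efret))
    assert fit_mm.mg_half * 1000.0 == pytest.approx(fit_um.mg_half, rel=1e-6)


def grid_search_oracle(conc, efret, ka_grid, n_grid):
    """Dense (K_A, n) grid with the analytic linear solve for (E0, dE)."""
    best = None
    for k_a in ka_grid:
        for n in n_grid:
            frac = k_a * conc**n / (1 + k_a * conc**n)
            design = np.column_stack([np.ones_like(conc), frac])
            coef, *_ = np.linalg.lstsq(design, efret)
            sse = float(np.sum((efret - design @ coef) ** 2))
            if best is None or sse < best[0]:
                best = (sse, coef[0], coef[1], k_a, n)
    return best


def test_fit_matches_grid_search_oracle(rng):
    """On 8-point curves the optimizer lands on the grid-search optimum."""
    conc = np.logspace(0, 3.5, 8)
    efret = kf.efret_two_state(conc, 0.28, 0.3, 1 / 150.0, 1.2) + rng.normal(
        0, 0.01, 8
    )
    curve = TitrationCurve(conc, efret)
    fit = kf.fit_two_state(curve)
    ka_grid = np.geomspace(1e-4, 1e-1, 120)
    n_grid = np.linspace(0.5, 4.0, 120)
    sse, e0, de, k_a, n = grid_search_oracle(conc, efret, ka_grid, n_grid)
    fit_sse = float(np.sum((efret - fit.predict(conc)) ** 2))
    assert fit_sse <= sse + 1e-10  # optimizer at least as good as the grid
    assert fit.k_a == pytest.approx(k_a, rel=0.1)  # within grid resolution
    assert fit.n == pytest.approx(n, abs=np.diff(n_grid)[0] * 2)


def test_monte_carlo_mg_half_recovery():
    """Median mg_half error < 5% over seeded Monte-Carlo experiments,
    each fitting the average of 8 replicate titrations at sigma = 0.02
    (single-curve precision is information-bounded well above 5%)."""
    replicates, experiments = 8, 100
    spec = kf.TitrationSpec(sigma=0.02, replicates=replicates * experiments, seed=7)
    true_half = kf.half_transition(spec.k_a, spec.n)
    curves = kf.gen_titration(spec)
    fitted = []
    for i in range(experiments):
        averaged = kf.folding.average_replicates(
            curves[replicates * i : replicates * (i + 1)]
        )
        fitted.append(kf.fit_two_state(averaged).mg_half)
    rel_err = np.abs(np.array(fitted) - true_half) / true_half
    assert np.median(rel_err) < 0.05


def test_summarize_final_state_bands():
    fit = kf.fit_two_state(
        TitrationCurve(
            np.logspace(0, 4, 12),
            kf.efret_two_state(np.logspace(0, 4, 12), 0.30, 0.33, 1 / 110.0, 1.0),
        )
    )
    summary = kf.summarize_final_state(fit)
    assert summary.final_efret == pytest.approx(0.63, abs=1e-6)
    assert summary.folding_call == "folds"

    flat = kf.fit_two_state(TitrationCurve(np.logspace(0, 3, 8), np.full(8, 0.42)))
    summary = kf.summarize_final_state(flat)
    assert summary.folding_call == "none"
    assert summary.final_efret == summary.initial_efret

    conc = np.logspace(0, 4, 12)
    mid = kf.fit_two_state(
        TitrationCurve(conc, kf.efret_two_state(conc, 0.235, 0.1, 1 / 110.0, 1.0))
    )
    assert kf.summarize_final_state(mid).folding_call == "impaired"


def test_summarize_from_plateau_points():
    """Plateau fallback averages the top-concentration points."""
    conc = np.array([0.0, 1.0, 10.0, 100.0, 1000.0, 3000.0])
    efret = np.array([0.30, 0.31, 0.45, 0.60, 0.62, 0.64])
    summary = kf.summarize_final_state(TitrationCurve(conc, efret))
    assert summary.final_efret == pytest.approx(np.mean([0.60, 0.62, 0.64]))
    assert summary.folding_call == "folds"


def test_titration_csv_round_trip(tmp_path):
    path = tmp_path / "titrations.csv"
    with open(path, "w") as fh:
        fh.write("construct_id,conc_uM,efret,replicate\n")
        for conc in (0, 1, 10, 100, 1000):
            fh.write(f"wt,{conc},{0.3 + conc / 5000:.4f},0\n")
    curves = kf.folding.read_titrations_csv(path)
    assert len(curves) == 1
    assert curves[0].construct_id == "wt"
    assert curves[0].conc.size == 5
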