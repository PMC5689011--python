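"""FRET efficiency from steady-state spectra by acceptor normalization.

The donor-excited emission spectrum of a doubly labelled duplex is unmixed
into donor and acceptor components by linear least squares against
unit-area reference emission shapes.  The acceptor component, normalized by
the acceptor component under direct acceptor excitation, gives

    (ratio)_A = (eps_D(exD) * E + eps_A(exD)) / eps_A(exA)

so that, assuming 1:1 donor:acceptor labelling,

    E = ((ratio)_A - eps_A(exD)/eps_A(exA)) * eps_A(exA)/eps_D(exD).

Extinction coefficients are relative; only their ratios enter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import DegenerateAcceptor, DomainError, GridMismatch


@dataclass(frozen=True)
class Spectrum:
    """Wavelength-resolved intensities on a strictly increasing nm grid."""

    wavelengths: np.ndarray
    intensities: np.ndarray
    excitation_nm: float | None = None

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        if wl.shape != it.shape or wl.ndim != 1:
            raise ValueError("wavelengths and intensities must be equal-length 1-D")
        if wl.size < 2 or np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensities", it)

    def area(self) -> float:
        return float(np.trapezoid(self.intensities, self.wavelengths))

    def unit_area(self) -> "Spectrum":
        return Spectrum(self.wavelengths, self.intensities / self.area(), self.excitation_nm)

    def value_at(self, nm: float) -> float:
        return float(np.interp(nm, self.wavelengths, self.intensities))

    def same_grid(self, other: "Spectrum") -> bool:
        return self.wavelengths.shape == other.wavelengths.shape and bool(
            np.allclose(self.wavelengths, other.wavelengths)
        )


@dataclass(frozen=True)
class FluorophorePair:
    """Reference emission shapes and relative extinction coefficients.

    ``eps_d_at_exd``: donor extinction at the donor excitation wavelength;
    ``eps_a_at_exd``: acceptor extinction at donor excitation (direct
    excitation of the acceptor); ``eps_a_at_exa``: acceptor extinction at
    its own excitation wavelength.
    """

    donor_emission_shape: Spectrum
    acceptor_emission_shape: Spectrum
    eps_d_at_exd: float
    eps_a_at_exd: float
    eps_a_at_exa: float
    donor_excitation_nm: float = 490.0
    acceptor_excitation_nm: float = 547.0

    def __post_init__(self) -> None:
        if not self.donor_emission_shape.same_grid(self.acceptor_emission_shape):
            raise GridMismatch("reference emission shapes on different grids")
        if self.eps_d_at_exd <= 0 or self.eps_a_at_exa <= 0 or self.eps_a_at_exd < 0:
            raise ValueError("extinction coefficients out of range")


@dataclass(frozen=True)
class SpectrumSet:
    """Donor-excited and acceptor-excited emission spectra of one sample."""

    donor_excited: Spectrum
    acceptor_excited: Spectrum
    pair: FluorophorePair

    def __post_init__(self) -> None:
        if not self.donor_excited.same_grid(self.acceptor_excited):
            raise GridMismatch("spectra in a set must share one grid")
        if not self.donor_excited.same_grid(self.pair.donor_emission_shape):
            raise GridMismatch("spectra not on the reference grid")


class Deconvolution(NamedTuple):
    a_donor: float
    a_acceptor: float
    rms_residual: float
    negative_coefficient: bool


def deconvolve_emission(observed: Spectrum, pair: FluorophorePair) -> Deconvolution:
    """Least-squares unmixing of an emission spectrum into the two shapes.

    Coefficients are reported even when negative (clipping would bias E
    toward zero); the flag marks that case.
    """
    if not observed.same_grid(pair.donor_emission_shape):
        raise GridMismatch("observed spectrum not on the reference grid")
    design = np.column_stack(
        [pair.donor_emission_shape.intensities, pair.acceptor_emission_shape.intensities]
    )
    coef, *_ = np.linalg.lstsq(design, observed.intensities)
    resid = observed.intensities - design @ coef
    return Deconvolution(
        a_donor=float(coef[0]),
        a_acceptor=float(coef[1]),
        rms_residual=float(np.sqrt(np.mean(resid**2))),
        negative_coefficient=bool(np.any(coef < 0)),
    )


def ratio_a(spectrum_set: SpectrumSet) -> float:
    """Acceptor component under donor excitation over that under direct
    acceptor excitation."""
    num = deconvolve_emission(spectrum_set.donor_excited, spectrum_set.pair).a_acceptor
    den = deconvolve_emission(spectrum_set.acceptor_excited, spectrum_set.pair).a_acceptor
    if den <= 0:
        raise DegenerateAcceptor(
            f"acceptor-excited acceptor component {den:.3g} <= 0"
        )
    return num / den


class EfretResult(NamedTuple):
    efret: float
    ratio_a: float
    out_of_range: bool


def efret_from_spectra(
    spectrum_set: SpectrumSet, labeling_correction: float = 1.0
) -> EfretResult:
    """FRET efficiency by acceptor normalization.

    ``labeling_correction`` multiplies the result to correct for
    incomplete acceptor labelling; default 1 assumes 1:1 stoichiometry.
    The ``out_of_range`` flag marks E outside [-0.05, 1.05].
    """
    pair = spectrum_set.pair
    r = ratio_a(spectrum_set)
    direct = pair.eps_a_at_exd / pair.eps_a_at_exa
    e = (r - direct) * (pair.eps_a_at_exa / pair.eps_d_at_exd) * labeling_correction
    return EfretResult(efret=float(e), ratio_a=float(r), out_of_range=not -0.05 <= e <= 1.05)


class AbsorptionRatio(NamedTuple):
    eps_ratio: float
    residual: float
    negative_remainder: bool


def absorption_ratio(
    duplex_absorbance: Spectrum,
    acceptor_only_absorbance: Spectrum,
    donor_excitation_nm: float = 490.0,
    acceptor_excitation_nm: float = 547.0,
    band_threshold: float = 0.05,
) -> AbsorptionRatio:
    """Donor:acceptor absorbance ratio at their excitation wavelengths.

    The acceptor-only reference is scaled to the duplex spectrum by least
    squares over the acceptor band (where the reference exceeds
    ``band_threshold`` of its own maximum, restricted to wavelengths above
    the donor excitation); the remainder over the donor band is attributed
    to the donor.
    """
    if not duplex_absorbance.same_grid(acceptor_only_absorbance):
        raise GridMismatch("absorbance spectra on different grids")
    wl = duplex_absorbance.wavelengths
    ref = acceptor_only_absorbance.intensities
    obs = duplex_absorbance.intensities
    band = (ref >= band_threshold * ref.max()) & (wl >= acceptor_excitation_nm)
    if not band.any():
        raise DegenerateAcceptor("acceptor-only reference has no usable band")
    scale = float(ref[band] @ obs[band] / (ref[band] @ ref[band]))
    remainder = obs - scale * ref
    donor_abs = float(np.interp(donor_excitation_nm, wl, remainder))
    acceptor_abs = scale * float(np.interp(acceptor_excitation_nm, wl, ref))
    if acceptor_abs <= 0:
        raise DegenerateAcceptor("scaled acceptor absorbance <= 0 at excitation")
    residual = float(np.sqrt(np.mean(remainder[band] ** 2)))
    tol = 1e-9 * max(obs.max(), 1.0)
    return AbsorptionRatio(
        eps_ratio=donor_abs / acceptor_abs,
        residual=residual,
        negative_remainder=bool(np.any(remainder < -tol)),
    )


# ---------------------------------------------------------------------------
# CSV interface

def read_spectrum_csv(path) -> Spectrum:
    """Read a spectrum CSV (wavelength_nm, intensity) with optional
    ``# excitation_nm=`` metadata header lines."""
    import pandas as pd

    excitation = None
    with open(path) as fh:
        header_rows = 0
        for line in fh:
            if line.startswith("#"):
                header_rows += 1
                if "excitation_nm=" in line:
                    excitation = float(line.split("excitation_nm=")[1].strip())
            else:
                break
    frame = pd.read_csv(path, skiprows=header_rows)
    return Spectrum(
        frame["wavelength_nm"].to_numpy(float),
        frame["intensity"].to_numpy(float),
        excitation_nm=excitation,
    )


def write_spectrum_csv(spectrum: Spectrum, path) -> None:
    with open(path, "w") as fh:
        if spectrum.excitation_nm is not None:
            fh.write(f"# excitation_nm={spectrum.excitation_nm:g}\n")
        fh.write("wavelength_nm,intensity\n")
        for wl, it in zip(spectrum.wavelengths, spectrum.intensities):
            fh.write(f"{wl:g},{it:.10g}\n")
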