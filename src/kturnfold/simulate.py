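"""Seeded generators for every input the pipeline consumes.

Includes the printed construct catalog (the Kt-7 and box C/D FRET
duplexes, their exchange variants, the inosine and core-mutant controls,
and the chimeric DNA-RNA-DNA gel strands), plus generators that invert
the analysis models: two-state titration curves, donor/acceptor emission
spectra at a known transfer efficiency, and k-turn populations drawn from
per-position or per-pair frequency distributions.

All randomness flows through ``numpy.random.default_rng(seed)``; the same
seed reproduces output bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError
from .folding import TitrationCurve, efret_two_state
from .motif import (
    ElementId,
    KTurnDuplex,
    Strand,
    annotate_kturn,
    exchange_element,
    substitute,
    substitute_many,
)
from .seqstats import sample_pair
from .spectra import FluorophorePair, Spectrum, SpectrumSet

# ---------------------------------------------------------------------------
# printed construct catalog

_KT7_BULGED = "CCAGUCAGUGGCGAAGAACCAUGUCAGG"
_KT7_NONBULGED = "CCUGACAUGGGGAGCCACUGACUGG"
_BOXCD_BULGED = "CCUCAGUGGGCGUGAUGCAUGUCAUG"
_BOXCD_NONBULGED = "CAUGACAUGCUGACCCACUGAGG"

# chimeric gel strands: 20-nt DNA flanks around the FRET-construct RNA core
_GEL_UPPER_5P_DNA = "CGCAAGCGACAGGAACCTCG"
_GEL_UPPER_3P_DNA = "GGACTGTCAAGTTGAACAGG"
_GEL_LOWER_5P_DNA = "CCTGTTCAACTTGACAGTCC"
_GEL_LOWER_3P_DNA = "CGAGGTTCCTGTCGCTTGCG"


def _chimera(strand_id: str, dna5: str, rna: str, dna3: str) -> Strand:
    return Strand(
        id=strand_id,
        residues=dna5 + rna + dna3,
        chemistry="D" * len(dna5) + "R" * len(rna) + "D" * len(dna3),
    )


class FixtureCatalog(dict):
    """Named duplexes keyed by construct id (a dict of KTurnDuplex)."""


def fixtures() -> FixtureCatalog:
    """The construct catalog: printed parents, exchange variants, controls.

    Parent sequences are stored verbatim; variants are derived from them
    by element exchange / substitution so they stay consistent with the
    annotation layer by construction.
    """
    kt7 = KTurnDuplex(
        bulged=Strand("kt7_fret_bulged", _KT7_BULGED, fluorophore="fluorescein"),
        nonbulged=Strand("kt7_fret_nonbulged", _KT7_NONBULGED, fluorophore="Cy3"),
    )
    boxcd = KTurnDuplex(
        bulged=Strand("boxcd_fret_bulged", _BOXCD_BULGED, fluorophore="fluorescein"),
        nonbulged=Strand("boxcd_fret_nonbulged", _BOXCD_NONBULGED, fluorophore="Cy3"),
    )
    kt7_ann = annotate_kturn(kt7)
    boxcd_ann = annotate_kturn(boxcd)

    catalog = FixtureCatalog()
    catalog["kt7_fret"] = kt7
    catalog["boxcd_fret"] = boxcd

    # single-element exchanges in both directions
    for element in ElementId:
        name = element.value.lower()
        catalog[f"kt7_x_{name}"] = exchange_element(kt7_ann, element, boxcd_ann)
        catalog[f"boxcd_x_{name}"] = exchange_element(boxcd_ann, element, kt7_ann)

    # representative multi-exchange variants from the titration figures
    kt7_3uu = annotate_kturn(catalog["kt7_x_pair_3"])
    catalog["kt7_x_pair_3+minus1"] = exchange_element(
        kt7_3uu, ElementId.MINUS1_PAIR, boxcd_ann
    )
    boxcd_m1 = annotate_kturn(catalog["boxcd_x_minus1_pair"])
    catalog["boxcd_x_minus1+pair_3"] = exchange_element(
        boxcd_m1, ElementId.PAIR_3, kt7_ann
    )
    # the four-change variant: box C/D converted element-by-element to Kt-7
    current = boxcd_ann
    for element in ElementId:
        current = annotate_kturn(exchange_element(current, element, kt7_ann))
    four_change = current.strands()
    catalog["boxcd_all4_from_kt7"] = four_change

    # atomic mutagenesis: G at -1n replaced by inosine
    catalog["kt7_g1ni"] = substitute(kt7_ann, "-1n", "I")
    # k-turn-removed control: the three G•A pairs made Watson-Crick G-C
    catalog["kt7_core_mutant"] = substitute_many(
        kt7_ann, {"1n": "C", "2b": "C", "3b": "C"}
    )

    catalog["gel_kt7"] = KTurnDuplex(
        bulged=_chimera("gel_kt7_upper", _GEL_UPPER_5P_DNA, _KT7_BULGED, _GEL_UPPER_3P_DNA),
        nonbulged=_chimera("gel_kt7_lower", _GEL_LOWER_5P_DNA, _KT7_NONBULGED, _GEL_LOWER_3P_DNA),
    )
    return catalog


# ---------------------------------------------------------------------------
# declared synthetic study conditions for exchange panels

#: final E_FRET of the fully Kt-7-like parent (complete folding level)
PANEL_BASELINE = 0.63
#: additive final-E_FRET effect of swapping each element to its box C/D
#: form: the -1 pair dominates, 3b:3n and 4b:4n are smaller, the loop is
#: smallest and slightly favourable.  Chosen so every -1n = G combination
#: stays above 0.35 and every -1n = C combination below 0.32.
PANEL_EFFECTS = {
    "MINUS1_PAIR": -0.34,
    "LOOP": 0.02,
    "PAIR_3": -0.10,
    "PAIR_4": -0.08,
}
#: zero-ion E_FRET; the CGU loop bends the unfolded bulge slightly more
E0_LOOP_GAA = 0.30
E0_LOOP_CGU = 0.33


def exchange_panel_conditions():
    """The 2^4 factorial of exchange variants with their generating
    parameters: indicators (0 = Kt-7 element, 1 = box C/D element), E0 and
    exactly additive final E_FRET."""
    import itertools

    import pandas as pd

    rows = []
    for bits in itertools.product((0, 1), repeat=4):
        indicator = dict(zip(PANEL_EFFECTS, bits))
        final = PANEL_BASELINE + sum(
            PANEL_EFFECTS[e] * indicator[e] for e in PANEL_EFFECTS
        )
        rows.append(
            {
                "variant_id": "v" + "".join(map(str, bits)),
                **indicator,
                "e0": E0_LOOP_CGU if indicator["LOOP"] else E0_LOOP_GAA,
                "final_efret": round(final, 6),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# titrations

@dataclass(frozen=True)
class TitrationSpec:
    """Parameters for synthetic two-state titrations.

    Defaults reproduce the wild-type Kt-7 condition: E0 = 0.30 rising by
    dE = 0.33 to 0.63 at saturation, half-transition 110 uM (K_A = 1/110
    uM^-1, n = 1), with 2% additive Gaussian noise on efficiency.
    """

    e0: float = 0.30
    de: float = 0.33
    k_a: float = 1.0 / 110.0
    n: float = 1.0
    conc: np.ndarray = field(
        default_factory=lambda: np.concatenate(
            [[0.0], np.logspace(0.0, np.log10(11000.0), 23)]
        )
    )
    sigma: float = 0.02
    replicates: int = 1
    seed: int = 0
    construct_id: str = "synthetic"

    def __post_init__(self) -> None:
        conc = np.asarray(self.conc, dtype=float)
        if np.any(conc < 0) or np.any(np.diff(conc) < 0):
            raise ValueError("conc grid must be non-negative and increasing")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        object.__setattr__(self, "conc", conc)


def gen_titration(spec: TitrationSpec) -> list[TitrationCurve]:
    """Noisy two-state titration curves, one per replicate, seeded."""
    rng = np.random.default_rng(spec.seed)
    ideal = efret_two_state(spec.conc, spec.e0, spec.de, spec.k_a, spec.n)
    curves = []
    for rep in range(spec.replicates):
        noise = rng.normal(0.0, spec.sigma, size=spec.conc.size) if spec.sigma else 0.0
        curves.append(
            TitrationCurve(
                spec.conc,
                ideal + noise,
                construct_id=spec.construct_id,
                replicate_id=str(rep),
            )
        )
    return curves


# ---------------------------------------------------------------------------
# spectra

#: synthetic fluorophore model (declared defaults, not measured values):
#: donor emission Gaussian at 520 nm (sigma 18), acceptor at 565 nm
#: (sigma 20), grid 480-700 nm at 1 nm, excitation 490 / 547 nm.
_GRID = np.arange(480.0, 701.0, 1.0)
_DONOR_PEAK, _DONOR_SIGMA = 520.0, 18.0
_ACCEPTOR_PEAK, _ACCEPTOR_SIGMA = 565.0, 20.0
#: arbitrary quantum-yield scalars; they cancel in acceptor normalization
_PHI_DONOR, _PHI_ACCEPTOR = 0.9, 0.15


def _gaussian_shape(grid: np.ndarray, peak: float, sigma: float) -> Spectrum:
    values = np.exp(-0.5 * ((grid - peak) / sigma) ** 2)
    return Spectrum(grid, values).unit_area()


def default_pair(grid: np.ndarray | None = None) -> FluorophorePair:
    """The synthetic fluorescein/Cy3-like reference pair."""
    grid = _GRID if grid is None else np.asarray(grid, dtype=float)
    return FluorophorePair(
        donor_emission_shape=_gaussian_shape(grid, _DONOR_PEAK, _DONOR_SIGMA),
        acceptor_emission_shape=_gaussian_shape(grid, _ACCEPTOR_PEAK, _ACCEPTOR_SIGMA),
        eps_d_at_exd=1.0,
        eps_a_at_exd=0.08,
        eps_a_at_exa=1.0,
    )


def gen_spectra(
    e_true: float,
    pair: FluorophorePair | None = None,
    noise: float = 0.0,
    seed: int = 0,
) -> SpectrumSet:
    """Emission spectra of a doubly labelled duplex at a known E_FRET.

    Under donor excitation the donor emits in proportion to
    eps_D(exD) * (1 - E) and the acceptor to eps_D(exD) * E + eps_A(exD)
    (sensitized plus direct excitation); under acceptor excitation only
    the acceptor emits, in proportion to eps_A(exA).  ``noise`` is the
    Gaussian sigma as a fraction of each spectrum's peak intensity.
    """
    if not 0.0 <= e_true <= 1.0:
        raise DomainError("E_true must lie in [0, 1]")
    pair = pair or default_pair()
    rng = np.random.default_rng(seed)
    donor_amp = pair.eps_d_at_exd * (1.0 - e_true) * _PHI_DONOR
    acceptor_amp = (pair.eps_d_at_exd * e_true + pair.eps_a_at_exd) * _PHI_ACCEPTOR
    donor_excited = (
        donor_amp * pair.donor_emission_shape.intensities
        + acceptor_amp * pair.acceptor_emission_shape.intensities
    )
    acceptor_excited = (
        pair.eps_a_at_exa * _PHI_ACCEPTOR * pair.acceptor_emission_shape.intensities
    )
    grid = pair.donor_emission_shape.wavelengths
    spectra = []
    for values, excitation in (
        (donor_excited, pair.donor_excitation_nm),
        (acceptor_excited, pair.acceptor_excitation_nm),
    ):
        if noise > 0:
            values = values + rng.normal(0.0, noise * values.max(), size=values.size)
        spectra.append(Spectrum(grid, values, excitation_nm=excitation))
    return SpectrumSet(donor_excited=spectra[0], acceptor_excited=spectra[1], pair=pair)


# ---------------------------------------------------------------------------
# sequence populations

@dataclass(frozen=True)
class PopulationSpec:
    """A k-turn population over a template background.

    ``pair_freqs`` draws paired labels jointly (e.g. the -1b:-1n pair from
    a database survey distribution); ``label_freqs`` draws single labels
    independently.  Unlisted labels keep the template residue, so the
    conserved core stays intact and every member annotates.
    """

    n: int = 1000
    seed: int = 0
    pair_freqs: dict = field(default_factory=dict)  # (b_lbl, n_lbl) -> {"X:Y": p}
    label_freqs: dict = field(default_factory=dict)  # label -> {"X": p}
    template: KTurnDuplex | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("population size must be >= 1")
        for dist in (*self.pair_freqs.values(), *self.label_freqs.values()):
            total = sum(dist.values())
            if not np.isclose(total, 1.0, atol=1e-9):
                raise ValueError(f"distribution sums to {total}, not 1")


def gen_population(spec: PopulationSpec) -> list[KTurnDuplex]:
    """Draw N annotatable duplexes from the spec distributions."""
    rng = np.random.default_rng(spec.seed)
    template = spec.template or fixtures()["kt7_fret"]
    annotation = annotate_kturn(template)
    duplexes = []
    for i in range(spec.n):
        edits: dict[str, str] = {}
        for (b_lbl, n_lbl), dist in sorted(spec.pair_freqs.items()):
            b_res, n_res = sample_pair(rng, dist).split(":")
            edits[b_lbl] = b_res
            edits[n_lbl] = n_res
        for lbl, dist in sorted(spec.label_freqs.items()):
            keys = sorted(dist)
            probs = np.array([dist[k] for k in keys], dtype=float)
            edits[lbl] = keys[rng.choice(len(keys), p=probs / probs.sum())]
        member = substitute_many(annotation, edits) if edits else template
        duplexes.append(
            KTurnDuplex(
                bulged=Strand(f"member_{i:05d}_b", member.bulged.residues),
                nonbulged=Strand(f"member_{i:05d}_n", member.nonbulged.residues),
            )
        )
    return duplexes
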