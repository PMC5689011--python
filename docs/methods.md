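# Methods

This note records the models, the numerical choices, and what the
synthetic data do and do not emulate.

## K-turn annotation

A duplex is two strands written 5′→3′, the bulged strand exactly three
residues longer than its partner (the constructs analysed here pair
end-to-end outside the bulge; overhang trimming is out of scope). The
annotator slides the bulge position `j` along the bulged strand: prefix
`[0, j)` opposes the partner's 3′ end, the 3-nt bulge `[j, j+3)` is
skipped, and the suffix opposes the partner's 5′ end. A candidate
registration must place (G,A,A,G) at (1b,1n,2b,2n) — the tandem
G•A/A•G core — immediately 3′ of the bulge, and have at least one
Watson–Crick/wobble pair in the C-helix span and one at NC positions
≥ 3. Candidates are ranked by total paired appositions; ties are then
broken by similarity of the core to (G,A,A,G), which only discriminates
when core checking is disabled (`require_core=False`, used to register
core-mutant controls); remaining ties raise `AmbiguousKTurn`.

Helix spans: the labelled core pairs belong to their helix by
definition — the −1 pair to the C helix, pairs 1–4 to the NC helix —
so the NC span is never shorter than 4 even when 3b:3n is a
non-canonical pair such as U:U (as in the box C/D k-turn, whose NC
helix is 13 bp). Beyond the labelled core a span extends while
appositions are Watson–Crick or G:U wobble and stops at the first
other pair or a strand end. For pairing purposes inosine reads as G
(it retains guanine's Watson–Crick face) and DNA thymine as U; the
residues themselves are reported unchanged, so the rule layer can
treat I distinctly. Consequences of these rules: a duplex whose
flanks pair completely satisfies `c_bp + 3 + nc_bp = len(bulged)`,
and the smallest annotatable k-turn has helix lengths (1, 4) — a
single C-helix pair plus the labelled core.

Fluorophores and per-residue chemistry (RNA/DNA in the gel chimeras)
are metadata; they never affect registration.

## FRET from spectra

Donor-excited emission is unmixed by linear least squares against
unit-area donor and acceptor reference shapes. Negative coefficients
are reported with a flag, not clipped — clipping would bias E toward
zero. `(ratio)_A` is the acceptor coefficient under donor excitation
over that under direct acceptor excitation, and

E = ((ratio)_A − ε_A(exD)/ε_A(exA)) · ε_A(exA)/ε_D(exD) · f,

with `f` an optional labelling-stoichiometry correction (default 1,
i.e. 1:1 donor:acceptor). Quantum yields cancel in the ratio, so the
extinction coefficients are relative.

The synthetic fluorophore model is declared, not measured: donor
emission Gaussian at 520 nm (σ 18 nm), acceptor at 565 nm (σ 20 nm),
grid 480–700 nm at 1 nm, excitation 490/547 nm, ε_A(exD)/ε_A(exA) =
0.08. The generator inverts the analysis model exactly, so the
noiseless round trip is exact by construction; what the round-trip
tests add is that unmixing stays unbiased under per-point Gaussian
noise and under grid refinement. Real spectra differ in ways the
generator does not emulate — non-Gaussian emission shapes, Raman and
buffer background, instrument spectral response — so round-trip
closure demonstrates correctness of the arithmetic, not robustness to
instrument artifacts (the assay's lamp/polarizer corrections are
hardware-bound and out of scope).

The absorbance-based extinction-ratio estimate scales an acceptor-only
reference onto the duplex absorbance by least squares over the
acceptor band (reference ≥ 5% of its maximum, at wavelengths ≥ the
acceptor excitation) and attributes the remainder at the donor
excitation wavelength to the donor. Overlapping absorption bands bias
this at the level of the donor tail inside the acceptor band.

## Two-state titration fits

`fit_two_state` runs bounded nonlinear least squares
(`scipy.optimize.curve_fit`, trf) on E(c) = E0 + ΔE·K_A cⁿ/(1+K_A cⁿ),
parameterized in log K_A for scale invariance. Initialization: E0 =
first point, ΔE = last − first, K_A = 1/median(c>0), n = 1. Bounds:
E0 ∈ [−0.1, 1.1], |ΔE| ≤ 1, n ∈ [0.5, 4] (or fixed via `fix_n`; the
assay's own fits do not state whether n was free). c = 0 points enter
directly — the model is defined there. Decreasing titrations fit with
ΔE < 0 (the box C/D parent falls with added ions); `folding_detected`
requires convergence, ΔE ≥ 0.05 and ΔE > 2 standard errors, the
declared operationalization of "no detectable folding". Failed
optimizations return `converged=False` with the initial parameters
rather than raising, so batch runs never drop records.

Final-state summaries report E0 + ΔE for detected transitions, the
initial value when nothing was detected, or a top-3-point plateau mean
when only raw points are available. Calls use the empirical bands:
final E_FRET ≥ 0.35 folds, ≤ 0.32 none, between is indeterminate.

Precision of the recovered half-transition is information-bounded: at
σ = 0.02 per point, the Cramér–Rao bound for a single 16–31-point log
grid gives a CV of ≥ 13% on [Mg²⁺]₁/₂, whatever the fitter. The
parameter-recovery analysis therefore fits replicate-averaged curves
(8 replicates of the standard grid per experiment), the usual practice
for noisy titrations, which brings the median recovery error under 5%.
The fitter itself is validated separately against a dense (K_A, n)
grid search with analytic (E0, ΔE) solves.

## Synthetic study conditions

- Titrations: grid 0 plus 23 log-spaced points over 1–11,000 µM
  (±2 decades around the wild-type transition; the source data's grids
  are not published), σ = 0.02 additive Gaussian on efficiency,
  wild-type condition E0 = 0.30, ΔE = 0.33 (final 0.63, complete
  folding), [Mg²⁺]₁/₂ = 110 µM with n = 1.
- Exchange panel: final E_FRET is exactly additive by construction,
  baseline 0.63 with element effects −0.34 (−1 pair), −0.10 (3b:3n),
  −0.08 (4b:4n), +0.02 (loop), and E0 = 0.33 for CGU-loop variants
  (the CGU loop bends the unfolded bulge slightly more) versus 0.30
  for GAA. The effect sizes are declared so that the panel respects
  the observed bands — every −1n = G variant ends above 0.35, every
  −1n = C variant below 0.32 — and reproduces the observed ordering
  (−1 dominant, loop smallest and favourable). Real panels are only
  approximately additive; the decomposition's residuals exist to
  expose exactly that, and the tests inject a pairwise interaction to
  confirm it surfaces (a 2⁴ factorial maps an interaction δ to
  residuals of magnitude δ/4).
- Populations: members are the Kt-7 background with labelled
  positions resampled. Shipped fixture distributions for the −1b:−1n
  pair: the archaeal box C/D survey values (C:G 39.42%, G:C 23.08%,
  A:U 11.54%, U:U 7.21%, G:U 4.33%, U:G 2.89%) and the bacterial
  ribosomal values (C:G 94.3%, G:C 3.0%, U:A 1.7%, U:G 0.8%, A:U
  0.2%). The archaeal list sums to 88.47%; the unitemized remainder is
  spread uniformly over unlisted canonical pairs, which here means U:A
  alone. Database scraping is out of scope — the machinery runs on
  user FASTA. Generated populations are i.i.d. per position and carry
  none of the phylogenetic correlation of real alignments, so
  recovery-within-binomial-bounds validates the counting, not
  database realism.

## Rules and logos

Classification applies −1n dominance first (blocking set {C, I}), then
combines the 3b:3n class ({A:G, U:G} folding, U:U intermediate) and
4b:4n class (C:G folding, G:C impaired): all favorable → ion_folding,
otherwise impaired. Pairs outside the maps are "unknown" and cap the
call at impaired — the maps deliberately contain only classes
established by this exchange design, and the config file lets users
extend them. The loop is recorded as neutral evidence and never
changes a call; its measured effects are smaller than any other
element's, and no weighting for it is defined. U:U at 3b:3n is
context-dependent (intermediate alone, strongly impairing combined
with 4b:4n = G:C); the conservative combination rule above is the
declared resolution.

Logo matrices use the WebLogo convention IC = 2 − H₂ (bits,
0·log 0 := 0), letter height = frequency × IC; the optional
small-sample correction subtracts 3/(2 ln2 · N). Only the matrix is
produced — rendering is out of scope.

## Problem sizes and determinism

Every stochastic routine takes a seed through
`numpy.random.default_rng`; analyses and tests fix theirs, so reruns
are byte-identical. Sizes used by the shipped analyses: 100 titration
replicates for Monte-Carlo recovery, 100 seeds for the noisy spectra
round trip, N = 10,000 for population-frequency recovery, the 2⁴
factorial for decomposition. Known limitations: only standard k-turns
(3-nt bulge, G•A/A•G core) are annotated — k-loops and longer bulges
are rejected, not approximated; no protein-binding isotherm is
modelled (the L7Ae endpoint enters only as a worked efficiency
level); and no thermodynamic or 3D-structural prediction is
attempted.
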