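# Methods

## Model and assumptions

`rpmspin` models a radical pair of two electrons, one on a serine or
tyrosine oxyradical (radical A) and one on a hydrated magnesium cation
radical (radical B), in a static field B ∥ z.  The Hamiltonian keeps only
the electron Zeeman interaction and the isotropic (Fermi-contact) hyperfine
coupling of each electron to the single nucleus with the dominant coupling
constant:

    H = ω (S_Az + S_Bz) + a_A S_A·I_A + a_B S_B·I_B,   ω = g μ_B B / ħ.

Assumptions baked into this form, and when they hold:

- **Free-electron g for both radicals.**  Organic oxyradicals and Mg⁺ have
  g ≈ 2.00 to within ~1e-3; at ≤ 100 mT the resulting Δg dephasing is
  negligible next to mT-scale hyperfine couplings.
- **No exchange or dipolar electron–electron coupling** — valid for
  sufficiently separated radicals.
- **Isotropic hyperfine only** — appropriate for orientationally
  disordered (non-crystalline, tumbling) molecular arrangements.
- **One nucleus per radical.**  The nucleus with the largest coupling
  dominates singlet–triplet mixing; remaining weakly coupled nuclei are
  dropped.  This is a standard truncation, not an exact limit.
- **Nuclear Zeeman terms omitted** — three orders of magnitude below the
  electron terms over the field range scanned.

The basis ordering is fixed everywhere: electron A ⊗ electron B ⊗ nuclei
of A ⊗ nuclei of B, each factor in |s, m⟩ order m = s…−s.  All Hamiltonian
terms are stored in angular-frequency units; mT inputs are converted once
at build time with γ = g μ_B/ħ, so eigenvalue differences are directly
commensurate with the kinetic rates (s⁻¹) in the yield formula.  Spaces in
scope are ≤ a few hundred dimensions, so all operators are dense.

## Singlet yield

The pair is singlet-born with maximally mixed nuclear spins,
ρ(0) = P_S/M with M = Π(2I+1) (the 1/M prefactor of the yield formula is
exactly this normalization).  Singlet and triplet products form with the
same rate k, and a single phenomenological rate r relaxes the electron
pair toward the maximally mixed state.  The ultimate fractional singlet
yield is then

    Φ_S = (1/M) Σ_{m,n} |⟨m|P_S|n⟩|² k(k+r)/((k+r)² + (ω_m−ω_n)²)
          − k/(4(k+r)) + 1/4,

evaluated over the eigensystem of H (`singlet_yield`).  Diagonal and
degenerate pairs are kept in the double sum — they contribute the
Lorentzian maximum k/(k+r) — with no special-casing.  Useful exact limits,
used as unit tests: with a_A = a_B = 0, Φ_S = ¼ + ¾·k/(k+r) (hence 1 at
r = 0, 0.625 at k = r); for any parameters ¼ ≤ Φ_S ≤ 1.

A note on the multiplicity: the defining property of M is that it counts
nuclear configurations, M = Π(2I+1).  Any other convention breaks the
normalization — e.g. Π I(I+1) gives a non-integer (¾ for one proton) and
a hyperfine-free "yield" of 4/3.  The package uses Π(2I+1) throughout and
asserts the normalization in its test suite.

### Independent oracles

Two independent evaluations of the same quantity guard the closed form:

- `singlet_yield_liouville` solves the Liouville–von Neumann dynamics
  exactly through its damped time integral:
  Y = ∫₀^∞ e^{−iHt} ρ(0) e^{iHt} e^{−(k+r)t} dt satisfies the Sylvester
  equation (k+r)Y + i[H, Y] = ρ(0), solved by the Schur-based
  Bartels–Stewart algorithm — no eigendecomposition of H, no time
  stepping; then Φ_S = k·Tr[P_S Y] + r/(4(k+r)).  Agreement with the
  closed form is at machine precision and is asserted at 1e-3 relative
  tolerance over 50 seeded random configurations spanning spins
  {0, ½, 1, 3/2, 5/2}, |a| ≤ 20 mT, B ≤ 200 mT, k, r ∈ [10⁴, 10⁸] s⁻¹.
- `singlet_yield_timedomain` is the brute-force route: an exact
  matrix-exponential propagator stepped on a uniform grid fine enough to
  resolve the fastest coherence (step < 0.1/max|ω_m − ω_n|, bounded
  spectrally without diagonalizing), Simpson quadrature to
  t_max = 20/(k+r), the relaxed ¼-term integrated analytically.  When the
  requested grid cannot resolve the dynamics within its step budget it
  refuses (`ResolutionError`) instead of returning an aliased number, so
  it is exercised on configurations with moderate frequency/rate ratios.

## Parameters

| parameter | meaning | default | why |
|---|---|---|---|
| a_A (Ser) | dominant ¹H coupling, serine oxyradical | 7.45 mT | shipped constants bundle (DFT-derived) |
| a_A (Tyr) | dominant ¹H coupling, tyrosine oxyradical | 1.86 mT | shipped constants bundle |
| a_B | ²⁵Mg coupling on Mg(H₂O)ₙ⁺ | −11.22 mT | shipped constants bundle; sign is carried but Φ_S depends only on the spectrum (regression-tested) |
| isotope table | Mg isotopologue weights | 0.9 spin-0 / 0.1 spin-5/2 | natural abundance; spin-0 ²⁴Mg and ²⁶Mg are spectroscopically identical and lumped |
| g | electron g-factor | 2.00232 | free-electron value, both radicals |
| B₀ | control field | 0.15 mT | midpoint of the 0–0.3 mT control range of the motivating experiments |
| B_exp | exposure field | 100 mT | the experimental exposure |
| k | recombination rate | 2×10⁶ s⁻¹ | reference kinetics of the headline ratio; the k–r plane is scanned because neither rate is measured |
| r | relaxation rate | 1×10⁶ s⁻¹ | idem |

## Scans and feature detection

- **k–r scan**: S on a log-spaced 50×50 grid over [10⁵, 10⁸] s⁻¹ by
  default, bracketing literature-typical radical-pair kinetics.  H is
  kinetics-independent, so each (field, isotopologue) pair is
  diagonalized once and |⟨m|P_S|n⟩|² and ω_m − ω_n are reused across all
  cells; the cached scan is asserted equal to naive cell-wise evaluation
  to 1e-12.
- **Field sweep**: 400 log-spaced points over [0.15, 100] mT plus a
  100-point linear refinement below 2 mT by default — the low-field dip
  and the spikes are narrow.
- **Low-field dip**: minimum of the sweep over the weak-field window
  (< 2 mT, ≥ 20 samples enforced), with depth reported against both the
  B = 0 yield and the control-field yield, since the two references
  differ.  A minimum on the window edge is reported as "no dip".
- **Spikes**: narrow features of the ²⁵Mg-isotopologue curve are isolated
  by subtracting a running-median baseline (window ≈ 1/150 of the grid)
  so the broad dip and high-field rise cancel; residual extrema with
  prominence above 1 % of the curve range (configurable — no sharper
  criterion is physically given) are candidates.  Each candidate is then
  validated mechanistically: it must sit at a local minimum of the
  smallest eigenvalue gap among eigenstate pairs coupled through the
  singlet projector (|⟨m|P_S|n⟩|² > 1e-3), i.e. at a level anticrossing.
  For the serine/²⁵Mg system at the reference kinetics the detector finds
  three spikes (≈ 25.9, 40.3, 56.8 mT), each co-located with a coupled
  anticrossing, and the count is stable under doubling of the grid
  density from 1600 log points; the spin-0 isotopologue yields none.

## Experimental-table arithmetic

The two shipped Ca²⁺-uptake tables (sustained and repeated exposure) are
approximate values extracted from published plots; percentages and the
published ratio column are both printed at one decimal.  Recomputed
field/control quotients therefore cannot be expected to reproduce every
printed ratio cell under a fixed rounding rule (e.g. 11.5/6.2 = 1.8548
rounds to 1.9 against a printed 1.8, because the source ratio was formed
before the percentages were rounded).  The package asserts
*rounding-interval consistency* instead: a printed cell matches if it is
attainable as the half-up 1-d.p. rounding of field′/control′ for some
percentages within ±0.05 of the printed ones.  All ten cells pass, and the
row means round to 1.5 (sustained) and 1.4 (repeated).  Model-to-table
comparison is a magnitude comparison, not a fit: the cascade between
singlet yield and Ca²⁺ influx is unmodelled and amplification between the
two scales is expected.

## Synthetic data

The generator module makes the pipeline exercisable with no downloads:
the constants bundle above; seeded random radical-pair configurations
(spins from {0, ½, 1, 3/2, 5/2}, signed |a| ≤ 20 mT, B ≤ 200 mT, rates
log-uniform in [10⁴, 10⁸] s⁻¹ — one `numpy` Generator per draw, no global
state) for property tests; and synthetic uptake tables with a saturating
control curve and per-row enhancement declining with NMDA concentration
whose mean equals a prescribed factor exactly.  What passing tests on
these inputs do **not** show: anything about anisotropic couplings,
multi-nuclear registers, exchange/dipolar interactions, unequal T₁/T₂
relaxation, or the biochemistry linking yield to Ca²⁺ flux — none of
which the generator emulates.

## Numerical choices

- Dense `numpy.linalg.eigh` everywhere (largest space 4·2·6 = 48 for the
  shipped systems; a configurable cap of 4096 guards synthetic inputs).
- Hermiticity, unitarity of eigenvector matrices, total-Jz conservation
  and projector idempotency are asserted at tolerances 1e-9–1e-12.
- Degenerate eigenvalues need no special handling anywhere: the yield
  formula is continuous in ω_m − ω_n.
- Problem sizes in the test suite (sweep lengths, grid sizes, oracle
  counts) are chosen so the whole suite runs in well under a minute on a
  single core while still crossing every dimension regime (4, 8, 12, 48,
  144) the model admits.

## Known limitations

- The relaxation model is the simplest possible (one rate, mixing toward
  ¼-identity); unequal spin-lattice/spin-spin times are out of scope.
- Hyperfine constants are consumed as given; no electronic-structure
  recomputation.
- The k–r "plausible region" is reported as the full S surface; drawing a
  region boundary is left to the user, as no quantitative criterion
  exists.
- Yield ratios near 1.24 against uptake ratios near 1.4–1.5 is a
  consistency-of-magnitude argument, not an inference about mechanism.
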