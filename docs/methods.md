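# Methods

This note records the models, parameter choices and numerical decisions
behind `fragscreen`, and what the synthetic fixtures do and do not emulate.

## Spectrum model

Spectra are sampled traces on a strictly monotone ppm axis (stored ascending;
NMR's descending display convention is presentation only). Synthetic peaks
are pure Lorentzians: a multiplet with n protons contributes total area
`scale × n`, optionally split into 1–J equal-area sub-lines spread evenly
across its range when a multiplicity label (s/d/t/q/…) is given. J-coupling
fine structure beyond equal spacing is not modeled: every downstream
procedure consumes ranges and areas, not coupling constants. Noise is
additive i.i.d. Gaussian — sufficient for every cost function in scope.
Baseline/phase/apodization artifacts are out of scope (treated as handled by
spectrometer-side processing).

Integration is trapezoidal over closed ppm intervals, hence exactly additive
over adjacent regions and linear in intensity. Noise is estimated as the
sample SD of a signal-free region (≥ 16 points, mean-centred).

Peak picking returns local maxima above `k_noise × noise_sd`. Two
refinements matter in practice:

- **Minimum width** (default 0.01 ppm, half a typical linewidth): a genuine
  line spans at least its linewidth at half prominence, while Gaussian noise
  crosses any multiple of its own SD on single samples somewhere in a few
  thousand points. Without this filter, threshold-only picking produces a
  steady stream of one-sample false peaks at any noise level.
- **Merging** (optional): maxima closer than one linewidth collapse to the
  taller one, avoiding double counts on shoulders.

The threshold multiplier `k_noise = 3` is a package default, configurable
everywhere it is used.

## Library filter

All Rule-of-Three bounds are inclusive; a missing property fails its rule
with reason `<rule>:missing` rather than raising (failures are data). The
aromatic-proton rule is optional — it only matters when protonated buffers
obscure the aliphatic region. The diversity gate is greedy and
order-dependent by design: each candidate is compared against the accepted
members so far and rejected only when max Tanimoto is *strictly above* the
threshold (0.80 default; a score exactly at threshold passes). No global
diversity optimization is attempted. Fingerprints are path-based hashed
bit sets (RDKit topological, 1024 bits) when computed from SMILES, but any
precomputed bit-set fingerprint works — the gate logic, not the fingerprint
flavor, is the point.

## Quantification (qNMR)

The AOI defaults to 6–10 ppm to dodge DMSO and protonated-buffer signal.
Window membership of a multiplet is decided by its **center** — the simplest
testable reading of "protons within the range". The H_T lower bound counts
non-exchangeable protons centred in 7–9 ppm (a predicted aromatic shift stays
inside 6–10 even under ~1 ppm prediction error); the upper bound counts all
protons, exchangeables included, in 5–11 ppm. The lower bound clamps to ≥ 1
(configurable): a compound with no predicted peak in the inner window must
still admit a candidate.

Best-fit H_T: per-region integrals are normalized **globally** (rescaled so
their sum equals the candidate H), then scored by the RMS deviation from
nearest integers; ties break to the smallest H, the conservative choice
(larger H lowers intensity-per-proton and would overstate solubility).
Per-region normalization is a defensible alternative reading; the global
version is isolated in `best_fit_ht` for substitution. Recovery is unique on
noise-free data whenever the region proton counts are not integer-degenerate
(gcd > 1 lets H_T/gcd reproduce integers as well); the synthetic fixture
enforces coprime counts so that the recovery-rate statistic measures noise
robustness, not degeneracy.

Concentration = reference concentration × (sample intensity per proton) /
(reference intensity per proton), both acquired under identical parameters.
The impurity fraction is realized concretely as the share of AOI area outside
all predicted peak regions (the wet-lab protocol leaves this to visual
inspection); QC passes at concentration ≥ 0.1 mM and impurity < 15%.

## Cocktail design

Dispersity is **count-based**: D(i,k) = max of the two overlapped-multiplet
fractions, where overlap requires a positive-length range intersection
(touching endpoints carry no integral and do not count). A length-weighted
variant would be defensible; the count-based form matches the operative
semantics "D = 0.5 ⇒ at least 50% of peaks distinct for either compound" and
lives behind a single function for substitution. Pairs conflict at D ≥
threshold (strict "below 0.5" acceptance).

Grouping is sequential with forward swap: fill the current group in input
order; when the next compound conflicts, scan the not-yet-placed compounds
for one that fits and take it instead, leaving the conflicting compound for a
later group. Every compound is eventually placed (worst case as a singleton);
an optional `max_groups` cap returns leftovers explicitly unassigned. No
backtracking or Monte-Carlo global overlap minimization is attempted — the
greedy pass suffices for well-dispersed libraries and keeps the audit trivial
(tests re-check every emitted pair exhaustively). Rack layout is row-major
A1…H12, overflowing to new plates.

## Screening

Negative controls (no protein): STD should be flat — aromatic STD peaks flag
aggregation or cancellation artifacts — and WaterLOGSY should be same-sign
except for exchangeable protons; sign-inverted non-exchangeable peaks are
flagged with their shifts.

Hit calling: STD peaks in the AOI are confirmed by a WaterLOGSY peak (either
sign) within 0.15 ppm, then assigned to the member whose reference pattern
has a peak within the same tolerance. The tolerance default covers the
buffer-induced shift between reference conditions (H₂O/D₂O stock) and screen
conditions with margin; it is configurable. A member is called when at least
`ceil(0.5 × its aromatic reference peak count)` distinct reference peaks are
matched — a pattern quorum rather than a single-peak match; the 0.5 quorum is
a package default. Peaks matching no member are reported unassigned; peaks
matching several members are flagged ambiguous and auto-called for neither
(a human resolves them). WaterLOGSY-only peaks (direct water–ligand
interaction) are ignored.

Secondary confirmation re-runs hit calling on the single-compound record and
requires the candidate's matched shifts to reproduce within tolerance with
both evidences; aggregation artifacts, whose signal exists only in the
crowded cocktail, fail this and are rejected.

## Titration analysis

CSP: Δδ = √(Δδ_H² + (Δδ_N/5)²), the standard amide-weighted combination.

K_d fit: one-site fast exchange **with ligand depletion** — protein (0.5 mM)
and ligand (ratios 0.1–5) are comparable, so the dilute-ligand hyperbola
would bias K_d low. The global fit shares K_d across residues with one
Δδ_max per residue, unweighted least squares. Numerically this is variable
projection: for fixed K_d each Δδ_max has a closed-form linear LS solution
(clamped non-negative), reducing the problem to a 1-D search over log₁₀ K_d
— a coarse multistart grid over 10⁻³–10 mM followed by bounded scalar
minimization (xatol 10⁻⁷ in log units). Fits pinned to the lower K_d bound,
or fed curves with ≤ 5% relative dose variation (flat at Δδ_max from the
first point), are flagged `saturated`: such data carry no K_d information.

Intensity titrations: normalized peak intensity of the labeled protein is
taken as proportional to its free fraction (complex peaks broaden away;
chemical-exchange broadening is deliberately neglected). Residues dropping
below 3× noise at any point are excluded; the pooled free fraction is the
per-ratio median, fitted to 1 − f_b under the same depletion model.
Identifiability is weak when protein ≫ K_d (the early titration is
stoichiometric), so this K_d is an order-of-magnitude estimate — tests hold
it to a factor of two.

Competition: P binds partner G (K_d,complex) or ligand L (K_d,ligand),
mutually exclusively. Substituting the two binding isotherms into protein
conservation gives a scalar equation in free P, strictly increasing on
[0, P_total], solved by Brent bracketing (rtol 10⁻¹⁵); all three totals are
conserved to 10⁻⁹ relative or the solver raises. Tests cross-check against a
brute-force 2-D grid search over the two bound-species concentrations.

## Synthetic fixtures: what they emulate, and what they don't

Generators are pure functions of (parameters, seed) and reproduce
bit-identically. Study conditions baked into the defaults: ~1000-compound
candidate pools, ten compounds per cocktail, D threshold 0.5, binder rate 5%
and artifact rate 2% (PPI hit rates run below 10%), 2% spectral noise
relative to planted peak height, titration ratios {0.1, 0.25, 0.5, 1, 2, 5}
at 0.5 mM protein, and a 0.11 mM reference K_d.

The cocktail-design fixture partitions the AOI into M disjoint 0.4-ppm
blocks and gives the compound at position p of each cohort its 2–5 multiplets
inside block p: a valid grouping exists by construction (cohorts are mutually
dispersed) while compounds across cohorts reuse blocks and overlap freely.
The screening fixture confines each member's reference peaks to the middle of
its block so that a ≤ 0.08 ppm buffer shift plus the 0.15 ppm matching
tolerance cannot reach a neighbour — the unambiguous-assignment property that
dispersity-designed cocktails are built to deliver.

Fixtures emulate observable signatures only: co-located STD/WaterLOGSY lines
for binders, cocktail-only signal for aggregation artifacts, fast-exchange
shift averaging, intensity ∝ free fraction. They do **not** simulate NOE
buildup, relaxation, saturation-transfer kinetics, exchange broadening,
baseline/phase artifacts, or peak overlap between a binder and another
member. Passing tests therefore demonstrate the decision logic — thresholds,
matching, fitting, bookkeeping — under controlled noise, not robustness to
every pathology of real spectra (overlapped cocktails, ring-current shifted
references, intermediate exchange).

Problem sizes used in the campaign-scale tests — 200 quantification spectra,
100 noisy titration seeds, 50-cocktail screening campaigns, the 893-compound
grouping — were chosen to make the reported rates statistically meaningful
while the whole suite stays fast enough to run on every commit.

## Known limitations

- The greedy grouping can exceed ceil(n/M) groups on adversarially ordered
  inputs; it never violates the pairwise constraint (audited), it just
  fragments more.
- Impurity estimation attributes *all* unpredicted AOI signal to impurities;
  a badly mispredicted multiplet inflates it.
- The JCAMP-DX reader handles fixed-point AFFN `(X++(Y..Y))` data only, not
  SQZ/DIF compression.
- `fit_kd_global` assumes a single binding site and fast exchange; slow or
  intermediate exchange (peak disappearance/reappearance) needs the intensity
  pathway instead.
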