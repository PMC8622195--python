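# Methods

`gslscreen` implements a semi-targeted screening workflow for acidic
glycosphingolipids (gangliosides and sulfatides) measured by negative-mode
HILIC-ESI high-resolution MS: an in-silico mass library, accurate-mass MS1
annotation, MS/MS subclass confirmation, pooled-QC preprocessing, and the
screening statistics. This note records the models, the parameters that
matter, and the design choices made where the design was genuinely open.

## In-silico library

A lipid species is a glycan headgroup plus a ceramide sum composition.
Headgroups are integer compositions over five building blocks (residue
masses from CODATA monoisotopic atomic masses, C 12, H 1.00782503,
N 14.0030740, O 15.9949146, S 31.9720707):

| block  | formula  | residue mass (Da) |
|--------|----------|-------------------|
| Hex    | C6H10O5  | 162.05282 |
| HexNAc | C8H13NO5 | 203.07937 |
| NeuAc  | C11H17NO8| 291.09542 |
| OAc    | +C2H2O   | 42.01057 |
| SO3    | +SO3     | 79.95681 |

Ceramides follow `<d|t><carbons>:<double bonds>` with elemental formula
C(n)H(2n+1−2·db)NO3 for dihydroxy (d) and one extra oxygen for trihydroxy
(t) bases. Neutral masses are computed twice — residue-mass summation and
atom-count summation — and the two routes agree to < 1e-6 Da (tested; also
cross-checked against `pyteomics.mass.calculate_mass`).

The default class list covers the gangliotetraose series (GM3…GQ1c), the
O-acetylated variants (+Ac on GD1, GT1b, GQ1b; +Ac2 on GT1b, GQ1b — each
acetyl adds 42.0106 Da on a sialic acid), and the sulfatides ST and
dihexST. O-acetyl *placement* is mass-invariant, so only counts are
tracked; linkage isomers (GM1a/GM1b, …) are mass-identical and carried via
an isomer label. The class list, ceramide grid (default carbons 28–48, all
parities; db 0–4; bases d and t), charge-state policy (1–/2– for ≤1 sialic
acid and sulfatides, 2– for disialo, 2–/3– for ≥3 sialic acids) and the
m/z export clip [300, 2000] (the acquired range) are all configurable.

**Anchor search.** `find_anchor_species` recovers the ceramide composition
behind a rounded figure-caption m/z by exhaustive grid search. For
gangliosides the search restricts to d-series bases: brain ganglioside
ceramides carry dihydroxy sphingoids, while the t-series part of the grid
exists for the sulfatides (e.g. ST t36:1). This matters because the grid
contains near-isobars across base types (GT1b-Ac2 t37:2 lies 0.037 Da from
GT1b-Ac2 d38:1); under the d-series restriction both printed anchors
(1119.1 at 2–, 842.7 at 3–) resolve uniquely to d38:1.

**A genuine MS1 degeneracy.** GT1b-Ac t40:2 has *exactly* the same
elemental formula as GT1b-Ac2 d38:1 (moving C2H2O between ceramide and
acetyl count). Accurate mass alone can never separate such pairs —
annotation therefore reports ties at equal rank, and subclass assignment
is delegated to MS/MS, where the +42/+84-shifted sialo-B ions are
decisive.

## Annotation and isotopes

Features match library ions when |1e6·(obs−theo)/theo| ≤ tol (default
10 ppm, the positive-identification threshold of the screen); a known
feature charge must agree, charge 0 matches anything. Candidates are
ranked by |ppm error| with dense ranking for exact-isobar ties; an
optional HILIC plausibility re-rank (more sialylated elutes later) never
rejects a mass match.

Aggregated isotopologue patterns (M+0..M+2) come from convolving
per-element nominal-mass-shift distributions (13C 1.07%, 2H 0.0115%,
15N 0.364%, 17O 0.038%, 18O 0.205%, 33S 0.75%, 34S 4.25%). The overlap
correction addresses the double-bond ladder: at 2– charge states the
~9 mDa/charge split between a species and the M+2 isotopologue of its
(db+1) neighbour (same class, base, carbons) may be unresolved, so, working
from most- to least-unsaturated, the predicted M+2 contribution
(M+2/M+0 × corrected donor signal) is subtracted from the (db−1) partner
and clipped at zero. Column totals can only decrease. The correction
assumes columns are species-level signals; an optional charge map
restricts it to equal-charge pairs.

## Fragment prediction and scoring

Predicted negative-mode fragments are (a) sialo-B ions: k·NeuAc + a·OAc −
H for k = 1..sialic count, a = 0..acetyl count, singly charged and
ceramide-independent; (b) Y ions: precursor minus terminal NeuAc(±OAc)
losses at charges 1..z; (c) precursor − k·NeuAc neutral losses at the
precursor charge. Cross-ring (A/X) and ceramide-internal cleavages are out
of scope for subclass assignment. The diagnostic set is the sialo-B series
plus the first NeuAc loss at the precursor charge; MS/MS matching uses a
20 ppm window (wider than MS1). Candidates are ordered by (diagnostic
fraction, matched count, matched intensity fraction), ties by precursor
ppm error and then shorthand, so ranking is input-order independent. A
scalar composite (0.6/0.3/0.1 weights) is exposed for strict
better-than comparisons; non-acetylated candidates cannot explain the
+42/+84-shifted sialo ions and always lose to the true acetylated
subclass on coverage even when the shared ions tie the diagnostics.

## Preprocessing chain

Fixed order, enforced and logged by the runner: QC-LOESS drift correction
→ QC-CV filter → tissue-weight correction → ln transform → per-lipid mean
centering.

* **LOESS**: per lipid, a tricube-weighted local polynomial (span 0.75,
  degree 2, both configurable) is fitted to pooled-QC intensity versus
  injection order; every sample is divided by the fitted value at its
  position and rescaled so the lipid's median QC intensity is preserved.
  Positions beyond the terminal QCs take the nearest fitted value. A
  non-positive fitted curve triggers a straight-line fallback (logged);
  if that is also non-positive the lipid passes through uncorrected. The
  smoother is hand-written because the degree-2 local fit is not available
  in the installed smoothers; it is cross-checked against
  `statsmodels.lowess` at degree 1.
* **CV filter**: CV = sd/mean over QC injections, computed after drift
  correction; lipids with CV > 30% (default) are dropped and reported.
* **Weight correction**: study intensities divided by tissue weight (mg);
  QC pools (fixed-volume aliquots) untouched. Ordered after the CV filter
  following the workflow narrative; on the ln scale it is a per-sample
  constant, so downstream group statistics are insensitive to the order.
* **ln + centering**: zeros are imputed at half the lipid's smallest
  positive value (logged); lipids missing in > 50% of study samples are
  dropped with a warning. "Centering" is per-lipid mean centering; no
  unit-variance scaling.

## Statistics

Per-lipid Welch two-sample t-tests on ln values; effect size
log2FC = Δln/ln 2. The test is reported with Benjamini–Hochberg adjusted
p-values alongside, but the reproduction-mode "significant" flag uses raw
p < 0.05 (strict inequality), matching the screen's volcano convention.
Default comparisons: oldest control ages vs the youngest controls
(aging), and transgenic vs age-matched control at every age (genotype).
PCA (full SVD) and two-class PLS-DA (NIPALS partial least squares on a ±1
indicator response; no scaling) provide the multivariate survey; component
signs are fixed by making each component's largest-magnitude loading
positive. Pearson correlation of lipid levels with the pathology-load
covariate uses the exact t transform for two-sided p-values.

## Synthetic data generator

The generator emulates the study shape: 2 genotypes × 6 ages (4–14
months) × 10 animals (balanced; the real cohort of 131 was unbalanced
across cells), QC pool injections opening the run and after every 10th
study injection (120 study + 13 QC), injection order randomized by seed,
tissue weights U(10, 20) mg around the nominal 15 mg. Per-lipid baselines
are lognormal (ln-mean 13.8 ≈ 1e6 counts, between-lipid sd 1.0, class
offsets sd 0.5 — chosen as typical for lipidomic peak areas, since real
per-lipid abundance distributions are unknown). Multiplicative analytical
noise defaults to 10% CV; smooth injection-order drift (linear decay or
dip-and-recover, default amplitude ±10%) multiplies study and QC samples
alike; study signal scales linearly with tissue mass (so that the weight
correction removes, rather than injects, a per-sample factor); QC values
are the pooled study mean under the same noise and drift. m/z features
carry N(0, 2 ppm) mass error — under which the mean absolute error,
2·√(2/π) ≈ 1.6 ppm, sits near the instrument's reported 1.68 ppm average
accuracy — plus optional decoys kept ≥ 50 ppm from every library ion.

Ground-truth effects default to the screen's qualitative findings: GM3 +1
log2FC in transgenics at 8–12 months, sulfatide/dihexosyl-sulfatide decline
and GM1a d42:2 / d40:2 rise linearly with age. The tau-load covariate is
logistic in age for transgenics (half-maximal at 7 months, rate 1.2
months), plateauing by 10 months, zero in controls, with 10% lognormal
noise; one lipid (default GM3 d42:2) has its ln-residual constructed to
correlate with the load at a target r (default 0.8) among transgenic
samples — the realized total correlation also reflects the shared age
structure, so the target is approximate.

What the generator does *not* emulate: chromatographic peak shapes,
co-elution and in-source fragmentation, intensity-dependent mass error,
missingness mechanisms beyond random zeros, unbalanced group sizes, and
batch structure. Passing tests therefore demonstrate correctness of the
computations under the stated statistical model, not instrument-level
realism.

## Numerical choices and problem sizes

Deterministic ordering everywhere (stable sorts with explicit tie-break
keys); all generators are pure functions of (config, seed). Monte-Carlo
checks use 500 replicates × 200 lipids for the null rejection rate, 500
replicates for power at log2FC 1 (20% CV, n = 10/group), 1000 replicates
(5 independent covariate batches) for Pearson CI coverage at r = 0.8,
n = 18, and 100 seeded spectra for subclass ranking; the end-to-end
recovery check runs 60 replicates of a reduced 40-lipid, single-age
study. These sizes were chosen so the full suite completes in well under
a minute while keeping Monte-Carlo standard errors far from the asserted
bounds.

## Known limitations

* MS1 annotation cannot separate exact isobars (acetyl-count/ceramide
  trades, linkage isomers); ties are reported, not resolved.
* The isotope correction handles only the db-ladder M+2 overlap, not
  arbitrary co-isolation.
* PLS-DA is two-class only and reported without a permutation/Q2
  validation by default (available separately via the permutation check in
  the test suite's approach).
* The LOESS fallback to a straight line is per-lipid and silent except in
  the structured log.
* Published brain-tissue species counts and study-specific p-values
  depend on real raw data and are outside what synthetic inputs can
  reproduce.
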