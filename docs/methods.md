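# Methods

## Model of the measurement

`driftlink` operates on centroided 4-D all-ions peak lists: records of
(retention time [min], drift time [ms], m/z, intensity) from an
LC–drift-tube-IM–QTOF run in positive mode.  Two physical facts carry the
whole method:

1. **Fragmentation happens after the drift tube.**  All fragments of one
   precursor inherit its drift time exactly; co-eluting ions of other
   compounds have their own, compound-specific drift times.  Drift-time
   equality at one chromatographic peak is therefore evidence of a shared
   precursor, far more specific than retention-time alignment alone.
2. **Fragments are lighter than their precursor.**  Within a drift-linked
   ion family, the highest m/z member is the intact molecule.

Drug conjugates cleave their conjugation residues at low collision energy
while the drug backbone survives, so one characteristic fragment per
backbone tags every family worth inspecting.

## Mass arithmetic

A fixed monoisotopic table is used (C 12 exactly, H 1.0078250319,
N 14.0030740052, O 15.9949146221, Cl 34.96885271, Na 22.9897692820,
S 31.9720711744; proton 1.007276467).  Ion m/z follows the proton-adduct
convention `(M + z·m_p)/z` with the electron mass ignored; the resulting
values agree with standard screening-report rounding (m/z to 4 decimals,
ppm to 1 decimal) for every species in the shipped reference table, whose
largest |deviation| between printed observed m/z and composed formula is
3.3 ppm.

Metabolite names are compositional: backbone base (`DCF` or `DCF-Lac`),
hydroxylation count (`OH`, `diOH`), then residues in fixed order
Glc, GlcA, Mal.  Positional isomers deliberately share a name — a
screening-level assignment cannot place the attachment site.

## Pipeline and its parameters

| parameter | default | role |
|---|---|---|
| `frag_tol_ppm` | 10 | anchor match to a backbone fragment m/z |
| `dt_tol_ms` | 0.05 | co-drift grouping half-window |
| `rt_half_window` | 0.1 min | chromatographic bounds around the anchor |
| `precursor_tol_ppm` | 5 | residue decomposition of the precursor delta |
| `loss_tol_ppm` | 10 | corroboration of intermediate fragments |
| `min_intensity` | 100 | feature filter |
| `rt_range` | 2–10 min | feature filter |
| `max_charge` | 3 | feature filter (isotopologue-spacing inference) |
| caps | OH ≤ 2, Glc ≤ 2, GlcA ≤ 1, Mal ≤ 2 | residue multiset bounds |

The precursor tolerance (5 ppm) is looser than the reference species'
accurate-mass deviations (≤ 3.3 ppm) but tight enough that the residue
decomposition is unique for every multiset within the caps; the loss
tolerance is wider (10 ppm) because observed fragment-difference masses
carry two feature centroids' worth of error.

**Why dt_tol = ±0.05 ms.**  Converting the reference table's (m/z, CCS)
pairs to drift times under the shipped calibration shows the closest
co-eluting, same-sample pair of distinct species is separated by 0.091 ms;
feature-level drift precision under the default simulation noise is
~0.015 ms.  ±0.05 ms sits between those scales: wide enough that a true
family member is essentially never lost (≈ 3.5 σ), narrow enough that the
nearest neighbouring family is essentially never captured (≈ 3 σ).  A wider
window (e.g. ±0.15 ms) demonstrably merges real neighbouring families.

**Drift-resolved anchoring and aggregation.**  Anchors are created per
(backbone, rt-peak, drift-time) — not one per rt-peak — because conjugates
sharing a backbone genuinely co-elute and are separable only in mobility
(the reference set contains same-name isomer pairs at identical retention
time whose CCS differ by ~5 Å²).  For the same reason, replicate hits merge
into report rows on (name, retention time, drift time), keeping
drift-resolved isomers as separate rows.

**Singleton relaxation.**  An anchor fragment must come from *some*
precursor.  If the strict drift window contains only the anchor itself,
the group is retried once at 2× the tolerance before concluding the anchor
is the intact parent drug.  The relaxation can only extend a singleton
group — it never overrides a found precursor — and guards against rare
(~4 σ) drift-centroid fluctuations turning a conjugate's fragment into a
spurious parent-drug detection.

**Precursor ties** break on higher intensity, then lower drift time:
arbitrary but deterministic, so permutations of the input never change the
result.

## CCS calibration

Single-field model `dt = β·γ·CCS + t_fix`, `γ = sqrt(mM/(m+M))/z` with the
neutral ion mass `m = z·(m/z) − z·m_p` and nitrogen (28.00615 Da) as drift
gas.  β and t_fix come from a least-squares fit over reference ions of
known CCS (tune-mix style); degenerate designs (< 2 points, coincident
abscissae) are rejected and the residual RMS is stored.  The simulator's
fixed calibration is the exact two-point fit through the two worked-example
anchor pairs — (544.0788, 211.6 Å²) at 28.66 ms and (632.0942, 233.4 Å²) at
31.74 ms — giving β = 0.026405 and t_fix = −0.1746 ms.  The slightly
negative intercept is a fitted instrument constant, not a physical transit
time; conversions require dt > t_fix, which every physical drift time
satisfies by a wide margin.

## Synthetic data: what it emulates, what it does not

Each simulated species is a Gaussian chromatographic profile (σ = 0.05 min)
sampled on a regular 0.0185 min frame grid (0.9 frames/s), with the
precursor and its planned fragments sharing one base drift time.  Noise:
per-record Gaussian drift jitter (default 0.03 ms) and m/z noise (default
1 ppm); matrix interferents with their own retention/drift/m-z coordinates,
drawn at least 0.5 ms away from any true family's drift time; and
sub-threshold intensity specks that exercise the intensity filter.  A seed
fixes every run bit-for-bit (per-run generators are derived from
(seed, sample, replicate)).

The 31-species study scenario encodes the reference screening table —
printed retention times, observed m/z (so accurate-mass bias up to 3.3 ppm
is part of the conditions), CCS, and the per-plant presence matrix over 9
samples × 3 replicates.  Printed detection counts not divisible by three
imply one missing replicate; the deficit is assigned to the last-listed
positive sample of the row.

Not emulated: isotope envelopes (charge inference is still tested through
explicitly constructed isotopologue records, and the two-chlorine M+2/M
plausibility check is provided as a library function), ion suppression,
peak tailing, retention-time drift between runs, and chimeric co-drifting
families sharing one backbone.  Passing the recovery study therefore shows
the linking/annotation logic is correct under realistic geometry and noise
— not that the screen is robust to every matrix effect of real extracts.

## Problem sizes

The recovery study is 27 runs of roughly 1 000–1 600 records each (~32 000
records total); the full screen completes in well under a minute on one
CPU.  The decomposition oracle in the tests enumerates all residue
multisets within caps over ~3 500 mass deltas in [0, 600] Da.

## Known limitations

* Compositional annotation only: isobaric residue combinations beyond mass
  accuracy, attachment sites and stereochemistry are out of scope.
* One precursor per anchor: two same-backbone conjugates co-eluting at the
  *same* drift time would be reported as one family (not observed in the
  reference data).
* Profile-mode spectra and vendor raw files are not read; the native
  dialect is the flat CSV frame table.
* The shipped calibration is self-consistent with the simulator; absolute
  CCS accuracy on real data depends on the user's own tune-mix references.
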