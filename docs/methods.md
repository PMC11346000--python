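# Methods

This note documents the models and procedures implemented in `ki67flow`,
the parameters that matter, the numerical conventions, and what the
synthetic data generator does and does not emulate.

## Cleavage census and enzyme selection

A cleavage *site* is the peptide bond between residues `i` and `i+1`
(1-based); a rule either matches a residue on one side of the bond
(C-side or N-side) with optional context vetoes, or matches a
position-specific motif over subsites P4..P2′.  The shipped catalog
(`data/enzyme_rules.yaml`, versioned and editable) encodes:

| enzyme | dialect |
|---|---|
| trypsin | C-side of K/R, vetoed before P |
| dispase | N-side of {A,V,L,I,M,F,W,G,P} (the set is the editable part) |
| clostripain | C-side of R only; the minor Lys activity reported in the literature is deliberately not modelled and is flagged in the catalog notes |
| proline endopeptidase | P2 ∈ {H,K,R}, P1 = P, P1′ ≠ P |
| thrombin | G-R-↓-G, or hydrophobic P4/P3 + P at P2 + R at P1 with non-acidic P1′/P2′ |

The restricted prolyl-endopeptidase dialect is a deliberate calibration:
the MIB-1 epitope carries a proline at its second position, so a plain
"C-side of P" rule would cut inside the epitope, contradicting the
enzyme's known epitope-sparing behaviour in this assay; requiring a basic
P2 (the PeptideCutter convention) resolves this.

Epitope safety scans the **full protein** (so flanking context is
honoured) and fails if any site falls strictly between the first and last
residue of *any* occurrence of the epitope — the conservative reading.

Sequence stand-ins: the package cannot redistribute database protein
sequences, so `ki67flow.standins` builds synthetic ones, labelled as such.
The two Ki67 stand-ins are tile constructions (3256 and 2896 residues)
whose per-enzyme census — trypsin 530/480, dispase 2183/1931, thrombin
3/2 — follows from tile arithmetic independent of the scanner, making them
genuine end-to-end fixtures; the published census of the real isoforms has
the same totals, so the selection report behaves as in the real analysis.
The cytokeratin and collagen stand-ins are random-composition chains with
guaranteed thrombin and prolyl-endopeptidase motifs spliced in.  Scanner
correctness itself rests on brute-force positional oracles and the
closed-form trypsin identity `#K + #R − #KP − #RP − [last residue ∈ KR]`
on random sequences, not on the stand-ins.

## Gating

**2n peak.** The DNA (DAPI) channel's dominant mode, from a Gaussian KDE
(Scott's rule) on a 256-point grid over `[0, max·1.05]`.  The analysis gate
is the "2n and above" region: `[peak·(1−w), ∞)` with the 2n window
`peak·(1±w)`, default `w = 0.2` — wide enough for DAPI staining CV, narrow
enough not to swallow the 4n peak at twice the 2n position.  Aggregates
(≥4n) are retained by design; there is no pulse-geometry doublet
discrimination in this assay.  QC rates are exact count ratios: recovery
= 2n/total·100, debris = <2n/2n, single-cell = 2n/≥2n·100; undefined
denominators raise rather than return sentinels.

**Percentile cutoffs.** Thresholds are the q-th percentile (default 95,
linear interpolation between order statistics — the `numpy.percentile`
default, matching common cytometry software) of the isotype control's
channel *under the same gate chain as the stained events*.  Positivity uses
strict `>`: a cutoff equal to a control event must not count that event
positive.  Consequences used throughout the tests: control self-positivity
≤ 5% + 1/n, and a mixture with true positive fraction `p` and
background-distributed negatives reads `100(p + 0.05(1−p))`.

**Main population (HDR).** The FSC–SSC "main population" is the
highest-density region holding a mass fraction (default 0.40 — "about 40%"
is treated as exactly 0.40, configurable) of the events: a 128×128
histogram on `[min(0, data·1.05), max·1.05]` per axis, smoothed with a
Gaussian kernel (Scott's 2-D rule, converted to bin units), cells
accumulated in decreasing density order (ties by cell index) until the
mass is covered.  The grid's lower bound follows the data when it is
negative so the estimator is also correct on centred test distributions.
This construction is deterministic, nests across masses, and for Gaussian
data reproduces the chi-square(2) HDR contour area within a few percent at
n = 10⁵.

**AreaX.** One ellipse on FSC–SSC that contains the CK-positive main
population and excludes the CK-negative one.  Fitting: Gaussian moments of
the CK+ events *inside their HDR* give center and orientation — robust to
CK+ events far from the main population (aggregates).  Truncation to the
HDR shrinks the covariance; for a Gaussian truncated at its mass-`m` HDR
the shrinkage factor is closed-form,

    k(m) = (2 − (t+2) e^{−t/2}) / (2 (1 − e^{−t/2})),  t = −2 ln(1−m),

(≈ 0.234 at m = 0.40), so the core covariance is divided by `k` to recover
the population covariance.  The ellipse level is then the larger of the
smallest level containing every CK+ HDR cell center and the chi-square(2)
`retain` quantile (default 0.99), so the gate holds the bulk of the CK+
population rather than only its densest 40% — an ellipse drawn at the HDR
level itself would retain less than half of the cancer nuclei, which is
plainly not how the gate is used.  If the CK− HDR intrudes, the level is
shrunk to just exclude every CK− HDR cell center; if that would keep less
than half of the CK+ HDR (configurable floor), the populations are
declared inseparable and the fit fails with overlap diagnostics.  In both
branches the fitted gate is disjoint from the CK− HDR by construction.
Membership is the closed quadratic-form test (boundary events are
members).  In cohorts the gate is fitted once from training samples
(default: the first 10 pairs, pooling each pair's CK classification) and
then applied fixed; per-sample refitting sits behind a flag.

**Schemes.** `dapi_only` stops at the DNA gate; `ck` adds the CK cutoff;
`areax` adds the ellipse.  The positivity denominator after AreaX keeps
>2n events (consistent with the "2n and above" analysis gate); this is a
configuration default, not a hard-wired choice.

## Synthetic data

`simulate_pair` draws a mixture of populations — cancer (FSC/SSC means
(600, 500) a.u., CK+, Ki67+ fraction = the true labelling index), lymphocytes
(0.4× the cancer scatter means, CK−, Ki67−), rare normal epithelium (mixed
CK), sub-2n debris, and ≥4n aggregates — with a 2n-dominant DNA histogram
(2n mean 100 a.u., CV 5%, S-phase plateau 8%, G2/M 7%).  Antibody-positive
signals are lognormals separated from background by >10× in median, so the
default conditions are cleanly separable; overlap stress tests supply
their own specs.  The isotype twin shares the stained member's
FSC/SSC/DNA draws and redraws the antibody channels from background —
which makes the percentile-cutoff algebra exact by construction.  All
draws come from a single `numpy` Generator seeded explicitly; identical
seeds give bit-identical tables.

`simulate_cohort` (default 30 cases, 2×10⁴ events/case, true LI uniform on
5–50%) emulates the pathology reference as
`clip(true_li · hotspot_multiplier + N(0, σ), 0, 100)` with multiplier 1.4
and σ = 3 percentage points: a pathologist scores the hottest region, so
the reference runs above the whole-section truth by roughly the
hotspot-vs-average bias reported for luminal breast cancer, with observer
noise on top.  These problem sizes keep the whole suite and the acceptance
script in the seconds-to-a-minute range on one CPU while leaving binomial
errors well below the tested tolerances.

What the generator does **not** emulate: spectral spillover/compensation,
cross-instrument scaling, acquisition drift, physical light scatter, or
realistic S-phase/debris spectra (the S-phase and debris settings are
conventions).  Passing tests therefore demonstrate the correctness and
calibration of the *analysis* under the stated statistical structure, not
instrument-level fidelity.

## Statistics

Spearman's rho (average ranks on ties) is reported together with an OLS
line on the raw percentages; the pairing is statistically unusual but is
the field's reporting convention for method comparisons, and both numbers
answer different questions (rank concordance vs. visual slope).  The
paired t-test is the classical two-sided test on differences; zero-variance
non-zero differences raise.  ROC declares a case positive when its score is
strictly above a threshold, sweeps all observed values, and integrates by
trapezoid — identical to the normalized Mann–Whitney U, which the tests
assert; the Youden point maximizes sens + spec − 1 with ties broken toward
the higher threshold (higher specificity).  P-values are asymptotic
(two-sided); at cohort sizes around n = 30 this is standard.
Reproducibility CV is `100·SD/mean` per case (sample SD), summarized as the
mean of per-case CVs.

## I/O

CSV round-trips are bit-exact (the reader uses the `round_trip` float
parser).  FCS 3.1 support is a minimal list-mode float reader/writer
written for this package ($PnN naming, float32/float64, both byte orders);
integer/bit-packed data, multiple datasets and analysis segments are out
of scope.  No compensation or transform is applied at I/O — gating
operates on linear values; `plotting.arcsinh_display` exists for display
only.

## Known limitations

- The AreaX fit assumes the CK+ main population is roughly elliptical;
  strongly non-Gaussian cancer populations would call for a nonparametric
  gate boundary.
- The 2n peak finder takes the global KDE mode; in a sample dominated by
  debris or aneuploid peaks the dominant mode may not be the diploid peak.
- The cleavage dialects are deliberately simple; they capture site counts
  and epitope safety, not kinetics, accessibility or partial digestion.
- Cohort statistics are point estimates; confidence intervals for AUC
  (DeLong) and multiple-testing control are out of scope.
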