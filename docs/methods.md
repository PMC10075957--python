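# Methods

## Problem setting

Histone tails carry dense, combinatorial acyl and methyl marks. After
enrichment, an LC-MS/MS run yields a *small* set of PSM candidates — often
dozens — and the usual target-decoy FDR filter becomes unstable: the decoy
and target score distributions overlap almost completely, and the estimator
FDR(s) = D(s)/T(s) cannot reach a 1% level until T(s) ≥ 100. This package
implements an identification strategy built for that regime.

## Model and procedure

1. **Database & digestion.** Target proteins plus reversed-sequence decoys
   (`rev_` prefix) are digested in silico with trypsin (cleave after K/R,
   blocked by a following P). Defaults: up to 4 missed cleavages, peptide
   length 5–35. Histone tails are K/R-rich and acylation suppresses cleavage,
   so generous missed cleavages are required; the original workflow's setting
   is unrecorded, so these are engineering defaults. When a protein starts
   with Met, the Met-clipped variant is digested too; coordinates stay in
   full-sequence numbering.

2. **Form enumeration.** Each peptide is expanded into modified forms: the
   target PTM (default Kla) on any subset of eligible sites, plus at most
   `max_background = 3` background modifications (Kac, Kme1, Rme1) in total,
   one modification per residue. Enumeration above a 10,000-form ceiling
   raises a capacity error; the pipeline skips such peptides and records
   them in the manifest. Forms ending in an acylated C-terminal lysine are
   discarded (trypsin would not have cut there) unless the peptide ends at
   the protein C-terminus; this filter is configurable off.

3. **Scoring.** Candidates are selected by precursor neutral mass within
   10 ppm (unknown charge: union over 2–4). Theoretical b/y ladders carry
   modification deltas at their positions; fragments are matched at 40 ppm,
   a position counting as observed if any considered charge state has a
   peak in tolerance (positions are ions: the FIC denominator is always
   2(n−1)). The rank score is `#matched ions + explained intensity
   fraction`; the delta score is the gap to the best *non-isomeric*
   competitor, so positional isomers do not suppress each other. Fragment
   charges considered: 1..min(z−1, 2).

4. **Filtration.** A PSM is accepted when FIC ≥ 0.5 (inclusive). No decoy
   information is consulted; decoy hits remain in the PSM table so the FDR
   comparison machinery can run on the same search.

5. **Chimera dissection.** When ≥2 isomeric candidates share the precursor
   window, each is scored against the full spectrum. A member is accepted
   iff its FIC passes the cutoff *and* at least one of its site-determining
   ions is matched. Site-determining ions are computed set-wise: a fragment
   is unique to a member only if its 1+ m/z matches nothing in any other
   member's theoretical ladder at fragment tolerance. Groups in which no
   member has a matched unique ion are reported with a site-ambiguity flag
   (peptide-level evidence retained, site claim withheld); one matched
   member collapses the group to an ordinary PSM. A minimum of one unique
   ion is this package's recorded choice; the level of evidence required
   for localization is otherwise a judgment call.

6. **Confidence triage.** Accepted PSMs are classified high/moderate by
   three automated checks: (i) no unexplained peak above the precursor m/z
   with relative intensity > 5% of the base peak, (ii) ≥ 50% of the top-10
   matched peaks carry a +1 isotope companion at +1.00335/z within fragment
   tolerance, (iii) no loud unexplained peak beyond the largest matched
   fragment. Isotope companions of matched peaks count as explained in (i)
   and (iii) — otherwise the companion of the last ladder peak would always
   fail (iii) on perfectly clean spectra. These flags approximate manual
   spectrum scrutiny; they are triage, not verdicts.

7. **Reporting.** Sites are aggregated per (protein, position,
   modification) and numbered in mature histone convention (initiator Met
   removed). Homologous-site merging across histone subtypes is curation,
   not computation, and is deliberately not automated; subtypes stay
   separate. Coexistence summaries count distinct peptide forms on which
   each background mark co-occurs with the target PTM.

## Evaluation machinery

* **Target-decoy FDR** is the plain ratio D(s)/T(s) without pseudocount
  (matching a "manually calculated" threshold), with q-values as the running
  minimum over thresholds admitting the PSM, and the reported threshold the
  smallest score at q ≤ level. Exhaustive sweeps over all distinct scores
  are the test oracle.
* **ROC sweeps** compare an FDR-level grid (1–100%) against an FIC-cutoff
  grid (100–0%), strict to loose, with explicit accept-nothing and
  accept-everything endpoints so both are monotone step functions through
  (0,0) and (1,1).
* **Cross-referencing** computes per-dataset loss rates: the union of
  accepted (sequence, mod-site) keys defines verified forms; a dataset
  misses a key only if its own raw spectra contain a matching precursor
  (10 ppm, 2 min RT — the RT tolerance is this package's choice, the
  source workflows record only "similar retention times").

## Synthetic data

The generator plants known peptide forms and emits their 1+ b/y ladders with
per-position retention probability *p*, optional +1 isotope companions
(0.45 relative intensity), uniform noise peaks over [100, 1.05·precursor m/z]
(deliberately allowing planted violations of QC checks (i)/(iii)), optional
ppm jitter, and chimeric mixtures at chosen ratios. One RNG stream per
dataset is keyed by the seed with per-spectrum substreams, so identical
configurations are byte-identical on disk. Defaults emulate the stated
regime: 30-spectrum datasets, p = 0.7 ladders with a few noise peaks for the
degraded case, p = 1 with no noise for closure.

What it does **not** model: learned fragmentation intensities, multiply
charged fragments beyond the configured maximum, isotope envelopes past +1,
co-isolation of different-mass peptides, or chromatographic peak shape. A
green test on this generator certifies the search, filtering and reporting
arithmetic — not instrument realism.

The small-dataset benchmark (29 true spectra + 1 clean decoy ladder,
searched against a fixed 80-form pool) is intentionally pool-bounded rather
than a full-database search so that 100-seed sweeps stay fast; the measured
quantity — how a single strong decoy moves the 1% FDR threshold versus how
the FIC filter behaves — is unchanged by the pool restriction.

## Numerical choices

* Monoisotopic masses are compiled from an atomic-mass table
  (proton 1.00727646688, water 18.0105646); modification deltas come from
  elemental compositions (ac C2H2O = 42.010565, la C3H4O2 = 72.021129,
  cr C4H4O = 68.026215, hib C4H6O2 = 86.036779, bz C7H4O = 104.026215,
  me1 CH2 = 14.015650, me2/me3 accordingly), all user-overridable via the
  modification TSV.
* Acetyl vs trimethyl differ by 0.03639 Da and stay resolvable at 40 ppm
  for fragments below ~900 m/z; the test suite asserts the matcher never
  merges them there.
* The 50% FIC boundary is inclusive. Matching keeps the nearest-in-ppm peak
  per position; peaks are not consumed (one peak may support two positions
  whose windows overlap).
* Ranking ties break by explained intensity, then lexicographic form key,
  making all outputs order-independent and deterministic.

## Known limitations

* The candidate-ranking score is intentionally simple (matched ions +
  explained intensity); it is not a calibrated probability and is not meant
  to compare across spectra.
* Site localization requires a single matched unique ion; noisy spectra can
  satisfy this spuriously, which the confidence triage only partly guards.
* Semi-enzymatic digestion, neutral losses, a/c/z ions and open searches
  are out of scope; chimera handling covers exact positional isomers only.
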