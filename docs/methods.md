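# Methods

## Identification filtering and protein inference

PSMs arrive as a TSV export (one row per identified spectrum) with a
log10 expectation value and, optionally, an engine-reported confidence.
Two filters apply:

* **Expectation filter** — keep PSMs with log10 expectation strictly
  below −1.5.  By default this is applied on the iTRAQ (ratio) path,
  where mis-identified spectra would contaminate the population fits; the
  label-free path accepts all PSMs unless the caller opts in
  (`max_log_expectation`), since spectral counting is robust to a small
  identification error rate and benefits from depth.
* **Two-peptide rule** — a protein is *detected* iff it has ≥ 2 distinct
  member peptides and (when confidences are present) a best member
  confidence ≥ 0.999.  The confidence is treated as an engine-supplied
  per-protein quantity (its best member PSM); we do not attempt to
  re-derive engine scoring.

Shared peptides (mapping to k > 1 database entries) contribute one
spectrum to each of the k protein groups and are flagged, with a
`unique-only` policy available.  Counting-with-flag preserves information
and keeps the grouping auditable; discarding or razor-assigning shared
spectra are both defensible alternatives, but either silently changes
spectral counts in ways a reader cannot reconstruct.

Protein masses come from sequence using **average** residue masses plus
one water, in kDa.  Average rather than monoisotopic masses because the
abundance index below is a coarse ratio where the ~0.06% systematic
difference is irrelevant, and kDa so that typical index magnitudes fall
in the 0.01–20 range.

## Relative abundance index

RAI = SpC / Mr.  Percentiles within a detected cohort are defined as
100 × (number of entries with rai ≤ this one)/n, ties sharing the maximal
value, so percentiles lie in (0, 100] and "top X%" is exactly
percentile ≥ 100 − X (boundary inclusive).  The percentile convention is
a package choice: nothing downstream depends on it beyond the band
statements it makes readable.

Between two acquisitions of the same sample (e.g. a single-plex shotgun
run and a 4-plex labelled run), `compare_cohorts` reports the Spearman
correlation of RAI over shared proteins and the fraction lower in the
second cohort.  Multiplexing splits acquisition time across labels, so
per-protein RAI is expected lower in the 4-plex run while the ordering
(and hence the rank correlation) is preserved.

## Reporter-ion normalization

Only PSMs with all four reporter intensities strictly positive enter
ratio space; the rest are counted and excluded (but still contribute to
spectral counts — the two quantitation paths are deliberately
independent).  Each of the four ratio channels is fit on the whole run's
quantifiable peptide population: arithmetic mean and **population**
standard deviation (denominator n).  "Width" means this SD — it is the
only width definition under which "distance from the population mean in
units of standard deviation" is self-consistent.  A median/MAD variant
(`robust=True`) exists for outlier-heavy runs; it is not the default
because the simulated and typical real populations are near-lognormal in
intensity, hence near-normal in log-ratio, where the SD is efficient.

Fitting is global (one distribution per channel over all peptides), not
per-protein: the population defines the null against which individual
peptides are scored.  This assumes most proteins do not change; see the
simulator notes below.

## Vector difference

Protein Z-scores Z0..Z3 are the channel-wise arithmetic means of the
member-peptide Z-scores; a PSM shared between proteins contributes to
each.  Proteins with fewer than 2 distinct quantified peptides are
reported (`low_evidence=True`) but never called, and are excluded from
the scale fit.

    m_diff = sqrt(Z0² + Z1²)        # between-condition displacement
    m_rep  = sqrt(Z2² + Z3²)        # between-replicate scatter
    d      = (m_diff − m_rep) / s
    V_diff = direction × d,  direction = +1 iff Z0 + Z1 ≥ 0

Design choices that were genuinely open:

* **Scale s.**  After peptide-level standardization the channel widths
  are 1 by construction, so re-scaling "by the widths of the peptide
  histogram distributions" would be a no-op at the peptide level.  The
  default (`scale="auto"`) therefore uses the mean of the four
  protein-level Z-channel population SDs on the called cohort — the same
  population-width idea applied at the level where the statistic lives.
  Aggregation over k peptides shrinks replicate channels by ~1/sqrt(k),
  so auto scale is typically < 1 and adapts to peptide depth.  A fixed
  scale (`"fixed:1.0"`) is available and is what the noiseless-limit
  exactness property uses.  Every run's metadata records the resolved
  value.
* **Sign rule.**  The direction of a call is read off the (Z0, Z1)
  vector: "+" iff Z0 + Z1 ≥ 0, i.e. the vector lies within ±90° of the
  consistent-increase diagonal (1,1); ties break to "+".  This is the
  minimal reading of "the angle subtended by a vector from the origin to
  (Z0, Z1)" that yields a binary increase/decrease label.
* **Fold change.**  2^((Z0+Z1)/2) — the replicate-symmetric mean of the
  two differential Z-scores, since neither replicate is privileged.
  Values < 1 read as a 1/x-fold decrease.
* **Negative d.**  Replicate noise exceeding signal is diagnostic, so d
  is reported unclipped but always classed "none".

Classification bands at the default thresholds (0.5, 1, 2): d < 0.5 no
call; 0.5 ≤ d < 1 moderate; 1 ≤ d ≤ 2 strong; d > 2 highest — chosen so
that "≥ 0.5 is a confident change" and "> 2 is the highest band" are both
honoured literally, paired with increase/decrease from the sign rule.
The classification is monotone in d by construction.

No p-values are attached to V_diff: the statistic is a scaled contrast of
two norms of correlated Gaussian-mixture coordinates whose null
distribution depends on peptide depth; calibrating it is out of scope,
and the thresholds are used as fixed operating points.

## Category summary

A two-column locus-tag → category map drives the report; unmapped tags
fall into "other" and duplicate tags are an error.  The packaged seed map
covers the *C. thermocellum* locus tags of the core-metabolism pathways
(cellulosome anchors and scaffoldin, glycosidases, ABC transporters,
glycolysis, pentose phosphate pathway, glycogen metabolism,
oxidoreductases and hydrogenases of end-product synthesis, ATP synthases)
and is user-replaceable; a real analysis should supply a genome-wide map.
One category (pyruvate formation from phosphoenolpyruvate) ships without
seed entries because no locus tags for it appear in the sources the seed
was drawn from.

Detection totals are strict per-protein unions of the two acquisition
methods; increased/decreased counts take confident calls split by
direction; the totals row is the column-wise sum.  Headline percentages
are computed over the 4-plex-detected cohort and rounded half-up to whole
percent (34/144 = 23.6 → 24, 6/144 = 4.2 → 4).

## Synthetic data

The generator emulates the statistical skeleton of the experiment:

| parameter | default | meaning |
|---|---|---|
| `mass_lognormal` | (ln 35, 0.45) | protein mass, kDa — median 35 kDa, typical bacterial protein |
| `abundance_lognormal` | (0, 1.0) | molar abundance, ~2 orders of magnitude spread |
| `spc_rate` | 0.25 | expected spectra per (abundance × kDa); median detected protein ≈ 10 spectra |
| `frac_differential` | 0.15 | fraction of proteins with a true change — keeps the null-dominated assumption of global normalization valid while matching the observed scale of growth-phase remodelling (~¼ of proteins) |
| `log2fc_distribution` | (0, 1.5) | true log2 fold changes of differential proteins |
| `reporter_noise_sd` | 0.3 | per-channel log2-scale noise SD, independent across the four tags |
| `peptides_per_protein` | 4.0 | truncated-Poisson (≥ 1) observable peptides |
| `frac_shared_peptides` | 0.05 | peptides mapped to a second database entry |
| `frac_low_confidence` | 0.05 | PSMs drawn to fail the expectation filter |

Sequences are assembled from random tryptic segments (7–20 residues
ending K/R; cleavage in the simulator ignores the proline rule) sized to
the target mass, so the FASTA, the peptide assignments and the masses are
mutually consistent.  Channels 114/115 follow exponential-phase
abundance; 116/117 are shifted by the protein's true log2FC.  An optional
within-phase noise correlation (`replicate_noise_corr`) stress-tests the
replicate-noise subtraction.

What the simulator does **not** model — and therefore what passing tests
do not establish about real data: retention/fragmentation physics,
search-engine score distributions, reporter-channel isotope impurity
bleed-through, intensity-dependent (heteroscedastic) noise, missing
channels within a PSM, ratio compression from co-eluting precursors, and
batch effects between runs.  Recall/false-call rates measured on it are
properties of the model, not of any instrument.

## Numerical notes

* Population SDs use denominator n throughout (ddof = 0); standardizing
  the fitting cohort returns mean 0 / SD 1 to 1e−9.
* Degenerate inputs error early: empty cohorts, zero-spread channels,
  non-positive masses or scales, fewer than two quantifiable PSMs.
* Grouping operations sort by protein_id, making results invariant under
  PSM input permutation; simulations are deterministic given the seed,
  with independent child streams for proteome, 4-plex and 1-plex draws.
* Monte-Carlo regression points (verified by `tests/test_acceptance.py`):
  with 25 × 200-protein simulations at the defaults, proteins with
  |log2FC| ≥ 1 and ≥ 3 quantified peptides are called in the correct
  direction in > 99% of cases, and < 6% of call-eligible null proteins
  are called; problem sizes (5000 PSMs for the standardization check,
  500 proteins for correlation/slope checks) were chosen to make these
  estimates stable at a few-second runtime.

## Limitations

The pipeline quantifies exactly one 4-plex run; there is no multi-run
batch correction, no missing-channel imputation, and no FDR control on
either the identification side (inputs are assumed pre-scored) or the
calling side (thresholds are operating points, not error rates).  The
"99.9% confidence" detection rule consumes an engine-supplied column; if
the upstream engine defines confidence differently (peptide- vs
protein-level), detection counts shift accordingly.
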