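# Methods

## Measures

**Site entropy.** For alignment column *i* with residue frequencies
`p_ij` over the 20 canonical amino acids, `H_i = -Σ_j p_ij ln p_ij`
(natural log; range 0 to ln 20 ≈ 2.996 nats), with `0·ln 0 := 0`. Gaps and
unknown characters (`X B Z J U O`) are excluded from the counts and the
frequencies renormalised over observed residues. An alignment's overall
variability is the arithmetic mean of `H_i` over its mapped sites. The
entropy is always the standard Shannon form with the leading minus sign, so
that larger values mean more variable sites.

**KL divergence.** `D_i = Σ_j p_ij ln(p_ij / q_ij)` compares a focal
per-site distribution `p` (designed sequences) to a reference `q` (natural
sequences). Both are computed from counts after adding 1/20 to each of the
20 residue counts (row denominator `n + 1`), which keeps every frequency
strictly positive; the divergence is therefore always finite. The
pseudocount is a KL-only device: entropies use raw frequencies by default
(a config flag can extend it). Per-protein scores are means of `D_i` over
sites. The focal/reference asymmetry is preserved — the code never
symmetrises.

**Rank-ordered KL.** Both 20-vectors are sorted in descending order and the
KL sum is taken over rank index. This compares the *shape* of the two
distributions while ignoring residue identity: a designed column using
entirely different residues at exactly the natural frequencies scores zero.
Implemented as elementwise comparison of sorted vectors, which is invariant
to tie-breaking order, so no tie rule is needed.

**Split-half control.** The natural alignment's rows are partitioned
uniformly at random into halves of ⌊n/2⌋ and ⌈n/2⌉ rows; the smaller half is
the focal set. The mean standard KL between the two halves (both
pseudocounted) is the natural-vs-natural baseline against which designed
divergences are judged. The partition is seeded; the config exposes
`control_reps` to average several splits (default 1, single split).

**RSA and exposure.** Absolute accessibility comes from classic DSSP output
(the fixed-column ACC field, parsed by column slice; mmCIF-style output is
rejected) or from a precomputed TSV. RSA = ASA / max-ASA(residue) with the
Tien 2013 theoretical maxima embedded as the default table and the Miller
1987 empirical scale as an alternative. RSA > 1 can occur under theoretical
scales and is kept unclipped (clipping would bias the exposed class);
occurrences are counted in the log. Exposure classes: three-class at
0.05/0.25 for entropy summaries and hybrids, two-class at 0.05 for pooled
amino-acid frequency tables; both boundaries are inclusive on the buried
side. RSA is computed only on the native structure — designed sequences
inherit it by structure position.

**Coordinates.** Alignment columns are 0-based; structure positions are
1-based over the reference row's ungapped sequence, matching DSSP habit.
Columns where the reference row is gapped are dropped from all statistics
(per-site statistics are only defined at structure positions; how insertion
columns in natural alignments should otherwise be treated is a genuinely
open choice and dropping is the conservative one). Correlations require at
least 3 joined sites and are reported as missing — never as 0 — when either
axis is constant.

**Correlation method.** Pearson by default, Spearman available via config.
The qualitative contrasts the package is built to expose (designed
correlations below natural) hold under both on synthetic data.

**Cys.** Design algorithms in this setting never place cysteines, so
designed columns have Cys frequency exactly 0. The 20-letter alphabet is
nevertheless retained everywhere; the pseudocount absorbs the structural
zeros in KL computations and no letter is ever dropped.

## Synthetic data model

The generator produces study conditions with known ground truth.

*RSA*: a two-component Beta mixture on [0,1] — weight 0.45 on Beta(0.7, 9)
(buried-enriched) and 0.55 on Beta(2.2, 1.8) (exposed-enriched) — which
populates all three exposure classes at realistic proportions (roughly a
quarter of sites buried).

*Natural model*: per site, a categorical distribution drawn from
Dirichlet(α(r)·b(r)) where r is the site's RSA, the base measure b(r)
interpolates linearly from a hydrophobic-favouring composition (85% of mass
on A V I L M F W Y C) at r = 0 to a polar-favouring one at r = 1, and the
concentration α(r) = 0.8 + 12·r grows with exposure. Small concentrations
produce sparse, conserved columns; larger ones track the broad base measure
— hence conserved hydrophobic cores and variable polar surfaces, with a
ground-truth entropy–RSA correlation around 0.8 at the defaults. The
alignment rows are i.i.d. draws from the site distribution (100 sequences by
default); the consensus sequence serves as the reference row. A calibration
helper greedily selects the concentration slope that hits a requested
ground-truth correlation (evaluated at 2000 sites under a fixed calibration
seed), used for parameter-recovery checks at a target of 0.6.

*Design model*: per site, energies over the 19 designable residues
(no Cys) are `E_j = -ln((1-w)·p_nat,j + w/19) + σ·ε_j` with flat-anchor
weight w = 0.6, noise σ = 0.5, ε standard normal drawn once per site and
shared across all temperatures; sequences are i.i.d. draws from
`softmax(-E/T)` (500 per condition, temperatures 0.03–2.4). The anchor ties
design preferences to the natural site distribution so the sweep brackets
natural variability and the shape divergence has an interior minimum, while
the flat component and the noise make designed variability more uniform
across exposure classes than natural variability — the regime the hybrid
analysis is about. At T → 0 designs collapse onto the energy minimum; at
T → ∞ they approach uniform over 19 letters (entropy ln 19 ≈ 2.944).

The generator draws sites independently: it emulates no covariation between
sites, no phylogenetic structure among the natural rows (rows are i.i.d.,
not a tree), and no energetic realism. Passing tests on synthetic data
therefore demonstrate that the statistics and their contrasts are computed
correctly under the stated model, not that real designed proteins behave
this way.

## Numerical and design choices

- All randomness flows from `numpy.random.default_rng` seeded per spec; the
  seed and a small stream index are combined so natural distributions,
  design energies and sequence draws are independent streams. No global RNG
  state is used or mutated.
- Frequency rows must sum to 1 within 1e-9; KL values are clamped at
  -1e-12 ≥ 0 to absorb rounding; oracle tests require agreement with naive
  loop implementations to 1e-12.
- Boxplot-style condition summaries use linearly interpolated quartiles
  (numpy's default percentile).
- Hybrid construction pairs row *k* of the core source with row *k* of the
  surface source; columnwise statistics are identical under any pairing, and
  row pairing keeps the output a well-formed alignment. Columns outside the
  site map are taken from the core source. Hybrids carry no plausibility or
  energy checks — they are an analysis construct, not proposed sequences.
- Per-protein failure isolation in the pipeline: an error in one protein's
  inputs records a failure row and the run continues; the run aborts only if
  every protein fails.
- A generic paired-comparison helper (mean difference + paired t-test) is
  provided as plumbing; the package asserts no particular significance
  values, which would require the original multi-protein structural
  datasets.

## Problem sizes

Tests and the acceptance script run the default scenario (150 sites, 100
natural, 500 designed sequences, 8 temperatures) for single-protein checks
and 6 independent synthetic proteins for distribution-level checks (hybrid
correlation gaps, class-entropy medians); parameter recovery uses 20 seeds
at 200 sites × 500 sequences. These sizes give stable qualitative contrasts
(the quantities involved differ by factors of 2–10, far beyond their
seed-to-seed spread) while keeping a full run in the tens of seconds.

## Known limitations

- The DSSP parser reads the classic fixed-column dialect only.
- No sequence weighting for phylogenetic redundancy in natural alignments;
  columns are unweighted counts.
- No symmetric divergences (e.g. Jensen–Shannon) and no profile-similarity
  scores beyond those described above.
- Undefined correlations (constant entropy, e.g. designs at the lowest
  temperature) are reported as missing values and excluded from summaries.
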