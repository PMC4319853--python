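# Methods

This note documents the models and procedures the package implements,
the parameters that matter, what the synthetic-data generator does and
does not emulate, and the numerical/design choices that were genuinely
open.

## Read cleaning

Raw reads are screened in a fixed order, each read receiving at most one
removal reason: 5′-adaptor contamination (the 5′ adaptor occurs anywhere
in the read), no insert (the first 8 nt of the 3′ adaptor are not found,
or are found at position 0 — adaptor–adaptor ligation), low quality
(contains N, or mean Phred < 20 when qualities are present; FASTA input
skips the quality test), poly(A) (A fraction of the insert ≥ 0.8), then
the inclusive 15–30 nt length window. Survivors are collapsed to unique
tags; internally everything is uppercase RNA (T→U). The poly(A) and
quality rules are this package's declared definitions — vendor pipelines
leave them unspecified — and both thresholds are configurable.
Locating the 3′ adaptor by an exact 8-nt prefix match is a deliberate,
deterministic stand-in for error-tolerant vendor trimmers; it makes the
cleaning report exactly reproducible at the cost of missing adaptors
with sequencing errors in their first 8 nt.

## Conserved miRNA identification

The three-step temporary-database procedure treats cross-species
conservation as alignment tolerance rather than homology search:

1. every tag is aligned, ungapped, against every catalog mature
   (end-to-end with a ±2 nt terminal offset, ≤ 2 substitutions over the
   overlap) and against catalog precursors (best same-length window);
2. per family, the aligning tag with the highest count becomes the
   temporary representative (ties: lexicographically smaller sequence,
   so output is total-ordered);
3. the library is re-aligned to the representatives; each tag is
   assigned to at most one family (fewest mismatches, then family name)
   and family expression is the sum of member counts.

"Allowing two mismatches and free gaps" is implemented as gap-free with
≤ 2 substitutions: the gapped reading is ambiguous, and ungapped
alignment is the conservative, testable interpretation. A 6-mer exact
seed prefilter (pigeonhole-safe for ≤ 2 substitutions over ≥ 19 nt
overlaps) keeps the scan linear in library size.

ncRNA degradation fragments are classified before miRNA identification,
by exact substring match against the reference classes in the priority
order rRNA > tRNA > snoRNA > snRNA (the order is not specified by any
standard; it is fixed here so the annotation is a partition).

## The folding engine

Hairpin prediction needs only relative, reproducible energies, so the
package embeds a deliberately small Zuker-style dynamic program over a
simplified nearest-neighbor table (version `PEONY-NN-1`, "engine units"
≈ kcal/mol):

* stack energy between two pairs = −(w₁+w₂)/2 with w(GC)=3.3,
  w(AU)=1.1, w(GU)=0.6 — exactly symmetric under helix reversal, and
  monotone: adding a stack never raises the energy;
* hairpin/bulge/internal-loop penalties tabulated by size with
  logarithmic extrapolation (1.08·ln(n/n_max));
* affine multibranch model (+3.4 close, +0.4 per branch, unpaired
  free); duplex initiation +4.1; no dangles, no coaxial stacking, no
  pseudoknots; lonely pairs allowed; interior loops capped at 30 nt in
  the DP.

The matrix fill is O(n³) and JIT-compiled with numba; traceback reads
the filled matrices in Python. Two independent routes through the same
table exist — the DP, and explicit enumeration of all structures scored
by loop decomposition — and they are required to agree exactly on
sequences up to 18 nt. Absolute energies are **not** comparable to
Turner-parameter folders; the −18 threshold on precursor MFE is
therefore a configurable parameter, honored at its conventional value
by default. An `external` backend delegating to RNAfold is provided
under the same output contract for users who want literature-comparable
energies; all tests and defaults use the embedded engine.

Duplex (miRNA:target) energy is initiation plus stacking over runs of
consecutively paired positions; unpaired positions break stacks. The
target rule that matters — duplex MFE ≥ 75 % of the perfect-complement
MFE — divides two energies from the same model, so a perfect site has a
ratio of exactly 1 regardless of the parameter scale.

## Hairpin discovery

Windows are excised around clustered loci of unannotated mapped tags
(two asymmetric windows per candidate mature: 150 nt far flank, 20 nt
near flank, clipped to the transcript; at most 3 candidate matures per
locus by count). Criteria, per candidate:

* **c2** ≥ 75 % of mature positions paired, all partners on one side of
  the mature and monotonically ordered (a single helix, the mature not
  spanning the terminal loop);
* **c3** window MFE ≤ −18 (configurable);
* **c4** no loop/bulge > 3 nt between consecutive paired mature
  positions (the community's reading of "no large internal loops or
  bulges"; configurable);
* **c5** 2-nt 3′ overhangs of the mature:star duplex with 1 nt slack:
  the mature 5′ end paired within 1 nt, 2±1 unpaired nt at the mature
  3′ end, and room in the window for the star's 2-nt 3′ tail;
* **c6** read support > 5, summing tags that match the mature exactly
  over their overlap with ≤ 3 nt total terminal divergence.

Overlapping accepted candidates keep the lowest-MFE precursor, so a
highly expressed 1-nt-shifted isomiR can occasionally win the call for
its locus; recovery is accordingly scored with a 3-nt terminal
tolerance. MFEI = (MFE/length × 100)/GC% is computed and reported but
not used as a filter. The precursor-excision policy and the bulge
cutoff are tool-internal conventions in the original programs; both are
exposed in the config.

## IsomiRs

A tag places on a precursor when a prefix of length ≥ (tag length − 3)
matches exactly; the remainder (≤ 3 nt) is the candidate non-template
tail. Placements overlapping the canonical mature by < 10 nt are
skipped. Class priority when several apply: nontemplate > both >
5′/3′ variant — the most specific label wins. Each tag contributes to
one precursor (shortest tail, then precursor id). The placement
tolerance mirrors the read-support tolerance of discovery, which keeps
the two counts consistent.

## Differential expression

The Audic–Claverie conditional probability is computed in log space via
log-gamma and exponentiated per term; the lower tail C is a finite sum,
the infinite upper tail D is evaluated as 1 − (C − p_point), so
C + D − p_point = 1 holds to machine precision and no truncation bias
enters. Two-sidedness is the standard doubling, min(1, 2·min(C, D)) —
the original formulation defines the tails but not their combination.
The test is exact and discrete, hence conservative: under a Poisson
null its two-sided p-values fall below 0.05 in less than 5 % of cases.
Note the conditional statistic is not exactly symmetric under swapping
the libraries (p(x|y; 1/r) = r·p(y|x; r)); the fold-change is exactly
antisymmetric, and swapped p-values agree within a small factor at
informative counts.

TPM normalization uses each library's total clean reads. Zeros in the
fold-change are guarded by a pseudo-TPM of 0.01 on both arms (the
original analysis reports finite fold-changes for library-exclusive
miRNAs without stating its rule). Multiplicity adjustment is
Benjamini–Hochberg (the "adjusted p" procedure is otherwise unnamed);
raw-p mode is available via `adjust=False`. Significance requires
p_adj < 0.01 **and** |log₂FC| > 1, both strict. The equal-tail count
interval [y_min, y_max] at level ε is exposed as a utility but plays no
role in the significance path.

## The synthetic-data generator

The generator emulates the study conditions, not the instrument: two
libraries (control/treated) of 100 000 reads by default, a transcriptome
of 30 random transcripts (500–3000 nt) carrying 30 planted hairpin
precursors, a 12-family conserved catalog, 12 structural ncRNAs, planted
perfect target sites for a subset of conserved matures, and one
dinucleotide-shuffled decoy transcript per planted precursor
(Altschul–Erickson shuffle, exact doublet preservation). Hairpins are
built by explicit stem design — mature and star (reverse complement of
all but the last two mature bases, giving 2-nt 3′ overhangs) around a
homopolymer loop, enclosed by a perfect 12-bp lower stem — and each
plant is verified to pass the structural criteria in its final
transcript context, with bounded retries; this guarantees criterion
margins rather than hoping rejection sampling finds them.

Per-miRNA counts are Poisson with mean = TPM × depth/10⁶ (treated
means scaled by 2^lfc); base TPMs are log-uniform (conserved
10²–10^3.5, novel 10²–10^3.3), and 25 % of miRNAs carry a planted
|log₂FC| of 2. Poisson matches the DE test's own sampling assumption,
so the calibration fixture tests the test under its model; real
libraries are over-dispersed and real power will be lower. Reads are
drawn from an isomiR cloud (5′ variant rate 0.10, 3′ rate 0.20 — 3′
heterogeneity twice 5′, as observed in plant isomiR data — non-template
tail rate 0.05, tail bases chosen to differ from the templated
continuation), and the remaining depth is filled with ncRNA fragments
(25 %), 5′-adaptor contaminants (5 %), poly(A) (3 %), adaptor–adaptor
ligation (4 %), low-quality reads (2 %) and random tags, on a length
profile with modes at 21 and 24 nt and a 5′-U bias. All randomness
flows from one integer seed; identical (config, seed) produce
byte-identical FASTQ and truth JSON.

What passing tests show: the pipeline's logic is correct against ground
truth under its own model assumptions. What they do not show: behavior
under sequencing error, over-dispersion, repeat-rich transcriptomes, or
genuine miRNA families with paralogs — none of which the generator
emulates (an over-dispersed count mode exists for robustness
experiments but is not part of the default conditions).

## Problem sizes and determinism

Default simulations use 10⁵ reads per library; the full pipeline on one
CPU runs in about two minutes, and the brute-force fold oracle is
restricted to sequences ≤ 18 nt where enumeration is exhaustive.
Floating-point comparisons in tracebacks use a 10⁻⁶ tolerance;
everything that iterates over dicts or sets is explicitly sorted, so
every output table is byte-stable across runs and platforms.

## Known limitations

* Embedded fold energies are model-specific; only orderings and ratios,
  not absolute kcal/mol, should be compared with published values.
* Ungapped alignment throughout (conserved matching, target duplexes):
  bulged duplexes are invisible to the target rules by construction.
* One library per condition: the exact test measures sampling noise
  only; biological replication is out of scope, as in the original
  design.
* Genome-based discovery (intergenic miRNAs) is impossible against a
  transcriptome; loci not represented in the assembly are missed.
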