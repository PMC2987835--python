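# Methods

This note documents the models implemented in `aphidmine`, the
judgement calls where the underlying screening procedure is open to
interpretation, the design of the synthetic-data generator, and what
the package's validation does and does not demonstrate.

## ORF calling

ESTs are single-pass cDNA reads: they may lie on either strand and be
truncated at either end, so all six frames are scanned.  An ORF runs
from an ATG to the first in-frame stop (TAA/TAG/TGA, standard nuclear
code) or to the sequence end, and must encode ≥ 70 residues
(`min_orf_len`).  Codons containing N translate to X, and X never opens
or closes an ORF — ambiguous sequence cannot fabricate a start or a
stop.  Nested in-frame ATGs share a stop; by default one ORF per
stop-free stretch is reported, anchored at the 5′-most ATG (the
longest-ORF convention, which the full-length criterion about upstream
methionines presupposes); `all_starts=True` reports every ATG for
sensitivity analysis.  Coordinates are 0-based half-open on the
forward strand of the EST regardless of ORF strand, so one convention
covers reporting, testing and provenance.

## Secretion gate

A protein passes when its signal-peptide score strictly exceeds 0.9,
the predicted cleavage site falls in residues 1–30, and no
transmembrane segment ends after the cleavage site.  The last clause
operationalises "a TM domain in addition to the signal peptide":
signal peptides are themselves hydrophobic, so helices confined to the
signal region must not count.

Evidence normally comes from parsed external reports (two plain-text
dialects, `signalp3_short` and `tmhmm_short`, are defined in
`aphidmine.io`).  For self-contained operation two builtin components
are provided.  **They are intentionally simple classical models, not
reimplementations of trained predictors, and no equivalence is
claimed** — real reproductions should feed genuine report files.

* Builtin signal-peptide score: product of three sub-scores in [0, 1] —
  (i) n-region charge, the net count of {K,R} minus {D,E} in residues
  1–5 through a logistic centred at +1 (slope 3, chosen so that net +2
  maps to ≈ 0.95 — the textbook one-to-two-positive-charge n-region
  scores high, while a neutral n-region sits at 0.5);
  (ii) h-region hydrophobicity, the maximum mean Kyte–Doolittle
  hydropathy over 8-residue windows within residues 3–25, rescaled
  linearly with 1.6 → 0.5 and 3.0 → 1.0 and clamped; (iii) the
  (−3,−1) rule at the best cleavage position in 16–30: 1.0 when both
  the −1 and −3 residues are small ({A,G,S,C,T}), 0.6 for one, 0.2 for
  none; ties between candidate positions resolve to the smallest.
  Proteins shorter than 25 residues score 0.
* Builtin TM detector: 19-residue windows over the mature region with
  mean Kyte–Doolittle hydropathy > 1.6 seed segments; overlapping
  seeds merge; merged segments shorter than 15 residues are discarded.
  Window length and threshold follow the classic hydropathy-plot
  convention for membrane helices.

## Alignment and E-values

All similarity searches are exact Smith–Waterman with affine gaps
(BLOSUM62, gap open 11, extend 1 — standard protein-search defaults),
executed by Biopython's `PairwiseAligner`; at a few hundred to a few
thousand translated ORFs, exhaustive all-vs-all alignment is tractable
and removes a heuristic search binary and its version drift.
Translated (protein vs nucleotide) search aligns the query against all
six frame translations of the subject, with stop codons translated to
a sentinel scoring −4 against everything; frame ties resolve in
(+0, +1, +2, −0, −1, −2) order.

Significance uses the Karlin–Altschul form `E = K·m·n·exp(−λS)` with
the published gapped-BLOSUM62/11,1 constants λ = 0.267, K = 0.041,
where n is the subject length (nucleotides for translated search).
This keeps the conventional meaning of thresholds such as 10⁻⁵ and
10⁻¹⁰ but only approximates database-search E-values; every E-value
cutoff is therefore exposed in `PipelineConfig` for sensitivity
analysis.  Identity is counted over all alignment columns including
gaps (the conservative denominator), and coverage is aligned-span
length over sequence length.  Sequences aligning with non-positive
optimal score (e.g. all-X) yield a flagged degenerate result with
score 0.

## Selection cascade: operationalised judgement calls

The redundancy rule "> 95% identity throughout most of the alignment"
needs an automated reading of *most*: an edge requires identity > 95%,
E < 10⁻¹⁰, **and coverage of the shorter sequence ≥ 0.8**
(`redundancy_coverage`).  Clusters are single-linkage connected
components; the representative is the longest member (ties:
lexicographically smallest id).

Full-length assessment combines three criteria: (1) at least two
same-species ESTs align over the entire candidate with the start Met
matched and a stop codon immediately following the aligned subject
end; (2) no supporting read shows an in-frame Met upstream of the
candidate start without an intervening stop; (3) some other-species
protein already annotated full-length is covered to ≥ 90%.  The
logical connective is genuinely open; the default is
`c1 or (c2 and c3)` — direct EST confirmation, or no evidence of a
missed upstream start plus a full-length ortholog — with `any_of` and
`all_of` switchable.

The polymorphism (diversifying-selection) filter drops a candidate
when its same-species alignments show no amino-acid variation *and*
its best other-species mature-region alignment differs by ≤ 1 residue
(differences counted as non-identical columns, so indels count).
Candidates with neither variation nor any ortholog alignment are also
dropped, matching the filter's rationale; they are flagged with a
distinct reason code since genuinely species-specific effectors can
land here.  Only near-identical hits count as "alignments" for
variation: identity ≥ 90% and query coverage ≥ 0.8.  Weaker or shorter
hits are paralogs — or merely a shared signal-peptide architecture —
and say nothing about polymorphism of this transcript; without the
coverage clause, hydrophobic-core matches between unrelated secreted
proteins masquerade as variation.

Cross-species overlap is judged on **mature-region** alignments
(E < `overlap_evalue`).  Signal peptides are compositionally
constrained (one hydrophobic core looks much like another), so
full-sequence overlap calls are dominated by the one region that
carries no information about homology of the secreted product.
Unmatched other-species candidates are translated-searched against the
focal species' full EST set; recovered ORFs must pass the secretion
gate, and by default (`filter_added_candidates`) also the full-length
and polymorphism gates — otherwise a monomorphic decoy removed at the
polymorphism stage would simply re-enter through its ortholog,
defeating the filter.

Gut-library matches (E < 10⁻¹⁵) flag possible salivary-gland
dissection contaminants; flags never remove candidates.  Names are
assigned serially per species in input order (Mp1, Mp2, …/Ap1, …);
historical names (e.g. MpC002) are honoured through an explicit
mapping, since published numbering encodes curation history that
cannot be derived from the data.

## Assay statistics

The per-well fecundity statistic is R = N12/A6 + N14/A12 + N17/A14,
computed per well and then averaged per construct ("per-well then
average"; the first ratio's definition is explicitly per-well and the
same reading is applied to all three).  Any zero denominator excludes
the well — a generalisation of the stated all-four-adults-died rule to
deaths occurring after day 6, without which R is undefined anyway.
R is linear in nymph counts and independent of the number of nymphs
initially placed.

The initial screen flags a construct when |mean − mean_EV| ≥ 1 × SE.
Which SE is the yardstick is configurable; the default is the standard
error of the observed difference, √(SE_c² + SE_EV²).  Under that
choice a null construct is flagged with probability 2Φ(−1) ≈ 31.7%,
the deliberately liberal first-pass behaviour this screen is designed
for; using the candidate's own SE instead (also available) inflates
the null rate to ≈ 47% once the control's sampling noise is accounted
for.  A scale-free consequence worth knowing: for a true shift of
k × SE under a 1 × SE threshold the flag probability is
P(|N(k, 1)| ≥ 1) regardless of sample size or noise level — ≈ 0.70 at
k = 1.5 — so the rule's per-candidate power on 1.5-SE effects plateaus
around 70% and only confirmation assays separate real effects from the
~32% of false leads.

The confirmation test is a two-way additive ANOVA (construct +
replicate block), F for construct against the residual, computed via
statsmodels OLS; designs with an empty construct × block cell are
rejected as singular, and all-constant data returns F = 0 by
convention.  ROS series are summarised by the per-disc maximum photon
count, averaged over discs, and compared with a Welch (unequal
variance) two-sample t-test — "two-sample t-test" is underspecified
and Welch is the safer default; zero-variance-in-both-groups cases are
reported as undefined with p = 1 when means agree.

## Synthetic-data generator

`simulate_library` emulates the statistical structure the cascade
assumes, not sequencing physics.  Implanted first-species proteins
come in four classes: true candidates (signal peptide + hydrophilic
mature region, 3 EST copies, 2 non-synonymous mature substitutions
among copies, a ~15%-diverged ortholog in the second species), TM
decoys (a 21-leucine helix inserted in the mature region),
non-secreted decoys (no signal peptide), and monomorphic decoys
(identical copies, ortholog within 1 mature residue).  Signal peptides
are generated to satisfy the builtin scorer by construction (MKR +
LIV-run + A-x-A); back-translation uses one fixed codon per residue,
since nucleotide realism matters only for ATG/stop placement; 5′/3′
UTRs of 40/120 nt are appended with an in-frame stop immediately
before the start codon (as in most real transcripts, and necessary for
the longest-ORF convention to land on the true start); reads are
reverse-complemented with probability 0.5 and truncated (10–50% off
one end) with probability 0.3.  Background reads are uniform random
nucleotides.  Defaults: 20 true candidates, 10 decoys of each class,
multiplicity 3, plus 40/60/30 background reads in the
salivary/whole-body/gut libraries.  Matching predictor-report files
are emitted from the builtin predictors so the parsed-report code path
sees the same evidence.

What this does **not** emulate: sequencing error, codon usage and
composition bias, transcript-abundance skew, paralogous gene families,
alternative splicing, real signal-peptide diversity, or genuine
SignalP/TMHMM behaviour.  Recovery results on synthetic libraries
therefore validate the *cascade logic* — gating, clustering,
full-length and polymorphism reasoning, reconciliation — not predictor
accuracy on real proteins.  Plate simulation: adults survive each
inter-count interval with probability 0.95 (independent coin flips)
and nymph counts are Poisson with mean = surviving adults × baseline
(1.0) × construct multiplier, so E[R] = 3 × multiplier exactly; dead
wells are emitted, exclusion being the analysis module's job.  ROS
curves are gamma-shaped bursts (peak 4000 at t = 10) with additive
truncated-Gaussian noise (sd 400).

## Validation sizes and numerical conventions

The test suite checks the ORF caller against a brute-force
every-ATG/six-frame oracle on 1000 random sequences of ≤ 200 nt (at a
10-residue floor, so the gate is actually exercised at that length),
the aligner against an exhaustive recursive search over all gapped
local alignments on 200 peptide pairs of length ≤ 8, and the full
screen on 10 simulated libraries at the default conditions
(sensitivity and precision ≥ 0.9 aggregated over seeds).  ANOVA size
is calibrated over 1000 null plate simulations (observed ≈ 4–5% at
α = 0.05); screen-rule rates over 500 seeds.  These sizes keep the
whole suite within a few minutes on one CPU while leaving each check
statistically meaningful.

Determinism: every generator is a pure function of its seed; alignment
tie-breaking is fixed (first traceback of the aligner, fixed frame
order); cluster and candidate order follow input order.  Identical
inputs, configuration and seed reproduce byte-identical funnel
reports.

## Known limitations

* The E-value surrogate approximates BLAST statistics; published
  funnel counts obtained with real BLAST, SignalP v3.0 and TMHMM v2.0
  on the original GenBank EST snapshots are not reproducible offline
  and remain external integration targets.
* The exhaustive all-vs-all strategy is O(n²) in the number of
  ORFs — comfortable at EST-library scale, wrong for genome-scale
  input.
* The polymorphism filter sees only the variation present in the EST
  sample; low-coverage transcripts are biased toward "monomorphic".
* The ±1-SE screen is a lead generator, not a test; its per-candidate
  power on small effects is bounded near 70% (see above) and its false
  lead rate is by design ≈ 32%.
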