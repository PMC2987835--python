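# aphidmine

Candidate-effector mining from aphid salivary-gland ESTs, with the
statistics of the accompanying leaf-disc fecundity and ROS-burst assays.

## The problem

Aphids feed by threading their stylets between plant cells into the
phloem, secreting watery saliva directly into host tissue.  Like plant
pathogens, they are thought to deliver **effectors** — secreted proteins
that manipulate host-cell processes, suppress PAMP-triggered immunity,
or (when recognised) trigger defence.  Candidate effectors can be mined
from salivary-gland expressed sequence tags (ESTs) by asking which
translated reading frames look like classically secreted, full-length,
rapidly evolving proteins.

`aphidmine` implements that mining cascade end-to-end for two aphid
species (a focal species, e.g. *Myzus persicae*, and a reference
species, e.g. *Acyrthosiphon pisum*), plus the downstream assay
statistics used to screen candidates for effects on aphid fecundity and
on the flg22-induced oxidative burst.  Because genuine EST snapshots and
licensed predictor binaries are not always available, the package also
ships a synthetic-data generator that implants candidates and decoys
with known ground truth, so every stage is testable offline.

## The cascade

Starting from an EST library, a candidate survives when it

1. **is an ORF** of ≥ 70 residues (ATG→stop or ATG→sequence end, six
   frames, both strands);
2. **carries a signal peptide** — score > 0.9 (strict) with a predicted
   cleavage site in residues 1–30, from a parsed SignalP-v3-style report
   or from a builtin heuristic scorer;
3. **is non-redundant** — single-linkage clustering of pairs with > 95%
   identity, E < 10⁻¹⁰, covering ≥ 80% of the shorter sequence; one
   representative per cluster;
4. **has no transmembrane segment in the mature region** (TMHMM-style
   report or a builtin Kyte–Doolittle window detector);
5. **is full-length**, judged from translated alignments against the
   species' full EST set (conserved start/stop in ≥ 2 reads, no
   upstream in-frame Met, or a full-length ortholog covered ≥ 90%);
6. **shows amino-acid polymorphism** consistent with diversifying
   selection — monomorphic sequences whose other-species ortholog
   differs by ≤ 1 mature residue are removed.

Candidate sets from the two species are then reconciled: overlapping
pairs (mature-region E < 10⁻⁵) are recorded, and unmatched
other-species candidates are searched back against the focal species'
full EST collection to recover candidates its salivary library missed.
Gut-EST matches (E < 10⁻¹⁵) are flagged as possible dissection
contaminants, and the chemosensory-protein cysteine spacing
C-x(6)-C-x(18)-C-x(2)-C is annotated.  Alignment throughout is exact
Smith–Waterman (BLOSUM62, affine gaps 11/1) with a Karlin–Altschul
E-value surrogate `E = K·m·n·exp(−λS)` (λ = 0.267, K = 0.041).

## Assay statistics

For the 24-well leaf-disc fecundity assay (4 first-instar nymphs per
well; adults counted on days 6, 12, 14; new nymphs on days 12, 14, 17)
the per-well statistic is the chained production rate

    R = N12/A6 + N14/A12 + N17/A14   (nymphs per adult),

with wells excluded once every adult has died by a count day.
Construct summaries (mean ± SE over wells) feed a deliberately liberal
±1-SE initial screen against the empty-vector control and a one-way
ANOVA blocked on experiment repeat.  ROS time courses are summarised by
the per-disc maximum photon count and compared with a Welch two-sample
t-test.

## Worked example

```python
from aphidmine.simulate import LibrarySimConfig, simulate_library, evaluate_screen
from aphidmine.pipeline import run_screen

cfg = LibrarySimConfig(seed=1, n_true_candidates=5, n_tm_decoys=3,
                       n_nonsecreted_decoys=3, n_monomorphic_decoys=3,
                       n_background_salivary=10, n_background_all=15,
                       n_background_gut=8)
sim = simulate_library(cfg)
result = run_screen(sim.mp_salivary, sim.ap_salivary, sim.mp_all, sim.mp_gut)
print(result.funnel.to_text())
metrics = evaluate_screen(result.candidates, sim.truth)
print(f"sensitivity={metrics.sensitivity:.2f} precision={metrics.precision:.2f}")
```

prints

```
ests_in                           40
orfs_called                       41
with_signal_peptide_nonredundant  10
with_tm_removed                   8
predicted_secreted                8
full_length                       8
after_polymorphism_filter         5
added_cross_species               5
final_candidates                  5
sensitivity=1.00 precision=1.00
```

Reading the funnel: 40 simulated salivary ESTs yield 41 ORFs of ≥ 70
residues; 10 non-redundant ORFs carry a signal peptide; removing the
ones with a mature-region transmembrane helix leaves 8 predicted
secreted proteins, all judged full-length; the polymorphism filter then
drops the 3 implanted monomorphic-conserved decoys, leaving exactly the
5 implanted true candidates (named Mp1–Mp5), with the 2 gut-implanted
contaminant candidates flagged but kept.  The same cascade is available
from the shell:

```sh
aphidmine simulate --seed 1 --outdir lib/
aphidmine screen --mp-salivary lib/mp_salivary.fasta \
    --ap-salivary lib/ap_salivary.fasta --mp-all lib/mp_all.fasta \
    --gut lib/mp_gut.fasta --out out/
aphidmine fecundity lib/plate.tsv --control EV
aphidmine ros lib/ros.tsv --control EV
```

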