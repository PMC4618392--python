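# checseq

Analysis of **ChEC-seq** (chromatin endogenous cleavage with sequencing)
data: a transcription factor (TF) fused to micrococcal nuclease (MNase)
cleaves DNA near its binding sites when calcium is added, and sequencing
the resulting small fragments over a digestion time course maps binding
sites genome-wide. `checseq` takes mapped paired-end cleavage fragments
through the complete downstream analysis:

1. **Cleavage-end tracks** — each fragment `[start, end)` contributes one
   count at `start` and one at `end − 1`; tracks are depth-normalized
   (`v / total_ends × total_mapped_bases`) for visualization and
   cross-time comparison, or genome-scaled
   (`v × G / fragments_mapped`, yeast `G = 12,495,000` bp) for profile
   analysis, with elementwise free-MNase control subtraction.
2. **Peak calling** — per-base maximum over all time points, threshold at
   `fold × genome-wide mean` (default 10, zeros included), merge
   qualifying positions within 30 bp; FDR = % of TF peaks overlapping
   peaks called on the untargeted free-MNase control.
3. **Kinetics** — 50-bp window cleavage sums per peak per time point,
   row Z-scoring, k-means (k = 2); the class reaching its row maximum
   earlier is "fast". Fast sites carry strong consensus motifs, slow
   sites degenerate ones.
4. **Motif scanning** — FIMO-style PSSM scoring of 50-bp peak windows on
   both strands with *exact* p-values (dynamic programming over the
   integer-discretized null score distribution); sites split at
   `p < 0.001` into high-/low-scoring classes.
5. **Cleavage profiles** — strand-oriented average end counts in 100-bp
   windows around motif-match centers, bootstrap confidence bands, and an
   asymmetry index `(U − D)/(U + D)` quantifying upstream-biased cleavage.
6. **DNA shape** — sliding-pentamer prediction of minor groove width,
   propeller twist, roll and helix twist; per-class average profiles
   compared by Pearson correlation and a two-sample KS test.
7. **Discrimination** — L2-regularized linear regression on one-hot
   sequence vs min-max-scaled shape encodings, scored by cross-validated
   AUROC (0.5 = random classifier).

A first-class **simulator** generates a random genome with planted
consensus (fast) and degenerate (slow) motif instances, time-stamped
fragment sets with saturating vs delayed-onset cleavage kinetics, and a
background-only free-MNase control, so the whole pipeline runs and is
testable at desk scale.

## Worked example

```sh
chec simulate --out sim/ --genome-length 100000 --n-fast 200 --n-slow 200 --seed 1
chec run --sim-dir sim/ --out run/ --seed 1
```

which prints

```
wrote simulation to sim/
pipeline complete -> run/
```

and leaves in `run/` a peak BED, the Z-scored peaks × time matrix, the
motif match table and `manifest.json`. On this dataset the pipeline calls
**379 peaks** at threshold **717.13** (10× the genome-wide mean of the
composite depth-normalized track), splits them into **200 fast / 179
slow** kinetic classes, and classifies **318 high / 61 low** scoring
sites at `p < 0.001`; zero peaks are called on the free-MNase control, so
the overlap FDR is 0%. Matched against the planted-site manifest, 94.8%
of the 400 planted sites are recovered, the kinetic labels agree with the
planted fast/slow classes for 100% of matched peaks, and all recovered
fast sites are high-scoring — the motif-strength/kinetics relationship
the method is designed to expose. The same library calls are available in
Python; see `checseq.pipeline.run_pipeline`.

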