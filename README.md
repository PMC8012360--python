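# grescan

Classification of glucocorticoid receptor (GR) ChIP-seq peaks by their
glucocorticoid response element (GRE) content, with the supporting peak
operations, an unwanted-variation estimator for the companion RNA-seq
track, and a synthetic-data generator with planted ground truth.

## The scientific problem

GR binds DNA as a dimer (or tetramer) at the ~15-bp palindromic GRE,
consensus `AGAACAnnnTGTTCT`. Whether GR can also act through *monomeric*
binding at half-GREs (one hexameric arm, `AGAACA`) is a long-standing
question with direct pharmacological consequences: the "dissociated"
model of glucocorticoid action rests on dimerization-impaired mutants
(GRdim, GRmon) supposedly binding only half-sites. Testing this
genome-wide requires classifying every ChIP peak as containing

* only a full GRE (`full_only`),
* only a half-GRE (`half_only`),
* both (`both`), or
* neither (`none`),

and then correcting two systematic artifacts:

1. **Misclassification correction.** A half-site motif model happily
   re-detects one arm of a genuine full GRE. A `both` site is therefore
   moved to `full_only` when the ACA (or TGT) core of every half-site
   hit overlaps one terminal hexamer of a detected full GRE.
2. **Degenerate rescue.** Half-only sites are rescanned with relaxed
   full-site consensus patterns (e.g. `ACAnnnTnT`); matches are
   plausibly weak full GREs. The adjusted half-site share of a cluster
   of *n* peaks with *h* half-only sites, *r* of them rescued, is
   `100 * (h - r) / n`.

Motif detection uses position weight matrices scored by the natural-log
likelihood ratio against a uniform background,
`S(x) = Σ_i ln(p_i(x_i) / 0.25)`, on both strands, with a per-motif
detection threshold. Peaks are grouped into receptor-occupancy clusters
C1–C4 (C1 GRwt-specific, C2 shared GRwt/GRdim, C3 GRdim-specific, C4
shared by all three) via a four-gate peak filter (Benjamini–Hochberg
FDR < 0.001 on Poisson enrichment over a depth-matched control, fold
change > 4 over control and over local background, > 75 tags) and a
Poisson differential test (p < 1e-4, FC > 4).

The RNA-seq track implements a modified RUVg: factors of unwanted
variation are the sample-space singular vectors of the per-gene-centered
`ln(size-factor-normalized count + 1)` matrix of empirical control
genes, with the *ranks* of the retained components exposed — default
(1, 4) for k = 2, the configuration that skips middle components
presumed to carry wanted treatment variation.

Because the original ChIP/RNA data are external, every operation is
exercised on synthetic data in which the truth is planted: full-GRE
instances are PWM-sampled above the detection threshold, windows are
rejection-sampled motif-free before insertion, and each assembled window
is verified to classify to its intended class noise-free.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (each prints what it found and writes tables under `results/`):

```sh
python analysis/01_simulate_sites.py        # genome + 200 planted peaks
python analysis/02_occupancy_clusters.py    # peak calling, C1-C4 clusters
python analysis/03_gre_classification.py    # classify, correct, rescue
python analysis/04_ruv_factors.py           # RUV on a simulated count matrix
python analysis/05_reported_arithmetic.py   # published worked-example checks
```

Script 03 prints, for the default seed:

```
classified 200 peaks; planted-truth agreement 1.000
cluster  n_sites  pct_full_only  pct_half_only  pct_both  pct_none  n_rescued  adjusted_half_pct_rounded
     C1       50           76.0            2.0      22.0       0.0          0                          2
     C2       50           52.0           24.0      24.0       0.0          4                         16
     C3       50           24.0           46.0      10.0      20.0          9                         28
     C4       50           26.0           34.0       8.0      32.0          6                         22
```

Every planted site is recovered (`agreement 1.000`), and the per-cluster
rows show the rescue arithmetic at work: C3 has 46% half-only sites of
which 9 contain the degenerate consensus, so its adjusted half-GRE share
drops to 28%. Script 05 checks the published bookkeeping directly:

```
cluster sizes sum to 6067; shares {'C1': 27, 'C2': 66, 'C3': 2, 'C4': 5}
C3: 65 half-only of 144, 26 rescued -> adjusted 27.08% (rounds to 27); end-to-end pipeline measures 27 == formula
C4: 102 half-only of 300, 36 rescued -> adjusted 22.00% (rounds to 22); end-to-end pipeline measures 22 == formula
```

Script 04 reports recovery of the two planted unwanted factors
(`best |r| = 0.999` and `0.998`) and a 99.9% reduction of
planted-factor variance after adjustment.

A `grescan` console command exposes the same steps as subcommands
(`simulate`, `scan`, `cluster`, `classify`, `summarize`, `ruv`, `demo`);
`grescan demo --seed 0 --outdir out/` runs everything end to end and
asserts planted-truth recovery.

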