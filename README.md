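# rtpquant

Absolute protein quantification from targeted (PRM) mass-spectrometry data
with heavy spike-in standards, and RNA-to-protein (RTP) modeling on top of
it. The pipeline goes from a transition-level quant report to:

1. **peptide light/heavy ratios** — per-fragment endogenous/standard ratios
   rolled up per peptide and replicate, with quantifiability filters;
2. **effective cell numbers** — the four core histones (H2A, H2B, H3, H4)
   quantified like any target act as a ruler for the number of cells in
   each replicate (constant histones-per-cell anchor, or calibrated against
   counted cell-line aliquots);
3. **protein copies per cell** — ratio × spiked fmol × molecules-per-fmol /
   effective cells, median-rolled over peptides and replicates;
4. **RTP conversion factors** — per-gene median of copies/TPM across
   samples, leave-one-out prediction of copy numbers from TPM, per-sample
   and per-gene correlation summaries, protein-length and subcellular-
   compartment analyses;
5. **robustness** — random training-subset cross-validation of the
   prediction as a function of training-set size.

A first-class synthetic-data generator (`rtpquant.simulate`) emits the four
input tables with known ground truth, so the entire pipeline is testable
without any external data.

## CLI

Everything is reachable from one entry point:

```sh
# full pipeline from a config (either real input paths or a simulate block)
rtpquant run --config run.yaml

# individual stages
rtpquant simulate --config sim.yaml --seed 1 --out bundle/
rtpquant quantify-peptides --transitions bundle/transitions.csv --out ratios.tsv
rtpquant cell-count --peptide-ratios ratios.tsv --spikes bundle/spikes.tsv \
    --samples bundle/samples.tsv --mode calibrated --out cells.tsv
rtpquant copy-number --peptide-ratios ratios.tsv --spikes bundle/spikes.tsv \
    --cells cells.tsv --out copies.tsv
rtpquant rtp --copies copies.tsv --tpm bundle/tpm.tsv --out-prefix results/
rtpquant cv --copies copies.tsv --tpm bundle/tpm.tsv --sizes 1:19 \
    --predictions-per-size 5000 --seed 1 --out cv.tsv
```

A minimal `run.yaml`:

```yaml
output_dir: out
seed: 1
simulate: {}            # all defaults: 55 genes, 9 cell lines + 11 tissues, 3 reps
cv: {enabled: true, n_predictions_per_size: 500}
```

or, with real data:

```yaml
output_dir: out
inputs:
  transitions: transitions.csv   # CSV: Sample,Replicate,Gene,Peptide,Fragment,Label,Area
  spikes: spikes.tsv             # TSV: Gene,Peptide,Sample,HeavyAmount_fmol
  samples: samples.tsv           # TSV: Sample,Class,Replicates,CountedCells,LysateMass_mg
  tpm: tpm.tsv                   # TSV: Gene + one column per sample
options:
  policy: median_of_fragments    # or sum_areas
  rollup: peptides-first         # or replicates-first
  cellcount_mode: auto           # constant | calibrated | auto
```

## Layout

```
src/rtpquant/
  simulate.py     ground truth + synthetic measurement bundles
  io.py           table readers/writers and cross-file validation
  prm.py          fragment -> peptide ratio rollup, quantifiability filters
  cellcount.py    histone-anchored cell counting, normalization factors
  copies.py       absolute copies per cell, median rollups
  rtp.py          RTP factors, leave-one-out prediction, correlations
  robustness.py   training-set-size cross-validation
  pipeline.py     orchestration, manifest, in-memory `analyze`
  cli.py          click CLI
```
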