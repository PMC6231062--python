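# bfndecode

Decoding 3-D hand trajectories from multichannel scalp EEG via brain
functional network (BFN) analysis and a two-level (hierarchical) linear
model.

The pipeline:

1. **Ingestion** (`bfndecode.io`) — EDF or delimited EEG plus a
   `time,x,y,z` trajectory file are preprocessed (DC removal, 50 Hz notch,
   zero-phase 55 Hz low-pass), synchronized on absolute timestamps
   (trajectory interpolated, EEG anti-alias decimated to the 100 Hz
   analysis rate) and cut into 2-s epochs.
2. **Network construction** (`bfndecode.bfn`) — per epoch the EEG is
   decomposed with a complex Morlet wavelet into eight bands (delta 1–3,
   theta 4–7, alpha1 8–9, alpha2 10–12, beta1 13–17, beta2 18–30, gamma1
   31–40, gamma2 41–50 Hz); Spearman correlations of the band envelopes are
   thresholded by a network cost (default 0.18) into a weighted graph, and
   node degree, average path length, clustering and mean link weight are
   extracted.
3. **Feature selection** (`bfndecode.selection`) — degree vectors are
   compared across the three motion modes (UD/LR/BF) with Kruskal–Wallis
   tests per (band, electrode); bands with enough significant electrodes
   and electrodes significant in every retained band become the
   characteristic set (delta/theta/gamma1 and
   F4, F8, C3, Cz, C4, CP4, T3, T4 on the published tables).
4. **Decoding** (`bfndecode.decoder`) — a composite ridge regression where
   epoch-level network covariates (clustering, path length, over an epoch
   history) modulate the intercept and every lagged-EEG slope (HLM), with a
   plain lagged linear model (MLR) as baseline.
5. **Evaluation** (`bfndecode.evaluation`) — decoded trajectories are
   smoothed (zero-phase 4th-order Butterworth, 1 Hz), scored per axis by
   Pearson correlation and averaged; repeated 10×10-fold cross-validation
   and a 95% reference-range ROC/AUC are provided.
6. **Synthetic data** (`bfndecode.synthetic`) — seeded generators emulate
   both experiment designs (single-axis oscillations; ~5.91-s spirals ×40
   repeats) with planted band-specific connectivity and a known
   EEG→kinematics coupling, so every stage is testable without external
   data.

`bfndecode.reference_tables` bundles the published summary tables (per-mode
metric means, degree spreads, p-values, per-subject decoding correlations)
used as worked examples by the tests and the acceptance report.

## CLI

```sh
bfndecode simulate --preset planted --seed 3 --trials-per-mode 4 --out sim/
bfndecode ingest   --eeg rec.edf --traj hand.csv --mode UD --unit-s 2.0 --out trial/
bfndecode bfn      --bundle trial --bands all --cost 0.18 --out metrics.tsv
bfndecode select   --degrees metrics.degrees.tsv --alpha 0.05 --out selection.json
bfndecode fit      --bundles sim/ --model hlm --l1 10 --l2 3 --out model.json
bfndecode decode   --model model.json --bundle trial --out decoded.csv
bfndecode evaluate --bundles sim/ --model hlm --runs 10 --folds 10 --seed 7 --out report.json
```

Trial bundles are plain-text directories (`meta.json`, `eeg.csv`,
`eeg_analysis.csv`, `trajectory.csv`), versioned via `meta.json`.

## Notes

- The subject-level decoding correlations themselves are not recomputable:
  no EEG/trajectory recordings are deposited with the source. They are
  covered by the printed-table arithmetic above plus property-level
  acceptance on synthetic data (oracle equivalence, type-I calibration,
  planted-effect power, HLM-over-MLR advantage, nesting identity) in
  `tests/test_acceptance.py`.
- Ocular/EMG artifact rejection is out of scope; the filter chain plus an
  optional channel-exclusion list replace it.
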