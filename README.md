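# infodyn

Information dynamics of epoched two-site neural recordings.

`infodyn` estimates directed information transfer and local information
processing between two continuously recorded sites (e.g. two cortical local
field potentials cut into epochs): differential entropy, active information
storage (AIS), and transfer entropy with an explicit, optimized information
transfer delay. Two estimation backends are provided — nearest-neighbor
estimators for continuous data (Kozachenko-Leonenko entropy,
Kraskov-Stögbauer-Grassberger mutual/conditional mutual information) and a
Bayesian backend for discretized data (Nemenman-Shafee-Bialek entropy with
entropy decomposition) — together with the inference machinery the analysis
needs: epoch-shuffle surrogate tests with binomial aggregation across
recordings, two-factor permutation ANOVA with restricted permutation
schemes, linear mixed-model comparison for nested epoch/recording designs,
and restricted-permutation Spearman correlations.

Because the original recordings are not redistributable, the package ships a
first-class synthetic-data generator (`infodyn.synth`) that produces epoched
two-site recordings with known ground-truth entropy, storage, coupling gain
and coupling delay, so the full pipeline is testable end to end, plus the
two in-silico studies (`infodyn.sims`): the effect of band-pass filtering on
transfer-delay reconstruction, and the effect of reduced source entropy on
transfer entropy at constant coupling.

## Layout

| module               | contents |
|----------------------|----------|
| `infodyn.synth`      | `SynthParams`, `generate_recording`, `generate_condition_set` |
| `infodyn.preproc`    | `Recording` container + HDF5/CSV I/O, epoching, z-normalization, delta-power and amplitude QC, multitaper band power, autocorrelation decay time, Butterworth band-pass |
| `infodyn.embedding`  | delay embedding (`EmbeddingSpec`, `delay_embed`), local-predictor embedding optimization (`ragwitz_optimize`), common-dimension rule |
| `infodyn.knn`        | `kl_entropy`, `ksg_mi`, `ksg_cmi`, `ais`, `te_spo`, `scan_delay`, `te_net` |
| `infodyn.bayes`      | `discretize`, state-word histograms, `nsb_entropy`, decomposed TE/AIS, subsample-robustness check |
| `infodyn.stats`      | surrogate tests, binomial aggregation, permutation ANOVA, LMM comparison, ICC, restricted-permutation Spearman, permutation t-test |
| `infodyn.sims`       | `sim_filter_effect`, `sim_source_entropy` |
| `infodyn.pipeline`   | `PipelineConfig`, `run_pipeline` |
| `infodyn.cli`        | `infodyn` command-line entry point |

## CLI

```sh
infodyn synth --params params.yaml --out data/          # synthetic recordings
infodyn preprocess --in data/ --delta-threshold 0.30 --out results/
infodyn embed --in data/rec.h5 --optimize
infodyn estimate --in data/rec.h5 --measure TE --backend knn --out te.tsv
infodyn simulate filter-effect --profile desk --seed 1 --out results/
infodyn simulate source-entropy --profile desk --seed 1 --out results/
infodyn run --config pipeline.yaml                      # full pipeline
```

A pipeline config (YAML or JSON) mirrors `infodyn.pipeline.PipelineConfig`;
every stochastic stage takes an explicit seed and identical config + seed
reproduces the output bundle byte for byte.

## Conventions

- All k-NN searches use the maximum norm, `k = 4` by default.
- Continuous estimates are in nats (`infodyn.knn.to_bits` converts);
  discretized/Bayesian estimates are in bits.
- Assumed transfer delays are `u >= 1` sample; `u = 0` is excluded since a
  physical delay is at least one sample.
- Bayesian estimation uses a working support of `K' = 1e12` independent of
  the combinatorial word-space size.
- Surrogate/permutation p-values carry the +1 correction and are never 0.
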