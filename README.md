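# gliotype

Transcriptome-based tumor subtyping for bulk expression cohorts, built for
the glioma setting: discover molecular subtypes without supervision, turn
them into a portable classifier, and characterize what the subtypes mean
clinically.

Gliomas are classified by integrating histology with mutation markers (IDH
status, 1p/19q codeletion), but the systems disagree on a meaningful
fraction of patients. Global transcriptomic profiles offer an independent,
automatable axis of classification. `gliotype` implements that workflow in
two stages:

- **DBU** (density-based UMAP consensus clustering): repeat
  {subsample genes → UMAP → DBSCAN} many times, align cluster labels across
  iterations by optimal assignment, and call each sample by plurality vote —
  a sample is assigned only if ≥ 70% of the retained iterations agree, and
  is "ambiguous" otherwise. Consensus groups can be probed for hidden
  substructure (e.g. a low-tumor-purity subgroup) by re-running DBU on the
  subset.
- **ETC** (ensemble transcriptomic classification): from the discovered
  subtypes, select a gene signature (one-vs-rest differential expression +
  curated genes + recursive feature elimination under a linear SVC),
  partition it into six expression-pattern groups, and train many linear
  SVCs on random half-draws of each group. Calls are made by plurality
  voting with a confidence score p1/p2 (vote share of the top class over
  the runner-up); a call requires confidence > 3. In-cohort calls are
  leak-free via fourfold cross-fitting; external cohorts may lack signature
  genes, in which case affected ensemble members are refit on the surviving
  genes.

Downstream, the package provides one-vs-rest chi-squared mutation
enrichment with Benjamini–Hochberg correction, Kaplan–Meier / log-rank /
Cox survival stratification, tumor-purity comparisons (ANOVA), and
concordance cross-tabulation against other classification systems under
optimal class matching.

A first-class synthetic-cohort generator (`gliotype.synthetic`) produces
expression/mutation/survival/purity data with known subtype ground truth —
including a subtype distinguishable only through low tumor purity — so every
stage of the pipeline is testable end-to-end. See `docs/methods.md` for the
model and all numerical choices.

## Worked example

Run the whole pipeline on a simulated cohort:

```bash
cat > pipeline.yaml <<'YAML'
seed: 11
out_dir: demo_out
simulate:
  n_samples: 240
  n_genes: 1000
  n_informative_genes: 120
dbu:
  n_iterations: 25
  genes_per_iteration: 300
  min_points: 15
signature:
  n_select: 30
dictionary:
  n_models: 30
characterize:
  compare: truth
YAML
tp run --config pipeline.yaml
cat demo_out/run_log.json
```

which prints (numbers from this exact configuration):

```json
{
 "config_hash": "73c549c3fda6",
 "seed": 11,
 "subclusters_split": [],
 "dbu_retained_iterations": 12,
 "dbu_removed_iterations": 13,
 "dbu_ambiguous": 17,
 "dictionary_entries": 30,
 "dictionary_mean_accuracy": 0.9707167167167168,
 "etc_ambiguous": 10,
 "concordance": 0.9869565217391304
}
```

Reading it: 13 of 25 DBU iterations were dropped for disagreeing with the
modal cluster count; 17 of 240 samples could not be assigned by ≥ 70% of
the retained iterations; no consensus group showed a coherent split at this
reduced scale (`subclusters_split` is empty); all 30 ensemble entries cleared the 95% CV-accuracy
floor with mean accuracy 97.1%; the ensemble left 10 samples ambiguous; and
the final calls agree with the simulated ground truth on 98.7% of
non-ambiguous samples under optimal class matching. The output directory
also contains the consensus calls and vote matrix, the signature and
dictionary JSONs, the serialized ensemble, per-sample predictions with
confidence scores, and the mutation-enrichment / survival / purity /
concordance reports as TSV.

Each stage is also a library call (`run_dbu_with_subclustering`,
`build_signature`, `build_model_dictionary`, `crossfit_calls`,
`predict_external`, …) and a CLI subcommand
(`tp simulate|preprocess|dbu|signature|dictionary|fit|classify|characterize`).

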