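# immunet

Correlation-network analysis of immune-measure panels. Starting from a
subjects × measures matrix (with missing values) and a measure-annotation
table, the package:

1. **preprocesses** the data — drops measures (explicit list and/or a
   missingness-fraction rule), drops subjects missing an entire measure
   battery, and mean-imputes the rest per dataset;
2. builds **thresholded Pearson correlation networks** (positive or
   negative), selecting the *bottleneck threshold*: the largest correlation
   at which the network is still a single connected component (the minimum
   edge of the maximum spanning tree);
3. detects **communities** with a degree-corrected microcanonical SBM
   minimized by description length (exact objective documented in
   `src/immunet/_sbm.py`), combined over many seeded fits into a
   **consensus partition** that can leave unstable nodes unassigned;
4. runs **randomization tests**: concentration of a marked node set into few
   communities, chain-likeness of a community trio against degree-preserving
   rewirings, cross-network common-node counts, and an adjusted-Rand
   partition-similarity test — all with add-one permutation p-values;
5. compares against **PCA** with automatic outlier-measure removal and
   re-run.

A synthetic-data generator (`immunet.synthetic_data`) plants block-correlated
communities — including a chain-like cytokine trio and a mutually
negatively correlated pair of blocks — plus per-cell and whole-battery
missingness, so the entire pipeline is testable without any external data.

## CLI

```bash
immunet simulate --seed 1 --n-subjects 300 --out data/
immunet preprocess --matrix data/matrix.tsv --annotation data/annotation.tsv --out pre/
immunet network --matrix pre/matrix_imputed.tsv --annotation pre/annotation_used.tsv --out net/
immunet communities --graphml net/network_positive.graphml --seed 2 --n-runs 50 --out comm/
immunet run --config config.yaml --out run1/        # full pipeline + manifest.json
immunet compare --run-a run1/ --run-b run2/ --out cmp/
immunet pca --matrix pre/matrix_imputed.tsv --annotation pre/annotation_used.tsv --out pca/
```

A minimal `config.yaml` for `immunet run`:

```yaml
seed: 1
synthetic:            # or `input: {matrix: ..., annotation: ..., environment: wild}`
  n_subjects: 400
communities:
  n_runs: 100
  theta: 0.9
tests:
  - {type: concentration, marked_category: CR, m: 3, n_null: 10000}
  - {type: chain, n_null: 1000}
pca:
  max_removals: 1
```

The run manifest (`manifest.json`) records seeds, thresholds, community
counts, densities and p-values; its schema is published at
`schema/manifest.schema.json`.

## Layout

| module | role |
| --- | --- |
| `immunet.synthetic_data` | factor-model generator with planted blocks and MCAR missingness |
| `immunet.preprocess` | `ImmuneMatrix` container, TSV I/O, exclusion + mean imputation |
| `immunet.corrnet` | Pearson matrix, bottleneck threshold, network building, densities |
| `immunet.communities` | SBM fits, description length, consensus partition |
| `immunet._sbm` | the DC-SBM objective and agglomerative/local-move search |
| `immunet.netstats` | randomization tests and community-overlap statistics |
| `immunet.pca_compare` | PCA with outlier-measure removal |
| `immunet.cli_report` | pipeline orchestration, manifest, CLI |
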