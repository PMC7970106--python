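# omicstack

Stepwise multi-omics integration for feature-by-sample matrices, in four
steps:

1. **Explore** — per-omic PCA with association of component scores against
   sample metadata (Kruskal-Wallis / Spearman / Cox score test, Bonferroni or
   BH adjusted).
2. **Decompose** — joint + individual + residual decomposition of two or more
   aligned blocks, with the joint and per-block individual ranks selected by
   a sequential permutation test (a PCA + canonical-correlation cross-check
   is also provided).
3. **NPC** — non-parametric combination of statistical evidence across
   gene-mapped feature tuples: per-block permutation p-values under a joint
   permutation scheme (coupled across omics; partially overlapping sample
   sets supported), combined with Fisher / Liptak / Tippett functions into
   global permutation p-values, plus a closed-form parametric alternative
   and novel-feature accounting against single-omic analyses.
4. **Cluster** — gene-set over-representation analysis (right-tailed Fisher
   exact), significance/size filtering, relative-risk similarity between
   gene sets, and k-means clustering with gap-statistic model selection,
   with cross-analysis membership matrices.

A `synthetic` module generates seeded datasets with known ground truth for
every stage (shared low-rank structure, paired differential features with
controllable cross-omic correlation, survival outcomes, planted gene-set
clusters), so the whole pipeline is testable without any download.

## Data formats

All inputs and outputs are tab-delimited UTF-8 text:

- **Omics matrix** — TSV, features on rows (first column = feature ids),
  samples in columns (header row = sample ids).
- **Sample metadata** — TSV, samples on rows; numeric columns are numeric
  variables, other columns categorical; a pair `V_time` / `V_event`
  (positive times, 0/1 events) defines a time-to-event variable `V`.
- **Feature mapping** — TSV with columns `gene`, `feature_a`, `feature_b`
  (empty cell = absent feature), built with `combine_mappings` from two
  feature→gene tables.
- **Gene sets** — standard GMT.

## CLI

```bash
# synthetic data with ground truth
omicstack simulate --scenario paired-differential --n-per-group 50 \
    --n-features 200 --n-true 30 --effect 0.4 --seed 1 --out data/

# step 1: per-omic PCA + metadata association
omicstack explore --data mrna=data/omic_a.tsv --data mirna=data/omic_b.tsv \
    --metadata data/metadata.tsv --components 3 --out step1/

# step 2: joint/individual decomposition (ranks selected by permutation)
omicstack decompose --data mrna=data/omic_a.tsv --data mirna=data/omic_b.tsv \
    --n-perm 100 --seed 1 --out step2/

# step 3: non-parametric combination across mapped features
omicstack npc --data-a mrna=data/omic_a.tsv --data-b mirna=data/omic_b.tsv \
    --metadata data/metadata.tsv --mapping data/mapping.tsv \
    --outcome group --covariate age --perms 1000 --seed 1 --out step3/

# step 4: ORA + relative-risk clustering of gene sets
omicstack cluster --gene-sets sets.gmt --genes significant_genes.txt \
    --alpha 0.05 --min-genes 3 --seed 1 --out step4/

# chain steps from a YAML config
omicstack pipeline --config run.yaml --out run/
```

Every subcommand writes a `manifest.json` (input checksums, configuration,
seed, version); runs with identical manifests produce byte-identical
outputs, and results are independent of `--threads`.

## Library use

```python
import omicstack as om

blocks, truth = om.simulate_joint_blocks(40, [60, 80], joint_rank=2,
                                         individual_ranks=[1, 3], snr=10, seed=0)
blocks = [om.center_and_frobenius_scale(b) for b in blocks]
r, ranks = om.select_model_jive(blocks, n_perm=100, seed=0)
model = om.jive_decompose(blocks, r, ranks)

a, b, mapping, meta, _ = om.simulate_paired_differential(50, 200, 30, 0.4, seed=0)
result = om.omics_npc([a, b], meta, mapping, om.Design("group"),
                      B=1000, seed=0, mode="overlap")
print(result.to_frame().head())
```
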