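# reporank

Drug repositioning by **contrastive graph pretraining** and
**residual-convolution ranking fine-tuning**.

The pipeline operates on a drug–disease heterogeneous graph (drug–drug,
disease–disease, and disease–drug relations) whose nodes carry expression
perturbation signatures as initial features:

1. **Features** (`reporank.features`) — drugs with recorded signatures use
   them directly; unrecorded drugs borrow the mean signature of recorded
   drug–drug neighbors (1-hop → 2-hop → global mean); disease rows are the
   (optionally sign-flipped) mean over their treating drugs.
2. **Pretraining** (`reporank.pretrain`) — two augmented graph views
   (Bernoulli edge removal + shared-mask feature-dimension zeroing) are
   encoded by one weight-shared GCN whose propagation depth is jittered
   between views; a symmetric cosine InfoNCE loss aligns nodes across views.
3. **Fine-tuning** (`reporank.finetune`) — a residual graph convolution
   (`relu(Â H W) + H`) over the bipartite treat graph, trained with two
   pairwise ranking losses: a binary treat-relation loss `L_I` and a drug
   effectiveness-comparison loss `L_E`, combined per step with weights
   `w_I = L_IET/(L_IET+β)`, `w_E = β/(L_IET+β)` where `L_IET = L_I + L_E`
   (computed from detached loss values), plus L2 regularization.
4. **Evaluation** (`reporank.evaluate`) — filtered per-pair ranking with
   pessimistic tie handling; MRR, Hit@K, relative improvement rates, ECR
   ordering accuracy, and drug-vs-disease silhouette scores.
5. **Synthetic studies** (`reporank.synthetic`) — complete input sets with
   planted latent affinities so every stage is testable offline.

All training runs on a small NumPy reverse-mode autodiff engine
(`reporank._autodiff`) — no deep-learning framework required.

## CLI

```bash
# generate a synthetic study (five TSVs + truth table)
reporank simulate --out-dir data/ --seed 7 --n-drugs 150 --n-diseases 30

# contrastive pretraining -> embeddings.tsv
reporank pretrain --data-dir data/ --out-dir runs/pre --seed 7

# split, fine-tune, evaluate -> metrics.json + per-query ranks
reporank finetune-evaluate --data-dir data/ --embeddings runs/pre/embeddings.tsv \
    --out-dir runs/ft --seed 7 --split-mode warm_edge

# ablations: no_pretrain | no_ddge | no_pretrain_ddge | no_LI | no_LE
reporank ablate --data-dir data/ --out-dir runs/no_le --seed 7 --variant no_LE

# improvement rates between two metrics.json files
reporank improvement --new runs/ft/metrics.json --baseline runs/no_le/metrics.json
```

Every command echoes its resolved configuration (`run_config.json`) next to
its outputs; hyperparameters can also be supplied as a flat YAML file via
`--config-file` (unknown keys are rejected).

### File formats

Tab-separated, UTF-8, header row, `#` comments:

| file | columns |
|---|---|
| `nodes.tsv` | `node_id`, `node_type` (`drug`/`disease`) |
| `edges.tsv` | `source_id`, `target_id`, `relation` (`drug-drug`/`disease-disease`/`disease-drug`) |
| `treat.tsv` | `disease_id`, `drug_id` |
| `ecr.tsv` | `disease_id`, `better_drug_id`, `worse_drug_id` |
| `features.tsv` | `node_id`, then numeric feature columns |

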