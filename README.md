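# bcrlm — antibody language modeling for BCR repertoires

`bcrlm` is a scale-configurable implementation of an antibody-specific
language-model workflow for unpaired B-cell receptor (BCR) chains. It is
aimed at computational immunologists who want to study, end to end and
on a single CPU, how masked-language-model (MLM) pretraining combined
with **phenotype-aware supervised contrastive learning** turns raw
repertoire sequences into embeddings that encode B-cell functional
state — and how those representations can then be probed for subtype
classification, paratope (antigen-contact residue) prediction, and
residue-level attribution.

The package covers the whole workflow:

1. **Simulation** (`bcrlm.sim`) — synthetic repertoires with germline
   V(D)J recombination, junctional diversity, subtype-dependent somatic
   hypermutation (SHM) and isotype usage, planted subtype CDR3 motifs,
   and paratope-labeled antibody sets. Everything downstream is testable
   without any external download.
2. **Curation** (`bcrlm.curation`) — AIRR TSV ingestion, quality-control
   filters (CDR3 present, complete V(D)J annotation, CDR3 length
   6–29 aa), CD-HIT-style greedy identity clustering at 95% **before**
   the 90:5:5 train/validation/test split, which guarantees that every
   test sequence is <95% identical to every training sequence.
3. **Tokenization** (`bcrlm.tokenization`) — a composite 260-token
   vocabulary (5 specials + 20 amino acids + 230 gene symbols + 5
   isotypes) and sentence-pair encodings
   `[CLS] residues… [SEP] v (d) j isotype [SEP]` truncated at 148
   tokens, in full-length or HCDR3-focused mode.
4. **Model** (`bcrlm.model`) — a BERT-style post-layer-norm Transformer
   encoder on numpy + `autograd`, with MLM, sequence-classification and
   per-token heads, exposed hidden states and attention maps. The full
   preset (12 layers, 12 heads, hidden 768, FFN 3072) counts ≈86 M
   trainable parameters; desk-scale presets train in minutes.
5. **Training** (`bcrlm.training`) — BERT masking (15% selected;
   80/10/10 mask/random/keep), the joint objective
   `L = (1 − w_cl)·L_mlm + w_cl·L_cl` with a temperature-scaled
   supervised InfoNCE contrastive term on [CLS] embeddings,
   class-balanced sampling, and a linear-warmup + plateau-decay
   learning-rate schedule.
6. **Evaluation** (`bcrlm.evaluation`) — ARI/NMI/silhouette embedding
   quality, subtype fine-tuning with macro precision/recall/F1,
   multiclass MCC and confusion matrices, and the six-metric paratope
   benchmark (Precision, Recall, F1, MCC, AUROC, APR).
7. **Interpretability** (`bcrlm.interpretability`) — per-residue
   attention-received scores with paratope-enrichment statistics and
   layer trajectories; integrated gradients with a completeness audit;
   in-silico saturation mutagenesis with the decrease-frequency fold
   statistic.

## The model in brief

Each unpaired chain is encoded with its germline and isotype metadata
and corrupted with BERT-style masking. For a batch *B* the MLM loss is

```
L_mlm = −(1/|B|) Σ_{S∈B} Σ_{i∈M} log P(s_i | S\M)
```

Sequences of the same B-cell subtype are treated as positive pairs in a
supervised InfoNCE loss over cosine similarities of [CLS] embeddings
h_i with temperature τ:

```
L_cl(i) = −(1/|P(i)|) Σ_{p∈P(i)} log [ exp(sim(h_i,h_p)/τ) / Σ_{a≠i} exp(sim(h_i,h_a)/τ) ]
```

and the total objective is the convex combination
`L = (1 − w_cl)·L_mlm + w_cl·L_cl`. Class-balanced sampling counters
the natural dominance of naive B cells so that functionally mature
receptors contribute equally to the contrastive geometry.

## Worked example

The bundled demo config simulates a three-subtype repertoire with fully
planted CDR3 motifs, curates it, pretrains a tiny 2-layer encoder with
`w_cl = 0.5` for 300 steps, evaluates the embeddings, and runs the
attribution analyses (about 40 s on one CPU):

```bash
bcrlm run --config configs/demo.yaml
cat runs/demo/metrics.json
```

```json
{
  "embedding": {
    "ari": 1.0,
    "nmi": 1.0,
    "silhouette": 0.9113981232954601
  },
  "subtype_classification": {
    "precision": 1.0, "recall": 1.0, "f1": 1.0, "mcc": 1.0, ...
  }
}
```

Held-out [CLS] embeddings cluster perfectly by subtype (ARI/NMI = 1,
silhouette 0.91), and the linear subtype probe is error-free — the
contrastive term has recovered the planted phenotype signal. The
`explain.json` artifact shows the causal side: for the first record,
substitutions at top integrated-gradient positions decreased the
predicted-subtype probability **15×** more frequently than matched
random-position substitutions (`"fold_change": 15.0`).

The same stages are available piecewise:

```bash
bcrlm simulate repertoire --n 1000 --seed 1 --out data/
bcrlm curate --in data/repertoire.tsv --identity 0.95 --ratios 90,5,5 --seed 1 --out curated/
bcrlm pretrain --config configs/demo.yaml
bcrlm eval embeddings --checkpoint runs/demo/checkpoint.npz --vocab runs/demo/vocab.tsv \
      --data runs/demo/test.tsv --labels subtype --mode hcdr3
bcrlm explain ig --checkpoint runs/demo/checkpoint.npz --vocab runs/demo/vocab.tsv \
      --data runs/demo/test.tsv --mode hcdr3 --out ig.tsv
```

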