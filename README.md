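# netimage

Image-like network representations of genes for disease-gene
classification.

Each vertex of a weighted biological network is converted into a small
`m x m` matrix: the adjacency block of a node-induced sub-network over the
vertex and `m - 1` selected neighbors, plus a diagonal "environment" matrix
carrying the neighbors' disease-class values. Neighbors are drawn from a
window around the vertex in the leaf order of an agglomerative clustering of
row-vector similarities, so hubs and leaves of a scale-free network both
receive information of comparable scale. The resulting images feed a small
CNN (implemented directly on numpy) or classical learners (SVMs, trees,
naive Bayes) for binary target-class gene identification, with support for
multi-network fusion and a no-environment baseline.

## Layout

- `src/netimage/network.py` — `GeneNetwork`, `DiseaseAnnotation` domain types
- `src/netimage/io.py` — edge-list / annotation TSV readers and writers,
  multi-view gene-universe harmonization
- `src/netimage/representation.py` — similarity, clustering leaf order,
  receptive-field neighbor selection, sub-adjacency + class-diagonal images,
  baseline and multi-view fusion
- `src/netimage/classifiers.py` — balanced dataset assembly, flattening,
  the six classifiers, permutation augmentation
- `src/netimage/cnn.py` — the numpy CNN (conv-pool-conv-pool-dense-sigmoid)
- `src/netimage/evaluation.py` — confusion matrices, ROC/AUC, least-error
  threshold
- `src/netimage/synthetic.py` — scale-free planted-partition generator with
  multi-tag annotations and correlated views
- `src/netimage/pipeline.py` — end-to-end experiments (masked
  representation, cross-validated scoring)
- `src/netimage/benchmarks.py` — preset recovery/ablation/fusion/null
  experiments used by the acceptance checks

## CLI

```sh
# generate a synthetic network + annotations
netimage synth --n 500 --classes 8 --seed 1 --out-dir data/

# represent every gene as a 21x21 image
netimage represent --network data/view0.tsv --annotations data/annotations.tsv \
    --classes 8 --target 8 --m 21 --out data/rep

# train a classifier and score the held-out split
netimage train --data data/rep --annotations data/annotations.tsv \
    --classes 8 --target 8 --kind cnn --out-dir run/

# metrics, ROC table, confusion matrix
netimage evaluate --scores run/scores.tsv --out-dir run/eval
```

Edge lists are TSV (`gene_a<TAB>gene_b[<TAB>weight]`, `#` comments);
annotations are TSV (`gene<TAB>code[,code...]`, integer class codes in
`1..K`, `0` reserved for "no tag").

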