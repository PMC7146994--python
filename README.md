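# smilesgen

Character-level recurrent SMILES generators trained under an independent
online statistical-quality-control (SQC) examiner, plus the evaluation
suite used to compare generator architectures: validity / uniqueness /
training-recall rates, a 12-property distribution panel matched by
continuous Tanimoto and Jensen–Shannon divergence, and chunked novelty
/ efficiency analysis.

The recurrent backend (LSTM / GRU, bidirectional layers, parallel
encoder branches with concatenate / average / learnable-average
merging, BPTT, Adam) is implemented in pure NumPy, so the package has
no deep-learning framework dependency. Chemistry is delegated to RDKit.

## Components

| module                 | what it does |
|------------------------|--------------|
| `smilesgen.corpus`     | organic filtering, stereo removal, Cl/Br/[nH] → L/R/A substitution, de-duplication, randomized-SMILES augmentation, vocabulary inventory, sliding-window encoding |
| `smilesgen.nn`         | NumPy layers: LSTM, GRU, bidirectional wrapper, dropout, dense softmax, branch merges, Adam |
| `smilesgen.model`      | the four architecture families (A: uni 2-layer, B: bi 2-layer, C: shared embedding + k parallel encoders, D: k parallel stacks), training loop, multinomial sampling |
| `smilesgen.examiner`   | binomial CI control margins (normal approximation + finite population correction; exact quantiles optional), the patience/streak stopping automaton, earliest-stable-model selection |
| `smilesgen.metrics`    | validity verdicts (InChIKey-based, with ring/branch mismatch classification), summary rates, 12-property panel, histogram Tanimoto / JSD, chunked novelty and efficiency |
| `smilesgen.fixtures`   | valid-by-construction synthetic SMILES corpora, guaranteed-invalid mutants, scripted mock generators |
| `smilesgen.cli`        | `smilesgen fixtures / prep / train / generate / evaluate` |

## CLI walkthrough

```bash
# 1. a synthetic corpus (or bring your own one-SMILES-per-line file)
smilesgen fixtures --n 2000 --hac-min 5 --hac-max 12 --seed 0 --out raw.txt

# 2. clean + substitute (+ optional randomized augmentation)
smilesgen prep --input raw.txt --out-dir corpus/ --augment 2 --seed 42

# 3. train under the examiner (YAML config: architecture, window, SQC)
smilesgen train --config run.yaml --seed 0 --out-dir run/
# exit code 0 = examiner converged, 2 = stopped at max_epochs unstable

# 4. sample from the selected (earliest stable) model
smilesgen generate --run-dir run/ --n 2000 --seed 1 \
    --vocabulary corpus/vocabulary.json --out generated.txt

# 5. evaluate (several --generated files are treated as replicates)
smilesgen evaluate --generated generated.txt --training corpus/corpus.txt \
    --chunk-size 10000 --out-dir eval/
```

A minimal `run.yaml`:

```yaml
corpus_dir: corpus/
window_length: 20
step: 1
max_epochs: 30
learning_rate: 0.002
architecture:
  family: C            # A | B | C | D
  unit: LSTM           # LSTM | GRU
  embedding_size: 32
  encoding_size: 32
  branch_count: 2
  merge_mode: concatenate   # concatenate | average | learnable_average
sqc:
  target_rate: 0.5
  sample_size: 300
  patience: 3
```

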