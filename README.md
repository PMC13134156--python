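# atomgps

Switchable local/global atomistic graph learning: a compact, reproducible
testbed for the question *when does global attention help molecular property
prediction beyond well-tuned message passing?*

Graph neural networks for chemistry increasingly bolt transformer-style
global attention onto local message-passing layers, motivated by long-range
interactions (electrostatics, induction, dispersion) whose influence decays
as inverse powers of distance and therefore persists far beyond bonded or
radius-cutoff neighborhoods — while deep message passing suffers
over-smoothing and over-squashing.  Whether the attention is actually worth
its quadratic cost is hard to judge from heterogeneous implementations.
`atomgps` isolates the question with four model classes sharing one code
path, one training pipeline, and one conditional hyperparameter space:

| scheme | local messages | encoders | global attention |
|--------|----------------|----------|------------------|
| S1     | yes            | –        | –                |
| S2     | yes            | yes      | –                |
| S3     | yes            | –        | yes              |
| S4     | yes            | yes      | yes              |

The hybrid layers fuse both branches additively,
`X' = MLP(GNN(X, E) + MHA(X))`, with attention computed strictly within
each graph of a batch.  The encoder suite supplies per-atom element
descriptors (15 channels), node/edge topological measures (9/4 channels),
and Laplacian eigenvector positional encodings (the d_l smallest nonzero
eigenpairs of L = D − A), all standardized on the training split; samples
with invalid encodings are discarded with a reason code.  A synthetic-data
generator produces molecular graphs whose targets have *controlled
locality* — in particular a beyond-cutoff dispersion energy
`y = Σ_{u<v, r ≥ r_c} −√(C6_u C6_v) / r_uv⁶` that no 1-hop local model can
see — so the central claim is testable offline on one CPU.  All learnable
layers run on a small built-in reverse-mode autodiff engine (numpy), with
Adam, early stopping, per-epoch checkpointing, and uniform random search
over the conditional hyperparameter grids.

## Worked example

Train a plain MPNN (S1) and a fused local/global model (S4), single layer
each, on the long-range dispersion task:

```python
from atomgps.encoders import filter_invalid
from atomgps.graph_core import DatasetSplit, make_split
from atomgps.model import (AtomGraphModel, ModelConfig, PreparedDataset,
                           TaskSpec, parameter_count)
from atomgps.synthetic import GenSpec, generate_dataset
from atomgps.training import train, evaluate

spec = GenSpec(n_graphs=100, n_atoms=(16, 24), palette=(1, 6, 7, 8),
               r_c=3.0, target="dispersion", dispersion_mode="beyond_cutoff",
               noise_sd=0.024, seed=0)
graphs = generate_dataset(spec)
kept, _, log = filter_invalid(graphs, d_l=4)
split = DatasetSplit(graphs=kept, split=make_split(len(kept), seed=0))

for scheme in ("S1", "S4"):
    config = ModelConfig.for_scheme(
        scheme, mpnn_type="edgecond-sum", num_conv_layers=1,
        hidden_dim=16, edge_embed_dim=0 if scheme == "S1" else 8,
        lpe_dim=4, learning_rate=3e-3, tasks=[TaskSpec("dispersion")])
    dataset = PreparedDataset(split, config)
    model = AtomGraphModel(config, dataset.layout(), seed=0)
    record = train(model, dataset, epochs=150, patience=30, seed=0)
    mae = evaluate(model, dataset, "val")["dispersion"]["mae"]
    print(f"{scheme}: {parameter_count(model):5d} parameters, "
          f"stopped at epoch {record.stopped_epoch}, val MAE {mae:.3f}")
```

Output:

```
S1:   881 parameters, stopped at epoch 49, val MAE 0.721
S4:  3545 parameters, stopped at epoch 36, val MAE 0.345
```

The target is standardized, so an MAE of 0.72 means the plain local model
explains little beyond the mean — the signal lives in atom pairs farther
apart than its 3 Å receptive field — while the fused model halves the
error.  On the complementary *local* target family (a 1-hop-computable
atomic sum), encoder-augmented message passing (S2) matches or beats the
hybrids at the same parameter budget; `atomgps.locality` runs that full
budget-matched comparison across three seeds.

## Command line

```sh
atomgps generate --spec spec.yaml --out data.jsonl   # synthetic datasets
atomgps encode   --data data.jsonl --out enc.jsonl --lpe-dim 4
atomgps train    --config model.yaml --data data.jsonl --out run/
atomgps hpo      --config flags.yaml --data data.jsonl --out run/ --trials 10
atomgps evaluate --checkpoint run/final/best.npz --data data.jsonl
atomgps convert  molecule.xyz molecule.jsonl
```

Datasets use a line-delimited JSON container (one graph per line: atomic
numbers, optional coordinates and features, undirected edge list, targets);
every run writes a JSON manifest with the config snapshot, seeds, data
hash, split sizes, discard log, and metrics.

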