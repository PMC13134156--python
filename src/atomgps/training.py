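"""Training loop and conditional random hyperparameter search.

The search space branches on three flags: coordinate availability
(``has_pos``), global attention (``global_attn_engine``) and encoder usage
(``use_encodings``).  Attention-on hidden widths are restricted to multiples
of lcm(2, 4, 8) = 8 so every width is compatible with every admissible head
count; the sampler additionally enforces hidden_dim % heads == 0 (vacuously
true on these grids).

Each trial trains with Adam, per-epoch checkpointing, and early stopping
after ``patience`` consecutive epochs without validation improvement; the
best configuration h* = argmin over trials of the best validation loss is
then retrained from a fresh initialization with an extended budget, and test
metrics are computed exactly once on the held-out split.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam
from .model import (AtomGraphModel, ModelConfig, PreparedDataset, metrics,
                    multitask_loss, save_checkpoint, task_losses)

__all__ = [
    "SearchSpace",
    "DEFAULT_SPACE",
    "sample_config",
    "TrialRecord",
    "train",
    "run_hpo",
    "retrain",
    "evaluate",
]


@dataclass
class SearchSpace:
    """Conditional hyperparameter grids.

    ``hidden_dim`` is an inclusive integer range when attention is off and an
    explicit grid when attention is on.
    """

    num_conv_layers_no_attn: tuple = (1, 2, 3, 4, 5, 6)
    num_conv_layers_attn: tuple = (1, 2, 3)
    heads_no_attn: tuple = (0,)
    heads_attn: tuple = (2, 4, 8)
    hidden_range_no_attn_no_enc: tuple = (4, 32)
    hidden_range_no_attn_enc: tuple = (16, 64)
    hidden_grid_attn_no_enc: tuple = (8, 16, 24, 32, 40, 48)
    hidden_grid_attn_enc: tuple = (16, 24, 32, 40, 48, 56, 64)
    edge_no_attn_no_enc: tuple = (0,)
    edge_no_attn_enc: tuple = (0, 4, 5, 6, 7, 8, 9, 10, 11, 12)
    edge_attn_no_enc: tuple = (0, 4, 5, 6, 8, 9, 10, 11, 12)
    edge_attn_enc: tuple = (0, 4, 5, 6, 7, 8, 9, 10, 11, 12)
    mpnn_types_pos: tuple = ("geometric-mpnn", "edgecond-sum",
                             "edgecond-mean", "neighbor-attention")
    mpnn_types_no_pos: tuple = ("edgecond-sum", "edgecond-mean",
                                "neighbor-attention")
    learning_rates: tuple = (1e-2, 3e-3, 1e-3, 3e-4)

    def grids(self, has_pos: bool, global_attn_engine: bool,
              use_encodings: bool) -> dict:
        if global_attn_engine:
            hidden = self.hidden_grid_attn_enc if use_encodings \
                else self.hidden_grid_attn_no_enc
            edge = self.edge_attn_enc if use_encodings else self.edge_attn_no_enc
            layers, heads = self.num_conv_layers_attn, self.heads_attn
        else:
            lo, hi = self.hidden_range_no_attn_enc if use_encodings \
                else self.hidden_range_no_attn_no_enc
            hidden = tuple(range(lo, hi + 1))
            edge = self.edge_no_attn_enc if use_encodings \
                else self.edge_no_attn_no_enc
            layers, heads = self.num_conv_layers_no_attn, self.heads_no_attn
        mpnn = self.mpnn_types_pos if has_pos else self.mpnn_types_no_pos
        return {"num_conv_layers": layers, "global_attn_heads": heads,
                "hidden_dim": hidden, "edge_embed_dim": edge,
                "mpnn_type": mpnn, "learning_rate": self.learning_rates}


DEFAULT_SPACE = SearchSpace()


def sample_config(space: SearchSpace, has_pos: bool, global_attn_engine: bool,
                  use_encodings: bool, rng: np.random.Generator,
                  **fixed) -> ModelConfig:
    """Uniform draw from the conditioned grids.

    Any (hidden_dim, heads) pair violating divisibility is rejected and
    redrawn; by construction of the grids none exists.
    """
    grids = space.grids(has_pos, global_attn_engine, use_encodings)
    if any(len(v) == 0 for v in grids.values()):
        raise ValueError("empty conditioned grid")
    while True:
        draw = {k: v[rng.integers(len(v))] for k, v in grids.items()}
        if not global_attn_engine or \
                draw["hidden_dim"] % draw["global_attn_heads"] == 0:
            break
    kwargs = {
        "mpnn_type": str(draw["mpnn_type"]),
        "num_conv_layers": int(draw["num_conv_layers"]),
        "hidden_dim": int(draw["hidden_dim"]),
        "edge_embed_dim": int(draw["edge_embed_dim"]),
        "global_attn_engine": bool(global_attn_engine),
        "use_encodings": bool(use_encodings),
        "global_attn_heads": int(draw["global_attn_heads"]),
        "has_pos": bool(has_pos),
        "learning_rate": float(draw["learning_rate"]),
    }
    kwargs.update(fixed)  # pinned values override the draw
    return ModelConfig(**kwargs)


@dataclass
class TrialRecord:
    """One training trial: config, loss curves, best epoch, checkpoint."""

    config: ModelConfig
    train_losses: list = field(default_factory=list)
    val_losses: list = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = np.inf
    checkpoint_path: str | None = None
    seed: int = 0
    stopped_epoch: int = 0


def _epoch_loss(model: AtomGraphModel, dataset: PreparedDataset, part: str,
                batch_size: int, rng=None, optimizer: Adam | None = None) -> float:
    """Mean multitask loss over minibatches; steps the optimizer if given."""
    weights = {t.name: t.weight for t in model.config.tasks}
    total, count = 0.0, 0
    for batch in dataset.minibatches(part, batch_size, rng):
        preds = model(batch)
        losses = task_losses(preds, batch, model.config.tasks)
        loss = multitask_loss(losses, weights)
        if not np.isfinite(loss.item()):
            raise FloatingPointError(
                f"non-finite {part} loss at step {count}; aborting trial")
        if optimizer is not None:
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
        total += loss.item() * batch.num_graphs
        count += batch.num_graphs
    return total / max(count, 1)


def train(model: AtomGraphModel, dataset: PreparedDataset, epochs: int,
          patience: int, seed: int = 0, batch_size: int = 32,
          checkpoint_dir: str | None = None) -> TrialRecord:
    """Minimize the weighted multitask training loss with early stopping.

    A checkpoint is written every epoch when ``checkpoint_dir`` is given and
    the best-validation epoch's checkpoint is flagged; training stops once
    ``patience`` consecutive epochs fail to improve the best validation loss.
    """
    if epochs < 1 or patience < 1:
        raise ValueError("epochs and patience must be >= 1")
    rng = np.random.default_rng(seed)
    opt = Adam(model.parameters(), lr=model.config.learning_rate)
    rec = TrialRecord(config=model.config, seed=seed)
    since_best = 0
    for epoch in range(1, epochs + 1):
        tr = _epoch_loss(model, dataset, "train", batch_size, rng, opt)
        va = _epoch_loss(model, dataset, "val", batch_size)
        rec.train_losses.append(tr)
        rec.val_losses.append(va)
        if checkpoint_dir is not None:
            os.makedirs(checkpoint_dir, exist_ok=True)
            path = os.path.join(checkpoint_dir, f"epoch_{epoch:04d}.npz")
            save_checkpoint(model, path, extra={"epoch": epoch,
                                                "val_loss": va})
        if va < rec.best_val_loss:
            rec.best_val_loss = va
            rec.best_epoch = epoch
            since_best = 0
            if checkpoint_dir is not None:
                best = os.path.join(checkpoint_dir, "best.npz")
                save_checkpoint(model, best, extra={"epoch": epoch,
                                                    "val_loss": va})
                rec.checkpoint_path = best
        else:
            since_best += 1
            if since_best >= patience:
                break
        rec.stopped_epoch = epoch
    rec.stopped_epoch = len(rec.train_losses)
    return rec


def run_hpo(dataset_builder, flags: dict, n_trials: int, epochs: int,
            patience: int, seed: int = 0, space: SearchSpace = DEFAULT_SPACE,
            batch_size: int = 32, work_dir: str | None = None,
            fixed: dict | None = None):
    """Random search: h* = argmin over sampled configs of best val loss.

    ``dataset_builder(config)`` must return a PreparedDataset for the trial's
    config (encodings depend on the sampled flags).  Ties resolve to the
    earliest trial.  Returns (best TrialRecord, leaderboard sorted ascending).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    records: list[TrialRecord] = []
    for trial in range(n_trials):
        config = sample_config(space, rng=rng, **flags, **(fixed or {}))
        trial_seed = int(rng.integers(2 ** 31 - 1))
        dataset = dataset_builder(config)
        model = AtomGraphModel(config, dataset.layout(), seed=trial_seed)
        ckpt = os.path.join(work_dir, f"trial_{trial:03d}") \
            if work_dir is not None else None
        try:
            rec = train(model, dataset, epochs, patience, seed=trial_seed,
                        batch_size=batch_size, checkpoint_dir=ckpt)
        except FloatingPointError:
            continue
        records.append(rec)
    if not records:
        raise RuntimeError("all HPO trials failed")
    leaderboard = sorted(records, key=lambda r: r.best_val_loss)
    best = min(records, key=lambda r: r.best_val_loss)  # earliest wins ties
    return best, leaderboard


def evaluate(model: AtomGraphModel, dataset: PreparedDataset,
             part: str = "test") -> dict:
    """Per-task metrics on one split (standardized scale for regression)."""
    batch = dataset.batch(part)
    preds = model(batch)
    out = {}
    for task in model.config.tasks:
        out[task.name] = metrics(preds[task.name].data,
                                 batch.targets[task.name], task.kind)
    return out


def retrain(best_config: ModelConfig, dataset: PreparedDataset,
            epochs: int, patience: int, seed: int = 0, batch_size: int = 32,
            checkpoint_dir: str | None = None):
    """Fresh initialization with h*, extended budget, one test evaluation."""
    model = AtomGraphModel(best_config, dataset.layout(), seed=seed)
    rec = train(model, dataset, epochs, patience, seed=seed,
                batch_size=batch_size, checkpoint_dir=checkpoint_dir)
    test_metrics = evaluate(model, dataset, "test")
    return model, rec, test_metrics


def hpo_cost_epochs(n_trials: int, epochs: int) -> int:
    """Upper-bound accounting of the HPO budget in epoch units."""
    return n_trials * epochs


def record_to_manifest(rec: TrialRecord) -> dict:
    from dataclasses import asdict

    cfg = asdict(rec.config)
    return {"config": cfg, "seed": rec.seed, "best_epoch": rec.best_epoch,
            "best_val_loss": rec.best_val_loss,
            "stopped_epoch": rec.stopped_epoch,
            "train_losses": rec.train_losses, "val_losses": rec.val_losses,
            "checkpoint": rec.checkpoint_path}
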