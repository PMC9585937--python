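"""Seeded training loop and evaluation pipeline.

Training minimizes binary cross-entropy plus soft Dice with Adam
(defaults: learning rate 1e-4, weight decay 1e-8, batch 16, 300 epochs —
the full-scale settings; desk-scale runs override them).  Model selection
keeps the epoch with the best validation Dice.  Evaluation thresholds
probability maps at 0.5 and reports per-image Dice / ASSD / mIoU with
mean +/- standard deviation aggregates.
"""

from __future__ import annotations

import csv
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import metrics as M
from .arch import NNet, NNetSpec, assemble_nnet, default_nnet_spec
from .data import SegSample, SynthConfig, generate_synthetic
from .design import CascadeSpec
from .nn import Adam, Tensor
from .nn import functional as F

__all__ = [
    "TrainConfig",
    "TrainResult",
    "TrainingDiverged",
    "EvalReport",
    "segmentation_loss",
    "train",
    "evaluate",
    "evaluate_masks",
    "ablation_grid",
    "spec_to_dict",
    "spec_from_dict",
    "save_checkpoint",
    "load_checkpoint",
    "SMOKE_BENCHMARK",
    "smoke_config",
    "smoke_data",
]


class TrainingDiverged(RuntimeError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    weight_decay: float = 1e-8
    batch_size: int = 16
    epochs: int = 300
    seed: int = 0
    device: str = "cpu"  # the numpy engine is CPU-only; field kept for config compatibility
    checkpoint_dir: str | None = None

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise ValueError("rates must be positive (weight decay non-negative)")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch size and epochs must be positive")


@dataclass
class TrainResult:
    history: list[dict]
    best_val_dice: float
    best_epoch: int
    best_state: dict[str, np.ndarray]
    model: NNet
    checkpoint_path: str | None = None


def segmentation_loss(logits: Tensor, target: np.ndarray) -> Tensor:
    """BCE-with-logits plus soft Dice on the sigmoid probabilities (eps 1e-6)."""
    bce = F.bce_with_logits(logits, target)
    p = logits.sigmoid()
    t = np.asarray(target, dtype=logits.dtype)
    num = 2.0 * (p * t).sum() + M.SOFT_DICE_EPS
    den = p.sum() + float(t.sum()) + M.SOFT_DICE_EPS
    soft_dice = 1.0 - num / den
    return bce + soft_dice


def _to_batch(samples: Sequence[SegSample]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([s.image for s in samples]).astype(np.float32) / 255.0
    x = np.ascontiguousarray(x.transpose(0, 3, 1, 2))
    y = np.stack([s.mask for s in samples]).astype(np.float32)[:, None]
    return x, y


def _predict_probs(model: NNet, samples: Sequence[SegSample], batch_size: int = 8) -> np.ndarray:
    model.eval()
    outs = []
    for i in range(0, len(samples), batch_size):
        x, _ = _to_batch(samples[i : i + batch_size])
        outs.append(model(Tensor(x)).data)
    return np.concatenate(outs)[:, 0]


def train(
    spec: NNetSpec,
    train_set: Sequence[SegSample],
    val_set: Sequence[SegSample],
    config: TrainConfig,
) -> TrainResult:
    """Train an N-Net described by ``spec``; fully reproducible given the seed.

    Logs per-epoch mean train loss and validation Dice, retains the
    best-validation-Dice parameters, and aborts with :class:`TrainingDiverged`
    (reporting the epoch) if the loss goes non-finite.
    """
    if not train_set:
        raise ValueError("training set is empty")
    model = assemble_nnet(spec, seed=config.seed)
    opt = Adam(model.parameters(), lr=config.learning_rate, weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed)
    history: list[dict] = []
    best = (-1.0, -1, None)  # (val dice, epoch, state)
    for epoch in range(config.epochs):
        model.train()
        order = rng.permutation(len(train_set))
        losses = []
        t0 = time.perf_counter()
        for start in range(0, len(order), config.batch_size):
            batch = [train_set[i] for i in order[start : start + config.batch_size]]
            x, y = _to_batch(batch)
            logits = model.forward_logits(Tensor(x))
            loss = segmentation_loss(logits, y)
            if not np.isfinite(loss.data):
                raise TrainingDiverged(f"non-finite loss at epoch {epoch + 1}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        val_dice = float("nan")
        if val_set:
            probs = _predict_probs(model, val_set, batch_size=config.batch_size)
            val_dice = float(
                np.mean([M.dice(p >= 0.5, s.mask) for p, s in zip(probs, val_set)])
            )
            if val_dice > best[0]:
                best = (val_dice, epoch + 1, model.state_dict())
        history.append(
            {
                "epoch": epoch + 1,
                "train_loss": float(np.mean(losses)),
                "val_dice": val_dice,
                "seconds": time.perf_counter() - t0,
            }
        )
    if best[2] is None:  # no validation set: keep final weights
        best = (float("nan"), config.epochs, model.state_dict())
    model.load_state_dict(best[2])
    path = None
    if config.checkpoint_dir is not None:
        ckpt_dir = Path(config.checkpoint_dir)
        ckpt_dir.mkdir(parents=True, exist_ok=True)
        path = str(ckpt_dir / "best.npz")
        save_checkpoint(path, spec, best[2], meta={"val_dice": best[0], "epoch": best[1]})
    return TrainResult(
        history=history,
        best_val_dice=best[0],
        best_epoch=best[1],
        best_state=best[2],
        model=model,
        checkpoint_path=path,
    )


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class EvalReport:
    """Per-image Dice/ASSD/mIoU records plus mean/std aggregates."""

    records: list[dict]
    aggregates: dict[str, dict[str, float]]
    config_fingerprint: str = ""

    def to_json(self) -> str:
        return json.dumps(
            {
                "records": self.records,
                "aggregates": self.aggregates,
                "config_fingerprint": self.config_fingerprint,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "EvalReport":
        d = json.loads(text)
        return cls(d["records"], d["aggregates"], d.get("config_fingerprint", ""))

    def write_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["id", "dice", "assd", "miou"])
            writer.writeheader()
            writer.writerows(self.records)


def evaluate_masks(
    pairs: Sequence[tuple[str, np.ndarray, np.ndarray]], fingerprint: str = ""
) -> EvalReport:
    """Score (id, predicted mask, truth mask) triples; ASSD uses the worst-case
    image-diagonal sentinel when a mask is empty (documented, never silent 0)."""
    if not pairs:
        raise ValueError("nothing to evaluate")
    records = []
    for sample_id, pred, truth in pairs:
        records.append(
            {
                "id": sample_id,
                "dice": M.dice(pred, truth),
                "assd": M.assd(pred, truth, empty="worst"),
                "miou": M.miou(pred, truth),
            }
        )
    aggregates = {}
    for key in ("dice", "assd", "miou"):
        s = M.summarize(r[key] for r in records)
        aggregates[key] = {"mean": s.mean, "std": s.std}
    return EvalReport(records=records, aggregates=aggregates, config_fingerprint=fingerprint)


def evaluate(model_or_ckpt, test_set: Sequence[SegSample], batch_size: int = 8) -> EvalReport:
    """Threshold the model's probability maps at 0.5 and score against truth."""
    if not test_set:
        raise ValueError("test set is empty")
    if isinstance(model_or_ckpt, (str, Path)):
        spec, state, _ = load_checkpoint(model_or_ckpt)
        model = assemble_nnet(spec)
        model.load_state_dict(state)
    else:
        model = model_or_ckpt
    probs = _predict_probs(model, test_set, batch_size=batch_size)
    pairs = [
        (s.id, (p >= 0.5).astype(np.uint8), s.mask) for p, s in zip(probs, test_set)
    ]
    return evaluate_masks(pairs, fingerprint=f"n={len(test_set)}")


def ablation_grid(
    block_subsets: Sequence[Sequence[int]],
    data: tuple[Sequence[SegSample], Sequence[SegSample], Sequence[SegSample]],
    config: TrainConfig,
    base_spec: NNetSpec | None = None,
) -> dict[tuple[int, ...], EvalReport]:
    """Train and evaluate one model per GHDC-block subset, same seed/schedule.

    The empty subset is the plain-skip baseline; {1,2,3,4} is the full N-Net.
    """
    train_set, val_set, test_set = data
    if base_spec is None:
        base_spec = default_nnet_spec()
    results: dict[tuple[int, ...], EvalReport] = {}
    for subset in block_subsets:
        key = tuple(sorted(subset))
        if not set(key) <= {1, 2, 3, 4}:
            raise ValueError(f"block subset {subset} not within {{1,2,3,4}}")
        spec = NNetSpec(
            encoder=base_spec.encoder,
            ghdc_blocks=base_spec.ghdc_blocks,
            decoder=base_spec.decoder,
            input_size=base_spec.input_size,
            active_blocks=frozenset(key),
        )
        result = train(spec, train_set, val_set, config)
        results[key] = evaluate(result.model, test_set, batch_size=config.batch_size)
    return results


# ---------------------------------------------------------------------------
# checkpoints and spec serialization


def spec_to_dict(spec: NNetSpec) -> dict:
    return {
        "encoder": {
            "stem_channels": spec.encoder.stem_channels,
            "growth_rate": spec.encoder.growth_rate,
            "dense_layers": list(spec.encoder.dense_layers),
            "pretrained": spec.encoder.pretrained,
        },
        "ghdc_blocks": [
            {
                "rates": list(b.cascade.rates),
                "kernels": list(b.cascade.kernels),
                "in_channels": b.in_channels,
                "out_channels": b.out_channels,
                "branch_width": b.branch_width,
            }
            for b in spec.ghdc_blocks
        ],
        "decoder": {"out_channels": list(spec.decoder.out_channels)},
        "input_size": list(spec.input_size),
        "active_blocks": sorted(spec.active_blocks),
    }


def spec_from_dict(d: dict) -> NNetSpec:
    from .arch import DecoderSpec, EncoderSpec, GHDCBlockSpec

    return NNetSpec(
        encoder=EncoderSpec(
            stem_channels=d["encoder"]["stem_channels"],
            growth_rate=d["encoder"]["growth_rate"],
            dense_layers=tuple(d["encoder"]["dense_layers"]),
            pretrained=d["encoder"].get("pretrained", False),
        ),
        ghdc_blocks=tuple(
            GHDCBlockSpec(
                cascade=CascadeSpec.from_lists(b["rates"], b["kernels"]),
                in_channels=b["in_channels"],
                out_channels=b["out_channels"],
                branch_width=b["branch_width"],
            )
            for b in d["ghdc_blocks"]
        ),
        decoder=DecoderSpec(out_channels=tuple(d["decoder"]["out_channels"])),
        input_size=tuple(d["input_size"]),
        active_blocks=frozenset(d["active_blocks"]),
    )


def save_checkpoint(path, spec: NNetSpec, state: dict[str, np.ndarray], meta: dict | None = None) -> None:
    payload = {f"state/{k}": v for k, v in state.items()}
    payload["spec_json"] = np.frombuffer(
        json.dumps({"spec": spec_to_dict(spec), "meta": meta or {}}).encode(), dtype=np.uint8
    )
    np.savez(path, **payload)


def load_checkpoint(path) -> tuple[NNetSpec, dict[str, np.ndarray], dict]:
    with np.load(path) as z:
        header = json.loads(bytes(z["spec_json"]).decode())
        state = {k[len("state/"):]: z[k] for k in z.files if k.startswith("state/")}
    return spec_from_dict(header["spec"]), state, header.get("meta", {})


# ---------------------------------------------------------------------------
# the synthetic smoke benchmark (desk-scale stand-in for full training)

#: Desk-scale benchmark conditions: a width-reduced N-Net (width_divisor 8) on
#: 64x64 synthetic lesion images, 150 train / 40 val, batch 8, 10 epochs, Adam
#: 1e-3 (the short-schedule rate; see docs/methods.md), generator seed 7.
#: 64x64 is the smallest input whose encoder taps (16x16 .. 2x2) leave the
#: skip-block receptive fields meaningful.
SMOKE_BENCHMARK = {
    "image_size": (64, 64),
    "width_divisor": 8,
    "n_train": 150,
    "n_val": 40,
    "batch_size": 8,
    "epochs": 10,
    "learning_rate": 1e-3,
    "data_seed": 7,
}


def smoke_config(seed: int) -> TrainConfig:
    bm = SMOKE_BENCHMARK
    return TrainConfig(
        learning_rate=bm["learning_rate"],
        batch_size=bm["batch_size"],
        epochs=bm["epochs"],
        seed=seed,
    )


def smoke_data(
    n_train: int | None = None, n_val: int | None = None, seed: int | None = None
) -> tuple[list[SegSample], list[SegSample]]:
    """Generate the smoke-benchmark train/val synthetic datasets."""
    bm = SMOKE_BENCHMARK
    n_train = bm["n_train"] if n_train is None else n_train
    n_val = bm["n_val"] if n_val is None else n_val
    seed = bm["data_seed"] if seed is None else seed
    h, w = bm["image_size"]
    cfg = SynthConfig(image_size=(h, w), seed=seed)
    all_samples = generate_synthetic(cfg, n_train + n_val)
    return all_samples[:n_train], all_samples[n_train:]
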