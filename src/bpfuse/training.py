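"""Adversarial training loop, dataset splitting, fusion and ablation runs.

One optimization cycle draws a mini-batch, performs ``p`` discriminator
updates (least-squares loss against the joint gradient map as "true" and
the fused image's gradient map as "false"), then one generator update on
the full objective ``L_Gan + lambda1 L_pixel + lambda2 L_grad``.  The
update ratio ``disc_updates == p * gen_updates`` is maintained exactly and
asserted at checkpoint time.

Screening maps, input Laplacians and joint gradient maps depend only on
the input pair, so they are computed once per record and cached.

A single seed drives weight initialization and batch ordering; two runs
with the same config and seed produce bit-identical final weights.

Defaults follow the published training protocol (batch 32, two
discriminator updates per generator update, 300 epochs, Adam); the
desk-scale profile used by the test-suite (64x64 phantoms, 8 base
channels, batch 4) is available via :func:`desk_config`.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import colorspace
from .errors import ConfigurationError, InvalidInputError, TrainingDivergedError
from .gradients import joint_gradient, laplacian
from .losses import (AdversarialLabels, LossWeights, ScreeningMaps,
                     calibrate_weights, screening_maps)
from .losses import _laplacian_tensor
from .metrics import MetricReport, metric_report
from .nn.autograd import Tensor
from .nn.layers import Adam
from .nn.models import (Discriminator, DiscriminatorConfig, Generator,
                        GeneratorConfig)

__all__ = [
    "AblationFlags", "TrainConfig", "FusionRecord", "Checkpoint",
    "split_dataset", "train", "fuse_pair", "evaluate_records",
    "run_ablation", "desk_config",
]


@dataclass(frozen=True)
class AblationFlags:
    use_bpdb: bool = True
    use_cbam: bool = True
    use_pixel_loss: bool = True
    use_grad_loss: bool = True


@dataclass(frozen=True)
class TrainConfig:
    """Everything one training run needs; defaults are the published protocol."""

    batch_size: int = 32
    disc_steps_per_gen: int = 2           # p
    epochs: int = 300                     # M
    steps_per_iteration: int | None = None  # K; None -> ceil(n / batch_size)
    learning_rate: float = 1e-4
    betas: tuple[float, float] = (0.9, 0.999)
    seed: int = 0
    split: tuple[float, float, float] = (0.7, 0.2, 0.1)
    loss_weights: LossWeights = field(default_factory=LossWeights)
    calibrate_loss_weights: bool = False  # rebalance on the first batch
    ablation: AblationFlags = field(default_factory=AblationFlags)
    screening_window: int = 7
    laplacian_kernel: str = "4"
    dtype: str = "float32"                # training precision (float32/float64)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    discriminator: DiscriminatorConfig = field(default_factory=DiscriminatorConfig)

    def __post_init__(self):
        if self.batch_size < 1 or self.disc_steps_per_gen < 1 or self.epochs < 1:
            raise ConfigurationError("batch_size, disc_steps_per_gen and epochs must be >= 1")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ConfigurationError("split fractions must sum to 1")


def desk_config(**overrides) -> TrainConfig:
    """CPU-sized profile: 8 base channels, batch 4, few epochs."""
    base = dict(
        batch_size=4,
        epochs=5,
        generator=GeneratorConfig(base_channels=8),
        discriminator=DiscriminatorConfig(channel_schedule=(8, 16, 32)),
    )
    base.update(overrides)
    return TrainConfig(**base)


@dataclass
class FusionRecord:
    """One co-registered training example."""

    structural: np.ndarray                 # H x W grayscale (MRI/CT)
    companion: np.ndarray                  # H x W gray (CT) or H x W x 3 color
    cached_maps: ScreeningMaps | None = None

    def __post_init__(self):
        s = np.asarray(self.structural, dtype=np.float64)
        c = np.asarray(self.companion, dtype=np.float64)
        if s.ndim != 2:
            raise InvalidInputError("structural image must be 2-D")
        if c.shape[:2] != s.shape:
            raise InvalidInputError(
                f"companion {c.shape[:2]} not co-registered with structural {s.shape}"
            )
        self.structural = s
        self.companion = c

    @property
    def companion_gray(self) -> np.ndarray:
        """The companion's fusion channel: Y for color, identity for gray."""
        if self.companion.ndim == 3:
            return colorspace.rgb_to_ycbcr(self.companion).y
        return self.companion


def split_dataset(records: list, fractions=(0.7, 0.2, 0.1), seed: int = 0):
    """Disjoint, exhaustive, reproducible train/val/test partition.

    Sizes follow the largest-remainder rule, so 10 records at 7:2:1 give
    exactly (7, 2, 1).
    """
    fracs = np.asarray(fractions, dtype=np.float64)
    if fracs.min() < 0 or abs(fracs.sum() - 1.0) > 1e-9:
        raise InvalidInputError("fractions must be non-negative and sum to 1")
    n = len(records)
    n_parts = int(np.count_nonzero(fracs))
    if n < n_parts:
        raise InvalidInputError(f"{n} records cannot fill {n_parts} partitions")
    ideal = fracs * n
    sizes = np.floor(ideal).astype(int)
    remainder = ideal - sizes
    for idx in np.argsort(-remainder)[: n - sizes.sum()]:
        sizes[idx] += 1
    order = np.random.default_rng(seed).permutation(n)
    out, start = [], 0
    for s in sizes:
        out.append([records[j] for j in order[start:start + s]])
        start += s
    return tuple(out)


# ---------------------------------------------------------------------------

def _prepare(record: FusionRecord, cfg: TrainConfig):
    """Cache the static per-pair quantities the loop needs every step."""
    m = record.structural
    i = record.companion_gray
    if record.cached_maps is None:
        record.cached_maps = screening_maps(m, i, cfg.screening_window)
    return {
        "m": m,
        "i": i,
        "maps": record.cached_maps,
        "lap_m": laplacian(m, cfg.laplacian_kernel),
        "lap_i": laplacian(i, cfg.laplacian_kernel),
        "grad2": joint_gradient(m, i, cfg.laplacian_kernel),
    }


@dataclass
class Checkpoint:
    """Trained weights plus everything needed to reproduce the run."""

    generator: Generator
    discriminator: Discriminator
    config: TrainConfig
    seed: int
    loss_log: list[dict]
    gen_updates: int
    disc_updates: int
    val_history: list[dict] = field(default_factory=list)

    def save(self, path) -> None:
        path = Path(path)
        arrays = {f"gen_{k}": a for k, a in enumerate(self.generator.state_arrays())}
        arrays |= {f"disc_{k}": a for k, a in enumerate(self.discriminator.state_arrays())}
        meta = {
            "config": _config_to_dict(self.config),
            "seed": self.seed,
            "gen_updates": self.gen_updates,
            "disc_updates": self.disc_updates,
            "loss_log": self.loss_log,
            "val_history": self.val_history,
        }
        arrays["meta_json"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8
        )
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path) -> "Checkpoint":
        with np.load(Path(path)) as z:
            meta = json.loads(bytes(z["meta_json"].tobytes()).decode())
            cfg = _config_from_dict(meta["config"])
            gen, disc = _build_models(cfg)
            gen_arrays = [z[f"gen_{k}"] for k in range(len(gen.parameters()))]
            disc_arrays = [z[f"disc_{k}"] for k in range(len(disc.parameters()))]
        gen.load_state_arrays(gen_arrays)
        disc.load_state_arrays(disc_arrays)
        return cls(generator=gen, discriminator=disc, config=cfg,
                   seed=meta["seed"], loss_log=meta["loss_log"],
                   gen_updates=meta["gen_updates"],
                   disc_updates=meta["disc_updates"],
                   val_history=meta.get("val_history", []))

    def write_loss_csv(self, path) -> None:
        cols = ["step", "l_gan", "l_pixel", "l_grad", "l_total", "l_d"]
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=cols)
            writer.writeheader()
            writer.writerows(self.loss_log)


def _config_to_dict(cfg: TrainConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return d


def _config_from_dict(d: dict) -> TrainConfig:
    d = dict(d)
    d["loss_weights"] = LossWeights(**d["loss_weights"])
    d["ablation"] = AblationFlags(**d["ablation"])
    d["generator"] = GeneratorConfig(**d["generator"])
    disc = dict(d["discriminator"])
    disc["channel_schedule"] = tuple(disc["channel_schedule"])
    d["discriminator"] = DiscriminatorConfig(**disc)
    d["betas"] = tuple(d["betas"])
    d["split"] = tuple(d["split"])
    return TrainConfig(**d)


def _build_models(cfg: TrainConfig) -> tuple[Generator, Discriminator]:
    rng = np.random.default_rng(cfg.seed)
    gen_cfg = replace(cfg.generator,
                      use_bpdb=cfg.ablation.use_bpdb,
                      use_cbam=cfg.ablation.use_cbam)
    return Generator(gen_cfg, rng=rng), Discriminator(cfg.discriminator, rng=rng)


def train(cfg: TrainConfig, train_set: list, val_set: list | None = None,
          *, log_path=None, progress: bool = False) -> Checkpoint:
    """Run the alternating adversarial loop and return a checkpoint.

    Raises
    ------
    TrainingDivergedError
        If any logged loss becomes non-finite.
    """
    if not train_set:
        raise InvalidInputError("training set is empty")
    records = [r if isinstance(r, FusionRecord) else FusionRecord(*r)
               for r in train_set]
    prepared = [_prepare(r, cfg) for r in records]
    shape = prepared[0]["m"].shape
    for p_ in prepared:
        if p_["m"].shape != shape:
            raise InvalidInputError("all training images must share one size")

    gen, disc = _build_models(cfg)
    dt = np.dtype(cfg.dtype)
    gen.astype(dt)
    disc.astype(dt)
    disc._u = [u.astype(dt) for u in disc._u]
    opt_g = Adam(gen.parameters(), cfg.learning_rate, cfg.betas)
    opt_d = Adam(disc.parameters(), cfg.learning_rate, cfg.betas)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    labels = AdversarialLabels()
    weights = cfg.loss_weights

    n = len(prepared)
    b = cfg.batch_size
    K = cfg.steps_per_iteration or max(int(np.ceil(n / b)), 1)

    loss_log: list[dict] = []
    val_history: list[dict] = []
    gen_updates = disc_updates = 0
    step = 0

    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        for k in range(K):
            idx = [order[(k * b + j) % n] for j in range(b)]
            batch = [prepared[j] for j in idx]
            mb = np.stack([s["m"] for s in batch])[:, None].astype(dt)
            ib = np.stack([s["i"] for s in batch])[:, None].astype(dt)
            map1 = np.stack([s["maps"].map1 for s in batch])[:, None].astype(dt)
            map2 = np.stack([s["maps"].map2 for s in batch])[:, None].astype(dt)
            lap_m = np.stack([s["lap_m"] for s in batch])[:, None].astype(dt)
            lap_i = np.stack([s["lap_i"] for s in batch])[:, None].astype(dt)
            grad2 = np.stack([s["grad2"] for s in batch])[:, None].astype(dt)

            # --- p discriminator updates against frozen generator output
            fused_const = gen(Tensor(mb), Tensor(ib)).data
            lap_fc = np.stack(
                [laplacian(f[0], cfg.laplacian_kernel) for f in fused_const]
            )[:, None]
            grad1 = np.abs(lap_fc)
            l_d = np.nan
            for _ in range(cfg.disc_steps_per_gen):
                d_false = disc(Tensor(grad1))
                d_true = disc(Tensor(grad2))
                ld_t = (((d_false - labels.a) ** 2).mean()
                        + ((d_true - labels.b) ** 2).mean())
                l_d = ld_t.item()
                if not np.isfinite(l_d):
                    raise TrainingDivergedError(
                        f"discriminator loss non-finite at step {step}"
                    )
                disc.zero_grad()
                ld_t.backward()
                opt_d.step()
                disc_updates += 1

            # --- one generator update on the full objective
            fused = gen(Tensor(mb), Tensor(ib))
            lap_f = _laplacian_tensor(fused, cfg.laplacian_kernel)
            scores = disc(lap_f.abs())
            l_gan = ((scores - labels.c) ** 2).mean()
            l_pix = (map1 * (fused - mb) ** 2 + map2 * (fused - ib) ** 2).mean()
            l_grad = (map1 * (lap_f - lap_m) ** 2
                      + map2 * (lap_f - lap_i) ** 2).mean()
            if cfg.calibrate_loss_weights and step == 0:
                weights = calibrate_weights(
                    l_gan.item(), l_pix.item(), l_grad.item()
                )
            total = l_gan
            if cfg.ablation.use_pixel_loss:
                total = total + weights.lambda1 * l_pix
            if cfg.ablation.use_grad_loss:
                total = total + weights.lambda2 * l_grad
            lt = total.item()
            if not np.isfinite(lt):
                raise TrainingDivergedError(
                    f"generator loss non-finite at step {step}"
                )
            gen.zero_grad()
            disc.zero_grad()   # discard gan-term gradients w.r.t. D
            total.backward()
            opt_g.step()
            gen_updates += 1

            loss_log.append({
                "step": step,
                "l_gan": l_gan.item(),
                "l_pixel": l_pix.item(),
                "l_grad": l_grad.item(),
                "l_total": lt,
                "l_d": l_d,
            })
            step += 1
        if val_set:
            reports = evaluate_records(
                Checkpoint(gen, disc, cfg, cfg.seed, [], gen_updates,
                           disc_updates),
                val_set,
            )
            mean = {k: float(np.mean([r.as_dict()[k] for r in reports]))
                    for k in ("ag", "ei", "q_abf", "q_cv")}
            val_history.append({"epoch": epoch, **mean})
        if progress:
            print(f"epoch {epoch + 1}/{cfg.epochs}  "
                  f"L={loss_log[-1]['l_total']:.4f}  L_D={loss_log[-1]['l_d']:.4f}")

    assert disc_updates == cfg.disc_steps_per_gen * gen_updates
    ckpt = Checkpoint(generator=gen, discriminator=disc, config=cfg,
                      seed=cfg.seed, loss_log=loss_log,
                      gen_updates=gen_updates, disc_updates=disc_updates,
                      val_history=val_history)
    if log_path is not None:
        ckpt.write_loss_csv(log_path)
    return ckpt


def fuse_pair(checkpoint: Checkpoint, structural: np.ndarray,
              companion: np.ndarray) -> np.ndarray:
    """Fuse one pair with a trained (or freshly initialized) checkpoint.

    A 3-channel companion takes the YCbCr route — its luminance is fused
    with the structural image and its chroma passes through untouched; a
    single-channel companion (CT) is fused directly in grayscale.
    """
    structural = np.asarray(structural, dtype=np.float64)
    companion = np.asarray(companion, dtype=np.float64)
    if companion.shape[:2] != structural.shape:
        raise InvalidInputError(
            f"companion {companion.shape[:2]} does not match structural "
            f"{structural.shape}"
        )
    if companion.ndim == 3:
        planes = colorspace.rgb_to_ycbcr(companion)
        fused_y = checkpoint.generator.fuse(structural, planes.y)
        return colorspace.recombine(fused_y, planes)
    return checkpoint.generator.fuse(structural, companion)


def evaluate_records(checkpoint: Checkpoint, records: list) -> list[MetricReport]:
    """Fuse each record and score it with the four quality metrics.

    For color companions the metrics are computed in the fusion domain
    (structural image, companion luminance, fused luminance).
    """
    reports = []
    for r in records:
        rec = r if isinstance(r, FusionRecord) else FusionRecord(*r)
        i = rec.companion_gray
        fused = checkpoint.generator.fuse(rec.structural, i)
        reports.append(metric_report(rec.structural, i, fused))
    return reports


def load_records(data_dir) -> list[FusionRecord]:
    """Load the image pairs listed in a dataset directory's manifest.tsv."""
    from . import io as bio

    data_dir = Path(data_dir)
    manifest = data_dir / "manifest.tsv"
    if not manifest.exists():
        raise InvalidInputError(f"no manifest.tsv in {data_dir}")
    records = []
    for line in manifest.read_text().splitlines():
        if not line or line.startswith("#") or line.startswith("structural\t"):
            continue
        sname, fname = line.split("\t")[:2]
        records.append(FusionRecord(
            structural=bio.load_image(data_dir / sname),
            companion=bio.load_image(data_dir / fname),
        ))
    return records


_MODULE_GRID = [
    ("backbone", AblationFlags(use_bpdb=False, use_cbam=False)),
    ("backbone+bpdb", AblationFlags(use_bpdb=True, use_cbam=False)),
    ("backbone+cbam", AblationFlags(use_bpdb=False, use_cbam=True)),
    ("backbone+bpdb+cbam", AblationFlags(use_bpdb=True, use_cbam=True)),
]

_LOSS_GRID = [
    ("gan+grad", AblationFlags(use_pixel_loss=False)),
    ("gan+pixel", AblationFlags(use_grad_loss=False)),
    ("gan+pixel+grad", AblationFlags()),
]


def run_ablation(cfg: TrainConfig, train_set: list, test_set: list,
                 grid: str = "modules"):
    """Train one model per grid row and report mean test metrics per row.

    ``grid="modules"`` sweeps {backbone, +BPDB, +CBAM, +both} (4 rows);
    ``grid="losses"`` sweeps the loss combinations (3 rows).  Returns a
    pandas DataFrame with one MetricReport per configuration.
    """
    import pandas as pd

    rows = {"modules": _MODULE_GRID, "losses": _LOSS_GRID}.get(grid)
    if rows is None:
        raise InvalidInputError(f"unknown ablation grid {grid!r}")
    out = []
    for name, flags in rows:
        ckpt = train(replace(cfg, ablation=flags), train_set)
        reports = evaluate_records(ckpt, test_set)
        mean = {k: float(np.mean([r.as_dict()[k] for r in reports]))
                for k in ("ag", "ei", "q_abf", "q_cv")}
        out.append({"architecture": name, **mean})
    return pd.DataFrame(out)
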