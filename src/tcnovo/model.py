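"""The fully convolutional spectrum-to-peptide network.

Architecture: five TCN blocks (stacks of paired dilated convolutions with
residual connections) separated by factor-2 max-pooling, so successive
blocks see the spectrum at halved resolution with ~1.5x more channels
([192, 288, 384, 576, 768] at full scale). A bottom-up fusion branch pools
every block's output to the 32 decoder positions, projects each to a common
width and sums them; a learned position embedding plus a small stack of
dilated convolutions over the 32 positions produce the feature tensor.
Meta information (charge one-hot,
scaled precursor m/z, normalized collision energy) passes through a
sigmoid-activated linear layer and is concatenated to every position before
the per-position softmax decoding layer outputs the 32 x 23 probability
matrix. Auxiliary task heads (tryptic flag, length, residue presence,
composition, adjacent pairs) branch off the pooled feature tensor.

The receptive field of one block with kernel size k and n dilation levels
is 1 + 2*(k-1)*(2^n - 1).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .encoding import META_LENGTH, EncodingConfig
from . import nn
from .nn import Tensor


def receptive_field(kernel_size: int, n_dilated_layers: int) -> int:
    """Receptive field (in bins) of one TCN block: 1 + 2(k-1)(2^n - 1)."""
    if kernel_size < 1 or n_dilated_layers < 1:
        raise ValueError("kernel_size and n_dilated_layers must be >= 1")
    return 1 + 2 * (kernel_size - 1) * (2 ** n_dilated_layers - 1)


@dataclass(frozen=True)
class ModelConfig:
    input_length: int = 20480
    n_blocks: int = 5
    layers_per_block: int = 5
    kernel_size: int = 5
    channels: tuple[int, ...] = (192, 288, 384, 576, 768)
    downsample_factor: int = 2
    out_positions: int = 32
    n_classes: int = 23
    scale: float = 1.0
    fusion_channels: int = 256
    meta_channels: int = 32
    head_kernel_size: int = 3
    head_dilations: tuple[int, ...] = (1, 2, 4, 8)
    stem_pool: int = 1  # optional input max-pool before block 1
    dropout: float = 0.0

    def __post_init__(self) -> None:
        if len(self.channels) != self.n_blocks:
            raise ValueError("channels list length must equal n_blocks")
        eff = self.input_length // self.stem_pool
        if self.input_length % self.stem_pool != 0:
            raise ValueError("input_length not divisible by stem_pool")
        if eff % self.downsample_factor ** self.n_blocks != 0:
            raise ValueError(
                f"effective length {eff} not divisible by "
                f"{self.downsample_factor}^{self.n_blocks}")
        for i in range(self.n_blocks):
            if (eff // self.downsample_factor ** i) % self.out_positions:
                raise ValueError(
                    "every block output length must be divisible by out_positions")

    def scaled_channels(self) -> tuple[int, ...]:
        return tuple(max(8, int(round(c * self.scale))) for c in self.channels)

    def scaled_fusion(self) -> int:
        return max(16, int(round(self.fusion_channels * min(1.0, self.scale * 2))))

    @classmethod
    def desk_scale(cls, **overrides) -> "ModelConfig":
        """A 0.1-scale model over the 2048-bin coarse encoding (CPU training)."""
        cfg = cls(input_length=2048, scale=0.1, layers_per_block=2,
                  fusion_channels=320, meta_channels=16, stem_pool=2,
                  head_dilations=(1, 2, 4, 8), dropout=0.0)
        return replace(cfg, **overrides) if overrides else cfg


AUX_TASKS = ("tryptic", "length", "presence", "composition", "pairs")
AUX_SIZES = {"tryptic": 1, "length": 30, "presence": 20,
             "composition": 20, "pairs": 400}


class SpectrumTCN(nn.Module):
    """TCN encoder + fusion + softmax decoder + auxiliary heads."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        ch = cfg.scaled_channels()
        fus = cfg.scaled_fusion()
        self.blocks = []
        n_in = 4
        for c in ch:
            self.blocks.append(nn.TCNBlock(
                n_in, c, cfg.kernel_size, cfg.layers_per_block, rng,
                dropout=cfg.dropout))
            n_in = c
        # fusion branch: per-block 1x1 projection to the common width
        self.fusion_proj = [nn.Linear(c, fus, rng) for c in ch]
        self.pos_embedding = nn.Parameter(
            rng.normal(0.0, 0.1, (cfg.out_positions, fus)))
        # dilated head over the 32 positions: global receptive field
        self.fuse_convs = [
            nn.Conv1d(fus, fus, cfg.head_kernel_size, d, rng)
            for d in cfg.head_dilations]
        self.fuse_norms = [nn.LayerNorm(fus) for _ in cfg.head_dilations]
        self.meta_linear = nn.Linear(META_LENGTH, cfg.meta_channels, rng)
        self.decoder = nn.Linear(fus + cfg.meta_channels, cfg.n_classes, rng)
        self.aux_heads = {
            task: nn.Linear(fus, AUX_SIZES[task], rng) for task in AUX_TASKS
        }

    def forward(self, x: np.ndarray | Tensor, meta: np.ndarray | Tensor
                ) -> dict[str, Tensor]:
        """Map (B, L, 4) input and (B, 10) meta to the probability matrix.

        Returns a dict with ``probs`` (B, 32, 23; per-position softmax),
        ``features`` (B, 32, F) and one logit tensor per auxiliary task.
        """
        cfg = self.cfg
        x = x if isinstance(x, Tensor) else Tensor(x)
        meta = meta if isinstance(meta, Tensor) else Tensor(meta)
        if x.shape[1] != cfg.input_length:
            raise ValueError(
                f"input length {x.shape[1]} != configured {cfg.input_length}")
        h = x if cfg.stem_pool == 1 else nn.maxpool1d(x, cfg.stem_pool)
        fused = None
        for block, proj in zip(self.blocks, self.fusion_proj):
            h = block(h)
            pooled = nn.avgpool_to(h, cfg.out_positions)
            contrib = proj(pooled)
            fused = contrib if fused is None else fused + contrib
            h = nn.maxpool1d(h, cfg.downsample_factor)
        fused = fused + self.pos_embedding
        f = fused
        for conv, norm in zip(self.fuse_convs, self.fuse_norms):
            f = norm(conv(f)).relu() + f
        meta_feat = self.meta_linear(meta).sigmoid()
        meta_rep = nn.broadcast_positions(meta_feat, cfg.out_positions)
        dec_in = nn.concat([f, meta_rep], axis=-1)
        logits = self.decoder(dec_in)
        probs = nn.softmax(logits, axis=-1)
        pooled_feat = f.mean(axis=1)
        out: dict[str, Tensor] = {"probs": probs, "features": f}
        for task, head in self.aux_heads.items():
            out[task] = head(pooled_feat)
        return out


def build_model(cfg: ModelConfig, seed: int = 0) -> SpectrumTCN:
    return SpectrumTCN(cfg, seed=seed)


def save_checkpoint(model: SpectrumTCN, path: str | Path,
                    encoding_config: EncodingConfig | None = None) -> None:
    """Write weights (.npz) plus a JSON sidecar with the configurations."""
    path = Path(path)
    arrays = {f"param_{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = {"model_config": dataclasses.asdict(model.cfg)}
    if encoding_config is not None:
        sidecar["encoding_config"] = dataclasses.asdict(encoding_config)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path: str | Path, seed: int = 0
                    ) -> tuple[SpectrumTCN, EncodingConfig | None]:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    mcfg_dict = sidecar["model_config"]
    mcfg_dict["channels"] = tuple(mcfg_dict["channels"])
    if "head_dilations" in mcfg_dict:
        mcfg_dict["head_dilations"] = tuple(mcfg_dict["head_dilations"])
    mcfg = ModelConfig(**mcfg_dict)
    model = SpectrumTCN(mcfg, seed=seed)
    with np.load(path.with_suffix(".npz")) as data:
        arrays = [data[f"param_{i}"] for i in range(len(data.files))]
    model.load_state_arrays(arrays)
    ecfg = None
    if "encoding_config" in sidecar:
        ecfg = EncodingConfig(**sidecar["encoding_config"])
    return model, ecfg
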