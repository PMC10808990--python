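"""Backbone, feature-fusion neck, and per-layer prediction heads.

The neck is built by *iterative deep-to-shallow aggregation*: every
fusion node at downsampling factor m and step n combines the same-scale
node one step earlier with the upsampled node from the next-deeper
scale,

    O_n^m = DC(O_{n−1}^m) + DU(O_{n−1}^{2m}),

over the index set m=16:n=0; m=8:n≤1; m=4:n≤2; m=2:n≤3 (six fusion
nodes). The shallow-to-deep fusion path of the classic aggregation neck
is deliberately cropped away, and predictions are emitted from two
layers: O_3^2 at 2× downsampling (small fruits) and O_2^4 at 4×
(everything else). The uncropped single-output neck,

    F_n^4 = DC(F_{n−1}^4) + DU(O^{2^{n+2}}),   n = 1..3,

is kept as the ablation baseline with its lone 4× output.

DC here is a 3×3 convolution + batchnorm + relu and DU the same block
followed by 2× bilinear upsampling. Deformable sampling offsets are not
implemented in this build; requesting ``deformable=True`` raises.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np

from . import nn
from .heatmap import ConfigurationError
from .nn.autograd import DTYPE, Tensor

CROPPED_FACTORS = (2, 4, 8, 16)
ORIGINAL_FACTORS = (4, 8, 16, 32)

# (m, n) fusion nodes of the cropped neck, in dependency order
CROPPED_NODES = ((8, 1), (4, 1), (4, 2), (2, 1), (2, 2), (2, 3))


@dataclass(frozen=True)
class ModelConfig:
    """Architecture knobs; the defaults are the desk-scale 'tiny' setup."""

    variant: str = "cropped_double"  # or "original_single"
    stage_channels: tuple[int, ...] = ()  # per stride-2 stage; () = per-variant default
    blocks_per_stage: int = 1
    neck_channels: int = 16
    head_channels: int = 16
    deformable: bool = False
    heat_prior: float = 0.1  # initial heatmap output probability
    seed: int = 0

    def resolved_stage_channels(self) -> tuple[int, ...]:
        if self.stage_channels:
            return self.stage_channels
        if self.variant == "cropped_double":
            return (8, 16, 24, 32)  # factors 2, 4, 8, 16
        return (8, 8, 16, 24, 32)  # factors 2(hidden), 4, 8, 16, 32


def pad_to_multiple(images: np.ndarray, multiple: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Zero-pad NCHW images on the bottom/right to a size multiple."""
    n, c, h, w = images.shape
    ph = (-h) % multiple
    pw = (-w) % multiple
    if ph or pw:
        images = np.pad(images, ((0, 0), (0, 0), (0, ph), (0, pw)))
    return images, (ph, pw)


class Backbone(nn.Module):
    """Plain strided-conv feature extractor emitting a pyramid of maps."""

    def __init__(self, factors: tuple[int, ...], stage_channels: tuple[int, ...],
                 blocks_per_stage: int, rng: np.random.Generator):
        super().__init__()
        self.factors = factors
        n_stages = int(math.log2(max(factors)))
        if len(stage_channels) != n_stages:
            raise ConfigurationError(
                f"need {n_stages} stage channel widths for factors {factors}, "
                f"got {len(stage_channels)}"
            )
        self.stage_factor = [2**(i + 1) for i in range(n_stages)]
        cin = 3
        stages = []
        for i, cout in enumerate(stage_channels):
            blocks = [nn.conv_block(cin, cout, rng, stride=2)]
            blocks += [
                nn.conv_block(cout, cout, rng) for _ in range(blocks_per_stage - 1)
            ]
            stages.append(nn.Sequential(*blocks))
            cin = cout
        self.stages = nn.Sequential(*stages)  # container only; run stage-wise
        self.channels = {
            f: stage_channels[self.stage_factor.index(f)] for f in factors
        }

    def forward(self, x: Tensor) -> dict[int, Tensor]:
        maps: dict[int, Tensor] = {}
        for factor, stage in zip(self.stage_factor, self.stages.modules):
            x = stage(x)
            if factor in self.factors:
                maps[factor] = x
        return maps


class _Head(nn.Module):
    """Three conv branches: heatmap (sigmoid), size (2ch), offset (2ch)."""

    def __init__(self, cin: int, chead: int, heat_prior: float,
                 rng: np.random.Generator):
        super().__init__()
        self.heat = nn.Sequential(
            nn.conv_block(cin, chead, rng, norm=False), nn.Conv2d(chead, 1, rng=rng)
        )
        # bias so the initial heatmap sits at the configured prior
        self.heat.modules[1].bias.data[:] = math.log(heat_prior / (1 - heat_prior))
        self.size = nn.Sequential(
            nn.conv_block(cin, chead, rng, norm=False), nn.Conv2d(chead, 2, rng=rng)
        )
        self.offset = nn.Sequential(
            nn.conv_block(cin, chead, rng, norm=False), nn.Conv2d(chead, 2, rng=rng)
        )

    def forward(self, x: Tensor) -> dict[str, Tensor]:
        return {
            "heat": self.heat(x).sigmoid(),
            "size": self.size(x),
            "offset": self.offset(x),
        }


class CroppedNeck(nn.Module):
    """Deep-to-shallow iterative aggregation with the up-path cropped."""

    def __init__(self, in_channels: dict[int, int], width: int,
                 rng: np.random.Generator):
        super().__init__()
        self.proj = {}
        for m in CROPPED_FACTORS:
            self.proj[m] = nn.Conv2d(in_channels[m], width, kernel=1, rng=rng)
            self._children[f"proj{m}"] = self.proj[m]
        self.dc = {}
        self.du = {}
        for m, n in CROPPED_NODES:
            self.dc[(m, n)] = nn.conv_block(width, width, rng)
            self.du[(m, n)] = nn.Sequential(
                nn.conv_block(width, width, rng), nn.Upsample2x()
            )
            self._children[f"dc{m}_{n}"] = self.dc[(m, n)]
            self._children[f"du{m}_{n}"] = self.du[(m, n)]

    @staticmethod
    def fusion_edges() -> list[tuple[tuple[int, int], tuple[int, int]]]:
        """Graph edges (source node → fusion node), nodes keyed (m, n)."""
        edges = []
        for m, n in CROPPED_NODES:
            edges.append(((m, n - 1), (m, n)))
            edges.append(((2 * m, n - 1), (m, n)))
        return edges

    def forward(self, pyramid: dict[int, Tensor]) -> tuple[Tensor, Tensor]:
        missing = set(CROPPED_FACTORS) - set(pyramid)
        if missing:
            raise ConfigurationError(f"pyramid missing factors {sorted(missing)}")
        O: dict[tuple[int, int], Tensor] = {
            (m, 0): self.proj[m](pyramid[m]) for m in CROPPED_FACTORS
        }
        for m, n in CROPPED_NODES:
            O[(m, n)] = self.dc[(m, n)](O[(m, n - 1)]) + self.du[(m, n)](O[(2 * m, n - 1)])
        return O[(2, 3)], O[(4, 2)]


class OriginalNeck(nn.Module):
    """Uncropped baseline: shallow-to-deep fusion emitting one 4× map."""

    N_FUSIONS = 3

    def __init__(self, in_channels: dict[int, int], width: int,
                 rng: np.random.Generator):
        super().__init__()
        self.proj = {}
        for m in ORIGINAL_FACTORS:
            self.proj[m] = nn.Conv2d(in_channels[m], width, kernel=1, rng=rng)
            self._children[f"proj{m}"] = self.proj[m]
        self.dc = {}
        self.du = {}
        for n in range(1, self.N_FUSIONS + 1):
            self.dc[n] = nn.conv_block(width, width, rng)
            # deeper map at factor 2^(n+2) needs n doublings to reach 4x
            ups = [nn.conv_block(width, width, rng)]
            ups += [nn.Upsample2x() for _ in range(n)]
            self.du[n] = nn.Sequential(*ups)
            self._children[f"dc{n}"] = self.dc[n]
            self._children[f"du{n}"] = self.du[n]
        self.fusion_trace: list[tuple[int, int]] = []

    def forward(self, pyramid: dict[int, Tensor]) -> Tensor:
        missing = set(ORIGINAL_FACTORS) - set(pyramid)
        if missing:
            raise ConfigurationError(f"pyramid missing factors {sorted(missing)}")
        self.fusion_trace = []
        F = self.proj[4](pyramid[4])
        for n in range(1, self.N_FUSIONS + 1):
            m_deep = 2 ** (n + 2)
            F = self.dc[n](F) + self.du[n](self.proj[m_deep](pyramid[m_deep]))
            self.fusion_trace.append((n, m_deep))
        return F


class Detector(nn.Module):
    """Full center-point detector: backbone → neck → heads."""

    def __init__(self, config: ModelConfig = ModelConfig()):
        super().__init__()
        if config.deformable:
            raise ConfigurationError(
                "deformable convolution is not implemented in this build; "
                "set deformable=False to use plain 3x3 convolution blocks"
            )
        self.config = config
        rng = np.random.default_rng(config.seed)
        factors = CROPPED_FACTORS if config.variant == "cropped_double" else ORIGINAL_FACTORS
        if config.variant not in ("cropped_double", "original_single"):
            raise ConfigurationError(f"unknown neck variant {config.variant!r}")
        self.backbone = Backbone(
            factors, config.resolved_stage_channels(), config.blocks_per_stage, rng
        )
        if config.variant == "cropped_double":
            self.neck = CroppedNeck(self.backbone.channels, config.neck_channels, rng)
            self.head1 = _Head(config.neck_channels, config.head_channels,
                               config.heat_prior, rng)
            self.head2 = _Head(config.neck_channels, config.head_channels,
                               config.heat_prior, rng)
        else:
            self.neck = OriginalNeck(self.backbone.channels, config.neck_channels, rng)
            self.head2 = _Head(config.neck_channels, config.head_channels,
                               config.heat_prior, rng)
        self.pad_multiple = max(factors)
        self.last_pad = (0, 0)

    @property
    def layer_factors(self) -> dict[int, int]:
        """Prediction layer id → downsampling factor r."""
        if self.config.variant == "cropped_double":
            return {1: 2, 2: 4}
        return {2: 4}

    def forward(self, images: np.ndarray) -> dict[int, dict[str, Tensor]]:
        """images: float NCHW in [0, 1]; returns per-layer head outputs."""
        images = np.asarray(images, dtype=DTYPE)
        images, self.last_pad = pad_to_multiple(images, self.pad_multiple)
        x = Tensor(images)
        pyramid = self.backbone(x)
        if self.config.variant == "cropped_double":
            o2, o4 = self.neck(pyramid)
            return {1: self.head1(o2), 2: self.head2(o4)}
        f4 = self.neck(pyramid)
        return {2: self.head2(f4)}

    # -- checkpointing -------------------------------------------------

    CHECKPOINT_VERSION = 1

    def save(self, path) -> None:
        arrays = {f"param:{k}": t.data for k, t in self.named_parameters()}
        arrays.update({f"buffer:{k}": b for k, b in self.buffers()})
        meta = json.dumps(
            {"version": self.CHECKPOINT_VERSION, "config": asdict(self.config)}
        )
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "Detector":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            if meta["version"] != cls.CHECKPOINT_VERSION:
                raise ValueError(f"unsupported checkpoint version {meta['version']}")
            cfg = meta["config"]
            cfg["stage_channels"] = tuple(cfg["stage_channels"])
            model = cls(ModelConfig(**cfg))
            params = dict(model.named_parameters())
            for key in data.files:
                if key.startswith("param:"):
                    params[key[6:]].data[...] = data[key]
                elif key.startswith("buffer:"):
                    name = key[7:]
                    obj = model
                    *parents, leaf = name.split(".")
                    for p in parents:
                        obj = obj._children[p]
                    getattr(obj, leaf)[...] = data[key]
        model.set_training(False)
        return model
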