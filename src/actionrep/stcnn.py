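"""Fixed-template spatiotemporal convolutional models.

The three fixed-template model variants share the same computational stack —
scale pyramid, moving-Gabor convolution (Conv1), spatial max pooling with
scale-pair pooling (Pool1), sampled-template convolution spanning the full
channel depth (Conv2), and a final pooling stage (Pool2) — and differ only in
how Conv2 channels are wired to Pool2 units:

* ``per-channel``  — one Pool2 unit per Conv2 channel (purely convolutional),
* ``structured``   — channels whose templates were sampled from the same
  actor performing the same action (at any viewpoint) are pooled together,
  separately per template size class and scale channel, so that the 3D
  viewpoint of a matched template is discarded the way spatial pooling
  discards position,
* ``unstructured`` — a random partition of the channels with the same
  group-size multiset as the structured partition (the control).

Template matching is normalized cross-correlation by default: templates are
mean-subtracted and l2-normalized, and each input patch is l2-normalized, so
a response of 1 means an exact (contrast-invariant) match.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage.transform import resize

from .gabor import Template, TemplateBank, build_conv1_bank

__all__ = [
    "PoolGroups",
    "FixedTemplateModel",
    "build_scale_pyramid",
    "conv3d",
    "max_pool",
    "pool_scale_pairs",
    "sample_templates",
    "make_pool_groups",
    "even_partition_sizes",
    "random_even_groups",
    "extract_signature",
]

_EPS = 1e-12
# chunk conv windows when the scratch array would exceed this many floats
_MAX_WINDOW_FLOATS = 3e7


# ---------------------------------------------------------------------------
# scale pyramid
# ---------------------------------------------------------------------------

def build_scale_pyramid(
    pixels: np.ndarray, factors: Sequence[float] = (1.0, 0.5, 0.25)
) -> list[np.ndarray]:
    """Spatially rescaled copies of a (H, W, T) clip; frame count unchanged.

    Rescaling is anti-aliased; factor 1 returns the input untouched.
    """
    pixels = np.asarray(pixels, dtype=float)
    if pixels.ndim != 3:
        raise ValueError(f"expected (H, W, T) clip, got shape {pixels.shape}")
    H, W, _ = pixels.shape
    out = []
    for f in factors:
        if not (0 < f <= 1):
            raise ValueError(f"scale factor must be in (0, 1], got {f}")
        if f == 1.0:
            out.append(pixels)
            continue
        h, w = round(H * f), round(W * f)
        if h < 1 or w < 1:
            raise ValueError(f"scale factor {f} rescales {H}x{W} below 1 px")
        out.append(
            resize(pixels, (h, w, pixels.shape[2]), order=1,
                   anti_aliasing=True, mode="reflect", preserve_range=True)
        )
    return out


# ---------------------------------------------------------------------------
# spatiotemporal convolution (template matching)
# ---------------------------------------------------------------------------

def _stack_weights(bank) -> np.ndarray:
    """Stack templates sharing a size class into one (N, [c,] h, w, t) array."""
    if isinstance(bank, np.ndarray):
        return bank[None] if bank.ndim in (3, 4) else bank
    tpls = list(bank) if isinstance(bank, TemplateBank) else list(bank)
    ws = [t.weights if isinstance(t, Template) else np.asarray(t, float) for t in tpls]
    shapes = {w.shape for w in ws}
    if len(shapes) != 1:
        raise ValueError(f"templates passed to conv3d must share a size class, got {shapes}")
    return np.stack(ws)


def conv3d(
    x: np.ndarray,
    bank,
    stride: tuple[int, int, int] = (1, 1, 1),
    *,
    normalize: bool = True,
    boundary: str = "valid",
) -> np.ndarray:
    """Valid spatiotemporal cross-correlation of a response stack with a bank.

    Parameters
    ----------
    x : (C, H, W, T) or (H, W, T) array
        Input response stack (a raw clip is a single-channel stack).
    bank : TemplateBank, sequence of Template, or array
        Templates of one size class, each (h, w, t) for single-channel input
        or (C, h, w, t) spanning the full channel depth.
    stride : (sy, sx, st)
        Subsampling in the two spatial axes and time.
    normalize : bool
        Divide each response by the l2 norm of the underlying input patch
        (normalized cross-correlation). Zero-norm patches respond 0.
    boundary : {"valid", "wrap"}
        ``wrap`` pads all three axes periodically so the output extent equals
        the input extent; used by the translation-invariance harness.

    Returns
    -------
    (N, H', W', T') response stack, one output channel per template.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 3:
        x = x[None]
    if x.ndim != 4:
        raise ValueError(f"expected (C, H, W, T) input, got shape {x.shape}")
    w = _stack_weights(bank)
    if w.ndim == 4:  # (N, h, w, t): per-channel templates require C == 1
        if x.shape[0] != 1:
            raise ValueError(
                f"templates without a channel axis require single-channel input, "
                f"input has {x.shape[0]} channels"
            )
        w = w[:, None]
    if w.shape[1] != x.shape[0]:
        raise ValueError(
            f"template channel depth {w.shape[1]} != input channels {x.shape[0]}"
        )
    _, h, wd, t = w.shape[1:]
    if boundary == "wrap":
        x = np.pad(x, ((0, 0), (0, h - 1), (0, wd - 1), (0, t - 1)), mode="wrap")
    elif boundary != "valid":
        raise ValueError(f"unknown boundary mode {boundary!r}")
    C, H, W, T = x.shape
    if h > H or wd > W or t > T:
        raise ValueError(
            f"template ({h}x{wd}x{t}) larger than input ({H}x{W}x{T})"
        )
    sy, sx, st = stride
    if min(sy, sx, st) < 1:
        raise ValueError(f"strides must be >= 1, got {stride}")

    win_shape = (C, h, wd, t)
    n_pos = (H - h + 1) * (W - wd + 1) * (T - t + 1)
    windows = sliding_window_view(x, win_shape)[0]  # (H', W', T', C, h, w, t)
    windows = windows[::sy, ::sx, ::st]
    out_shape = windows.shape[:3]
    n_out = int(np.prod(out_shape))
    per_pos = C * h * wd * t

    def _correlate(block):  # block: (..., C, h, w, t)
        resp = np.tensordot(block, w, axes=([-4, -3, -2, -1], [1, 2, 3, 4]))
        if normalize:
            norms = np.sqrt(np.einsum("...chwt,...chwt->...", block, block))
            resp = np.where(norms[..., None] > _EPS, resp / np.maximum(norms, _EPS)[..., None], 0.0)
        return resp  # (..., N)

    if n_out * per_pos <= _MAX_WINDOW_FLOATS:
        resp = _correlate(windows)
    else:
        chunks = []
        step = max(1, int(_MAX_WINDOW_FLOATS // max(1, out_shape[1] * out_shape[2] * per_pos)))
        for i in range(0, out_shape[0], step):
            chunks.append(_correlate(np.ascontiguousarray(windows[i : i + step])))
        resp = np.concatenate(chunks, axis=0)
    return np.moveaxis(resp, -1, 0)  # (N, H', W', T')


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------

@dataclass
class PoolGroups:
    """Partition of Conv2 channels into Pool2 units, plus pooling extents.

    ``groups[i]`` is the list of channel indices pooled by unit i. ``scheme``
    is one of per-channel / structured / unstructured. ``keys`` optionally
    records, for structured partitions, the (actor, action, size_class,
    scale_channel) key of each group.
    """

    groups: list[list[int]]
    scheme: str
    n_channels: int
    keys: list[tuple] | None = None
    spatial: str = "full"
    temporal_units: int = 1
    pool_scales: bool = True

    def __post_init__(self) -> None:
        flat = sorted(i for g in self.groups for i in g)
        if flat != list(range(self.n_channels)):
            raise ValueError(
                "pool groups must partition the channel set "
                f"0..{self.n_channels - 1}; got a partition covering {len(flat)} slots"
            )

    def size_multiset(self) -> Counter:
        return Counter(len(g) for g in self.groups)

    def __len__(self) -> int:
        return len(self.groups)


def max_pool(
    x,
    region: tuple[int, int, int],
    stride: tuple[int, int, int] | None = None,
    *,
    scale_groups: Sequence[tuple[int, int]] | None = None,
    channel_groups: PoolGroups | None = None,
):
    """Max pooling over spatiotemporal windows, scale pairs and channel groups.

    ``x`` is a (C, H, W, T) stack, or a list of such stacks (one per pyramid
    scale) when ``scale_groups`` is given; each pair (i, j) of scale indices
    is then combined into one output scale channel by resampling the finer
    response onto the coarser grid and taking the elementwise max.
    """
    if scale_groups is not None:
        if not isinstance(x, (list, tuple)):
            raise ValueError("scale_groups requires a list of per-scale stacks")
        pooled = [max_pool(s, region, stride, channel_groups=channel_groups) for s in x]
        return pool_scale_pairs(pooled, scale_groups)
    x = np.asarray(x, dtype=float)
    if x.ndim != 4:
        raise ValueError(f"expected (C, H, W, T) stack, got shape {x.shape}")
    py, px, pt = region
    if stride is None:
        stride = region
    sy, sx, st = stride
    _, H, W, T = x.shape
    if py > H or px > W or pt > T:
        raise ValueError(f"pooling region {region} does not fit input {x.shape[1:]}")
    win = sliding_window_view(x, (py, px, pt), axis=(1, 2, 3))
    win = win[:, ::sy, ::sx, ::st]
    out = win.max(axis=(-3, -2, -1))
    if channel_groups is not None:
        if channel_groups.n_channels != x.shape[0]:
            raise ValueError(
                f"channel_groups partition {channel_groups.n_channels} channels, "
                f"input has {x.shape[0]}"
            )
        out = np.stack([out[g].max(axis=0) for g in channel_groups.groups])
    return out


def pool_scale_pairs(
    stacks: Sequence[np.ndarray], pairs: Sequence[tuple[int, int]]
) -> list[np.ndarray]:
    """Max over paired pyramid scales; finer maps are resampled to the coarser grid.

    With the default 3-scale pyramid the adjacent pairs (0, 1) and (1, 2)
    produce two output scale channels.
    """
    out = []
    for i, j in pairs:
        a, b = stacks[i], stacks[j]
        if a.shape[1] * a.shape[2] < b.shape[1] * b.shape[2]:
            a, b = b, a  # a = finer (larger) map
        a_rs = resize(a, (a.shape[0],) + b.shape[1:], order=1,
                      anti_aliasing=False, mode="edge", preserve_range=True)
        out.append(np.maximum(a_rs, b))
    return out


# ---------------------------------------------------------------------------
# sampled second-layer templates
# ---------------------------------------------------------------------------

def sample_templates(
    pool1_responses: Sequence[tuple[tuple, Sequence[np.ndarray]]],
    sizes: Sequence[tuple[int, int, int]],
    count: int,
    seed: int,
) -> TemplateBank:
    """Sample Conv2 templates from Pool1 responses to the embedding set.

    Parameters
    ----------
    pool1_responses : sequence of (label, per-scale-channel stacks)
        ``label`` is (actor, action, viewpoint, clip); each stack is
        (C, H, W, T) for one Pool1 scale channel.
    sizes : list of (h, w, t)
        Template size classes in Pool1 units; ``count`` is split as evenly
        as possible across them.
    count : int
        Total number of templates.
    seed : int
        Governs the uniform draws over (clip, scale channel, position).

    Each sampled patch spans the full channel depth, is mean-subtracted and
    l2-normalized, and records its provenance (source actor, action,
    viewpoint, size class, scale channel, clip index, position).
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = np.random.default_rng(seed)
    per_size = [count // len(sizes)] * len(sizes)
    for i in range(count % len(sizes)):
        per_size[i] += 1
    bank = TemplateBank()
    for (h, w, t), n_size in zip(sizes, per_size):
        # enumerate valid (clip, scale channel) sources for this size
        sources = []
        for ci, (label, stacks) in enumerate(pool1_responses):
            for si, st in enumerate(stacks):
                _, H, W, T = st.shape
                if h <= H and w <= W and t <= T:
                    sources.append((ci, si))
        if not sources:
            raise ValueError(
                f"template size ({h}x{w}x{t}) exceeds every Pool1 response extent"
            )
        drawn = 0
        while drawn < n_size:
            ci, si = sources[rng.integers(len(sources))]
            label, stacks = pool1_responses[ci]
            stack = stacks[si]
            _, H, W, T = stack.shape
            y0 = int(rng.integers(H - h + 1))
            x0 = int(rng.integers(W - w + 1))
            t0 = int(rng.integers(T - t + 1))
            patch = np.array(stack[:, y0 : y0 + h, x0 : x0 + w, t0 : t0 + t])
            patch -= patch.mean()
            nrm = np.linalg.norm(patch)
            if nrm <= _EPS:
                continue  # flat patch carries no template; redraw
            patch /= nrm
            actor, action, viewpoint, clip = label
            bank.templates.append(
                Template(
                    patch,
                    meta={
                        "actor": actor,
                        "action": action,
                        "viewpoint": viewpoint,
                        "clip": clip,
                        "size_class": (h, w, t),
                        "scale_channel": si,
                        "position": (y0, x0, t0),
                    },
                )
            )
            drawn += 1
    return bank


# ---------------------------------------------------------------------------
# Pool2 wiring schemes
# ---------------------------------------------------------------------------

def make_pool_groups(
    bank: TemplateBank,
    scheme: str,
    seed: int = 0,
    *,
    n_scale_channels: int = 1,
) -> PoolGroups:
    """Wire Conv2 channels to Pool2 units.

    Channels are indexed as ``template_index * n_scale_channels +
    scale_channel`` (each template produces one response map per scale
    channel it is applied to).

    * ``per-channel``: one unit per template, pooling that template's
      channels across all remaining scale channels (the purely convolutional
      wiring: a single Conv2 channel, all remaining scales).
    * ``structured``: channels grouped by (actor, action, size class, scale
      channel) of the template provenance — all viewpoints merged, sizes and
      scale channels pooled independently.
    * ``unstructured``: uniform random partition (without replacement) whose
      group-size multiset equals the structured partition's.
    """
    n_channels = len(bank) * n_scale_channels
    if scheme == "per-channel":
        groups = [
            [ti * n_scale_channels + sc for sc in range(n_scale_channels)]
            for ti in range(len(bank))
        ]
        return PoolGroups(groups, scheme, n_channels)

    keys = []
    for tpl in bank:
        meta = tpl.meta
        if not isinstance(meta, dict) or not {"actor", "action", "size_class"} <= meta.keys():
            raise ValueError(
                f"scheme {scheme!r} requires sampling provenance metadata on every template"
            )
        keys.append((meta["actor"], meta["action"], tuple(meta["size_class"])))
    grouped: dict[tuple, list[int]] = {}
    for ti, key in enumerate(keys):
        for sc in range(n_scale_channels):
            grouped.setdefault(key + (sc,), []).append(ti * n_scale_channels + sc)
    group_keys = sorted(grouped)
    groups = [grouped[k] for k in group_keys]
    if scheme == "structured":
        return PoolGroups(groups, scheme, n_channels, keys=group_keys)
    if scheme == "unstructured":
        sizes = [len(g) for g in groups]
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n_channels)
        out, start = [], 0
        for s in sizes:
            out.append(sorted(int(i) for i in perm[start : start + s]))
            start += s
        return PoolGroups(out, scheme, n_channels)
    raise ValueError(f"unknown pooling scheme {scheme!r}")


def even_partition_sizes(n_channels: int, n_groups: int) -> list[int]:
    """Sizes of the most even partition of n_channels into n_groups.

    E.g. 512 channels into 60 groups gives sizes 8 and 9 only.
    """
    if n_groups < 1 or n_channels < n_groups:
        raise ValueError(f"cannot partition {n_channels} channels into {n_groups} groups")
    base, extra = divmod(n_channels, n_groups)
    return [base + 1] * extra + [base] * (n_groups - extra)


def random_even_groups(n_channels: int, n_groups: int, seed: int = 0) -> PoolGroups:
    """Uniform random even partition of channels (the 512-into-60 wiring)."""
    sizes = even_partition_sizes(n_channels, n_groups)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_channels)
    groups, start = [], 0
    for s in sizes:
        groups.append(sorted(int(i) for i in perm[start : start + s]))
        start += s
    return PoolGroups(groups, "unstructured", n_channels)


# ---------------------------------------------------------------------------
# assembled fixed-template model
# ---------------------------------------------------------------------------

@dataclass
class FixedTemplateModel:
    """A fully assembled fixed-template ST-CNN (purely convolutional,
    structured- or unstructured-pooling, depending on ``pool_groups``).

    The pipeline is: scale pyramid -> Conv1 -> Pool1 (space + scale pairs) ->
    Conv2 -> Pool2 (global space, one time unit, max over scale channels and
    channel groups) -> global max over the residual time axis.
    """

    conv1_bank: TemplateBank
    conv2_bank: TemplateBank
    pool_groups: PoolGroups
    pyramid_factors: tuple[float, ...] = (1.0, 0.5, 0.25)
    scale_pairs: tuple[tuple[int, int], ...] = ((0, 1), (1, 2))
    pool1_region: tuple[int, int, int] = (4, 4, 1)
    pool1_stride: tuple[int, int, int] = (2, 2, 1)
    conv1_stride: tuple[int, int, int] = (1, 1, 1)
    conv2_stride: tuple[int, int, int] = (1, 1, 1)
    normalize: bool = True
    boundary: str = "valid"

    def pool1_responses(self, pixels: np.ndarray) -> list[np.ndarray]:
        """Per-scale-channel Pool1 stacks (C1, H, W, T) for one clip."""
        pyramid = build_scale_pyramid(pixels, self.pyramid_factors)
        per_scale = []
        for img in pyramid:
            per_class = [
                conv3d(img, [self.conv1_bank[i] for i in idx],
                       self.conv1_stride, normalize=self.normalize,
                       boundary=self.boundary)
                for idx in self.conv1_bank.by_size_class().values()
            ]
            per_scale.append(_crop_stack(per_class))
        return max_pool(per_scale, self.pool1_region, self.pool1_stride,
                        scale_groups=self.scale_pairs)

    def conv2_responses(self, pool1: list[np.ndarray]) -> list[np.ndarray]:
        """Per-scale-channel Conv2 stacks; channels ordered template-major."""
        by_size = self.conv2_bank.by_size_class()
        out = []
        for stack in pool1:
            per_class = {}
            for size, idx in by_size.items():
                resp = conv3d(stack, [self.conv2_bank[i] for i in idx],
                              self.conv2_stride, normalize=self.normalize,
                              boundary=self.boundary)
                for j, ti in enumerate(idx):
                    per_class[ti] = resp[j]
            maps = [per_class[i] for i in range(len(self.conv2_bank))]
            out.append(_crop_stack([m[None] for m in maps]))
        return out

    def extract(self, pixels: np.ndarray) -> np.ndarray:
        conv2 = self.conv2_responses(self.pool1_responses(pixels))
        n_sc = len(conv2)
        # Pool2: global spatial max per scale channel, one temporal unit
        per_scale = [s.max(axis=(1, 2)) for s in conv2]  # (C2, T) each
        t_min = min(s.shape[1] for s in per_scale)
        # channel index = template * n_scale_channels + scale_channel
        M = np.empty((len(self.conv2_bank) * n_sc, t_min))
        for sc, s in enumerate(per_scale):
            M[sc::n_sc] = s[:, :t_min]
        if self.pool_groups.n_channels != M.shape[0]:
            raise ValueError(
                f"pool groups partition {self.pool_groups.n_channels} channels, "
                f"model produces {M.shape[0]} (= {len(self.conv2_bank)} templates "
                f"x {n_sc} scale channels)"
            )
        grouped = np.stack([M[g].max(axis=0) for g in self.pool_groups.groups])
        return grouped.max(axis=1)  # global max over the residual time axis

    @property
    def signature_length(self) -> int:
        return len(self.pool_groups)


def _crop_stack(stacks: Sequence[np.ndarray]) -> np.ndarray:
    """Center-crop (C, H, W, T) stacks to the smallest common extent and stack."""
    Hs = min(s.shape[1] for s in stacks)
    Ws = min(s.shape[2] for s in stacks)
    Ts = min(s.shape[3] for s in stacks)
    out = []
    for s in stacks:
        dy = (s.shape[1] - Hs) // 2
        dx = (s.shape[2] - Ws) // 2
        dt = (s.shape[3] - Ts) // 2
        out.append(s[:, dy : dy + Hs, dx : dx + Ws, dt : dt + Ts])
    return np.concatenate(out, axis=0)


def extract_signature(video, model: FixedTemplateModel) -> np.ndarray:
    """Fixed-length signature of a clip under an assembled model."""
    pixels = video.pixels if hasattr(video, "pixels") else np.asarray(video, float)
    return model.extract(pixels)
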