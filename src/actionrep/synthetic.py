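"""Synthetic action videos and neural-style responses.

The video generator emulates a factorial action-recognition stimulus set: a
small cast of actors (parametric articulated stick figures with distinct limb
proportions and body intensity) each performing a set of periodic actions
(drink, eat, jump, run, walk as the base motion patterns) on a fixed
background, filmed from several viewpoints. Viewpoint is a 3D rotation of the
figure about the vertical axis followed by orthographic projection, so the
background is constant across all conditions. Two small static distractor
blobs are attached to the figure regardless of the action (the held-object
confound control), and each clip starts at a random phase of the action
cycle.

The neural generator produces multi-subject stimulus x sensor response
matrices with a planted, analytically known representational geometry: each
stimulus receives a latent vector built from weighted orthonormal embeddings
of its action, viewpoint and actor labels, mapped through one fixed random
linear projection to sensor space, plus i.i.d. Gaussian subject noise.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "DatasetConfig",
    "VideoTensor",
    "DatasetIndex",
    "ClipRecord",
    "NeuralRecordingSet",
    "render_clip",
    "generate_dataset",
    "generate_neural_responses",
    "ACTION_PATTERNS",
]

#: Base motion patterns, indexed by ``action_id % len(ACTION_PATTERNS)``.
ACTION_PATTERNS = ("drink", "eat", "jump", "run", "walk")


@dataclass(frozen=True)
class DatasetConfig:
    """Factorial design of the synthetic video dataset.

    Defaults are the desk-scale rendering (64 x 38 px, 30 frames at 15 fps,
    i.e. 2 s clips); the full-scale 128 x 76 x 60 geometry is available by
    configuration.
    """

    n_actors: int = 5
    n_actions: int = 5
    viewpoints: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0, 180.0)
    clips_per_condition: int = 26
    clip_len: int = 30
    frame_size: tuple[int, int] = (64, 38)  # (height, width) px
    fps: float = 15.0
    #: fixed downward camera tilt (degrees), constant across conditions; keeps
    #: sagittal limb motion visible at the frontal viewpoint
    camera_elevation: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_actors, self.n_actions, self.clips_per_condition) < 1:
            raise ValueError("all counts must be >= 1")
        if self.clip_len < 2:
            raise ValueError(f"clip_len must be >= 2, got {self.clip_len}")
        if len(set(self.viewpoints)) != len(self.viewpoints):
            raise ValueError(f"viewpoints must be distinct, got {self.viewpoints}")
        if min(self.frame_size) < 8:
            raise ValueError(f"frame size too small: {self.frame_size}")

    @property
    def n_clips(self) -> int:
        return (self.n_actors * self.n_actions * len(self.viewpoints)
                * self.clips_per_condition)


@dataclass
class VideoTensor:
    """Grayscale H x W x T clip with its (actor, action, viewpoint, clip) label."""

    pixels: np.ndarray
    label: tuple[int, int, float, int]

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3:
            raise ValueError(f"expected (H, W, T) pixels, got {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("pixel values must lie in [0, 1]")

    @property
    def actor(self) -> int:
        return self.label[0]

    @property
    def action(self) -> int:
        return self.label[1]

    @property
    def viewpoint(self) -> float:
        return self.label[2]

    @property
    def clip(self) -> int:
        return self.label[3]


@dataclass(frozen=True)
class ClipRecord:
    actor: int
    action: int
    viewpoint: float
    clip: int
    path: str | None = None

    @property
    def key(self) -> tuple:
        return (self.actor, self.action, self.viewpoint, self.clip)


@dataclass
class DatasetIndex:
    """Ordered clip records of a factorial dataset, with optional in-memory clips."""

    records: list[ClipRecord]
    config: DatasetConfig | None = None
    clips: dict[tuple, VideoTensor] = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [r.key for r in self.records]
        if len(set(keys)) != len(keys):
            raise ValueError("clip records must have unique (actor, action, viewpoint, clip) keys")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get_clip(self, record: ClipRecord) -> VideoTensor:
        if record.key in self.clips:
            return self.clips[record.key]
        if record.path is None:
            raise KeyError(f"clip {record.key} is neither in memory nor on disk")
        return _read_clip_dir(Path(record.path), record)

    def labels(self, which: str) -> np.ndarray:
        return np.array([getattr(r, which) for r in self.records])

    def to_manifest(self, path: Path) -> None:
        with open(path, "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["clip_id", "actor", "action", "viewpoint", "clip_index", "path"])
            for i, r in enumerate(self.records):
                wr.writerow([i, r.actor, r.action, r.viewpoint, r.clip, r.path or ""])

    @classmethod
    def from_manifest(cls, path: Path) -> "DatasetIndex":
        records = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                records.append(ClipRecord(
                    actor=int(row["actor"]), action=int(row["action"]),
                    viewpoint=float(row["viewpoint"]), clip=int(row["clip_index"]),
                    path=row["path"] or None,
                ))
        return cls(records)


# ---------------------------------------------------------------------------
# articulated-figure renderer
# ---------------------------------------------------------------------------

def _actor_params(actor: int, cfg_seed: int) -> dict:
    """Deterministic per-actor body parameters (proportions and intensity)."""
    rng = np.random.default_rng([cfg_seed, 977, actor])
    u = rng.uniform
    return {
        "leg_len": 0.46 * u(0.85, 1.15),
        "arm_len": 0.34 * u(0.85, 1.15),
        "torso_len": 0.36 * u(0.9, 1.1),
        "head_r": 0.075 * u(0.85, 1.2),
        "shoulder_w": 0.13 * u(0.8, 1.2),
        "hip_w": 0.08 * u(0.85, 1.15),
        "limb_w": 0.030 * u(0.8, 1.3),
        "body_tone": u(0.55, 0.95),
    }


def _pose(pattern: str, phase: float, p: dict) -> dict:
    """Joint angles / offsets for one motion pattern at cycle phase in [0, 2pi)."""
    s, c = math.sin(phase), math.cos(phase)
    pose = {"leg_l": 0.0, "leg_r": 0.0, "knee_l": 0.0, "knee_r": 0.0,
            "arm_l": 0.0, "arm_r": 0.0, "elbow_l": 0.2, "elbow_r": 0.2,
            "body_dy": 0.0, "crouch": 0.0}
    if pattern == "walk":
        pose.update(leg_l=0.45 * s, leg_r=-0.45 * s,
                    knee_l=0.3 * max(0.0, -s), knee_r=0.3 * max(0.0, s),
                    arm_l=-0.35 * s, arm_r=0.35 * s, body_dy=0.015 * abs(c))
    elif pattern == "run":
        pose.update(leg_l=0.85 * s, leg_r=-0.85 * s,
                    knee_l=0.9 * max(0.0, -s) + 0.2, knee_r=0.9 * max(0.0, s) + 0.2,
                    arm_l=-0.65 * s, arm_r=0.65 * s,
                    elbow_l=1.0, elbow_r=1.0, body_dy=0.04 * abs(c))
    elif pattern == "jump":
        lift = max(0.0, s)
        pose.update(body_dy=0.16 * lift, crouch=0.35 * max(0.0, -s),
                    knee_l=0.5 * max(0.0, -s), knee_r=0.5 * max(0.0, -s),
                    arm_l=1.2 * lift - 0.3, arm_r=1.2 * lift - 0.3,
                    elbow_l=0.3, elbow_r=0.3)
    elif pattern == "eat":
        # both forearms cycle toward the head
        pose.update(arm_l=0.45 + 0.15 * s, arm_r=0.45 - 0.15 * s,
                    elbow_l=1.6 + 0.5 * s, elbow_r=1.6 - 0.5 * s)
    elif pattern == "drink":
        # one arm raises to the head and holds
        raise_amt = 0.5 * (1 + math.tanh(2.5 * s))
        pose.update(arm_r=0.2 + 0.9 * raise_amt, elbow_r=0.7 + 1.3 * raise_amt,
                    arm_l=0.05 * s, elbow_l=0.3)
    else:
        raise ValueError(f"unknown motion pattern {pattern!r}")
    return pose


def _skeleton(p: dict, pose: dict) -> list[tuple[np.ndarray, np.ndarray, float, float]]:
    """3D line segments (p1, p2, width, intensity) of the figure in body frame.

    Body frame: x lateral, y up, z sagittal (facing +z at viewpoint 0);
    pelvis at the origin. Limb swing angles rotate about the lateral axis,
    so walking/running motion lies in the sagittal plane.
    """
    tone = p["body_tone"]
    lw = p["limb_w"]
    dy = pose["body_dy"] - pose["crouch"] * 0.5 * p["leg_len"]
    pelvis = np.array([0.0, p["leg_len"] + dy, 0.0])
    neck = pelvis + [0, p["torso_len"], 0]
    segs = []

    def sag(origin, angle, length):
        """Endpoint of a segment swung by `angle` about the lateral axis."""
        return origin + length * np.array([0.0, -math.cos(angle), math.sin(angle)])

    # legs: hip -> knee -> ankle
    for side, swing, knee in (("l", pose["leg_l"], pose["knee_l"]),
                              ("r", pose["leg_r"], pose["knee_r"])):
        sx = -p["hip_w"] if side == "l" else p["hip_w"]
        hip = pelvis + [sx, 0, 0]
        kneept = sag(hip, swing, 0.5 * p["leg_len"] * (1 - pose["crouch"] * 0.3))
        ankle = sag(kneept, swing - knee, 0.5 * p["leg_len"])
        segs.append((hip, kneept, lw, tone))
        segs.append((kneept, ankle, lw * 0.9, tone))
    # torso
    segs.append((pelvis, neck, lw * 2.2, tone))
    # arms: shoulder -> elbow -> hand
    for side, swing, elbow in (("l", pose["arm_l"], pose["elbow_l"]),
                               ("r", pose["arm_r"], pose["elbow_r"])):
        sx = -p["shoulder_w"] if side == "l" else p["shoulder_w"]
        sh = neck + [sx, -0.02, 0]
        el = sag(sh, swing, 0.55 * p["arm_len"])
        hand = sag(el, swing + elbow, 0.45 * p["arm_len"])
        segs.append((sh, el, lw * 0.85, tone))
        segs.append((el, hand, lw * 0.8, tone))
    # head as a short fat segment
    head_c = neck + [0, p["head_r"] * 1.6, 0]
    segs.append((head_c - [0, p["head_r"] * 0.5, 0], head_c + [0, p["head_r"] * 0.5, 0],
                 p["head_r"], tone))
    # two static distractor blobs attached at fixed body offsets, identical
    # across actions (the held-object confound control)
    for off, inten in (([-0.16, 0.12, 0.06], 0.35), ([0.17, 0.10, 0.05], 0.85)):
        b = pelvis + off
        segs.append((b, b + [0, 0.015, 0], 0.028, inten))
    return segs


def _render_frame(segs, viewpoint_deg: float, shape: tuple[int, int],
                  scale: float, center: tuple[float, float],
                  elevation_deg: float = 20.0) -> np.ndarray:
    """Orthographic projection + soft rasterization of 3D segments.

    A small fixed downward camera tilt (identical for every condition) keeps
    depth-axis motion visible at the frontal viewpoint.
    """
    H, W = shape
    phi = math.radians(viewpoint_deg)
    cphi, sphi = math.cos(phi), math.sin(phi)
    el = math.radians(elevation_deg)
    cel, sel = math.cos(el), math.sin(el)
    rows = np.arange(H, dtype=float)[:, None]
    cols = np.arange(W, dtype=float)[None, :]
    img = np.zeros((H, W))
    for p1, p2, width, inten in segs:
        # yaw about the vertical axis, then tilt: (u, v) = image (x, y)
        d1 = -p1[0] * sphi + p1[2] * cphi
        d2 = -p2[0] * sphi + p2[2] * cphi
        u1, v1 = p1[0] * cphi + p1[2] * sphi, p1[1] * cel + d1 * sel
        u2, v2 = p2[0] * cphi + p2[2] * sphi, p2[1] * cel + d2 * sel
        # to pixel coordinates (row grows downward)
        x1, y1 = center[1] + u1 * scale, center[0] - v1 * scale
        x2, y2 = center[1] + u2 * scale, center[0] - v2 * scale
        dx, dy = x2 - x1, y2 - y1
        L2 = dx * dx + dy * dy
        if L2 < 1e-12:
            t = np.zeros((H, W))
        else:
            t = np.clip(((cols - x1) * dx + (rows - y1) * dy) / L2, 0.0, 1.0)
        d = np.hypot(cols - (x1 + t * dx), rows - (y1 + t * dy))
        r = width * scale
        mask = np.clip((r + 0.8 - d) / 1.6, 0.0, 1.0)  # soft 1.6 px edge
        img = np.maximum(img, inten * mask)
    return img


def _background(shape: tuple[int, int]) -> np.ndarray:
    """Constant background: dim base with a fixed vertical gradient."""
    H, W = shape
    return 0.10 + 0.05 * (np.arange(H, dtype=float)[:, None] / max(1, H - 1)) * np.ones((1, W))


def render_clip(actor: int, action: int, viewpoint: float,
                cfg: DatasetConfig, seed: int) -> VideoTensor:
    """Render one clip of an actor performing an action at a viewpoint.

    Deterministic given (actor, action, viewpoint, cfg, seed); the seed
    governs only the starting phase of the action cycle.
    """
    if not (0 <= actor < cfg.n_actors):
        raise ValueError(f"actor id {actor} out of range [0, {cfg.n_actors})")
    if not (0 <= action < cfg.n_actions):
        raise ValueError(f"action id {action} out of range [0, {cfg.n_actions})")
    if viewpoint not in cfg.viewpoints:
        raise ValueError(f"viewpoint {viewpoint} not in configured set {cfg.viewpoints}")

    p = _actor_params(actor, cfg.seed)
    pattern = ACTION_PATTERNS[action % len(ACTION_PATTERNS)]
    # extra action ids reuse base patterns at shifted cadence
    freq_mult = 1.0 + 0.25 * (action // len(ACTION_PATTERNS))
    base_freq = {"drink": 0.6, "eat": 1.2, "jump": 0.9, "run": 1.8, "walk": 1.0}[pattern]
    freq = base_freq * freq_mult  # cycles per second

    rng = np.random.default_rng([seed, actor, action, int(round(viewpoint * 1000))])
    phase0 = rng.uniform(0.0, 2.0 * math.pi)

    H, W = cfg.frame_size
    fig_height = p["leg_len"] + p["torso_len"] + p["head_r"] * 3
    scale = 0.80 * H / fig_height
    center = (H * 0.92, W / 2.0)  # feet near the bottom of the frame
    bg = _background(cfg.frame_size)
    frames = np.empty((H, W, cfg.clip_len))
    for fi in range(cfg.clip_len):
        phase = phase0 + 2.0 * math.pi * freq * fi / cfg.fps
        segs = _skeleton(p, _pose(pattern, phase, p))
        fig = _render_frame(segs, viewpoint, cfg.frame_size, scale, center,
                            cfg.camera_elevation)
        frames[:, :, fi] = np.where(fig > 0.02, np.maximum(fig, bg), bg)
    return VideoTensor(np.clip(frames, 0.0, 1.0), (actor, action, viewpoint, 0))


def _clip_seed(cfg: DatasetConfig, actor: int, action: int,
               view_idx: int, clip: int) -> int:
    rng = np.random.default_rng([cfg.seed, 131, actor, action, view_idx, clip])
    return int(rng.integers(2**31))


def generate_dataset(cfg: DatasetConfig, out_dir: Path | None = None,
                     *, keep_in_memory: bool = True) -> DatasetIndex:
    """Render the complete factorial dataset described by ``cfg``.

    Emits exactly n_actors x n_actions x n_viewpoints x clips_per_condition
    clips. When ``out_dir`` is given, clips are written as per-clip
    directories of zero-padded PNG frames plus a ``manifest.csv``; otherwise
    (or additionally with ``keep_in_memory``) clips are held in memory.
    """
    records: list[ClipRecord] = []
    clips: dict[tuple, VideoTensor] = {}
    if out_dir is not None:
        out_dir = Path(out_dir)
        try:
            out_dir.mkdir(parents=True, exist_ok=True)
        except OSError as exc:
            raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc
    for actor in range(cfg.n_actors):
        for action in range(cfg.n_actions):
            for vi, view in enumerate(cfg.viewpoints):
                for ci in range(cfg.clips_per_condition):
                    vid = render_clip(actor, action, view, cfg,
                                      _clip_seed(cfg, actor, action, vi, ci))
                    vid.label = (actor, action, view, ci)
                    path = None
                    if out_dir is not None:
                        cdir = out_dir / f"a{actor}_x{action}_v{int(view)}_c{ci:03d}"
                        _write_clip_dir(cdir, vid)
                        path = str(cdir)
                    rec = ClipRecord(actor, action, view, ci, path)
                    records.append(rec)
                    if keep_in_memory:
                        clips[rec.key] = vid
    index = DatasetIndex(records, config=cfg, clips=clips)
    if out_dir is not None:
        index.to_manifest(out_dir / "manifest.csv")
    return index


def _write_clip_dir(cdir: Path, vid: VideoTensor) -> None:
    import imageio.v3 as iio

    cdir.mkdir(parents=True, exist_ok=True)
    arr = np.round(vid.pixels * 255).astype(np.uint8)
    for fi in range(arr.shape[2]):
        iio.imwrite(cdir / f"frame_{fi:04d}.png", arr[:, :, fi])


def _read_clip_dir(cdir: Path, record: ClipRecord) -> VideoTensor:
    import imageio.v3 as iio

    frames = sorted(cdir.glob("frame_*.png"))
    if not frames:
        raise FileNotFoundError(f"no frames found in {cdir}")
    arr = np.stack([iio.imread(f) for f in frames], axis=-1).astype(float) / 255.0
    return VideoTensor(arr, record.key)


# ---------------------------------------------------------------------------
# synthetic neural responses
# ---------------------------------------------------------------------------

@dataclass
class NeuralRecordingSet:
    """Subjects x stimuli x sensors responses with planted geometry."""

    responses: np.ndarray
    index: DatasetIndex
    params: dict
    seed: int

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        if self.responses.ndim != 3:
            raise ValueError("responses must be (subjects, stimuli, sensors)")
        if self.responses.shape[0] < 2:
            raise ValueError("need >= 2 subjects (leave-one-out noise ceiling)")
        if self.responses.shape[2] < 2:
            raise ValueError("need >= 2 sensors")
        if not np.all(np.isfinite(self.responses)):
            raise ValueError("responses contain non-finite entries")

    @property
    def n_subjects(self) -> int:
        return self.responses.shape[0]

    def subject_mean(self, exclude: int | None = None) -> np.ndarray:
        if exclude is None:
            return self.responses.mean(axis=0)
        keep = [s for s in range(self.n_subjects) if s != exclude]
        return self.responses[keep].mean(axis=0)

    def save(self, path: Path) -> None:
        np.savez(path, responses=self.responses, seed=self.seed,
                 **{f"param_{k}": v for k, v in self.params.items()})


def _one_hot_embedding(levels: Sequence) -> dict:
    uniq = sorted(set(levels))
    eye = np.eye(len(uniq))
    return {lvl: eye[i] for i, lvl in enumerate(uniq)}


def generate_neural_responses(
    index: DatasetIndex,
    n_subjects: int = 8,
    n_sensors: int = 306,
    action_w: float = 1.0,
    view_w: float = 0.25,
    actor_w: float = 0.25,
    noise_sd: float = 0.75,
    seed: int = 0,
) -> NeuralRecordingSet:
    """Multi-subject responses with a planted representational geometry.

    Each stimulus's latent vector concatenates weighted orthonormal one-hot
    embeddings of its action, viewpoint and actor labels; a fixed random
    linear projection maps latents to sensor space and each subject adds
    i.i.d. Gaussian noise of standard deviation ``noise_sd``. When the sensor
    count allows (n_sensors >= latent dimension) the projection is
    semi-orthogonal, so the planted geometry is preserved exactly — e.g.
    purely categorical action geometry yields equal dissimilarities for every
    between-action pair. Defaults emulate 8 subjects x 306 sensors with
    action-dominated geometry carrying weaker viewpoint and actor structure.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2 (noise ceiling is undefined otherwise)")
    if min(action_w, view_w, actor_w) < 0:
        raise ValueError("geometry weights must be >= 0")
    if action_w == view_w == actor_w == 0:
        raise ValueError("at least one geometry weight must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")

    emb_action = _one_hot_embedding([r.action for r in index])
    emb_view = _one_hot_embedding([r.viewpoint for r in index])
    emb_actor = _one_hot_embedding([r.actor for r in index])
    latents = np.stack([
        np.concatenate([
            action_w * emb_action[r.action],
            view_w * emb_view[r.viewpoint],
            actor_w * emb_actor[r.actor],
        ])
        for r in index
    ])  # (stimuli, latent_dim)

    rng = np.random.default_rng([seed, 613])
    d = latents.shape[1]
    if n_sensors >= d:
        # distance-preserving embedding of the latent space into sensor space
        q, _ = np.linalg.qr(rng.standard_normal((n_sensors, d)))
        proj = q.T
    else:
        proj = rng.standard_normal((d, n_sensors)) / math.sqrt(d)
    clean = latents @ proj
    noise = np.random.default_rng([seed, 807]).standard_normal(
        (n_subjects,) + clean.shape) * noise_sd
    params = dict(action_w=action_w, view_w=view_w, actor_w=actor_w,
                  noise_sd=noise_sd, n_subjects=n_subjects, n_sensors=n_sensors)
    return NeuralRecordingSet(clean[None] + noise, index, params, seed)
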