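"""End-to-end orchestration: generate -> banks/training -> features -> decode -> rsa -> report.

A single :class:`RunConfig` (YAML-mappable) fixes every stage parameter and a
global seed; every random draw is governed by the global seed plus a fixed
stage-specific offset, so a rerun with an unchanged config reproduces the
report payload exactly. Stage outputs are cached under the output root and
reloaded when the config hash matches, so a deleted intermediate is recomputed
to identical numbers.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .decoding import ClassifierSpec, ExperimentResult, run_experiment, significance_tests
from .gabor import build_conv1_bank
from .learned import (LearnedArch, TrainConfig, build_learned_model,
                      extract_learned_features, reduced_arch, train_model)
from .rsa import oracle_matrix, rsa_significance, score_models, spearman_lower, \
    dissimilarity_matrix
from .stcnn import FixedTemplateModel, make_pool_groups, sample_templates
from .synthetic import DatasetConfig, DatasetIndex, generate_dataset, \
    generate_neural_responses

log = logging.getLogger(__name__)

FIXED_MODELS = ("conv", "unstructured", "structured")
ALL_MODELS = FIXED_MODELS + ("learned",)

# stage-specific seed offsets
_SEED_OFFSETS = {"dataset": 11, "rsa_stimuli": 13, "bank": 17, "unstructured": 19,
                 "learned": 23, "neural": 29, "rsa": 31}


@dataclass
class RunConfig:
    """Complete configuration of one pipeline run.

    Defaults are the desk-scale study: a 3-actor x 5-action x 2-viewpoint
    dataset keeping all five base motion patterns, a reduced Gabor bank (8
    orientations x 1 speed x 1 size class, 2 pyramid scales -> 1 scale
    channel), 48 sampled second-layer templates and a reduced learned
    architecture. Synthetic neural responses carry action-dominant, largely
    view-invariant geometry.
    """

    seed: int = 0
    # dataset
    n_actors: int = 3
    n_actions: int = 5
    viewpoints: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0, 180.0)
    decode_viewpoints: tuple[float, float] = (0.0, 90.0)
    clips_per_condition: int = 3
    clip_len: int = 16
    frame_size: tuple[int, int] = (40, 28)
    fps: float = 8.0
    rsa_clips_per_condition: int = 2
    # fixed-template models
    orientations: tuple[float, ...] = (0, 45, 90, 135, 180, 225, 270, 315)
    speeds: tuple[float, ...] = (2.0,)
    size_classes: tuple[tuple[int, int], ...] = ((7, 3),)
    pyramid_factors: tuple[float, ...] = (1.0, 0.5)
    scale_pairs: tuple[tuple[int, int], ...] = ((0, 1),)
    pool1_region: tuple[int, int, int] = (2, 2, 1)
    pool1_stride: tuple[int, int, int] = (2, 2, 1)
    conv2_count: int = 80
    conv2_sizes: tuple[tuple[int, int, int], ...] = ((3, 3, 3),)
    # learned model
    learned_epochs: int = 30
    learned_lr: float = 0.05
    learned_batch: int = 10
    # neural generator
    n_subjects: int = 8
    n_sensors: int = 306
    action_w: float = 1.0
    view_w: float = 0.15
    actor_w: float = 0.15
    noise_sd: float = 0.6
    # rsa
    rsa_rounds: int = 50
    rsa_subset: int = 30
    ceiling_rounds: int = 100
    floor_rounds: int = 100
    # io
    out_root: str | None = None

    def dataset_config(self, *, rsa: bool = False) -> DatasetConfig:
        # the RSA stimulus set mirrors the neural-experiment design: the two
        # decode viewpoints only, with fresh clips
        offset = _SEED_OFFSETS["rsa_stimuli" if rsa else "dataset"]
        return DatasetConfig(
            n_actors=self.n_actors, n_actions=self.n_actions,
            viewpoints=(tuple(self.decode_viewpoints) if rsa
                        else tuple(self.viewpoints)),
            clips_per_condition=(self.rsa_clips_per_condition if rsa
                                 else self.clips_per_condition),
            clip_len=self.clip_len, frame_size=tuple(self.frame_size),
            fps=self.fps, seed=_stage_seed(self.seed, offset),
        )

    def learned_arch(self) -> LearnedArch:
        H, W = self.frame_size
        return reduced_arch((H, W, self.clip_len))

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_root", None)  # an IO location, not a study parameter
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=list).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for k, v in raw.items():
            kwargs[k] = _tuplify(v)
        return cls(**kwargs)

    def to_yaml(self, path: Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(asdict(self), default=list)), fh)


def _tuplify(v):
    if isinstance(v, list):
        return tuple(_tuplify(x) for x in v)
    return v


def _stage_seed(seed: int, offset: int) -> int:
    return int(np.random.default_rng([seed, offset]).integers(2**31))


@dataclass
class RunReport:
    """Aggregated results of one pipeline run, JSON-serializable."""

    config_hash: str
    seed: int
    version: str
    decoding: dict
    rsa: dict
    significance: dict

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def summary(self) -> str:
        lines = [f"pipeline run (seed {self.seed}, config {self.config_hash})"]
        for proto in ("match", "mismatch"):
            accs = ", ".join(
                f"{m}={self.decoding[m][proto]['mean']:.3f}" for m in ALL_MODELS
            )
            lines.append(f"  {proto:9s} accuracy: {accs}")
        scores = ", ".join(
            f"{m}={self.rsa[m]['normalized_score']:.3f}"
            for m in ALL_MODELS + ("oracle",)
        )
        lines.append(f"  normalized RSA: {scores}")
        return "\n".join(lines)


class Pipeline:
    """Runs the full analysis; construction is cheap, stages run lazily."""

    def __init__(self, config: RunConfig):
        self.cfg = config
        self.out = Path(config.out_root) if config.out_root else None
        if self.out:
            self.out.mkdir(parents=True, exist_ok=True)
            (self.out / "config.yaml").write_text(
                yaml.safe_dump(json.loads(json.dumps(asdict(config), default=list))))
        self._pool1_cache: dict = {}
        self._feature_cache: dict = {}
        self._learned_cache: dict = {}

    # -- stages -----------------------------------------------------------

    def dataset(self) -> DatasetIndex:
        if not hasattr(self, "_dataset"):
            log.info("stage dataset: generating %d clips",
                     self.cfg.dataset_config().n_clips)
            self._dataset = generate_dataset(self.cfg.dataset_config())
        return self._dataset

    def rsa_stimuli(self) -> DatasetIndex:
        if not hasattr(self, "_rsa_stimuli"):
            cfg = self.cfg.dataset_config(rsa=True)
            log.info("stage rsa_stimuli: generating %d clips", cfg.n_clips)
            self._rsa_stimuli = generate_dataset(cfg)
        return self._rsa_stimuli

    def decode_index(self) -> DatasetIndex:
        """Clips at the two decode viewpoints (classifier train/test pool)."""
        if not hasattr(self, "_decode_index"):
            full = self.dataset()
            keep = [r for r in full.records
                    if r.viewpoint in self.cfg.decode_viewpoints]
            self._decode_index = DatasetIndex(keep, clips=full.clips)
        return self._decode_index

    def base_model(self) -> FixedTemplateModel:
        """Conv1/Pool1 stack shared by all fixed-template models (no Conv2 yet)."""
        if not hasattr(self, "_base"):
            bank = build_conv1_bank(self.cfg.orientations, self.cfg.speeds,
                                    self.cfg.size_classes)
            self._base = FixedTemplateModel(
                conv1_bank=bank, conv2_bank=bank, pool_groups=None,
                pyramid_factors=tuple(self.cfg.pyramid_factors),
                scale_pairs=tuple(self.cfg.scale_pairs),
                pool1_region=tuple(self.cfg.pool1_region),
                pool1_stride=tuple(self.cfg.pool1_stride),
            )
        return self._base

    def pool1_responses(self, index: DatasetIndex, tag: str) -> list:
        key = tag
        if key not in self._pool1_cache:
            log.info("stage pool1[%s]: %d clips", tag, len(index))
            base = self.base_model()
            out = []
            for rec in index:
                clip = index.get_clip(rec)
                out.append((rec.key, base.pool1_responses(clip.pixels)))
            self._pool1_cache[key] = out
        return self._pool1_cache[key]

    def conv2_bank(self, embedding_actors: tuple | None):
        """Sampled once per embedding set and shared by all three fixed models."""
        key = embedding_actors
        if key not in self._feature_cache.setdefault("banks", {}):
            pool1 = self.pool1_responses(self.dataset(), "main")
            if embedding_actors is not None:
                pool1 = [(lbl, st) for lbl, st in pool1 if lbl[0] in embedding_actors]
            bank = sample_templates(pool1, self.cfg.conv2_sizes, self.cfg.conv2_count,
                                    seed=_stage_seed(self.cfg.seed, _SEED_OFFSETS["bank"]))
            self._feature_cache["banks"][key] = bank
        return self._feature_cache["banks"][key]

    def fixed_model(self, scheme: str, embedding_actors: tuple | None) -> FixedTemplateModel:
        bank = self.conv2_bank(embedding_actors)
        n_sc = len(self.cfg.scale_pairs)
        groups = make_pool_groups(
            bank, {"conv": "per-channel", "structured": "structured",
                   "unstructured": "unstructured"}[scheme],
            seed=_stage_seed(self.cfg.seed, _SEED_OFFSETS["unstructured"]),
            n_scale_channels=n_sc,
        )
        return replace(self.base_model(), conv2_bank=bank, pool_groups=groups)

    def _index_for(self, tag: str) -> DatasetIndex:
        return {"main": self.dataset, "decode": self.decode_index,
                "rsa": self.rsa_stimuli}[tag]()

    def fixed_features(self, scheme: str, index_tag: str,
                       embedding_actors: tuple | None) -> np.ndarray:
        key = (scheme, index_tag, embedding_actors)
        if key not in self._feature_cache:
            index = self._index_for(index_tag)
            model = self.fixed_model(scheme, embedding_actors)
            if index_tag == "decode":  # reuse the full-dataset Pool1 stacks
                wanted = {r.key for r in index}
                pool1 = [(k, s) for k, s in self.pool1_responses(self.dataset(), "main")
                         if k in wanted]
            else:
                pool1 = self.pool1_responses(index, index_tag)
            feats = []
            for _, stacks in pool1:
                conv2 = model.conv2_responses(stacks)
                feats.append(_pool2_signature(model, conv2))
            self._feature_cache[key] = np.asarray(feats)
        return self._feature_cache[key]

    def learned_features(self, index_tag: str,
                         embedding_actors: tuple | None) -> np.ndarray:
        key = (index_tag, embedding_actors)
        if key not in self._learned_cache:
            model = self._trained_model(embedding_actors)
            index = self._index_for(index_tag)
            clips = np.stack([index.get_clip(r).pixels for r in index])
            self._learned_cache[key] = extract_learned_features(model, clips)
        return self._learned_cache[key]

    def _trained_model(self, embedding_actors: tuple | None):
        key = ("model", embedding_actors)
        if key not in self._learned_cache:
            # trained on the embedding actors' clips at the decode viewpoints
            index = self.decode_index()
            recs = [r for r in index
                    if embedding_actors is None or r.actor in embedding_actors]
            clips = np.stack([index.get_clip(r).pixels for r in recs])
            labels = [r.action for r in recs]
            seed = _stage_seed(self.cfg.seed, _SEED_OFFSETS["learned"])
            model = build_learned_model(self.cfg.learned_arch(), self.cfg.n_actions,
                                        seed=seed)
            cfg = TrainConfig(batch_size=self.cfg.learned_batch,
                              learning_rate=self.cfg.learned_lr,
                              epochs=self.cfg.learned_epochs, seed=seed)
            log.info("stage learned[%s]: training on %d clips", embedding_actors,
                     len(recs))
            model, trace = train_model(model, clips, labels, cfg)
            model.loss_trace = trace
            self._learned_cache[key] = model
        return self._learned_cache[key]

    # -- experiments ------------------------------------------------------

    def decode(self) -> dict[str, dict[str, ExperimentResult]]:
        index = self.decode_index()
        results: dict[str, dict[str, ExperimentResult]] = {}
        for name in ALL_MODELS:
            results[name] = {}
            if name == "learned":
                fn = lambda emb: self.learned_features("decode", emb)
            else:
                fn = lambda emb, s=name: self.fixed_features(s, "decode", emb)
            for proto in ("match", "mismatch"):
                results[name][proto] = run_experiment(
                    fn, index, proto, tuple(self.cfg.decode_viewpoints))
                log.info("decode %s/%s: %.3f", name, proto, results[name][proto].mean)
        return results

    def rsa(self) -> dict:
        stimuli = self.rsa_stimuli()
        neural = generate_neural_responses(
            stimuli, n_subjects=self.cfg.n_subjects, n_sensors=self.cfg.n_sensors,
            action_w=self.cfg.action_w, view_w=self.cfg.view_w,
            actor_w=self.cfg.actor_w, noise_sd=self.cfg.noise_sd,
            seed=_stage_seed(self.cfg.seed, _SEED_OFFSETS["neural"]),
        )
        feats = {name: (self.learned_features("rsa", None) if name == "learned"
                        else self.fixed_features(name, "rsa", None))
                 for name in ALL_MODELS}
        results = score_models(
            feats, neural, rounds=self.cfg.rsa_rounds,
            subset=min(self.cfg.rsa_subset, len(stimuli)),
            ceiling_rounds=self.cfg.ceiling_rounds,
            floor_rounds=self.cfg.floor_rounds,
            seed=_stage_seed(self.cfg.seed, _SEED_OFFSETS["rsa"]),
        )
        # categorical oracle scored on the same floor/ceiling
        manifest = tuple(r.key for r in stimuli)
        D_neural = dissimilarity_matrix(neural.subject_mean(), manifest)
        D_oracle = oracle_matrix([r.action for r in stimuli], manifest)
        any_model = next(iter(results.values()))
        raw = spearman_lower(D_oracle, D_neural)
        from .rsa import RSAResult, bootstrap_rsa, normalize_score

        samples = bootstrap_rsa(D_oracle, D_neural, rounds=self.cfg.rsa_rounds,
                                subset=min(self.cfg.rsa_subset, len(stimuli)),
                                seed=any_model.seed)
        norm, oob = normalize_score(raw, any_model.floor, any_model.ceiling)
        results["oracle"] = RSAResult(raw, samples, any_model.floor,
                                      any_model.ceiling, norm, oob,
                                      self.cfg.rsa_rounds,
                                      min(self.cfg.rsa_subset, len(stimuli)),
                                      any_model.seed)
        return results

    def run(self) -> RunReport:
        cache = self.out / "report.json" if self.out else None
        chash = self.cfg.config_hash()
        if cache and cache.exists():
            payload = json.loads(cache.read_text())
            if payload.get("config_hash") == chash:
                log.info("loaded cached report for config %s", chash)
                return RunReport(**payload)
        decoding = self.decode()
        rsa_results = self.rsa()
        sig = {
            "decoding": {
                proto: significance_tests(
                    {m: decoding[m][proto] for m in ALL_MODELS},
                    learned_models=("learned",))
                for proto in ("match", "mismatch")
            },
            "rsa": rsa_significance(
                {m: rsa_results[m].samples for m in ALL_MODELS},
                learned_models=("learned",)),
        }
        report = RunReport(
            config_hash=chash, seed=self.cfg.seed, version=__version__,
            decoding={m: {p: r.to_dict() for p, r in d.items()}
                      for m, d in decoding.items()},
            rsa={m: r.to_dict() for m, r in rsa_results.items()},
            significance=sig,
        )
        if cache:
            cache.write_text(report.to_json())
        return report


def _pool2_signature(model: FixedTemplateModel, conv2: list) -> np.ndarray:
    n_sc = len(conv2)
    per_scale = [s.max(axis=(1, 2)) for s in conv2]
    t_min = min(s.shape[1] for s in per_scale)
    M = np.empty((len(model.conv2_bank) * n_sc, t_min))
    for sc, s in enumerate(per_scale):
        M[sc::n_sc] = s[:, :t_min]
    grouped = np.stack([M[g].max(axis=0) for g in model.pool_groups.groups])
    return grouped.max(axis=1)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage in dependency order and return the report."""
    return Pipeline(config).run()


# ---------------------------------------------------------------------------
# manifest validation
# ---------------------------------------------------------------------------

def validate_manifests(index: DatasetIndex,
                       feature_files: dict[str, np.ndarray] | None = None,
                       neural_manifest: list | None = None) -> dict:
    """Integrity checks: factorial completeness, label consistency, stimulus order.

    Returns a report dict with ``ok`` plus itemized problems.
    """
    problems = []
    if index.config is not None:
        cfg = index.config
        actors: tuple = tuple(range(cfg.n_actors))
        actions: tuple = tuple(range(cfg.n_actions))
        views: tuple = tuple(cfg.viewpoints)
        n_clips = cfg.clips_per_condition
    else:  # infer the factorial frame from the observed labels
        actors = tuple(sorted({r.actor for r in index.records}))
        actions = tuple(sorted({r.action for r in index.records}))
        views = tuple(sorted({r.viewpoint for r in index.records}))
        n_clips = max((r.clip for r in index.records), default=-1) + 1
    expected = {
        (a, x, v, c)
        for a in actors for x in actions for v in views for c in range(n_clips)
    }
    have = {r.key for r in index.records}
    for key in sorted(expected - have):
        problems.append(f"missing clip for cell {key}")
    for key in sorted(have - expected):
        problems.append(f"unexpected clip {key}")
    keys = [r.key for r in index.records]
    if feature_files:
        for name, F in feature_files.items():
            if np.asarray(F).shape[0] != len(keys):
                problems.append(
                    f"feature file {name!r}: {np.asarray(F).shape[0]} rows for "
                    f"{len(keys)} stimuli"
                )
    if neural_manifest is not None and list(neural_manifest) != keys:
        problems.append("stimulus-order mismatch between neural data and dataset index")
    return {"ok": not problems, "problems": problems}
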