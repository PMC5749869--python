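"""Representational similarity analysis.

A representation of a stimulus set — model feature matrix, neural response
matrix, or an idealized oracle — is summarized by its empirical dissimilarity
matrix: one minus the Pearson correlation between the representation vectors
of every stimulus pair, min-max normalized over the off-diagonal to [0, 1].
Two representations are compared by the Spearman rank correlation (SCC) of
the strictly-lower-triangular parts of their dissimilarity matrices.
Uncertainty comes from subsample bootstrap over stimuli; scores are anchored
by a noise ceiling (each subject against the mean of the others) and a noise
floor (models against a row/column-scrambled neural matrix) and reported on
the normalized scale where the floor is 0 and the ceiling is 1.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .synthetic import NeuralRecordingSet

__all__ = [
    "DissimilarityMatrix",
    "RSAResult",
    "dissimilarity_matrix",
    "oracle_matrix",
    "spearman_lower",
    "bootstrap_rsa",
    "noise_ceiling",
    "noise_floor",
    "normalize_score",
    "rsa_significance",
    "score_models",
]


@dataclass
class DissimilarityMatrix:
    """n x n symmetric zero-diagonal dissimilarities in [0, 1].

    ``manifest`` identifies the stimuli (row order); ``norm_record`` stores
    the (min, max) used for min-max normalization, or None for matrices that
    are binary by construction (oracles).
    """

    values: np.ndarray
    manifest: tuple = ()
    norm_record: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"dissimilarity matrix must be square, got {v.shape}")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-10):
            raise ValueError("dissimilarity matrix must have a zero diagonal")
        off = v[~np.eye(v.shape[0], dtype=bool)]
        if off.size and (off.min() < -1e-10 or off.max() > 1 + 1e-10):
            raise ValueError("off-diagonal dissimilarities must lie in [0, 1]")
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 0.0)
        self.values = np.clip(v, 0.0, 1.0)
        self.manifest = tuple(self.manifest) or tuple(range(v.shape[0]))
        if len(self.manifest) != v.shape[0]:
            raise ValueError("manifest length must match matrix size")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def restrict(self, idx: Sequence[int]) -> "DissimilarityMatrix":
        idx = np.asarray(idx)
        return DissimilarityMatrix(
            self.values[np.ix_(idx, idx)],
            manifest=tuple(self.manifest[i] for i in idx),
            norm_record=self.norm_record,
        )

    def lower(self) -> np.ndarray:
        i, j = np.tril_indices(self.n, k=-1)
        return self.values[i, j]

    def to_csv(self, path: Path) -> None:
        with open(path, "w") as fh:
            fh.write("# manifest: " + json.dumps(list(map(str, self.manifest))) + "\n")
            np.savetxt(fh, self.values, delimiter=",")


def dissimilarity_matrix(features: np.ndarray, manifest: tuple = ()) -> DissimilarityMatrix:
    """Correlation-based dissimilarity of a stimuli x dims representation.

    d(i, j) = 1 - Pearson(features[i], features[j]), then min-max normalized
    over the off-diagonal entries; the diagonal is forced to 0.
    """
    F = np.asarray(features, dtype=float)
    if F.ndim != 2 or F.shape[0] < 3:
        raise ValueError(f"need a (stimuli >= 3) x dims matrix, got shape {F.shape}")
    sd = F.std(axis=1)
    bad = np.nonzero(sd == 0)[0]
    if bad.size:
        ids = [manifest[i] if manifest else i for i in bad[:5]]
        raise ValueError(
            f"constant feature vector(s) make correlation undefined for stimuli {ids}"
        )
    d = 1.0 - np.corrcoef(F)
    np.fill_diagonal(d, 0.0)
    off = ~np.eye(d.shape[0], dtype=bool)
    lo, hi = d[off].min(), d[off].max()
    if hi > lo:
        d[off] = (d[off] - lo) / (hi - lo)
    else:
        d[off] = 0.0
    return DissimilarityMatrix(d, manifest=manifest, norm_record=(float(lo), float(hi)))


def oracle_matrix(labels: Sequence, manifest: tuple = ()) -> DissimilarityMatrix:
    """Idealized categorical dissimilarity: 0 within a class, 1 across classes."""
    labels = list(labels)
    if not labels:
        raise ValueError("labels must be non-empty")
    level_id = {lvl: i for i, lvl in enumerate(dict.fromkeys(labels))}
    arr = np.asarray([level_id[l] for l in labels])
    d = (arr[:, None] != arr[None, :]).astype(float)
    return DissimilarityMatrix(d, manifest=manifest)


def spearman_lower(A: DissimilarityMatrix, B: DissimilarityMatrix) -> float:
    """Spearman rank correlation of the strictly-lower-triangle entries."""
    if A.manifest != B.manifest:
        raise ValueError("dissimilarity matrices cover different stimulus manifests")
    rho = stats.spearmanr(A.lower(), B.lower()).statistic
    return float(rho)


def bootstrap_rsa(
    D_model: DissimilarityMatrix,
    D_neural: DissimilarityMatrix,
    rounds: int = 50,
    subset: int = 30,
    seed: int = 0,
) -> np.ndarray:
    """Subsample-bootstrap SCC samples between two dissimilarity matrices.

    Each round draws ``subset`` stimuli uniformly without replacement,
    restricts both matrices to them, and records the lower-triangle SCC.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    if subset < 3:
        raise ValueError("subset must be >= 3 (need at least 3 pairs to rank)")
    if subset > D_model.n:
        raise ValueError(f"subset {subset} exceeds the {D_model.n} available stimuli")
    rng = np.random.default_rng(seed)
    out = np.empty(rounds)
    for r in range(rounds):
        idx = rng.choice(D_model.n, size=subset, replace=False)
        out[r] = spearman_lower(D_model.restrict(idx), D_neural.restrict(idx))
    return out


def noise_ceiling(
    neural: NeuralRecordingSet,
    rounds: int = 100,
    subset: int | None = None,
    seed: int = 0,
) -> float:
    """Highest subject-vs-mean-of-rest SCC across subjects and bootstrap rounds."""
    manifest = tuple(r.key for r in neural.index)
    n_stim = neural.responses.shape[1]
    subset = subset if subset is not None else min(30, n_stim)
    best = -np.inf
    for s in range(neural.n_subjects):
        D_s = dissimilarity_matrix(neural.responses[s], manifest)
        D_rest = dissimilarity_matrix(neural.subject_mean(exclude=s), manifest)
        samples = bootstrap_rsa(D_s, D_rest, rounds=rounds, subset=subset,
                                seed=np.random.default_rng([seed, 41, s]).integers(2**31))
        best = max(best, float(samples.max()))
    return best


def noise_floor(
    models: Sequence[DissimilarityMatrix],
    D_neural: DissimilarityMatrix,
    rounds: int = 100,
    seed: int = 0,
) -> float:
    """Highest model-vs-scrambled-neural SCC across rounds and models.

    Each round applies one random permutation simultaneously to the rows and
    columns of the neural matrix (preserving symmetry) before scoring.
    """
    if not models:
        raise ValueError("need at least one model matrix")
    rng = np.random.default_rng(seed)
    best = -np.inf
    n = D_neural.n
    for _ in range(rounds):
        perm = rng.permutation(n)
        D_scr = DissimilarityMatrix(
            D_neural.values[np.ix_(perm, perm)], manifest=D_neural.manifest
        )
        for D_m in models:
            best = max(best, spearman_lower(D_m, D_scr))
    return float(best)


def normalize_score(raw: float, floor: float, ceiling: float) -> tuple[float, bool]:
    """(raw - floor) / (ceiling - floor); flag marks scores outside [0, 1]."""
    if ceiling <= floor:
        raise ValueError(
            f"degenerate normalization: ceiling {ceiling} <= floor {floor}"
        )
    score = (raw - floor) / (ceiling - floor)
    return float(score), not (0.0 <= score <= 1.0)


@dataclass
class RSAResult:
    """Raw and normalized agreement of one model with the neural data."""

    raw: float
    samples: np.ndarray
    floor: float
    ceiling: float
    normalized: float
    out_of_range: bool
    rounds: int
    subset: int
    seed: int

    @property
    def sample_sd(self) -> float:
        return float(np.std(self.samples, ddof=1)) if len(self.samples) > 1 else 0.0

    def to_dict(self) -> dict:
        return {
            "raw_scc": self.raw,
            "noise_floor": self.floor,
            "noise_ceiling": self.ceiling,
            "normalized_score": self.normalized,
            "out_of_range": self.out_of_range,
            "bootstrap_rounds": self.rounds,
            "bootstrap_subset": self.subset,
            "bootstrap_sd": self.sample_sd,
            "seed": self.seed,
        }

    def summary(self) -> str:
        return (
            f"raw SCC {self.raw:+.3f}  floor {self.floor:+.3f}  "
            f"ceiling {self.ceiling:+.3f}  normalized {self.normalized:+.3f}"
            f"{'  (outside [0,1])' if self.out_of_range else ''}"
        )


def score_models(
    model_features: dict[str, np.ndarray],
    neural: NeuralRecordingSet,
    rounds: int = 50,
    subset: int = 30,
    ceiling_rounds: int = 100,
    floor_rounds: int = 100,
    seed: int = 0,
) -> dict[str, RSAResult]:
    """Full RSA of several model feature matrices against one recording set.

    The headline neural dissimilarity matrix is computed from the
    subject-averaged responses; per-subject matrices enter only the ceiling.
    """
    manifest = tuple(r.key for r in neural.index)
    subset = min(subset, len(manifest))
    D_neural = dissimilarity_matrix(neural.subject_mean(), manifest)
    D_models = {name: dissimilarity_matrix(F, manifest)
                for name, F in model_features.items()}
    ceil = noise_ceiling(neural, rounds=ceiling_rounds, subset=subset,
                         seed=int(np.random.default_rng([seed, 3]).integers(2**31)))
    floor = noise_floor(list(D_models.values()), D_neural, rounds=floor_rounds,
                        seed=int(np.random.default_rng([seed, 5]).integers(2**31)))
    out = {}
    for name, D_m in D_models.items():
        raw = spearman_lower(D_m, D_neural)
        bs_seed = int(np.random.default_rng([seed, 7]).integers(2**31))
        samples = bootstrap_rsa(D_m, D_neural, rounds=rounds, subset=subset, seed=bs_seed)
        norm, oob = normalize_score(raw, floor, ceil)
        out[name] = RSAResult(raw, samples, floor, ceil, norm, oob, rounds, subset, bs_seed)
    return out


def rsa_significance(
    samples_by_model: dict[str, np.ndarray],
    learned_models: Sequence[str] = (),
    alpha: float = 0.05,
) -> dict:
    """Group ANOVA (fixed vs learned) plus Bonferroni-corrected paired t-tests.

    Bootstrap samples must be paired across models (same rounds and seed).
    """
    names = list(samples_by_model)
    lengths = {len(v) for v in samples_by_model.values()}
    if len(lengths) != 1:
        raise ValueError("bootstrap sample vectors must have equal, paired lengths")
    report: dict = {"pairwise": {}, "alpha": alpha}
    fixed = [np.asarray(samples_by_model[n]) for n in names if n not in learned_models]
    learned = [np.asarray(samples_by_model[n]) for n in names if n in learned_models]
    if fixed and learned:
        F, p = stats.f_oneway(np.concatenate(fixed), np.concatenate(learned))
        report["group_anova"] = {"F": float(F), "p": float(p),
                                 "significant": bool(p < alpha)}
    m = len(names) * (len(names) - 1) // 2
    report["bonferroni_factor"] = m
    for a, b in itertools.combinations(names, 2):
        report["pairwise"][f"{a} vs {b}"] = _paired_test(
            np.asarray(samples_by_model[a]), np.asarray(samples_by_model[b]),
            alpha / max(m, 1))
    return report


def _paired_test(x: np.ndarray, y: np.ndarray, threshold: float) -> dict:
    """Paired t-test with an exact fast path for zero-variance differences."""
    d = x - y
    if np.allclose(d.std(ddof=0), 0.0):
        if np.allclose(d, 0.0):
            return {"t": 0.0, "p": 1.0, "significant": False,
                    "note": "identical samples"}
        return {"t": float(np.inf) * np.sign(d.mean()), "p": 0.0,
                "significant": True, "note": "constant nonzero difference"}
    t, p = stats.ttest_rel(x, y)
    return {"t": float(t), "p": float(p), "significant": bool(p < threshold)}
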