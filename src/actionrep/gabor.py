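"""Moving Gabor filter bank for the first convolutional layer.

The first layer of the fixed-template models consists of spatiotemporal
templates obtained by letting an oriented Gabor receptive field drift at a
constant speed in the direction orthogonal to its preferred orientation,
modulated in time by a biphasic temporal kernel — the classic V1/MT motion
template. A template is fully described by a :class:`GaborSpec`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "GaborSpec",
    "Template",
    "TemplateBank",
    "temporal_kernel",
    "make_gabor_template",
    "build_conv1_bank",
    "DEFAULT_ORIENTATIONS",
    "DEFAULT_SPEEDS",
    "DEFAULT_SIZE_CLASSES",
]

#: Preferred orientations in degrees with respect to vertical.
DEFAULT_ORIENTATIONS: tuple[float, ...] = (0, 45, 90, 135, 180, 225, 270, 315)

#: Drift speeds in px/frame: a 3-point linear grid between 4/3 and 4.
DEFAULT_SPEEDS: tuple[float, ...] = (4 / 3, 8 / 3, 4.0)

#: Spatial size S (px, odd) and temporal extent T (frames) per size class.
DEFAULT_SIZE_CLASSES: tuple[tuple[int, int], ...] = ((7, 3), (9, 4), (11, 5))


def temporal_kernel(
    t: float | np.ndarray,
    n: int = 3,
    k: float = 1.0,
    form: str = "canonical",
) -> float | np.ndarray:
    """Biphasic temporal modulation f(t) of the moving-Gabor templates.

    Parameters
    ----------
    t : scalar or array
        Time in frames, t >= 0.
    n : int
        Kernel order (default 3).
    k : float
        Rate in 1/frame; sets the time scale of the two lobes.
    form : {"canonical", "literal"}
        ``canonical`` is the motion-energy form
        ``(kt)^n e^{-kt} [1/n! - (kt)^2/(n+2)!]``; ``literal`` keeps the
        prefactor ``(kt)^2`` and a Gaussian decay ``e^{-(kt)^2}`` instead.

    Notes
    -----
    Both forms vanish at t = 0 and change sign exactly once, at
    ``kt = sqrt((n+2)!/n!) = sqrt((n+1)(n+2))``, where the bracket crosses
    zero; the kernel is excitatory then inhibitory (biphasic).
    """
    if n < 1:
        raise ValueError(f"temporal kernel order n must be >= 1, got {n}")
    if k <= 0:
        raise ValueError(f"temporal kernel rate k must be > 0, got {k}")
    kt = k * np.asarray(t, dtype=float)
    bracket = 1.0 / math.factorial(n) - kt**2 / math.factorial(n + 2)
    if form == "canonical":
        out = kt**n * np.exp(-kt) * bracket
    elif form == "literal":
        out = kt**2 * np.exp(-(kt**2)) * bracket
    else:
        raise ValueError(f"unknown temporal kernel form {form!r}")
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class GaborSpec:
    """Parameters of one moving Gabor template.

    ``sigma`` defaults to 0.6*S, ``lam`` (carrier wavelength) to 2*sqrt(2)*sigma
    and ``k`` to 2n/T so that the positive lobe of the temporal kernel peaks
    near the temporal midpoint.
    """

    theta: float  # orientation, degrees w.r.t. vertical
    rho: float  # drift speed, px/frame, orthogonal to theta
    S: int  # spatial extent, px (odd)
    T: int  # temporal extent, frames
    sigma: float | None = None
    lam: float | None = None
    n: int = 3
    k: float | None = None
    form: str = "canonical"

    def __post_init__(self) -> None:
        if self.S < 1 or self.S % 2 == 0:
            raise ValueError(f"spatial size S must be odd and >= 1, got {self.S}")
        if self.T < 1:
            raise ValueError(f"temporal size T must be >= 1, got {self.T}")
        if self.rho < 0:
            raise ValueError(f"drift speed rho must be >= 0, got {self.rho}")
        if self.n < 1:
            raise ValueError(f"order n must be >= 1, got {self.n}")
        if self.sigma is None:
            object.__setattr__(self, "sigma", 0.6 * self.S)
        if self.lam is None:
            object.__setattr__(self, "lam", 2.0 * math.sqrt(2.0) * self.sigma)
        if self.k is None:
            object.__setattr__(self, "k", 2.0 * self.n / self.T)
        if self.k <= 0:
            raise ValueError(f"rate k must be > 0, got {self.k}")
        if self.form not in ("canonical", "literal"):
            raise ValueError(f"unknown temporal kernel form {self.form!r}")

    @property
    def size_class(self) -> tuple[int, int]:
        return (self.S, self.T)


@dataclass
class Template:
    """A spatiotemporal template: weights (h, w, t) plus provenance metadata.

    ``meta`` is a :class:`GaborSpec` for layer-1 templates, or a dict with
    sampling provenance (actor, action, viewpoint, size_class, scale_channel,
    clip, position) for layer-2 templates, where the weights then carry an
    extra leading channel axis (c, h, w, t).
    """

    weights: np.ndarray
    meta: object = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("template weights must be finite")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.weights.shape


@dataclass
class TemplateBank:
    """Ordered collection of templates grouped by size class."""

    templates: list[Template] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.templates)

    def __iter__(self):
        return iter(self.templates)

    def __getitem__(self, i: int) -> Template:
        return self.templates[i]

    def size_classes(self) -> list[tuple[int, ...]]:
        """Distinct (spatial, temporal) template extents, in insertion order."""
        seen: list[tuple[int, ...]] = []
        for tpl in self.templates:
            sc = tpl.weights.shape[-3:]
            if sc not in seen:
                seen.append(sc)
        # all templates of one size class must share dimensions
        return seen

    def by_size_class(self) -> dict[tuple[int, ...], list[int]]:
        groups: dict[tuple[int, ...], list[int]] = {}
        for i, tpl in enumerate(self.templates):
            groups.setdefault(tpl.weights.shape[-3:], []).append(i)
        return groups


def make_gabor_template(spec: GaborSpec) -> Template:
    """Evaluate a moving Gabor on an S x S x T grid.

    The Gabor envelope and carrier translate together by ``rho`` px per frame
    along the direction orthogonal to the preferred orientation; the shift in
    the first frame is chosen so the envelope trajectory is centred on the
    middle frame. The temporal kernel is evaluated at t = 1..T (it vanishes
    identically at t = 0). The template is mean-subtracted and l2-normalized.
    """
    S, T = spec.S, spec.T
    half = (S - 1) / 2.0
    coords = np.arange(S, dtype=float) - half
    # row index = vertical (y, increasing downward), column index = horizontal (x)
    y, x = np.meshgrid(coords, coords, indexing="ij")
    th = math.radians(spec.theta)
    # axis along the orientation and the orthogonal (drift) axis
    xo = x * math.cos(th) + y * math.sin(th)
    yo = -x * math.sin(th) + y * math.cos(th)

    w = np.empty((S, S, T), dtype=float)
    f = temporal_kernel(np.arange(1, T + 1), n=spec.n, k=spec.k, form=spec.form)
    for ti in range(T):
        shift = spec.rho * (ti - (T - 1) / 2.0)
        yo_t = yo - shift
        envelope = np.exp(-(xo**2 + yo_t**2) / (2.0 * spec.sigma**2))
        carrier = np.cos(2.0 * math.pi * yo_t / spec.lam)
        w[:, :, ti] = f[ti] * envelope * carrier

    w -= w.mean()
    nrm = np.linalg.norm(w)
    if nrm > 0:
        w /= nrm
    return Template(w, meta=spec)


def build_conv1_bank(
    orientations: Sequence[float] = DEFAULT_ORIENTATIONS,
    speeds: Sequence[float] = DEFAULT_SPEEDS,
    size_classes: Sequence[tuple[int, int]] = DEFAULT_SIZE_CLASSES,
    *,
    form: str = "canonical",
    k: float | None = None,
) -> TemplateBank:
    """One moving-Gabor template per (orientation, speed, size class).

    Defaults give the 8 x 3 x 3 = 72-template first-layer bank.
    """
    for name, grid in (("orientations", orientations), ("speeds", speeds),
                       ("size_classes", size_classes)):
        if len(grid) == 0:
            raise ValueError(f"{name} grid must be non-empty")
        if len(set(map(tuple, grid)) if name == "size_classes" else set(grid)) != len(grid):
            raise ValueError(f"duplicate grid points in {name}: {grid}")
    bank = TemplateBank()
    for (S, T) in size_classes:
        for theta in orientations:
            for rho in speeds:
                spec = GaborSpec(theta=theta, rho=rho, S=S, T=T, form=form, k=k)
                bank.templates.append(make_gabor_template(spec))
    return bank
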