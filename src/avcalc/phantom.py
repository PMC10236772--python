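"""Digital CT phantoms with analytically known calcium scores.

The generator builds simple axis-aligned volumes: a soft-tissue background
(default -50 HU), box or ellipsoid lesion plateaus placed in patient space
(voxel-center membership, later lesions overwrite earlier ones), optional
additive Gaussian noise, and a set of annulus landmarks. Lesions carry an
anatomical tag (aortic / mitral / coronary / sinus) so decoy calcium
outside the annular slab — the structures a reader would exclude — can be
simulated, including mitral calcium touching aortic calcium across the
slab boundary.

``expected_agatston`` is a deliberately independent re-derivation of the
ground-truth score (its own rasterisation, slab test, flood fill and
weight logic), used as the oracle against the production pipeline. It is
exact for noise-free phantoms and, in robust mode, for noisy phantoms
whose plateau values keep a wide margin from every weight boundary.

No partial-volume, beam-hardening, motion or contrast effects are
modelled: ground truth stays exact by construction.
"""

from __future__ import annotations

import math
import warnings
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .agatston import ScoringConfig, DEFAULT_CONFIG
from .agreement_stats import PairedScores
from .ct_io import CTVolume, LandmarkSet
from .geometry import ROISlab

_TAGS = ("aortic", "mitral", "coronary", "sinus")


@dataclass(frozen=True)
class LesionPrimitive:
    """A homogeneous calcific lesion: box or ellipsoid plateau in mm space."""

    shape: str                      # "box" | "ellipsoid"
    center: tuple[float, float, float]   # mm, patient space
    half_sizes: tuple[float, float, float]  # mm
    plateau_hu: float
    tag: str = "aortic"

    def __post_init__(self) -> None:
        if self.shape not in ("box", "ellipsoid"):
            raise ValueError(f"lesion shape must be 'box' or 'ellipsoid', got {self.shape!r}")
        if self.tag not in _TAGS:
            raise ValueError(f"lesion tag must be one of {_TAGS}, got {self.tag!r}")
        if any(h <= 0 for h in self.half_sizes):
            raise ValueError("half_sizes must be strictly positive")
        if self.plateau_hu < -1024:
            raise ValueError("plateau HU below the air floor (-1024)")

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Voxel-center membership test; points shape (..., 3), mm."""
        rel = (np.asarray(points, float) - np.asarray(self.center)) / np.asarray(self.half_sizes)
        if self.shape == "box":
            return np.all(np.abs(rel) <= 1.0, axis=-1)
        return np.sum(rel**2, axis=-1) <= 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative description of a synthetic scored CT study."""

    grid_shape: tuple[int, int, int] = (64, 64, 24)
    spacing: tuple[float, float, float] = (0.5, 0.5, 3.0)
    background_hu: float = -50.0
    lesions: tuple[LesionPrimitive, ...] = ()
    noise_sd: float = 0.0
    seed: int = 0
    landmarks: LandmarkSet | None = None

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.grid_shape) or any(s <= 0 for s in self.spacing):
            raise ValueError("grid_shape and spacing must be strictly positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        extent = np.asarray(self.grid_shape) * np.asarray(self.spacing)
        for les in self.lesions:
            c = np.asarray(les.center)
            h = np.asarray(les.half_sizes)
            if np.any(c - h < -np.asarray(self.spacing)) or np.any(c + h > extent + np.asarray(self.spacing)):
                raise ValueError(
                    f"lesion at {les.center} with half sizes {les.half_sizes} "
                    f"extends outside the grid (extent {tuple(extent)})"
                )

    @property
    def default_landmarks(self) -> LandmarkSet:
        """Landmarks placed mid-volume if none were supplied: an annulus
        plane halfway up the slice stack with the aortic side toward
        increasing slice index."""
        if self.landmarks is not None:
            return self.landmarks
        extent = np.asarray(self.grid_shape) * np.asarray(self.spacing)
        cx, cy, cz = extent / 2.0
        r = min(cx, cy) / 2.0
        nadirs = np.array(
            [[cx + r, cy, cz], [cx - r / 2, cy + r, cz], [cx - r / 2, cy - r, cz]]
        )
        return LandmarkSet(nadir_points=nadirs, aortic_reference=np.array([cx, cy, cz + max(self.spacing[2], 1.0)]))


def _rasterize(spec: PhantomSpec) -> tuple[np.ndarray, list[int]]:
    """Noise-free HU grid plus per-lesion voxel counts (overwrite order)."""
    shape = spec.grid_shape
    idx = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1)
    centers = idx * np.asarray(spec.spacing)  # origin (0,0,0), identity orientation
    hu = np.full(shape, float(spec.background_hu))
    owner = np.full(shape, -1, dtype=int)
    for li, les in enumerate(spec.lesions):
        inside = les.contains(centers)
        hu[inside] = les.plateau_hu
        owner[inside] = li
    counts = [int(np.sum(owner == li)) for li in range(len(spec.lesions))]
    return hu, counts


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, LandmarkSet, dict]:
    """Build the phantom volume, its landmarks, and a ground-truth record.

    The volume has identity orientation and origin (0, 0, 0); voxel (i,j,k)
    is centered at ``index * spacing``. Deterministic: the same spec and
    seed yield a bit-identical volume. The ground-truth record lists each
    lesion's surviving voxel count (after overwrite by later lesions) and
    plateau, and warns about overlaps between differently tagged lesions.
    """
    hu, counts = _rasterize(spec)
    warnings_list = []
    for i, a in enumerate(spec.lesions):
        for j in range(i + 1, len(spec.lesions)):
            b = spec.lesions[j]
            if a.tag != b.tag:
                gap = np.abs(np.asarray(a.center) - np.asarray(b.center))
                reach = np.asarray(a.half_sizes) + np.asarray(b.half_sizes)
                if np.all(gap <= reach):
                    msg = (
                        f"lesions {i} ({a.tag}) and {j} ({b.tag}) overlap or touch; "
                        "later lesion overwrites"
                    )
                    warnings_list.append(msg)
                    warnings.warn(msg, stacklevel=2)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        hu = hu + rng.normal(0.0, spec.noise_sd, size=hu.shape)
    volume = CTVolume(
        voxels=hu,
        spacing=np.asarray(spec.spacing, float),
        origin=np.zeros(3),
        orientation=np.eye(3),
    )
    truth = {
        "lesions": [
            {
                "tag": les.tag,
                "shape": les.shape,
                "plateau_hu": les.plateau_hu,
                "voxel_count": counts[i],
            }
            for i, les in enumerate(spec.lesions)
        ],
        "background_hu": spec.background_hu,
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
        "warnings": warnings_list,
    }
    return volume, spec.default_landmarks, truth


# ---------------------------------------------------------------------------
# independent scoring oracle


def expected_agatston(
    spec: PhantomSpec,
    slab: ROISlab,
    config: ScoringConfig = DEFAULT_CONFIG,
) -> float:
    """Ground-truth Agatston score of a phantom by direct enumeration.

    This is a separate code path from the production pipeline: it
    rasterises the noise-free lesions, tests each voxel center against the
    slab by an explicit point-plane dot product, thresholds, finds
    per-slice 8-connected components with its own flood fill, weights by
    an explicit if-chain on peak HU, and sums the weighted areas.

    With noise (robust mode) the noise-free expectation is returned only
    when every plateau and the background keep a margin of at least
    5 * noise_sd from the detection threshold and every weight boundary;
    otherwise the ground truth is ambiguous and the call refuses.
    """
    if spec.noise_sd > 0:
        margins = [abs(spec.background_hu - config.threshold_hu)]
        boundaries = (config.threshold_hu,) + tuple(config.weight_boundaries)
        for les in spec.lesions:
            for b in boundaries:
                margins.append(abs(les.plateau_hu - b))
        if min(margins) < 5.0 * spec.noise_sd:
            raise ValueError(
                "robust-mode margin violated: a plateau or the background is "
                f"within 5*noise_sd = {5*spec.noise_sd:.1f} HU of a scoring boundary"
            )
    hu, _ = _rasterize(spec)
    ni, nj, nk = spec.grid_shape
    sx, sy, sz = spec.spacing
    p0 = slab.plane.point
    n = slab.plane.normal

    candidate: set[tuple[int, int, int]] = set()
    for i, j, k in np.argwhere(hu >= config.threshold_hu):
        center = np.array([i * sx, j * sy, k * sz])
        d = float(np.dot(center - p0, n))
        if slab.lower_offset_mm <= d <= slab.upper_offset_mm:
            candidate.add((int(i), int(j), int(k)))

    if config.connectivity_2d == 8:
        neigh = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    else:
        neigh = [(-1, 0), (1, 0), (0, -1), (0, 1)]

    pixel_area = sx * sy
    factor = sz / config.thickness_reference_mm
    terms: list[float] = []
    visited: set[tuple[int, int, int]] = set()
    for start in sorted(candidate):
        if start in visited:
            continue
        k = start[2]
        component = []
        queue = deque([start])
        visited.add(start)
        while queue:
            ci, cj, ck = queue.popleft()
            component.append((ci, cj, ck))
            for di, dj in neigh:
                nb = (ci + di, cj + dj, ck)
                if nb in candidate and nb not in visited:
                    visited.add(nb)
                    queue.append(nb)
        area = len(component) * pixel_area
        if area < config.min_lesion_area_mm2:
            continue
        peak = max(hu[c] for c in component)
        b = config.weight_boundaries
        if peak < b[0]:
            w = 0
        elif peak < b[1]:
            w = 1
        elif peak < b[2]:
            w = 2
        elif peak < b[3]:
            w = 3
        elif peak > b[3] or config.hi_bin_inclusive:
            w = 4
        else:
            w = 3
        terms.append(area * w * factor)
    return math.fsum(terms)


def random_phantom_spec(rng: np.random.Generator, max_extent_voxels: int = 48) -> PhantomSpec:
    """Draw a randomized noise-free phantom spec with random geometry.

    Random grid size and spacing, an obliquely oriented annulus (random
    non-degenerate nadir triangle inside the volume), and 0-6 box/ellipsoid
    lesions with plateaus spread over the calcium density range, tagged
    aortic or as decoys. Intended for oracle-equivalence sweeps.
    """
    shape = tuple(int(rng.integers(12, max_extent_voxels + 1)) for _ in range(2)) + (
        int(rng.integers(6, 20)),
    )
    spacing = (
        float(rng.choice([0.4, 0.5, 0.6, 0.7])),
        float(rng.choice([0.4, 0.5, 0.6, 0.7])),
        float(rng.choice([1.5, 2.5, 3.0])),
    )
    extent = np.asarray(shape) * np.asarray(spacing)

    while True:  # rejection-sample a well-conditioned nadir triangle
        nadirs = rng.uniform(0.25, 0.75, size=(3, 3)) * extent
        cross = np.cross(nadirs[1] - nadirs[0], nadirs[2] - nadirs[0])
        if np.linalg.norm(cross) / 2 > 1.0:  # area > 1 mm^2
            break
    normal = cross / np.linalg.norm(cross)
    ref = nadirs.mean(axis=0) + normal * float(rng.choice([-10.0, 10.0]))
    landmarks = LandmarkSet(nadir_points=nadirs, aortic_reference=ref)

    n_lesions = int(rng.integers(0, 7))
    lesions = []
    for _ in range(n_lesions):
        center = rng.uniform(0.15, 0.85, size=3) * extent
        room = np.minimum(center, extent - center)  # stay inside the grid
        half = tuple(
            float(rng.uniform(0.3, max(0.35, min(4.0, r)))) for r in room
        )
        center = tuple(float(c) for c in center)
        lesions.append(
            LesionPrimitive(
                shape=str(rng.choice(["box", "ellipsoid"])),
                center=center,
                half_sizes=half,
                plateau_hu=float(rng.uniform(131.0, 1500.0)),
                tag=str(rng.choice(_TAGS)),
            )
        )
    return PhantomSpec(
        grid_shape=shape,
        spacing=spacing,
        background_hu=-50.0,
        lesions=tuple(lesions),
        noise_sd=0.0,
        seed=int(rng.integers(0, 2**31 - 1)),
        landmarks=landmarks,
    )


# ---------------------------------------------------------------------------
# paired-score simulation for the agreement statistics


def simulate_paired_scores(
    n: int,
    between_sd: float,
    error_sd_a: float,
    error_sd_b: float,
    bias_b: float = 0.0,
    seed: int = 0,
    mean_score: float = 3400.0,
) -> PairedScores:
    """Simulate per-subject paired Agatston readings.

    Each subject's true score is Normal(mean_score, between_sd^2) truncated
    at 0 (calcium scores are non-negative); each method reads the truth plus
    independent Gaussian error, method B with an additive bias. The default
    mean of 3400 reflects a severely calcified pre-TAVR population.
    Deterministic under the seed.
    """
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if min(between_sd, error_sd_a, error_sd_b) < 0:
        raise ValueError("standard deviations must be non-negative")
    rng = np.random.default_rng(seed)
    truth = rng.normal(mean_score, between_sd, size=n)
    while np.any(truth < 0):  # truncate at zero by resampling
        neg = truth < 0
        truth[neg] = rng.normal(mean_score, between_sd, size=int(neg.sum()))
    a = truth + rng.normal(0.0, error_sd_a, size=n) if error_sd_a > 0 else truth.copy()
    b = truth + bias_b + (rng.normal(0.0, error_sd_b, size=n) if error_sd_b > 0 else 0.0)
    a = np.clip(a, 0.0, None)
    b = np.clip(b, 0.0, None)
    return PairedScores(
        subject_ids=tuple(f"S{i:04d}" for i in range(n)),
        method_a=a,
        method_b=b,
    )


# ---------------------------------------------------------------------------
# YAML spec I/O


def spec_from_yaml(path: str | Path) -> PhantomSpec:
    """Load a PhantomSpec from YAML.

    Keys mirror the dataclass fields; ``landmarks`` is an optional mapping
    with ``nadir_points`` and ``aortic_reference``. Unknown keys are
    rejected.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError("phantom spec YAML must be a mapping")
    known = set(PhantomSpec.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown phantom spec keys: {sorted(unknown)}")
    kwargs = dict(data)
    if "grid_shape" in kwargs:
        kwargs["grid_shape"] = tuple(int(x) for x in kwargs["grid_shape"])
    if "spacing" in kwargs:
        kwargs["spacing"] = tuple(float(x) for x in kwargs["spacing"])
    if "lesions" in kwargs:
        kwargs["lesions"] = tuple(
            LesionPrimitive(
                shape=l["shape"],
                center=tuple(float(x) for x in l["center"]),
                half_sizes=tuple(float(x) for x in l["half_sizes"]),
                plateau_hu=float(l["plateau_hu"]),
                tag=l.get("tag", "aortic"),
            )
            for l in kwargs["lesions"]
        )
    if kwargs.get("landmarks") is not None:
        lm = kwargs["landmarks"]
        kwargs["landmarks"] = LandmarkSet(
            nadir_points=np.asarray(lm["nadir_points"], float),
            aortic_reference=np.asarray(lm["aortic_reference"], float),
        )
    return PhantomSpec(**kwargs)
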