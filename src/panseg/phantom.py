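"""Synthetic labeled pancreas phantoms.

The generator emulates the gross anatomy the segmentation model relies
on: a single connected, curved tubular organ whose head, body and tail
cover roughly 40%, 33% and 26% of its centerline length, with the head
thicker than the tapered tail.  Three curvature presets are provided —
``straight`` (idealized), ``J`` (the typical hockey-stick shape, ~90°
bend) and ``U`` (the strongly bent worst-case morphology, ~160°).
Intensities are produced in arbitrary raw units (distinct per-region
means plus Gaussian noise over a nonzero background) so that phantoms
exercise the real preprocessing path (crop, zero background, min-max
normalize) rather than arriving pre-normalized.  An optional tumor-like
perturbation alters local texture without deforming the mask.

Phantoms are deterministic given their seed, which makes them usable both
as unit-test fixtures and as a desk-scale stand-in dataset for the full
cross-validation pipeline.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree

from .io_prep import BODY, CONN26, HEAD, TAIL, PancreasVolume

#: centerline control points per preset, in fractional grid coordinates.
#: The head end comes first and always sits at the smallest axis-0
#: coordinate, matching the laterality convention used at inference.
PRESET_CONTROL_POINTS = {
    "straight": [(0.12, 0.50, 0.50), (0.38, 0.50, 0.50),
                 (0.64, 0.50, 0.50), (0.88, 0.50, 0.50)],
    "J": [(0.12, 0.68, 0.46), (0.40, 0.76, 0.50), (0.64, 0.70, 0.54),
          (0.80, 0.50, 0.50), (0.84, 0.26, 0.46)],
    "U": [(0.14, 0.24, 0.46), (0.52, 0.32, 0.50), (0.74, 0.52, 0.54),
          (0.52, 0.72, 0.50), (0.24, 0.80, 0.46)],
}


@dataclass
class PhantomSpec:
    """Parameters of one synthetic pancreas.

    ``fractions`` are the head/body/tail shares of centerline length and
    are renormalized to sum to 1.  Radii are in voxels; intensities in
    arbitrary raw units (the preprocessing path rescales them).
    """

    shape: tuple = (40, 40, 40)
    preset: str = "J"
    fractions: tuple = (0.40, 0.33, 0.26)
    radius_head: float = 4.0
    radius_tail: float = 2.0
    intensity_means: tuple = (110.0, 90.0, 70.0)
    noise_sd: float = 8.0
    background_mean: float = 25.0
    tumor: bool = False
    tumor_radius: float = 3.0
    tumor_contrast: float = 40.0
    spacing: tuple = (1.0, 1.0, 1.0)
    seed: int = 0
    control_points: tuple | None = None
    scale: float = 1.0  # isotropic size factor about the grid centre

    def __post_init__(self):
        if any(f <= 0 for f in self.fractions):
            raise ValueError("fractions must be positive")
        if self.radius_head < 1 or self.radius_tail < 1:
            raise ValueError("radii must be >= 1 voxel")
        if self.preset not in PRESET_CONTROL_POINTS and self.control_points is None:
            raise ValueError(f"unknown preset {self.preset!r}")

    @property
    def norm_fractions(self):
        f = np.asarray(self.fractions, dtype=float)
        return tuple(f / f.sum())


def _centerline(spec: PhantomSpec, n_samples=600):
    """Densely sampled centerline points (voxel coords) and arc-length t in [0,1]."""
    pts = np.asarray(spec.control_points
                     if spec.control_points is not None
                     else PRESET_CONTROL_POINTS[spec.preset], dtype=float)
    pts = pts * (np.asarray(spec.shape) - 1)
    centre = (np.asarray(spec.shape) - 1) / 2.0
    pts = centre + (pts - centre) * spec.scale
    chord = np.r_[0.0, np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))]
    if chord[-1] <= 0:
        raise ValueError("degenerate (zero-length) centerline")
    spline = CubicSpline(chord / chord[-1], pts, axis=0)
    u = np.linspace(0.0, 1.0, n_samples)
    samples = spline(u)
    seg = np.linalg.norm(np.diff(samples, axis=0), axis=1)
    arc = np.r_[0.0, np.cumsum(seg)]
    return samples, arc / arc[-1]


def _radius_profile(spec: PhantomSpec, t):
    return spec.radius_head + (spec.radius_tail - spec.radius_head) * t


def generate_phantom(spec: PhantomSpec):
    """Build one phantom: (PancreasVolume with raw intensities, labels).

    The mask is the union of spheres along the centerline with a linearly
    tapering radius; labels follow arc-length fractions; intensities are
    per-region means plus noise over a noisy background, all clipped at 0.
    """
    rng = np.random.default_rng(spec.seed)
    samples, t = _centerline(spec, n_samples=int(8 * max(spec.shape)))
    radii = _radius_profile(spec, t)
    if np.any(samples - radii[:, None] < -0.5) or np.any(
        samples + radii[:, None] > np.asarray(spec.shape) - 0.5
    ):
        raise ValueError("tube exits the grid; enlarge shape or shrink the tube")

    grid = np.indices(spec.shape).reshape(3, -1).T.astype(float)
    tree = cKDTree(samples)
    dist, nearest = tree.query(grid, k=1)
    dist = dist.reshape(spec.shape)
    t_near = t[nearest].reshape(spec.shape)
    mask = dist <= _radius_profile(spec, t_near)

    lab_struct, n_comp = ndimage.label(mask, structure=CONN26)
    if n_comp != 1:
        raise ValueError(f"phantom mask has {n_comp} components (expected 1)")

    f_h, f_b, _ = spec.norm_fractions
    labels = np.zeros(spec.shape, dtype=np.uint8)
    labels[mask & (t_near <= f_h)] = HEAD
    labels[mask & (t_near > f_h) & (t_near <= f_h + f_b)] = BODY
    labels[mask & (t_near > f_h + f_b)] = TAIL

    head_dil = ndimage.binary_dilation(labels == HEAD, structure=CONN26)
    if np.any(head_dil & (labels == TAIL)):
        raise ValueError("phantom violates head/tail non-adjacency; "
                         "adjust preset or radii")

    intensities = rng.normal(spec.background_mean, spec.noise_sd, spec.shape)
    for region, mean in zip((HEAD, BODY, TAIL), spec.intensity_means):
        sel = labels == region
        intensities[sel] = rng.normal(mean, spec.noise_sd, int(sel.sum()))
    if spec.tumor:
        centre_t = rng.uniform(0.2, 0.8)
        centre = samples[np.searchsorted(t, centre_t)]
        d2 = ((grid - centre) ** 2).sum(axis=1).reshape(spec.shape)
        blob = mask & (d2 <= spec.tumor_radius ** 2)
        intensities[blob] += spec.tumor_contrast
    intensities = np.clip(intensities, 0.0, None)

    vol = PancreasVolume(intensities, mask, spacing=spec.spacing)
    return vol, labels


def generate_dataset(n, base_spec=None, seed=0, size_jitter=0.30,
                     fraction_jitter=0.05, noise_jitter=0.25, presets=None,
                     tumor_probability=0.0):
    """Generate ``n`` phantoms with per-case anatomical variation.

    Each case jitters the overall size (scale factor within
    ``1 ± size_jitter``), the subregion length fractions (each within
    ``± fraction_jitter``, then renormalized), the noise level and,
    optionally, the curvature preset; a tumor-like texture perturbation is
    added with probability ``tumor_probability``.  Deterministic given the
    master seed.  Returns ``(cases, manifest)`` where cases are
    ``(PancreasVolume, labels, PhantomSpec)`` triples and the manifest is
    a DataFrame with one row per resolved spec.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= size_jitter < 1) or fraction_jitter < 0 or noise_jitter < 0:
        raise ValueError("invalid jitter ranges")
    base = base_spec or PhantomSpec()
    presets = presets or [base.preset]
    rng = np.random.default_rng(seed)
    cases, manifest_rows = [], []
    for i in range(n):
        fractions = np.asarray(base.fractions, dtype=float) + rng.uniform(
            -fraction_jitter, fraction_jitter, 3
        )
        fractions = np.clip(fractions, 0.05, None)
        # size jitter scales the grid and the radii together, so the tube
        # grows or shrinks isotropically while keeping its grid margins
        size = float(rng.uniform(1 - size_jitter, 1 + size_jitter))
        spec = replace(
            base,
            preset=presets[int(rng.integers(len(presets)))],
            fractions=tuple(fractions),
            shape=tuple(int(round(s * size)) for s in base.shape),
            radius_head=float(max(1.0, base.radius_head * size)),
            radius_tail=float(max(1.0, base.radius_tail * size)),
            noise_sd=float(base.noise_sd * rng.uniform(1 - noise_jitter,
                                                       1 + noise_jitter)),
            tumor=bool(rng.uniform() < tumor_probability),
            seed=int(rng.integers(2 ** 31)),
        )
        vol, labels = generate_phantom(spec)
        cases.append((vol, labels, spec))
        row = asdict(spec)
        row["case_id"] = f"phantom{i:03d}"
        row["n_voxels"] = int(vol.mask.sum())
        manifest_rows.append(row)
    return cases, pd.DataFrame(manifest_rows)
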