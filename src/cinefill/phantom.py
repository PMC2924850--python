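"""Short-axis cine phantoms and a stand-in blood-pool segmenter.

A synthetic patient's volume model is rasterised into a multi-slice stack of
bright-disk images per cine phase: per-slice radii follow a truncated
ellipsoid taper from base to apex, scaled each phase so the analytic stack
volume (sum of disk areas times the effective slice spacing) equals the
model volume.  Disk edges are drawn with linear sub-pixel coverage so that
thresholding at half intensity recovers the disk area to well under a
percent.

The segmenter is deliberately simple plumbing -- global intensity threshold
plus per-slice 4-connected region growth from a seed point -- standing in
for a full clinical segmentation algorithm, which is prior work outside
this package.  Volume summation follows the short-axis summation-of-disks
convention (2D area times slice spacing); because acquisitions leave an
inter-slice gap, the effective spacing includes the gap by default so that
contiguous myocardium is represented (configurable).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from skimage.segmentation import flood

from .cohort import PatientTruth, VolumeModel
from .curve import VolumeCurve
from .errors import InfeasibleParametersError, SeedPointError


@dataclass(frozen=True)
class CineGeometry:
    """Raster and slice geometry for a phantom stack."""

    n_slices: int = 10
    grid_size: int = 224
    pixel_spacing_mm: float = 1.0
    slice_thickness_mm: float = 6.0
    slice_gap_mm: float = 4.0
    include_gap: bool = True

    def __post_init__(self) -> None:
        if self.n_slices < 3:
            raise InfeasibleParametersError("need at least 3 slices")
        if self.grid_size < 16 or self.pixel_spacing_mm <= 0:
            raise InfeasibleParametersError("invalid raster geometry")
        if self.slice_thickness_mm <= 0 or self.slice_gap_mm < 0:
            raise InfeasibleParametersError("invalid slice geometry")

    @property
    def effective_spacing_mm(self) -> float:
        gap = self.slice_gap_mm if self.include_gap else 0.0
        return self.slice_thickness_mm + gap

    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_spacing_mm**2


@dataclass(frozen=True)
class CineStack:
    """Per-phase, per-slice grayscale rasters (blood pool bright)."""

    frames: np.ndarray  # (n_phases, n_slices, ny, nx) in [0, 1]
    phase_times: np.ndarray  # ms
    geometry: CineGeometry
    rr_ms: float
    analytic_volumes: np.ndarray | None = None  # ml, per phase (phantoms only)

    def __post_init__(self) -> None:
        if self.frames.ndim != 4:
            raise InfeasibleParametersError("frames must be 4-D (phase, slice, y, x)")
        if np.any(np.diff(self.phase_times) <= 0):
            raise InfeasibleParametersError("phase times must strictly increase")

    @property
    def n_phases(self) -> int:
        return int(self.frames.shape[0])

    @property
    def n_slices(self) -> int:
        return int(self.frames.shape[1])

    def write(self, out_dir: str | Path) -> Path:
        """Write per-phase TIFF stacks plus a JSON geometry manifest."""
        import json

        import tifffile

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for i in range(self.n_phases):
            tifffile.imwrite(
                out / f"phase{i:03d}.tif",
                (self.frames[i] * 255).astype(np.uint8),
            )
        manifest = {
            "rr_ms": self.rr_ms,
            "phase_times_ms": list(map(float, self.phase_times)),
            "n_slices": self.geometry.n_slices,
            "pixel_spacing_mm": self.geometry.pixel_spacing_mm,
            "slice_thickness_mm": self.geometry.slice_thickness_mm,
            "slice_gap_mm": self.geometry.slice_gap_mm,
        }
        (out / "geometry.json").write_text(json.dumps(manifest, indent=2))
        return out


@dataclass(frozen=True)
class SegmentationResult:
    """Cavity areas and summed volumes recovered from a stack."""

    areas_mm2: np.ndarray  # (n_phases, n_slices)
    volumes_ml: np.ndarray  # (n_phases,)
    phase_times: np.ndarray
    rr_ms: float

    def to_curve(self) -> VolumeCurve:
        return VolumeCurve(
            phase_times=self.phase_times,
            volumes=self.volumes_ml,
            rr_ms=self.rr_ms,
            provenance="segmented",
        )


# ---------------------------------------------------------------------------
# Rasterisation
# ---------------------------------------------------------------------------


def _taper_profile(n_slices: int) -> np.ndarray:
    """Unit cross-section areas of a truncated ellipsoid, base to apex."""
    z = (np.arange(n_slices) + 0.5) / n_slices
    # keep a small apical cap so every slice has a segmentable pool
    return np.maximum(1.0 - z**2, 0.04)


def _disk(grid_size: int, radius_px: float, center: tuple[float, float]) -> np.ndarray:
    yy, xx = np.mgrid[0:grid_size, 0:grid_size]
    d = np.hypot(yy - center[0], xx - center[1])
    # linear edge coverage over one pixel: exact area to O(px^2)
    return np.clip(radius_px - d + 0.5, 0.0, 1.0)


def rasterize_stack(
    truth: PatientTruth,
    geometry: CineGeometry | None = None,
    n_phases: int = 30,
) -> CineStack:
    """Render a synthetic patient as a multi-slice short-axis cine stack.

    Per phase, per-slice disk areas follow the ellipsoid taper scaled so
    that the analytic stack volume equals the patient's model volume; the
    rasterised volume differs only by sub-pixel boundary coverage error.
    """
    geometry = geometry or CineGeometry()
    model = VolumeModel(truth)
    times = np.arange(n_phases) * truth.rr_ms / n_phases
    volumes = np.asarray(model.volume(times), dtype=float)  # ml

    taper = _taper_profile(geometry.n_slices)
    dz = geometry.effective_spacing_mm
    unit_volume = float(np.sum(taper)) * dz  # mm^3 per unit base area
    base_areas = volumes * 1000.0 / unit_volume  # mm^2 at unit taper

    max_radius_mm = np.sqrt(np.max(base_areas) * np.max(taper) / np.pi)
    half_fov = geometry.grid_size / 2.0 * geometry.pixel_spacing_mm
    if max_radius_mm > half_fov - 3 * geometry.pixel_spacing_mm:
        raise InfeasibleParametersError(
            f"chamber radius {max_radius_mm:.1f} mm does not fit the "
            f"{geometry.grid_size}x{geometry.grid_size} raster"
        )

    mid = (geometry.grid_size - 1) / 2.0
    frames = np.zeros(
        (n_phases, geometry.n_slices, geometry.grid_size, geometry.grid_size),
        dtype=np.float32,
    )
    for p in range(n_phases):
        for s in range(geometry.n_slices):
            area = base_areas[p] * taper[s]
            radius_px = np.sqrt(area / np.pi) / geometry.pixel_spacing_mm
            # deterministic sub-pixel slice offsets break the coherence of
            # pixel-quantisation error across slices so it averages out in
            # the summed volume instead of adding up
            center = (
                mid + ((s * 0.381966) % 1.0) - 0.5,
                mid + ((s * 0.618034) % 1.0) - 0.5,
            )
            frames[p, s] = _disk(geometry.grid_size, radius_px, center)
    return CineStack(
        frames=frames,
        phase_times=times,
        geometry=geometry,
        rr_ms=truth.rr_ms,
        analytic_volumes=volumes,
    )


# ---------------------------------------------------------------------------
# Segmentation and volume summation
# ---------------------------------------------------------------------------


def stack_volume(
    areas_mm2: Sequence[float],
    thickness_mm: float = 6.0,
    gap_mm: float = 4.0,
    include_gap: bool = True,
) -> float:
    """Summation-of-disks chamber volume (ml) from per-slice areas (mm^2).

    Effective spacing is slice thickness plus the inter-slice gap when
    ``include_gap`` (the default, assuming contiguous chamber coverage).
    """
    areas = np.asarray(list(areas_mm2), dtype=float)
    if areas.size and np.any(areas < 0):
        raise InfeasibleParametersError("areas must be non-negative")
    if thickness_mm <= 0 or gap_mm < 0:
        raise InfeasibleParametersError("invalid slice geometry")
    spacing = thickness_mm + (gap_mm if include_gap else 0.0)
    return float(np.sum(areas) * spacing / 1000.0)


def segment_stack(
    stack: CineStack,
    seed_point: tuple[int, int] | None = None,
    intensity_threshold: float = 0.5,
    reference_phase: int = 0,
    slice_range: tuple[int, int] | None = None,
) -> SegmentationResult:
    """Threshold + 4-connected region growth from a seed, slice by slice.

    ``seed_point`` is an (row, col) pixel in the blood pool at the reference
    phase (defaults to the image centre); ``slice_range`` optionally
    restricts segmentation to ``[start, stop)`` slices, emulating basal
    truncation at the mitral annulus plane.  Pixels strictly above
    ``intensity_threshold`` times the stack maximum are candidate blood
    pool; the grown-region pixel count times the pixel area gives each
    slice's cavity area.  Deterministic.
    """
    g = stack.geometry
    if seed_point is None:
        seed_point = (g.grid_size // 2, g.grid_size // 2)
    row, col = int(seed_point[0]), int(seed_point[1])
    ny, nx = stack.frames.shape[2:]
    if not (0 <= row < ny and 0 <= col < nx):
        raise SeedPointError(f"seed {seed_point} lies outside the image")
    vmax = float(stack.frames.max())
    if vmax <= 0:
        raise SeedPointError("stack has no bright blood pool")

    lo, hi = slice_range if slice_range is not None else (0, g.n_slices)
    if not (0 <= lo < hi <= g.n_slices):
        raise InfeasibleParametersError(f"invalid slice range {slice_range}")

    ref = stack.frames[reference_phase, lo]
    if ref[row, col] <= 0:
        raise SeedPointError(
            f"seed {seed_point} is on background at phase {reference_phase}"
        )

    areas = np.zeros((stack.n_phases, g.n_slices), dtype=float)
    for p in range(stack.n_phases):
        for s in range(lo, hi):
            mask = stack.frames[p, s] > intensity_threshold * vmax
            if not mask[row, col]:
                continue  # apical slice pinched off at this phase
            grown = flood(mask, (row, col), connectivity=1)
            areas[p, s] = float(np.sum(grown & mask)) * g.pixel_area_mm2
    volumes = np.array(
        [
            stack_volume(
                areas[p],
                g.slice_thickness_mm,
                g.slice_gap_mm,
                include_gap=g.include_gap,
            )
            for p in range(stack.n_phases)
        ]
    )
    return SegmentationResult(
        areas_mm2=areas,
        volumes_ml=volumes,
        phase_times=stack.phase_times,
        rr_ms=stack.rr_ms,
    )
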