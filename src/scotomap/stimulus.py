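"""Drifting-bar retinotopy aperture movies (LCR) and simulated-scotoma variants.

The luminance-contrast retinotopy (LCR) stimulus is a high-contrast bar that
drifts across a circular field of 7 degrees radius in eight motion directions.
A full pass crosses the whole field in 16 steps of one repetition time (TR)
each; after every full pass the bar crosses half of the field in 8 steps,
followed by 8 blank frames at mean luminance.  With the default TR of 1.5 s a
run is 8 dummy frames + 128 design frames = 136 frames, 204 s.

The flickering checkerboard carrier (0.5 cycles/degree) is deliberately not
rendered: receptive-field fitting operates on the stimulus aperture, so movies
store contrast apertures in [0, 1] only; carrier parameters are metadata.

The simulated-scotoma variant (LCR SS) is the same movie multiplied pixel-wise
by a perimetry-derived contrast mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .perimetry import ContrastMask, FrameGeometry

__all__ = [
    "BarSpec",
    "ApertureMovie",
    "make_lcr_movie",
    "make_localizer_movie",
    "preset_movie",
    "apply_scotoma",
    "effective_aperture",
]

#: motion directions (degrees, 0 = rightward, counterclockwise) of the default
#: run: the four cardinal directions are presented as full passes, the four
#: diagonals as truncated (half) passes followed by a blank.  The exact
#: interleaving is a configuration default; only pass structure and frame
#: counts are constrained by the run timing.
DEFAULT_FULL_DIRECTIONS = (0.0, 90.0, 180.0, 270.0)
DEFAULT_HALF_DIRECTIONS = (45.0, 135.0, 225.0, 315.0)

#: carrier metadata (not rendered): 100% contrast, 0.5 cycles/degree checks.
CARRIER = {"contrast": 1.0, "spatial_frequency_cpd": 0.5}


@dataclass(frozen=True)
class BarSpec:
    """Geometry of the drifting bar."""

    width: float = 1.75  # degrees
    n_steps_full: int = 16  # steps of one TR per full pass
    directions: tuple[float, ...] = DEFAULT_FULL_DIRECTIONS + DEFAULT_HALF_DIRECTIONS
    contrast: float = 1.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("bar width must be positive")
        if self.n_steps_full % 2 != 0:
            raise ValueError("n_steps_full must be even")
        if not 0 < self.contrast <= 1:
            raise ValueError("contrast must lie in (0, 1]")


@dataclass(frozen=True)
class ApertureMovie:
    """Time-resolved stimulus aperture: T x H x W contrast values in [0, 1]."""

    frames: np.ndarray
    tr_seconds: float
    deg_per_pixel: float
    field_radius: float = 7.0
    dummy_frames: int = 0

    def __post_init__(self) -> None:
        fr = np.asarray(self.frames, dtype=np.float32)
        if fr.ndim != 3:
            raise ValueError("frames must be a T x H x W array")
        if fr.size == 0:
            raise ValueError("movie has no frames")
        if fr.min() < 0 or fr.max() > 1:
            raise ValueError("aperture values must lie in [0, 1]")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        object.__setattr__(self, "frames", fr)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames * self.tr_seconds

    @property
    def geometry(self) -> FrameGeometry:
        return FrameGeometry(self.frames.shape[1:], self.deg_per_pixel)

    def design(self) -> "ApertureMovie":
        """Return the movie with the initial dummy frames stripped."""
        if self.dummy_frames == 0:
            return self
        return replace(self, frames=self.frames[self.dummy_frames :], dummy_frames=0)

    def pixel_coords(self) -> tuple[np.ndarray, np.ndarray]:
        return self.geometry.pixel_coords()

    def to_nifti(self, path) -> None:
        import nibabel as nib

        img = nib.Nifti1Image(
            np.transpose(self.frames, (1, 2, 0)).astype(np.float32), affine=np.eye(4)
        )
        img.header["pixdim"][4] = self.tr_seconds
        nib.save(img, str(path))


def _bar_frame(
    X: np.ndarray,
    Y: np.ndarray,
    direction_deg: float,
    center: float,
    width: float,
    field_radius: float,
    contrast: float,
) -> np.ndarray:
    """One binary bar frame: the bar is perpendicular to its motion axis."""
    phi = np.deg2rad(direction_deg)
    u = X * np.cos(phi) + Y * np.sin(phi)  # signed position along motion axis
    inside_bar = np.abs(u - center) <= width / 2.0
    inside_field = X**2 + Y**2 <= field_radius**2
    return (inside_bar & inside_field).astype(np.float32) * contrast


def make_lcr_movie(
    bar: BarSpec | None = None,
    tr: float = 1.5,
    shape: tuple[int, int] = (101, 101),
    field_radius: float = 7.0,
    dummy_frames: int = 8,
) -> ApertureMovie:
    """Build the default drifting-bar run.

    Design: alternating full passes (16 frames, cardinal directions) and
    truncated passes (8 bar frames + 8 blank frames, diagonal directions),
    totalling 128 design frames; ``dummy_frames`` blank frames are prepended,
    giving 136 frames (204 s at TR 1.5 s) by default.
    """
    bar = bar or BarSpec()
    if tr <= 0:
        raise ValueError("tr must be positive")
    if bar.width > 2 * field_radius:
        raise ValueError("bar is wider than the stimulated field")
    geom = FrameGeometry(shape, 2 * field_radius / (max(shape) - 1))
    X, Y = geom.pixel_coords()
    n = bar.n_steps_full
    step = 2 * field_radius / n
    centers_full = -field_radius + (np.arange(n) + 0.5) * step
    centers_half = centers_full[: n // 2]
    blank = np.zeros(shape, dtype=np.float32)

    full_dirs = bar.directions[: len(bar.directions) // 2]
    half_dirs = bar.directions[len(bar.directions) // 2 :]
    frames: list[np.ndarray] = [blank] * dummy_frames
    for d_full, d_half in zip(full_dirs, half_dirs):
        for c in centers_full:
            frames.append(
                _bar_frame(X, Y, d_full, c, bar.width, field_radius, bar.contrast)
            )
        for c in centers_half:
            frames.append(
                _bar_frame(X, Y, d_half, c, bar.width, field_radius, bar.contrast)
            )
        frames.extend([blank] * (n // 2))
    return ApertureMovie(
        frames=np.stack(frames),
        tr_seconds=tr,
        deg_per_pixel=geom.deg_per_pixel,
        field_radius=field_radius,
        dummy_frames=dummy_frames,
    )


def make_localizer_movie(
    tr: float = 1.5,
    shape: tuple[int, int] = (101, 101),
    field_radius: float = 7.0,
    dummy_frames: int = 8,
    block_frames: int = 8,
) -> ApertureMovie:
    """Scotoma-localizer preset: full-field on/off block design.

    136 design frames of alternating full-field and blank blocks plus the
    dummy frames give 144 frames, 216 s at TR 1.5 s, matching the localizer
    run length.  The block structure itself is a generic on/off design.
    """
    geom = FrameGeometry(shape, 2 * field_radius / (max(shape) - 1))
    X, Y = geom.pixel_coords()
    disc = (X**2 + Y**2 <= field_radius**2).astype(np.float32)
    blank = np.zeros(shape, dtype=np.float32)
    n_design = 136
    frames: list[np.ndarray] = [blank] * dummy_frames
    k = 0
    while len(frames) - dummy_frames < n_design:
        block = disc if k % 2 == 0 else blank
        take = min(block_frames, n_design - (len(frames) - dummy_frames))
        frames.extend([block] * take)
        k += 1
    return ApertureMovie(
        frames=np.stack(frames),
        tr_seconds=tr,
        deg_per_pixel=geom.deg_per_pixel,
        field_radius=field_radius,
        dummy_frames=dummy_frames,
    )


PRESETS = {
    "lcr-default": make_lcr_movie,
    "localizer": make_localizer_movie,
}


def preset_movie(name: str, **kwargs) -> ApertureMovie:
    """Build a named preset movie: ``lcr-default`` (136 frames) or ``localizer`` (144)."""
    try:
        factory = PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return factory(**kwargs)


def apply_scotoma(movie: ApertureMovie, mask: ContrastMask) -> ApertureMovie:
    """Multiply every frame of the movie pointwise by a contrast mask."""
    if mask.values.shape != movie.frames.shape[1:]:
        raise ValueError(
            f"mask shape {mask.values.shape} does not match frames {movie.frames.shape[1:]}"
        )
    return replace(movie, frames=movie.frames * mask.values[None].astype(np.float32))


def effective_aperture(
    movie: ApertureMovie, model: str, mask: ContrastMask | None = None
) -> ApertureMovie:
    """Aperture seen by the pRF fitter under the full-field or scotoma-field model.

    ``model="FF"`` returns the undamaged, dummy-stripped binary aperture;
    ``model="SF"`` additionally multiplies it by the scotoma mask, so the
    fitter "knows" the simulated scotoma.  Pass the pristine (un-masked)
    movie; any residual graded contrast is binarized to the bar footprint.
    """
    if model not in ("FF", "SF"):
        raise ValueError(f"model must be 'FF' or 'SF', got {model!r}")
    design = movie.design()
    binary = (design.frames > 0).astype(np.float32)
    if model == "FF":
        return replace(design, frames=binary)
    if mask is None:
        raise ValueError("the SF model requires a contrast mask")
    if mask.values.shape != binary.shape[1:]:
        raise ValueError("mask geometry does not match the movie frames")
    return replace(design, frames=binary * mask.values[None].astype(np.float32))
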