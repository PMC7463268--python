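"""Seeded synthetic cohorts of IR-retina-like images.

Clinical IR-SLO datasets for macular edema are rarely shared, so this module
fabricates labelled case/control cohorts whose two classes differ in spatial
texture. The background of each image is a Gaussian random field: white noise
smoothed at a group-specific correlation length. A longer correlation length
produces a smoother field and hence a higher gray-level co-occurrence
correlation, which is the direction of the empirically reported group
difference (healthy retinas show smoother IR texture than edematous ones).
On top of the background the generator composites a bright optic disc, dark
curvilinear vessels with a one-pixel central light reflex, and — for cases
only — bright lesion-like Gaussian blobs emulating exudate/edema speckle.

Everything is driven by per-image random substreams keyed on
``(cohort seed, image index)`` so a cohort is bit-reproducible and any subset
of it can be regenerated independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import disk as draw_disk, line as draw_line

from .image import GrayImage, ParameterError, write_image

Label = Literal["control", "case"]


@dataclass
class CohortSpec:
    """Parameters of the synthetic case/control image generator.

    Defaults mirror the cohort the method was reported on: 23 cases and
    18 controls, with a strong between-group difference in background
    correlation length (8 px vs 2 px) and case-only lesions. Image size
    defaults to 256x256 for speed; the clinical scans were larger.
    """

    n_cases: int = 23
    n_controls: int = 18
    height: int = 256
    width: int = 256
    bit_depth: int = 8
    corr_length_control: float = 8.0
    corr_length_case: float = 2.0
    lesion_count: int = 30
    lesion_radius_range: tuple[float, float] = (2.0, 6.0)
    lesion_amplitude: float = 40.0
    vessel_count: int = 6
    vessel_width: float = 3.0
    vessel_contrast: float = 40.0
    disc_center_jitter: float = 10.0
    disc_radius: float = 30.0
    disc_brightness: float = 240.0
    noise_sd: float = 2.0
    seed: int = 0
    null_cohort: bool = False  # identical parameters in both groups, no lesions

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise ParameterError("group sizes must be non-negative")
        if self.n_cases + self.n_controls < 1:
            raise ParameterError("cohort must contain at least one image")
        if self.height < 32 or self.width < 32:
            raise ParameterError("images must be at least 32x32")
        if self.corr_length_control <= 0 or self.corr_length_case <= 0:
            raise ParameterError("correlation lengths must be positive")
        lo, hi = self.lesion_radius_range
        if lo > hi:
            raise ParameterError("lesion_radius_range is inverted")
        if self.vessel_width < 1:
            raise ParameterError("vessel_width must be >= 1 pixel")
        if self.vessel_count < 0 or self.lesion_count < 0:
            raise ParameterError("counts must be non-negative")

    @property
    def n_total(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def max_intensity(self) -> int:
        return 2**self.bit_depth - 1


@dataclass
class SyntheticRecord:
    """One generated image plus its label and realized ground truth."""

    image_id: str
    image: GrayImage
    label: Label
    truth: dict = field(default_factory=dict)


def make_background(spec: CohortSpec, group: Label, rng: np.random.Generator) -> GrayImage:
    """Gaussian random field background for one group.

    White noise is smoothed with a Gaussian kernel whose sigma is the group's
    correlation length, then min-max rescaled to the full intensity range.
    The expected GLCM correlation of the result increases monotonically with
    the correlation length.
    """
    if group not in ("control", "case"):
        raise ParameterError(f"unknown group {group!r}")
    corr_length = (
        spec.corr_length_control
        if (group == "control" or spec.null_cohort)
        else spec.corr_length_case
    )
    if corr_length <= 0:
        raise ParameterError("correlation length must be positive")
    noise = rng.standard_normal((spec.height, spec.width))
    field_ = gaussian_filter(noise, sigma=corr_length, mode="reflect")
    lo, hi = field_.min(), field_.max()
    if hi == lo:  # degenerate; cannot happen for real noise but keep total
        scaled = np.zeros_like(field_)
    else:
        scaled = (field_ - lo) / (hi - lo) * spec.max_intensity
    return GrayImage(np.rint(scaled), bit_depth=spec.bit_depth)


def add_optic_disc(
    img: GrayImage,
    center: tuple[float, float],
    radius: float,
    brightness: float,
) -> GrayImage:
    """Composite a bright disc with a smooth rim falloff.

    Pixels are blended toward ``brightness`` with weight 1 inside 0.85*radius,
    falling to 0 at the rim along a cosine taper; a disc partially off-border
    is clipped to the frame. A disc entirely outside the frame is an error.
    """
    if radius <= 0:
        raise ParameterError("disc radius must be positive")
    cy, cx = center
    if (
        cy + radius < 0
        or cx + radius < 0
        or cy - radius >= img.ny
        or cx - radius >= img.nx
    ):
        raise ParameterError("optic disc lies entirely outside the image")
    yy, xx = np.ogrid[: img.ny, : img.nx]
    r = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    flat = 0.85 * radius
    w = np.where(
        r <= flat,
        1.0,
        np.where(
            r < radius,
            0.5 * (1 + np.cos(np.pi * (r - flat) / (radius - flat))),
            0.0,
        ),
    )
    out = img.astype_float()
    out = out + w * (brightness - out)
    return img.like(out)


def _walk_vessel(
    shape: tuple[int, int], rng: np.random.Generator, step: float = 3.0
) -> list[tuple[int, int]]:
    """Random-walk polyline from a border point across the frame."""
    h, w = shape
    side = rng.integers(4)
    if side == 0:  # top
        pos = np.array([0.0, rng.uniform(0, w - 1)])
        angle = rng.uniform(0.25 * np.pi, 0.75 * np.pi)
    elif side == 1:  # bottom
        pos = np.array([h - 1.0, rng.uniform(0, w - 1)])
        angle = rng.uniform(-0.75 * np.pi, -0.25 * np.pi)
    elif side == 2:  # left
        pos = np.array([rng.uniform(0, h - 1), 0.0])
        angle = rng.uniform(-0.25 * np.pi, 0.25 * np.pi)
    else:  # right
        pos = np.array([rng.uniform(0, h - 1), w - 1.0])
        angle = rng.uniform(0.75 * np.pi, 1.25 * np.pi)
    points = [(int(round(pos[0])), int(round(pos[1])))]
    for _ in range(int(2 * (h + w) / step)):
        angle += rng.normal(0.0, 0.15)
        pos = pos + step * np.array([np.sin(angle), np.cos(angle)])
        if not (0 <= pos[0] <= h - 1 and 0 <= pos[1] <= w - 1):
            break
        points.append((int(round(pos[0])), int(round(pos[1]))))
    return points


def add_vessels(img: GrayImage, spec: CohortSpec, rng: np.random.Generator) -> GrayImage:
    """Dark curvilinear vessel tracks with a 1-px brighter central streak.

    Each vessel is a random walk rasterized at ``vessel_width``; intensity is
    lowered by ``vessel_contrast`` along the track and raised by half the
    contrast along the central line, emulating the light reflex running along
    vessels in IR reflectance images. ``vessel_count = 0`` is the identity.
    """
    if spec.vessel_width < 1:
        raise ParameterError("vessel_width must be >= 1 pixel")
    if spec.vessel_count == 0:
        return GrayImage(img.pixels.copy(), bit_depth=img.bit_depth)
    shape = (img.ny, img.nx)
    track = np.zeros(shape, dtype=bool)
    streak = np.zeros(shape, dtype=bool)
    stamp_radius = max(spec.vessel_width / 2.0, 0.5)
    for _ in range(spec.vessel_count):
        pts = _walk_vessel(shape, rng)
        for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
            rr, cc = draw_line(r0, c0, r1, c1)
            streak[rr, cc] = True
            for r, c in zip(rr, cc):
                dr, dc = draw_disk((r, c), stamp_radius + 0.5, shape=shape)
                track[dr, dc] = True
    out = img.astype_float()
    out[track] -= spec.vessel_contrast
    out[streak] += 0.5 * spec.vessel_contrast
    return img.like(out)


def add_lesions(
    img: GrayImage, spec: CohortSpec, rng: np.random.Generator
) -> tuple[GrayImage, list[dict]]:
    """Add ``lesion_count`` bright Gaussian blobs at seeded positions.

    Returns the composited image together with the realized placements
    (row, col, radius) so the ground truth can be recorded.
    """
    lo, hi = spec.lesion_radius_range
    if lo > hi:
        raise ParameterError("lesion_radius_range is inverted")
    placements: list[dict] = []
    if spec.lesion_count == 0 or spec.lesion_amplitude == 0:
        # rng is still advanced identically so truth stays reproducible
        return GrayImage(img.pixels.copy(), bit_depth=img.bit_depth), placements
    out = img.astype_float()
    yy, xx = np.ogrid[: img.ny, : img.nx]
    for _ in range(spec.lesion_count):
        row = rng.uniform(0, img.ny - 1)
        col = rng.uniform(0, img.nx - 1)
        radius = rng.uniform(lo, hi)
        sigma = radius / 2.0
        out += spec.lesion_amplitude * np.exp(
            -((yy - row) ** 2 + (xx - col) ** 2) / (2 * sigma**2)
        )
        placements.append({"row": row, "col": col, "radius": radius})
    return img.like(out), placements


def _image_rng(seed: int, index: int) -> np.random.Generator:
    """Independent substream for image ``index`` of cohort ``seed``."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def generate_one(spec: CohortSpec, index: int, label: Label) -> SyntheticRecord:
    """Generate image ``index`` of the cohort (reproducible in isolation)."""
    rng = _image_rng(spec.seed, index)
    img = make_background(spec, label, rng)

    cy = spec.height / 2.0 + rng.normal(0, spec.disc_center_jitter)
    cx = spec.width / 2.0 + rng.normal(0, spec.disc_center_jitter)
    cy = float(np.clip(cy, spec.disc_radius, spec.height - 1 - spec.disc_radius))
    cx = float(np.clip(cx, spec.disc_radius, spec.width - 1 - spec.disc_radius))
    img = add_optic_disc(img, (cy, cx), spec.disc_radius, spec.disc_brightness)
    img = add_vessels(img, spec, rng)

    lesions: list[dict] = []
    if label == "case" and not spec.null_cohort:
        img, lesions = add_lesions(img, spec, rng)

    if spec.noise_sd > 0:
        img = img.like(img.astype_float() + rng.normal(0, spec.noise_sd, img.pixels.shape))

    truth = {
        "disc_center": [cy, cx],
        "disc_radius": spec.disc_radius,
        "lesions": lesions,
    }
    return SyntheticRecord(
        image_id=f"img{index:03d}", image=img, label=label, truth=truth
    )


def generate_cohort(spec: CohortSpec) -> list[SyntheticRecord]:
    """Generate the full labelled cohort: cases first, then controls."""
    if spec.n_total < 1:
        raise ParameterError("cohort must contain at least one image")
    records = []
    for i in range(spec.n_total):
        label: Label = "case" if i < spec.n_cases else "control"
        records.append(generate_one(spec, i, label))
    return records


def save_cohort(records: list[SyntheticRecord], outdir: str | Path) -> None:
    """Write images (PNG/TIFF), ``labels.csv`` and ``truth.json``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows, truth = [], {}
    for rec in records:
        ext = "png" if rec.image.bit_depth == 8 else "tiff"
        write_image(rec.image, outdir / f"{rec.image_id}.{ext}")
        rows.append(f"{rec.image_id},{rec.label}")
        truth[rec.image_id] = rec.truth
    (outdir / "labels.csv").write_text("image_id,label\n" + "\n".join(rows) + "\n")
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1))


def spec_to_dict(spec: CohortSpec) -> dict:
    return asdict(spec)
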