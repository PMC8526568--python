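"""Forward-model generator of ground-truthed dual-biosensor scenes.

The generator emulates a five-channel live-cell acquisition of a motile
cell co-expressing a FRET-based RAC1 activity sensor (donor / FRET /
acceptor channels) and a ratiometric GTP sensor (two excitation channels).
Latent per-pixel GTP concentration and RAC1 activity fields are drawn with
a configurable pixel correlation ``rho``, then pushed through every
acquisition artifact the preprocessing chain is meant to undo:

* saturating sensor response (single-site hyperbola, Keff 32.3 µM for the
  GTP-sensitive variant; the Null variant reports a constant ratio),
* spectral bleed-through of donor (α) and acceptor (β) into FRET,
* per-channel double-exponential photobleaching,
* affine misregistration of the GTP-sensor camera (≤ 2 px),
* multiplicative shading, additive dark current, shot and read noise.

Ground truth (latent fields, mask, true correction assets) is returned
alongside the rendered stack so every correction stage can be verified
against a known answer.  A separate helper emulates the paired cell-body /
cell-protrusion (CB/CP) ratio tables of the transwell experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .preprocess import AffineTransform
from .sensors import GEVAL30, SensorModel, sensor_response
from .stack import CHANNEL_ROLES, BackgroundRegion, CorrectionBundle, RawStack

__all__ = [
    "SceneConfig",
    "GroundTruth",
    "default_bleach_params",
    "bleach_curve",
    "generate_latent_fields",
    "render_channels",
    "simulate_scene",
    "generate_cbcp_dataset",
]


def default_bleach_params() -> dict[str, tuple[float, float, float, float]]:
    """Per-channel double-exponential bleach parameters (a1, k1, a2, k2).

    Amplitudes sum to 1 so every curve starts at 1; rates are per minute.
    The FRET channel bleaches faster than the donor so the FRET index
    drifts over a 30-min series and the photobleach correction has real
    work to do.
    """
    return {
        "donor": (0.6, 0.03, 0.4, 0.005),
        "fret": (0.6, 0.05, 0.4, 0.010),
        "acceptor": (0.6, 0.02, 0.4, 0.004),
        "ex409": (0.6, 0.04, 0.4, 0.008),
        "ex494": (0.6, 0.025, 0.4, 0.006),
    }


def bleach_curve(params: tuple[float, float, float, float], t: np.ndarray) -> np.ndarray:
    """a1·exp(−k1·t) + a2·exp(−k2·t)."""
    a1, k1, a2, k2 = params
    t = np.asarray(t, dtype=float)
    return a1 * np.exp(-k1 * t) + a2 * np.exp(-k2 * t)


def _default_misregistration() -> AffineTransform:
    # ~0.2 degree rotation about the frame centre plus a sub-2-px shift
    theta = math.radians(0.2)
    c, s = math.cos(theta), math.sin(theta)
    centre = np.array([90.0, 90.0])
    lin = np.array([[c, -s], [s, c]])
    off = centre - lin @ centre + np.array([1.2, -0.7])
    return AffineTransform(np.hstack([lin, off[:, None]]))


@dataclass
class SceneConfig:
    """Study conditions for one synthetic dual-biosensor scene.

    Defaults follow the imaging protocol being emulated: 30 frames at
    1-min intervals, latent GTP fluctuating around the sensor's Keff
    (32.3 µM) where the sensor is most responsive, and a cell mask of
    ~10^4 pixels (ellipsoidal body plus one protrusion lobe).
    """

    shape: tuple[int, int] = (180, 180)
    n_frames: int = 30
    frame_interval: float = 1.0  # minutes
    rho: float = 0.5  # target in-mask corr(gtp, activity)
    gtp_mean: float = 32.0  # µM
    gtp_sd: float = 9.0  # µM
    protrusion_gtp_offset: float = 0.0  # µM added inside the protrusion lobe
    activity_mean: float = 1.5  # dimensionless FRET ratio scale
    activity_sd: float = 0.3
    alpha: float = 0.2  # donor bleed-through into FRET
    beta: float = 0.1  # acceptor bleed-through into FRET
    shading_amplitude: float = 0.3
    dark_offset: float = 100.0  # counts
    shot_gain: float = 1.0  # counts per photon; 0 disables shot noise
    read_sd: float = 2.0  # counts; 0 disables read noise
    donor_base: float = 5000.0  # counts
    acceptor_ratio: float = 0.8  # acceptor abundance relative to donor
    geval_base: float = 20000.0  # total GTP-sensor counts (both channels)
    bleach: Optional[dict[str, tuple[float, float, float, float]]] = field(
        default_factory=default_bleach_params
    )
    misregistration: AffineTransform = field(default_factory=_default_misregistration)
    spatial_corr_len: float = 8.0  # px, Gaussian smoothing of latent fields
    temporal_ar: float = 0.8  # AR(1) coefficient between frames
    n_beads: int = 12
    background_region: Optional[BackgroundRegion] = None  # auto: cell-free corner
    control_frames: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must lie in [-1, 1], got {self.rho}")
        if not (0 <= self.alpha < 1 and 0 <= self.beta < 1):
            raise ValueError("bleed-through fractions must lie in [0, 1)")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        if self.bleach is not None:
            for role, (a1, _, a2, _) in self.bleach.items():
                if abs(a1 + a2 - 1.0) > 1e-9:
                    raise ValueError(f"bleach amplitudes for {role!r} must sum to 1")
        if not np.all(np.isfinite([self.gtp_mean, self.gtp_sd, self.activity_mean,
                                   self.activity_sd, self.shading_amplitude,
                                   self.dark_offset])):
            raise ValueError("config amplitudes must be finite")
        if self.background_region is None:
            # top-left corner; the cell body starts at ~0.18 x frame size
            h, w = self.shape
            self.background_region = BackgroundRegion(2, int(0.14 * h), 2, int(0.14 * w))
        rs, cs = self.background_region.slices()
        if _cell_mask(self.shape)[0][rs, cs].any():
            raise ValueError("background region overlaps the synthetic cell mask")

    def noiseless(self) -> "SceneConfig":
        """Copy with shot and read noise disabled."""
        return replace(self, shot_gain=0.0, read_sd=0.0)

    def artifact_free(self) -> "SceneConfig":
        """Copy with every acquisition artifact disabled (identity forward model)."""
        return replace(
            self,
            alpha=0.0,
            beta=0.0,
            shading_amplitude=0.0,
            dark_offset=0.0,
            shot_gain=0.0,
            read_sd=0.0,
            bleach=None,
            misregistration=AffineTransform.identity(),
        )


@dataclass
class GroundTruth:
    """Latent quantities behind a rendered scene.

    ``gtp_field`` (µM) and ``activity_field`` are (T, H, W) with NaN off
    the cell mask; their in-mask sample correlation equals ``config.rho``
    by construction in every frame.
    """

    mask: np.ndarray  # (H, W) bool
    protrusion_mask: np.ndarray  # (H, W) bool, subset of mask
    gtp_field: np.ndarray  # (T, H, W), NaN off-mask
    activity_field: np.ndarray  # (T, H, W), NaN off-mask
    alpha: float
    beta: float
    shading: dict[str, np.ndarray]
    affine: AffineTransform
    bleach: Optional[dict[str, tuple[float, float, float, float]]]
    config: SceneConfig


def _smooth_unit_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Zero-mean, unit-variance Gaussian random field with correlation length sigma."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    sd = f.std()
    return (f - f.mean()) / (sd if sd > 0 else 1.0)


def _cell_mask(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Elliptical cell body plus one elliptical protrusion lobe."""
    h, w = shape
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    body = ((rr - 0.5 * h) / (0.32 * h)) ** 2 + ((cc - 0.44 * w) / (0.27 * w)) ** 2 <= 1.0
    lobe = ((rr - 0.5 * h) / (0.12 * h)) ** 2 + ((cc - 0.77 * w) / (0.17 * w)) ** 2 <= 1.0
    return body | lobe, lobe & ~body


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise ValueError("degenerate latent field (zero variance in mask)")
    return (v - v.mean()) / sd


def generate_latent_fields(config: SceneConfig) -> GroundTruth:
    """Draw the latent GTP and activity fields with planted correlation.

    Each frame's in-mask activity is built as
    ``rho · z(gtp) + sqrt(1 − rho²) · z⊥`` with the independent component
    orthogonalized against the (clipped, protrusion-offset) GTP field, so
    the in-mask sample correlation equals ``rho`` exactly in every frame.
    Frames evolve as an AR(1) series to resemble 1-min live-cell dynamics.
    """
    rng = np.random.default_rng([config.seed, 101])
    mask, lobe = _cell_mask(config.shape)
    t_frames = config.n_frames
    h, w = config.shape
    ar = config.temporal_ar
    innov_scale = math.sqrt(max(0.0, 1.0 - ar * ar))

    gtp = np.full((t_frames, h, w), np.nan)
    act = np.full((t_frames, h, w), np.nan)
    g_prev = e_prev = None
    for t in range(t_frames):
        g_new = _smooth_unit_field(rng, config.shape, config.spatial_corr_len)
        e_new = _smooth_unit_field(rng, config.shape, config.spatial_corr_len)
        if t == 0:
            g_t, e_t = g_new, e_new
        else:
            g_t = ar * g_prev + innov_scale * g_new
            e_t = ar * e_prev + innov_scale * e_new
        g_prev, e_prev = g_t, e_t

        gtp_frame = config.gtp_mean + config.gtp_sd * _standardize(g_t[mask])
        if config.protrusion_gtp_offset:
            gtp_frame = gtp_frame + config.protrusion_gtp_offset * lobe[mask]
        np.clip(gtp_frame, 0.5, None, out=gtp_frame)

        # correlate against the field as realized (after offset and clipping)
        zg = _standardize(gtp_frame)
        e_in = e_t[mask]
        e_orth = e_in - (e_in @ zg) / (zg @ zg) * zg
        rho = config.rho
        if abs(rho) == 1.0:
            az = math.copysign(1.0, rho) * zg
        else:
            az = rho * zg + math.sqrt(1.0 - rho * rho) * _standardize(e_orth)
        gtp[t, mask] = gtp_frame
        act[t, mask] = config.activity_mean + config.activity_sd * _standardize(az)

    shading = {}
    srng = np.random.default_rng([config.seed, 202])
    for role in CHANNEL_ROLES:
        if config.shading_amplitude > 0:
            f = 1.0 + config.shading_amplitude * _smooth_unit_field(srng, config.shape, 0.25 * h)
            f = np.clip(f, 0.2, None)
            f /= f.mean()
        else:
            f = np.ones(config.shape)
        shading[role] = f

    return GroundTruth(
        mask=mask,
        protrusion_mask=lobe,
        gtp_field=gtp,
        activity_field=act,
        alpha=config.alpha,
        beta=config.beta,
        shading=shading,
        affine=config.misregistration,
        bleach=config.bleach,
        config=config,
    )


def _camera_noise(rng: np.random.Generator, signal: np.ndarray, config: SceneConfig) -> np.ndarray:
    out = np.clip(signal, 0.0, None)
    if config.shot_gain > 0:
        out = rng.poisson(out / config.shot_gain).astype(float) * config.shot_gain
    if config.read_sd > 0:
        out = out + rng.normal(0.0, config.read_sd, size=out.shape)
    return out


def _warp_to_moving_camera(image: np.ndarray, affine: AffineTransform) -> np.ndarray:
    """Render a reference-frame image as seen by the misregistered camera."""
    h, w = image.shape
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    pts = np.stack([rr.ravel(), cc.ravel()], axis=1)
    sample = affine.apply_points(pts).T.reshape(2, h, w)
    return ndimage.map_coordinates(image, sample, order=1, mode="constant", cval=0.0)


def _dark_frame(config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    if config.dark_offset <= 0:
        return np.zeros(config.shape)
    pattern = ndimage.gaussian_filter(rng.standard_normal(config.shape), 20, mode="reflect")
    sd = pattern.std()
    if sd > 0:
        pattern = pattern / sd
    return config.dark_offset + 0.02 * config.dark_offset * pattern


def _render_frame_channels(
    truth: GroundTruth,
    config: SceneConfig,
    geval_sensor: SensorModel,
    donor_ab: np.ndarray,
    geval_ab: np.ndarray,
    t: int,
) -> dict[str, np.ndarray]:
    mask = truth.mask
    act = np.where(mask, truth.activity_field[t], 0.0)
    gtp = np.where(mask, truth.gtp_field[t], 0.0)
    donor = np.where(mask, donor_ab, 0.0)
    acceptor = config.acceptor_ratio * donor
    fret = act * donor + config.alpha * donor + config.beta * acceptor
    ratio = sensor_response(geval_sensor, gtp)
    gev = np.where(mask, geval_ab, 0.0)
    ex409 = gev * ratio / (1.0 + ratio)
    ex494 = gev / (1.0 + ratio)
    return {"donor": donor, "fret": fret, "acceptor": acceptor, "ex409": ex409, "ex494": ex494}


def render_channels(
    truth: GroundTruth,
    config: SceneConfig | None = None,
    geval_sensor: SensorModel = GEVAL30,
) -> tuple[RawStack, CorrectionBundle]:
    """Render the 5-channel raw stack and its matching correction bundle.

    Forward model per frame: latent channels on the reference grid →
    bleed-through mixing into FRET → per-channel double-exponential bleach
    → affine misregistration of the GTP-sensor channels → multiplicative
    shading → additive dark current → shot/read noise.  The bundle carries
    the exact dark frames and shading references, bead fiducials consistent
    with the true affine, and noise-matched donor-only / acceptor-only
    control stacks for bleed-through estimation.
    """
    if config is None:
        config = truth.config
    rng = np.random.default_rng([config.seed, 303])
    h, w = config.shape
    times = np.arange(config.n_frames, dtype=float) * config.frame_interval

    donor_ab = config.donor_base * np.clip(
        1.0 + 0.15 * _smooth_unit_field(rng, config.shape, 15.0), 0.3, None
    )
    geval_ab = config.geval_base * np.clip(
        1.0 + 0.15 * _smooth_unit_field(rng, config.shape, 15.0), 0.3, None
    )

    dark = {role: _dark_frame(config, rng) for role in CHANNEL_ROLES}
    bleach = {
        role: (
            bleach_curve(config.bleach[role], times) if config.bleach else np.ones_like(times)
        )
        for role in CHANNEL_ROLES
    }

    data = np.zeros((config.n_frames, len(CHANNEL_ROLES), h, w))
    geval_roles = {"ex409", "ex494"}
    for t in range(config.n_frames):
        chans = _render_frame_channels(truth, config, geval_sensor, donor_ab, geval_ab, t)
        for c, role in enumerate(CHANNEL_ROLES):
            img = chans[role] * bleach[role][t]
            if role in geval_roles and not truth.affine.is_identity():
                img = _warp_to_moving_camera(img, truth.affine)
            img = img * truth.shading[role] + dark[role]
            data[t, c] = _camera_noise(rng, img, config)
    stack = RawStack(data, CHANNEL_ROLES, config.frame_interval)

    # fiducial beads: positions in the reference frame and where the moving
    # camera sees them (src -> dst under the true affine)
    margin = 12
    dst = np.column_stack(
        [rng.uniform(margin, h - margin, config.n_beads), rng.uniform(margin, w - margin, config.n_beads)]
    )
    src = truth.affine.inverse().apply_points(dst)

    donor_only = _render_control(config, rng, "donor", dark, truth.shading)
    acceptor_only = _render_control(config, rng, "acceptor", dark, truth.shading)

    bundle = CorrectionBundle(
        dark=dark,
        shading=truth.shading,
        background=config.background_region,
        alpha=None,
        beta=None,
        fiducials_src=src,
        fiducials_dst=dst,
        donor_only=donor_only,
        acceptor_only=acceptor_only,
    )
    return stack, bundle


def _render_control(
    config: SceneConfig,
    rng: np.random.Generator,
    kind: str,
    dark: dict[str, np.ndarray],
    shading: dict[str, np.ndarray],
) -> RawStack:
    """Single-fluorophore control stack from the same session.

    Shares the session's dark frames and shading references; rendered
    without bleach (a short control acquisition) on the reference camera.
    """
    h, w = config.shape
    mask, _ = _cell_mask(config.shape)
    ab = config.donor_base * np.clip(
        1.0 + 0.25 * _smooth_unit_field(rng, config.shape, 12.0), 0.2, None
    )
    ab = np.where(mask, ab, 0.0)
    zeros = np.zeros((h, w))
    if kind == "donor":
        chans = {"donor": ab, "fret": config.alpha * ab, "acceptor": zeros,
                 "ex409": zeros, "ex494": zeros}
    elif kind == "acceptor":
        chans = {"donor": zeros, "fret": config.beta * ab, "acceptor": ab,
                 "ex409": zeros, "ex494": zeros}
    else:  # pragma: no cover
        raise ValueError(kind)
    data = np.zeros((config.control_frames, len(CHANNEL_ROLES), h, w))
    for t in range(config.control_frames):
        for c, role in enumerate(CHANNEL_ROLES):
            img = chans[role] * shading[role] + dark[role]
            data[t, c] = _camera_noise(rng, img, config)
    return RawStack(data, CHANNEL_ROLES, config.frame_interval)


def simulate_scene(
    config: SceneConfig, geval_sensor: SensorModel = GEVAL30
) -> tuple[RawStack, CorrectionBundle, GroundTruth]:
    """Convenience: latent fields + rendered stack + bundle in one call."""
    truth = generate_latent_fields(config)
    stack, bundle = render_channels(truth, config, geval_sensor)
    return stack, bundle, truth


def generate_cbcp_dataset(
    n_cells: int = 30,
    offset: float = 0.15,
    seed: int = 0,
    *,
    cb_mean: float = 1.8,
    between_cell_sd: float = 0.15,
    noise_sd: float = 0.08,
) -> pd.DataFrame:
    """Paired cell-body / cell-protrusion GTP-sensor ratio table.

    Emulates the transwell experiment in which each cell contributes one
    mean sensor ratio in its body (CB) and one in its protrusion (CP);
    ``offset`` is the true CP − CB ratio difference (0 for a null sensor).
    Columns: ``cell``, ``cb``, ``cp``.
    """
    if n_cells < 2:
        raise ValueError("need at least 2 cells")
    rng = np.random.default_rng([seed, 404])
    cb = cb_mean + between_cell_sd * rng.standard_normal(n_cells)
    cp = cb + offset + noise_sd * rng.standard_normal(n_cells)
    return pd.DataFrame({"cell": np.arange(n_cells), "cb": cb, "cp": cp})
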