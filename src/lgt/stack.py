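"""Core in-memory containers for multi-channel time-lapse stacks.

A dual-biosensor acquisition produces five channels per frame: three for the
FRET-based RAC1 activity sensor (donor, FRET, acceptor) and two for the
ratiometric GTP sensor (excitation 409 nm and 494 nm, shared emission).
These containers carry the raster data plus the channel-role metadata and
the correction assets (dark frames, shading references, background region,
bleed-through coefficients, fiducial bead coordinates) that the
preprocessing chain consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "CHANNEL_ROLES",
    "RawStack",
    "BackgroundRegion",
    "CorrectionBundle",
    "MaskStack",
]

#: canonical channel order: RAC1 sensor triplet, then the GTP sensor pair
CHANNEL_ROLES = ("donor", "fret", "acceptor", "ex409", "ex494")


@dataclass
class RawStack:
    """Time × channel × row × column intensity raster.

    ``data`` is float64 in detector counts; ``channel_roles`` names each
    channel axis entry; ``frame_interval`` is in minutes.
    """

    data: np.ndarray
    channel_roles: tuple[str, ...] = CHANNEL_ROLES
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"expected (T, C, H, W) array, got shape {self.data.shape}")
        if self.data.shape[0] < 1:
            raise ValueError("stack needs at least one frame")
        if len(self.channel_roles) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.channel_roles)} roles for {self.data.shape[1]} channels"
            )
        if len(set(self.channel_roles)) != len(self.channel_roles):
            raise ValueError("channel roles must be unique")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    def channel_index(self, role: str) -> int:
        try:
            return self.channel_roles.index(role)
        except ValueError:
            raise KeyError(f"no channel with role {role!r}") from None

    def channel(self, role: str) -> np.ndarray:
        """(T, H, W) view of one channel."""
        return self.data[:, self.channel_index(role)]

    def copy(self) -> "RawStack":
        return RawStack(self.data.copy(), self.channel_roles, self.frame_interval)

    @property
    def times(self) -> np.ndarray:
        """Acquisition times in minutes, frame 0 at t = 0."""
        return np.arange(self.n_frames, dtype=float) * self.frame_interval


@dataclass(frozen=True)
class BackgroundRegion:
    """Rectangular cell-free region used for per-frame background levels."""

    row0: int
    row1: int
    col0: int
    col1: int

    def __post_init__(self) -> None:
        if self.row1 <= self.row0 or self.col1 <= self.col0:
            raise ValueError("background region must have positive extent")

    @property
    def n_pixels(self) -> int:
        return (self.row1 - self.row0) * (self.col1 - self.col0)

    def slices(self) -> tuple[slice, slice]:
        return slice(self.row0, self.row1), slice(self.col0, self.col1)

    def mask(self, frame_shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(frame_shape, dtype=bool)
        m[self.slices()] = True
        return m


@dataclass
class CorrectionBundle:
    """Correction assets acquired alongside a biosensor session.

    dark : role -> 2-D dark frame (counts, acquired without excitation)
    shading : role -> 2-D unit-mean shading reference (uniform dye image)
    background : cell-free rectangle for per-frame background subtraction
    alpha, beta : bleed-through fractions of donor / directly excited
        acceptor into the FRET channel (estimated from single-fluorophore
        controls when None)
    fiducials_src/dst : bead coordinates (N, 2) as (row, col) in the moving
        (GTP-sensor camera) and reference frames
    donor_only, acceptor_only : control stacks from cells expressing a
        single fluorophore, used to estimate alpha and beta
    """

    dark: dict[str, np.ndarray] = field(default_factory=dict)
    shading: dict[str, np.ndarray] = field(default_factory=dict)
    background: Optional[BackgroundRegion] = None
    alpha: Optional[float] = None
    beta: Optional[float] = None
    fiducials_src: Optional[np.ndarray] = None
    fiducials_dst: Optional[np.ndarray] = None
    donor_only: Optional[RawStack] = None
    acceptor_only: Optional[RawStack] = None

    def __post_init__(self) -> None:
        for role, ref in self.shading.items():
            ref = np.asarray(ref, dtype=float)
            if not np.all(ref > 0):
                raise ValueError(f"shading reference for {role!r} must be strictly positive")
            if abs(ref.mean() - 1.0) > 1e-6:
                raise ValueError(
                    f"shading reference for {role!r} must have mean 1 "
                    f"(got {ref.mean():.8f})"
                )
            self.shading[role] = ref
        for coef, name in ((self.alpha, "alpha"), (self.beta, "beta")):
            if coef is not None and not (0 <= coef < 1):
                raise ValueError(f"{name} must lie in [0, 1), got {coef}")


@dataclass
class MaskStack:
    """Per-frame boolean cell masks plus the threshold that produced each."""

    masks: np.ndarray  # (T, H, W) bool
    thresholds: np.ndarray  # (T,) float

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks, dtype=bool)
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if self.masks.ndim != 3:
            raise ValueError("masks must be (T, H, W)")
        if self.thresholds.shape != (self.masks.shape[0],):
            raise ValueError("one threshold per frame required")
        if not np.all(np.isfinite(self.thresholds)):
            raise ValueError("thresholds must be finite")

    @property
    def n_frames(self) -> int:
        return self.masks.shape[0]
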