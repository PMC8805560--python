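"""Line-profile statistics for high-speed holographic height recordings.

A recording is a stack of height line-profiles along a cell (nm versus
position, one profile per camera frame) with a stimulus window embedded in
the timeline — by default 25 ms of baseline, a 50 ms ultrasound stimulus
and a 25 ms post-stimulus dwell.  The statistic mirrors the instrument
analysis: the per-position mean profile over the pre-stimulus frames
defines the baseline, and the maximum deflection is the largest deviation
from that baseline over all positions and stimulus frames.

Because instrument data are not redistributable, the module also generates
synthetic stacks with a known injected deflection (optionally taken from a
membrane-model run) and recorded ground truth, so the statistic is testable
end to end.  The max-over-noise statistic carries the positive bias of any
extreme-value estimate; it is reported as-is, uncorrected.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .membrane import ParameterError

if TYPE_CHECKING:  # pragma: no cover
    from .membrane import DeflectionTrace

__all__ = [
    "ProfileStack",
    "BaselineProfile",
    "MaxDeflection",
    "mean_baseline_profile",
    "max_deflection",
    "generate_fixture",
    "write_stack",
    "read_stack",
]


@dataclass
class ProfileStack:
    """Height line-profiles per frame.

    x_um            : positions along the profile [um]
    t_s             : frame timestamps [s], increasing
    height_nm       : (n_frames, n_positions) heights [nm]
    stimulus_window : (t_on, t_off) [s] within the recording
    metadata        : free-form (cell label, seed, ground truth, ...)
    """

    x_um: np.ndarray
    t_s: np.ndarray
    height_nm: np.ndarray
    stimulus_window: tuple[float, float]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.height_nm = np.asarray(self.height_nm, dtype=float)
        if self.height_nm.shape != (self.t_s.size, self.x_um.size):
            raise ParameterError("height_nm must be (n_frames, n_positions)")
        if np.any(np.diff(self.t_s) <= 0):
            raise ParameterError("frames must be strictly time-ordered")
        t_on, t_off = self.stimulus_window
        if not (self.t_s[0] <= t_on < t_off <= self.t_s[-1] + 1e-12):
            raise ParameterError("stimulus_window must lie within the recording")

    @property
    def baseline_mask(self) -> np.ndarray:
        return self.t_s < self.stimulus_window[0]

    @property
    def stimulus_mask(self) -> np.ndarray:
        t_on, t_off = self.stimulus_window
        return (self.t_s >= t_on) & (self.t_s <= t_off)


@dataclass
class BaselineProfile:
    """Per-position baseline mean with a 95% normal-approximation band."""

    x_um: np.ndarray
    mean_nm: np.ndarray
    lo_nm: np.ndarray
    hi_nm: np.ndarray

    @property
    def band_width_nm(self) -> np.ndarray:
        return self.hi_nm - self.lo_nm


def mean_baseline_profile(stack: ProfileStack) -> BaselineProfile:
    """Mean height per position over pre-stimulus frames, with a 95% band
    of the per-frame values (mean +/- 1.96 sd)."""
    mask = stack.baseline_mask
    if mask.sum() < 2:
        raise ParameterError("need at least 2 pre-stimulus frames for a baseline")
    base = stack.height_nm[mask]
    mean = base.mean(axis=0)
    sd = base.std(axis=0, ddof=1)
    return BaselineProfile(
        x_um=stack.x_um, mean_nm=mean,
        lo_nm=mean - 1.96 * sd, hi_nm=mean + 1.96 * sd,
    )


@dataclass
class MaxDeflection:
    """Largest deviation from the baseline mean during the stimulus."""

    max_nm: float
    t_argmax_s: float
    x_argmax_um: float
    profile_at_argmax_nm: np.ndarray  # deflection vs position at the argmax frame
    per_position_max_nm: np.ndarray


def max_deflection(stack: ProfileStack, baseline: BaselineProfile | None = None) -> MaxDeflection:
    """Max over (position, stimulus frame) of |height - baseline mean|.

    Also returns the full deflection profile at the argmax frame and the
    per-position maxima, since whether the instrument statistic is taken at
    a fixed position or across the whole profile is a user-level choice.
    """
    if baseline is None:
        baseline = mean_baseline_profile(stack)
    mask = stack.stimulus_mask
    if not mask.any():
        raise ParameterError("stimulus window contains no frames")
    defl = stack.height_nm[mask] - baseline.mean_nm[None, :]
    mag = np.abs(defl)
    i_frame, i_pos = np.unravel_index(np.argmax(mag), mag.shape)
    t_stim = stack.t_s[mask]
    return MaxDeflection(
        max_nm=float(mag[i_frame, i_pos]),
        t_argmax_s=float(t_stim[i_frame]),
        x_argmax_um=float(stack.x_um[i_pos]),
        profile_at_argmax_nm=defl[i_frame],
        per_position_max_nm=mag.max(axis=0),
    )


# --------------------------------------------------------------------------
# synthetic stacks


def _default_cell_profile(x_um: np.ndarray) -> np.ndarray:
    """Smooth dome-shaped static cell height [nm] over the profile span."""
    span = x_um[-1] - x_um[0]
    xi = (x_um - x_um[0]) / span
    return 1500.0 * np.sin(np.pi * xi) ** 2


def generate_fixture(
    *,
    seed: int,
    n_positions: int = 64,
    length_um: float = 20.0,
    frame_rate_hz: float = 4000.0,
    layout_s: tuple[float, float, float] = (0.025, 0.050, 0.025),
    base_profile_nm: np.ndarray | None = None,
    noise_amp_nm: float = 20.0,
    noise_kind: str = "uniform",
    deflection_nm: float = 200.0,
    deflection_source: "DeflectionTrace | None" = None,
    cell_label: str = "synthetic-cell",
) -> ProfileStack:
    """Reproducible synthetic recording with known ground truth.

    Emulates the measurement protocol: ``layout_s`` gives baseline /
    stimulus / post durations (default 25/50/25 ms); the native 40 kHz
    frame rate is decimated to 4 kHz by default for speed (the decimation
    factor is recorded in metadata).  Baseline noise is bounded uniform
    (half-range ``noise_amp_nm``) or Gaussian (sigma ``noise_amp_nm``).

    The stimulus-locked deflection is either a smooth bump of peak
    ``deflection_nm`` (raised-cosine in time, fundamental sine in space) or,
    if ``deflection_source`` is given, a membrane-model displacement field
    resampled onto the frames; its true peak is stored in
    ``metadata["true_max_deflection_nm"]``.
    """
    rng = np.random.default_rng(seed)
    x_um = np.linspace(0.0, length_um, n_positions)
    t_base, t_stim, t_post = layout_s
    total = t_base + t_stim + t_post
    n_frames = int(round(total * frame_rate_hz))
    t_s = np.arange(n_frames) / frame_rate_hz
    window = (t_base, t_base + t_stim)

    if base_profile_nm is None:
        base_profile_nm = _default_cell_profile(x_um)
    base_profile_nm = np.asarray(base_profile_nm, dtype=float)
    if base_profile_nm.shape != x_um.shape:
        raise ParameterError("base_profile_nm must match n_positions")

    height = np.tile(base_profile_nm, (n_frames, 1))

    if noise_amp_nm > 0:
        if noise_kind == "uniform":
            noise = rng.uniform(-noise_amp_nm, noise_amp_nm, size=height.shape)
        elif noise_kind == "gaussian":
            noise = rng.normal(0.0, noise_amp_nm, size=height.shape)
        else:
            raise ParameterError(f"unknown noise_kind {noise_kind!r}")
        height = height + noise

    in_stim = (t_s >= window[0]) & (t_s <= window[1])
    if deflection_source is not None:
        trace = deflection_source
        d_m = float(trace.x_grid[-1] - trace.x_grid[0])
        # map the model span onto the central portion of the profile
        x_m = (x_um - x_um[0]) * 1.0e-6
        x_model = np.clip(x_m * d_m / (x_m[-1] if x_m[-1] > 0 else 1.0), 0.0, d_m)
        u_nm = trace.u * 1.0e9  # (nx_model, nt_model)
        t_rel = t_s[in_stim] - window[0]
        t_model = np.clip(t_rel, trace.t_grid[0], trace.t_grid[-1])
        # bilinear resample: positions then times
        from scipy.interpolate import RegularGridInterpolator

        interp = RegularGridInterpolator(
            (trace.x_grid, trace.t_grid), u_nm, bounds_error=False, fill_value=0.0
        )
        XX, TT = np.meshgrid(x_model, t_model, indexing="ij")
        bump = interp(np.stack([XX.ravel(), TT.ravel()], axis=-1)).reshape(XX.shape).T
        true_max = float(np.max(np.abs(bump)))
    else:
        tt = t_s[in_stim]
        envelope = 0.5 * (1.0 - np.cos(2.0 * np.pi * (tt - window[0]) / t_stim))
        shape = np.sin(np.pi * (x_um - x_um[0]) / (x_um[-1] - x_um[0]))
        bump = deflection_nm * envelope[:, None] * shape[None, :]
        true_max = float(np.max(np.abs(bump)))  # as sampled on the grid

    height[in_stim] += bump

    return ProfileStack(
        x_um=x_um, t_s=t_s, height_nm=height, stimulus_window=window,
        metadata={
            "cell": cell_label,
            "seed": int(seed),
            "true_max_deflection_nm": true_max,
            "noise_amp_nm": float(noise_amp_nm),
            "noise_kind": noise_kind,
            "native_frame_rate_hz": 40000.0,
            "frame_rate_hz": float(frame_rate_hz),
            "decimation_factor": 40000.0 / frame_rate_hz,
        },
    )


# --------------------------------------------------------------------------
# CSV round trip (long format with a small comment header)

_HEADER_KEYS = ("cell", "seed", "true_max_deflection_nm")


def write_stack(stack: ProfileStack, path) -> None:
    """Long-format CSV: t_s, x_um, height_nm; stimulus window and selected
    metadata in '#'-prefixed header lines."""
    path = Path(path)
    buf = io.StringIO()
    t_on, t_off = stack.stimulus_window
    buf.write(f"# stimulus_window_s: {t_on!r} {t_off!r}\n")
    for key in _HEADER_KEYS:
        if key in stack.metadata:
            buf.write(f"# {key}: {stack.metadata[key]}\n")
    df = pd.DataFrame({
        "t_s": np.repeat(stack.t_s, stack.x_um.size),
        "x_um": np.tile(stack.x_um, stack.t_s.size),
        "height_nm": stack.height_nm.ravel(),
    })
    df.to_csv(buf, index=False)
    path.write_text(buf.getvalue())


def read_stack(path) -> ProfileStack:
    path = Path(path)
    meta: dict = {}
    window = None
    n_header = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            key, _, value = line[1:].strip().partition(":")
            key, value = key.strip(), value.strip()
            if key == "stimulus_window_s":
                a, b = value.split()
                window = (float(a), float(b))
            else:
                meta[key] = value
    if window is None:
        raise ParameterError(f"{path}: missing '# stimulus_window_s' header")
    df = pd.read_csv(path, skiprows=n_header)
    t = np.unique(df["t_s"].to_numpy())
    x = np.unique(df["x_um"].to_numpy())
    height = (
        df.sort_values(["t_s", "x_um"])["height_nm"].to_numpy().reshape(t.size, x.size)
    )
    return ProfileStack(x_um=x, t_s=t, height_nm=height, stimulus_window=window,
                        metadata=meta)
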