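"""Raw two-channel stacks to hemodynamics-corrected, parcellated region traces.

The correction scheme follows the standard isosbestic-reference design for
widefield calcium imaging: the calcium-dependent channel (470 nm excitation)
and the calcium-independent reference channel (405 nm excitation) are acquired
in alternation; both are converted to ΔF/F against their per-pixel whole-series
median, the reference is smoothed (400-ms moving average) and regressed onto
the signal, and the scaled reference is subtracted, removing shared
hemodynamic/absorption artifacts.  Corrected pixels are then averaged within
each atlas subdivision and subdivisions are averaged (unweighted) into the 12
grouped regions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .regions import REGIONS, RegionAtlas

SIGNAL_TAG = "signal_470"
REFERENCE_TAG = "reference_405"


class DialectError(ValueError):
    """Raised when an input stack violates the expected acquisition layout."""


@dataclass
class TwoChannelMovie:
    """Interleaved signal/reference frame stack with per-frame channel tags."""

    frames: np.ndarray  # (time, height, width)
    channel_tags: np.ndarray  # per-frame, SIGNAL_TAG or REFERENCE_TAG
    fps_per_channel: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.channel_tags = np.asarray(self.channel_tags)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (time, height, width) stack")
        if len(self.channel_tags) != len(self.frames):
            raise ValueError("one channel tag per frame required")

    def save(self, path: str | Path, meta: dict | None = None) -> None:
        """Write the stack (TIFF or HDF5 by extension) plus a JSON sidecar."""
        path = Path(path)
        if path.suffix in (".h5", ".hdf5"):
            import h5py

            with h5py.File(path, "w") as f:
                f.create_dataset("frames", data=self.frames)
        else:
            import tifffile

            tifffile.imwrite(path, self.frames.astype(np.float32))
        sidecar = {
            "channel_tags": self.channel_tags.tolist(),
            "fps_per_channel": self.fps_per_channel,
            **(meta or {}),
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path: str | Path) -> "TwoChannelMovie":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        if path.suffix in (".h5", ".hdf5"):
            import h5py

            with h5py.File(path, "r") as f:
                frames = f["frames"][...]
        else:
            import tifffile

            frames = tifffile.imread(path)
        return cls(
            frames=frames,
            channel_tags=np.asarray(sidecar["channel_tags"]),
            fps_per_channel=float(sidecar["fps_per_channel"]),
        )


@dataclass
class RegionTraces:
    """Regions x frames matrix of ΔF/F or z-scored activity."""

    values: np.ndarray  # (n_regions, n_frames)
    region_names: tuple[str, ...]
    fps: float
    units: str = "dff"  # "dff" or "zscore"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.region_names = tuple(self.region_names)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.region_names):
            raise ValueError("values must be (n_regions, n_frames) matching region_names")
        if np.isnan(self.values).any():
            raise ValueError("region traces contain missing values")

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    def to_csv(self, path: str | Path) -> None:
        """Frames x regions CSV (header = region names) with a JSON metadata sidecar."""
        path = Path(path)
        pd.DataFrame(self.values.T, columns=list(self.region_names)).to_csv(path, index=False)
        side = {"fps": self.fps, "units": self.units, **self.meta}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(side))

    @classmethod
    def from_csv(cls, path: str | Path) -> "RegionTraces":
        path = Path(path)
        df = pd.read_csv(path)
        side = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        fps = side.pop("fps")
        units = side.pop("units", "dff")
        return cls(values=df.to_numpy().T, region_names=tuple(df.columns), fps=fps, units=units, meta=side)


def deinterleave(movie: TwoChannelMovie) -> tuple[np.ndarray, np.ndarray]:
    """Split an interleaved stack into (signal, reference), trimming the tail.

    Tags must strictly alternate; a violation raises :class:`DialectError`
    naming the first offending frame.  If one channel has one frame more than
    the other (odd total), the trailing frame is dropped.
    """
    tags = movie.channel_tags
    for i in range(1, len(tags)):
        if tags[i] == tags[i - 1]:
            raise DialectError(f"channel tags do not alternate at frame {i}")
    sig = movie.frames[tags == SIGNAL_TAG]
    ref = movie.frames[tags == REFERENCE_TAG]
    n = min(len(sig), len(ref))
    if abs(len(sig) - len(ref)) > 1:
        raise DialectError("channel frame counts differ by more than one")
    return sig[:n], ref[:n]


def downsample(stack: np.ndarray, factor: int) -> np.ndarray:
    """Non-overlapping block mean over the spatial axes (e.g. 512->128 at factor 4)."""
    stack = np.asarray(stack, dtype=float)
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return stack.copy()
    squeeze = stack.ndim == 2
    if squeeze:
        stack = stack[None]
    t, h, w = stack.shape
    if h % factor or w % factor:
        raise ValueError(f"dimensions ({h}, {w}) not divisible by factor {factor}")
    out = stack.reshape(t, h // factor, factor, w // factor, factor).mean(axis=(2, 4))
    return out[0] if squeeze else out


def compute_dff(stack: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel ΔF/F against the whole-series median.

    Returns ``(dff, valid_mask)``.  Pixels whose median is not strictly
    positive cannot be normalized; they are flagged invalid (mask False), set
    to zero, and should be excluded from region averages downstream.
    """
    stack = np.asarray(stack, dtype=float)
    med = np.median(stack, axis=0)
    valid = med > 0
    safe = np.where(valid, med, 1.0)
    dff = (stack - med) / safe
    dff = np.where(valid, dff, 0.0)
    return dff, valid


def smooth_reference(trace: np.ndarray, window_s: float = 0.4, fps: float = 11.7) -> np.ndarray:
    """Centered moving average of width ``window_s`` (shrinking windows at edges).

    Works along axis 0 for 1-D traces or whole stacks.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    x = np.asarray(trace, dtype=float)
    w = max(1, int(round(window_s * fps)))
    if w == 1:
        return x.copy()
    n = x.shape[0]
    kernel = np.ones(w)
    flat = x.reshape(n, -1)
    num = np.apply_along_axis(lambda c: np.convolve(c, kernel, mode="same"), 0, flat)
    counts = np.convolve(np.ones(n), kernel, mode="same")
    return (num / counts[:, None]).reshape(x.shape)


def hemodynamic_correct(sig: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Regress signal on the smoothed reference and subtract the fit.

    Least squares ``sig ~ alpha + beta * ref`` per pixel (time on axis 0);
    returns ``(corrected, alpha, beta)`` where corrected is the OLS residual.
    A constant reference leaves beta undefined: beta is set to 0, the mean of
    the signal is removed, and a warning is issued.
    """
    sig = np.asarray(sig, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if sig.shape != ref.shape:
        raise ValueError("signal and reference must have identical shapes")
    if sig.shape[0] < 2:
        raise ValueError("need at least two frames")
    mu_s = sig.mean(axis=0)
    mu_r = ref.mean(axis=0)
    ds = sig - mu_s
    dr = ref - mu_r
    var_r = (dr * dr).mean(axis=0)
    cov = (ds * dr).mean(axis=0)
    degenerate = var_r <= 0
    if np.any(degenerate):
        warnings.warn("constant reference: beta undefined, removing signal mean only")
    beta = np.where(degenerate, 0.0, cov / np.where(degenerate, 1.0, var_r))
    alpha = mu_s - beta * mu_r
    corrected = sig - (alpha + beta * ref)
    return corrected, np.asarray(alpha), np.asarray(beta)


def parcellate(
    stack: np.ndarray,
    atlas: RegionAtlas,
    fps: float,
    valid_mask: np.ndarray | None = None,
    units: str = "dff",
    meta: dict | None = None,
) -> RegionTraces:
    """Average pixels into subdivision traces, then subdivisions into regions.

    The grouped-region trace is the unweighted mean of its constituent
    subdivision traces (not a pixel-weighted mean).  A region with no valid
    pixels in any subdivision is a hard error naming the region.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.shape[1:] != atlas.label_image.shape:
        raise ValueError("atlas dimensions do not match the stack")
    if valid_mask is None:
        valid_mask = np.ones(atlas.label_image.shape, dtype=bool)
    flat = stack.reshape(stack.shape[0], -1)
    labels = atlas.label_image.ravel()
    vmask = valid_mask.ravel()
    label_of = atlas.subdivisions.set_index("acronym")["label"]
    region_rows = []
    for region in REGIONS:
        acrs = atlas.grouping.loc[atlas.grouping["region"] == region, "acronym"]
        sub_traces = []
        for acr in acrs:
            if acr not in label_of.index:
                continue
            sel = (labels == int(label_of[acr])) & vmask
            if sel.any():
                sub_traces.append(flat[:, sel].mean(axis=1))
        if not sub_traces:
            raise ValueError(f"region {region} has no valid pixels")
        region_rows.append(np.mean(sub_traces, axis=0))
    return RegionTraces(
        values=np.asarray(region_rows),
        region_names=REGIONS,
        fps=fps,
        units=units,
        meta=meta or {},
    )


def preprocess_movie(
    movie: TwoChannelMovie,
    atlas: RegionAtlas,
    downsample_factor: int = 1,
    hemo_correct: bool = True,
    window_s: float = 0.4,
    meta: dict | None = None,
) -> RegionTraces:
    """Full stack pipeline: deinterleave, downsample, ΔF/F, correct, parcellate."""
    sig, ref = deinterleave(movie)
    if downsample_factor > 1:
        sig = downsample(sig, downsample_factor)
        ref = downsample(ref, downsample_factor)
    sig_dff, sig_ok = compute_dff(sig)
    if hemo_correct:
        ref_dff, ref_ok = compute_dff(ref)
        ref_smooth = smooth_reference(ref_dff, window_s=window_s, fps=movie.fps_per_channel)
        corrected, _, _ = hemodynamic_correct(sig_dff, ref_smooth)
        valid = sig_ok & ref_ok
    else:
        corrected, valid = sig_dff, sig_ok
    return parcellate(corrected, atlas, fps=movie.fps_per_channel, valid_mask=valid, meta=meta)
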