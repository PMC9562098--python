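"""Ridgeline traces and curved B-scan strips.

The fibrovascular ridge in ROP runs along the vascular-avascular junction,
so a single native B-scan rarely follows it. The measurement geometry is
therefore a *curved reformation*: an open polyline traced on the en face
projection (the ridgeline), resampled to uniform arc-length spacing, and the
A-scan at each resampled point extracted by bilinear interpolation between
the four neighbouring lateral columns. Stacking those A-scans yields a 2-D
"ridge strip" — a B-scan that follows the ridge — on which surfaces are
segmented and thickness measured.

Coordinate convention (used package-wide): en face points are ``(slow,
fast)`` pixel coordinates, 0-based, real-valued, y-down; the slow axis
indexes B-scans. Traces mark the ridge crest; clinically the junction is
traced on the vascular side, which is a labelling guideline rather than
enforced geometry.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .volume import OCTVolume


@dataclass
class RidgeTrace:
    """An ordered open polyline in en face pixel coordinates.

    ``points`` has shape ``(n, 2)`` with columns ``(slow, fast)``; consecutive
    points must be distinct and there must be at least two of them.
    ``source`` records provenance: ``"manual"`` for human tracings,
    ``"truth"`` for phantom ground-truth ridgelines.
    """

    points: np.ndarray
    source: str = "manual"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(f"trace points must have shape (n, 2); got {pts.shape}")
        if pts.shape[0] < 2:
            raise ValueError(f"a trace needs >= 2 points; got {pts.shape[0]}")
        if not np.all(np.isfinite(pts)):
            raise ValueError("trace points must be finite")
        seg = np.diff(pts, axis=0)
        if np.any(np.all(seg == 0.0, axis=1)):
            raise ValueError("consecutive trace points must be distinct")
        self.points = pts

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def arc_length(self) -> float:
        """Total polyline length in en face pixels."""
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))

    def reversed(self) -> "RidgeTrace":
        return RidgeTrace(points=self.points[::-1].copy(), source=self.source)

    def check_bounds(self, enface_shape: tuple[int, int]) -> None:
        """Raise if any point lies outside ``[0, n-1]`` in either axis."""
        n_slow, n_fast = enface_shape
        s, f = self.points[:, 0], self.points[:, 1]
        bad = (s < 0) | (s > n_slow - 1) | (f < 0) | (f > n_fast - 1)
        if np.any(bad):
            idx = int(np.argmax(bad))
            raise ValueError(
                f"trace point {idx} at {tuple(self.points[idx])} is outside the "
                f"en face bounds {enface_shape}"
            )


@dataclass
class RidgeStrip:
    """The curved B-scan along a trace: one interpolated A-scan per column."""

    pixels: np.ndarray  # (axial, n_samples)
    sample_positions: np.ndarray  # (n_samples, 2) en face (slow, fast)
    arc_spacing_px: float
    axial_pixel_um: float = field(default=4.4)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        self.sample_positions = np.asarray(self.sample_positions, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("strip pixels must be 2-D (axial, samples)")
        if self.sample_positions.shape != (self.pixels.shape[1], 2):
            raise ValueError("one sample position is required per strip column")

    @property
    def n_columns(self) -> int:
        return self.pixels.shape[1]

    @property
    def n_axial(self) -> int:
        return self.pixels.shape[0]


def resample_trace(trace: RidgeTrace, spacing_px: float) -> RidgeTrace:
    """Resample a polyline at uniform arc-length spacing.

    Samples sit at arc lengths ``0, s, 2s, ...`` up to the last multiple of
    ``s`` not exceeding the total length ``L``, giving ``floor(L/s) + 1``
    points; the far endpoint is included exactly when ``L`` is an integer
    multiple of ``s`` (within 1e-9 px), so total length is preserved to
    within one spacing.
    """
    if not spacing_px > 0:
        raise ValueError(f"spacing_px must be > 0; got {spacing_px}")
    pts = trace.points
    seg = np.diff(pts, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    total = float(seg_len.sum())
    if total <= 0:
        raise ValueError("cannot resample a zero-length trace")
    # snap near-integer multiples so endpoints survive float noise
    n_steps = int(np.floor(total / spacing_px + 1e-9))
    if n_steps == 0:
        # spacing exceeds the trace: degrade to the two endpoints
        return RidgeTrace(points=pts[[0, -1]].copy(), source=trace.source)
    arcs = np.arange(n_steps + 1) * spacing_px
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    slow = np.interp(arcs, cum, pts[:, 0])
    fast = np.interp(arcs, cum, pts[:, 1])
    out = np.column_stack([slow, fast])
    # drop accidental duplicates from arc samples landing on the same point
    keep = np.ones(len(out), dtype=bool)
    keep[1:] = np.any(np.abs(np.diff(out, axis=0)) > 1e-12, axis=1)
    return RidgeTrace(points=out[keep], source=trace.source)


def extract_ridge_strip(
    volume: OCTVolume, trace: RidgeTrace, spacing_px: float = 1.0
) -> RidgeStrip:
    """Extract the curved strip of A-scans along a trace.

    The trace is resampled to ``spacing_px``; column ``j`` of the strip is
    the A-scan at resampled position ``j``, bilinearly interpolated between
    the four neighbouring lateral columns of the volume. Default spacing of
    1 px preserves the native lateral sampling.
    """
    trace.check_bounds(volume.enface_shape)
    resampled = resample_trace(trace, spacing_px)
    n_slow, n_fast = volume.enface_shape
    pts = resampled.points
    bad = (
        (pts[:, 0] < 0)
        | (pts[:, 0] > n_slow - 1)
        | (pts[:, 1] < 0)
        | (pts[:, 1] > n_fast - 1)
    )
    if np.any(bad):
        idx = int(np.argmax(bad))
        raise ValueError(
            f"resampled trace position {idx} at {tuple(pts[idx])} exits the "
            f"volume lateral bounds {(n_slow, n_fast)}"
        )

    s = pts[:, 0]
    f = pts[:, 1]
    s0 = np.clip(np.floor(s).astype(int), 0, n_slow - 2) if n_slow > 1 else np.zeros(len(s), int)
    f0 = np.clip(np.floor(f).astype(int), 0, n_fast - 2) if n_fast > 1 else np.zeros(len(f), int)
    ds = s - s0
    df = f - f0
    s1 = np.minimum(s0 + 1, n_slow - 1)
    f1 = np.minimum(f0 + 1, n_fast - 1)
    vol = volume.intensities
    # (n_samples, axial) then transpose
    cols = (
        vol[s0, :, f0] * ((1 - ds) * (1 - df))[:, None]
        + vol[s1, :, f0] * (ds * (1 - df))[:, None]
        + vol[s0, :, f1] * ((1 - ds) * df)[:, None]
        + vol[s1, :, f1] * (ds * df)[:, None]
    )
    return RidgeStrip(
        pixels=cols.T.astype(np.float32),
        sample_positions=pts,
        arc_spacing_px=spacing_px,
        axial_pixel_um=volume.axial_pixel_um,
    )


def save_trace(trace: RidgeTrace, path: str | Path) -> None:
    """Write a trace as CSV with header ``slow,fast``, full float precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["slow", "fast"])
        for slow, fast in trace.points:
            writer.writerow([repr(float(slow)), repr(float(fast))])


def load_trace(
    path: str | Path,
    enface_shape: tuple[int, int] | None = None,
    source: str = "manual",
) -> RidgeTrace:
    """Read a ``slow,fast`` CSV trace; a header row is tolerated.

    If ``enface_shape`` is given, points are bounds-checked against it.
    """
    path = Path(path)
    rows: list[tuple[float, float]] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or all(not c.strip() for c in row):
                continue
            if lineno == 1 and any(not _is_number(c) for c in row[:2]):
                continue  # header
            if len(row) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns (slow, fast)")
            try:
                rows.append((float(row[0]), float(row[1])))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric cell in trace CSV") from exc
    if len(rows) < 2:
        raise ValueError(f"{path}: a trace needs at least 2 points; found {len(rows)}")
    trace = RidgeTrace(points=np.asarray(rows, dtype=np.float64), source=source)
    if enface_shape is not None:
        trace.check_bounds(enface_shape)
    return trace


def _is_number(cell: str) -> bool:
    try:
        float(cell)
        return True
    except ValueError:
        return False
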