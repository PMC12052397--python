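"""PT3 32-bit TTTR event records, scan markers, and FLIM image assembly.

Each event is one little-endian 32-bit word:

====== ======= ==========================================================
bits   field   meaning
====== ======= ==========================================================
31:28  channel 1-4 photon route; 15 = special (marker / nsync overflow)
27:16  dtime   relative time in TDC units (12 bits, 0-4095)
15:0   nsync   laser-cycle counter (wraps at 65536)
====== ======= ==========================================================

For special records (channel 15), ``dtime == 0`` marks an nsync-counter
overflow (+65536 cycles) and a non-zero low nibble of ``dtime`` carries scan
marker bits (bit0 = frame, bit1 = line start, bit2 = line stop, bit3 = pixel
clock).  This is a headerless record stream; acquisition metadata travels in
a JSON sidecar rather than a vendor binary header.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .sim_core import EventStream, LaserConfig

__all__ = [
    "MarkerEvent",
    "ScanConfig",
    "FLIMImage",
    "TDC_RESOLUTION",
    "encode_pt3",
    "decode_pt3",
    "write_pt3",
    "read_pt3",
    "assemble_flim_image",
]

#: Default TDC bin width, ns (3.26 ps).
TDC_RESOLUTION = 0.00326

NSYNC_WRAP = 65536
MAX_DTIME = 4096
SPECIAL_CHANNEL = 15
OVERFLOW_WORD = np.uint32(SPECIAL_CHANNEL << 28)

MARKER_BITS = {"frame": 1, "line_start": 2, "line_stop": 4, "pixel": 8}
BIT_MARKERS = {v: k for k, v in MARKER_BITS.items()}


@dataclass(frozen=True)
class MarkerEvent:
    """Microscope synchronization event at an absolute time (ns)."""

    kind: str
    time: float

    def __post_init__(self) -> None:
        if self.kind not in MARKER_BITS:
            raise ValueError(f"unknown marker kind {self.kind!r}")


@dataclass(frozen=True)
class ScanConfig:
    """Raster scan geometry for FLIM image assembly."""

    pixels_x: int
    pixels_y: int
    pixel_dwell: float | None = None  # microseconds, metadata only
    frame_rate: float | None = None  # Hz, metadata only

    def __post_init__(self) -> None:
        if self.pixels_x < 1 or self.pixels_y < 1:
            raise ValueError("scan dimensions must be positive")


@dataclass
class FLIMImage:
    """Per-pixel decay histograms plus the intensity (photon-count) image.

    ``decays`` has shape (pixels_y, pixels_x, n_bins); ``intensity`` is its
    per-pixel sum.  Photons that could not be assigned to any pixel window
    (before the first frame marker, or between a frame marker and its first
    pixel clock) are counted in ``n_discarded`` so photons are conserved:
    photons in == intensity.sum() + n_discarded.
    """

    decays: np.ndarray
    intensity: np.ndarray
    n_discarded: int
    n_frames: int
    bin_width: float
    scan: ScanConfig | None = None


# ---------------------------------------------------------------------------
# PT3 codec
# ---------------------------------------------------------------------------


def _marker_records(markers, laser: LaserConfig):
    """(cycle, marker_bits, time) arrays for the marker list."""
    if not markers:
        return (np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0))
    times = np.array([m.time for m in markers], dtype=np.float64)
    if np.any(np.diff(times) < 0):
        raise ValueError("marker times must be non-decreasing")
    bits = np.array([MARKER_BITS[m.kind] for m in markers], dtype=np.int64)
    # tolerate 1-ulp float error for markers lying exactly on a cycle boundary
    cycles = np.floor(times / laser.period + 1e-9).astype(np.int64)
    return cycles, bits, times


def encode_pt3(stream: EventStream, tdc_resolution: float = TDC_RESOLUTION) -> bytes:
    """Serialize an event stream to PT3 bytes.

    Photons and markers are interleaved by absolute time; a marker coinciding
    exactly with a photon is encoded first (markers gate pixel assignment, so
    the ordering must be deterministic).  Overflow specials are inserted
    whenever the cycle counter advances past another multiple of 65536.
    """
    laser = stream.laser
    if not stream.is_sorted():
        raise ValueError("stream must be sorted before encoding")
    # the epsilon keeps an exact multiple of the resolution (e.g. a decoded
    # record) from flooring down one unit through float roundoff
    dtime = np.floor(stream.rel_time / tdc_resolution + 1e-9).astype(np.int64)
    bad = np.nonzero(dtime >= MAX_DTIME)[0]
    if len(bad):
        i = int(bad[0])
        raise ValueError(
            f"event {i} (cycle {int(stream.cycle[i])}, rel_time "
            f"{stream.rel_time[i]:.4f} ns) exceeds the 4096-unit dtime range "
            f"at {tdc_resolution * 1e3:.3f} ps resolution"
        )
    if np.any((stream.channel < 1) | (stream.channel > 4)):
        raise ValueError("photon channels must be in 1..4")

    ph_cycle = stream.cycle.astype(np.int64)
    ph_time = stream.abs_time
    mk_cycle, mk_bits, mk_time = _marker_records(stream.markers, laser)

    # merge photons and markers; markers first on exact ties
    n_ph, n_mk = len(ph_cycle), len(mk_cycle)
    all_time = np.concatenate([mk_time, ph_time])
    tie_rank = np.concatenate([np.zeros(n_mk), np.ones(n_ph)])
    order = np.lexsort((tie_rank, all_time))
    cycles = np.concatenate([mk_cycle, ph_cycle])[order]
    dt_field = np.concatenate([mk_bits, dtime])[order]
    chans = np.concatenate(
        [np.full(n_mk, SPECIAL_CHANNEL, np.int64), stream.channel.astype(np.int64)]
    )[order]
    if np.any(np.diff(cycles) < 0):
        raise ValueError("marker/photon cycle indices are not jointly sorted")

    words = (
        (chans.astype(np.uint32) << 28)
        | (dt_field.astype(np.uint32) << 16)
        | (cycles % NSYNC_WRAP).astype(np.uint32)
    )
    ovf = cycles // NSYNC_WRAP
    n_pre = np.diff(np.concatenate([[0], ovf]))  # overflow records before each event
    if len(words) == 0:
        return b""
    total = len(words) + int(ovf[-1])
    out = np.full(total, OVERFLOW_WORD, dtype=np.uint32)
    pos = np.arange(len(words)) + np.cumsum(n_pre)
    out[pos] = words
    return out.astype("<u4").tobytes()


def decode_pt3(
    data: bytes,
    tdc_resolution: float = TDC_RESOLUTION,
    laser: LaserConfig | None = None,
) -> EventStream:
    """Parse PT3 bytes back into an event stream.

    Overflow specials are consumed to reconstruct absolute cycle indices.
    Unknown special codes are skipped with a warning and counted on the
    returned stream as ``stream.n_skipped``.
    """
    laser = laser or LaserConfig()
    if len(data) % 4 != 0:
        raise ValueError(
            f"truncated PT3 record at byte offset {len(data) - len(data) % 4}"
        )
    words = np.frombuffer(data, dtype="<u4")
    chan = (words >> 28).astype(np.int64)
    dtime = ((words >> 16) & 0xFFF).astype(np.int64)
    nsync = (words & 0xFFFF).astype(np.int64)

    special = chan == SPECIAL_CHANNEL
    overflow = special & (dtime == 0)
    is_marker = special & ((dtime & 0xF) != 0)
    photon = (chan >= 1) & (chan <= 4)
    unknown = ~(overflow | is_marker | photon)
    n_skipped = int(unknown.sum())
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} unknown PT3 record(s)", stacklevel=2)

    base = NSYNC_WRAP * (np.cumsum(overflow.astype(np.int64)) - overflow)
    cycles = nsync + base

    markers = []
    for c, bits in zip(cycles[is_marker], dtime[is_marker]):
        for bit, kind in BIT_MARKERS.items():
            if bits & bit:
                markers.append(MarkerEvent(kind, float(c * laser.period)))

    stream = EventStream(
        cycles[photon],
        dtime[photon] * tdc_resolution,
        laser,
        chan[photon].astype(np.int16),
        markers,
    )
    stream.n_skipped = n_skipped
    return stream


def write_pt3(
    stream: EventStream,
    path: str | Path,
    tdc_resolution: float = TDC_RESOLUTION,
    sidecar: dict | None = None,
) -> None:
    """Write a .pt3 record file plus a .json metadata sidecar."""
    path = Path(path)
    path.write_bytes(encode_pt3(stream, tdc_resolution))
    meta = {
        "format": "pt3-records",
        "tdc_resolution_ns": tdc_resolution,
        "rep_rate_hz": stream.laser.rep_rate,
        "n_photons": len(stream),
        "n_markers": len(stream.markers),
    }
    if sidecar:
        meta.update(sidecar)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_pt3(path: str | Path, header_bytes: int = 0) -> EventStream:
    """Read a .pt3 record file, using the .json sidecar when present.

    ``header_bytes`` skips a fixed-length foreign header prepended by other
    acquisition software.
    """
    path = Path(path)
    data = path.read_bytes()[header_bytes:]
    tdc = TDC_RESOLUTION
    laser = LaserConfig()
    side = path.with_suffix(".json")
    if side.exists():
        meta = json.loads(side.read_text())
        tdc = meta.get("tdc_resolution_ns", tdc)
        if "rep_rate_hz" in meta:
            laser = LaserConfig(rep_rate=meta["rep_rate_hz"])
    return decode_pt3(data, tdc, laser)


# ---------------------------------------------------------------------------
# FLIM image assembly
# ---------------------------------------------------------------------------


def assemble_flim_image(
    stream: EventStream, scan: ScanConfig, n_bins: int = 256
) -> FLIMImage:
    """Bin photons into per-pixel decay histograms using the scan markers.

    Pixel windows are half-open ``[pixel clock, next boundary)``: a photon
    exactly on a pixel-clock edge belongs to the *later* pixel.  Each frame
    must contain exactly ``pixels_x * pixels_y`` pixel clocks; photons before
    the first frame marker, or inside a frame but ahead of its first pixel
    clock, are discarded and tallied.  Frames accumulate into one image.
    """
    period = stream.laser.period
    frame_t = np.array(
        [m.time for m in stream.markers if m.kind == "frame"], dtype=np.float64
    )
    pixel_t = np.array(
        [m.time for m in stream.markers if m.kind == "pixel"], dtype=np.float64
    )
    if len(frame_t) == 0:
        raise ValueError("no frame markers in stream")
    n_pix = scan.pixels_x * scan.pixels_y
    # pixel clocks per frame
    frame_of_pixel = np.searchsorted(frame_t, pixel_t, side="right") - 1
    if np.any(frame_of_pixel < 0):
        raise ValueError("pixel clock before the first frame marker")
    counts = np.bincount(frame_of_pixel, minlength=len(frame_t))
    for f, c in enumerate(counts):
        if c != n_pix:
            raise ValueError(
                f"frame {f}: expected {n_pix} pixel clocks "
                f"({scan.pixels_x}x{scan.pixels_y}), found {int(c)}"
            )
    n_frames = len(frame_t)

    t = stream.abs_time
    rel = stream.rel_time
    # pixel index within the full pixel-clock sequence
    idx = np.searchsorted(pixel_t, t, side="right") - 1
    frame_of_photon = np.searchsorted(frame_t, t, side="right") - 1
    assigned = (idx >= 0) & (frame_of_photon >= 0)
    # photon must land in a pixel window of its own frame, not a stale one
    assigned &= np.where(assigned, frame_of_pixel[np.clip(idx, 0, None)], -1) == frame_of_photon
    n_discarded = int((~assigned).sum())

    flat_pixel = idx[assigned] % n_pix  # row-major pixel order within frame
    bin_width = period / n_bins
    bins = np.minimum((rel[assigned] / bin_width).astype(np.int64), n_bins - 1)

    decays = np.zeros((n_pix, n_bins), dtype=np.uint32)
    np.add.at(decays, (flat_pixel, bins), 1)
    decays = decays.reshape(scan.pixels_y, scan.pixels_x, n_bins)
    intensity = decays.sum(axis=2).astype(np.int64)
    return FLIMImage(decays, intensity, n_discarded, n_frames, bin_width, scan)


def save_flim_h5(image: FLIMImage, path: str | Path) -> None:
    """Save decays + intensity + assembly metadata to an HDF5 container."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("decays", data=image.decays, compression="gzip")
        f.create_dataset("intensity", data=image.intensity)
        f.attrs["n_discarded"] = image.n_discarded
        f.attrs["n_frames"] = image.n_frames
        f.attrs["bin_width_ns"] = image.bin_width
        if image.scan is not None:
            f.attrs["pixels_x"] = image.scan.pixels_x
            f.attrs["pixels_y"] = image.scan.pixels_y


def save_intensity_tiff(image: FLIMImage, path: str | Path) -> None:
    """Save the intensity image as a 16-bit TIFF raster."""
    import tifffile

    tifffile.imwrite(
        str(path), np.clip(image.intensity, 0, 65535).astype(np.uint16)
    )
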