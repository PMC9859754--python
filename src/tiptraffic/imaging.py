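"""Microscopy-side analysis: comet intensity profiles, condensates, trace velocities.

Mirrors the quantitative steps of a TIRF plus-end-tracking study: rolling-ball
background subtraction, length-binning and integer-pixel alignment of
per-microtubule intensity profiles, averaged comet profiles and
high/low-condition intensity ratios, threshold segmentation of condensates
with per-channel mean intensities (scaffold/tag vs recruited client), and
median velocity statistics of linear particle traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label, regionprops
from skimage.restoration import rolling_ball

__all__ = [
    "IntensityProfile",
    "ProfileSet",
    "CondensateRecord",
    "TraceSet",
    "subtract_background",
    "bin_and_align",
    "average_profiles",
    "condition_ratio",
    "detect_condensates",
    "client_recruitment",
    "trace_velocities",
]


@dataclass
class IntensityProfile:
    """Per-pixel intensity along one microtubule, seed at index 0, tip at the end."""

    values: np.ndarray
    pixel_size_um: float
    condition: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("profile must be a non-empty 1-D array")
        if np.any(self.values < 0):
            raise ValueError("intensities must be non-negative")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be > 0")

    @property
    def length_um(self) -> float:
        return self.values.size * self.pixel_size_um

    def region_mean(self, region_um: tuple[float, float]) -> float:
        """Mean intensity over a distance-from-tip window [start, stop) in µm."""
        start, stop = region_um
        if stop <= start:
            raise ValueError("empty region")
        dist = (self.values.size - 1 - np.arange(self.values.size)) * self.pixel_size_um
        mask = (dist >= start) & (dist < stop)
        if not mask.any():
            raise ValueError(f"region {region_um} µm selects no pixels")
        return float(self.values[mask].mean())


@dataclass
class ProfileSet:
    """Length-binned profiles with per-profile integer alignment offsets."""

    profiles: list[IntensityProfile]
    bin_index: np.ndarray        # bin id per profile
    bin_centers_um: np.ndarray   # µm, one per bin id
    offsets_px: np.ndarray       # alignment shift applied to each profile
    reference: np.ndarray        # index of the reference profile per bin id
    bin_halfwidth_um: float

    def members(self, b: int) -> list[int]:
        return [int(i) for i in np.flatnonzero(self.bin_index == b)]

    @property
    def n_bins(self) -> int:
        return int(self.bin_centers_um.size)


@dataclass
class CondensateRecord:
    """One segmented condensate: position, second-moment ellipse axes, intensities."""

    centroid: tuple[float, float]          # (row, col), px
    major_axis_px: float
    minor_axis_px: float
    mean_tag: float
    mean_client: float | None = None
    coords: np.ndarray = field(default=None, repr=False)  # (n, 2) pixel indices
    image_shape: tuple[int, int] = None


@dataclass
class TraceSet:
    """Particle traces, each an (n, 2) array of (time s, position µm)."""

    traces: list[np.ndarray]

    def __post_init__(self) -> None:
        checked = []
        for k, tr in enumerate(self.traces):
            tr = np.asarray(tr, dtype=float)
            if tr.ndim != 2 or tr.shape[1] != 2 or tr.shape[0] < 2:
                raise ValueError(f"trace {k} must be an (n>=2, 2) array")
            if np.any(np.diff(tr[:, 0]) <= 0):
                raise ValueError(f"trace {k}: times must be strictly increasing")
            checked.append(tr)
        self.traces = checked


def subtract_background(image: np.ndarray, radius_px: float = 50) -> np.ndarray:
    """Rolling-ball background subtraction, clipped at zero.

    The classical algorithm: a ball of the given radius rolled under the
    intensity surface defines the background.  Shift-invariant: adding a
    constant offset to the image does not change the result.
    """
    image = np.asarray(image, dtype=float)
    if radius_px <= 0:
        raise ValueError("radius must be > 0")
    if radius_px >= min(image.shape):
        raise ValueError(
            f"rolling-ball radius {radius_px} px does not fit image {image.shape}")
    background = rolling_ball(image, radius=radius_px)
    return np.clip(image - background, 0.0, None)


def _best_shift(reference: np.ndarray, other: np.ndarray, max_shift: int) -> int:
    """Integer shift of ``other`` minimizing the s.d. of its pointwise
    difference to ``reference`` over the overlapping support."""
    best = 0
    best_sd = np.inf
    # smallest |shift| wins ties (degenerate, e.g. flat, profiles)
    for shift in sorted(range(-max_shift, max_shift + 1), key=abs):
        lo = max(0, shift)
        hi = min(reference.size, other.size + shift)
        if hi - lo < 2:
            continue
        diff = reference[lo:hi] - other[lo - shift:hi - shift]
        sd = float(np.std(diff))
        if sd < best_sd - 1e-12:
            best_sd = sd
            best = shift
    return best


def bin_and_align(
    profiles: list[IntensityProfile],
    bin_halfwidth_um: float = 0.64,
    max_shift_px: int = 20,
    seed: int = 0,
) -> ProfileSet:
    """Group profiles into microtubule-length bins and align each bin.

    Bins are a fixed grid of width ``2 * bin_halfwidth_um`` starting at the
    shortest profile, so every member lies within ±halfwidth of its bin
    centre.  Within a bin one profile is drawn (seeded) as the reference and
    every other profile is shifted by the integer pixel offset that minimizes
    the standard deviation of the pointwise difference to it.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    lengths = np.array([p.length_um for p in profiles])
    binw = 2.0 * bin_halfwidth_um
    bin_ids_raw = np.floor((lengths - lengths.min()) / binw).astype(int)
    uniq = np.unique(bin_ids_raw)
    remap = {int(b): k for k, b in enumerate(uniq)}
    bin_index = np.array([remap[int(b)] for b in bin_ids_raw])
    centers = lengths.min() + (uniq + 0.5) * binw

    rng = np.random.default_rng(seed)
    offsets = np.zeros(len(profiles), dtype=int)
    reference = np.zeros(len(uniq), dtype=int)
    for b in range(len(uniq)):
        members = np.flatnonzero(bin_index == b)
        ref = int(rng.choice(members))
        reference[b] = ref
        for i in members:
            if i == ref:
                continue
            offsets[i] = _best_shift(profiles[ref].values, profiles[i].values,
                                     max_shift_px)
    return ProfileSet(
        profiles=list(profiles),
        bin_index=bin_index,
        bin_centers_um=centers,
        offsets_px=offsets,
        reference=reference,
        bin_halfwidth_um=bin_halfwidth_um,
    )


def average_profiles(pset: ProfileSet) -> dict[int, IntensityProfile]:
    """Pointwise mean per bin over the common support after alignment."""
    out: dict[int, IntensityProfile] = {}
    for b in range(pset.n_bins):
        members = pset.members(b)
        if not members:
            raise ValueError(f"bin {b} is empty")
        # position j on the reference axis receives profile i's pixel j - offset_i
        los, his = [], []
        for i in members:
            off = int(pset.offsets_px[i])
            los.append(off)
            his.append(off + pset.profiles[i].values.size)
        lo, hi = max(0, max(los)), min(his)
        if hi <= lo:
            raise ValueError(f"bin {b}: no common support after alignment")
        acc = np.zeros(hi - lo)
        for i in members:
            off = int(pset.offsets_px[i])
            acc += pset.profiles[i].values[lo - off:hi - off]
        out[b] = IntensityProfile(
            values=acc / len(members),
            pixel_size_um=pset.profiles[members[0]].pixel_size_um,
            condition=pset.profiles[members[0]].condition,
        )
    return out


def condition_ratio(
    high_profiles: list[IntensityProfile],
    low_profiles: list[IntensityProfile],
    region_um: tuple[float, float],
) -> np.ndarray:
    """Each high-condition region mean divided by the low-condition average.

    ``region_um`` is a distance-from-tip window.  Mirrors the
    high-vs-low-motor-concentration intensity ratio construction: individual
    intensities in the high condition are normalized by the across-profile
    mean of the low condition over the same region.
    """
    if not low_profiles:
        raise ValueError("low condition is empty")
    low_mean = float(np.mean([p.region_mean(region_um) for p in low_profiles]))
    if low_mean <= 0:
        raise ZeroDivisionError("low-condition mean is zero over the region")
    return np.array([p.region_mean(region_um) / low_mean for p in high_profiles])


def detect_condensates(
    tag_image: np.ndarray,
    threshold: float = 0.05,
    min_area_px: int = 2,
) -> list[CondensateRecord]:
    """Threshold the (normalized, background-subtracted) tag channel and
    measure connected components.

    The image is expected on a [0, 1] scale; pixels above ``threshold`` form
    the mask.  Per component: centroid, second-moment ellipse axes and mean
    tag intensity.  Components touching the border are kept; degenerate
    components (fewer than ``min_area_px`` pixels or zero minor axis) are
    dropped.
    """
    img = np.asarray(tag_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("tag image must be 2-D")
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    mask = img > threshold
    records: list[CondensateRecord] = []
    for rp in regionprops(label(mask), intensity_image=img):
        if rp.num_pixels < min_area_px or rp.axis_minor_length <= 0:
            continue
        records.append(CondensateRecord(
            centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
            major_axis_px=float(rp.axis_major_length),
            minor_axis_px=float(rp.axis_minor_length),
            mean_tag=float(rp.intensity_mean),
            coords=rp.coords.copy(),
            image_shape=img.shape,
        ))
    return records


def client_recruitment(records: list[CondensateRecord],
                       client_image: np.ndarray) -> np.ndarray:
    """Mean client intensity within each condensate mask (also stored on the
    records)."""
    client = np.asarray(client_image, dtype=float)
    means = np.empty(len(records))
    for k, rec in enumerate(records):
        if rec.image_shape is not None and client.shape != tuple(rec.image_shape):
            raise ValueError(
                f"client image shape {client.shape} != tag image shape "
                f"{tuple(rec.image_shape)}")
        vals = client[rec.coords[:, 0], rec.coords[:, 1]]
        rec.mean_client = float(vals.mean())
        means[k] = rec.mean_client
    return means


def trace_velocities(traces: TraceSet | list[np.ndarray]) -> tuple[float, float]:
    """Median velocity and s.d./sqrt(N) over per-trace least-squares slopes.

    Each trace's velocity is the slope of the least-squares line of position
    vs time over the whole trace (µm/s); minus-end-directed traces simply
    have negative slope.
    """
    if not isinstance(traces, TraceSet):
        traces = TraceSet(list(traces))
    v = np.empty(len(traces.traces))
    for k, tr in enumerate(traces.traces):
        t, x = tr[:, 0], tr[:, 1]
        if t[-1] - t[0] <= 0:
            raise ValueError(f"trace {k} has zero time span")
        v[k] = np.polyfit(t, x, 1)[0]
    median = float(np.median(v))
    sem = float(np.std(v, ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
    return median, sem
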