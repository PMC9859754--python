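"""Synthetic microscopy data with full ground truth.

Every input the analysis stages consume can be generated here: kymographs
rendered from simulation snapshots or from a parametric comet profile,
two-channel (tag + client) condensate images, and linear particle traces.
Each generator is deterministic in (parameters, seed) and returns the
generating parameters alongside the data, so analysis round-trips can be
tested against known truth.

Default imaging constants (0.107 µm pixels, 1 s frames, 0.3 µm PSF FWHM) are
typical TIRF values and are all configurable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .engine import SnapshotSeries
from .imaging import IntensityProfile, TraceSet

__all__ = [
    "RenderConfig",
    "GroundTruth",
    "render_kymograph",
    "parametric_comet_profile",
    "synth_condensate_image",
    "synth_traces",
    "lognormal_velocities",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class RenderConfig:
    """Imaging model: geometry, point-spread function, counts and noise."""

    pixel_size_um: float = 0.107
    frame_interval_s: float = 1.0
    psf_fwhm_um: float = 0.3
    intensity_per_particle: float = 100.0
    background: float = 10.0
    noise: str = "none"            # one of none | poisson | gaussian
    noise_sigma: float = 0.0       # counts, gaussian only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("pixel size and frame interval must be > 0")
        if self.psf_fwhm_um < 0:
            raise ValueError("PSF FWHM must be >= 0")
        if self.noise not in ("none", "poisson", "gaussian"):
            raise ValueError(f"unknown noise model {self.noise!r}")

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_fwhm_um * _FWHM_TO_SIGMA / self.pixel_size_um


@dataclass
class GroundTruth:
    """Generating parameters of a synthetic dataset; serializable to JSON."""

    kind: str
    params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def _default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            raise TypeError(f"not serializable: {type(o)}")
        return json.dumps({"kind": self.kind, "params": self.params},
                          default=_default, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(kind=d["kind"], params=d["params"])

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def _apply_noise(image: np.ndarray, cfg: RenderConfig,
                 rng: np.random.Generator) -> np.ndarray:
    if cfg.noise == "poisson":
        return rng.poisson(np.clip(image, 0, None)).astype(float)
    if cfg.noise == "gaussian":
        return image + rng.normal(0.0, cfg.noise_sigma, image.shape)
    return image


def render_kymograph(
    source: SnapshotSeries | IntensityProfile,
    cfg: RenderConfig,
    n_frames: int | None = None,
    a_nm: float = 8.4,
) -> tuple[np.ndarray, GroundTruth]:
    """Render a space-time image; returns (kymograph, ground truth).

    From a :class:`SnapshotSeries`, two channels are rendered — channel 0 is
    motor counts, channel 1 total cargo stack height per site (so multi-layer
    cargo is brighter, mirroring a cargo-channel readout that does not
    saturate at one per motor).  From an :class:`IntensityProfile` (parametric
    comet), a single-channel static scene of ``n_frames`` rows is rendered.
    Each particle contributes a Gaussian PSF; background and noise follow
    ``cfg``.  Output shape: (channels, frames, pixels).
    """
    rng = np.random.default_rng(cfg.seed)
    if isinstance(source, SnapshotSeries):
        site_um = (a_nm if source.params is None else source.params.a) / 1000.0
        n = source.n_snapshots
        width_sites = int((source.origins + source.lengths).max())
        width_px = int(np.ceil(width_sites * site_um / cfg.pixel_size_um)) + 1
        kymo = np.zeros((2, n, width_px))
        for k in range(n):
            L = int(source.lengths[k])
            o = int(source.origins[k])
            px = ((np.arange(L) + o) * site_um / cfg.pixel_size_um).astype(int)
            np.add.at(kymo[0, k], px, source.motor[k, :L].astype(float))
            np.add.at(kymo[1, k], px, source.cargo[k, :L].astype(float))
        truth = GroundTruth("kymograph_from_series", {
            "n_frames": n, "width_px": width_px, "site_um": site_um,
            "render": asdict(cfg)})
    else:
        if n_frames is None:
            n_frames = 1
        scale = source.pixel_size_um / cfg.pixel_size_um
        width_px = int(np.ceil(source.values.size * scale))
        x_px = (np.arange(source.values.size) * scale).astype(int)
        row = np.zeros(width_px)
        np.add.at(row, x_px, source.values / cfg.intensity_per_particle)
        kymo = np.tile(row, (1, n_frames, 1))
        truth = GroundTruth("kymograph_from_profile", {
            "n_frames": n_frames, "width_px": width_px, "render": asdict(cfg)})
    sigma = cfg.psf_sigma_px
    if sigma > 0:
        kymo = gaussian_filter1d(kymo, sigma, axis=-1)
    kymo = kymo * cfg.intensity_per_particle + cfg.background
    kymo = _apply_noise(kymo, cfg, rng)
    return kymo, truth


def parametric_comet_profile(
    length_um: float,
    lattice_level: float = 100.0,
    end_amplitude: float = 300.0,
    end_decay_um: float = 0.35,
    seed_rise_um: float = 1.0,
    pixel_size_um: float = 0.107,
    condition: str = "",
) -> tuple[IntensityProfile, GroundTruth]:
    """Idealized comet: smooth rise at the seed, flat lattice, exponential end peak.

    The profile runs from the microtubule seed (index 0) to the plus-end
    (last pixel); the value at the tip is ``lattice_level + end_amplitude``.
    """
    if min(length_um, lattice_level, end_amplitude, end_decay_um,
           seed_rise_um) < 0 or length_um <= 0:
        raise ValueError("all comet parameters must be positive")
    if length_um <= seed_rise_um:
        raise ValueError(
            f"length ({length_um} µm) must exceed the seed rise region "
            f"({seed_rise_um} µm)")
    n_px = int(round(length_um / pixel_size_um))
    x = np.arange(n_px) * pixel_size_um
    tip = x[-1]
    u = np.clip(x / seed_rise_um, 0.0, 1.0)
    rise = lattice_level * u * u * (3.0 - 2.0 * u)       # smoothstep
    peak = end_amplitude * np.exp(-(tip - x) / end_decay_um)
    values = rise + peak
    profile = IntensityProfile(values=values, pixel_size_um=pixel_size_um,
                               condition=condition)
    truth = GroundTruth("parametric_comet", {
        "length_um": length_um, "lattice_level": lattice_level,
        "end_amplitude": end_amplitude, "end_decay_um": end_decay_um,
        "seed_rise_um": seed_rise_um, "pixel_size_um": pixel_size_um})
    return profile, truth


def synth_condensate_image(
    n: int,
    radii_px: np.ndarray | list[float],
    tag_intensities: np.ndarray | list[float],
    recruitment_factor: float,
    cfg: RenderConfig,
    shape: tuple[int, int] = (256, 256),
    max_attempts: int = 10_000,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Non-overlapping disks in a tag channel plus a correlated client channel.

    The client channel is ``recruitment_factor`` × the tag signal inside
    condensates (zero outside), both blurred by the PSF with background and
    noise added.  Placement is rejection sampling; raises if ``n``
    non-overlapping disks cannot be placed in ``max_attempts`` draws.
    """
    rng = np.random.default_rng(cfg.seed)
    radii = np.broadcast_to(np.asarray(radii_px, dtype=float), (n,)).copy()
    intens = np.broadcast_to(np.asarray(tag_intensities, dtype=float), (n,)).copy()
    if recruitment_factor < 0:
        raise ValueError("recruitment factor must be >= 0")
    centers = np.zeros((n, 2))
    placed = 0
    attempts = 0
    margin = 4.0
    while placed < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could only place {placed}/{n} non-overlapping condensates "
                f"in {max_attempts} attempts")
        attempts += 1
        r = radii[placed]
        c = rng.uniform([r + margin, r + margin],
                        [shape[0] - r - margin, shape[1] - r - margin])
        ok = True
        for j in range(placed):
            if np.hypot(*(c - centers[j])) < r + radii[j] + 2.0:
                ok = False
                break
        if ok:
            centers[placed] = c
            placed += 1

    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    tag = np.zeros(shape)
    for k in range(n):
        mask = (yy - centers[k, 0]) ** 2 + (xx - centers[k, 1]) ** 2 <= radii[k] ** 2
        tag[mask] = intens[k]
    client = recruitment_factor * tag
    sigma = cfg.psf_sigma_px
    if sigma > 0:
        tag = gaussian_filter(tag, sigma)
        client = gaussian_filter(client, sigma)
    tag = _apply_noise(tag + cfg.background, cfg, rng)
    client = _apply_noise(client + cfg.background, cfg, rng)
    truth = GroundTruth("condensates", {
        "n": n, "centers": centers, "radii_px": radii,
        "tag_intensities": intens, "recruitment_factor": recruitment_factor,
        "shape": list(shape), "render": asdict(cfg)})
    return tag, client, truth


def lognormal_velocities(median_um_s: float = 0.23, sigma_log: float = 1.1):
    """Heavy-tailed velocity law with the given median (µm/s).

    A log-normal with this spread reproduces the situation where the s.d.
    across traces is a few-fold larger than the median, as seen for
    plus-end-directed cargo traces.
    """
    def draw(rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.lognormal(np.log(median_um_s), sigma_log, size)
    draw.median = median_um_s
    return draw


def synth_traces(
    n: int,
    velocity_distribution=None,
    noise_sd_um: float = 0.02,
    duration_s: float = 30.0,
    dt_s: float = 1.0,
    seed: int = 0,
) -> tuple[TraceSet, GroundTruth]:
    """Linear traces with velocities drawn from the given law plus positional noise.

    ``velocity_distribution`` is a callable ``(rng, size) -> velocities``
    (see :func:`lognormal_velocities`, the default), a scalar constant
    velocity, or anything with an ``rvs(size, random_state)`` method (frozen
    scipy distribution).  Negative velocities (minus-end-directed) are valid.
    """
    if n < 1:
        raise ValueError("need n >= 1 traces")
    rng = np.random.default_rng(seed)
    vd = velocity_distribution
    if vd is None:
        vd = lognormal_velocities()
    if np.isscalar(vd):
        v0 = float(vd)
        velocities = np.full(n, v0)
    elif hasattr(vd, "rvs"):
        velocities = np.asarray(vd.rvs(size=n, random_state=rng), dtype=float)
    else:
        velocities = np.asarray(vd(rng, n), dtype=float)
    t = np.arange(0.0, duration_s + 0.5 * dt_s, dt_s)
    traces = []
    for k in range(n):
        x = velocities[k] * t + rng.normal(0.0, noise_sd_um, t.size)
        traces.append(np.column_stack([t, x]))
    truth = GroundTruth("traces", {
        "n": n, "velocities": velocities,
        "median_velocity": float(np.median(velocities)),
        "noise_sd_um": noise_sd_um, "duration_s": duration_s,
        "dt_s": dt_s, "seed": seed})
    return TraceSet(traces), truth
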