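"""Tip-aligned density profiles, region occupations, concentration sweeps and
the non-linearity index.

These are the quantities the simulation is interrogated for: how much motor
and cargo sits in a ~200 nm window behind the growing plus-end versus on the
bulk lattice, how both scale with motor concentration, and whether end
accumulation is super-linear (tip fold-change outrunning lattice fold-change).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from .engine import RunSchedule, SnapshotSeries, run_simulation
from .model import ModelParams

__all__ = [
    "DensityProfile",
    "SweepResult",
    "TIP_WINDOW_SITES",
    "LATTICE_WINDOW_SITES",
    "tip_aligned_profile",
    "region_occupation",
    "concentration_sweep",
    "nonlinearity_index",
]

#: default tip window: ~200 nm at 8.4 nm per site -> round(200/8.4) = 24 sites
TIP_WINDOW_SITES = 24
#: default bulk-lattice window, sites from the tip — far from tip and minus-end
LATTICE_WINDOW_SITES = (300, 600)


@dataclass
class DensityProfile:
    """Mean motor density and cargo occupation vs distance from the plus-end.

    ``distance_sites[0] = 0`` is the tip; the axis increases toward the
    minus-end.  Motor density is in [0, 1]; cargo occupation counts all
    stack layers so it may exceed 1.
    """

    distance_sites: np.ndarray
    distance_nm: np.ndarray
    motor_density: np.ndarray
    cargo_occupation: np.ndarray
    n_snapshots: int

    def __post_init__(self) -> None:
        if np.any(self.motor_density < 0) or np.any(self.motor_density > 1):
            raise ValueError("motor density must lie in [0, 1]")
        if np.any(self.cargo_occupation < 0):
            raise ValueError("cargo occupation must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "distance_sites": self.distance_sites,
            "distance_nm": self.distance_nm,
            "motor_density": self.motor_density,
            "cargo_occupation": self.cargo_occupation,
        })


@dataclass
class SweepResult:
    """Per-concentration tip and lattice occupations (cargo and motor)."""

    concentrations_nM: np.ndarray
    tip_cargo: np.ndarray
    lattice_cargo: np.ndarray
    tip_motor: np.ndarray
    lattice_motor: np.ndarray
    tip_window: int = TIP_WINDOW_SITES
    lattice_window: tuple[int, int] = LATTICE_WINDOW_SITES
    seeds: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations_nM, dtype=float)
        if np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        for name in ("tip_cargo", "lattice_cargo", "tip_motor", "lattice_motor"):
            if np.any(np.asarray(getattr(self, name)) < 0):
                raise ValueError(f"{name} must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "concentration_nM": self.concentrations_nM,
            "tip_cargo": self.tip_cargo,
            "lattice_cargo": self.lattice_cargo,
            "tip_motor": self.tip_motor,
            "lattice_motor": self.lattice_motor,
        })

    def at(self, c_nm: float) -> dict:
        idx = np.flatnonzero(np.isclose(self.concentrations_nM, c_nm))
        if idx.size == 0:
            raise ValueError(f"concentration {c_nm} nM not in sweep")
        k = int(idx[0])
        return {name: float(getattr(self, name)[k])
                for name in ("tip_cargo", "lattice_cargo", "tip_motor", "lattice_motor")}


def tip_aligned_profile(series: SnapshotSeries, window_sites: int) -> DensityProfile:
    """Average the last ``window_sites`` sites of every snapshot, tip-aligned.

    Index 0 of the result is the plus-end-most site of each snapshot.
    """
    if window_sites < 1:
        raise ValueError("window_sites must be >= 1")
    min_len = int(series.lengths.min())
    if window_sites > min_len:
        k = int(np.argmin(series.lengths))
        raise ValueError(
            f"window of {window_sites} sites exceeds snapshot {k} "
            f"(length {min_len} sites at t={series.times[k]:.6g} s)")
    n = series.n_snapshots
    motor = np.zeros(window_sites)
    cargo = np.zeros(window_sites)
    for k in range(n):
        L = int(series.lengths[k])
        sl = slice(L - window_sites, L)
        motor += series.motor[k, sl][::-1]
        cargo += series.cargo[k, sl][::-1]
    motor /= n
    cargo /= n
    dist = np.arange(window_sites)
    return DensityProfile(
        distance_sites=dist,
        distance_nm=dist * series.params.a,
        motor_density=motor,
        cargo_occupation=cargo,
        n_snapshots=n,
    )


def region_occupation(profile: DensityProfile, region: tuple[int, int],
                      quantity: str = "cargo") -> float:
    """Mean cargo occupation (or motor density) per site over ``region``.

    ``region`` is a half-open site interval ``[start, stop)`` on the
    distance-from-tip axis.
    """
    start, stop = region
    if stop <= start:
        raise ValueError("empty region")
    if start < 0 or stop > profile.distance_sites.size:
        raise ValueError(f"region {region} outside profile axis "
                         f"[0, {profile.distance_sites.size})")
    values = (profile.cargo_occupation if quantity == "cargo"
              else profile.motor_density)
    return float(values[start:stop].mean())


def concentration_sweep(
    base_params: ModelParams,
    concentrations: list[float],
    schedule: RunSchedule,
    tip_window: int = TIP_WINDOW_SITES,
    lattice_window: tuple[int, int] = LATTICE_WINDOW_SITES,
) -> SweepResult:
    """One run per motor concentration; seeds are ``base seed + index``.

    Each run is summarized by mean cargo occupation and motor density in the
    tip and bulk-lattice windows.
    """
    concs = [float(c) for c in concentrations]
    if any(c < 0 for c in concs):
        raise ValueError("concentrations must be >= 0")
    rows = {k: [] for k in ("tc", "lc", "tm", "lm")}
    seeds = []
    for i, c in enumerate(concs):
        params = base_params.at_concentration(c).replace(seed=base_params.seed + i)
        seeds.append(params.seed)
        series = run_simulation(params, schedule)
        window = max(tip_window, lattice_window[1])
        profile = tip_aligned_profile(series, window)
        rows["tc"].append(region_occupation(profile, (0, tip_window), "cargo"))
        rows["lc"].append(region_occupation(profile, lattice_window, "cargo"))
        rows["tm"].append(region_occupation(profile, (0, tip_window), "motor"))
        rows["lm"].append(region_occupation(profile, lattice_window, "motor"))
    return SweepResult(
        concentrations_nM=np.array(concs),
        tip_cargo=np.array(rows["tc"]),
        lattice_cargo=np.array(rows["lc"]),
        tip_motor=np.array(rows["tm"]),
        lattice_motor=np.array(rows["lm"]),
        tip_window=tip_window,
        lattice_window=lattice_window,
        seeds=seeds,
    )


def nonlinearity_index(sweep: SweepResult, c_low: float, c_high: float) -> float:
    """(tip cargo fold-change) / (lattice cargo fold-change) from c_low to c_high.

    1 means cargo at the tip merely tracks the lattice (proportional
    recruitment); > 1 means super-linear end accumulation.
    """
    lo = sweep.at(c_low)
    hi = sweep.at(c_high)
    if lo["tip_cargo"] <= 0 or lo["lattice_cargo"] <= 0:
        raise ZeroDivisionError(
            "zero occupation at the low concentration: fold-change undefined")
    if hi["lattice_cargo"] <= 0:
        raise ZeroDivisionError("zero lattice occupation at the high concentration")
    tip_fold = hi["tip_cargo"] / lo["tip_cargo"]
    lattice_fold = hi["lattice_cargo"] / lo["lattice_cargo"]
    return float(tip_fold / lattice_fold)
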