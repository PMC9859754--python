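"""State space, parameters and rate laws of the growing-lattice motor-cargo model.

A growing microtubule is a one-dimensional lattice of tubulin-dimer-sized
sites, indexed 0 (minus-end) to ``length - 1`` (plus-end).  Kinesin-like
motors attach, detach and hop toward the plus-end under mutual exclusion
(TASEP with Langmuir kinetics in the low-density phase).  Each bound motor
can carry a stack of cargo particles: a first cargo binds/unbinds directly to
the motor, further layers adsorb/desorb on top of the stack (LIFO), so cargo
can accumulate beyond one-per-motor.  The lattice grows at the plus-end by
appending fresh GTP-tubulin sites which hydrolyse GTP -> GDP-Pi -> GDP
site-autonomously; motors hop slower on the GTP/GDP-Pi cap, which jams
traffic at the fast->slow transition near the tip.  Two further scenario
switches couple cargo stacks laterally: neighbouring cargo-bearing motors
move as rigid *trains*, and/or are *stabilized* (their detachment slowed by a
factor ``s``) while clustered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields, replace
from typing import Iterator

import numpy as np

__all__ = [
    "GTP",
    "GDP_PI",
    "GDP",
    "NUCLEOTIDE_NAMES",
    "ModelParams",
    "LatticeState",
    "InvalidStateError",
    "propensity_catalogue",
    "identify_trains",
    "stabilized_sites",
    "apply_event",
    "hop_rate_into",
]

# nucleotide encoding used throughout (arrays are uint8)
GTP = 0
GDP_PI = 1
GDP = 2
NUCLEOTIDE_NAMES = {GTP: "GTP", GDP_PI: "GDP_Pi", GDP: "GDP"}

#: attachment rate per empty site per nM of motor concentration, 1/s/nM.
#: Chosen so that 100 nM gives a Langmuir occupancy
#: omega_a/(omega_a+omega_d) = 0.05 with omega_d = 0.25/s (LD phase).
DEFAULT_KAPPA_A = 0.25 * 0.05 / 0.95 / 100.0


class InvalidStateError(ValueError):
    """A lattice state violating a structural invariant."""


@dataclass(frozen=True)
class ModelParams:
    """All kinetic rates, scenario switches and geometry of the lattice model.

    Rates are per second; ``a`` is the site length in nm (one tubulin
    heterodimer).  ``omega_a`` defaults to ``kappa_a * c_motor`` so motor
    concentration sweeps only change ``c_motor``.
    """

    a: float = 8.4                  # site length, nm
    L0: int = 1000                  # initial lattice length, sites
    p: float = 20.0                 # hop rate on GDP sites, 1/s
    p_slow: float = 20.0 / 3.0      # hop rate on GTP and GDP-Pi sites, 1/s
    c_motor: float = 100.0          # motor concentration, nM
    kappa_a: float = DEFAULT_KAPPA_A
    omega_a: float | None = None    # attachment rate per empty site, 1/s
    omega_d: float = 0.25           # detachment rate per bound motor, 1/s
    gamma: float = 3.0              # lattice growth rate, sites/s
    k_h1: float = 0.25              # GTP -> GDP-Pi, 1/s per site
    k_h2: float = 0.25              # GDP-Pi -> GDP, 1/s per site
    k_c_on: float = 2.0             # first-layer cargo binding, 1/s per bare motor
    k_c_off: float = 0.5            # first-layer cargo unbinding, 1/s
    k_m_on: float = 1.0             # extra-layer adsorption on exposed cargo top, 1/s
    k_m_off: float = 0.5            # extra-layer desorption, 1/s
    s: float = 3.0                  # stabilization dwell-time multiplier, >= 1
    enable_cap: bool = False
    enable_trains: bool = False
    enable_stabilization: bool = False
    seed: int = 0
    #: co-moving tip window, sites.  None = lattice grows without bound
    #: (minus-end never shrinks); an integer W keeps at most W sites by
    #: dropping the minus-end-most site (removing any motor on it) whenever
    #: growth would exceed W.  Tip-aligned observables are unaffected because
    #: the bulk lattice is homogeneous.
    window: int | None = None

    def __post_init__(self) -> None:
        rate_names = ("p", "p_slow", "omega_d", "gamma", "k_h1", "k_h2",
                      "k_c_on", "k_c_off", "k_m_on", "k_m_off", "kappa_a")
        for name in rate_names:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"rate {name} must be finite and >= 0, got {v}")
        if self.omega_a is None:
            object.__setattr__(self, "omega_a", self.kappa_a * self.c_motor)
        if not np.isfinite(self.omega_a) or self.omega_a < 0:
            raise ValueError(f"omega_a must be finite and >= 0, got {self.omega_a}")
        if self.a <= 0:
            raise ValueError(f"site length a must be > 0, got {self.a}")
        if self.L0 < 2:
            raise ValueError(f"L0 must be >= 2, got {self.L0}")
        if self.s < 1:
            raise ValueError(f"stabilization factor s must be >= 1, got {self.s}")
        if self.p_slow > self.p:
            raise ValueError(f"p_slow ({self.p_slow}) must be <= p ({self.p})")
        if self.c_motor < 0:
            raise ValueError(f"c_motor must be >= 0, got {self.c_motor}")
        if self.window is not None and self.window < self.L0:
            raise ValueError("window must be >= L0")
        denom = self.omega_a + self.omega_d
        if denom > 0 and self.omega_a / denom >= 0.5:
            warnings.warn(
                "omega_a/(omega_a+omega_d) >= 0.5: outside the low-density "
                "regime the model targets", stacklevel=2)

    def at_concentration(self, c_nm: float) -> "ModelParams":
        """Same model at motor concentration ``c_nm`` (omega_a = kappa_a*c)."""
        return replace(self, c_motor=c_nm, omega_a=self.kappa_a * c_nm)

    def replace(self, **kw) -> "ModelParams":
        if "c_motor" in kw and "omega_a" not in kw:
            kw["omega_a"] = self.kappa_a * kw["c_motor"]
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown ModelParams fields: {sorted(unknown)}")
        return cls(**d)


@dataclass
class LatticeState:
    """Per-site motor occupancy, cargo stack heights and nucleotide states.

    ``motor[i]`` is 0/1, ``cargo[i]`` is the cargo stack height carried by the
    motor at site ``i`` (0 when no motor), ``nucleotide[i]`` is one of
    GTP/GDP_PI/GDP.  ``origin`` counts minus-end sites dropped by a co-moving
    window, so the absolute lattice coordinate of local site ``i`` is
    ``origin + i``.
    """

    motor: np.ndarray
    cargo: np.ndarray
    nucleotide: np.ndarray
    time: float = 0.0
    origin: int = 0

    @property
    def length(self) -> int:
        return self.motor.shape[0]

    @classmethod
    def empty(cls, length: int, nucleotide: int = GDP) -> "LatticeState":
        return cls(
            motor=np.zeros(length, dtype=np.uint8),
            cargo=np.zeros(length, dtype=np.int64),
            nucleotide=np.full(length, nucleotide, dtype=np.uint8),
            time=0.0,
        )

    def copy(self) -> "LatticeState":
        return LatticeState(self.motor.copy(), self.cargo.copy(),
                            self.nucleotide.copy(), self.time, self.origin)

    def validate(self) -> None:
        if not (self.motor.shape == self.cargo.shape == self.nucleotide.shape):
            raise InvalidStateError("motor/cargo/nucleotide arrays differ in length")
        bad = np.flatnonzero((self.motor > 1))
        if bad.size:
            raise InvalidStateError(f"motor occupancy > 1 at site {bad[0]}")
        bad = np.flatnonzero((self.cargo > 0) & (self.motor == 0))
        if bad.size:
            raise InvalidStateError(f"cargo on empty site {bad[0]}")
        if np.any(self.cargo < 0):
            raise InvalidStateError("negative cargo stack height")
        if not np.all(np.isin(self.nucleotide, (GTP, GDP_PI, GDP))):
            raise InvalidStateError("unknown nucleotide state")


def hop_rate_into(dest_nucleotide: int, params: ModelParams) -> float:
    """Hop rate governed by the destination site's nucleotide state.

    With the cap disabled every site is fast.  A motor at the terminal site
    steps off the plus-end at the rate of a (hypothetical) fresh GTP
    destination — the open-boundary convention with no end-specific retention.
    """
    if not params.enable_cap:
        return params.p
    return params.p_slow if dest_nucleotide in (GTP, GDP_PI) else params.p


def identify_trains(state: LatticeState) -> list[tuple[int, ...]]:
    """Maximal runs of adjacent cargo-bearing motors (cargo-free motors break runs)."""
    carrying = (state.motor == 1) & (state.cargo > 0)
    trains: list[tuple[int, ...]] = []
    run: list[int] = []
    for i in range(state.length):
        if carrying[i]:
            run.append(i)
        elif run:
            trains.append(tuple(run))
            run = []
    if run:
        trains.append(tuple(run))
    return trains


def stabilized_sites(state: LatticeState) -> set[int]:
    """Sites with a cargo-bearing motor adjacent to >= 1 other cargo-bearing motor."""
    carrying = (state.motor == 1) & (state.cargo > 0)
    out: set[int] = set()
    L = state.length
    for i in np.flatnonzero(carrying):
        i = int(i)
        if (i > 0 and carrying[i - 1]) or (i + 1 < L and carrying[i + 1]):
            out.add(i)
    return out


def propensity_catalogue(
    state: LatticeState, params: ModelParams
) -> list[tuple[tuple, float]]:
    """Every currently possible event with its strictly positive rate.

    Events are tagged tuples:

    ``("attach", i)``, ``("detach", i)``, ``("hop", i)`` (motor at ``i`` moves
    to ``i+1``, or off the lattice if ``i`` is terminal), ``("train_hop", i)``
    (rigid advance of the train whose leading motor is at ``i``),
    ``("cargo_on", i)``, ``("cargo_off", i)``, ``("layer_on", i)``,
    ``("layer_off", i)``, ``("hyd1", i)``, ``("hyd2", i)``, ``("grow",)``.

    Impossible events are omitted, never listed at rate zero.
    """
    state.validate()
    P = params
    L = state.length
    motor = state.motor
    cargo = state.cargo
    nuc = state.nucleotide
    events: list[tuple[tuple, float]] = []

    stab = stabilized_sites(state) if P.enable_stabilization else set()

    for i in range(L):
        if not motor[i]:
            if P.omega_a > 0:
                events.append((("attach", i), P.omega_a))
            continue
        # detachment (entire stack leaves with the motor)
        rate_d = P.omega_d / P.s if i in stab else P.omega_d
        if rate_d > 0:
            events.append((("detach", i), rate_d))
        # cargo kinetics
        if cargo[i] == 0:
            if P.k_c_on > 0:
                events.append((("cargo_on", i), P.k_c_on))
        else:
            if cargo[i] == 1 and P.k_c_off > 0:
                events.append((("cargo_off", i), P.k_c_off))
            if P.k_m_on > 0:
                events.append((("layer_on", i), P.k_m_on))
            if cargo[i] >= 2 and P.k_m_off > 0:
                events.append((("layer_off", i), P.k_m_off))
        # movement; stepping off the plus-end terminates the dwell, so the
        # stabilization dwell multiplier also divides the terminal walk-off
        # of a clustered motor-cargo (interior hops are never slowed)
        in_train = P.enable_trains and cargo[i] > 0
        if in_train:
            leading = i + 1 >= L or not motor[i + 1] or cargo[i + 1] == 0
            if leading:
                dest_free = i + 1 >= L or not motor[i + 1]
                if dest_free:
                    rate = hop_rate_into(GTP if i + 1 >= L else int(nuc[i + 1]), P)
                    if i + 1 >= L and i in stab:
                        rate /= P.s
                    if rate > 0:
                        events.append((("train_hop", i), rate))
        else:
            dest_free = i + 1 >= L or not motor[i + 1]
            if dest_free:
                rate = hop_rate_into(GTP if i + 1 >= L else int(nuc[i + 1]), P)
                if i + 1 >= L and i in stab:
                    rate /= P.s
                if rate > 0:
                    events.append((("hop", i), rate))

    if P.enable_cap:
        for i in np.flatnonzero(nuc == GTP):
            if P.k_h1 > 0:
                events.append((("hyd1", int(i)), P.k_h1))
        for i in np.flatnonzero(nuc == GDP_PI):
            if P.k_h2 > 0:
                events.append((("hyd2", int(i)), P.k_h2))

    if P.gamma > 0:
        events.append((("grow",), P.gamma))

    return events


def _remove_motor(state: LatticeState, i: int) -> None:
    state.motor[i] = 0
    state.cargo[i] = 0


def _move_motor(state: LatticeState, i: int) -> None:
    """Motor at i advances to i+1, or walks off the plus-end if terminal."""
    if i + 1 < state.length:
        state.motor[i + 1] = 1
        state.cargo[i + 1] = state.cargo[i]
    _remove_motor(state, i)


def apply_event(state: LatticeState, event: tuple, params: ModelParams) -> LatticeState:
    """Execute ``event`` on ``state`` in place and return it."""
    kind = event[0]
    if kind == "attach":
        state.motor[event[1]] = 1
    elif kind == "detach":
        _remove_motor(state, event[1])
    elif kind == "hop":
        _move_motor(state, event[1])
    elif kind == "train_hop":
        lead = event[1]
        tail = lead
        while tail - 1 >= 0 and state.motor[tail - 1] and state.cargo[tail - 1] > 0:
            tail -= 1
        for j in range(lead, tail - 1, -1):
            _move_motor(state, j)
    elif kind == "cargo_on":
        state.cargo[event[1]] = 1
    elif kind == "cargo_off":
        state.cargo[event[1]] = 0
    elif kind == "layer_on":
        state.cargo[event[1]] += 1
    elif kind == "layer_off":
        state.cargo[event[1]] -= 1
    elif kind == "hyd1":
        state.nucleotide[event[1]] = GDP_PI
    elif kind == "hyd2":
        state.nucleotide[event[1]] = GDP
    elif kind == "grow":
        if params.window is not None and state.length >= params.window:
            # co-moving window: drop the minus-end site, append fresh GTP tip
            state.motor[:-1] = state.motor[1:]
            state.cargo[:-1] = state.cargo[1:]
            state.nucleotide[:-1] = state.nucleotide[1:]
            state.motor[-1] = 0
            state.cargo[-1] = 0
            state.nucleotide[-1] = GTP
            state.origin += 1
        else:
            state.motor = np.append(state.motor, np.uint8(0))
            state.cargo = np.append(state.cargo, np.int64(0))
            state.nucleotide = np.append(state.nucleotide, np.uint8(GTP))
    else:
        raise ValueError(f"unknown event {event!r}")
    return state
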