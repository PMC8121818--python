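"""Hypersound velocity-pulse protocol.

A hypersound "shock wave" is a series of additive velocity pulses applied to
the solvent molecules in a 1-nm-deep slab at one face of the periodic box.
Pulses fire every ``N`` MD steps, cosine-modulated so that one acoustic cycle
spans 16 pulses (16·N steps); a wave is five such cycles (80 pulses).  Six
waves are irradiated back to back, one per box face in the order
+X, +Y, +Z, −X, −Y, −Z, followed by a recovery delay ``T_int`` during which
the thermostat removes the injected energy.  With a 2 fs step and N = 50 the
pulse cycle lasts 1.6 ps, i.e. a 625 GHz acoustic frequency.

The pulse speed for step-within-wave ``m`` (a multiple of N) is

    v = ±v_max · cos(2π · m / (16 N))

positive for the low faces (X0, Y0, Z0; waves travelling in +X/+Y/+Z) and
negative for the high faces (X1, Y1, Z1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import TYPE_CHECKING, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .engine import SystemFrame

#: The six box faces. Low faces sit at coordinate 0, high faces at box edge.
FACES = ("X0", "Y0", "Z0", "X1", "Y1", "Z1")

#: Default irradiation order: +X, +Y, +Z, −X, −Y, −Z.
DEFAULT_FACE_ORDER = FACES

_FACE_AXIS = {"X0": 0, "Y0": 1, "Z0": 2, "X1": 0, "Y1": 1, "Z1": 2}
_FACE_HIGH = {"X0": False, "Y0": False, "Z0": False, "X1": True, "Y1": True, "Z1": True}


class ScheduleError(ValueError):
    """Raised for pulse requests inconsistent with the schedule definition."""


def face_axis(face: str) -> int:
    """Cartesian axis index (0/1/2) of a face."""
    try:
        return _FACE_AXIS[face]
    except KeyError:
        raise ScheduleError(f"unknown face {face!r}; expected one of {FACES}") from None


def face_is_high(face: str) -> bool:
    """True for the X1/Y1/Z1 faces at coordinate = box edge."""
    face_axis(face)
    return _FACE_HIGH[face]


@dataclass(frozen=True)
class ShockWaveParams:
    """Parameters of the hypersound forcing protocol.

    Parameters
    ----------
    n_interval
        Pulse interval N in MD steps.
    v_max
        Maximum pulse speed in nm/ps (0.4 nm/ps = 400 m/s).
    t_int
        Recovery delay after the six-wave series, in MD steps
        (the reference protocol uses 2400·N).
    cycles_per_wave, pulses_per_cycle
        One wave = cycles_per_wave × pulses_per_cycle pulses (default 5 × 16
        = 80 pulses over 16·N·5 steps).
    boundary_depth
        Depth of the perturbed solvent slab at each face, nm.
    face_order
        Order in which the six faces are irradiated.
    """

    n_interval: int = 50
    v_max: float = 0.4
    t_int: int | None = None
    cycles_per_wave: int = 5
    pulses_per_cycle: int = 16
    boundary_depth: float = 1.0
    face_order: tuple[str, ...] = DEFAULT_FACE_ORDER

    def __post_init__(self) -> None:
        if self.n_interval < 1:
            raise ValueError("n_interval must be >= 1")
        if self.v_max < 0:
            raise ValueError("v_max must be >= 0")
        if self.t_int is None:
            object.__setattr__(self, "t_int", 2400 * self.n_interval)
        if self.t_int < 0:
            raise ValueError("t_int must be >= 0")
        if self.cycles_per_wave < 1 or self.pulses_per_cycle < 1:
            raise ValueError("cycles_per_wave and pulses_per_cycle must be >= 1")
        unknown = set(self.face_order) - set(FACES)
        if unknown:
            raise ValueError(f"unknown faces in face_order: {sorted(unknown)}")
        object.__setattr__(self, "face_order", tuple(self.face_order))

    @property
    def pulses_per_wave(self) -> int:
        return self.cycles_per_wave * self.pulses_per_cycle

    @property
    def wave_steps(self) -> int:
        """Duration of one wave in MD steps (16·N·cycles at defaults)."""
        return self.pulses_per_cycle * self.n_interval * self.cycles_per_wave

    @property
    def period(self) -> int:
        """Steps of one full super-cycle: six waves plus the recovery delay."""
        return len(self.face_order) * self.wave_steps + self.t_int


@dataclass(frozen=True)
class PulseEvent:
    """A single velocity pulse: absolute step, face, signed speed (nm/ps)."""

    step: int
    face: str
    increment: float


@dataclass
class PulseSchedule:
    """Ordered pulse events covering a run of ``total_steps`` MD steps."""

    params: ShockWaveParams
    events: list[PulseEvent] = field(default_factory=list)

    @property
    def period(self) -> int:
        return self.params.period

    def events_at(self, step: int) -> list[PulseEvent]:
        """Pulses scheduled at an absolute MD step (usually 0 or 1)."""
        lo = _bisect_left_step(self.events, step)
        out = []
        for ev in self.events[lo:]:
            if ev.step != step:
                break
            out.append(ev)
        return out

    def to_table(self) -> "np.ndarray":
        """Plain-text export: structured array of (step, face, increment)."""
        return np.array(
            [(ev.step, ev.face, ev.increment) for ev in self.events],
            dtype=[("step", "i8"), ("face", "U2"), ("increment", "f8")],
        )


def _bisect_left_step(events: Sequence[PulseEvent], step: int) -> int:
    lo, hi = 0, len(events)
    while lo < hi:
        mid = (lo + hi) // 2
        if events[mid].step < step:
            lo = mid + 1
        else:
            hi = mid
    return lo


def pulse_increment(face: str, m: int, n_interval: int, v_max: float,
                    pulses_per_cycle: int = 16) -> float:
    """Signed pulse speed for step-within-wave ``m``.

    The cosine argument is reduced as an exact rational m/(16·N) before
    multiplying by 2π, so pulses at quarter- and half-cycle positions are
    exactly 0 / ±v_max up to the cosine's own rounding.
    """
    axis = face_axis(face)
    del axis
    if m % n_interval != 0:
        raise ScheduleError(
            f"step-within-wave {m} is not a multiple of the pulse interval {n_interval}"
        )
    frac = Fraction(m, pulses_per_cycle * n_interval) % 1
    # reduce to the first quadrant so symmetric pulses cancel bit-exactly
    # (cos(2pi f) = cos(2pi (1-f)) = -cos(2pi (1/2 - f)))
    sign = -1.0 if face_is_high(face) else 1.0
    if frac > Fraction(1, 2):
        frac = 1 - frac
    if frac > Fraction(1, 4):
        frac = Fraction(1, 2) - frac
        sign = -sign
    if frac == 0:
        c = 1.0
    elif frac == Fraction(1, 4):
        c = 0.0
    else:
        c = math.cos(2.0 * math.pi * float(frac))
    return sign * v_max * c


def build_schedule(params: ShockWaveParams, total_steps: int) -> PulseSchedule:
    """Lay out all pulse events in [0, total_steps).

    One wave spans 16·N·cycles steps with pulses at every multiple of N; the
    six waves run back to back in ``face_order``; after the last wave,
    ``t_int`` steps elapse with no pulses; the pattern then repeats.
    """
    if total_steps < 0:
        raise ValueError("total_steps must be >= 0")
    events: list[PulseEvent] = []
    period = params.period
    wave_steps = params.wave_steps
    n = params.n_interval
    start = 0
    while start < total_steps:
        offset = 0
        for face in params.face_order:
            for m in range(0, wave_steps, n):
                step = start + offset + m
                if step >= total_steps:
                    break
                events.append(PulseEvent(
                    step=step,
                    face=face,
                    increment=pulse_increment(face, m, n, params.v_max,
                                              params.pulses_per_cycle),
                ))
            offset += wave_steps
        start += period
    return PulseSchedule(params=params, events=events)


def select_boundary_solvent(frame: "SystemFrame", face: str,
                            boundary_depth: float) -> np.ndarray:
    """Indices of solvent particles within ``boundary_depth`` of a face plane.

    Coordinates must be wrapped into [0, box_edge) on every axis; solute
    (receptor) and ligand particles are never selected.
    """
    axis = face_axis(face)
    edge = frame.box[axis]
    if boundary_depth >= edge / 2:
        raise ValueError("boundary_depth must be below half the box edge")
    x = frame.positions[:, axis]
    if np.any(x < 0) or np.any(x >= edge):
        raise ValueError("positions must be wrapped into [0, box_edge) before selection")
    if face_is_high(face):
        mask = x >= edge - boundary_depth
    else:
        mask = x < boundary_depth
    mask &= frame.species == "solvent"
    return np.nonzero(mask)[0]


def apply_pulse(frame: "SystemFrame", face: str, increment: float,
                selection: np.ndarray) -> "SystemFrame":
    """Add ``increment`` to the face-axis velocity of every selected particle.

    Positions are untouched; total injected momentum is
    increment × Σ selected masses. Returns a new frame.
    """
    axis = face_axis(face)
    out = frame.copy()
    if increment != 0.0 and len(selection) > 0:
        out.velocities[selection, axis] += increment
    return out
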