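"""Displacement-controlled loading protocols for indentation testing.

A protocol is an ordered list of contiguous segments; each segment either
ramps the indentation depth linearly, holds it, or superimposes a sinusoid.
Depths are expressed as fractions of sample thickness (strain of the
indentation protocol) and converted to mm against a geometry.

The reference testing protocol is: seek a 12.5 kPa pre-stress contact,
then a 4-step stress-relaxation test (5% strain per step, 15 min hold per
step), then sinusoidal sweeps of 2% strain amplitude at
0.005, 0.05, 0.1, 0.25, 0.5, 0.625, 0.833 and 1 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ProtocolError
from .mesh import SampleGeometry

__all__ = [
    "Segment",
    "LoadingProtocol",
    "relaxation_protocol",
    "paper_protocol",
    "PROTOCOL_FREQUENCIES",
    "PRE_STRESS_MPA",
    "STEP_STRAIN",
    "HOLD_DURATION_S",
    "DYNAMIC_STRAIN_AMPLITUDE",
]

#: sinusoidal sweep frequencies (Hz) of the reference protocol
PROTOCOL_FREQUENCIES = (0.005, 0.05, 0.1, 0.25, 0.5, 0.625, 0.833, 1.0)
#: contact-seeking pre-stress (MPa)
PRE_STRESS_MPA = 0.0125
#: strain increment per stress-relaxation step
STEP_STRAIN = 0.05
#: relaxation hold per step (s)
HOLD_DURATION_S = 900.0
#: strain amplitude of the sinusoidal sweeps
DYNAMIC_STRAIN_AMPLITUDE = 0.02
#: default indenter speed during ramps (mm/s)
RAMP_SPEED_MM_S = 0.1

MAX_PROTOCOL_STRAIN = 0.25


@dataclass(frozen=True)
class Segment:
    """One protocol segment.

    kind      : 'ramp' | 'hold' | 'sinusoid'
    duration  : s
    target    : indentation depth (strain fraction of h) at segment end
                (ramp); ignored for hold; offset for sinusoid
    amplitude : strain amplitude (sinusoid only)
    frequency : Hz (sinusoid only)
    label     : optional annotation ('step1', 'dyn_0.1Hz', ...)
    """

    kind: str
    duration: float
    target: float = 0.0
    amplitude: float = 0.0
    frequency: float = 0.0
    label: str = ""

    def __post_init__(self):
        if self.kind not in ("ramp", "hold", "sinusoid"):
            raise ProtocolError(f"unknown segment kind {self.kind!r}")
        if self.duration <= 0:
            raise ProtocolError("segment duration must be positive")


@dataclass
class LoadingProtocol:
    """Contiguous displacement protocol starting from a given depth."""

    segments: list
    start_strain: float = 0.0

    def __post_init__(self):
        strain = self.start_strain
        hi = strain
        for s in self.segments:
            if s.kind == "ramp":
                strain = s.target
            elif s.kind == "sinusoid":
                strain = s.target
                hi = max(hi, strain + s.amplitude)
            hi = max(hi, strain)
        if not 0.0 <= hi <= MAX_PROTOCOL_STRAIN:
            raise ProtocolError(
                f"protocol strain {hi:.3f} outside [0, {MAX_PROTOCOL_STRAIN}]"
            )
        self.max_strain = hi

    def displacement(self, geometry: SampleGeometry):
        """Piecewise displacement function w(t) in mm (indentation depth)."""
        h = geometry.thickness
        t0 = 0.0
        pieces = []  # (t_start, t_end, callable)
        w = self.start_strain * h
        for s in self.segments:
            t1 = t0 + s.duration
            if s.kind == "ramp":
                w0, w1 = w, s.target * h
                pieces.append(
                    (t0, t1, lambda t, t0=t0, t1=t1, w0=w0, w1=w1: w0 + (w1 - w0) * (t - t0) / (t1 - t0))
                )
                w = w1
            elif s.kind == "hold":
                pieces.append((t0, t1, lambda t, w=w: np.full_like(np.asarray(t, float), w)))
            else:
                off, amp, f = s.target * h, s.amplitude * h, s.frequency
                pieces.append(
                    (t0, t1, lambda t, t0=t0, off=off, amp=amp, f=f: off + amp * np.sin(2 * np.pi * f * (t - t0)))
                )
                w = s.target * h
            t0 = t1

        def w_of_t(t):
            t = np.asarray(t, dtype=float)
            out = np.empty_like(t)
            for ts, te, fn in pieces:
                m = (t >= ts - 1e-12) & (t <= te + 1e-12)
                out[m] = fn(t[m])
            return out

        return w_of_t

    @property
    def total_duration(self) -> float:
        return sum(s.duration for s in self.segments)


def relaxation_protocol(
    start_strain: float,
    n_steps: int = 4,
    step_strain: float = STEP_STRAIN,
    hold: float = HOLD_DURATION_S,
    ramp_speed: float = RAMP_SPEED_MM_S,
    thickness: float = 2.0,
) -> LoadingProtocol:
    """Multi-step stress-relaxation protocol on top of an equilibrated
    pre-stress depth ``start_strain`` (fraction of thickness)."""
    segments = []
    strain = start_strain
    for i in range(1, n_steps + 1):
        target = strain + step_strain
        ramp_t = step_strain * thickness / ramp_speed
        segments.append(Segment("ramp", ramp_t, target=target, label=f"step{i}"))
        segments.append(Segment("hold", hold, label=f"step{i}"))
        strain = target
    return LoadingProtocol(segments, start_strain=start_strain)


def paper_protocol(
    start_strain: float,
    n_steps: int = 4,
    frequencies=PROTOCOL_FREQUENCIES,
    cycles: int = 5,
    dynamic_amplitude: float = DYNAMIC_STRAIN_AMPLITUDE,
    thickness: float = 2.0,
    hold: float = HOLD_DURATION_S,
) -> LoadingProtocol:
    """Full reference protocol: 4-step relaxation then the 8-frequency sweep."""
    proto = relaxation_protocol(start_strain, n_steps=n_steps, thickness=thickness, hold=hold)
    offset = start_strain + n_steps * STEP_STRAIN
    segments = list(proto.segments)
    for f in frequencies:
        segments.append(
            Segment(
                "sinusoid",
                duration=cycles / f,
                target=offset,
                amplitude=dynamic_amplitude,
                frequency=f,
                label=f"dyn_{f:g}Hz",
            )
        )
    return LoadingProtocol(segments, start_strain=start_strain)
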