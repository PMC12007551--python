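"""Parameterized TMS electric fields and their coupling into neuron models.

The external field is described by a polar angle theta (to the
somato-dendritic z-axis), an azimuth phi, a soma-level magnitude E_soma and a
relative magnitude change delta in %/mm along z:

    E(z) = E_soma * u(theta, phi) * max(delta/100 * (z - z_soma) + 1, 0)

with z in mm.  The field enters the cable equation as an extracellular
quasipotential, the line integral of E along the neurite tree, accumulated
edge by edge with the trapezoid rule (exact for the linear profile above
along straight edges).  The quasipotential is defined up to a constant; we
fix it to 0 at the root (soma) compartment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, TopologyError
from .morphology import CompartmentModel

__all__ = [
    "FieldParams",
    "PulseWaveform",
    "DrivePotentials",
    "field_vectors",
    "quasipotentials",
    "make_waveform",
    "assemble_drive",
    "load_waveform_csv",
    "save_waveform_csv",
]

UM_PER_MM = 1000.0


@dataclass(frozen=True)
class FieldParams:
    """Direction, soma magnitude and axial decay of the external field."""

    theta: float  # degrees, [0, 180]
    phi: float = 0.0  # degrees, [0, 360)
    delta: float = 0.0  # %/mm, [-100, 100]
    E_soma: float = 1.0  # V/m; equals E_thres at firing threshold
    z_soma: float = 0.0  # mm

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta <= 180.0):
            raise ConfigurationError("theta must lie in [0, 180] degrees")
        if not (0.0 <= self.phi < 360.0):
            raise ConfigurationError("phi must lie in [0, 360) degrees")
        if not (-100.0 <= self.delta <= 100.0):
            raise ConfigurationError("delta must lie in [-100, 100] %/mm")
        if self.E_soma < 0:
            raise ConfigurationError("E_soma must be non-negative")

    @property
    def direction(self) -> np.ndarray:
        th = math.radians(self.theta)
        ph = math.radians(self.phi)
        u = np.array([math.sin(th) * math.cos(ph),
                      math.sin(th) * math.sin(ph),
                      math.cos(th)])
        return u / np.linalg.norm(u)


@dataclass
class PulseWaveform:
    """Normalized pulse time course; samples peak at |1|, dt in µs."""

    kind: str
    samples: np.ndarray
    dt: float  # µs

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")
        peak = np.max(np.abs(self.samples))
        if abs(peak - 1.0) > 1e-9:
            raise ConfigurationError("waveform must be normalized to unit peak")

    @property
    def duration(self) -> float:
        return (len(self.samples) - 1) * self.dt

    def padded(self, duration: float) -> "PulseWaveform":
        """Zero-pad (or keep) the samples to span at least ``duration`` µs."""
        n = int(round(duration / self.dt)) + 1
        if n <= len(self.samples):
            return self
        out = np.zeros(n)
        out[: len(self.samples)] = self.samples
        return PulseWaveform(self.kind, out, self.dt)


@dataclass
class DrivePotentials:
    """Extracellular quasipotential for every compartment and time step, mV."""

    phi_e: np.ndarray  # (compartments, time)
    dt: float  # µs
    reference_compartment: int = 0

    def __post_init__(self) -> None:
        ref = self.phi_e[self.reference_compartment]
        if np.max(np.abs(ref)) > 1e-12:
            raise ConfigurationError("reference compartment potential must be 0")


def field_vectors(cm: CompartmentModel, fp: FieldParams) -> np.ndarray:
    """Per-compartment E-field vectors (V/m) of the parameterized field."""
    if len(cm) == 0:
        raise ConfigurationError("compartment model is empty")
    z_mm = cm.centers[:, 2] / UM_PER_MM
    factor = np.maximum(fp.delta / 100.0 * (z_mm - fp.z_soma) + 1.0, 0.0)
    return fp.E_soma * factor[:, None] * fp.direction[None, :]


def _field_at_points(points_um: np.ndarray, fp: FieldParams) -> np.ndarray:
    z_mm = points_um[:, 2] / UM_PER_MM
    factor = np.maximum(fp.delta / 100.0 * (z_mm - fp.z_soma) + 1.0, 0.0)
    return fp.E_soma * factor[:, None] * fp.direction[None, :]


def quasipotentials(cm: CompartmentModel, vectors: np.ndarray) -> np.ndarray:
    """Static extracellular potentials (mV) from per-compartment field vectors.

    Accumulates -integral(E . dl) from the root along tree edges between
    compartment centers using the trapezoid rule.  For a spatially uniform
    field this reduces exactly to -E.(r - r_root), independent of the path.
    """
    n = len(cm)
    vectors = np.asarray(vectors, dtype=float)
    if vectors.shape != (n, 3):
        raise ConfigurationError("vectors must align with the compartment model")
    parents = cm.adjacency
    centers = cm.centers
    phi = np.zeros(n)
    for i in range(1, n):
        p = parents[i]
        if p < 0:
            raise TopologyError("disconnected compartment encountered")
        dr_um = centers[i] - centers[p]
        e_mid = 0.5 * (vectors[i] + vectors[p])
        # V/m * µm = 1e-3 mV
        phi[i] = phi[p] - float(np.dot(e_mid, dr_um)) * 1e-3
    return phi


def static_quasipotentials(cm: CompartmentModel, fp: FieldParams) -> np.ndarray:
    """Convenience: field_vectors followed by quasipotentials."""
    return quasipotentials(cm, field_vectors(cm, fp))


# ---------------------------------------------------------------------------
# Waveforms
# ---------------------------------------------------------------------------

def make_waveform(
    kind: str,
    dt: float = 5.0,
    duration: float | None = None,
    *,
    period: float = 280.0,
    damping_tau: float = 600.0,
    rise: float = 60.0,
    hold: float = 30.0,
    fall: float = 43.2,
    samples: np.ndarray | None = None,
) -> PulseWaveform:
    """Analytic pulse shapes, normalized to unit peak.

    ``monophasic``: damped half-sine E-field stand-in (recordings of real
    stimulator coils are not distributable); ``biphasic``: one full cycle of
    a damped cosine, approximately charge-balanced; ``trapezoidal_monophasic``:
    linear rise (60 µs), hold (30 µs), linear fall (43.2 µs);
    ``custom``: caller-provided samples.
    Positive sample = field along the (theta, phi) direction.
    """
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    if kind == "custom":
        if samples is None:
            raise ConfigurationError("custom waveform requires samples")
        arr = np.asarray(samples, dtype=float)
        arr = arr / np.max(np.abs(arr))
        return PulseWaveform(kind, arr, dt)

    if kind == "monophasic":
        t_end = period / 2.0
    elif kind == "biphasic":
        t_end = period
    elif kind == "trapezoidal_monophasic":
        t_end = rise + hold + fall
    else:
        raise ConfigurationError(f"unknown waveform kind {kind!r}")

    total = t_end if duration is None else max(duration, t_end)
    n = int(math.floor(total / dt + 1e-9)) + 1
    t = np.arange(n) * dt
    if kind == "monophasic":
        w = np.where(t <= period / 2.0,
                     np.sin(2.0 * np.pi * t / period) * np.exp(-t / damping_tau), 0.0)
    elif kind == "biphasic":
        w = np.where(t <= period,
                     np.cos(2.0 * np.pi * t / period) * np.exp(-t / damping_tau), 0.0)
    else:
        w = np.zeros(n)
        rising = t < rise
        w[rising] = t[rising] / rise
        holding = (t >= rise) & (t <= rise + hold)
        w[holding] = 1.0
        falling = (t > rise + hold) & (t < rise + hold + fall)
        w[falling] = 1.0 - (t[falling] - rise - hold) / fall
    w = w / np.max(np.abs(w))
    return PulseWaveform(kind, w, dt)


def assemble_drive(static_phi_e: np.ndarray, w: PulseWaveform,
                   amplitude: float, sim_dt: float | None = None) -> DrivePotentials:
    """phi_e[i, t] = amplitude * w[t] * static_phi_e[i]; linear in amplitude."""
    if sim_dt is not None and abs(sim_dt - w.dt) > 1e-12:
        raise ConfigurationError(
            f"waveform dt {w.dt} µs does not match simulation dt {sim_dt} µs"
        )
    static_phi_e = np.asarray(static_phi_e, dtype=float)
    phi = amplitude * static_phi_e[:, None] * w.samples[None, :]
    return DrivePotentials(phi, dt=w.dt, reference_compartment=0)


def save_waveform_csv(w: PulseWaveform, path) -> None:
    t = np.arange(len(w.samples)) * w.dt
    arr = np.column_stack([t, w.samples])
    np.savetxt(path, arr, delimiter=",", header="time_us,amplitude_normalized",
               comments="")


def load_waveform_csv(path, kind: str = "custom") -> PulseWaveform:
    arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    t, a = arr[:, 0], arr[:, 1]
    dts = np.diff(t)
    if len(dts) == 0 or np.any(dts <= 0) or np.ptp(dts) > 1e-6 * dts[0]:
        raise ConfigurationError("waveform CSV must have uniformly increasing time")
    if abs(np.max(np.abs(a)) - 1.0) > 1e-6:
        raise ConfigurationError("waveform CSV must be normalized to unit peak")
    a = a / np.max(np.abs(a))
    return PulseWaveform(kind, a, float(dts[0]))
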