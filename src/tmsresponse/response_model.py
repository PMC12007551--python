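"""Reduced average-response model: threshold grids, maps, recruitment surfaces.

Per-cell firing thresholds are computed on a (theta, phi, delta) grid of
field configurations and reduced by averaging over cells and azimuth, on the
assumption that cortical neurons sit at random tangential orientations.  The
population's cumulative threshold distribution at each (theta, delta) bin is
smoothed into a recruitment-rate sigmoid

    f(E) = 1 / (1 + exp(-r (E - E0)))

whose shift E0 is the half-recruitment field and whose slope r reflects the
population threshold spread.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.optimize import curve_fit

from .cable_sim import MembraneModel, SimConfig, find_threshold, prepare_simcell
from .errors import ConfigurationError, EmptyBinError, RangeError
from .field_coupling import FieldParams, PulseWaveform, static_quasipotentials
from .morphology import CompartmentModel, Morphology, discretize

__all__ = [
    "default_theta_axis",
    "default_phi_axis",
    "default_delta_axis",
    "ThresholdGrid",
    "AverageThresholdMap",
    "RecruitmentSigmoid",
    "RecruitmentSurface",
    "build_threshold_grid",
    "average_map",
    "interpolate_threshold",
    "empirical_recruitment",
    "fit_sigmoid",
    "recruitment_surface",
    "polar_sensitivity_curve",
    "save_grid",
    "load_grid",
    "save_map",
    "load_map",
]

NOT_EXCITABLE = np.inf  # grid sentinel


def default_theta_axis(step: float = 3.0) -> np.ndarray:
    """Polar angles [0, 180] degrees, inclusive of both ends."""
    return np.arange(0.0, 180.0 + step / 2, step)


def default_phi_axis(step: float = 6.0) -> np.ndarray:
    """Azimuths [0, 360) degrees, half-open so 0 and 360 are not both counted."""
    return np.arange(0.0, 360.0, step)


def default_delta_axis(step: float = 10.0) -> np.ndarray:
    """Field decays [-100, 100] %/mm."""
    return np.arange(-100.0, 100.0 + step / 2, step)


def _check_uniform(axis: np.ndarray, name: str) -> None:
    axis = np.asarray(axis, dtype=float)
    if axis.ndim != 1 or len(axis) < 1:
        raise ConfigurationError(f"{name} must be a 1-D axis")
    if len(axis) > 2:
        d = np.diff(axis)
        if np.ptp(d) > 1e-9 * abs(d[0]):
            raise ConfigurationError(f"{name} must be uniformly spaced")


@dataclass
class ThresholdGrid:
    theta_axis: np.ndarray
    phi_axis: np.ndarray
    delta_axis: np.ndarray
    thresholds: np.ndarray  # (cells, theta, phi, delta), V/m; inf = not excitable
    waveform_kind: str = "monophasic"
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("theta_axis", "phi_axis", "delta_axis"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
            _check_uniform(getattr(self, name), name)
        expected = (self.thresholds.shape[0], len(self.theta_axis),
                    len(self.phi_axis), len(self.delta_axis))
        if self.thresholds.shape != expected:
            raise ConfigurationError(
                f"threshold array shape {self.thresholds.shape} != {expected}"
            )


@dataclass
class AverageThresholdMap:
    theta_axis: np.ndarray
    delta_axis: np.ndarray
    mean: np.ndarray  # (theta, delta), V/m
    ci95_halfwidth: np.ndarray
    n_samples: np.ndarray  # finite samples per bin
    excluded_fraction: float = 0.0
    metadata: dict = field(default_factory=dict)

    _interp: RegularGridInterpolator | None = field(default=None, repr=False,
                                                    compare=False)

    def interpolator(self) -> RegularGridInterpolator:
        if self._interp is None:
            self._interp = RegularGridInterpolator(
                (self.theta_axis, self.delta_axis), self.mean,
                method="linear", bounds_error=True)
        return self._interp


def build_threshold_grid(
    cells: Sequence[Morphology] | Sequence[CompartmentModel],
    waveform: PulseWaveform,
    cfg: SimConfig | None = None,
    mm: MembraneModel | None = None,
    theta_axis: np.ndarray | None = None,
    phi_axis: np.ndarray | None = None,
    delta_axis: np.ndarray | None = None,
    precision: float = 0.05,
    max_compartment_len: float = 20.0,
    progress: Callable[[int, int], None] | None = None,
) -> ThresholdGrid:
    """One threshold search per (cell, theta, phi, delta) field configuration.

    Azimuthal rotation is implemented by rotating the field about z, which is
    equivalent to rotating the cell.  Non-excitable configurations propagate
    as inf sentinels without aborting the sweep.
    """
    if len(cells) == 0:
        raise ConfigurationError("at least one cell is required")
    cfg = cfg or SimConfig()
    mm = mm or MembraneModel()
    theta_axis = default_theta_axis() if theta_axis is None else np.asarray(theta_axis, float)
    phi_axis = default_phi_axis() if phi_axis is None else np.asarray(phi_axis, float)
    delta_axis = default_delta_axis() if delta_axis is None else np.asarray(delta_axis, float)

    models = [c if isinstance(c, CompartmentModel) else discretize(c, max_compartment_len)
              for c in cells]
    out = np.empty((len(models), len(theta_axis), len(phi_axis), len(delta_axis)))
    total = out.size
    done = 0
    for ci, cm in enumerate(models):
        cell = prepare_simcell(cm, mm, cfg)
        for ti, theta in enumerate(theta_axis):
            for pi, phi in enumerate(phi_axis):
                for di, delta in enumerate(delta_axis):
                    fp = FieldParams(theta=theta, phi=phi, delta=delta, E_soma=1.0)
                    res = find_threshold(cm, mm, fp, waveform, cfg,
                                         precision=precision, _cell=cell)
                    out[ci, ti, pi, di] = res.threshold if res.excitable else NOT_EXCITABLE
                    done += 1
                if progress is not None:
                    progress(done, total)
    return ThresholdGrid(theta_axis, phi_axis, delta_axis, out,
                         waveform_kind=waveform.kind,
                         cell_ids=[cm.cell_id for cm in models])


def average_map(g: ThresholdGrid) -> AverageThresholdMap:
    """Mean threshold over cells and azimuth per (theta, delta) bin.

    Non-excitable sentinels are excluded from the mean (their overall
    fraction is reported); the 95% CI half-width uses the normal
    approximation 1.96 * SE of the mean.  An all-sentinel bin keeps the inf
    sentinel and shows n_samples = 0.
    """
    thr = g.thresholds
    finite = np.isfinite(thr)
    n = finite.sum(axis=(0, 2)).astype(float)  # (theta, delta)
    vals = np.where(finite, thr, 0.0)
    mean = np.divide(vals.sum(axis=(0, 2)), n, out=np.full_like(n, np.inf),
                     where=n > 0)
    sq = np.where(finite, (np.where(finite, thr, 0.0)
                           - np.where(np.isfinite(mean), mean, 0.0)[None, :, None, :]) ** 2,
                  0.0)
    var = np.divide(sq.sum(axis=(0, 2)), n - 1, out=np.zeros_like(n), where=n > 1)
    ci = 1.96 * np.sqrt(np.divide(var, n, out=np.zeros_like(n), where=n > 0))
    excluded = 1.0 - finite.sum() / thr.size
    meta = {
        "ci_rule": "normal-approximation 95% CI of the mean (1.96*SE)",
        "waveform_kind": g.waveform_kind,
        "n_cells": thr.shape[0],
        "n_phi": thr.shape[2],
        "flagged_bins": int(np.sum(n == 0)),
    }
    return AverageThresholdMap(g.theta_axis.copy(), g.delta_axis.copy(), mean, ci,
                               n.astype(int), excluded, meta)


def interpolate_threshold(m: AverageThresholdMap, theta: float, delta: float) -> float:
    """Bilinear interpolation of the averaged map; exact at grid nodes."""
    try:
        val = m.interpolator()((theta, delta))
    except ValueError as exc:
        raise RangeError(
            f"query (theta={theta}, delta={delta}) outside the map axes"
        ) from exc
    return float(val)


class EmpiricalRecruitment:
    """Empirical CDF of pooled thresholds: fraction with threshold <= E."""

    def __init__(self, samples: np.ndarray):
        self.samples = np.sort(np.asarray(samples, dtype=float))

    def __call__(self, E):
        frac = np.searchsorted(self.samples, np.asarray(E, dtype=float),
                               side="right") / len(self.samples)
        return float(frac) if np.isscalar(E) or np.ndim(E) == 0 else frac


def _bin_index(axis: np.ndarray, value: float, name: str) -> int:
    idx = int(np.argmin(np.abs(axis - value)))
    if abs(axis[idx] - value) > 1e-6 * max(1.0, abs(value)):
        raise ConfigurationError(f"{name}={value} is not a grid axis value")
    return idx


def empirical_recruitment(g: ThresholdGrid, theta: float, delta: float) -> EmpiricalRecruitment:
    """Pooled (cells × phi) threshold CDF at one (theta, delta) bin."""
    ti = _bin_index(g.theta_axis, theta, "theta")
    di = _bin_index(g.delta_axis, delta, "delta")
    pooled = g.thresholds[:, ti, :, di].ravel()
    pooled = pooled[np.isfinite(pooled)]
    if len(pooled) == 0:
        raise EmptyBinError(f"no finite thresholds at theta={theta}, delta={delta}")
    return EmpiricalRecruitment(pooled)


@dataclass(frozen=True)
class RecruitmentSigmoid:
    r: float  # slope, (V/m)^-1
    E0: float  # shift, V/m; f(E0) = 0.5 identically

    def __post_init__(self) -> None:
        if not (self.r > 0):
            raise ConfigurationError("sigmoid slope r must be positive")

    def __call__(self, E):
        E = np.asarray(E, dtype=float)
        out = 1.0 / (1.0 + np.exp(-self.r * (E - self.E0)))
        return float(out) if out.ndim == 0 else out


def _sigmoid(E, r, E0):
    return 1.0 / (1.0 + np.exp(-r * (E - E0)))


def fit_sigmoid(E: np.ndarray, f: np.ndarray) -> RecruitmentSigmoid:
    """Least-squares sigmoid fit of recruitment points (r constrained > 0).

    Initialization: E0 at the median abscissa, r = 1.1/IQR — a robust
    starting point for threshold-CDF-shaped data.
    """
    E = np.asarray(E, dtype=float)
    f = np.asarray(f, dtype=float)
    if len(np.unique(E)) < 3:
        raise ConfigurationError("sigmoid fit requires at least 3 distinct E points")
    e25, e50, e75 = np.percentile(E, [25, 50, 75])
    iqr = max(e75 - e25, 1e-9 * max(abs(e50), 1.0))
    p0 = (1.1 / iqr, e50)
    popt, _ = curve_fit(_sigmoid, E, f, p0=p0,
                        bounds=([1e-12, -np.inf], [np.inf, np.inf]),
                        maxfev=10000)
    return RecruitmentSigmoid(r=float(popt[0]), E0=float(popt[1]))


@dataclass
class RecruitmentSurface:
    theta_axis: np.ndarray
    delta_axis: np.ndarray
    r: np.ndarray  # (theta, delta); nan where not converged
    E0: np.ndarray
    residual_rms: np.ndarray
    converged: np.ndarray  # bool mask

    def sigmoid_at(self, theta: float, delta: float) -> RecruitmentSigmoid:
        ti = _bin_index(self.theta_axis, theta, "theta")
        di = _bin_index(self.delta_axis, delta, "delta")
        if not self.converged[ti, di]:
            raise EmptyBinError(f"no converged fit at theta={theta}, delta={delta}")
        return RecruitmentSigmoid(float(self.r[ti, di]), float(self.E0[ti, di]))


def recruitment_surface(g: ThresholdGrid) -> RecruitmentSurface:
    """Sigmoid parameters of the pooled threshold CDF per (theta, delta) bin."""
    nt, nd = len(g.theta_axis), len(g.delta_axis)
    r = np.full((nt, nd), np.nan)
    E0 = np.full((nt, nd), np.nan)
    rms = np.full((nt, nd), np.nan)
    ok = np.zeros((nt, nd), dtype=bool)
    for ti in range(nt):
        for di in range(nd):
            pooled = g.thresholds[:, ti, :, di].ravel()
            pooled = pooled[np.isfinite(pooled)]
            if len(pooled) == 0:
                continue
            samples = np.sort(pooled)
            cdf = EmpiricalRecruitment(samples)
            uniq = np.unique(samples)
            if len(uniq) < 3 or np.ptp(uniq) < 1e-6 * max(abs(uniq[-1]), 1.0):
                # step-like population: all thresholds (nearly) identical
                E0[ti, di] = float(np.median(samples))
                r[ti, di] = 1e6 / max(abs(E0[ti, di]), 1.0)
                rms[ti, di] = 0.0
                ok[ti, di] = True
                continue
            lo, hi = uniq[0], uniq[-1]
            pad = 0.05 * (hi - lo)
            xs = np.concatenate([[lo - pad], uniq, [hi + pad]])
            ys = cdf(xs)
            try:
                sig = fit_sigmoid(xs, ys)
            except (RuntimeError, ConfigurationError):
                continue
            r[ti, di] = sig.r
            E0[ti, di] = sig.E0
            rms[ti, di] = float(np.sqrt(np.mean((sig(xs) - ys) ** 2)))
            ok[ti, di] = True
    return RecruitmentSurface(g.theta_axis.copy(), g.delta_axis.copy(),
                              r, E0, rms, ok)


def polar_sensitivity_curve(
    s: RecruitmentSurface,
    intensities_rel: Sequence[float],
    delta: float = 0.0,
    theta_ref: float = 0.0,
    normalize: bool = True,
) -> dict[float, np.ndarray]:
    """Recruitment over theta at multiples of a reference half-recruitment field.

    The reference intensity is E0 at (theta_ref, delta) — the model analog of
    the resting motor threshold.  Curves are normalized to their maxima for
    comparability (directional modulation depth is then directly readable).
    """
    intensities_rel = list(intensities_rel)
    if any(x <= 0 for x in intensities_rel):
        raise ConfigurationError("relative intensities must be positive")
    ti_ref = _bin_index(s.theta_axis, theta_ref, "theta_ref")
    di = _bin_index(s.delta_axis, delta, "delta")
    if not s.converged[ti_ref, di]:
        raise EmptyBinError("no converged sigmoid at the reference bin")
    e_ref = float(s.E0[ti_ref, di])
    out: dict[float, np.ndarray] = {}
    for rel in intensities_rel:
        E = rel * e_ref
        vals = np.array([
            RecruitmentSigmoid(float(s.r[ti, di]), float(s.E0[ti, di]))(E)
            if s.converged[ti, di] else np.nan
            for ti in range(len(s.theta_axis))
        ])
        if normalize:
            peak = np.nanmax(vals)
            if peak > 0:
                vals = vals / peak
        out[rel] = vals
    return out


# ---------------------------------------------------------------------------
# Serialization (HDF5 datasets + JSON metadata attribute)
# ---------------------------------------------------------------------------

def save_grid(g: ThresholdGrid, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("theta_axis", data=g.theta_axis)
        f.create_dataset("phi_axis", data=g.phi_axis)
        f.create_dataset("delta_axis", data=g.delta_axis)
        f.create_dataset("thresholds", data=g.thresholds)
        f.attrs["metadata"] = json.dumps({
            "waveform_kind": g.waveform_kind,
            "cell_ids": g.cell_ids,
            "units": {"thresholds": "V/m", "theta": "deg", "phi": "deg",
                      "delta": "%/mm"},
        })


def load_grid(path) -> ThresholdGrid:
    import h5py

    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs["metadata"])
        return ThresholdGrid(f["theta_axis"][:], f["phi_axis"][:],
                             f["delta_axis"][:], f["thresholds"][:],
                             waveform_kind=meta["waveform_kind"],
                             cell_ids=list(meta["cell_ids"]))


def save_map(m: AverageThresholdMap, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("theta_axis", data=m.theta_axis)
        f.create_dataset("delta_axis", data=m.delta_axis)
        f.create_dataset("mean", data=m.mean)
        f.create_dataset("ci95", data=m.ci95_halfwidth)
        f.create_dataset("n_samples", data=m.n_samples)
        f.attrs["metadata"] = json.dumps(
            {**m.metadata, "excluded_fraction": m.excluded_fraction,
             "units": {"mean": "V/m", "theta": "deg", "delta": "%/mm"}})


def load_map(path) -> AverageThresholdMap:
    import h5py

    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs["metadata"])
        return AverageThresholdMap(f["theta_axis"][:], f["delta_axis"][:],
                                   f["mean"][:], f["ci95"][:], f["n_samples"][:],
                                   meta.pop("excluded_fraction", 0.0), meta)
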