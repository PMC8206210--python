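"""Fitting the random-community spectral model to abundance time series.

Pipeline (mirroring how a field survey is analysed): raw samples are averaged
to daily values, species observed at zero on any day are discarded, means are
subtracted, a smooth empirical mean spectrum is estimated per species by the
autoregressive covariance method (order 8 by default) and averaged, and the
mean-field Lotka-Volterra spectrum is fitted to it by nonlinear least squares.

Identifiability: a mean spectrum determines only the self-regulation ``b``,
the composite interaction strength ``c sigma^2``, the symmetry parameter
``gamma`` and an overall scale. The model curve is therefore

    phi(omega) = scale * |r(omega)|^2 / (1 - |r(omega)|^2 * c sigma^2),

with the resolvent r depending on (b, gamma * c sigma^2) only; the noise-level
numerator is absorbed into ``scale``.

The public surface is a statsmodels-style pair: ``LVSpectrumModel`` built
from an empirical spectrum (or directly from an abundance table), whose
``fit`` returns an ``LVSpectrumResults`` carrying estimates, diagnostics and a
``summary`` table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.optimize
from scipy.stats import qmc

from .cavity import MomentInputs, resolvent_mean_field
from .communities import stability_edge
from .spectral import SpectralDensity

__all__ = [
    "preprocess_abundance_table",
    "ar_covariance_psd",
    "LVSpectrumModel",
    "LVSpectrumResults",
    "FitResult",
    "fit_mean_field_spectrum",
    "spectral_edge_from_fit",
    "read_abundance_table",
]

_BOUNDS = {"b": (0.01, 5.0), "c_sigma2": (1e-4, 4.0), "gamma": (-1.0, 1.0)}


def read_abundance_table(path: str | Path) -> pd.DataFrame:
    """Read a wide abundance table from CSV/TSV (or xlsx if openpyxl is present)."""
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep)


def preprocess_abundance_table(
    table: pd.DataFrame | np.ndarray, samples_per_day: int
) -> tuple[np.ndarray, list[str]]:
    """Daily-average, drop zero-observed species, and mean-centre.

    Returns the (days x retained species) matrix of mean-subtracted daily
    abundances plus the retained species names. A species is discarded if any
    of its daily averages is exactly zero (absent that day).
    """
    if samples_per_day < 1:
        raise ValueError("samples_per_day must be >= 1")
    if isinstance(table, pd.DataFrame):
        names = [str(c) for c in table.columns]
        data = table.to_numpy(dtype=float)
    else:
        data = np.asarray(table, dtype=float)
        names = [f"sp{j + 1:03d}" for j in range(data.shape[1])]
    if data.ndim != 2:
        raise ValueError("abundance table must be two-dimensional")
    if np.any(data < 0):
        raise ValueError("abundances must be nonnegative")
    n_rows = data.shape[0]
    if n_rows % samples_per_day:
        raise ValueError(
            f"row count {n_rows} not divisible by samples_per_day={samples_per_day}"
        )
    n_days = n_rows // samples_per_day
    daily = data.reshape(n_days, samples_per_day, -1).mean(axis=1)
    keep = ~np.any(daily == 0.0, axis=0)
    if not keep.any():
        raise ValueError("no species retained after zero-abundance filtering")
    daily = daily[:, keep]
    kept_names = [n for n, k in zip(names, keep) if k]
    return daily - daily.mean(axis=0, keepdims=True), kept_names


def _ar_covariance_fit(x: np.ndarray, order: int) -> tuple[np.ndarray, float]:
    """AR coefficients and driving variance by the covariance method.

    Unwindowed least-squares prediction: regress x[t] on x[t-1..t-order] over
    t = order..n-1 (no zero padding, no trend term). Implemented through
    statsmodels' conditional-least-squares autoregression.
    """
    from statsmodels.tsa.ar_model import AutoReg

    res = AutoReg(x, lags=order, trend="n").fit()
    return np.asarray(res.params), float(res.sigma2)


def ar_covariance_psd(
    series_matrix: np.ndarray,
    order: int = 8,
    omegas: np.ndarray | None = None,
    delta: float = 1.0,
) -> SpectralDensity:
    """Mean AR-spectrum of mean-centred series (columns = species).

    Each species' spectrum is sigma_e^2 * delta / |1 - sum a_k e^{-i omega k
    delta}|^2, the two-sided angular-frequency density of the fitted AR
    process (``delta`` is the sampling interval, 1 day by default); species
    whose normal equations are ill-conditioned (e.g. constant series) are
    skipped with a warning, and the remaining spectra averaged.
    """
    X = np.asarray(series_matrix, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if order >= n // 2:
        raise ValueError(f"AR order {order} too high for {n} samples")
    if omegas is None:
        omegas = np.linspace(np.pi / delta / 200, np.pi / delta, 200)
    omegas = np.asarray(omegas, dtype=float)
    phase = np.exp(-1j * np.outer(omegas * delta, np.arange(1, order + 1)))
    spectra = []
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.allclose(col, col[0]):
            warnings.warn(f"species column {j} is constant; skipped in AR estimation")
            continue
        try:
            coeffs, sig2 = _ar_covariance_fit(col, order)
        except (np.linalg.LinAlgError, ValueError):
            warnings.warn(f"AR normal equations ill-conditioned for column {j}; skipped")
            continue
        denom = np.abs(1.0 - phase @ coeffs) ** 2
        spectra.append(sig2 * delta / denom)
    if not spectra:
        raise ValueError("no species could be AR-fitted")
    return SpectralDensity(omegas=omegas, values=np.mean(spectra, axis=0))


def _model_shape(omegas: np.ndarray, b: float, c_sigma2: float, gamma: float) -> np.ndarray | None:
    """|r|^2 / (1 - |r|^2 c sigma^2) up to the overall scale; None if the
    parameter vector is outside the stable/valid region."""
    if stability_edge(b, c_sigma2, gamma) >= 0:
        return None
    m = MomentInputs(
        EAii=-b, EBii=1.0, EAij2=c_sigma2, EAijAji=gamma * c_sigma2, EAijBij=0.0, c=1.0
    )
    r = np.atleast_1d(resolvent_mean_field(omegas, m))
    r2 = np.abs(r) ** 2
    denom = 1.0 - r2 * c_sigma2
    if np.any(denom <= 0):
        return None
    return r2 / denom


@dataclass
class FitResult:
    """Fitted spectral-model parameters and diagnostics."""

    b: float
    c_sigma2: float
    gamma: float
    scale: float
    residual: float
    lambda_max: float
    constrained: str | None = None
    n_starts: int = 0

    def to_dict(self) -> dict:
        return {
            "b": self.b,
            "c_sigma2": self.c_sigma2,
            "gamma": self.gamma,
            "scale": self.scale,
            "residual": self.residual,
            "lambda_max": self.lambda_max,
            "constrained": self.constrained,
        }


def spectral_edge_from_fit(fit: FitResult) -> float:
    """Rightmost eigenvalue-support edge implied by a fit,
    sqrt(c sigma^2) (1 + gamma) - b."""
    return stability_edge(fit.b, fit.c_sigma2, fit.gamma)


class LVSpectrumModel:
    """Mean-field Lotka-Volterra spectral model for an empirical mean spectrum.

    Parameters
    ----------
    empirical : SpectralDensity
        Mean power spectrum on an angular-frequency grid (two-sided
        convention). Use :meth:`from_abundance` to build it from a raw
        abundance table via the AR covariance method.
    """

    def __init__(self, empirical: SpectralDensity):
        if empirical.omegas.size < 8:
            raise ValueError("empirical grid shorter than 8 points")
        if not np.all(np.isfinite(empirical.mean)):
            raise ValueError("empirical spectrum must be finite on its grid")
        self.empirical = empirical
        self.omegas = empirical.omegas
        self.phi_emp = empirical.mean

    @classmethod
    def from_abundance(
        cls,
        table: pd.DataFrame | np.ndarray,
        samples_per_day: int = 3,
        ar_order: int = 8,
        omegas: np.ndarray | None = None,
    ) -> "LVSpectrumModel":
        daily, names = preprocess_abundance_table(table, samples_per_day)
        model = cls(ar_covariance_psd(daily, order=ar_order, omegas=omegas))
        model.retained_species = names
        return model

    def predict(self, params: FitResult, omegas: np.ndarray | None = None) -> np.ndarray:
        om = self.omegas if omegas is None else np.asarray(omegas, float)
        shape = _model_shape(om, params.b, params.c_sigma2, params.gamma)
        if shape is None:
            raise ValueError("parameters outside the stable region")
        return params.scale * shape

    def _residuals(self, theta: np.ndarray) -> tuple[np.ndarray, float]:
        b, cs2, gamma = theta
        shape = _model_shape(self.omegas, b, cs2, gamma)
        if shape is None:
            # smooth-ish penalty ramp guiding the optimiser back inside
            viol = max(stability_edge(b, cs2, gamma), 0.0) + 1.0
            return np.full_like(self.phi_emp, 1e3 * viol), 0.0
        scale = float(np.dot(shape, self.phi_emp) / np.dot(shape, shape))
        if scale <= 0:
            return np.full_like(self.phi_emp, 1e3), 0.0
        return scale * shape - self.phi_emp, scale

    def fit(
        self,
        constraint: str | None = None,
        init: tuple[float, float, float] | None = None,
        n_starts: int = 20,
        seed: int = 0,
    ) -> "LVSpectrumResults":
        """Nonlinear least squares with Latin-hypercube multi-start.

        ``constraint="gamma<0"`` restricts the symmetry parameter to negative
        values (the predator-prey-dominated hypothesis). Ties in the residual
        are broken toward smaller ``b``.
        """
        lo = np.array([_BOUNDS["b"][0], _BOUNDS["c_sigma2"][0], _BOUNDS["gamma"][0]])
        hi = np.array([_BOUNDS["b"][1], _BOUNDS["c_sigma2"][1], _BOUNDS["gamma"][1]])
        if constraint == "gamma<0":
            hi[2] = -1e-6
        elif constraint is not None:
            raise ValueError(f"unknown constraint {constraint!r}")

        starts: list[np.ndarray] = []
        if init is not None:
            starts.append(np.clip(np.asarray(init, float), lo, hi))
        sampler = qmc.LatinHypercube(d=3, seed=seed)
        starts.extend(lo + qmc_sample * (hi - lo) for qmc_sample in sampler.random(n_starts))

        best: tuple[float, np.ndarray, float] | None = None
        n_ok = 0
        for x0 in starts:
            try:
                sol = scipy.optimize.least_squares(
                    lambda th: self._residuals(th)[0],
                    x0,
                    bounds=(lo, hi),
                    method="trf",
                    xtol=1e-14,
                    ftol=1e-14,
                    gtol=1e-14,
                    max_nfev=400,
                )
            except Exception:
                continue
            res_vec, scale = self._residuals(sol.x)
            ssq = float(np.dot(res_vec, res_vec))
            if not np.isfinite(ssq) or scale == 0.0:
                continue
            n_ok += 1
            if (
                best is None
                or ssq < best[0] * (1 - 1e-9)
                or (abs(ssq - best[0]) <= best[0] * 1e-9 and sol.x[0] < best[1][0])
            ):
                best = (ssq, sol.x, scale)
        if best is None:
            raise RuntimeError("all optimisation starts failed to converge")
        ssq, theta, scale = best
        b, cs2, gamma = (float(v) for v in theta)
        result = FitResult(
            b=b,
            c_sigma2=cs2,
            gamma=gamma,
            scale=scale,
            residual=ssq,
            lambda_max=stability_edge(b, cs2, gamma),
            constrained=constraint,
            n_starts=n_ok,
        )
        return LVSpectrumResults(self, result)


class LVSpectrumResults:
    """Results wrapper: parameter access, fitted curve, summary table."""

    def __init__(self, model: LVSpectrumModel, params: FitResult):
        self.model = model
        self._params = params

    # convenient attribute passthrough (b, c_sigma2, gamma, scale, ...)
    def __getattr__(self, name):
        try:
            return getattr(self.__dict__["_params"], name)
        except AttributeError:
            raise AttributeError(name) from None

    @property
    def params(self) -> FitResult:
        return self._params

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.model.predict(self._params)

    def summary(self) -> str:
        p = self._params
        lines = [
            "Mean-field spectrum fit",
            "=" * 44,
            f"{'grid points':<24}{self.model.omegas.size:>20d}",
            f"{'multi-starts kept':<24}{p.n_starts:>20d}",
            f"{'constraint':<24}{str(p.constrained):>20}",
            "-" * 44,
            f"{'b (self-regulation)':<24}{p.b:>20.6g}",
            f"{'c*sigma^2':<24}{p.c_sigma2:>20.6g}",
            f"{'gamma (symmetry)':<24}{p.gamma:>20.6g}",
            f"{'scale':<24}{p.scale:>20.6g}",
            "-" * 44,
            f"{'sum sq. residual':<24}{p.residual:>20.6g}",
            f"{'spectral edge':<24}{p.lambda_max:>20.6g}",
            "=" * 44,
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Quick-look comparison of the empirical and fitted spectra."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.loglog(self.model.omegas, self.model.phi_emp, "o", ms=3, label="empirical")
        ax.loglog(self.model.omegas, self.fittedvalues, "-", label="fitted")
        ax.set_xlabel(r"$\omega$ (rad/day)")
        ax.set_ylabel(r"$\phi(\omega)$")
        ax.legend()
        return ax


def fit_mean_field_spectrum(
    empirical: SpectralDensity,
    constraint: str | None = None,
    init: tuple[float, float, float] | None = None,
    seed: int = 0,
    n_starts: int = 20,
) -> FitResult:
    """Functional wrapper: fit the mean-field spectrum, return the FitResult."""
    model = LVSpectrumModel(empirical)
    return model.fit(constraint=constraint, init=init, n_starts=n_starts, seed=seed).params
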