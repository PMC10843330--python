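"""Double Kelvin-Voigt model of post-ablation tissue recoil.

A laser ablation removes a spring (elastic constant ``k``, the ablated cell
patch) from a circuit that also contains two Kelvin-Voigt elements in series
(springs ``kf``, ``ks``; dashpots ``eta_f``, ``eta_s``) under constant tissue
stress ``sigma``.  After the cut the bond displacement relaxes as a sum of two
saturating exponentials,

    dx(t) = Xf * (1 - exp(-t/tau_f)) + Xs * (1 - exp(-t/tau_s)),

with ``Xf = sigma*kappa/kf``, ``Xs = sigma*kappa/ks``, ``tau_f = eta_f/kf``,
``tau_s = eta_s/ks`` and ``kappa = k/(k + kbar)`` the fraction of the overall
circuit elasticity destroyed by the ablation (``kbar = kf*ks/(kf+ks)``).

Only the four observable combinations (Xf, Xs, tau_f, tau_s) are identifiable
from a recoil trace; the five mechanical parameters are constrained but not
unique.  Displacements are in micrometres, times in seconds; stresses and
elastic constants are in consistent arbitrary units (only ratios are
observable).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "MechanicalParams",
    "RelaxationParams",
    "DisplacementTrace",
    "FitResult",
    "FitError",
    "displacement",
    "relaxation_from_mechanics",
    "initial_recoil_velocity",
    "fast_fraction",
    "relaxed_fraction",
    "fit_relaxation",
    "compare_exponential_orders",
    "recoil_anisotropy",
    "active_stress",
]

#: First observed timepoint after the ablation (s); the movie is dark during
#: the cut itself, so the earliest displacement sample sits at this offset.
DEFAULT_GAP_S = 0.65


class FitError(RuntimeError):
    """Raised when a relaxation fit cannot be set up or is degenerate."""


@dataclass(frozen=True)
class MechanicalParams:
    """Pre-ablation mechanical state of the rheological circuit.

    All six parameters are strictly positive.  ``sigma`` is the constant
    tissue stress, ``k`` the spring removed by the ablation, ``kf``/``ks``
    and ``eta_f``/``eta_s`` the elastic constants and viscosities of the
    fast and slow Kelvin-Voigt elements.
    """

    sigma: float
    k: float
    kf: float
    ks: float
    eta_f: float
    eta_s: float

    def __post_init__(self) -> None:
        for name in ("sigma", "k", "kf", "ks", "eta_f", "eta_s"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")

    @property
    def kbar(self) -> float:
        """Series elasticity of the two KV elements, kf*ks/(kf+ks)."""
        return self.kf * self.ks / (self.kf + self.ks)

    @property
    def kappa(self) -> float:
        """Fraction of the overall elasticity destroyed by the ablation."""
        return self.k / (self.k + self.kbar)

    @property
    def x0(self) -> float:
        """Pre-ablation end-to-end distance, sigma/(k + kbar)."""
        return self.sigma / (self.k + self.kbar)


@dataclass(frozen=True)
class RelaxationParams:
    """The four observable recoil parameters (Xf, Xs in um; tau_f, tau_s in s).

    Canonical ordering ``tau_f <= tau_s`` is enforced on construction by
    swapping the (X, tau) pairs if needed; the model is symmetric under
    exchange of the two elements.
    """

    X_f: float
    X_s: float
    tau_f: float
    tau_s: float

    def __post_init__(self) -> None:
        for name in ("X_f", "X_s", "tau_f", "tau_s"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")
        if self.tau_f > self.tau_s:
            xf, xs, tf, ts = self.X_f, self.X_s, self.tau_f, self.tau_s
            object.__setattr__(self, "X_f", xs)
            object.__setattr__(self, "X_s", xf)
            object.__setattr__(self, "tau_f", ts)
            object.__setattr__(self, "tau_s", tf)

    @property
    def total_displacement(self) -> float:
        """Long-time displacement Xf + Xs (um)."""
        return self.X_f + self.X_s


def _ordered_relaxation(X_f: float, X_s: float, tau_f: float, tau_s: float) -> RelaxationParams:
    if tau_f > tau_s:
        X_f, X_s, tau_f, tau_s = X_s, X_f, tau_s, tau_f
    return RelaxationParams(X_f=X_f, X_s=X_s, tau_f=tau_f, tau_s=tau_s)


@dataclass
class DisplacementTrace:
    """Membrane displacement after ablation.

    ``times`` are seconds since the first post-ablation frame (the unobserved
    dark gap of duration ``delta_t`` precedes them, so model time is
    ``times + delta_t``).  ``displacements`` are um relative to the
    pre-ablation bond distance.
    """

    times: np.ndarray
    displacements: np.ndarray
    delta_t: float = DEFAULT_GAP_S
    orientation: str = "PD"
    genotype: str = ""
    specimen_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.displacements = np.asarray(self.displacements, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.displacements.shape:
            raise ValueError("times and displacements must be 1-D and equal length")
        if len(self.times) and self.times[0] < 0:
            raise ValueError("first time must be >= 0")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.displacements)):
            raise ValueError("displacements must be finite")
        if self.delta_t < 0:
            raise ValueError("delta_t must be >= 0")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class FitResult:
    """Outcome of a relaxation fit (model_order 1 = single, 2 = double exp)."""

    params: RelaxationParams | None
    residual_rms: float
    n_points: int
    converged: bool
    model_order: int
    flags: list[str] = field(default_factory=list)
    # single-exponential fits carry (X, tau) here; params holds a degenerate
    # RelaxationParams view with both elements identical for convenience
    single: tuple[float, float] | None = None

    def to_json(self) -> str:
        d = {
            "model_order": self.model_order,
            "residual_rms": self.residual_rms,
            "n_points": self.n_points,
            "converged": self.converged,
            "flags": self.flags,
        }
        if self.params is not None:
            d["params"] = dataclasses.asdict(self.params)
        if self.single is not None:
            d["single"] = {"X": self.single[0], "tau": self.single[1]}
        return json.dumps(d, indent=2)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


# ---------------------------------------------------------------------------
# forward model and derived proxies


def displacement(t, params: RelaxationParams):
    """Bond displacement dx(t) (um) at time(s) ``t`` (s) since ablation.

    Vectorised over ``t``; rejects negative times.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = params.X_f * (1.0 - np.exp(-t / params.tau_f)) + params.X_s * (
        1.0 - np.exp(-t / params.tau_s)
    )
    return out if out.ndim else float(out)


def relaxation_from_mechanics(mech: MechanicalParams) -> RelaxationParams:
    """Map the six mechanical parameters to the four observables.

    Xf = sigma*kappa/kf, Xs = sigma*kappa/ks, tau_f = eta_f/kf,
    tau_s = eta_s/ks.  The identity Xf + Xs = sigma/kbar - sigma/(k+kbar)
    (new minus old equilibrium length) holds by construction.
    """
    kappa = mech.kappa
    return _ordered_relaxation(
        X_f=mech.sigma * kappa / mech.kf,
        X_s=mech.sigma * kappa / mech.ks,
        tau_f=mech.eta_f / mech.kf,
        tau_s=mech.eta_s / mech.ks,
    )


def initial_recoil_velocity(params: RelaxationParams, delta_t: float = DEFAULT_GAP_S) -> float:
    """Initial recoil velocity v = dx(delta_t)/delta_t (um/s).

    The proxy used when only the first post-gap frame is analysed: mean
    displacement rate over the dark ablation interval.
    """
    if delta_t <= 0:
        raise ValueError("delta_t must be > 0")
    return displacement(delta_t, params) / delta_t


def fast_fraction(params: RelaxationParams, delta_t: float = DEFAULT_GAP_S) -> float:
    """Fraction of the initial recoil contributed by the fast element.

    Returns Xf(1-e^{-dt/tau_f}) / [Xf(1-e^{-dt/tau_f}) + Xs(1-e^{-dt/tau_s})],
    in (0, 1].  With the fast timescale comparable to ``delta_t`` and the
    slow one much longer, the fast element dominates the initial recoil.
    """
    if delta_t <= 0:
        raise ValueError("delta_t must be > 0")
    fast = params.X_f * relaxed_fraction(params.tau_f, delta_t)
    slow = params.X_s * relaxed_fraction(params.tau_s, delta_t)
    if fast + slow == 0:
        raise ValueError("no relaxation over delta_t; fraction undefined")
    return fast / (fast + slow)


def relaxed_fraction(tau: float, delta_t: float) -> float:
    """Fraction 1 - exp(-delta_t/tau) of an element's long-time displacement
    that has relaxed after ``delta_t`` seconds."""
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if delta_t < 0:
        raise ValueError("delta_t must be >= 0")
    return 1.0 - float(np.exp(-delta_t / tau))


def recoil_anisotropy(v_pd: float, v_ap: float) -> float:
    """Signed difference dv = v_PD - v_AP (um/s) between the two cut
    orientations; proportional to the shear stress along the PD axis."""
    if not (np.isfinite(v_pd) and np.isfinite(v_ap)):
        raise ValueError("velocities must be finite")
    return v_pd - v_ap


def active_stress(normalized_shear_stress: float, Q: float) -> float:
    """Normalized active anisotropic stress zeta/2K = sigma~/2K - Q.

    From the constitutive relation sigma~ = 2K*Q + zeta linking tissue shear
    stress to cell elongation; ``normalized_shear_stress`` is sigma~/2K as
    produced by an external stress-measurement method.
    """
    return normalized_shear_stress - Q


# ---------------------------------------------------------------------------
# fitting


def _model(t, delta_t, theta, order):
    tt = t + delta_t
    if order == 1:
        X, tau = theta
        return X * (1.0 - np.exp(-tt / tau))
    Xf, Xs, tf, ts = theta
    return Xf * (1.0 - np.exp(-tt / tf)) + Xs * (1.0 - np.exp(-tt / ts))


def _initial_guess(trace: DisplacementTrace, order: int):
    t = trace.times + trace.delta_t
    d = trace.displacements
    n_tail = max(1, len(d) // 10)
    d_final = float(np.mean(d[-n_tail:]))
    if d_final <= 0:
        d_final = max(float(np.max(d)), 1e-3)
    # first sample at >= 30% of the plateau estimates the fast timescale,
    # time-to-80% the slow one
    above = np.nonzero(d >= 0.3 * d_final)[0]
    tau_f0 = float(t[above[0]]) if len(above) else float(t[0])
    above80 = np.nonzero(d >= 0.8 * d_final)[0]
    tau_s0 = float(t[above80[0]]) if len(above80) else float(t[-1])
    tau_f0 = max(tau_f0, 1e-3)
    tau_s0 = max(tau_s0, 2 * tau_f0)
    if order == 1:
        return np.array([d_final, tau_s0])
    return np.array([0.2 * d_final, 0.8 * d_final, tau_f0, tau_s0])


def fit_relaxation(trace: DisplacementTrace, model_order: int = 2) -> FitResult:
    """Bounded least-squares fit of the recoil model to a displacement trace.

    Model time is ``trace.times + trace.delta_t`` (the dark ablation gap is
    unobserved).  Initialisation is deterministic and data-driven, so the fit
    is reproducible: the plateau is estimated from the last 10% of samples,
    tau_f from the first sample at 30% of the plateau, tau_s from the
    time-to-80%.  Fitted parameters are returned in canonical order
    ``tau_f <= tau_s``; fits where the two timescales agree within 5% are
    flagged ``effectively_single_exponential``.
    """
    if model_order not in (1, 2):
        raise ValueError("model_order must be 1 or 2")
    n_min = 3 if model_order == 1 else 5
    if len(trace) < n_min:
        raise FitError(f"need >= {n_min} points for model_order {model_order}")
    d = trace.displacements
    if np.allclose(d, d[0]):
        raise FitError("displacements are constant; nothing to fit")
    flags: list[str] = []
    if len(d) > 1 and np.all(np.diff(d) < 0):
        flags.append("monotone_decreasing_trace")

    theta0 = _initial_guess(trace, model_order)
    lo = np.full_like(theta0, 1e-9)
    hi = np.full_like(theta0, np.inf)

    def resid(theta):
        return _model(trace.times, trace.delta_t, theta, model_order) - d

    sol = least_squares(resid, theta0, bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12)
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    converged = bool(sol.success)
    if not converged:
        flags.append("did_not_converge")

    if model_order == 1:
        X, tau = map(float, sol.x)
        params = RelaxationParams(X_f=X / 2, X_s=X / 2, tau_f=tau, tau_s=tau)
        return FitResult(
            params=params,
            residual_rms=rms,
            n_points=len(trace),
            converged=converged,
            model_order=1,
            flags=flags,
            single=(X, tau),
        )

    Xf, Xs, tf, ts = map(float, sol.x)
    params = _ordered_relaxation(Xf, Xs, tf, ts)
    if abs(params.tau_s - params.tau_f) < 0.05 * params.tau_s:
        flags.append("effectively_single_exponential")
    return FitResult(
        params=params,
        residual_rms=rms,
        n_points=len(trace),
        converged=converged,
        model_order=2,
        flags=flags,
    )


def _aicc(rss: float, n: int, k: int) -> float:
    # Gaussian log-likelihood up to constants; k counts the noise variance too
    rss = max(rss, 1e-300)
    aic = n * np.log(rss / n) + 2 * k
    if n - k - 1 > 0:
        aic += 2 * k * (k + 1) / (n - k - 1)
    return float(aic)


def compare_exponential_orders(trace: DisplacementTrace) -> dict:
    """Fit single- and double-exponential models and pick one.

    Selection uses the small-sample corrected information criterion (AICc)
    on Gaussian residuals; a single graphical comparison cannot distinguish
    nested exponential models, but the criterion penalises the two extra
    parameters of the double fit.  Returns both fits, the RMS ratio and the
    preferred order.
    """
    fit1 = fit_relaxation(trace, model_order=1)
    fit2 = fit_relaxation(trace, model_order=2)
    n = len(trace)
    aicc1 = _aicc(n * fit1.residual_rms**2, n, 3)
    aicc2 = _aicc(n * fit2.residual_rms**2, n, 5)
    preferred = 2 if aicc2 < aicc1 else 1
    if "effectively_single_exponential" in fit2.flags:
        preferred = 1
    return {
        "fit_order1": fit1,
        "fit_order2": fit2,
        "rms_ratio": fit2.residual_rms / fit1.residual_rms if fit1.residual_rms else np.inf,
        "aicc_order1": aicc1,
        "aicc_order2": aicc2,
        "preferred_order": preferred,
    }
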