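"""Biophysical parameters of the voltage-dependent theta model.

The model describes quadratic integrate-and-fire (QIF) neurons written in
phase form.  The membrane potential V relates to the phase variable theta
through

    V = (V_R + V_T)/2 + (V_T - V_R)/2 * tan(theta / 2),

so that a spike (divergence of V and reset) corresponds to theta crossing pi.
All quantities use the unit system of the model table: time in ms, voltages
in mV, conductances in mS/cm^2, currents in uA/cm^2, capacitance in uF/cm^2.
Rates are kHz internally and converted to Hz only at reporting boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Optional, Union

import numpy as np

RngLike = Union[int, np.random.Generator, np.random.SeedSequence, None]


def as_rng(seed: RngLike) -> np.random.Generator:
    """Coerce an int / SeedSequence / Generator / None into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


class ParameterError(ValueError):
    """Raised when a parameter set violates the model's invariants."""


@dataclass
class BiophysicalParameters:
    """Default values reproduce the published table of the model.

    Conductance subscript convention: ``g_peak_XY`` is the peak conductance of
    synapses from population Y onto population X (E = excitatory,
    I = inhibitory).
    """

    C: float = 1.0            # membrane capacitance, uF/cm^2
    g_LE: float = 0.1         # leak conductance of E cells, mS/cm^2
    g_LI: float = 0.1         # leak conductance of I cells, mS/cm^2
    V_R: float = -62.0        # resting potential, mV
    V_T: float = -55.0        # threshold potential, mV
    V_E: float = 0.0          # excitatory reversal potential, mV
    V_I: float = -70.0        # inhibitory reversal potential, mV
    tau_d_E: float = 2.0      # excitatory synaptic decay, ms
    tau_d_I: float = 5.0      # inhibitory synaptic decay, ms
    g_peak_EE: float = 0.00407
    g_peak_EI: float = 0.02672   # I -> E
    g_peak_IE: float = 0.003276  # E -> I
    g_peak_II: float = 0.02138
    eta: float = 2.0          # Cauchy centre of background currents, uA/cm^2
    delta: float = 0.04       # Cauchy half-width, uA/cm^2
    N_E: int = 800
    N_I: int = 200

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (self.V_R < self.V_T):
            raise ParameterError(f"require V_R < V_T, got {self.V_R} >= {self.V_T}")
        if not (self.V_I < self.V_R):
            raise ParameterError(f"require V_I < V_R, got {self.V_I} >= {self.V_R}")
        if not (self.V_E > self.V_T):
            raise ParameterError(f"require V_E > V_T, got {self.V_E} <= {self.V_T}")
        for name in ("C", "g_LE", "g_LI", "tau_d_E", "tau_d_I",
                     "g_peak_EE", "g_peak_EI", "g_peak_IE", "g_peak_II"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.delta < 0:
            raise ParameterError("delta must be >= 0")
        if self.N_E < 1 or self.N_I < 1:
            raise ParameterError("population sizes must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "BiophysicalParameters":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ParameterError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)

    def with_overrides(self, **kw) -> "BiophysicalParameters":
        return replace(self, **kw)


@dataclass(frozen=True)
class DerivedConstants:
    """Coefficients of the phase-form equation.

    c0 (1/mV) scales injected currents, c1 and c2 (dimensionless) scale the
    excitatory and inhibitory conductance terms.  For the default potentials
    c0 = 2/7, c1 = 117/7, c2 = -23/7.
    """

    c0: float
    c1: float
    c2: float


def derive_constants(params: BiophysicalParameters) -> DerivedConstants:
    """c0 = 2/(V_T-V_R); c_X = (2 V_X - V_T - V_R)/(V_T - V_R) for X in {E, I}."""
    dv = params.V_T - params.V_R
    if dv == 0:
        raise ParameterError("V_T == V_R: phase transform is degenerate")
    c0 = 2.0 / dv
    c1 = (2.0 * params.V_E - params.V_T - params.V_R) / dv
    c2 = (2.0 * params.V_I - params.V_T - params.V_R) / dv
    return DerivedConstants(c0=c0, c1=c1, c2=c2)


def sample_background_currents(
    n: int,
    eta: float,
    delta: float,
    rng: RngLike = None,
    clip_quantile: Optional[float] = None,
) -> np.ndarray:
    """Draw i.i.d. Cauchy(eta, delta) background currents by inverse CDF.

    I = eta + delta * tan(pi (u - 1/2)), u ~ U(0, 1).  The heavy tails are
    intrinsic to the Lorentzian mean-field closure and are NOT truncated by
    default; ``clip_quantile`` (e.g. 1e-4) optionally clips both tails at the
    corresponding Cauchy quantiles for numerical-robustness experiments.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if delta < 0:
        raise ValueError("delta must be >= 0")
    rng = as_rng(rng)
    u = rng.uniform(0.0, 1.0, size=n)
    currents = eta + delta * np.tan(np.pi * (u - 0.5))
    if clip_quantile is not None:
        if not (0 < clip_quantile < 0.5):
            raise ValueError("clip_quantile must lie in (0, 0.5)")
        bound = delta * np.tan(np.pi * (0.5 - clip_quantile))
        np.clip(currents, eta - bound, eta + bound, out=currents)
    return currents


def rheobase(params: BiophysicalParameters, population: str = "E") -> float:
    """Current at which an isolated neuron starts firing: g_L (V_T - V_R)/4."""
    g_L = params.g_LE if population == "E" else params.g_LI
    return g_L * (params.V_T - params.V_R) / 4.0


def tonic_rate(params: BiophysicalParameters, I: float, population: str = "E") -> float:
    """Closed-form firing rate (kHz) of an isolated neuron at constant drive.

    For the QIF written as C dV/dt = a (V - V_m)^2 + b with
    a = g_L/(V_T - V_R), b = I - g_L (V_T - V_R)/4, the interspike interval is
    T = pi C / sqrt(a b); below rheobase (b <= 0) the rate is 0.
    """
    g_L = params.g_LE if population == "E" else params.g_LI
    a = g_L / (params.V_T - params.V_R)
    b = I - rheobase(params, population)
    if b <= 0:
        return 0.0
    return float(np.sqrt(a * b) / (np.pi * params.C))
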