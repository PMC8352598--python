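"""Model parameters and the contrast nonlinearity.

The hierarchical rivalry model has twelve constants: pool size ``N``, two
baseline Poisson rates (given in the literature as their inverses, in
seconds), two baseline potentials, six synaptic couplings, and the contrast
nonlinearity ``gamma``.  :class:`ModelParams` is the single source of truth
for these values; every simulation and statistic in the package reads them
from here.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass

import numpy as np

__all__ = ["ModelParams", "AltParams", "contrast_transfer"]


@dataclass(frozen=True)
class ModelParams:
    """Constants of the nested attractor model of binocular rivalry.

    Defaults are the fitted values for human observers.  Rates are stored as
    inverse rates (``inv_nu_e``, ``inv_nu_r``, seconds) because that is how
    they are usually tabulated; the ``nu_e``/``nu_r`` properties give the
    rates in Hz.

    Attributes
    ----------
    N : int
        Number of bistable variables per pool (evidence and decision pools
        share the same size).
    inv_nu_e, inv_nu_r : float
        Inverse baseline rates of evidence and decision variables (s).
    ue0, ur0 : float
        Baseline activation-energy offsets (dimensionless).
    w_vis : float
        Coupling of visual drive onto evidence pools.
    w_exc, w_inh : float
        Feedforward selective excitation and indiscriminate inhibition from
        evidence onto decision pools.
    w_comp, w_coop : float
        Lateral competition between, and cooperation within, decision pools.
    w_supp : float
        Feedback suppression from a decision pool onto its own evidence pool.
    gamma : float
        Parameter of the logarithmic contrast transfer function.
    """

    N: int = 25
    inv_nu_e: float = 1.95
    inv_nu_r: float = 0.018
    ue0: float = -1.65
    ur0: float = -4.94
    w_vis: float = 1.780
    w_exc: float = 152.2
    w_inh: float = 32.10
    w_comp: float = 33.4
    w_coop: float = 15.21
    w_supp: float = 2.34
    gamma: float = 0.071

    def __post_init__(self) -> None:
        if int(self.N) != self.N or self.N < 1:
            raise ValueError(f"N must be a positive integer, got {self.N}")
        if self.inv_nu_e <= 0 or self.inv_nu_r <= 0:
            raise ValueError("baseline inverse rates must be > 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")

    @property
    def nu_e(self) -> float:
        """Baseline rate of evidence variables (Hz)."""
        return 1.0 / self.inv_nu_e

    @property
    def nu_r(self) -> float:
        """Baseline rate of decision variables (Hz)."""
        return 1.0 / self.inv_nu_r

    def replace(self, **changes) -> "ModelParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


@dataclass(frozen=True)
class AltParams:
    """Constants of the competition + adaptation + colored-noise model.

    ``beta``, ``tau_r``, ``tau_n`` and ``kappa`` are conventionally fixed;
    adaptation strength/time constant and the contrast laws for input and
    noise amplitude are the free parameters.  Defaults are the published
    best-fit values.
    """

    beta: float = 10.0
    tau_r: float = 0.050
    tau_a: float = 22.78
    tau_n: float = 0.500
    phi_a: float = 18.39
    kappa: float = 0.1
    b_i: float = 2.92
    k_i: float = 1.52
    b_sigma: float = 0.19
    k_sigma: float = 0.57

    def __post_init__(self) -> None:
        if min(self.tau_r, self.tau_a, self.tau_n) <= 0:
            raise ValueError("time constants must be > 0")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")

    def replace(self, **changes) -> "AltParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AltParams":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


def contrast_transfer(c, gamma: float = ModelParams.gamma):
    """Logarithmic contrast transfer ``I = ln(1 + c/gamma) / ln(1 + 1/gamma)``.

    Maps image contrast ``c`` in [0, 1] onto normalized visual drive in
    [0, 1]; strictly increasing, with I(0) = 0 and I(1) = 1.

    Parameters
    ----------
    c : float or array_like
        Image contrast(s) in [0, 1].
    gamma : float
        Curvature of the nonlinearity (> 0); small values make the transfer
        more compressive.
    """
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    arr = np.asarray(c, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("contrast must lie in [0, 1]")
    out = np.log1p(arr / gamma) / math.log1p(1.0 / gamma)
    if np.isscalar(c) or arr.ndim == 0:
        return float(out)
    return out
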