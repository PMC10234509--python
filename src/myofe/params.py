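"""Material parameters of the three-element Hill-type muscle model.

The model describes muscle as a fiber-reinforced composite whose strain
energy splits into an isotropic exponential matrix part, a quadratic
volumetric penalty enforcing quasi-incompressibility, and a fiber part
carrying the parallel-elastic (PE), series-elastic (SEE) and contractile
(CE) elements.  :class:`MaterialParams` holds the full parameter vector;
the default constructor reproduces the calibrated rabbit tibialis-anterior
parameter set this model family was validated on.

All quantities are SI (Pa, s); millimetre-based inputs are converted at
I/O boundaries, never here.
"""

from __future__ import annotations

import dataclasses
import json
import math
from importlib import resources
from pathlib import Path

import yaml

from .errors import ConfigurationError

__all__ = ["MaterialParams", "load_params", "save_params", "default_params_path"]


@dataclasses.dataclass(frozen=True)
class MaterialParams:
    """Full parameter vector of the constitutive law.

    Parameters
    ----------
    D : float
        Compressibility constant [1/Pa] of the volumetric energy
        ``(1/D)(J-1)^2``.  Small values enforce quasi-incompressibility.
    b, c : float
        Dimensionless exponent and modulus [Pa] of the exponential
        isotropic matrix energy ``c(exp(b(I1bar-3)) - 1)``.
    A : float
        Dimensionless quadratic coefficient of the parallel element.
    sigma0 : float
        Maximum isometric fiber stress [Pa].
    alpha, beta : float
        Dimensionless exponent and modulus [Pa] of the series elastic
        element stress ``beta(exp(alpha(lambda_s - 1)) - 1)``.
    lambda_opt : float
        Optimal fiber stretch at which sarcomeres produce peak force.
    k : float
        Ratio of CE rest length to SEE rest length in the series pair.
    kc, ke : float
        Curvature constants of the concentric and eccentric branches of
        the force-velocity relation.
    d : float
        Eccentric offset (supra-isometric plateau level).
    lambda_dot_m_min : float
        Minimum (most negative) CE stretch rate [1/s]; force vanishes at
        maximal shortening speed.
    S : float
        Exponential activation rate factor [1/s].
    n1, n2 : float
        Baseline and peak activation levels in [0, 1].
    t0, t1 : float
        Activation onset and deactivation times [s].
    """

    D: float = 5.0e-9
    b: float = 15.0
    c: float = 3.79e2
    A: float = 4.0
    sigma0: float = 7.0e5
    alpha: float = 10.0
    beta: float = 1.0e3
    lambda_opt: float = 1.05
    k: float = 0.3
    kc: float = 4.0
    ke: float = 5.0
    d: float = 1.45
    lambda_dot_m_min: float = -1.7e1
    S: float = 5.0e1
    n1: float = 0.0
    n2: float = 1.0
    t0: float = 0.0
    t1: float = 1.0e6

    def __post_init__(self) -> None:
        positive = {
            "D": self.D, "c": self.c, "beta": self.beta, "sigma0": self.sigma0,
            "alpha": self.alpha, "k": self.k, "lambda_opt": self.lambda_opt,
        }
        for name, value in positive.items():
            if not (value > 0.0 and math.isfinite(value)):
                raise ConfigurationError(f"{name} must be positive, got {value!r}")
        if self.A < 0.0:
            raise ConfigurationError(f"A must be >= 0, got {self.A!r}")
        if not self.lambda_dot_m_min < 0.0:
            raise ConfigurationError(
                f"lambda_dot_m_min must be negative, got {self.lambda_dot_m_min!r}")
        if not (0.0 <= self.n1 <= self.n2 <= 1.0):
            raise ConfigurationError(
                f"need 0 <= n1 <= n2 <= 1, got n1={self.n1!r}, n2={self.n2!r}")
        if not self.t0 <= self.t1:
            raise ConfigurationError(
                f"need t0 <= t1, got t0={self.t0!r}, t1={self.t1!r}")

    def replace(self, **changes: float) -> "MaterialParams":
        """Return a copy with the given fields replaced (validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "MaterialParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{key: float(value) for key, value in data.items()})

    @classmethod
    def field_names(cls) -> tuple:
        return tuple(f.name for f in dataclasses.fields(cls))


def default_params_path():
    """Path-like handle to the packaged default parameter config."""
    return resources.files("myofe").joinpath("data/default_params.json")


def load_params(path: str | Path) -> MaterialParams:
    """Read a flat key/value JSON or YAML parameter file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in {".yaml", ".yml"}:
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise ConfigurationError(f"parameter file {path} must hold a flat mapping")
    return MaterialParams.from_dict(data)


def save_params(params: MaterialParams, path: str | Path) -> None:
    """Write parameters as flat JSON or YAML, keyed by field name."""
    path = Path(path)
    data = params.to_dict()
    if path.suffix.lower() in {".yaml", ".yml"}:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2) + "\n")
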