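"""Parametric sweeps and sensitivity tables for material calibration.

Replays the calibration workflow used to fix the adjustable constitutive
parameters (compressibility D, matrix b and c, force-velocity d, kc, ke,
and the isometric stress sigma0): one homogeneous elongation run per
parameter value, with summary outputs (stress at strain levels, peak
stress) tabulated against the parameter, plus normalized log-log
central-difference sensitivities.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json

import numpy as np
import pandas as pd

from .params import MaterialParams
from .uniaxial import ElongationProtocol, curve_metrics, run_elongation

__all__ = ["SweepSpec", "run_sweep", "sensitivity_table"]


@dataclasses.dataclass(frozen=True)
class SweepSpec:
    """One-parameter sweep over homogeneous elongation runs."""

    parameter: str
    values: tuple
    protocol: ElongationProtocol = ElongationProtocol.passive()
    outputs: tuple = ("stress_at_0.1", "peak_stress")
    strain_levels: tuple = (0.05, 0.1, 0.15, 0.2)

    def __post_init__(self) -> None:
        if self.parameter not in MaterialParams.field_names():
            raise ValueError(
                f"unknown material parameter {self.parameter!r}")
        if len(self.values) == 0:
            raise ValueError("empty sweep")


def _params_hash(params: MaterialParams) -> str:
    blob = json.dumps(params.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def run_sweep(spec: SweepSpec,
              baseline: MaterialParams | None = None) -> pd.DataFrame:
    """Run the sweep; one row per parameter value, deterministic order.

    Invalid parameter values are recorded as an error row and the sweep
    continues.  Each row carries the hash of the exact parameter set used
    (provenance for bit-reproducible reruns).
    """
    baseline = baseline or MaterialParams()
    rows = []
    for value in spec.values:
        row = {spec.parameter: value}
        try:
            params = baseline.replace(**{spec.parameter: value})
            curve = run_elongation(spec.protocol, params)
            metrics = curve_metrics(curve, spec.strain_levels)
            row.update({k: metrics[k] for k in spec.outputs})
            row["params_hash"] = _params_hash(params)
            row["error"] = ""
        except Exception as exc:  # recorded, sweep continues
            row.update({k: np.nan for k in spec.outputs})
            row["params_hash"] = ""
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)


def sensitivity_table(baseline: MaterialParams,
                      protocol: ElongationProtocol,
                      perturbation: float = 0.05,
                      parameters=("D", "b", "c", "d", "kc", "ke", "sigma0"),
                      output: str = "peak_stress",
                      strain_levels=(0.05, 0.1, 0.15, 0.2)) -> pd.DataFrame:
    """Normalized sensitivities d(log output)/d(log parameter).

    Central differences at +/- ``perturbation`` (fractional) around the
    baseline.  Outputs <= 0 at the baseline make the log sensitivity
    undefined; such rows are flagged rather than dropped.
    """
    if not 0.0 < perturbation <= 0.5:
        raise ValueError("perturbation fraction must be in (0, 0.5]")
    base_curve = run_elongation(protocol, baseline)
    y0 = curve_metrics(base_curve, strain_levels)[output]
    rows = []
    for name in parameters:
        x0 = getattr(baseline, name)
        try:
            hi = baseline.replace(**{name: x0 * (1.0 + perturbation)})
            lo = baseline.replace(**{name: x0 * (1.0 - perturbation)})
            y_hi = curve_metrics(run_elongation(protocol, hi),
                                 strain_levels)[output]
            y_lo = curve_metrics(run_elongation(protocol, lo),
                                 strain_levels)[output]
        except Exception as exc:
            rows.append({"parameter": name, "baseline": x0,
                         "sensitivity": np.nan, "defined": False,
                         "note": f"{type(exc).__name__}: {exc}"})
            continue
        if y0 <= 0.0 or y_hi <= 0.0 or y_lo <= 0.0:
            if abs(y_hi - y_lo) <= 1e-30:
                # dead branch: parameter has no pathway to the output
                rows.append({"parameter": name, "baseline": x0,
                             "sensitivity": 0.0, "defined": True,
                             "note": "no effect"})
            else:
                rows.append({"parameter": name, "baseline": x0,
                             "sensitivity": np.nan, "defined": False,
                             "note": "output <= 0; log sensitivity undefined"})
            continue
        dlog = (np.log(y_hi) - np.log(y_lo)) \
            / (np.log1p(perturbation) - np.log1p(-perturbation))
        rows.append({"parameter": name, "baseline": x0,
                     "sensitivity": float(dlog), "defined": True,
                     "note": ""})
    df = pd.DataFrame(rows)
    df.attrs["output"] = output
    df.attrs["baseline_hash"] = _params_hash(baseline)
    return df
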