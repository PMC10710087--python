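"""Kinetic parameters of the negative-feedback (linearizer) gene circuit.

The circuit couples a tetracycline repressor (TetR) to its own promoter:
TetR represses a two-operator promoter that drives a single mRNA encoding
both TetR and a fluorescent reporter (eGFP, standing in for the co-expressed
resistance gene).  Doxycycline (Dox) enters the cell, binds TetR and
releases repression, so external Dox tunes expression.

Units: time in hours, species in molecule counts per cell, Dox dose in
ng/mL mapped into an intracellular influx through ``f``.
"""

from __future__ import annotations

import dataclasses
import numbers
from dataclasses import dataclass
from importlib import resources
from typing import Any, Mapping

import yaml

__all__ = [
    "CircuitParameters",
    "ParameterError",
    "default_parameters",
    "default_calibration",
    "load_parameters",
    "save_parameters",
]

_RATE_FIELDS = (
    "m",
    "r",
    "k_off",
    "f",
    "g_dox",
    "k_seq_on",
    "k_seq_off",
    "k_tl_tetr",
    "k_tl_gfp",
    "d_m",
    "d_tetr",
    "d_gfp",
    "d_complex",
)


class ParameterError(ValueError):
    """Raised when a circuit parameter violates its constraints.

    Carries the offending field name in :attr:`field`.
    """

    def __init__(self, field: str, message: str):
        super().__init__(f"{field}: {message}")
        self.field = field


@dataclass(frozen=True)
class CircuitParameters:
    """All kinetic rates and conditions of the circuit model.

    Attributes
    ----------
    m : float
        Maximum transcription rate from an unbound promoter copy
        (mRNA molecules per hour per promoter).
    leak_r1, leak_r2 : float
        Leak fractions of ``m`` for the singly and doubly repressor-bound
        promoter states.  ``0 <= leak_r2 <= leak_r1 <= 1``.
    r : float
        TetR->operator association rate constant (per molecule per hour).
    k_off : float
        TetR-operator dissociation rate (per hour).
    f : float
        Dox cell-entry rate constant; intracellular influx is
        ``f * dox_ext`` molecules per hour.
    g_dox : float
        Intracellular Dox clearance rate (per hour).
    k_seq_on, k_seq_off : float
        TetR-Dox association (per molecule per hour) and dissociation
        (per hour) rates for repressor sequestration.
    k_tl_tetr, k_tl_gfp : float
        Translation rates of TetR and eGFP from the shared mRNA (per hour).
    d_m, d_tetr, d_gfp, d_complex : float
        First-order decay rates of mRNA, free TetR, eGFP and the TetR:Dox
        complex (per hour).
    copy_number : int
        Number of integrated promoter (DNA template) copies, ``>= 0``.
    dox_ext : float
        Extracellular Dox concentration (ng/mL), held constant.
    """

    m: float
    leak_r1: float
    leak_r2: float
    r: float
    k_off: float
    f: float
    g_dox: float
    k_seq_on: float
    k_seq_off: float
    k_tl_tetr: float
    k_tl_gfp: float
    d_m: float
    d_tetr: float
    d_gfp: float
    d_complex: float
    copy_number: int = 1
    dox_ext: float = 0.0

    def __post_init__(self) -> None:
        for name in _RATE_FIELDS:
            value = getattr(self, name)
            if not isinstance(value, numbers.Real) or isinstance(value, bool):
                raise ParameterError(name, f"must be a real number, got {value!r}")
            if value < 0:
                raise ParameterError(name, f"rate must be >= 0, got {value}")
        for name in ("leak_r1", "leak_r2"):
            value = getattr(self, name)
            if not isinstance(value, numbers.Real) or isinstance(value, bool):
                raise ParameterError(name, f"must be a real number, got {value!r}")
            if not 0.0 <= value <= 1.0:
                raise ParameterError(name, f"leak fraction must lie in [0, 1], got {value}")
        if self.leak_r2 > self.leak_r1:
            raise ParameterError(
                "leak_r2",
                f"doubly bound leak ({self.leak_r2}) cannot exceed singly bound leak ({self.leak_r1})",
            )
        cn = self.copy_number
        if isinstance(cn, bool) or not isinstance(cn, numbers.Integral):
            raise ParameterError("copy_number", f"must be an integer, got {cn!r}")
        if cn < 0:
            raise ParameterError("copy_number", f"must be >= 0, got {cn}")
        object.__setattr__(self, "copy_number", int(cn))
        if not isinstance(self.dox_ext, numbers.Real) or self.dox_ext < 0:
            raise ParameterError("dox_ext", f"must be a number >= 0, got {self.dox_ext!r}")

    def replace(self, **changes: Any) -> "CircuitParameters":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "CircuitParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(sorted(unknown)[0], "unknown parameter name")
        return cls(**dict(data))


def _load_default_config() -> dict[str, Any]:
    text = resources.files("linamp.data").joinpath("default_params.yaml").read_text()
    return yaml.safe_load(text)


def default_parameters() -> CircuitParameters:
    """The packaged default calibration of the circuit model."""
    return CircuitParameters.from_dict(_load_default_config()["parameters"])


def default_calibration() -> dict[str, Any]:
    """Calibration metadata: the Dox range over which the default dose
    response is designed to be approximately linear, and the default
    copy-number sweep conditions."""
    return dict(_load_default_config()["calibration"])


def load_parameters(path: str) -> CircuitParameters:
    """Load circuit parameters from a YAML file.

    The file may either be a flat mapping of parameter names or contain a
    top-level ``parameters`` section (as the packaged default file does).
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ParameterError("<file>", f"expected a mapping in {path}")
    if "parameters" in data:
        data = data["parameters"]
    return CircuitParameters.from_dict(data)


def save_parameters(params: CircuitParameters, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"parameters": params.to_dict()}, fh, sort_keys=True)
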