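"""Physical property estimates with units, uncertainty and provenance."""

from __future__ import annotations

from dataclasses import dataclass, field

#: Recognized property kinds.
PROPERTY_KINDS = ("dHvap", "kappa", "Cp", "alpha", "rho", "D")


@dataclass
class PropertyEstimate:
    """A physical property value with its uncertainty.

    value : in `units`
    std_error : same units; None for single runs with no error estimate
    n_repeats : number of independent runs behind the value
    property_kind : one of dHvap, kappa, Cp, alpha, rho, D
    units : unit string for `value`
    meta : free-form provenance (seeds, fit windows, alternates)
    """

    value: float
    property_kind: str
    units: str
    std_error: float | None = None
    n_repeats: int = 1
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.property_kind not in PROPERTY_KINDS:
            raise ValueError(f"unknown property_kind {self.property_kind!r}")
        if self.std_error is not None and self.std_error < 0:
            raise ValueError("std_error must be non-negative")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")

    def __str__(self) -> str:
        err = f" ± {self.std_error:.4g}" if self.std_error is not None else ""
        return f"{self.property_kind} = {self.value:.6g}{err} {self.units}"
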