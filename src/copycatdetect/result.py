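"""Common result container for the statistical test battery."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test.

    ``extras`` carries method-specific quantities (expected runs,
    degrees of freedom, pooled bin layout, ...) so every report cell is
    traceable to the operation that produced it.
    """

    method: str
    statistic: float
    p_value: float
    n: int
    extras: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or self.p_value != self.p_value):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_value < alpha

    def as_dict(self) -> dict[str, Any]:
        return {
            "method": self.method,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n": self.n,
            **self.extras,
        }
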