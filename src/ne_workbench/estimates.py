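"""Common return contract of every effective-size estimator."""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass
class NeEstimate:
    """Point estimate of effective size with uncertainty and metadata.

    ``point`` is ``math.inf`` when the drift signal is at or below its
    pure-sampling expectation (``infinite`` is then set).  ``adjusted``
    is filled only after a demographic bias correction was applied.
    """

    method: str
    point: float
    ci_low: float | None = None
    ci_high: float | None = None
    se: float | None = None
    adjusted: float | None = None
    cohort: str | None = None
    n: int | None = None
    infinite: bool = False
    notes: dict = field(default_factory=dict)

    def __post_init__(self):
        if math.isinf(self.point):
            self.infinite = True
        if (
            not self.infinite
            and self.ci_low is not None
            and self.ci_high is not None
            and self.ci_low > self.ci_high
        ):
            self.ci_low, self.ci_high = self.ci_high, self.ci_low

    @property
    def ci(self) -> tuple[float | None, float | None]:
        return (self.ci_low, self.ci_high)

    def fmt(self, digits: int = 1) -> str:
        if self.infinite:
            return "inf"
        s = f"{self.point:.{digits}f}"
        if self.ci_low is not None and self.ci_high is not None:
            s += f" ({self.ci_low:.{digits}f}; {self.ci_high:.{digits}f})"
        elif self.se is not None:
            s += f" +/- {self.se:.{digits}f}"
        return s
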