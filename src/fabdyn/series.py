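"""Uniformly sampled angle time series."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import SamplingError, ValidationError


@dataclass(frozen=True)
class AngleSeries:
    """An angle (or distance) time series with uniform sampling.

    Parameters
    ----------
    values:
        One value per frame. Degrees for angle measures, Å for ``dc``.
    dt_ps:
        Sampling interval in picoseconds, strictly positive.
    periodic:
        True for torsions/angles living on a circle (wrap at ±180°);
        False for aperiodic quantities such as the interdomain distance.
    name:
        Measure label (``elbow``, ``ch1cl``, ``HL``, ``dc``, ...).
    """

    values: np.ndarray
    dt_ps: float
    periodic: bool = True
    name: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1:
            raise ValidationError("AngleSeries values must be one-dimensional")
        if not np.all(np.isfinite(vals)):
            raise ValidationError("AngleSeries values must be finite")
        if not (self.dt_ps > 0):
            raise ValidationError(f"dt must be positive, got {self.dt_ps}")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.values.size

    @property
    def times_ps(self) -> np.ndarray:
        return np.arange(self.values.size) * self.dt_ps

    @property
    def duration_ns(self) -> float:
        return self.values.size * self.dt_ps / 1000.0

    def with_values(self, values: np.ndarray, **kwargs) -> "AngleSeries":
        return replace(self, values=np.asarray(values, dtype=float), **kwargs)

    def require_min_length(self, n: int) -> None:
        if len(self) < n:
            raise SamplingError(
                f"series '{self.name}' has {len(self)} samples, needs >= {n}"
            )
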