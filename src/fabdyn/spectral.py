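"""FFT power spectra and timescale-band decomposition of angle series.

The periodogram is one-sided and normalized so that the powers sum exactly
to the variance of the (unwrapped, demeaned) series — Parseval bookkeeping
is exact because no window function is applied (rectangular window). The
price is spectral leakage for lines that do not fall on the frequency grid;
band-integrated fractions, the quantity of interest here, are insensitive
to it.

Fluctuations are assigned to three period bands (default edges 0.1 ns and
10 ns): faster than the first edge, between the edges — the 0.1–10 GHz
regime of collective Fab interdomain motion — and slower than the second
edge. The zero-frequency component (the mean) belongs to the slow band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .config import AnalysisConfig
from .errors import SamplingError, ValidationError
from .series import AngleSeries

BAND_LABELS = ("fast", "middle", "slow")


def unwrap_periodic(series: AngleSeries) -> AngleSeries:
    """Remove ±180° wrap-around jumps from a periodic angle series.

    Successive differences are mapped into (−180°, +180°] and re-accumulated
    from the first value. Aperiodic series are returned unchanged.
    """
    if not series.periodic:
        return series
    vals = series.values
    diffs = np.diff(vals)
    wrapped = -((-diffs + 180.0) % 360.0 - 180.0)  # maps into (-180, 180]
    out = np.empty_like(vals)
    out[0] = vals[0]
    np.cumsum(wrapped, out=out[1:])
    out[1:] += vals[0]
    return series.with_values(out)


@dataclass(frozen=True)
class Spectrum:
    """One-sided periodogram of an angle series."""

    frequencies_ghz: np.ndarray
    power: np.ndarray            # deg² per bin; sums to total_variance
    total_variance: float        # deg²
    dt_ps: float
    n: int

    @property
    def periods_ns(self) -> np.ndarray:
        """Bin periods in ns; the DC bin maps to an infinite period."""
        with np.errstate(divide="ignore"):
            return 1.0 / self.frequencies_ghz


def power_spectrum(series: AngleSeries) -> Spectrum:
    """Periodogram of a series, normalized to the series variance.

    Periodic series are unwrapped first; the mean is removed internally.
    """
    series.require_min_length(8)
    x = unwrap_periodic(series).values
    n = x.size
    x = x - x.mean()
    coeffs = np.fft.rfft(x)
    power = np.abs(coeffs) ** 2 / n**2
    # one-sided: double everything except DC and (for even n) Nyquist
    power[1:] *= 2.0
    if n % 2 == 0:
        power[-1] /= 2.0
    # frequency grid: k / (n dt) in 1/ps = THz -> GHz
    freqs = np.fft.rfftfreq(n, d=series.dt_ps) * 1000.0
    return Spectrum(frequencies_ghz=freqs, power=power,
                    total_variance=float(np.var(x)), dt_ps=series.dt_ps, n=n)


def _band_masks(periods_ns: np.ndarray, band_edges_ns) -> dict[str, np.ndarray]:
    lo, hi = band_edges_ns
    return {
        "fast": periods_ns < lo,
        "middle": (periods_ns >= lo) & (periods_ns <= hi),
        "slow": periods_ns > hi,  # includes the infinite-period DC bin
    }


@dataclass(frozen=True)
class Band:
    label: str
    period_lo_ns: float          # inclusive lower period edge (0 = none)
    period_hi_ns: float          # exclusive upper period edge (inf = none)
    power: float                 # deg²
    power_fraction: float
    rms_amplitude: float         # deg, sqrt of band power


@dataclass(frozen=True)
class BandSummary:
    """Per-timescale-band power split of one series."""

    bands: tuple[Band, Band, Band]
    total_variance: float
    band_edges_ns: tuple[float, float]

    def fraction(self, label: str) -> float:
        for b in self.bands:
            if b.label == label:
                return b.power_fraction
        raise ValidationError(f"no band {label!r}")

    def as_dict(self) -> dict:
        return {
            b.label: {"power_fraction": b.power_fraction,
                      "rms_amplitude_deg": b.rms_amplitude}
            for b in self.bands
        }


def band_decompose(spec: Spectrum, cfg: AnalysisConfig | None = None) -> BandSummary:
    """Sum spectral power into the three timescale bands of the config."""
    cfg = cfg or AnalysisConfig()
    lo, hi = cfg.band_edges_ns
    resolvable_lo = 2 * spec.dt_ps / 1000.0          # Nyquist period
    resolvable_hi = spec.n * spec.dt_ps / 1000.0     # record length
    if lo < resolvable_lo or hi > resolvable_hi:
        warnings.warn(
            f"band edges {cfg.band_edges_ns} ns partly outside the resolvable "
            f"period range [{resolvable_lo:.4g}, {resolvable_hi:.4g}] ns",
            stacklevel=2)
    masks = _band_masks(spec.periods_ns, (lo, hi))
    total = spec.total_variance
    bands = []
    edges = {"fast": (0.0, lo), "middle": (lo, hi), "slow": (hi, np.inf)}
    for label in BAND_LABELS:
        p = float(spec.power[masks[label]].sum())
        frac = p / total if total > 0 else 0.0
        bands.append(Band(label=label, period_lo_ns=edges[label][0],
                          period_hi_ns=edges[label][1], power=p,
                          power_fraction=frac, rms_amplitude=float(np.sqrt(p))))
    return BandSummary(bands=tuple(bands), total_variance=total,
                       band_edges_ns=(lo, hi))


def band_filter(series: AngleSeries, band: str | tuple[float, float],
                cfg: AnalysisConfig | None = None) -> AngleSeries:
    """Hard spectral-mask filter: keep only components whose period falls in
    the requested band.

    ``band`` is either one of the labels 'fast'/'middle'/'slow' (edges taken
    from the config) or an explicit (period_lo_ns, period_hi_ns) interval.
    The series mean (DC) is kept only when the band contains infinite
    periods, i.e. the slow band or an explicit interval with an infinite
    upper edge.
    """
    cfg = cfg or AnalysisConfig()
    series.require_min_length(8)
    x_full = unwrap_periodic(series).values
    n = x_full.size
    mean = x_full.mean()
    coeffs = np.fft.rfft(x_full - mean)
    periods = Spectrum(
        frequencies_ghz=np.fft.rfftfreq(n, d=series.dt_ps) * 1000.0,
        power=np.zeros(coeffs.size), total_variance=0.0,
        dt_ps=series.dt_ps, n=n).periods_ns

    if isinstance(band, str):
        if band not in BAND_LABELS:
            raise ValidationError(f"unknown band {band!r}")
        mask = _band_masks(periods, cfg.band_edges_ns)[band]
        keep_mean = band == "slow"
    else:
        lo, hi = band
        if not (0 <= lo < hi):
            raise ValidationError(f"invalid period interval {band}")
        mask = (periods >= lo) & (periods <= hi)
        keep_mean = np.isinf(hi)
    out = np.fft.irfft(np.where(mask, coeffs, 0.0), n=n)
    if keep_mean:
        out = out + mean
    return series.with_values(out, periodic=False,
                              name=f"{series.name}[{band}]" if series.name else "")
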