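"""Per-site bulk-comparison statistics and the filters applied before windowing.

The allele frequency difference AFD = |f_high - f_low| measures how strongly
a biallelic site segregates between the two extreme-phenotype bulks.  Raising
it to a power > 1 (PowerAFD = AFD^4 by default, in the tradition of the
Euclidean-distance ED^4 statistic) shrinks the ubiquitous small background
differences toward zero while preserving the large differences produced by
linkage to a causal locus.

Two site filters precede the windowed scans:

* the *informative-frequency band*: a bulk frequency near 0.5 carries no
  segregation signal, so both bulks must lie outside the open band
  (``af_band_low``, ``af_band_high``) = (0.45, 0.55) by default;
* the *AFD threshold*: AFD >= ``afd_min`` (0.3 by default), inclusive.

All statistics are computed at full floating precision; rounding to 7
decimals happens only in the table writers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Union

import numpy as np

from .errors import ConfigurationError, DomainError

if TYPE_CHECKING:  # pragma: no cover
    from .sitetable_io import BulkSite

__all__ = ["ScanParams", "afd", "power_afd", "is_afd_snp", "passes_afd_threshold"]

ArrayLike = Union[float, np.ndarray]


@dataclass
class ScanParams:
    """Tunable thresholds of the per-site filters and the window scans.

    Attributes
    ----------
    af_band_low, af_band_high : float
        Edges of the uninformative bulk-frequency band; a site qualifies as
        an AFD-SNP only if each bulk frequency is <= ``af_band_low`` or
        >= ``af_band_high`` (both bounds inclusive).
    afd_min : float
        Minimum allele frequency difference, inclusive.
    power : float
        Exponent of :func:`power_afd`; 4 suppresses background noise.
    density_window_bp, density_step_bp : int
        Sliding-window geometry of the density scan (1 Mb windows advanced
        by 200 kb).
    min_density : float
        A window is flagged when its density strictly exceeds this many
        qualifying SNPs per Mb.
    var_window_snps, var_step_snps : int
        SNP-count window geometry of the variance scan (10 SNPs, step 5).
    dfscore_epsilon : float
        A window whose mean squared deviation from the genetic expectations
        is <= this value is flagged as a best window; the default 0.0025
        corresponds to a root-mean deviation of 0.05 frequency units.
    """

    af_band_low: float = 0.45
    af_band_high: float = 0.55
    afd_min: float = 0.3
    power: float = 4.0
    density_window_bp: int = 1_000_000
    density_step_bp: int = 200_000
    min_density: float = 30.0
    var_window_snps: int = 10
    var_step_snps: int = 5
    dfscore_epsilon: float = 0.0025

    def __post_init__(self) -> None:
        if not 0.0 <= self.af_band_low <= self.af_band_high <= 1.0:
            raise ConfigurationError(
                "require 0 <= af_band_low <= af_band_high <= 1, got "
                f"{self.af_band_low}, {self.af_band_high}"
            )
        if not 0.0 <= self.afd_min <= 1.0:
            raise ConfigurationError(f"afd_min must lie in [0, 1], got {self.afd_min}")
        if self.power < 1:
            raise ConfigurationError(f"power must be >= 1, got {self.power}")
        if self.density_window_bp <= 0 or self.var_window_snps <= 0:
            raise ConfigurationError("window sizes must be positive")
        if not 0 < self.density_step_bp <= self.density_window_bp:
            raise ConfigurationError("require 0 < density_step_bp <= density_window_bp")
        if not 0 < self.var_step_snps <= self.var_window_snps:
            raise ConfigurationError("require 0 < var_step_snps <= var_window_snps")


def _check_freq(name: str, f: ArrayLike) -> np.ndarray:
    arr = np.asarray(f, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise DomainError(f"{name} must lie in [0, 1], got {f!r}")
    return arr


def afd(f_high: ArrayLike, f_low: ArrayLike) -> ArrayLike:
    """Allele frequency difference |f_high - f_low| between the paired bulks.

    Accepts scalars or numpy arrays; both frequencies must lie in [0, 1].
    """
    fh = _check_freq("f_high", f_high)
    fl = _check_freq("f_low", f_low)
    out = np.abs(fh - fl)
    return float(out) if out.ndim == 0 else out


def power_afd(f_high: ArrayLike, f_low: ArrayLike, power: float = 4.0) -> ArrayLike:
    """|f_high - f_low| ** power (default power 4).

    With power 4 a background difference of 0.3 contributes only 0.0081
    while a linked-signal difference of 0.9 retains 0.656.
    """
    if power < 1:
        raise DomainError(f"power must be >= 1, got {power}")
    out = np.asarray(afd(f_high, f_low)) ** power
    return float(out) if out.ndim == 0 else out


def _outside_band(f: float, params: ScanParams) -> bool:
    return f <= params.af_band_low or f >= params.af_band_high


def is_afd_snp(site: "BulkSite", params: ScanParams | None = None) -> bool:
    """Does a site qualify for the density scan?

    True iff each bulk frequency lies outside the open uninformative band
    (band edges inclusive on the outside) and the site's AFD is nonzero.
    """
    params = params or ScanParams()
    return (
        _outside_band(site.f_high, params)
        and _outside_band(site.f_low, params)
        and afd(site.f_high, site.f_low) > 0.0
    )


def passes_afd_threshold(site: "BulkSite", params: ScanParams | None = None) -> bool:
    """True iff the site's AFD is >= ``params.afd_min`` (inclusive)."""
    params = params or ScanParams()
    return afd(site.f_high, site.f_low) >= params.afd_min
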