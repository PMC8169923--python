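"""Bulk allele-frequency expectations under classical cross designs.

In bulked-segregant analysis the alternate-allele frequency observed in an
extreme-phenotype bulk is, at a marker tightly linked to the causal locus,
pinned to one of a small set of Mendelian values determined by the cross
design and by the role the bulk plays:

* **F2 intercross** (F1 x F1).  If the trait allele is dominant, the bulk of
  individuals showing the dominant phenotype contains AA and Aa genotypes in
  a 1:2 ratio, so the trait-allele frequency is 2/3 (and 1/3 for the other
  allele); the recessive bulk is fixed, frequency 0 or 1.
* **Homozygous bulks**.  When both extreme bulks are composed of homozygous
  individuals (e.g. after repeated selfing or when selection is extreme
  enough), each bulk is fixed at 0 or 1.
* **Backcross** to a homozygous recurrent parent.  Progeny are Aa or aa (one
  haplotype is always the recurrent-parent allele), so a bulk's frequency at
  a linked marker is 1/2 when the segregating haplotype class is absent,
  1 when it is fixed, and 1/2 or 1 (or 0 for the opposite allele) in
  between; the admissible set is {0, 1/2, 1}.

Away from any causal locus the bulk frequencies drift toward the unselected
population value; the distance of an observed frequency from its *nearest*
admissible value is therefore the per-site building block of the windowed
goodness-of-fit score (:func:`bsascan.window_scans.variance_scan`).

Expected values are stored as :class:`fractions.Fraction` so that 1/3 is
exact, never a decimal rounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Tuple

from .errors import ConfigurationError, DomainError

__all__ = ["ExpectationSet", "expectation_set", "nearest_deviation", "VALID_PAIRS"]


@dataclass(frozen=True)
class ExpectationSet:
    """The admissible bulk allele frequencies for one (design, role) pair.

    ``values`` is sorted ascending and holds exact rationals.
    """

    design: str
    role: str
    values: Tuple[Fraction, ...]

    def __post_init__(self) -> None:
        if not self.values:
            raise ConfigurationError("ExpectationSet requires at least one value")
        vals = tuple(sorted(Fraction(v) for v in self.values))
        if vals[0] < 0 or vals[-1] > 1:
            raise ConfigurationError(f"expected frequencies must lie in [0, 1]: {vals}")
        object.__setattr__(self, "values", vals)

    def __contains__(self, f: object) -> bool:
        try:
            return any(Fraction(f) == v for v in self.values)  # type: ignore[arg-type]
        except (TypeError, ValueError):
            return False


# (design, role) -> admissible frequencies of the ALT (trait-associated) allele
_EXPECTATIONS = {
    ("f2_intercross", "dominant_bulk"): (Fraction(1, 3), Fraction(2, 3)),
    ("f2_intercross", "recessive_bulk"): (Fraction(0), Fraction(1)),
    ("homozygous_bulks", "high_bulk"): (Fraction(0), Fraction(1)),
    ("homozygous_bulks", "low_bulk"): (Fraction(0), Fraction(1)),
    ("backcross", "high_bulk"): (Fraction(0), Fraction(1, 2), Fraction(1)),
    ("backcross", "low_bulk"): (Fraction(0), Fraction(1, 2), Fraction(1)),
}

VALID_PAIRS = tuple(sorted(_EXPECTATIONS))


def expectation_set(design: str, role: str) -> ExpectationSet:
    """Return the fixed admissible-frequency set for a design/role pair.

    Parameters
    ----------
    design : {"f2_intercross", "homozygous_bulks", "backcross"}
    role : {"dominant_bulk", "recessive_bulk", "high_bulk", "low_bulk"}

    Raises
    ------
    ConfigurationError
        If the pair is not recognized; the message lists the valid pairs.
    """
    key = (str(design).lower(), str(role).lower())
    try:
        values = _EXPECTATIONS[key]
    except KeyError:
        valid = ", ".join(f"{d}/{r}" for d, r in VALID_PAIRS)
        raise ConfigurationError(
            f"unknown design/role pair {key[0]!r}/{key[1]!r}; valid pairs: {valid}"
        ) from None
    return ExpectationSet(design=key[0], role=key[1], values=values)


def nearest_deviation(f: float, exp: ExpectationSet) -> Tuple[float, float]:
    """Nearest admissible frequency to ``f`` and the absolute deviation.

    Ties (``f`` equidistant from two admissible values) break toward the
    *smaller* expected value, deterministically; the deviation is identical
    either way.

    Returns ``(nearest, |f - nearest|)`` with the deviation in [0, 0.5].
    """
    f = float(f)
    if not 0.0 <= f <= 1.0:
        raise DomainError(f"frequency must lie in [0, 1], got {f}")
    best = None
    best_dev = None
    for e in exp.values:  # ascending: first minimum wins ties with smaller value
        dev = abs(f - float(e))
        if best_dev is None or dev < best_dev:
            best, best_dev = float(e), dev
    assert best is not None and best_dev is not None
    return best, best_dev
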