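"""Closed-form mosaic mixture model for SNP-array signals.

A mosaic aberration carried by a fraction ``f`` of cells in a bulk sample
shifts two array observables:

* the B-allele frequency (BAF) of constitutionally heterozygous probes
  splits symmetrically around 0.5 by an amount ``delta`` that depends on the
  aberration class and on ``f``;
* the log R ratio (LRR, log2 total-intensity ratio) shifts by an amount
  proportional to the log2 change in total copy number.

The three aberration classes form a complete partition of the events this
model covers: single-copy gains (2 -> 3 copies in carrier cells), single-copy
deletions (2 -> 1), and copy-number-neutral loss of heterozygosity (CNNLOH,
2 -> 2 with one parental homolog duplicated and the other lost).

For carrier fraction ``f`` the expected B-allele dosage at a het probe is

* GAIN:    B reads ``(1+f)`` of ``(2+f)`` alleles  ->  delta = (1+f)/(2+f) - 1/2
* DEL:     B reads ``1`` of ``(2-f)`` alleles      ->  delta = 1/(2-f) - 1/2
* CNNLOH:  B reads ``(1+f)`` of ``2`` alleles      ->  delta = f/2

and the expected LRR is ``c * log2((2 + k*f)/2)`` with ``k`` = +1 (GAIN),
-1 (DEL), 0 (CNNLOH); ``c`` is a platform response (attenuation) factor,
1.0 for ideal data.

The inverse map (``estimate_fraction``) recovers ``f`` from an observed BAF
split; it is exact (a round trip through ``expected_baf_split`` is identity
to machine precision).  For GAIN a split above 1/6 cannot be produced by a
single-copy gain at any ``f`` <= 1 and is flagged as a multi-copy
amplification, with the estimate clipped to 1.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

__all__ = [
    "AberrationClass",
    "MosaicParams",
    "FractionEstimate",
    "expected_baf_split",
    "expected_lrr_shift",
    "estimate_fraction",
]


class AberrationClass(str, enum.Enum):
    """The three mosaic aberration classes scored by the pipeline."""

    GAIN = "GAIN"
    DEL = "DEL"
    CNNLOH = "CNNLOH"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @property
    def copy_delta(self) -> int:
        """Signed copy-number change ``k`` in carrier cells (+1, -1, 0)."""
        return {"GAIN": 1, "DEL": -1, "CNNLOH": 0}[self.value]


@dataclass(frozen=True)
class MosaicParams:
    """Mosaic state of one aberration: carrier fraction and LRR response.

    Parameters
    ----------
    f
        Fraction of cells carrying the aberration, in [0, 1].
    c
        Dimensionless LRR response factor (> 0).  Real Illumina LRR is
        attenuated relative to the ideal log2 copy ratio; 1.0 means no
        attenuation and is the self-consistent default for synthetic data.
    """

    f: float
    c: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"cell fraction f={self.f} outside [0, 1]")
        if not self.c > 0.0:
            raise ValueError(f"LRR response factor c={self.c} must be > 0")


@dataclass(frozen=True)
class FractionEstimate:
    """Result of inverting a BAF split into a cell fraction."""

    fraction: float
    #: True when the observed split exceeds the single-copy GAIN maximum
    #: (1/6) and the estimate was clipped to 1 — a multi-copy amplification.
    clipped: bool = False


def _check_fraction(f: float) -> None:
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"cell fraction f={f} outside [0, 1]")


def expected_baf_split(cls: AberrationClass, f: float) -> float:
    """Expected absolute deviation of het-probe BAF from 0.5.

    Strictly increasing in ``f`` for every class, 0 at ``f`` = 0, and at
    ``f`` = 1 reaches 1/6 (GAIN), 1/2 (DEL), 1/2 (CNNLOH).
    """
    _check_fraction(f)
    cls = AberrationClass(cls)
    if cls is AberrationClass.GAIN:
        return (1.0 + f) / (2.0 + f) - 0.5
    if cls is AberrationClass.DEL:
        return 1.0 / (2.0 - f) - 0.5
    return f / 2.0


def expected_lrr_shift(cls: AberrationClass, f: float, c: float = 1.0) -> float:
    """Expected mean LRR of a segment carrying the aberration.

    ``c * log2((2 + k*f)/2)`` with ``k`` the class's signed copy change;
    identically 0 for CNNLOH.
    """
    _check_fraction(f)
    if not c > 0.0:
        raise ValueError(f"LRR response factor c={c} must be > 0")
    k = AberrationClass(cls).copy_delta
    if k == 0:
        return 0.0
    return c * math.log2((2.0 + k * f) / 2.0)


#: Largest BAF split a single-copy gain can produce (f = 1).
GAIN_MAX_SPLIT = 1.0 / 6.0


def estimate_fraction(cls: AberrationClass, delta: float) -> FractionEstimate:
    """Invert an observed het-BAF split into a carrier cell fraction.

    CNNLOH: f = 2*delta;  DEL: f = 4*delta/(1 + 2*delta);
    GAIN: f = 4*delta/(1 - 2*delta), clipped to 1 (and flagged) for
    delta > 1/6, which no single-copy gain can reach.
    """
    if not 0.0 <= delta <= 0.5:
        raise ValueError(f"BAF split delta={delta} outside [0, 0.5]")
    cls = AberrationClass(cls)
    if cls is AberrationClass.CNNLOH:
        return FractionEstimate(2.0 * delta)
    if cls is AberrationClass.DEL:
        return FractionEstimate(4.0 * delta / (1.0 + 2.0 * delta))
    # GAIN
    if delta > GAIN_MAX_SPLIT:
        return FractionEstimate(1.0, clipped=True)
    f = 4.0 * delta / (1.0 - 2.0 * delta)
    return FractionEstimate(min(f, 1.0))


def lrr_implied_fraction(cls: AberrationClass, lrr: float, c: float = 1.0) -> float:
    """Carrier fraction implied by a segment's mean LRR (consistency check).

    Inverts ``expected_lrr_shift``; returns NaN for CNNLOH (LRR carries no
    information) and clips to [0, 1].
    """
    if not c > 0.0:
        raise ValueError(f"LRR response factor c={c} must be > 0")
    k = AberrationClass(cls).copy_delta
    if k == 0:
        return math.nan
    f = k * (2.0 ** (lrr / c) * 2.0 - 2.0)
    return min(max(f, 0.0), 1.0)
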