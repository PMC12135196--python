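"""Closed-form estimators of genetic parameters from predictivity.

Predictivity ``c`` is the Pearson correlation between validation animals'
phenotypes adjusted for fixed effects, ``y - Xb``, and their (G)EBVs computed
without those phenotypes.  Two classic results about genomic accuracy,

    acc = c / h                       (accuracy from predictivity)
    acc = sqrt(N h^2 / (N h^2 + Me))  (expected accuracy from population theory)

share the unknown heritability ``h^2``; equating them yields a closed-form
heritability estimator that needs only ``c``, the reference size ``N``, and the
number of independent chromosome segments ``Me``:

    h2_hat = ( c^2 + sqrt(c^4 + 4 c^2 Me / N) ) / 2.

Cross-trait predictivity (phenotype of trait i against GEBV of trait j)
similarly identifies the genetic correlation:

    r_g = Corr(y_i - X b_i, u_hat_j) / (h_i * acc_j).

All functions here are pure and accept scalars or equally shaped arrays;
vectorized output equals elementwise scalar evaluation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .errors import ClampWarning, InflatedAccuracyWarning, InvalidInputError

__all__ = [
    "PredictivityRecord",
    "HeritabilityEstimate",
    "AccuracyEstimate",
    "GeneticCorrelationEstimate",
    "h2_from_predictivity",
    "acc_from_predictivity",
    "expected_accuracy",
    "gencorr_from_predictivity",
    "se_accuracy",
    "se_gencorr",
    "se_h2",
    "min_reference_size",
]

Number = Union[float, np.ndarray]


def _asfloat(x, name: str) -> Number:
    a = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(a)):
        raise InvalidInputError(f"{name} must be finite, got {x!r}")
    return a if a.ndim else float(a)


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise InvalidInputError(msg)


def _maybe_scalar(a: np.ndarray) -> Number:
    return float(a) if np.ndim(a) == 0 else a


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PredictivityRecord:
    """A validation-set correlation between adjusted phenotypes of ``trait_pheno``
    and GEBVs of ``trait_ebv``."""

    c: float
    trait_pheno: str
    trait_ebv: str
    n_validation: int
    window_id: Optional[str] = None

    def __post_init__(self):
        _check(math.isfinite(self.c) and abs(self.c) <= 1.0,
               f"predictivity must be a finite correlation in [-1, 1], got {self.c}")
        _check(self.n_validation >= 4,
               f"n_validation must be >= 4, got {self.n_validation}")


@dataclass(frozen=True)
class HeritabilityEstimate:
    h2: Number
    se: Optional[Number]
    c_used: Number
    n_reference: Number
    me_used: Number
    raw: Number = field(repr=False, default=None)  # pre-clamp value


@dataclass(frozen=True)
class AccuracyEstimate:
    acc: Number
    source: str  # "from_predictivity" (c/h) or "expected" (sqrt(Nh2/(Nh2+Me)))
    se: Optional[Number] = None
    raw: Number = field(repr=False, default=None)


@dataclass(frozen=True)
class GeneticCorrelationEstimate:
    r_g: Number
    trait_pheno: str
    trait_ebv: str
    se: Optional[Number] = None
    window_id: Optional[str] = None
    raw: Number = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------


def h2_from_predictivity(c, n_reference, me, n_validation=None) -> HeritabilityEstimate:
    """Heritability from predictivity, reference size and segment count.

    h2_hat = ( c^2 + sqrt(c^4 + 4 c^2 Me / N) ) / 2

    Parameters
    ----------
    c : float or array
        Predictivity Corr(y - Xb, u_hat) on the validation set, in [-1, 1].
    n_reference : int or array
        N, individuals with both genotype and phenotype in the reference set.
    me : float or array
        Number of independent chromosome segments.
    n_validation : int, optional
        If given, a standard error is attached via :func:`se_h2` (requires c > 0;
        the SE is undefined at c = 0 and reported as NaN there).
    """
    c = _asfloat(c, "c")
    n_ref = _asfloat(n_reference, "n_reference")
    me = _asfloat(me, "me")
    _check(np.all(np.abs(c) <= 1.0), f"|c| must be <= 1, got {c!r}")
    _check(np.all(np.asarray(n_ref) >= 1), "n_reference must be >= 1")
    _check(np.all(np.asarray(me) > 0), "me must be > 0")

    ratio = np.asarray(me, dtype=float) / np.asarray(n_ref, dtype=float)
    c2 = np.square(c)
    raw = 0.5 * (c2 + np.sqrt(np.square(c2) + 4.0 * c2 * ratio))
    if np.any(raw > 1.0):
        warnings.warn(f"heritability estimate {raw!r} exceeds 1; clamped", ClampWarning,
                      stacklevel=2)
    h2 = np.clip(raw, 0.0, 1.0)

    se = None
    if n_validation is not None:
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.where(np.abs(np.asarray(c, dtype=float)) > 0,
                          _se_h2_raw(np.abs(c), n_validation, me, n_ref), np.nan)
        se = _maybe_scalar(se)
    return HeritabilityEstimate(h2=_maybe_scalar(h2), se=se, c_used=c,
                                n_reference=n_reference, me_used=me,
                                raw=_maybe_scalar(np.asarray(raw)))


def acc_from_predictivity(c, h2) -> AccuracyEstimate:
    """Accuracy of the GEBVs from predictivity: acc = c / sqrt(h2).

    Values above 1 indicate an inconsistency (e.g. an understated heritability
    or overstated Me); they are clamped and a warning is raised.
    """
    c = _asfloat(c, "c")
    h2 = _asfloat(h2, "h2")
    _check(np.all(np.asarray(h2) > 0) and np.all(np.asarray(h2) <= 1.0),
           f"h2 must be in (0, 1], got {h2!r}")
    raw = np.asarray(c, dtype=float) / np.sqrt(h2)
    if np.any(raw > 1.0):
        warnings.warn(f"predictivity-implied accuracy {raw!r} exceeds 1; clamped",
                      InflatedAccuracyWarning, stacklevel=2)
    acc = np.clip(raw, 0.0, 1.0)
    return AccuracyEstimate(acc=_maybe_scalar(acc), source="from_predictivity",
                            raw=_maybe_scalar(raw))


def expected_accuracy(n_reference, h2, me) -> AccuracyEstimate:
    """Expected accuracy from population theory: sqrt(N h2 / (N h2 + Me))."""
    n_ref = _asfloat(n_reference, "n_reference")
    h2 = _asfloat(h2, "h2")
    me = _asfloat(me, "me")
    _check(np.all(np.asarray(n_ref) >= 0), "n_reference must be >= 0")
    _check(np.all((np.asarray(h2) >= 0) & (np.asarray(h2) <= 1)), "h2 must be in [0, 1]")
    _check(np.all(np.asarray(me) > 0), "me must be > 0")
    nh2 = np.asarray(n_ref, dtype=float) * np.asarray(h2, dtype=float)
    acc = np.sqrt(nh2 / (nh2 + np.asarray(me, dtype=float)))
    return AccuracyEstimate(acc=_maybe_scalar(acc), source="expected",
                            raw=_maybe_scalar(acc))


def gencorr_from_predictivity(c_cross, h2_i, acc_j, n_validation=None,
                              trait_pheno: str = "i", trait_ebv: str = "j",
                              window_id: Optional[str] = None) -> GeneticCorrelationEstimate:
    """Genetic correlation from cross-trait predictivity.

    r_g = Corr(y_i - X b_i, u_hat_j) / (h_i * acc_j),  h_i = sqrt(h2_i).

    The raw (possibly out-of-range) value is retained in ``raw``; the clamped
    copy lies in [-1, 1].  Note the two trait orderings (i, j) and (j, i) are
    asymptotically equal but differ in finite samples, and their SEs differ.
    """
    c = _asfloat(c_cross, "c_cross")
    h2_i = _asfloat(h2_i, "h2_i")
    acc_j = _asfloat(acc_j, "acc_j")
    _check(np.all(np.abs(np.asarray(c)) <= 1.0), "|c_cross| must be <= 1")
    _check(np.all(np.asarray(h2_i) > 0), "h2_i must be > 0 for an identifiable correlation")
    _check(np.all(np.asarray(acc_j) > 0), "acc_j must be > 0 for an identifiable correlation")
    raw = np.asarray(c, dtype=float) / (np.sqrt(h2_i) * np.asarray(acc_j, dtype=float))
    if np.any(np.abs(raw) > 1.0):
        warnings.warn(f"genetic correlation estimate {raw!r} outside [-1, 1]; clamped",
                      ClampWarning, stacklevel=2)
    r_g = np.clip(raw, -1.0, 1.0)
    se = se_gencorr(h2_i, acc_j, n_validation) if n_validation is not None else None
    return GeneticCorrelationEstimate(r_g=_maybe_scalar(r_g), trait_pheno=trait_pheno,
                                      trait_ebv=trait_ebv, se=se, window_id=window_id,
                                      raw=_maybe_scalar(raw))


# ---------------------------------------------------------------------------
# Standard errors
# ---------------------------------------------------------------------------


def _check_nval(n_validation) -> Number:
    n = _asfloat(n_validation, "n_validation")
    _check(np.all(np.asarray(n) >= 4), "n_validation must be >= 4")
    return n


def se_accuracy(h2_i, n_validation) -> Number:
    """Upper bound on the SE of the predictivity-based accuracy: 1 / (h_i sqrt(n))."""
    h2_i = _asfloat(h2_i, "h2_i")
    _check(np.all(np.asarray(h2_i) > 0), "h2_i must be > 0")
    n = _check_nval(n_validation)
    return _maybe_scalar(1.0 / (np.sqrt(h2_i) * np.sqrt(n)))


def se_gencorr(h2_i, acc_j, n_validation) -> Number:
    """Upper bound on the SE of the genetic-correlation estimate:
    1 / (h_i * acc_j * sqrt(n)).  Swapping the trait roles changes the value."""
    h2_i = _asfloat(h2_i, "h2_i")
    acc_j = _asfloat(acc_j, "acc_j")
    _check(np.all(np.asarray(h2_i) > 0), "h2_i must be > 0")
    _check(np.all(np.asarray(acc_j) > 0), "acc_j must be > 0")
    n = _check_nval(n_validation)
    return _maybe_scalar(1.0 / (np.sqrt(h2_i) * np.asarray(acc_j, dtype=float) * np.sqrt(n)))


def _se_h2_raw(c, n_validation, me, n_reference):
    k = np.asarray(me, dtype=float) / np.asarray(n_reference, dtype=float)
    c = np.asarray(c, dtype=float)
    bracket = c + (2.0 * c * c + 4.0 * k) / np.sqrt(c * c + 4.0 * k)
    return bracket / (2.0 * np.sqrt(np.asarray(n_validation, dtype=float)))


def se_h2(c, n_validation, me, n_reference) -> Number:
    """Linear-approximation SE of the heritability estimate,

    SE(h2_hat) ~= (1 / (2 sqrt(n))) * [ c + (2c^2 + 4 Me/N) / sqrt(c^2 + 4 Me/N) ],

    which for N >> Me collapses to 1.5 c / sqrt(n).  Undefined at c = 0
    (the estimator's slope degenerates there); c must be strictly positive.
    """
    c = _asfloat(c, "c")
    _check(np.all(np.asarray(c) > 0), "se_h2 requires c > 0")
    _check(np.all(np.abs(np.asarray(c)) <= 1.0), "|c| must be <= 1")
    me = _asfloat(me, "me")
    n_ref = _asfloat(n_reference, "n_reference")
    _check(np.all(np.asarray(me) > 0), "me must be > 0")
    _check(np.all(np.asarray(n_ref) >= 1), "n_reference must be >= 1")
    n = _check_nval(n_validation)
    return _maybe_scalar(np.asarray(_se_h2_raw(c, n, me, n_ref)))


def min_reference_size(me, h2) -> int:
    """Minimum reference-population size N > Me / (3 h2); integer ceiling.

    This is the regime in which the expected-accuracy formula is robust to the
    assumed Me (the rule's boundary N h2 = Me/3 corresponds to an expected
    accuracy of 0.5; comfortably above it, accuracy approaches its asymptote).
    """
    me = _asfloat(me, "me")
    h2 = _asfloat(h2, "h2")
    _check(np.all(np.asarray(me) > 0), "me must be > 0")
    _check(np.all(np.asarray(h2) > 0), "h2 must be > 0")
    n = np.ceil(np.asarray(me, dtype=float) / (3.0 * np.asarray(h2, dtype=float)))
    return int(n) if np.ndim(n) == 0 else n.astype(int)
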