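"""Number of independent chromosome segments (Me).

Me governs the asymptote of genomic prediction accuracy.  Two estimates are
provided: the population-parameter rule Me = 4 Ne L (Ne effective population
size, L genome length in Morgans) and the spectral rule counting how many
eigenvalues of the genomic relationship matrix explain a given fraction
(default 98%) of its variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import DegenerateInputError, InvalidInputError
from .gblup import GRM

__all__ = ["SegmentsEstimate", "me_from_ne_l", "me_from_grm_eigenvalues"]


@dataclass(frozen=True)
class SegmentsEstimate:
    me: int
    method: str                     # "ne_l" or "eigenvalue"
    detail: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.me < 1:
            raise InvalidInputError("me must be >= 1")


def me_from_ne_l(ne: float, genome_length: float) -> SegmentsEstimate:
    """Me = 4 Ne L with L in Morgans."""
    if not (ne > 0 and np.isfinite(ne)):
        raise InvalidInputError(f"ne must be > 0, got {ne}")
    if not (genome_length > 0 and np.isfinite(genome_length)):
        raise InvalidInputError(f"genome_length must be > 0 Morgans, got {genome_length}")
    me = int(round(4.0 * ne * genome_length))
    return SegmentsEstimate(me=max(me, 1), method="ne_l",
                            detail={"ne": ne, "genome_length": genome_length})


def me_from_grm_eigenvalues(grm: GRM, fraction: float = 0.98,
                            max_individuals: int = 5000,
                            rng: Optional[np.random.Generator] = None
                            ) -> SegmentsEstimate:
    """Smallest k such that the k largest eigenvalues of G explain ``fraction``
    of its total variation.

    Eigenvalues are taken on the unblended G (identity blending flattens the
    spectrum's tail and distorts the cutoff).  For matrices larger than
    ``max_individuals`` a random subset of individuals is analyzed.
    """
    if not (0.0 < fraction < 1.0):
        raise InvalidInputError("fraction must be in (0, 1)")
    g = grm.unblended()
    if not np.allclose(g, g.T, atol=1e-8):
        raise InvalidInputError("GRM must be symmetric")
    n = g.shape[0]
    sampled = None
    if n > max_individuals:
        rng = rng or np.random.default_rng()
        idx = np.sort(rng.choice(n, size=max_individuals, replace=False))
        g = g[np.ix_(idx, idx)]
        sampled = max_individuals
    w = np.linalg.eigvalsh(g)
    w = np.clip(w, 0.0, None)[::-1]          # descending, negatives truncated
    total = w.sum()
    if total <= 0.0:
        raise DegenerateInputError("GRM has no positive eigenvalues")
    # tiny slack so an exact boundary (e.g. a flat spectrum) is not pushed up
    # by floating-point rounding of the cumulative sum
    k = int(np.searchsorted(np.cumsum(w) / total, fraction - 1e-12) + 1)
    return SegmentsEstimate(me=k, method="eigenvalue",
                            detail={"fraction": fraction, "n_used": g.shape[0],
                                    "sampled": sampled})
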