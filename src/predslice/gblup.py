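"""Genomic relationship matrices, single-trait GBLUP, and predictivity.

The evaluation model is y = Xb + u + e with u ~ N(0, G sigma_u^2),
e ~ N(0, I sigma_e^2).  Only the variance ratio lambda = sigma_e^2/sigma_u^2 =
(1 - h2)/h2 matters for the solutions, so phenotypes need not be standardized.

The mixed-model equations are solved through the equivalent reference-block
form: with V = sigma_u^2 G_rr + sigma_e^2 I over the reference individuals,

    b_hat = (X' V^-1 X)^-1 X' V^-1 y
    u_hat = sigma_u^2 G[:, ref] V^-1 (y - X b_hat)

which yields GEBVs for every genotyped individual, including validation
animals whose phenotypes never enter the solve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.linalg.blas import dsyrk

from .errors import (DegenerateInputError, InvalidInputError, RankDeficiencyError,
                     UnadjustableRecordError)
from .estimators import PredictivityRecord

__all__ = ["GenotypeMatrix", "GRM", "EvaluationResult", "build_grm", "solve_gblup",
           "adjusted_phenotype", "predictivity"]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Individuals x markers allele-dosage matrix with entries in {0, 1, 2}."""

    dosages: np.ndarray
    individual_ids: list
    marker_ids: list

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages)
        n, m = self.dosages.shape
        if n != len(self.individual_ids):
            raise InvalidInputError("row count does not match individual_ids")
        if m != len(self.marker_ids):
            raise InvalidInputError("column count does not match marker_ids")
        if len(set(self.individual_ids)) != n or len(set(self.marker_ids)) != m:
            raise InvalidInputError("individual and marker ids must be unique")
        d = self.dosages
        if d.size:
            ok = ((d >= 0) & (d <= 2)).all()
            if ok and not np.issubdtype(d.dtype, np.integer):
                ok = bool(np.equal(np.mod(d, 1), 0).all())
            if not ok:
                raise InvalidInputError("dosages must be 0/1/2 with no missing values")
        self._index = {iid: k for k, iid in enumerate(self.individual_ids)}

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def subset(self, individual_ids: Sequence) -> "GenotypeMatrix":
        idx = [self._index[i] for i in individual_ids]
        return GenotypeMatrix(self.dosages[idx], list(individual_ids),
                              list(self.marker_ids))


@dataclass
class GRM:
    """Genomic relationship matrix with its blending metadata."""

    values: np.ndarray
    individual_ids: list
    blend_alpha: float
    allele_freqs: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != self.values.shape[1]:
            raise InvalidInputError("GRM must be square")
        if self.values.shape[0] != len(self.individual_ids):
            raise InvalidInputError("GRM size does not match individual_ids")
        self._index = {iid: k for k, iid in enumerate(self.individual_ids)}

    def indices(self, ids: Sequence) -> np.ndarray:
        try:
            return np.asarray([self._index[i] for i in ids], dtype=int)
        except KeyError as e:
            raise InvalidInputError(f"individual {e.args[0]!r} not in GRM") from None

    def unblended(self) -> np.ndarray:
        """Remove identity blending: G0 = (G - alpha I) / (1 - alpha)."""
        if self.blend_alpha == 0:
            return self.values
        g = self.values - self.blend_alpha * np.eye(len(self.individual_ids))
        return g / (1.0 - self.blend_alpha)


@dataclass
class EvaluationResult:
    gebv: pd.Series                      # indexed by individual id, all genotyped
    fixed_effect_estimates: pd.Series    # indexed by fixed-effect level
    lambda_used: float
    h2_used: float
    reference_ids: list


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def build_grm(genotypes: GenotypeMatrix, blend_alpha: float = 0.05) -> GRM:
    """VanRaden method-1 GRM: G = ZZ' / (2 sum p(1-p)), Z frequency-centered.

    Allele frequencies are computed from all supplied individuals (reference and
    validation together).  The result is blended as (1-alpha) G + alpha I so the
    matrix is strictly positive definite.
    """
    if genotypes.n_individuals < 2:
        raise InvalidInputError("need at least 2 individuals to build a GRM")
    if not (0.0 <= blend_alpha < 1.0):
        raise InvalidInputError("blend_alpha must be in [0, 1)")
    m = np.asarray(genotypes.dosages, dtype=np.float64)
    p = m.mean(axis=0) / 2.0
    het = 2.0 * np.sum(p * (1.0 - p))
    if het <= 0.0:
        raise DegenerateInputError("all markers are monomorphic; GRM undefined")
    z = m - 2.0 * p
    # dsyrk computes only one triangle of Z Z'; mirror it afterwards
    g = dsyrk(alpha=1.0 / het, a=z, lower=1)
    d = g.diagonal().copy()
    g = g + g.T
    g[np.diag_indices_from(g)] = d
    if blend_alpha > 0.0:
        g *= (1.0 - blend_alpha)
        g[np.diag_indices_from(g)] += blend_alpha
    return GRM(values=g, individual_ids=list(genotypes.individual_ids),
               blend_alpha=blend_alpha, allele_freqs=p)


def _design_matrix(ids: Sequence, fixed_design, levels=None):
    """Incidence matrix for the fixed effects: overall mean (fixed_design None)
    or a single categorical factor in cell-means coding."""
    if fixed_design is None:
        return np.ones((len(ids), 1)), ["mean"]
    fd = pd.Series(fixed_design)
    missing = [i for i in ids if i not in fd.index]
    if missing:
        raise InvalidInputError(f"fixed_design missing levels for {missing[:5]!r}")
    lab = fd.loc[list(ids)].astype(str)
    if levels is None:
        levels = sorted(lab.unique())
    unseen = sorted(set(lab) - set(levels))
    if unseen:
        raise UnadjustableRecordError(
            f"fixed-effect level(s) {unseen!r} have no estimate")
    x = np.zeros((len(ids), len(levels)))
    pos = {lv: k for k, lv in enumerate(levels)}
    for r, lv in enumerate(lab):
        x[r, pos[lv]] = 1.0
    return x, list(levels)


def solve_gblup(phenotypes, fixed_design, grm: GRM, h2: float,
                reference_ids: Sequence) -> EvaluationResult:
    """Single-trait GBLUP with shrinkage ratio lambda = (1-h2)/h2.

    ``phenotypes`` is a mapping/Series id -> phenotype covering at least the
    reference individuals; only reference phenotypes enter the right-hand side.
    ``fixed_design`` is None for a mean-only model, or a mapping id -> level of
    one categorical factor.  GEBVs are returned for every individual in ``grm``.
    """
    if not (0.0 < h2 < 1.0):
        raise InvalidInputError(f"h2 must be in (0, 1), got {h2}")
    y_all = pd.Series(phenotypes)
    reference_ids = list(reference_ids)
    missing = [i for i in reference_ids if i not in y_all.index or pd.isna(y_all[i])]
    if missing:
        raise InvalidInputError(f"reference individuals without phenotype: {missing[:5]!r}")
    ref_idx = grm.indices(reference_ids)
    y = y_all.loc[reference_ids].to_numpy(dtype=float)

    x, levels = _design_matrix(reference_ids, fixed_design)
    su2, se2 = h2, 1.0 - h2
    nr = len(ref_idx)
    if np.array_equal(ref_idx, np.arange(nr)):
        # reference ids lead the GRM ordering: plain slices, no gather copies
        g_rr = grm.values[:nr, :nr]
        g_all_r = grm.values[:, :nr]
    else:
        g_rr = grm.values[np.ix_(ref_idx, ref_idx)]
        g_all_r = grm.values[:, ref_idx]
    v = su2 * g_rr
    v[np.diag_indices_from(v)] += se2
    cf = cho_factor(v, lower=True, overwrite_a=True, check_finite=False)

    viy = cho_solve(cf, y, check_finite=False)
    vix = cho_solve(cf, x, check_finite=False)
    xtvix = x.T @ vix
    try:
        b = np.linalg.solve(xtvix, x.T @ viy)
    except np.linalg.LinAlgError:
        raise RankDeficiencyError("fixed-effect equations are singular") from None
    if not np.isfinite(b).all() or np.linalg.cond(xtvix) > 1e12:
        raise RankDeficiencyError("fixed-effect equations are (near-)singular")

    resid = y - x @ b
    w = cho_solve(cf, resid, check_finite=False)
    u = su2 * (g_all_r @ w)
    return EvaluationResult(
        gebv=pd.Series(u, index=grm.individual_ids),
        fixed_effect_estimates=pd.Series(b, index=levels),
        lambda_used=se2 / su2, h2_used=h2, reference_ids=reference_ids)


def adjusted_phenotype(phenotypes, fixed_design, fixed_estimates,
                       ids: Optional[Sequence] = None) -> pd.Series:
    """y - X b_hat for the given individuals (default: all ids in phenotypes).

    ``fixed_estimates`` is the Series produced by :func:`solve_gblup`
    (index = fixed-effect levels, or the single level "mean").
    """
    y = pd.Series(phenotypes)
    ids = list(ids) if ids is not None else list(y.index)
    est = pd.Series(fixed_estimates)
    x, levels = _design_matrix(ids, fixed_design, levels=list(est.index))
    return pd.Series(y.loc[ids].to_numpy(dtype=float) - x @ est.to_numpy(dtype=float),
                     index=ids)


def predictivity(adjusted_phenotypes, gebv, trait_pheno: str = "trait",
                 trait_ebv: str = "trait", window_id: Optional[str] = None
                 ) -> PredictivityRecord:
    """Pearson correlation of adjusted validation phenotypes with GEBVs."""
    a = np.asarray(pd.Series(adjusted_phenotypes).to_numpy(), dtype=float)
    g = np.asarray(pd.Series(gebv).to_numpy(), dtype=float)
    if a.shape != g.shape:
        raise InvalidInputError("adjusted phenotypes and GEBVs must align")
    n = a.size
    if n < 4:
        raise InvalidInputError(f"need >= 4 validation individuals, got {n}")
    if np.std(a) == 0.0 or np.std(g) == 0.0:
        raise DegenerateInputError(
            "zero variance in adjusted phenotypes or GEBVs (constant vector)")
    c = float(np.corrcoef(a, g)[0, 1])
    return PredictivityRecord(c=c, trait_pheno=trait_pheno, trait_ebv=trait_ebv,
                              n_validation=n, window_id=window_id)
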