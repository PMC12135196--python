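"""Sliding-window ("time slice") estimation of genetic parameters.

For each window — a run of consecutive reference generations followed by one
validation generation — the procedure is:

1. build the GRM over reference + validation individuals;
2. run univariate GBLUP per trait with reference phenotypes only (traits
   treated as uncorrelated, validation phenotypes masked);
3. compute predictivities of validation adjusted phenotypes against GEBVs,
   within and across traits;
4. re-estimate each heritability from its within-trait predictivity
   (h2 = (c^2 + sqrt(c^4 + 4 c^2 Me/N))/2, N = reference individuals with both
   genotype and phenotype for that trait);
5. iterate 2-4 with the updated heritabilities until the largest per-trait
   change is below ``tol`` or ``max_iter`` is reached;
6. report accuracies (c/h at the final heritability), both trait orders of
   each genetic correlation, and the closed-form standard errors.

Window results are independent of each other; trends over time come from
running every feasible window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InvalidInputError, PredsliceError
from .estimators import (acc_from_predictivity, gencorr_from_predictivity,
                         h2_from_predictivity, se_accuracy, se_gencorr, se_h2)
from .gblup import (GRM, GenotypeMatrix, adjusted_phenotype, build_grm,
                    predictivity, solve_gblup)

__all__ = ["WindowSpec", "SliceResult", "make_windows", "estimate_window",
           "run_timeslice", "results_table", "window_grm", "window_individuals"]


@dataclass(frozen=True)
class WindowSpec:
    reference_generations: tuple
    validation_generation: object
    window_id: str

    def __post_init__(self):
        if not self.reference_generations:
            raise InvalidInputError("window needs at least one reference generation")
        if not all(g < self.validation_generation for g in self.reference_generations):
            raise InvalidInputError(
                "validation generation must come strictly after all reference generations")


@dataclass
class SliceResult:
    window_id: str
    validation_generation: object
    traits: List[str]
    n_reference: Dict[str, int] = field(default_factory=dict)
    n_validation: int = 0
    h2: Dict[str, float] = field(default_factory=dict)
    h2_se: Dict[str, float] = field(default_factory=dict)
    acc: Dict[str, float] = field(default_factory=dict)
    acc_se: Dict[str, float] = field(default_factory=dict)
    predictivities: Dict[Tuple[str, str], float] = field(default_factory=dict)
    r_g: Dict[Tuple[str, str], float] = field(default_factory=dict)
    r_g_raw: Dict[Tuple[str, str], float] = field(default_factory=dict)
    r_g_se: Dict[Tuple[str, str], float] = field(default_factory=dict)
    iterations_run: int = 0
    converged: bool = False
    failed: bool = False
    message: str = ""


def make_windows(generations: Sequence, ref_len: int = 2,
                 first_validation=None) -> List[WindowSpec]:
    """All sliding windows of ``ref_len`` consecutive reference generations
    plus the next generation as validation.

    ``first_validation`` restricts output to windows whose validation
    generation is at or after that label (useful to skip early generations).
    """
    gens = sorted(set(generations))
    if len(gens) < ref_len + 1:
        raise InvalidInputError(
            f"need at least {ref_len + 1} generations, got {len(gens)}")
    windows = []
    for k in range(ref_len, len(gens)):
        val = gens[k]
        if first_validation is not None and val < first_validation:
            continue
        refs = tuple(gens[k - ref_len:k])
        windows.append(WindowSpec(refs, val, window_id=f"w{val}"))
    if not windows:
        raise InvalidInputError("no feasible window at or after first_validation")
    return windows


def window_individuals(genotypes: GenotypeMatrix, phenotypes: pd.DataFrame,
                       window: WindowSpec) -> Tuple[list, list]:
    """Genotyped reference and validation individual ids of a window."""
    geno_ids = set(genotypes.individual_ids)
    ref_rows = phenotypes.loc[phenotypes["generation"].isin(window.reference_generations)]
    val_rows = phenotypes.loc[phenotypes["generation"] == window.validation_generation]
    ref_all = [i for i in ref_rows["id"] if i in geno_ids]
    val_ids = [i for i in val_rows["id"] if i in geno_ids]
    return ref_all, val_ids


def window_grm(genotypes: GenotypeMatrix, phenotypes: pd.DataFrame,
               window: WindowSpec, blend_alpha: float = 0.05) -> GRM:
    """GRM over a window's reference + validation individuals (reference first,
    which lets the solver slice instead of gather)."""
    ref_all, val_ids = window_individuals(genotypes, phenotypes, window)
    return build_grm(genotypes.subset(ref_all + val_ids), blend_alpha=blend_alpha)


def _trait_ids(phenotypes: pd.DataFrame, ids: Sequence, trait: str) -> list:
    sub = phenotypes.loc[phenotypes["id"].isin(set(ids)), ["id", trait]]
    return sub.loc[sub[trait].notna(), "id"].to_list()


def estimate_window(genotypes: GenotypeMatrix, phenotypes: pd.DataFrame,
                    window: WindowSpec, me: float,
                    initial_h2: Dict[str, float], max_iter: int = 10,
                    tol: float = 0.01, blend_alpha: float = 0.05,
                    grm: Optional[GRM] = None) -> SliceResult:
    """Estimate heritabilities, accuracies and genetic correlations in one window.

    ``phenotypes`` must have columns id, generation and one column per trait
    named in ``initial_h2``.  ``me`` is the assumed number of independent
    chromosome segments.  A precomputed ``grm`` over exactly the window's
    reference + validation individuals may be supplied to avoid rebuilding it
    (e.g. when re-running the same window under different starting values).
    """
    traits = list(initial_h2)
    ref_all, val_ids = window_individuals(genotypes, phenotypes, window)
    if not ref_all or len(val_ids) < 4:
        raise InvalidInputError(
            f"window {window.window_id}: insufficient genotyped reference or "
            f"validation individuals")

    result = SliceResult(window_id=window.window_id,
                         validation_generation=window.validation_generation,
                         traits=traits, n_validation=len(val_ids))
    y = {t: phenotypes.set_index("id")[t] for t in traits}
    ref_t = {t: _trait_ids(phenotypes, ref_all, t) for t in traits}
    result.n_reference = {t: len(ref_t[t]) for t in traits}
    for t in traits:
        if not ref_t[t]:
            raise InvalidInputError(f"no reference phenotypes for trait {t!r}")

    if grm is None:
        grm = build_grm(genotypes.subset(ref_all + val_ids), blend_alpha=blend_alpha)

    h2_cur = dict(initial_h2)
    try:
        for it in range(1, max_iter + 1):
            evals, adj_val, c_within, h2_new = {}, {}, {}, {}
            for t in traits:
                # keep the shrinkage ratio finite even if an update hit a bound
                h2_solve = min(max(h2_cur[t], 1e-6), 1.0 - 1e-6)
                res = solve_gblup(y[t], None, grm, h2_solve, ref_t[t])
                evals[t] = res
                adj_val[t] = adjusted_phenotype(y[t], None,
                                                res.fixed_effect_estimates, val_ids)
                rec = predictivity(adj_val[t], res.gebv.loc[val_ids], t, t,
                                   window.window_id)
                c_within[t] = rec.c
                h2_new[t] = h2_from_predictivity(rec.c, result.n_reference[t],
                                                 me).h2
            delta = max(abs(h2_new[t] - h2_cur[t]) for t in traits)
            h2_cur = h2_new
            result.iterations_run = it
            if delta < tol:
                result.converged = True
                break
    except (DegenerateInputError, np.linalg.LinAlgError) as e:
        result.failed = True
        result.message = str(e)
        return result

    n_val = len(val_ids)
    for t in traits:
        result.h2[t] = h2_cur[t]
        result.predictivities[(t, t)] = c_within[t]
        result.h2_se[t] = (se_h2(abs(c_within[t]), n_val, me, result.n_reference[t])
                           if c_within[t] > 0 else float("nan"))
        if h2_cur[t] > 0:
            a = acc_from_predictivity(abs(c_within[t]), h2_cur[t])
            result.acc[t] = a.acc
            result.acc_se[t] = se_accuracy(h2_cur[t], n_val)
        else:
            result.acc[t] = float("nan")
            result.acc_se[t] = float("nan")

    for i in traits:
        for jt in traits:
            if i == jt:
                continue
            try:
                rec = predictivity(adj_val[i], evals[jt].gebv.loc[val_ids], i, jt,
                                   window.window_id)
            except DegenerateInputError as e:
                result.failed = True
                result.message = str(e)
                continue
            result.predictivities[(i, jt)] = rec.c
            if result.h2.get(i, 0) > 0 and result.acc.get(jt, 0) > 0:
                est = gencorr_from_predictivity(rec.c, result.h2[i],
                                                result.acc[jt], n_val,
                                                trait_pheno=i, trait_ebv=jt,
                                                window_id=window.window_id)
                result.r_g[(i, jt)] = est.r_g
                result.r_g_raw[(i, jt)] = est.raw
                result.r_g_se[(i, jt)] = est.se
    return result


def run_timeslice(genotypes: GenotypeMatrix, phenotypes: pd.DataFrame,
                  windows: Sequence[WindowSpec], me: float,
                  initial_h2: Dict[str, float], **options) -> List[SliceResult]:
    """Run :func:`estimate_window` independently for every window, ordered by
    validation generation; per-window failures become flagged rows rather than
    aborting the run."""
    results = []
    for w in sorted(windows, key=lambda w: w.validation_generation):
        try:
            results.append(estimate_window(genotypes, phenotypes, w, me,
                                           initial_h2, **options))
        except PredsliceError as e:
            results.append(SliceResult(window_id=w.window_id,
                                       validation_generation=w.validation_generation,
                                       traits=list(initial_h2), failed=True,
                                       message=str(e)))
    return results


def results_table(results: Sequence[SliceResult]) -> pd.DataFrame:
    """Tidy table: one row per estimate (h2 / acc / predictivity / r_g)."""
    rows = []
    for r in results:
        base = dict(window_id=r.window_id, val_generation=r.validation_generation,
                    n_val=r.n_validation, iterations=r.iterations_run,
                    converged=r.converged, failed=r.failed)
        for t in r.traits:
            if t in r.h2:
                rows.append(dict(base, kind="h2", trait_pheno=t, trait_ebv=t,
                                 estimate=r.h2[t], se=r.h2_se.get(t),
                                 n_ref=r.n_reference.get(t)))
            if t in r.acc:
                rows.append(dict(base, kind="acc", trait_pheno=t, trait_ebv=t,
                                 estimate=r.acc[t], se=r.acc_se.get(t),
                                 n_ref=r.n_reference.get(t)))
        for (i, jt), c in r.predictivities.items():
            rows.append(dict(base, kind="predictivity", trait_pheno=i, trait_ebv=jt,
                             estimate=c, se=None, n_ref=r.n_reference.get(jt)))
        for (i, jt), v in r.r_g.items():
            rows.append(dict(base, kind="r_g", trait_pheno=i, trait_ebv=jt,
                             estimate=v, se=r.r_g_se.get((i, jt)),
                             n_ref=r.n_reference.get(jt)))
        if r.failed and not rows:
            rows.append(dict(base, kind="failed", trait_pheno=None, trait_ebv=None,
                             estimate=None, se=None, n_ref=None))
    return pd.DataFrame(rows)
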