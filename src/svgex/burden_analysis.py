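"""Correlates of the total per-tumor SSV burden.

Burden enters all models as log10(count + 1).  Translocation mate
entries are merged upstream (``io_formats``), so each rearrangement
counts once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cis_association import (
    ModelSpec,
    _covariate_matrix,
    _orthonormal_basis,
    _partial_fit,
    log2_expression,
    storey_fdr,
)
from .io_formats import TumorMeta

MIN_MUTATED_TUMORS = 3


@dataclass(frozen=True)
class BurdenProfile:
    counts: pd.Series  # per-tumor SSV counts

    def __post_init__(self) -> None:
        if (self.counts < 0).any():
            raise ValueError("SSV counts must be non-negative")

    @property
    def log_burden(self) -> pd.Series:
        return np.log10(self.counts + 1).rename("log_burden")


def burden_expression_correlates(
    expr: pd.DataFrame,
    burden: BurdenProfile,
    meta: Sequence[TumorMeta] | None,
    cna: pd.DataFrame | None,
    spec: ModelSpec = ModelSpec(),
    log_transform: bool = True,
) -> pd.DataFrame:
    """Per-gene OLS of log2 expression on log burden (+ covariates)."""
    tumors = [t for t in expr.columns if t in burden.counts.index]
    expr_l = log2_expression(expr[tumors], spec.pseudocount) if log_transform else expr[tumors]
    lb = burden.log_burden.loc[tumors].to_numpy()
    if np.allclose(lb, lb[0]):
        warnings.warn("burden is constant across tumors; no results", stacklevel=2)
        return pd.DataFrame(
            columns=["gene_id", "coefficient", "direction", "p_value", "reason", "q_storey"]
        )
    types = None
    if meta is not None and "tumor_type" in spec.covariates:
        by_id = {m.tumor_id: m.tumor_type for m in meta}
        types = [by_id[t] for t in tumors]
    use_cna = cna is not None and "cna" in spec.covariates

    rows = []
    n = len(tumors)
    for gene in expr_l.index:
        cna_row = None
        if use_cna and gene in cna.index:
            cna_row = cna.loc[gene, tumors].to_numpy(dtype=float)
        C = _covariate_matrix(types, cna_row, n)
        Q = _orthonormal_basis(C)
        beta, pv, reason = _partial_fit(expr_l.loc[gene].to_numpy(dtype=float), lb, Q)
        rows.append((gene, beta, pv, reason or ""))
    table = pd.DataFrame(rows, columns=["gene_id", "coefficient", "p_value", "reason"])
    table["direction"] = np.where(table["coefficient"] > 0, "positive", "negative")
    table.loc[table["p_value"].isna(), "direction"] = ""
    ok = table["p_value"].notna()
    q = np.full(len(table), np.nan)
    if ok.any():
        q[ok.to_numpy()] = storey_fdr(table.loc[ok, "p_value"].to_numpy())
    table["q_storey"] = q
    return table.sort_values("p_value", kind="mergesort").reset_index(drop=True)


def burden_mutation_correlates(
    mutations: pd.DataFrame, burden: BurdenProfile, min_tumors: int = MIN_MUTATED_TUMORS
) -> pd.DataFrame:
    """Point-biserial (Pearson) correlation of binary inactivating
    mutation status with log burden, per gene with >= ``min_tumors``
    mutated tumors."""
    tumors = [t for t in mutations.columns if t in burden.counts.index]
    lb = burden.log_burden.loc[tumors].to_numpy()
    rows = []
    for gene in mutations.index:
        m = mutations.loc[gene, tumors].to_numpy(dtype=float)
        n_mut = int(m.sum())
        if n_mut < min_tumors or n_mut == len(m):
            continue
        r, p = stats.pearsonr(m, lb)
        rows.append((gene, n_mut, r, p))
    table = pd.DataFrame(rows, columns=["gene_id", "n_mutated", "r", "p_value"])
    if len(table):
        table["q_storey"] = storey_fdr(table["p_value"].to_numpy())
    else:
        table["q_storey"] = np.nan
    return table.sort_values("p_value", kind="mergesort").reset_index(drop=True)


def burden_group_test(
    burden: BurdenProfile,
    groups: pd.Series,
    meta: Sequence[TumorMeta] | None = None,
    reference: str = "unaligned",
    min_group: int = 2,
) -> pd.DataFrame:
    """OLS of log burden on alteration-group indicators (+ tumor type),
    each group contrasted against the reference group."""
    import statsmodels.api as sm

    tumors = [t for t in groups.index if t in burden.counts.index]
    groups = groups.loc[tumors]
    if reference not in set(groups):
        raise ValueError(f"reference group {reference!r} not present")
    sizes = groups.value_counts()
    small = [g for g, n in sizes.items() if n < min_group and g != reference]
    if small:
        warnings.warn(f"dropping groups with <{min_group} tumors: {small}", stacklevel=2)
        keep = ~groups.isin(small)
        groups = groups[keep]
        tumors = list(groups.index)

    y = np.log10(burden.counts.loc[tumors].to_numpy() + 1)
    dummies = pd.get_dummies(groups, dtype=float)
    contrast_cols = [c for c in dummies.columns if c != reference]
    X = dummies[contrast_cols]
    if meta is not None:
        by_id = {m.tumor_id: m.tumor_type for m in meta}
        type_d = pd.get_dummies(
            pd.Series([by_id[t] for t in tumors], index=tumors), dtype=float, drop_first=True
        )
        type_d.columns = [f"type_{c}" for c in type_d.columns]
        X = pd.concat([X, type_d], axis=1)
    X = sm.add_constant(X)
    fit = sm.OLS(y, X).fit()
    rows = [
        (g, float(fit.params[g]), float(fit.pvalues[g]), int(sizes[g]))
        for g in contrast_cols
    ]
    return pd.DataFrame(rows, columns=["group", "coefficient", "p_value", "n_tumors"])


def paired_burden_test(
    burden: BurdenProfile, meta: Sequence[TumorMeta]
) -> tuple[float, float, int]:
    """Paired t-test of log burden: progressive/recurrent vs initial.

    Uses patients with at least one tumor in each arm; within an arm the
    first-listed tumor is taken.  Returns (t, p, n_pairs); t > 0 means
    higher burden in the progressive/recurrent arm.
    """
    initial: dict[str, str] = {}
    advanced: dict[str, str] = {}
    for m in meta:
        if m.tumor_id not in burden.counts.index:
            continue
        if m.status == "initial":
            initial.setdefault(m.patient_id, m.tumor_id)
        elif m.status in ("progressive", "recurrent"):
            advanced.setdefault(m.patient_id, m.tumor_id)
    patients = sorted(set(initial) & set(advanced))
    if len(patients) < 2:
        raise ValueError("need >= 2 complete initial/advanced pairs")
    lb = burden.log_burden
    a = lb.loc[[advanced[p] for p in patients]].to_numpy()
    b = lb.loc[[initial[p] for p in patients]].to_numpy()
    if np.allclose(a, b):
        return 0.0, 1.0, len(patients)
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p), len(patients)


def gene_set_fisher(
    selected: set[str], universe: set[str], category: set[str]
) -> float:
    """One-sided (upper-tail) hypergeometric p for the overlap of the
    selected set with a category, within the universe."""
    if not universe:
        raise ValueError("universe must be non-empty")
    if not selected <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    cat = category & universe
    if not cat:
        return 1.0
    k = len(selected & cat)
    return float(stats.hypergeom.sf(k - 1, len(universe), len(cat), len(selected)))
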