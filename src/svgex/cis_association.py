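"""Per-gene linear models of expression against breakpoint predictors.

The model for each gene is ordinary least squares of log2 expression on
the breakpoint predictor plus optional covariates: dummy-coded tumor
type and the gene's thresholded copy-number value entered as a single
numeric term.  Two FDR procedures are provided: the direct
p * N / #{p' <= p} estimator, and a stratified-permutation estimate that
shuffles whole per-tumor breakpoint profiles within tumor types.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .breakpoint_matrices import BreakpointPresenceMatrix, DistanceMatrix
from .io_formats import TumorMeta

_RANK_TOL = 1e-9


@dataclass(frozen=True)
class ModelSpec:
    """Model configuration for the per-gene regressions."""

    covariates: tuple[str, ...] = ("tumor_type", "cna")
    pseudocount: float = 1.0
    min_tumors: int = 3

    def __post_init__(self) -> None:
        if self.min_tumors < 1:
            raise ValueError("min_tumors must be >= 1")
        unknown = set(self.covariates) - {"tumor_type", "cna"}
        if unknown:
            raise ValueError(f"unknown covariates: {sorted(unknown)}")


@dataclass(frozen=True)
class GeneFit:
    coefficient: float | None
    p_value: float | None
    reason: str | None = None  # set when the fit is degenerate

    @property
    def ok(self) -> bool:
        return self.reason is None


def log2_expression(expr: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(x + pseudocount) transform of a raw expression matrix."""
    return np.log2(expr + pseudocount)


def sd_from_median(expr_log2: pd.DataFrame) -> pd.DataFrame:
    """Per-gene (value - median) / SD scores across the cohort."""
    med = expr_log2.median(axis=1)
    sd = expr_log2.std(axis=1, ddof=1)
    return expr_log2.sub(med, axis=0).div(sd.replace(0.0, np.nan), axis=0)


def _covariate_matrix(
    types: Sequence[str] | None, cna_row: np.ndarray | None, n: int
) -> np.ndarray:
    cols = [np.ones(n)]
    if types is not None:
        levels = sorted(set(types))
        for lev in levels[1:]:  # drop first level; intercept carries it
            cols.append(np.asarray([1.0 if t == lev else 0.0 for t in types]))
    if cna_row is not None:
        cols.append(np.asarray(cna_row, dtype=float))
    return np.column_stack(cols)


def _orthonormal_basis(C: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space of C (rank-robust, via SVD)."""
    u, s, _ = np.linalg.svd(C, full_matrices=False)
    rank = int(np.sum(s > _RANK_TOL * max(s[0], 1.0)))
    return u[:, :rank]


def _partial_fit(
    y: np.ndarray, p: np.ndarray, Q: np.ndarray
) -> tuple[float, float, str | None]:
    """OLS coefficient and two-sided t-test p for p given covariate basis Q."""
    n = len(y)
    k = Q.shape[1]
    df = n - k - 1
    if df <= 0:
        return np.nan, np.nan, "insufficient_df"
    ep = p - Q @ (Q.T @ p)
    epep = float(ep @ ep)
    scale = max(float(p @ p), 1.0)
    if epep <= _RANK_TOL * scale:
        if np.allclose(p, p[0]):
            return np.nan, np.nan, "constant_predictor"
        return np.nan, np.nan, "collinear_predictor"
    ey = y - Q @ (Q.T @ y)
    beta = float(ep @ ey) / epep
    rss = float(ey @ ey) - beta * beta * epep
    rss = max(rss, 0.0)
    if rss == 0.0:
        return beta, 0.0, None
    se = np.sqrt(rss / df / epep)
    t = beta / se
    p_value = 2.0 * stats.t.sf(abs(t), df)
    return beta, float(p_value), None


def fit_gene_model(
    expr_row: np.ndarray | pd.Series,
    predictor_row: np.ndarray | pd.Series,
    types: Sequence[str] | None = None,
    cna_row: np.ndarray | pd.Series | None = None,
    spec: ModelSpec = ModelSpec(),
) -> GeneFit:
    """Fit one gene: log2 expression ~ predictor + covariates.

    ``expr_row`` is expected on log scale already.  Returns the
    predictor coefficient and its two-sided t-test p-value, or a
    degenerate result with a reason code.
    """
    y = np.asarray(expr_row, dtype=float)
    p = np.asarray(predictor_row, dtype=float)
    n = len(y)
    if len(p) != n:
        raise ValueError("expression and predictor rows must align")
    use_types = types if "tumor_type" in spec.covariates else None
    use_cna = None
    if "cna" in spec.covariates and cna_row is not None:
        use_cna = np.asarray(cna_row, dtype=float)
    C = _covariate_matrix(use_types, use_cna, n)
    Q = _orthonormal_basis(C)
    beta, pv, reason = _partial_fit(y, p, Q)
    if reason is not None:
        return GeneFit(None, None, reason)
    return GeneFit(beta, pv, None)


def storey_fdr(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """q(g) = p(g) * N / #{p <= p(g)}, capped at 1.

    This is the direct estimator as printed; no additional monotonicity
    enforcement is applied beyond the formula itself.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    order = np.sort(p)
    counts = np.searchsorted(order, p, side="right")
    q = p * p.size / counts
    return np.minimum(q, 1.0)


def _predictor_kind(predictor) -> str:
    if isinstance(predictor, DistanceMatrix):
        return "log_distance"
    if isinstance(predictor, BreakpointPresenceMatrix):
        return "window_presence"
    raise TypeError("predictor must be a BreakpointPresenceMatrix or DistanceMatrix")


def _aligned_inputs(expr, pred_values, meta, cna):
    tumors = [t for t in expr.columns if t in set(pred_values.columns)]
    if meta is not None:
        meta_ids = {m.tumor_id for m in meta}
        missing = [t for t in tumors if t not in meta_ids]
        if missing:
            raise ValueError(f"tumors missing from metadata: {missing[:5]}")
    genes = [g for g in expr.index if g in set(pred_values.index)]
    return genes, tumors


class _AssociationEngine:
    """Pre-computed per-gene designs for repeated (permutation) testing.

    Covariates are fixed per gene; only the predictor row changes under
    permutation, so each gene stores an orthonormal covariate basis and
    the covariate-residualized expression once.
    """

    def __init__(self, expr_log2, predictor, meta, cna, spec):
        kind = _predictor_kind(predictor)
        genes, tumors = _aligned_inputs(expr_log2, predictor.values, meta, cna)
        self.kind = kind
        self.tumors = tumors
        self.spec = spec
        pred = predictor.values.loc[
            [g for g in genes if g in predictor.values.index], tumors
        ]

        if kind == "log_distance":
            informative = (~predictor.imputed.loc[pred.index, tumors]).sum(axis=1)
        else:
            informative = pred.sum(axis=1)
        keep = informative >= spec.min_tumors
        self.genes = [g for g, k in zip(pred.index, keep) if k]
        self.n_ssv_tumors = informative[keep].to_numpy()
        self.P = pred.loc[self.genes].to_numpy(dtype=float)
        self.Y = expr_log2.loc[self.genes, tumors].to_numpy(dtype=float)

        types = None
        if meta is not None and "tumor_type" in spec.covariates:
            by_id = {m.tumor_id: m.tumor_type for m in meta}
            types = [by_id[t] for t in tumors]
        self.types = types

        n = len(tumors)
        self.Qs: list[np.ndarray] = []
        self.Ey = np.empty_like(self.Y)
        use_cna = cna is not None and "cna" in spec.covariates
        for i, g in enumerate(self.genes):
            cna_row = None
            if use_cna and g in cna.index:
                cna_row = cna.loc[g, tumors].to_numpy(dtype=float)
            C = _covariate_matrix(types, cna_row, n)
            Q = _orthonormal_basis(C)
            self.Qs.append(Q)
            y = self.Y[i]
            self.Ey[i] = y - Q @ (Q.T @ y)

    def fit_all(self, P: np.ndarray | None = None):
        """Coefficient and p per gene for predictor matrix P (genes x tumors)."""
        if P is None:
            P = self.P
        n = len(self.tumors)
        G = len(self.genes)
        coefs = np.full(G, np.nan)
        pvals = np.full(G, np.nan)
        reasons: list[str | None] = [None] * G
        # group genes by covariate rank so each group vectorizes cleanly
        ranks = np.asarray([Q.shape[1] for Q in self.Qs])
        for k in np.unique(ranks):
            gi = np.flatnonzero(ranks == k)
            df = n - int(k) - 1
            if df <= 0:
                for i in gi:
                    reasons[i] = "insufficient_df"
                continue
            Q = np.stack([self.Qs[i] for i in gi])  # (g, n, k)
            Pg = P[gi]
            proj = np.einsum("gnk,gn->gk", Q, Pg)
            Ep = Pg - np.einsum("gnk,gk->gn", Q, proj)
            epep = np.einsum("gn,gn->g", Ep, Ep)
            Eyg = self.Ey[gi]
            eyey = np.einsum("gn,gn->g", Eyg, Eyg)
            epey = np.einsum("gn,gn->g", Ep, Eyg)
            scale = np.maximum(np.einsum("gn,gn->g", Pg, Pg), 1.0)
            good = epep > _RANK_TOL * scale
            beta = np.zeros_like(epep)
            beta[good] = epey[good] / epep[good]
            rss = np.maximum(eyey - beta * beta * epep, 0.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                se = np.sqrt(rss / df / epep)
                t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
            pv = np.where(np.isfinite(t), 2.0 * stats.t.sf(np.abs(t), df), 0.0)
            pv = np.where(rss == 0.0, 0.0, pv)
            for j, i in enumerate(gi):
                if not good[j]:
                    reasons[i] = (
                        "constant_predictor"
                        if np.allclose(P[i], P[i][0])
                        else "collinear_predictor"
                    )
                else:
                    coefs[i] = beta[j]
                    pvals[i] = pv[j]
        return coefs, pvals, reasons


def run_association(
    expr: pd.DataFrame,
    predictor: BreakpointPresenceMatrix | DistanceMatrix,
    meta: Sequence[TumorMeta] | None,
    cna: pd.DataFrame | None,
    spec: ModelSpec = ModelSpec(),
    log_transform: bool = True,
) -> pd.DataFrame:
    """Per-gene association table for one predictor matrix.

    Genes with fewer than ``spec.min_tumors`` breakpoint-bearing tumors
    (non-imputed cells for the distance metric) are excluded.  The
    direction convention makes ``positive`` mean "higher expression with
    a breakpoint present / closer", so for the log-distance predictor a
    negative coefficient maps to direction ``positive``.
    """
    expr_l = log2_expression(expr, spec.pseudocount) if log_transform else expr
    engine = _AssociationEngine(expr_l, predictor, meta, cna, spec)
    if not engine.genes:
        warnings.warn("run_association: no genes pass the min_tumors filter", stacklevel=2)
        return _empty_result()
    coefs, pvals, reasons = engine.fit_all()
    kind = engine.kind
    if kind == "log_distance":
        direction = np.where(coefs < 0, "positive", "negative")
    else:
        direction = np.where(coefs > 0, "positive", "negative")
    direction = np.where(np.isnan(coefs), "", direction)

    table = pd.DataFrame(
        {
            "gene_id": engine.genes,
            "predictor_kind": kind,
            "coefficient": coefs,
            "direction": direction,
            "p_value": pvals,
            "n_ssv_tumors": engine.n_ssv_tumors,
            "reason": [r or "" for r in reasons],
        }
    )
    ok = table["p_value"].notna()
    q = np.full(len(table), np.nan)
    if ok.any():
        q[ok.to_numpy()] = storey_fdr(table.loc[ok, "p_value"].to_numpy())
    table["q_storey"] = q
    return table.sort_values("p_value", kind="mergesort").reset_index(drop=True)


def _empty_result() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "gene_id", "predictor_kind", "coefficient", "direction",
            "p_value", "n_ssv_tumors", "reason", "q_storey",
        ]
    )


def _strata(meta: Sequence[TumorMeta], tumors: Sequence[str]) -> list[np.ndarray]:
    """Tumor-index groups by tumor type; singleton types merge into 'other'."""
    by_id = {m.tumor_id: m.tumor_type for m in meta}
    groups: dict[str, list[int]] = {}
    for i, t in enumerate(tumors):
        groups.setdefault(by_id[t], []).append(i)
    merged: list[int] = []
    out = []
    for members in groups.values():
        if len(members) == 1:
            merged.extend(members)
        else:
            out.append(np.asarray(members))
    if merged:
        out.append(np.asarray(merged))
    return out


@dataclass
class PermutationFDR:
    estimated_fdr: float | None
    observed_count: int
    perm_counts: np.ndarray = field(repr=False)


def permutation_fdr(
    expr: pd.DataFrame,
    predictor: BreakpointPresenceMatrix | DistanceMatrix,
    meta: Sequence[TumorMeta],
    cna: pd.DataFrame | None,
    spec: ModelSpec,
    threshold: float,
    n_perm: int,
    seed: int,
    threshold_kind: str = "p",
    log_transform: bool = True,
) -> PermutationFDR:
    """Estimate the FDR of a selection rule by stratified permutation.

    Each permutation shuffles whole per-tumor breakpoint profiles
    (predictor columns) among tumors of the same tumor type; expression,
    tumor type, and CNA stay fixed with the tumor.  The estimate is the
    mean permuted count of genes passing the rule divided by the
    observed count.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if threshold_kind not in ("p", "q"):
        raise ValueError("threshold_kind must be 'p' or 'q'")
    expr_l = log2_expression(expr, spec.pseudocount) if log_transform else expr
    engine = _AssociationEngine(expr_l, predictor, meta, cna, spec)
    if not engine.genes:
        raise ValueError("no genes pass the min_tumors filter")

    def count_passing(pvals: np.ndarray) -> int:
        p = pvals[~np.isnan(pvals)]
        if threshold_kind == "p":
            return int(np.sum(p < threshold))
        return int(np.sum(storey_fdr(p) < threshold))

    _, pvals, _ = engine.fit_all()
    observed = count_passing(pvals)

    rng = np.random.default_rng(seed)
    strata = _strata(meta, engine.tumors)
    n = len(engine.tumors)
    perm_counts = np.empty(n_perm, dtype=np.int64)
    for b in range(n_perm):
        perm = np.arange(n)
        for members in strata:
            perm[members] = members[rng.permutation(len(members))]
        _, pv, _ = engine.fit_all(engine.P[:, perm])
        perm_counts[b] = count_passing(pv)

    if observed == 0:
        return PermutationFDR(None, 0, perm_counts)
    return PermutationFDR(float(perm_counts.mean()) / observed, observed, perm_counts)


def subgroup_breakpoint_enrichment(
    presence: BreakpointPresenceMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> pd.DataFrame:
    """Per-gene one-sided Fisher p for breakpoint excess in group A.

    ``group_a`` and ``group_b`` must partition the presence-matrix
    tumor columns.
    """
    cols = set(presence.values.columns)
    a = [t for t in group_a]
    b = [t for t in group_b]
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    if set(a) | set(b) != cols or set(a) & set(b):
        raise ValueError("groups must partition the tumor set")
    va = presence.values[a].to_numpy()
    vb = presence.values[b].to_numpy()
    x = va.sum(axis=1)  # breakpoint tumors in A
    k = x + vb.sum(axis=1)  # breakpoint tumors overall
    n_total = len(a) + len(b)
    p = stats.hypergeom.sf(x - 1, n_total, k, len(a))
    return pd.DataFrame(
        {
            "gene_id": presence.values.index,
            "n_breakpoint_a": x,
            "n_breakpoint_total": k,
            "p_value": p,
        }
    ).reset_index(drop=True)
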