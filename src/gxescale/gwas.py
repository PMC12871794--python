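"""Desk-scale GWAS, LD clumping, shared-hit labeling, and scale-aware PRS.

GWAS summary statistics live in a pandas DataFrame with columns
``snp, chr, bp, a1, beta, se, p, n`` (one row per SNP; ``a2`` optional).
Clumping follows the greedy plink convention: repeatedly promote the
remaining SNP with the smallest p-value to lead and absorb every unassigned
SNP within the base-pair window whose r² with the lead meets the threshold.

PRS construction is clump-then-threshold over a grid of p-value cutoffs,
with the cutoff chosen by prediction R² in a tuning cohort on the same
scale the GWAS was run on.  Evaluation is scale-aware: a score trained on
the log scale enters the default-scale evaluation model exponentiated,
``Y = exp(PGS_log)·b + C·eta + eps``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import GenotypePanel

__all__ = [
    "GWAS_COLUMNS",
    "ClumpParams",
    "PrsModel",
    "LdLookup",
    "ld_from_panel",
    "run_gwas",
    "clump",
    "shared_hits",
    "build_prs",
    "score_prs",
    "evaluate_prs",
    "relative_r2",
    "naive_genetic_correlation",
]

GWAS_COLUMNS = ("snp", "chr", "bp", "a1", "beta", "se", "p", "n")


@dataclass(frozen=True)
class ClumpParams:
    """Greedy-clumping parameters (plink-style defaults)."""

    r2_threshold: float = 0.1
    window_bp: int = 250_000
    p_threshold: float = 5e-8

    def __post_init__(self) -> None:
        if not 0 < self.r2_threshold <= 1:
            raise ValueError("r2_threshold must lie in (0, 1]")
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if not 0 < self.p_threshold <= 1:
            raise ValueError("p_threshold must lie in (0, 1]")


@dataclass
class PrsModel:
    """SNP weights with the scale and p-value cutoff they were trained on."""

    weights: pd.DataFrame  # columns snp, a1, weight
    train_scale: str = "default"
    p_threshold_used: float = 1.0

    def __post_init__(self) -> None:
        if self.train_scale not in ("default", "log"):
            raise ValueError("train_scale must be 'default' or 'log'")
        if len(self.weights) == 0:
            raise ValueError("a PRS model needs at least one weighted SNP")
        if self.weights["snp"].duplicated().any():
            raise ValueError("duplicate SNP ids in PRS weights")


class LdLookup:
    """Pairwise r² lookup by SNP id.

    Wraps either a square DataFrame (index/columns = SNP ids) or a dict
    keyed by frozenset pairs.  A missing pair is treated as r²=0 (the SNP is
    not clumped), logged once per pair via ``warnings``.
    """

    def __init__(self, table):
        if isinstance(table, pd.DataFrame):
            self._frame = table
            self._dict = None
        else:
            self._frame = None
            self._dict = {frozenset(k): float(v) for k, v in table.items()}
        self._warned: set[frozenset] = set()

    def r2(self, snp_a: str, snp_b: str) -> float:
        if snp_a == snp_b:
            return 1.0
        if self._frame is not None:
            try:
                return float(self._frame.at[snp_a, snp_b])
            except KeyError:
                pass
        else:
            key = frozenset((snp_a, snp_b))
            if key in self._dict:
                return self._dict[key]
        key = frozenset((snp_a, snp_b))
        if key not in self._warned:
            self._warned.add(key)
            warnings.warn(f"no LD entry for ({snp_a}, {snp_b}); treating r2 as 0")
        return 0.0


def ld_from_panel(panel: GenotypePanel) -> LdLookup:
    """Empirical pairwise dosage r² for every SNP pair in a panel."""
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(panel.dosages, rowvar=False)
    r2 = np.nan_to_num(r, nan=0.0) ** 2
    np.fill_diagonal(r2, 1.0)
    return LdLookup(pd.DataFrame(r2, index=panel.snp_ids, columns=panel.snp_ids))


def _validate_gwas(gwas: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in GWAS_COLUMNS if c not in gwas.columns and c != "a1"]
    if missing:
        raise ValueError(f"GWAS table is missing columns {missing}")
    if gwas["snp"].duplicated().any():
        raise ValueError("GWAS table has duplicate SNP ids")
    return gwas


def run_gwas(panel: GenotypePanel, y, covariates=None) -> pd.DataFrame:
    """Per-SNP OLS association scan: y ~ dosage + covariates.

    Uses the Frisch–Waugh–Lovell residualization, which reproduces the
    per-SNP OLS coefficient, classical standard error, and two-sided t-test
    exactly while sharing the covariate projection across SNPs.  A
    zero-variance SNP yields a row of missing statistics and a warning.
    """
    y = np.asarray(y, dtype=float)
    n = panel.n_samples
    if len(y) != n:
        raise ValueError("phenotype is not sample-aligned with the panel")
    if covariates is None:
        Z = np.ones((n, 1))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        Z = np.column_stack([np.ones(n), C])
    k = Z.shape[1]
    # residualize y and all dosages on the covariates (incl. intercept)
    Q, _ = np.linalg.qr(Z)
    y_r = y - Q @ (Q.T @ y)
    D_r = panel.dosages - Q @ (Q.T @ panel.dosages)

    gg = np.einsum("ij,ij->j", D_r, D_r)
    dof = n - k - 1
    beta = np.full(panel.n_snps, np.nan)
    se = np.full(panel.n_snps, np.nan)
    pvals = np.full(panel.n_snps, np.nan)
    ok = gg > 1e-10 * n  # ~0 after residualization: constant or covariate-collinear SNP
    if not np.all(ok):
        bad = [panel.snp_ids[j] for j in np.flatnonzero(~ok)]
        warnings.warn(f"zero-variance SNPs emitted with missing statistics: {bad}")
    beta[ok] = (D_r[:, ok] * y_r[:, None]).sum(axis=0) / gg[ok]
    rss = (y_r @ y_r) - beta[ok] ** 2 * gg[ok]
    sigma2 = np.maximum(rss, 0.0) / dof
    se[ok] = np.sqrt(sigma2 / gg[ok])
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta[ok] / se[ok]
    pvals[ok] = 2.0 * stats.t.sf(np.abs(tstat), dof)
    pvals[ok] = np.maximum(pvals[ok], 5e-324)

    out = panel.snp_map[["snp", "chr", "bp", "a1"]].copy()
    out["beta"] = beta
    out["se"] = se
    out["p"] = pvals
    out["n"] = n
    return out


def clump(gwas: pd.DataFrame, ld: LdLookup, params: ClumpParams) -> pd.DataFrame:
    """Greedy LD clumping of a GWAS table.

    Returns one row per lead SNP (in promotion order) with its p-value,
    clump membership, and whether the lead passes ``params.p_threshold``.
    Ties in p are broken by smaller position, then lexicographic id, so the
    output is invariant to input row order.
    """
    g = _validate_gwas(gwas).dropna(subset=["p"])
    g = g.sort_values(["p", "bp", "snp"], kind="mergesort").reset_index(drop=True)
    unassigned = dict(zip(g["snp"], zip(g["chr"], g["bp"], g["p"])))
    order = list(g["snp"])
    rows = []
    assigned: set[str] = set()
    for snp in order:
        if snp in assigned:
            continue
        chrom, bp, p = unassigned[snp]
        members = [snp]
        assigned.add(snp)
        for other, (oc, ob, _) in unassigned.items():
            if other in assigned or oc != chrom or abs(ob - bp) > params.window_bp:
                continue
            if ld.r2(snp, other) >= params.r2_threshold:
                members.append(other)
                assigned.add(other)
        rows.append(
            {
                "lead": snp,
                "chr": chrom,
                "bp": bp,
                "p": p,
                "members": members,
                "n_members": len(members),
                "significant": p < params.p_threshold,
            }
        )
    return pd.DataFrame(rows, columns=["lead", "chr", "bp", "p", "members", "n_members", "significant"])


def shared_hits(
    gwas_a: pd.DataFrame,
    gwas_b: pd.DataFrame,
    ld: LdLookup,
    params: ClumpParams,
) -> tuple[pd.DataFrame, dict]:
    """Label clumped hits of two GWAS as shared or study-specific.

    Builds the per-SNP minimum of the two p-values, clumps that min-p table,
    keeps leads below the significance threshold, and labels each lead
    ``shared`` when both studies pass the threshold at that SNP, otherwise
    ``a_only``/``b_only``.  Returns the labeled leads and a summary with
    counts and the percent of leads shared.
    """
    a = _validate_gwas(gwas_a)
    b = _validate_gwas(gwas_b)
    sa, sb = set(a["snp"]), set(b["snp"])
    if sa != sb:
        raise ValueError(
            f"GWAS tables must cover the same SNPs; symmetric difference has {len(sa ^ sb)} SNPs"
        )
    b_p = b.set_index("snp")["p"]
    merged = a[["snp", "chr", "bp", "a1"]].copy()
    merged["p_a"] = a["p"].to_numpy()
    merged["p_b"] = b_p.loc[merged["snp"]].to_numpy()
    merged["p"] = np.minimum(merged["p_a"], merged["p_b"])
    merged["beta"] = np.nan
    merged["se"] = np.nan
    merged["n"] = np.nan

    leads = clump(merged, ld, params)
    leads = leads[leads["significant"]].reset_index(drop=True)
    pa = merged.set_index("snp")["p_a"]
    pb = merged.set_index("snp")["p_b"]
    labels = []
    for snp in leads["lead"]:
        in_a = pa[snp] < params.p_threshold
        in_b = pb[snp] < params.p_threshold
        labels.append("shared" if in_a and in_b else ("a_only" if in_a else "b_only"))
    leads["label"] = labels
    counts = {lab: int((leads["label"] == lab).sum()) for lab in ("shared", "a_only", "b_only")}
    total = len(leads)
    summary = {
        "n_leads": total,
        **counts,
        "percent_shared": (100.0 * counts["shared"] / total) if total else float("nan"),
    }
    return leads, summary


def score_prs(model: PrsModel, panel: GenotypePanel) -> np.ndarray:
    """Weighted dosage sum for every sample in a panel."""
    idx = {s: j for j, s in enumerate(panel.snp_ids)}
    missing = [s for s in model.weights["snp"] if s not in idx]
    if missing:
        raise ValueError(f"panel is missing {len(missing)} PRS SNPs (e.g. {missing[:3]})")
    cols = [idx[s] for s in model.weights["snp"]]
    return panel.dosages[:, cols] @ model.weights["weight"].to_numpy()


def build_prs(
    gwas: pd.DataFrame,
    ld: LdLookup,
    params: ClumpParams,
    threshold_grid,
    tuning_panel: GenotypePanel,
    tuning_y,
    train_scale: str = "default",
) -> PrsModel:
    """Clump-then-threshold PRS with the cutoff tuned by prediction R².

    For each cutoff in ``threshold_grid`` the model keeps clump leads with
    p below the cutoff, weighted by their GWAS beta, and scores the tuning
    cohort; the cutoff maximizing squared Pearson correlation with the
    tuning phenotype *on the training scale* wins (first maximum on ties).
    """
    thresholds = sorted(float(t) for t in np.atleast_1d(threshold_grid))
    if not thresholds:
        raise ValueError("threshold grid must be nonempty")
    tuning_y = np.asarray(tuning_y, dtype=float)
    if train_scale == "log":
        if np.min(tuning_y) <= 0:
            raise ValueError("log-scale tuning requires a strictly positive phenotype")
        y_eval = np.log(tuning_y)
    else:
        y_eval = tuning_y

    leads = clump(gwas, ld, ClumpParams(params.r2_threshold, params.window_bp, 1.0))
    beta_by_snp = gwas.set_index("snp")["beta"]
    a1_by_snp = gwas.set_index("snp")["a1"]

    best = None
    for thr in thresholds:
        chosen = leads.loc[leads["p"] < thr, "lead"]
        if len(chosen) == 0:
            continue
        weights = pd.DataFrame(
            {
                "snp": chosen.to_numpy(),
                "a1": a1_by_snp.loc[chosen].to_numpy(),
                "weight": beta_by_snp.loc[chosen].to_numpy(),
            }
        )
        model = PrsModel(weights=weights, train_scale=train_scale, p_threshold_used=thr)
        score = score_prs(model, tuning_panel)
        r2 = _squared_corr(score, y_eval, "pearson_r2")
        if best is None or r2 > best[0]:
            best = (r2, model)
    if best is None:
        raise ValueError("no threshold on the grid yielded a nonempty weight set")
    return best[1]


def _squared_corr(a: np.ndarray, b: np.ndarray, metric: str) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    if metric == "spearman_r2":
        return float(stats.spearmanr(a, b).statistic ** 2)
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def evaluate_prs(
    model: PrsModel,
    panel: GenotypePanel,
    y,
    covariates=None,
    groups=None,
    metric: str = "pearson_r2",
    eval_scale: str = "default",
) -> pd.DataFrame:
    """Scale-aware PRS evaluation, overall and within groups.

    The evaluation regression is ``y_eval ~ score_term + covariates`` with
    ``y_eval`` the phenotype on ``eval_scale`` and ``score_term`` the PRS —
    exponentiated when a log-trained score is evaluated on the default scale
    (Y = exp(PGS_log)·b + C·eta + eps).  R² is the squared Pearson (or
    Spearman) correlation between ``y_eval`` and the fitted values; group
    rows come from refitting the regression within each group.
    """
    if metric not in ("pearson_r2", "spearman_r2"):
        raise ValueError("metric must be 'pearson_r2' or 'spearman_r2'")
    if eval_scale not in ("default", "log"):
        raise ValueError("eval_scale must be 'default' or 'log'")
    y = np.asarray(y, dtype=float)
    if eval_scale == "log":
        if np.min(y) <= 0:
            raise ValueError("log-scale evaluation requires a strictly positive phenotype")
        y_eval = np.log(y)
    else:
        y_eval = y

    score = score_prs(model, panel)
    if model.train_scale == "log" and eval_scale == "default":
        score_term = np.exp(score - score.mean())  # centered to avoid overflow
    else:
        score_term = score

    def fit_r2(mask: np.ndarray) -> tuple[float, int]:
        ys = y_eval[mask]
        X = [np.ones(mask.sum()), score_term[mask]]
        if covariates is not None:
            C = np.asarray(covariates, dtype=float)
            if C.ndim == 1:
                C = C[:, None]
            X.extend(C[mask].T)
        X = np.column_stack(X)
        coef, *_ = np.linalg.lstsq(X, ys, rcond=None)
        fitted = X @ coef
        return _squared_corr(ys, fitted, metric), int(mask.sum())

    rows = []
    all_mask = np.ones(len(y), dtype=bool)
    r2, n = fit_r2(all_mask)
    rows.append({"group": "overall", "r2": r2, "n": n})
    if groups is not None:
        groups = np.asarray(groups)
        for g in sorted(pd.unique(groups)):
            r2, n = fit_r2(groups == g)
            rows.append({"group": str(g), "r2": r2, "n": n})
    return pd.DataFrame(rows)


def relative_r2(r2_log: float, r2_baseline: float) -> float:
    """Relative gain of the log-trained score: (R²_log - R²_base) / R²_base."""
    if r2_baseline == 0:
        raise ValueError("baseline R² is zero; relative R² is undefined")
    return (r2_log - r2_baseline) / r2_baseline


def naive_genetic_correlation(gwas_a: pd.DataFrame, gwas_b: pd.DataFrame, snp_ids=None) -> float:
    """Pearson correlation of effect sizes over an independent SNP set.

    A desk-scale summary of cross-study effect concordance; this is a plain
    effect-size correlation over (assumed) mutually independent SNPs, not an
    LD-score-regression genetic correlation — estimation noise in the betas
    attenuates it toward zero.  Symmetric in its arguments; requires at
    least 10 SNPs.
    """
    a = _validate_gwas(gwas_a).set_index("snp")["beta"]
    b = _validate_gwas(gwas_b).set_index("snp")["beta"]
    if snp_ids is None:
        snp_ids = a.index.intersection(b.index)
    snp_ids = list(snp_ids)
    if len(snp_ids) < 10:
        raise ValueError(f"need at least 10 independent SNPs, got {len(snp_ids)}")
    return float(np.corrcoef(a.loc[snp_ids], b.loc[snp_ids])[0, 1])
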