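import numpy as np
import pandas as pd
import pytest

from gxescale import ClumpParams, GenotypePanel, LdLookup, SimulationConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20_260_921)


@pytest.fixture
def small_cohort():
    """A small additive cohort on the identity observation scale."""
    return simulate_cohort(SimulationConfig(n_samples=600, n_pgs=5, seed=42))


@pytest.fixture
def tiny_panel(rng):
    """A 12-SNP unlinked panel with 150 samples for oracle comparisons."""
    n, p = 150, 12
    freqs = rng.uniform(0.1, 0.9, p)
    dosages = rng.binomial(2, freqs, size=(n, p)).astype(float)
    snp_map = pd.DataFrame(
        {
            "snp": [f"snp{i + 1}" for i in range(p)],
            "chr": 1,
            "bp": np.arange(1, p + 1) * 100_000,
            "a1": "A",
            "a2": "G",
            "freq": freqs,
        }
    )
    return GenotypePanel(dosages=dosages, snp_map=snp_map)


def normal_equations_ols(X, y):
    """Independent OLS oracle: (X'X)^-1 X'y with classical Wald inference."""
    import scipy.stats

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    dof = X.shape[0] - X.shape[1]
    sigma2 = resid @ resid / dof
    se = np.sqrt(sigma2 * np.diag(XtX_inv))
    t = beta / se
    p = 2 * scipy.stats.t.sf(np.abs(t), dof)
    return beta, se, p


def greedy_clump_oracle(records, r2_lookup, r2_threshold, window_bp):
    """Direct re-execution of the greedy clumping definition.

    ``records``: list of (snp, chr, bp, p).  Returns [(lead, member_set)] in
    promotion order with ties in p broken by bp then id.
    """
    remaining = sorted(records, key=lambda r: (r[3], r[2], r[0]))
    assigned = set()
    out = []
    for snp, chrom, bp, p in remaining:
        if snp in assigned:
            continue
        members = {snp}
        assigned.add(snp)
        for o_snp, o_chr, o_bp, _ in remaining:
            if o_snp in assigned or o_chr != chrom or abs(o_bp - bp) > window_bp:
                continue
            if r2_lookup(snp, o_snp) >= r2_threshold:
                members.add(o_snp)
                assigned.add(o_snp)
        out.append((snp, members))
    return out


@pytest.fixture
def clump_params():
    return ClumpParams(r2_threshold=0.1, window_bp=250_000, p_threshold=5e-8)


def identity_ld(snp_ids):
    """LD lookup in which all distinct SNPs are independent (r2 = 0)."""
    frame = pd.DataFrame(np.eye(len(snp_ids)), index=snp_ids, columns=snp_ids)
    return LdLookup(frame)
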