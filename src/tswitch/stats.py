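"""Hypothesis tests and the empirical-versus-simulated enrichment procedure.

Two tests are used downstream: a two-sided one-proportion z test (loop
motif and length frequencies) and an independent-sample t test in the
Welch (unequal-variance) form (per-category event counts, empirical
clusters versus each simulated replicate).  A category is called enriched
only when the empirical counts are significantly different from *every*
replicate and the empirical mean exceeds each replicate mean; depletion is
flagged symmetrically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


def one_proportion_ztest(x: int, n: int, p0: float) -> tuple[float, float]:
    """Two-sided one-proportion z test of x successes in n trials vs p0.

    z = (x/n - p0) / sqrt(p0 (1 - p0) / n); p = 2 (1 - Phi(|z|)).
    """
    if not 0.0 < p0 < 1.0:
        raise ValueError("null proportion must lie strictly between 0 and 1")
    if n <= 0:
        raise ValueError("n must be positive")
    phat = x / n
    z = (phat - p0) / math.sqrt(p0 * (1.0 - p0) / n)
    p = 2.0 * sps.norm.sf(abs(z))
    return z, p


def two_sample_ttest(a, b) -> tuple[float, float]:
    """Welch's independent two-sample t test, two-sided.

    Degenerate samples (zero variance on both sides) give t = 0, p = 1
    when the means are equal, and +/-inf, p = 0 otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least two observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    ma, mb = a.mean(), b.mean()
    if va == 0.0 and vb == 0.0:
        if ma == mb:
            return 0.0, 1.0
        return math.copysign(math.inf, ma - mb), 0.0
    se = math.sqrt(va / a.size + vb / b.size)
    t = (ma - mb) / se
    # Welch-Satterthwaite degrees of freedom
    df = (va / a.size + vb / b.size) ** 2 / (
        (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
    )
    p = 2.0 * sps.t.sf(abs(t), df)
    return t, p


@dataclass
class EnrichmentResult:
    """Per-category empirical-vs-simulated comparison."""

    category: str
    branch_type: str
    empirical: np.ndarray  # per-cluster counts
    simulated: np.ndarray  # (replicates, clusters), correction applied
    p_values: list[float] = field(default_factory=list)
    enriched: bool = False
    depleted: bool = False


def enrichment_test(
    empirical,
    replicates,
    correction_factor=1.0,
    alpha: float = 0.05,
    category: str = "",
    branch_type: str = "",
) -> EnrichmentResult:
    """Test a category's per-cluster counts against each simulated replicate.

    ``empirical`` is a per-cluster count vector; ``replicates`` an array of
    shape (n_replicates, n_clusters).  Simulated counts are multiplied by
    ``correction_factor`` (scalar, per-replicate vector, or full matrix)
    before testing.  Enriched means: significant (p < alpha) against every
    replicate and empirical mean above every replicate mean.
    """
    emp = np.asarray(empirical, dtype=float)
    sim = np.atleast_2d(np.asarray(replicates, dtype=float))
    if emp.size < 2:
        raise ValueError("need at least two clusters")
    if sim.shape[1] != emp.size:
        raise ValueError("replicate cluster sets must match the empirical set")
    corr = np.asarray(correction_factor, dtype=float)
    sim = sim * (corr if corr.ndim else float(corr))
    p_values = []
    greater = []
    for rep in sim:
        _, p = two_sample_ttest(emp, rep)
        p_values.append(p)
        greater.append(emp.mean() > rep.mean())
    significant = all(p < alpha for p in p_values)
    return EnrichmentResult(
        category=category,
        branch_type=branch_type,
        empirical=emp,
        simulated=sim,
        p_values=p_values,
        enriched=significant and all(greater),
        depleted=significant and not any(greater),
    )
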