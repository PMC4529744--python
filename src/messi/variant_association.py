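"""Mixed-model association of variants with pathway activities.

The model for a pathway activity phenotype ``y`` over ``n`` haploid
strains is the standard single-marker linear mixed model

    y = b0 + b * g + u + e,   u ~ N(0, sg^2 K),   e ~ N(0, se^2 I)

with ``K`` an identity-by-state kinship matrix capturing strain
relatedness.  Writing d = se^2 / sg^2 and eigendecomposing K = U S U^T
once, the model rotates into independent coordinates where the covariance
is diagonal, sg^2 (S + d).  For each variant, d is estimated by REML on a
log-spaced grid over [1e-5, 1e5] (100 points) followed by golden-section
refinement, and the fixed effect b is tested with a generalized
least-squares t-test (two-sided, n - 2 df).  At K = I the weights are
constant in the rotated frame and the test reduces exactly to the
ordinary least-squares t-test.

Permutation adjustment reruns the scan on B seeded permutations of the
phenotype; the adjusted P for a variant is (1 + #{b : P_b <= P_obs}) /
(1 + B), either pointwise per variant (default) or family-wise against
the per-permutation minimum P (min-P flavor).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model_io import GenotypeMatrix

logger = logging.getLogger(__name__)

DELTA_GRID_LO = 1e-5
DELTA_GRID_HI = 1e5
DELTA_GRID_POINTS = 100
REFINE_ITERATIONS = 40
SIGNIFICANCE_P = 0.05


@dataclass
class KinshipMatrix:
    """Symmetric strain x strain relatedness, entries in [0, 1], unit
    diagonal."""

    K: np.ndarray

    def __post_init__(self) -> None:
        K = np.asarray(self.K, dtype=float)
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError("kinship must be square")
        if not np.allclose(K, K.T):
            raise ValueError("kinship must be symmetric")
        if not np.allclose(np.diag(K), 1.0):
            raise ValueError("kinship diagonal must be 1")
        if K.min() < -1e-12 or K.max() > 1 + 1e-12:
            raise ValueError("kinship entries must lie in [0, 1]")
        self.K = K


@dataclass
class AssociationResult:
    variant_key: str
    pathway_id: str
    beta: float
    p_value: float
    adjusted_p: float | None = None

    @property
    def significant(self) -> bool:
        p = self.adjusted_p if self.adjusted_p is not None else self.p_value
        return p < SIGNIFICANCE_P


def filter_variants(
    gm: GenotypeMatrix,
    min_af: float = 0.05,
    effect_classes: set[str] | None = None,
) -> GenotypeMatrix:
    """Drop variants with minor presence frequency below ``min_af`` (both
    rare presence and rare absence), and optionally restrict to a set of
    effect classes."""
    af = gm.allele_frequency()
    keep = (af >= min_af) & (af <= 1.0 - min_af)
    keep &= ~np.isnan(af)
    if effect_classes is not None:
        cls = np.array([v.effect_class in effect_classes for v in gm.variants])
        keep &= cls
    if not keep.any():
        logger.warning("variant filter removed every variant")
    return gm.subset_variants(keep)


def kinship(gm: GenotypeMatrix) -> KinshipMatrix:
    """Identity-by-state kinship: K[a, b] = fraction of variants where
    strains a and b carry the same allele.  Missing calls are imputed as 0
    (reference) so the matrix stays rectangular and positive semidefinite.
    """
    if gm.n_variants < 2:
        raise ValueError("kinship needs at least 2 variants")
    G = np.where(gm.presence == -1, 0, gm.presence).astype(float)
    m = G.shape[0]
    K = (G.T @ G + (1 - G).T @ (1 - G)) / m
    return KinshipMatrix(K=K)


# ---------------------------------------------------------------------------
# REML machinery
# ---------------------------------------------------------------------------


def _eigendecompose(K: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    vals, vecs = np.linalg.eigh(K)
    if vals.min() < -1e-8:
        logger.warning("kinship not PSD (min eigenvalue %.3g); clipping", vals.min())
    vals = np.clip(vals, 0.0, None)
    return vals, vecs


def _reml_criterion(
    s: np.ndarray,
    deltas: np.ndarray,
    Xr: np.ndarray,
    yr: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Profile REML criterion on a batch of delta values for a batch of
    markers sharing the rotated intercept.

    ``Xr``: (m, n, 2) rotated design per marker; ``yr``: (n,) rotated
    phenotype; ``deltas``: (m, d) candidate values per marker.  Returns
    (criterion, beta, rss) each of shape (m, d) [beta is the marker
    coefficient].  The criterion drops terms constant in delta.
    """
    m, n, _ = Xr.shape
    d = deltas.shape[1]
    # weights: (m, d, n)
    w = 1.0 / (s[None, None, :] + deltas[:, :, None])
    x0 = Xr[:, :, 0]  # (m, n) intercept column, identical across markers
    x1 = Xr[:, :, 1]  # (m, n) marker column
    a00 = np.einsum("mdn,mn,mn->md", w, x0, x0)
    a01 = np.einsum("mdn,mn,mn->md", w, x0, x1)
    a11 = np.einsum("mdn,mn,mn->md", w, x1, x1)
    b0 = np.einsum("mdn,mn,n->md", w, x0, yr)
    b1 = np.einsum("mdn,mn,n->md", w, x1, yr)
    yy = np.einsum("mdn,n,n->md", w, yr, yr)
    det = a00 * a11 - a01 * a01
    det = np.maximum(det, 1e-300)
    beta1 = (a00 * b1 - a01 * b0) / det
    beta0 = (a11 * b0 - a01 * b1) / det
    rss = np.maximum(yy - beta0 * b0 - beta1 * b1, 1e-300)
    logdet_h = np.log(s[None, None, :] + deltas[:, :, None]).sum(axis=2)
    crit = -(n - 2) * np.log(rss) - logdet_h - np.log(det)
    return crit, beta1, rss


def _scan_rotated(
    s: np.ndarray, Xr: np.ndarray, yr: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Grid + golden-section REML scan in the rotated frame.

    Returns (beta, t, p) arrays of length m (NaN where degenerate).
    """
    m, n, _ = Xr.shape
    grid = np.geomspace(DELTA_GRID_LO, DELTA_GRID_HI, DELTA_GRID_POINTS)
    crit, _, _ = _reml_criterion(s, np.broadcast_to(grid, (m, grid.size)), Xr, yr)
    best = np.argmax(crit, axis=1)
    lo = np.log(grid[np.maximum(best - 1, 0)])
    hi = np.log(grid[np.minimum(best + 1, grid.size - 1)])
    # golden-section refinement in log-delta, vectorized over markers
    gr = (np.sqrt(5.0) - 1.0) / 2.0
    c = hi - gr * (hi - lo)
    d_ = lo + gr * (hi - lo)
    fc, _, _ = _reml_criterion(s, np.exp(c)[:, None], Xr, yr)
    fd, _, _ = _reml_criterion(s, np.exp(d_)[:, None], Xr, yr)
    fc, fd = fc[:, 0], fd[:, 0]
    for _ in range(REFINE_ITERATIONS):
        take_left = fc > fd
        hi = np.where(take_left, d_, hi)
        lo = np.where(take_left, lo, c)
        c = hi - gr * (hi - lo)
        d_ = lo + gr * (hi - lo)
        fc, _, _ = _reml_criterion(s, np.exp(c)[:, None], Xr, yr)
        fd, _, _ = _reml_criterion(s, np.exp(d_)[:, None], Xr, yr)
        fc, fd = fc[:, 0], fd[:, 0]
    delta_hat = np.exp((lo + hi) / 2.0)

    # final GLS t-test at the REML delta
    w = 1.0 / (s[None, :] + delta_hat[:, None])  # (m, n)
    x0 = Xr[:, :, 0]
    x1 = Xr[:, :, 1]
    a00 = np.einsum("mn,mn,mn->m", w, x0, x0)
    a01 = np.einsum("mn,mn,mn->m", w, x0, x1)
    a11 = np.einsum("mn,mn,mn->m", w, x1, x1)
    b0 = np.einsum("mn,mn,n->m", w, x0, yr)
    b1 = np.einsum("mn,mn,n->m", w, x1, yr)
    yy = np.einsum("mn,n,n->m", w, yr, yr)
    det = a00 * a11 - a01 * a01
    with np.errstate(divide="ignore", invalid="ignore"):
        beta1 = (a00 * b1 - a01 * b0) / det
        beta0 = (a11 * b0 - a01 * b1) / det
        rss = np.maximum(yy - beta0 * b0 - beta1 * b1, 0.0)
        sigma2 = rss / (n - 2)
        var_b1 = sigma2 * a00 / det
        t = beta1 / np.sqrt(var_b1)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return beta1, t, p


class MixedModelScanner:
    """Reusable scanner: eigendecomposes K once and scans phenotypes.

    Monomorphic variants get P = NaN.  Variants with missing genotype
    calls take a slow path that drops the affected strains and
    re-decomposes the subset kinship for that variant alone.
    """

    def __init__(self, gm: GenotypeMatrix, K: KinshipMatrix):
        n = len(gm.strains)
        if K.K.shape[0] != n:
            raise ValueError("kinship dimension does not match strain count")
        self.gm = gm
        self.K = K.K
        self.s, self.U = _eigendecompose(self.K)
        self.ones_r = self.U.T @ np.ones(n)
        self.G = gm.presence.astype(float)  # (m, n), -1 for missing

    def scan(self, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Scan one phenotype vector; returns (beta, p) per variant."""
        y = np.asarray(y, dtype=float)
        n = self.K.shape[0]
        if y.shape != (n,):
            raise ValueError("phenotype length must equal strain count")
        m = self.G.shape[0]
        beta = np.full(m, np.nan)
        pval = np.full(m, np.nan)

        missing = (self.gm.presence == -1).any(axis=1)
        mono = np.array(
            [
                len(np.unique(row[row >= 0])) < 2
                for row in self.gm.presence
            ]
        )
        fast = ~missing & ~mono
        if fast.any():
            idx = np.flatnonzero(fast)
            yr = self.U.T @ y
            Gr = self.G[idx] @ self.U  # (k, n)
            Xr = np.stack(
                [np.broadcast_to(self.ones_r, Gr.shape), Gr], axis=2
            )
            b, _, p = _scan_rotated(self.s, Xr, yr)
            beta[idx] = b
            pval[idx] = p
        for i in np.flatnonzero(missing & ~mono):
            g = self.gm.presence[i]
            keep = g >= 0
            if len(np.unique(g[keep])) < 2:
                continue
            sub_s, sub_U = _eigendecompose(self.K[np.ix_(keep, keep)])
            yr = sub_U.T @ y[keep]
            ones_r = sub_U.T @ np.ones(keep.sum())
            gr = (g[keep].astype(float) @ sub_U)[None, :]
            Xr = np.stack([ones_r[None, :], gr], axis=2)
            b, _, p = _scan_rotated(sub_s, Xr, yr)
            beta[i], pval[i] = b[0], p[0]
        return beta, pval


def mixed_model_scan(
    y: np.ndarray, gm: GenotypeMatrix, K: KinshipMatrix, pathway_id: str = ""
) -> list[AssociationResult]:
    """Test every variant against one phenotype; monomorphic variants are
    skipped (absent from the result list)."""
    scanner = MixedModelScanner(gm, K)
    beta, pval = scanner.scan(np.asarray(y, dtype=float))
    out = []
    for v, b, p in zip(gm.variants, beta, pval):
        if np.isnan(p):
            continue
        out.append(
            AssociationResult(
                variant_key=v.key, pathway_id=pathway_id, beta=float(b),
                p_value=float(p),
            )
        )
    return out


def permutation_adjust(
    y: np.ndarray,
    gm: GenotypeMatrix,
    K: KinshipMatrix,
    n_permutations: int = 1000,
    seed: int = 0,
    family_wise: bool = False,
) -> np.ndarray:
    """Permutation-adjusted P values for a full scan.

    Pointwise (default): each variant is compared against its own null
    distribution across permutations.  ``family_wise`` compares against
    the per-permutation minimum P over all variants (min-P adjustment).
    Returns an array aligned with ``gm.variants``; NaN for monomorphic
    variants.
    """
    if n_permutations < 1:
        raise ValueError("need at least 1 permutation")
    rng = np.random.default_rng(seed)
    scanner = MixedModelScanner(gm, K)
    y = np.asarray(y, dtype=float)
    _, p_obs = scanner.scan(y)
    exceed = np.zeros_like(p_obs)
    for _ in range(n_permutations):
        _, p_b = scanner.scan(rng.permutation(y))
        if family_wise:
            ref = np.nanmin(p_b)
            exceed += (ref <= p_obs).astype(float)
        else:
            exceed += (p_b <= p_obs).astype(float)
    adj = (1.0 + exceed) / (1.0 + n_permutations)
    adj[np.isnan(p_obs)] = np.nan
    return adj
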