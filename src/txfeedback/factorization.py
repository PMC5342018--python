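"""Uncertainty-weighted nonnegative matrix factorization of condition means.

The model is elementwise normal: ``D ~ N(AP, Sigma)`` with nonnegative
amplitude matrix ``A`` (genes x k) and pattern matrix ``P`` (k x conditions).
The point estimate minimizes the weighted residual (chi-squared)

    sum_ij ((D_ij - (AP)_ij) / Sigma_ij)^2

by deterministic alternating weighted nonnegative least squares: each sweep
solves the gene-wise amplitude rows and condition-wise pattern columns
exactly, so the objective is monotone non-increasing and iterates reach the
nonnegativity boundary (exact zeros), which resolves the rotational
ambiguity of interior solutions.  Uncertainty in A and P is quantified by a
parametric bootstrap: resample ``D* ~ N(AP, Sigma)``, refit warm-started
from the point estimate, and retain the draws.  Pattern rows are normalized to sum to one,
with the compensating scale moved into the matching column of A, so the
product AP is unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .errors import DegeneratePatternError, InputError
from .preprocess import FactorInput

_EPS = 1e-12
#: Pattern rows whose coefficient of variation falls below this are treated as
#: constant-type when correlating patterns: a (near-)flat sum-to-one row
#: carries no shape information, so Pearson r against it is undefined or pure
#: noise.  Two constant-type rows agree by convention (r = 1, they both
#: represent the baseline program); a constant/structured pair scores 0.
FLAT_PATTERN_CV = 0.3


@dataclass
class FactorizationResult:
    """Point estimate, bootstrap draws and bookkeeping for one factorization."""

    A: pd.DataFrame                     # genes x k, nonnegative
    P: pd.DataFrame                     # k x conditions, rows sum to 1
    samples: list                       # [(A_draw, P_draw) ndarrays], normalized
    k: int
    chi2: float
    seed: int
    n_iter: int
    n_sweeps: int = 0
    converged: bool = False
    chi2_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def pattern_names(self) -> list[str]:
        return list(self.P.index)


def weighted_residual(fi: FactorInput, A: np.ndarray, P: np.ndarray) -> float:
    """Chi-squared of the normal model: sum of squared standardized residuals."""
    D = np.asarray(fi.D, dtype=float)
    Sigma = np.asarray(fi.Sigma, dtype=float)
    A = np.asarray(A, dtype=float)
    P = np.asarray(P, dtype=float)
    if A.shape[0] != D.shape[0] or P.shape[1] != D.shape[1] or A.shape[1] != P.shape[0]:
        raise InputError("A/P shapes do not conform with D")
    if (Sigma <= 0).any():
        raise InputError("Sigma must be strictly positive")
    return float(np.sum(((D - A @ P) / Sigma) ** 2))


def normalize_patterns(A, P):
    """Rescale each pattern row to sum to one; A absorbs the scale.

    Accepts and returns either ndarrays or DataFrames; the product ``A @ P``
    is invariant.
    """
    A_arr = np.asarray(A, dtype=float).copy()
    P_arr = np.asarray(P, dtype=float).copy()
    sums = P_arr.sum(axis=1)
    if (sums <= 0).any():
        raise DegeneratePatternError("pattern row with non-positive sum")
    P_arr /= sums[:, None]
    A_arr *= sums[None, :]
    if isinstance(A, pd.DataFrame) and isinstance(P, pd.DataFrame):
        return (pd.DataFrame(A_arr, index=A.index, columns=A.columns),
                pd.DataFrame(P_arr, index=P.index, columns=P.columns))
    return A_arr, P_arr


def _batched_nnls(M: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Exact nonnegative least squares for a batch of small quadratic problems.

    Solves, for every batch item b, ``min_{a >= 0} a'M[b]a - 2 a'v[b]`` by
    enumerating all supports (k is small, at most the pattern count): the
    optimum's support yields the unconstrained solution on that support, so
    the best feasible candidate over all supports is the exact optimum.
    """
    n, k = v.shape
    best_obj = np.zeros(n)            # a = 0 candidate
    best_a = np.zeros((n, k))
    ridge = 1e-10 * (np.trace(M, axis1=1, axis2=2)[:, None, None] + 1.0)
    for mask in range(1, 2**k):
        support = [i for i in range(k) if mask >> i & 1]
        Ms = M[np.ix_(range(n), support, support)] + ridge * np.eye(len(support))
        vs = v[:, support]
        try:
            a_s = np.linalg.solve(Ms, vs[..., None])[..., 0]
        except np.linalg.LinAlgError:  # pragma: no cover - ridge prevents this
            continue
        feasible = (a_s >= -1e-12).all(axis=1)
        # objective value at the LS solution: -a'v (lower is better)
        obj = -np.einsum("ni,ni->n", a_s, vs)
        better = feasible & (obj < best_obj)
        if better.any():
            a_full = np.zeros((n, k))
            a_full[:, support] = np.clip(a_s, 0.0, None)
            best_a[better] = a_full[better]
            best_obj[better] = obj[better]
    return best_a


def _fit(D: np.ndarray, W: np.ndarray, A: np.ndarray, P: np.ndarray,
         max_sweeps: int, tol: float) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """Alternating exact weighted NNLS on the chi-squared objective.

    Each sweep solves the gene-wise amplitude rows exactly for fixed P, then
    the condition-wise pattern columns exactly for fixed A; both block
    updates are exact minimizers, so the objective never increases.  Returns
    updated (A, P), the chi2 trace (one entry per sweep), and a convergence
    flag.
    """
    WD = W * D
    history = np.empty(max_sweeps)
    prev = np.inf
    converged = False
    n = 0
    for n in range(max_sweeps):
        # A rows: M_g = P diag(W_g) P', v_g = P (W_g * D_g)
        M = np.einsum("kc,gc,lc->gkl", P, W, P, optimize=True)
        v = np.einsum("kc,gc->gk", P, WD, optimize=True)
        A = _batched_nnls(M, v)
        # P columns: M_c = A' diag(W_c) A, v_c = A' (W_c * D_c)
        M = np.einsum("gk,gc,gl->ckl", A, W, A, optimize=True)
        v = np.einsum("gk,gc->ck", A, WD, optimize=True)
        P = _batched_nnls(M, v).T
        chi2 = np.sum(W * (D - A @ P) ** 2)
        history[n] = chi2
        if np.isfinite(prev) and prev - chi2 <= tol * max(prev, _EPS):
            converged = True
            break
        prev = chi2
    return A, P, history[: n + 1], converged


def factorize(fi: FactorInput, k: int, n_iter: int = 50_000, seed: int = 0,
              n_draws: int = 50, tol: float = 1e-8,
              boot_sweeps: int = 300) -> FactorizationResult:
    """Fit the uncertainty-weighted NMF and draw bootstrap samples.

    Parameters
    ----------
    fi
        Condition means and floored uncertainties.
    k
        Number of patterns.
    n_iter
        Budget of optimizer update sweeps for the point estimate; descent
        stops earlier when the relative chi2 change drops below ``tol``.
    n_draws
        Parametric-bootstrap refits retained for downstream z-scores
        (minimum 2).
    boot_sweeps
        Sweep budget per warm-started bootstrap refit.
    """
    D = np.asarray(fi.D, dtype=float)
    Sigma = np.asarray(fi.Sigma, dtype=float)
    if not (np.isfinite(D).all() and np.isfinite(Sigma).all()):
        raise InputError("non-finite values in D or Sigma")
    if (Sigma <= 0).any():
        raise InputError("Sigma must be strictly positive (apply the floor first)")
    if k < 1 or k > min(D.shape):
        raise InputError(f"k must lie in [1, min(genes, conditions)], got {k}")
    if n_iter < 1:
        raise InputError("n_iter must be >= 1")
    if n_draws < 2:
        raise InputError("need at least 2 bootstrap draws")

    rng = np.random.default_rng(seed)
    W = 1.0 / Sigma**2
    A, P = _nndsvd_init(D, k, rng)

    A, P, history, converged = _fit(D, W, A, P, n_iter, tol)
    A, P = _sharpen_against_baseline(A, P)
    A, P = _repair_empty_patterns(A, P)
    A, P = normalize_patterns(A, P)
    chi2 = float(np.sum(W * (D - A @ P) ** 2))

    samples = []
    for _ in range(n_draws):
        D_star = rng.normal(A @ P, Sigma)
        A_b, P_b, _, _ = _fit(D_star, W, A.copy(), P.copy(), boot_sweeps, tol)
        A_b, P_b = _sharpen_against_baseline(A_b, P_b)
        A_b, P_b = _repair_empty_patterns(A_b, P_b)
        samples.append(normalize_patterns(A_b, P_b))

    pattern_ids = [f"pattern_{i + 1}" for i in range(k)]
    return FactorizationResult(
        A=pd.DataFrame(A, index=fi.D.index, columns=pattern_ids),
        P=pd.DataFrame(P, index=pattern_ids, columns=fi.D.columns),
        samples=samples, k=k, chi2=chi2, seed=seed, n_iter=n_iter,
        n_sweeps=len(history), converged=converged, chi2_history=history,
    )


#: Relative amplitude of the seeded multiplicative jitter applied to the
#: SVD-based initialization; run-to-run variation under different seeds
#: probes basin stability without leaving a good starting region.
_INIT_JITTER = 0.1


def _nndsvd_init(D: np.ndarray, k: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """SVD-based nonnegative initialization (NNDSVD) with seeded jitter.

    The leading singular pair is nonnegative (Perron-Frobenius) and seeds a
    baseline-like component; later components contribute whichever of their
    positive or negative parts carries more energy.
    """
    U, s, Vt = np.linalg.svd(D, full_matrices=False)
    A = np.empty((D.shape[0], k))
    P = np.empty((k, D.shape[1]))
    A[:, 0] = np.abs(U[:, 0]) * np.sqrt(s[0])
    P[0] = np.abs(Vt[0]) * np.sqrt(s[0])
    for j in range(1, k):
        u, v = U[:, j], Vt[j]
        up, un = np.clip(u, 0, None), np.clip(-u, 0, None)
        vp, vn = np.clip(v, 0, None), np.clip(-v, 0, None)
        if np.linalg.norm(up) * np.linalg.norm(vp) >= np.linalg.norm(un) * np.linalg.norm(vn):
            uu, vv = up, vp
        else:
            uu, vv = un, vn
        nu = np.linalg.norm(uu) + _EPS
        nv = np.linalg.norm(vv) + _EPS
        A[:, j] = uu / nu * np.sqrt(s[j] * nu * nv)
        P[j] = vv / nv * np.sqrt(s[j] * nu * nv)
    A *= rng.uniform(1.0 - _INIT_JITTER, 1.0 + _INIT_JITTER, A.shape)
    P *= rng.uniform(1.0 - _INIT_JITTER, 1.0 + _INIT_JITTER, P.shape)
    floor = 1e-6 * max(np.abs(D).mean(), _EPS)
    A[A <= 0] = floor
    P[P <= 0] = floor
    return A, P


def _sharpen_against_baseline(A: np.ndarray, P: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Canonicalize the offset ambiguity: make patterns maximally distinct from baseline.

    The model is invariant to moving a multiple of a flat baseline pattern
    into any other pattern (``p_j -> p_j + lam * p_b`` with the amplitude
    column of ``b`` compensating), which leaves fitted patterns with an
    arbitrary shared offset.  This picks the flattest pattern (lowest
    coefficient of variation) as the baseline and subtracts from every other
    pattern the largest multiple of it that keeps the row nonnegative; the
    baseline amplitude column absorbs the difference.  ``A @ P`` is exactly
    unchanged.
    """
    k = P.shape[0]
    if k < 2:
        return A, P
    A = A.copy()
    P = P.copy()
    means = P.mean(axis=1)
    cv = np.where(means > 0, P.std(axis=1) / np.maximum(means, _EPS), np.inf)
    b = int(np.argmin(cv))
    base = P[b]
    if (base <= 0).any():
        return A, P
    for j in range(k):
        if j == b:
            continue
        lam = float(np.min(P[j] / base))
        if lam > 0:
            P[j] -= lam * base
            A[:, b] += lam * A[:, j]
    return A, P


def _repair_empty_patterns(A: np.ndarray, P: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Replace all-zero pattern rows with a uniform row and zero amplitude.

    Keeps ``A @ P`` unchanged (the amplitude column is zero) while making the
    row normalizable; such patterns carry no signal and surface as unstable
    in robustness checks.
    """
    empty = P.sum(axis=1) <= _EPS
    if empty.any():
        P = P.copy()
        A = A.copy()
        P[empty] = 1.0 / P.shape[1]
        A[:, empty] = 0.0
    return A, P


def _pattern_correlations(P_ref: np.ndarray, P_other: np.ndarray,
                          flat_cv: float = FLAT_PATTERN_CV) -> np.ndarray:
    """Pairwise Pearson correlation between pattern rows.

    Pearson is undefined against a constant row and meaningless against a
    near-flat one (its residual wiggle is noise).  Rows with coefficient of
    variation at or below ``flat_cv`` are treated as constant-type: two such
    rows correlate at 1 by convention, a constant/structured pair at 0.
    """
    ref = np.asarray(P_ref, dtype=float)
    oth = np.asarray(P_other, dtype=float)
    rc = ref - ref.mean(axis=1, keepdims=True)
    oc = oth - oth.mean(axis=1, keepdims=True)
    sd_r = rc.std(axis=1)
    sd_o = oc.std(axis=1)
    const_r = sd_r <= flat_cv * np.maximum(np.abs(ref).mean(axis=1), _EPS)
    const_o = sd_o <= flat_cv * np.maximum(np.abs(oth).mean(axis=1), _EPS)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (rc @ oc.T) / np.outer(sd_r, sd_o) / ref.shape[1]
    corr = np.nan_to_num(corr, nan=0.0)
    both = np.outer(const_r, const_o)
    corr[both] = 1.0
    corr[np.outer(const_r, ~const_o) | np.outer(~const_r, const_o)] = 0.0
    return corr


@dataclass
class PatternMatching:
    """One-to-one assignment of pattern rows maximizing total correlation."""

    pairs: list[tuple[int, int]]        # (ref row, other row)
    correlations: list[float]
    unmatched_ref: list[int] = field(default_factory=list)
    unmatched_other: list[int] = field(default_factory=list)

    @property
    def min_correlation(self) -> float:
        return min(self.correlations) if self.correlations else float("nan")


def match_patterns(P_ref, P_other, flat_cv: float = FLAT_PATTERN_CV) -> PatternMatching:
    """Hungarian assignment of ``P_other`` rows to ``P_ref`` rows by Pearson r.

    When both inputs are DataFrames their condition columns are aligned by
    label first.
    """
    if isinstance(P_ref, pd.DataFrame) and isinstance(P_other, pd.DataFrame):
        if set(P_ref.columns) != set(P_other.columns):
            raise InputError("pattern matrices have different condition labels")
        P_other = P_other[P_ref.columns]
    ref = np.atleast_2d(np.asarray(P_ref, dtype=float))
    oth = np.atleast_2d(np.asarray(P_other, dtype=float))
    if ref.shape[1] != oth.shape[1]:
        raise InputError("pattern matrices have different condition dimensions")
    corr = _pattern_correlations(ref, oth, flat_cv=flat_cv)
    rows, cols = linear_sum_assignment(-corr)
    pairs = list(zip(rows.tolist(), cols.tolist()))
    return PatternMatching(
        pairs=pairs,
        correlations=[float(corr[i, j]) for i, j in pairs],
        unmatched_ref=sorted(set(range(ref.shape[0])) - set(rows.tolist())),
        unmatched_other=sorted(set(range(oth.shape[0])) - set(cols.tolist())),
    )


@dataclass
class DimensionSelection:
    """Outcome of the pattern-robustness scan over candidate k."""

    k: int
    robustness: dict[int, float]        # k -> min matched pattern stability
    threshold: float
    warning: bool = False               # no k met the threshold


def select_dimension(fi: FactorInput, k_range=range(2, 7), n_runs: int = 3,
                     seed: int = 0, threshold: float = 0.9,
                     n_iter: int = 300, n_draws: int | None = None) -> DimensionSelection:
    """Choose the pattern count by pattern robustness under data perturbation.

    For each candidate k the factorization is fit once and re-fit on
    ``n_runs`` parametric-bootstrap resamples of the data; robustness is the
    worst matched-pattern correlation between the point estimate and any
    resample fit.  Patterns that track real structure persist when the noise
    is redrawn; patterns that chase a particular noise realization do not.
    The largest k whose robustness reaches ``threshold`` is selected; if none
    qualifies the smallest candidate is returned with a warning flag.
    """
    if n_runs < 2:
        raise InputError("n_runs must be >= 2")
    ks = sorted(k_range)
    if not ks:
        raise InputError("empty k range")
    if n_draws is None:
        n_draws = n_runs
    robustness: dict[int, float] = {}
    for k in ks:
        run_seed = int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))
        res = factorize(fi, k, n_iter=n_iter, seed=run_seed, n_draws=n_draws,
                        boot_sweeps=n_iter)
        worst = 1.0
        for A_b, P_b in res.samples[:n_runs]:
            m = match_patterns(res.P.to_numpy(), P_b)
            worst = min(worst, m.min_correlation)
        robustness[k] = worst
    qualifying = [k for k in ks if robustness[k] >= threshold]
    if qualifying:
        return DimensionSelection(k=max(qualifying), robustness=robustness,
                                  threshold=threshold)
    return DimensionSelection(k=min(ks), robustness=robustness,
                              threshold=threshold, warning=True)
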