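"""Monotone data augmentation (MDA) Gibbs sampler for LNI regression.

Model (on the log scale): for case i,

    log Y_i | B, Psi, w_i ~ N_p(B' x_i,  Psi / w_i),   w_i ~ H(w | nu),

with the response matrix arranged into a monotone missing pattern.  The
prior on (B, Psi) is flat in B and inverse-Wishart-type in Psi,

    P(B, Psi)  propto  det(Psi)^(-(m+1)/2) etr(-Psi^{-1} A / 2),

with noninformative default A = 0, m = p.  The nu prior is ``nu^(-2)``
(improper) for the log-t family and Gamma(a, b) (default a=6, b=2) for the
log-slash family.

The joint (B, Psi) draw exploits the monotone layout: with columns ordered
so that cases observing column k also observe columns 1..k-1, the
likelihood factorizes into p sequential weighted regressions of column k of
log Y on (X, columns 1..k-1), each over the N_k cases covering column k.
Writing Psi in its sequential-conditional parameterization
(phi_k = regression coefficients of column k on 1..k-1, tau_k = conditional
variance), the prior factorizes as well — det(Psi) = prod tau_k, the etr
term splits into per-k Gaussian pseudo-observations built from a square
root of A, and the Jacobian of Psi -> (phi, tau) contributes
prod_k tau_k^(p-k).  Each block is then a standard normal-inverse-gamma
draw:

    tau_k ~ InvGamma(alpha_k, s_k / 2),
    a_k | tau_k ~ N(ahat_k, tau_k G_k^{-1}),

with G_k the (pseudo-)weighted cross-product matrix, s_k the weighted
residual sum of squares, and

    alpha_k = (m + N_k - q_k - 2(p - k) - 1) / 2,   q_k = r + k - 1.

(B, Psi) are reassembled from the blocks by the usual recursions.  The
complete-data p=1 and p=2 conjugate posteriors pin this convention exactly.

Per sweep the update order follows the family:

* log-t (ECME flavour):  nu -> w -> fill-in imputation -> (Psi, B)
* log-slash (EM flavour): w -> fill-in imputation -> (B, Psi) -> nu
* log-normal: fill-in imputation -> (B, Psi), w identically 1.

nu is drawn from its observed-data conditional (griddy Gibbs on a
logarithmic grid) for log-t, and from the conjugate
Gamma(a + n, b - sum log w_i) for log-slash.  Only the fill-in cells are
ever imputed; trailing missing cells in the monotone layout integrate out.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, special

from .families import LOG_NORMAL, LOG_SLASH, LOG_T, MixingFamily, get_family
from .monotone import MonotoneArrangement, RegressionData, arrange_monotone

__all__ = [
    "PriorSpec",
    "ModelSpec",
    "ChainState",
    "PosteriorDraws",
    "PosteriorSummary",
    "init_state",
    "draw_b_psi",
    "impute_monotone_missing",
    "draw_weights",
    "draw_nu_slash",
    "draw_nu_t",
    "run_mda",
    "summarize",
]


@dataclass
class PriorSpec:
    """Hyperparameters of the (B, Psi) and nu priors.

    ``A = None`` means the zero matrix and ``m = None`` means m = p (the
    noninformative default).  ``slash_a``/``slash_b`` are the Gamma prior
    for the slash tail parameter; the log-t nu prior is fixed at
    ``nu^(-2)`` restricted to the griddy grid ``[grid_lo, grid_hi]``.
    """

    A: np.ndarray | None = None
    m: int | None = None
    slash_a: float = 6.0
    slash_b: float = 2.0
    grid_lo: float = 0.5
    grid_hi: float = 200.0
    grid_size: int = 400

    def resolved(self, p: int) -> tuple[np.ndarray, int]:
        cached = self.__dict__.get("_resolved_cache")
        if cached is not None and cached[0] == p:
            return cached[1], cached[2]
        A = np.zeros((p, p)) if self.A is None else np.asarray(self.A, dtype=float)
        if A.shape != (p, p):
            raise ValueError(f"prior scale A must be {p}x{p}")
        if not np.allclose(A, A.T):
            raise ValueError("prior scale A must be symmetric")
        if np.any(np.linalg.eigvalsh(A) < -1e-10):
            raise ValueError("prior scale A must be nonnegative definite")
        m = p if self.m is None else int(self.m)
        self.__dict__["_resolved_cache"] = (p, A, m)
        return A, m

    def nu_grid(self):
        """Cached (grid, edges, widths, prior log-density) for griddy Gibbs."""
        key = (self.grid_lo, self.grid_hi, self.grid_size)
        cached = self.__dict__.get("_grid_cache")
        if cached is not None and cached[0] == key:
            return cached[1]
        grid = np.geomspace(self.grid_lo, self.grid_hi, self.grid_size)
        edges = np.empty(self.grid_size + 1)
        edges[1:-1] = np.sqrt(grid[:-1] * grid[1:])
        edges[0], edges[-1] = grid[0], grid[-1]
        widths = np.diff(edges)
        bundle = (grid, edges, widths, -2.0 * np.log(grid), {})
        self.__dict__["_grid_cache"] = (key, bundle)
        return bundle


@dataclass
class ModelSpec:
    """Family choice plus prior hyperparameters."""

    family: MixingFamily | str = LOG_SLASH
    prior: PriorSpec = field(default_factory=PriorSpec)

    def __post_init__(self):
        self.family = get_family(self.family)


@dataclass
class ChainState:
    """Current Gibbs state (all response-indexed arrays in ascending-
    missingness arranged coordinates)."""

    B: np.ndarray
    Psi: np.ndarray
    nu: float | None
    w: np.ndarray
    T: np.ndarray  # completed log-responses; NaN on never-imputed cells
    iteration: int = 0


@dataclass
class PosteriorSummary:
    """Elementwise posterior medians and equal-tail 95% intervals."""

    B_median: np.ndarray
    B_lower: np.ndarray
    B_upper: np.ndarray
    Psi_median: np.ndarray
    Psi_lower: np.ndarray
    Psi_upper: np.ndarray
    nu_median: float | None
    nu_lower: float | None
    nu_upper: float | None
    response_names: list[str]
    covariate_names: list[str]

    @property
    def B_excludes_zero(self) -> np.ndarray:
        """True where the 95% interval for a coefficient excludes zero."""
        return (self.B_lower > 0) | (self.B_upper < 0)

    def coefficient_table(self) -> pd.DataFrame:
        """Coefficient report: estimate with lower/upper interval bounds."""
        rows = []
        for k, resp in enumerate(self.response_names):
            for j, cov in enumerate(self.covariate_names):
                rows.append(
                    {
                        "response": resp,
                        "covariate": cov,
                        "estimate": self.B_median[j, k],
                        "lower": self.B_lower[j, k],
                        "upper": self.B_upper[j, k],
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class PosteriorDraws:
    """Retained post-burn-in chains, in the original response order."""

    B: np.ndarray  # (S, r, p)
    Psi: np.ndarray  # (S, p, p)
    nu: np.ndarray | None  # (S,) or None for log-normal
    family: MixingFamily
    response_names: list[str]
    covariate_names: list[str]
    config: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.B.shape[0]

    def summarize(self) -> PosteriorSummary:
        return summarize(self)

    def to_frame(self) -> pd.DataFrame:
        """Flatten draws to one row per retained iteration.

        Columns ``B[j,k]`` (1-based), upper-triangle ``Psi[j,k]`` and, for
        heavy-tailed families, ``nu``.
        """
        S, r, p = self.B.shape
        cols = {}
        for j in range(r):
            for k in range(p):
                cols[f"B[{j + 1},{k + 1}]"] = self.B[:, j, k]
        for j in range(p):
            for k in range(j, p):
                cols[f"Psi[{j + 1},{k + 1}]"] = self.Psi[:, j, k]
        if self.nu is not None:
            cols["nu"] = self.nu
        return pd.DataFrame(cols)


def summarize(draws: PosteriorDraws) -> PosteriorSummary:
    """Elementwise posterior medians and equal-tail 95% credible intervals."""
    if len(draws) == 0:
        raise ValueError("empty chain")
    qs = (0.025, 0.5, 0.975)
    Bq = np.quantile(draws.B, qs, axis=0)
    Pq = np.quantile(draws.Psi, qs, axis=0)
    if draws.nu is not None:
        nq = np.quantile(draws.nu, qs)
        nu_l, nu_m, nu_u = float(nq[0]), float(nq[1]), float(nq[2])
    else:
        nu_l = nu_m = nu_u = None
    return PosteriorSummary(
        B_median=Bq[1],
        B_lower=Bq[0],
        B_upper=Bq[2],
        Psi_median=Pq[1],
        Psi_lower=Pq[0],
        Psi_upper=Pq[2],
        nu_median=nu_m,
        nu_lower=nu_l,
        nu_upper=nu_u,
        response_names=draws.response_names,
        covariate_names=draws.covariate_names,
    )


# --------------------------------------------------------------------------
# precomputed layout (ascending-missingness coordinates)
# --------------------------------------------------------------------------


class _Layout:
    """Index structures derived once from the monotone arrangement.

    Internally the sampler works with columns in *ascending* missingness
    order (column 1 the most observed), the reverse of the presentation
    order of :func:`arrange_monotone`, because the sequential factorization
    then regresses column k on columns 1..k-1.
    """

    def __init__(self, data: RegressionData, arr: MonotoneArrangement):
        n, p, r = data.n, data.p, data.r
        self.n, self.p, self.r = n, p, r
        self.arr = arr
        # ascending columns = reversed arranged columns
        Y_arr = arr.apply(data.Y)[:, ::-1]
        self.X = np.ascontiguousarray(data.X[arr.row_order])
        with np.errstate(invalid="ignore"):
            self.T_obs = np.log(Y_arr)
        self.obs_mask = ~np.isnan(Y_arr)
        # coverage: case of (descending) pattern k covers ascending cols
        # 1..p-k+1; rows are sorted by pattern so coverage is nonincreasing
        pat = np.repeat(np.arange(1, p + 1), arr.pattern_counts)
        self.cover = p - pat + 1
        self.N = np.array([(self.cover >= k).sum() for k in range(1, p + 1)])
        # fill-in cells mapped to ascending coords
        fill_mask = np.zeros((n, p), dtype=bool)
        for (i, k) in arr.fill_in_cells:
            fill_mask[i, p - 1 - k] = True
        self.fill_mask = fill_mask
        # groups of rows sharing an observedness pattern (for weights);
        # index grids are precomputed once because they sit on the hot path
        self.obs_groups = []
        for cols_mask, idx in _group_rows(self.obs_mask):
            cols = np.nonzero(cols_mask)[0]
            if cols.size:
                self.obs_groups.append(
                    (cols, idx, np.ix_(idx, cols), np.ix_(cols, cols))
                )
            else:
                self.empty_rows = idx
        # groups of rows sharing (observed set, fill set) (for imputation)
        both = np.concatenate([self.obs_mask, fill_mask], axis=1)
        self.fill_groups = []
        for cols_mask, idx in _group_rows(both):
            if not cols_mask[p:].any():
                continue
            o = np.nonzero(cols_mask[:p])[0]
            mc = np.nonzero(cols_mask[p:])[0]
            psi_grids = (np.ix_(o, o), np.ix_(o, mc), np.ix_(mc, mc), np.ix_(mc, o))
            self.fill_groups.append(
                (o, mc, idx, np.ix_(idx, o), np.ix_(idx, mc), psi_grids)
            )


def _group_rows(mask: np.ndarray):
    """Group row indices by identical boolean rows; deterministic order."""
    order = np.lexsort(mask.T[::-1])
    groups = []
    start = 0
    for i in range(1, len(order) + 1):
        if i == len(order) or not np.array_equal(mask[order[i]], mask[order[start]]):
            idx = np.sort(order[start:i])
            groups.append((mask[idx[0]].copy(), idx))
            start = i
    return groups


# --------------------------------------------------------------------------
# component draws
# --------------------------------------------------------------------------


def _mahalanobis_obs(layout: _Layout, eta: np.ndarray, Psi: np.ndarray):
    """Squared Mahalanobis distance of each case's observed log-responses.

    ``eta = X @ B``.  Returns (delta2, p_obs) arrays of length n; cases
    with nothing observed get delta2 = 0, p_obs = 0.
    """
    delta2 = np.zeros(layout.n)
    p_obs = np.zeros(layout.n, dtype=np.int64)
    for cols, idx, grid, psi_grid in layout.obs_groups:
        R = layout.T_obs[grid] - eta[grid]
        L = np.linalg.cholesky(Psi[psi_grid])
        Z = linalg.solve_triangular(L, R.T, lower=True, check_finite=False)
        delta2[idx] = np.einsum("ji,ji->i", Z, Z)
        p_obs[idx] = cols.size
    return delta2, p_obs


def draw_weights(
    family: MixingFamily,
    nu: float | None,
    delta2: np.ndarray,
    p_obs: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw latent case weights from P(w | B, Psi, Y_obs, X, nu).

    Per case the target is proportional to
    ``h(w | nu) w^(p_i/2) exp(-w delta2_i / 2)``:

    * log-normal: w = 1.
    * log-t: Gamma((nu + p_i)/2, rate (nu + delta2_i)/2).
    * log-slash: Gamma(nu + p_i/2, rate delta2_i/2) truncated to (0, 1),
      drawn by inverse CDF through the regularized incomplete gamma.
    """
    n = delta2.shape[0]
    if family is LOG_NORMAL:
        return np.ones(n)
    if family is LOG_T:
        return rng.gamma(shape=(nu + p_obs) / 2.0, scale=2.0 / (nu + delta2))
    shape = nu + p_obs / 2.0
    rate = delta2 / 2.0
    u = rng.uniform(size=n)
    w = np.empty(n)
    small = rate < 1e-8  # exp factor within 5e-9 of 1 on (0,1): power law
    if np.any(small):
        w[small] = u[small] ** (1.0 / shape[small])
    big = ~small
    if np.any(big):
        F1 = special.gammainc(shape[big], rate[big])
        w[big] = special.gammaincinv(shape[big], u[big] * F1) / rate[big]
    return np.clip(w, 1e-300, 1.0 - 1e-16)


def draw_nu_slash(w: np.ndarray, prior: PriorSpec, rng: np.random.Generator) -> float:
    """Conjugate tail-parameter draw for the log-slash family.

    With w_i ~ Beta(nu, 1) and prior nu ~ Gamma(a, b), the posterior is
    Gamma(a + n, b - sum log w_i); the product of ``nu w_i^(nu-1)`` over
    cases contributes ``nu^n exp(nu sum log w_i)`` to the kernel.
    """
    w = np.asarray(w, dtype=float)
    if np.any((w <= 0) | (w >= 1)):
        raise ValueError("slash weights must lie strictly inside (0, 1)")
    rate = prior.slash_b - float(np.sum(np.log(w)))
    return float(rng.gamma(shape=prior.slash_a + w.size, scale=1.0 / rate))


def draw_nu_t(
    delta2: np.ndarray,
    p_obs: np.ndarray,
    prior: PriorSpec,
    rng: np.random.Generator,
) -> float:
    """Griddy-Gibbs draw of the log-t degrees of freedom.

    Target: P(nu | Y_obs, B, Psi)  propto  nu^(-2) prod_i t_{p_i}(delta2_i),
    the observed-data conditional with the weights integrated out.  The
    unnormalized log-density is evaluated on a fixed logarithmic grid, a
    cell is sampled with probability proportional to density x cell width,
    and the draw is jittered uniformly within the cell.
    """
    grid, edges, widths, lp_prior, table = prior.nu_grid()
    lp = lp_prior.copy()
    nz = p_obs > 0
    d2 = delta2[nz]
    po = p_obs[nz]
    if d2.size:
        # the gamma/log terms depend on the case only through p_i; collapse
        # them over the few distinct observed dimensions (cached per grid)
        upo, counts = np.unique(po, return_counts=True)
        for pk, c in zip(upo, counts):
            term = table.get(int(pk))
            if term is None:
                term = (
                    special.gammaln((grid + pk) / 2.0)
                    - special.gammaln(grid / 2.0)
                    - (pk / 2.0) * np.log(grid)
                )
                table[int(pk)] = term
            lp += c * term
        logq = np.log1p(d2 / grid[:, None])  # (grid, cases)
        lp -= 0.5 * (grid * logq.sum(axis=1) + logq @ po)
    if not np.any(np.isfinite(lp)):
        raise FloatingPointError("nu conditional non-finite on the whole grid")
    prob = np.exp(lp - lp.max()) * widths
    prob /= prob.sum()
    cell = int(np.searchsorted(np.cumsum(prob), rng.uniform(), side="right"))
    cell = min(cell, prior.grid_size - 1)
    return float(rng.uniform(edges[cell], edges[cell + 1]))


def impute_monotone_missing(
    layout: _Layout, state: ChainState, rng: np.random.Generator, eta=None
) -> None:
    """Draw the fill-in cells from their Gaussian conditional, in place.

    For each case the missing sub-vector of log Y given its observed
    components under N(B'x, Psi / w_i) has the textbook conditional mean
    and covariance; observed cells are never touched.  ``eta = X @ B`` may
    be passed to avoid recomputation.
    """
    Psi, w, T = state.Psi, state.w, state.T
    if eta is None:
        eta = layout.X @ state.B
    for o, m_cols, idx, grid_o, grid_m, psi_grids in layout.fill_groups:
        g_oo, g_om, g_mm, g_mo = psi_grids
        if o.size:
            K = np.linalg.solve(Psi[g_oo], Psi[g_om])
            mean = eta[grid_m] + (T[grid_o] - eta[grid_o]) @ K
            C = Psi[g_mm] - Psi[g_mo] @ K
        else:
            mean = eta[grid_m]
            C = Psi[g_mm]
        L = np.linalg.cholesky(C)
        z = rng.standard_normal((idx.size, m_cols.size))
        T[grid_m] = mean + (z @ L.T) / np.sqrt(w[idx])[:, None]


def draw_b_psi(
    layout: _Layout,
    T: np.ndarray,
    w: np.ndarray,
    prior: PriorSpec,
    rng: np.random.Generator,
):
    """One exact joint draw of (B, Psi) from the factorized monotone posterior.

    ``T`` must be monotone-complete (fill-in cells imputed) on the log
    scale, in ascending-missingness column order.  See the module docstring
    for the derivation of the per-block normal-inverse-gamma conditionals.
    """
    n, p, r = layout.n, layout.p, layout.r
    A, m = prior.resolved(p)
    U = np.linalg.cholesky(A + 1e-300 * np.eye(p)).T if A.any() else None
    if not np.all(w > 0):
        raise ValueError("all case weights must be positive")
    B = np.zeros((r, p))
    Psi = np.zeros((p, p))
    ZT = np.concatenate([layout.X, T], axis=1)
    for k in range(p):
        Nk = layout.N[k]
        qk = r + k
        Z = ZT[:Nk, : r + k]
        t = ZT[:Nk, r + k]
        wr = w[:Nk]
        Zw = Z * wr[:, None]
        G = Z.T @ Zw
        h = Zw.T @ t
        tWt = float(wr @ (t * t))
        if U is not None:
            # pseudo-observations from A = U'U: design (0_r, U[:, :k]),
            # response U[:, k], unit weight
            Pk = np.concatenate([np.zeros((p, r)), U[:, :k]], axis=1)
            G += Pk.T @ Pk
            h += Pk.T @ U[:, k]
            tWt += float(U[:, k] @ U[:, k])
        alpha_k = (m + Nk - qk - 2 * (p - 1 - k) - 1) / 2.0
        if alpha_k <= 0 or Nk + (p if U is not None else 0) < qk:
            raise ValueError(
                f"unidentifiable block: stage {k + 1} has {Nk} cases for "
                f"{qk} regressors (prior m={m})"
            )
        try:
            Lg = np.linalg.cholesky(G)
        except np.linalg.LinAlgError:
            raise ValueError(
                f"rank deficiency in stage {k + 1} design matrix"
            ) from None
        ahat = linalg.cho_solve((Lg, True), h, check_finite=False)
        s = max(tWt - float(h @ ahat), 1e-300)
        tau = (s / 2.0) / rng.gamma(alpha_k)
        z = rng.standard_normal(qk)
        a = ahat + math.sqrt(tau) * linalg.solve_triangular(
            Lg.T, z, lower=False, check_finite=False
        )
        bk, phik = a[:r], a[r:]
        B[:, k] = bk + B[:, :k] @ phik
        Psi[:k, k] = Psi[:k, :k] @ phik
        Psi[k, :k] = Psi[:k, k]
        Psi[k, k] = tau + float(phik @ Psi[:k, k])
    return B, Psi


# --------------------------------------------------------------------------
# initialization and main loop
# --------------------------------------------------------------------------


def _impute_covariate_free(T: np.ndarray, obs_mask: np.ndarray, tol: float = 1e-8):
    """Iterated conditional-mean completion of log Y without covariates.

    Starting from column means of the observed cells, missing cells are
    replaced by their Gaussian conditional means under the current
    (mean, covariance) of the completed matrix, iterating to convergence.
    """
    n, p = T.shape
    Tc = T.copy()
    col_means = np.array(
        [np.nanmean(T[:, k]) if obs_mask[:, k].any() else 0.0 for k in range(p)]
    )
    miss = ~obs_mask
    Tc[miss] = np.broadcast_to(col_means, (n, p))[miss]
    if not miss.any():
        return Tc
    groups = _group_rows(obs_mask)
    for _ in range(500):
        mu = Tc.mean(axis=0)
        S = np.cov(Tc, rowvar=False, ddof=0) + 1e-8 * np.eye(p)
        prev = Tc[miss].copy()
        for cols_mask, idx in groups:
            o = np.nonzero(cols_mask)[0]
            mcols = np.nonzero(~cols_mask)[0]
            if mcols.size == 0:
                continue
            if o.size == 0:
                Tc[np.ix_(idx, mcols)] = mu[mcols]
                continue
            K = np.linalg.solve(S[np.ix_(o, o)], S[np.ix_(o, mcols)])
            Tc[np.ix_(idx, mcols)] = mu[mcols] + (
                Tc[np.ix_(idx, o)] - mu[o]
            ) @ K
        if np.max(np.abs(Tc[miss] - prev)) < tol:
            break
    return Tc


def init_state(layout: _Layout, spec: ModelSpec) -> ChainState:
    """Starting values: normal-theory fit to an imputed completion of log Y.

    The missing log-responses are first completed without covariates by
    iterated conditional-mean imputation; B and Psi are then the OLS
    solution of the completed log Y on X and its residual covariance.
    nu starts at 7 for the heavy-tailed families; all weights start at 1.
    """
    n, p, r = layout.n, layout.p, layout.r
    if np.linalg.matrix_rank(layout.X) < r:
        raise ValueError("covariate matrix X is rank deficient")
    Tc = _impute_covariate_free(layout.T_obs, layout.obs_mask)
    B0, *_ = np.linalg.lstsq(layout.X, Tc, rcond=None)
    resid = Tc - layout.X @ B0
    Psi0 = resid.T @ resid / max(n - r, 1) + 1e-8 * np.eye(p)
    T = layout.T_obs.copy()
    T[layout.fill_mask] = Tc[layout.fill_mask]
    nu0 = 7.0 if spec.family.has_nu else None
    return ChainState(B=B0, Psi=Psi0, nu=nu0, w=np.ones(n), T=T)


def run_mda(
    data: RegressionData,
    spec: ModelSpec | None = None,
    iterations: int = 10_000,
    burn_in: int = 1_000,
    seed: int | np.random.Generator | None = None,
    check_invariants: bool = False,
) -> PosteriorDraws:
    """Run the MDA Gibbs sampler and return retained posterior draws.

    Defaults follow the reference protocol: 10,000 iterations with the
    first 1,000 discarded as burn-in, no thinning.  The run is deterministic
    under a fixed integer seed.  ``check_invariants`` re-verifies at every
    sweep that observed cells were never altered (test mode).
    """
    spec = spec if spec is not None else ModelSpec()
    if burn_in < 0 or iterations <= burn_in:
        raise ValueError("need iterations > burn_in >= 0")
    family = spec.family
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    arr = arrange_monotone(data)
    layout = _Layout(data, arr)
    state = init_state(layout, spec)
    n, p, r = layout.n, layout.p, layout.r

    keep = iterations - burn_in
    B_out = np.empty((keep, r, p))
    Psi_out = np.empty((keep, p, p))
    nu_out = np.empty(keep) if family.has_nu else None
    # map ascending-arranged columns back to the original response order
    orig_cols = arr.column_order[::-1]

    obs_vals = layout.T_obs[layout.obs_mask]
    for it in range(iterations):
        if family is LOG_T:
            eta = layout.X @ state.B
            delta2, p_obs = _mahalanobis_obs(layout, eta, state.Psi)
            state.nu = draw_nu_t(delta2, p_obs, spec.prior, rng)
            state.w = draw_weights(family, state.nu, delta2, p_obs, rng)
            impute_monotone_missing(layout, state, rng, eta)
            state.B, state.Psi = draw_b_psi(layout, state.T, state.w, spec.prior, rng)
        elif family is LOG_SLASH:
            eta = layout.X @ state.B
            delta2, p_obs = _mahalanobis_obs(layout, eta, state.Psi)
            state.w = draw_weights(family, state.nu, delta2, p_obs, rng)
            impute_monotone_missing(layout, state, rng, eta)
            state.B, state.Psi = draw_b_psi(layout, state.T, state.w, spec.prior, rng)
            state.nu = draw_nu_slash(state.w, spec.prior, rng)
        else:
            impute_monotone_missing(layout, state, rng)
            state.B, state.Psi = draw_b_psi(layout, state.T, state.w, spec.prior, rng)
        state.iteration = it + 1
        if check_invariants and not np.array_equal(
            state.T[layout.obs_mask], obs_vals
        ):
            raise AssertionError("observed cells were modified by the sampler")
        if it >= burn_in:
            s = it - burn_in
            B_out[s][:, orig_cols] = state.B
            Psi_out[s][np.ix_(orig_cols, orig_cols)] = state.Psi
            if nu_out is not None:
                nu_out[s] = state.nu

    return PosteriorDraws(
        B=B_out,
        Psi=Psi_out,
        nu=nu_out,
        family=family,
        response_names=data.response_names,
        covariate_names=data.covariate_names,
        config={
            "family": family.name,
            "iterations": iterations,
            "burn_in": burn_in,
            "n": n,
            "p": p,
            "r": r,
        },
    )
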