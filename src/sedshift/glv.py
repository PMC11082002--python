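"""Per-stage generalized Lotka-Volterra inference and local stability analysis.

The community model is

    dN_i/dt = N_i (r_i - sum_j a_ij N_j),   i = 1..S,

with N_i the relative abundance of taxon i, r_i its intrinsic growth rate
(per year) and a_ij the strength with which taxon j inhibits taxon i.
Dividing by N_i and applying a forward difference over consecutive dated
samples linearizes the system:

    Delta ln N_i(t_k) / Delta t_k = r_i - sum_j a_ij N_j(t_k),

so each taxon yields a linear regression with coefficients (r_i, a_i1..a_iS).
Because the number of equations per stage window is small relative to S + 1,
the regressions are solved with Tikhonov (ridge) regularization of the
interaction coefficients (the intercept r_i is unpenalized), with the ridge
weight chosen by k-fold cross-validation over contiguous blocks of equations
(one shared weight per stage by default, so the rows of A stay on a common
shrinkage scale).

Stability of a fitted stage follows classic local stability analysis: the
interior equilibrium N* solves A N* = r, the Jacobian there is
-diag(N*) A, and the stage is asymptotically stable when every eigenvalue
has negative real part.  The mean of the real parts ("centroid") is used as
a graded stability level, and pairwise interactions are typed from the signs
of the growth effects e_ij = -a_ij as mutualism (+/+), antagonism (-/-) or
exploitation (+/-).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables_io import CommunityMatrix

DEFAULT_LAMBDA_GRID = np.logspace(-4, 2, 25)
CONDITION_LIMIT = 1e8


@dataclass(frozen=True)
class StageWindow:
    """Contiguous block of samples analyzed as one quasi-stationary stage."""
    index: int  # 1-based stage number
    start: int  # first sample (0-based, inclusive)
    stop: int   # past-the-end sample index

    def __len__(self) -> int:
        return self.stop - self.start


@dataclass
class GLVDesign:
    """Forward-difference regression systems for one window.

    ``X`` (rows = consecutive sample pairs) holds (1, -N_1(t_k), ..., -N_S(t_k));
    column i+1 of the response matrix ``Y`` holds Delta ln N_i / Delta t_k.
    The predictor matrix is shared by all S per-taxon regressions.
    """
    taxa: list
    X: np.ndarray
    Y: np.ndarray
    dt: np.ndarray
    pseudocount: float
    dropped: list = field(default_factory=list)  # all-zero taxa, equations dropped

    @property
    def n_equations(self) -> int:
        return self.X.shape[0]


@dataclass
class GLVFit:
    taxa: list
    r: np.ndarray          # intrinsic growth rates, per year
    A: np.ndarray          # S x S interaction matrix, a_ij = inhibition of i by j
    lambdas: np.ndarray    # chosen ridge weight per taxon
    cv_error: float        # mean out-of-fold squared error at the chosen weights
    pseudocount: float
    dropped: list = field(default_factory=list)

    @property
    def S(self) -> int:
        return len(self.taxa)


@dataclass
class StabilityResult:
    equilibrium: np.ndarray        # N* solving A N* = r
    feasible: bool                 # all N* > 0
    jacobian: np.ndarray
    eigenvalues: np.ndarray        # complex spectrum of the Jacobian
    centroid_re: float             # mean of eigenvalue real parts
    stable: bool                   # max real part < 0


@dataclass
class InteractionSet:
    pairs: pd.DataFrame            # taxon_i, taxon_j, e_ij, e_ji, type
    proportions: dict              # type -> fraction of classified pairs
    strength: dict                 # type -> mean |e| over that type's entries
    n_null: int                    # pairs with an exactly-zero effect, excluded


@dataclass
class StageResult:
    window: StageWindow
    fit: GLVFit | None
    stability: StabilityResult | None
    interactions: InteractionSet | None
    error: str | None = None


# ---------------------------------------------------------------------------
# Windows and design matrices


def stage_windows(n: int, w: int = 10, s: int = 5) -> list[StageWindow]:
    """Sliding stage windows of length ``w`` advancing by ``s`` samples.

    A trailing window may be truncated but never shorter than ``s``; 35
    samples with w=10, s=5 give 7 stages, the last covering 5 samples.
    """
    if w <= s:
        raise ValueError("window length must exceed the step size")
    if n < w:
        raise ValueError(f"need at least {w} samples, got {n}")
    windows = []
    start, k = 0, 1
    while start <= n - s:
        windows.append(StageWindow(index=k, start=start, stop=min(start + w, n)))
        start += s
        k += 1
    return windows


def build_design(matrix: CommunityMatrix, window: StageWindow,
                 pseudocount: float | None = None) -> GLVDesign:
    """Forward-difference design for one stage window.

    Zero abundances are replaced by ``pseudocount`` (default: half the
    smallest nonzero abundance in the window) before taking logs; the
    predictor columns use the raw abundances.
    """
    if len(window) < 3:
        raise ValueError("window must contain at least 3 samples")
    N = matrix.rel.to_numpy(dtype=float)[window.start:window.stop]
    t = matrix.ages.to_numpy(dtype=float)[window.start:window.stop]
    dt = np.diff(t)
    if not np.all(dt > 0):
        raise ValueError("ages must be strictly increasing within the window")
    if pseudocount is None:
        nonzero = N[N > 0]
        if nonzero.size == 0:
            raise ValueError("window is entirely zero")
        pseudocount = 0.5 * float(nonzero.min())
    dropped = [tax for tax, col in zip(matrix.taxon_ids, N.T) if not col.any()]
    if dropped:
        warnings.warn(f"all-zero taxa in window {window.index}: {dropped}")
    Npos = np.where(N > 0, N, pseudocount)
    Y = np.diff(np.log(Npos), axis=0) / dt[:, None]
    X = np.hstack([np.ones((N.shape[0] - 1, 1)), -N[:-1]])
    return GLVDesign(taxa=matrix.taxon_ids, X=X, Y=Y, dt=dt,
                     pseudocount=float(pseudocount), dropped=dropped)


def pool_designs(designs: list[GLVDesign]) -> GLVDesign:
    """Concatenate regression systems from several windows or episodes.

    All designs must share the same taxon list.  Pooling keeps each window's
    forward differences intact — no equation spans the boundary between two
    windows, so between-window state jumps never enter a response.
    """
    if not designs:
        raise ValueError("no designs to pool")
    taxa = designs[0].taxa
    for d in designs[1:]:
        if list(d.taxa) != list(taxa):
            raise ValueError("designs have mismatched taxa")
    dropped = sorted({t for d in designs for t in d.dropped})
    return GLVDesign(taxa=list(taxa),
                     X=np.vstack([d.X for d in designs]),
                     Y=np.vstack([d.Y for d in designs]),
                     dt=np.concatenate([d.dt for d in designs]),
                     pseudocount=float(np.median([d.pseudocount for d in designs])),
                     dropped=dropped)


# ---------------------------------------------------------------------------
# Ridge fitting with k-fold CV


def _ridge_solve(G: np.ndarray, b: np.ndarray, lam: float) -> np.ndarray:
    """Solve (G + lam*D) beta = b with the intercept (index 0) unpenalized."""
    D = np.eye(G.shape[0])
    D[0, 0] = 0.0
    M = G + lam * D
    try:
        return np.linalg.solve(M, b)
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(M, b, rcond=None)[0]


def fit_glv(design: GLVDesign, lambda_grid=DEFAULT_LAMBDA_GRID, k_folds: int = 5,
            per_taxon_lambda: bool = False, seed: int | None = None) -> GLVFit:
    """Per-taxon ridge regression of the forward-difference system.

    The penalty lam * ||(a_i1..a_iS)||^2 leaves the intercept r_i free; a
    single lam shared by all taxa (or one per taxon with
    ``per_taxon_lambda=True``; a shared lam keeps the rows of A on a common
    shrinkage scale, which the equilibrium solve needs) is chosen to minimize
    mean out-of-fold squared prediction error over ``k_folds`` contiguous
    blocks of equations (contiguous folds respect the serial dependence of
    the time series, and make the fit deterministic; ``seed`` is accepted for
    interface stability but unused in this mode).
    """
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if lambda_grid.size == 0:
        raise ValueError("lambda grid is empty")
    X, Y = design.X, design.Y
    n_eq, p = X.shape
    if n_eq < k_folds:
        raise ValueError(
            f"only {n_eq} equations for {k_folds} folds; use a smaller k")
    S = Y.shape[1]
    keep = np.array([t not in set(design.dropped) for t in design.taxa])
    folds = np.array_split(np.arange(n_eq), k_folds)
    D = np.eye(p)
    D[0, 0] = 0.0

    sse = np.zeros((lambda_grid.size, S))
    for test_idx in folds:
        train = np.setdiff1d(np.arange(n_eq), test_idx)
        Xtr, Xte = X[train], X[test_idx]
        G = Xtr.T @ Xtr
        B = Xtr.T @ Y[train]
        M = G[None, :, :] + lambda_grid[:, None, None] * D[None, :, :]
        try:
            beta = np.linalg.solve(M, np.broadcast_to(B, (lambda_grid.size, p, S)))
        except np.linalg.LinAlgError:
            beta = np.stack([_ridge_solve(G, B, lam) for lam in lambda_grid])
        resid = Y[test_idx][None, :, :] - Xte[None, :, :] @ beta
        sse += (resid**2).sum(axis=1)
    cv = sse / n_eq  # mean squared out-of-fold error per (lambda, taxon)

    if per_taxon_lambda:
        best = cv.argmin(axis=0)
    else:
        best = np.full(S, cv.mean(axis=1).argmin())
    lambdas = lambda_grid[best]

    G_full = X.T @ X
    B_full = X.T @ Y
    coef = np.empty((p, S))
    for lam in np.unique(lambdas):
        cols = lambdas == lam
        coef[:, cols] = _ridge_solve(G_full, B_full[:, cols], lam)
    r = coef[0].copy()
    A = coef[1:].T.copy()  # row i = interaction coefficients of taxon i
    r[~keep] = np.nan
    A[~keep, :] = np.nan
    cv_error = float(cv[best, np.arange(S)][keep].mean()) if keep.any() else np.nan
    return GLVFit(taxa=list(design.taxa), r=r, A=A, lambdas=lambdas,
                  cv_error=cv_error, pseudocount=design.pseudocount,
                  dropped=list(design.dropped))


# ---------------------------------------------------------------------------
# Dynamics, equilibrium, stability


def glv_rhs(fit_or_params, N: np.ndarray) -> np.ndarray:
    """gLV right-hand side f_i(N) = N_i (r_i - sum_j a_ij N_j)."""
    r, A = _unpack(fit_or_params)
    N = np.asarray(N, dtype=float)
    return N * (r - A @ N)


def steady_state(fit_or_params) -> tuple[np.ndarray, bool]:
    """Interior equilibrium N* solving A N* = r, with a feasibility flag.

    Raises if A is ill-conditioned (condition number above 1e8).
    """
    r, A = _unpack(fit_or_params)
    if not np.all(np.isfinite(A)) or not np.all(np.isfinite(r)):
        raise ValueError("fit contains non-finite coefficients (dropped taxa?)")
    cond = np.linalg.cond(A)
    if cond > CONDITION_LIMIT:
        raise np.linalg.LinAlgError(
            f"interaction matrix too ill-conditioned for a steady state "
            f"(cond = {cond:.3g})")
    n_star = np.linalg.solve(A, r)
    return n_star, bool(np.all(n_star > 0))


def jacobian(fit_or_params, N: np.ndarray) -> np.ndarray:
    """Jacobian J_ik = d f_i / d N_k = delta_ik (r_i - sum_j a_ij N_j) - N_i a_ik.

    At an interior equilibrium the bracket vanishes and J = -diag(N*) A.
    """
    r, A = _unpack(fit_or_params)
    N = np.asarray(N, dtype=float)
    growth = r - A @ N
    return np.diag(growth) - N[:, None] * A


def stability_spectrum(J: np.ndarray) -> tuple[np.ndarray, float, bool]:
    """Eigenvalues of J, centroid of their real parts, and the stability verdict."""
    J = np.asarray(J, dtype=float)
    if not np.all(np.isfinite(J)):
        raise ValueError("Jacobian contains non-finite entries")
    eig = np.linalg.eigvals(J)
    centroid = float(eig.real.mean())
    return eig, centroid, bool(eig.real.max() < 0)


def stability_analysis(fit: GLVFit) -> StabilityResult:
    """Equilibrium, Jacobian at the equilibrium, spectrum and verdict in one step."""
    n_star, feasible = steady_state(fit)
    J = jacobian(fit, n_star)
    eig, centroid, stable = stability_spectrum(J)
    return StabilityResult(equilibrium=n_star, feasible=feasible, jacobian=J,
                           eigenvalues=eig, centroid_re=centroid, stable=stable)


# ---------------------------------------------------------------------------
# Interaction classification


def classify_interactions(fit_or_params, taxa=None, on: str = "effects") -> InteractionSet:
    """Type every unordered taxon pair as mutualism, antagonism or exploitation.

    Effects are e_ij = -a_ij, the growth effect of taxon j on taxon i
    (positive = activation), so "+/+" is mutual promotion.  ``on="raw"``
    classifies on a_ij as written instead.  Pairs with an exactly-zero effect
    are flagged null and excluded from the proportions.
    """
    r, A = _unpack(fit_or_params)
    S = A.shape[0]
    if S < 2:
        raise ValueError("classification needs at least 2 taxa")
    if taxa is None:
        taxa = getattr(fit_or_params, "taxa", None) or list(range(S))
    if on == "effects":
        e = -A
    elif on == "raw":
        e = A.copy()
    else:
        raise ValueError("on must be 'effects' or 'raw'")
    rows, n_null = [], 0
    for i in range(S):
        for j in range(i + 1, S):
            eij, eji = e[i, j], e[j, i]
            if eij == 0 or eji == 0 or not np.isfinite(eij) or not np.isfinite(eji):
                n_null += 1
                kind = "null"
            elif eij > 0 and eji > 0:
                kind = "mutualism"
            elif eij < 0 and eji < 0:
                kind = "antagonism"
            else:
                kind = "exploitation"
            rows.append({"taxon_i": taxa[i], "taxon_j": taxa[j],
                         "e_ij": eij, "e_ji": eji, "type": kind})
    pairs = pd.DataFrame(rows)
    classified = pairs[pairs["type"] != "null"]
    n_cls = len(classified)
    proportions, strength = {}, {}
    for kind in ("mutualism", "antagonism", "exploitation"):
        sub = classified[classified["type"] == kind]
        proportions[kind] = len(sub) / n_cls if n_cls else np.nan
        strength[kind] = (float(np.abs(sub[["e_ij", "e_ji"]].to_numpy()).mean())
                          if len(sub) else np.nan)
    return InteractionSet(pairs=pairs, proportions=proportions,
                          strength=strength, n_null=n_null)


# ---------------------------------------------------------------------------
# Stage orchestration


def stage_analysis(matrix: CommunityMatrix, w: int = 10, s: int = 5,
                   lambda_grid=DEFAULT_LAMBDA_GRID, k_folds: int = 5,
                   per_taxon_lambda: bool = False, pseudocount: float | None = None,
                   classify_on: str = "effects",
                   min_window_abund: float = 0.005) -> list[StageResult]:
    """Run windows -> design -> ridge fit -> stability -> classification per stage.

    Taxa that are effectively absent from a window (mean abundance below
    ``min_window_abund``) carry no dynamical information there and would make
    the interaction matrix singular; each stage is fitted on the taxa present
    in its own window.  In a truncated trailing window the fold count adapts
    to the number of equations available.  Failures in one stage are recorded
    on that stage's result without aborting the others.
    """
    results = []
    for win in stage_windows(matrix.rel.shape[0], w=w, s=s):
        try:
            sub_rel = matrix.rel.iloc[win.start:win.stop]
            present = sub_rel.columns[sub_rel.mean(axis=0) >= min_window_abund]
            if len(present) < 2:
                raise ValueError("fewer than 2 taxa present in window")
            # an S x S interaction matrix is only identifiable from the
            # window's forward differences when S < number of equations
            max_s = len(win) - 2
            if len(present) > max_s:
                present = (sub_rel[present].mean(axis=0)
                           .sort_values(ascending=False).index[:max_s])
                present = [c for c in sub_rel.columns if c in set(present)]
            sub = CommunityMatrix(rel=matrix.rel[present],
                                  ages=matrix.ages.copy(), closed=False)
            design = build_design(sub, win, pseudocount=pseudocount)
            k_eff = min(k_folds, design.n_equations)
            fit = fit_glv(design, lambda_grid=lambda_grid, k_folds=k_eff,
                          per_taxon_lambda=per_taxon_lambda)
            stab = stability_analysis(fit)
            inter = classify_interactions(fit, on=classify_on)
            results.append(StageResult(window=win, fit=fit, stability=stab,
                                       interactions=inter))
        except (ValueError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"stage {win.index} failed: {exc}")
            results.append(StageResult(window=win, fit=None, stability=None,
                                       interactions=None, error=str(exc)))
    return results


def stage_summary(results: list[StageResult], ages=None) -> pd.DataFrame:
    """One row per stage: ridge weight, CV error, centroid, verdicts, strengths."""
    rows = []
    for res in results:
        row = {"stage": res.window.index, "start": res.window.start,
               "stop": res.window.stop, "n_samples": len(res.window)}
        if ages is not None:
            age = np.asarray(ages, dtype=float)
            row["age_start"] = age[res.window.start]
            row["age_end"] = age[res.window.stop - 1]
        if res.error is not None:
            row["error"] = res.error
        else:
            row.update({
                "lambda_median": float(np.median(res.fit.lambdas)),
                "cv_error": res.fit.cv_error,
                "centroid_re": res.stability.centroid_re,
                "stable": res.stability.stable,
                "feasible": res.stability.feasible,
            })
            for kind in ("mutualism", "antagonism", "exploitation"):
                row[f"prop_{kind}"] = res.interactions.proportions[kind]
                row[f"strength_{kind}"] = res.interactions.strength[kind]
        rows.append(row)
    return pd.DataFrame(rows).set_index("stage")


def _unpack(fit_or_params) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(fit_or_params, GLVFit):
        return fit_or_params.r, fit_or_params.A
    r, A = fit_or_params
    return np.asarray(r, dtype=float), np.asarray(A, dtype=float)
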