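"""PCA-reduced data envelopment analysis.

When the number of accessions s is small relative to the number of traits
m + n, plain DEA declares most accessions efficient: the multiplier LP has
too many free weights. Reducing each trait block (inputs and outputs
separately) to the principal components that explain a chosen fraction of
the variance restores discriminatory power while keeping most of the
information.

The transformed LPs act on score matrices X_k = L_X X and Y_k = L_Y Y,
where L_X (k x m) and L_Y (k x n) hold the leading eigenvectors of the
respective trait covariance (or correlation) matrices as rows. The
multiplier coefficients V, U are free in sign, but the implied
original-trait weights V L_X and U L_Y are constrained nonnegative, and the
envelopment slacks live in the original trait space, premultiplied by the
loadings. Scores fed to the LPs are uncentered projections, so retaining
all components is exactly a change of coordinates and reproduces the
raw-data efficiencies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dea_core import (
    DEFAULT_TOL,
    DEAInstance,
    DEASolverError,
    _run_lp,
)

__all__ = [
    "PCAModel",
    "PCADEAResult",
    "PCADEAReport",
    "fit_pca",
    "transform",
    "solve_pca_dea",
    "pca_dea_pipeline",
]


@dataclass(frozen=True)
class PCAModel:
    """Eigendecomposition of one trait block's covariance/correlation matrix.

    ``loadings`` is K x K with orthonormal eigenvector columns ordered by
    decreasing eigenvalue; ``explained`` are the variance fractions
    ζ_l = α_l / Σα; ``k_selected`` is the smallest k whose cumulative
    explained variance reaches the threshold. ``center`` (and ``scale`` in
    correlation mode) record the fitting statistics.
    """

    role: str
    trait_names: tuple
    loadings: np.ndarray
    eigenvalues: np.ndarray
    explained: np.ndarray
    k_selected: int
    threshold: float
    center: np.ndarray
    standardized: bool
    scale: np.ndarray

    @property
    def n_traits(self) -> int:
        return self.loadings.shape[0]

    @property
    def selected_loadings(self) -> np.ndarray:
        """K x k_selected matrix of the retained eigenvectors."""
        return self.loadings[:, : self.k_selected]

    @property
    def cumulative_explained(self) -> np.ndarray:
        return np.cumsum(self.explained)


def fit_pca(
    data: np.ndarray,
    threshold: float,
    mode: str = "covariance",
    trait_names: Sequence | None = None,
    role: str = "input",
) -> PCAModel:
    """Fit a PCA model on an accessions x traits matrix.

    ``mode`` selects the covariance matrix of the centered traits (default)
    or the correlation matrix (traits standardized to unit variance).
    Eigenvalue ties are broken by the original trait order (stable sort);
    each eigenvector's sign is fixed so its largest-magnitude coefficient
    is positive, for determinism across platforms.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if mode not in ("covariance", "correlation"):
        raise ValueError(f"mode must be 'covariance' or 'correlation', got {mode!r}")
    A = np.asarray(data, dtype=float)
    if A.ndim != 2 or A.shape[0] < 2:
        raise ValueError("need an accessions x traits matrix with >= 2 accessions")
    if not np.all(np.isfinite(A)):
        raise ValueError("data contains non-finite values")
    K = A.shape[1]
    names = tuple(trait_names) if trait_names is not None else tuple(f"{role}_{i}" for i in range(K))
    if len(names) != K:
        raise ValueError("trait_names length does not match number of columns")
    center = A.mean(axis=0)
    std = A.std(axis=0, ddof=1)
    if mode == "correlation":
        dead = [names[i] for i in range(K) if std[i] == 0]
        if dead:
            raise ValueError(f"zero-variance trait(s) in correlation mode: {dead}")
        scale = std
    else:
        scale = np.ones(K)
    Z = (A - center) / scale
    C = np.cov(Z, rowvar=False, ddof=1)
    C = np.atleast_2d(C)
    evals, evecs = np.linalg.eigh(C)
    evals = np.maximum(evals, 0.0)
    # eigh returns ascending; stable descending sort preserves trait order on ties
    order = np.argsort(-evals, kind="stable")
    evals = evals[order]
    evecs = evecs[:, order]
    for l in range(K):
        j = np.argmax(np.abs(evecs[:, l]))
        if evecs[j, l] < 0:
            evecs[:, l] = -evecs[:, l]
    total = evals.sum()
    if total <= 0:
        raise ValueError("all traits have zero variance; PCA is undefined")
    zeta = evals / total
    cum = np.cumsum(zeta)
    k_selected = int(np.searchsorted(cum, threshold - 1e-12) + 1)
    k_selected = min(k_selected, K)
    return PCAModel(
        role=role,
        trait_names=names,
        loadings=evecs,
        eigenvalues=evals,
        explained=zeta,
        k_selected=k_selected,
        threshold=float(threshold),
        center=center,
        standardized=(mode == "correlation"),
        scale=scale,
    )


def transform(model: PCAModel, data: np.ndarray, center: bool = True) -> np.ndarray:
    """Project an accessions x traits matrix onto the retained components.

    With ``center=True`` (default) the scores are the usual centered (and,
    in correlation mode, standardized) projections. The DEA path uses
    ``center=False``: uncentered scores keep the full-component case an
    exact change of coordinates of the raw LP.
    """
    A = np.asarray(data, dtype=float)
    if A.ndim != 2 or A.shape[1] != model.n_traits:
        raise ValueError(
            f"data has {A.shape[1] if A.ndim == 2 else '?'} traits, "
            f"model expects {model.n_traits}: {model.trait_names}"
        )
    Z = A / model.scale
    if center:
        Z = Z - model.center / model.scale
    return Z @ model.selected_loadings


@dataclass
class PCADEAResult:
    """PCA-DEA solution for one accession.

    Slacks are original-trait-space vectors (length m for inputs, n for
    outputs); ``V`` and ``U`` are the free-sign multiplier coefficients on
    the component scores, with implied nonnegative original-trait weights
    ``implied_input_weights`` = V L_X and ``implied_output_weights`` = U L_Y.
    """

    accession_id: object
    theta: float
    lambdas: np.ndarray
    input_slacks: np.ndarray
    output_slacks: np.ndarray
    V: np.ndarray
    U: np.ndarray
    implied_input_weights: np.ndarray
    implied_output_weights: np.ndarray
    fully_efficient: bool
    solver_status: str = "optimal"

    @property
    def efficiency(self) -> float:
        return 1.0 / self.theta


@dataclass
class PCADEAReport:
    """All-accession PCA-DEA results plus the fitted PCA models."""

    results: list
    input_model: PCAModel
    output_model: PCAModel

    @property
    def thetas(self) -> np.ndarray:
        return np.array([r.theta for r in self.results])

    @property
    def fully_efficient_ids(self) -> list:
        return [r.accession_id for r in self.results if r.fully_efficient]

    @property
    def n_fully_efficient(self) -> int:
        return sum(1 for r in self.results if r.fully_efficient)


def _check_models(instance: DEAInstance, input_model: PCAModel, output_model: PCAModel):
    if input_model.n_traits != instance.n_inputs:
        raise ValueError("input PCA model does not match the instance's input traits")
    if output_model.n_traits != instance.n_outputs:
        raise ValueError("output PCA model does not match the instance's output traits")
    if instance.scale != "VRS":
        raise ValueError("the PCA-transformed program is defined for the VRS (BCC) model")


def solve_pca_dea(
    instance: DEAInstance,
    input_model: PCAModel,
    output_model: PCAModel,
    accession_index: int,
    tolerance: float = DEFAULT_TOL,
    duality_tol: float = 1e-6,
) -> PCADEAResult:
    """Solve the transformed envelopment and multiplier problems for one
    accession and cross-check their objectives.

    Envelopment:  max Θ  s.t.  X_k λ + L_X s_X = X_k[:,q],
                               Y_k λ − L_Y s_Y = Θ Y_k[:,q],
                               Σλ = 1,  λ, s_X, s_Y, Θ ≥ 0,
    with L_X the k x m selected-loading matrix (rows = components) and the
    slacks s_X, s_Y in the original trait space. Phase 2 fixes Θ and
    maximizes total slack before the Pareto-Koopmans classification.

    An unbounded Θ can occur at aggressive reduction when the retained
    output components mix signs; the diagnostic suggests raising the
    variance threshold.
    """
    _check_models(instance, input_model, output_model)
    if not 0 <= accession_index < instance.n_accessions:
        raise IndexError(f"accession index {accession_index} out of range")
    acc = instance.accession_ids[accession_index]
    LX = input_model.selected_loadings.T  # kx x m
    LY = output_model.selected_loadings.T  # ky x n
    Xk = transform(input_model, instance.X.T, center=False).T  # kx x s
    Yk = transform(output_model, instance.Y.T, center=False).T  # ky x s
    kx, ky = Xk.shape[0], Yk.shape[0]
    m, n, s = instance.n_inputs, instance.n_outputs, instance.n_accessions

    # envelopment variables: lambda (s), s_X (m), s_Y (n), theta (1)
    nv = s + m + n + 1
    c = np.zeros(nv)
    c[-1] = -1.0
    A_eq = np.zeros((kx + ky + 1, nv))
    b_eq = np.zeros(kx + ky + 1)
    A_eq[:kx, :s] = Xk
    A_eq[:kx, s : s + m] = LX
    b_eq[:kx] = Xk[:, accession_index]
    A_eq[kx : kx + ky, :s] = Yk
    A_eq[kx : kx + ky, s + m : s + m + n] = -LY
    A_eq[kx : kx + ky, -1] = -Yk[:, accession_index]
    A_eq[-1, :s] = 1.0
    b_eq[-1] = 1.0
    bounds = [(0, None)] * nv
    try:
        res = _run_lp(c, None, None, A_eq, b_eq, bounds,
                      f"PCA-DEA envelopment for accession {acc!r}")
    except DEASolverError as exc:
        if "unbounded" in str(exc):
            raise DEASolverError(
                f"{exc}; the retained output components mix signs — "
                "consider a higher variance threshold"
            ) from exc
        raise
    theta = float(res.x[-1])

    c2 = np.zeros(nv)
    c2[s : s + m + n] = -1.0
    bounds2 = list(bounds)
    bounds2[-1] = (theta, theta)
    status = "optimal"
    try:
        res2 = _run_lp(c2, None, None, A_eq, b_eq, bounds2,
                       f"PCA-DEA envelopment phase 2 for accession {acc!r}")
        x = res2.x
    except DEASolverError:
        x = res.x
        status = "optimal (phase-2 fallback to phase-1 slacks)"
    lambdas = x[:s].copy()
    s_in = np.maximum(x[s : s + m], 0.0)
    s_out = np.maximum(x[s + m : s + m + n], 0.0)

    # multiplier: variables V (kx, free), U (ky, free), u (free)
    nvm = kx + ky + 1
    cm = np.zeros(nvm)
    cm[:kx] = Xk[:, accession_index]
    cm[-1] = -1.0
    Am_eq = np.zeros((1, nvm))
    Am_eq[0, kx : kx + ky] = Yk[:, accession_index]
    bm_eq = np.array([1.0])
    # accession rows: -V.Xk_a + U.Yk_a + u <= 0; sign rows: -(V LX) <= 0, -(U LY) <= 0
    Am_ub = np.zeros((s + m + n, nvm))
    Am_ub[:s, :kx] = -Xk.T
    Am_ub[:s, kx : kx + ky] = Yk.T
    Am_ub[:s, -1] = 1.0
    Am_ub[s : s + m, :kx] = -LX.T
    Am_ub[s + m :, kx : kx + ky] = -LY.T
    bm_ub = np.zeros(s + m + n)
    bm_bounds = [(None, None)] * nvm
    resm = _run_lp(cm, Am_ub, bm_ub, Am_eq, bm_eq, bm_bounds,
                   f"PCA-DEA multiplier for accession {acc!r}")
    V = resm.x[:kx].copy()
    U = resm.x[kx : kx + ky].copy()
    gap = abs(float(resm.fun) - theta)
    if gap > duality_tol * max(1.0, abs(theta)):
        status = f"duality gap {gap:.2e}"
    fully = bool(
        abs(theta - 1.0) <= tolerance
        and np.all(s_in <= tolerance)
        and np.all(s_out <= tolerance)
    )
    return PCADEAResult(
        accession_id=acc,
        theta=theta,
        lambdas=lambdas,
        input_slacks=s_in,
        output_slacks=s_out,
        V=V,
        U=U,
        implied_input_weights=LX.T @ V,
        implied_output_weights=LY.T @ U,
        fully_efficient=fully,
        solver_status=status,
    )


def _identity_model(trait_names: tuple, role: str, threshold: float) -> PCAModel:
    K = len(trait_names)
    return PCAModel(
        role=role,
        trait_names=tuple(trait_names),
        loadings=np.eye(K),
        eigenvalues=np.ones(K),
        explained=np.full(K, 1.0 / K),
        k_selected=K,
        threshold=float(threshold),
        center=np.zeros(K),
        standardized=False,
        scale=np.ones(K),
    )


def pca_dea_pipeline(
    instance: DEAInstance,
    threshold: float,
    mode: str = "covariance",
    tolerance: float = DEFAULT_TOL,
) -> PCADEAReport:
    """Fit input and output PCA models on the instance's own trait matrices
    and solve the transformed programs for every accession."""
    if instance.n_accessions == 1:
        # covariance is undefined for one accession; the full trait basis is
        # the only consistent choice and makes the lone accession efficient
        input_model = _identity_model(instance.input_trait_names, "input", threshold)
        output_model = _identity_model(instance.output_trait_names, "output", threshold)
        results = [solve_pca_dea(instance, input_model, output_model, 0, tolerance)]
        return PCADEAReport(results=results, input_model=input_model, output_model=output_model)
    input_model = fit_pca(
        instance.X.T, threshold, mode=mode,
        trait_names=instance.input_trait_names, role="input",
    )
    output_model = fit_pca(
        instance.Y.T, threshold, mode=mode,
        trait_names=instance.output_trait_names, role="output",
    )
    results = [
        solve_pca_dea(instance, input_model, output_model, q, tolerance)
        for q in range(instance.n_accessions)
    ]
    return PCADEAReport(results=results, input_model=input_model, output_model=output_model)
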