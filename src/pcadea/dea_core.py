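"""Classical data envelopment analysis (DEA) for accession trait tables.

Each accession (genotype) is a decision making unit converting m input traits
(e.g. metabolite contents) into n output traits (e.g. growth and morphology).
Relative efficiency is scored against the frontier spanned by all accessions,
either under constant returns to scale (CCR model) or variable returns to
scale (BCC model, convexity constraint on the reference weights).

The radial score Θ follows the output-expansion convention: Θ = 1 on the
frontier and Θ > 1 for dominated accessions (Θ is the factor by which all
outputs could be expanded using a convex combination of peers that needs no
more of any input). Full (Pareto-Koopmans) efficiency additionally requires
all input and output slacks to vanish after a second-phase slack
maximization, because a radial optimum with Θ = 1 can hide residual input
excess or output shortfall.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "DEAInstance",
    "EnvelopmentSolution",
    "MultiplierSolution",
    "DEASolverError",
    "solve_envelopment",
    "solve_multiplier",
    "efficiency_table",
    "count_fully_efficient",
    "DEFAULT_TOL",
]

DEFAULT_TOL = 1e-6

CRS = "CRS"
VRS = "VRS"


class DEASolverError(RuntimeError):
    """Raised when an efficiency LP is infeasible or unbounded."""


def _as_matrix(M, name: str) -> np.ndarray:
    A = np.asarray(M, dtype=float)
    if A.ndim != 2:
        raise ValueError(f"{name} must be 2-D (traits x accessions), got shape {A.shape}")
    if not np.all(np.isfinite(A)):
        raise ValueError(f"{name} contains non-finite entries")
    return A


@dataclass(frozen=True)
class DEAInstance:
    """Paired input/output trait matrices over a common accession set.

    X is m x s (input traits x accessions), Y is n x s. ``scale`` selects the
    returns-to-scale assumption: "VRS" (BCC, convexity constraint) or "CRS"
    (CCR). Raw trait instances must be strictly positive; PCA-transformed
    score matrices (which are sign-mixed) are built with ``raw=False``.
    """

    accession_ids: tuple
    X: np.ndarray
    Y: np.ndarray
    input_trait_names: tuple
    output_trait_names: tuple
    scale: str = VRS
    raw: bool = True

    def __post_init__(self):
        X = _as_matrix(self.X, "X")
        Y = _as_matrix(self.Y, "Y")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Y", Y)
        object.__setattr__(self, "accession_ids", tuple(self.accession_ids))
        object.__setattr__(self, "input_trait_names", tuple(self.input_trait_names))
        object.__setattr__(self, "output_trait_names", tuple(self.output_trait_names))
        if self.scale not in (CRS, VRS):
            raise ValueError(f"scale must be 'CRS' or 'VRS', got {self.scale!r}")
        s = len(self.accession_ids)
        if s < 1:
            raise ValueError("need at least one accession")
        if X.shape[1] != s or Y.shape[1] != s:
            raise ValueError(
                f"X has {X.shape[1]} and Y has {Y.shape[1]} accession columns, "
                f"but there are {s} accession ids"
            )
        if X.shape[0] < 1 or Y.shape[0] < 1:
            raise ValueError("need at least one input and one output trait")
        if len(set(self.accession_ids)) != s:
            raise ValueError("accession ids must be unique")
        if len(set(self.input_trait_names)) != X.shape[0]:
            raise ValueError("input trait names must be unique and match X rows")
        if len(set(self.output_trait_names)) != Y.shape[0]:
            raise ValueError("output trait names must be unique and match Y rows")
        if self.raw:
            if np.any(X <= 0) or np.any(Y <= 0):
                raise ValueError(
                    "raw trait matrices must be strictly positive; "
                    "use replace_zeros() for exact zeros or raw=False for "
                    "transformed score matrices"
                )

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_inputs(self) -> int:
        return self.X.shape[0]

    @property
    def n_outputs(self) -> int:
        return self.Y.shape[0]

    def drop_input_trait(self, trait: str) -> "DEAInstance":
        """Return a copy with one input trait removed (leave-one-trait-out)."""
        if trait not in self.input_trait_names:
            raise KeyError(f"unknown input trait {trait!r}; have {self.input_trait_names}")
        if self.n_inputs < 2:
            raise ValueError("cannot remove the only input trait")
        keep = [i for i, t in enumerate(self.input_trait_names) if t != trait]
        return DEAInstance(
            accession_ids=self.accession_ids,
            X=self.X[keep, :],
            Y=self.Y,
            input_trait_names=tuple(self.input_trait_names[i] for i in keep),
            output_trait_names=self.output_trait_names,
            scale=self.scale,
            raw=self.raw,
        )


def replace_zeros(M: np.ndarray, epsilon: float) -> np.ndarray:
    """Replace exact zeros by ``epsilon`` (opt-in; negatives still rejected)."""
    A = np.asarray(M, dtype=float).copy()
    if np.any(A < 0):
        raise ValueError("negative trait values cannot be imputed")
    A[A == 0.0] = float(epsilon)
    return A


@dataclass
class EnvelopmentSolution:
    """Envelopment-form LP solution for one accession.

    ``theta`` is the radial output-expansion factor (>= 1 up to tolerance);
    ``efficiency`` = 1/theta lies in (0, 1]. Slacks are the phase-2
    (slack-maximal) values used for the Pareto-Koopmans classification.
    """

    accession_id: object
    theta: float
    lambdas: np.ndarray
    input_slacks: np.ndarray
    output_slacks: np.ndarray
    fully_efficient: bool
    solver_status: str = "optimal"

    @property
    def efficiency(self) -> float:
        return 1.0 / self.theta


@dataclass
class MultiplierSolution:
    """Multiplier-form (weight-space) LP solution for one accession.

    ``nu`` / ``mu`` are nonnegative input/output trait weights; ``u`` is the
    free returns-to-scale intercept (0 under CRS). ``objective`` equals the
    envelopment theta by strong duality.
    """

    accession_id: object
    nu: np.ndarray
    mu: np.ndarray
    u: float
    objective: float
    solver_status: str = "optimal"


_LINPROG_OPTS = {"presolve": True}


def _run_lp(c, A_ub, b_ub, A_eq, b_eq, bounds, context: str):
    res = linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds,
        method="highs", options=_LINPROG_OPTS,
    )
    if res.status != 0:
        kind = {2: "infeasible", 3: "unbounded"}.get(res.status, f"status {res.status}")
        raise DEASolverError(f"{context}: LP {kind} ({res.message.strip()})")
    return res


def solve_envelopment(
    instance: DEAInstance, accession_index: int, tolerance: float = DEFAULT_TOL
) -> EnvelopmentSolution:
    """Solve the envelopment LP for one accession, with phase-2 slacks.

    Phase 1 maximizes Θ subject to
        Σ_a λ_a x_ia + s_i = x_iq            (input constraints)
        Σ_a λ_a y_ja − s_j = Θ y_jq          (output constraints)
        Σ_a λ_a = 1 under VRS
        λ, s ≥ 0.
    Phase 2 fixes Θ at its optimum and maximizes Σ s_i + Σ s_j; the accession
    is fully efficient iff Θ = 1 and all phase-2 slacks vanish (within
    ``tolerance``).
    """
    if not 0 <= accession_index < instance.n_accessions:
        raise IndexError(f"accession index {accession_index} out of range")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    X, Y = instance.X, instance.Y
    m, n, s = instance.n_inputs, instance.n_outputs, instance.n_accessions
    acc = instance.accession_ids[accession_index]
    xq = X[:, accession_index]
    yq = Y[:, accession_index]

    # variables: lambda (s), s_in (m), s_out (n), theta (1)
    nv = s + m + n + 1
    c = np.zeros(nv)
    c[-1] = -1.0  # maximize theta
    rows = []
    rhs = []
    for i in range(m):
        r = np.zeros(nv)
        r[:s] = X[i]
        r[s + i] = 1.0
        rows.append(r)
        rhs.append(xq[i])
    for j in range(n):
        r = np.zeros(nv)
        r[:s] = Y[j]
        r[s + m + j] = -1.0
        r[-1] = -yq[j]
        rows.append(r)
        rhs.append(0.0)
    if instance.scale == VRS:
        r = np.zeros(nv)
        r[:s] = 1.0
        rows.append(r)
        rhs.append(1.0)
    A_eq = np.array(rows)
    b_eq = np.array(rhs)
    bounds = [(0, None)] * (s + m + n) + [(None, None)]

    res = _run_lp(c, None, None, A_eq, b_eq, bounds, f"envelopment phase 1 for accession {acc!r}")
    theta = float(res.x[-1])

    # phase 2: theta fixed, maximize total slack
    c2 = np.zeros(nv)
    c2[s : s + m + n] = -1.0
    bounds2 = list(bounds)
    bounds2[-1] = (theta, theta)
    status = "optimal"
    try:
        res2 = _run_lp(
            c2, None, None, A_eq, b_eq, bounds2, f"envelopment phase 2 for accession {acc!r}"
        )
        x = res2.x
    except DEASolverError:
        # tolerance-edge infeasibility: keep phase-1 slacks
        x = res.x
        status = "optimal (phase-2 fallback to phase-1 slacks)"
    lambdas = x[:s].copy()
    s_in = np.maximum(x[s : s + m], 0.0)
    s_out = np.maximum(x[s + m : s + m + n], 0.0)
    fully = bool(abs(theta - 1.0) <= tolerance and np.all(s_in <= tolerance) and np.all(s_out <= tolerance))
    return EnvelopmentSolution(
        accession_id=acc,
        theta=theta,
        lambdas=lambdas,
        input_slacks=s_in,
        output_slacks=s_out,
        fully_efficient=fully,
        solver_status=status,
    )


def solve_multiplier(
    instance: DEAInstance, accession_index: int, tolerance: float = DEFAULT_TOL
) -> MultiplierSolution:
    """Solve the multiplier (weight-space) LP, the exact dual of the
    envelopment problem:

        min  Σ ν_i x_iq − u
        s.t. Σ μ_j y_jq = 1
             Σ ν_i x_ia − Σ μ_j y_ja − u ≥ 0   for every accession a
             ν, μ ≥ 0,  u free (u ≡ 0 under CRS).

    Sign convention: the accession constraints bound u from above; writing
    them with the opposite sense would let u grow without limit and make the
    program unbounded. The optimal objective equals the envelopment Θ.
    """
    if not 0 <= accession_index < instance.n_accessions:
        raise IndexError(f"accession index {accession_index} out of range")
    X, Y = instance.X, instance.Y
    m, n, s = instance.n_inputs, instance.n_outputs, instance.n_accessions
    acc = instance.accession_ids[accession_index]
    vrs = instance.scale == VRS
    # variables: nu (m), mu (n), [u (1) if VRS]
    nv = m + n + (1 if vrs else 0)
    c = np.zeros(nv)
    c[:m] = X[:, accession_index]
    if vrs:
        c[-1] = -1.0
    A_eq = np.zeros((1, nv))
    A_eq[0, m : m + n] = Y[:, accession_index]
    b_eq = np.array([1.0])
    # -nu.x_a + mu.y_a + u <= 0
    A_ub = np.zeros((s, nv))
    A_ub[:, :m] = -X.T
    A_ub[:, m : m + n] = Y.T
    if vrs:
        A_ub[:, -1] = 1.0
    b_ub = np.zeros(s)
    bounds = [(0, None)] * (m + n) + ([(None, None)] if vrs else [])
    res = _run_lp(c, A_ub, b_ub, A_eq, b_eq, bounds, f"multiplier LP for accession {acc!r}")
    nu = res.x[:m].copy()
    mu = res.x[m : m + n].copy()
    u = float(res.x[-1]) if vrs else 0.0
    return MultiplierSolution(
        accession_id=acc, nu=nu, mu=mu, u=u, objective=float(res.fun)
    )


def efficiency_table(
    instance: DEAInstance,
    tolerance: float = DEFAULT_TOL,
    check_duality: bool = True,
    duality_tol: float = 1e-6,
) -> list[EnvelopmentSolution]:
    """Score every accession; order matches ``instance.accession_ids``.

    Per-accession solver failures are collected and reported together
    instead of aborting the remaining accessions. With ``check_duality``
    each envelopment theta is verified against the multiplier objective.
    """
    records: list[EnvelopmentSolution] = []
    failures: list[str] = []
    for q in range(instance.n_accessions):
        try:
            rec = solve_envelopment(instance, q, tolerance)
            if check_duality:
                dual = solve_multiplier(instance, q, tolerance)
                gap = abs(dual.objective - rec.theta)
                if gap > duality_tol * max(1.0, abs(rec.theta)):
                    rec.solver_status = f"duality gap {gap:.2e}"
            records.append(rec)
        except DEASolverError as exc:
            failures.append(str(exc))
            records.append(
                EnvelopmentSolution(
                    accession_id=instance.accession_ids[q],
                    theta=float("nan"),
                    lambdas=np.full(instance.n_accessions, np.nan),
                    input_slacks=np.full(instance.n_inputs, np.nan),
                    output_slacks=np.full(instance.n_outputs, np.nan),
                    fully_efficient=False,
                    solver_status=f"failed: {exc}",
                )
            )
    if failures:
        raise DEASolverError(
            f"{len(failures)} of {instance.n_accessions} accessions failed: "
            + "; ".join(failures)
        )
    return records


def count_fully_efficient(records: Sequence[EnvelopmentSolution]) -> int:
    """Number of accessions classified Pareto-Koopmans (fully) efficient."""
    return sum(1 for r in records if r.fully_efficient)


def theta_vector(records: Sequence[EnvelopmentSolution]) -> np.ndarray:
    """Radial scores in accession order, for ranking comparisons."""
    return np.array([r.theta for r in records])
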