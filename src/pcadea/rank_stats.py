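"""Rank concordance statistics for efficiency vectors.

Kendall's τ here is the tau-a variant: (concordant − discordant) pairs over
ALL s(s−1)/2 pairs, with tied pairs (equal in either vector) counted in the
denominator only. Ties matter — fully efficient accessions share Θ = 1 — so
the variant choice is not cosmetic; tau-b (which rescales for ties) is
available as an option but nothing downstream uses it.

Two derived statistics rank input traits by importance:

* trait influence τ_c^t — the τ between efficiency vectors computed with
  and without input trait t under condition c; values nearer zero mean the
  trait's removal scrambles the ranking more, i.e. the trait is more
  influential.
* valency Φ_{c1,c2}^t = |τ(e_c1, e_c2) − τ(e_c1^−t, e_c2^−t)| — how much of
  the cross-condition ranking concordance trait t accounts for; Φ ∈ [0, 2].

Significance uses a seeded Monte-Carlo permutation test by default (valid
at small s with ties); a normal approximation is available for speed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .dea_core import DEFAULT_TOL, DEAInstance
from .pca_dea import PCADEAReport, pca_dea_pipeline

__all__ = [
    "RankingComparison",
    "InfluenceResult",
    "ValencyResult",
    "ConcordanceMatrix",
    "kendall_tau",
    "trait_influence",
    "influence_panel",
    "valency",
    "valency_panel",
    "condition_concordance_matrix",
]

ALPHA = 0.05


@dataclass
class RankingComparison:
    """Kendall τ between two score vectors with the full pair taxonomy."""

    tau: float
    n_items: int
    concordant: int
    discordant: int
    tied: int
    p_value: float
    significant: bool

    @property
    def total_pairs(self) -> int:
        return self.n_items * (self.n_items - 1) // 2


def _pair_counts(x: np.ndarray, y: np.ndarray) -> tuple[int, int, int]:
    """Concordant / discordant / tied pair counts, vectorized over all pairs."""
    sx = np.sign(x[:, None] - x[None, :])
    sy = np.sign(y[:, None] - y[None, :])
    prod = sx * sy
    iu = np.triu_indices(len(x), k=1)
    p = prod[iu]
    return int(np.sum(p > 0)), int(np.sum(p < 0)), int(np.sum(p == 0))


def _tau_a(x: np.ndarray, y: np.ndarray) -> float:
    c, d, _ = _pair_counts(x, y)
    n = len(x)
    return (c - d) / (n * (n - 1) / 2)


def kendall_tau(
    e1,
    e2,
    variant: str = "tau-a",
    p_method: str = "permutation",
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> RankingComparison:
    """Kendall rank correlation between two equal-length score vectors.

    ``p_method``: "permutation" (seeded Monte-Carlo, two-sided, default) or
    "normal" (large-sample z approximation). The permutation p-value uses
    the add-one estimator (count+1)/(B+1), never exactly zero.
    """
    x = np.asarray(e1, dtype=float).ravel()
    y = np.asarray(e2, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    s = len(x)
    if s < 2:
        raise ValueError("need at least two items to compare rankings")
    c, d, t = _pair_counts(x, y)
    total = s * (s - 1) // 2
    if variant == "tau-a":
        tau = (c - d) / total
    elif variant == "tau-b":
        tx = np.sum(np.sign(x[:, None] - x[None, :])[np.triu_indices(s, 1)] == 0)
        ty = np.sum(np.sign(y[:, None] - y[None, :])[np.triu_indices(s, 1)] == 0)
        denom = np.sqrt((total - tx) * (total - ty))
        tau = (c - d) / denom if denom > 0 else 0.0
    else:
        raise ValueError(f"unknown variant {variant!r}")

    if p_method == "permutation":
        rng = np.random.default_rng(seed)
        hits = 0
        obs = abs(tau)
        for _ in range(n_permutations):
            yp = rng.permutation(y)
            if variant == "tau-a":
                tp = _tau_a(x, yp)
            else:
                tp = kendall_tau(x, yp, variant="tau-b", p_method="normal").tau
            if abs(tp) >= obs - 1e-12:
                hits += 1
        p = (hits + 1) / (n_permutations + 1)
    elif p_method == "normal":
        z = 3 * tau * np.sqrt(s * (s - 1)) / np.sqrt(2 * (2 * s + 5))
        p = float(2 * norm.sf(abs(z)))
    else:
        raise ValueError(f"unknown p_method {p_method!r}")
    return RankingComparison(
        tau=float(tau),
        n_items=s,
        concordant=c,
        discordant=d,
        tied=t,
        p_value=float(p),
        significant=bool(p < ALPHA),
    )


@dataclass
class InfluenceResult:
    condition: str
    trait: str
    tau_without: float
    p_value: float
    rank_position: int | None = None


def _efficiencies(
    instance: DEAInstance, threshold: float, mode: str, tolerance: float
) -> np.ndarray:
    # snap solver noise (~1e-12) so ties between efficient accessions stay
    # ties under the strict pair comparison; real score gaps are far larger
    return np.round(
        pca_dea_pipeline(instance, threshold, mode=mode, tolerance=tolerance).thetas, 10
    )


def trait_influence(
    condition_data: DEAInstance,
    trait: str,
    threshold: float,
    mode: str = "covariance",
    tolerance: float = DEFAULT_TOL,
    seed: int | None = None,
    condition: str = "",
    n_permutations: int = 10_000,
    full_report: PCADEAReport | None = None,
) -> InfluenceResult:
    """τ_c^t: Kendall τ between efficiencies with and without input trait t.

    The input PCA is refit on the reduced trait set; the output side is
    untouched. ``full_report`` lets callers reuse the all-trait solve when
    scanning many traits.
    """
    if full_report is None:
        e_full = _efficiencies(condition_data, threshold, mode, tolerance)
    else:
        e_full = full_report.thetas
    reduced = condition_data.drop_input_trait(trait)
    e_red = _efficiencies(reduced, threshold, mode, tolerance)
    cmp = kendall_tau(e_full, e_red, seed=seed, n_permutations=n_permutations)
    return InfluenceResult(
        condition=condition, trait=trait, tau_without=cmp.tau, p_value=cmp.p_value
    )


def influence_panel(
    condition_data: DEAInstance,
    threshold: float,
    mode: str = "covariance",
    tolerance: float = DEFAULT_TOL,
    seed: int | None = None,
    condition: str = "",
    n_permutations: int = 10_000,
) -> list[InfluenceResult]:
    """τ_c^t for every input trait, rank positions assigned in ascending
    order of τ (most influential — nearest zero from above — first)."""
    report = pca_dea_pipeline(condition_data, threshold, mode=mode, tolerance=tolerance)
    out = []
    for i, trait in enumerate(condition_data.input_trait_names):
        sub_seed = None if seed is None else seed + 7919 * i
        out.append(
            trait_influence(
                condition_data, trait, threshold, mode, tolerance,
                seed=sub_seed, condition=condition,
                n_permutations=n_permutations, full_report=report,
            )
        )
    for pos, r in enumerate(sorted(out, key=lambda r: r.tau_without), start=1):
        r.rank_position = pos
    return out


@dataclass
class ValencyResult:
    condition_pair: tuple
    trait: str
    phi: float
    base_tau: float
    reduced_tau: float
    base_p_value: float
    reduced_p_value: float


def _check_same_accessions(c1: DEAInstance, c2: DEAInstance):
    s1, s2 = set(c1.accession_ids), set(c2.accession_ids)
    if c1.accession_ids != c2.accession_ids:
        diff = sorted(map(str, s1.symmetric_difference(s2)))
        if diff:
            raise ValueError(f"condition accession sets differ: {diff}")
        raise ValueError("conditions list the same accessions in different orders")


def valency(
    c1_data: DEAInstance,
    c2_data: DEAInstance,
    trait: str,
    threshold: float,
    mode: str = "covariance",
    tolerance: float = DEFAULT_TOL,
    seed: int | None = None,
    labels: tuple = ("c1", "c2"),
    n_permutations: int = 10_000,
    _cache: dict | None = None,
) -> ValencyResult:
    """Valency Φ of input trait t between two conditions.

    Φ = |τ(e_c1, e_c2) − τ(e_c1^−t, e_c2^−t)| where the reduced
    efficiencies come from refitting the input PCA per condition with the
    trait removed. Symmetric in the two conditions.
    """
    _check_same_accessions(c1_data, c2_data)
    if trait not in c1_data.input_trait_names or trait not in c2_data.input_trait_names:
        raise KeyError(f"trait {trait!r} missing from one of the conditions")
    cache = _cache if _cache is not None else {}
    key = ("full",)
    if key not in cache:
        cache[key] = (
            _efficiencies(c1_data, threshold, mode, tolerance),
            _efficiencies(c2_data, threshold, mode, tolerance),
        )
    e1, e2 = cache[key]
    e1r = _efficiencies(c1_data.drop_input_trait(trait), threshold, mode, tolerance)
    e2r = _efficiencies(c2_data.drop_input_trait(trait), threshold, mode, tolerance)
    base = kendall_tau(e1, e2, seed=seed, n_permutations=n_permutations)
    red = kendall_tau(
        e1r, e2r,
        seed=None if seed is None else seed + 1,
        n_permutations=n_permutations,
    )
    return ValencyResult(
        condition_pair=tuple(labels),
        trait=trait,
        phi=abs(base.tau - red.tau),
        base_tau=base.tau,
        reduced_tau=red.tau,
        base_p_value=base.p_value,
        reduced_p_value=red.p_value,
    )


def valency_panel(
    c1_data: DEAInstance,
    c2_data: DEAInstance,
    threshold: float,
    mode: str = "covariance",
    tolerance: float = DEFAULT_TOL,
    seed: int | None = None,
    labels: tuple = ("c1", "c2"),
    n_permutations: int = 10_000,
) -> list[ValencyResult]:
    """Φ for every shared input trait, sorted in descending order of Φ."""
    cache: dict = {}
    out = []
    for i, trait in enumerate(c1_data.input_trait_names):
        sub_seed = None if seed is None else seed + 104729 * i
        out.append(
            valency(
                c1_data, c2_data, trait, threshold, mode, tolerance,
                seed=sub_seed, labels=labels,
                n_permutations=n_permutations, _cache=cache,
            )
        )
    out.sort(key=lambda r: -r.phi)
    return out


@dataclass
class ConcordanceMatrix:
    """Pairwise Kendall τ between condition-wise efficiency vectors."""

    labels: list
    tau: np.ndarray
    p_values: np.ndarray
    fully_efficient_counts: dict
    comparisons: dict


def condition_concordance_matrix(
    instances: dict,
    threshold: float,
    mode: str = "covariance",
    tolerance: float = DEFAULT_TOL,
    seed: int | None = None,
    n_permutations: int = 10_000,
) -> ConcordanceMatrix:
    """Symmetric unit-diagonal τ matrix across ≥ 2 conditions, plus the
    fully-efficient accession count per condition."""
    labels = list(instances)
    if len(labels) < 2:
        raise ValueError("need at least two conditions")
    first = instances[labels[0]]
    for lbl in labels[1:]:
        _check_same_accessions(first, instances[lbl])
    reports = {
        lbl: pca_dea_pipeline(instances[lbl], threshold, mode=mode, tolerance=tolerance)
        for lbl in labels
    }
    k = len(labels)
    tau = np.eye(k)
    pv = np.zeros((k, k))
    comparisons = {}
    for i in range(k):
        for j in range(i + 1, k):
            sub_seed = None if seed is None else seed + 31 * (i * k + j)
            cmp = kendall_tau(
                reports[labels[i]].thetas,
                reports[labels[j]].thetas,
                seed=sub_seed,
                n_permutations=n_permutations,
            )
            tau[i, j] = tau[j, i] = cmp.tau
            pv[i, j] = pv[j, i] = cmp.p_value
            comparisons[(labels[i], labels[j])] = cmp
    counts = {lbl: reports[lbl].n_fully_efficient for lbl in labels}
    return ConcordanceMatrix(
        labels=labels, tau=tau, p_values=pv,
        fully_efficient_counts=counts, comparisons=comparisons,
    )
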