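"""Seeded synthetic trait tables with known efficiency ground truth.

The generator emulates a natural-variation phenotyping design: s accessions
measured for m metabolic input traits and n morphological output traits,
optionally under several environmental conditions. Ground truth is planted
through a one-dimensional latent resource axis u: frontier accessions sit
on a strictly concave, strictly increasing production curve g(u) = 3 u^0.6
(diminishing returns), and every trait is a positive per-trait multiple of
u (inputs) or g(u) (outputs). By units invariance of DEA this makes the
multi-trait instance equivalent to the 1-D curve, so the planted accessions
are exactly the fully efficient set when noise is zero.

Dominated accessions are frontier points with all inputs inflated by their
inefficiency factor f > 1 and all outputs deflated by f, which forces a
radial score of at least f. Measurement noise is multiplicative lognormal
(positivity is preserved); correlated trait blocks arise because duplicate
traits are noisy copies of shared base traits, which makes principal
component selection nontrivial.

Default parameters mirror the motivating study design: 23 accessions,
10 input and 8 output traits, three conditions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .dea_core import DEAInstance

__all__ = ["SyntheticScenario", "generate_planted_frontier", "generate_condition_family"]


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of one synthetic study.

    ``inefficiency_factors`` has one entry (> 1) per dominated accession,
    i.e. length s − len(planted_efficient). ``trait_redundancy`` is the
    number of correlated duplicates per base trait; ``noise_sd`` the
    relative (lognormal sigma) measurement noise. ``perturbation_strengths``
    holds one relative perturbation per condition (first usually 0: the
    base environment); ``scramble_trait`` optionally designates one input
    trait whose values are reassigned in reverse rank order across
    accessions in every non-base condition, planting a known driver of
    ranking discordance; that trait
    is also rescaled by ``scramble_boost`` in every condition so it
    carries the dominant share of the input variance (a pure change of
    units that leaves raw DEA untouched) — without the boost a single
    scrambled trait among many correlated ones barely moves the principal
    components and the planted signal would drown.
    """

    seed: int = 0
    s: int = 23
    m: int = 10
    n: int = 8
    planted_efficient: tuple = tuple(f"acc{i:02d}" for i in range(1, 9))
    inefficiency_factors: tuple = ()
    trait_redundancy: int = 1
    noise_sd: float = 0.05
    conditions: int = 3
    perturbation_strengths: tuple = (0.0, 0.15, 0.30)
    scramble_trait: str | None = None
    scramble_boost: float = 5.0

    def __post_init__(self):
        if self.s < 1 or self.m < 1 or self.n < 1:
            raise ValueError("need s, m, n >= 1")
        if not self.planted_efficient:
            raise ValueError("planted_efficient must be nonempty")
        if len(self.planted_efficient) > self.s:
            raise ValueError("more planted accessions than accessions")
        n_dom = self.s - len(self.planted_efficient)
        factors = self.inefficiency_factors
        if not factors and n_dom > 0:
            # deterministic defaults spread over a realistic range
            rng = np.random.default_rng(self.seed + 1_000_003)
            factors = tuple(np.round(rng.uniform(1.3, 2.2, size=n_dom), 6))
            object.__setattr__(self, "inefficiency_factors", factors)
        if len(self.inefficiency_factors) != n_dom:
            raise ValueError(
                f"need {n_dom} inefficiency factors, got {len(self.inefficiency_factors)}"
            )
        if any(f <= 1 for f in self.inefficiency_factors):
            raise ValueError("inefficiency factors must all be > 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.conditions >= 1 and len(self.perturbation_strengths) != self.conditions:
            raise ValueError("need one perturbation strength per condition")

    @property
    def accession_ids(self) -> tuple:
        n_dom = self.s - len(self.planted_efficient)
        dominated = tuple(f"dom{i:02d}" for i in range(1, n_dom + 1))
        return tuple(self.planted_efficient) + dominated

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=list)


def _frontier_curve(u: np.ndarray) -> np.ndarray:
    return 3.0 * u ** 0.6


def _lift(base: np.ndarray, n_traits: int, redundancy: int, weights_rng, noise_rng,
          noise_sd: float, prefix: str) -> tuple[np.ndarray, tuple]:
    """Lift a latent profile (length s) to n_traits positive rows.

    Traits come in blocks: a base trait (fresh positive weight on the
    latent) followed by ``redundancy`` noisy duplicates of it.
    """
    block = redundancy + 1
    s = len(base)
    rows, names = [], []
    b = 0
    while len(rows) < n_traits:
        b += 1
        w = weights_rng.uniform(0.5, 2.0)
        base_row = w * base
        if noise_sd > 0:
            base_row = base_row * np.exp(noise_rng.normal(0.0, noise_sd, size=s))
        rows.append(base_row)
        names.append(f"{prefix}{b}")
        for d in range(1, block):
            if len(rows) >= n_traits:
                break
            # duplicates inherit the base trait's noise, plus a smaller
            # independent component, giving tight within-block correlation
            wd = weights_rng.uniform(0.5, 2.0)
            dup = wd / w * base_row
            if noise_sd > 0:
                dup = dup * np.exp(noise_rng.normal(0.0, noise_sd / 2, size=s))
            rows.append(dup)
            names.append(f"{prefix}{b}_dup{d}")
    return np.array(rows[:n_traits]), tuple(names[:n_traits])


def generate_planted_frontier(scenario: SyntheticScenario) -> tuple[DEAInstance, set]:
    """Build one trait table with a planted fully-efficient set.

    Returns the VRS instance and the set of planted accession ids. With
    ``noise_sd = 0`` and factors ≥ 1.5 the planted set is recovered exactly
    by the envelopment solver; noise blurs the frontier the way measurement
    error would.
    """
    rng = np.random.default_rng(scenario.seed)
    n_eff = len(scenario.planted_efficient)
    n_dom = scenario.s - n_eff
    # distinct latent positions for the frontier accessions
    u_eff = np.sort(rng.uniform(1.0, 10.0, size=n_eff))
    while n_eff > 1 and np.min(np.diff(u_eff)) < 0.2:
        u_eff = np.sort(rng.uniform(1.0, 10.0, size=n_eff))
    # dominated accessions start from a frontier point, then move inside
    anchors = rng.integers(0, n_eff, size=n_dom)
    factors = np.asarray(scenario.inefficiency_factors, dtype=float)
    u = np.concatenate([u_eff, u_eff[anchors] * factors]) if n_dom else u_eff
    v = np.concatenate([_frontier_curve(u_eff), _frontier_curve(u_eff[anchors]) / factors]) \
        if n_dom else _frontier_curve(u_eff)

    w_rng = np.random.default_rng(scenario.seed + 1)
    e_rng = np.random.default_rng(scenario.seed + 2)
    X, in_names = _lift(u, scenario.m, scenario.trait_redundancy, w_rng, e_rng,
                        scenario.noise_sd, "met")
    Y, out_names = _lift(v, scenario.n, scenario.trait_redundancy, w_rng, e_rng,
                         scenario.noise_sd, "morph")
    if np.any(X <= 0) or np.any(Y <= 0):
        raise ValueError("scenario parameters produced nonpositive trait values")
    instance = DEAInstance(
        accession_ids=scenario.accession_ids,
        X=X, Y=Y,
        input_trait_names=in_names,
        output_trait_names=out_names,
        scale="VRS",
    )
    return instance, set(scenario.planted_efficient)


def generate_condition_family(scenario: SyntheticScenario) -> dict:
    """Trait tables for several environmental conditions of one study.

    Condition 1 is the base table from :func:`generate_planted_frontier`.
    Each further condition multiplies every trait value by seeded lognormal
    noise of the stated relative strength; if ``scramble_trait`` is set,
    that input trait's values are additionally reassigned in reverse rank
    order across accessions (other traits untouched), planting a
    maximal-valency trait.
    """
    if scenario.conditions < 2:
        raise ValueError("need at least two conditions")
    base, _ = generate_planted_frontier(scenario)
    if scenario.scramble_trait is not None:
        if scenario.scramble_trait not in base.input_trait_names:
            raise ValueError(
                f"scramble_trait {scenario.scramble_trait!r} is not an input trait; "
                f"have {base.input_trait_names}"
            )
        idx = base.input_trait_names.index(scenario.scramble_trait)
        Xb = base.X.copy()
        Xb[idx, :] *= scenario.scramble_boost  # pure rescaling: raw DEA unchanged
        base = DEAInstance(
            accession_ids=base.accession_ids,
            X=Xb, Y=base.Y,
            input_trait_names=base.input_trait_names,
            output_trait_names=base.output_trait_names,
            scale=base.scale,
        )
    out = {}
    for c, strength in enumerate(scenario.perturbation_strengths, start=1):
        label = f"C{c}"
        if c == 1:
            out[label] = base
            continue
        if strength < 0:
            raise ValueError("perturbation strengths must be >= 0")
        rng = np.random.default_rng(scenario.seed + 10_000 * c)
        X = base.X.copy()
        Y = base.Y.copy()
        if strength > 0:
            X = X * np.exp(rng.normal(0.0, strength, size=X.shape))
            Y = Y * np.exp(rng.normal(0.0, strength, size=Y.shape))
        if scenario.scramble_trait is not None:
            # reassign the trait's values in reverse rank order: the
            # strongest possible rank scramble (a random permutation can,
            # by chance, leave the cross-accession ranking nearly intact)
            idx = base.input_trait_names.index(scenario.scramble_trait)
            row = base.X[idx]
            order = np.argsort(row, kind="stable")
            X[idx, order] = np.sort(row)[::-1]
        if np.any(X <= 0) or np.any(Y <= 0):
            raise ValueError("perturbation produced nonpositive trait values")
        out[label] = DEAInstance(
            accession_ids=base.accession_ids,
            X=X, Y=Y,
            input_trait_names=base.input_trait_names,
            output_trait_names=base.output_trait_names,
            scale=base.scale,
        )
    return out
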