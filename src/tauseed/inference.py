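"""Permutation inference for predicted tau seeding regions.

The null model randomizes the spatial pattern of the anomaly field: regional
PET SUVRs are shuffled across regions, the stationary solution recomputed,
and all regional concentrations pooled across permutations into a null
distribution.  A single seeding threshold is derived from the pooled null as
the midpoint of the largest gap between adjacent values in its upper half
(strictly above the median).  Regions of the unshuffled solution above that
threshold are "seeded"; the test statistic is the count of seeded regions in
Braak stage 1 (bilateral entorhinal cortex) and in Braak stages 1-3, with a
permutation p-value and a z-score against the per-permutation null counts.

Hippocampi are included in the stage 1-3 family here: the empirical-tau
hippocampus exclusion concerns tracer off-target binding, not the model.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .atlas import RegionAtlas, braak_regions
from .connectome import Connectome
from .transport import AnomalyField, TransportParams, TauTransportModel, SteadyStateResults

__all__ = [
    "NullDistribution",
    "SeedingTestResults",
    "SeedingPermutationTest",
    "shuffle_null",
    "gap_threshold",
    "seeded_regions",
    "braak_seed_test",
]

#: Braak families tested, as stage-label sets.
FAMILIES = {"braak1": frozenset({1}), "braak1_3": frozenset({1, "2/3"})}

#: All-permutations enumeration is feasible for tiny graphs only.
ENUMERATION_MAX_N = 8


@dataclass(frozen=True)
class NullDistribution:
    """Pooled permutation null of stationary concentrations.

    ``pooled_null`` holds n_perm * N concentrations; ``per_perm_counts`` maps
    each Braak family to the per-permutation count of null-seeded regions
    (evaluated against the single global ``threshold``).
    """

    pooled_null: np.ndarray
    per_perm_counts: Mapping[str, np.ndarray]
    threshold: float
    n_perm: int
    rng_seed: int
    exhaustive: bool = False

    def __post_init__(self):
        n_total = self.pooled_null.size
        if n_total % self.n_perm != 0:
            raise ValueError("pooled null size not a multiple of n_perm")
        med = float(np.median(self.pooled_null))
        # strictly above the median except in the degenerate all-equal guard
        if self.threshold < med:
            raise ValueError("threshold below the null median")


class SeedingTestResults:
    """Results of the Braak-family seeding permutation test."""

    def __init__(self, seeded: frozenset, observed_counts: dict,
                 p_values: dict, z_scores: dict, null: NullDistribution,
                 family_sizes: dict):
        self.seeded_regions = seeded
        self.observed_counts = observed_counts
        self.p_values = p_values
        self.z_scores = z_scores
        self.null = null
        self.family_sizes = family_sizes

    @property
    def threshold(self) -> float:
        return self.null.threshold

    def summary(self) -> str:
        lines = [
            "Seeding permutation test",
            f"  permutations: {self.null.n_perm}"
            + ("  (exhaustive)" if self.null.exhaustive else ""),
            f"  seeding threshold: {self.threshold:.6f}",
            f"  seeded regions ({len(self.seeded_regions)}): "
            + ", ".join(sorted(self.seeded_regions)[:8]),
        ]
        for fam in sorted(self.observed_counts):
            lines.append(
                f"  {fam}: observed {self.observed_counts[fam]}/{self.family_sizes[fam]}"
                f"  p = {self.p_values[fam]:.4g}  z = {self.z_scores[fam]:.2f}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "seeded_regions": sorted(self.seeded_regions),
            "observed_counts": dict(self.observed_counts),
            "p_values": dict(self.p_values),
            "z_scores": {k: (v if math.isfinite(v) else None)
                         for k, v in self.z_scores.items()},
            "n_perm": self.null.n_perm,
        }


def gap_threshold(values: Sequence[float]) -> float:
    """Seeding threshold from a pooled null distribution.

    Sort ascending, retain values strictly above the median, take the
    midpoint of the largest gap between adjacent retained values (ties on
    gap size resolved toward the highest-concentration gap).  If fewer than
    two values remain above the median the maximum value is returned as a
    degenerate guard.
    """
    v = np.sort(np.asarray(values, dtype=float).ravel())
    if v.size == 0:
        raise ValueError("empty null distribution")
    upper = v[v > np.median(v)]
    if upper.size < 2:
        return float(v[-1])
    gaps = np.diff(upper)
    # argmax on the reversed array prefers the last (highest) maximal gap
    i = len(gaps) - 1 - int(np.argmax(gaps[::-1]))
    return float((upper[i] + upper[i + 1]) / 2.0)


def seeded_regions(state: SteadyStateResults, threshold: float,
                   atlas: RegionAtlas) -> frozenset:
    """Regions whose stationary concentration strictly exceeds the threshold."""
    names = np.asarray(atlas.region_names)
    return frozenset(names[state.u_star > threshold])


def _family_indices(atlas: RegionAtlas) -> dict:
    out = {}
    for fam, stages in FAMILIES.items():
        names = braak_regions(atlas, stages, exclude_hippocampus=False)
        out[fam] = np.asarray([atlas.index_of(n) for n in sorted(names)], dtype=int)
    return out


def shuffle_null(conn: Connectome, field: AnomalyField,
                 params: TransportParams = None, n_perm: int = 10_000,
                 rng_seed: int = 0, method: str = "auto") -> NullDistribution:
    """Build the regional-shuffle null distribution.

    Each permutation draws a uniform random permutation of the anomaly
    values over all regions (without replacement), recomputes the stationary
    solution and pools all regional concentrations.  The threshold is
    computed once from the pooled null; per-permutation Braak-family counts
    are evaluated against that global threshold.

    ``method='enumerate'`` replaces Monte-Carlo sampling with all N!
    permutations (N <= 8), making downstream p-values exact;
    ``method='auto'`` picks Monte-Carlo sampling.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    model = TauTransportModel(conn, field, params)
    n = conn.atlas.n_regions
    fam_idx = _family_indices(conn.atlas)

    if method not in ("auto", "shuffle", "enumerate"):
        raise ValueError(f"unknown method {method!r}")
    exhaustive = method == "enumerate"
    if exhaustive:
        if n > ENUMERATION_MAX_N:
            raise ValueError(f"enumeration infeasible for N={n} regions")
        perms = [np.asarray(p) for p in itertools.permutations(range(n))]
    else:
        rng = np.random.default_rng(rng_seed)
        perms = [rng.permutation(n) for _ in range(n_perm)]

    pooled = np.empty((len(perms), n))
    for i, perm in enumerate(perms):
        try:
            pooled[i] = model.with_field(field.permuted(perm)).fit().u_star
        except Exception as exc:
            raise RuntimeError(f"stationary solve failed at permutation {i}") from exc

    threshold = gap_threshold(pooled.ravel())
    counts = {
        fam: (pooled[:, idx] > threshold).sum(axis=1)
        for fam, idx in fam_idx.items()
    }
    return NullDistribution(
        pooled_null=pooled.ravel(),
        per_perm_counts=counts,
        threshold=threshold,
        n_perm=len(perms),
        rng_seed=rng_seed,
        exhaustive=exhaustive,
    )


def braak_seed_test(state: SteadyStateResults, null: NullDistribution,
                    atlas: RegionAtlas) -> SeedingTestResults:
    """Braak-family seeded-region counts against the permutation null.

    p = (1 + #{permutations with null count >= observed}) / (n_perm + 1);
    z = (observed - mean null count) / sd(null counts).  A zero-variance
    null yields z = +inf (with a warning); p remains valid.
    """
    fam_idx = _family_indices(atlas)
    seeded = seeded_regions(state, null.threshold, atlas)
    observed, p_values, z_scores, fam_sizes = {}, {}, {}, {}
    for fam, idx in fam_idx.items():
        obs = int((state.u_star[idx] > null.threshold).sum())
        null_counts = np.asarray(null.per_perm_counts[fam])
        n_perm = null_counts.size
        p = (1 + int((null_counts >= obs).sum())) / (n_perm + 1)
        mu = null_counts.mean()
        sd = null_counts.std(ddof=0)
        if sd == 0:
            warnings.warn(f"zero-variance null counts for {fam}; z set to +inf")
            z = math.inf if obs > mu else (0.0 if obs == mu else -math.inf)
        else:
            z = (obs - mu) / sd
        observed[fam] = obs
        p_values[fam] = float(p)
        z_scores[fam] = float(z)
        fam_sizes[fam] = int(idx.size)
    return SeedingTestResults(seeded, observed, p_values, z_scores, null, fam_sizes)


class SeedingPermutationTest:
    """Model-style wrapper: build from a transport model, ``fit()`` runs the
    permutation null and the Braak-count tests."""

    def __init__(self, conn: Connectome, field: AnomalyField,
                 params: TransportParams = None):
        self.conn = conn
        self.field = field
        self.params = params

    def fit(self, n_perm: int = 10_000, rng_seed: int = 0,
            method: str = "auto") -> SeedingTestResults:
        null = shuffle_null(self.conn, self.field, self.params,
                            n_perm=n_perm, rng_seed=rng_seed, method=method)
        state = TauTransportModel(self.conn, self.field, self.params).fit()
        return braak_seed_test(state, null, self.conn.atlas)
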