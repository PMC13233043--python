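"""Synthetic cohort generation.

Real inputs to this analysis (a tractography-derived structural connectome
and clinical-cohort regional PET SUVR tables) are access-restricted, so
this module
generates stand-ins carrying the statistical structure the analysis
assumes: a connected weighted connectome; per-subject regional FDG, amyloid
and tau SUVR patterns built as group mean profiles plus spatially
correlated between-subject noise; demographics; scan dates that exercise
the +/-12-month pairing logic; and tau outcomes generated from the
transport model's own subject-level predictions with a known slope, so
regression recovery is testable against exact ground truth.

Two presets encode the qualitative regimes of interest:

``PART_like``
    An FDG-driven scenario: the bilateral entorhinal cortex has the lowest
    metabolic activity among connected regions, so activity-scaled
    transport concentrates tau seeds there even without amyloid —
    the primary age-related tauopathy configuration.
``AD_like``
    An amyloid-driven scenario: neocortical amyloid burden is high while
    the entorhinal cortex is relatively spared, amplifying entorhinal
    seeding — the Alzheimer-type configuration.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .atlas import Region, RegionAtlas, braak_regions, default_atlas
from .connectome import Connectome, build_connectome
from .pet import ScanRecord, SubjectRecord, correct_unstable_regions
from .stats import predict_subject_seeding
from .transport import TransportParams

__all__ = [
    "ScenarioConfig",
    "synth_atlas",
    "synth_connectome",
    "synth_pet_cohort",
    "synth_tau_outcomes",
    "scenario_presets",
    "make_scenario_bundle",
]

GROUPS = ("Abeta-", "Abeta+tauMTL-tauNEO-", "Abeta+tauMTL+tauNEO-",
          "Abeta+tauMTL+tauNEO+")

#: Biomarker-group sizes of a realistic FDG cohort (sums to 457).
DEFAULT_GROUP_SIZES = {
    "Abeta-": 285,
    "Abeta+tauMTL-tauNEO-": 47,
    "Abeta+tauMTL+tauNEO-": 37,
    "Abeta+tauMTL+tauNEO+": 88,
}
#: APOE4 carrier rates per biomarker group (graded along the AD continuum).
DEFAULT_APOE4_RATES = {
    "Abeta-": 0.22, "Abeta+tauMTL-tauNEO-": 0.44,
    "Abeta+tauMTL+tauNEO-": 0.65, "Abeta+tauMTL+tauNEO+": 0.80,
}
#: Diagnosis mix (CN, MCI, AD) per biomarker group.
DEFAULT_DIAGNOSIS_MIX = {
    "Abeta-": (0.33, 0.63, 0.04),
    "Abeta+tauMTL-tauNEO-": (0.11, 0.83, 0.06),
    "Abeta+tauMTL+tauNEO-": (0.03, 0.81, 0.16),
    "Abeta+tauMTL+tauNEO+": (0.01, 0.64, 0.35),
}


@dataclass(frozen=True)
class ScenarioConfig:
    """Full specification of a synthetic cohort scenario.

    ``group_means`` maps biomarker group -> modality -> length-N mean SUVR
    profile; subject scans are these means plus spatially correlated
    Gaussian noise (``between_subject_sd``, correlation length
    ``noise_corr_length`` in connectome hops; 0 = independent noise).
    The tau outcome in the designated ``target_regions`` is
    ``tau_intercept + tau_slope * predicted_seeding + N(0, tau_noise_sd)``.
    """

    name: str
    modality: str                                   # "FDG" | "amyloid"
    group_means: Mapping[str, Mapping[str, np.ndarray]]
    target_regions: Tuple[str, ...]
    n_regions: int = 84
    n_subjects: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    between_subject_sd: float = 0.08
    noise_corr_length: float = 1.0
    tau_intercept: float = 1.0
    tau_slope: float = 6.7
    tau_noise_sd: float = 0.25
    tau_baseline: float = 1.1
    age_mean: float = 72.0
    age_sd: float = 7.0
    female_rate: float = 0.47
    education_mean: float = 16.2
    education_sd: float = 2.6
    apoe4_rates: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_APOE4_RATES))
    diagnosis_mix: Mapping[str, tuple] = field(default_factory=lambda: dict(DEFAULT_DIAGNOSIS_MIX))
    frac_out_of_window: float = 0.1
    window_days: int = 365
    edge_density: float = 0.35
    weight_sigma: float = 0.5
    cutoff: float = 0.01
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_regions < 6:
            raise ValueError("n_regions must be >= 6")
        for nm in ("between_subject_sd", "tau_noise_sd", "noise_corr_length"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be >= 0")

    def manifest(self) -> dict:
        """Ground-truth parameters for recovery tests and reports."""
        return {
            "name": self.name,
            "modality": self.modality,
            "n_regions": self.n_regions,
            "n_subjects": dict(self.n_subjects),
            "tau_intercept": self.tau_intercept,
            "tau_slope": self.tau_slope,
            "tau_noise_sd": self.tau_noise_sd,
            "between_subject_sd": self.between_subject_sd,
            "noise_corr_length": self.noise_corr_length,
            "target_regions": list(self.target_regions),
            "frac_out_of_window": self.frac_out_of_window,
            "rng_seed": self.rng_seed,
        }


# ---------------------------------------------------------------------------
# Atlas and connectome
# ---------------------------------------------------------------------------

def synth_atlas(n_regions: int) -> RegionAtlas:
    """Minimal valid atlas with ``n_regions`` regions for toy scenarios.

    The first two regions are the bilateral (pseudo-)entorhinal cortex
    (Braak stage 1); subsequent bilateral pairs are assigned to Braak 2/3
    when at least 12 regions are available.  Composite sets are small but
    structurally valid.
    """
    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    bases = ["entorhinal", "amygdala", "fusiform", "lingual", "parahippocampal"]
    names, hemis = [], []
    i = 0
    while len(names) < n_regions:
        base = bases[i] if i < len(bases) else f"region{i:02d}"
        for suffix, hemi in (("-L", "left"), ("-R", "right")):
            if len(names) < n_regions:
                names.append(base + suffix)
                hemis.append(hemi)
        i += 1
    # drop a dangling unpaired staged region: last single region gets a
    # neutral name so bilaterality of staged structures always holds
    if n_regions % 2 == 1:
        names[-1] = f"region{i:02d}-L"
    regions = tuple(
        Region(index=j, name=nm, hemisphere=h, tissue="cortical")
        for j, (nm, h) in enumerate(zip(names, hemis))
    )
    universe = set(names)
    braak_map = {}
    for nm in ("entorhinal-L", "entorhinal-R"):
        braak_map[nm] = 1
    if n_regions >= 12:
        for base in ("amygdala", "fusiform", "lingual", "parahippocampal"):
            if {base + "-L", base + "-R"} <= universe:
                braak_map[base + "-L"] = "2/3"
                braak_map[base + "-R"] = "2/3"
    non_ent = [nm for nm in names if not nm.startswith("entorhinal")]
    composites = {
        "amyloid_cortical_summary": frozenset(non_ent),
        "tau_mtl_composite": frozenset(["entorhinal-L", "entorhinal-R"]),
        "tau_neo_composite": frozenset(non_ent[:2] or names[:2]),
        "unstable_regions": frozenset(),
    }
    return RegionAtlas(regions=regions, braak_map=braak_map,
                       composites=composites, neighbour_map={},
                       name=f"synth{n_regions}")


def synth_connectome(config: ScenarioConfig, atlas: Optional[RegionAtlas] = None,
                     max_retries: int = 20) -> Connectome:
    """Random weighted connectome passing all Connectome invariants.

    Edges are Bernoulli(edge_density) with log-normal weights; a random
    ring over a permutation of the regions guarantees baseline
    connectivity.  If cutoff filtering still disconnects the graph the draw
    is retried (deterministically from the seeded generator).
    """
    atlas = atlas if atlas is not None else _atlas_for(config)
    n = atlas.n_regions
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 101]))
    last_err = None
    for _ in range(max_retries):
        mask = rng.random((n, n)) < config.edge_density
        weights = rng.lognormal(mean=0.0, sigma=config.weight_sigma, size=(n, n))
        M = np.where(mask, weights, 0.0)
        order = rng.permutation(n)
        for a, b in zip(order, np.roll(order, 1)):
            M[a, b] = max(M[a, b], rng.lognormal(0.0, config.weight_sigma))
        try:
            return build_connectome([M], cutoff=config.cutoff, atlas=atlas)
        except Exception as exc:   # disconnected after cutoff; redraw
            last_err = exc
    raise RuntimeError(f"could not build a connected connectome in "
                       f"{max_retries} attempts") from last_err


def _atlas_for(config: ScenarioConfig) -> RegionAtlas:
    if config.n_regions == 84:
        return default_atlas()
    return synth_atlas(config.n_regions)


# ---------------------------------------------------------------------------
# Group mean SUVR profiles
# ---------------------------------------------------------------------------

def _spread(rng: np.random.Generator, n: int, lo: float, hi: float) -> np.ndarray:
    """Evenly spread values over [lo, hi] in a random (but seeded) order."""
    vals = np.linspace(lo, hi, n)
    return vals[rng.permutation(n)]


def build_group_means(atlas: RegionAtlas, rng_seed: int = 0) -> dict:
    """Default group -> modality -> regional mean SUVR profiles.

    FDG: a stable metabolic topography, nearly identical across groups,
    with the bilateral entorhinal cortex distinctly the least active region
    and other medial temporal structures moderately low.  Amyloid: the
    amyloid-negative group sits uniformly below the cortical positivity
    threshold; positive groups carry a graded neocortical elevation that
    spares the entorhinal cortex.  Tau: group mean composites respect the
    MTL/neocortical positivity thresholds defining each group.
    """
    rng = np.random.default_rng(np.random.SeedSequence([rng_seed, 202]))
    n = atlas.n_regions
    names = np.asarray(atlas.region_names)
    ent = [atlas.index_of(r) for r in sorted(braak_regions(atlas, {1}))]
    mtl23 = [atlas.index_of(r) for r in sorted(braak_regions(atlas, {"2/3"}))]
    mtl_comp = [atlas.index_of(r) for r in sorted(atlas.composites["tau_mtl_composite"])]
    neo_comp = [atlas.index_of(r) for r in sorted(atlas.composites["tau_neo_composite"])]
    summary = [atlas.index_of(r) for r in sorted(atlas.composites["amyloid_cortical_summary"])]

    fdg = _spread(rng, n, 1.10, 1.50)
    fdg[mtl23] = _spread(rng, len(mtl23), 0.88, 0.98)
    fdg[ent] = (0.55, 0.57)

    abeta_neg = _spread(rng, n, 0.90, 1.05)
    abeta_neg[ent] = (0.82, 0.84)

    out: dict = {}
    for gi, group in enumerate(GROUPS):
        fdg_g = fdg * (1.0 - 0.01 * gi)       # slight global hypometabolism
        if group == "Abeta-":
            abeta_g = abeta_neg.copy()
        else:
            abeta_g = abeta_neg.copy()
            lift = 0.35 + 0.15 * gi           # graded neocortical burden
            abeta_g[summary] = _spread(rng, len(summary), 1.10 + lift * 0.5,
                                       1.10 + lift)
            abeta_g[ent] = (0.80, 0.82)       # entorhinal spared
        tau_g = np.full(n, 1.05) + _spread(rng, n, 0.0, 0.08)
        if "tauMTL+" in group:
            tau_g[mtl_comp] = _spread(rng, len(mtl_comp), 1.55, 1.70)
        if "tauNEO+" in group:
            tau_g[neo_comp] = _spread(rng, len(neo_comp), 1.55, 1.70)
        out[group] = {"FDG": fdg_g, "amyloid": abeta_g, "tau": tau_g}
    return out


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _noise_chol(conn: Connectome, corr_length: float) -> np.ndarray:
    """Cholesky factor of the spatial noise correlation (connectome-hop
    exponential kernel); identity when corr_length == 0."""
    n = conn.n_regions
    if corr_length == 0:
        return np.eye(n)
    D = shortest_path(csr_matrix((conn.W > 0).astype(float)), unweighted=True,
                      directed=False)
    K = np.exp(-D / corr_length)
    # an exponential of graph hop distance need not be positive definite;
    # clip the spectrum and renormalize the diagonal to unit variance
    w, V = np.linalg.eigh((K + K.T) / 2)
    K = (V * np.clip(w, 1e-6, None)) @ V.T
    d = np.sqrt(np.diag(K))
    K = K / np.outer(d, d) + 1e-10 * np.eye(n)
    return np.linalg.cholesky(K)


_BASE_DATE = _dt.date(2016, 6, 1)


def synth_pet_cohort(config: ScenarioConfig, atlas: Optional[RegionAtlas] = None,
                     conn: Optional[Connectome] = None,
                     modalities: Tuple[str, ...] = ("FDG", "amyloid", "tau")):
    """Generate per-subject FDG, amyloid and tau scans plus demographics.

    Returns ``(scans, subjects, groups)`` where ``scans`` maps modality to a
    list of ScanRecord, ``subjects`` is a list of SubjectRecord and
    ``groups`` maps subject_id to the intended biomarker group.  A
    configured fraction of subjects receives a primary-modality scan date
    outside the pairing window so pairing logic is exercised.
    """
    atlas = atlas if atlas is not None else _atlas_for(config)
    if conn is None:
        conn = synth_connectome(config, atlas)
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 303]))
    chol = _noise_chol(conn, config.noise_corr_length)
    n = atlas.n_regions

    scans = {m: [] for m in modalities}
    subjects, groups = [], {}
    sid_counter = 0
    for group in GROUPS:
        size = int(config.n_subjects.get(group, 0))
        means = config.group_means[group]
        for _ in range(size):
            sid = f"S{sid_counter:04d}"
            sid_counter += 1
            groups[sid] = group

            tau_date = _BASE_DATE + _dt.timedelta(days=int(rng.integers(-360, 360)))
            out_of_window = rng.random() < config.frac_out_of_window
            if out_of_window:
                gap = int(rng.integers(config.window_days + 30,
                                       config.window_days + 240))
            else:
                gap = int(rng.integers(-config.window_days, config.window_days + 1))
            primary_date = tau_date + _dt.timedelta(days=gap)

            for modality in modalities:
                noise = config.between_subject_sd * (chol @ rng.standard_normal(n))
                suvr = np.clip(means[modality] + noise, 0.05, None)
                date = tau_date if modality == "tau" else primary_date
                scans[modality].append(ScanRecord(
                    subject_id=sid, modality=modality, date=date,
                    suvr=suvr, atlas=atlas,
                ))

            age = float(np.clip(rng.normal(config.age_mean, config.age_sd), 50, 95))
            diag = rng.choice(("CN", "MCI", "AD"),
                              p=np.asarray(config.diagnosis_mix[group]) /
                                sum(config.diagnosis_mix[group]))
            subjects.append(SubjectRecord(
                subject_id=sid,
                age=age,
                sex="female" if rng.random() < config.female_rate else "male",
                education=float(np.clip(
                    rng.normal(config.education_mean, config.education_sd), 8, 24)),
                apoe4_carrier=bool(rng.random() < config.apoe4_rates[group]),
                diagnosis=str(diag),
            ))
    return scans, subjects, groups


def synth_tau_outcomes(primary_scans: Sequence[ScanRecord], conn: Connectome,
                       params: TransportParams, config: ScenarioConfig,
                       rng: Optional[np.random.Generator] = None,
                       return_predictions: bool = False):
    """Tau outcome scans tied to the model's own subject-level predictions.

    For every primary (FDG/amyloid) scan, the target regions receive
    ``tau_intercept + tau_slope * predicted_seeding + noise`` and all other
    regions ``tau_baseline + noise``; predictions are computed on
    unstable-region-corrected scans, the same path the analysis uses, so the
    generative slope is recoverable without attenuation.  The tau scan date
    is copied from the primary scan so every subject pairs.
    """
    atlas = conn.atlas
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 404]))
    tgt_idx = [atlas.index_of(r) for r in config.target_regions]
    out, preds = [], []
    for scan in primary_scans:
        corrected = correct_unstable_regions(scan, atlas)
        pred = predict_subject_seeding(corrected, conn, params,
                                       target=list(config.target_regions))
        suvr = config.tau_baseline + config.tau_noise_sd * rng.standard_normal(atlas.n_regions)
        suvr[tgt_idx] = (config.tau_intercept + config.tau_slope * pred
                         + config.tau_noise_sd * rng.standard_normal(len(tgt_idx)))
        out.append(ScanRecord(
            subject_id=scan.subject_id, modality="tau", date=scan.date,
            suvr=np.clip(suvr, 0.05, None), atlas=atlas,
        ))
        preds.append(pred)
    if return_predictions:
        return out, np.asarray(preds)
    return out


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def scenario_presets(rng_seed: int = 0) -> dict:
    """Named scenario configurations.

    ``PART_like``: FDG-driven, entorhinal cortex least active — activity
    gradients alone steer tau seeds into the entorhinal cortex.
    ``AD_like``: amyloid-driven, neocortical amyloid sparing the entorhinal
    cortex — amyloid gradients amplify entorhinal seeding.
    """
    atlas = default_atlas()
    means = build_group_means(atlas, rng_seed=rng_seed)
    ent = tuple(sorted(braak_regions(atlas, {1})))
    common = dict(group_means=means, target_regions=ent, rng_seed=rng_seed)
    return {
        "PART_like": ScenarioConfig(name="PART_like", modality="FDG",
                                    tau_slope=6.7, **common),
        "AD_like": ScenarioConfig(name="AD_like", modality="amyloid",
                                  tau_slope=11.3, **common),
    }


def get_preset(name: str, rng_seed: int = 0) -> ScenarioConfig:
    presets = scenario_presets(rng_seed)
    try:
        return presets[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(presets)}") from None


def make_scenario_bundle(config: ScenarioConfig, params: TransportParams = None):
    """Generate every artefact of a scenario in one call.

    Returns a dict with the atlas, connectome, scans (with tau outcomes
    replacing the group-pattern tau scans for the primary modality),
    subjects, intended group labels and the ground-truth manifest.
    """
    params = params if params is not None else TransportParams()
    atlas = _atlas_for(config)
    conn = synth_connectome(config, atlas)
    scans, subjects, groups = synth_pet_cohort(config, atlas, conn)
    tau_outcomes = synth_tau_outcomes(scans[config.modality], conn, params, config)
    return {
        "atlas": atlas,
        "connectome": conn,
        "scans": scans,
        "tau_outcomes": tau_outcomes,
        "subjects": subjects,
        "groups": groups,
        "manifest": config.manifest(),
    }
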