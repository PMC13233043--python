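"""PET SUVR cohort handling: loading, correction, composites, biomarker
stratification and cross-modality scan pairing.

SUVR tables are the input boundary — one row per scan with a subject id, an
ISO date and one column per atlas region.  Reference-region conventions
(pons for FDG, whole cerebellum for amyloid, inferior cerebellum for tau)
are carried as metadata only.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .atlas import RegionAtlas

__all__ = [
    "ScanRecord",
    "SubjectRecord",
    "ScanPair",
    "BIOMARKER_GROUPS",
    "MODALITY_REFERENCE",
    "load_suvr_table",
    "load_demographics",
    "correct_unstable_regions",
    "composite_suvr",
    "classify_amyloid",
    "classify_tau",
    "assign_biomarker_group",
    "pair_scans",
    "stratify_cohort",
    "AMYLOID_THRESHOLD",
    "TAU_MTL_THRESHOLD",
    "TAU_NEO_THRESHOLD",
]

# Positivity cutpoints (SUVR, strict ">"): amyloid cortical summary vs whole
# cerebellum; tau MTL (entorhinal + amygdala) and tau neocortical (inferior +
# middle lateral temporal) vs inferior cerebellum.
AMYLOID_THRESHOLD = 1.11
TAU_MTL_THRESHOLD = 1.375
TAU_NEO_THRESHOLD = 1.395

MODALITY_REFERENCE = {
    "FDG": "pons",
    "amyloid": "whole_cerebellum",
    "tau": "inferior_cerebellum",
}

#: Biomarker strata.  Amyloid-negative subjects are pooled regardless of tau
#: status; amyloid-positives are subdivided by tau MTL/neocortical status,
#: and the rare Abeta+ tauMTL- tauNEO+ combination is excluded.
BIOMARKER_GROUPS = (
    "Abeta-",
    "Abeta+tauMTL-tauNEO-",
    "Abeta+tauMTL+tauNEO-",
    "Abeta+tauMTL+tauNEO+",
    "EXCLUDED",
)

DIAGNOSES = ("CN", "MCI", "AD")


@dataclass(frozen=True)
class ScanRecord:
    subject_id: str
    modality: str        # "FDG" | "amyloid" | "tau"
    date: _dt.date
    suvr: np.ndarray     # aligned to atlas order
    atlas: RegionAtlas
    reference_region: str = ""

    def __post_init__(self):
        if self.modality not in MODALITY_REFERENCE:
            raise ValueError(f"unknown modality {self.modality!r}")
        suvr = np.asarray(self.suvr, dtype=float)
        object.__setattr__(self, "suvr", suvr)
        if suvr.shape != (self.atlas.n_regions,):
            raise ValueError("SUVR vector length does not match atlas")
        if not np.all(np.isfinite(suvr)) or np.any(suvr <= 0):
            raise ValueError(f"nonpositive/non-finite SUVR for {self.subject_id}")
        if not self.reference_region:
            object.__setattr__(
                self, "reference_region", MODALITY_REFERENCE[self.modality]
            )


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    age: float
    sex: str                   # "female" | "male"
    education: float
    apoe4_carrier: bool
    diagnosis: Optional[str]   # "CN" | "MCI" | "AD" | None
    centiloid: Optional[float] = None

    def __post_init__(self):
        if self.age <= 0:
            raise ValueError(f"nonpositive age for {self.subject_id}")
        if self.sex not in ("female", "male"):
            raise ValueError(f"bad sex {self.sex!r} for {self.subject_id}")
        if self.diagnosis is not None and self.diagnosis not in DIAGNOSES:
            raise ValueError(f"bad diagnosis {self.diagnosis!r}")


@dataclass(frozen=True)
class ScanPair:
    subject_id: str
    primary_scan: ScanRecord
    tau_scan: ScanRecord
    gap_days: int


def load_suvr_table(path, atlas: RegionAtlas, modality: str) -> list:
    """Read a regional SUVR table (subject_id, date, one column per region)."""
    df = pd.read_csv(path)
    required = {"subject_id", "date"}
    if not required <= set(df.columns):
        raise ValueError(f"SUVR table must have columns {sorted(required)}")
    region_cols = [c for c in df.columns if c not in required]
    names = set(atlas.region_names)
    unknown = sorted(set(region_cols) - names)
    if unknown:
        raise ValueError(f"unknown region columns: {unknown}")
    missing = sorted(names - set(region_cols))
    if missing:
        raise ValueError(f"missing region columns: {missing[:6]}")
    records = []
    for _, row in df.iterrows():
        suvr = row[list(atlas.region_names)].to_numpy(dtype=float)
        if np.any(~np.isfinite(suvr)) or np.any(suvr <= 0):
            raise ValueError(
                f"nonpositive SUVR in row subject={row['subject_id']} date={row['date']}"
            )
        records.append(
            ScanRecord(
                subject_id=str(row["subject_id"]),
                modality=modality,
                date=_dt.date.fromisoformat(str(row["date"])),
                suvr=suvr,
                atlas=atlas,
            )
        )
    return records


def load_demographics(path) -> list:
    """Read a demographics table: subject_id,age,sex,education,apoe4,diagnosis[,centiloid]."""
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        cent = row.get("centiloid")
        out.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                education=float(row["education"]),
                apoe4_carrier=bool(int(row["apoe4"])),
                diagnosis=None if pd.isna(row.get("diagnosis")) else str(row["diagnosis"]),
                centiloid=None if cent is None or pd.isna(cent) else float(cent),
            )
        )
    return out


def correct_unstable_regions(scan: ScanRecord, atlas: RegionAtlas) -> ScanRecord:
    """Stabilize segmentation-artefact-prone regions.

    Each region in the ``unstable_regions`` composite (frontal pole, temporal
    pole, banks of the superior temporal sulcus) has its SUVR replaced by the
    unweighted mean over itself and its anatomical neighbours.  All
    replacements use pre-correction values (simultaneous update, no cascade);
    every other region is untouched.
    """
    unstable = atlas.composites["unstable_regions"]
    suvr = scan.suvr.copy()
    for name in sorted(unstable):
        nbrs = atlas.neighbour_map.get(name, ())
        if not nbrs:
            raise ValueError(f"unstable region {name!r} has no neighbours defined")
        idx = [atlas.index_of(name)] + [atlas.index_of(n) for n in nbrs]
        suvr[atlas.index_of(name)] = scan.suvr[idx].mean()
    return replace(scan, suvr=suvr)


def composite_suvr(scan: ScanRecord, regions: Iterable[str]) -> float:
    """Unweighted mean SUVR over a named region set."""
    regions = list(regions)
    if not regions:
        raise ValueError("empty composite region set")
    idx = [scan.atlas.index_of(r) for r in regions]
    return float(scan.suvr[idx].mean())


def classify_amyloid(scan: ScanRecord, atlas: RegionAtlas,
                     threshold: float = AMYLOID_THRESHOLD) -> bool:
    """Amyloid positivity: cortical summary SUVR strictly > threshold."""
    if scan.modality != "amyloid":
        raise ValueError("amyloid classification requires an amyloid scan")
    return composite_suvr(scan, atlas.composites["amyloid_cortical_summary"]) > threshold


def classify_tau(scan: ScanRecord, atlas: RegionAtlas,
                 mtl_threshold: float = TAU_MTL_THRESHOLD,
                 neo_threshold: float = TAU_NEO_THRESHOLD):
    """Tau positivity in the MTL and neocortical composites (strict ">")."""
    if scan.modality != "tau":
        raise ValueError("tau classification requires a tau scan")
    mtl = composite_suvr(scan, atlas.composites["tau_mtl_composite"]) > mtl_threshold
    neo = composite_suvr(scan, atlas.composites["tau_neo_composite"]) > neo_threshold
    return mtl, neo


def assign_biomarker_group(abeta_pos: bool, tau_mtl: bool, tau_neo: bool) -> str:
    """Map positivity calls to the four-group biomarker stratification.

    Amyloid-negative subjects are grouped "Abeta-" regardless of tau; the
    Abeta+ tauMTL- tauNEO+ combination is EXCLUDED (rare discordant profile).
    """
    if not abeta_pos:
        return "Abeta-"
    if not tau_mtl and tau_neo:
        return "EXCLUDED"
    return f"Abeta+tauMTL{'+' if tau_mtl else '-'}tauNEO{'+' if tau_neo else '-'}"


def pair_scans(primary: Sequence[ScanRecord], tau: Sequence[ScanRecord],
               window_days: int = 365, policy: str = "earliest") -> list:
    """Pair each subject's primary-modality scan with a tau scan.

    Among all cross-modality pairs within ``window_days`` of each other,
    select per subject the pair whose tau-scan date is earliest
    (policy="earliest") or latest (policy="latest"); remaining ties broken by
    smallest absolute gap, then by earliest primary date.  At most one pair
    per subject.
    """
    if policy not in ("earliest", "latest"):
        raise ValueError(f"unknown pairing policy {policy!r}")
    for records in (primary, tau):
        seen = set()
        for r in records:
            key = (r.subject_id, r.modality, r.date)
            if key in seen:
                raise ValueError(f"duplicate scan row {key}")
            seen.add(key)
    by_subject: dict = {}
    for r in primary:
        by_subject.setdefault(r.subject_id, ([], []))[0].append(r)
    for r in tau:
        by_subject.setdefault(r.subject_id, ([], []))[1].append(r)

    pairs = []
    sign = 1 if policy == "earliest" else -1
    for sid in sorted(by_subject):
        prim, taus = by_subject[sid]
        candidates = []
        for p in prim:
            for t in taus:
                gap = (t.date - p.date).days
                if abs(gap) <= window_days:
                    candidates.append((sign * t.date.toordinal(), abs(gap),
                                       p.date.toordinal(), p, t, gap))
        if not candidates:
            continue
        candidates.sort(key=lambda c: c[:3])
        _, _, _, p, t, gap = candidates[0]
        pairs.append(ScanPair(subject_id=sid, primary_scan=p, tau_scan=t,
                              gap_days=gap))
    return pairs


def stratify_cohort(amyloid_scans: Sequence[ScanRecord],
                    tau_scans: Sequence[ScanRecord],
                    atlas: RegionAtlas,
                    window_days: int = 365,
                    policy: str = "earliest") -> pd.DataFrame:
    """Biomarker-group assignment from paired amyloid/tau scans.

    Returns one row per pairable subject with positivity calls and group
    label (including EXCLUDED rows, flagged so callers can drop them).
    """
    pairs = pair_scans(amyloid_scans, tau_scans, window_days=window_days,
                       policy=policy)
    rows = []
    for pr in pairs:
        abeta = classify_amyloid(pr.primary_scan, atlas)
        mtl, neo = classify_tau(pr.tau_scan, atlas)
        group = assign_biomarker_group(abeta, mtl, neo)
        rows.append({
            "subject_id": pr.subject_id,
            "abeta_positive": abeta,
            "tau_mtl_positive": mtl,
            "tau_neo_positive": neo,
            "group": group,
            "gap_days": pr.gap_days,
        })
    return pd.DataFrame(rows)
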