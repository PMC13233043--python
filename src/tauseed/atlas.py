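"""Region atlas: region universe, Braak staging, composites, neighbour maps.

The atlas defines the ordered list of brain regions over which every other
object (connectome, anomaly field, SUVR scan) is aligned.  Regions carry a
hemisphere and a tissue class; Braak-stage membership follows the canonical
anatomical ordering of tau pathology (stage 1 = bilateral entorhinal cortex),
and named composite sets drive amyloid/tau positivity classification and the
unstable-region SUVR correction.

Atlas files are JSON with keys ``regions``, ``braak``, ``composites`` and
``neighbours``; region names use Desikan-Killiany base names with explicit
``-L``/``-R`` hemisphere suffixes.  A default 84-region atlas (68 cortical +
16 subcortical) ships with the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Region",
    "RegionAtlas",
    "AtlasError",
    "load_atlas",
    "default_atlas",
    "braak_regions",
    "BRAAK_STAGES",
]

#: Valid Braak stage labels, in anatomical order.  Stages 2 and 3 are pooled
#: ("2/3") because at the resolution of this parcellation they cannot be
#: separated.
BRAAK_STAGES: tuple = (1, "2/3", 4, 5, 6)

REQUIRED_COMPOSITES = (
    "amyloid_cortical_summary",
    "tau_mtl_composite",
    "tau_neo_composite",
    "unstable_regions",
)


class AtlasError(ValueError):
    """Raised when an atlas definition violates a structural invariant."""


@dataclass(frozen=True)
class Region:
    index: int
    name: str
    hemisphere: str  # "left" | "right"
    tissue: str      # "cortical" | "subcortical"


@dataclass(frozen=True)
class RegionAtlas:
    """Ordered region universe with Braak staging and composite sets.

    Attributes
    ----------
    regions : tuple of Region
        Ordered regions; indices contiguous from 0.
    braak_map : mapping
        Region name -> stage label in {1, "2/3", 4, 5, 6}; unstaged regions
        are absent from the map.
    composites : mapping
        Composite-set name -> frozenset of region names.  The four required
        sets are ``amyloid_cortical_summary``, ``tau_mtl_composite``,
        ``tau_neo_composite`` and ``unstable_regions``.
    neighbour_map : mapping
        Region name -> tuple of anatomically adjacent region names, used for
        the unstable-region SUVR correction.
    name : str
        Identifier for provenance checks between aligned objects.
    """

    regions: tuple
    braak_map: Mapping[str, object]
    composites: Mapping[str, frozenset]
    neighbour_map: Mapping[str, tuple]
    name: str = "atlas"

    # -- basic views -----------------------------------------------------
    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def region_names(self) -> tuple:
        return tuple(r.name for r in self.regions)

    def index_of(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise AtlasError(f"unknown region {name!r}") from None

    def __post_init__(self):
        object.__setattr__(
            self, "_index", {r.name: r.index for r in self.regions}
        )
        _validate(self)

    def __eq__(self, other):
        if not isinstance(other, RegionAtlas):
            return NotImplemented
        return self.name == other.name and self.region_names == other.region_names

    def __hash__(self):
        return hash((self.name, self.region_names))


def _base_name(name: str) -> str:
    for suffix in ("-L", "-R"):
        if name.endswith(suffix):
            return name[: -len(suffix)]
    return name


def _validate(atlas: RegionAtlas) -> None:
    names = [r.name for r in atlas.regions]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise AtlasError(f"duplicate region names: {dupes}")
    for i, r in enumerate(atlas.regions):
        if r.index != i:
            raise AtlasError(f"non-contiguous region indices at {r.name}")
        if r.hemisphere not in ("left", "right"):
            raise AtlasError(f"bad hemisphere {r.hemisphere!r} for {r.name}")
        if r.tissue not in ("cortical", "subcortical"):
            raise AtlasError(f"bad tissue class {r.tissue!r} for {r.name}")
    universe = set(names)

    staged = list(atlas.braak_map.items())
    for name, stage in staged:
        if stage not in BRAAK_STAGES:
            raise AtlasError(f"unknown Braak stage {stage!r} for {name}")
        if name not in universe:
            raise AtlasError(f"Braak-staged region {name!r} not in region list")
    # bilaterality: every staged anatomical structure appears in both
    # hemispheres with the same stage
    by_stage: dict = {}
    for name, stage in staged:
        by_stage.setdefault(stage, set()).add(name)
    for stage, members in by_stage.items():
        bases = {}
        for name in members:
            bases.setdefault(_base_name(name), set()).add(name)
        for base, sided in bases.items():
            expect = {f"{base}-L", f"{base}-R"}
            if sided != expect:
                raise AtlasError(
                    f"Braak stage {stage!r}: {base!r} not bilateral "
                    f"(found {sorted(sided)})"
                )
    stage1 = by_stage.get(1, set())
    if stage1 and {_base_name(n) for n in stage1} != {"entorhinal"}:
        raise AtlasError(
            f"stage 1 must be exactly the bilateral entorhinal cortex, got {sorted(stage1)}"
        )

    for comp in REQUIRED_COMPOSITES:
        if comp not in atlas.composites:
            raise AtlasError(f"missing required composite set {comp!r}")
    for comp, members in atlas.composites.items():
        extra = set(members) - universe
        if extra:
            raise AtlasError(f"composite {comp!r} has unknown regions {sorted(extra)}")

    for name, nbrs in atlas.neighbour_map.items():
        if name not in universe:
            raise AtlasError(f"neighbour map key {name!r} not in region list")
        if name in nbrs:
            raise AtlasError(f"region {name!r} listed as its own neighbour")
        extra = set(nbrs) - universe
        if extra:
            raise AtlasError(f"neighbours of {name!r} unknown: {sorted(extra)}")


def _from_dict(doc: dict, name: str) -> RegionAtlas:
    try:
        raw_regions = doc["regions"]
        raw_braak = doc["braak"]
        raw_comp = doc["composites"]
        raw_nbr = doc.get("neighbours", {})
    except KeyError as exc:
        raise AtlasError(f"atlas file missing key {exc}") from None

    regions = tuple(
        Region(index=i, name=r["name"], hemisphere=r["hemisphere"], tissue=r["tissue"])
        for i, r in enumerate(raw_regions)
    )
    braak_map: dict = {}
    for stage_key, members in raw_braak.items():
        stage: object = int(stage_key) if stage_key in ("1", "4", "5", "6") else stage_key
        for m in members:
            if m in braak_map:
                raise AtlasError(f"region {m!r} assigned to two Braak stages")
            braak_map[m] = stage
    composites = {k: frozenset(v) for k, v in raw_comp.items()}
    neighbour_map = {k: tuple(v) for k, v in raw_nbr.items()}
    return RegionAtlas(
        regions=regions,
        braak_map=braak_map,
        composites=composites,
        neighbour_map=neighbour_map,
        name=name,
    )


def load_atlas(path) -> RegionAtlas:
    """Load and validate a region atlas from a JSON definition file."""
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    return _from_dict(doc, name=doc.get("name", path.stem))


def default_atlas() -> RegionAtlas:
    """The bundled 84-region Desikan-Killiany-style atlas."""
    text = resources.files("tauseed.data").joinpath("dk84.json").read_text()
    doc = json.loads(text)
    return _from_dict(doc, name=doc.get("name", "dk84"))


def braak_regions(
    atlas: RegionAtlas,
    stages: Iterable,
    exclude_hippocampus: bool = False,
) -> frozenset:
    """Region names belonging to the requested Braak stages.

    Parameters
    ----------
    stages
        Subset of {1, "2/3", 4, 5, 6}.
    exclude_hippocampus
        Drop both hippocampi from the result when stage "2/3" is requested.
        Tau-PET tracers show off-target binding in the adjacent choroid
        plexus, so empirical-tau comparisons exclude the hippocampus; the
        model-side seeding tests do not.
    """
    stages = set(stages)
    unknown = stages - set(BRAAK_STAGES)
    if unknown:
        raise ValueError(f"unknown Braak stage labels: {sorted(map(str, unknown))}")
    out = {name for name, st in atlas.braak_map.items() if st in stages}
    if exclude_hippocampus and "2/3" in stages:
        out -= {n for n in out if _base_name(n) == "hippocampus"}
    return frozenset(out)
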