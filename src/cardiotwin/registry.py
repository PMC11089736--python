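"""Model parameter registry and subset bookkeeping.

Every parameter eligible for personalization is described by a
:class:`ParameterSpec` carrying its category, cardiac wall, scope
(global / regional / global-offset), physiological reference value and
two nested sampling ranges: the screening range used for sensitivity
analysis and quasi-Monte Carlo sampling (``msm_range``) and the extended
boundaries used by the particle swarm optimizer (``pso_bounds``).

The homogeneous-wall model exposes 100 parameters: 3 global-hemodynamic,
12 pulmonary/systemic, 8 valve, 3 pericardium, 4 mechanical-activation
and 70 myocardial-tissue (28 for septum + LV free wall, 14 each for RV,
LA and RA).  Subdividing the LV into ``n_seg`` segments replicates the
14 LV tissue-parameter types per segment and adds one mechanical
activation delay per extra segment, giving ``100 + 14*n_seg - 28 +
(n_seg - 2)`` parameters (160 at 6 segments, 340 at 18).  Global-offset
(GO) parameters add a single LV-wide value per regional tissue type
(174 at 6 segments with offsets).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import yaml

CATEGORIES = (
    "global-hemodynamic",
    "pulmonary-systemic",
    "valve",
    "pericardium",
    "mechanical-activation",
    "myocardial-tissue",
)
WALLS = ("LV", "RV", "LA", "RA", "septum-LVFW", "none")
SCOPES = ("global", "regional", "global-offset")

#: The 14 per-segment myocardial tissue parameter types of the LV wall.
#: Names follow the lumped-parameter sarcomere convention (reference wall
#: area, wall volume, sarcomere reference/zero-passive-stress lengths,
#: passive stiffness scale and exponents, active stress scale, shortening
#: velocity, rise/decay time factors, length-dependent activation
#: duration and contraction-inactivation coefficients).
LV_TISSUE_TYPES = (
    "AmRef", "VWall", "LsRef", "Ls0Pas", "dLsPas", "SfPas", "k1",
    "k3", "SfAct", "vMax", "TR", "TD", "LDAD", "LDCI",
)

#: Default 6-to-18 segment mapping: each of the six LV walls is
#: triplicated in the apex-to-base dimension (apical, mid, basal level),
#: following the 18-segment longitudinal strain convention.
DEFAULT_6_TO_18 = {i: (3 * i, 3 * i + 1, 3 * i + 2) for i in range(6)}


class RegistryError(ValueError):
    """Raised on malformed subsets or unknown parameter groups."""


@dataclass(frozen=True)
class ParameterSpec:
    """One model parameter: identity, scope, reference value and ranges."""

    name: str
    category: str
    wall: str = "none"
    scope: str = "global"
    segment_index: Optional[int] = None
    reference_value: float = 0.0
    msm_range: Tuple[float, float] = (0.0, 1.0)
    pso_bounds: Tuple[float, float] = (0.0, 1.0)
    provenance: str = "placeholder"

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise RegistryError(f"unknown category {self.category!r}")
        if self.wall not in WALLS:
            raise RegistryError(f"unknown wall {self.wall!r}")
        if self.scope not in SCOPES:
            raise RegistryError(f"unknown scope {self.scope!r}")
        lo, hi = self.msm_range
        plo, phi = self.pso_bounds
        if not (plo <= lo <= hi <= phi):
            raise RegistryError(
                f"{self.name}: msm_range {self.msm_range} not nested in "
                f"pso_bounds {self.pso_bounds}"
            )
        if self.scope == "regional" and self.segment_index is None:
            raise RegistryError(f"{self.name}: regional scope needs a segment index")
        if self.scope == "global-offset":
            if self.wall not in ("LV", "septum-LVFW"):
                raise RegistryError(f"{self.name}: global-offset requires an LV wall")
            if self.category not in ("myocardial-tissue", "mechanical-activation"):
                raise RegistryError(
                    f"{self.name}: global-offset requires a tissue/activation category"
                )

    @property
    def key(self) -> Tuple[str, Optional[int]]:
        return (self.name, self.segment_index)

    @property
    def group(self) -> str:
        """Parameter-group label: regional specs of one type share a group."""
        return self.name


@dataclass(frozen=True)
class ParameterSubset:
    """An ordered collection of parameter specs on one LV segment scheme.

    ``fixed`` records parameters that were removed from the estimation
    subset and pinned to their reference values, so that no parameter
    silently disappears during subset reduction.
    """

    specs: Tuple[ParameterSpec, ...]
    n_seg: int = 2
    fixed: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [s.key for s in self.specs]
        if len(keys) != len(set(keys)):
            raise RegistryError("duplicate (name, segment_index) pairs in subset")

    def __len__(self) -> int:
        return len(self.specs)

    def __iter__(self):
        return iter(self.specs)

    @property
    def size(self) -> int:
        return len(self.specs)

    def category_counts(self) -> Dict[str, int]:
        out: Dict[str, int] = {c: 0 for c in CATEGORIES}
        for s in self.specs:
            out[s.category] += 1
        return out

    def groups(self) -> Dict[str, List[ParameterSpec]]:
        """Parameter groups: a non-LV or global parameter forms its own
        group; regional LV specs of one tissue type form one group."""
        out: Dict[str, List[ParameterSpec]] = {}
        for s in self.specs:
            out.setdefault(s.group, []).append(s)
        return out

    def get(self, name: str, segment_index: Optional[int] = None) -> ParameterSpec:
        for s in self.specs:
            if s.key == (name, segment_index):
                return s
        raise RegistryError(f"no spec ({name}, {segment_index})")

    def has_group(self, name: str) -> bool:
        return any(s.name == name for s in self.specs)

    def select(self, names: Iterable[str]) -> "ParameterSubset":
        """Restrict the subset to the given parameter names (all segments)."""
        wanted = set(names)
        unknown = wanted - {s.name for s in self.specs}
        if unknown:
            raise RegistryError(f"unknown parameter names: {sorted(unknown)}")
        kept = tuple(s for s in self.specs if s.name in wanted)
        return ParameterSubset(kept, n_seg=self.n_seg, fixed=dict(self.fixed))

    def to_records(self) -> List[dict]:
        return [
            {
                "name": s.name,
                "category": s.category,
                "wall": s.wall,
                "scope": s.scope,
                "segment": s.segment_index,
                "ref": s.reference_value,
                "msm_lo": s.msm_range[0],
                "msm_hi": s.msm_range[1],
                "pso_lo": s.pso_bounds[0],
                "pso_hi": s.pso_bounds[1],
                "provenance": s.provenance,
            }
            for s in self.specs
        ]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"n_seg": self.n_seg, "fixed": dict(self.fixed),
                 "specs": self.to_records()},
                fh, sort_keys=False,
            )

    @staticmethod
    def from_yaml(path) -> "ParameterSubset":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        specs = tuple(
            ParameterSpec(
                name=r["name"], category=r["category"], wall=r["wall"],
                scope=r["scope"], segment_index=r["segment"],
                reference_value=r["ref"],
                msm_range=(r["msm_lo"], r["msm_hi"]),
                pso_bounds=(r["pso_lo"], r["pso_hi"]),
                provenance=r.get("provenance", "placeholder"),
            )
            for r in doc["specs"]
        )
        return ParameterSubset(specs, n_seg=doc["n_seg"], fixed=doc.get("fixed", {}))


# ---------------------------------------------------------------------------
# Default parameter table
# ---------------------------------------------------------------------------

def _pso_from_msm(lo: float, hi: float, positive: bool) -> Tuple[float, float]:
    """Extended swarm boundaries: screening range widened by 25% per side."""
    w = hi - lo
    plo, phi = lo - 0.25 * w, hi + 0.25 * w
    if positive and plo <= 0.0:
        plo = min(lo, 1e-3 * max(hi, 1.0))
    return (plo, phi)


# name -> (reference, msm_lo, msm_hi, positive, provenance)
# Provenance "paper-named" marks parameters whose names appear in the source
# literature for this model family; the numeric ranges themselves are
# versioned package defaults.
_LV_TISSUE_TABLE = {
    "AmRef":  (None, None, None, True, "paper-named"),   # cm^2, per segment
    "VWall":  (None, None, None, True, "placeholder"),   # mL, per segment
    "LsRef":  (2.0, 1.8, 2.2, True, "placeholder"),      # um
    "Ls0Pas": (1.8, 1.6, 2.0, True, "paper-named"),      # um
    "dLsPas": (0.6, 0.4, 0.8, True, "placeholder"),
    "SfPas":  (0.6, 0.1, 6.0, True, "paper-named"),      # kPa
    "k1":     (10.0, 5.0, 40.0, True, "paper-named"),
    "k3":     (30.0, 10.0, 60.0, True, "placeholder"),
    "SfAct":  (100.0, 20.0, 160.0, True, "paper-named"), # kPa
    "vMax":   (7.0, 2.0, 14.0, True, "paper-named"),     # um/s
    "TR":     (0.25, 0.1, 0.5, True, "placeholder"),
    "TD":     (0.25, 0.1, 0.5, True, "placeholder"),
    "LDAD":   (1.0, 0.5, 3.0, True, "paper-named"),
    "LDCI":   (1.0, 0.5, 3.0, True, "paper-named"),
}

#: Total LV midwall reference area (cm^2) and wall volume (mL) shared out
#: over segments; keeps cavity size physiological at any segmentation.
TOTAL_AMREF_CM2 = 140.0
TOTAL_VWALL_ML = 160.0

_GLOBAL_TABLE = [
    # (name, category, wall, ref, lo, hi, positive, provenance)
    ("q0", "global-hemodynamic", "none", 70.0, 30.0, 140.0, True, "paper-named"),  # mL/s
    ("p0", "global-hemodynamic", "none", 12.2, 8.0, 20.0, True, "placeholder"),    # kPa
    ("tCycle", "global-hemodynamic", "none", 850.0, 600.0, 1200.0, True, "paper-named"),  # ms
    ("dTauAv", "mechanical-activation", "none", 0.0, -50.0, 50.0, False, "paper-named"),  # ms
    ("ADO_LV", "mechanical-activation", "LV", 380.0, 250.0, 550.0, True, "paper-named"),  # ms
    ("tauVV", "mechanical-activation", "none", 0.0, -60.0, 60.0, False, "paper-named"),   # ms
    ("tauSL", "mechanical-activation", "LV", 0.0, 0.0, 130.0, False, "paper-named"),      # ms
    ("KPeri", "pericardium", "none", 10.0, 1.0, 30.0, True, "placeholder"),
    ("VRefPeri", "pericardium", "none", 700.0, 400.0, 1000.0, True, "placeholder"),
    ("SfPeri", "pericardium", "none", 0.5, 0.05, 5.0, True, "placeholder"),
]

_PS_VESSELS = ("SyArt", "SyVen", "PuArt", "PuVen")
_PS_PROPS = {"A0": (5.0, 2.0, 10.0), "p0Ref": (10.0, 2.0, 20.0), "kWall": (8.0, 4.0, 16.0)}
_VALVES = ("Mi", "Ao", "Tri", "Pu")
_VALVE_PROPS = {"AOpen": (5.0, 2.0, 8.0), "ALeak": (1e-6, 1e-7, 1e-2)}


def _spec(name, category, wall, scope, seg, ref, lo, hi, positive, prov) -> ParameterSpec:
    return ParameterSpec(
        name=name, category=category, wall=wall, scope=scope, segment_index=seg,
        reference_value=ref, msm_range=(lo, hi),
        pso_bounds=_pso_from_msm(lo, hi, positive), provenance=prov,
    )


def _lv_tissue_spec(tname: str, seg: int, n_seg: int) -> ParameterSpec:
    ref, lo, hi, positive, prov = _LV_TISSUE_TABLE[tname]
    if tname == "AmRef":
        ref = TOTAL_AMREF_CM2 / n_seg
        lo, hi = 0.6 * ref, 1.4 * ref
    elif tname == "VWall":
        ref = TOTAL_VWALL_ML / n_seg
        lo, hi = 0.6 * ref, 1.4 * ref
    return _spec(tname, "myocardial-tissue", "septum-LVFW", "regional", seg,
                 ref, lo, hi, positive, prov)


def _other_wall_tissue(wall: str) -> List[ParameterSpec]:
    out = []
    for tname in LV_TISSUE_TYPES:
        ref, lo, hi, positive, prov = _LV_TISSUE_TABLE[tname]
        if tname == "AmRef":
            ref, lo, hi = 80.0, 48.0, 112.0
        elif tname == "VWall":
            ref, lo, hi = 60.0, 36.0, 84.0
        out.append(_spec(tname + "_" + wall, "myocardial-tissue", wall, "global",
                         None, ref, lo, hi, positive, "placeholder"))
    return out


def build_homogeneous_registry() -> ParameterSubset:
    """The 100-parameter registry of the homogeneous-wall model.

    The LV (septum + free wall) is represented as the minimal two-segment
    scheme, so its 14 tissue types contribute 28 regional specs; the RV,
    LA and RA walls keep one global spec per type (14 each).
    """
    specs: List[ParameterSpec] = []
    for row in _GLOBAL_TABLE:
        specs.append(_spec(row[0], row[1], row[2], "global", None, *row[3:]))
    for vessel in _PS_VESSELS:
        for prop, (ref, lo, hi) in _PS_PROPS.items():
            specs.append(_spec(f"{prop}{vessel}", "pulmonary-systemic", "none",
                               "global", None, ref, lo, hi, True, "placeholder"))
    for valve in _VALVES:
        for prop, (ref, lo, hi) in _VALVE_PROPS.items():
            specs.append(_spec(f"{prop}{valve}", "valve", "none", "global", None,
                               ref, lo, hi, True, "placeholder"))
    for seg in range(2):
        for tname in LV_TISSUE_TYPES:
            specs.append(_lv_tissue_spec(tname, seg, n_seg=2))
    for wall in ("RV", "LA", "RA"):
        specs.extend(_other_wall_tissue(wall))
    return ParameterSubset(tuple(specs), n_seg=2)


def apply_segmentation(registry: ParameterSubset, n_seg: int) -> ParameterSubset:
    """Subdivide the LV into ``n_seg`` segments.

    Each of the 14 LV tissue types is replicated per segment, and one
    mechanical activation delay ``dT`` is added for each segment beyond
    the homogeneous two-wall scheme.
    """
    if n_seg < 2:
        raise RegistryError(f"n_seg must be >= 2, got {n_seg}")
    if registry.n_seg != 2:
        raise RegistryError("apply_segmentation expects the homogeneous registry")
    specs: List[ParameterSpec] = []
    for s in registry.specs:
        if s.wall == "septum-LVFW" and s.scope == "regional":
            continue  # replaced below
        specs.append(s)
    for seg in range(n_seg):
        for tname in LV_TISSUE_TYPES:
            specs.append(_lv_tissue_spec(tname, seg, n_seg=n_seg))
    for k in range(n_seg - 2):
        specs.append(_spec("dT", "mechanical-activation", "LV", "regional",
                           k + 2, 0.0, 0.0, 150.0, False, "paper-named"))
    return ParameterSubset(tuple(specs), n_seg=n_seg, fixed=dict(registry.fixed))


def add_global_offsets(subset: ParameterSubset) -> ParameterSubset:
    """Add one global-offset (GO) spec per distinct regional LV
    myocardial-tissue type present.  Idempotent."""
    present_go = {s.name for s in subset.specs if s.scope == "global-offset"}
    regional_types: List[str] = []
    for s in subset.specs:
        if (s.scope == "regional" and s.category == "myocardial-tissue"
                and s.wall == "septum-LVFW" and s.name not in regional_types):
            regional_types.append(s.name)
    new = list(subset.specs)
    for tname in regional_types:
        go_name = tname + "_GO"
        if go_name in present_go:
            continue
        proto = next(s for s in subset.specs
                     if s.name == tname and s.scope == "regional")
        # GO offsets multiply the regional reference values; neutral at 1.
        new.append(ParameterSpec(
            name=go_name, category="myocardial-tissue", wall="septum-LVFW",
            scope="global-offset", segment_index=None, reference_value=1.0,
            msm_range=(0.6, 1.4), pso_bounds=(0.4, 1.6),
            provenance=proto.provenance,
        ))
    return ParameterSubset(tuple(new), n_seg=subset.n_seg, fixed=dict(subset.fixed))


def expand_subset(
    subset6: ParameterSubset,
    mapping_table: Mapping[int, Sequence[int]] = DEFAULT_6_TO_18,
) -> ParameterSubset:
    """Expand a 6-segment subset to the 18-segment scheme.

    Regional specs are replicated to the mapped children segments; global
    and global-offset specs are carried over once.  Group structure is
    preserved.
    """
    if subset6.n_seg != 6:
        raise RegistryError("expand_subset expects a 6-segment subset")
    n_children = sum(len(v) for v in mapping_table.values())
    specs: List[ParameterSpec] = []
    for s in subset6.specs:
        if s.scope != "regional":
            specs.append(s)
            continue
        if s.segment_index not in mapping_table:
            raise RegistryError(f"segment {s.segment_index} unmapped")
        for child in mapping_table[s.segment_index]:
            specs.append(replace(s, segment_index=child))
    return ParameterSubset(tuple(specs), n_seg=n_children, fixed=dict(subset6.fixed))


def build_estimation_subset(
    registry: ParameterSubset, names: Iterable[str]
) -> ParameterSubset:
    """Select an estimation subset by parameter name.

    In estimation subsets the mechanical activation delay ``dT`` is
    estimated for every LV segment (the counting registry carries delays
    only for segments beyond the homogeneous two-wall scheme, whose
    delays are implicit references).  Requesting ``dT`` therefore fills
    in specs for all ``n_seg`` segments.
    """
    sub = registry.select(names)
    if "dT" in set(names):
        present = {s.segment_index for s in sub.specs if s.name == "dT"}
        extra = [
            _spec("dT", "mechanical-activation", "LV", "regional", seg,
                  0.0, 0.0, 150.0, False, "paper-named")
            for seg in range(registry.n_seg) if seg not in present
        ]
        merged = list(sub.specs) + extra
        # keep segment order within each regional group
        merged.sort(key=lambda s: (s.name, s.segment_index
                                   if s.segment_index is not None else -1))
        order = {n: i for i, n in enumerate(names)}
        merged.sort(key=lambda s: order[s.name])
        sub = ParameterSubset(tuple(merged), n_seg=sub.n_seg,
                              fixed=dict(sub.fixed))
    return sub


def demote_to_global_offset(subset: ParameterSubset, group_name: str) -> ParameterSubset:
    """Remove a parameter group from the estimation subset.

    A regional LV group is replaced by a single global-offset spec for
    that tissue type; a global or global-offset spec is removed and
    recorded as fixed to its reference value.
    """
    members = [s for s in subset.specs if s.name == group_name]
    if not members:
        raise RegistryError(f"unknown parameter group {group_name!r}")
    scope = members[0].scope
    fixed = dict(subset.fixed)
    if scope == "regional":
        kept = [s for s in subset.specs if s.name != group_name]
        proto = members[0]
        go_name = group_name + "_GO"
        if any(s.name == go_name for s in kept):
            raise RegistryError(f"group {group_name!r} already demoted")
        category = proto.category
        if category not in ("myocardial-tissue", "mechanical-activation"):
            category = "myocardial-tissue"
        if category == "mechanical-activation":
            # activation delays are additive (ms); the offset spans the
            # regional range and is neutral at 0
            kept.append(ParameterSpec(
                name=go_name, category=category, wall="LV",
                scope="global-offset", segment_index=None, reference_value=0.0,
                msm_range=proto.msm_range, pso_bounds=proto.pso_bounds,
                provenance=proto.provenance,
            ))
        else:
            kept.append(ParameterSpec(
                name=go_name, category=category, wall="septum-LVFW",
                scope="global-offset", segment_index=None, reference_value=1.0,
                msm_range=(0.6, 1.4), pso_bounds=(0.4, 1.6),
                provenance=proto.provenance,
            ))
        return ParameterSubset(tuple(kept), n_seg=subset.n_seg, fixed=fixed)
    # global or global-offset: fix to reference
    kept = [s for s in subset.specs if s.name != group_name]
    fixed[group_name] = members[0].reference_value
    return ParameterSubset(tuple(kept), n_seg=subset.n_seg, fixed=fixed)
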