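"""Antibiotic depots and their release-kinetics laws.

Three local-delivery vehicles are modelled: an antibiotic-loaded PMMA bone
cement spacer (non-absorbable; slow, diffusion-limited surface release), a set
of antibiotic-loaded calcium sulfate beads (fully absorbable; releases
essentially all of its load), and a plain vancomycin powder bolus (dissolves
immediately).  The release laws are the standard pharmaceutics repertoire —
bolus, zero-order, first-order, Higuchi (square-root-of-time) and a biphasic
burst + sustained combination.  Masses in mg, times in hours.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "VANCOMYCIN",
    "TOBRAMYCIN",
    "ANTIBIOTICS",
    "ARMS",
    "ReleaseModel",
    "BolusRelease",
    "ZeroOrderRelease",
    "FirstOrderRelease",
    "HiguchiRelease",
    "BiphasicRelease",
    "make_release_model",
    "cumulative_released",
    "release_rate",
    "DepotSpec",
    "Depot",
    "default_depots",
    "SPACER_BURST_FRACTION",
    "SPACER_HIGUCHI_K_MG_SQRTH",
    "CSB_BURST_FRACTION",
    "CSB_FIRST_ORDER_K_PER_H",
]

VANCOMYCIN = "vancomycin"
TOBRAMYCIN = "tobramycin"
ANTIBIOTICS = (VANCOMYCIN, TOBRAMYCIN)

#: The three administration arms: loaded spacer alone, loaded spacer plus
#: loaded calcium sulfate beads, and (unloaded spacer with) vancomycin powder.
ARMS = ("spacer_only", "csb_plus_spacer", "vp_bolus")

# Reference release-law constants.  The burst fractions and rate constants are
# model choices (the in vitro study reports concentrations, not release laws),
# calibrated once so the simulated arms reproduce the qualitative effluent
# behaviour: an early burst, a dip while drainage is fast, then a rise as
# drainage declines; and near-complete calcium sulfate release within 48 h.
SPACER_BURST_FRACTION = 0.05
SPACER_HIGUCHI_K_MG_SQRTH = 20.0
CSB_BURST_FRACTION = 0.15
CSB_FIRST_ORDER_K_PER_H = 0.05


class ReleaseModel:
    """Base class: cumulative drug release from a depot as a function of time.

    Subclasses define ``_continuous(t)``, the continuously released mass
    (mg) at time t >= 0, and may carry ``instantaneous_mass`` released at
    t = 0 (a bolus / burst), which enters the reactor as an initial condition
    rather than as a rate.
    """

    total_mass_mg: float
    instantaneous_mass_mg: float = 0.0

    def _continuous(self, t: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def _continuous_rate(self, t: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def cumulative(self, t):
        """Cumulative mass released (mg) by time ``t`` (h), burst included."""
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise ValueError("release is defined for t >= 0 only")
        out = self.instantaneous_mass_mg + self._continuous(t_arr)
        out = np.minimum(out, self.total_mass_mg)
        return float(out) if out.ndim == 0 else out

    def continuous_cumulative(self, t):
        """Cumulative mass released (mg) excluding the instantaneous burst."""
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise ValueError("release is defined for t >= 0 only")
        cap = self.total_mass_mg - self.instantaneous_mass_mg
        out = np.minimum(self._continuous(t_arr), cap)
        return float(out) if out.ndim == 0 else out

    def rate(self, t):
        """Instantaneous release rate (mg/h) at ``t`` > 0; 0 once exhausted."""
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr <= 0):
            raise ValueError("release rate is defined for t > 0 (bolus is an "
                             "initial condition, not a rate)")
        cap = self.total_mass_mg - self.instantaneous_mass_mg
        r = np.where(self._continuous(t_arr) < cap, self._continuous_rate(t_arr), 0.0)
        return float(r) if r.ndim == 0 else r


@dataclass
class BolusRelease(ReleaseModel):
    """Entire load dissolves instantaneously at t = 0."""

    total_mass_mg: float

    def __post_init__(self) -> None:
        _check_mass(self.total_mass_mg)
        self.instantaneous_mass_mg = self.total_mass_mg

    def _continuous(self, t):
        return np.zeros_like(t)

    def _continuous_rate(self, t):
        return np.zeros_like(t)


@dataclass
class ZeroOrderRelease(ReleaseModel):
    """Constant-rate release ``k0`` (mg/h) until the load is exhausted."""

    total_mass_mg: float
    k0_mg_h: float

    def __post_init__(self) -> None:
        _check_mass(self.total_mass_mg)
        if self.k0_mg_h < 0:
            raise ValueError("k0 must be >= 0")
        self.instantaneous_mass_mg = 0.0

    def _continuous(self, t):
        return np.minimum(self.total_mass_mg, self.k0_mg_h * t)

    def _continuous_rate(self, t):
        return np.full_like(t, self.k0_mg_h)


@dataclass
class FirstOrderRelease(ReleaseModel):
    """Exponential-approach release ``M (1 - exp(-k1 t))`` with ``k1`` in 1/h."""

    total_mass_mg: float
    k1_per_h: float

    def __post_init__(self) -> None:
        _check_mass(self.total_mass_mg)
        if self.k1_per_h < 0:
            raise ValueError("k1 must be >= 0")
        self.instantaneous_mass_mg = 0.0

    def _continuous(self, t):
        return self.total_mass_mg * -np.expm1(-self.k1_per_h * t)

    def _continuous_rate(self, t):
        return self.total_mass_mg * self.k1_per_h * np.exp(-self.k1_per_h * t)


@dataclass
class HiguchiRelease(ReleaseModel):
    """Diffusion-limited square-root-of-time release ``kH * sqrt(t)`` (kH in mg/h^0.5)."""

    total_mass_mg: float
    kh_mg_sqrth: float

    def __post_init__(self) -> None:
        _check_mass(self.total_mass_mg)
        if self.kh_mg_sqrth < 0:
            raise ValueError("kH must be >= 0")
        self.instantaneous_mass_mg = 0.0

    def _continuous(self, t):
        return np.minimum(self.total_mass_mg, self.kh_mg_sqrth * np.sqrt(t))

    def _continuous_rate(self, t):
        # diverges as t -> 0+ but is integrable; simulation consumes
        # cumulative differences, not point rates, near zero
        return self.kh_mg_sqrth / (2.0 * np.sqrt(t))


_SECONDARY_FORMS = {
    "zero_order": ZeroOrderRelease,
    "first_order": FirstOrderRelease,
    "higuchi": HiguchiRelease,
}


@dataclass
class BiphasicRelease(ReleaseModel):
    """Burst fraction ``f`` of the load at t = 0, the rest by a secondary law.

    ``f = 1`` degenerates to a pure bolus; ``f = 0`` to the secondary law.
    The secondary law acts on the remaining ``(1 - f) * M``.
    """

    total_mass_mg: float
    burst_fraction: float
    secondary_form: str = "higuchi"
    secondary_params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_mass(self.total_mass_mg)
        if not 0.0 <= self.burst_fraction <= 1.0:
            raise ValueError("burst fraction must lie in [0, 1]")
        if self.secondary_form not in _SECONDARY_FORMS:
            raise ValueError(f"unknown secondary release form {self.secondary_form!r}")
        self.instantaneous_mass_mg = self.burst_fraction * self.total_mass_mg
        remaining = self.total_mass_mg - self.instantaneous_mass_mg
        self._secondary = _SECONDARY_FORMS[self.secondary_form](
            remaining, **dict(self.secondary_params)
        )

    def _continuous(self, t):
        return self._secondary._continuous(t)

    def _continuous_rate(self, t):
        return self._secondary._continuous_rate(t)


def _check_mass(m: float) -> None:
    if m < 0:
        raise ValueError("total mass must be >= 0")


def make_release_model(form: str, total_mass_mg: float, **params) -> ReleaseModel:
    """Build a release model from a plain-config description."""
    forms = {
        "bolus": BolusRelease,
        "zero_order": ZeroOrderRelease,
        "first_order": FirstOrderRelease,
        "higuchi": HiguchiRelease,
        "biphasic": BiphasicRelease,
    }
    if form not in forms:
        raise ValueError(f"unknown release form {form!r}; expected one of {sorted(forms)}")
    return forms[form](total_mass_mg, **params)


def cumulative_released(model: ReleaseModel, t):
    """Cumulative mass released (mg) by time ``t`` hours (burst included)."""
    return model.cumulative(t)


def release_rate(model: ReleaseModel, t):
    """Release rate (mg/h) at ``t`` > 0; boluses contribute 0 for t > 0."""
    return model.rate(t)


@dataclass(frozen=True)
class DepotSpec:
    """Composition of one depot: kind, per-antibiotic loading, carrier, geometry.

    Geometry is descriptive only under the default laws (an extension point
    for surface-area-scaled release variants).
    """

    kind: str  # {"csb", "pmma_spacer", "powder_bolus"}
    loadings_mg: Mapping[str, float]
    carrier_mass_g: float | None = None
    bead_diameter_mm: float | None = None
    spacer_diameter_cm: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("csb", "pmma_spacer", "powder_bolus"):
            raise ValueError(f"unknown depot kind {self.kind!r}")
        for ab, m in self.loadings_mg.items():
            if ab not in ANTIBIOTICS:
                raise ValueError(f"unknown antibiotic {ab!r}")
            if m < 0:
                raise ValueError("loadings must be >= 0")
        if self.kind == "powder_bolus" and self.carrier_mass_g is not None:
            raise ValueError("a powder bolus has no carrier")


@dataclass(frozen=True)
class Depot:
    """A depot spec paired with one release model per loaded antibiotic."""

    spec: DepotSpec
    models: Mapping[str, ReleaseModel]

    def __post_init__(self) -> None:
        for ab, model in self.models.items():
            loading = self.spec.loadings_mg.get(ab, 0.0)
            if not np.isclose(model.total_mass_mg, loading):
                raise ValueError(
                    f"release model mass {model.total_mass_mg} mg does not match "
                    f"{ab} loading {loading} mg"
                )


def _spacer_depot() -> Depot:
    spec = DepotSpec(
        kind="pmma_spacer",
        loadings_mg={VANCOMYCIN: 2000.0, TOBRAMYCIN: 2000.0},
        carrier_mass_g=40.0,
        spacer_diameter_cm=3.45,
    )
    models = {
        ab: BiphasicRelease(
            spec.loadings_mg[ab],
            burst_fraction=SPACER_BURST_FRACTION,
            secondary_form="higuchi",
            secondary_params={"kh_mg_sqrth": SPACER_HIGUCHI_K_MG_SQRTH},
        )
        for ab in (VANCOMYCIN, TOBRAMYCIN)
    }
    return Depot(spec, models)


def _csb_depot() -> Depot:
    spec = DepotSpec(
        kind="csb",
        loadings_mg={VANCOMYCIN: 1000.0, TOBRAMYCIN: 240.0},
        carrier_mass_g=20.0,
        bead_diameter_mm=4.8,
    )
    models = {
        ab: BiphasicRelease(
            spec.loadings_mg[ab],
            burst_fraction=CSB_BURST_FRACTION,
            secondary_form="first_order",
            secondary_params={"k1_per_h": CSB_FIRST_ORDER_K_PER_H},
        )
        for ab in (VANCOMYCIN, TOBRAMYCIN)
    }
    return Depot(spec, models)


def _vp_depot() -> Depot:
    spec = DepotSpec(kind="powder_bolus", loadings_mg={VANCOMYCIN: 1000.0})
    return Depot(spec, {VANCOMYCIN: BolusRelease(1000.0)})


def depots_from_yaml(path) -> list[Depot]:
    """Load a custom depot set from a YAML file.

    Schema: a top-level ``depots`` list; each entry has ``kind``,
    ``loadings_mg`` (antibiotic -> mg) and ``release`` — either one shared
    ``{form, <params>}`` mapping applied to every loaded antibiotic, or a
    per-antibiotic mapping of such entries.  Optional keys ``carrier_mass_g``,
    ``bead_diameter_mm`` and ``spacer_diameter_cm`` pass through to the spec.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "depots" not in raw or not isinstance(raw["depots"], list):
        raise ValueError("depot config must contain a top-level 'depots' list")

    depots = []
    for i, entry in enumerate(raw["depots"]):
        for key in ("kind", "loadings_mg", "release"):
            if key not in entry:
                raise ValueError(f"depot #{i}: missing required key {key!r}")
        spec = DepotSpec(
            kind=entry["kind"],
            loadings_mg={ab: float(m) for ab, m in entry["loadings_mg"].items()},
            carrier_mass_g=entry.get("carrier_mass_g"),
            bead_diameter_mm=entry.get("bead_diameter_mm"),
            spacer_diameter_cm=entry.get("spacer_diameter_cm"),
        )
        release = entry["release"]
        models = {}
        for ab, mass in spec.loadings_mg.items():
            cfg = dict(release if "form" in release else release[ab])
            form = cfg.pop("form")
            models[ab] = make_release_model(form, mass, **cfg)
        depots.append(Depot(spec, models))
    return depots


def default_depots(arm: str) -> list[Depot]:
    """Reference depot set for one administration arm.

    ``spacer_only``: loaded PMMA spacer (2000 mg each of vancomycin and
    tobramycin).  ``csb_plus_spacer``: the same spacer plus calcium sulfate
    beads (1000 mg vancomycin + 240 mg tobramycin).  ``vp_bolus``: a 1000 mg
    vancomycin powder bolus (the accompanying unloaded spacer carries no
    antibiotic and is omitted from the mass model).
    """
    if arm == "spacer_only":
        return [_spacer_depot()]
    if arm == "csb_plus_spacer":
        return [_spacer_depot(), _csb_depot()]
    if arm == "vp_bolus":
        return [_vp_depot()]
    raise ValueError(f"unknown arm {arm!r}; expected one of {ARMS}")
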