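"""Physiological and flux-measurement constraints.

Fasting-state boundary conditions follow the asymmetric rule used for
perfused-liver exchange data: measured uptake rates are enforced exactly
(both bounds of the exchange reaction), measured secretion rates only as
lower bounds, explicitly unconstrained metabolites (vitamins, O2, CO2)
stay fully open, and every other exchange is closed to uptake.  Measured
intracellular fluxes (MFA means +/- SD) become bound intervals on mapped
reactions.  A chi-square utility reproduces the sum-of-squared-residuals
acceptance region used to judge MFA fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .model import DEFAULT_UB, MetabolicModel

__all__ = [
    "BoundaryConditions",
    "MFAFluxSet",
    "ConstraintConflictError",
    "apply_boundary_conditions",
    "apply_mfa_constraints",
    "derive_5h_fluxes",
    "chi2_ssr_acceptance",
    "perturb_constraints",
]


class ConstraintConflictError(ValueError):
    """Bound intersection is empty for a named reaction."""


@dataclass
class BoundaryConditions:
    """Fasting-state exchange constraints.

    uptake: metabolite -> rate taken up (non-negative, model flux units);
    secretion_min: metabolite -> minimum secretion rate;
    unconstrained: metabolites whose exchanges stay fully open.
    """

    uptake: dict[str, float] = field(default_factory=dict)
    secretion_min: dict[str, float] = field(default_factory=dict)
    unconstrained: list[str] = field(default_factory=list)
    units: str = "mmol/h"

    def __post_init__(self):
        for name, rates in (("uptake", self.uptake), ("secretion_min", self.secretion_min)):
            for met, rate in rates.items():
                if rate < 0:
                    raise ValueError(f"{name} rate for {met!r} must be >= 0, got {rate}")
        overlap = set(self.uptake) & set(self.secretion_min)
        if overlap:
            raise ValueError(
                f"metabolites listed as both uptake and secretion: {sorted(overlap)}"
            )

    @classmethod
    def from_yaml(cls, path) -> "BoundaryConditions":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            uptake={k: float(v) for k, v in (raw.get("uptake") or {}).items()},
            secretion_min={
                k: float(v) for k, v in (raw.get("secretion_min") or {}).items()
            },
            unconstrained=list(raw.get("unconstrained") or []),
            units=raw.get("units", "mmol/h"),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "uptake": dict(self.uptake),
                    "secretion_min": dict(self.secretion_min),
                    "unconstrained": list(self.unconstrained),
                    "units": self.units,
                },
                fh,
                sort_keys=True,
            )


@dataclass
class MFAFluxSet:
    """Measured fluxes as mean +/- SD per reaction name.

    ``units`` declares whether values are absolute or relative to a
    reference flux (e.g. citrate synthase = 100); relative sets must be
    rescaled with :meth:`to_absolute` before constraining a model.
    """

    fluxes: dict[str, tuple[float, float]]
    units: str = "absolute"

    def __post_init__(self):
        for name, (mean, sd) in self.fluxes.items():
            if sd < 0:
                raise ValueError(f"SD for {name!r} must be >= 0, got {sd}")

    @classmethod
    def from_tsv(cls, path, units: str = "absolute") -> "MFAFluxSet":
        df = pd.read_csv(path, sep="\t")
        return cls(
            fluxes={
                str(row["reaction_name"]): (float(row["mean"]), float(row["sd"]))
                for _, row in df.iterrows()
            },
            units=units,
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            [
                {"reaction_name": name, "mean": mean, "sd": sd}
                for name, (mean, sd) in self.fluxes.items()
            ]
        ).to_csv(path, sep="\t", index=False)

    def to_absolute(self, scale: float) -> "MFAFluxSet":
        """Rescale relative fluxes (reference = 100) to absolute units."""
        return MFAFluxSet(
            fluxes={n: (m * scale, s * scale) for n, (m, s) in self.fluxes.items()},
            units="absolute",
        )


def apply_boundary_conditions(
    model: MetabolicModel,
    bc: BoundaryConditions,
    tolerance_frac: float = 0.0,
) -> MetabolicModel:
    """Constrain exchange reactions to the fasting-state rates.

    Uptake u: exchange bounds [-u*(1+tol), -u*(1-tol)] — both ends
    enforced (tol=0 fixes the rate exactly).  Secretion s: lower bound s,
    upper bound untouched.  Unconstrained metabolites: fully open
    (-DEFAULT_UB, DEFAULT_UB).  Every other exchange: closed to uptake
    (lb = 0), open to secretion.
    """
    listed = set(bc.uptake) | set(bc.secretion_min) | set(bc.unconstrained)
    missing = [m for m in listed if model.exchange_for(m) is None]
    if missing:
        raise KeyError(
            "no exchange reaction for metabolites: "
            + ", ".join(sorted(missing))
            + " (add one with add_exchange_reaction first)"
        )

    new_bounds: dict[str, tuple[float, float]] = {}
    for r in model.exchange_reactions:
        (met_id,) = r.stoich
        if met_id in bc.uptake:
            u = bc.uptake[met_id]
            new_bounds[r.id] = (-u * (1 + tolerance_frac), -u * (1 - tolerance_frac))
        elif met_id in bc.secretion_min:
            new_bounds[r.id] = (bc.secretion_min[met_id], r.ub)
        elif met_id in bc.unconstrained:
            new_bounds[r.id] = (-DEFAULT_UB, DEFAULT_UB)
        else:
            new_bounds[r.id] = (0.0, r.ub)
    return model.with_reaction_bounds(new_bounds)


def apply_mfa_constraints(
    model: MetabolicModel,
    mfa: MFAFluxSet,
    reaction_map: dict[str, str],
    sd_multiplier: float = 1.0,
) -> MetabolicModel:
    """Constrain mapped reactions to measured flux intervals.

    Each measured reaction gets bounds [mean - k*sd, mean + k*sd]
    (k = ``sd_multiplier``), intersected with its existing bounds.  An
    empty intersection raises :class:`ConstraintConflictError` naming the
    reaction.  Relative-unit flux sets must be converted to absolute
    first.
    """
    if mfa.units != "absolute":
        raise ValueError(
            f"MFA flux set has units {mfa.units!r}; convert with to_absolute() first"
        )
    new_bounds: dict[str, tuple[float, float]] = {}
    for name, (mean, sd) in mfa.fluxes.items():
        if name not in reaction_map:
            raise KeyError(f"MFA reaction {name!r} missing from reaction map")
        rxn_id = reaction_map[name]
        r = model.reaction(rxn_id)
        lb = max(r.lb, mean - sd_multiplier * sd)
        ub = min(r.ub, mean + sd_multiplier * sd)
        if lb > ub:
            raise ConstraintConflictError(
                f"reaction {rxn_id!r} ({name}): measured interval "
                f"[{mean - sd_multiplier * sd}, {mean + sd_multiplier * sd}] does "
                f"not intersect existing bounds [{r.lb}, {r.ub}]"
            )
        new_bounds[rxn_id] = (lb, ub)
    return model.with_reaction_bounds(new_bounds)


def derive_5h_fluxes(
    fractions: dict[str, float],
    glucose_output_10h: float,
    rel_sd: float = 0.1,
) -> MFAFluxSet:
    """Literature-derived short-fast flux set.

    Hepatic glucose output after a 5-h fast is taken as 20% above the
    measured 10-h output; each contributing pathway (glycogenolysis,
    gluconeogenesis from lactate/amino acids/glycerol) receives its
    literature fractional contribution of that output, with SD set to
    ``rel_sd`` of the mean.
    """
    total = sum(fractions.values())
    if any(f < 0 for f in fractions.values()):
        raise ValueError("fractions must be non-negative")
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"fractions must sum to 1, got {total}")
    output_5h = 1.2 * glucose_output_10h
    fluxes = {
        pathway: (frac * output_5h, abs(frac * output_5h) * rel_sd)
        for pathway, frac in fractions.items()
    }
    fluxes["glucose_output"] = (output_5h, abs(output_5h) * rel_sd)
    return MFAFluxSet(fluxes=fluxes, units="absolute")


def chi2_ssr_acceptance(dof: int, level: float) -> tuple[float, float]:
    """Two-sided chi-square acceptance region for an SSR at ``level``.

    Returns the ((1-level)/2, 1-(1-level)/2) quantiles of chi2(dof): a
    fitted sum of squared residuals inside this interval is statistically
    consistent with the measurement error model at the given confidence.
    """
    if dof < 1 or int(dof) != dof:
        raise ValueError(f"dof must be a positive integer, got {dof}")
    if not (0.0 < level < 1.0):
        raise ValueError(f"level must lie in (0, 1), got {level}")
    alpha = 1.0 - level
    lower = stats.chi2.ppf(alpha / 2.0, dof)
    upper = stats.chi2.ppf(1.0 - alpha / 2.0, dof)
    return float(lower), float(upper)


def perturb_constraints(
    bc: BoundaryConditions,
    mode: str,
    scale: float,
    seed: int,
    metabolite: Optional[str] = None,
) -> BoundaryConditions:
    """Sensitivity-analysis perturbation of uptake rates.

    ``mode='local'`` multiplies one uptake (``metabolite``, or the first
    listed) by ``scale``; ``mode='global'`` multiplies every uptake by an
    i.i.d. LogNormal(0, ln(scale)) factor (scale=1 is the identity).
    """
    if scale <= 0:
        raise ValueError(f"scale must be positive, got {scale}")
    if mode not in ("local", "global"):
        raise ValueError(f"mode must be 'local' or 'global', got {mode!r}")

    uptake = dict(bc.uptake)
    if mode == "local":
        if not uptake:
            raise ValueError("no uptake rates to perturb")
        target = metabolite if metabolite is not None else next(iter(uptake))
        if target not in uptake:
            raise KeyError(f"metabolite {target!r} has no uptake rate")
        uptake[target] = uptake[target] * scale
    else:
        rng = np.random.default_rng(seed)
        sigma = abs(np.log(scale))
        factors = rng.lognormal(mean=0.0, sigma=sigma, size=len(uptake))
        uptake = {m: rate * f for (m, rate), f in zip(uptake.items(), factors)}
    return BoundaryConditions(
        uptake=uptake,
        secretion_min=dict(bc.secretion_min),
        unconstrained=list(bc.unconstrained),
        units=bc.units,
    )
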