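"""Normalization between experiments: back-exchange, pH clock, empirical.

Three corrections bring uptake data from different solution conditions
onto a common footing:

* **Back-exchange** — deuterium lost to hydrogen during quench/analysis
  is corrected by scaling measured uptake by N_max / maxD, where maxD is
  either an experimentally measured maximal-deuteration control or the
  plateau of the species' own fitted curve.
* **pH adjustment** — in the base-catalyzed regime (pH 5–10) intrinsic
  exchange speeds up tenfold per pH unit, so labeling times of a state
  at pH_exp are multiplied by ``10**(pH_exp - pH_ref)`` to express them
  on the reference-pH clock.
* **Empirical adjustment** — residual solution effects (salts, ionic
  strength) are calibrated away with an unstructured reference peptide:
  per-state scaling factors ``f_k = k_ref/k_state`` and
  ``f_beta = beta_ref/beta_state`` are read off the reference peptide's
  single-phase fits and multiplied onto every fit of the protein of
  interest.  This is deliberately phenomenological.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .cluster_io import Species
from .kinetics import KineticFit, Phase

logger = logging.getLogger(__name__)


class CorrectionError(ValueError):
    pass


@dataclass
class BackExchangeSpec:
    """How to back-exchange correct: none / experimental maxD / plateau maxD."""

    method: str = "none"                       # none | experimental_maxD | plateau_maxD
    maxd_by_species: dict = field(default_factory=dict)   # Species.key -> Da
    tolerance: float = 0.10                    # slack on maxD <= N_max checks

    def __post_init__(self):
        if self.method not in ("none", "experimental_maxD", "plateau_maxD"):
            raise CorrectionError(f"unknown back-exchange method {self.method!r}")


def backexchange_factor(n_max: float, maxd: float, tolerance: float = 0.10) -> float:
    if maxd <= 0:
        raise CorrectionError("maxD must be > 0")
    if n_max <= 0:
        raise CorrectionError("N_max must be > 0")
    if maxd > n_max * (1 + tolerance):
        raise CorrectionError(
            f"maxD={maxd:.3g} exceeds N_max={n_max:.3g} beyond tolerance"
        )
    return n_max / maxd


def correct_backexchange(table: pd.DataFrame, spec: BackExchangeSpec,
                         fits: Mapping[tuple, KineticFit] | None = None,
                         ) -> pd.DataFrame:
    """Scale the uptake column of an uptake table by N_max / maxD.

    ``experimental_maxD`` reads maxD per species from the spec;
    ``plateau_maxD`` derives maxD from the plateau (sum of amplitudes) of
    the species' own fitted curve — only valid for species that fully
    exchange within the experimental window, so fits whose plateau was
    never reached are rejected.  Applied before (re-)fitting.
    """
    if spec.method == "none":
        return table.copy()
    out = table.copy()
    from .cluster_io import iter_species  # local import to avoid cycle

    missing = []
    for species, sub in iter_species(out):
        if spec.method == "experimental_maxD":
            maxd = spec.maxd_by_species.get(species.key)
            if maxd is None:
                missing.append(species.label)
                continue
        else:
            fit = None if fits is None else fits.get(species.key)
            if fit is None:
                missing.append(species.label)
                continue
            from .kinetics import compute_x_plat
            if compute_x_plat(fit) is None:
                raise CorrectionError(
                    f"{species.label}: plateau maxD requested but the fitted "
                    "curve does not plateau within the experimental window"
                )
            maxd = fit.n_total
        factor = backexchange_factor(species.max_uptake, maxd, spec.tolerance)
        out.loc[sub.index, "uptake"] = sub["uptake"] * factor
    if missing:
        raise CorrectionError(
            "maxD unavailable for species: " + ", ".join(missing[:10])
        )
    return out


# ---------------------------------------------------------------------------
# pH adjustment


def ph_adjust_factor(ph_ref: float, ph_exp: float, permissive: bool = False) -> float:
    """Time-rescaling factor ``10**(pH_exp - pH_ref)``.

    Valid for the base-catalyzed regime only, pH 5–10 at both ends;
    outside that range an error is raised (warning in permissive mode).
    Higher experimental pH means faster intrinsic exchange, hence longer
    equivalent times on the reference-pH clock.
    """
    for name, value in (("pH_ref", ph_ref), ("pH_exp", ph_exp)):
        if not 5.0 <= value <= 10.0:
            msg = f"{name}={value} outside the applicable pH range 5-10"
            if permissive:
                logger.warning(msg)
            else:
                raise CorrectionError(msg)
    return 10.0 ** (ph_exp - ph_ref)


def ph_adjust_times(times, ph_ref: float, ph_exp: float,
                    permissive: bool = False) -> np.ndarray:
    """Multiply labeling times by the pH adjustment factor."""
    return np.asarray(times, dtype=float) * ph_adjust_factor(ph_ref, ph_exp, permissive)


def ph_adjust_table(table: pd.DataFrame, ph_ref: float,
                    ph_by_state: Mapping[str, float],
                    permissive: bool = False) -> pd.DataFrame:
    """Apply per-state pH time-rescaling to an uptake table."""
    out = table.copy()
    for state, ph_exp in ph_by_state.items():
        mask = out["state"] == state
        out.loc[mask, "time_s"] = ph_adjust_times(
            out.loc[mask, "time_s"].to_numpy(), ph_ref, ph_exp, permissive)
    return out


# ---------------------------------------------------------------------------
# Empirical (k_obs, beta) calibration


@dataclass(frozen=True)
class EmpiricalFactors:
    """Per-state 2D scaling factors calibrated on a reference peptide."""

    reference_state: str
    per_state: Mapping[str, tuple[float, float]]   # state -> (f_k, f_beta)

    def factors(self, state: str) -> tuple[float, float]:
        if state not in self.per_state:
            raise CorrectionError(f"state {state!r} missing from empirical factors")
        return self.per_state[state]


def _require_single_phase(fit: KineticFit, state: str) -> None:
    if fit.fit_kind != "stretched_exp":
        raise CorrectionError(
            f"state {state!r}: empirical calibration needs a stretched-"
            "exponential fit, not an interpolation"
        )
    if fit.nexp != 1:
        raise CorrectionError(
            f"state {state!r}: empirical calibration is only defined for "
            "single-phase fits"
        )


def calibrate_empirical(reference_fits: Mapping[str, KineticFit],
                        reference_state: str) -> EmpiricalFactors:
    """Derive per-state (f_k, f_beta) from reference-peptide fits.

    The reference peptide must be unstructured (its exchange reflects
    solution chemistry only) and fitted single-phase after back-exchange
    correction.  Applying the factors to each state's own reference fit
    reproduces the reference state's fit exactly.
    """
    if reference_state not in reference_fits:
        raise CorrectionError(f"reference state {reference_state!r} has no fit")
    ref = reference_fits[reference_state]
    _require_single_phase(ref, reference_state)
    k_ref, beta_ref = ref.phases[0].k, ref.phases[0].beta
    per_state = {}
    for state, fit in reference_fits.items():
        _require_single_phase(fit, state)
        per_state[state] = (k_ref / fit.phases[0].k, beta_ref / fit.phases[0].beta)
    return EmpiricalFactors(reference_state, per_state)


def apply_empirical(fit: KineticFit, factors: EmpiricalFactors) -> KineticFit:
    """Multiply every phase's k_obs by f_k and beta by f_beta.

    A product beta exceeding 1 is clipped back into (0, 1] with a logged
    warning — the stretched-exponential model does not admit beta > 1.
    """
    if fit.fit_kind != "stretched_exp":
        raise CorrectionError("empirical factors require a stretched-exponential fit")
    f_k, f_beta = factors.factors(fit.state)
    new_phases = []
    for ph in fit.phases:
        beta = ph.beta * f_beta
        if beta > 1.0:
            logger.warning(
                "state %s: beta %.4g * f_beta %.4g exceeds 1; clipping to 1.0",
                fit.state, ph.beta, f_beta)
            beta = 1.0
        new_phases.append(Phase(ph.n, ph.k * f_k, beta))
    return replace(fit, phases=tuple(new_phases))
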