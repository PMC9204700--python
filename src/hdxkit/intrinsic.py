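"""Intrinsic amide exchange rates and protection factors.

The intrinsic (chemical, unprotected) exchange rate of each backbone
amide is predicted from sequence, pH and temperature with the
reference-rate/neighbor-factor model of Bai et al.:

    k_int = k_A * F_A * 10**(-pD)  +  k_B * F_B * 10**(pD - pK_D)
                                   +  k_W * F_B,

where F_A and F_B combine the log-additive side-chain factors of the
residue itself (lambda) and its left neighbor (rho), plus terminal
contributions, and the reference rates carry Arrhenius temperature
corrections.  The N-terminal residue and prolines carry no amide NH and
are undefined.

A peptide-level intrinsic rate constant k_int is obtained by simulating
the theoretical uptake curve D(t) = sum_j (1 - exp(-k_int,j t)) over the
defined residues and fitting it with a single stretched-exponential
phase (N fixed at the residue count).  The protection factor of an
experimental fit is then Pf = k_int / k_obs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import _bai
from .cluster_io import Species
from .kinetics import FitError, KineticFit, fit_stretched_exponential


class IntrinsicError(ValueError):
    pass


@dataclass
class IntrinsicRates:
    """Per-residue intrinsic exchange rate constants (1/s).

    ``k_int[i]`` is ``None`` exactly at the first residue and at
    prolines.  ``ph`` is the working value actually used in the
    acid/base terms (pD-corrected when requested).
    """

    sequence: str
    ph: float
    temperature: float
    k_int: list  # float | None per residue

    def defined(self) -> np.ndarray:
        return np.array([k for k in self.k_int if k is not None], dtype=float)


def _arrhenius(log_k_ref: float, ea: float, temperature: float) -> float:
    k_ref = 10.0 ** log_k_ref
    return k_ref * math.exp(-(ea / _bai.R_GAS) * (1.0 / temperature - 1.0 / _bai.T_REF))


def _blended_factors(residue: str, pd_value: float) -> tuple[float, float, float, float]:
    """(10**la, 10**ra, 10**lb, 10**rb) with ionization blending for D/E/H."""
    if residue in _bai.SIDECHAIN_PKA:
        pka = _bai.SIDECHAIN_PKA[residue]
        f_prot = 1.0 / (1.0 + 10.0 ** (pd_value - pka))
        prot = _bai.FACTORS[residue + ("+" if residue == "H" else "0")]
        deprot = _bai.FACTORS[residue + ("0" if residue == "H" else "-")]
        return tuple(
            f_prot * 10.0 ** p + (1.0 - f_prot) * 10.0 ** d
            for p, d in zip(prot, deprot)
        )
    if residue not in _bai.FACTORS:
        raise IntrinsicError(f"unknown residue code {residue!r}")
    return tuple(10.0 ** v for v in _bai.FACTORS[residue])


def residue_intrinsic_rates(sequence: str, ph: float, temperature: float,
                            pd_correction: bool = False) -> IntrinsicRates:
    """Intrinsic exchange rate of every amide in ``sequence``.

    Parameters
    ----------
    sequence
        One-letter amino-acid string (standard residues).
    ph
        pH-meter reading of the labeling buffer; with ``pd_correction``
        the glass-electrode offset is applied (pD = pH + 0.4).
    temperature
        Labeling temperature in Kelvin.
    """
    if not 2.0 <= ph <= 12.0:
        raise IntrinsicError(f"pH {ph} outside the sane range 2-12")
    if not sequence:
        raise IntrinsicError("empty sequence")
    pd_value = ph + 0.4 if pd_correction else ph

    ka = _arrhenius(_bai.LOG_KA_REF, _bai.EA_ACID, temperature) / 60.0   # 1/(M s)
    kb = _arrhenius(_bai.LOG_KB_REF, _bai.EA_BASE, temperature) / 60.0
    kw = _arrhenius(_bai.LOG_KW_REF, _bai.EA_WATER, temperature) / 60.0  # 1/s

    conc_d = 10.0 ** (-pd_value)
    conc_od = 10.0 ** (pd_value - _bai.PKD_D2O)

    rates: list = []
    last = len(sequence) - 1
    for i, res in enumerate(sequence):
        if i == 0 or res == "P":
            if res not in _bai.FACTORS and res not in _bai.SIDECHAIN_PKA:
                raise IntrinsicError(f"unknown residue code {res!r}")
            rates.append(None)
            continue
        la, _, lb, _ = _blended_factors(res, pd_value)
        _, ra, _, rb = _blended_factors(sequence[i - 1], pd_value)
        fa = la * ra
        fb = lb * rb
        if i == 1:
            fa *= 10.0 ** _bai.NTERM_RHO_ACID
            fb *= 10.0 ** _bai.NTERM_RHO_BASE
        if i == last:
            fa *= 10.0 ** _bai.CTERM_LAMBDA_ACID
            fb *= 10.0 ** _bai.CTERM_LAMBDA_BASE
        k = ka * fa * conc_d + kb * fb * conc_od + kw * fb
        rates.append(float(k))
    return IntrinsicRates(sequence, pd_value, temperature, rates)


def rates_for_species(species: Species, ph: float, temperature: float,
                      pd_correction: bool = False) -> IntrinsicRates:
    """Intrinsic rates over a species' covered interval.

    The full parent-peptide sequence provides the neighbor context; the
    returned object is restricted to the covered interval (fragment
    residues for c/z ions), with the parent peptide's first residue and
    prolines undefined.
    """
    full = residue_intrinsic_rates(species.sequence, ph, temperature, pd_correction)
    a, b = species.covered_interval
    lo, hi = a - species.start, b - species.start
    return IntrinsicRates(species.sequence[lo:hi + 1], full.ph, temperature,
                          full.k_int[lo:hi + 1])


def simulate_intrinsic_uptake(rates: IntrinsicRates, times) -> np.ndarray:
    """Theoretical uptake D(t) = sum_j (1 - exp(-k_j t)) over defined residues."""
    ks = rates.defined()
    if len(ks) == 0:
        raise IntrinsicError("no residue has a defined intrinsic rate")
    t = np.atleast_1d(np.asarray(times, dtype=float))
    return (-np.expm1(-np.outer(t, ks))).sum(axis=1)


def fit_kint(rates: IntrinsicRates, n_times: int = 40) -> tuple[float, float]:
    """Peptide-level (k_int, beta_int) from the simulated intrinsic curve.

    The multi-residue curve is evaluated on a log-spaced grid spanning
    the full dynamic range of the rates and fitted with one stretched-
    exponential phase, N fixed at the number of defined residues.
    Homogeneous rates give beta = 1 exactly; heterogeneous rates stretch
    the fit (beta < 1).
    """
    ks = rates.defined()
    if len(ks) == 0:
        raise IntrinsicError("no residue has a defined intrinsic rate")
    t_lo = 0.01 / ks.max()
    t_hi = 50.0 / ks.min()
    times = np.logspace(math.log10(t_lo), math.log10(t_hi), n_times)
    uptake = simulate_intrinsic_uptake(rates, times)
    fit = fit_stretched_exponential((times, uptake), nexp=1,
                                    n_max=float(len(ks)), fix_n=True)
    return fit.phases[0].k, fit.phases[0].beta


@dataclass(frozen=True)
class ProtectionFactor:
    """Fold slowdown of exchange relative to the unprotected chain."""

    species: Species | None
    state: str
    k_int: float
    k_obs: float
    pf: float
    ln_pf: float


def protection_factor(k_int: float, fit: KineticFit) -> ProtectionFactor:
    """Pf = k_int / k_obs for a single-phase stretched-exponential fit."""
    if fit.fit_kind != "stretched_exp":
        raise FitError("rate unavailable for interpolation fits")
    k_obs = fit.k_obs   # raises for multi-phase fits
    pf = k_int / k_obs
    return ProtectionFactor(fit.species, fit.state, k_int, k_obs, pf, math.log(pf))


def filter_by_pf(results: Sequence[ProtectionFactor],
                 ln_pf_max: float = 10.0) -> list[ProtectionFactor]:
    """Drop species too protected to quantify within the labeling window.

    The measurable labeling times put an upper limit of detection on Pf;
    species at or above ``ln_pf_max`` (in either compared state) exchange
    too slowly to yield a trustworthy k_obs and are excluded from
    differential analysis.
    """
    kept, removed = [], []
    for res in results:
        (removed if res.ln_pf >= ln_pf_max else kept).append(res)
    if removed:
        import logging
        logging.getLogger(__name__).info(
            "protection-factor filter removed %d species with ln(Pf) >= %g",
            len(removed), ln_pf_max)
    return kept
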