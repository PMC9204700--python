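"""Synthetic HDX datasets with known ground truth.

The generator emulates the cluster-CSV dialect end to end: per-residue
first-order exchange is simulated, aggregated to species-level uptake
over each peptide/fragment's covered interval, attenuated by a
back-exchange loss fraction, converted to charge-state centroid rows
(two charge states per species) and perturbed with Gaussian replicate
noise.  Ground-truth tables (per-residue rates, true species uptake)
are emitted alongside so that every downstream module can be tested
against known kinetics without any experimental download.
"""

from __future__ import annotations

import io
import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pyteomics import mass as pt_mass

from .cluster_io import (PROTON_MASS, ClusterRecord, Species, UptakeCurve,
                         write_cluster_csv)

_AA = "ACDEFGHIKLMNQRSTVWY"          # proline added separately
_REFERENCE_PEPTIDE = "RPPGFSPFR"     # bradykinin, unstructured in water


@dataclass
class StateSpec:
    """One solution condition of the synthetic experiment."""

    name: str
    ph: float = 7.0
    rate_scale: float = 1.0            # solution effect on all residue rates
    effect_regions: tuple = ()         # ((start, end, protection_factor), ...)
    ref_k: float = 0.05                # reference-peptide k_obs (1/s)
    ref_beta: float = 0.9              # reference-peptide stretching factor

    def protection_at(self, residue: int) -> float:
        for a, b, pf in self.effect_regions:
            if a <= residue <= b:
                return pf
        return 1.0


@dataclass
class SyntheticSpec:
    """Study conditions of a synthetic HDX experiment.

    Defaults emulate a 140-residue disordered protein digested into ~60
    peptides with c/z fragments on 30% of them, seven log-spaced
    labeling times and three replicates with 0.05 Da Gaussian noise —
    a desk-scale version of a millisecond-timescale bottom-up +
    middle-down experiment.
    """

    protein_length: int = 140
    protein_name: str = "SYNPROT"
    n_peptides: int = 60
    peptide_length: tuple[int, int] = (8, 20)
    fragment_fraction: float = 0.3
    rate_range: tuple[float, float] = (1e-3, 1.0)   # per-residue k bounds (1/s)
    states: tuple[StateSpec, ...] = (StateSpec("State_A"), StateSpec("State_B"))
    times: tuple[float, ...] = (0.1, 0.5, 2.5, 12.0, 60.0, 300.0, 1500.0)
    replicates: int = 3
    noise_sd: float = 0.05             # Da, per measurement
    noise_dispersion: float = 0.0      # log-normal spread of per-species noise
    backexchange_loss: float = 0.0     # fraction of deuterium lost, in [0, 1)
    include_reference: bool = True     # add the unstructured reference peptide
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.backexchange_loss < 1:
            raise ValueError("backexchange_loss must be in [0, 1)")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        if self.peptide_length[1] > self.protein_length:
            raise ValueError("peptides cannot exceed the protein length")


@dataclass
class SyntheticDataset:
    """Generated records plus the ground truth that produced them."""

    spec: SyntheticSpec
    records: list
    species: list
    residue_rates: pd.DataFrame       # residue, base_k, per-state effective k
    species_truth: pd.DataFrame       # species key, state, time_s, true uptake
    maxd_by_species: dict             # Species.key -> maxD (Da) after loss
    noise_sd_by_species: dict         # Species.key -> per-species noise sd

    @property
    def csv_text(self) -> str:
        buf = io.StringIO()
        write_cluster_csv(self.records, buf, time_unit="s")
        return buf.getvalue()

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {"cluster": out_dir / "cluster.csv",
                 "rates": out_dir / "ground_truth_rates.csv",
                 "uptake": out_dir / "ground_truth_uptake.csv"}
        paths["cluster"].write_text(self.csv_text)
        self.residue_rates.to_csv(paths["rates"], index=False)
        self.species_truth.to_csv(paths["uptake"], index=False)
        return paths


def _random_species(spec: SyntheticSpec, rng: np.random.Generator,
                    sequence: str) -> list[Species]:
    species: list[Species] = []
    seen_peptides: set[tuple] = set()
    lo, hi = spec.peptide_length
    attempts = 0
    while len(seen_peptides) < spec.n_peptides and attempts < 50 * spec.n_peptides:
        attempts += 1
        length = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(1, spec.protein_length - length + 2))
        end = start + length - 1
        seq = sequence[start - 1:end]
        pep = Species(spec.protein_name, start, end, seq,
                      max_uptake=_exchangeable(seq, full_start=True))
        if pep.key in seen_peptides:
            continue
        seen_peptides.add(pep.key)
        species.append(pep)
        if rng.random() < spec.fragment_fraction:
            for series in ("c", "z"):
                n = int(rng.integers(2, length))
                frag_label = f"{series}{n}"
                frag = Species(spec.protein_name, start, end, seq,
                               fragment=frag_label, max_uptake=0)
                a, b = frag.covered_interval
                mu = len(frag.exchangeable_residues())
                if mu > 0:
                    species.append(Species(spec.protein_name, start, end, seq,
                                           fragment=frag_label, max_uptake=mu))
    # dedupe while keeping order
    seen, out = set(), []
    for sp in species:
        if sp.key not in seen:
            seen.add(sp.key)
            out.append(sp)
    return out


def _exchangeable(seq: str, full_start: bool = True) -> int:
    return sum(1 for i, c in enumerate(seq) if i > 0 and c != "P")


def _species_mass(sp: Species) -> float:
    a, b = sp.covered_interval
    sub = sp.sequence[a - sp.start:b - sp.start + 1]
    if not sp.fragment:
        return pt_mass.calculate_mass(sequence=sub)
    ion = sp.fragment[0]
    return pt_mass.calculate_mass(sequence=sub, ion_type=ion, charge=0)


def _true_uptake(sp: Species, state: StateSpec, base_rates: Mapping[int, float],
                 t: float) -> float:
    total = 0.0
    for r in sp.exchangeable_residues():
        k = base_rates[r] * state.rate_scale / state.protection_at(r)
        total += -math.expm1(-k * t)
    return total


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Simulate a full cluster CSV plus ground-truth tables.

    The same seed yields byte-identical CSV output.  With zero noise and
    zero back-exchange loss, parsing + deconvolution reproduces the
    ground-truth uptake to floating-point precision.
    """
    rng = np.random.default_rng(spec.seed)
    # protein sequence with ~5% prolines
    seq_chars = [
        "P" if rng.random() < 0.05 else _AA[int(rng.integers(len(_AA)))]
        for _ in range(spec.protein_length)
    ]
    sequence = "".join(seq_chars)
    species = _random_species(spec, rng, sequence)

    lo, hi = spec.rate_range
    base_rates = {
        r: float(10 ** rng.uniform(math.log10(lo), math.log10(hi)))
        for r in range(1, spec.protein_length + 1)
    }

    noise_by_species = {
        sp.key: spec.noise_sd * float(np.exp(spec.noise_dispersion
                                             * rng.standard_normal()))
        for sp in species
    }
    intensity_by_species = {
        sp.key: float(10 ** rng.uniform(4, 6)) for sp in species
    }

    ref_species = None
    if spec.include_reference:
        ref_species = Species("REFERENCE", 1, len(_REFERENCE_PEPTIDE),
                              _REFERENCE_PEPTIDE,
                              max_uptake=_exchangeable(_REFERENCE_PEPTIDE))
        noise_by_species[ref_species.key] = spec.noise_sd
        intensity_by_species[ref_species.key] = 1e5

    loss = spec.backexchange_loss
    records: list[ClusterRecord] = []
    truth_rows = []

    def emit(sp: Species, state_name: str, t_idx: int, t: float, repl: int,
             uptake_obs: float):
        mono = _species_mass(sp)
        neutral = mono + uptake_obs
        fname = f"{state_name}_t{t_idx:02d}_{repl:02d}"
        for z, frac in ((2, 0.6), (3, 0.4)):
            records.append(ClusterRecord(
                protein=sp.protein, start=sp.start, end=sp.end,
                sequence=sp.sequence, modification=sp.modification,
                fragment=sp.fragment, max_uptake=sp.max_uptake,
                mono_mass=mono, state=state_name, exposure_s=t, file=fname,
                charge=z, rt=round(5 + (sp.start % 37) * 0.5, 3),
                intensity=intensity_by_species[sp.key] * frac,
                centroid=(neutral + z * PROTON_MASS) / z))

    for state in spec.states:
        for sp in species + ([ref_species] if ref_species else []):
            if sp is ref_species:
                n_ref = sp.max_uptake
                truth_fn = lambda t: n_ref * -math.expm1(
                    -((state.ref_k * t) ** state.ref_beta))
            else:
                truth_fn = lambda t: _true_uptake(sp, state, base_rates, t)
            sd = noise_by_species[sp.key]
            for t_idx, t in enumerate((0.0,) + tuple(spec.times)):
                true_u = truth_fn(t)
                truth_rows.append({
                    "protein": sp.protein, "start": sp.start, "end": sp.end,
                    "sequence": sp.sequence, "modification": sp.modification,
                    "fragment": sp.fragment, "state": state.name,
                    "time_s": t, "true_uptake": true_u,
                    "true_uptake_observed": true_u * (1 - loss),
                })
                for repl in range(1, spec.replicates + 1):
                    if t == 0.0:
                        obs = 0.0   # undeuterated control, measured clean
                    else:
                        obs = true_u * (1 - loss) + sd * rng.standard_normal()
                    emit(sp, state.name, t_idx, t, repl, obs)

    all_species = species + ([ref_species] if ref_species else [])
    rate_rows = []
    for r in range(1, spec.protein_length + 1):
        row = {"residue": r, "amino_acid": sequence[r - 1],
               "base_k": base_rates[r]}
        for state in spec.states:
            row[f"k_{state.name}"] = (base_rates[r] * state.rate_scale
                                      / state.protection_at(r))
        rate_rows.append(row)

    maxd = {sp.key: sp.max_uptake * (1 - loss) for sp in all_species}
    return SyntheticDataset(spec, records, all_species,
                            pd.DataFrame(rate_rows), pd.DataFrame(truth_rows),
                            maxd, noise_by_species)


# ---------------------------------------------------------------------------
# Reference-peptide curves (for calibration tests) and null experiments


def reference_peptide_curves(params_by_state: Mapping[str, tuple[float, float]],
                             n_max: float,
                             times: Sequence[float],
                             replicates: int = 3,
                             noise_sd: float = 0.0,
                             seed: int | None = None) -> dict[str, UptakeCurve]:
    """Single-phase stretched-exponential curves of an unstructured peptide.

    ``params_by_state`` maps state name -> (k_obs, beta); a common
    amplitude ``n_max`` plays the role of the back-exchange-corrected
    maximum deuteration.
    """
    rng = np.random.default_rng(seed)
    sp = Species("REFERENCE", 1, len(_REFERENCE_PEPTIDE), _REFERENCE_PEPTIDE,
                 max_uptake=max(int(round(n_max)), 1))
    out = {}
    t = np.asarray(times, dtype=float)
    for state, (k, beta) in params_by_state.items():
        ts, us, rs = [], [], []
        for repl in range(1, replicates + 1):
            u = n_max * -np.expm1(-((k * t) ** beta))
            if noise_sd > 0:
                u = u + noise_sd * rng.standard_normal(len(t))
            ts.append(t), us.append(u), rs.append(np.full(len(t), repl))
        out[state] = UptakeCurve(sp, state, np.concatenate(ts),
                                 np.concatenate(us), np.concatenate(rs))
    return out


def generate_null_pair(n_replicates: int, n_groups: int = 2
                       ) -> list[tuple[tuple[int, ...], ...]]:
    """All distinct partitions of replicates into equal pseudo-groups.

    For four replicates and two groups this yields the three unordered
    pairings {12|34, 13|24, 14|23} — six groups of two — used for null
    (within-state) false-positive experiments.
    """
    if n_replicates < 2 * n_groups:
        raise ValueError(
            f"need >= {2 * n_groups} replicates for {n_groups} groups of >= 2")
    if n_replicates % n_groups:
        raise ValueError("replicates must split evenly into groups")
    size = n_replicates // n_groups
    reps = tuple(range(1, n_replicates + 1))

    def partitions(pool: tuple[int, ...]):
        if not pool:
            yield ()
            return
        first = pool[0]
        for rest in itertools.combinations(pool[1:], size - 1):
            group = (first,) + rest
            remaining = tuple(r for r in pool if r not in group)
            for tail in partitions(remaining):
                yield (group,) + tail

    return sorted(set(partitions(reps)))


def relabel_pseudo_states(table: pd.DataFrame, state: str,
                          groups: Sequence[Sequence[int]],
                          names: Sequence[str] | None = None) -> pd.DataFrame:
    """Split one state's replicates into pseudo-states for null testing.

    Replicates in ``groups[i]`` are relabeled to pseudo-state i and
    renumbered 1..len(group); rows of other replicates are dropped.
    """
    if names is None:
        names = [f"{state}_null{i + 1}" for i in range(len(groups))]
    sub = table[table["state"] == state]
    parts = []
    for name, group in zip(names, groups):
        renum = {r: i + 1 for i, r in enumerate(sorted(group))}
        part = sub[sub["replicate"].isin(group)].copy()
        part["state"] = name
        part["replicate"] = part["replicate"].map(renum)
        parts.append(part)
    return pd.concat(parts, ignore_index=True)
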