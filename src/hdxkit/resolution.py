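"""Merging peptide/fragment coverage into residue-level profiles.

Overlapping peptides and their c/z fragments cut the sequence into the
finest segments that the combined boundary set can resolve; a metric
value per species is "flattened" onto residues by dividing it by the
species' exchangeable-hydrogen count q and spreading the quotient over
the covered residues (prolines and each species' N-terminal residue are
fixed at zero — they carry no observable amide deuterium).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cluster_io import Species
from .significance import ComparisonResult

FLAG_NORMAL = "normal"
FLAG_NTERM = "fixed_zero_nterm"
FLAG_PROLINE = "fixed_zero_proline"
FLAG_UNCOVERED = "uncovered"


class ResolutionError(ValueError):
    pass


@dataclass
class SegmentMap:
    """Partition of the covered region into finest resolvable segments."""

    protein: str
    segments: list[tuple[int, int]]            # sorted, disjoint, 1-based inclusive
    provenance: dict[tuple[int, int], list[tuple]]  # segment -> species keys at its cuts

    def lengths(self) -> list[int]:
        return [b - a + 1 for a, b in self.segments]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"start": a, "end": b, "length": b - a + 1} for a, b in self.segments])


def merged_segments(species_list: Sequence[Species]) -> SegmentMap:
    """Cut the covered region at every species boundary.

    Each species' covered interval contributes its start and end+1 as
    cut points; the atomic intervals between consecutive cuts, within
    covered stretches, are the resolvable segments.  Adding species can
    only refine the partition.
    """
    if not species_list:
        raise ResolutionError("need at least one species")
    proteins = {sp.protein for sp in species_list}
    if len(proteins) > 1:
        raise ResolutionError(f"species span multiple proteins: {sorted(proteins)}")
    covered: set[int] = set()
    cuts: dict[int, list[tuple]] = {}
    for sp in species_list:
        a, b = sp.covered_interval
        covered.update(range(a, b + 1))
        cuts.setdefault(a, []).append(sp.key)
        cuts.setdefault(b + 1, []).append(sp.key)

    segments: list[tuple[int, int]] = []
    provenance: dict[tuple[int, int], list[tuple]] = {}
    residues = sorted(covered)
    seg_start = residues[0]
    prev = residues[0]
    for r in residues[1:] + [None]:
        boundary = r is None or r != prev + 1 or r in cuts
        if boundary:
            seg = (seg_start, prev)
            segments.append(seg)
            provenance[seg] = sorted(
                set(cuts.get(seg_start, []) + cuts.get(prev + 1, [])))
            if r is not None:
                seg_start = r
        if r is not None:
            prev = r
    return SegmentMap(next(iter(proteins)), segments, provenance)


def resolution_histogram(segment_map: SegmentMap) -> dict[int, int]:
    """Counts of resolvable segments by length (1 = single residues)."""
    return dict(sorted(Counter(segment_map.lengths()).items()))


@dataclass
class ResidueProfile:
    """Per-residue metric values (units per exchangeable hydrogen)."""

    protein: str
    residues: np.ndarray          # 1-based residue indices, contiguous 1..L
    values: np.ndarray            # nan where uncovered
    flags: list[str]
    n_covering: np.ndarray

    def value_at(self, residue: int) -> float | None:
        i = residue - int(self.residues[0])
        if not 0 <= i < len(self.residues):
            return None
        v = self.values[i]
        return None if math.isnan(v) else float(v)

    def flag_at(self, residue: int) -> str:
        i = residue - int(self.residues[0])
        if not 0 <= i < len(self.residues):
            return FLAG_UNCOVERED
        return self.flags[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "protein": self.protein,
            "residue": self.residues,
            "value": self.values,
            "flag": self.flags,
            "n_covering_species": self.n_covering,
        })


def flatten(species_values: Mapping[Species, float],
            q: Mapping[Species, int] | None = None) -> ResidueProfile:
    """Flatten species-level values onto residues.

    Each species' value is divided by its exchangeable-hydrogen count q
    (default: its ``max_uptake``) and the per-hydrogen quotient assigned
    to every residue of the covered interval.  Prolines and the species'
    N-terminal residue are fixed at 0.  Residues covered by several
    species get the unweighted mean of the informative contributions;
    uncovered residues are missing (``nan``), never 0.
    """
    if not species_values:
        raise ResolutionError("no species values to flatten")
    proteins = {sp.protein for sp in species_values}
    if len(proteins) > 1:
        raise ResolutionError(f"species span multiple proteins: {sorted(proteins)}")

    max_end = max(sp.covered_interval[1] for sp in species_values)
    L = max_end
    contrib: list[list[float]] = [[] for _ in range(L + 1)]
    zero_flags: list[set[str]] = [set() for _ in range(L + 1)]
    covering = np.zeros(L + 1, dtype=int)

    for sp, value in species_values.items():
        qi = sp.max_uptake if q is None else q[sp]
        if qi is None or qi <= 0:
            raise ResolutionError(f"{sp.label}: q must be > 0")
        per_h = value / qi
        a, b = sp.covered_interval
        for r in range(a, b + 1):
            covering[r] += 1
            if sp.residue_char(r) == "P":
                zero_flags[r].add(FLAG_PROLINE)
            elif r == sp.start:
                zero_flags[r].add(FLAG_NTERM)
            else:
                contrib[r].append(per_h)

    residues = np.arange(1, L + 1)
    values = np.full(L, np.nan)
    flags = [FLAG_UNCOVERED] * L
    for r in range(1, L + 1):
        i = r - 1
        if contrib[r]:
            values[i] = float(np.mean(contrib[r]))
            flags[i] = FLAG_NORMAL
        elif FLAG_PROLINE in zero_flags[r]:
            values[i] = 0.0
            flags[i] = FLAG_PROLINE
        elif FLAG_NTERM in zero_flags[r]:
            values[i] = 0.0
            flags[i] = FLAG_NTERM
    return ResidueProfile(next(iter(proteins)), residues, values, flags,
                          covering[1:])


def flatten_difference(profile_a: ResidueProfile, profile_b: ResidueProfile,
                       significance: Mapping[int, tuple[float, bool]] | None = None,
                       state_a: str = "a", state_b: str = "b",
                       metric: str = "uptake_area") -> list[ComparisonResult]:
    """Per-residue differences between two flattened profiles.

    Δ = value_a − value_b where both residues carry values; residues
    covered in only one profile give no comparison (missing, not 0).
    ``significance`` optionally maps residue -> (p_value, significant)
    inherited from the hybrid test on the flattened metric.
    """
    if profile_a.protein != profile_b.protein:
        raise ResolutionError(
            f"protein mismatch: {profile_a.protein!r} vs {profile_b.protein!r}")
    out: list[ComparisonResult] = []
    lo = int(min(profile_a.residues[0], profile_b.residues[0]))
    hi = int(max(profile_a.residues[-1], profile_b.residues[-1]))
    for r in range(lo, hi + 1):
        va, vb = profile_a.value_at(r), profile_b.value_at(r)
        if va is None or vb is None:
            continue
        p, sig = (math.nan, None)
        if significance is not None and r in significance:
            p, sig = significance[r]
        out.append(ComparisonResult(r, state_a, state_b, metric, va - vb, p,
                                    significant=sig))
    return out


def flatten_distributions(dists_by_species: Mapping[Species, np.ndarray],
                          q: Mapping[Species, int] | None = None
                          ) -> dict[int, np.ndarray]:
    """Residue-level sample vectors from aligned per-species samples.

    ``dists_by_species`` maps each species to its replicate-level metric
    samples (all the same length, aligned by replicate index).  Each
    sample column is flattened independently, yielding per-residue
    replicate-level samples suitable for residue-level Welch tests.
    """
    lengths = {len(v) for v in dists_by_species.values()}
    if len(lengths) != 1:
        raise ResolutionError("per-species sample vectors must align")
    n = lengths.pop()
    per_residue: dict[int, list[float]] = {}
    for j in range(n):
        profile = flatten({sp: float(samples[j])
                           for sp, samples in dists_by_species.items()}, q)
        for r in profile.residues:
            v = profile.value_at(int(r))
            if v is not None and profile.flag_at(int(r)) == FLAG_NORMAL:
                per_residue.setdefault(int(r), []).append(v)
    return {r: np.array(v) for r, v in sorted(per_residue.items()) if len(v) == n}
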