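"""Parsing, validation and charge deconvolution of cluster-data CSVs.

The cluster CSV is the entry point of the pipeline: one row per observed
isotopic cluster, i.e. one charge-state observation of one species
(peptide or c/z fragment) in one state / labeling time / acquisition
file.  Everything downstream works on the deuterium-uptake table that
this module derives from it.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Mass of the proton in Da, used for charge deconvolution.
PROTON_MASS = 1.007276466

#: Canonical column order of the cluster CSV.
COLUMNS = (
    "protein", "start", "end", "sequence", "modification", "fragment",
    "max_uptake", "mono_mass", "state", "exposure", "file", "charge",
    "rt", "intensity", "centroid",
)

_TIME_FACTORS = {"ms": 1e-3, "s": 1.0, "min": 60.0}

SPECIES_KEY_COLUMNS = ("protein", "start", "end", "sequence", "modification", "fragment")


class ClusterCSVError(ValueError):
    """Raised when a cluster CSV (or mapping file) fails validation."""


def _parse_fragment(label: str, sequence: str):
    """Parse a c/z fragment label like ``c5`` -> ('c', 5); '' -> None."""
    if label == "":
        return None
    series, num = label[0].lower(), label[1:]
    if series not in ("c", "z") or not num.isdigit():
        raise ValueError(f"fragment label {label!r} is not c<n> or z<n>")
    n = int(num)
    if not 1 <= n < len(sequence):
        raise ValueError(
            f"fragment {label!r} length {n} outside 1..{len(sequence) - 1}"
        )
    return series, n


@dataclass(frozen=True)
class Species:
    """Identity of a peptide or c/z fragment.

    ``start``/``end`` are 1-based inclusive residue indices of the parent
    peptide in the protein sequence.  For a fragment, ``covered_interval``
    is the sub-interval actually spanned: a c_n ion covers the first n
    residues of the peptide, a z_n ion the last n.
    """

    protein: str
    start: int
    end: int
    sequence: str
    modification: str = ""
    fragment: str = ""
    max_uptake: int = 0

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad interval [{self.start}, {self.end}]")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError(
                f"sequence length {len(self.sequence)} != interval "
                f"{self.end - self.start + 1}"
            )
        _parse_fragment(self.fragment, self.sequence)  # validates label
        if self.max_uptake < 0:
            raise ValueError("max_uptake must be >= 0")

    @property
    def covered_interval(self) -> tuple[int, int]:
        frag = _parse_fragment(self.fragment, self.sequence)
        if frag is None:
            return self.start, self.end
        series, n = frag
        if series == "c":
            return self.start, self.start + n - 1
        return self.end - n + 1, self.end

    def residue_char(self, residue: int) -> str:
        """Amino-acid one-letter code at 1-based protein residue index."""
        if not self.start <= residue <= self.end:
            raise ValueError(f"residue {residue} outside [{self.start},{self.end}]")
        return self.sequence[residue - self.start]

    def exchangeable_residues(self) -> list[int]:
        """Residues in the covered interval carrying an observable amide.

        Excludes prolines (no backbone amide NH) and the peptide's
        N-terminal residue (its amide deuterium is lost to fast
        back-exchange during quench).
        """
        a, b = self.covered_interval
        return [
            r for r in range(a, b + 1)
            if r != self.start and self.residue_char(r) != "P"
        ]

    @property
    def key(self) -> tuple:
        return (self.protein, self.start, self.end, self.sequence,
                self.modification, self.fragment)

    @property
    def label(self) -> str:
        frag = f"+{self.fragment}" if self.fragment else ""
        return f"{self.protein}[{self.start}-{self.end}]{frag}"


@dataclass
class ClusterRecord:
    """One validated cluster CSV row; ``exposure_s`` is in seconds."""

    protein: str
    start: int
    end: int
    sequence: str
    modification: str
    fragment: str
    max_uptake: int
    mono_mass: float
    state: str
    exposure_s: float
    file: str
    charge: int
    rt: float
    intensity: float
    centroid: float
    replicate: int | None = None

    def species(self) -> Species:
        return Species(self.protein, self.start, self.end, self.sequence,
                       self.modification, self.fragment, self.max_uptake)


_FIELD_PARSERS = {
    "start": int, "end": int, "max_uptake": int, "charge": int,
    "mono_mass": float, "exposure": float, "rt": float,
    "intensity": float, "centroid": float,
}


def _validate_row(values: Mapping[str, str], line_no: int, factor: float) -> ClusterRecord:
    parsed: dict = {}
    for col in COLUMNS:
        raw = values[col].strip()
        parser = _FIELD_PARSERS.get(col)
        if parser is None:
            parsed[col] = raw
            continue
        try:
            parsed[col] = parser(raw)
        except ValueError:
            raise ClusterCSVError(
                f"line {line_no}: column '{col}' has malformed value {raw!r}"
            ) from None

    def err(col, msg):
        raise ClusterCSVError(f"line {line_no}: column '{col}' {msg}")

    if parsed["start"] < 1:
        err("start", "must be >= 1")
    if parsed["end"] < parsed["start"]:
        err("end", f"must be >= start ({parsed['start']})")
    if len(parsed["sequence"]) != parsed["end"] - parsed["start"] + 1:
        err("sequence", f"length {len(parsed['sequence'])} does not match "
                        f"interval length {parsed['end'] - parsed['start'] + 1}")
    if parsed["charge"] < 1:
        err("charge", "must be >= 1")
    if parsed["intensity"] < 0:
        err("intensity", "must be >= 0")
    if parsed["centroid"] <= 0:
        err("centroid", "must be > 0")
    if parsed["max_uptake"] < 0:
        err("max_uptake", "must be >= 0")
    if parsed["exposure"] < 0:
        err("exposure", "must be >= 0")
    try:
        _parse_fragment(parsed["fragment"], parsed["sequence"])
    except ValueError as exc:
        err("fragment", str(exc))

    parsed["exposure_s"] = parsed.pop("exposure") * factor
    return ClusterRecord(**parsed)


def parse_cluster_csv(path_or_buffer, time_unit: str = "s") -> list[ClusterRecord]:
    """Parse and validate a cluster CSV into :class:`ClusterRecord` objects.

    Parameters
    ----------
    path_or_buffer
        File path or text file object with 15 comma-separated columns per
        row in :data:`COLUMNS` order.  A header row is auto-detected; when
        present its names must cover the canonical columns (any order).
    time_unit
        Unit of the exposure column: ``ms``, ``s`` or ``min``.  Exposure
        values are canonicalized to seconds.
    """
    if time_unit not in _TIME_FACTORS:
        raise ClusterCSVError(
            f"unknown time unit {time_unit!r}; expected one of ms, s, min"
        )
    factor = _TIME_FACTORS[time_unit]

    if hasattr(path_or_buffer, "read"):
        rows = list(csv.reader(path_or_buffer))
    else:
        with open(path_or_buffer, newline="", encoding="utf-8") as fh:
            rows = list(csv.reader(fh))
    rows = [(i + 1, row) for i, row in enumerate(rows) if any(c.strip() for c in row)]
    if not rows:
        raise ClusterCSVError("empty cluster CSV")

    # Header auto-detection: in a data row column 2 ('start') is an integer.
    first = rows[0][1]
    header_names = None
    try:
        int(first[1].strip())
    except (ValueError, IndexError):
        header_names = [c.strip().lower() for c in first]
        missing = set(COLUMNS) - set(header_names)
        if missing:
            raise ClusterCSVError(
                f"line 1: header does not map required columns: {sorted(missing)}"
            )
        rows = rows[1:]
        if not rows:
            raise ClusterCSVError("cluster CSV contains a header but no data rows")

    records, errors = [], []
    for line_no, row in rows:
        if header_names is None:
            if len(row) != len(COLUMNS):
                errors.append(
                    f"line {line_no}: expected {len(COLUMNS)} columns, got {len(row)}"
                )
                continue
            values = dict(zip(COLUMNS, row))
        else:
            if len(row) != len(header_names):
                errors.append(
                    f"line {line_no}: expected {len(header_names)} columns, got {len(row)}"
                )
                continue
            named = dict(zip(header_names, row))
            values = {col: named[col] for col in COLUMNS}
        try:
            records.append(_validate_row(values, line_no, factor))
        except ClusterCSVError as exc:
            errors.append(str(exc))
    if errors:
        shown = "\n".join(errors[:20])
        more = f"\n... and {len(errors) - 20} more" if len(errors) > 20 else ""
        raise ClusterCSVError(f"invalid cluster CSV:\n{shown}{more}")
    return records


def write_cluster_csv(records: Iterable[ClusterRecord], path_or_buffer,
                      time_unit: str = "s", header: bool = True) -> None:
    """Write records back to the cluster CSV dialect (round-trip safe)."""
    if time_unit not in _TIME_FACTORS:
        raise ClusterCSVError(f"unknown time unit {time_unit!r}")
    factor = _TIME_FACTORS[time_unit]

    def _write(fh):
        writer = csv.writer(fh, lineterminator="\n")
        if header:
            writer.writerow(COLUMNS)
        for rec in records:
            writer.writerow([
                rec.protein, rec.start, rec.end, rec.sequence,
                rec.modification, rec.fragment, rec.max_uptake,
                repr(rec.mono_mass), rec.state, repr(rec.exposure_s / factor),
                rec.file, rec.charge, repr(rec.rt), repr(rec.intensity),
                repr(rec.centroid),
            ])

    if hasattr(path_or_buffer, "write"):
        _write(path_or_buffer)
    else:
        with open(path_or_buffer, "w", newline="", encoding="utf-8") as fh:
            _write(fh)


# ---------------------------------------------------------------------------
# Replicate assignment


def read_mapping_csv(path_or_buffer) -> dict[str, tuple[str, int]]:
    """Read a ``file,state,replicate`` mapping CSV."""
    df = pd.read_csv(path_or_buffer, dtype={"file": str, "state": str})
    for col in ("file", "state", "replicate"):
        if col not in df.columns:
            raise ClusterCSVError(f"mapping file lacks column '{col}'")
    return {row.file: (row.state, int(row.replicate)) for row in df.itertuples()}


def assign_replicates(records: Sequence[ClusterRecord],
                      mapping: Mapping[str, tuple[str, int]] | None = None,
                      ) -> list[ClusterRecord]:
    """Annotate every record with a replicate index.

    Without a mapping, file names within each (state, exposure) group are
    sorted lexicographically and numbered 1..n — the convention for
    trivially named files (``file_01``, ``file_02``, ...).  An explicit
    ``file -> (state, replicate)`` mapping overrides this.
    """
    if mapping is not None:
        known_files = {r.file for r in records}
        unknown = set(mapping) - known_files
        if unknown:
            raise ClusterCSVError(
                f"mapping references unknown files: {sorted(unknown)}"
            )
        seen: dict[tuple[str, float, int], str] = {}
        out = []
        for rec in records:
            if rec.file not in mapping:
                raise ClusterCSVError(f"file {rec.file!r} missing from mapping")
            state, repl = mapping[rec.file]
            slot = (state, rec.exposure_s, repl)
            if seen.setdefault(slot, rec.file) != rec.file:
                raise ClusterCSVError(
                    f"files {seen[slot]!r} and {rec.file!r} both map to "
                    f"state {state!r}, time {rec.exposure_s} s, replicate {repl}"
                )
            out.append(replace(rec, state=state, replicate=repl))
        return out

    by_group: dict[tuple[str, float], set[str]] = {}
    for rec in records:
        by_group.setdefault((rec.state, rec.exposure_s), set()).add(rec.file)
    index = {
        group: {f: i + 1 for i, f in enumerate(sorted(files))}
        for group, files in by_group.items()
    }
    return [
        replace(rec, replicate=index[(rec.state, rec.exposure_s)][rec.file])
        for rec in records
    ]


def missing_replicate_report(records: Sequence[ClusterRecord]) -> pd.DataFrame:
    """Flag (state, time) groups missing replicate indices seen elsewhere."""
    rows = []
    by_state: dict[str, dict[float, set[int]]] = {}
    for rec in records:
        if rec.replicate is None:
            raise ClusterCSVError("records have no replicate assignment")
        by_state.setdefault(rec.state, {}).setdefault(rec.exposure_s, set()).add(rec.replicate)
    for state, times in by_state.items():
        all_reps = set().union(*times.values())
        for t, reps in sorted(times.items()):
            for missing in sorted(all_reps - reps):
                rows.append({"state": state, "time_s": t, "missing_replicate": missing})
    return pd.DataFrame(rows, columns=["state", "time_s", "missing_replicate"])


# ---------------------------------------------------------------------------
# Charge deconvolution and uptake


def neutral_mass(centroid: float, charge: int) -> float:
    """Neutral mass from an m/z centroid: ``centroid*z - z*m_proton``."""
    return centroid * charge - charge * PROTON_MASS


def deconvolute_neutral(records: Sequence[ClusterRecord]) -> float:
    """Intensity-weighted mean neutral mass over charge-state observations."""
    if not records:
        raise ClusterCSVError("no records to deconvolute")
    masses = np.array([neutral_mass(r.centroid, r.charge) for r in records])
    weights = np.array([r.intensity for r in records], dtype=float)
    total = weights.sum()
    if total <= 0:
        raise ClusterCSVError(
            f"total intensity is 0 for {records[0].species().label} "
            f"state={records[0].state} t={records[0].exposure_s}s"
        )
    return float(np.average(masses, weights=weights))


def deconvolute_uptake(records: Sequence[ClusterRecord],
                       undeuterated_reference: float) -> float:
    """Deuterium uptake (Da) of one species/state/time/replicate group."""
    if undeuterated_reference is None:
        raise ClusterCSVError("no undeuterated reference mass available")
    return deconvolute_neutral(records) - undeuterated_reference


def build_uptake_table(records: Sequence[ClusterRecord],
                       reference: str | Mapping[tuple, float] = "auto",
                       clamp_negative: bool = False) -> pd.DataFrame:
    """Deconvolute all records into a replicate-resolved uptake table.

    The undeuterated reference per species is taken from time-0 rows when
    present (``reference="auto"``); otherwise the theoretical monoisotopic
    mass column is used with a logged warning.  ``reference`` may also be
    ``"mono_mass"`` or an explicit ``species.key -> mass`` mapping.

    Negative uptake after reference subtraction is retained by default so
    that replicate noise statistics stay unbiased; pass
    ``clamp_negative=True`` to floor at zero.
    """
    groups: dict[tuple, list[ClusterRecord]] = {}
    for rec in records:
        if rec.replicate is None:
            raise ClusterCSVError(
                "records must have replicates assigned (see assign_replicates)"
            )
        key = (rec.species().key, rec.state, rec.exposure_s, rec.replicate)
        groups.setdefault(key, []).append(rec)

    refs: dict[tuple, float] = {}
    if isinstance(reference, Mapping):
        refs.update(reference)
    else:
        by_species: dict[tuple, list[ClusterRecord]] = {}
        for rec in records:
            by_species.setdefault(rec.species().key, []).append(rec)
        for skey, recs in by_species.items():
            t0 = [r for r in recs if r.exposure_s == 0]
            if reference == "auto" and t0:
                refs[skey] = deconvolute_neutral(t0)
            else:
                if reference == "auto":
                    logger.warning(
                        "species %s has no time-0 control; falling back to the "
                        "theoretical monoisotopic mass as undeuterated reference",
                        recs[0].species().label,
                    )
                refs[skey] = recs[0].mono_mass

    rows = []
    for (skey, state, time_s, repl), recs in sorted(
            groups.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2], kv[0][3])):
        uptake = deconvolute_uptake(recs, refs.get(skey))
        if clamp_negative:
            uptake = max(uptake, 0.0)
        sp = recs[0].species()
        rows.append({
            "protein": sp.protein, "start": sp.start, "end": sp.end,
            "sequence": sp.sequence, "modification": sp.modification,
            "fragment": sp.fragment, "max_uptake": sp.max_uptake,
            "state": state, "time_s": time_s, "replicate": repl,
            "uptake": uptake,
        })
    return pd.DataFrame(rows)


def species_from_row(row) -> Species:
    """Rebuild a :class:`Species` from an uptake-table row."""
    frag = row["fragment"]
    if frag is None or (isinstance(frag, float) and np.isnan(frag)):
        frag = ""
    mod = row["modification"]
    if mod is None or (isinstance(mod, float) and np.isnan(mod)):
        mod = ""
    return Species(row["protein"], int(row["start"]), int(row["end"]),
                   row["sequence"], str(mod), str(frag), int(row["max_uptake"]))


def iter_species(table: pd.DataFrame):
    """Yield (Species, sub-table) for every species in an uptake table."""
    for _, sub in table.groupby(list(SPECIES_KEY_COLUMNS), dropna=False, sort=True):
        yield species_from_row(sub.iloc[0]), sub


@dataclass
class UptakeCurve:
    """Replicate-resolved uptake vs labeling time for one species/state."""

    species: Species
    state: str
    times: np.ndarray        # seconds, one entry per measurement
    uptakes: np.ndarray      # Da
    replicates: np.ndarray   # integer replicate index per measurement

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.uptakes = np.asarray(self.uptakes, dtype=float)
        self.replicates = np.asarray(self.replicates, dtype=int)
        if not (len(self.times) == len(self.uptakes) == len(self.replicates)):
            raise ValueError("times, uptakes and replicates must align")
        if np.any(self.times < 0):
            raise ValueError("labeling times must be >= 0")

    @classmethod
    def from_table(cls, table: pd.DataFrame, species: Species, state: str,
                   include_t0: bool = False) -> "UptakeCurve":
        mask = (
            (table["protein"] == species.protein)
            & (table["start"] == species.start)
            & (table["end"] == species.end)
            & (table["fragment"].fillna("") == species.fragment)
            & (table["modification"].fillna("") == species.modification)
            & (table["state"] == state)
        )
        sub = table[mask]
        if not include_t0:
            sub = sub[sub["time_s"] > 0]
        if sub.empty:
            raise ValueError(f"no uptake data for {species.label} state={state!r}")
        sub = sub.sort_values(["time_s", "replicate"])
        return cls(species, state, sub["time_s"].to_numpy(),
                   sub["uptake"].to_numpy(), sub["replicate"].to_numpy())

    @property
    def n_replicates(self) -> int:
        return len(np.unique(self.replicates))

    def replicate_ids(self) -> list[int]:
        return sorted(np.unique(self.replicates).tolist())

    def unique_times(self) -> np.ndarray:
        return np.unique(self.times)

    def replicates_at(self, t: float) -> list[int]:
        return sorted(self.replicates[self.times == t].tolist())

    def subset_replicate(self, replicate: int) -> "UptakeCurve":
        """Measurements of a single replicate index (times where present)."""
        mask = self.replicates == replicate
        if not mask.any():
            raise ValueError(f"replicate {replicate} absent from curve")
        return UptakeCurve(self.species, self.state, self.times[mask],
                           self.uptakes[mask], self.replicates[mask])

    def subset_assignment(self, assignment: Mapping[float, int]) -> "UptakeCurve":
        """One measurement per time, chosen by a time -> replicate map."""
        idx = []
        for t, r in assignment.items():
            hit = np.flatnonzero((self.times == t) & (self.replicates == r))
            if len(hit) == 0:
                raise ValueError(f"no measurement at t={t}s replicate={r}")
            idx.append(hit[0])
        idx = np.array(sorted(idx))
        return UptakeCurve(self.species, self.state, self.times[idx],
                           self.uptakes[idx], self.replicates[idx])

    def mean_by_time(self) -> tuple[np.ndarray, np.ndarray]:
        ts = self.unique_times()
        means = np.array([self.uptakes[self.times == t].mean() for t in ts])
        return ts, means

    def scaled(self, factor: float) -> "UptakeCurve":
        return UptakeCurve(self.species, self.state, self.times,
                           self.uptakes * factor, self.replicates)

    def with_times(self, times: np.ndarray) -> "UptakeCurve":
        return UptakeCurve(self.species, self.state, np.asarray(times, float),
                           self.uptakes, self.replicates)
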