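"""Difference plots, volcano plots and PyMOL coloring scripts.

Figures are derived artifacts: every plot writes a machine-readable CSV
twin with exactly the plotted values, and the CSV — not the image — is
the source of truth.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .resolution import ResidueProfile
from .significance import ComparisonResult


class ReportingError(ValueError):
    pass


#: 9-level diverging scale (blue -> white -> red), symmetric about 0.
DIVERGING_9 = (
    "0x2166ac", "0x4393c3", "0x92c5de", "0xd1e5f0", "0xf7f7f7",
    "0xfddbc7", "0xf4a582", "0xd6604d", "0xb2182b",
)
NEUTRAL_COLOR = "0xf7f7f7"
UNCOVERED_COLOR = "gray70"


def _comparison_frame(comparisons: Sequence[ComparisonResult]) -> pd.DataFrame:
    rows = []
    for c in comparisons:
        if isinstance(c.species, int):
            x, label = c.species, str(c.species)
            start = end = c.species
        else:
            start, end = c.species.start, c.species.end
            label = c.species.label
            x = None
        rows.append({"start": start, "end": end, "label": label,
                     "difference": c.difference, "p_value": c.p_value,
                     "threshold": c.threshold, "significant": bool(c.significant)})
    df = pd.DataFrame(rows).sort_values(["start", "end"], kind="stable")
    df["x"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


def make_difference_plot(comparisons: Sequence[ComparisonResult], kind: str,
                         out_prefix: str | Path | None = None,
                         threshold: float | None = None):
    """Δmetric vs peptide index (ordered by start, then end) or residue.

    Significant entries are marked with a red asterisk; horizontal lines
    mark ±threshold.  Returns (figure, frame); with ``out_prefix`` the
    figure (.png) and its CSV twin are written.
    """
    if not comparisons:
        raise ReportingError("no comparisons to plot")
    if kind not in ("difference_peptide", "difference_residue"):
        raise ReportingError(f"unknown difference plot kind {kind!r}")
    df = _comparison_frame(comparisons)
    if kind == "difference_residue":
        df["x"] = df["start"]
    thr = threshold if threshold is not None else (
        df["threshold"].iloc[0] if np.isfinite(df["threshold"].iloc[0]) else None)

    fig, ax = plt.subplots(figsize=(8, 3.2))
    ax.axhline(0.0, color="black", lw=0.6)
    ax.plot(df["x"], df["difference"], "o-", ms=3, lw=0.8, color="#404080")
    sig = df[df["significant"]]
    if len(sig):
        ax.plot(sig["x"], sig["difference"], "r*", ms=10, ls="none")
    if thr is not None:
        ax.axhline(thr, color="red", ls="--", lw=0.8)
        ax.axhline(-thr, color="red", ls="--", lw=0.8)
    ax.set_xlabel("residue" if kind == "difference_residue" else "peptide index")
    ax.set_ylabel("Δ metric")
    fig.tight_layout()
    if out_prefix is not None:
        out_prefix = Path(out_prefix)
        fig.savefig(out_prefix.with_suffix(".png"), dpi=150)
        df.to_csv(out_prefix.with_suffix(".csv"), index=False)
    return fig, df


def make_volcano_plot(comparisons: Sequence[ComparisonResult],
                      alpha: float, threshold: float,
                      out_prefix: str | Path | None = None):
    """−log10(p) vs Δmetric with the significant region shaded.

    A point lies in the significant region only when |Δ| strictly
    exceeds the threshold and p < alpha.  p = 0 is capped at the plot's
    maximum with an annotation.
    """
    if not comparisons:
        raise ReportingError("no comparisons to plot")
    df = _comparison_frame(comparisons)
    with np.errstate(divide="ignore"):
        df["neg_log10_p"] = -np.log10(df["p_value"])
    finite = df.loc[np.isfinite(df["neg_log10_p"]), "neg_log10_p"]
    cap = float(finite.max()) * 1.1 + 1.0 if len(finite) else 10.0
    capped = ~np.isfinite(df["neg_log10_p"])
    df.loc[capped, "neg_log10_p"] = cap

    fig, ax = plt.subplots(figsize=(4.5, 4))
    span = max(float(np.abs(df["difference"]).max()) * 1.2, threshold * 1.5, 1e-9)
    y_alpha = -math.log10(alpha)
    for sign in (-1, 1):
        ax.axvspan(sign * threshold, sign * span, ymin=0, color="red", alpha=0.08)
    ax.axhline(y_alpha, color="gray", ls="--", lw=0.8)
    ax.axvline(threshold, color="gray", ls="--", lw=0.8)
    ax.axvline(-threshold, color="gray", ls="--", lw=0.8)
    ax.plot(df["difference"], df["neg_log10_p"], "o", ms=4,
            color="#555555", mfc="none")
    sig = df[df["significant"]]
    if len(sig):
        ax.plot(sig["difference"], sig["neg_log10_p"], "o", ms=4, color="red")
    if capped.any():
        ax.annotate("p=0 capped", (0.02, 0.98), xycoords="axes fraction",
                    va="top", fontsize=7)
    ax.set_xlim(-span, span)
    ax.set_xlabel("Δ metric")
    ax.set_ylabel("-log10(p)")
    fig.tight_layout()
    if out_prefix is not None:
        out_prefix = Path(out_prefix)
        fig.savefig(out_prefix.with_suffix(".png"), dpi=150)
        df.to_csv(out_prefix.with_suffix(".csv"), index=False)
    return fig, df


def make_uptake_plot(curves, fits=None, out_prefix: str | Path | None = None):
    """Uptake vs time (log axis) with fitted curves overlaid."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    rows = []
    for curve in curves:
        ax.plot(curve.times, curve.uptakes, "o", ms=4, label=curve.state)
        for t, u, r in zip(curve.times, curve.uptakes, curve.replicates):
            rows.append({"state": curve.state, "time_s": t, "replicate": r,
                         "uptake": u})
    if fits:
        for fit in fits:
            tmax = max(c.times.max() for c in curves)
            tmin = min(c.times[c.times > 0].min() for c in curves)
            grid = np.logspace(math.log10(tmin / 2), math.log10(tmax * 2), 200)
            ax.plot(grid, fit.evaluate(grid), "-", lw=1)
    ax.set_xscale("log")
    ax.set_xlabel("labeling time (s)")
    ax.set_ylabel("uptake (Da)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    df = pd.DataFrame(rows)
    if out_prefix is not None:
        out_prefix = Path(out_prefix)
        fig.savefig(out_prefix.with_suffix(".png"), dpi=150)
        df.to_csv(out_prefix.with_suffix(".csv"), index=False)
    return fig, df


# ---------------------------------------------------------------------------
# PyMOL scripts


def _bin_values(values: np.ndarray, bounds: float) -> np.ndarray:
    edges = np.linspace(-bounds, bounds, len(DIVERGING_9) + 1)
    idx = np.searchsorted(edges, values, side="right") - 1
    return np.clip(idx, 0, len(DIVERGING_9) - 1)


def write_pml(residue_values: Mapping[int, float] | ResidueProfile,
              out_path: str | Path, *,
              chain: str = "A", offset: int = 0,
              structure: str | None = None,
              bounds: float | None = None,
              covered: Sequence[int] | None = None) -> str:
    """Emit a PyMOL coloring script for one set of residue differences.

    Residues are binned on a 9-level diverging scale symmetric about 0
    (bounds default to max |value|); uncovered residues are grayed.
    ``offset`` shifts sequence numbering to the structure's numbering,
    ``chain`` scopes the selections.  Returns the script text (also
    written to ``out_path``).
    """
    if isinstance(residue_values, ResidueProfile):
        pairs = {int(r): residue_values.value_at(int(r))
                 for r in residue_values.residues}
        pairs = {r: v for r, v in pairs.items() if v is not None}
    else:
        pairs = {int(r): float(v) for r, v in residue_values.items()}
    if not pairs:
        raise ReportingError("no residue values to color")

    res = np.array(sorted(pairs))
    vals = np.array([pairs[r] for r in res])
    if bounds is None:
        bounds = float(np.abs(vals).max())
    if bounds == 0:
        bins = np.full(len(res), len(DIVERGING_9) // 2)  # neutral
    else:
        bins = _bin_values(vals, bounds)

    lines = ["# generated by hdxkit", "bg_color white"]
    if structure:
        lines.append(f"load {structure}")
    lines.append(f"color {UNCOVERED_COLOR}, chain {chain}")
    if covered is not None:
        uncov_note = sorted(set(covered) - set(res.tolist()))
        if uncov_note:
            lines.append(f"# residues without data: {len(uncov_note)}")

    # one color command per contiguous run of residues in the same bin
    run_start = 0
    for i in range(1, len(res) + 1):
        end_run = (i == len(res) or bins[i] != bins[run_start]
                   or res[i] != res[i - 1] + 1)
        if end_run:
            a = res[run_start] + offset
            b = res[i - 1] + offset
            sel = f"resi {a}-{b}" if b > a else f"resi {a}"
            lines.append(
                f"color {DIVERGING_9[bins[run_start]]}, chain {chain} and {sel}")
            if i < len(res):
                run_start = i
    text = "\n".join(lines) + "\n"
    Path(out_path).write_text(text)
    return text


def write_pml_series(profiles_by_time: Mapping[float, Mapping[int, float]],
                     out_dir: str | Path, **kwargs) -> list[Path]:
    """One .pml script per selected time point."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for t, values in sorted(profiles_by_time.items()):
        path = out_dir / f"difference_t{t:g}s.pml"
        write_pml(values, path, **kwargs)
        paths.append(path)
    return paths
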