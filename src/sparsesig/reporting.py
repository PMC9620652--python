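"""Figures for cohort calls, spectra and accessibility rankings.

Each figure writes a sidecar JSON of the exact arrays plotted, so tests and
downstream tooling can assert on data rather than raster bytes.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .calibration import CutoffCurve
from .channels import CHANNELS, SUBSTITUTION_TYPES
from .spectrum import Spectrum96

_CLASS_COLORS = {
    "C>A": "#03bcee",
    "C>G": "#010101",
    "C>T": "#e32926",
    "T>A": "#cac9c9",
    "T>C": "#a1ce63",
    "T>G": "#ebc6c4",
}


def _write_sidecar(path: Path, payload: dict) -> Path:
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(payload, indent=2))
    return sidecar


def plot_cohort_scatter(
    calls: pd.DataFrame,
    curve_primary: CutoffCurve,
    curve_skin: CutoffCurve | None = None,
    *,
    out_path,
) -> Path:
    """Score-versus-count scatter with the 1% FDR curves overlaid.

    Positives are highlighted; the x axis is logarithmic in mutation count.
    """
    if calls.empty:
        raise ValueError("empty calls table")
    out_path = Path(out_path)
    calls = calls[calls["n"] >= 1]

    fig, ax = plt.subplots(figsize=(7, 4.5))
    neg = calls[~calls["positive"]]
    pos = calls[calls["positive"]]
    ax.scatter(neg["n"], neg["gcv_score"], s=8, c="#9e9e9e", label="negative", alpha=0.6)
    ax.scatter(pos["n"], pos["gcv_score"], s=22, c="#d62728", label="positive")

    grid = np.unique(
        np.rint(
            np.geomspace(curve_primary.counts_grid[0], curve_primary.counts_grid[-1], 200)
        ).astype(int)
    )
    curves = {"primary": (curve_primary, "#2ca02c")}
    if curve_skin is not None:
        curves["skin"] = (curve_skin, "#1f77b4")
    curve_payload = {}
    for name, (curve, color) in curves.items():
        ax.plot(
            grid,
            curve.value_at(grid),
            color=color,
            label=f"1% FDR ({curve.null_signature})",
        )
        curve_payload[name] = {
            "null_signature": curve.null_signature,
            "counts_grid": curve.counts_grid.tolist(),
            "cutoffs": curve.cutoffs.tolist(),
        }

    ax.set_xscale("log")
    ax.set_xlabel("mutation count")
    ax.set_ylabel("focal signature score")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)

    _write_sidecar(
        out_path,
        {
            "samples": {
                "sample_id": calls["sample_id"].tolist(),
                "n": calls["n"].tolist(),
                "gcv_score": calls["gcv_score"].tolist(),
                "positive": calls["positive"].astype(bool).tolist(),
            },
            "curves": curve_payload,
        },
    )
    return out_path


def plot_spectrum(spectrum: Spectrum96, *, out_path, title: str = "") -> Path:
    """96-bar trinucleotide spectrum grouped by substitution class."""
    if spectrum.total == 0:
        raise ValueError("empty spectrum")
    out_path = Path(out_path)
    colors = [_CLASS_COLORS[label[2:5]] for label in CHANNELS]
    fig, ax = plt.subplots(figsize=(12, 3))
    ax.bar(np.arange(96), spectrum.counts, color=colors, width=0.8)
    ax.set_xticks(np.arange(96))
    ax.set_xticklabels(
        [f"{l[0]}{l[2]}{l[6]}" for l in CHANNELS], rotation=90, fontsize=4
    )
    for i, sub in enumerate(SUBSTITUTION_TYPES):
        ax.text(i * 16 + 7.5, ax.get_ylim()[1], sub, ha="center", va="bottom", fontsize=8)
    ax.set_ylabel("mutations")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)

    _write_sidecar(
        out_path,
        {"channels": list(CHANNELS), "counts": spectrum.counts.tolist()},
    )
    return out_path
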