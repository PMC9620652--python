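"""Simulation-calibrated 1% FDR cutoffs for sparse-panel signature detection.

Panels yield few mutations per sample, so a refit can attribute spurious
exposure to the focal (ganciclovir) signature purely by sampling noise,
especially when a genuine process (SBS18; SBS38 in skin) resembles it. The
calibration simulates null spectra — a 0.95 focal-null / 0.05 SBS5 mixture
by default — refits each, and takes the 99th percentile of the focal
signature's score as the score cutoff at which a null sample is flagged
with 1% probability (the 1% FDR cutoff), per mutation count.

Two artifacts are produced:

* :class:`CutoffCurve` — cutoffs over a grid of mutation counts in
  [1, 10000] at the fixed 0.95 null contribution, queried by log-linear
  interpolation;
* :class:`CutoffRegression` — an OLS surface fitted to cutoffs simulated
  over a grid of null contributions (0.05–0.95) and counts (5–250),

      cutoff = b0 + b1*count + b2*log(count) + b3*contrib
               + b4*contrib*log(count)

  which prices the cutoff for samples whose mutations come from several
  processes, without a per-sample simulation.

Seeding: every (signature, contrib, count) cell derives an independent
child stream from the root seed, so curve and surface cells that share a
cell key produce identical cutoffs and reruns are reproducible.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import statsmodels.api as sm

from .catalog_io import SignatureCatalog
from .refit import em_refit_matrix, simulate_spectra

DEFAULT_FOCAL_WEIGHT = 0.95
DEFAULT_BACKGROUND = "SBS5"
DEFAULT_TARGET = "GCVsig"
DEFAULT_PERCENTILE = 99.0


def default_counts_grid(n_points: int = 40) -> np.ndarray:
    """Log-spaced integer mutation counts spanning [1, 10000]."""
    return np.unique(np.rint(np.geomspace(1, 10_000, n_points)).astype(int))


def default_surface_contribs() -> np.ndarray:
    return np.round(np.arange(0.05, 0.951, 0.05), 10)


def default_surface_counts() -> np.ndarray:
    return np.arange(5, 251, 5)


def cell_rng(
    seed: int, null_signature: str, contrib: float, count: int
) -> np.random.Generator:
    """Independent child stream for one simulation cell.

    Keyed by (signature, contribution, count) so identical cells agree
    between the curve and the surface built from the same root seed.
    """
    key = (
        zlib.crc32(null_signature.encode()),
        int(round(contrib * 10_000)),
        int(count),
    )
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def percentile_cutoff(scores, percentile: float) -> float:
    """Nearest-rank percentile: sorted ascending, element ceil(p/100*n) - 1."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty score list")
    if not (0 < percentile <= 100):
        raise ValueError(f"percentile must be in (0, 100], got {percentile}")
    rank = max(math.ceil(percentile / 100 * scores.size) - 1, 0)
    return float(np.sort(scores)[rank])


def simulate_null_scores(
    null_signature: str,
    contrib: float,
    n: int,
    reps: int,
    catalog: SignatureCatalog,
    rng: np.random.Generator,
    *,
    background: str = DEFAULT_BACKGROUND,
    target: str = DEFAULT_TARGET,
    max_iter: int = 10_000,
    tol: float = 1e-8,
) -> np.ndarray:
    """Focal-signature scores of ``reps`` refitted null spectra.

    Each spectrum is a multinomial draw of ``n`` mutations from the mixture
    {null_signature: contrib, background: 1 - contrib}, refitted against the
    full detection catalog; the returned scores are the fitted exposures of
    ``target``.
    """
    if not (0 < contrib <= 1):
        raise ValueError(f"contrib must be in (0, 1], got {contrib}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    for name in (null_signature, background, target):
        if name not in catalog:
            raise KeyError(f"signature {name!r} not in catalog")
    mixture = {null_signature: contrib, background: 1.0 - contrib}
    counts = simulate_spectra(mixture, catalog, n, reps, rng)
    exposures = em_refit_matrix(counts, catalog.probs, max_iter=max_iter, tol=tol)
    return exposures[:, catalog.index(target)]


@dataclass
class CutoffCurve:
    """99th-percentile null-score cutoffs over a mutation-count grid."""

    null_signature: str
    counts_grid: np.ndarray
    cutoffs: np.ndarray
    reps: int = 1000
    percentile: float = DEFAULT_PERCENTILE
    focal_weight: float = DEFAULT_FOCAL_WEIGHT
    background: str = DEFAULT_BACKGROUND
    target: str = DEFAULT_TARGET
    seed: int | None = None

    def __post_init__(self) -> None:
        self.counts_grid = np.asarray(self.counts_grid, dtype=int)
        self.cutoffs = np.asarray(self.cutoffs, dtype=float)
        if self.counts_grid.shape != self.cutoffs.shape:
            raise ValueError("counts_grid and cutoffs must have equal length")
        if np.any(np.diff(self.counts_grid) <= 0):
            raise ValueError("counts_grid must be strictly increasing")
        if np.any((self.cutoffs < 0) | (self.cutoffs > 1)):
            raise ValueError("cutoffs must lie in [0, 1]")

    def value_at(self, count) -> np.ndarray | float:
        """Cutoff at arbitrary counts: linear interpolation in log(count),
        constant extrapolation beyond the grid ends."""
        count = np.asarray(count, dtype=float)
        if np.any(count < 1):
            raise ValueError("count must be >= 1")
        out = np.interp(np.log(count), np.log(self.counts_grid), self.cutoffs)
        return float(out) if out.ndim == 0 else out

    def to_dict(self) -> dict:
        return {
            "null_signature": self.null_signature,
            "counts_grid": self.counts_grid.tolist(),
            "cutoffs": self.cutoffs.tolist(),
            "reps": self.reps,
            "percentile": self.percentile,
            "focal_weight": self.focal_weight,
            "background": self.background,
            "target": self.target,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CutoffCurve":
        return cls(**d)


@dataclass
class CutoffRegression:
    """OLS cutoff surface over (mutation count, null contribution)."""

    null_signature: str
    beta: np.ndarray
    r_squared: float
    contrib_range: tuple[float, float] = (0.05, 0.95)
    count_range: tuple[int, int] = (5, 250)
    target: str = DEFAULT_TARGET
    seed: int | None = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (5,):
            raise ValueError(f"beta must have 5 coefficients, got {self.beta.shape}")

    def predict(self, count, contrib) -> np.ndarray | float:
        return predict_cutoff(self, count, contrib)

    def to_dict(self) -> dict:
        return {
            "null_signature": self.null_signature,
            "beta": self.beta.tolist(),
            "r_squared": self.r_squared,
            "contrib_range": list(self.contrib_range),
            "count_range": list(self.count_range),
            "target": self.target,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CutoffRegression":
        d = dict(d)
        d["contrib_range"] = tuple(d["contrib_range"])
        d["count_range"] = tuple(d["count_range"])
        return cls(**d)


def build_cutoff_curve(
    null_signature: str,
    catalog: SignatureCatalog,
    *,
    counts_grid=None,
    reps: int = 1000,
    seed: int = 0,
    percentile: float = DEFAULT_PERCENTILE,
    focal_weight: float = DEFAULT_FOCAL_WEIGHT,
    background: str = DEFAULT_BACKGROUND,
    target: str = DEFAULT_TARGET,
    max_iter: int = 10_000,
    tol: float = 1e-8,
) -> CutoffCurve:
    """Build the per-count cutoff curve for one null signature."""
    grid = default_counts_grid() if counts_grid is None else np.asarray(
        sorted(set(int(c) for c in counts_grid))
    )
    if np.any(grid < 1) or np.any(grid > 10_000):
        raise ValueError("counts grid must lie within [1, 10000]")
    cutoffs = np.empty(grid.size)
    for i, count in enumerate(grid):
        rng = cell_rng(seed, null_signature, focal_weight, int(count))
        scores = simulate_null_scores(
            null_signature,
            focal_weight,
            int(count),
            reps,
            catalog,
            rng,
            background=background,
            target=target,
            max_iter=max_iter,
            tol=tol,
        )
        cutoffs[i] = percentile_cutoff(scores, percentile)
    return CutoffCurve(
        null_signature=null_signature,
        counts_grid=grid,
        cutoffs=cutoffs,
        reps=reps,
        percentile=percentile,
        focal_weight=focal_weight,
        background=background,
        target=target,
        seed=seed,
    )


def build_training_surface(
    null_signature: str,
    catalog: SignatureCatalog,
    *,
    contribs=None,
    counts=None,
    reps: int = 1000,
    seed: int = 0,
    percentile: float = DEFAULT_PERCENTILE,
    background: str = DEFAULT_BACKGROUND,
    target: str = DEFAULT_TARGET,
    max_iter: int = 10_000,
    tol: float = 1e-8,
):
    """Simulated cutoffs over a (contribution, count) grid, as a DataFrame.

    Default grid: contributions 0.05–0.95 in steps of 0.05, counts 5–250 in
    steps of 5 (950 cells), one 99th-percentile cutoff per cell.
    """
    import pandas as pd

    contribs = default_surface_contribs() if contribs is None else np.asarray(contribs, dtype=float)
    counts = default_surface_counts() if counts is None else np.asarray(
        sorted(set(int(c) for c in counts))
    )
    if np.any((contribs < 0.05) | (contribs > 0.95)):
        raise ValueError("contributions must lie within [0.05, 0.95]")
    if np.any((counts < 5) | (counts > 250)):
        raise ValueError("counts must lie within [5, 250]")
    rows = []
    for contrib in contribs:
        for count in counts:
            rng = cell_rng(seed, null_signature, float(contrib), int(count))
            scores = simulate_null_scores(
                null_signature,
                float(contrib),
                int(count),
                reps,
                catalog,
                rng,
                background=background,
                target=target,
                max_iter=max_iter,
                tol=tol,
            )
            rows.append(
                {
                    "contrib": float(contrib),
                    "count": int(count),
                    "cutoff": percentile_cutoff(scores, percentile),
                }
            )
    return pd.DataFrame(rows)


def fit_cutoff_regression(surface, null_signature: str, *, seed: int | None = None) -> CutoffRegression:
    """OLS fit of the cutoff surface on (count, log count, contrib, interaction).

    R-squared is the ordinary coefficient of determination on the training
    surface, defined as 1 when the residuals vanish (e.g. a constant surface
    fitted exactly).
    """
    if len(surface) < 5 or surface[["contrib", "count"]].drop_duplicates().shape[0] < 5:
        raise ValueError("need at least 5 distinct (contrib, count) rows")
    count = surface["count"].to_numpy(dtype=float)
    contrib = surface["contrib"].to_numpy(dtype=float)
    y = surface["cutoff"].to_numpy(dtype=float)
    logc = np.log(count)
    X = np.column_stack([np.ones_like(count), count, logc, contrib, contrib * logc])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design: grid does not identify all coefficients")
    res = sm.OLS(y, X).fit()
    beta = np.asarray(res.params)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_res <= 1e-20 else 1.0 - ss_res / ss_tot
    return CutoffRegression(
        null_signature=null_signature,
        beta=beta,
        r_squared=r2,
        contrib_range=(float(contrib.min()), float(contrib.max())),
        count_range=(int(count.min()), int(count.max())),
        seed=seed,
    )


def predict_cutoff(model: CutoffRegression, count, contrib) -> np.ndarray | float:
    """Evaluate the regression cutoff, clamped into [0, 1]."""
    count = np.asarray(count, dtype=float)
    contrib = np.asarray(contrib, dtype=float)
    if np.any(count < 1):
        raise ValueError("count must be >= 1")
    if np.any((contrib < 0) | (contrib > 1)):
        raise ValueError("contrib must lie in [0, 1]")
    b = model.beta
    logc = np.log(count)
    out = np.clip(b[0] + b[1] * count + b[2] * logc + b[3] * contrib + b[4] * contrib * logc, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class Calibration:
    """Bundle of the four calibration artifacts for one detection catalog.

    ``curve_primary``/``regression_primary`` use the primary null signature
    (SBS18); the skin pair uses the skin-specific null (SBS38) and is applied
    only to skin malignancies. ``signature_names`` records the catalog the
    artifacts were built from, so a mismatched catalog is rejected at call
    time.
    """

    curve_primary: CutoffCurve
    regression_primary: CutoffRegression
    curve_skin: CutoffCurve | None = None
    regression_skin: CutoffRegression | None = None
    signature_names: tuple[str, ...] = field(default_factory=tuple)

    @property
    def target(self) -> str:
        return self.curve_primary.target

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        payload = {
            "curve_primary": self.curve_primary.to_dict(),
            "regression_primary": self.regression_primary.to_dict(),
            "curve_skin": self.curve_skin.to_dict() if self.curve_skin else None,
            "regression_skin": (
                self.regression_skin.to_dict() if self.regression_skin else None
            ),
            "signature_names": list(self.signature_names),
        }
        (directory / "calibration.json").write_text(json.dumps(payload, indent=2))

    @classmethod
    def load(cls, directory) -> "Calibration":
        payload = json.loads((Path(directory) / "calibration.json").read_text())
        return cls(
            curve_primary=CutoffCurve.from_dict(payload["curve_primary"]),
            regression_primary=CutoffRegression.from_dict(payload["regression_primary"]),
            curve_skin=(
                CutoffCurve.from_dict(payload["curve_skin"])
                if payload.get("curve_skin")
                else None
            ),
            regression_skin=(
                CutoffRegression.from_dict(payload["regression_skin"])
                if payload.get("regression_skin")
                else None
            ),
            signature_names=tuple(payload.get("signature_names", ())),
        )


def calibrate(
    catalog: SignatureCatalog,
    *,
    null_primary: str = "SBS18",
    null_skin: str | None = "SBS38",
    seed: int = 0,
    curve_reps: int = 1000,
    curve_counts=None,
    surface_reps: int = 1000,
    surface_contribs=None,
    surface_counts=None,
    target: str = DEFAULT_TARGET,
    max_iter: int = 10_000,
    tol: float = 1e-8,
) -> Calibration:
    """Build curves and regression surfaces for the primary and skin nulls."""

    def _one(null_sig: str) -> tuple[CutoffCurve, CutoffRegression]:
        curve = build_cutoff_curve(
            null_sig,
            catalog,
            counts_grid=curve_counts,
            reps=curve_reps,
            seed=seed,
            target=target,
            max_iter=max_iter,
            tol=tol,
        )
        surface = build_training_surface(
            null_sig,
            catalog,
            contribs=surface_contribs,
            counts=surface_counts,
            reps=surface_reps,
            seed=seed,
            target=target,
            max_iter=max_iter,
            tol=tol,
        )
        reg = fit_cutoff_regression(surface, null_sig, seed=seed)
        return curve, reg

    curve18, reg18 = _one(null_primary)
    curve38 = reg38 = None
    if null_skin is not None:
        curve38, reg38 = _one(null_skin)
    return Calibration(
        curve_primary=curve18,
        regression_primary=reg18,
        curve_skin=curve38,
        regression_skin=reg38,
        signature_names=catalog.names,
    )
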