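"""Per-sample ganciclovir-signature calls and cohort-level error control.

Decision logic per sample:

1. Samples with fewer than 10 mutations are not evaluable (refits on such
   sparse spectra assign uniformly low scores to every signature, so the
   1% FDR threshold is meaningless there).
2. The sample's score is its fitted exposure of the focal signature.
3. The applicable cutoff depends on how much CA>AA signal the sample has:
   with more than 10 CA>AA mutations, the null contribution is estimated by
   the CA>AA fraction and the regression surface prices the cutoff at
   (count, contribution); otherwise the dominant-process (0.95-mixture)
   curve applies at the sample's count.
4. A sample is positive when its score exceeds the SBS18-null cutoff, and —
   for skin malignancies only — also the SBS38-null cutoff.

Cohort error control: a chi-square test compares each evaluable sample's
observed focal-mutation frequency (score x count) against the expectation
under the cohort-wide average spectrum (simulated refits), with
Benjamini-Hochberg adjustment across evaluable samples; a permutation
scheme (replace every spectrum by a draw from the cohort average, repeat
the calls, 10 times) estimates the cohort-wide FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .calibration import Calibration, calibrate, cell_rng
from .catalog_io import (
    SignatureCatalog,
    dedup_latest_sample,
    read_mutation_table,
    read_signature_catalog,
)
from .channels import CA_AA_CHANNELS
from .refit import em_refit_matrix
from .spectrum import CaAaSummary, Spectrum96, build_spectrum, ca_aa_fraction, cohort_average_spectrum

logger = logging.getLogger(__name__)

MIN_EVALUABLE_MUTATIONS = 10
MIN_CA_AA_FOR_REGRESSION = 10  # regression path requires strictly more than this
DEFAULT_SKIN_GROUPS = ("SKIN",)


@dataclass
class SampleCall:
    """Detection record for one sample."""

    sample_id: str
    n: int
    gcv_score: float
    ca_aa: CaAaSummary
    cutoff_sbs18: float
    cutoff_sbs38: float | None
    evaluable: bool
    positive: bool
    p_value: float | None = None
    p_adjusted: float | None = None


@dataclass
class CohortFdrEstimate:
    """Cohort-wide FDR from average-spectrum permutations."""

    permutation_positive_counts: list[int]
    observed_positive_count: int
    estimated_fdr: float = field(init=False)

    def __post_init__(self) -> None:
        self.estimated_fdr = float(
            np.mean(self.permutation_positive_counts)
            / max(self.observed_positive_count, 1)
        )


def _check_catalog(catalog: SignatureCatalog, calibration: Calibration) -> None:
    if calibration.signature_names and tuple(calibration.signature_names) != catalog.names:
        raise ValueError(
            "calibration was built from a different signature catalog "
            f"({calibration.signature_names} != {catalog.names})"
        )


def _call_matrix(
    counts: np.ndarray,
    skin: np.ndarray,
    catalog: SignatureCatalog,
    calibration: Calibration,
    *,
    max_iter: int = 10_000,
    tol: float = 1e-8,
) -> dict[str, np.ndarray]:
    """Vectorized decision logic over an (m, 96) count matrix.

    ``skin`` is a boolean mask of skin-malignancy samples. Returns per-sample
    arrays: n, score, ca_count, ca_fraction, cutoff18, cutoff38 (NaN where
    not applicable), evaluable, positive.
    """
    _check_catalog(catalog, calibration)
    counts = np.asarray(counts, dtype=float)
    m = counts.shape[0]
    n = counts.sum(axis=1)
    evaluable = n >= MIN_EVALUABLE_MUTATIONS

    score = np.zeros(m)
    fittable = n >= 1
    if fittable.any():
        exposures = em_refit_matrix(
            counts[fittable], catalog.probs, max_iter=max_iter, tol=tol
        )
        score[fittable] = exposures[:, catalog.index(calibration.target)]

    ca_count = counts[:, list(CA_AA_CHANNELS)].sum(axis=1)
    ca_fraction = np.divide(ca_count, n, out=np.zeros(m), where=n > 0)

    cutoff18 = np.full(m, np.nan)
    cutoff38 = np.full(m, np.nan)
    use_reg = evaluable & (ca_count > MIN_CA_AA_FOR_REGRESSION)
    use_curve = evaluable & ~use_reg
    def _reg_predict(model, ns, fracs):
        # the surface is trained on bounded (count, contrib) grids; beyond
        # them the fitted linear terms are meaningless, so inputs are clamped
        # to the trained ranges (constant extrapolation, like the curve)
        ns = np.clip(ns, model.count_range[0], model.count_range[1])
        fracs = np.clip(fracs, model.contrib_range[0], model.contrib_range[1])
        return model.predict(ns, fracs)

    if use_reg.any():
        cutoff18[use_reg] = _reg_predict(
            calibration.regression_primary, n[use_reg], ca_fraction[use_reg]
        )
    if use_curve.any():
        cutoff18[use_curve] = calibration.curve_primary.value_at(n[use_curve])
    skin_eval = skin & evaluable
    if skin_eval.any():
        if calibration.regression_skin is None or calibration.curve_skin is None:
            raise ValueError("cohort contains skin samples but no skin calibration")
        reg_mask = skin_eval & use_reg
        curve_mask = skin_eval & use_curve
        if reg_mask.any():
            cutoff38[reg_mask] = _reg_predict(
                calibration.regression_skin, n[reg_mask], ca_fraction[reg_mask]
            )
        if curve_mask.any():
            cutoff38[curve_mask] = calibration.curve_skin.value_at(n[curve_mask])

    positive = evaluable & (score > cutoff18)
    positive[skin] &= score[skin] > np.where(
        np.isnan(cutoff38[skin]), np.inf, cutoff38[skin]
    )
    return {
        "n": n.astype(int),
        "score": score,
        "ca_count": ca_count.astype(int),
        "ca_fraction": ca_fraction,
        "cutoff18": cutoff18,
        "cutoff38": cutoff38,
        "evaluable": evaluable,
        "positive": positive,
    }


def call_sample(
    spectrum: Spectrum96,
    cancer_group: str,
    catalog: SignatureCatalog,
    calibration: Calibration,
    *,
    sample_id: str = "",
    skin_groups: Sequence[str] = DEFAULT_SKIN_GROUPS,
    max_iter: int = 10_000,
    tol: float = 1e-8,
) -> SampleCall:
    """Apply the detection decision logic to one sample."""
    skin = np.array([cancer_group in set(skin_groups)])
    res = _call_matrix(
        spectrum.counts[None, :], skin, catalog, calibration, max_iter=max_iter, tol=tol
    )
    is_skin = bool(skin[0])
    cutoff38 = res["cutoff38"][0]
    return SampleCall(
        sample_id=sample_id,
        n=int(res["n"][0]),
        gcv_score=float(res["score"][0]),
        ca_aa=ca_aa_fraction(spectrum),
        cutoff_sbs18=float(res["cutoff18"][0]),
        cutoff_sbs38=float(cutoff38) if is_skin and not np.isnan(cutoff38) else None,
        evaluable=bool(res["evaluable"][0]),
        positive=bool(res["positive"][0]),
    )


def chisq_pvalue(call: SampleCall, expected_score: float) -> float:
    """1-df chi-square p-value of a sample's focal-mutation frequency.

    Observed categories are (score*n, (1-score)*n); expected categories are
    (expected_score*n, (1-expected_score)*n). Category totals are used as-is
    (frequencies, not rounded counts).
    """
    if not call.evaluable:
        raise ValueError("chi-square test requires an evaluable sample")
    if not (0 < expected_score < 1):
        raise ValueError(f"expected_score must be in (0, 1), got {expected_score}")
    n = call.n
    observed = np.array([call.gcv_score * n, (1 - call.gcv_score) * n])
    expected = np.array([expected_score * n, (1 - expected_score) * n])
    if np.any(expected < 1e-12):
        raise ValueError("degenerate expectation")
    stat = float(np.sum((observed - expected) ** 2 / expected))
    return float(stats.chi2.sf(stat, df=1))


def expected_score_from_cohort(
    avg_spectrum: np.ndarray,
    n: int,
    catalog: SignatureCatalog,
    *,
    reps: int = 1000,
    rng: np.random.Generator,
    target: str = "GCVsig",
    max_iter: int = 10_000,
    tol: float = 1e-8,
) -> float:
    """Expected focal score at count ``n`` under the cohort-average spectrum.

    Mean fitted score over ``reps`` multinomial draws of size ``n`` from the
    average spectrum, each refitted against the catalog.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    counts = rng.multinomial(n, np.asarray(avg_spectrum, dtype=float), size=reps)
    exposures = em_refit_matrix(counts, catalog.probs, max_iter=max_iter, tol=tol)
    return float(exposures[:, catalog.index(target)].mean())


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def cohort_permutation_fdr(
    spectra: Sequence[Spectrum96],
    cancer_groups: Sequence[str],
    catalog: SignatureCatalog,
    calibration: Calibration,
    *,
    repeats: int = 10,
    rng: np.random.Generator,
    skin_groups: Sequence[str] = DEFAULT_SKIN_GROUPS,
    observed_positive_count: int | None = None,
    max_iter: int = 10_000,
    tol: float = 1e-8,
) -> CohortFdrEstimate:
    """Cohort-wide FDR by refitting average-spectrum permutations.

    Per repeat, every sample's mutation count is preserved but its spectrum
    is replaced by a multinomial draw from the cohort-wide average; the full
    decision logic is rerun and positives counted.
    """
    counts = np.stack([s.counts for s in spectra])
    skin = np.array([g in set(skin_groups) for g in cancer_groups])
    n = counts.sum(axis=1)
    if not np.any(n >= MIN_EVALUABLE_MUTATIONS):
        raise ValueError("no evaluable samples in cohort")
    avg = cohort_average_spectrum(list(spectra))

    if observed_positive_count is None:
        observed = _call_matrix(
            counts, skin, catalog, calibration, max_iter=max_iter, tol=tol
        )
        observed_positive_count = int(observed["positive"].sum())

    fittable = n >= 1
    perm_counts: list[int] = []
    for _ in range(repeats):
        permuted = np.zeros_like(counts)
        permuted[fittable] = np.stack(
            [rng.multinomial(int(ni), avg) for ni in n[fittable]]
        )
        res = _call_matrix(
            permuted, skin, catalog, calibration, max_iter=max_iter, tol=tol
        )
        perm_counts.append(int(res["positive"].sum()))
    return CohortFdrEstimate(
        permutation_positive_counts=perm_counts,
        observed_positive_count=observed_positive_count,
    )


@dataclass
class RunConfig:
    """Configuration of a cohort run."""

    seed: int = 0
    expected_reps: int = 1000
    fdr_repeats: int = 10
    skin_groups: tuple[str, ...] = DEFAULT_SKIN_GROUPS
    columns: dict | None = None
    target: str = "GCVsig"
    max_iter: int = 10_000
    tol: float = 1e-8

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(open(path)) or {}
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in raw.items() if k in known}
        if "skin_groups" in kwargs:
            kwargs["skin_groups"] = tuple(kwargs["skin_groups"])
        return cls(**kwargs)


def run_cohort(
    mutations_path,
    catalog_path,
    calibration: Calibration | str,
    *,
    out_path=None,
    config: RunConfig | None = None,
    reference=None,
) -> tuple[pd.DataFrame, CohortFdrEstimate]:
    """End-to-end cohort driver: read, dedup, call, test, adjust, write.

    Returns the calls table (sorted by score descending) and the cohort
    permutation-FDR estimate. ``calibration`` may be a loaded bundle or a
    directory containing a serialized one.
    """
    config = config or RunConfig()
    if not isinstance(calibration, Calibration):
        calibration = Calibration.load(calibration)
    catalog = read_signature_catalog(catalog_path)
    records = read_mutation_table(mutations_path, columns=config.columns)
    records = dedup_latest_sample(records)
    if not records:
        raise ValueError("empty cohort after filtering")

    by_sample: dict[str, list] = {}
    group_of: dict[str, str] = {}
    for r in records:
        by_sample.setdefault(r.sample_id, []).append(r)
        group_of[r.sample_id] = r.cancer_group
    sample_ids = sorted(by_sample)
    spectra = [build_spectrum(by_sample[s], reference=reference) for s in sample_ids]
    groups = [group_of[s] for s in sample_ids]

    counts = np.stack([s.counts for s in spectra])
    skin = np.array([g in set(config.skin_groups) for g in groups])
    res = _call_matrix(
        counts, skin, catalog, calibration, max_iter=config.max_iter, tol=config.tol
    )

    # expected score under the cohort average, shared across samples with the
    # same mutation count (the expectation depends only on n)
    avg = cohort_average_spectrum(spectra)
    evaluable = res["evaluable"]
    expected_by_n: dict[int, float] = {}
    for ni in sorted(set(res["n"][evaluable].tolist())):
        rng = cell_rng(config.seed, "expected-score", 0.0, ni)
        expected_by_n[ni] = expected_score_from_cohort(
            avg,
            ni,
            catalog,
            reps=config.expected_reps,
            rng=rng,
            target=config.target,
            max_iter=config.max_iter,
            tol=config.tol,
        )

    p_values = np.full(len(sample_ids), np.nan)
    for i in np.nonzero(evaluable)[0]:
        expected = expected_by_n[int(res["n"][i])]
        expected = min(max(expected, 1e-10), 1 - 1e-10)
        call = SampleCall(
            sample_id=sample_ids[i],
            n=int(res["n"][i]),
            gcv_score=float(res["score"][i]),
            ca_aa=ca_aa_fraction(spectra[i]),
            cutoff_sbs18=float(res["cutoff18"][i]),
            cutoff_sbs38=None,
            evaluable=True,
            positive=bool(res["positive"][i]),
        )
        p_values[i] = chisq_pvalue(call, expected)
    p_adj = np.full(len(sample_ids), np.nan)
    if evaluable.any():
        p_adj[evaluable] = bh_adjust(p_values[evaluable])
        logger.info(
            "BH correction over m=%d evaluable samples", int(evaluable.sum())
        )

    calls = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "n": res["n"],
            "gcv_score": res["score"],
            "ca_aa_fraction": res["ca_fraction"],
            "cutoff_sbs18": res["cutoff18"],
            "cutoff_sbs38": res["cutoff38"],
            "evaluable": res["evaluable"],
            "positive": res["positive"],
            "p_value": p_values,
            "p_adjusted": p_adj,
        }
    ).sort_values(["gcv_score", "sample_id"], ascending=[False, True], kind="mergesort")
    calls = calls.reset_index(drop=True)

    fdr = cohort_permutation_fdr(
        spectra,
        groups,
        catalog,
        calibration,
        repeats=config.fdr_repeats,
        rng=np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(0xFD2,))
        ),
        skin_groups=config.skin_groups,
        observed_positive_count=int(res["positive"].sum()),
        max_iter=config.max_iter,
        tol=config.tol,
    )

    if out_path is not None:
        calls.to_csv(out_path, sep="\t", index=False, float_format="%.6g")
    return calls, fdr


class GcvSignatureDetector(BaseEstimator):
    """Scikit-learn style detector for the ganciclovir signature.

    ``fit`` runs the simulation calibration (cutoff curves and regression
    surfaces) for the configured catalog; ``predict`` applies the decision
    logic to an (m, 96) matrix of channel counts and returns boolean calls.
    ``decision_function`` returns the margin score - primary cutoff (NaN for
    non-evaluable samples), and ``score_samples`` the raw focal exposures.
    """

    def __init__(
        self,
        catalog: SignatureCatalog | None = None,
        *,
        null_primary: str = "SBS18",
        null_skin: str | None = "SBS38",
        target: str = "GCVsig",
        curve_reps: int = 1000,
        curve_counts=None,
        surface_reps: int = 1000,
        surface_contribs=None,
        surface_counts=None,
        skin_groups: tuple[str, ...] = DEFAULT_SKIN_GROUPS,
        max_iter: int = 10_000,
        tol: float = 1e-8,
        random_state: int = 0,
    ) -> None:
        self.catalog = catalog
        self.null_primary = null_primary
        self.null_skin = null_skin
        self.target = target
        self.curve_reps = curve_reps
        self.curve_counts = curve_counts
        self.surface_reps = surface_reps
        self.surface_contribs = surface_contribs
        self.surface_counts = surface_counts
        self.skin_groups = skin_groups
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X=None, y=None) -> "GcvSignatureDetector":
        if self.catalog is None:
            raise ValueError("a SignatureCatalog is required")
        self.calibration_ = calibrate(
            self.catalog,
            null_primary=self.null_primary,
            null_skin=self.null_skin,
            seed=self.random_state,
            curve_reps=self.curve_reps,
            curve_counts=self.curve_counts,
            surface_reps=self.surface_reps,
            surface_contribs=self.surface_contribs,
            surface_counts=self.surface_counts,
            target=self.target,
            max_iter=self.max_iter,
            tol=self.tol,
        )
        self.curve_primary_ = self.calibration_.curve_primary
        self.regression_primary_ = self.calibration_.regression_primary
        self.curve_skin_ = self.calibration_.curve_skin
        self.regression_skin_ = self.calibration_.regression_skin
        self.n_features_in_ = 96
        return self

    def _results(self, X, cancer_groups=None) -> dict[str, np.ndarray]:
        if not hasattr(self, "calibration_"):
            raise ValueError("detector is not fitted; call fit() first")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if cancer_groups is None:
            skin = np.zeros(X.shape[0], dtype=bool)
        else:
            skin = np.array([g in set(self.skin_groups) for g in cancer_groups])
        return _call_matrix(
            X, skin, self.catalog, self.calibration_, max_iter=self.max_iter, tol=self.tol
        )

    def predict(self, X, cancer_groups=None) -> np.ndarray:
        return self._results(X, cancer_groups)["positive"]

    def decision_function(self, X, cancer_groups=None) -> np.ndarray:
        res = self._results(X, cancer_groups)
        return res["score"] - res["cutoff18"]

    def score_samples(self, X) -> np.ndarray:
        return self._results(X)["score"]
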