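"""Signature refitting: exposure estimation under a fixed signature catalog.

Given an observed 96-channel spectrum and a catalog of known signatures, the
refit estimates the exposure vector e (non-negative, summing to 1) that
maximizes the multinomial log-likelihood

    L(e) = sum_c counts_c * log( sum_k e_k * P_ck )

by expectation-maximization with uniform initialization. This is the
classical mixture-of-multinomials refit (equivalently, KL-objective NMF with
fixed signatures). The fit is deterministic; the exposure of the focal
signature (named ``GCVsig`` by default) is the per-sample "contribution
score" used throughout the detection pipeline.

An optional Dirichlet(alpha) pseudo-count prior is exposed; the default
alpha = 1 is the plain maximum-likelihood estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .catalog_io import SignatureCatalog
from .channels import CHANNELS, N_CHANNELS
from .spectrum import Spectrum96

_TINY = 1e-300


@dataclass(frozen=True)
class ExposureFit:
    """Result of refitting one spectrum against a catalog."""

    names: tuple[str, ...]
    exposures: np.ndarray
    log_likelihood: float
    n: int

    def get(self, name: str, default: float = 0.0) -> float:
        """Exposure of a named signature; ``default`` if absent."""
        try:
            return float(self.exposures[self.names.index(name)])
        except ValueError:
            return default

    def __getitem__(self, name: str) -> float:
        return float(self.exposures[self.names.index(name)])

    def as_dict(self) -> dict[str, float]:
        return {n: float(e) for n, e in zip(self.names, self.exposures)}


def _validate_mixture(
    mixture: Mapping[str, float], catalog: SignatureCatalog
) -> np.ndarray:
    weights = np.zeros(catalog.n_signatures)
    for name, w in mixture.items():
        if name not in catalog:
            raise KeyError(f"signature {name!r} not in catalog")
        if w < 0 or w > 1:
            raise ValueError(f"weight for {name!r} must be in [0,1], got {w}")
        weights[catalog.index(name)] = w
    if abs(weights.sum() - 1.0) > 1e-8:
        raise ValueError(f"mixture weights must sum to 1, got {weights.sum()}")
    return weights


def mixture_probabilities(
    mixture: Mapping[str, float], catalog: SignatureCatalog
) -> np.ndarray:
    """96-channel probability vector of a signature mixture."""
    return catalog.probs @ _validate_mixture(mixture, catalog)


def em_refit_matrix(
    counts: np.ndarray,
    probs: np.ndarray,
    *,
    max_iter: int = 10_000,
    tol: float = 1e-8,
    alpha: float = 1.0,
) -> np.ndarray:
    """Vectorized EM refit of many spectra at once.

    ``counts`` is (m, 96); ``probs`` is the (96, K) catalog matrix. Returns
    the (m, K) exposure matrix. Rows converge independently: a row leaves the
    active set once its maximum absolute exposure change drops below ``tol``.

    The update is the standard multiplicative EM step
    ``e_k <- e_k * sum_c counts_c P_ck / mix_c / n`` which never decreases
    the likelihood; with a Dirichlet(alpha) prior the responsibilities gain
    ``alpha - 1`` pseudo-counts per signature (clipped at zero).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != N_CHANNELS:
        raise ValueError(f"counts must be (m, 96), got {counts.shape}")
    m, _ = counts.shape
    k = probs.shape[1]
    totals = counts.sum(axis=1)
    if np.any(totals < 1):
        raise ValueError("unfittable: every spectrum needs at least one mutation")
    pseudo = alpha - 1.0

    exposures = np.full((m, k), 1.0 / k)
    active = np.arange(m)
    for _ in range(max_iter):
        e = exposures[active]
        mix = e @ probs.T  # (a, 96)
        ratio = np.divide(
            counts[active],
            np.maximum(mix, _TINY),
            out=np.zeros_like(mix),
            where=counts[active] > 0,
        )
        e_new = e * (ratio @ probs)
        if pseudo != 0.0:
            e_new = np.maximum(e_new + pseudo, 0.0)
        e_new /= e_new.sum(axis=1, keepdims=True)
        delta = np.abs(e_new - e).max(axis=1)
        exposures[active] = e_new
        still = delta >= tol
        if not still.any():
            break
        active = active[still]
    return exposures


def multinomial_log_likelihood(counts: np.ndarray, channel_probs: np.ndarray) -> float:
    """Log-likelihood (up to the multinomial coefficient) of counts under
    per-channel probabilities."""
    counts = np.asarray(counts, dtype=float)
    mask = counts > 0
    return float(
        np.sum(counts[mask] * np.log(np.maximum(channel_probs[mask], _TINY)))
    )


def fit_exposures(
    spectrum: Spectrum96,
    catalog: SignatureCatalog,
    *,
    max_iter: int = 10_000,
    tol: float = 1e-8,
    alpha: float = 1.0,
) -> ExposureFit:
    """Maximum-likelihood exposures of one spectrum under a catalog.

    Raises ``ValueError`` for an empty (unfittable) spectrum.
    """
    if spectrum.total == 0:
        raise ValueError("unfittable: spectrum has no mutations")
    if tuple(catalog.channels) != CHANNELS:
        raise ValueError("catalog channels do not match canonical SBS96 order")
    exposures = em_refit_matrix(
        spectrum.counts[None, :], catalog.probs, max_iter=max_iter, tol=tol, alpha=alpha
    )[0]
    ll = multinomial_log_likelihood(spectrum.counts, catalog.probs @ exposures)
    return ExposureFit(
        names=catalog.names,
        exposures=exposures,
        log_likelihood=ll,
        n=spectrum.total,
    )


def simulate_spectrum(
    mixture: Mapping[str, float],
    catalog: SignatureCatalog,
    n: int,
    rng: np.random.Generator,
) -> Spectrum96:
    """One multinomial draw of ``n`` mutations from a signature mixture."""
    if n < 0:
        raise ValueError(f"n must be non-negative, got {n}")
    p = mixture_probabilities(mixture, catalog)
    return Spectrum96(rng.multinomial(n, p))


def simulate_spectra(
    mixture: Mapping[str, float],
    catalog: SignatureCatalog,
    n: int,
    reps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """``reps`` independent multinomial draws, as a (reps, 96) count matrix."""
    if n < 0:
        raise ValueError(f"n must be non-negative, got {n}")
    p = mixture_probabilities(mixture, catalog)
    return rng.multinomial(n, p, size=reps)


class SignatureRefitter(TransformerMixin, BaseEstimator):
    """Scikit-learn style transformer mapping spectra to exposure fractions.

    ``transform`` takes an (m, 96) matrix of channel counts and returns the
    (m, K) matrix of per-sample signature exposures under the fixed catalog.
    The estimator is stateless apart from validation; ``fit`` records the
    catalog's signature names.
    """

    def __init__(
        self,
        catalog: SignatureCatalog | None = None,
        *,
        max_iter: int = 10_000,
        tol: float = 1e-8,
        alpha: float = 1.0,
    ) -> None:
        self.catalog = catalog
        self.max_iter = max_iter
        self.tol = tol
        self.alpha = alpha

    def fit(self, X=None, y=None) -> "SignatureRefitter":
        if self.catalog is None:
            raise ValueError("a SignatureCatalog is required")
        self.signature_names_ = self.catalog.names
        self.components_ = self.catalog.probs.T.copy()
        self.n_features_in_ = N_CHANNELS
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "signature_names_"):
            self.fit()
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        return em_refit_matrix(
            X, self.catalog.probs, max_iter=self.max_iter, tol=self.tol, alpha=self.alpha
        )
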