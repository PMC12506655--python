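"""Downstream population-genetic estimators fed by genotype likelihoods.

These are the quantities on which mapping bias is actually measured:
maximum-likelihood allele frequencies under Hardy-Weinberg equilibrium
(HWE), per-site f2 differentiation, and supervised admixture proportions
under the Pritchard-Stephens-Donnelly (PSD) model with fixed source
frequencies.  All estimators consume genotype-likelihood triplets — default
or bias-corrected — so the two likelihood models can be compared on equal
footing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from biasgl.genolik import GLTriplet
from biasgl.snp_panel import SnpSite

_EPS = 1e-12


@dataclass(frozen=True)
class FrequencyEstimate:
    """Per-site ML reference-allele frequency from genotype likelihoods."""

    site: Optional[SnpSite]
    f_ref: float
    n_eff: int
    iterations: int
    flat_flag: bool = False
    converged: bool = True


@dataclass(frozen=True)
class AdmixtureResult:
    """Per-individual admixture proportions over K fixed source clusters."""

    individual: str
    q: tuple[float, ...]
    loglik: float
    iterations: int
    flat_flag: bool = False
    converged: bool = True


def _as_gl_array(gls: Union[Sequence[GLTriplet], np.ndarray]) -> np.ndarray:
    """Normalize GL input to an (n, 3) array of relative likelihoods."""
    if isinstance(gls, np.ndarray):
        arr = np.asarray(gls, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError(f"expected an (n, 3) array, got shape {arr.shape}")
        return arr
    return np.asarray([t.normalized() for t in gls], dtype=float)


def _hwe(f: float) -> np.ndarray:
    """HWE genotype probabilities (RR, RA, AA) at reference frequency f."""
    return np.array([f * f, 2.0 * f * (1.0 - f), (1.0 - f) * (1.0 - f)])


def estimate_af_ml(
    gls: Union[Sequence[GLTriplet], np.ndarray],
    site: Optional[SnpSite] = None,
    tol: float = 1e-6,
    max_iter: int = 200,
    f_init: float = 0.5,
) -> FrequencyEstimate:
    """ML reference-allele frequency at one site by EM over individuals.

    Maximizes ``sum_i log sum_g GL_ig * HWE(g | f)`` over ``f in [0, 1]``.
    E-step: posterior genotype weights per individual; M-step: ``f`` becomes
    the mean expected reference-allele dosage divided by 2.  Individuals
    with uninformative (constant) likelihood triplets do not move the
    estimate; if no individual is informative the likelihood is flat and
    the initialization is returned flagged.
    """
    arr = _as_gl_array(gls)
    if arr.shape[0] < 1:
        raise ValueError("need at least one individual")
    informative = ~np.all(np.isclose(arr, arr[:, [0]]), axis=1)
    n_eff = int(informative.sum())
    if n_eff == 0:
        return FrequencyEstimate(site, f_init, 0, 0, flat_flag=True)
    # flat triplets contribute exactly the current f to the M-step mean, so
    # dropping them leaves the maximizer unchanged and speeds convergence
    arr = arr[informative]

    f = f_init
    dosage_weights = np.array([2.0, 1.0, 0.0])
    iterations = 0
    for iterations in range(1, max_iter + 1):
        post = arr * _hwe(f)[None, :]
        denom = post.sum(axis=1, keepdims=True)
        denom = np.where(denom < _EPS, _EPS, denom)
        post = post / denom
        f_new = float((post @ dosage_weights).mean() / 2.0)
        delta = abs(f_new - f)
        f = f_new
        if delta < tol:
            return FrequencyEstimate(site, f, n_eff, iterations)
    return FrequencyEstimate(site, f, n_eff, iterations, converged=False)


def af_loglik(gls: Union[Sequence[GLTriplet], np.ndarray], f: float) -> float:
    """Log-likelihood of reference frequency ``f`` given per-individual GLs."""
    arr = _as_gl_array(gls)
    per_ind = arr @ _hwe(f)
    return float(np.log(np.maximum(per_ind, _EPS)).sum())


def f2_per_site(
    f1: float,
    f2_: float,
    n1: Optional[int] = None,
    n2: Optional[int] = None,
) -> float:
    """Per-site f2 differentiation between two populations.

    Plain mode (default) returns the squared frequency difference
    ``(f1 - f2)**2``.  When both sample sizes (in chromosomes) are given,
    the finite-sample bias ``E[p_hat(1-p_hat)]`` of each frequency estimate
    is removed by subtracting ``f(1-f)/(n-1)`` per population, the unbiased
    moment correction.
    """
    for name, f in (("f1", f1), ("f2", f2_)):
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {f}")
    stat = (f1 - f2_) ** 2
    if n1 is None and n2 is None:
        return stat
    if n1 is None or n2 is None:
        raise ValueError("give both sample sizes or neither")
    if n1 <= 1 or n2 <= 1:
        raise ValueError("sample-size correction requires n > 1 in both populations")
    return stat - f1 * (1.0 - f1) / (n1 - 1) - f2_ * (1.0 - f2_) / (n2 - 1)


def admixture_loglik(gl_arr: np.ndarray, sources: np.ndarray, q: np.ndarray) -> float:
    """Log-likelihood of admixture proportions ``q`` for one individual.

    ``gl_arr`` is (L, 3); ``sources`` is (L, K) reference-allele frequencies;
    the individual's per-site reference frequency is ``p = sources @ q`` and
    genotypes follow HWE at ``p``.
    """
    p = np.clip(sources @ q, _EPS, 1.0 - _EPS)
    hwe = np.stack([p * p, 2.0 * p * (1.0 - p), (1.0 - p) ** 2], axis=1)
    per_site = (gl_arr * hwe).sum(axis=1)
    return float(np.log(np.maximum(per_site, _EPS)).sum())


def estimate_admixture_em(
    gls: Union[Sequence[GLTriplet], np.ndarray],
    sources: np.ndarray,
    individual: str = "",
    tol: float = 1e-6,
    max_iter: int = 200,
) -> AdmixtureResult:
    """Supervised PSD admixture proportions for one individual by EM.

    Model: each of the individual's two allele copies at site ``l`` descends
    from cluster ``k`` with probability ``q_k`` and is the reference allele
    with probability ``f_kl`` (the fixed source frequency), so the
    individual's genotype is HWE at ``p_l = sum_k q_k f_kl``.  The E-step
    combines the posterior expected reference/alternative allele dosage
    (from the GLs and HWE at the current ``p_l``) with the per-copy cluster
    responsibilities; the M-step averages the expected cluster assignments
    over all ``2L`` copies.  Initialization is uniform, ``q = (1/K, ...)``,
    making the procedure deterministic.

    When the source frequencies are identical across clusters at every site
    the likelihood is flat in ``q``; the initialization is returned flagged.
    """
    gl_arr = _as_gl_array(gls)
    sources = np.asarray(sources, dtype=float)
    if sources.ndim != 2 or sources.shape[0] != gl_arr.shape[0]:
        raise ValueError(
            f"sources must be (n_sites, K); got {sources.shape} for {gl_arr.shape[0]} sites"
        )
    if np.any((sources < 0) | (sources > 1)):
        raise ValueError("source frequencies must lie in [0, 1]")
    n_sites, k = sources.shape
    if k < 2:
        raise ValueError("need at least K=2 source clusters")
    q = np.full(k, 1.0 / k)
    if np.allclose(sources, sources[:, [0]]):
        return AdmixtureResult(
            individual, tuple(q), admixture_loglik(gl_arr, sources, q), 0, flat_flag=True
        )

    f_src = np.clip(sources, _EPS, 1.0 - _EPS)
    dosage_weights = np.array([2.0, 1.0, 0.0])
    iterations = 0
    for iterations in range(1, max_iter + 1):
        p = np.clip(f_src @ q, _EPS, 1.0 - _EPS)
        hwe = np.stack([p * p, 2.0 * p * (1.0 - p), (1.0 - p) ** 2], axis=1)
        post = gl_arr * hwe
        denom = post.sum(axis=1, keepdims=True)
        post = post / np.where(denom < _EPS, _EPS, denom)
        # Expected reference / alternative allele-copy counts per site.
        a_ref = post @ dosage_weights          # in [0, 2]
        a_alt = 2.0 - a_ref
        # Per-copy cluster responsibilities for a ref and an alt copy.
        resp_ref = (q[None, :] * f_src) / p[:, None]
        resp_alt = (q[None, :] * (1.0 - f_src)) / (1.0 - p)[:, None]
        counts = (a_ref[:, None] * resp_ref + a_alt[:, None] * resp_alt).sum(axis=0)
        q_new = counts / (2.0 * n_sites)
        q_new = q_new / q_new.sum()
        delta = float(np.abs(q_new - q).max())
        q = q_new
        if delta < tol:
            return AdmixtureResult(
                individual, tuple(q), admixture_loglik(gl_arr, sources, q), iterations
            )
    return AdmixtureResult(
        individual, tuple(q), admixture_loglik(gl_arr, sources, q), iterations,
        converged=False,
    )


def mean_population_admixture(results: Sequence[AdmixtureResult]) -> tuple[float, ...]:
    """Arithmetic mean of per-individual proportions; the population estimate."""
    if not results:
        raise ValueError("need at least one individual")
    k = len(results[0].q)
    if any(len(r.q) != k for r in results):
        raise ValueError("inconsistent number of clusters across individuals")
    mean = np.mean([r.q for r in results], axis=0)
    mean = mean / mean.sum()
    return tuple(float(x) for x in mean)
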