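import numpy as np
import pytest

from biasgl.genolik import base_prob, phred_to_error
from biasgl.reads import ReadObservation
from biasgl.snp_panel import SnpPanel, SnpSite


@pytest.fixture
def site_ac() -> SnpSite:
    return SnpSite("chr1", 100, "A", "C")


@pytest.fixture
def panel3() -> SnpPanel:
    return SnpPanel(
        (
            SnpSite("chr1", 100, "A", "C"),
            SnpSite("chr1", 250, "G", "T"),
            SnpSite("chr2", 50, "T", "A"),
        )
    )


def obs(base: str, q: int = 30, mapq: int = 60, read_id: str = "r", modified: bool = False) -> ReadObservation:
    return ReadObservation(
        read_id=read_id, base=base, base_quality=q, mapping_quality=mapq, is_modified=modified
    )


@pytest.fixture
def make_obs():
    return obs


# --- independent oracles -------------------------------------------------

def oracle_gl(bases, quals, site: SnpSite, r: float = 0.5):
    """Scalar-product genotype-likelihood oracle, written independently of
    the log-space implementation: plain floating products."""
    l_rr = l_ra = l_aa = 1.0
    for b, q in zip(bases, quals):
        e = phred_to_error(q)
        l_rr *= base_prob(b, site.ref_allele, e)
        l_aa *= base_prob(b, site.alt_allele, e)
        l_ra *= r * base_prob(b, site.ref_allele, e) + (1 - r) * base_prob(b, site.alt_allele, e)
    return l_rr, l_ra, l_aa


def grid_af(gl_arr: np.ndarray, n_points: int = 1001) -> float:
    """Grid-search ML reference frequency oracle."""
    grid = np.linspace(0.0, 1.0, n_points)
    best, best_ll = 0.0, -np.inf
    for f in grid:
        hwe = np.array([f * f, 2 * f * (1 - f), (1 - f) ** 2])
        per = gl_arr @ hwe
        ll = float(np.log(np.maximum(per, 1e-300)).sum())
        if ll > best_ll:
            best, best_ll = f, ll
    return best


def grid_admixture_k2(gl_arr: np.ndarray, sources: np.ndarray, n_points: int = 1001) -> float:
    """Grid-search oracle for the S3 proportion in a K=2 supervised fit."""
    grid = np.linspace(0.0, 1.0, n_points)
    best, best_ll = 0.0, -np.inf
    for q3 in grid:
        p = np.clip((1 - q3) * sources[:, 0] + q3 * sources[:, 1], 1e-12, 1 - 1e-12)
        hwe = np.stack([p * p, 2 * p * (1 - p), (1 - p) ** 2], axis=1)
        per = (gl_arr * hwe).sum(axis=1)
        ll = float(np.log(np.maximum(per, 1e-300)).sum())
        if ll > best_ll:
            best, best_ll = q3, ll
    return best
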