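"""Genotype likelihoods, default and mapping-bias corrected.

The default model is the classical direct genotype likelihood: for a site
covered by reads with observed bases ``b_1..b_n`` and genotype ``A1 A2``,

    P(D | A1,A2) = prod_i [ P(b_i | A1) + P(b_i | A2) ] / 2

with ``P(b|A) = 1 - e`` when ``b == A`` and ``e/3`` otherwise, where ``e``
is the phred-derived sequencing-error probability of the base.  Under
mapping bias the two alleles of a heterozygote are *not* sampled with equal
probability: a read carrying the reference allele survives mapping more
often.  Given the empirically measured reference-read proportion ``r`` from
the flip-remap procedure, the heterozygote likelihood becomes the unequal
mixture

    P(D | R,A) = prod_i [ r * P(b_i | R) + (1 - r) * P(b_i | A) ]

while the two homozygote likelihoods are unchanged (bias has no allele to
favor when both chromosomes agree).  At ``r = 0.5`` the corrected model
reduces exactly to the default one.

All products are accumulated in log space; the plain product form
underflows at depth.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

from biasgl.bias_estim import SiteBiasRecord
from biasgl.reads import ReadObservation
from biasgl.snp_panel import SnpSite

ALLELE_CODES = {"A": 0, "C": 1, "G": 2, "T": 3}
CODE_ALLELES = {v: k for k, v in ALLELE_CODES.items()}

# r estimated as exactly 0 or 1 from a handful of reads is a sampling
# artifact; clamping keeps heterozygotes from receiving a hard zero.
DEFAULT_R_CLAMP = (0.001, 0.999)


def phred_to_error(q: int) -> float:
    """Sequencing-error probability ``10**(-q/10)`` from a phred score."""
    if q < 0:
        raise ValueError(f"phred quality must be >= 0, got {q}")
    return 10.0 ** (-q / 10.0)


def base_prob(b: str, a: str, e: float) -> float:
    """P(observed base ``b`` | true allele ``a``): ``1-e`` on match, ``e/3`` otherwise."""
    return 1.0 - e if b == a else e / 3.0


@dataclass(frozen=True)
class GLTriplet:
    """Likelihoods of the three genotypes (RR, RA, AA) at one site.

    Stored as log10 to survive high depth; the linear-scale values are
    exposed as properties and may underflow to 0.0 for very deep sites,
    which is why :func:`normalize_gl` works from the logs.
    """

    site: SnpSite
    individual: str
    log10_rr: float
    log10_ra: float
    log10_aa: float
    n_reads: int
    mode: str = "default"  # "default" | "corrected"
    r_used: float = 0.5

    @property
    def l_rr(self) -> float:
        return 10.0 ** self.log10_rr

    @property
    def l_ra(self) -> float:
        return 10.0 ** self.log10_ra

    @property
    def l_aa(self) -> float:
        return 10.0 ** self.log10_aa

    @property
    def values(self) -> tuple[float, float, float]:
        return (self.l_rr, self.l_ra, self.l_aa)

    def normalized(self) -> tuple[float, float, float]:
        logs = (self.log10_rr, self.log10_ra, self.log10_aa)
        m = max(logs)
        if math.isinf(m):
            raise ValueError("all genotype likelihoods are zero")
        rel = [10.0 ** (x - m) for x in logs]
        total = sum(rel)
        return tuple(x / total for x in rel)  # type: ignore[return-value]


def _log10_mixture(obs: Sequence[ReadObservation], site: SnpSite, w_ref: float) -> float:
    """log10 prod_i [ w_ref * P(b_i|R) + (1 - w_ref) * P(b_i|A) ]."""
    total = 0.0
    for o in obs:
        e = phred_to_error(o.base_quality)
        p = w_ref * base_prob(o.base, site.ref_allele, e) + (1.0 - w_ref) * base_prob(
            o.base, site.alt_allele, e
        )
        total += math.log10(p) if p > 0 else -math.inf
    return total


def _log10_hom(obs: Sequence[ReadObservation], allele: str) -> float:
    total = 0.0
    for o in obs:
        p = base_prob(o.base, allele, phred_to_error(o.base_quality))
        total += math.log10(p) if p > 0 else -math.inf
    return total


def gl_default(obs: Sequence[ReadObservation], site: SnpSite, individual: str = "") -> GLTriplet:
    """Default (uncorrected) genotype likelihoods at a site.

    With no observations the three likelihoods are the empty product 1, so
    the normalized triplet is uninformative (1/3, 1/3, 1/3).
    """
    return GLTriplet(
        site=site,
        individual=individual,
        log10_rr=_log10_hom(obs, site.ref_allele),
        log10_ra=_log10_mixture(obs, site, 0.5),
        log10_aa=_log10_hom(obs, site.alt_allele),
        n_reads=len(obs),
        mode="default",
        r_used=0.5,
    )


def gl_corrected(
    obs: Sequence[ReadObservation],
    site: SnpSite,
    r: float,
    individual: str = "",
    r_clamp: Optional[tuple[float, float]] = DEFAULT_R_CLAMP,
) -> GLTriplet:
    """Bias-corrected genotype likelihoods: heterozygote uses the r-mixture.

    Only the heterozygote changes; homozygote likelihoods are identical to
    the default model.  ``r`` is clamped into ``r_clamp`` first (set
    ``r_clamp=None`` to disable).
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"r must be in [0, 1], got {r}")
    if r_clamp is not None:
        r = min(max(r, r_clamp[0]), r_clamp[1])
    return GLTriplet(
        site=site,
        individual=individual,
        log10_rr=_log10_hom(obs, site.ref_allele),
        log10_ra=_log10_mixture(obs, site, r),
        log10_aa=_log10_hom(obs, site.alt_allele),
        n_reads=len(obs),
        mode="corrected",
        r_used=r,
    )


def gl_from_bias(
    obs: Sequence[ReadObservation],
    site: SnpSite,
    bias: Optional[SiteBiasRecord],
    individual: str = "",
    mode: str = "corrected",
    r_clamp: Optional[tuple[float, float]] = DEFAULT_R_CLAMP,
) -> GLTriplet:
    """Dispatch on mode and the bias record's evidence flag.

    Low-evidence (or absent) bias records fall back to the default model:
    with no retained reads there is no measurement to correct with.
    """
    if mode == "default" or bias is None or bias.low_evidence:
        return gl_default(obs, site, individual)
    if mode != "corrected":
        raise ValueError(f"mode must be 'default' or 'corrected', got {mode!r}")
    return gl_corrected(obs, site, bias.r, individual, r_clamp=r_clamp)


def normalize_gl(t: GLTriplet) -> GLTriplet:
    """Rescale so the three likelihoods sum to 1 (the Beagle convention)."""
    norm = t.normalized()
    from dataclasses import replace

    return replace(
        t,
        log10_rr=math.log10(norm[0]) if norm[0] > 0 else -math.inf,
        log10_ra=math.log10(norm[1]) if norm[1] > 0 else -math.inf,
        log10_aa=math.log10(norm[2]) if norm[2] > 0 else -math.inf,
    )


def write_beagle(
    triplets_by_individual: Mapping[str, Sequence[GLTriplet]],
    path: Union[str, Path],
) -> None:
    """Serialize normalized genotype likelihoods in Beagle GL text format.

    One row per marker: ``marker allele1 allele2`` then three columns per
    individual (P(RR), P(RA), P(AA), summing to 1).  Alleles are coded
    0=A, 1=C, 2=G, 3=T.  Every individual must cover the same sites in the
    same order.  A ``.gz`` suffix triggers gzip compression.
    """
    path = Path(path)
    individuals = list(triplets_by_individual)
    if individuals:
        ref_sites = [t.site.key for t in triplets_by_individual[individuals[0]]]
        for ind in individuals[1:]:
            if [t.site.key for t in triplets_by_individual[ind]] != ref_sites:
                raise ValueError(f"individual {ind} covers a different site set/order")
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:  # type: ignore[operator]
        header = ["marker", "allele1", "allele2"]
        for ind in individuals:
            header.extend([ind, ind, ind])
        fh.write("\t".join(header) + "\n")
        if not individuals:
            return
        n_sites = len(triplets_by_individual[individuals[0]])
        for i in range(n_sites):
            site = triplets_by_individual[individuals[0]][i].site
            row = [site.marker, str(ALLELE_CODES[site.ref_allele]), str(ALLELE_CODES[site.alt_allele])]
            for ind in individuals:
                row.extend(f"{v:.6g}" for v in triplets_by_individual[ind][i].normalized())
            fh.write("\t".join(row) + "\n")


def read_beagle(path: Union[str, Path]) -> tuple[list[SnpSite], list[str], "np.ndarray"]:
    """Read a Beagle GL file back: (sites, individuals, array[n_sites, n_ind, 3]).

    Marker names must follow the ``chrom_pos`` convention used by
    :func:`write_beagle`.
    """
    import numpy as np

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:  # type: ignore[operator]
        header = fh.readline().split()
        if len(header) < 3 or (len(header) - 3) % 3 != 0:
            raise ValueError(f"{path}: malformed Beagle header")
        individuals = header[3::3]
        sites: list[SnpSite] = []
        rows: list[list[float]] = []
        for line in fh:
            fields = line.split()
            marker = fields[0]
            chrom, _, pos_s = marker.rpartition("_")
            sites.append(
                SnpSite(chrom, int(pos_s), CODE_ALLELES[int(fields[1])], CODE_ALLELES[int(fields[2])])
            )
            rows.append([float(x) for x in fields[3:]])
    arr = np.asarray(rows, dtype=float).reshape(len(sites), len(individuals), 3)
    return sites, individuals, arr
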