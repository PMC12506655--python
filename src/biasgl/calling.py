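"""Pseudohaploid genotype calling.

The standard treatment of very-low-coverage (ancient) DNA: at each
ascertained SNP one read passing the quality thresholds is drawn uniformly
at random and its allele taken as a haploid genotype.  This sidesteps
genotype likelihood modelling entirely — and is therefore unaffected by the
per-site bias ratio r — at the cost of discarding all but one read.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from biasgl.reads import ReadObservation
from biasgl.snp_panel import SnpPanel, SnpSite

MISSING = "missing"


@dataclass(frozen=True)
class PseudohaploidCall:
    """A single-read haploid call: ``ref``, ``alt`` or ``missing``."""

    site: SnpSite
    individual: str
    allele: str  # "ref" | "alt" | "missing"

    def __post_init__(self) -> None:
        if self.allele not in ("ref", "alt", MISSING):
            raise ValueError(f"allele must be ref/alt/missing, got {self.allele!r}")

    @property
    def base(self) -> Optional[str]:
        if self.allele == "ref":
            return self.site.ref_allele
        if self.allele == "alt":
            return self.site.alt_allele
        return None


def call_pseudohaploid(
    obs: Sequence[ReadObservation],
    site: SnpSite,
    rng: Union[int, np.random.Generator],
    min_baseq: int = 30,
    min_mapq: int = 30,
    individual: str = "",
) -> PseudohaploidCall:
    """Draw one eligible read uniformly and return its allele.

    Eligible reads have base quality and mapping quality at or above the
    thresholds and carry one of the two panel alleles.  With no eligible
    read the call is missing.  Deterministic given the rng state and the
    input order.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    eligible = [
        o
        for o in obs
        if o.base_quality >= min_baseq
        and o.mapping_quality >= min_mapq
        and o.base in (site.ref_allele, site.alt_allele)
    ]
    if not eligible:
        return PseudohaploidCall(site, individual, MISSING)
    pick = eligible[int(rng.integers(len(eligible)))]
    allele = "ref" if pick.base == site.ref_allele else "alt"
    return PseudohaploidCall(site, individual, allele)


def call_panel_pseudohaploid(
    obs_by_site: Mapping[tuple[str, int], Sequence[ReadObservation]],
    panel: SnpPanel,
    seed: int,
    min_baseq: int = 30,
    min_mapq: int = 30,
    individual: str = "",
) -> list[PseudohaploidCall]:
    """Per-site independent pseudohaploid calls over a panel, one seed per run."""
    rng = np.random.default_rng(seed)
    return [
        call_pseudohaploid(
            obs_by_site.get(site.key, ()), site, rng,
            min_baseq=min_baseq, min_mapq=min_mapq, individual=individual,
        )
        for site in panel
    ]


def af_from_pseudohaploid(calls: Sequence[PseudohaploidCall]) -> Optional[float]:
    """Reference-allele frequency among non-missing calls; ``None`` if all missing."""
    non_missing = [c for c in calls if c.allele != MISSING]
    if not non_missing:
        return None
    return sum(1 for c in non_missing if c.allele == "ref") / len(non_missing)


def write_tped(
    calls_by_individual: Mapping[str, Sequence[PseudohaploidCall]],
    prefix: Union[str, Path],
    family_id: str = "POP",
) -> tuple[Path, Path]:
    """Write transposed-Plink text files (``.tped``/``.tfam``).

    The haploid allele is duplicated into a homozygous diploid genotype
    ("A A"); missing calls become "0 0".  Returns the two paths written.
    """
    prefix = Path(prefix)
    individuals = list(calls_by_individual)
    if individuals:
        ref_keys = [c.site.key for c in calls_by_individual[individuals[0]]]
        for ind in individuals[1:]:
            if [c.site.key for c in calls_by_individual[ind]] != ref_keys:
                raise ValueError(f"individual {ind} covers a different site set/order")
    tped = prefix.with_suffix(".tped")
    tfam = prefix.with_suffix(".tfam")
    with tped.open("w") as fh:
        n_sites = len(calls_by_individual[individuals[0]]) if individuals else 0
        for i in range(n_sites):
            site = calls_by_individual[individuals[0]][i].site
            row = [site.chrom, site.marker, "0", str(site.pos)]
            for ind in individuals:
                base = calls_by_individual[ind][i].base
                row.extend([base, base] if base is not None else ["0", "0"])
            fh.write(" ".join(row) + "\n")
    with tfam.open("w") as fh:
        for ind in individuals:
            fh.write(f"{family_id} {ind} 0 0 0 -9\n")
    return tped, tfam
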