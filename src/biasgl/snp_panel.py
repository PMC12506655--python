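"""Ascertained biallelic SNP panels.

All per-site computation in this package is scoped by a user-provided panel
of pre-ascertained biallelic SNPs (the common situation for low-coverage and
capture-based ancient DNA data, where novel variant discovery is not
attempted).  The panel file is a whitespace-delimited text table with four
columns — CHROM, POS (1-based), REF, ALT — and an optional ``#`` header.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

_BASES = frozenset("ACGT")
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def is_transition(a: str, b: str) -> bool:
    """True when the pair is purine↔purine or pyrimidine↔pyrimidine."""
    pair = {a, b}
    return pair <= _PURINES or pair <= _PYRIMIDINES


@dataclass(frozen=True, order=True)
class SnpSite:
    """A single ascertained biallelic SNP.

    Coordinates are 1-based inclusive (VCF convention); conversion to
    0-based offsets for alignment access is done at the point of use.
    """

    chrom: str
    pos: int
    ref_allele: str = field(compare=False)
    alt_allele: str = field(compare=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref_allele), ("alt", self.alt_allele)):
            if allele not in _BASES:
                raise ValueError(f"{name} allele must be one of A/C/G/T, got {allele!r}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(
                f"ref and alt alleles are identical ({self.ref_allele}) at "
                f"{self.chrom}:{self.pos}"
            )

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)

    @property
    def is_transversion(self) -> bool:
        return not is_transition(self.ref_allele, self.alt_allele)

    @property
    def marker(self) -> str:
        """Marker name used in Beagle-format output, e.g. ``chr1_100``."""
        return f"{self.chrom}_{self.pos}"


@dataclass(frozen=True)
class SnpPanel:
    """An ordered collection of :class:`SnpSite`, sorted by (chrom, pos)."""

    sites: tuple[SnpSite, ...]
    transversions_only: bool = False

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.sites))
        object.__setattr__(self, "sites", ordered)
        seen: set[tuple[str, int]] = set()
        for site in ordered:
            if site.key in seen:
                raise ValueError(f"duplicate panel site {site.chrom}:{site.pos}")
            seen.add(site.key)
            if self.transversions_only and not site.is_transversion:
                raise ValueError(
                    f"transition site {site.chrom}:{site.pos} "
                    f"{site.ref_allele}/{site.alt_allele} in a transversions-only panel"
                )

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)

    def __getitem__(self, i: int) -> SnpSite:
        return self.sites[i]

    def by_key(self) -> dict[tuple[str, int], SnpSite]:
        return {s.key: s for s in self.sites}

    def subset(self, keep: Iterable[SnpSite]) -> "SnpPanel":
        keep_keys = {s.key for s in keep}
        return replace(self, sites=tuple(s for s in self.sites if s.key in keep_keys))


def load_panel(path: str | Path, transversions_only: bool = False) -> SnpPanel:
    """Load and validate a panel TSV (CHROM POS REF ALT, ``#`` comments).

    Rows may appear in any order; the returned panel is sorted.  Malformed
    rows and duplicate (chrom, pos) entries raise ``ValueError`` naming the
    offending line.
    """
    path = Path(path)
    sites: list[SnpSite] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 4 columns (CHROM POS REF ALT), "
                    f"got {len(fields)}"
                )
            chrom, pos_s, ref, alt = fields
            try:
                pos = int(pos_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: position {pos_s!r} is not an integer")
            try:
                sites.append(SnpSite(chrom, pos, ref.upper(), alt.upper()))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    try:
        return SnpPanel(tuple(sites), transversions_only=transversions_only)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_panel(panel: SnpPanel, path: str | Path) -> None:
    """Write a panel as a 4-column TSV; inverse of :func:`load_panel`."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("#CHROM\tPOS\tREF\tALT\n")
        for s in panel:
            fh.write(f"{s.chrom}\t{s.pos}\t{s.ref_allele}\t{s.alt_allele}\n")


def filter_sites(
    panel: SnpPanel,
    missingness: Mapping[tuple[str, int], float],
    pooled_maf: Mapping[tuple[str, int], float],
    max_missing: float = 0.5,
    min_maf: float = 0.1,
) -> SnpPanel:
    """Retain sites with missingness strictly below ``max_missing`` and
    pooled minor-allele frequency at least ``min_maf``.

    ``missingness`` and ``pooled_maf`` map (chrom, pos) to the per-site
    fraction of missing calls and the minor-allele frequency computed on all
    analysed populations pooled (equal weight per retained call).  The
    missingness cut is strict (``<``) and the MAF cut inclusive (``>=``).
    """
    absent = [s.key for s in panel if s.key not in missingness or s.key not in pooled_maf]
    if absent:
        shown = ", ".join(f"{c}:{p}" for c, p in absent[:10])
        raise ValueError(
            f"per-site statistics missing for {len(absent)} panel site(s): {shown}"
        )
    kept = tuple(
        s
        for s in panel
        if missingness[s.key] < max_missing and pooled_maf[s.key] >= min_maf
    )
    return replace(panel, sites=kept)
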