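"""Empirical per-site mapping-bias estimation by allele-flipped remapping.

For every read overlapping an ascertained SNP, a copy is made that carries
the *other* allele at that position and is remapped with the same mapper and
parameters as the original data.  In the absence of mapping bias every
modified copy maps back to where it came from, so among original plus
modified reads exactly half carry the reference allele.  The observed
proportion of reference alleles, ``r``, is therefore an empirical, locus-
and individual-specific measurement of mapping bias: ``r > 0.5`` indicates
reference bias (alternative-carrying copies were lost in remapping),
``r < 0.5`` alternative bias.
"""

from __future__ import annotations

import bisect
import shutil
import subprocess
import tempfile
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Protocol, Sequence, Union

import numpy as np
import pandas as pd

from biasgl.reads import AlignedRead, FlippedRead, ReadObservation, from_pysam
from biasgl.snp_panel import SnpPanel, SnpSite

DEFAULT_MIN_MAPQ = 30
DEFAULT_MIN_BASEQ = 30


@dataclass(frozen=True)
class SiteBiasRecord:
    """Reference-read proportion at one site for one individual.

    ``r = n_ref / n_total`` over retained original plus remapped modified
    reads.  When no read is retained (``n_total == 0``) the record falls
    back to the unbiased value 0.5 and is flagged as low evidence so that
    downstream genotype-likelihood code reverts to the uncorrected model.
    """

    site: SnpSite
    n_total: int
    n_ref: int
    low_evidence: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.n_ref <= self.n_total:
            raise ValueError("need 0 <= n_ref <= n_total")

    @property
    def r(self) -> float:
        if self.n_total == 0:
            return 0.5
        return self.n_ref / self.n_total


class MapperAdapter(Protocol):
    """Maps flipped reads back to the reference.

    Implementations must be deterministic given fixed inputs (and seed) and
    return one entry per input read: the new alignment, or ``None`` when the
    read failed to map.
    """

    def map(self, reads: Sequence[FlippedRead]) -> list[Optional[AlignedRead]]: ...


class IdentityMapper:
    """Maps every flipped read back to its original coordinates.

    This is the no-bias reference point: with it, the flip-remap procedure
    yields r = 0.5 at every covered site.
    """

    def __init__(self, mapq: int = 60):
        self.mapq = mapq

    def map(self, reads: Sequence[FlippedRead]) -> list[Optional[AlignedRead]]:
        from dataclasses import replace

        return [replace(fr.source, name=fr.name, mapq=self.mapq) for fr in reads]


class BwaAlnMapper:
    """Shells out to ``bwa aln`` with ancient-DNA-style parameters.

    Uses ``-l 16500`` (disable seeding), ``-n 0.01`` and ``-o 2`` by default,
    the settings commonly used for short, damaged fragments.  The reference
    FASTA must already be indexed with ``bwa index``.
    """

    def __init__(self, reference: str | Path, extra_args: Sequence[str] = ("-l", "16500", "-n", "0.01", "-o", "2")):
        if shutil.which("bwa") is None:
            raise RuntimeError("bwa executable not found on PATH")
        self.reference = Path(reference)
        self.extra_args = list(extra_args)

    def map(self, reads: Sequence[FlippedRead]) -> list[Optional[AlignedRead]]:
        import pysam

        if not reads:
            return []
        results: dict[str, Optional[AlignedRead]] = {fr.name: None for fr in reads}
        with tempfile.TemporaryDirectory() as tmp:
            fq = Path(tmp) / "flipped.fq"
            sai = Path(tmp) / "flipped.sai"
            sam = Path(tmp) / "flipped.sam"
            with fq.open("w") as fh:
                for fr in reads:
                    fh.write(fr.to_fastq())
            with sai.open("wb") as out:
                subprocess.run(
                    ["bwa", "aln", *self.extra_args, str(self.reference), str(fq)],
                    stdout=out, stderr=subprocess.DEVNULL, check=True,
                )
            with sam.open("wb") as out:
                subprocess.run(
                    ["bwa", "samse", str(self.reference), str(sai), str(fq)],
                    stdout=out, stderr=subprocess.DEVNULL, check=True,
                )
            with pysam.AlignmentFile(str(sam), "r", check_sq=False) as fh:
                for seg in fh:
                    if seg.is_unmapped or seg.is_secondary or seg.is_supplementary:
                        continue
                    rec = from_pysam(seg)
                    if rec is not None:
                        results[seg.query_name] = rec
        return [results[fr.name] for fr in reads]


def flip_read_at_snp(read: AlignedRead, site: SnpSite) -> Optional[FlippedRead]:
    """Copy ``read`` with the base at ``site`` swapped ref↔alt.

    Returns ``None`` when the read has no aligned base at the site (deletion
    or reference skip) or when the observed base matches neither allele —
    such reads carry no allelic information to flip.
    """
    base = read.base_at(site.pos) if read.chrom == site.chrom else None
    if base is None:
        return None
    if base == site.ref_allele:
        new_base = site.alt_allele
    elif base == site.alt_allele:
        new_base = site.ref_allele
    else:
        return None
    return FlippedRead(
        source=read.with_base(site.pos, new_base),
        origin_chrom=site.chrom,
        origin_pos=site.pos,
        flipped_to=new_base,
    )


class _PanelIndex:
    """Per-chromosome sorted position index for overlap queries."""

    def __init__(self, panel: SnpPanel):
        self.by_chrom: dict[str, list[int]] = defaultdict(list)
        self.lookup = panel.by_key()
        for site in panel:
            self.by_chrom[site.chrom].append(site.pos)

    def overlapping(self, read: AlignedRead) -> list[SnpSite]:
        positions = self.by_chrom.get(read.chrom)
        if not positions:
            return []
        lo = bisect.bisect_left(positions, read.start)
        hi = bisect.bisect_right(positions, read.end)
        return [
            self.lookup[(read.chrom, positions[i])]
            for i in range(lo, hi)
            if read.query_offset(positions[i]) is not None
        ]


def _observation(read: AlignedRead, site: SnpSite, is_modified: bool) -> Optional[ReadObservation]:
    base = read.base_at(site.pos)
    if base is None:
        return None
    qual = read.qual_at(site.pos)
    return ReadObservation(
        read_id=read.name,
        base=base,
        base_quality=int(qual),
        mapping_quality=read.mapq,
        is_modified=is_modified,
        mapped_pos=(read.chrom, site.pos),
    )


def iter_bam_reads(bam: Union[str, Path], panel: SnpPanel) -> Iterator[AlignedRead]:
    """Yield reads from an indexed BAM that overlap any panel site.

    A read overlapping several sites is yielded once.
    """
    import pysam

    with pysam.AlignmentFile(str(bam), "rb") as fh:
        if not fh.has_index():
            raise ValueError(f"{bam} is not indexed; run samtools index first")
        seen: set[str] = set()
        for site in panel:
            if site.chrom not in fh.references:
                continue
            for seg in fh.fetch(site.chrom, site.pos - 1, site.pos):
                if seg.is_secondary or seg.is_supplementary:
                    continue
                key = f"{seg.query_name}/{seg.reference_start}/{int(seg.is_reverse)}"
                if key in seen:
                    continue
                seen.add(key)
                rec = from_pysam(seg)
                if rec is not None:
                    yield rec


def collect_observations(
    reads: Iterable[AlignedRead],
    panel: SnpPanel,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    min_baseq: int = DEFAULT_MIN_BASEQ,
    exclude_duplicates: bool = False,
) -> dict[tuple[str, int], list[ReadObservation]]:
    """Pile up per-site base observations for genotype-likelihood input.

    Applies mapping- and base-quality thresholds.  Bases matching neither
    panel allele are *kept* here (they enter the likelihood through the
    mismatch term); they are excluded later from flipping and from the
    r-denominator, which are defined on the biallelic model only.
    """
    index = _PanelIndex(panel)
    out: dict[tuple[str, int], list[ReadObservation]] = {s.key: [] for s in panel}
    for read in reads:
        if read.mapq < min_mapq or (exclude_duplicates and read.is_duplicate):
            continue
        for site in index.overlapping(read):
            obs = _observation(read, site, is_modified=False)
            if obs is not None and obs.base_quality >= min_baseq and obs.base != "N":
                out[site.key].append(obs)
    return out


def extract_and_flip(
    source: Union[str, Path, Iterable[AlignedRead]],
    panel: SnpPanel,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    min_baseq: int = DEFAULT_MIN_BASEQ,
    exclude_duplicates: bool = False,
) -> Iterator[tuple[SnpSite, ReadObservation, FlippedRead]]:
    """Stream (site, original observation, flipped copy) triples.

    ``source`` is a BAM path or an iterable of :class:`AlignedRead`.  A read
    overlapping k panel SNPs yields k records, each flipped at exactly one
    site: flipping is a marginal, per-site operation so that r stays a
    per-site quantity.  Reads failing the quality thresholds, or whose base
    at a site matches neither allele, yield nothing for that site.
    """
    if isinstance(source, (str, Path)):
        reads: Iterable[AlignedRead] = iter_bam_reads(source, panel)
    else:
        reads = source
    index = _PanelIndex(panel)
    for read in reads:
        if read.mapq < min_mapq or (exclude_duplicates and read.is_duplicate):
            continue
        for site in index.overlapping(read):
            qual = read.qual_at(site.pos)
            if qual is None or qual < min_baseq:
                continue
            flipped = flip_read_at_snp(read, site)
            if flipped is None:
                continue
            obs = _observation(read, site, is_modified=False)
            assert obs is not None
            yield site, obs, flipped


def retained_flip_observations(
    site: SnpSite,
    flipped: Sequence[FlippedRead],
    mapped: Sequence[Optional[AlignedRead]],
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> list[ReadObservation]:
    """Filter remapped flipped reads down to those informative at ``site``.

    A modified read is retained only when it maps back to the site — same
    chromosome, alignment covering the SNP (identical start is not required,
    since soft-clipping can shift starts) — with mapping quality at or above
    the threshold and an aligned base equal to one of the two alleles.  The
    loss of modified reads that fail this rule is precisely the signal that
    moves r away from 0.5.
    """
    out: list[ReadObservation] = []
    for fr, aln in zip(flipped, mapped):
        if aln is None or aln.mapq < min_mapq:
            continue
        if not aln.covers(site.chrom, site.pos):
            continue
        base = aln.base_at(site.pos)
        if base not in (site.ref_allele, site.alt_allele):
            continue
        obs = _observation(aln, site, is_modified=True)
        if obs is not None:
            out.append(obs)
    return out


def compute_site_bias(
    site: SnpSite,
    originals: Sequence[ReadObservation],
    remapped_flipped: Sequence[ReadObservation],
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> SiteBiasRecord:
    """Count reference alleles among retained original plus modified reads.

    Observations with bases outside {ref, alt} or mapping quality below the
    threshold are excluded from both numerator and denominator.
    """
    alleles = (site.ref_allele, site.alt_allele)
    retained = [
        o
        for o in list(originals) + list(remapped_flipped)
        if o.mapping_quality >= min_mapq and o.base in alleles
    ]
    n_total = len(retained)
    n_ref = sum(1 for o in retained if o.base == site.ref_allele)
    return SiteBiasRecord(site=site, n_total=n_total, n_ref=n_ref, low_evidence=n_total == 0)


def run_flip_remap(
    source: Union[str, Path, Iterable[AlignedRead]],
    panel: SnpPanel,
    mapper: MapperAdapter,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    min_baseq: int = DEFAULT_MIN_BASEQ,
    exclude_duplicates: bool = False,
) -> list[SiteBiasRecord]:
    """Full flip-remap pipeline for one individual: one record per panel site.

    Deterministic whenever the mapper is.  Mapper failures propagate with
    context.
    """
    per_site_originals: dict[tuple[str, int], list[ReadObservation]] = defaultdict(list)
    per_site_flipped: dict[tuple[str, int], list[FlippedRead]] = defaultdict(list)
    for site, obs, flipped in extract_and_flip(
        source, panel, min_mapq=min_mapq, min_baseq=min_baseq,
        exclude_duplicates=exclude_duplicates,
    ):
        per_site_originals[site.key].append(obs)
        per_site_flipped[site.key].append(flipped)

    all_flipped: list[FlippedRead] = []
    for site in panel:
        all_flipped.extend(per_site_flipped.get(site.key, ()))
    try:
        mapped = mapper.map(all_flipped)
    except Exception as exc:  # pragma: no cover - mapper-specific failures
        raise RuntimeError(f"mapper {type(mapper).__name__} failed: {exc}") from exc
    if len(mapped) != len(all_flipped):
        raise RuntimeError(
            f"mapper returned {len(mapped)} results for {len(all_flipped)} reads"
        )

    records: list[SiteBiasRecord] = []
    cursor = 0
    for site in panel:
        flipped = per_site_flipped.get(site.key, [])
        site_mapped = mapped[cursor : cursor + len(flipped)]
        cursor += len(flipped)
        remapped_obs = retained_flip_observations(site, flipped, site_mapped, min_mapq=min_mapq)
        records.append(
            compute_site_bias(site, per_site_originals.get(site.key, []), remapped_obs, min_mapq=min_mapq)
        )
    return records


def bias_table(records: Sequence[SiteBiasRecord]) -> pd.DataFrame:
    """Tabulate bias records (CHROM POS REF ALT N_TOTAL N_REF R FLAG)."""
    return pd.DataFrame(
        {
            "CHROM": [r.site.chrom for r in records],
            "POS": [r.site.pos for r in records],
            "REF": [r.site.ref_allele for r in records],
            "ALT": [r.site.alt_allele for r in records],
            "N_TOTAL": [r.n_total for r in records],
            "N_REF": [r.n_ref for r in records],
            "R": [r.r for r in records],
            "FLAG": ["low_evidence" if r.low_evidence else "." for r in records],
        }
    )


def write_bias_table(records: Sequence[SiteBiasRecord], path: str | Path) -> None:
    bias_table(records).to_csv(path, sep="\t", index=False, float_format="%.6g")


def load_bias_table(path: str | Path) -> dict[tuple[str, int], SiteBiasRecord]:
    """Read a bias TSV back into records keyed by (chrom, pos)."""
    df = pd.read_csv(path, sep="\t", dtype={"CHROM": str})
    out: dict[tuple[str, int], SiteBiasRecord] = {}
    for row in df.itertuples(index=False):
        site = SnpSite(str(row.CHROM), int(row.POS), str(row.REF), str(row.ALT))
        out[site.key] = SiteBiasRecord(
            site=site,
            n_total=int(row.N_TOTAL),
            n_ref=int(row.N_REF),
            low_evidence=row.FLAG == "low_evidence",
        )
    return out


def r_by_site(records: Sequence[SiteBiasRecord]) -> dict[tuple[str, int], float]:
    return {rec.site.key: rec.r for rec in records}


def pooled_r(records: Sequence[SiteBiasRecord]) -> tuple[float, float]:
    """Pooled reference-read proportion over many sites with its binomial SE.

    The pooled ratio sum(n_ref)/sum(n_total) is the natural genome-wide bias
    summary; per-site ratios at low depth are strongly discretized.
    """
    n_ref = sum(r.n_ref for r in records)
    n_total = sum(r.n_total for r in records)
    if n_total == 0:
        return 0.5, float("nan")
    p = n_ref / n_total
    return p, float(np.sqrt(p * (1 - p) / n_total))
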